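#!/usr/bin/env python
"""Generate the synthetic study compendium every later stage consumes.

Writes, under results/data/: seven tumour/normal expression cohorts
(30+30 samples, 1000 miRNA features, 50 planted DE at |g| = 1.5) with
their label files and the ground-truth table, a 240-subject censored
survival cohort whose hazard depends on a marker, and two GMT databases
(four target-prediction sources sharing a 71-gene core, and 50 random
pathways with one set seeded from that core).
"""

from pathlib import Path

from mirmeta.cli import run_cli

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 17


def main() -> int:
    rc = run_cli(["simulate", "--seed", str(SEED), "--out", str(OUT)])
    if rc == 0:
        n_files = len(list(OUT.iterdir()))
        print(f"wrote {n_files} files to {OUT} (seed {SEED})")
    return rc


if __name__ == "__main__":
    raise SystemExit(main())
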