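#!/usr/bin/env python
"""Build a diagnostic risk-score panel from the top meta-analysis hits.

Takes the four most significant downregulated miRNAs from stage 02,
fits the OLS risk score (a 0/1 tumour indicator regressed on the four
log2 expression values) on the first cohort, prints the fitted equation
in the conventional `score = c1*E_m1 + ... + intercept` form, and
reports the in-sample AUC of the panel next to each single marker's AUC.

Outputs under results/biomarker/: model.tsv, scores.tsv, roc.tsv.
"""

from pathlib import Path

from mirmeta.cli import run_cli
from mirmeta.io import read_expression_matrix, read_results_table
from mirmeta.biomarker import roc_auc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    res = read_results_table(ROOT / "meta_de" / "meta_de_results.tsv")
    down = res[res["direction"] == "down"].nsmallest(4, "p_perm")
    markers = sorted(down["feature_id"])
    print(f"panel: 4 top downregulated miRNAs {markers}")
    rc = run_cli(["biomarker",
                  "--expr", str(ROOT / "data" / "study1.tsv"),
                  "--labels", str(ROOT / "data" / "study1_labels.tsv"),
                  "--markers", ",".join(markers),
                  "--out", str(ROOT / "biomarker")])
    if rc != 0:
        return rc
    model = read_results_table(ROOT / "biomarker" / "model.tsv")
    terms = [f"{c:+.3f}*E_{m}" for m, c in
             zip(model["marker"][1:], model["coefficient"][1:])]
    print(f"risk score = {' '.join(terms)} {model['coefficient'][0]:+.3f}")
    study = read_expression_matrix(ROOT / "data" / "study1.tsv",
                                   ROOT / "data" / "study1_labels.tsv")
    for m in markers:
        # downregulated markers discriminate with LOW expression in tumour,
        # so score each univariate classifier by negated expression
        auc = roc_auc(-study.values.loc[m], study.sample_classes.to_numpy(),
                      case_label="T").auc
        print(f"  single-marker AUC {m} (low expression = tumour): {auc:.3f}")
    scores = read_results_table(ROOT / "biomarker" / "scores.tsv")
    panel_auc = roc_auc(scores["risk_score"], scores["class"],
                        case_label="T").auc
    print(f"panel AUC: {panel_auc:.3f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
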