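"""Readers and writers for the tab-delimited formats the pipeline touches.

Expression matrices are features x samples TSV (first column feature IDs,
first row sample IDs); labels are two-column TSV (sample_id, class); gene
sets use GMT; survival tables are TSV with ``time`` and ``event`` columns;
ID maps are two-column TSV (source_id, canonical_id).  All outputs are TSV
to avoid locale decimal-comma ambiguity.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneSetDB, StudyMatrix, SurvivalTable

log = logging.getLogger("mirmeta")


def read_expression_matrix(
    path: str | Path,
    labels_path: str | Path,
    study_id: str | None = None,
    transpose: bool = False,
) -> StudyMatrix:
    """Read a log2 expression TSV plus its two-column sample-label TSV.

    Duplicated feature IDs, samples absent from the label file, and
    classes with fewer than two samples are all rejected.
    """
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        values = values.T
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    dupes = values.index[values.index.duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicated feature ID: {dupes[0]!r}")
    try:
        arr = values.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc
    if not np.isfinite(arr).all():
        raise ValueError(f"{path}: non-finite expression values")
    values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if labels.shape[1] < 2:
        raise ValueError(f"{labels_path}: expected columns (sample_id, class)")
    labels = labels.set_index(labels.columns[0])
    classes = labels.iloc[:, 0]
    pair = labels["pair_id"] if "pair_id" in labels.columns else None
    missing = values.columns.difference(classes.index)
    if len(missing):
        raise ValueError(
            f"{path}: samples missing from labels file: {list(missing)}"
        )
    return StudyMatrix(
        study_id=study_id or path.stem,
        values=values,
        sample_classes=classes,
        pair_id=pair.loc[values.columns] if pair is not None else None,
    )


def write_expression_matrix(study: StudyMatrix, path: str | Path, labels_path: str | Path) -> None:
    """Write a StudyMatrix back to the matrix + labels TSV pair."""
    study.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")
    lab = pd.DataFrame(
        {"sample_id": study.values.columns, "class": study.sample_classes.to_numpy()}
    )
    if study.pair_id is not None:
        lab["pair_id"] = study.pair_id.to_numpy()
    lab.to_csv(labels_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetDB:
    """Read gene sets from GMT (set name, description, members...)."""
    sets: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            members = [g for g in fields[2:] if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = tuple(members)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetDB(sets=sets)


def write_gmt(db: GeneSetDB, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in db.set_names:
            fh.write("\t".join([name, description, *db.sets[name]]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blanks ignored; order preserved, deduplicated."""
    seen: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if g:
            seen.setdefault(g, None)
    return list(seen)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source feature IDs to canonical names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (source_id, canonical_id)")
    src = df.iloc[:, 0]
    if src.duplicated().any():
        raise ValueError(f"{path}: duplicated source ID {src[src.duplicated()].iloc[0]!r}")
    return dict(zip(src, df.iloc[:, 1]))


def read_survival_table(path: str | Path) -> SurvivalTable:
    return SurvivalTable(pd.read_csv(path, sep="\t"))


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_results_table(
    frame: pd.DataFrame,
    path: str | Path,
    sort_by: str | None = None,
    ascending: bool = True,
    comment: str | None = None,
) -> None:
    """Write a results table as TSV with >= 6 significant digits.

    Rows are ordered by descending significance (ascending p in
    ``sort_by``) with the first column as deterministic tie-break, so two
    runs with the same seed produce byte-identical files.  A header
    comment (lines starting with '#') documents the columns.
    """
    df = frame.copy()
    if sort_by is not None and len(df):
        tie = df.columns[0]
        df = df.sort_values([sort_by, tie], ascending=[ascending, True], kind="mergesort")
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# columns: " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    log.info("wrote %d rows to %s", len(df), path)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
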