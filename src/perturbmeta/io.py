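"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated.  Expression matrices have the gene symbol in
the first column and one column per sample; sample annotations carry one
row per sample (columns ``group``, ``batch``, ``tissue``).  Edge lists are
two-column node-pair tables.  Writers accept an optional comment header
(lines prefixed ``# ``) used by the pipeline for provenance.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthdata import ExpressionStudy


def _write_tsv(df: pd.DataFrame, path, header_lines=None, index=True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_expression(study: ExpressionStudy, out_dir, header_lines=None) -> tuple[Path, Path]:
    """Write one study as ``<id>_expr.tsv`` + ``<id>_samples.tsv``."""
    out_dir = Path(out_dir)
    expr_path = out_dir / f"{study.study_id}_expr.tsv"
    annot_path = out_dir / f"{study.study_id}_samples.tsv"
    expr = study.expr.copy()
    expr.index.name = "gene"
    annot = study.samples.copy()
    annot.index.name = "sample"
    _write_tsv(expr, expr_path, header_lines)
    _write_tsv(annot, annot_path, header_lines)
    return expr_path, annot_path


def read_expression(expr_path, annot_path, study_id: str | None = None) -> ExpressionStudy:
    """Read a study written by :func:`write_expression` (or a curated
    matrix in the same layout)."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    annot = pd.read_csv(annot_path, sep="\t", index_col=0, comment="#")
    expr.index = expr.index.str.upper()
    if study_id is None:
        study_id = Path(expr_path).stem.removesuffix("_expr")
    if "batch" not in annot:
        annot["batch"] = "b1"
    tissue = str(annot["tissue"].iloc[0]) if "tissue" in annot else "unspecified"
    if "tissue" not in annot:
        annot["tissue"] = tissue
    return ExpressionStudy(study_id, expr, annot, tissue)


def write_edge_list(edges: pd.DataFrame, path, header_lines=None) -> None:
    _write_tsv(edges, path, header_lines, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, header_lines=None) -> None:
    _write_tsv(df, path, header_lines, index=False)
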