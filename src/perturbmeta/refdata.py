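"""Bundled reference tables from a published 16-study, four-tissue type 2
diabetes microarray meta-analysis, used by the worked example and the
validation suite.

Three tables ship with the package:

* ``t2d_meta_gene_sets.tsv`` — the highly-perturbed gene lists selected by
  the three meta-analytic strategies (random-effects, vote-counting,
  p-value combining), each gene labelled up or down;
* ``t2d_hub_genes.tsv`` — the 28 hub genes with their network
  centralities; six nodes contributed by the interaction-prediction
  service carry the ``predicted`` label instead of a direction;
* ``t2d_deg_counts.tsv`` — per-tissue counts of down- vs upregulated DEGs
  and of tissue-specific vs shared DEGs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metaperturb import PerturbedGeneSet

__all__ = ["load_meta_gene_sets", "load_hub_genes", "load_deg_counts"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("perturbmeta.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_meta_gene_sets() -> list[PerturbedGeneSet]:
    """The three model gene sets (REM / VC / CA) with regulation labels."""
    df = _read("t2d_meta_gene_sets.tsv")
    sets = []
    for source in ["REM", "VC", "CA"]:
        sub = df.loc[df["source"] == source]
        sets.append(
            PerturbedGeneSet(
                genes=list(sub["gene"]),
                regulation=dict(zip(sub["gene"], sub["regulation"])),
                source=source,
            )
        )
    return sets


def load_hub_genes() -> pd.DataFrame:
    """Hub-gene centrality table (gene, betweenness, closeness, degree,
    regulation in {up, down, predicted})."""
    return _read("t2d_hub_genes.tsv")


def load_deg_counts() -> pd.DataFrame:
    """Per-tissue DEG count pairs (down vs up; tissue-specific vs shared)."""
    return _read("t2d_deg_counts.tsv")
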