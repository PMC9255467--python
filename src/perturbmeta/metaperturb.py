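"""Three-way meta-analysis of per-study differential-expression tables.

Three complementary strategies summarise the evidence for each gene across
studies:

* **REM** — DerSimonian-Laird random-effects synthesis of the log2
  fold-changes, with within-study variances recovered from the reported
  95% CI widths; a summary p tests whether the summary fold-change differs
  from zero.
* **VC** — vote counting: how many studies called the gene a DEG, and how
  consistent the fold-change sign was across them.
* **CA** — Fisher's method on the per-study p-values, alongside the mean
  (or median) fold-change.

Each strategy ranks genes and the top ``metathr`` fraction (default the
top 1%) forms its highly-perturbed gene set; the compiled set is the
de-duplicated union of the three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaConfig",
    "PerturbedGeneSet",
    "rem_meta",
    "vc_meta",
    "ca_meta",
    "inverse_cumulative_distribution",
    "top_perturbed",
    "compile_union",
]

#: p-values are floored here before Fisher's log to avoid -inf.
P_FLOOR = 1e-300

_Z95 = 1.96  # CI width -> variance conversion uses the normal 97.5% point


@dataclass(frozen=True)
class MetaConfig:
    """Thresholds for the meta-analysis stage.

    ``metathr`` is the top fraction of genes each strategy retains (0.01 =
    top 1%); ``vc_p_threshold`` / ``vc_abs_fc_threshold`` define what the
    vote counter accepts as a differential call in a single study;
    ``ca_median`` switches the combining strategy's central tendency from
    mean to median fold-change.
    """

    metathr: float = 0.01
    vc_p_threshold: float = 0.05
    vc_abs_fc_threshold: float = 0.0
    ca_median: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.metathr <= 1.0:
            raise ValueError("metathr must lie in (0, 1]")


@dataclass
class PerturbedGeneSet:
    """An ordered highly-perturbed gene list with up/down labels."""

    genes: list[str]
    regulation: dict[str, str]
    source: str

    def __len__(self) -> int:
        return len(self.genes)


def _long_format(study_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for study_id, table in study_tables.items():
        t = table.copy()
        t["gene"] = t["gene"].str.upper()
        t["study"] = study_id
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def rem_meta(
    study_tables: dict[str, pd.DataFrame], config: MetaConfig | None = None
) -> pd.DataFrame:
    """DerSimonian-Laird random-effects summary per gene.

    Within-study variance is ``((CI.R - CI.L) / (2 * 1.96))^2``; the
    between-study variance tau^2 comes from the moment estimator
    ``max(0, (Q - (k-1)) / C)``; weights are inverse total variance, and
    the summary p is the two-sided normal tail of summary FC / SE.
    """
    long = _long_format(study_tables)
    if (long["CI.R"] < long["CI.L"]).any():
        bad = long.loc[long["CI.R"] < long["CI.L"], "gene"].tolist()
        raise ValueError(f"CI.R < CI.L for genes {bad[:5]}")
    vg = ((long["CI.R"] - long["CI.L"]) / (2.0 * _Z95)) ** 2
    long = long.assign(vg=np.maximum(vg, 1e-12))

    records = []
    for gene, sub in long.groupby("gene", sort=True):
        fc = sub["log2FC"].to_numpy()
        v = sub["vg"].to_numpy()
        k = len(fc)
        w = 1.0 / v
        fc_fixed = float((w * fc).sum() / w.sum())
        if k > 1:
            q = float((w * (fc - fc_fixed) ** 2).sum())
            c = float(w.sum() - (w**2).sum() / w.sum())
            tau_sq = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
        else:
            tau_sq = 0.0
        w_star = 1.0 / (v + tau_sq)
        summary = float((w_star * fc).sum() / w_star.sum())
        se = math.sqrt(1.0 / w_star.sum())
        p = 2.0 * stats.norm.sf(abs(summary / se))
        records.append((gene, k, summary, se, p, tau_sq))
    return pd.DataFrame(
        records,
        columns=["gene", "n_studies_present", "rem_fc", "rem_se", "rem_p", "tau_sq"],
    )


def vc_meta(
    study_tables: dict[str, pd.DataFrame], config: MetaConfig | None = None
) -> pd.DataFrame:
    """Vote counting: per-study differential calls and sign consistency.

    A study votes "up" for a gene when ``P.Value < vc_p_threshold`` and
    ``log2FC > vc_abs_fc_threshold`` (symmetric rule for "down");
    ``ndiff = n_up + n_down`` and ``sign_consistency = n_up - n_down``.
    """
    config = config or MetaConfig()
    long = _long_format(study_tables)
    sig = long["P.Value"] < config.vc_p_threshold
    long = long.assign(
        vote_up=(sig & (long["log2FC"] > config.vc_abs_fc_threshold)).astype(int),
        vote_down=(sig & (long["log2FC"] < -config.vc_abs_fc_threshold)).astype(int),
    )
    grouped = long.groupby("gene", sort=True).agg(
        n_studies_present=("study", "size"),
        n_up=("vote_up", "sum"),
        n_down=("vote_down", "sum"),
        mean_fc=("log2FC", "mean"),
    )
    grouped["ndiff"] = grouped["n_up"] + grouped["n_down"]
    grouped["sign_consistency"] = grouped["n_up"] - grouped["n_down"]
    return grouped.reset_index()


def inverse_cumulative_distribution(vc_summaries: pd.DataFrame) -> pd.DataFrame:
    """For each k >= 1, the number of genes differentially expressed in at
    least k studies (non-increasing in k; empty when no gene has a vote)."""
    ndiff = vc_summaries["ndiff"].to_numpy()
    kmax = int(ndiff.max()) if len(ndiff) else 0
    rows = [(k, int((ndiff >= k).sum())) for k in range(1, kmax + 1)]
    return pd.DataFrame(rows, columns=["k", "n_genes"])


def ca_meta(
    study_tables: dict[str, pd.DataFrame], config: MetaConfig | None = None
) -> pd.DataFrame:
    """Fisher's combining approach: -2 sum(ln p) against chi2 with 2k df,
    with the mean (or median) log2 fold-change as the effect summary."""
    config = config or MetaConfig()
    long = _long_format(study_tables)
    long = long.assign(logp=np.log(np.maximum(long["P.Value"], P_FLOOR)))
    agg = long.groupby("gene", sort=True).agg(
        n_studies_present=("study", "size"),
        ca_fc=("log2FC", "median" if config.ca_median else "mean"),
        fisher_stat=("logp", lambda s: -2.0 * s.sum()),
    )
    agg["fisher_p"] = stats.chi2.sf(agg["fisher_stat"], 2 * agg["n_studies_present"])
    return agg.reset_index()


_RANK_RULES = {
    # model -> (sort keys as (column, ascending)), effect column
    "REM": ([("rem_p", True), ("abs_fc", False), ("gene", True)], "rem_fc"),
    "VC": (
        [
            ("ndiff", False),
            ("abs_consistency", False),
            ("abs_fc", False),
            ("gene", True),
        ],
        "mean_fc",
    ),
    "CA": ([("fisher_p", True), ("abs_fc", False), ("gene", True)], "ca_fc"),
}


def top_perturbed(
    summaries: pd.DataFrame, model: str, config: MetaConfig | None = None
) -> PerturbedGeneSet:
    """Extract the top ``metathr`` fraction of genes under a model's ranking.

    REM ranks by summary p (tie: |summary FC|); VC by ndiff, then
    |sign consistency|, then |mean FC|; CA by Fisher p.  The cut keeps
    ``ceil(metathr * G)`` genes where G counts genes present in >= 1 study.
    Regulation is the sign of the model's effect summary.
    """
    if model not in _RANK_RULES:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_RANK_RULES)}")
    config = config or MetaConfig()
    keys, effect_col = _RANK_RULES[model]
    df = summaries.copy()
    df["abs_fc"] = df[effect_col].abs()
    if model == "VC":
        df["abs_consistency"] = df["sign_consistency"].abs()
    df = df.sort_values(
        [k for k, _ in keys], ascending=[a for _, a in keys], kind="stable"
    )
    n_top = math.ceil(config.metathr * len(summaries))
    top = df.head(n_top)
    regulation = {
        g: ("up" if fc > 0 else "down")
        for g, fc in zip(top["gene"], top[effect_col])
    }
    return PerturbedGeneSet(list(top["gene"]), regulation, source=model)


def compile_union(sets: list[PerturbedGeneSet]) -> PerturbedGeneSet:
    """Symbol-unique union of model gene sets, carrying regulation labels.

    Raises if two sources disagree on a gene's direction — the compiled
    list must be internally consistent.
    """
    if not sets:
        raise ValueError("need at least one input set")
    genes: list[str] = []
    regulation: dict[str, str] = {}
    conflicts = []
    for s in sets:
        for g in s.genes:
            if g not in regulation:
                genes.append(g)
                regulation[g] = s.regulation[g]
            elif regulation[g] != s.regulation[g]:
                conflicts.append(g)
    if conflicts:
        raise ValueError(
            f"conflicting regulation labels across sources for: {sorted(set(conflicts))}"
        )
    return PerturbedGeneSet(genes, regulation, source="compiled")
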