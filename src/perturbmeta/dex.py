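"""Per-study preprocessing and moderated differential expression.

The stage mirrors the standard microarray workflow: log2 transform where
needed, least-squares batch-effect removal, median expression filtering, a
gene-wise two-group linear model, empirical-Bayes variance moderation
(shrinking gene variances toward a scaled inverse-chi-square prior with
hyperparameters ``d0``/``s0^2`` estimated by moment matching on the log
sample variances), Benjamini-Hochberg adjustment, and the asymmetric DEG
call: up means log2FC > 1 with adjusted p < 0.05, down means
log2FC < -0.5 with adjusted p < 0.05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModerationParams",
    "TissueVennSummary",
    "maybe_log2",
    "remove_batch_effect",
    "batch_diagnostic",
    "median_filter",
    "fit_linear_model",
    "estimate_moderation",
    "ebayes_moderate",
    "bh_adjust",
    "call_degs",
    "differential_expression",
    "tissue_venn",
]

#: DEG thresholds: asymmetric fold-change cut-offs with strict inequalities.
FC_UP = 1.0
FC_DOWN = -0.5
ALPHA = 0.05

#: Matrices whose maximum exceeds this are treated as linear-scale and
#: log2(x+1)-transformed.  Log2 microarray intensities rarely exceed ~20.
LINEAR_SCALE_MAX = 30.0


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes hyperparameters: prior df ``d0`` (may be inf), prior
    variance ``s0_sq``, and the per-gene residual df ``dg``."""

    d0: float
    s0_sq: float
    dg: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValueError("d0 and s0_sq must be positive")


def maybe_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Log2-transform a matrix judged to be on the linear scale.

    The heuristic treats the matrix as linear when its maximum exceeds
    ``LINEAR_SCALE_MAX``; such matrices get elementwise ``log2(x + 1)``.
    Matrices already on the log scale pass through unchanged.
    """
    values = matrix.to_numpy()
    if np.nanmax(values) <= LINEAR_SCALE_MAX:
        return matrix
    if np.nanmin(values) < 0:
        raise ValueError("negative values in a matrix judged linear-scale")
    return pd.DataFrame(
        np.log2(values + 1.0), index=matrix.index, columns=matrix.columns
    )


def _design(group: pd.Series, batch: pd.Series | None):
    """Intercept + case indicator + batch indicators (first level dropped)."""
    g = np.asarray(group)
    cols = [np.ones(len(g)), (g == "case").astype(float)]
    names = ["intercept", "case"]
    if batch is not None:
        levels = sorted(set(np.asarray(batch, dtype=str)))
        for lev in levels[1:]:
            cols.append((np.asarray(batch, dtype=str) == lev).astype(float))
            names.append(f"batch_{lev}")
    return np.column_stack(cols), names


def remove_batch_effect(
    matrix: pd.DataFrame, batch: pd.Series, group: pd.Series
) -> pd.DataFrame:
    """Subtract least-squares batch effects while protecting the group effect.

    Batch coefficients are estimated jointly with the group effect per gene,
    and only the batch component is removed, so group-difference estimates
    are unchanged (exactly so in balanced designs).
    """
    levels = sorted(set(np.asarray(batch, dtype=str)))
    if len(levels) < 2:
        return matrix
    X, names = _design(group, batch)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "batch is confounded with the group design: levels "
            f"{levels} cannot be separated from the case/control contrast"
        )
    coef, *_ = np.linalg.lstsq(X, matrix.to_numpy().T, rcond=None)
    batch_cols = [i for i, n in enumerate(names) if n.startswith("batch_")]
    component = X[:, batch_cols] @ coef[batch_cols]
    return pd.DataFrame(
        matrix.to_numpy() - component.T, index=matrix.index, columns=matrix.columns
    )


def batch_diagnostic(matrix: pd.DataFrame, batch: pd.Series) -> dict:
    """PCA-based batch diagnostic on the transposed expression matrix.

    Returns the top-2 sample principal-component scores and the fraction of
    variance along each explained by between-batch differences; a flag is
    raised when that fraction exceeds 0.5 on PC1.
    """
    data = matrix.to_numpy().T  # samples x genes
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples for the diagnostic")
    centered = data - data.mean(axis=0)
    total = float((centered**2).sum())
    if total == 0.0:
        scores = np.zeros((data.shape[0], 2))
        fracs = [0.0, 0.0]
    else:
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        scores = u[:, :2] * s[:2]
        labels = np.asarray(batch, dtype=str)
        fracs = []
        for j in range(scores.shape[1]):
            col = scores[:, j]
            ss_total = float(((col - col.mean()) ** 2).sum())
            ss_between = sum(
                (col[labels == lev].mean() - col.mean()) ** 2 * (labels == lev).sum()
                for lev in set(labels)
            )
            fracs.append(ss_between / ss_total if ss_total > 0 else 0.0)
    scores_df = pd.DataFrame(
        scores, index=matrix.columns, columns=["PC1", "PC2"]
    )
    return {
        "scores": scores_df,
        "batch_variance_fraction": fracs,
        "flag": bool(fracs[0] > 0.5),
    }


def median_filter(
    matrix: pd.DataFrame, floor: float = 0.0, min_samples: int = 2
) -> pd.DataFrame:
    """Low-expression filter applied before model fitting.

    Step 1 keeps genes whose per-gene median is at or above the median of
    all per-gene medians (``>=`` so that a constant matrix is fully
    retained).  Step 2 then keeps genes detected (above ``floor``) in more
    than ``min_samples`` samples.
    """
    if matrix.shape[0] < 1:
        raise ValueError("empty expression matrix")
    medians = matrix.median(axis=1)
    cutoff = float(np.median(medians.to_numpy()))
    step1 = matrix.loc[medians >= cutoff]
    expressed = (step1 > floor).sum(axis=1)
    result = step1.loc[expressed > min_samples]
    if result.shape[0] == 0:
        raise ValueError(
            "median filter removed every gene; review the detection floor "
            f"(floor={floor}) and min_samples={min_samples}"
        )
    return result


def fit_linear_model(matrix: pd.DataFrame, group: pd.Series) -> pd.DataFrame:
    """Gene-wise two-group linear fit (contrast: case - control).

    Returns per gene the log2 fold-change, its standard error, the pooled
    residual variance ``sg_sq`` and residual df ``dg = n1 + n2 - 2``.
    """
    g = np.asarray(group)
    case = matrix.loc[:, g == "case"].to_numpy()
    control = matrix.loc[:, g == "control"].to_numpy()
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >= 2 samples (case={n1}, control={n2}): "
            "residual variance undefined otherwise"
        )
    fc = case.mean(axis=1) - control.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    dg = n1 + n2 - 2
    sg_sq = ss / dg
    c = math.sqrt(1.0 / n1 + 1.0 / n2)
    return pd.DataFrame(
        {
            "log2FC": fc,
            "stderr": np.sqrt(sg_sq) * c,
            "sg_sq": sg_sq,
            "dg": dg,
            "stdunit": c,
        },
        index=matrix.index,
    )


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex target)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < tol:
            return y
    raise ConvergenceError(
        f"trigamma inversion did not converge in {max_iter} iterations"
    )


def estimate_moderation(sg_sq: np.ndarray, dg: float) -> ModerationParams:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    Under the hierarchical model, ``log(sg_sq)`` is a shifted log-F whose
    mean and variance are closed forms in digamma/trigamma; inverting the
    variance identity with Newton's method on the trigamma function gives
    d0, and the mean identity then gives s0^2.  When the observed spread of
    log variances is no larger than sampling noise alone, d0 is infinite
    and the prior collapses to a single common variance.
    """
    sg_sq = np.asarray(sg_sq, dtype=float)
    if len(sg_sq) < 10:
        raise ValueError("hyperparameter estimation needs >= 10 genes")
    positive = sg_sq[sg_sq > 0]
    if len(positive) == 0:
        raise ValueError("all sample variances are zero; nothing to moderate")
    z = np.log(positive)
    e = z - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, dg / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        # spread of log variances no larger than sampling noise: the prior
        # collapses and the best single variance is the plain mean
        d0 = math.inf
        s0_sq = float(sg_sq.mean())
    return ModerationParams(d0=d0, s0_sq=s0_sq, dg=float(dg))


def ebayes_moderate(
    fits: pd.DataFrame, params: ModerationParams | None = None
) -> tuple[pd.DataFrame, ModerationParams]:
    """Moderated t-statistics, p-values and 95% CIs from gene-wise fits.

    The posterior variance ``(d0*s0^2 + dg*sg_sq) / (d0 + dg)`` replaces
    the gene variance; the moderated t is referred to a Student-t with
    ``d0 + dg`` df, which also supplies the CI quantile.
    """
    dg = float(fits["dg"].iloc[0])
    if params is None:
        params = estimate_moderation(fits["sg_sq"].to_numpy(), dg)
    d0, s0 = params.d0, params.s0_sq
    sg = fits["sg_sq"].to_numpy()
    if math.isinf(d0):
        s2_post = np.full(len(sg), s0)
    else:
        s2_post = (d0 * s0 + dg * sg) / (d0 + dg)
    # reference df capped at the pooled residual df: the moderated t can
    # never be better-calibrated than a single pooled-variance t-test
    df_total = min(d0 + dg, dg * len(sg))
    c = fits["stdunit"].to_numpy()
    se_post = np.sqrt(s2_post) * c
    t_mod = fits["log2FC"].to_numpy() / se_post
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = stats.t.ppf(0.975, df_total)
    out = pd.DataFrame(
        {
            "log2FC": fits["log2FC"],
            "CI.L": fits["log2FC"] - q * se_post,
            "CI.R": fits["log2FC"] + q * se_post,
            "t": t_mod,
            "P.Value": p,
        },
        index=fits.index,
    )
    return out, params


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_degs(
    table: pd.DataFrame,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Assign up/down/ns status with strict inequalities on both axes."""
    table = table.copy()
    sig = table["adj.P.Val"] < alpha
    status = np.where(
        sig & (table["log2FC"] > fc_up),
        "up",
        np.where(sig & (table["log2FC"] < fc_down), "down", "ns"),
    )
    table["status"] = status
    return table


def differential_expression(
    expr: pd.DataFrame,
    group: pd.Series,
    batch: pd.Series | None = None,
    correct_batch: bool = True,
    apply_median_filter: bool = True,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Full per-study DEG pipeline.

    log2 transform (if needed) -> batch removal -> median filter -> linear
    model -> empirical-Bayes moderation -> BH adjustment -> DEG call.
    Returns a table with columns gene, log2FC, CI.L, CI.R, t, P.Value,
    adj.P.Val, status.
    """
    matrix = maybe_log2(expr)
    if correct_batch and batch is not None and len(set(batch)) > 1:
        matrix = remove_batch_effect(matrix, batch, group)
    if apply_median_filter:
        matrix = median_filter(matrix)
    fits = fit_linear_model(matrix, group)
    table, _ = ebayes_moderate(fits)
    table["adj.P.Val"] = bh_adjust(table["P.Value"].to_numpy())
    table = call_degs(table, fc_up=fc_up, fc_down=fc_down, alpha=alpha)
    table.insert(0, "gene", table.index.str.upper())
    return table.reset_index(drop=True)


@dataclass
class TissueVennSummary:
    """Per-tissue DEG sets and the counts of every Venn region."""

    tissue_sets: dict[str, set[str]]
    region_counts: dict[frozenset, int]
    specific: dict[str, int]
    shared: dict[str, int]

    @property
    def union_size(self) -> int:
        return len(set().union(*self.tissue_sets.values())) if self.tissue_sets else 0


def tissue_venn(
    deg_tables: dict[str, pd.DataFrame], study_to_tissue: dict[str, str]
) -> TissueVennSummary:
    """Pool DEGs per tissue and count all Venn regions.

    The per-tissue set is the union of DEG symbols over that tissue's
    studies; a gene is tissue-specific when it falls in exactly one set.
    """
    missing = set(deg_tables) - set(study_to_tissue)
    if missing:
        raise ValueError(f"studies without a tissue mapping: {sorted(missing)}")
    tissue_sets: dict[str, set[str]] = {}
    for study, table in deg_tables.items():
        degs = set(table.loc[table["status"] != "ns", "gene"])
        tissue_sets.setdefault(study_to_tissue[study], set()).update(degs)
    tissues = sorted(tissue_sets)
    region_counts: dict[frozenset, int] = {}
    for r in range(1, len(tissues) + 1):
        for combo in itertools.combinations(tissues, r):
            inside = set.intersection(*(tissue_sets[t] for t in combo))
            outside = set().union(
                *(tissue_sets[t] for t in tissues if t not in combo), set()
            )
            region_counts[frozenset(combo)] = len(inside - outside)
    specific = {
        t: region_counts[frozenset([t])] for t in tissues
    }
    shared = {t: len(tissue_sets[t]) - specific[t] for t in tissues}
    return TissueVennSummary(tissue_sets, region_counts, specific, shared)
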