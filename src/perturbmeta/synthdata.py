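"""Synthetic multi-study expression data, interactomes, and gene-set libraries.

The generator emulates the structure the downstream pipeline assumes: a
collection of small two-group (case/control) expression studies on the log2
scale, with gene-wise variances drawn from a scaled inverse-chi-square prior
(the same hierarchical model the empirical-Bayes moderation step fits), a
planted fraction of genes carrying a nonzero log2 fold-change with a sign
that is consistent across every study, optional per-batch offsets, and
tissue labels partitioning the studies into groups.  Everything is
deterministic for a fixed master seed: study ``i`` uses substream
``seed + i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_GROUPS",
    "SimulationConfig",
    "ExpressionStudy",
    "generate_study",
    "generate_collection",
    "generate_interactome",
    "generate_gene_set_library",
]

#: The four tissue groups used when no explicit labels are supplied
#: (circulatory, adipose, digestive and skeletal-muscle tissues are the
#: classic insulin-responsive compartments profiled in T2D expression
#: compendia).
TISSUE_GROUPS = ("circulatory", "adipose", "digestive", "skeletal_muscle")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the multi-study generative model.

    Parameters
    ----------
    n_studies:
        Number of independent two-group studies in the collection.
    genes_per_study:
        Number of genes measured in every study (symbols ``G000001`` ...).
    samples_per_group:
        Samples per group (case and control each get this many).
    deg_fraction:
        Fraction of genes planted with a true nonzero log2 fold-change.
        The planted identity list is shared across all studies.
    effect_size_log2fc:
        Absolute true log2 fold-change of planted genes (case - control).
    sign_mix:
        Fraction of planted genes that are upregulated; the rest are
        downregulated with the same absolute effect.
    prior_df_d0, prior_scale_s0sq:
        Degrees of freedom and scale of the scaled inverse-chi-square prior
        on gene-wise variances: ``sigma_g^2 = s0sq * d0 / chi2(d0)``.
    batch_count, batch_sd:
        Number of batches per study (0 or 1 disables batch structure) and
        the standard deviation of the per-gene, per-batch offsets.
    tissue_labels:
        One label per study; ``None`` cycles through :data:`TISSUE_GROUPS`.
    baseline_mean, baseline_sd:
        Gene baseline abundances are Normal(baseline_mean, baseline_sd^2)
        on the log2 scale.
    seed:
        Master seed; study ``i`` draws from substream ``seed + i``.
    """

    n_studies: int = 16
    genes_per_study: int = 2000
    samples_per_group: int = 10
    deg_fraction: float = 0.01
    effect_size_log2fc: float = 1.5
    sign_mix: float = 0.5
    prior_df_d0: float = 4.0
    prior_scale_s0sq: float = 0.25
    batch_count: int = 0
    batch_sd: float = 0.0
    tissue_labels: tuple[str, ...] | None = None
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.genes_per_study < 1:
            raise ConfigurationError("n_studies and genes_per_study must be positive")
        if self.samples_per_group < 2:
            raise ConfigurationError("need at least 2 samples per group")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ConfigurationError("deg_fraction must lie in [0, 1]")
        if not 0.0 <= self.sign_mix <= 1.0:
            raise ConfigurationError("sign_mix must lie in [0, 1]")
        if self.prior_df_d0 <= 0 or self.prior_scale_s0sq <= 0:
            raise ConfigurationError("variance prior parameters must be positive")
        if self.batch_count < 0 or self.batch_sd < 0:
            raise ConfigurationError("batch parameters must be non-negative")
        if self.tissue_labels is not None and len(self.tissue_labels) != self.n_studies:
            raise ConfigurationError(
                f"tissue_labels has {len(self.tissue_labels)} entries "
                f"for {self.n_studies} studies"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:06d}" for i in range(self.genes_per_study)]

    @property
    def n_planted(self) -> int:
        return int(round(self.deg_fraction * self.genes_per_study))

    def planted_effects(self) -> pd.Series:
        """True log2 fold-change per planted gene (shared across studies).

        The first ``round(sign_mix * n_planted)`` planted genes are up, the
        remainder down; identities and signs are a pure function of the
        config, so every study plants the same genes with the same sign.
        """
        k = self.n_planted
        n_up = int(round(self.sign_mix * k))
        signs = np.ones(k)
        signs[n_up:] = -1.0
        return pd.Series(
            signs * self.effect_size_log2fc, index=self.gene_ids[:k], dtype=float
        )

    def tissues(self) -> tuple[str, ...]:
        if self.tissue_labels is not None:
            return tuple(self.tissue_labels)
        return tuple(
            TISSUE_GROUPS[i % len(TISSUE_GROUPS)] for i in range(self.n_studies)
        )


@dataclass
class ExpressionStudy:
    """One study's expression matrix plus sample annotations.

    ``expr`` is genes x samples on the log2 scale with the gene symbol as
    index; ``samples`` carries one row per sample with columns ``group``
    (``case``/``control``), ``batch`` and ``tissue``.  ``true_effects``
    records the planted ground truth (empty for null simulations) and is
    carried for validation only — no pipeline stage reads it.
    """

    study_id: str
    expr: pd.DataFrame
    samples: pd.DataFrame
    tissue: str
    true_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.samples.index):
            raise ValueError("expression columns and sample annotations disagree")
        groups = set(self.samples["group"])
        if groups != {"case", "control"}:
            raise ValueError(f"both group levels required, got {sorted(groups)}")
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def group(self) -> pd.Series:
        return self.samples["group"]

    @property
    def batch(self) -> pd.Series:
        return self.samples["batch"]


def generate_study(config: SimulationConfig, study_index: int) -> ExpressionStudy:
    """Draw one study from the generative model.

    Gene-wise variances come from the scaled inverse-chi-square prior,
    planted genes receive the configured group-mean shift, and per-batch
    offsets (per gene) are added when ``batch_count >= 2``.  Deterministic
    for fixed ``(config.seed, study_index)``.
    """
    if not 0 <= study_index < config.n_studies:
        raise ConfigurationError(
            f"study_index {study_index} outside [0, {config.n_studies})"
        )
    rng = np.random.default_rng(config.seed + study_index)
    g = config.genes_per_study
    n = config.samples_per_group
    study_id = f"SYN{study_index + 1:03d}"

    sigma_sq = config.prior_scale_s0sq * config.prior_df_d0 / rng.chisquare(
        config.prior_df_d0, size=g
    )
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)

    # control samples first, then case samples
    group = np.array(["control"] * n + ["case"] * n)
    mean = np.tile(baseline[:, None], (1, 2 * n))
    effects = config.planted_effects()
    if len(effects):
        mean[: len(effects), group == "case"] += effects.to_numpy()[:, None]

    if config.batch_count >= 2:
        # cyclic assignment within each group keeps the design balanced
        batch = np.array(
            [f"b{i % config.batch_count + 1}" for i in range(n)] * 2
        )
        offsets = rng.normal(0.0, config.batch_sd, size=(g, config.batch_count))
        for j, label in enumerate(sorted(set(batch))):
            mean[:, batch == label] += offsets[:, [j]]
    else:
        batch = np.array(["b1"] * (2 * n))

    matrix = mean + rng.normal(size=(g, 2 * n)) * np.sqrt(sigma_sq)[:, None]

    sample_ids = [f"{study_id}_s{i + 1:02d}" for i in range(2 * n)]
    tissue = config.tissues()[study_index]
    samples = pd.DataFrame(
        {"group": group, "batch": batch, "tissue": tissue}, index=sample_ids
    )
    expr = pd.DataFrame(matrix, index=config.gene_ids, columns=sample_ids)
    return ExpressionStudy(study_id, expr, samples, tissue, effects)


def generate_collection(config: SimulationConfig) -> list[ExpressionStudy]:
    """Generate the full multi-tissue study collection."""
    return [generate_study(config, i) for i in range(config.n_studies)]


def generate_interactome(
    n_nodes: int,
    edges_per_new_node: int,
    seed: int,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Scale-free interaction network as an undirected edge list.

    Uses preferential attachment, giving the heavy-tailed degree
    distribution typical of gene-regulatory and protein-interaction
    networks.  Returns a two-column DataFrame of unordered node pairs with
    no self-loops and no duplicates.
    """
    if edges_per_new_node < 1 or n_nodes <= edges_per_new_node:
        raise ConfigurationError(
            "need n_nodes > edges_per_new_node >= 1 for preferential attachment"
        )
    if labels is not None and len(labels) != n_nodes:
        raise ConfigurationError("labels length must equal n_nodes")
    graph = nx.barabasi_albert_graph(n_nodes, edges_per_new_node, seed=seed)
    if labels is None:
        labels = [f"N{i + 1:05d}" for i in range(n_nodes)]
    mapping = dict(zip(graph.nodes(), labels))
    rows = [(mapping[u], mapping[v]) for u, v in graph.edges()]
    return pd.DataFrame(rows, columns=["node_a", "node_b"])


def generate_gene_set_library(
    universe: list[str],
    n_terms: int,
    size_range: tuple[int, int],
    seed: int,
) -> dict[str, set[str]]:
    """Random gene-set library: each term is a uniform draw without
    replacement from the universe, with sizes uniform over ``size_range``.
    """
    if not universe:
        raise ConfigurationError("universe must be non-empty")
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ConfigurationError(
            f"size_range {size_range} infeasible for universe of {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    universe = [g.upper() for g in universe]
    library: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        library[f"TERM{t + 1:04d}"] = set(members.tolist())
    return library
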