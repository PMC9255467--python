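"""Over-representation analysis on GMT gene-set libraries.

For a query of ``n`` genes against a term of ``m`` genes drawn from a
background of ``N`` (default 20000, the conventional protein-coding
universe), with overlap ``k``:

* ``p`` is the upper hypergeometric tail P(X >= k);
* the odds ratio uses the 2x2 deviation form
  ``k * (N - m - n + k) / ((n - k) * (m - k))``, with a 0.5 continuity
  addition to all four cells when a margin is exhausted;
* the combined score is ``OR * (-ln p)``, computed from the raw p;
* BH adjustment runs across the library's tested terms.

Each enriched term carries a regulation label: "up"/"down" when every
overlapping query gene shares that direction, "mixed" otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dex import bh_adjust

__all__ = [
    "GeneSetLibrary",
    "read_gmt",
    "write_gmt",
    "hypergeom_p",
    "enrichr_odds_ratio",
    "combined_score",
    "enrich",
]

DEFAULT_BACKGROUND = 20000


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets with a fixed background size."""

    name: str
    terms: dict[str, set[str]]
    background_size: int = DEFAULT_BACKGROUND
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("library has no terms")
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} is empty")
            if len(genes) > self.background_size:
                raise ValueError(
                    f"term {term!r} larger than background {self.background_size}"
                )


def read_gmt(path, name: str | None = None, background_size: int = DEFAULT_BACKGROUND) -> GeneSetLibrary:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    Symbols are uppercased and de-duplicated within each term.
    """
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">=1 gene ({len(fields)} fields found)"
                )
            term, description, *genes = fields
            terms[term] = {g.upper() for g in genes if g}
            descriptions[term] = description
    return GeneSetLibrary(
        name or Path(path).stem, terms, background_size, descriptions
    )


def write_gmt(library: GeneSetLibrary | dict[str, set[str]], path) -> None:
    if isinstance(library, dict):
        library = GeneSetLibrary("library", library)
    with open(path, "w") as fh:
        for term in library.terms:
            desc = library.descriptions.get(term, "na")
            genes = "\t".join(sorted(library.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def _check_counts(k: int, n: int, m: int, N: int) -> None:
    if not (0 <= k <= min(n, m) and 0 < n <= N and 0 < m <= N):
        raise ValueError(f"invalid contingency counts k={k}, n={n}, m={m}, N={N}")


def hypergeom_p(k: int, n: int, m: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N population, m successes,
    n draws)."""
    _check_counts(k, n, m, N)
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def enrichr_odds_ratio(k: int, n: int, m: int, N: int) -> float:
    """Deviation-form odds ratio of the 2x2 overlap table.

    ``k * (N - m - n + k) / ((n - k) * (m - k))``; when the query or term
    margin is exhausted (``n == k`` or ``m == k``) a 0.5 continuity term is
    added to all four cells.
    """
    _check_counts(k, n, m, N)
    if k == 0:
        return 0.0
    if n - k == 0 or m - k == 0:
        return ((k + 0.5) * (N - m - n + k + 0.5)) / ((n - k + 0.5) * (m - k + 0.5))
    return (k * (N - m - n + k)) / ((n - k) * (m - k))


def combined_score(odds_ratio: float, p: float) -> float:
    """Enrichment ranking statistic ``OR * (-ln p)`` (0 when p = 1)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return odds_ratio * (-math.log(p))


def enrich(
    query_genes,
    library: GeneSetLibrary,
    regulation_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Over-representation of a query against every library term.

    One row per term with non-empty overlap, sorted by p ascending; BH
    adjustment runs across the tested terms.  Query genes missing from the
    background still count toward ``n`` (the raw query size).
    """
    query = {g.upper() for g in query_genes}
    if not query:
        raise ValueError("query gene list is empty")
    regulation_labels = {
        g.upper(): r for g, r in (regulation_labels or {}).items()
    }
    n = len(query)
    N = library.background_size
    rows = []
    for term, members in library.terms.items():
        overlap = sorted(query & members)
        k = len(overlap)
        if k == 0:
            continue
        m = len(members)
        p = hypergeom_p(k, n, m, N)
        oratio = enrichr_odds_ratio(k, n, m, N)
        labels = {regulation_labels.get(g) for g in overlap}
        if labels == {"up"}:
            regulation = "up"
        elif labels == {"down"}:
            regulation = "down"
        else:
            regulation = "mixed"
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "m": m,
                "N": N,
                "p": p,
                "odds_ratio": oratio,
                "combined_score": combined_score(oratio, p),
                "overlap_genes": ";".join(overlap),
                "regulation": regulation,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "k", "n", "m", "N", "p", "p_adj", "odds_ratio",
                "combined_score", "overlap_genes", "regulation",
            ]
        )
    result = pd.DataFrame(rows)
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    result = result.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return result[
        [
            "term", "k", "n", "m", "N", "p", "p_adj", "odds_ratio",
            "combined_score", "overlap_genes", "regulation",
        ]
    ]
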