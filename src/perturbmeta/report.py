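"""Summary statistics over pipeline outputs.

The workhorse is :func:`larger_proportion_test`: given two counts that
partition a set (e.g. down- vs upregulated DEGs), it asks whether the
larger proportion exceeds one half, using the one-sided normal
approximation to the binomial with a 0.5 continuity correction applied to
the larger count:

    z = (max(a, b) - 0.5 - n/2) / sqrt(n/4),   p = P(Z > z),  n = a + b.

An exact binomial tail is available behind ``exact=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["ProportionComparison", "larger_proportion_test", "summarize_counts"]


@dataclass(frozen=True)
class ProportionComparison:
    count_a: int
    count_b: int
    n: int
    larger: int
    z: float
    p_one_sided: float


def larger_proportion_test(
    count_a: int, count_b: int, exact: bool = False
) -> ProportionComparison:
    """One-sided test that the larger of two partition counts exceeds half.

    Symmetric in its arguments.  With ``exact=True`` the p-value is the
    exact Binomial(n, 1/2) upper tail at the larger count instead of the
    continuity-corrected normal approximation.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    if n < 1:
        raise ValueError("need at least one observation")
    larger = max(count_a, count_b)
    z = (larger - 0.5 - n / 2.0) / math.sqrt(n / 4.0)
    if exact:
        p = float(stats.binom.sf(larger - 1, n, 0.5))
    else:
        p = float(stats.norm.sf(z))
    return ProportionComparison(count_a, count_b, n, larger, z, p)


def summarize_counts(
    deg_tables: dict[str, pd.DataFrame],
    study_to_tissue: dict[str, str] | None = None,
    compiled_regulation: dict[str, str] | None = None,
    hub_table: pd.DataFrame | None = None,
) -> dict:
    """Count tables plus proportion tests over every up/down partition.

    Produces per-study up/down counts, per-tissue totals with a
    down-vs-up test, tissue-specific vs shared counts (when a tissue map
    is given), and up/down partitions of the compiled perturbed set and of
    the hub set (predicted nodes, which carry no direction, are excluded
    from the hub comparison).  Comparisons with zero total are skipped
    with a note instead of a test.
    """
    from .dex import tissue_venn  # local import to avoid cycle at module load

    out: dict = {}
    per_study = []
    for study, table in deg_tables.items():
        n_up = int((table["status"] == "up").sum())
        n_down = int((table["status"] == "down").sum())
        per_study.append((study, n_up, n_down, n_up + n_down))
    out["per_study"] = pd.DataFrame(
        per_study, columns=["study", "n_up", "n_down", "n_deg"]
    )

    def _test_row(label, a, b):
        if a + b == 0:
            return {"label": label, "count_a": a, "count_b": b,
                    "z": None, "p": None, "note": "no observations; test skipped"}
        t = larger_proportion_test(a, b)
        return {"label": label, "count_a": a, "count_b": b,
                "z": t.z, "p": t.p_one_sided, "note": ""}

    comparisons = []
    total_up = int(out["per_study"]["n_up"].sum())
    total_down = int(out["per_study"]["n_down"].sum())
    comparisons.append(_test_row("all_down_vs_up", total_down, total_up))

    if study_to_tissue is not None:
        venn = tissue_venn(deg_tables, study_to_tissue)
        out["tissue_venn"] = venn
        per_tissue = []
        for tissue in sorted(venn.tissue_sets):
            studies = [s for s, t in study_to_tissue.items() if t == tissue]
            t_up = sum(
                int((deg_tables[s]["status"] == "up").sum()) for s in studies
            )
            t_down = sum(
                int((deg_tables[s]["status"] == "down").sum()) for s in studies
            )
            per_tissue.append(
                (tissue, t_up, t_down, venn.specific[tissue], venn.shared[tissue])
            )
            comparisons.append(_test_row(f"{tissue}_down_vs_up", t_down, t_up))
            comparisons.append(
                _test_row(
                    f"{tissue}_specific_vs_shared",
                    venn.specific[tissue],
                    venn.shared[tissue],
                )
            )
        out["per_tissue"] = pd.DataFrame(
            per_tissue, columns=["tissue", "n_up", "n_down", "specific", "shared"]
        )

    if compiled_regulation is not None:
        c_up = sum(1 for r in compiled_regulation.values() if r == "up")
        c_down = sum(1 for r in compiled_regulation.values() if r == "down")
        comparisons.append(_test_row("compiled_up_vs_down", c_up, c_down))

    if hub_table is not None and "is_hub" in hub_table:
        hubs = hub_table.loc[hub_table["is_hub"]]
        if compiled_regulation is not None:
            reg = hubs["node"].map(compiled_regulation)
            h_up = int((reg == "up").sum())
            h_down = int((reg == "down").sum())
            comparisons.append(_test_row("hub_up_vs_down", h_up, h_down))

    out["comparisons"] = pd.DataFrame(comparisons)
    return out
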