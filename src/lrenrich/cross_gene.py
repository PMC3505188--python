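"""Gene-level cross-study analyses.

Given a concept that is enriched in several studies, are the *same* member
genes driving the signal?  For each study pair, member genes measured in
both studies are cross-tabulated by significance (2x2) and tested for
positive association with a one-sided Fisher's exact test.  Also here:
group-wise proportion summaries (e.g. PRC2-target vs non-target
stratifications) and waterfall-plot data (significant members sorted by
methylation change).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concept_db import Concept
from .enrichment import benjamini_hochberg
from .errors import InputError
from .gene_input import GeneStatTable


@dataclass(frozen=True)
class OverlapResult:
    """Fisher's-exact overlap between two studies for one concept.

    ``counts`` = (both significant, a only, b only, neither) over the
    concept's genes measured in both studies; they sum to the shared
    measured concept size.
    """

    concept_id: str
    study_a: str
    study_b: str
    counts: tuple[int, int, int, int]
    p_fisher: float
    odds_ratio: float

    @property
    def n_shared(self) -> int:
        return sum(self.counts)


def overlap_test(
    concept: Concept,
    a: GeneStatTable,
    b: GeneStatTable,
    sig_cutoff: float = 0.05,
) -> OverlapResult:
    """One-sided (positive association) Fisher's exact test of shared hits.

    A gene counts as significant in a study iff its p < ``sig_cutoff``.  The
    p-value is the hypergeometric upper tail Pr(X >= both) with population
    the shared measured concept genes.  The odds ratio uses the Haldane 0.5
    correction when any cell is zero.
    """
    pa = a.data.set_index("gene_id")["p_value"]
    pb = b.data.set_index("gene_id")["p_value"]
    if pa.index.duplicated().any() or pb.index.duplicated().any():
        raise InputError("overlap_test requires collapsed tables (one record per gene)")
    shared = sorted(concept.gene_ids & set(pa.index) & set(pb.index))
    if not shared:
        raise InputError(
            f"concept {concept.concept_id!r} has no genes measured in both "
            f"{a.study_id!r} and {b.study_id!r}"
        )
    sig_a = pa[shared].to_numpy() < sig_cutoff
    sig_b = pb[shared].to_numpy() < sig_cutoff
    n11 = int(np.sum(sig_a & sig_b))
    n10 = int(np.sum(sig_a & ~sig_b))
    n01 = int(np.sum(~sig_a & sig_b))
    n00 = int(np.sum(~sig_a & ~sig_b))
    total = n11 + n10 + n01 + n00
    # upper tail of the hypergeometric with margins fixed
    p = float(stats.hypergeom.sf(n11 - 1, total, n11 + n10, n11 + n01))
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    odds = float(cells[0] * cells[3] / (cells[1] * cells[2]))
    return OverlapResult(concept.concept_id, a.study_id, b.study_id, (n11, n10, n01, n00), p, odds)


def all_pairs_overlap(
    concept: Concept,
    tables: Sequence[GeneStatTable],
    sig_cutoff: float = 0.05,
) -> list[OverlapResult]:
    """Overlap tests for every unordered study pair (k choose 2 results)."""
    if len(tables) < 2:
        raise InputError("need at least two studies")
    results = [overlap_test(concept, a, b, sig_cutoff) for a, b in combinations(tables, 2)]
    return results


def overlap_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """Tabulate overlap results with a BH-adjusted p column appended."""
    frame = pd.DataFrame(
        [
            {
                "concept_id": r.concept_id,
                "study_a": r.study_a,
                "study_b": r.study_b,
                "n_both": r.counts[0],
                "n_a_only": r.counts[1],
                "n_b_only": r.counts[2],
                "n_neither": r.counts[3],
                "p_fisher": r.p_fisher,
                "odds_ratio": r.odds_ratio,
            }
            for r in results
        ]
    )
    frame["fdr"] = benjamini_hochberg(frame["p_fisher"].to_numpy())
    return frame


@dataclass(frozen=True)
class GroupProportion:
    n_passing: int
    n_measured: int

    @property
    def proportion(self) -> float | None:
        return None if self.n_measured == 0 else self.n_passing / self.n_measured


def group_proportions(
    table: GeneStatTable,
    groups: Mapping[str, Sequence[str] | set[str]],
    p_cutoff: float = 0.05,
    min_effect: float = 0.05,
) -> dict[str, GroupProportion]:
    """Per group: fraction of measured member genes passing p and effect cuts.

    This backs stratified summaries such as the percentage of PRC2-target vs
    non-target genes with significant differential methylation.  Groups with
    no measured genes are returned with n_measured = 0 (proportion None).
    """
    if not groups:
        raise InputError("groups must be non-empty")
    df = table.data
    passing = set(df.loc[(df["p_value"] < p_cutoff) & (df["effect"].abs() >= min_effect), "gene_id"])
    measured = set(df["gene_id"])
    out: dict[str, GroupProportion] = {}
    for name, genes in groups.items():
        member = set(map(str, genes)) & measured
        out[name] = GroupProportion(len(member & passing), len(member))
    return out


def waterfall_data(
    table: GeneStatTable,
    concept: Concept,
    p_cutoff: float = 0.05,
) -> list[tuple[str, float]]:
    """Significant concept members sorted by effect, descending.

    Ready to plot as a waterfall of methylation change; ties in effect are
    broken by gene id for a stable order.
    """
    df = table.data
    mask = df["gene_id"].isin(concept.gene_ids) & (df["p_value"] < p_cutoff)
    sub = df.loc[mask, ["gene_id", "effect"]]
    rows = sorted(sub.itertuples(index=False), key=lambda r: (-r.effect, r.gene_id))
    return [(r.gene_id, float(r.effect)) for r in rows]
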