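"""Cross-study integration: merge enrichment runs, filter, cluster, export.

Per-study enrichment results are merged into a concepts x studies matrix of
signed scores v = s * (-log10 p_enrich), with s = +1 for enriched/up and
-1 for depleted/down, so hyper- and hypo-methylated concepts separate in a
heatmap.  Rows are filtered by the significance-in-k-studies criterion,
then rows and/or columns are clustered agglomeratively under the uncentered
Pearson correlation distance, and the result is written in the Eisen
Cluster 3.0 formats (cdt/gtr/atr) consumed by Java TreeView.

Centroid linkage follows the Cluster 3.0 convention: a merged cluster is
represented by the size-weighted element-wise mean of its leaves and
distances are re-evaluated against that centroid profile.  This can produce
inversions (non-monotone merge heights); average and complete linkage are
monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import ResultSet
from .errors import ConsistencyError, InputError
from .gene_input import P_FLOOR

logger = logging.getLogger(__name__)

LINKAGES = ("centroid", "average", "complete")


@dataclass
class ProfileMatrix:
    """Concepts x studies matrix of signed -log10 enrichment p-values.

    NaN marks concepts not tested in a study (e.g. filtered by size there).
    ``names`` optionally maps concept ids to display names for the cdt NAME
    column.
    """

    values: pd.DataFrame = field(repr=False)
    mode: str = "nondirectional"
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise InputError("row and column labels must be unique")

    @property
    def concept_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def study_ids(self) -> list[str]:
        return list(self.values.columns)


def _signed_score(p: float, direction: str) -> float:
    sign = 1.0 if direction in ("enriched", "up") else -1.0
    return sign * (-np.log10(max(p, P_FLOOR)))


def merge_results(runs: Sequence[ResultSet]) -> ProfileMatrix:
    """Merge per-study runs (all arms) into one ProfileMatrix.

    All runs must share one mode.  Non-directional runs contribute one
    column per study directly.  Directional runs contribute one row per
    concept and study — the best arm (smaller p_enrich, tie broken toward
    up) with sign +up / -down — matching one-row-per-concept heatmaps.
    """
    if len(runs) < 2:
        raise InputError("merge_results needs at least two result sets")
    modes = {rs.mode for rs in runs}
    if len(modes) > 1:
        raise InputError(f"cannot mix directional and non-directional runs: {sorted(modes)}")
    mode = modes.pop()

    by_study: dict[str, list[ResultSet]] = {}
    for rs in runs:
        by_study.setdefault(rs.study_id, []).append(rs)
    if len(by_study) < 2:
        raise InputError("merge_results needs results from at least two studies")

    names: dict[str, str] = {}
    cols: dict[str, dict[str, float]] = {}
    for study, arms in by_study.items():
        col: dict[str, float] = {}
        if mode == "nondirectional":
            for rs in arms:
                for r in rs.results:
                    col[r.concept_id] = _signed_score(r.p_enrich, r.direction)
                    names[r.concept_id] = r.name
        else:
            best: dict[str, tuple[float, str]] = {}
            for rs in sorted(arms, key=lambda a: 0 if a.arm == "up" else 1):
                for r in rs.results:
                    names[r.concept_id] = r.name
                    cur = best.get(r.concept_id)
                    if cur is None or r.p_enrich < cur[0]:
                        best[r.concept_id] = (r.p_enrich, r.direction)
            for cid, (p, direction) in best.items():
                col[cid] = _signed_score(p, direction)
        cols[study] = col

    all_concepts = sorted({cid for col in cols.values() for cid in col})
    frame = pd.DataFrame(
        {study: [cols[study].get(cid, np.nan) for cid in all_concepts] for study in cols},
        index=all_concepts,
    )
    return ProfileMatrix(frame, mode=mode, names=names)


def filter_concepts(m: ProfileMatrix, p_cutoff: float, min_studies: int = 1) -> ProfileMatrix:
    """Keep concepts significant (|v| >= -log10 cutoff) in >= min_studies.

    With min_studies about half the panel this selects concepts shared
    across tumor types; with min_studies=1 and a stricter cutoff it selects
    study-specific concepts.
    """
    if not (0 < p_cutoff <= 1):
        raise InputError("p_cutoff must be in (0, 1]")
    if min_studies < 1:
        raise InputError("min_studies must be >= 1")
    threshold = -np.log10(p_cutoff)
    hits = (m.values.abs() >= threshold).sum(axis=1)
    kept = m.values[hits >= min_studies]
    logger.info("filter_concepts: kept %d of %d concepts (p<%g in >=%d studies)",
                len(kept), len(m.values), p_cutoff, min_studies)
    return ProfileMatrix(kept.copy(), mode=m.mode, names=m.names)


def uncentered_pearson_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 minus the uncentered (cosine-like) Pearson correlation.

    Computed over pairwise-complete positions.  Ranges over [0, 2]; a vector
    that is all zero over the shared positions is treated as orthogonal
    (d = 1), the documented convention for degenerate profiles.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise InputError("no overlapping positions between profiles")
    a, b = a[ok], b[ok]
    na = np.sqrt(np.sum(a * a))
    nb = np.sqrt(np.sum(b * b))
    if na == 0.0 or nb == 0.0:
        return 1.0
    r = float(np.sum(a * b) / (na * nb))
    return 1.0 - max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class DendrogramRecord:
    """One agglomeration step: node ids are integers, leaves are 0..n-1 and
    internal nodes n, n+1, ... in merge order; similarity = 1 - distance."""

    node_id: int
    left: int
    right: int
    similarity: float


def hierarchical_cluster(
    m: ProfileMatrix,
    axis: str = "rows",
    linkage: str = "centroid",
) -> list[DendrogramRecord]:
    """Agglomerative clustering of rows or columns under uncentered Pearson.

    ``centroid``: merged clusters are size-weighted mean profiles (missing
    cells averaged over present leaves) and distances are re-evaluated to
    the centroid.  ``average``/``complete``: mean/max of the leaf-pair base
    distances.  Ties in the minimum distance break toward the
    lexicographically smallest active pair (i, j), making the merge sequence
    deterministic.
    """
    if linkage not in LINKAGES:
        raise InputError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if axis not in ("rows", "columns"):
        raise InputError("axis must be 'rows' or 'columns'")
    data = m.values.to_numpy(dtype=float)
    if axis == "columns":
        data = data.T
    n = data.shape[0]
    if n < 2:
        raise InputError("need at least two items to cluster")

    base = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base[i, j] = base[j, i] = uncentered_pearson_distance(data[i], data[j])

    profiles: dict[int, np.ndarray] = {i: data[i].copy() for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    active: list[int] = list(range(n))

    def cluster_distance(ci: int, cj: int) -> float:
        if linkage == "centroid":
            return uncentered_pearson_distance(profiles[ci], profiles[cj])
        pair = base[np.ix_(leaves[ci], leaves[cj])]
        return float(pair.mean()) if linkage == "average" else float(pair.max())

    records: list[DendrogramRecord] = []
    dist: dict[tuple[int, int], float] = {}
    for a_i in range(len(active)):
        for b_i in range(a_i + 1, len(active)):
            i, j = active[a_i], active[b_i]
            dist[(i, j)] = cluster_distance(i, j)

    next_id = n
    while len(active) > 1:
        best_pair = min(dist, key=lambda ij: (dist[ij], ij))
        d = dist[best_pair]
        i, j = best_pair
        records.append(DendrogramRecord(next_id, i, j, 1.0 - d))
        # merge j into a new cluster
        new_leaves = leaves[i] + leaves[j]
        if linkage == "centroid":
            # size-weighted nan-aware mean over the member leaves
            member = data[new_leaves]
            with np.errstate(invalid="ignore"):
                prof = np.nanmean(member, axis=0)
            profiles[next_id] = prof
        leaves[next_id] = new_leaves
        sizes[next_id] = sizes[i] + sizes[j]
        active = [c for c in active if c not in (i, j)]
        dist = {ij: v for ij, v in dist.items() if i not in ij and j not in ij}
        for c in active:
            dist[(min(c, next_id), max(c, next_id))] = cluster_distance(c, next_id)
        active.append(next_id)
        next_id += 1
    return records


def leaf_order(records: Sequence[DendrogramRecord], n_leaves: int) -> list[int]:
    """Left-to-right leaf ordering implied by the merge sequence."""
    if not records:
        return list(range(n_leaves))
    children = {r.node_id: (r.left, r.right) for r in records}
    order: list[int] = []

    def walk(node: int) -> None:
        if node < n_leaves:
            order.append(node)
        else:
            left, right = children[node]
            walk(left)
            walk(right)

    walk(records[-1].node_id)
    return order


# ---------------------------------------------------------------------------
# Cluster 3.0 / TreeView files


def _node_name(idx: int, n_leaves: int, leaf_prefix: str) -> str:
    if idx < n_leaves:
        return f"{leaf_prefix}{idx}X"
    return f"NODE{idx - n_leaves + 1}X"


def _fmt(v: float) -> str:
    return "" if np.isnan(v) else f"{v:.6g}"


def _write_tree(records: Sequence[DendrogramRecord], n_leaves: int, leaf_prefix: str, path: Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        _node_name(r.node_id, n_leaves, leaf_prefix),
                        _node_name(r.left, n_leaves, leaf_prefix),
                        _node_name(r.right, n_leaves, leaf_prefix),
                        f"{r.similarity:.6g}",
                    ]
                )
                + "\n"
            )


def write_treeview(
    m: ProfileMatrix,
    row_tree: Sequence[DendrogramRecord] | None = None,
    col_tree: Sequence[DendrogramRecord] | None = None,
    prefix: str | Path = "cluster",
) -> dict[str, Path]:
    """Write cdt (+ gtr/atr when trees are given) files for Java TreeView.

    Rows/columns are emitted in the leaf order of the corresponding tree
    when present, original order otherwise.  Numeric cells carry 6
    significant digits; missing cells are empty.
    """
    prefix = Path(prefix)
    n_rows = len(m.values)
    n_cols = len(m.values.columns)
    if row_tree and len(row_tree) != n_rows - 1:
        raise ConsistencyError(f"row tree has {len(row_tree)} records for {n_rows} rows")
    if col_tree and len(col_tree) != n_cols - 1:
        raise ConsistencyError(f"column tree has {len(col_tree)} records for {n_cols} columns")

    row_idx = leaf_order(row_tree, n_rows) if row_tree else list(range(n_rows))
    col_idx = leaf_order(col_tree, n_cols) if col_tree else list(range(n_cols))
    concept_ids = [m.values.index[i] for i in row_idx]
    study_ids = [m.values.columns[i] for i in col_idx]

    out: dict[str, Path] = {}
    cdt_path = prefix.with_suffix(".cdt")
    with open(cdt_path, "w") as fh:
        fh.write("\t".join(["GID", "UNIQID", "NAME", "GWEIGHT", *study_ids]) + "\n")
        if col_tree:
            fh.write("\t".join(["AID", "", "", "", *[f"ARRY{i}X" for i in col_idx]]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", "", *["1"] * n_cols]) + "\n")
        vals = m.values.to_numpy(dtype=float)
        for i, cid in zip(row_idx, concept_ids):
            name = m.names.get(cid, cid)
            cells = [_fmt(vals[i, j]) for j in col_idx]
            fh.write("\t".join([f"GENE{i}X", str(cid), str(name), "1", *cells]) + "\n")
    out["cdt"] = cdt_path
    if row_tree:
        gtr = prefix.with_suffix(".gtr")
        _write_tree(row_tree, n_rows, "GENE", gtr)
        out["gtr"] = gtr
    if col_tree:
        atr = prefix.with_suffix(".atr")
        _write_tree(col_tree, n_cols, "ARRY", atr)
        out["atr"] = atr
    return out


def read_cdt(path: str | Path) -> ProfileMatrix:
    """Re-read a written cdt file into a ProfileMatrix (row order as written)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n").split("\t") for ln in fh]
    header = lines[0]
    studies = header[4:]
    rows = [ln for ln in lines[1:] if ln[0] not in ("AID", "EWEIGHT")]
    ids = [r[1] for r in rows]
    names = {r[1]: r[2] for r in rows}
    vals = [[float(c) if c != "" else np.nan for c in r[4:]] for r in rows]
    frame = pd.DataFrame(vals, index=ids, columns=studies)
    return ProfileMatrix(frame, names=names)
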