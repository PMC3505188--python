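"""Per-study gene-level differential statistics: parsing, filtering, collapsing.

The enrichment test consumes one table per study holding a gene (or probe)
identifier, a differential p-value and a signed effect (fold-change or
delta-methylation).  Tables may contain several rows per gene — typically one
per microarray probe — and are collapsed to one row per gene before testing.

A small differential stage is included for beta-value matrices (proportion-
scale methylation in [0, 1], samples x probes): a plain two-sided t test,
paired or unpaired according to the study design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, RowError

logger = logging.getLogger(__name__)

#: Smallest p-value retained anywhere in the pipeline.  p = 0 is clamped here
#: so that -log10(p), the regression covariate, stays finite.
P_FLOOR = 1e-15

#: Default column names for tab-delimited per-study statistics files.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "gene_id": "geneid",
    "p_value": "pvalue",
    "effect": "foldchange",
}

COLLAPSE_METHODS = ("min_p", "fisher", "mean")


@dataclass(frozen=True)
class GeneStat:
    """One gene's (or probe's) differential statistic.

    ``effect`` carries a signed magnitude (fold-change or tumor-normal
    methylation difference); directional tests consume only its sign, delta
    filters consume its magnitude.  ``effect`` may be NaN when the input file
    had no effect column, in which case only non-directional analyses apply.
    """

    gene_id: str
    p_value: float
    effect: float = float("nan")

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if not (0.0 <= self.p_value <= 1.0):
            raise InputError(f"p_value {self.p_value!r} outside [0, 1]")


@dataclass
class GeneStatTable:
    """Ordered per-study table of differential statistics.

    Duplicate ``gene_id`` values are allowed and represent multiple probes
    mapping to one gene; :func:`collapse_probes` reduces them.
    The underlying frame has columns ``gene_id`` (str), ``p_value`` (float),
    ``effect`` (float, NaN allowed) and may carry extra bookkeeping columns
    (e.g. ``degenerate`` flags from :func:`differential_stats`).
    """

    study_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"gene_id", "p_value", "effect"}
        missing = required - set(self.data.columns)
        if missing:
            raise InputError(f"GeneStatTable missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise InputError(f"GeneStatTable for study {self.study_id!r} is empty")
        p = self.data["p_value"].to_numpy(dtype=float)
        if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
            raise InputError("p_value column must lie in [0, 1]")
        gid = self.data["gene_id"]
        if gid.isna().any() or (gid.astype(str).str.len() == 0).any():
            raise InputError("gene_id column must be non-empty strings")
        self.data = self.data.reset_index(drop=True)
        self.data["gene_id"] = self.data["gene_id"].astype(str)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.data["gene_id"])

    def records(self) -> list[GeneStat]:
        return [
            GeneStat(r.gene_id, float(r.p_value), float(r.effect))
            for r in self.data.itertuples(index=False)
        ]

    @classmethod
    def from_records(cls, study_id: str, records: Iterable[GeneStat]) -> "GeneStatTable":
        rows = [(r.gene_id, r.p_value, r.effect) for r in records]
        return cls(study_id, pd.DataFrame(rows, columns=["gene_id", "p_value", "effect"]))


def read_gene_stats(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    study_id: str | None = None,
    sep: str = "\t",
) -> GeneStatTable:
    """Read a tab-delimited per-study statistics file.

    The file must have a header row.  ``columns`` maps the logical fields
    ``gene_id``, ``p_value`` and ``effect`` to header names (defaults:
    ``geneid``, ``pvalue``, ``foldchange``).  Mapping ``effect`` to ``None``
    declares the file has no effect column (non-directional use only).
    p-values of exactly 0 are clamped to ``P_FLOOR`` with a logged warning.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        raw = pd.read_csv(path, sep=sep, header=0, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty") from None
    if len(raw) == 0:
        raise InputError(f"{path}: no data rows")

    for logical in ("gene_id", "p_value"):
        if colmap[logical] not in raw.columns:
            raise ConfigurationError(
                f"{path}: required column {colmap[logical]!r} (for {logical}) not in header "
                f"{list(raw.columns)}"
            )
    has_effect = colmap.get("effect") is not None
    if has_effect and colmap["effect"] not in raw.columns:
        raise ConfigurationError(
            f"{path}: effect column {colmap['effect']!r} not in header; "
            "map 'effect' to None if the file has none"
        )

    p = pd.to_numeric(raw[colmap["p_value"]], errors="coerce").astype(float)
    bad = p.isna() & raw[colmap["p_value"]].notna() | raw[colmap["p_value"]].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RowError(f"{path}: unparsable p-value on line {line}")
    if ((p < 0) | (p > 1)).any():
        line = int(((p < 0) | (p > 1)).idxmax()) + 2
        raise RowError(f"{path}: p-value outside [0, 1] on line {line}")
    n_clamped = int((p < P_FLOOR).sum())
    if n_clamped:
        logger.warning("%s: clamped %d p-value(s) below %g to %g", path, n_clamped, P_FLOOR, P_FLOOR)
        p = p.clip(lower=P_FLOOR)

    if has_effect:
        eff = pd.to_numeric(raw[colmap["effect"]], errors="coerce")
        bad = eff.isna() & raw[colmap["effect"]].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise RowError(f"{path}: unparsable effect on line {line}")
        eff = eff.to_numpy(dtype=float)
    else:
        eff = np.full(len(raw), np.nan)

    frame = pd.DataFrame(
        {
            "gene_id": raw[colmap["gene_id"]].astype(str),
            "p_value": p.to_numpy(dtype=float),
            "effect": eff,
        }
    )
    return GeneStatTable(study_id or path.stem, frame)


def write_gene_stats(table: GeneStatTable, path: str | Path, sep: str = "\t") -> None:
    """Serialize a table in the same three-column tab-delimited layout."""
    out = table.data[["gene_id", "p_value", "effect"]].rename(
        columns={"gene_id": "geneid", "p_value": "pvalue", "effect": "foldchange"}
    )
    out.to_csv(path, sep=sep, index=False, float_format="%.10g")


def filter_complete(tables: Sequence[GeneStatTable]) -> list[GeneStatTable]:
    """Keep only identifiers measured in every study.

    Mirrors the cross-study probe filter: an id missing from any one table is
    dropped everywhere, so all outputs share one id universe.
    """
    if not tables:
        raise InputError("filter_complete requires at least one table")
    shared = set.intersection(*(t.gene_ids for t in tables))
    if not shared:
        raise InputError("no identifiers shared by all tables")
    out = []
    for t in tables:
        kept = t.data[t.data["gene_id"].isin(shared)]
        out.append(GeneStatTable(t.study_id, kept.copy()))
    return out


def _fisher_combine(p: np.ndarray) -> float:
    # Fisher's method: -2 sum(ln p) ~ chi-square with 2k df under the null.
    statistic = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(statistic, 2 * len(p)))


def collapse_probes(table: GeneStatTable, method: str = "min_p") -> GeneStatTable:
    """Reduce a probe-level table to one record per gene.

    * ``min_p`` — keep the record with the smallest p (effect from that
      record); ties broken by first occurrence.
    * ``fisher`` — combine p-values by Fisher's method; effect is the
      -ln(p)-weighted mean effect (plain mean when all weights vanish), so
      its sign tracks the most significant probes.
    * ``mean`` — arithmetic mean of p and of effect.

    Output preserves first-occurrence gene order and is idempotent.
    """
    if method not in COLLAPSE_METHODS:
        raise ConfigurationError(f"unknown collapse method {method!r}; choose from {COLLAPSE_METHODS}")
    df = table.data
    rows: list[tuple[str, float, float]] = []
    for gene, grp in df.groupby("gene_id", sort=False):
        p = grp["p_value"].to_numpy(dtype=float)
        e = grp["effect"].to_numpy(dtype=float)
        if method == "min_p":
            i = int(np.argmin(p))  # argmin returns the first minimum: stable tie-break
            rows.append((gene, float(p[i]), float(e[i])))
        elif method == "mean":
            rows.append((gene, float(np.mean(p)), float(np.mean(e))))
        else:  # fisher
            pc = max(_fisher_combine(p), P_FLOOR)
            w = -np.log(p)
            if np.all(np.isnan(e)):
                eff = float("nan")
            elif w.sum() > 0:
                eff = float(np.average(e, weights=w))
            else:
                eff = float(np.mean(e))
            rows.append((gene, pc, eff))
    return GeneStatTable(table.study_id, pd.DataFrame(rows, columns=["gene_id", "p_value", "effect"]))


def delta_filter(table: GeneStatTable, p_cutoff: float, min_effect: float) -> GeneStatTable:
    """Keep records with p < ``p_cutoff`` and \\|effect\\| >= ``min_effect``.

    This is the study-level significance rule used to count differentially
    methylated sites (e.g. p < 0.01 and at least a 10% methylation change).
    """
    if p_cutoff < 0 or min_effect < 0:
        raise ConfigurationError("cutoffs must be non-negative")
    df = table.data
    mask = (df["p_value"] < p_cutoff) & (df["effect"].abs() >= min_effect)
    kept = df[mask].copy()
    logger.info("delta_filter(%s): %d of %d records survive", table.study_id, len(kept), len(df))
    if len(kept) == 0:
        raise InputError(f"delta_filter removed every record of study {table.study_id!r}")
    return GeneStatTable(table.study_id, kept)


# ---------------------------------------------------------------------------
# Beta-value matrices and the plain differential stage


@dataclass
class BetaMatrix:
    """Proportion-scale methylation matrix (probes x samples) with a design.

    ``values`` rows are probes, columns are samples; entries in [0, 1] with
    NaN allowed.  ``groups`` maps each sample to ``normal`` or ``tumor``.
    ``pairs`` optionally maps a pair label to (normal_sample, tumor_sample).
    """

    values: pd.DataFrame = field(repr=False)
    groups: Mapping[str, str]
    pairs: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise InputError("beta values must lie in [0, 1]")
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise InputError(f"group labels for unknown samples: {sorted(unknown)}")
        bad = set(self.groups.values()) - {"normal", "tumor"}
        if bad:
            raise InputError(f"group labels must be 'normal'/'tumor', got {sorted(bad)}")
        if self.pairs is not None:
            for pair_id, (n, t) in self.pairs.items():
                if self.groups.get(n) != "normal" or self.groups.get(t) != "tumor":
                    raise InputError(f"pair {pair_id!r} must map one normal to one tumor sample")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]


def read_beta_matrix(matrix_path: str | Path, sheet_path: str | Path, sep: str = "\t") -> BetaMatrix:
    """Read a probes-x-samples TSV matrix plus a sample sheet.

    The sheet has columns ``sample_id``, ``group`` and optionally ``pair_id``;
    samples sharing a pair_id form one normal/tumor pair.
    """
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    sheet = pd.read_csv(sheet_path, sep=sep, dtype=str)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ConfigurationError(f"{sheet_path}: sample sheet lacks column {col!r}")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    pairs = None
    if "pair_id" in sheet.columns and sheet["pair_id"].notna().any():
        pairs = {}
        for pid, grp in sheet.dropna(subset=["pair_id"]).groupby("pair_id"):
            by_group = dict(zip(grp["group"], grp["sample_id"]))
            if set(by_group) != {"normal", "tumor"} or len(grp) != 2:
                raise InputError(f"pair {pid!r} must contain exactly one normal and one tumor sample")
            pairs[pid] = (by_group["normal"], by_group["tumor"])
    return BetaMatrix(values, groups, pairs)


def differential_stats(m: BetaMatrix, paired: bool = False) -> GeneStatTable:
    """Per-probe tumor-vs-normal differential test on the beta scale.

    Effect is mean(tumor) - mean(normal) (paired: mean within-pair
    difference), so positive means hypermethylated in tumor.  p comes from a
    two-sided Welch t test (unpaired) or a paired t test.  Probes with fewer
    than two usable values per group (or two usable pairs), or with zero
    variance, are assigned p = 1 and flagged in a ``degenerate`` column;
    zero-variance probes with a non-zero mean difference get p = ``P_FLOOR``.
    """
    normal = m.samples("normal")
    tumor = m.samples("tumor")
    if not normal or not tumor:
        raise InputError("both a normal and a tumor group are required")
    if paired:
        if m.pairs is None:
            raise InputError("paired analysis requested but no pairing supplied")
        n_cols = [n for (n, _) in m.pairs.values()]
        t_cols = [t for (_, t) in m.pairs.values()]
        if len(n_cols) < 2:
            raise InputError("paired analysis needs at least two pairs")
        diffs = m.values[t_cols].to_numpy(dtype=float) - m.values[n_cols].to_numpy(dtype=float)
        rows = [_paired_row(d) for d in diffs]
    else:
        if len(normal) < 2 or len(tumor) < 2:
            raise InputError("unpaired analysis needs at least two samples per group")
        nv = m.values[normal].to_numpy(dtype=float)
        tv = m.values[tumor].to_numpy(dtype=float)
        rows = [_welch_row(t, n) for t, n in zip(tv, nv)]
    frame = pd.DataFrame(rows, columns=["p_value", "effect", "degenerate"])
    frame.insert(0, "gene_id", [str(i) for i in m.values.index])
    return GeneStatTable("differential", frame)


def _finish_row(effect: float, t_p: float, degenerate_variance: bool) -> tuple[float, float, bool]:
    if degenerate_variance:
        # zero spread: identical groups -> p=1; shifted constant -> floor
        return (1.0, effect, True) if effect == 0 else (P_FLOOR, effect, True)
    return (float(np.clip(t_p, P_FLOOR, 1.0)), effect, False)


def _welch_row(t: np.ndarray, n: np.ndarray) -> tuple[float, float, bool]:
    t, n = t[~np.isnan(t)], n[~np.isnan(n)]
    if len(t) < 2 or len(n) < 2:
        return (1.0, 0.0, True)
    effect = float(t.mean() - n.mean())
    if t.var(ddof=1) == 0 and n.var(ddof=1) == 0:
        return _finish_row(effect, 1.0, True)
    res = stats.ttest_ind(t, n, equal_var=False)
    return _finish_row(effect, float(res.pvalue), False)


def _paired_row(d: np.ndarray) -> tuple[float, float, bool]:
    d = d[~np.isnan(d)]
    if len(d) < 2:
        return (1.0, 0.0, True)
    effect = float(d.mean())
    if d.var(ddof=1) == 0:
        return _finish_row(effect, 1.0, True)
    res = stats.ttest_1samp(d, 0.0)
    return _finish_row(effect, float(res.pvalue), False)
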