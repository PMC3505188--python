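"""The cut-off-free enrichment test: logistic regression of set membership.

For each concept, membership of every measured gene (0/1) is regressed on a
significance covariate x = -log10(p) from the per-gene differential test.  A
positive slope means the concept's genes are more significant than a random
set of the same size (enriched); a negative slope means less significant
(depleted).  No significance cut-off is applied to the gene list — every
gene's evidence contributes in proportion to its p-value.

Directional testing converts each two-sided gene p into a one-sided p per
arm (up: p/2 when the effect is positive, 1 - p/2 otherwise; down symmetric)
so that concepts enriched among up- and down-regulated (hyper-/hypo-
methylated) genes are distinguished rather than enriched and depleted.

The reported odds ratio is exp(slope * (x_high - x_low)) where the anchors
are -log10 of a "null-ish" and a "clearly significant" p-value: the
multiplicative change in membership odds between two such genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .concept_db import Concept, ConceptDB, restrict_and_filter
from .errors import ConfigurationError, DegenerateConceptError, InputError
from .gene_input import GeneStatTable, P_FLOOR, collapse_probes

logger = logging.getLogger(__name__)

ARMS = ("twosided", "up", "down")
MODES = ("nondirectional", "directional")

#: Ridge penalty applied when the unpenalized fit separates or fails to
#: converge; keeps every concept reportable, flagged converged=False.
RIDGE_PENALTY = 1e-4
MAX_ITER = 100


@dataclass(frozen=True)
class EnrichmentParams:
    """Run configuration; defaults are the package defaults, all overridable.

    ``or_low_p``/``or_high_p`` anchor the odds ratio (see module docstring);
    ``driving_cutoff`` is the per-gene significance cut-off for reporting the
    member genes driving an enrichment signal.
    """

    min_genes: int = 10
    max_genes: int = 500
    or_low_p: float = 0.5
    or_high_p: float = 0.001
    driving_cutoff: float = 0.05
    collapse: str = "min_p"

    def odds_ratio_gap(self) -> float:
        return -np.log10(self.or_high_p) - (-np.log10(self.or_low_p))


@dataclass
class EnrichmentResult:
    concept_id: str
    name: str
    concept_type: str
    n_effective: int
    slope: float
    se: float
    z: float
    p_enrich: float
    fdr: float
    odds_ratio: float
    direction: str
    driving_genes: list[str]
    converged: bool


@dataclass
class ResultSet:
    """One study's enrichment run for one arm.

    ``arm`` is ``twosided`` for non-directional runs, ``up`` or ``down`` for
    the two directional arms.  ``params`` records the full configuration so
    the run can be reproduced exactly.
    """

    study_id: str
    mode: str
    arm: str
    results: list[EnrichmentResult]
    params: EnrichmentParams = field(default_factory=EnrichmentParams)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            d = asdict(r)
            d["driving_genes"] = ",".join(r.driving_genes)
            rows.append(d)
        frame = pd.DataFrame(
            rows,
            columns=[
                "concept_id", "name", "concept_type", "n_effective", "slope", "se",
                "z", "p_enrich", "fdr", "odds_ratio", "direction", "driving_genes",
                "converged",
            ],
        )
        frame.insert(0, "mode", self.mode)
        frame.insert(0, "study_id", self.study_id)
        return frame


def write_results(runs: Sequence[ResultSet], path: str | Path) -> None:
    """Write one or more arms of a study's run to a tab-delimited file."""
    frame = pd.concat([rs.to_frame() for rs in runs], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> list[ResultSet]:
    """Re-read a result TSV into one ResultSet per (study, arm)."""
    frame = pd.read_csv(path, sep="\t", dtype={"study_id": str, "driving_genes": str})
    out: list[ResultSet] = []
    for (study, mode, _arm_dir), grp in frame.groupby(["study_id", "mode", "direction"], sort=False):
        results = []
        for r in grp.itertuples(index=False):
            driving = [] if pd.isna(r.driving_genes) or r.driving_genes == "" else str(r.driving_genes).split(",")
            results.append(
                EnrichmentResult(
                    str(r.concept_id), str(r.name), str(r.concept_type), int(r.n_effective),
                    float(r.slope), float(r.se), float(r.z), float(r.p_enrich), float(r.fdr),
                    float(r.odds_ratio), str(r.direction), driving, bool(r.converged),
                )
            )
        arm = _arm_dir if _arm_dir in ("up", "down") else "twosided"
        out.append(ResultSet(str(study), str(mode), arm, results))
    return out


# ---------------------------------------------------------------------------
# covariate construction


def significance_covariate(table: GeneStatTable, arm: str = "twosided") -> pd.Series:
    """Per-gene significance covariate x, indexed by gene_id.

    ``twosided``: x = -log10(p).  ``up``: the two-sided p is converted to a
    one-sided p toward the positive-effect tail (p/2 when effect > 0, else
    1 - p/2) before the log transform; ``down`` is symmetric.  One-sided
    values are clamped to [P_FLOOR, 1] so x stays finite.
    The table must already be collapsed to one record per gene.
    """
    if arm not in ARMS:
        raise ConfigurationError(f"unknown arm {arm!r}; choose from {ARMS}")
    df = table.data
    if df["gene_id"].duplicated().any():
        raise InputError("significance_covariate requires a collapsed table (one record per gene)")
    p = df["p_value"].to_numpy(dtype=float)
    if arm == "twosided":
        x = -np.log10(np.clip(p, P_FLOOR, 1.0))
    else:
        eff = df["effect"].to_numpy(dtype=float)
        if np.any(np.isnan(eff)):
            raise InputError(f"arm {arm!r} requires an effect for every gene")
        toward = eff > 0 if arm == "up" else eff < 0
        one_sided = np.where(toward, p / 2.0, 1.0 - p / 2.0)
        x = -np.log10(np.clip(one_sided, P_FLOOR, 1.0))
    return pd.Series(x, index=df["gene_id"].to_numpy(), name=f"x_{arm}")


# ---------------------------------------------------------------------------
# the per-concept fit


@dataclass(frozen=True)
class FitResult:
    slope: float
    se: float
    z: float
    p: float
    converged: bool


def _ridge_logistic(y: np.ndarray, X: np.ndarray, penalty: float = RIDGE_PENALTY) -> tuple[np.ndarray, np.ndarray]:
    """Newton solver for logistic regression with a small quadratic penalty.

    Used as the fallback under separation or non-convergence: the penalty
    bounds the coefficients, and standard errors come from the penalized
    Hessian.  Returns (coefficients, standard errors).
    """
    beta = np.zeros(X.shape[1])
    eye = np.eye(X.shape[1])
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - penalty * beta
        hess = (X * w[:, None]).T @ X + penalty * eye
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return beta, se


def _fit_membership(y: np.ndarray, x: np.ndarray) -> FitResult:
    """Maximum-likelihood logistic fit of membership y on intercept + x."""
    if np.ptp(x) == 0.0:
        # zero-variance covariate carries no information: slope 0, p 1
        return FitResult(0.0, float("nan"), 0.0, 1.0, True)
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER)
            ok = bool(res.mle_retvals.get("converged", False))
            se = float(np.sqrt(res.cov_params()[1, 1]))
            if ok and np.isfinite(se) and se < 1e6:
                slope = float(res.params[1])
                z = slope / se
                return FitResult(slope, se, z, float(2 * stats.norm.sf(abs(z))), True)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            pass
    beta, ses = _ridge_logistic(y, X)
    slope, se = float(beta[1]), float(ses[1])
    z = slope / se
    return FitResult(slope, se, z, float(2 * stats.norm.sf(abs(z))), False)


def fit_concept(
    x: Mapping[str, float] | pd.Series,
    members: Iterable[str],
    universe: Sequence[str],
) -> FitResult:
    """Fit one concept: membership within ``universe`` regressed on x.

    ``universe`` is the ordered list of measured genes; ``members`` the
    concept's genes.  Wald inference: z = slope/se, two-sided normal p.
    """
    member_set = set(members) & set(universe)
    if not member_set or len(member_set) == len(universe):
        raise DegenerateConceptError(
            f"concept has {len(member_set)} members in a universe of {len(universe)}"
        )
    xs = x[list(universe)].to_numpy(dtype=float) if isinstance(x, pd.Series) else np.array(
        [x[g] for g in universe], dtype=float
    )
    y = np.fromiter((1.0 if g in member_set else 0.0 for g in universe), dtype=float, count=len(universe))
    return _fit_membership(y, xs)


def benjamini_hochberg(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up FDR-adjusted p-values, order-preserving with the input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full per-study run


def run_enrichment(
    table: GeneStatTable,
    db: ConceptDB,
    mode: str = "nondirectional",
    params: EnrichmentParams | None = None,
) -> list[ResultSet]:
    """Run the enrichment test for one study against a concept collection.

    Returns one ResultSet for a non-directional run, two (up and down arms)
    for a directional run.  FDR is computed by Benjamini-Hochberg within
    each concept type and arm.  Per-concept fit failures degrade to the
    penalized fallback rather than aborting the run; degenerate concepts
    (empty after restriction) are skipped with a log message.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; choose from {MODES}")
    params = params or EnrichmentParams()

    collapsed = table
    if table.data["gene_id"].duplicated().any():
        collapsed = collapse_probes(table, params.collapse)
    universe = list(collapsed.data["gene_id"])
    fdb = restrict_and_filter(db, universe, params.min_genes, params.max_genes)

    arms = ["twosided"] if mode == "nondirectional" else ["up", "down"]
    gap = params.odds_ratio_gap()
    out: list[ResultSet] = []
    gene_p = collapsed.data.set_index("gene_id")["p_value"]
    gene_eff = collapsed.data.set_index("gene_id")["effect"]

    for arm in arms:
        x = significance_covariate(collapsed, arm)
        xv = x.to_numpy(dtype=float)
        uni_index = {g: i for i, g in enumerate(universe)}
        results: list[EnrichmentResult] = []
        for concept in fdb:
            genes = sorted(concept.effective_genes(fdb.universe))
            idx = np.fromiter((uni_index[g] for g in genes), dtype=int, count=len(genes))
            y = np.zeros(len(universe))
            y[idx] = 1.0
            fit = _fit_membership(y, xv)
            if mode == "nondirectional":
                direction = "enriched" if fit.slope >= 0 else "depleted"
            else:
                direction = arm
            driving = _driving_genes(genes, gene_p, gene_eff, params.driving_cutoff, mode, arm)
            results.append(
                EnrichmentResult(
                    concept.concept_id, concept.name, concept.concept_type, len(genes),
                    fit.slope, fit.se, fit.z, fit.p, float("nan"),
                    float(np.exp(fit.slope * gap)), direction, driving, fit.converged,
                )
            )
        _fill_fdr(results)
        out.append(ResultSet(table.study_id, mode, arm, results, params))
    return out


def _driving_genes(
    genes: Sequence[str],
    gene_p: pd.Series,
    gene_eff: pd.Series,
    cutoff: float,
    mode: str,
    arm: str,
) -> list[str]:
    """Member genes below the reporting cut-off; directional arms also
    require the effect sign to match the arm.  Sorted by p ascending."""
    sig = [g for g in genes if gene_p[g] < cutoff]
    if mode == "directional":
        if arm == "up":
            sig = [g for g in sig if gene_eff[g] > 0]
        else:
            sig = [g for g in sig if gene_eff[g] < 0]
    return sorted(sig, key=lambda g: (gene_p[g], g))


def _fill_fdr(results: list[EnrichmentResult]) -> None:
    # BH within each concept type: FDR reported per concept family
    by_type: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        by_type.setdefault(r.concept_type, []).append(i)
    for idxs in by_type.values():
        adj = benjamini_hochberg([results[i].p_enrich for i in idxs])
        for i, a in zip(idxs, adj):
            results[i].fdr = float(a)
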