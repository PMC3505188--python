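"""Synthetic multi-study data with known truth.

Emulates the shape of a panel of tumor-vs-normal methylation studies: per
study, a probe-level table of gene ids, p-values and signed effects, where
most genes are null (uniform p) and a planted subset of concepts carries
signal.  Planted alternatives use Beta-distributed p-values:

* enriched-up / enriched-down members: p ~ Beta(a, 1) with a < 1 (mass near
  0; smaller a = stronger signal), effect sign matching the direction with
  probability 0.9 so directional tests see realistic sign noise;
* depleted members: p ~ Beta(1, a) with a < 1 (mass near 1 — the mirror
  image of the enriched arm under p -> 1 - p), i.e. members are *less*
  significant than a random set.

Genes in several planted concepts take the strongest (smallest a) signal.
A sharing design assigns the same planted concepts to several studies so
cross-study clustering has known positives.  All draws flow from one seed;
outputs are byte-identical across runs.

Not emulated: probe-level spatial correlation, realistic beta-value
covariance, or cellular-heterogeneity mixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concept_db import Concept, ConceptDB
from .errors import ConfigurationError, InputError
from .gene_input import BetaMatrix, GeneStatTable

STATUSES = ("enriched-up", "enriched-down", "depleted", "null")

#: Probability that a planted member's effect sign matches its direction.
SIGN_FIDELITY = 0.9
#: Scale of |effect| draws, on the delta-methylation scale.
NULL_EFFECT_SCALE = 0.05
PLANTED_EFFECT_LOC = 0.15


@dataclass
class SimulationTruth:
    """Everything needed to regenerate and score a synthetic panel."""

    seed: int
    n_genes: int
    concepts: ConceptDB
    #: study -> {concept_id: (status, strength a)}
    assignments: dict[str, dict[str, tuple[str, float]]]
    #: mean extra probes per gene: probes ~ 1 + Poisson(rate)
    probe_rate: float = 0.3

    def __post_init__(self) -> None:
        known = {c.concept_id for c in self.concepts}
        for study, planted in self.assignments.items():
            for cid, (status, a) in planted.items():
                if cid not in known:
                    raise InputError(f"study {study!r} plants unknown concept {cid!r}")
                if status not in STATUSES:
                    raise InputError(f"unknown status {status!r}")
                if not (a > 0):
                    raise InputError("signal strength a must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_genes": self.n_genes,
            "probe_rate": self.probe_rate,
            "assignments": {
                s: {cid: [st, a] for cid, (st, a) in planted.items()}
                for s, planted in self.assignments.items()
            },
            "concepts": {c.concept_id: sorted(c.gene_ids) for c in self.concepts},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def gene_universe(n_genes: int) -> list[str]:
    width = len(str(max(n_genes - 1, 1)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def simulate_concepts(
    n_genes: int,
    n_concepts: int,
    size_range: tuple[int, int] = (10, 100),
    overlap_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ConceptDB, list[str]]:
    """Draw random concepts over a synthetic gene universe.

    Sizes are uniform over ``size_range``.  With ``overlap_rate`` r > 0, a
    fraction r of each concept's members comes from a shared core pool (10%
    of the universe), mimicking the nesting of real ontologies; with r = 0
    members are uniform draws, so pairwise overlap follows the
    hypergeometric expectation.
    """
    lo, hi = size_range
    if lo < 2 or hi > n_genes or lo > hi:
        raise ConfigurationError(f"size range [{lo}, {hi}] infeasible for {n_genes} genes")
    if not (0.0 <= overlap_rate <= 1.0):
        raise ConfigurationError("overlap_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    core = genes[: max(1, n_genes // 10)]
    concepts: list[Concept] = []
    for k in range(n_concepts):
        size = int(rng.integers(lo, hi + 1))
        n_core = min(int(round(overlap_rate * size)), len(core))
        members: set[str] = set()
        if n_core:
            members.update(rng.choice(core, size=n_core, replace=False))
        rest = rng.choice(genes, size=size, replace=False)
        for g in rest:
            if len(members) >= size:
                break
            members.add(g)
        while len(members) < size:  # top up if core/rest collided
            members.add(genes[int(rng.integers(0, n_genes))])
        concepts.append(Concept(f"C{k:04d}", f"synthetic concept {k}", frozenset(members), "synthetic"))
    return ConceptDB(concepts), genes


def _gene_status(truth: SimulationTruth, study_id: str) -> dict[str, tuple[str, float]]:
    """Strongest planted (status, a) per gene; smaller a wins."""
    planted = truth.assignments.get(study_id, {})
    status: dict[str, tuple[str, float]] = {}
    for cid, (st, a) in sorted(planted.items()):
        if st == "null":
            continue
        for g in truth.concepts.get(cid).gene_ids:
            cur = status.get(g)
            if cur is None or a < cur[1]:
                status[g] = (st, a)
    return status


def simulate_study(truth: SimulationTruth, study_id: str) -> GeneStatTable:
    """One study's probe-level table under the truth's planted design.

    The RNG stream is seeded from (truth.seed, study index) so studies are
    independent but each is reproducible in isolation.
    """
    study_index = sorted(truth.assignments).index(study_id) if study_id in truth.assignments else 0
    rng = np.random.default_rng([truth.seed % (2**31), study_index, 7])
    genes = gene_universe(truth.n_genes)
    status = _gene_status(truth, study_id)

    rows: list[tuple[str, float, float]] = []
    n_probes = 1 + rng.poisson(truth.probe_rate, size=truth.n_genes)
    for g, k in zip(genes, n_probes):
        st, a = status.get(g, ("null", 1.0))
        for _ in range(int(k)):
            if st == "null":
                p = float(rng.uniform())
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                eff = sign * abs(rng.normal(0.0, NULL_EFFECT_SCALE))
            elif st == "depleted":
                p = float(rng.beta(1.0, a))  # mass near 1: less significant than chance
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                eff = sign * abs(rng.normal(0.0, NULL_EFFECT_SCALE))
            else:
                p = float(rng.beta(a, 1.0))  # mass near 0
                toward = 1.0 if st == "enriched-up" else -1.0
                sign = toward if rng.uniform() < SIGN_FIDELITY else -toward
                eff = sign * abs(rng.normal(PLANTED_EFFECT_LOC, NULL_EFFECT_SCALE))
            p = min(max(p, 1e-15), 1.0)
            rows.append((g, p, eff))
    return GeneStatTable(study_id, pd.DataFrame(rows, columns=["gene_id", "p_value", "effect"]))


def simulate_panel(truth: SimulationTruth) -> dict[str, GeneStatTable]:
    """All studies named in the truth's assignment map, in sorted order."""
    return {sid: simulate_study(truth, sid) for sid in sorted(truth.assignments)}


def make_panel_truth(
    n_genes: int = 5000,
    n_concepts: int = 60,
    n_studies: int = 10,
    n_shared: int = 6,
    shared_in: int = 10,
    strength: float = 0.2,
    size_range: tuple[int, int] = (30, 80),
    seed: int = 0,
    directions: Sequence[str] = ("enriched-up", "enriched-down"),
) -> SimulationTruth:
    """Convenience builder: a panel where ``n_shared`` concepts are planted
    (alternating direction) in the first ``shared_in`` studies and everything
    else is null.  ``shared_in`` < n_studies leaves unrelated studies for
    clustering contrasts."""
    if n_studies < 1:
        raise ConfigurationError("n_studies must be >= 1")
    if n_shared > n_concepts:
        raise ConfigurationError("cannot share more concepts than exist")
    db, _ = simulate_concepts(n_genes, n_concepts, size_range, 0.0, seed)
    shared_ids = [c.concept_id for c in list(db)[:n_shared]]
    assignments: dict[str, dict[str, tuple[str, float]]] = {}
    for s in range(n_studies):
        sid = f"study{s:02d}"
        planted: dict[str, tuple[str, float]] = {}
        if s < shared_in:
            for k, cid in enumerate(shared_ids):
                planted[cid] = (directions[k % len(directions)], strength)
        assignments[sid] = planted
    return SimulationTruth(seed=seed, n_genes=n_genes, concepts=db, assignments=assignments)


def simulate_beta_matrix(
    n_probes: int = 200,
    n_per_group: int = 10,
    paired: bool = False,
    n_shifted: int = 20,
    shift: float = 0.2,
    noise: float = 0.05,
    seed: int = 0,
) -> BetaMatrix:
    """A small tumor-vs-normal beta-value matrix with a planted shift.

    The first ``n_shifted`` probes are hypermethylated in tumor by ``shift``
    on the beta scale; values are clipped to [0, 1].  Paired designs share a
    per-sample baseline between the two members of each pair.
    """
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:05d}" for i in range(n_probes)]
    base = rng.uniform(0.2, 0.7, size=(n_probes, 1))
    normals = [f"N{i:02d}" for i in range(n_per_group)]
    tumors = [f"T{i:02d}" for i in range(n_per_group)]
    nv = np.clip(base + rng.normal(0, noise, size=(n_probes, n_per_group)), 0, 1)
    tv = np.clip(base + rng.normal(0, noise, size=(n_probes, n_per_group)), 0, 1)
    tv[:n_shifted] = np.clip(tv[:n_shifted] + shift, 0, 1)
    values = pd.DataFrame(np.hstack([nv, tv]), index=probes, columns=normals + tumors)
    groups = {s: "normal" for s in normals} | {s: "tumor" for s in tumors}
    pairs = {f"P{i:02d}": (normals[i], tumors[i]) for i in range(n_per_group)} if paired else None
    return BetaMatrix(values, groups, pairs)
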