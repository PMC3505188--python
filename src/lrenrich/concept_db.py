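"""Gene set ("concept") collections: GMT I/O and universe restriction.

A concept is a named, biologically related set of genes — a GO term, a
pathway, a transcription-factor target set, and so on.  Before enrichment
testing, concepts are intersected with the set of measured genes (the
universe) and filtered by effective size, since very small sets are unstable
and very large ones uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError, RowError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 500


@dataclass(frozen=True)
class Concept:
    concept_id: str
    name: str
    gene_ids: frozenset[str]
    concept_type: str = "concept"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise InputError(f"concept {self.concept_id!r} has no genes")

    def effective_genes(self, universe: frozenset[str] | None) -> frozenset[str]:
        return self.gene_ids if universe is None else self.gene_ids & universe

    def effective_size(self, universe: frozenset[str] | None) -> int:
        return len(self.effective_genes(universe))


@dataclass
class ConceptDB:
    """A collection of concepts, optionally restricted to a gene universe.

    Genes in the universe absent from every concept still count as
    non-members in each regression — the test compares a set against all
    other measured genes, not against annotated genes only.
    """

    concepts: list[Concept] = field(default_factory=list)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        ids = [c.concept_id for c in self.concepts]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate concept ids: {dupes}")

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    def get(self, concept_id: str) -> Concept:
        for c in self.concepts:
            if c.concept_id == concept_id:
                return c
        raise KeyError(concept_id)


def read_gmt(path: str | Path, concept_type: str = "concept") -> ConceptDB:
    """Read a GMT file: one set per line, tab-separated name, description, members.

    Duplicate member ids within a line are deduplicated; a line with fewer
    than three fields is a row error; duplicate set names are an input error.
    """
    path = Path(path)
    concepts: list[Concept] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        logger.warning("%s: empty GMT file", path)
        return ConceptDB([])
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise RowError(f"{path}: line {lineno} has {len(fields)} field(s); GMT needs >= 3")
        cid, desc, *members = fields
        if cid in seen:
            raise InputError(f"{path}: duplicate concept id {cid!r}")
        seen.add(cid)
        genes = frozenset(g for g in members if g)
        concepts.append(Concept(cid, desc or cid, genes, concept_type))
    return ConceptDB(concepts)


def write_gmt(db: ConceptDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in db.concepts:
            genes = sorted(c.gene_ids)
            fh.write("\t".join([c.concept_id, c.name, *genes]) + "\n")


def restrict_and_filter(
    db: ConceptDB,
    universe: Iterable[str],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> ConceptDB:
    """Intersect concepts with the measured-gene universe and filter by size.

    A concept is kept when its effective size |genes ∩ universe| lies in
    [min_size, max_size].  Drop counts are logged and attached to the result
    as ``filter_report``.
    """
    if min_size < 1 or max_size < min_size:
        raise InputError(f"need 1 <= min_size <= max_size, got [{min_size}, {max_size}]")
    uni = frozenset(str(g) for g in universe)
    if not uni:
        raise InputError("empty universe")
    kept: list[Concept] = []
    n_small = n_large = 0
    for c in db.concepts:
        size = c.effective_size(uni)
        if size < min_size:
            n_small += 1
        elif size > max_size:
            n_large += 1
        else:
            kept.append(c)
    logger.info(
        "restrict_and_filter: kept %d of %d concepts (%d below %d, %d above %d)",
        len(kept), len(db.concepts), n_small, min_size, n_large, max_size,
    )
    out = ConceptDB(kept, universe=uni)
    out.filter_report = {"kept": len(kept), "too_small": n_small, "too_large": n_large}  # type: ignore[attr-defined]
    return out
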