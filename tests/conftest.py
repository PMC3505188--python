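import numpy as np
import pandas as pd
import pytest

from lrenrich import Concept, ConceptDB, GeneStatTable


def make_table(study_id, gene_ids, p_values, effects=None):
    if effects is None:
        effects = np.zeros(len(gene_ids))
    return GeneStatTable(
        study_id,
        pd.DataFrame({"gene_id": list(gene_ids), "p_value": list(p_values), "effect": list(effects)}),
    )


@pytest.fixture
def uniform_table():
    """One collapsed 200-gene study with uniform null p-values."""
    rng = np.random.default_rng(11)
    genes = [f"g{i:03d}" for i in range(200)]
    effects = rng.normal(0, 0.1, size=200)
    return make_table("nullstudy", genes, rng.uniform(size=200), effects)


@pytest.fixture
def small_db():
    genes = [f"g{i:03d}" for i in range(200)]
    rng = np.random.default_rng(5)
    concepts = [
        Concept(f"S{k}", f"set {k}", frozenset(rng.choice(genes, 20, replace=False)), "testtype")
        for k in range(5)
    ]
    return ConceptDB(concepts)


@pytest.fixture
def stats_file(tmp_path):
    def _write(name="stats.tsv", rows=None, header="geneid\tpvalue\tfoldchange"):
        rows = rows if rows is not None else ["g1\t0.01\t1.2", "g2\t0.5\t-0.3", "g3\t1.0\t0.0"]
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
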