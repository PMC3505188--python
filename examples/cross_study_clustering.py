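"""Cluster enrichment profiles across a simulated study panel.

Simulates six studies — four sharing planted concepts, two pure noise —
runs the directional test per study, merges the runs into a concepts x
studies matrix of signed -log10 p scores, keeps concepts significant
(p < 1e-4) in at least half of the studies, clusters rows and columns under
the uncentered Pearson distance with centroid linkage, and writes
TreeView-ready cdt/gtr/atr files.  Studies sharing the planted template
should merge first in the column tree.
"""

from lrenrich import (
    filter_concepts,
    hierarchical_cluster,
    make_panel_truth,
    merge_results,
    run_enrichment,
    simulate_panel,
    write_treeview,
)

truth = make_panel_truth(n_genes=2500, n_concepts=25, n_studies=6, n_shared=4,
                         shared_in=4, strength=0.2, size_range=(30, 60), seed=3)
runs = []
for study_id, table in simulate_panel(truth).items():
    runs.extend(run_enrichment(table, truth.concepts, "directional"))

matrix = merge_results(runs)
print(f"merged matrix: {matrix.values.shape[0]} concepts x {matrix.values.shape[1]} studies")

kept = filter_concepts(matrix, p_cutoff=1e-4, min_studies=3)
print(f"significant in >=3 studies at p<1e-4: {list(kept.values.index)}")

row_tree = hierarchical_cluster(kept, "rows", "centroid")
col_tree = hierarchical_cluster(kept, "columns", "centroid")
first = col_tree[0]
print(f"first column merge: studies {kept.study_ids[first.left]} + "
      f"{kept.study_ids[first.right]} at similarity {first.similarity:.3f}")

files = write_treeview(kept, row_tree, col_tree, prefix="panel_cluster")
print("wrote:", ", ".join(str(p) for p in files.values()))
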