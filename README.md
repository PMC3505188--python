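# lrenrich

Cut-off-free gene set enrichment testing by logistic regression, with
cross-study clustering of enrichment profiles — built for pathway-level
analysis of differential DNA methylation (and any other per-gene
significance input), where picking a significance cut-off for the gene list
would otherwise drive the conclusions.

## Who this is for

Analysts with per-gene (or per-probe) differential statistics from several
studies — e.g. tumor-vs-normal methylation panels profiled on a common
platform — who want to know which biological concepts (GO terms, pathways,
target sets, ...) are enriched or depleted in differential signal, whether
the change is directional (hyper- vs hypomethylation), which concepts recur
across studies, and whether the same member genes drive the signal
everywhere.

## The model

For a concept $C$ and measured genes $g = 1 \dots N$, let $y_g =
\mathbf{1}[g \in C]$ and $x_g = -\log_{10} p_g$, the significance of gene
$g$'s differential test. The enrichment test fits the logistic regression

$$\operatorname{logit} \Pr(y_g = 1) = \beta_0 + \beta_1 x_g$$

and reports the Wald test of $\beta_1 = 0$. A positive slope means the
concept's genes are more significant than a randomly chosen set of the same
size (enriched); negative means less (depleted). No gene-list cut-off is
involved: every gene contributes evidence in proportion to its p-value.
The reported odds ratio is $e^{\beta_1 (x_{hi} - x_{lo})}$ — the
multiplicative change in membership odds between a null-ish gene
($p_{lo} = 0.5$) and a clearly significant one ($p_{hi} = 0.001$).

The *directional* test converts each two-sided $p_g$ into a one-sided value
per arm ($p_g/2$ when the effect sign matches the arm, $1 - p_g/2$
otherwise) before the log transform, distinguishing concepts enriched among
up-regulated (hypermethylated) genes from those enriched among
down-regulated (hypomethylated) genes.

Per-study results are merged into a concepts × studies matrix of signed
scores $s \cdot (-\log_{10} p)$ ($s = +1$ enriched/up, $-1$
depleted/down), filtered by a significance-in-$k$-studies rule, clustered
hierarchically under the uncentered Pearson correlation distance (centroid,
average or complete linkage), and written as Cluster 3.0 `cdt`/`gtr`/`atr`
files for Java TreeView. Gene-level concordance between study pairs is
tested with one-sided Fisher's exact tests on the 2×2 table of member-gene
significance.

## Worked example

`examples/enrichment_basics.py` simulates a 2,000-gene study with three
planted concepts and runs both test modes:

```
study: 2659 probe rows, 2000 genes
planted: ['C0000', 'C0001', 'C0002']

non-directional, top 4 by p:
  C0002  slope=+0.935  p=3.38e-19  fdr=5.06e-18  OR=12.47  enriched  (25 driving genes)
  C0001  slope=+0.839  p=5.51e-16  fdr=4.13e-15  OR=9.62  enriched  (23 driving genes)
  C0000  slope=+0.763  p=1e-13  fdr=5e-13  OR=7.83  enriched  (21 driving genes)
  C0011  slope=-0.936  p=0.0364  fdr=0.136  OR=0.08  depleted  (2 driving genes)

directional, top 2 per arm:
  [up] C0002  p=2.49e-16  fdr=3.73e-15
  [up] C0000  p=4.71e-15  fdr=3.53e-14
  [down] C0001  p=1.27e-18  fdr=1.91e-17
  [down] C0000  p=0.000425  fdr=0.00319
```

The three planted concepts top the ranking with positive slopes and
odds ratios ≫ 1; the directional arms separate the up-planted (C0000,
C0002) from the down-planted (C0001) concept. "Driving genes" are the
member genes individually below the reporting cut-off (default p < 0.05).
The other examples cover cross-study clustering
(`cross_study_clustering.py`), pairwise gene overlap (`gene_overlap.py`)
and the beta-value differential stage (`differential_methylation.py`).

## Command line

The same workflow is scriptable from a shell:

```sh
lrenrich simulate --out-dir panel --seed 1            # synthetic study panel + GMT + truth
lrenrich enrich --stats panel/study00.tsv --gmt panel/concepts.gmt \
    --out study00.res.tsv --directional
lrenrich cluster --results study00.res.tsv --results study01.res.tsv \
    --filter-p 1e-4 --min-studies 1 --out-prefix panel_cluster
lrenrich overlap --stats panel/study00.tsv --stats panel/study01.tsv \
    --gmt panel/concepts.gmt --concept C0000 --out overlap.tsv
```

Every command writes a JSON run manifest (parameters, input digests, seed,
version) next to its outputs.

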