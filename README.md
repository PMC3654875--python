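# tcnet — temporal coexpression networks from first-order partial correlations

`tcnet` is a Python package for asking how a gene coexpression network is
*rewired* over the course of a perturbation — the motivating setting is
sequential breast-tumor biopsies taken before, early in, and late in
endocrine (aromatase-inhibitor) treatment. Given a genes × samples
expression matrix whose samples fall into three ordered timepoints
(`pre`, `mid`, `post`), it:

1. selects a node set of differentially expressed genes (per-gene two-group
   linear model, Benjamini–Hochberg FDR), or accepts a user-supplied list;
2. infers one undirected network per timepoint: a pair (i, j) is linked iff
   its zero-order Spearman correlation **and** its first-order partial
   correlation ρ<sub>ij·k</sub> = (r<sub>ij</sub> − r<sub>ik</sub>r<sub>jk</sub>) /
   √((1−r<sub>ik</sub>²)(1−r<sub>jk</sub>²)) given *every* other gene k are
   significant at level α (t approximation, df = n−2−q) — so links represent
   direct correlations not explained by any single common regulator —
   and validates edge counts against a per-gene permutation null;
3. characterizes each network: degree distributions (with KS comparisons
   between timepoints), largest connected component, mean shortest path
   within the LCC, global clustering (transitivity);
4. classifies genes as hubs (degree outliers) and bottlenecks (betweenness
   outliers) by Tukey upper fences Q3 + 1.5·IQR, into the four categories
   hub-bottleneck / hub-nonbottleneck / nonhub-bottleneck /
   nonhub-nonbottleneck;
5. quantifies rewiring: conserved-link fractions between consecutive
   networks, category-transition flows, stable vs transiently prominent
   genes, and the nine degree-change patterns.

A synthetic-data generator plants known conditional-dependence graphs
(Gaussian graphical models with hub nodes, controlled edge overlap between
timepoints, and optional pre→post mean shifts), so every stage can be tested
against ground truth. See `docs/methods.md` for the model, its assumptions
and its limits.

## Worked example

Simulate a 60-gene dataset (90 planted edges per timepoint, two hubs,
120 samples per timepoint, half the genes shifted post-treatment), then run
the full pipeline:

```bash
tcnet simulate --genes 60 --edges 90 --hubs 2 --hub-degree 10 \
    --n-pre 120 --n-mid 120 --n-post 120 --strength 0.6 --shift-size 1.5 \
    --seed 11 --out demo/data
tcnet run-all --expr demo/data/expression.tsv --meta demo/data/samples.tsv \
    --fdr 0.05 --alpha 0.01 --nperm 100 --seed 11 --out demo/run
```

`demo/run/run_report.json` then contains (excerpt):

```json
"diffexpr":  {"n_selected": 30, "n_up": 30, "n_down": 0},
"network":   {"pre": {"n_links": 26}, "mid": {"n_links": 21}, "post": {"n_links": 24}},
"permutation_null": {"pre": {"observed": 26, "null_max": 6, "exceeds_null": true}},
"rewiring":  {"conserved_links": {"pre->mid": {"count": 3, "fraction_of_earlier": 0.115},
                                  "mid->post": {"count": 5, "fraction_of_earlier": 0.238}}}
```

Reading this: the screen recovered 30 differentially expressed genes (the
simulation shifted 30 upward); each timepoint's network has 21–26 links
among those 30 nodes, far above the permutation-null maximum of 6–8 links,
so the coexpression signal is not a chance artifact; and only ~12–24% of
links survive from one timepoint to the next — the planted truth shared 20%
of edges between consecutive graphs, and that rewiring is what the conserved
fractions recover. The per-timepoint topology table (`topology.tsv`), role
tables (`roles_<tp>.tsv` with the fences used), GraphML networks and the
per-gene category/degree-pattern table (`gene_status.tsv`) are written
alongside.

Every stage is also available separately (`tcnet simulate|diffexpr|network|
metrics|roles|rewiring`) and as a library (`import tcnet`).

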