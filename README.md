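# rbpregulon

Tools for dissecting how RNA-binding proteins (RBPs) relate to the
expression of the transcripts they bind.

RBPs control splicing, stability, transport and translation of their
target RNAs, forming dense post-transcriptional regulatory networks.
`rbpregulon` implements a complete analysis pipeline for asking, for each
RBP in a cohort, whether its own expression tracks the expression of its
CLIP-derived targets across tissues — and, if so, which properties of the
RBP or of its targets explain the association.

The pipeline has four stages:

1. **Network construction.** Each transcript is a target of an RBP if at
   least one CLIP peak of that RBP overlaps a window of ±300 bp around any
   of the transcript's exonic start or end coordinates (the window width
   reflects the empirical concentration of RBP binding near splice sites,
   and is configurable).
2. **Co-expression classification.** For each RBP, Spearman correlation
   ρ is computed between the RBP's expression profile across tissues and
   every target / non-target transcript. The target distribution is
   compared with the full non-target control set, and with 100 matched
   control resamples of equal size, by a two-sided Wilcoxon rank-sum test.
   Each RBP is labelled

   * **SC** (significantly congruent) — p < 0.05 and median target ρ above
     the control median,
   * **SIC** (significantly incongruent) — p < 0.05 and median below,
   * **NSC** — no significant difference.

   The same machinery runs at the *transcript level* (RBP mRNA profile)
   and at the *protein level* (RBP protein-abundance profile over the
   tissues shared with the RNA compendium), and applies unchanged to
   condition-based compendia such as yeast expression data.
3. **Feature modelling.** RBP-centric (one row per RBP; response = median
   target ρ) and transcript-centric (one row per RBP-target pair;
   response = that pair's ρ) feature tables are fitted with full
   multivariate OLS, backward stepwise elimination, and cross-validated
   elastic net, yielding per-feature significance / selection calls.
4. **Network centrality.** RBPs labelled identically at both levels
   ("sync": SC/SC or SIC/SIC) are compared with the remaining RBPs on
   closeness and betweenness centrality in a protein-protein interaction
   network.

Because the original CLIP, RNA-seq and proteomics compendia are large
external resources, the package ships a first-class synthetic-data
generator that emulates them — exon-structured annotation, peaks planted
inside or outside boundary windows, tissue expression with planted
positive/negative/null rank-correlation of chosen strength, matched
protein profiles, and a PPI graph with an optional dense core — while
recording every planted fact in a truth table, so the whole pipeline is
testable end to end with known ground truth.

## Worked example

```python
from rbpregulon import (
    GeneratorConfig, generate, map_targets, network_summary,
    run_level, class_summary,
)

data = generate(GeneratorConfig(seed=7, n_rbps=12, n_transcripts=600,
                                targets_per_rbp=(30, 40)))
net = map_targets(data.peaks, data.annotation, flank=300)
table, union = network_summary(net)
print(table.head(4).to_string(index=False))
print(f"union of unique targets: {union}")

records, summary = run_level(
    data.truth.rbp_genes, net, data.expr_rna, data.annotation,
    expr_protein=data.expr_protein, level="transcript", n_reps=100, seed=7,
)
for r in records[:4]:
    print(f"{r.rbp_id}  rho_med={r.median_target_rho:+.3f}  "
          f"ctrl={r.median_control_rho:+.3f}  p={r.p_vs_all:.3g}  {r.label}")
print(class_summary([r.label for r in records]))
```

prints

```
rbp_id  n_targets
RBP001         34
RBP002         35
RBP003         36
RBP004         33
union of unique targets: 408
RBP001  rho_med=+0.718  ctrl=+0.015  p=1.34e-22  SC
RBP002  rho_med=+0.768  ctrl=-0.024  p=6.13e-23  SC
RBP003  rho_med=+0.738  ctrl=+0.009  p=1.77e-23  SC
RBP004  rho_med=+0.753  ctrl=-0.053  p=1.39e-21  SC
{'n': 12, 'n_SC': 6, 'n_SIC': 6, 'n_NSC': 0, 'pct_SC': 50.0, ...}
```

Each line gives the RBP's median Spearman ρ against its targets, the
median against all non-targets, the rank-sum p-value of the comparison
and the resulting class; this cohort plants six positively and six
negatively coupled RBPs, all of which are recovered.

The same analysis runs from the shell:

```bash
rbpregulon synth --seed 7 -o fixtures/
rbpregulon build-network --peaks fixtures/peaks/*.bed --gtf fixtures/annotation.gtf -o network.tsv
rbpregulon classify --network network.tsv --gtf fixtures/annotation.gtf \
    --rna-expr fixtures/expression_rna.tsv --n-reps 100 --seed 7 -o classes.tsv
```

or end to end from one YAML config with `rbpregulon run --config cfg.yaml
-o out/`, which also writes a manifest with a SHA-256 for every output.

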