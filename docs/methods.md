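# Methods

## Peak-to-target mapping

A transcript is called a target of an RBP when at least one of the RBP's
CLIP peaks shares at least one base with a *boundary window* of the
transcript. For an exon `[s, e)` in 0-based half-open coordinates the two
windows are `[s − flank, s + flank + 1)` and `[(e−1) − flank, (e−1) +
flank + 1)`: each covers the boundary base itself plus `flank` bases on
both sides, clipped at the chromosome origin. The symmetric ±`flank`
window is our reading of "flanking or downstream" binding around exonic
start/end coordinates: it is the union of the stricter one-sided
readings, and `flank` (default 300 bp, the scale at which RBP binding
concentrates around splice sites) is a plain parameter so either stricter
convention is recoverable. Overlap is binary — no minimum-overlap
fraction — and strand is ignored by default because CLIP peak exports
frequently carry no strand; `respect_strand=True` restores strand
matching. An RBP's own gene is *not* excluded from its target set (an
`exclude_self` flag exists for sensitivity analysis).

All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted once at the boundary, so the window arithmetic is
free of ±1 case analysis. Mapping is done with an interval tree per
chromosome and is tested for exact agreement with a quadratic all-pairs
overlap check.

## SC / SIC / NSC classification

For each RBP the expressed transcripts are split into **targets**,
**control-all** (every expressed non-target) and **control-matched**
(`n_reps` = 100 random subsets of control-all, each the size of the
target set, drawn without replacement from a per-RBP deterministic
stream derived from the run seed). The RBP's own representative
transcript is excluded from the control pool; its self-correlation of +1
is not a meaningful null draw.

The RBP's profile at the transcript level is the expression of its
*representative transcript*: the protein-coding transcript of its gene
with the highest mean expression across all tissues (ties broken by
lexicographically smallest id, for determinism). At the protein level
the profile is the RBP gene's row of the protein-abundance matrix, and
all correlations are computed over the tissues shared by the protein and
RNA compendia (at least 3 required; the emulated design has 9 of 16).
RBPs without a protein row are skipped and reported, not silently
dropped. Protein matrices are gene-level with unique row ids.

Spearman ρ is computed with midranks for ties (vectorized ranking plus
a rank-space Pearson step; exact agreement with `scipy.stats.spearmanr`
is asserted in tests). Constant profiles have undefined ρ and are
excluded with a count. The target and control ρ distributions are then
compared with a two-sided two-sample Wilcoxon rank-sum (Mann-Whitney)
test using the tie-corrected normal approximation — the two vectors are
unpaired and of unequal length, so the signed-rank variant does not
apply. Labels: SC if p < α and median target ρ exceeds the control
median, SIC if p < α and it is lower, NSC otherwise; α defaults to 0.05
and no multiple-testing correction is applied across RBPs (a
Benjamini-Hochberg column can be derived from the emitted p-values).
Fewer than two usable values on either side yields NSC with an
`insufficient_data` flag.

The final label is taken against control-all; the 100 matched-control
p-values are reported in full, summarized by their median, and an
agreement rate (fraction of resamples whose verdict matches the final
label) is emitted. This precedence is a documented choice: the matched
resamples guard against control-set-size artifacts rather than defining
the call.

## Feature modelling

Two tables are built. The RBP-centric table has one row per RBP,
response = median target ρ, and nine predictors: number of targets,
median binding p-value over target-supporting peaks, number of
RNA-binding domains, PPI degree, number of protein-coding and of all
annotated transcripts of the RBP gene, length of the representative
transcript, median distance of supporting-peak starts to the nearest
transcript end, and the Spearman correlation between the RBP's mRNA and
protein profiles over shared tissues. Missing domain/PPI/protein entries
become 0 with a provenance flag rather than NA, keeping the design
complete. Distances use the transcript's genomic span (not spliced
coordinates): the 5′ end is the genomic start on + strand and the
genomic end on − strand.

The transcript-centric table has one row per (RBP, target) pair with an
expression-backed ρ; when several peaks support a pair, the peak with the
smallest binding p-value represents it. Predictors: binding p-value,
distances of the peak start to the 5′ and 3′ transcript ends, transcript
length, and transcript biotype.

Three procedures rank predictors:

* **Multivariate OLS** with per-coefficient two-sided t-tests.
  Categorical predictors expand to indicator contrasts against the first
  (sorted) level; levels observed once are merged into `other`. The
  significance of a categorical *feature* is the minimum BH-adjusted p
  over its contrasts, so each feature gets a single p. Rank-deficient
  designs are rejected with the offending columns named (the rank test
  runs on unit-norm columns, so it is scale-free).
* **Backward stepwise elimination**: refit OLS and drop the feature with
  the largest feature-p while that p ≥ α_stay (default 0.05). Ties break
  lexicographically, so the result is independent of column order.
  Eliminating everything leaves a valid intercept-only fit.
* **Elastic net** on standardized predictors and centered response, with
  (λ, l1-ratio) chosen by seeded k-fold cross-validated MSE (default
  grid: l1-ratio ∈ {0.1, 0.5, 0.9, 1.0}, 30 λ values on the automatic
  path, 10 folds, folds reduced with a warning when rows are scarce).
  Penalized fits have no native p-values; "significance" for this method
  means selection, i.e. a nonzero coefficient, and is reported in a
  separate column. Supplying a single (λ, l1-ratio) bypasses CV, which
  is how the λ→0 (OLS) and λ→∞ (all-zero) limits are verified.

Per-RBP transcript-centric fits require at least p+2 pairs; smaller RBPs
are skipped and reported. Outputs include an RBP × feature matrix of
−log10(p) from the multivariate fits, per-feature fractions of RBPs where
the feature is significant/retained/selected, and grouped median ρ per
biotype per RBP.

## Centrality comparison

Sync RBPs are those labelled SC at both levels or SIC at both levels.
The PPI graph is undirected and simple (self-loops and duplicate edges
removed with a warning). Closeness uses the classical definition with
the Wasserman-Faust component correction — `(r−1)/Σd × (r−1)/(n−1)` for a
node reaching r−1 others — because the convention matters on
disconnected PPI graphs; harmonic closeness is available by flag.
Betweenness is reported unnormalized (each unordered pair counted once)
with a normalized column alongside. Group comparison is a two-sided
rank-sum test; with no ties (the generic case for centralities of
distinct nodes) the exact null distribution is used, since the groups
are small, otherwise the tie-corrected normal approximation.

## Synthetic data

The generator emulates the *shape* of the real inputs at desk scale:
default 60 RBPs, 4 500 single-transcript candidate target genes plus
multi-transcript bystander genes, 16 RNA tissues of which the first 9
have matched protein data, 50–80 targets per RBP, per-peak binding
p-values log-uniform on [1e−10, 0.05], and 2 RBPs absent from the
protein matrix. Genes are laid out with inter-gene gaps wider than
2·flank so boundary windows of different genes never overlap; planted
peaks are placed inside a window of their target, decoys in a reserved
zone more than 2·flank beyond every boundary. Mapping therefore recovers
the planted network exactly, and the truth table is an exact oracle.

Expression planting works on ranks, because the pipeline's statistic is
Spearman: each RBP gets a latent tissue profile, and each planted target
is a Gaussian-copula coupling to it with Pearson weight
`2·sin(π·ρ_s/6)`, so the requested `effect_rho` (default 0.7) is the
target Spearman correlation; signs encode SC/SIC, zero encodes NSC, and
values map through `exp` to positive TPM-like numbers. Protein-level
labels use a second latent factor: shared with the RNA factor for sync
RBPs, and otherwise standardized and orthogonalized against it within
the protein-tissue block and the remainder. For RBPs planted null at one
level but coupled at the other, candidate factors are additionally
rejection-sampled against a Monte-Carlo estimate of the exact functional
the null level's test averages — the expected Spearman of a coupled
target against the other profile — until that expectation is ≤ ~0.015.
Without this step, chance structure between the two 9- and 16-tissue
profiles shifts the null level's entire target-ρ distribution coherently
and the rank-sum test detects it; this is a genuine hazard of latent-
factor designs at small tissue counts, not a pipeline artifact. Coupled
RBPs receive disjoint target sets so each transcript is driven by at most
one factor; fully-null RBPs may share targets freely.

The PPI generator attaches sync RBPs to a dense core (clique-like with
edge probability 0.7 over the core) and non-sync RBPs to the periphery,
yielding higher closeness for sync RBPs by construction; with planting
off, all RBPs attach uniformly and the group comparison is null.
Components are stitched so every RBP lies in the main component.

What the generator does *not* emulate: shared targets between coupled
RBPs, tissue-specific expression programs, heteroscedastic or
count-based measurement noise, isoform-level protein data, and any
sequence-level signal in peaks. Passing tests therefore demonstrate that
the pipeline's statistics behave correctly under the stated model, not
that any particular biological cohort will show these effect sizes.

## Determinism and problem sizes

One integer seed drives everything: the generator consumes a
`default_rng(seed)`, matched-control sampling derives an independent
stream per RBP from (seed, CRC32 of the RBP id), and elastic-net folds
are seeded. Identical configs produce byte-identical output files
(hash-compared in tests), and the orchestrator writes a manifest with a
SHA-256 per output; a completed run whose manifest matches the config is
not recomputed.

Test and acceptance workloads use the default 60-RBP cohort (both
levels, 100 matched resamples; ~15 s), a 200-RBP null cohort for type-I
calibration (~4 s), 100 random instances for the interval oracle, 20
random graphs (≤50 nodes) for the centrality oracle, and 100 seeded
replicates for the stepwise-selection check. These sizes were chosen so
the statistical assertions have comfortable margins while the whole
suite stays interactive.

## Known limitations

* The rank-sum test compares distributions whose members are themselves
  estimates from few tissues (9–16); with real data the per-target ρ
  values of one RBP are correlated through shared biology, which widens
  the null beyond what matched resampling of independent controls
  captures.
* Spliced-coordinate (mRNA-space) binding-site distances are not
  implemented; distances use the genomic span.
* Elastic-net selection is reported without stability analysis across
  resamples.
* The classifier's matched-resample agreement rate is descriptive; no
  formal combination of the 100 p-values is attempted.
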