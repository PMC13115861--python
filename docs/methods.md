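# Methods

## Coordinates and interval semantics

All intervals are 0-based half-open (BED convention); "overlap" always means
sharing at least one base, so `[0,100)` and `[100,200)` do not overlap.
Sorting ties break by (chromosome lexicographic, start, end). Strand is
ignored in every interval operation; gene strand is used only to locate the
TSS in promoter-window analyses. Merging uses a *strict* gap rule — two
intervals join when their gap is strictly less than the merge distance
(touching intervals always join) — which matches the "separated by less
than d" phrasing of SE stitching; note the reference CLI's `merge -d` uses
`<=`, a one-base difference covered by a boundary test.

The non-overlapping shuffle (used by both permutation nulls) preserves each
interval's chromosome and length, draws starts uniformly, and rejects
placements colliding with already-placed intervals or an optional exclusion
set, with a bounded per-interval retry budget and whole-chromosome restarts.
Sequential placement is exactly uniform for a single interval per
chromosome and matches the reference tool's behaviour for many; at the
occupancies used here (<10% of a chromosome) the deviation from the
uniform-over-configurations ideal is negligible, and the calibration test
(below) verifies the end-to-end null empirically. Shuffling does not exclude
the blacklist by default (blacklisted artifacts are removed from the input
fractions before any analysis); an opt-in flag excludes it.

## Contact-peak consensus

Split-probe (odd/even) peak sets per biological replicate are reconciled by
symmetric 250 bp extension: an odd and an even peak support each other when
their extended forms share ≥1 base, which admits original gaps of up to
499 bp under half-open arithmetic. The reconstructed interval is, by
default, the union of the two original peaks ("union" mode). A "literal"
mode instead computes `min(starts)+250` / `max(ends)−250` from the original
coordinates; this can invert short overlapping pairs, and such degenerate
records are dropped with a warning. Union mode is the default because it is
the unique reading that never produces inverted intervals and equals the
literal formula applied to the extended coordinates. Replicate-supported
intervals are merged within replicate; across replicates an interval is
retained when it overlaps intervals from at least `min_support − 1` other
replicates (default ≥2 of 3 in total), and the retained pool is merged into
the consensus set. Input-fraction files are accepted in the manifest for
provenance but are controls for the upstream peak caller, not this stage.

## SE atlas and specificity

Within each sample, SE entries separated by less than 12,500 bp are
stitched (the conventional SE consolidation distance). Cross-sample
candidates are formed by a gap-0 merge of the stitched sets (the
cross-sample distance is configurable; 0 is the closest reading of a plain
cross-sample merge). A candidate is kept with support from ≥3 of 3 cancer
samples or ≥5 of 6 normal samples (both configurable). Cancer and normal
consensus SEs sharing ≥1 bp are "shared" (shared regions are merged across
conditions for deduplicated reporting); Ψ/Ω analysis operates on
cancer-specific SEs only.

## Ψ/Ω classification

Stage one intersects the focal lncRNA's correlation peaks with the
consensus contacts (`-u` report-once semantics; annotations pass through
unchanged). Stage two labels a cancer-specific SE Ψ iff ≥1 confirmed peak
overlaps it. Mark "instances" count distinct (mark, sign) pairs per SE, so
the instance total can exceed the Ψ count; within-SE peak multiplicity is
reported separately. The promoter analyses use a TSS window of ±2,000 bp
(the window size is genuinely open; 2 kb is a conventional promoter
half-width and is a parameter). The lncRNA ranking counts, per lncRNA, the
number of SEs harbouring ≥1 of its peaks (SE-level presence, so duplicated
table rows cannot inflate it) and reports the focal percentile among
lncRNAs with ≥1 overlap using the `≤ focal` tie convention (a strict `<`
variant is available); neither the denominator nor the tie rule is forced
by the construction, so both choices are explicit parameters.

## Permutation statistics

Empirical p is (k+1)/(n+1) with k the number of null draws ≥ observed. The
add-one convention is the only one consistent with reporting p = 0.001 from
1000 iterations when the observed statistic exceeds the entire null range;
when k = 0 the display layer renders "< 1/(n+1)" while the numeric value
stays (0+1)/(n+1). Each iteration draws from its own seeded substream
(`default_rng([seed, iteration])`), so results are independent of iteration
order. Fold enrichment is observed/null-mean (a fold printed from an
unrounded null mean can differ in the last digit from one recomputed from
the rounded mean). The one-sided Mann–Whitney U (alternative: first sample
stochastically greater) uses exhaustive label enumeration with mid-rank tie
handling when n₁+n₂ ≤ 12, otherwise the tie-corrected normal approximation
with a 0.5 continuity correction; both are exposed because small SE groups
sit on either side of that boundary.

## Target genes and validation

A gene is an SE target when it overlaps the SE or its annotation start
coordinate lies within 100 kb (inclusive) of the nearer boundary, and mean
TPM is strictly greater than 1 — both read literally, giving the two
boundary behaviours (gene at exactly 100,000 bp: associated; TPM exactly
1.0: excluded). The gene *start* is used regardless of strand; TSS-aware
logic exists only in the promoter analyses. The lead gene per SE minimises
the adjusted DE p, with ties broken by larger |log2FC| then gene id; genes
missing from the DE table count as padj = 1 with a warning. Cohort DE is a
vectorised Welch's t-test on log2(TPM+1) with Satterthwaite df; zero-variance
equal-mean genes get t = 0, p = 1. The cell-line DE result is consumed as a
results table (gene, log2FC, p, padj) rather than refit — it comes from a
published negative-binomial estimator whose refitting is out of scope.

Triple validation: (1) cell-line padj < 0.05 and log2FC > 0; (2) cohort
p < 0.05 and log2FC > 0; (3) co-expression ρ > 0 with unadjusted p < 0.05.
The p-threshold on layer 3 is configurable (`coexpr_p_max=None` reduces it
to the sign of ρ, a reading some published tables imply); the synthetic
generator plants couplings that are decisively positive or negative, so its
ground truth is identical under both conventions.

## Co-expression and purity correction

Spearman ρ uses mid-rank ties; p is exact (full rank-permutation
enumeration) below n = 10 and a t-approximation otherwise. The partial
correlation rank-transforms both expression vectors and the purity
estimates, OLS-residualises each expression rank vector on the purity
ranks, and reports the Pearson correlation of the residuals; constant
purity degenerates exactly to ordinary Spearman, and samples without purity
are dropped only in purity-corrected analyses. The random-gene-set null
draws equal-size sets without replacement from the expressed background
(genes with a nonzero value in ≥20% of tumor samples — "expressed" is not
otherwise pinned down, so the threshold is a parameter; the focal gene is
always excluded, and the background is sorted internally so draws depend
only on its content). Three metrics are compared with add-one empirical p:
the count of significant positive correlations (ρ > 0, raw p < 0.05 — the
BH-significant count is reported alongside in the per-gene table), median
ρ, and mean ρ. BH adjustment delegates to statsmodels' step-up
implementation.

## Synthetic data: what it emulates, and what it does not

The generator emits every pipeline input as plain text with a ground-truth
JSON, at desk scale: 3 chromosomes × 2 Mb, ~170 planted consensus contact
peaks (widths 300–600 bp) plus 40 fraction-private noise peaks per
fraction, 29 planted SEs (12–20 kb; 12 cancer-specific / 11
normal-specific / 6 shared) across 3 cancer and 6 normal samples, ~250
genes, and a cohort of 120 tumor + 20 normal samples with purity present
for 110 tumors. These sizes keep the full pipeline plus the 1000-iteration
permutation tests inside a few minutes on one core while leaving every rule
(support thresholds, stitching, windows) with non-trivial work to do.

Planted structure: true contact peaks appear (jittered ≤50 bp) in both
fractions of all three replicates — 20 in exactly two, 10 in only one (and
thus absent from the truth), 5 inside blacklist zones (removed by the
filter); noise peaks are private to a single fraction. SE samples carry
boundary jitter (±500 bp) and occasional fragmentation into two pieces
10 kb apart, exercising the stitch rule; sample-private noise SEs are
placed >12.5 kb from everything so they cannot gain support. Correlation
peaks comprise confirming peaks inside Ψ-designated SEs (on planted
contacts), decoys inside Ω SEs (off contacts — establishing that contact
confirmation, not SE overlap, drives Ψ), promoter-mode peaks at two Ω
targets' TSSs, a background split into contact-overlapping and isolated
peaks, and 49 extra lncRNAs with known SE-overlap counts for the ranking.
Gene placement plants the window boundary cases (starts at exactly 100,000
and 100,001 bp from an unjittered SE; a TPM = 1.0 gene) and per-gene
validation categories. Independently placed features are kept ≥3 kb apart
(wider where the interaction radius demands it), and a generator-internal
check asserts that intended target associations are the only ones, so the
ground truth is exact rather than probabilistic.

Expression follows a latent-factor model on the log2(TPM+1) scale:
`x_gs = base_g + shift_g·tumor_s + β_g·f_s + γ_g·purity_s + ε`, with the
focal lncRNA loading 1 on the latent activity `f`. β ∈ {+0.5, −0.4, 0}
plants decisive co-expression outcomes; γ plants the purity confound; the
cell-line DE table is computed by the generator with Welch + BH on
simulated replicates around planted shifts (±1.5, or ≈0 for the
deliberately non-significant lead). A shared latent factor was chosen over
resampling a real cohort's covariance because it gives closed-form
targets — under the Gaussian copula the planted Spearman is
ρ_s = (6/π)·arcsin(ρ_pearson/2) — for recovery tests.

What passing these tests does *not* show about real data: real contact and
correlation peaks are spatially clustered (CpG islands, gene deserts,
copy-number effects), real SEs have fuzzy, assay-dependent boundaries,
cohort expression has heavy tails and batch structure, and real effect
sizes are far smaller than the planted ones. The synthetic design
demonstrates correctness of the rules and calibration of the nulls under
independence, not power or robustness on any particular real dataset.

## Numerical and testing choices

Calibration of both permutation tests is checked over 200 seeded runs of
99 iterations each on independently generated target/peak/correlation
layers, with the "observed" peak set drawn by the same non-overlapping
placement the null uses (otherwise the null's slight repulsion would bias
the comparison). The empirical p distribution must pass a KS uniformity
test at α = 0.001 — the calibration fixtures use enough intervals (400–1000
targets) that count-statistic discreteness stays well inside the KS band —
and the mean observed count must sit within 3 standard errors of the mean
null mean. Purity-confound checks evaluate the mean over the 20 planted
genes because a single gene's Spearman estimate at n = 500 has a sampling
sd (~0.045) comparable to the ±0.05 band of interest. Interval operations
are verified against a per-base occupancy-bitmap oracle on randomized
instances, and once against the bedtools CLI.

## Known limitations

- The O(n·m) per-chromosome pair scan in fraction reconciliation is sized
  for peak sets up to a few tens of thousands per chromosome; genome-scale
  inputs with millions of records would want an interval tree.
- The shuffle's sequential placement is not exactly uniform over joint
  configurations at high occupancy; dense exclusion sets can trigger the
  retry budget.
- Gene identifiers are taken as-is; cross-nomenclature mapping (e.g.
  Ensembl to HGNC) is accepted only as a pre-resolved table, and unmappable
  genes simply fail the affected validation layer, with a log message.
- The specificity classification uses single-interval overlap (≥1 bp by
  default); a reciprocal-overlap criterion is not implemented.
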