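# Methods

`glycopattern` analyzes label-free glycoproteomic dose-response experiments
of the kind used to study androgen signaling in prostate-cancer cells: an
AR-positive cell line (LNCaP-like) is challenged with a vehicle control and
an ascending androgen series — physiologic doses (0.1, 1.0 nM R1881) that
stimulate proliferation and a supraphysiologic dose (SPA, 10 nM) that
paradoxically represses it — and glycoprotein intensities are quantified per
condition. A parallel tissue cohort (NAT, BPH, localized PCa, metastatic
PCa) supports biomarker triage. This note records the models, parameters,
and numerical conventions the package uses.

## Quantification

**PSM filtering.** Search-engine peptide-spectrum matches are kept when all
four quality scores clear their thresholds simultaneously: forward-reverse
score ≥ 1.2, rank 1–2 score ≥ 2, identification score ≥ 3, scored peak
intensity ≥ 30 %. Comparisons are inclusive (a record exactly at a
threshold is kept); the filter is idempotent and order-preserving.

**Protein rollup.** Protein-level intensity in a sample is the **sum** of
member PSM intensities (mean and median are selectable). Summing conserves
total intensity per sample, which keeps downstream ratios loading-
interpretable.

**Spike-in normalization.** Each sample is scaled by
`reference spike total / sample spike total`, where the spike rows are the
externally added standard (BSA-like) and the reference defaults to the
first sample. This equalizes the recovered amount of a standard added in
known proportion, correcting loading differences. The operation is
invariant under global rescaling, idempotent once the spike is equalized,
and leaves missing values missing (no imputation). A zero or absent spike
total in any sample is an error naming the sample.

**qPCR.** Relative expression uses the comparative-Ct statistic
`2^(−ΔΔCt)` with `ΔΔCt = ΔCt(treated) − ΔCt(vehicle)` and
`ΔCt = Ct(target) − Ct(reference gene)`; the result is invariant under any
constant shift of all four Ct values.

## The ternary pattern framework

At each treated dose a protein either increases, decreases, or stays the
same relative to vehicle, giving `3^3 = 27` theoretical response patterns
for a three-dose series. Patterns are encoded base-3 (down = 0, same = 1,
up = 2; first dose most significant), so `(same, same, same)` is index 13.

**Direction calling.** Digit = up when `intensity / baseline ≥ f`, down
when `≤ 1/f`, same otherwise, with the fold threshold `f` defaulting to 1.5
and boundaries inclusive toward a change. The call is invariant under
positive scaling of the whole profile and antisymmetric under ratio
inversion. Missing values follow a policy: `drop-protein` (default for
pattern statistics), `treat-as-down` (presence/absence semantics for
Venn-style analyses), or `error`.

**SPA association.** The selection targets patterns whose SPA response is
*discordant with both proliferation-stimulating doses* (and hence
concordant with the non-proliferative vehicle state): the SPA digit must
differ from the digit at every physiologic dose. Exactly 12 of the 27
patterns qualify (3 SPA digits × 2 × 2 differing physiologic digits); the
looser reading "SPA digit = same" would select only 4 and is rejected as
inconsistent with the 12-pattern frame. The rule is symmetric under
permutation of the physiologic doses.

**Empirical clustering.** Profiles are log10-transformed (with a pseudo
intensity, default 1), centered, and scaled per protein to unit population
variance; zero-variance profiles map to zero vectors, and proteins with
missing values in the design's samples are excluded (the drop-protein
policy). K-means (k-means++ initialization, best of `n_init = 10` restarts,
`max_iter = 300`, seeded) partitions the standardized profiles with
`k = 27` by default — one slot per theoretical pattern. Each cluster's
representative profile is the per-dose **median of member raw
intensities**, which is then direction-coded with the same fold threshold;
matching on raw-scale medians keeps the threshold interpretable. The
cluster→pattern mapping may be many-to-one; empty clusters are reported
with a warning flag rather than dropped.

## Overrepresentation analysis

For a query set of `n` proteins inside a universe of `N` (by default the
quantified proteins, matching common ORA practice for per-condition
uploads), a term with `K` members in the universe and overlap `k` is scored
by the upper-tail hypergeometric probability `P(X ≥ k)`. Terms with fewer
than `min_term_size = 3` members in the universe are excluded.
Benjamini–Hochberg q-values are computed over the tested terms. Heatmap
export writes `−log10(p)` (base 10, stated in output headers) where
`p < α` (strict, default α = 0.05) and 0 elsewhere, keeping only terms
significant in at least one condition. The tail is monotone non-increasing
in `k`, and under a null annotation collection the empirical type-I rate at
α = 0.05 is calibrated up to hypergeometric discreteness (the test suite
uses term sizes 100–200 in a universe of 2,000, where attained levels sit
close to α).

## Tissue cohort analysis

**Display transform.** Clustergram values are
`min(log10(1 + x / floor), 5)` with missing shown as 0; `floor` defaults to
the table's smallest positive intensity, so the scale reads as decades
above the detection floor and saturates at five. The exact rescaling used
by the original visualization services is not recoverable; any monotone,
capped, zero-anchored transform supports the downstream logic, and this one
is documented. Display and statistics deliberately diverge: missing values
are *shown* as 0 but *excluded* from contrasts to avoid fold-change
inflation.

**Clustering.** Distances are `1 − Pearson r` over pairwise-complete
positions (range [0, 2]); fewer than two complete pairs or zero variance is
an error naming the offending pair, never a silent 0. Agglomeration is
complete linkage (merge height = maximum cross-pair distance, hence
monotone non-decreasing heights), samples fixed and proteins clustered
("supervised" layout), with an option to cluster both axes. Rows constant
on the display scale are dropped before clustering since their correlation
is undefined. Dendrograms export as Newick (heights as branch lengths) plus
a flat merge table.

**Contrasts and triage.** Group contrasts are differences of mean
`log10(x + pseudo)` over quantifying samples, reported with per-group
counts; the contrast is antisymmetric. A candidate biomarker passes when
(1) its cell-line pattern is non-flat (androgen-regulated), (2) its
tumor (PCa ∪ mPCa) vs BPH contrast is ≥ `min_log10_fc` (default 0.5
decades), and (3) optionally the median paired tumor−NAT log10 difference
is positive. Candidates are ranked by the tumor contrast. The thresholded
rule is an explicit formalization of what is, in the original workflow, a
visual inspection of magnified clustergrams.

## Synthetic data

The generators provide inputs with the statistical structure the analysis
assumes, so every stage can be tested against recorded ground truth without
access to raw mass-spectrometry data.

**Dose-response tables.** Protein abundances are log10-normal
(base mean 7.0, sd 1.0), matching the label-free convention and spanning
roughly 1e4–1e10 — the observed intensity range of such experiments. Each
protein draws a ternary pattern (uniform over the 27 by default); treated
intensity is `10^(base + step·effect + ε)` with a one-decade default effect
and `ε ~ N(0, 0.2)`. **Noise is modeled on the dose-response (contrast)
scale:** the vehicle column is the reference level `10^base`, so
`noise_log10_sd` is directly the dispersion of an observed log10 fold
change against vehicle. A per-sample loading distortion
(`loading_log10_sd`, default 0) can multiply every row — including the
spike — giving spike normalization something real to undo; before
distortion the spike row is exactly equal across samples. Missingness is
missing-completely-at-random per condition, with default rates
`1 − count/3341` chosen so expected per-condition presence counts are
1540/1558/1668/1586 of a 3,341-protein union, the summary structure of the
reference experiment; an intensity-dependent dropout option (low-abundance
proteins drop out preferentially) exists but is off by default. One column
per condition is the default layout (replicates optional), reflecting the
single-table-per-condition design of the profiling experiment.

**Annotation collections.** Null terms sample members uniformly from the
universe; enriched terms sample the designated pattern class (default: the
most populous non-flat pattern) with odds multiplied by
`enrichment_factor` (`inf` confines members to the class). With factor 1
enriched and null terms are distributionally identical.

**Tissue cohorts.** Default group sizes 8 NAT / 10 BPH / 4 PCa / 6 mPCa
mirror the reference cohort; `n_markers` tumor-upregulated and equally many
BPH-upregulated markers receive a one-decade (default) group shift, and one
additional *androgen-biphasic tumor-upregulated archetype* — modeled on
ENTPD5's behavior: cell-line profile up at physiologic doses, down at SPA
(`up/up/down`), tumor-elevated in tissue — is always planted. NAT samples
pair with tumor samples of the same simulated case.

**What the simulator does not emulate.** Peptide-level structure and
shared-peptide rollup ambiguity, correlated noise across proteins
(co-regulation, batch effects), non-normal heavy-tailed intensity error,
informative missingness (by default), replicate variance structure, and
annotation term overlap/hierarchy. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not performance guarantees on real tissue data.

## Validation problem sizes and tolerances

The test and acceptance suites run, per seed, 2,000-protein dose-response
simulations (5 seeds) with effect 1.0 and noise 0.2 — conditions under
which direction coding at the calibrated fold band `10^(effect/2)` recovers
≥ 90 % of planted codes and ≥ 90 % of pure planted clusters match their
theoretical pattern; 1,000 null enrichment terms for type-I calibration
(3 binomial SEs of α); 100 six-item brute-force complete-linkage
agglomerations (exact to 1e-12); 100 random normalization-invariance trials
(relative error ≤ 1e-9); and 20 tissue-cohort seeds at 0.5-decade
threshold (sensitivity ≥ 0.9, false-discovery proportion ≤ 0.1, archetype
passing in ≥ 18/20). Direction-call boundaries are exact arithmetic
comparisons; BH q-values and hypergeometric tails delegate to statsmodels
and scipy respectively.

## Known limitations

The fold threshold for "unchanged" is a free parameter with no universally
correct value; 1.5 is a common label-free convention, and analyses of noisy
data should calibrate it to the observed contrast dispersion (the
simulation studies use `10^(effect/2)`). Direction coding treats doses
independently and ignores trend information across the series. K-means with
k = 27 can split or merge pattern classes when effects are weak relative to
noise; cluster-median matching mitigates but does not eliminate this. The
hypergeometric test is conservative for small terms due to discreteness.
The candidate-biomarker rule is a screening heuristic, not an inferential
procedure — it reports no error control on real cohorts.
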