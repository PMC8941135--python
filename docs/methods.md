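# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Identification

A feature is a (m/z, RT, polarity) triple with per-sample ion counts.
Candidate matches are (compound, adduct) pairs of matching polarity;
the default adduct set is [M+H]⁺ and [M−H]⁻ derived from the neutral
monoisotopic mass with a proton mass of 1.007276 Da (other adducts can
be supplied as explicit library entries).

The gate is `(ppm ≤ 5 OR Da ≤ 0.001) AND ΔRT ≤ 0.5 min`, every
tolerance inclusive. The OR'd Da branch matters below m/z ≈ 200, where
a fixed 0.001 Da window is wider than 5 ppm. Among gate-passing
candidates the winner has the lowest ppm error, ties broken by RT
delta, then lexical name — fully deterministic.

MS/MS similarity is a greedy cosine: fragment pairs within 0.01 Da are
matched closest-first, each fragment used at most once, intensities
enter as square roots. The score is symmetric and equals 1 for
identical spectra; an empty spectrum yields *absent* similarity, never
0. The threshold (default 0.7) separates match from mismatch; a
mismatch invalidates the identification outright rather than falling
through to the next candidate, which preserves a useful monotonicity:
adding a mismatching reference spectrum to a library can only remove
identifications, never create one. The cosine metric and threshold are
design choices — a widely used, reproducible default — not an attempt
to reconstruct any particular vendor pipeline. Scores: 0 = no gate,
1 = mass gate only, 2 = mass + RT (MSI level 1), 3 = mass + RT + MS/MS.

## Differential abundance

Two-group Kruskal-Wallis is used deliberately even though a
Wilcoxon rank-sum is equivalent up to the χ²₁ reference: it is the
test named throughout the field's workflows. The asymptotic mode uses
the tie-corrected H statistic against χ² with 1 df; an all-tied input
returns p = 1 by contract. The exact mode enumerates all
C(n₁+n₂, n₁) group assignments and reports the proportion with
H ≥ H_obs (within 1e-12); it refuses combined n > 12, where
enumeration stops being sensible.

With n = 4 vs 4 the asymptotic p for complete separation is 0.0209
and the exact floor is 2/70 ≈ 0.0286. Two consequences worth knowing:

- At these sample sizes the asymptotic p-spectrum is discrete; BH-FDR
  across a family of m metabolites keeps complete-separation hits
  under q ≤ 0.05 only when at least ~42% of the family is
  significant (0.0209·m/k ≤ 0.05 ⟺ k/m ≥ 0.418).
- Consequently the family definition matters. The pipeline tests, per
  feeding direction, only the metabolites established as exuded by
  that direction's donor — the donor's exometabolome — not every
  feature on the platform. Metabolites that are blank-level in the
  donor's spent medium carry no information about that direction and
  only dilute the family.

LFC uses group means with pseudocount ε = 1 ion count: negligible
against real signals (≥10⁵ counts) yet it keeps complete depletions
finite (a 10³-count metabolite dropping to all-zero gives ≈ −10, not
−∞). Calls: depleted ⇔ q ≤ α and LFC < 0; exuded ⇔ q ≤ α and
LFC > 0; otherwise unchanged. `depletion_percent_from_lfc` converts a
non-positive LFC to 100×(1−2^LFC) percent consumed.

The growth-synergy test pairs replicate dry weights of the two
organisms grown alone by index, forms the sums, and compares them with
co-culture weights by the same Kruskal-Wallis; BH-FDR is applied
across the panel of conditions (e.g. pH levels) tested together.

## Exudation and the exchange map

No community standard exists for calling a metabolite "exuded" against
a medium blank; the rule here is mean_spent ≥ k·max(mean_blank, 1) with
k = 3, plus detection (count > 0) in ≥ 3 of 4 replicates, both
configurable and recorded in the run log. An exchange edge
donor → recipient requires both the donor's exudation call and a
depleted call in that direction, which makes the edge set monotone in
α. Reciprocal edges (both organisms exchanging the same compound) are
flagged, not resolved — both directions can be genuinely active. MSI
induction calls for the same metabolite name set a corroboration flag.

## MSI statistics

Ion images are dense per-channel grids with named boolean region masks
(two colonies, the interaction zone between them, an agar control);
pixel size (default 200 µm) converts transect positions to µm. Region
means are plain arithmetic means over the mask. TIC normalization
(per-pixel division by the cross-channel total) is available but off by
default — induction ratios compare raw ion images. The induction call
is region_mean(co)/max(region_mean(mono), 10⁻⁹) ≥ 2.0 by default; a
blank mono-culture region with positive co-culture signal reports a
capped ratio (10⁶) with an explicit zero-denominator flag. The
threshold is a reporting convention, always printed next to the raw
ratio.

## Gene-set response

Per-gene LFC is log₂ of condition-mean ratios with pseudocount 1
(inputs are assumed pre-normalized abundances; a counts-per-million
transform can be applied upstream). Set response is the mean and
sample sd (n−1) over member genes present, with missing members
counted. Enrichment is a competitive test: set LFCs vs all non-set
LFCs by Kruskal-Wallis, BH-FDR across all sets tested together; a set
equal to the background is degenerate (p = 1, warned).

Competitive testing assumes the background is predominantly
unshifted. If a large fraction of the transcriptome belongs to shifted
sets, a genuinely null set ranks systematically above the background
and is — correctly, by the test's semantics — called significant. The
pipeline's default synthetic scenario therefore keeps annotated shifts
under ~3% of a 4000-gene background. Per-gene and per-set outputs are
both emitted, since figures in this field annotate significance at
either level.

## Synthetic data: what it emulates, and what it does not

The cross-feeding generator draws ion counts log-normally with the
requested arithmetic mean and coefficient of variation (multiplicative
noise was chosen over Gaussian because ion counts are positive and
their spread scales with the mean); noise_cv = 0 reproduces the means
exactly, and everything is bit-reproducible under a fixed seed. The
default study conditions mirror a two-organism, four-replicate design:
15 metabolites per donor spanning six chemical classes — 8 depleted at
fractions {0.85, 0.98}, 3 exuded at 4-fold, 4 null — i.e. 53% of each
donor's exometabolome consumed by the partner, with base intensities
log-uniform over 10⁵–10⁸ counts and a 10³-count blank. Decoy library
entries sit at controllable m/z and RT offsets from true compounds so
each identification gate can be probed independently. MSI scenes place
each channel's base level in its source region with exponential decay
of configurable length and additive Gaussian noise (sd = 0.1 × base by
default, clipped at zero); co-culture multiplies the source level by
the planted induction ratio. Expression matrices shift set members'
log₂ means by the planted LFC in the second condition with Gaussian
log-scale dispersion (default 0.2).

Not emulated: chromatographic drift and batch effects, isotope
envelopes and adduct interference, RT alignment errors, spatial
registration errors in MSI, and library-size/compositional artifacts
in expression data. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated noise model, not robustness
to instrument-level artifacts.

## Numerical and degenerate-input choices

- All-tied Kruskal-Wallis inputs return p = 1 (scipy raises; wrapped).
- Asymptotic p is floored at the smallest positive float so extreme H
  (thousands of observations) cannot underflow to 0 and violate the
  p ∈ (0, 1] contract of the BH step.
- Exact-test comparisons use H ≥ H_obs − 1e-12 to absorb rank
  arithmetic round-off.
- Feature tables reject negative or non-finite values at construction,
  naming the offending feature and sample; missing intensities on read
  become 0 with a logged count.
- Problem sizes in the test suite — 200-metabolite null experiments
  (×200 seeds), 100-simulation recovery runs, 50-seed MSI recovery —
  were chosen as the smallest sizes at which the binomial/Monte-Carlo
  margins of the claims being checked are comfortably resolved.

## Known limitations

- The exact Kruskal-Wallis is limited to combined n ≤ 12.
- Identification considers protonated/deprotonated species only unless
  the library enumerates further adducts; no isotope-pattern scoring.
- Exudation calls depend on a fold-over-blank heuristic; with very low
  blank variance the k = 3 threshold is conservative.
- The MGF reader takes retention time values as given (the format does
  not carry units); MSP with minutes is the primary library format.
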