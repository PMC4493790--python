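# Methods

## The dosage model

A qPCR-RBIP marker interrogates one insertion site of an LTR
retrotransposon with two TaqMan reactions: a *presence* assay anchored in
the element's LTR and an *absence* assay spanning the empty site. If a
sample carries d presence alleles and 10−d absence alleles (dosage
expressed out of 10, since true allele counts in a polyploid are unknown),
and both reactions amplify with the same per-cycle fold efficiency E, the
presence template is d/(10−d) times the absence template, so

    Ct_absent − Ct_present = log_E( d / (10−d) ).

Inverting, the pipeline estimates R = Ē^(Ct_absent − Ct_present) and maps
it to presence = 10R/(1+R). This mapping is the unique choice that (a)
keeps scores in [0,10] with presence+absence = 10, and (b) is consistent
with the one-sided edge rule (an assay that never amplifies while its
converse does scores 0, i.e. the converse scores 10, the limit R→0 or ∞).
Ē pools the accepted reactions of *both* assays of the same sample×locus —
not the whole plate — because the ratio's exponent mixes both assays' Cts.

Assumptions: equal efficiency for the two assays of a locus (enforced
approximately by the 90–110% QC band), no cross-reactivity, and enough
template that Poisson sampling of the template itself is negligible.

## Efficiency and Ct from raw curves (window of linearity)

Per well: baseline = mean fluorescence of cycles 3..`ground_cycles`
(default 10; cycles 1–2 excluded as common instrument settling artifacts).
After subtraction, log10 fluorescence vs cycle is fitted in every
contiguous window of 4–6 cycles with positive slope; the window maximising
R² wins, with ties broken by larger slope, then earlier start, then longer
window (full determinism; the last tie-break only matters on exactly
degenerate fits). Efficiency is E = 10^slope, reported as
percent = (E−1)·100, so the 90–110% QC band is fold 1.90–2.10.

A well counts as *amplified* only when (a) a positive-slope window exists,
(b) its R² ≥ 0.99, and (c) the corrected signal reaches `min_signal`
(default 0.5 corrected-fluorescence units, half the default Ct threshold).
Guard (c) is this package's own addition: a flat noise-only well can by
chance present four nearly collinear positive log-points, and the
no-template wells of the d=0 / d=10 edge cases must classify reliably.

Ct is the fractional cycle where corrected fluorescence first crosses the
threshold, interpolating log-linearly between the bracketing cycles (exact
under exponential growth). The default threshold of 1.0 corrected units is
configurable; 0.5/1.0/1.5 all sit inside the exponential phase of the
default synthetic curves, and scores are insensitive to the choice (the
threshold-sensitivity study measures this). A crossing already present at
cycle 1 cannot be bracketed and is flagged unreliable.

## Replicate QC

Per assay: drop non-amplified wells and wells outside the efficiency band
(boundary comparisons carry a 1e-9 tolerance so float representation dust
cannot flip a well sitting exactly on 90 or 110); fewer than `min_valid`
(default 3) survivors ⇒ repeat. Across assays: repeat only when one
assay's Ct spread (max−min of accepted wells) exceeds 0.5 cycles AND the
two assays' summed spreads exceed 0.75 — a conjunction, so a single
moderately wide assay does not kill an otherwise clean call. `repeat_needed`
is terminal in software (re-running is a lab act) and is always reported,
never silently dropped. When both assays fail entirely the call is
`inconclusive`; the corresponding lab follow-up (a microsatellite template
control) is out of computational scope and surfaced as that status.

Scores are rounded to one decimal place at call time (the precision at
which such scores are tabulated); the unrounded mapping is exposed as
`presence_fraction` for anyone needing strict monotonicity.

## Profiles, Nei–Li distance, UPGMA, bootstrap

A profile (presence scores over a locus panel) is encoded as a cumulative
"band ladder": with bin width w (default 1, configurable), locus indicator
i is 1 iff score ≥ i·w. This ordinal encoding lets nearly identical
profiles sit at small but nonzero Dice distances, the behaviour replicate
re-runs show in practice; a plain present/absent bit per locus cannot.
Loci whose call is missing (inconclusive / repeat) form all-zero blocks
flagged absent and are excluded pairwise from distances. A profile with no
scored locus, or zero bands everywhere, has an undefined Dice similarity
against its like; such samples are excluded from clustering and reported
(`filter_informative`).

Nei–Li distance D = 1 − 2n_ab/(n_a+n_b) is a semimetric: symmetric, zero
iff encodings agree, but the triangle inequality is NOT guaranteed (a known
property of Dice-based distances) — UPGMA does not require it. UPGMA merges
the closest pair at height d/2 with size-weighted average linkage;
ties break on the lowest (row, column) index pair for exact
reproducibility. Bootstrap support resamples loci with replacement,
re-encodes, re-clusters, and counts how often each non-trivial clade of the
full-data tree recurs (Felsenstein-style clade counting; the resampling
unit is the locus because loci are the exchangeable observations here).
The root clade carries no support; a single-locus panel yields none.

## LTR insertion dating

The two LTRs of an element are identical at insertion and diverge
neutrally, so their Kimura two-parameter distance
k = −½ln(1−2P−Q) − ¼ln(1−2Q) (P transitions, Q transversions over gap-free,
unambiguous columns — the two-sequence analogue of complete deletion)
converts to age via T = k/(2r); the 2 because substitutions accrue on both
copies. Default r = 1.3×10⁻⁸ substitutions/site/year, a standard grass
nuclear rate; configurable. Saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raises an
explicit error rather than clamping. Unaligned pairs are globally aligned
(Needleman–Wunsch, affine gaps; defaults match +1 / mismatch −1 / open −5
/ extend −1, configurable).

Small-divergence caveat: at T = 0.3 mya and a 400-bp LTR only ~3
substitutions are expected, so a single element's age estimate is
dominated by binomial noise (the recovery test asserts only that the
median over 200 simulated elements lands in [0.15, 0.45] mya). Ages of
individual young elements should be read as order-of-magnitude.

## The synthetic generator

Each well's curve is logistic: F(c) = baseline + plateau/(1+e^{−(c−c_mid)/s})
with s = 1/ln(E), whose early phase grows exactly E-fold per cycle; c_mid
is solved so the corrected signal crosses 1.0 at the target Ct. Defaults:
baseline 3, plateau 1000, 40 cycles, base Ct 24, E = 2.0, 5 replicates —
chosen so the exponential phase offers ≥8 usable cycles well above the
noise floor and well below the inflection, and so the 0.5–1.5 threshold
range sits inside it. Noise has three independent knobs: per-well Ct jitter
(sd 0.15 cycles), per-well efficiency jitter (sd 2 percentage points) —
the replicate variability the QC rules police — and multiplicative
fluorescence noise (sd 1% of the reading), a typical optical noise level
that exercises the window search; `noiseless()` clears all three.
`template_scale` shifts both assays' Cts by −log_E(scale) (scores must be
invariant); `plate_offset_ct` shifts the presence assay only, emulating a
systematic cross-plate/machine offset — an offset common to both assays
would cancel exactly in the ratio and emulate nothing. d = 0 or 10 makes
the corresponding assay flat baseline noise.

What the generator does not emulate: probe chemistry differences between
assays, drifting baselines, pipetting-volume correlations across a plate,
inhibitor effects, or machine-specific optics beyond the constant offset.
Passing the closed-loop tests therefore shows the estimator inverts the
stated model under realistic replicate noise — not that every real
instrument artifact is handled.

The LTR simulator draws a random ancestor and mutates each copy
independently with per-site probability r·T; a substitution is a
transition with probability titv/(1+titv) (default titv = 2, a typical
plant nuclear value), otherwise one of the two transversions uniformly.

## Problem sizes and determinism

The validation studies run 200 plates × 9 dosage levels for recovery, 50
plates (25 duplicate pairs) for cross-plate reproducibility — differences
are computed within duplicate pairs, matching how plates are re-run in
pairs — and 10 plates × 3 thresholds for threshold sensitivity; these sizes
put Monte-Carlo error well below the tolerances being asserted. All
randomness flows through seeded numpy Generators: identical scenario + seed
gives bit-identical plates, and bootstrap support is deterministic given
its seed.

## Known limitations

- Dosage is relative by design; converting scores to absolute copy numbers
  would require genome size or standard curves, deliberately out of scope.
- The QC spread gate flags a substantial fraction of plates at Ct sd 0.15;
  that is the intended behaviour of the published thresholds, not a
  software tuning target.
- The band-ladder encoding is one defensible choice for ordinal dosage
  data; distances (not tree heights' ordering robustness) depend on bin
  width, which is exposed as a parameter.
- Only exported long-format tables are read; instrument binary formats and
  dye deconvolution/normalisation are out of scope.
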