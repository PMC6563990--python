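# Methods

## Setting and model

A paired BS/oxBS 450k experiment yields, for each probe (CpG) and sample,
four non-negative fluorescence intensities: methylated and unmethylated
channels under plain bisulfite conversion (`M_BS`, `U_BS`) and under
oxidative bisulfite conversion (`M_oxBS`, `U_oxBS`). The BS arm reads
5mC + 5hmC as methylated; the oxBS arm reads 5mC only. All screening
measures are deterministic per-entry functions of these four numbers;
nothing is fitted. The package therefore exposes plain functions over
container objects (panel → measure matrix → call matrix → summaries)
rather than a model/fit/results interface.

Probe and sample identifiers are opaque; genomic annotation, IDAT parsing
and channel normalisation are out of scope — the expected input is the
matrix export of a raw-preprocessing pipeline.

## Measures and their domains

| measure | definition | defined when | positive iff |
|---|---|---|---|
| β(α) | M/(M+U+α) | M+U+α > 0 | M > 0 |
| Δβ(α) | β_BS(α) − β_oxBS(α) | both β defined | M_BS(U_oxBS+α) > M_oxBS(U_BS+α) |
| Δm(α) | log2(M_BS/(U_BS+α)) − log2(M_oxBS/(U_oxBS+α)) | M > 0 both arms, U+α > 0 | same as Δβ(α) |
| Δm∞ | log2(M_BS/M_oxBS) | M > 0 both arms | M_BS > M_oxBS |
| Δh | 1 − T_oxBS/T_BS (T = M+U) | T_BS > 0 | T_BS > T_oxBS |
| naive 5hmC | max(0, Δβ(0)) | as Δβ(0) | Δβ(0) > 0 |

Two conventions deserve a note:

- **Δm(α) offset on the unmethylated channel only.** The common M-value
  convention puts the offset in numerator and denominator; here it is
  applied to `U` alone. This is the unique form under which
  Δm(α) → Δm∞ as α → ∞ and under which sign(Δm(α)) = sign(Δβ(α)) is an
  algebraic identity (both reduce to the sign of
  `M_BS(U_oxBS+α) − M_oxBS(U_BS+α)`); both properties are enforced by
  oracle tests.
- **α = 0 is admitted** although the proportion form is usually stated for
  α > 0: it is needed for the naive estimate that mirrors what the
  beta-distribution maximum-likelihood procedures (oxBS-MLE/OxyBS) flag.
  Degenerate 0/0 entries are masked.

Negative Δh values (oxBS total above BS total) are interpreted as
measurement noise. They are *retained* with a `noise_flag` rather than
deleted so that prevalence denominators equal the number of defined
entries, keeping "percentage of CpGs with Δh > 0" comparable across
measures.

## Masking

One mask convention runs through the package: `mask == True` means
valid/defined. Cells that are negative, non-numeric or missing on input are
masked at read time (with logged counts) rather than aborting, matching the
practice of excluding probes that exhibit measurement error; undefined
denominators downstream extend the mask. Every operation propagates masks
by logical AND, and every ratio statistic uses only (jointly-)unmasked
entries in numerator and denominator.

## Sensitivity to the offset α

Because the zero condition of Δβ(α) is linear in α, each probe has at most
one sign change on α ∈ (0, ∞), at

    α* = (M_oxBS·T_BS − M_BS·T_oxBS) / (M_BS − M_oxBS)   when α* > 0.

"May change its sign" is operationalised as: a finite α* exists in
(0, α_max]. α_max is a required, logged parameter because the alternative
reading (any finite crossing, reachable or not) is also defensible; both
are available (`alpha_max=inf`). The default scan grid is
{0, 100, 500, 2000}, extended log-uniformly when α_max exceeds 2000 —
the values conventionally displayed for this diagnostic.

Large-α facts verified by the diagnostics: Δβ(α) → 0 with
α·Δβ(α) → M_BS − M_oxBS; Δm(α) → Δm∞; and the positive call set
{Δβ(α) > 0} equals {M_BS > M_oxBS} once α exceeds every finite α* in the
panel. The finite-α tolerances used in the test suite come from the exact
error expansion: the relative error of α·Δβ(α) is
`((M_BS·U_oxBS − M_oxBS·U_BS)/(M_BS − M_oxBS) + T_BS + T_oxBS)/α + O(α⁻²)`,
and `Δm(α) − Δm∞ = log2((U_oxBS+α)/(U_BS+α))`, bounded by
`|U_oxBS − U_BS|/(α·ln 2)`. The oracle fixtures for these checks therefore
draw unmethylated intensities in a narrow band and keep a floor on
|M_BS − M_oxBS| so the asserted bounds (1% and 1e-4 at α = 10⁶) follow
analytically; realistic intensity scales satisfy the same laws at larger α.

## Screening summaries

A call is positive iff the measure value is *strictly* greater than the
threshold (default 0; exact zeros are non-positive, matching the indicator
partition into x > 0 and x ≤ 0). Prevalence is reported per sample (fraction
of the array flagged) or per CpG (the hydroxymethylation level across
samples). Joint prevalence uses jointly-unmasked denominators so it is
bounded by the marginals on the same entries. The "substantially
hydroxymethylated" rule is inclusive: per-CpG prevalence ≥ 75% (so 3 of 4
qualifies).

Tissue comparisons use the two-sided Wilcoxon signed-rank test on matched
units (Mann–Whitney when unpaired) with Benjamini–Hochberg adjustment
available across a family of comparisons; the choice is a package decision
— the underlying analysis tradition does not name its tests — and is logged
and swappable. With fewer than 3 informative (non-zero-difference) pairs no
p-value is reported.

## Concordance without a gold standard

For a measure pair over one unit with n jointly-unmasked entries, a
jointly-positive, d jointly-non-positive:

    S  = (a + d)/n ∈ [0, 1]       SH = 2S − 1 ∈ [−1, 1]
    SE_r(x1|x2) = P(x1>0 | x2>0)  SP_r(x1|x2) = P(x1≤0 | x2≤0)
    FDR_r(x1|x2) = 1 − SE_r(x2|x1)

All probabilities are empirical proportions. S is flagged as degenerate on
units where it is positive purely through shared negatives (a = 0), the
situation in which it misleads and SH should be consulted. Units with an
empty conditioning event yield NaN and are excluded from expectations.

Expectations over units come in two flavours, reported side by side because
the distributional construction behind the published expectation values is
not printed in the main text of the source analyses:

- `empirical_mean`: the mean of unit-wise coefficients;
- `independence_null`: fix each unit's marginal positive counts a, b and
  place calls independently at random, giving
  E[S] = (ab + (n−a)(n−b))/n² per unit (verified against exhaustive
  enumeration), averaged over units.

Under either method E[SH] = 2E[S] − 1 holds exactly, and the FDR/SE identity
holds unit-wise and in expectation; these identities are what the test
suite checks against the published concordance tables, since the original
38-pair colorectal dataset is not bundled.

Coefficients are defined per CpG across samples but are also reported per
sample across probes; the axis is part of every output table's metadata.

## Synthetic data generator

Per probe, true proportions p5mC ~ Beta(0.8, 0.8) (broad, mimicking the
bimodal methylation landscape) and p5hmC ~ Beta(1.5, 30) (mean ≈ 4.8%,
matching low somatic-tissue 5hmC) are drawn subject to p5mC + p5hmC ≤ 1 by
resampling (bounded; persistent infeasibility is fatal). Intensities are

    M_BS   = D·(p5mC+p5hmC)·ε + b        U_BS   = D·(1−p5mC−p5hmC)·ε + b
    M_oxBS = D·(1−γ·p5hmC)·p5mC·ε + b    U_oxBS = D·(1−γ·p5hmC)·(1−p5mC)·ε + b

with D log-normal per probe×sample (ln-scale mean 8, sd 0.5; median ≈ 3000
fluorescence units), independent unit-mean log-normal noises ε of CV
`noise_cv` (default 0.10), additive background b (default 100), and oxBS
attenuation γ (default 0.3) operationalising the assumption that a
substantial 5hmC level depresses the total oxBS intensity — γ = 0 is the
documented world in which Δh carries no signal. The cancer arm multiplies
p5hmC by `cancer_depletion` (default 0.5). Defaults use 10,000 probes and
38 matched samples, the size of the motivating paired colorectal study
scaled to desk runtimes in the probe dimension.

Closed forms used in tests: with b = 0 and no noise, Δh = γ·p5hmC exactly
and p5hmC = 0 forces M_BS = M_oxBS. With noise, the per-probe mean of Δh
is a consistent but slightly biased estimator of γ·p5hmC (the bias
−E[(1−γ·p5hmC)](E[1/T̃_BS·T̃_oxBS]−1) ≈ −(1−γp)·CV² ≈ −0.003 at CV = 0.05);
the Monte-Carlo recovery test asserts the across-probe bias within ±0.02,
not a per-probe worst case, whose expected magnitude (≈ 3–4 standard errors
of 0.01 over thousands of probes) exceeds that band for any implementation.

The generator does **not** emulate Infinium I/II chemistry differences, dye
bias, batch effects, spatial artefacts, or probe cross-reactivity. Passing
tests therefore demonstrate correctness of the measures and comparison
machinery under the stated signal model, not robustness to those real-data
artefacts — which is precisely why the upstream normalisation layer is out
of scope.

The counterexample constructions (`figure_demo_points`) generate points
where the Δβ(100) flag contradicts the intuitive intensity comparison:
`fig1` (both BS intensities lower, yet Δβ(100) > 0) and `fig2` (mirror
case, Δβ(100) < 0) pick a methylated-intensity ratio r ∈ (1.02, 1.15) and
shift the unmethylated channel past the proportion-equality point
`U' = r·(U+100) − 100`; `fig3` achieves Δβ(100) = 0 *exactly* by doubling
the BS point (a power-of-two scale factor keeps the float quotients
bit-identical). Each point is re-verified against its defining inequalities
before return.

## Numerical choices

- Critical offsets: the closed form is used directly (one subtraction and
  one division); tests cross-check against Brent root-finding at 1e-8
  relative tolerance and verify |Δβ(α*)| < 1e-10.
- Output tables serialise floats at full precision (repr), so write/read
  round-trips are lossless; "NA" is the sole missing token on output, with
  "NA"/"NaN"/empty accepted on input.
- Ties: exact zeros are never positive calls; Wilcoxon uses the
  zero-difference-discarding convention, with the informative-pair count
  reported.
- Degenerate inputs: all-zero intensity probes are masked (proportions) or
  flagged degenerate (critical offset); units with no unmasked entries are
  omitted from summaries with a logged warning, never silently zeroed.

## Problem sizes

The default test-suite and acceptance-script runs use 10,000 probes × 38
samples per arm (simulation), 10,000-probe oracle populations for the sign
law, and 1,000-probe populations for the root-finding and limit-law checks
— sizes chosen to estimate the relevant proportions to well under the
asserted tolerances while keeping a full run in seconds.

## Known limitations

- The published expectation values for the concordance coefficients on the
  38-pair colorectal dataset can only be reproduced up to the exact
  identities (SH = 2S − 1, FDR_r = 1 − SE_r) without downloading that
  dataset; the package verifies the identities on the printed values and
  computes fresh expectations on synthetic panels.
- The beta-distribution maximum-likelihood 5hmC estimators themselves
  (oxBS-MLE, OxyBS) are not implemented; only their screening-equivalent
  naive surrogate max(0, Δβ(0)) is.
- Kernel-density summaries of Δβ(α) are not produced; the α scan emits
  summary diagnostics instead.
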