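# Methods

`alliumcw` analyzes four measurement modalities of onion (*Allium cepa*)
epidermis along the developmental axis given by the bulb's concentric
scales — layers S1 (oldest, outer) to S6 (youngest, inner), each split
into basal (B), middle (M) and upper (U) zones. This note documents the
models, the defaults and their rationale, the synthetic world the tests
run in, and the known limitations.

## Proportional constant growth (morpho)

**Model.** Two zones of a layer satisfy proportional constant growth
when their cell-area distributions differ only by a constant
multiplicative factor: `area_M =d c · area_B`. The test multiplies every
source-zone area by `c` and compares the rescaled sample with the target
zone via a two-sample, two-sided Kolmogorov–Smirnov test. Failing to
reject supports scale-only growth; rejecting indicates a shape change
(e.g. a different dispersion of log areas) that no constant factor can
explain.

**Factor estimation.** `c = median(target) / median(source)`. Medians
are robust to the heavy right tails typical of cell-area data and
compose exactly across zones (`c_BM · c_MU = c_BU`). The convention is
always target-over-source, so both expanding (B→M) and shrinking (M→U,
expressed as U→M) comparisons use a factor > 1; no signed factors exist.

**Numerical choices.** KS p-values are exact below a combined n of 50
and asymptotic above; quantiles use linear interpolation (type 7) so
IQRs are bit-reproducible. The KS test is scale-equivariant: multiplying
every area by any k > 0 leaves D and p unchanged.

**Calibration caveat.** When the factor is *estimated from the same
sample*, the KS test becomes conservative (measured size ≈ 0.5% at
n = 150/zone instead of the nominal 5%), because matching medians pulls
the two empirical distributions together. With the true constructing
factor supplied, the size is ≈ 3.7% (1000-seed simulation). Calibration
tests therefore supply the factor; routine use estimates it and errs on
the side of not rejecting.

**Group tests.** Kruskal–Wallis with Dunn's post-hoc z-tests
(tie-corrected, Bonferroni-adjusted — no adjustment convention is
standard, Bonferroni is the most conservative common one) for zone
comparisons; Welch's unpaired t-test for two-group biochemical
comparisons. Two constant groups compare to p = 1 when equal and p = 0
when different, rather than raising.

## FTIR band integrals (ftir)

Spectra on the 800–1800 cm⁻¹ fingerprint grid are (1) baseline-corrected
by subtracting the straight line through the trace's values at the
window endpoints, then (2) area-normalized by the trapezoidal integral
over the window, in that order (correcting first makes the unit-area
property hold for the signal rather than signal-plus-offset). Features
are trapezoidal integrals over eleven canonical cell-wall bands (pectin
ring 840–880 through esterified pectin carboxyls 1720–1760), with linear
interpolation where bounds fall off-grid; intervals are closed.

Interval discovery runs a Welch t-test between every pair of layers at
every grid point; a point is significant when any pair has p ≤ α
(exploratory any-pair rule, deliberately without multiplicity correction
across wavenumbers — with 3 layers and α = 0.05 the per-point family
error is ≈ 0.13). Maximal significant runs spanning strictly more than
`min_width` (default 16 cm⁻¹, two points at 8 cm⁻¹ resolution) become
intervals, suppressing singleton noise.

## Pfaffl relative expression (qpcr)

`ratio = E_t^ΔCq_t / E_ref^ΔCq_ref`, with `ΔCq = Cq(calibrator) −
Cq(sample)` and E the per-gene amplification efficiency (fold per cycle,
in (1, 2]; default 2.0 when no standard curve is supplied; converted
from curve slopes by `E = 10^(−1/slope)`). Replicate Cq values are
arithmetically averaged within (gene, onion, layer) before the ratio —
a geometric mean on the concentration scale. The calibrator layer
defaults to S1 so ratios read as fold change versus the oldest layer.
With all E = 2 the method reduces exactly to 2^(−ΔΔCq); a constant Cq
shift within an onion cancels.

## Layer classification (mlclass)

A fixed registry of seven classifiers (logistic regression, RBF SVM
C = 1, 5-NN, decision tree, 100-tree random forest, 100-stage gradient
boosting, one-hidden-layer 100-unit MLP; scale-sensitive models are
standardized) is evaluated on a single stratified 70/30 split — per
class, round(0.7 n) samples train, the remainder test — matching common
practice for small spectroscopic tables; no cross-validation or
hyperparameter search by design.

Report-level CA is the fraction of correctly classified test samples
(confusion-matrix trace over total); the binary formula
`(TP+TN)/(TP+TN+FP+FN)` is exposed separately and agrees in the
two-class case. Precision is `TP/(TP+FP)` per class one-vs-rest,
reported both macro- and support-weighted. Confusion matrices are
row-normalized percentages (rows = true).

Feature importance is permutation importance (mean accuracy drop over
`n_repeats` shuffles, clipped at 0, normalized to unit sum over positive
drops) — model-agnostic and defined for every registry member.
*Limitation:* on very small samples the accuracy drops are coarse
multiples of 1/n, so for some models (notably kNN) a single noise
feature can absorb the whole share under the null; the SVM does not
show this pathology and is the model whose importances should be
interpreted.

## Bootstrap correlation of unpaired samples (bootcorr)

Biochemistry and expression are measured on different onions; both share
the (S1, S2, S6) layer structure. Each onion's triple is standardized to
mean 0, sample sd 1 (within-onion normalization), removing level
differences between onions. Per bootstrap replicate, `m = min(n_bio,
n_expr)` triple pairs are drawn with replacement from the two sets and
their layer-matched values pooled into 3m (x, y) points; Pearson r is
computed per replicate. After R replicates (default 2000, minimum 100)
the result is the mean r, the 2.5/97.5 percentile interval, and the
two-sided sign p-value `2·min(P(r* ≤ 0), P(r* ≥ 0))`.

Design choices: pooling 3m points per replicate (a single triple pair
would give |r| ≈ 1 almost surely); normalizing *both* sides, which makes
the estimate invariant to which onions are paired (normalizing only
expression is available via `normalize_biochem=False`); percentile CIs;
constant triples are excluded with a warning, never imputed. Pairs with
|mean r| strictly above 0.8 are flagged strong. The pairing bootstrap is
not an exact inference procedure; under independence its 95% CI covers
0 at roughly nominal rate (≥ 90% verified by simulation), but no
exactness is claimed.

## The synthetic world (synthgen)

The generator states a world in which every downstream stage's ground
truth is known:

- **Cell areas** are lognormal. The M-zone medians default to reported
  values for S1–S6 (26750.2, 17932.3, 17547.0, 8636.9, 6511.7,
  1540.1 µm²); B and U are the M distribution scaled by 1/c_BM and
  1/c_UM (defaults 2.0 and 1.5 — the factor magnitudes are free
  choices of plausible size), so the proportional-growth null is *exactly*
  true. The shape σ defaults to 0.6 (right-skewed, IQR comparable to the
  median, as real cell-area histograms show); calibration simulations
  use σ = 0.2, the widest shape at which a median-ratio estimate can sit
  within ±5% of truth in ≥ 90% of samples at n = 150–200.
- **Spectra** are sums of Gaussian bands centred on the 11 canonical
  intervals (width = interval width / 6), amplitudes ordered across
  layers (cellulose-type bands decrease toward S6, pectin-ester and
  aromatic bands increase), plus a random linear + half-cosine baseline
  (amplitude 0.05) and iid noise (sd 0.01, ≈ 1–2% of peak height).
- **Biochemistry** uses reported α-cellulose means (495.9/431.2/349.2
  µg/mg for S1/S2/S6) plus plausible layer-ordered means for total
  sugars, uronic acids and reducing sugars; noise is multiplicative with
  CV 0.08 (typical assay repeatability).
- **qPCR** inverts the Pfaffl model exactly: target Cq =
  base − log(ratio)/log(E), reference gene flat across layers; cycle
  noise sd 0.15. At zero noise the analysis recovers the configured
  ratios exactly.
- **Correlated triples** for the bootstrap share layer means (−1, 0, 1)
  on both sides; per-triple noise sd 0.432 is calibrated (once,
  numerically) so the population correlation of layer-matched normalized
  values is ±0.90; a flat expression profile gives exactly 0.

What the generator does *not* emulate: cell segmentation artifacts,
spectral water/CO₂ bands and scattering, between-batch qPCR effects,
heteroscedastic assay noise, or any dependence between modalities beyond
shared layer ordering. A green test therefore establishes correctness of
the statistical machinery under its stated assumptions, not agreement
with any particular measured dataset.

## Degenerate inputs and tie-breaks

Empty groups are omitted from summaries with a warning; fewer than 5
cells per zone is an error for the growth test. Zero-variance t-test
groups get exact 0/1 p-values. Zero-area spectra cannot be normalized
(error). Constant triples are excluded from the bootstrap. Bootstrap
replicates with zero variance on either axis are dropped; if all are
degenerate the estimation fails loudly. Classification requires complete
feature tables — imputation is out of scope.
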