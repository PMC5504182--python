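# Methods

## Scope and data model

The package analyses 1D ¹H-NMR spectra of tissue extracts from a multi-group
study: one reference group (healthy control), one disease-model group and one
or more treatment arms, with unbalanced sample counts.  A spectrum is an
intensity vector on a strictly descending chemical-shift axis (ppm); all
containers carry sample metadata (id, group, tissue) and feature matrices
track their processing state with explicit flags so each stage can assert its
preconditions.

Tissues are analysed independently; no cross-tissue statistics are computed.

## Synthetic study generator

The generator exists so that every downstream claim can be tested against a
known truth.  One sample's spectrum is

    I(δ) = baseline(δ) + Σ_m c_m Σ_k w_mk L(δ; δ_mk + j_m, γ_mk) + ε(δ),

with unit-area Lorentzian lines L (the natural NMR line shape), per-metabolite
multiplet weights w_mk summing to one, a per-sample, per-metabolite shift
jitter j_m ~ N(0, σ_shift²) applied coherently to all of a metabolite's
multiplets (pH-type drift that binning must absorb), additive Gaussian noise
ε, a smooth low-amplitude sinusoidal baseline, and clipping at zero.

Concentrations are log-normal around (reference abundance × group fold
change), parameterized so the *mean* equals the target:
c = μ·exp(σZ − σ²/2), σ² = log(1 + CV²).  Log-normal variation is strictly
positive and right-skewed, matching metabolomics practice.

Defaults (changeable per `StudyDesign`):

| parameter | default | meaning |
|---|---|---|
| ppm grid | 0.5–9.5 ppm, 8,192 points | desk-scale stand-in for a 32K acquisition |
| line half-width γ | 0.002 ppm | HWHM of a tissue-extract line at 500 MHz |
| concentration CV | 20 % | between-animal biological variation |
| shift jitter σ | 0.002 ppm | per-sample resonance drift |
| noise level | 2 % of median peak height | thermal noise |
| baseline amplitude | 1 % of median peak height | residual baseline after correction |
| dilution CV | 10 % | per-sample scale removed by normalization |
| group sizes | 7 / 16 / 12 / 9 | control / model / treatment arms |

The default library holds the 35 intestine metabolites with resonance
positions taken from standard reference assignments (the source study labels
peaks in figures but prints no shift table).  Crowded regions are kept
crowded on purpose: creatine/phosphocreatine (3.04/3.05), choline/
O-phosphorylcholine (3.20/3.22), betaine/taurine (3.25–3.27) and the BCAA
methyl region genuinely overlap at this line width, so the pipeline's
bin-to-metabolite aggregation blends them exactly as integration of real
spectra does — which is why published tables report identical fold changes
for the Cr/PCr pair.

**Total-area closure.**  Constant-sum normalization estimates relative
composition; a fold change read off normalized features equals the true
concentration ratio only when the expected total spectral area is the same in
every group.  Published fold-change tables computed on constant-sum
normalized spectra implicitly carry this property (the assigned metabolites
are a modest fraction of total area, and the remainder is stable).  The
generator reproduces that structure explicitly: an "unassigned signal" pool —
eighteen broader resonances placed clear of the quantified multiplets,
default one-half of the assigned total — whose group mean absorbs the signed
sum of the planted assigned-metabolite changes, holding the expected total
area group-invariant.  With `balance_totals=False` the closure is disabled
and the closure bias of compositional data becomes visible, which is itself
useful for teaching and sensitivity checks.  The placement of unassigned
signals away from quantified windows is a simplification: real spectra
overlap more severely, and recovery there additionally depends on curve
resolution or 2D experiments, which are out of scope.

The intestine effect table plants the published fold changes (model vs
control; treatments relative to model, converted to control-relative products),
so simulated studies have the same effect-size spectrum — succinate ×2.2 down
to near-null effects — as the real data.

## Preprocessing

* **Region exclusion** removes grid points inside given ppm intervals
  (default 4.7–5.0 ppm for residual water; the interval is a package default,
  stated, not inherited from any specific acquisition).
* **Adaptive intelligent binning** recursively splits bins at the boundary k
  maximizing V(left child) + V(right child), where for bin b over samples j

      V_b = Σ_j [(max_b,j − I_j(left edge)) (max_b,j − I_j(right edge))]^R ,

  with resolution exponent R = 0.5.  A split is accepted only if the best
  child sum exceeds both the parent's value and a noise value.  The noise
  value is `noise_factor` (default 2.0) times the best child sum achievable
  inside the signal-free noise region (default 9.0–9.5 ppm) — the same
  statistic the split test optimizes, evaluated on pure noise, so noise-level
  data stays in a single bin while real peaks (far above the noise amplitude)
  split freely.  The factor 2 absorbs the slow extreme-value growth of noise
  maxima between the noise-region width and the full window.  Monotone
  stretches score zero, so boundaries settle into inter-peak minima.  Ties in
  the split search resolve to the smallest array index (highest ppm);
  recursion is fully deterministic.  Bins never span excluded-region gaps;
  per-sample integrals use the trapezoid rule, and bin labels are center ppm
  rounded to 4 decimals.
* **Constant-sum normalization** scales each sample to a total of 100
  (a convention; only ratios matter downstream).
* **Generalized log** g(x) = log((x + √(x² + λ))/2) stabilizes variance for
  the univariate branch; λ defaults to the squared noise s.d. estimated from
  the raw spectra's noise region and is freely overridable.
* **Pareto scaling** (mean-center, divide by √s.d., n−1 denominator) feeds
  the multivariate branch; zero-variance features become zero columns.  The
  two transforms are deliberately forked: tests run on glog values,
  fold-change ratios and OPLS-DA on the normalized/Pareto branch.
* **Aggregation** maps each bin to the metabolite owning the nearest
  multiplet center within 0.015 ppm of the bin center and sums assigned bins
  per metabolite.  0.015 ppm ≈ 7.5 line widths: wide enough to absorb the
  jitter binning has already pooled, narrow enough to keep resolved
  neighbours (≥ 0.03 ppm apart) distinct.

## PCA screening and OPLS-DA

PCA (on the Pareto branch) provides the cluster overview and an explicit
outlier rule replacing visual inspection: a sample is flagged when its
Hotelling T² on the first two components exceeds the F-based critical value
k(n−1)(n+1)/(n(n−k)) · F₁₋α(k, n−k), α = 0.05 by default.

OPLS-DA uses the orthogonal-signal-corrected NIPALS recursion: per round,
w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/(tᵀt), w_o ∝ p − (wᵀp)w, t_o = Xw_o,
p_o = Xᵀt_o/(t_oᵀt_o), X ← X − t_o p_oᵀ; the predictive component is
extracted from the filtered matrix.  One orthogonal component is the default
(single predictive + single orthogonal is the usual choice for a two-class
tissue comparison); with zero orthogonal components the model is exactly
one-component PLS1, which is the oracle identity the tests exploit.  The
class vector is the mean-centered dummy coding of the two labels (values
n₀/n and −n₁/n); directions are invariant to any affine two-level coding.
t_p is oriented so the designated positive class (the case group) has a
positive mean score, fixing plot orientation across runs.

Corr(t_p, X) and Cov(t_p, X) are computed against the *unfiltered* scaled
matrix; the covariance is the pseudo-spectrum height (sign = direction of
change) and the squared correlation its color value in [0, 1].

**Q²Y** is 1 − PRESS/SS over a stratified k-fold partition (default 7 folds,
field convention; seeded shuffling).  Folds are dealt round-robin within each
class, with classes processed in a canonical order (smallest member index) so
the partition — and hence every statistic built on it — is exactly invariant
under relabeling the two classes.  Within each fold the training rows are
re-centered before fitting and test predictions are made with training means.

**Permutation validation** refits Q² under random label permutations and
reports the plus-one estimator p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1),
which can never return an impossible p = 0.  The fold seed is shared between
the observed and permuted fits, so the statistic is one fixed function of
(X, y) and exchangeability is exact.  2,000 permutations is the default for
full runs; calibration suites use fewer (see below).

## Univariate branch

Fold change is the ratio of group means on the normalized (pre-glog) scale;
FC(A,B)·FC(B,A) = 1 by construction.  Each feature is routed to a two-sided
test by Shapiro-Wilk at α = 0.05 on both groups independently: a t-test when
both pass (Welch by default — robust under the unbalanced group sizes; a flag
forces the pooled-variance form), otherwise Mann-Whitney with tie correction.
Benjamini-Hochberg step-up adjustment is applied per comparison.  Color
tables encode sign (red increase, blue decrease) and |log FC| (natural log;
the base only changes gradation, not sign), saturating at FC 4, with
significance stars at adjusted p < 0.05/0.01/0.001.  Whether published tables
used normalized areas or glog values for the printed FCs is not knowable from
the text; both modes are available and the reciprocity invariant holds either
way.

Lesion summary arithmetic: incidence = 100 × (mice with lesions)/(mice
sacrificed); average = (total lesions)/(mice sacrificed); both reported to
2 decimals.

## SUS-plots and networks

A SUS comparison takes two fitted models sharing the same reference class and
pairs each feature's Corr(t_p, X) values.  A feature is significant in a
model when |corr| ≥ 0.5 (default; the cutoff used by the source analysis is
unstated, so it is an explicit parameter).  Shared features are significant
in both models — sign agreement puts them on the positive diagonal,
opposition on the negative diagonal; features significant in exactly one
model are unique to it.  Diagonal proximity is deliberately implemented as
this sign/threshold rule rather than a geometric band; |corr_A − corr_B| is
reported for plotting only.  The Venn partition (A-only / B-only / shared
with sign pairs) follows directly.

Correlation networks are computed per group on the metabolite-aggregated
features: all pairwise Pearson r, edges where |r| > 0.6.  The threshold is
read as a magnitude ("over 0.6") because the display maps edge colors over
the full −1..1 range, implying negative edges exist; a signed-threshold mode
is a parameter away.  Zero-variance features remain isolated nodes.
SUS filtering induces the subgraph on significant features and flags each
node's direction from the sign of the correlation in the model where it is
significant.

STOCSY correlates a driver resonance's intensity across samples with every
feature (or every raw grid point); multiplets of one molecule correlate near
1 because they share the underlying concentration, which is how assignments
are confirmed.

## Pipeline and reproducibility

`run_pipeline` executes exclude → bin → normalize → {glog → univariate
tables; Pareto → PCA screen → OPLS-DA per comparison → permutation →
pseudo-spectra} → SUS (the two treatment models vs the shared disease-model
reference) → per-group networks → report.  One master seed feeds every stage
through fixed offsets (simulation, fold assignment, permutations), so reruns
with the same configuration are bit-identical and individual stages can be
reproduced in isolation.  The resolved configuration — thresholds, λ, folds,
seeds — is written into the report for auditability.  Validation errors
(unknown groups, bad thresholds) abort before any computation.

## Problem sizes in tests and the acceptance script

The shipped suites run the statistics at deliberate sizes: permutation
calibration uses 200 null datasets × 200 permutations with 3-fold Q² on
16 × 20 matrices; parameter-recovery suites use 20 simulation seeds at the
study's published group sizes and n = 50/group for fold-change recovery;
the acceptance script runs the full 2,000-permutation validation once on the
published design.  These sizes make the binomial/Monte-Carlo bands quoted in
the tests meaningful while keeping a full run in tens of seconds.

## Known limitations

* No FID-domain effects: phasing, apodization, J-coupling fine structure and
  2D spectra are not modeled; multiplets are fixed-weight line groups.
* No peak alignment algorithms; shift jitter is absorbed by binning, which is
  adequate at the default jitter but not for strong pH gradients.
* The unassigned-signal pool is placed clear of quantified windows, so
  aggregation overlap bias is milder than in the worst real spectra.
* Aggregation cannot separate resonances closer than the binning resolution
  (Cr/PCr and similar pairs report blended values — as real 1D integration
  does).
* Passing tests on synthetic data demonstrate correctness of the machinery
  and recoverability under the stated noise model, not performance on any
  particular real acquisition.
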