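# Methods

## The model

`prenotrace` analyzes unit-resolution isotopic envelopes of polyisoprenoid
alcohols (polyprenols Pren-n, dolichols Dol-n) and phytosterols from plants
fed deuterated pathway-specific precursors: (5,5-²H₂)-1-deoxy-D-xylulose
(D-DX, entering the plastidial MEP pathway, 2 deuteriums per isoprene unit)
or ((6,6,6-²H₃)methyl)mevalonolactone (D-MVL, entering the cytoplasmic MVA
pathway, 3 deuteriums per unit).

The observed isotopologue distribution over integer nominal mass shift Δm
(relative to the monoisotopic unlabeled ion) is modeled as the convolution
of three independent distributions:

1. **Natural ¹³C abundance** — Binomial(n, p¹³C) over the number of ¹³C
   atoms among the n carbons (n = 5N for an N-unit polyisoprenoid; 28/29
   for the phytosterols).
2. **Substrate deuterium purity** — the labeled precursor contains a
   fraction q of unlabeled (all-¹H) molecules, so a pathway-labeled unit
   may carry no deuterium.
3. **Pathway mixing ("cross-talk")** — the unknown distribution z(i),
   i = 0..N, of the number of isoprene units derived from the deuterated
   precursor's pathway; the remaining N−i units come from the other
   pathway (or from unlabeled endogenous precursor).

Each ¹³C and each ²H substitution contributes +1 to Δm. The ¹³C/²H
mass-defect difference (~3 mDa) is far below unit resolution, so a single
integer grid is used; fine isotope structure and peak shapes are out of
scope.

### Substrate-purity modes

Two interpretations of q are implemented (`ModelConfig.purity_mode`):

* **unit** (default): impurity is molecule-level and all-or-none — a
  labeled unit carries all d deuteriums with probability 1−q, none
  otherwise. Deuterium counts then live on multiples of d, and the
  deuteriation pattern (below) is the z distribution binomially thinned by
  q. This matches the convention of counting *deuteriated isoprene units*.
* **site**: each of the d·i deuterium sites is occupied independently with
  probability 1−q, i.e. counts ~ Binomial(d·i, 1−q). This produces
  satellite peaks 1..d−1 Da below each d-multiple.

**Identifiability.** Under the unit-level mode, (q, z) is *exactly* not
identifiable from an envelope: binomial thinning composes
(thin(r₁)∘thin(r₂) = thin(r₁r₂)), so any q′ ≤ q reproduces the data
perfectly with z′ = thin(z, (1−q)/(1−q′)), and often q′ > q does too. The
envelope determines only the thinned pattern. Under the site-level mode the
satellite peaks pin q down, and joint (q, z) estimation is well-posed: in
our noiseless round trips q is recovered to ~1e-12 and z to ~1e-7, and at
10⁶ counted ions q is recovered to better than ±0.001. Consequently:

* joint (q, z) estimation is validated in site-level mode;
* in unit-level mode, q should be fixed externally (`q_fixed`), e.g. at
  the value estimated from single-precursor experiments — also the right
  protocol for competitive experiments, where an unlabeled precursor unit
  is additionally confounded with an endogenous unit.

## Estimation

**p¹³C** is estimated once, globally, from native (unlabeled) envelopes of
one or more compounds by least squares against Binomial(nᵢ, p) with a
single shared p; the SE comes from the Gauss–Newton curvature, which adds
across envelopes. The fitted value is then held fixed for all labeling
fits (refitting per experiment would let ¹³C absorb deuterium signal).

**(q, z)** are estimated per labeling experiment by minimizing the
unweighted sum of squared residuals between the observed normalized
envelope and the forward model. Optional Poisson-variance weights are
available. The simplex constraint (z ≥ 0, Σz = 1) is enforced by the
reparameterization z = u²/‖u‖², leaving u unconstrained for a bounded
trust-region solver (`scipy.optimize.least_squares`, TRF); q is bounded to
[0, 1]. The parameterization carries one gauge degree of freedom (the
scale of u); covariance is propagated to z with a pseudo-inverse, which
projects the gauge direction out. The free-parameter count is
1 + (N + 1): 13 for Pren-11, 18 for Dol-16.

Numerical choices: ftol = xtol = 1e-12, gtol = 1e-14, at most 5000
evaluations (tolerances this tight are needed for the fitted z to track a
noiseless truth to ≤1e-6 per component). Initialization: z uniform,
q = 0.01. If the first solution's RSS exceeds 1e-5 — above the ~1e-6
residual floor of 10⁶-ion counting noise, so converged noisy fits do not
retrigger — ten seeded Dirichlet restarts are run; best RSS wins, ties
broken by the lowest q̂. Observed intensity beyond the model's maximal
shift is a data error naming the offending Δm, except for a ≤1e-9 total
tail (the float residue of support truncation), which is trimmed.

The ¹³C binomial support is truncated where its upper tail drops below
1e-12 and renormalized; this bounds convolution cost for long chains
(Dol-24: 120 carbons, ~12 relevant bins) at per-bin error below 1e-12.

**Deconvoluted grid.** The joint distribution
P(k_D, k¹³C) = D(k_D)·B(n, p¹³C, k¹³C), with D the deuterium-count
distribution implied by (ẑ, q̂), reproduces the fitted envelope when
collapsed along anti-diagonals (Δm = k_D + k¹³C) and makes the overlap of
differently deuterated isotopologues at equal m/z explicit.

## Metrics

From the deuteriation pattern P(k) (fraction of molecules with exactly k
deuterated units; in unit mode the q-thinned z):

* **deuteriation level** = 100·(1 − P(0)) — percent of molecules with at
  least one labeled unit; any k ≥ 1 counts, no abundance cutoff;
* **average number of deuteriated units** = Σ k·P(k);
* **population fractions** = 100·(P(0), Σ₀<k<N P(k), P(N)), summing to 100;
* **pathway view** — for MVL labeling the MEP-pathway contribution is the
  reversed index k → N−k (an involution); for DX it is the identity.

Report tables round percentages to integers and averages to one decimal;
all internal computation is full precision.

## Chain-elongation model

A step-by-step elongation with constant per-step probability p of drawing
the next unit from the labeled pathway gives the power law
y(k) = a + (b−a)·pᵏ (MVA orientation) or a + (b−a)·p^(N−k) (MEP
orientation), with a and b the asymptotic natural-abundance and
fully-deuteriated populations. Fitting choices:

* the pattern is normalized to total population 1 before fitting;
* the monoisotopic point k = 0 is always excluded; the default window is
  k = 1..min(6, N−1) (the initial turns of the machinery, while keeping
  ≥3 points for short chains); the fully labeled point may optionally be
  excluded since b dominates there;
* p is initialized from the log-linear slope of the window when all its
  values are positive, which makes exactly flat patterns converge to
  p = 1 deterministically;
* p̂ > 1 raises the `p_gt_1` flag: an elongation probability above one is
  mechanistically impossible and marks the model as inapplicable for that
  experiment (the diagnostic behavior seen for Pren-11 under D-MVL);
* a companion estimator returns p = exp(slope) from unweighted OLS of
  ln y(k) on k (optionally variance-stabilized with weights ∝ y(k)).

**Two-pool diagnostic.** The discrepancy is defined as
observed P(0) − model extrapolation at k = 0; a value strictly exceeding
3× the extrapolation SE (configurable; with a 1e-8 absolute floor so that
SE ≈ 0 noiseless fits are not tripped by round-off) yields a "two-pool"
verdict — evidence for a sub-population synthesized entirely from
unlabeled precursors on top of the power-law pool. The sign convention
makes an injected unlabeled-only pool of mass w appear as discrepancy ≈ +w.

**Initial-unit deviation.** Per-k residuals (observed − model) over
k = 1..N; contiguous runs of ≥2 same-signed residuals with magnitude above
a threshold (default 0.01 of total population) are flagged with their k
range — the signature of a preferred pathway origin for the first few
units of the chain.

## Synthetic data

The generator emulates the hydroponic feeding study design: 12 conditions
({leaves, roots} × {DX, MVL} × {single, competitive} for Pren-11 in leaves
and Dol-16 in leaves and roots). A spectrum is a multinomial draw of
n_ions (default 10⁶) from the forward envelope placed on the adduct m/z
grid, with optional Gaussian m/z jitter (σ = 0.05 Da) and 2% multiplicative
intensity noise (both off by default; no instrument noise model is
otherwise assumed). Per-condition seeds are BLAKE2b hashes of
(master seed, condition label), kept below 2³¹.

Default ground truths use p¹³C = 0.0102 and q = 0.029 (DX) / 0.007 (MVL) —
the fitted values for these substrates — and per-condition z distributions
with end masses mirroring the reported unlabeled/fully-labeled fractions
and geometric interiors. They are plausibility fixtures, not measured
truth. Competitive-condition truths never exceed their matched
single-precursor condition in fully labeled mass (isotopic dilution).

What passing recovery tests on these data do *not* show: robustness to
chimeric adduct mixtures, chromatographic co-elution, detector saturation,
baseline drift, or model misspecification of the purity mode — real
spectra carry all of these.

## Ingestion

Peak lists are two-column delimited text with optional `# key: value`
headers; duplicate m/z rows are summed. Binning assigns each peak to the
nearest integer Δm of the adduct grid within ±0.3 Da (default; configurable,
suited to unit-resolution envelopes); off-grid peaks are reported as
unassigned, never dropped silently, so intensity is conserved. Bins below a
configurable relative floor (default 0) are zeroed. A peak list with *no*
assignable peak raises an adduct-mismatch error; an empty Δm = 0 bin alone
does not, since heavily labeled samples legitimately lack unlabeled signal.
One adduct series is ingested per run; disentangling co-occurring adduct
series is out of scope.

## Problem sizes used in the test and acceptance suites

Noiseless round trips use 50 random Dol-16 truths; stochastic recovery uses
20 replicates × 10⁶ ions (site mode, q* = 0.007 and 0.029); elongation
noise tests use 20 replicates × 10⁵ molecules. These sizes give the
reported tolerances (TV(ẑ, z*) < 0.02, |q̂ − q*| < 0.005, |p̂ − p| ≤ 0.03 in
≥18/20 replicates) comfortable margins in seeded runs.

## Known limitations

* The paper-scale biological results (per-condition fitted z for real
  tissue) require the original raw spectra, which are not deposited; the
  package validates on synthetic data and on the printed summary table.
* Sterols are modeled as generic compounds with a configurable maximum
  label-bearing unit count; route-specific bookkeeping (cycloartenol vs.
  lanosterol M+10/M+12 predictions) is not modeled.
* No Bayesian posterior or smoothness regularization over z; no model
  selection beyond the two-pool diagnostic.
* Whether competitive-labeling kinetics alter the effective d for
  MVL-derived units is not modeled.
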