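# Methods

## Bulk fibril-formation model

The package works with the standard moment description of linear
self-assembly. Free monomer m(t), fibril mass M(t) and fibril number P(t)
(both in monomer-equivalent concentration units, μM) obey

    dP/dt = k_n m^{n_c} + k₂ m^{n₂} M + k₋ M
    dM/dt = 2 k₊ m P
    m     = m_tot − M

with primary nucleation (k_n, order n_c), fibril-surface-catalysed secondary
nucleation (k₂, order n₂), fragmentation (k₋) and elongation at both fibril
ends (k₊; the factor 2 follows the usual two-ended growth convention).
Nucleation consumes a mass-negligible amount of monomer, so monomer depletion
is by elongation only — the standard closure. Saturated secondary nucleation,
where monomer attachment to the fibril surface is not rate limiting, is
encoded simply as n₂ = 0 rather than through an explicit Michaelis constant;
with n₂ = 0 the secondary term is mathematically identical to fragmentation,
which is exactly why bulk curve shape alone cannot distinguish the two and a
fibril-length analysis is needed.

Internal units are hours and μM throughout; rates are converted to s⁻¹ only
when printed for comparison with literature values.

Two effective rates control macroscopic behaviour at total monomer m₀:
λ = √(2 k₊ k_n m₀^{n_c}) and κ = √(2 k₊ k₂ m₀^{n₂+1}) (fragmentation
analogue √(2 k₊ k₋ m₀)). Only composite products are identifiable from bulk
data, so everything downstream is parametrized by them.

### Exact first-integral solution

Besides the stiff ODE route (LSODA, rtol 1e-8, atol 1e-9·m_tot),
`closed_form_fibril_mass` evaluates the same dynamics through an exact
reduction: in the variable μ = ln(m₀/m) the system collapses to
μ'' = F(μ) with

    F(μ) = λ² e^{−n_c μ} + 2 k₊ (k₂ m^{n₂} + k₋)(m_tot − m),   m = m₀ e^{−μ},

because μ' = 2 k₊ P exactly. Multiplying by μ' and integrating gives an
energy-type first integral with elementary antiderivatives, so
μ'(μ) is known in closed form and t(μ) is a single 1-D quadrature
(performed on a √μ grid, which removes the integrable singularity of
unseeded starts; 4000 trapezoid nodes give ~1e-5 sup-norm agreement with the
ODE). This replaces the approximate generalized-logistic fixed-point
solution often used for this model: it retains κ and λ as the controlling
parameters but involves no linearization, and it provides a genuinely
independent cross-check of the ODE integrator (the two routes share no
stepping machinery). It is also the forward model inside the global fit,
being faster and free of stiffness failures.

Degenerate regimes: with no active pathway (λ = κ = 0 and no seeded
elongation flux) the solver raises rather than returning a silent constant;
an unseeded system with κ > 0 but λ = 0 is correctly reported as sitting at
the m = m₀ fixed point.

### Curve descriptors

Half-time and lag time are first crossings of 0.5 and 0.25 of the
normalized curve, linearly interpolated between samples, ties broken by the
first crossing. The scaling exponent is the OLS slope of log₁₀ t₁/₂ against
log₁₀ m_tot (≥3 distinct concentrations required).

## Trace normalization and global fitting

Raw signals are assumed affine in fibril mass (ThT increase or dye-quench
decrease). Normalization anchors the mean of the first 5% of points at 0 and
the last 5% at 1, flipping decreasing traces, and rejects traces whose range
is below 5× an estimated noise SD. Because this windowed anchoring is part
of the measurement model, the fit applies the identical windowed map to its
model curves before computing residuals (the `anchored` flag on
`NormalizedTrace`); otherwise seeded curves, which are already rising during
the baseline window, acquire a systematic bias of several percent in κ.

The global fit minimizes unweighted summed squared residuals on normalized
curves (no error model is available for plate-reader noise) over log₁₀ of
the composite parameters k₊k_n and k₊k₂ (or k₊k₋). When seeded traces are
present, k₊ itself joins the fit because the seed number enters through
k₊P₀ with P₀ = seed mass / seed mean length. Multi-start local least
squares (default 5 starts, seeded RNG, trf with log-bounds [1e-14, 1e8]);
the first start comes from curve features (κ ≈ e·max slope; λ from the
half-time), the rest are log-normal perturbations; best objective wins, ties
broken by the smaller parameter norm. Configurations that cannot constrain
the parameters (fewer than two traces or a single condition) are rejected
rather than fitted.

Model comparison fits primary-only and primary+secondary and reports the
objective ratio; "secondary required" needs a configurable factor (default
5×) because the misfit of interest is gross, and ratios between 1 and the
factor are reported indeterminate. The fragmentation-constrained fit pins
√(2 k₊k₋ m_ref) to a supplied κ(frag) (e.g. from the length analysis) and
refits everything else.

## Plateau-phase fibril lengths

With mass constant (M = M∞) and nucleation silenced by monomer depletion,
fragmentation alone gives dP/dt = k₋M∞, hence P(t) = k₋M∞t + P_plateau and

    L(t) = M∞ / P(t) = 1 / (k₋ t + 1/L_plateau).

k₋ and L_plateau are fitted jointly to timepoint means (weighted 1/SEM²
when individual lengths are given), initialized by the exact linear fit of
1/L vs t; joint estimation of L_plateau uses strictly more information than
plugging in a steady-state estimate. κ(frag) = L_plateau·k₋ is reported as
an upper bound on fragmentation-driven proliferation. Confidence intervals
are percentile bootstrap (resampling individual lengths within timepoints
when available, otherwise mean-level residuals). Lengths are carried in
monomer equivalents so κ(frag) is in h⁻¹ directly; the product is invariant
to the length unit. A fit pinned at k₋ = 0 (non-decreasing means) is
flagged as "≤ resolution". TEM capture bias against long fibrils is not
modelled; the generator can optionally attenuate bursts but not lengths.

## Oligomer population dynamics

Oligomer mass S(t) follows one of two linear-in-S rate laws along a given
bulk trajectory: a monomer-only source with first-order decay
(dS/dt = k_o1 m^{n_o} − k_e1 S) or a fibril-catalysed source and sink
(dS/dt = k_o2 m^{n_o} M − k_e2 S M). Reaction orders default to n_o = 1
(configurable); S(0) = 0 at reaction start. Integration uses a
second-order exponential time-differencing step on a 4×-refined grid —
exact for constant coefficients (steady states S* = (k_form/k_diss)·m^{n_o}
are preserved to machine precision) and unconditionally stable for
arbitrarily fast dissociation.

Measured oligomer signals are relative; the detection scale may be orders
of magnitude below one. The fitted amplitude is therefore
detection_scale × k_form, and the reported formation rate (converted to s⁻¹
at a 100 μM reference monomer concentration) is a lower bound on the true
rate. Fits are weighted least squares (1/SEM where present; single-sample
points get the median weight), multi-start over log parameters, with a
delta-method CI on the formation rate. Freezing the dissociation constant
on data with genuine decay produces a long terminal same-sign residual run,
which is flagged as systematic misfit.

Model selection fits both rate laws jointly across conditions (unseeded and
seeded share all oligomer parameters, including the amplitude — the paired
design is what discriminates the mechanisms, since only the
fibril-catalysed law shifts the oligomer peak together with the seeded
half-time). The lower objective wins; objectives within 10% relative, or
both negligibly small, are indeterminate. The peak locator uses parabolic
interpolation through the three samples around the discrete maximum and
flags boundary maxima.

## Photon-burst quantification

Timetraces are binned photon counts (1 ms default). Background statistics
are taken from all bins below the 99th percentile (so bursts cannot inflate
the threshold — this also makes the threshold invariant to appending more
background); the threshold is mean + k·σ with k = 8 by default, which keeps
the false-positive rate on pure Poisson background below one event per
minute at 20 counts/bin. Events are maximal runs of consecutive
supra-threshold bins; relative mass is the summed excess photons per second.
The estimate is proportional to oligomer concentration for a fixed
brightness distribution but carries no absolute scale. Pooling across
positions reports mean and SEM, with SEM omitted for single estimates.

## Synthetic-data generators

Defaults encode the study conditions: 100 μM monomer; seeds 0/0.25/1% by
mass; k₊ = 20 μM⁻¹h⁻¹ with k₂ and k_n chosen to give κ = 0.4 h⁻¹ and
λ = 0.004 h⁻¹ at 100 μM (unseeded half-time ≈ 24 h, plate-reader sampling
every 0.25 h for 60 h); fragmentation pair k₋ = 5×10⁻⁶ h⁻¹,
L_plateau = 2000 monomers (product 0.01 h⁻¹), 5 plateau timepoints over
0–100 h with 700 exponentially distributed lengths each; fibril-catalysed
oligomers at k_o2·(100 μM) = 4×10⁻⁵ s⁻¹ per μM fibril mass with fast
dissociation (k_e2 M∞ = 10 h⁻¹), 8 replicates with 10% multiplicative
log-normal noise and occasional single-sample points; photon traces with
Poisson background of 20 counts/bin and log-normal bursts (median 150
photons, σ_ln = 1) arriving at 2 Hz, spread over three bins.

Two generator-level choices deserve note. The primary-nucleation order
defaults to n_c = 1, the apparent order of a heterogeneous
(surface-catalysed) primary process; this also makes λ/κ independent of
m_tot, so the half-time scaling exponent of secondary- or
fragmentation-dominated kinetics is exactly −(n₂+1)/2 = −0.5 rather than
carrying a slowly-decaying logarithmic correction. The seed mean length
defaults to 5000 monomers (~1 μm unsonicated fibrils), at which 1% seeds
leave primary-only kinetics essentially unchanged (<5% half-time shift)
while still accelerating secondary-nucleation kinetics several-fold — the
qualitative asymmetry the seeding experiment relies on.

Bulk noise is additive Gaussian at 1% of the dynamic range; oligomer noise
multiplicative log-normal at 10% (counting-like). All generators are
deterministic under a fixed seed and return ground truth alongside the
data.

What the generators do **not** emulate: instrument drift and baseline
curvature in plate-reader signals, non-exponential length distributions and
TEM capture bias, structural oligomer heterogeneity, detector afterpulsing
or drift in photon traces, and any biological variation between replicates
beyond the stated noise models. Passing tests therefore demonstrate that
the estimators are correct and well-calibrated under the stated statistical
structure, not that they are robust to every artefact of real data.

## Problem sizes and numerical settings

Test-suite and acceptance computations use the condition grids above;
recovery and selection properties use 10–20 stochastic replicates and the
scaling analysis uses four concentrations (25–200 μM) on 4000-point time
grids — sizes chosen so the whole analysis reruns in a couple of minutes on
one core while keeping Monte-Carlo wobble well inside the stated
tolerances. Optimizer settings (trf, xtol/ftol 1e-12, log-space bounds
[1e-14, 1e8]) and integrator tolerances are fixed, not tuned per dataset.

## Known limitations

* Individual rate constants are not recoverable from bulk data — only the
  composites and κ, λ; `FitResult.rate_constants` requires an external k₊.
* The oligomer amplitude/detection-scale degeneracy means absolute oligomer
  concentrations are never estimated, only rates (as lower bounds).
* Model comparison uses objective ratios against a configured factor, not a
  formal statistic; with a single unseeded condition the mechanisms are
  close to indistinguishable by design of the rate laws.
* The burst estimator assumes fibrils were removed upstream
  (centrifugation) and a stationary background; slow background drift would
  bias the threshold.
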