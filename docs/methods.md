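# Methods

This note records the models implemented in `dceflow`, their assumptions,
the parameter choices that matter, and the numerical decisions a user
should know before trusting the output.

## Pharmacokinetic stage

**Signal model.** The dynamic series is a spoiled gradient-echo (SPGR)
steady-state acquisition: S = M₀ sin α (1 − E₁)/(1 − cos α E₁) with
E₁ = exp(−TR·R₁). The default protocol is TR 4.5 ms, flip angle 25°, 10
pre-injection + 30 dynamic phases at 5.5 s, 5 mm slices — midpoints of the
ranges of the brain dynamic protocol the package emulates. Without a
measured T1 map, the pre-contrast T10 is a constant per scan; both 0.8 s
and 1.0 s are in conventional use depending on field strength, and the
choice is left to the user (`t10` everywhere; default 1.0 s). Gadolinium
relaxivity r₁ defaults to 4.5 L/(mmol·s) (gadopentetate at clinical field
strengths) and is configurable.

**Signal → concentration.** The baseline signal S₀ (mean of pre-injection
phases) plus T10 fix M₀; the SPGR equation is then inverted *exactly* at
every phase, giving R₁(t), ΔR₁ = R₁ − 1/T10, and C = ΔR₁/r₁. The exact
inversion (rather than the linearized small-ΔR₁ approximation) makes the
synthetic forward model and the analysis stage mutual inverses to machine
precision, which the round-trip tests exploit. Voxels whose signal leaves
the invertible range of the SPGR equation at any phase are flagged invalid
rather than aborting the volume.

**Arterial input function.** The AIF is either extracted from a user-named
vessel voxel (whole-blood concentration scaled by 1/(1 − Hct), hematocrit
default 0.45) or, for synthetic work, generated from a population
bi-exponential bolus C_p(Δt) = A(e^{−m_slow Δt} − e^{−m_fast Δt}) with
defaults A = 6 mM, m_fast = 0.25 s⁻¹, m_slow = 0.01 s⁻¹ (peak ≈ 5 mM
about 13 s after arrival, washout over minutes — a dispersed venous-type
curve). The bolus arrives at the end of the baseline block by default.

**Extended Tofts fit.** Voxelwise bounded least squares of
C_t(t) = K^trans ∫ e^{−k_ep(t−τ)} C_p(τ) dτ + v_p C_p(t), with
k_ep = K^trans/v_e, inside the physiologic box K^trans ∈ [0, 5] min⁻¹,
v_e, v_p ∈ [0, 1]. The convolution uses trapezoidal quadrature on the
acquisition grid; a 10× finer-grid reference in the tests bounds the
quadrature error (< 0.5 % relative L2 when the bolus wash-in is resolved
by the sampling, < 2 % for the sharp default bolus, where input
undersampling — not quadrature — dominates). Two fitters minimize the same
SSE objective:

* `nls` — trust-region optimizer per voxel, single deterministic start
  (0.1 min⁻¹, 0.2, 0.05), optional 3-point multistart. Reference path.
* `profiled` — for fixed k_ep the model is linear in (K^trans, v_p), so
  the SSE is minimized in closed form (a 2-variable box QP) per candidate
  k_ep on a 64-point geometric grid plus k_ep = 0, with parabolic
  refinement on log k_ep. ~0.3 ms/voxel, median parameter error < 1 % on
  noiseless curves; default for whole-volume fits. The v_e ≤ 1 constraint
  is enforced by capping K^trans at k_ep per candidate.

Voxels that fail to fit are flagged, logged, and excluded from the Ktrans
field passed to the fluid stage.

## Interstitial flow stage

**Model.** The interstitium is an incompressible porous medium in Stokes
regime: Darcy's law u = −K_H ∇p plus steady-state mass balance with a
Starling transvascular source and zero lymphatic clearance (brain):

    −∇·(K_H ∇p) + c·p = c·P_eff,   c = (K^trans/⟨K^trans⟩) · L_p · S/V

The individual Starling constants (microvascular pressure, osmotic
pressures, reflection coefficient) are lumped into the single effective
pressure P_eff; they are not separately exposed. The K^trans ratio
modulates only tumor voxels (the map exists only in the lesion); normal
tissue uses ratio 1 and, by default, keeps its own filtration source
active (`source_in_normal=True`), since the parameter set assigns normal
tissue its own values.

**Tissue parameters** (SI; literature values for brain and brain
metastases):

| parameter | normal | tumor | units |
| --- | --- | --- | --- |
| K_H interstitial hydraulic conductivity | 5.65e-15 | 4.9e-13 | m²/(Pa·s) |
| L_p vascular hydraulic conductivity | 8e-14 | 6.4e-13 | m/(Pa·s) |
| S/V vessel exchange area | 1e4 | 2e4 | 1/m |
| P_eff effective pressure | 400 | 1550 | Pa |

The derived decay length √(K_H/(L_p·S/V)) is ≈ 6.2 mm in tumor and
≈ 2.7 mm in normal tissue: pressure structure on scales much smaller than
this is low-pass filtered away, and lesions much larger than it plateau at
P_eff inside. (The source table prints L_p with the same units as K_H;
dimensional consistency of the continuity equation requires m/(Pa·s),
which also reproduces the ≈ 6 mm decay length — the package uses that
convention.)

**Domain.** The lesion mask is resliced to an isotropic grid (default
1 mm) and padded with normal tissue (default 20 mm margin); the outer
voxel layer is a Dirichlet boundary at 0 Pa (normal brain far field). The
mask indicator is resliced by linear interpolation + 0.5 threshold:
nearest-neighbour duplication at strongly anisotropic zooms (5 mm slices →
1 mm) produces a lumpy staircase surface that measurably destabilizes the
histogram features downstream. A test verifies the central pressure moves
< 1 % when the margin is doubled from 20 to 40 mm. Non-cubic extended
domains (e.g., a spherical shell, used by the radial validation) are
supported through an additional fixed-voxel mask.

**Discretization and solver.** 7-point finite-volume stencil; face
conductivities are harmonic means of the adjacent voxel K_H (flux
continuity across the tumor interface); the assembled operator is
symmetric positive definite. Systems under 2×10⁴ unknowns are solved by
sparse LU, larger ones by Jacobi-preconditioned conjugate gradients
(3D LU fill-in makes direct factorization uncompetitive well below 10⁵
unknowns); the relative-residual tolerance is 1e-10 and non-convergence
raises. The scheme satisfies a discrete divergence identity — interior
filtration equals boundary outflow — which the tests assert to 1e-8, and
a discrete maximum principle (0 ≤ p ≤ max P_eff).

**Validation.** Against the closed-form two-region radial solution of a
10 mm spherical tumor (itself cross-checked by an independent collocation
solve of the radial ODE), the 3D solver's volume-averaged radial profile
over the tumor and inner half of the margin is accurate to 0.3 % relative
L2 at 1 mm spacing and converges at ≈ second order (error ratio ≈ 3.5-4.9×
on halving the spacing, binning-dependent). The comparison excludes the
outer boundary layer because the voxelized spherical Dirichlet surface is
a first-order perturbation confined there. A 50 mm tumor's central
pressure reproduces the P_eff asymptote to 0.01 %.

**Velocity.** u = −K_H ∇p with central differences (one-sided at the
domain faces) and the voxelwise tissue K_H; the magnitude |u| is the IFV
map. In spherical phantoms |u| peaks in a rim shell and points outward,
the expected pattern of an outward-seeping lesion.

## Synthetic data

The generator produces what the analysis consumes, with known truth:

* **Ktrans field** — mean + SD × (unit-variance Gaussian random field with
  a stated correlation length, built by kernel-normalized smoothing of
  white noise on a padded grid so edge statistics are stationary), clipped
  to [0, 5] min⁻¹; optional concentric low-Ktrans core (fraction of the
  lesion radius, multiplicative level). v_e and v_p are uniform in the
  lesion; background tissue is quiescent (Ktrans 0.002 min⁻¹, v_e 0.2,
  v_p 0.01).
* **Signal** — voxelwise extended Tofts forward model (one shared curve
  for the uniform background) → SPGR signal at M₀ = 1000, plus additive
  Gaussian noise on the magnitude signal (Rician optional). The default
  cohort noise SD of 1.0 corresponds to baseline SNR ≈ 20.
* **Determinism** — every phantom is bit-reproducible from its spec; the
  random field carries its own seed so pre/post scans of the same lesion
  share the vasculature while measurement noise refreshes.

**What the phantoms do not emulate:** motion, B1 inhomogeneity, partial
volume at the lesion rim beyond voxelization, realistic lesion shapes,
water-exchange effects, or measured patient AIFs. Passing tests therefore
demonstrate internal consistency of the method chain and correctness of
the numerics — not clinical accuracy on real data.

### The paired response cohort

`CohortSpec` builds 31 OR / 22 non-OR lesions (the study's group split)
with radii uniform in 5.5–8 mm on a 2.5 mm isotropic acquisition grid —
sizes scaled down so the 106 lesion-timepoint analyses run on one CPU in
minutes; single-phantom defaults keep the 5 mm-slice protocol.

The default effect structure models response as **perfusion
homogenization**: pre-treatment lesions are rim-enhancing (a hypoperfused
core at 10 % of the rim Ktrans within 60 % of the lesion radius, field SD
0.12 min⁻¹ at 3 mm correlation length); OR lesions lose the core contrast
and half the field SD after treatment (devascularization makes perfusion
uniformly low), non-OR lesions keep the pre-treatment structure. Through
the fluid model this yields, for OR lesions, a lower post-treatment IFP
kurtosis (the histogram flattens as the core/rim contrast disappears) and
a higher IFV mean, with pre-treatment feature values (IFP ≈ 1.44 kPa,
kurtosis ≈ 3.3, skewness ≈ −0.7) in the clinically reported range.

This design was chosen after systematic exploration of the model's
causal structure, and it deliberately inverts a simpler first idea (adding
a necrotic core post-treatment): with the parameter table above, the
pressure field low-pass filters the *normalized* Ktrans source over the
6 mm decay length, so a core *added* at fixed geometry raises kurtosis and
lowers IFV mean — the opposite of the observed response signature — and
random-field SD changes are damped by ≈ (1 + (2πλ/L)²)⁻¹, two orders of
magnitude for feasible patch sizes. A pre-existing core that *vanishes*
with response is both clinically standard (untreated metastases enhance at
the rim) and produces the correct signature robustly.

The end-to-end experiment (`response_experiment_config`) analyzes the
cohort with whole-VOI feature pooling: per-slice statistics of third and
fourth moments are unstable on resliced lesions this small (tens of voxels
per slice), while the literal per-slice averaging remains the default of
the feature module itself.

## Features and statistics

* Moments are population (n-denominator); skewness is Fisher–Pearson g₁;
  kurtosis is Pearson non-excess m₄/m₂² (normal → 3; an excess flag
  subtracts 3). Constant samples give NaN shape moments, and NaN
  propagates through Δ = post − pre.
* `per_slice_mean` (default) computes each statistic per axial slice with
  ≥ 8 lesion voxels and averages statistics across slices, falling back to
  whole-VOI pooling with a warning when no slice qualifies. IFP features
  are reported in kPa, IFV in m/s; maps are stored in Pa and converted
  only in tables.
* Wilcoxon rank-sum: exact null enumeration for tie-free pooled samples of
  ≤ 12, otherwise the normal approximation with tie and continuity
  corrections; two-sided throughout. The exact path matches full
  enumeration; the asymptotic path's type-I error at the study's group
  sizes (31 vs 22) is calibrated to [0.035, 0.065] at α = 0.05 over 2000
  null replicates.
* ROC: AUC by the Mann–Whitney identity (ties count ½); candidate cutoffs
  are midpoints of sorted unique scores plus ±∞ in both reading
  directions; the Youden index J = sens + spec − 1 picks the cutoff with
  ties broken toward higher sensitivity. The positive class is non-OR.
* No multiple-testing correction by default (univariate reporting);
  Benjamini–Hochberg available by flag.

## Known limitations

* The fluid model is steady-state and rigid: no poroelasticity, no solid
  stress, no time dependence, lymphatic clearance fixed at zero.
* Tissue parameters are two global constants per class; intratumoral
  variation enters only through the normalized Ktrans source, whose effect
  is strongly smoothed (see above). Consequently IFP *magnitudes* are set
  almost entirely by P_eff and lesion size.
* The K^trans handling outside the lesion (ratio 1, normal source on) is
  one of several defensible conventions; both switches are exposed.
* The SPGR inversion assumes the nominal flip angle everywhere and a
  single global T10.
* Feature values at desk-scale lesion sizes are sensitive to voxelization;
  the cohort experiment's effect detection is robust to this (paired
  design, shared fields), but absolute higher-moment values should not be
  compared across grids.
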