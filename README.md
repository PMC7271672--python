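# dceflow

Non-invasive estimation of tumor **interstitial fluid pressure (IFP)** and
**interstitial fluid velocity (IFV)** from dynamic contrast-enhanced MRI
(DCE-MRI), with per-lesion histogram features and response-group statistics
for treated brain metastases.

Elevated IFP is a hallmark of solid tumors: leaky microvasculature filters
plasma into the interstitium, and the brain has no lymphatics to drain it.
`dceflow` estimates the pressure and flow fields a lesion would need to
sustain its measured contrast leakage, entirely from imaging:

1. **Pharmacokinetics.** The dynamic SPGR signal is inverted to contrast
   concentration, and the two-compartment **extended Tofts model**

   C<sub>t</sub>(t) = K<sup>trans</sup> ∫₀ᵗ e<sup>−k<sub>ep</sub>(t−τ)</sup> C<sub>p</sub>(τ) dτ + v<sub>p</sub> C<sub>p</sub>(t),  k<sub>ep</sub> = K<sup>trans</sup>/v<sub>e</sub>

   is fitted voxelwise by bounded nonlinear least squares
   (K<sup>trans</sup> ∈ [0, 5] min⁻¹, v<sub>e</sub>, v<sub>p</sub> ∈ [0, 1]),
   giving the volume transfer constant K<sup>trans</sup> — a surrogate of
   vascular leakiness.

2. **Fluid model.** The interstitium is a porous medium obeying Darcy's law
   **u** = −K<sub>H</sub>∇p<sub>i</sub>. At steady state with zero lymphatic
   clearance, mass balance gives a linear reaction–diffusion equation

   −K<sub>H</sub>∇²p<sub>i</sub> = (K<sup>trans</sup>/⟨K<sup>trans</sup>⟩) · L<sub>p</sub>(S/V) · (P<sub>eff</sub> − p<sub>i</sub>)

   where the K<sup>trans</sup> map, normalized by its tumor mean, modulates
   the transvascular filtration source, and P<sub>eff</sub> lumps the
   Starling pressures. The equation is discretized with a 7-point
   finite-volume stencil (harmonic face conductivities) on a 1 mm isotropic
   grid with a zero-pressure boundary on an extended normal-tissue domain,
   and solved by preconditioned conjugate gradients to 1e-10.

3. **Features and statistics.** Each lesion's IFP (kPa) and IFV magnitude
   (m/s) maps are reduced to mean, SD, skewness and kurtosis (8 features,
   at pre- and post-treatment timepoints plus their change Δ), compared
   between objective-response (OR) and non-OR lesions with the Wilcoxon
   rank-sum test, and thresholded by ROC analysis with the Youden index.

Because clinical DCE volumes cannot be redistributed, the package ships a
fully specified **synthetic-data module**: SPGR phantoms with known
ground-truth parameter maps, population AIF, and paired pre/post lesion
cohorts with a controllable treatment-response effect, so every stage of
the pipeline is testable end to end.

## Worked example

```python
from dceflow import (PhantomSpec, TumorGeometry, generate_phantom,
                     signal_to_concentration, ExtendedToftsModel,
                     build_domain, make_ktrans_ratio, InterstitialFlowModel)

spec = PhantomSpec(
    grid_shape=(14, 14, 12), voxel_size_mm=(2.5, 2.5, 2.5),
    tumor=TumorGeometry.sphere((17.5, 17.5, 15.0), 6.0),
    ktrans_mean=0.3, ktrans_spatial_sd=0.08, seed=42,
)
phantom = generate_phantom(spec)

conc = signal_to_concentration(phantom.signal, spec.protocol, t10=1.0)
etm = ExtendedToftsModel(conc, phantom.aif, phantom.mask, method="profiled").fit()
print(etm.summary())

domain = build_domain(phantom.mask, spec.voxel_size_mm,
                      target_spacing_mm=1.0, margin_mm=20.0)
domain = make_ktrans_ratio(etm.ktrans, domain)
flow = InterstitialFlowModel(domain).solve()
print(flow.summary())
```

Output:

```
        parameter    median       q25       q75
0  ktrans_per_min  0.312590  0.275334  0.358103
1              ve  0.300131  0.300013  0.300339
2              vp  0.030501  0.030300  0.030604
3     kep_per_min  1.041164  0.916268  1.193602
                         quantity         value units
0                        n_voxels  3.937500e+05
1                  n_tumor_voxels  9.620000e+02
2                      spacing_mm  1.000000e+00    mm
3                  ifp_tumor_mean  1.425871e+03    Pa
4                   ifp_tumor_max  1.441217e+03    Pa
5                  ifv_tumor_mean  2.843325e-08   m/s
6                   ifv_tumor_max  1.212747e-07   m/s
7                 solver_residual  7.167978e-12
8               solver_iterations  1.260000e+02
9  source_minus_boundary_flux_rel  8.229558e-14
```

The fitted medians sit on the ground truth (K<sup>trans</sup> 0.3 min⁻¹,
v<sub>e</sub> 0.3, v<sub>p</sub> 0.03); the solved tumor IFP plateaus near
1.43 kPa — a lesion of radius ~6 mm approaches but does not reach the tumor
effective pressure of 1.55 kPa, because its size is comparable to the
pressure decay length √(K<sub>H</sub>/(L<sub>p</sub>S/V)) ≈ 6 mm. The last
row is the discrete conservation check: interior filtration balances the
boundary outflow to machine precision.

The full cohort experiment (31 OR / 22 non-OR paired lesions) runs from the
command line:

```bash
dceflow run-all --out results/demo --seed 0
```

and reports, among the 24 feature × timepoint comparisons, significantly
lower Δ IFP kurtosis and higher Δ IFV mean in the OR group — the designed
response signature.

## Layout

| module | contents |
| --- | --- |
| `dceflow.protocol` | acquisition constants, population AIF |
| `dceflow.spgr` | SPGR signal equation and its exact inverse |
| `dceflow.tofts` | extended Tofts kinetics: forward model and fitters |
| `dceflow.pk` | signal→concentration, AIF extraction, `ExtendedToftsModel` |
| `dceflow.phantom`, `dceflow.cohort` | synthetic lesions and paired cohorts |
| `dceflow.flow` | simulation domain, finite-volume IFP solver, Darcy IFV |
| `dceflow.features` | per-lesion histogram features |
| `dceflow.stats` | rank-sum tests, ROC/Youden, group comparison |
| `dceflow.pipeline`, `dceflow.cli` | orchestration, YAML config, CLI |

See `docs/methods.md` for the model assumptions, parameter tables, and
numerical choices.
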