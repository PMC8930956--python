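# Methods

`dmwear` compares polyethylene wear across five acetabular constructs on a
synthetic patient cohort. This note records the model, its assumptions, the
parameters that matter, and what the desk-scale surrogate can and cannot
show.

## Scope and overall design

The pipeline replaces two heavyweight stages of a patient-specific
finite-element workflow with fast, well-characterized surrogates:

- CT-derived musculoskeletal modeling → a **parametric gait synthesizer**
  (harmonic templates for three hip angles and the joint reaction force);
- solid elasto-plastic FE contact → an **elastic-foundation (Winkler)
  contact solver** on a triangulated bearing surface.

Everything downstream — Archard accumulation, million-cycle extrapolation,
paired cohort statistics — follows the standard computational-wear recipe.
Wear is a surface phenomenon in this model, so only bearing surfaces are
meshed; no solid mesh or subsurface stress field exists.

## Synthetic cohort and gait

Fifteen patients (8 male) with age ~ N(50, 14²) years truncated to
[18, 90] and BMI ~ N(30, 4²) kg/m² truncated to [18, 45]; heights are
sex-specific normals (men 1.75 ± 0.07 m, women 1.62 ± 0.065 m) and body
mass is BMI·height². Truncation bounds are plausibility limits, not fitted
quantities. Each patient carries a `jrf_scale` multiplier
~ N(1, 0.12²) (truncated ±3σ) expressing gait vigour independent of body
weight; BMI therefore influences wear only through body weight, which is
why wear tracks peak joint force much more strongly than BMI in the output
regressions.

Angle and load waveforms are sums of cosine harmonics over normalized cycle
time (defaults in `src/dmwear/data/defaults.yaml`): flexion 8° ± 20°
(peak ~30° at heel strike, ~−14° in late stance) plus a small second
harmonic; abduction ±4°; axial rotation ±5°; a double-peaked stance-phase
joint force reaching ~2.5 body weights with a near-unloaded swing phase;
and a force direction tilted 18° ± 13° medially and ±20° anteroposteriorly
off the pelvis superior axis. Per-patient amplitude multipliers (SD 8 %)
and a small phase jitter are seeded; eleven cycles with 2 % cycle-to-cycle
noise are averaged into one representative cycle per patient. Waveform
amplitudes are calibration constants: they were chosen once so that (a)
every curve stays physiological for level walking and (b) the cohort-mean
DM22PE volumetric wear lands near the published control value for this
implant class (~23 mm³/Mc) — the only quantitative anchor available for a
synthetic gait. They live in config, not code, and are not per-construct:
all five constructs see identical kinematics for a given patient.

What the generator does *not* emulate: inverse-dynamics consistency between
angles and forces, patient-specific anatomy (offset, cup position are fixed
at 40° inclination / 15° anteversion), activities other than level walking,
and any angle–force correlation structure beyond body-weight scaling.
Passing cohort-level tests therefore shows the *pipeline* reproduces the
comparative physics, not that these waveforms match any individual's gait.

## Implant geometry

All constructs share a 52-mm shell with a 3-mm wall (46-mm seat). Dual
mobility: liner outer diameter 46 mm, so the small-articulation liner
thickness is (46 − 22.2)/2 = 11.9 mm; conventional inserts have thickness
(46 − head)/2. Radial clearances default to 0.05 mm for 22.2-mm heads,
0.025 mm for 32-mm heads (small articulation) and 0.05 mm for the large
articulation. The size-dependent clearance reflects the tighter relative
manufacturing conformity of large metal-on-PE bearings; with a single
clearance and the geometric thickness difference, the foundation model
would predict a higher peak-pressure × radius product for the 32-mm head
and invert the clinically expected linear-wear ordering (32-mm heads wear
shallower but wider). All values are per-construct configurable.

Bearing surfaces are quasi-uniform triangulated hemispheres: a Fibonacci
point set plus a closed equatorial rim, triangulated by Delaunay in the
Lambert azimuthal equal-area projection. At the default 0.75-mm edge
length, node areas sum to the analytic 2πR² within 0.1 % and the mean edge
is within ~7 % of target. Node areas are one third of incident triangle
areas.

## Contact

Confined-layer foundation stiffness k_f = E(1−ν)/[(1+ν)(1−2ν)t] with the
liner thickness t of each construct (the same t is used for both
dual-mobility articulations; the liner is the only compliant layer either
way). Pressures follow p_i = min(σ_y, k_f(**d**·**n̂**_i − c)₊). The yield
cap is the simplest elasto-plastic surrogate (no hardening law is modeled)
and is switchable. Peak pressures at walking loads are ~8–16 MPa on the
22.2-mm constructs.

Equilibrium is solved on the full displacement vector **d** by semi-smooth
Newton (analytic Jacobian over uncapped contact nodes, backtracking line
search), seeded by a bracketed scalar solve along the load axis. A scalar
axial solve alone cannot meet a 10⁻⁴ vector force balance on an
unstructured mesh — the discrete node set leaves a transverse quadrature
residual ~10⁻³ — hence the vector formulation, which reduces to the
axisymmetric law exactly in the continuum limit and is verified against a
dense 0.01°-grid quadrature oracle (peak pressure within 2 %). Degenerate
notes: zero load returns a zero field; loads beyond the fully yielded
capacity σ_y·πR² are reported as unsupportable; "doubling E halves
penetration" holds exactly only at zero clearance (with clearance the
pressure profile is affine, not linear, in penetration).

Friction (µ = 0.01) is excluded from the normal solve — tangential coupling
at that level is negligible — and enters only the motion-partition torque
rule.

## Dual-mobility motion partition

Euler sequence flexion → abduction → rotation (intrinsic z–x–y in the
pelvis frame: x anterior, y superior, z lateral, right hip), conjugated
into the cup frame. Per step, the head-relative-to-shell increment goes to
whichever articulation resists with less friction torque
T ≈ µ·R_eff·∫p dA; at near-equal load integrals the small articulation
always wins on radius. The third articulation is a threshold rule: when the
head–liner excursion exceeds θ_lim = 25°, the excess rotates the liner
(large articulation). Orientations are tracked as quaternions and the split
composes exactly.

The liner starts each simulated cycle at the cycle-mean head orientation —
the settled state toward which the threshold rule drifts any start. With
the default waveforms, peak excursions exceed θ_lim by at most a degree or
two, so the large articulation receives ~1 % of cycle path length and
~1.3 % of volumetric wear, reproducing the retrieval-literature pattern
that motion and wear predominate at the small articulation. This fraction
is calibration-sensitive (it is the excess of peak excursion over θ_lim);
only its smallness, not its exact value, is meaningful.

## Wear accumulation

Archard per node and step: Δh = k_w·p·Δs with Δs = |ω × r| and the
per-step pressures evaluated at step start, sliding across the step (100
uniform steps/cycle by default; a mesh/step convergence table is exposed as
`mesh_convergence_report`, with <1.5 % volumetric change from 1.5 to
0.75 mm). k_w(UHMWPE) = 10.656×10⁻⁷ mm³ N⁻¹ m⁻¹; k_w(XLPE) is exactly
20 % of that. The coefficient is constant — no pressure or cross-shear
dependence — so volumetric wear is exactly linear in k_w and in cycle
count, and the XLPE/UHMWPE end-to-end ratio stays within a few percent of
0.20 (the stiffer XLPE concentrates pressure slightly, a second-order
effect). One cycle × 10⁶ with no geometry update: wear-in transients and
geometry feedback are out of scope. Volume is Σh·A (first-order volume
difference; h ≤ ~0.1 mm ≪ R, error < 1 %).

## Statistics

Paired two-sided t-tests (difference CI from the t distribution, n−1 df).
Cohen's d uses the pooled two-group SD √((s_a²+s_b²)/2) — the convention
that reproduces published effect sizes for this comparison layout from
group summaries — with the large-sample normal CI
d ± 1.96·√((n_a+n_b)/(n_a n_b) + d²/(2(n_a+n_b))); a noncentral-t CI is
available via `d_ci_method: noncentral-t` (the two differ by ~1 % at
moderate d and more at d > 5, where published intervals are also sensitive
to input rounding). Significance level 0.05, no multiple-testing
correction. Shapiro–Wilk and OLS R² wrap scipy.

## Numerical and reproducibility choices

- Contact: vector residual ≤ 10⁻⁶·‖F‖ target, hard failure above 10⁻⁴;
  Newton ≤ 60 iterations with 30-step backtracking.
- Meshes are deterministic functions of (radius, edge length).
- All randomness flows from one master seed through
  `numpy.random.SeedSequence`; cohort and per-patient gait use disjoint
  spawned streams. Identical config + seed → bitwise-identical tables.
- Default problem sizes: 15 patients, 100 steps/cycle, 0.75-mm mesh
  (~1.6–6.9 k nodes per surface). The full five-construct study runs in
  ~15 s on one CPU; tests use coarser meshes where only structure matters.

## Known limitations

- The gait synthesizer's amplitude calibration anchors absolute wear; only
  ratios, orderings and effect structure are robust conclusions.
- Dual-mobility vs conventional 22.2-mm constructs differ here only through
  the small large-articulation wear term, so DM22PE ≈ SD22PE; solid-FE
  studies report DM slightly *above* the conventional cup (≈ +7 %
  volumetric), a difference this surrogate's identical small-articulation
  treatment cannot produce.
- No edge loading, microseparation, creep, third-body particles, or wear of
  metal counterfaces; no neck–chamfer geometry (threshold rule instead).
- Cohort variability (SD/mean ≈ 25 % for volumetric wear) is set by the
  demographic and gait-variability defaults, somewhat wider than published
  patient-specific cohorts (~16 %).
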