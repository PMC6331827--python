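# Methods

This note documents the model, the numerical choices, the synthetic-data
generators and the known limitations of `cpc-photokin`. Units are SI
internally (m, s, W, kg/m³) except TOC, which is ppm ≡ mg C/L, and time
axes, which are minutes of standardized illumination time (t₃₀W) at the
package interfaces.

## Radiation: the six-flux model

The six-flux model (SFM) tracks scattered photons along the six Cartesian
directions and yields a closed-form one-dimensional absorption profile.
Its inputs are the spectrum-averaged optical properties of the catalyst
slurry; the shipped defaults are the Aeroxide P-25 values averaged over the
solar spectrum up to the TiO₂ absorption edge (385 nm): κ = 174.7 m²/kg,
σ = 1295.8 m²/kg, p_f = 0.110, p_b = 0.710, p_s = 0.045. The phase
probabilities must satisfy p_f + p_b + 4p_s = 1 (one forward, one backward,
four side directions); this is validated at construction.

Derived chain (0.6 g/L, δ = 33 mm): ω = 0.8812, a = 0.8713, b = 0.6574,
ω_corr = b/a = 0.7545, τ = 29.12, τ_app = 16.65, λ = 1.982 mm,
γ = 7·10⁻¹⁶.

Three transcription ambiguities in the source equations were resolved on
physical grounds, each guarded by a test:

* **Corrected albedo.** The rendered definition reads like a product a·b,
  which gives 0.573 and contradicts the documented 0.75; the standard SFM
  definition ω_corr = b/a gives 0.7545 and is used.
* **Second LVRPA term.** The rendered profile repeats +√(1−ω_corr²) in the
  growing-exponential term, which diverges and can go negative; the
  backward-travelling term uses −√(1−ω_corr²) (the standard closed form).
  Non-negativity over the slab is asserted in tests.
* **Involute denominator.** The rendered reflector profile divides by
  1 − sin(θ−θ_a), which is singular exactly at the AB/BC junction; the
  standard CPC involute uses 1 + sin(θ−θ_a), restoring continuity
  (property-tested over acceptance angles).

A documented working value that the equations do not reproduce: the
apparent maximum optical thickness is quoted as 17.1 (0.6 g/L) and 11.43
(0.4 g/L), while the chain above gives 16.65 and 11.10 (~3% low). The
implied constant per unit load (17.1/0.6 = 28.5 per g/L) is not derivable
from the stated inputs. The package reports both values with the deviation
visible and does not force a match.

For ω_corr < 10⁻⁸ the 0/0 closed form is replaced by the analytic
Beer–Lambert limit I₀κC·exp(−κC·rp). The SFM slab is formally a two-flux
(Kubelka–Munk) slab with attenuation rate 1/λ and semi-infinite reflectance
R∞ = (1−√(1−ω_corr²))/ω_corr; the package uses that equivalence for
closed-form slab reflectance/transmittance, and tests verify the energy
closure 1−R−T = ∫LVRPA/I₀ and the semi-infinite absorbed fraction
(ω_corr−1+√(1−ω_corr²))/ω_corr = 0.5445.

## Cross-sectional field and the loading optimum

The detailed reflector optics are not resolved; illumination enters through
pluggable models on a cell-centred polar grid (default 50 radial × 72
angular nodes; midpoint quadrature closes the disc area to rounding error).

* `direct-reflect` (default): a planar SFM slab entering at the top of the
  tube (direct beam) plus a planar slab entering from below, carrying the
  aperture flux that misses the tube (aperture 2πR at the 90° acceptance
  angle, concentration ratio one) after one reflection at the involute
  (reflectance 0.85, typical of weathered anodized aluminium). The slab
  depth at a node is its vertical distance from the top of the tube, so
  the field varies radially *and* angularly.
* `uniform-perimeter`: axisymmetric wall illumination, the slab evaluated
  at depth R−r. Useful for bounding checks and the thick-slurry limit.

The choice of default matters for the optimum-loading analysis. Integrated
over the circular cross-section, the planar mapping reproduces the
characteristic rise–optimum–decline of VRPA/H versus apparent optical
thickness: past the optimum the absorption layer (thickness ~λ ∝ 1/C_cat)
concentrates near the top of the circle where the chord width vanishes, so
absorption becomes effective in a cross-section smaller than the physical
one and VRPA/H decays like 1/√C_cat. It also ranks 0.4 g/L above 0.6 g/L
(ratio 1.19; the documented VRPA ordering is 5.18 W/4.86 W = 1.066). An
axisymmetric wall-illuminated model cannot do either: its absorbed
fraction is strictly monotone in loading (we verified this numerically for
the slab, for chord-resolved energy balances, and for multi-bounce
reflector recycling), which is why `uniform-perimeter` is kept as a
secondary model rather than the default.

The absolute scale of the field depends on reflector details the model
does not resolve. With ideal optics the model gives VRPA/H = 0.63 W/m at
0.6 g/L; the documented working point is 0.405 W/m (VRPA = 4.86 W over the
12 m bank). The configuration therefore exposes an explicit calibration:
`kinetics.calibrate_vrpa_W: 4.86` rescales the optical efficiency
(η = 0.644 results) so the absolute VRPA matches the working point. The
calibration constant is visible in every report, never implicit.

## Hydrodynamics

Re = 4Q/(πDν) = 1.94·10⁴ at 30.2 L/min in the 33 mm tube — fully
turbulent. The power-law profile v_z = v_max(1−r/R)^(1/n) uses
n = 0.41√(8/f) with the Darcy–Blasius friction factor f = 0.316 Re^−0.25
(warned outside 4·10³ < Re < 10⁵). At the operating point n = 7.09 — the
classical one-seventh profile — and v_max/v_avg = (n+1)(2n+1)/(2n²) =
1.222. Flow conservation of the profile is property-tested against
quadrature for arbitrary n. The tube diameter is ambiguous in the source
(29 mm abstract, 32 mm OD/1.4 mm wall, 33 mm used in the computations);
the default follows the 33 mm value that reproduces the documented Re and
τ, and the config accepts any other.

## Kinetics and estimation

The modified L–H rate law is
r_TOC = −k_T K_R [TOC]/(1+K_R[TOC])·(photon term)^m with m = 0.5 by
default (recombination-dominated regime at solar irradiance; configurable
in [0.5, 1]). Two photon-term conventions exist and are never mixed
silently:

* **lumped** — the fit convention: VRPA^m with the tank-scale rate
  V_T·d[TOC]/dt₃₀W; k_T in ppm·m³·s⁻¹·W^−m.
* **local** — the reactor-marching convention: LVRPA^m per streamline;
  k_T in ppm·m^(3m)·s⁻¹·W^−m.

They are connected by the radiation geometry factor
G = ∫LVRPA^m dV / VRPA^m (0.0660 m^1.5 for the calibrated default field),
computed from the field at run time. Fitted (lumped) constants passed to
the simulator are converted with G so that the simulated initial tank rate
reproduces the fitted rate law exactly (asserted in tests at 2%).

Estimation: initial rates are OLS slopes over the first `window` (default
3) points of a trajectory; the linearised plot of 1/(V_T|d[TOC]/dt|)
against 1/[TOC]₀ yields K_R = intercept/slope and
k_T = 1/(intercept·VRPA^m). From the published regression
(slope 348,947, intercept 25,773, VRPA = 4.86 W):
K_R = 7.386·10⁻² ppm⁻¹ and k_T = 1.76·10⁻⁵ — reproduced to three
significant figures. The apparent adsorption constant under irradiation is
a different quantity from the dark K_ads (4.42·10⁻³ ppm⁻¹ here, one order
smaller) and no equality is asserted.

**A known inconsistency, quantified.** Driving the forward model with
those fitted constants removes 1.07% of TOC in the 42-minute standard run
at 213.6 ppm, against the observed 31.1%. The shortfall (×29) is not a
convention artefact: we checked every coherent reading (SI m³/s lumped;
local-LVRPA, whose aggregate is bounded above by the uniform-field case;
minutes or litres, which make it smaller). Equivalently, the published
intercept implies an initial rate of 0.055 ppm/min at 213.6 ppm where the
trajectories show ~1.7 ppm/min. The package surfaces this: `paper-mode
--calibrate` reports the data-calibrated effective k_T (5.15·10⁻⁴,
ratio 29.3) obtained by root-finding on the full simulation, and the
acceptance test for the 25–37% removal band fails honestly with the
constants as published. With the data-calibrated k_T the model reproduces
the observed behaviour well: 30.8/20.6/15.8% removal across
214/328/433 ppm versus the observed 31.1/16.9/14.6%, with the correct
strict ordering.

Time axes: t₃₀W accumulates Δt·(I_UV/30 W m⁻²)·(V_irr/V_T); UV-B
radiometer readings are converted to UV A+B by dividing by 0.10.

## Reactor simulation

Per pass, the 12 m tube bank is split into 100 axial sub-reactors (the
result changes <0.1% on doubling). Along each streamline the balance with
the segment-inlet TOC frozen in the saturation denominator integrates
exactly; complete cross-sectional mixing (CSTR-like, justified by
turbulence) is applied at each segment exit via the flow-weighted
mixing-cup average. The cell-centred grid excludes the wall node (v_z = 0)
by construction; quadrature flow must match Q within 1% or the run aborts.
The LVRPA field is treated as axially uniform, axial dispersion is
neglected, and the dark tank and piping are reaction-free. Passes number
Q·t₃₀W/V_R (123.6 for the standard run; V_R = 10.26 L derived from
geometry); the fractional remainder is a proportionally shortened reactor
(configurable to "floor"). Verified properties: exact mass conservation
(10⁻¹² over 124 dark passes), monotone trajectories, convergence to the
first-order exponential (K_R·C ≪ 1) and zero-order linear (K_R·C ≫ 1)
closed forms at 0.5%, and 1% agreement with a full 2-D method-of-lines
integration that drops the per-segment linearisation.

## Synthetic data

The generators emulate the statistical structure of the study's
measurements, not their chemistry:

* **Adsorption**: Langmuir equilibria (defaults q₀ = 1.52 mg/g,
  K_ads = 4.42·10⁻³ ppm⁻¹) over 50–450 ppm with multiplicative noise; the
  emitted table is mass-balance-consistent.
* **Decay**: trajectories from the forward model at the pilot-plant
  operating point, sampled every 3 min over 42 min, with 3% multiplicative
  Gaussian TOC noise by default (typical analyser repeatability; additive
  mode available; non-positive draws are resampled and counted). The
  generator's kinetic constants default to the data-calibrated k_T (so the
  synthetic decays look like the observed ones) with K_R on the
  weak-adsorption scale. An estrogen channel is attached as
  (TOC/TOC₀)^2.25 — sized so ~57% estrogen removal accompanies ~31% TOC
  removal — for interface completeness only; it is never fitted.
* **Irradiance**: AR(1) cloud-attenuation logs, mean-correct by
  construction, with the accumulated dose (kJ/m²) reported.

All generators are byte-deterministic under a fixed seed. What passing
round-trip tests show is that the *pipeline* is correct — they cannot show
that the L–H form or the SFM describes real water matrices, excipient
chemistry or catalyst aging, none of which the generators emulate.

**Parameter-recovery study.** The study regenerates three decay
experiments (214/328/433 ppm) from known constants, pushes them through
the initial-rate + linearised-fit pipeline, and reports the error
distribution over 500 seeded replicates. Two structural facts limit what
any such design can achieve: (i) with K_R·C₀ ≫ 1 (the published K_R) the
regression ordinate varies only ~3% across the design, so K_R is
unidentifiable under realistic noise; (ii) the initial-rate OLS window
amplifies concentration noise roughly tenfold into rate noise
(relative rate error ≈ σ_rel·3.46/(√w·f_w), with f_w the fraction removed
inside the window). Consequently, at 5% TOC noise the recovery passes the
15%/25% tolerances in under 1% of replicates even in the identifiable
regime — the corresponding acceptance test is left failing as an honest
negative result — while at 0.2% noise with minute sampling the pipeline
recovers the constants in the majority of replicates (unit-tested).

## Numerical and problem-size choices

Defaults: 50×72 polar nodes, 100 sub-reactors, full 124-pass runs
(~0.5 s). Monte-Carlo and oracle-comparison tests use a 20×24×25
configuration whose standard-run removal differs from the default grid by
~0.1%. Tolerances quoted above are asserted in the test suite at the
stated values; seeded tests derive child seeds from `numpy SeedSequence`
and keep them below 2³¹.

## Limitations

No wavelength-resolved transfer, ray tracing, or solar-angle dependence;
no multilayer (BET/Freundlich) adsorption, although the data hint at it
above ~400 ppm TOC; no transformation-product chemistry, oxygen transfer,
pH or temperature dynamics; photolysis is neglected in the photocatalytic
model. The absolute radiation scale is calibrated, not predicted.
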