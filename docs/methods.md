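# Methods

This note documents the model equations, the numerical choices and the
design decisions behind `spac`, in the order water flows through the system.

## Forcing

The simulator consumes hourly series of air temperature, relative humidity,
shortwave radiation, pressure, wind, precipitation and CO₂.
Vapour pressure deficit is always derived, D = (1 − RH)·e_sat(Ta), with
e_sat the Tetens formulation (611 Pa base). Any standard saturation formula
would do — every model variant shares it, so variant comparisons are
insensitive to the choice. Photosynthetically active radiation is taken as
45% of shortwave energy at 4.57 μmol photons J⁻¹; spectral and
direct/diffuse partitioning are out of scope. Timestamps are hour-beginning
and the model step is one hour.

**Synthetic archive and percentile day.** The dry-down experiments need an
"average warm and sunny day". `forcing.synthetic_archive` generates a
multi-year June–August hourly archive with a sinusoidal diurnal temperature
cycle (default 24 °C mean, 7 °C amplitude, 2 °C day-to-day anomalies),
clear-sky radiation (900 W m⁻² peak) modulated by a Beta(5, 1.5) daily cloud
factor, relative humidity anti-correlated with temperature, and occasional
afternoon showers. `make_percentile_day` then composes, per hour of day, the
75th percentile of temperature and radiation, a chosen percentile of
relative humidity (10th for the high-VPD scenario, 90th for low-VPD), and
medians of everything else, recomputing D from the composed Ta and RH. The
generator emulates the statistical structure that the composite needs —
realistic diurnal shapes and day-to-day spread — but not weather
persistence, fronts, seasonality or site-specific climate; passing tests
therefore demonstrate correct model behaviour under controlled forcing, not
skill against any real site.

## Soil

A bucket column of (by default) three layers (0.3/0.3/0.4 m; root fractions
0.5/0.3/0.2) with van Genuchten–Mualem retention and conductivity
(θr = 0.05, θs = 0.45, α = 2 m⁻¹, n = 1.6, ks = 5·10⁻⁶ m s⁻¹ — a loam with
~110 mm of plant-available water per metre). Clapp–Hornberger power laws are
available behind `retention.model`. The soil water potential seen by the
plant is the retention curve applied to the root-weighted water content,
ψs = P(Σ wᵢθᵢ); the alternative (weighting per-layer potentials) is
provided but not the default. Soil-to-root conductance follows the
root-cylinder form kr = cf·ks(ψs)·2πRl / ln(rc/rr) with Rl = 5000 m m⁻²,
rc = 0.05 m, rr = 0.5 mm and cf = 10⁶/(ρg) so kr is in m s⁻¹ MPa⁻¹.

The water-balance step is operator-split: root uptake (limited by available
water per layer), then gravity percolation at the antecedent unsaturated
conductivity with free drainage at the base, then infiltration filling
layers top-down — so a soil-saturating storm leaves the column saturated at
the end of its hour. Mass balance closes to < 10⁻¹² m per step by
construction and is asserted to < 10⁻⁹ m in the tests. Negative uptake
(hydraulic redistribution from plant to soil) is rejected everywhere.

## Gas exchange

C3 photosynthesis is Farquhar-type: Rubisco- and RuBP-limited rates with
peaked Arrhenius temperature responses (standard published kinetic
coefficients; Vcmax25 = 60, Jmax25 = 114, Rd25 = 0.9 μmol m⁻² s⁻¹,
Γ*₍₂₅₎ = 42.75 μmol mol⁻¹). The canopy is a single big leaf at air
temperature, scaled linearly by LAI; there is no leaf energy balance and no
light extinction profile, simplifications shared by all variants.

Two stress factors act multiplicatively:

* fs = exp(−q|ψs|^p), the empirical soil-water stress on assimilation
  (defaults q = ln 2, p = 2: fs = 0.5 at −1 MPa). Realised assimilation is
  An = fs·Anpot in **all** variants, so the variants differ only in their
  stomatal behaviour.
* fl = exp(−a_l|ψs−ψl|^γl), the hydraulic stomatal down-regulation. The
  default (a_l, γl) = (ln 2, 1.1705) comes from the closed-form two-anchor
  calibration in `calibrate_fl`: a 1.0 MPa soil-to-leaf drop gives exactly a
  50% conductance reduction and a 0.2 MPa drop exactly 10%.

Stomatal models (gs is CO₂ conductance; water conductance is 1.6·gs):

* `leuning` (baseline): gs = g0 + a1·fs·Anpot / ((ci−Γ)(1+D/D0)),
  a1 = 7, g0 = 0.01 mol m⁻² s⁻¹, D0 = 1500 Pa.
* `tuzet` (hydraulic default): gs = g0 + a1·fs·Anpot/(ci−Γ)·fl.
* `tuzet_no_fs` and `tuzet_light_only`: decoupled alternatives using
  fl* = exp(−a_s|ψl|^γs); the light-only form needs a slope in conductance
  units per assimilation rate, implemented as a1·10⁻³ per μmol.

The An–gs–ci fixed point An = gs·(ca−ci) is solved by bisection on a bracket
that provably contains the root (expanded above ca for respiring leaves);
48 bisections put the residual far below 10⁻⁸. Transpiration is
T = 1.6·gs·LAI·(D/Patm)·Mw/ρ in m s⁻¹ of ground-area water flux.

## Plant hydraulics

Two nodes: stem xylem and leaf, with vulnerability curves
kx = kxmax·exp(−qx|ψx|^px) and kl analogous. Defaults: kxmax = 1.2·10⁻⁷,
klmax = 2.4·10⁻⁷ m s⁻¹ MPa⁻¹, P50 of 3 MPa (xylem) and 2.5 MPa (leaf) with
quadratic exponents. Whole-plant conductance can instead be scaled from
tissue conductivity as kxmax = k′x·Ax/(h·ρ). Gravitational potential is
neglected. Internode conductances are geometric means evaluated at the
*unknown* potentials, i.e. inside the solver residuals.

**Steady variant.** A Powell-hybrid root solve for (ψx, ψl) is the primary
method, warm-started from the previous hour. Convergence requires the
flux-conservation residual below 1% of T. If that fails, a deterministic
nested stage solves flux continuity exactly in ψx (48-step bisection) for
each candidate ψl and brackets the outer residual supply(ψl) − T(ψl) along a
64-point scan; this either refines to the shallowest root (the branch
physically continued from wet conditions — the system can have multiple
roots under strong vulnerability) or proves that no root exists (the g0
demand floor exceeding the maximum possible supply, which happens in deep
drought for a storage-free plant). Only in the ambiguous case does the
100-start seeded constrained multistart (trust-region interior point,
ψs ≥ ψx ≥ ψl) run. Hours with no root are flagged, the best-compromise state
is used, and the soil sees the actual root extraction J_s→x rather than the
unsatisfiable demand.

**Capacitance variant.** Storage capacities are Vxmax = h·Ax·nx (default
25 m × 2.5·10⁻³ × 0.4 = 25 mm — a deliberately high-capacitance canopy,
where storage signatures are strongest) and
Vlmax = LAI·LMA·((1−LDMC)/LDMC)/ρ ≈ 0.67 mm. Linear pressure–volume curves
ψ = c(1−V/Vmax) with cx = −12, cl = −6 MPa. The ODEs are integrated per
forcing hour with `solve_ivp`; the default method is LSODA — the system is
stiff (leaf time constant ~10 min against the 1 h step), and LSODA needs
~80 right-hand-side evaluations per hour where the embedded RK(2,3) pair
(also available as `ode_method="RK23"`, rtol 10⁻⁶, atol 10⁻¹² m) needs
~1500 for trajectories agreeing to ~10⁻⁸ relative. The state vector is
augmented with cumulative influx/outflux integrals, so the hourly balance
|ΔVx+ΔVl − ∫(J_s→x − T)| closes to round-off regardless of step size; both
integrators are asserted below 10⁻⁹ m per hour. Storage bounds are
intrinsic: at V = Vmax the potential is zero and inflow reverses, and
demand is smoothly throttled below 5% leaf fill (a numerical desiccation
guard). Xylem-to-soil backflow is clamped to zero (no hydraulic
redistribution); leaf-to-xylem backflow is allowed so leaves refill at
night. Soil state is recoupled each forcing hour by default (configurable);
at these flux magnitudes the root-zone water content changes by < 0.1% of
plant-available water per hour, so sub-hourly recoupling changes hourly
fluxes negligibly while multiplying cost.

## Irreversible damage

Each conducting tissue carries an age-density p(α) over daily classes
(10-year span for sapwood, 1-year for leaves; the oldest class is
absorbing) plus a per-class minimum-potential memory, initialised to the
steady-age truncated exponential with ψmin = 0. Effective conductivity is
k_eff = Σ pᵢ·kmax·exp(−q|ψmin,ᵢ|^p): no refilling, so with zero turnover
k_eff is non-increasing for any potential trajectory — the property is
asserted exactly over randomized traces. Inside the hydraulic solvers the
damaged vulnerability curve responds to the deeper of the candidate
potential and each cohort's memory; realised potentials are committed to
the memory hourly. Aging is an upwind shift (the within-day hydraulic step
never changes p), turnover removes mass oldest-first, and recruitment
enters at age zero undamaged ("born full of water"), with fractional rates
λ and μ supplied daily by the carbon module; the density is renormalised
each step (drift < 10⁻¹² over 10⁵ steps). Memory tracking is suspended
while the canopy is effectively leafless, avoiding spurious dormant-season
damage; the toggle `suspend_when_dormant` restores the raw behaviour.

## Vegetation carbon

A deliberately minimal two-pool scheme for the dynamic-vegetation
experiments: NPP = (1−0.5)·GPP, allocated 0.35/0.35 to leaves and sapwood,
first-order turnover at 1/120 d⁻¹ (leaves) and 1/1825 d⁻¹ (sapwood),
LAI = SLA·Cleaf with SLA = 25 m² (kg C)⁻¹. Initial pools (0.12, 2.0 kg C
m⁻²) sit near the equilibrium the defaults imply at LAI = 3. Damage-aware
allocation is deliberately absent — the damage legacy is therefore an upper
bound, since a real plant would prioritise rebuilding conducting tissue.

## Experiments and diagnostics

**E1** repeats the percentile day for 250 days with no rain, static
vegetation and saturated initial soil; variants run on identical forcing.
**E2** dries down until the empirical stress factor fs reaches 0.2
(evaluated hourly; the run stops at the end of that day), then saturates
the soil and follows ≥ 100 days of recovery with dynamic vegetation. The
relief hour is determined once from the no-damage capacitance run and
imposed on every variant so all share identical pre-relief forcing. Because
no rain falls after the relief event, a second dry-down eventually begins;
the damage variant transpires less, keeps its soil wetter and so is
stressed *later* in that recursive drought — the legacy ordering
(damage ≤ no-damage for GPP, T and LAI) is therefore asserted over the
recovery window in which both runs remain unstressed (fs ≥ 0.9), which is
the phase the legacy effect describes.

Diagnostics: the 90%→50% GPP decline time uses the mean of the first five
pre-drought days as the initial rate (the "initial rate" is otherwise
undefined) and linearly interpolated first crossings; water-use efficiency
is the mean daily GPP/T ratio over a window with zero-transpiration days
excluded; diurnal composites are per-hour means over complete days,
optionally normalised to a unit maximum; surface conductance is recovered
by the standard Penman–Monteith inversion
Gs = γ·λE·Ga / (Δ(Rn−G) + ρa·cp·D·Ga − λE(Δ+γ)) (non-physical denominators
flagged as missing) and binned against VPD in half-open 200 Pa bins.

## Numerical and scope notes

* All potentials are negative MPa; vulnerability and stress formulas
  consume |ψ|, and curves clamp ψ > 0 to the undamaged value.
* Runs are bit-reproducible: the multistart RNG is keyed on
  (seed, absolute hour), which also makes checkpoint restarts exact.
* Problem sizes in the shipped experiments — 250-day E1, ~160-day E2,
  50-case solver cross-checks — were chosen so the full property suite
  completes on a single CPU in minutes while still resolving every
  signature; all are configurable upward.
* Known limitations: single big leaf (no sun/shade split, no leaf energy
  balance), bucket soil (no Richards flow, no soil evaporation, no
  freeze–thaw), two carbon pools (no phenology, reserves or roots), linear
  pressure–volume curves, C3 only. The E-series experiments probe variant
  *differences* under controlled forcing; none of the defaults is a
  calibrated description of a particular site.
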