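# Methods

## Scope and model chain

`plaquesim` implements a continuum mechanobiological model of early atheroma
formation on a 2D (axial × transmural) arterial-wall domain. The chain is
one-way: a frozen endothelial WSS history determines haemodynamic stimuli and
endothelial transport properties once, the wall species then evolve for the
full horizon under those fixed boundary conditions, and growth is evaluated as
a closing stationary step. There is no fluid–structure interaction and no
reverse (wall → lumen) transport.

## Haemodynamic fixtures

Transient CFD is deliberately out of scope. Each endothelial station carries a
biased sinusoid τ(t) = m(1 + γ sin 2πt/T), T = 0.85 s. For γ > 1 the traction
reverses during part of the cycle; the cycle-mean magnitude is
|m|·g(γ) with g(γ) = (2/π)(θ₀ + γ cos θ₀), θ₀ = arcsin(1/γ), while the signed
mean stays m, so any target (TAWSS, OSI) pair is hit exactly by inverting
g(γ) = 1/(1 − 2·OSI) (closed form, Brent root find). Outside the atheroprone
patch the mean traction comes from the Poiseuille relation 4μQ/(πR³) at the
configured mean flow; the defaults (Q = 5.4 mL/s, R = 2 mm, μ = 3.5 mPa·s)
give TAWSS ≈ 3.0 Pa, i.e. a healthy carotid-like baseline. The patch defaults
(TAWSS = 0.5 Pa, OSI = 0.35 on s ∈ [20, 30] mm) represent a strongly
disturbed-flow niche such as the outer wall of a carotid bulb.

What the fixture emulates: the magnitude, pulsatility and directional reversal
of carotid WSS, with exact periodicity (so multi-cycle flow development is
unnecessary). What it does not: spatial waveform shape from a real bifurcation,
secondary/transverse flow components, and the correlation structure between
neighbouring stations. Passing end-to-end tests therefore demonstrate the
*mechanistic* behaviour of the downstream model under controlled stimuli, not
agreement with any patient geometry.

## Stimuli and shape index

TAWSS and OSI are composite-trapezoid integrals over the supplied cycle
samples; a quadrature-convergence property test guards accuracy, and the
fixtures control sampling density (64 samples/cycle by default). OSI at
TAWSS = 0 is defined as 0 with a warning (a shear-free node has no oscillation
to index). The three SI correlations and the thresholds (TAWSS < 2 Pa,
OSI > 0.1910, strict) are stored constants; the OSI threshold is a
configuration constant, not derived from chaining the correlations (the chain
does not reproduce it). With the fitted constants the TAWSS correlation has a
stationary point near 4.6 Pa, so its monotone decrease is only asserted on
[0, 4] Pa.

The monocyte-recruitment factor for the TAWSS mode is implemented as the
decreasing reciprocal 1/(1 + TAWSS/TAWSS₀), which matches the ≈1 → ≈1/3 range
of the OSI and combined factors over the atheroprone band; the increasing
literal product form is available behind the `tawss_factor_literal` toggle for
comparison.

## Three-pore endothelium

The SI → MC → LC → Φ_lj chain uses the experimental correlations quoted in the
README with the 0.64 mm² unit area. Hydraulics: Lp_slj = w_l²/(3 μ_p l_lj),
Lp_lj = (4 w_l/R_cell)·Φ_lj·Lp_slj, ΔP from linear interpolation of the
(70 → 18, 180 → 28) mmHg anchors, and J_v = (Lp_nj + Lp_lj)·ΔP with the
vesicular plasma pathway identically zero (kept in the audit output).

The hindered-transport closure for LDL in a leaky-junction slit (half-width
w_l = 20 nm, molecule radius a_m = 11 nm, α = 0.55) is pluggable; the default:

- partition coefficient Φ_p = 1 − α;
- diffusive hindrance H_d(α) = 1 − 1.004α + 0.418α³ + 0.21α⁴ − 0.169α⁵
  (centerline slit polynomial), so P_slj = Φ_p·H_d·D_free/l_lj;
- solvent-drag reflection σ_f = 1 − Φ_p(3 − Φ_p²)/2 (parabolic slit profile,
  no hydrodynamic lag);
- entrance-gradient factor Z_lj = 1.

Each piece can be overridden numerically or functionally without touching
callers. D_free defaults to Stokes–Einstein at 310 K (≈2.06·10⁻¹¹ m²/s). The
deposited fraction LDL_dep = 10⁻² multiplies the lumen concentration once
(dimensional consistency of the Kedem–Katchalsky solute flux); P_app,v is
exactly 0.1·P_app,lj, so P_app = 1.1·P_app,lj.

**Gating.** Endothelial species influx (LDL and monocytes) is applied only at
atheroprone stations in the selected stimulus mode. This realizes the model's
premise that the SI threshold marks where macromolecules cross the
endothelium; without it every station, including a fully healthy vessel,
accumulates foam cells.

**Monocyte saturation.** The recruitment flux
J_m = m_r·f(stimulus)·C_LDLox,w·C_m,l is multiplied by (1 − C_m,w/C_m,th),
applied implicitly in the transport solve so the wall-side monocyte pool is
bounded by its threshold at any step size. The threshold is tabulated with the
other inflammation parameters but appears in no printed rate law; without the
saturation the monocyte pool grows without bound and trips the blow-up guard.

**Adventitial LDL condition.** Default is outflow-only: convective export at
the adventitia, no diffusive re-entry. With the tabulated parameters the
wall-side LDL stays everywhere below the adventitial reference level
(11.6 ‰ of lumen), so a two-way Dirichlet condition at that value turns the
adventitia into the wall's dominant LDL source — in measurements on the patch
fixture it contributed 93 % of all oxidized LDL, drove C_LDLox three orders of
magnitude above the lumen concentration, and erased the stimulus-mode contrast
that is the model's central output. The one-way default keeps transport
lumen → wall → adventitia; the two-way Dirichlet remains available via
`ldl_adventitia_bc: dirichlet`.

## Wall model

**Darcy flow.** Cell-centered finite volumes on the tensor-product mesh;
u = −(k_w/μ_p)∇p; J_v imposed as endothelial inflow, p = 17.5 mmHg anchored at
the adventitia, no-flux lateral edges. The endothelial face velocity equals
the imposed J_v by construction. The thin-wall domain is treated as locally
Cartesian (unit circumferential depth); at thickness/radius ≈ 0.35 the metric
error this ignores is well below the model's parametric uncertainty.

**Species.** Nine fields; diffusion for LDL, oxidized LDL, monocytes and
macrophages (tabulated diffusivities), convection only for LDL at K_lag·u
(K_lag = 0.893), reactions for all. Initial state: zeros except contractile
SMCs at 3.16·10¹³ cells/m³. Non-LDL species have zero-flux walls apart from
the endothelial influx.

**Time integration.** Operator splitting with a macro step ramping
geometrically (×1.3) from 1 h to a 30-day cap over the 9.46·10⁸ s horizon:

1. *Reaction substep*: vectorized adaptive TR-BDF2 (trapezoid to γh,
   γ = 2 − √2, then BDF2; L-stable, 2nd order) with analytic 9×9 Jacobians,
   modified Newton, and a stage-matrix-filtered third-divided-difference error
   estimate; tolerances rtol = 10⁻⁵, atol = 10⁻⁶ × per-species reference
   scales.
2. *Transport substep*: backward-Euler sparse solves per diffusing species
   (direct LU, cached per step size), upwinded convection; the scheme is an
   M-matrix, so positivity is preserved.

Two linear fast processes are solved *inside* the implicit transport operator
rather than split: LDL oxidation (τ ≈ 1 h) and monocyte turnover (τ ≈ 9 d),
with the converted mass (d_LDL·C_LDL → oxidized LDL, d_m·C_m → macrophages)
added to the receiving field in the same step. Pure splitting at 30-day steps
mis-handles both — LDL crosses the wall un-oxidized (transit ≈ 18 h) and
monocytes die before transport refills them — producing first-order errors of
order 50 % on 2-year foam-cell counts; with the coupled treatment the measured
step-size sensitivity of 30-year foam cells is 0.16 % under a halved step.
Residual coupling error (monocyte influx evaluated from the start-of-step
oxidized-LDL field) is first order but small because that field evolves on
multi-month timescales.

Safeguards: tiny negative undershoots are clipped to zero with the clipped
mass logged; a blow-up guard aborts when any field exceeds 10³ × its reference
level (printed thresholds where they exist, generic scales otherwise). An LDL
mass ledger (endothelial influx, adventitial outflux, oxidized conversion,
stored mass) closes to machine precision by construction and is asserted to
1 % in the acceptance suite.

**SSMC apoptosis.** The tabulated rate r_apop = 0.087 s⁻¹ is used exactly as
printed. At that rate synthetic SMCs die within seconds of forming, so the
SSMC and collagen contributions to growth are negligible and plaque volume is
foam-cell dominated. If the intended unit was per day the SSMC/collagen terms
would matter; the rate is a single config field if a user wishes to explore
that.

## Growth and stenosis

Default (final-stationary-step) mode converts the 30-year species change into
∇·v with the printed cell volumes — spheres of radius 15.264 µm for foam
cells; (4/3)πR²l with the *full* SSMC length as printed (the geometric
ellipsoid with semi-axis l/2 is a toggle) — and collagen mass over
ρ_G = 1000 kg/m³. Growth is columnar: the transmural integral of ∇·v·horizon
becomes an inward endothelial displacement with the adventitia fixed, the
lumen radius floored at 5 % of healthy (capped stations logged). SR is
evaluated per station against the healthy radius and reported at the most
occluded station.

**Mid-course update.** The two-pass experiment runs to a split time, narrows
the lumen with the accumulated growth, re-evaluates the stimulus on the new
geometry and finishes the horizon with the species state carried over. The
WSS update uses the fixture flow model: TAWSS rescaled by (R₀/R_new)³
(Poiseuille at conserved flow), plus a post-stenotic disturbance surrogate —
downstream of any station whose area stenosis exceeds 20 %, OSI is raised to
the peak stenosis fraction (capped at 0.45) over a 4-diameter recovery
length, standing in for the separated, oscillatory flow behind a constriction
(separation onset in pulsatile stenotic flow is reported from roughly a
quarter of the area). A degenerate split at the horizon reproduces the
single-pass result exactly. Under the default study conditions the
half-horizon stenosis is ≈0.26 % area, far below the disturbance onset, so the
update is essentially inert there; meaningful two-pass effects require
geometries or conditions that reach tens of percent stenosis by the split.

## Problem sizes and determinism

The study configuration is 50 axial × 20 transmural cells over 30 simulated
years (≈410 macro steps, well under a minute on one core); scaled-down meshes
are used for self-convergence and invariant tests, and the well-mixed oracle
comparison runs on a 10-cell mesh so the PDE machinery can be checked against
a direct stiff-ODE integration over the full horizon. Every stage is
deterministic for a fixed configuration; the only randomness is the optional
per-node jitter of the fixture generator, driven by the configured seed.

## Known limitations

- No CFD, turbulence, non-Newtonian rheology or fluid–structure interaction;
  the fixture waveforms are parametric, not patient-matched.
- 2D axisymmetric-style growth: stenosis from a patch is treated as
  circumferentially uniform, so eccentric plaques and the area effects of
  partial-circumference lesions are not represented.
- One cytokine species; no T-cells, free radicals, mechanotaxis or collagen
  ageing; transport properties constant during growth.
- The growth step does not re-mesh the wall; displacement is bookkept against
  the healthy geometry.
- Patient-specific stenosis ratios are outside the fixture's reach by design;
  the end-to-end tests assert mechanistic behaviour (localization, healthy
  quiescence, stimulus-mode ordering), not clinical numbers.
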