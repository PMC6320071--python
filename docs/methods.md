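# Methods

## The dumbbell model

A protein construct is tethered between two optically trapped beads through a
2,260-bp dsDNA handle.  The control parameter is the trap separation `D`
(relative convention: constant bead diameters excluded, so they never enter
any equation).  Traps, handle, unfolded polypeptide and the folded "hard
core" `H` (the force-independent distance between the pulling points of the
folded portion) are in mechanical series:

    D = F/k1 + F/k2 + x_DNA(F) + x_p(F) + H.

Every component extension is strictly monotone in the tension `F`, so the
balance has a unique root, found by bracketed bisection to a residual below
1e-6 pN.  Polymers follow the Marko–Siggia worm-like chain interpolation; its
closed-form antiderivative supplies the entropic stretching energies, and the
total free energy of a construct state at separation `D` is

    G(D) = F²/(2 k_traps) + E_DNA + E_p + V,   k_traps = k1 k2/(k1+k2),

with `V` the state's zero-force free energy.  Two-state statistics on
`ΔG(D) = G_unfolded − G_folded` drive the occupancy model, the rate model and
the simulator, which therefore invert each other exactly.

Constants: kBT = 4.114 pN nm (298 K; the temperature is configurable),
persistence lengths 40 nm (dsDNA) and 0.6 nm (unfolded polypeptide), handle
contour 0.34 nm/bp × 2,260 bp (the B-DNA rise is our choice; the handle
length in bp is part of the construct), 0.365 nm of contour per amino acid.
Trap stiffnesses default to k1 = k2 = 0.2 pN/nm, a typical value for this
instrument class; the published energies and rates that the pipeline targets
are properties of the construct, not of the traps, and the recovery tests are
stiffness-independent because generator and fits share the model.

### Measured extension changes vs. protein length changes

At fixed `D` a folding transition changes the measured tether extension by
`ΔX = ΔF·(1/k1 + 1/k2)` — the bead retraction — which is *attenuated*
relative to the protein's length change `Δl(F) = z(F)·ΔL − ΔH` because the
DNA handle and the remaining unfolded polypeptide also relax when the force
drops.  (Here `z(F)` is the WLC relative extension of the polypeptide, `ΔL`
the contour change and `ΔH = H_folded − H_unfolded`.)  The HMM emission-mean
separation estimates `ΔX`; contour inference must therefore convert measured
jumps through the dumbbell model before dividing by 0.365 nm/aa.  Ignoring
this distinction is a classic factor-of-~2 error at these stiffnesses.

## Wild-type scenario calibration

The synthetic generator's wild-type scenario encodes the template complex's
measured landscape: unfolding energy ΔV = 5.2 kBT, midpoint force 5.1 pN,
measured extension change 5.42 nm at the midpoint, zero-force unfolding rate
0.7 s⁻¹ (lifetime 1.4 s).  With ΔV fixed, the transition's contour change ΔL
and hard-core change ΔH are the only structural unknowns; they are solved
(bounded least squares on the two residuals) so that the model's two states
are equally populated at exactly 5.1 pN with a measured jump of exactly
5.42 nm.  The calibration lands at ΔL = 34.1 nm (93 residues) and a hard
core *larger in the folded state* by 2.78 nm — both consistent with the
structural picture of a compact folded complex sequestering ~90 residues
with a ~3 nm hard-core growth.  The folded state's residual disordered
contour (35 nm) and hard core (5 nm) are fixed baseline choices; the
transition observables depend only on the state differences.

Detailed balance pins the zero-force folding rate to
k_f(0) = k_u(0)·exp(ΔV) = 0.7·e^5.2 = 126.9 s⁻¹, a few percent below the
measured average of 132 s⁻¹ (whose standard error is of the same order); the
generator keeps ΔV and k_u exact and lets k_f follow, because thermodynamic
closure is what the recovery tests exercise.

## Rate model

Rates derive from a minimal Kramers barrier: a transition state that is
itself a construct state, its contour and hard core linearly interpolated a
fraction `f` of the way from folded to unfolded (default f = 0.5), so that

    k_u(D) = k_u(0) · exp(−[mech‡(D) − mech_f(D)]),
    k_f(D) = k_f(0) · exp(−[mech‡(D) − mech_u(D)]),

with `mech` the mechanical part of `G`.  The attempt prefactor and the
transition state's zero-force energy enter only through k_u(0), so they are
not separately identifiable — the fit estimates (log k_u(0), f) by least
squares on log rates, with the barrier reported relative to a configurable
attempt rate (default 10⁴ s⁻¹) for orientation only.  When the data cannot
constrain `f`, it can be pinned at 0.5.

## Trajectory idealization

Constant-separation records are segmented with a two-state Gaussian-emission
HMM (hmmlearn's EM/Viterbi under a deterministic median-split initialization,
so results are a function of the data alone).  The higher-extension state is
labelled unfolded.  No minimum dwell is imposed; instead the first and last
(censored) dwells are excluded from rate estimates.  Rates are reciprocal
mean interior dwell times; a transition-matrix estimator (k = a_ij × sampling
rate) is provided as a cross-check and agrees within ~10% on well-sampled
records.  Records where one state holds >99.5% of samples, or whose emission
means are closer than half an emission sd, are flagged "no transition" rather
than fitted.  An optional moving-average filter is exposed but off by
default.  The equilibrium force is the mean of the two per-state average
forces interpolated to 50% occupancy, matching the operational definition
used with this instrument geometry.

Sampling defaults to 1 kHz with white Gaussian noise of σ = 1.5 nm — at the
5.42 nm transition this gives a signal-to-noise ratio of ~3.6, visually
matching published trace quality.  An exact-discretization Ornstein–Uhlenbeck
noise option (corner frequency configurable) is available; true instrument
noise spectra are not modeled beyond this idealization.  The force channel
carries the anti-correlated bead response `F = F_state − k_traps·δX`.

## Landscape fits

The occupancy fit is single-parameter: `P_u(D) = 1/(1+exp(ΔV + Δmech(D)))`
with the mechanical profile fixed by the structural model.  It is a binomial
maximum-likelihood fit (equivalently, iteratively reweighted least squares
with binomial weights) using per-record transition counts as effective
observation numbers; the SEM comes from the observed Fisher information.
Occupancies all saturated near 0 or 1 are rejected as unidentifiable.
Zero-force extrapolation always goes through the full nonlinear dumbbell
model; a linear force–log-rate (Bell) treatment is deliberately not used for
reported numbers.  Per-molecule results aggregate as unweighted means with
SEMs across molecules.

The mechanical work at the midpoint, `F_eq·Δx`, is reported as a separate
quantity: it exceeds ΔV by the entropic stretching energy of the released
polypeptide and must never be conflated with it (5.1 pN × 5.42 nm = 6.7 kBT
vs ΔV = 5.2 kBT for the wild type).  kBT converts to kcal/mol at 0.593.

## Tethered-ligand binding

The crosslinked conjugate holds the ligand at a Gaussian-chain effective
concentration `c = N_A⁻¹ (3/(4πpL))^{3/2} exp(−3R²/(4pL))` around its pocket
(p = 0.6 nm; the density integrates to unity over all pocket distances, which
the tests verify against direct quadrature).  Because folding is
binding-limited in this geometry, the measured folding and unfolding rates
double as association and dissociation rates at concentration `c`, giving
`k_on = k_f/c`, `K_d = k_off/k_on` and a binding energy `ln(1 M/K_d)` at the
1 M standard state (configurable).  Affinities extrapolate to an alternative
receptor conformation as `K_d·exp(ΔΔG)`.

Relative fusion-rate predictions use the stability/binding-probability model
`k_m/k_WT = (r_m/r_WT)·exp(G_m − G_WT)` with `r` taken as the raw downstream
binding probability (the simple ratio keeps saturated probabilities finite);
uncertainty propagates to first order from the energy SEMs only.  Variant
stabilities below the 1.5 kBT detection limit propagate as censored — the
prediction is reported as abolished, never as a number computed from the
detection limit.

## Synthetic data and what passing tests show

Constant-separation records use exact continuous-time (Gillespie) jumps —
never per-sample Bernoulli switching, which biases dwell statistics — sampled
onto the acquisition grid; pulls ramp `D` at 10 nm/s by default with
per-sample switching from grid-interpolated rates, and a quasi-static mode
returns the equilibrium force–extension curve.  A bead-noise generator
(exact OU, equipartition variance, Lorentzian spectrum) serves the trap
calibration, which fits the one-sided Welch PSD to `A/(f_c²+f²)` in log
space below fs/8 (the aliased tail near Nyquist would otherwise bias the
corner) and reports `k = 2πγf_c`.

The generator emulates two-state Markov switching, WLC state levels and
stationary Gaussian/OU noise.  It does not emulate drift, multistate or
off-pathway kinetics, bead rotation, hydrodynamic coupling, or detector
nonlinearity — so recovery tests demonstrate the correctness and statistical
calibration of the analysis chain under the stated model, not robustness to
every artifact of real data.

## Problem sizes and numerical choices

Recovery runs use 8 separations spanning folded-state forces 4.0–6.5 pN,
100 s per record at 1 kHz, ten seeds in the acceptance script (three in the
test suite) — enough for ~1,000 transitions per record near the midpoint and
sub-0.1-kBT statistical error on ΔV.  WLC inversion uses bracketed root
finding on [0, L) with machine-precision tolerances (round trips good to
1e-9 relative); the force balance brackets by doubling and solves to
1e-12 pN; scenario calibration is cached per parameter set.  Ties and
degenerate inputs (slack tether, constant signal, saturated occupancy,
probability-1 binding windows) are handled explicitly as documented errors
or flags rather than silent numbers.

## Known limitations

- Strictly two-state analysis; sequential multi-state records must be split
  by force window upstream.
- The Kramers prefactor is not identified; only rate ratios and zero-force
  rates are meaningful.
- Contour inference assumes the hard-core change is known from a structural
  model; its sign convention (ΔH = folded − unfolded) must match that model.
- Extensible-WLC (enthalpic stretching) corrections are omitted; above
  ~20 pN on short handles this matters.
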