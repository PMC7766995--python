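# Methods

`dendromd` post-processes molecular-dynamics trajectories of charged
peptide dendrimers — branched polycations built from lysine branching
points with dipeptide spacers (2Arg or 2Lys) whose protonated side groups
carry the charge.  This note records the models implemented, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Systems and the coarse-grained toy topology

The systems of interest are second-generation Lys-2Arg and Lys-2Lys
dendrimers: an alanine–lysine core, a binary branch tree in which every
edge carries a two-residue spacer (each residue contributing one +1 side
charge — guanidinium for Arg, ammonium for Lys), and doubly protonated
terminal lysines.  For generation *g* the tree has 2^(g+1) terminal
lysines, hence `Nend = 2^(g+2)` terminal NH3+ sites, `Nins = 2·(2^(g+2)−2)`
spacer residues, and bare charge `Qbare = Nend + Nins`; at g = 2 this is
16, 28 and +44, neutralised by 44 Cl⁻ counterions.

The toy builder is coarse-grained — one interaction site per heavy-atom
group, two explicit H satellites per side-chain CH2 so H–H vectors exist —
because every analysis below consumes only positions, masses, charges and
role labels.  Charges are formal (+1 per protonated amine/guanidinium);
no force-field partial charges are assigned.  Side segments reproduce the
chemical bond counts that matter for the mobility analysis: the CH2
carbons of an Arg side chain sit 3, 4 or 5 bonds from the terminal N of
the segment (Cδ, Cγ, Cβ through Nε–Cζ–NH), those of a Lys side chain 1–4
bonds (Cε…Cβ through Nζ).  Bond-path distances are computed by
breadth-first search; ties are impossible on a tree.

## Structural descriptors

* **Radius of gyration** `Rg² = (1/M) Σ mᵢ rᵢ²` about the mass-weighted
  COM, per frame; the mass-weighted gyration tensor's eigenvalues
  (ordered Ix ≥ Iy ≥ Iz) satisfy Ix+Iy+Iz = Rg² frame by frame.
* **Asphericity** `α = 1 − 3(IxIy + IxIz + IyIz)/(Ix+Iy+Iz)²`, 0 for a
  sphere, → 1 for a rod.  The headline number applies the formula to
  time-averaged eigenvalues (a single α, as published summaries quote);
  the per-frame series is available as an option.
* **Kirkwood hydrodynamic radius** `Rh = ⟨rᵢⱼ⁻¹⟩⁻¹ (i≠j)`, with the
  subset variants used for peptides: backbone Cα only, all dendrimer
  heavy atoms, plus ions, plus water oxygens within 0.35 nm of any heavy
  atom (the H-bond distance scale; re-selected every frame, since no
  published cutoff exists for this variant).
* **Terminal-group radius** `Re = ⟨(1/Nt) Σ rᵢ²⟩^{1/2}` over terminal
  nitrogens, compared against the rigid-sphere estimate √(5/3)·Rg.
* **Radial profiles** about the dendrimer COM with default dr = 0.05 nm.
  Bins are normalised by the *exact* shell volume (4π/3)(r₂³−r₁³) rather
  than 4πr²dr, so the mass closure Σ ρ·V_shell = M holds identically and
  the innermost bins are not biased; the two conventions differ by
  O((dr/2r)²) elsewhere.
* **Congregation coefficient k45**: for each member of a selection the
  fraction of the other members whose COM-direction lies within a 45°
  cone about its own is averaged and rescaled so the uniform-null
  expectation p₀ = (1−cos45°)/2 maps to 0 and total coincidence to 1.
  The published definition is by citation only; this cone-fraction form
  provably attains both published limits (1 for one sector, ≈0 for
  uniform scattering).  Members exactly at the COM carry no direction and
  are skipped.

## Electrostatics

All charges of dendrimer plus counterions are binned radially about the
dendrimer COM (water partial charges excluded by default — the toy
systems carry none and the double-layer shape is set by dendrimer + ions).
From the per-bin net charge q(r): the cumulative Q(r), the effective
charge Q* = max Q at radius Rmax, surface charge density
σ = Q*/(4πRmax²), and renormalisation Q*/Qbare.

The dimensionless potential ψ = eΨ/kBT obeys the spherically symmetric
Poisson equation ψ'' + (2/r)ψ' = −4πλ_B ρ(r) with the Bjerrum length
λ_B = e²/(4πεε₀kBT) (0.696 nm at 300 K, ε = 80; ε is treated as
temperature-independent 80 unless overridden).  Rather than stepping the
ODE, the solver superposes the exact shell solutions of the binned
charge: ψ(r) = λ_B Σⱼ qⱼ / max(r, rⱼ).  This *is* the Green's-function
solution with regularity at the origin and decay at infinity; it is exact
for the binned representation, has no grid-order error, and satisfies
Gauss's law −r²ψ'/λ_B = Q(<r) identically (the test suite still verifies
this by finite differences).  The profile is gauged to ψ = 0 at the outer
boundary; for a charge-closing system the shift is negligible, and a
warning is raised when |Q| > 0.5 e there.  The ζ potential is read as
ψ(Rmax)·kBT/e in mV, identifying Rmax with the slip plane.

Ion pairing: g(r) between counterions and each charged-group class
(side-spacer, terminal), normalised by the ideal-gas pair density within
the analysis sphere.  The pair count integrates the raw pair distribution
up to the first minimum after the first peak, located on a 5-point
moving-average smoothed curve (noise-robust); with no detectable peak a
fixed 0.5 nm cutoff is used with a warning.  Osmotic counterions follow
from the balance ⟨n_osmotic⟩ = Qbare − Q* − ⟨n_pairs⟩.

## Hydrogen bonds

Geometric criterion: D–A distance < 0.35 nm and angle < 30°.  The phrase
"D-H-A angle" below 30° is geometrically inconsistent with a near-linear
bond, so the standard MD-package convention is adopted: the
deviation-from-linearity angle ∠(H–D–A) between the D→H and D→A
directions.  Donors are N/O atoms with a bonded H (a configuration error
lists donors lacking hydrogens); acceptors are all N/O atoms.

Continuous lifetimes: bond presence is tracked as a signed criterion
margin min(d_cut − d_DA, (30° − θ)·s) with s = 0.01 nm/deg folding the
angle onto the distance scale.  Formation/breaking instants are refined
by a cubic spline through the 4 frames around each sign change and its
bracketed zero crossing; a single-frame event without refinement has
duration dt by convention.  Transient single-frame breaks are *not*
bridged (strict continuous definition).  Events touching a trajectory
boundary are censored: excluded from the mean, counted separately.  The
estimator is validated against telegraph processes with exponential
on-times (recovery well within 5% at 10⁴ events for mean on-times ≫ dt);
when the mean on-time approaches dt it is biased upward — sub-dt events
vanish and the survivors are length-biased — which the suite documents
rather than hides.

## Orientational dynamics and NMR observables

ACFs P1(t) = ⟨u(0)·u(t)⟩ and P2(t) = ⟨3(u(0)·u(t))² − 1⟩/2 are estimated
with every time origin (FFT-based; the quadratic products u_a u_b are
correlated directly for P2) and averaged over vector instances; the lag
window is capped at 10% of the trajectory for variance control.  The
size-pulsation ACF of Rg² is the normalised fluctuation autocovariance
and refuses constant series.  Characteristic times are 1/e crossings
located by log-linear interpolation; an ACF that never reaches 1/e in the
window yields a censored time (window end as lower bound).  For isotropic
rotational diffusion P2 = P1³ exactly; the check reports the maximum
deviation over lags with P1 > 0.1.

Spectral density J(ω) = 2∫₀^∞ P2(t)cos(ωt)dt.  The sampled window is
integrated as the *exact* cosine transform of the piecewise-linear
interpolant (it reduces to the trapezoid rule as ω → 0 but keeps full
accuracy at ω·dt ∼ 1, where the plain trapezoid rule fails the 1%
Lorentzian benchmark).  Beyond the window the ACF is extended by a
1–3-term multi-exponential fit (amplitudes by variable projection, decay
times optimised in log space, order by AIC) whose tail integral is
analytic; `tail_mode="truncate"` is available and warns when the ACF has
not decayed.  The reduced spin-lattice rate is ω[J(ω) + 4J(2ω)] and the
physical susceptibility-representation rate 1/T1H = (A0/ωH)·reduced, with
A0 = 0.56×10¹⁰ s⁻² (theoretical dipolar prefactor for CH2 protons,
overridable per class — terminal CH2 of Lys-2Arg uses 0.88×10¹⁰ s⁻² in
the published comparison) and ωH = 2π·400 MHz.

Per-class mobility pools the H–H unit vectors of all CH2 groups at the
same bond distance to their segment-end N into one P2 ACF; only P2 feeds
the NMR chain, so the H–H sign ambiguity is irrelevant there.

## Synthetic generators and what they do (not) emulate

Every generator is deterministic given its seed and ships its ground
truth:

* **Rotational diffusion**: small random rotations with angular variance
  4·Dr·dt per step about random transverse axes; exact ACFs
  P_l = exp(−l(l+1)Dr t).  A guard rejects Dr·dt > 0.01 (small-angle
  regime); the residual discretisation bias in the decay rates is O(Dr·dt).
* **Ornstein–Uhlenbeck scalar**: exact AR(1) discretisation, ACF
  exp(−t/θ) at any dt; defaults (mean 4.0 nm², sd 0.3) emulate an Rg²
  series pulsating in the 1.7–2.3 nm band an equilibrated G2 dendrimer
  shows.
* **Double-layer cloud**: 44 positive unit charges at Gaussian radii
  (μ = 2.6 nm, σ = 0.3 — the published positive-peak position) and 44
  counterions at exponential excess radii (decay 1.0 nm — the published
  1 nm gap between the positive maximum and the negative minimum);
  positions redrawn each frame, closed-form Q(r) available.  A heavy
  neutral bead pins the COM.
* **Telegraph bonds**: exponential on/off durations; the sampled margin
  is the signed distance to the nearest transition, crossing zero
  linearly at the exact instants — the signal shape the spline refinement
  expects.
* **Toy Brownian trajectory**: overdamped dynamics with harmonic bonds
  (k = 200 kT/nm², r₀ = 0.15 nm heavy / 0.105 nm X–H), soft linear
  repulsion inside 0.25 nm, and a weak radial tether on counterions
  standing in for their electrostatic confinement; friction γ = 1, step
  x += F·dt + √(2kT·dt)·ξ, abort on any displacement > 1 nm/step.

The generators reproduce the *statistical structure* the analyses assume
(exponential orientational decorrelation, mean-reverting size pulsation,
a radial double layer, two-state bond kinetics, a connected branch tree
with dendrimer-like radial ordering).  They do not reproduce atomistic
force-field physics: absolute sizes, ζ potentials and correlation times
of the toy runs are in reduced units and are *not* comparable to the
published absolute values (Rg = 2.0 nm, ζ ≈ 17 mV, τrot ≈ 7–14 ns, the
Table of per-group times), which require the original 1 µs atomistic
trajectories.  Passing tests therefore demonstrate correctness of the
estimators and the published numbers' internal consistency relations, not
recovery of the absolute atomistic values.

## Problem sizes and tolerances

Statistical acceptance checks are sized so the expected estimator noise
sits a factor ≳2 below the asserted band: the P2 = P1³ identity
(tolerance 1e-3 on the max deviation) uses 600 vectors × 2·10⁵ steps
(1.2·10⁸ samples, measured deviation ≈ 4·10⁻⁴); parameter-recovery
checks at 3–5% use 10⁶–10⁷ samples; the telegraph lifetime check uses
10⁴ events (sampling error ≈1%).  Brownian toy runs use generations 0–1
and 10³–2.4·10⁴ steps, enough for stationarity after burn-in while the
whole analysis chain stays desk-scale.  The sequential rotation update
runs in a compiled (numba) kernel with a pure-numpy fallback that
consumes the identical random stream, so results do not depend on which
path executes.

## Known limitations

* The toy topology has no inner-lysine or terminal CH2 hydrogens; the
  inner/terminal NMR classes are exercised through synthetic vector
  series rather than toy-trajectory geometry.
* g(r) normalisation assumes an ideal-gas reference inside the analysis
  sphere; for strongly structured toy systems the absolute g values are
  approximate (pair *counts*, used for the ion-pair balance, are exact).
* The first-minimum locator can fall back to a fixed 0.5 nm cutoff on
  noisy g(r); the fallback is warned about and recorded.
* Censored-event exclusion slightly biases lifetime means when events are
  not ≪ the trajectory length.
* No intermittent H-bond correlation function, no Poisson–Boltzmann
  self-consistency, no SAXS/SANS observables, and no T2/NOE — all outside
  the analysis scope.
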