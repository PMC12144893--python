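# Methods

This note documents the models, estimators and numerical choices behind
`pocketswitch`, in the spirit of a simulation package's model description.
Everything is in reduced units: kT = 1, unit length, unit friction, so the
diffusion coefficient D = kT/γ = 1 and time is measured in units of
(length²·γ/kT). A single optional `time_scale` factor in the run
configuration maps reduced to physical time; no physical-time magnitudes
are baked into any formula.

## Model landscapes

**Exit landscape.** The receptor–ligand system is replaced by a 2D
potential E(s, y): s is the exit-path collective variable (CV), y a lateral
coordinate. Basins are compactly supported bumps
exp(1 − 1/(1 − u²)), |u| < 1, so each basin's influence is strictly local.
Defaults: a 10 kT pocket at s = 1.2 (half-width 1.5), two 4 kT vestibule
intermediates at s = 4.5 and 6.5 (half-width 1.0), and a flat unbound
region beyond s ≈ 7.5, on the box s ∈ [0, 10], y ∈ [−4, 4]. The funnel
restraint of funnel metadynamics is realised as s-dependent lateral
stiffness k_lat(s) interpolating (logistically around s = 5.5) from 20
kT/len² in the pocket to 0.1 kT/len² outside; the widening funnel gives
the unbound region a ~2 kT entropic bonus, as a real funnel's mouth does.
Pocket depth 10 kT vs intermediates 4 kT was chosen so that spontaneous
exits are observable in minutes of CPU while the pocket still dominates the
equilibrium population (99%); the resulting group gaps (pocket→intermediate
≈ 4.8 kT, pocket→outside ≈ 6.9 kT) have the same ordering as the atomistic
system the model stands in for, at roughly half the magnitude.

**Region boundaries** are placed at the maxima (saddles) of the laterally
integrated free energy between basin centres, computed once at generation
time and stored with the surface. Regions partition the CV axis
(right-open intervals; the domain edge belongs to the last region).

**Isomer pair.** E and Z surfaces differ only in pocket depth (defaults
10 kT for Z, 7 kT for E). Compact bump support makes them bit-identical
outside the pocket, and the pair shares region boundaries, so state
definitions transfer across a mid-trajectory surface switch — the
in-silico analogue of inverting the azo-bond dihedral to isomerize the
bound ligand.

**Tether.** The covalent disulfide anchor is a half-harmonic restraint on
the distance to the anchor point (the pocket centre): zero below
`flat_radius` (0.5), harmonic with `spring_constant` 2.0 kT/len² beyond;
energy and gradient are continuous at the flat radius. With these defaults
the tether is invisible inside the pocket, adds ~1–2 kT at the
pocket–vestibule boundary and tens of kT in the unbound region — the
ligand can rattle but not leave, which is what covalency means here.

**Double well** (validation fixture). A quartic h((x/a)² − 1)² − cx with
(h, c) calibrated numerically (to 1e-10) so that the saddle sits exactly
`barrier` above the deeper minimum and the minima differ by exactly
`asymmetry`. Reflecting walls at ±1.8a (~5× the barrier) confine the
system while keeping the basins and saddle clear of wall artifacts.

## Dynamics

Overdamped (position) Langevin, Euler–Maruyama:
x ← x − (∇E/γ)dt + √(2kT dt/γ)·ξ, with reflecting boundaries by
coordinate mirroring (preserves the equilibrium distribution without
extra energy terms). No velocities are carried: the analysis consumes only
configurational statistics and first-passage times. Default dt = 0.004
(0.002 on the stiffer double well): the stiffest mode (k_lat = 20) then
has k·dt ≤ 0.08, giving <4% discretization bias in equilibrium variances,
well below every tolerance used downstream.

Randomness comes from counter-based Philox streams keyed per
(seed, purpose, walker/replica), so multi-walker and multi-replica runs
are bit-reproducible regardless of scheduling or chunking.

Brute-force first-passage sampling (the model-free kinetics oracle)
launches replicas equilibrated near the start region's minimum and records
first entry into the target region; censored replicas are counted and
excluded, never imputed. A 1D mean-first-passage ODE solved by double
quadrature provides a second, closed-form oracle for 1D cases.

## Metadynamics

Well-tempered, multiple walkers, one shared bias on s only (never on the
funnel coordinate). Hills of height w(s) = w₀·exp(−V(s)/((γ−1)kT)) are
deposited every `deposition_stride` steps; walkers advance in lockstep
between deposition events and deposit in walker-index order, trading the
realism of asynchronous walkers for exact determinism. The bias lives on a
uniform grid (512 points) with linear interpolation of its gradient;
an exact Gaussian summation over the hills log is kept as the slow
reference path. Defaults: w₀ = 1.2 kT, σ = 0.10 (0.15 on the 10-unit exit
CV), γ = 8, stride 500 steps, 4 walkers.

Two standard corrections are applied:

* **Image hills.** Each hill is mirrored across the reflecting walls.
  Without images the bias near a wall receives only half the deposition
  mass and the free energy there is systematically under-resolved.
* **Time-averaged bias.** The free-energy estimate uses the mean of
  mean-aligned bias snapshots over the last half of the deposition history
  rather than the single final bias; this suppresses the hill-sized
  ripples of a late-time snapshot (≈0.3–0.5 kT here) without touching the
  converged shape.

Free energy: F(s) = −γ/(γ−1)·V(s), shifted to min 0. Even with the image
correction, Gaussian hills cannot resolve the sharp corner where a steep
wall meets the reflecting boundary (convolution bias ~σ²F″/2); profile
accuracy statements are therefore made on the thermally relevant window
F ≤ barrier + 2 kT, which contains both basins and the saddle. On that
window the default double-well run recovers the profile to ≤0.35 kT and
the basin ΔF to ≤0.05 kT (tolerances asserted: 0.5 and 0.3 kT).

Reweighting uses the final-bias estimator: after discarding an
equilibration fraction (default 0.2) of each walker's frames, frame i gets
weight ∝ exp(+V(s_i)/kT), normalized. The time-dependent estimators were
not needed at these run lengths; the reweighted basin probabilities agree
with Boltzmann quadrature within ~1 block-bootstrap SE.

## State decomposition

Frames are fingerprinted by three interval conditions on the CV: region
(pocket / intermediate_k / outside), a key-contact flag (s below 2.0, the
analogue of the conserved salt bridge that only in-pocket poses form), and
a tether-extension bin (|s − anchor| binned). Microstates are the distinct
fingerprints with reweighted probability above a floor; rarer combinations
merge into their Hamming-nearest retained state (ties to the lower
lexicographic index). The construction is deterministic and frame-order
invariant. Macrostates derive from the region feature.

The pipeline uses this machinery at **two granularities**:

* an **interpretive decomposition** (bin width 1.4, floor 1e-5) whose
  handful of clusters (≈9 at defaults) is the reporting level for
  populations and inter-group ΔF — the analogue of grouping ligand poses
  into a small set of interaction clusters;
* a **kinetic discretization** (bin width 0.15, floor 1e-6, ≈65 states)
  used only to build the Markov model. The fine width matters: the
  MaxCal edge flux λ√(πᵢπⱼ) reproduces diffusive barrier crossing only
  when bins are small against kT/|F′|, i.e. when the free energy varies
  by ≲1 kT within a bin. Coarse bins overestimate interface fluxes by
  ~exp(ΔF_bin/2) and were measured to make exit kinetics several-fold
  too fast.

Both decompositions are clustered on frames pooled across conditions, so
tethered and free runs are compared on matched state definitions.

## Maximum-Caliber Markov state model

Given π (from reweighted metadynamics), an adjacency graph and a mean
jump rate r = Σ_{i≠j} πᵢ p_ij per lag, the transition matrix maximizes the
path entropy (caliber) subject to row normalization, detailed balance,
adjacency support and the rate constraint. In edge-flux variables
x_ij = πᵢp_ij the stationarity conditions give x_ij = λ√(x_ii x_jj) with a
single multiplier λ; the self-fluxes u_i = √x_ii solve coupled quadratics
iterated to a 1e-15 fixed point (conjugate root form for numerical
stability, light damping against two-cycles), and λ is bracketed by
Brent's method so the total off-diagonal flux matches r. The solve is
exact to ~1e-15 nats against exhaustive caliber maximization on all
bundled ≤4-state systems, and infeasible rates raise an error reporting
the attainable range.

**Calibration.** The lag time is one saved frame (0.004 reduced time at
stride 1) and r is the observed fraction of frame pairs one lag apart
with different microstate labels in an unbiased in-pocket run. For the
single-λ flux form to carry the correct absolute timescale, the lag must
be comparable to the diffusion time across one bin (τ ≈ Δ²/(πD)); the
defaults (Δ = 0.15, τ = 0.004) satisfy this.

**Adjacency.** Observed connectivity (any transition within the lag, in
any walker, unioned over conditions) intersected with *structural*
adjacency — states whose CV supports share a boundary. The intersection is
essential: MaxCal weights every allowed edge with the same λ, so a rare
observed i→i+2 hop (a discretization artifact at finite lag) would
otherwise become a genuine flux shortcut across the barrier. With these
choices the model MFPT(pocket→unbound) on the default free landscape is
within 0.96–1.18× of direct Langevin first-passage sampling across seeds
(asserted: within a factor of 2).

## Kinetics and comparison

Transition path theory on the MaxCal matrix: committors by direct linear
solve (q = 0 on A, 1 on B, harmonic elsewhere), set-to-set MFPT from
(I − P_¬target)m = τ·1 with π-conditioned averaging over the source, and
macrostate residence times from the internal block (an absorbing set
returns an explicit +inf marker, never an overflow). State counts are a
few dozen, so all linear systems are dense direct solves.

Uncertainties: circular block bootstrap (default 200 resamples, blocks of
10⁴ stride-1 frames ≈ 40 time units, chosen above the bias-sweep
correlation time) over time blocks within each walker, redrawing both π
and the jump rate and rebuilding the matrix per resample; infeasible
resamples are dropped and counted.

The tethered-vs-free report gives residence-time ratios and, per
condition, the in-pocket switching probability
P = k_switch/(k_switch + 1/τ_pocket). The verdict is "in-pocket" when P
exceeds 0.5 at its lower uncertainty bound (16th bootstrap percentile) in
both conditions. The default switching rate (1 per reduced time) encodes
that photoisomerization is orders of magnitude faster than unbinding, as
it is for arylazopyrazoles; it is configuration, not a fit.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis assumes:
a dominant bound basin, metastable vestibule states, a funnel-confined
unbound region, a tether that penalizes excursions, and an isomer-dependent
bound-state depth. It does not reproduce atomistic contact chemistry,
orthogonal slow degrees of freedom (the exit coordinate is the only slow
mode here), rugged multi-pathway exits, or physical time scales. Passing
tests therefore validate the estimators and the inference chain — free
energies from bias, populations from reweighting, kinetics from
MaxCal + TPT, and the direction of every tethered/free and pocket/vestibule
comparison — not any particular millisecond-scale prediction for a real
receptor.

## Known limitations

* The MaxCal single-rate constraint carries one global timescale; its
  absolute kinetics are reliable only with the fine, matched
  discretization described above. The coarse interpretive clusters are
  for thermodynamic reporting, not kinetics.
* The final-bias reweighting estimator is simple and slightly biased at
  short run lengths; the default equilibration fraction and run lengths
  keep that bias below one standard error.
* Under a strong tether the unbound region's equilibrium weight is
  astronomically small; its population and the tethered pocket→outside
  MFPT are then order-of-magnitude statements, reported with their (large)
  bootstrap spread.
* Problem sizes (2×10⁶ metadynamics steps per condition, 220 brute-force
  exits, 200 bootstrap resamples) are the package's defaults and keep a
  full validation run on one CPU in the ten-minute range.
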