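# Methods

This note records the models, conventions and numerical choices behind
`lipgate`, in the order data flows through the package.

## Contact definition and profiles

A contact is a lipid–residue minimum distance strictly below a cutoff,
0.6 nm by default (the customary coarse-grained bead contact range).
Ties at exactly the cutoff are non-contacts. All durations are counted
as (number of frames) × (frame spacing): a single-frame contact
contributes one frame's worth of time.

*Contact duration* of residue r for species S is the total time r is in
contact with any lipid of S inside the analysis window. *Maximum
occupancy* is the longest contiguous single-lipid run of contact with r.
Occupancy can therefore never exceed duration, and duration is additive
over a partition of the window. A single above-cutoff frame breaks a
run (gap tolerance 0); event extraction exposes a `gap_tolerance` in
frames for noisier data.

Normalisation of the profiles divides by the maximum across residues
within the species and window, so the peak residue reads 1.0. The
normaliser is a package convention — it makes profiles comparable
across conditions; absolute values are always available alongside.

The default analysis window discards the first 25 % of frames as
equilibration (production runs in this field typically equilibrate
within the first quarter of the trajectory); any explicit window
overrides it.

Density maps are per-frame mean counts per planar bin, averaged across
repeats, so the map sums to the mean number of tracked lipids — a mass
conservation property the tests assert. Cumulative occupancy is an
alternative convention some tools use; mean counts were chosen because
the invariant is then exact and resolution-independent.

Hydrogen-bond analysis is implemented as a distance-only criterion
(0.35 nm donor–acceptor cutoff) on a distance series; an angle column,
when a caller has one, can simply be pre-filtered before the series is
built. Salt-bridge stability and Cα separations use the same
`pair_distance_stats` operation with their own cutoffs.

## Binding events and site clustering

An *event* is one lipid's contiguous run of frames with min-over-residue
distance below the cutoff, with internal gaps of at most
`gap_tolerance` frames bridged. Only events with duration strictly
greater than `min_duration` (default 10 µs, the persistence filter that
separates resident lipids from brushes) are analysed. Events are never
merged across lipids or repeats; identity is (repeat, lipid, interval).

Per event, the residue co-occurrence matrix is the pairwise Pearson
correlation of the binary fingerprint rows. Constant rows (residues
never, or always, in contact during the event) make the correlation
undefined; the convention is 0, except the diagonal, which is 1 for
contacting residues and 0 for never-contacting ones, so the binarised
adjacency carries "this residue participates" information.

Event similarity is the phi (Matthews) coefficient of the two binarised
(> 0) adjacencies, flattened over the upper triangle including the
diagonal. Including the diagonal means a residue's participation counts
once even when it correlates with nothing; both the triangle and the
diagonal are config options since conventions differ between tools.
Constant vectors again yield 0, flagged.

Clustering is single linkage on d = 1 − φ (scipy's implementation; a
brute-force O(n³) agglomerator in the test suite verifies every merge).
The default cut keeps merges at d < 1 only, i.e. clusters are exactly
the groups connected through positive φ; a numeric level or cluster
count can be supplied instead. Each cluster's consensus site is the set
of residues contacted in at least 50 % of member events.

## Synthetic contact data

The generator states a world with the statistical structure the
analysis assumes, not a physical membrane:

- Lipids are points performing an overdamped 2D random walk with
  periodic wrap in a 24 × 24 nm box; the protein is an excluded disc of
  radius 4 nm at the centre with residues equally spaced on its
  perimeter. Only the inner (lower) leaflet is modelled — it is where
  PIP₂ resides; leaflet tags are kept in the data model.
- Default composition is the 2 %-PIP₂ inner leaflet of the mixed
  membranes used in this field: PC 18, Chol 30, PE 35, PS 15, PIP₂ 2
  per 100 lipids; five independent repeats.
- The diffusion coefficient is a free parameter (no measured value is
  available for the emulated systems); the default 0.05 nm²/ns is the
  order of magnitude of lipid diffusion in coarse-grained membranes.
- Binding sites are planted residue footprints with alternating-renewal
  exponential kinetics (mean bound and unbound dwells; capacity one
  lipid; an infinite unbound dwell disables binding). A bound lipid is
  parked at an anchor 1 nm outside the ring at the footprint's angular
  centroid, and its footprint distances are drawn uniformly in
  [0.3, 0.55] nm — safely below the cutoff with jitter. Unbound lipids
  cannot approach the residue ring closer than `approach_floor`
  (default 0.45 nm), so brief chance encounters occur; setting the
  floor above the cutoff switches them off.
- Ground-truth bound intervals are emitted beside the tables.

What a green recovery test establishes: the pipeline separates planted
footprints with clean exponential kinetics and frame-consistent
geometry. What it does not: robustness to conformational coupling,
correlated multi-lipid binding, leaflet asymmetry effects, or real
bead-level geometry — none of which the generator emulates.

## Single-channel model

The amplitude histogram (uniform bins, linear counts) is fitted by
non-linear least squares with

f(x) = Σᵢ αᵢ·exp(−((x − βᵢ)·γᵢ)²),  αᵢ ≥ 0, γᵢ > 0,

which maps exactly onto scaled normal densities via μᵢ = βᵢ,
σᵢ = (2γᵢ²)^(−1/2), ρᵢ = √π·γᵢ⁻¹·αᵢ; the tests assert pointwise
agreement of both forms at 1e−10 relative. "Logarithmic histogram"
refers to display scaling only — the fit consumes linear counts (a
log(counts+1) objective could be added behind the same surface if a
dataset demands it). The component count n is user-specified, matching
the three-state closed/sublevel/open scheme; no automatic model
selection is silently applied.

Initialisation picks the n tallest well-separated smoothed-histogram
peaks (minimum separation two initial sigmas, ties toward lower
amplitude), falling back to amplitude quantiles when fewer peaks exist.
Non-convergence is flagged, with parameters still returned. Components
are reported sorted by |β|.

State fractions are ρᵢ/Σρ. Labelling: the component with μ nearest the
baseline (0 pA after offset handling) is closed, the farthest is open,
the rest sublevels; components whose means sit within one σ of each
other flag the labelling as ambiguous. Unitary conductance is
(μ_o − μ_c)/V × 1000 pS and is invariant to DC offsets by construction.

The Gaussian low-pass filter is a zero-phase FIR kernel with
σ_t = √(ln 2)/(2π f_c) ≈ 0.1325/f_c, giving −3 dB at f_c exactly;
edges are reflected. The tests measure the realised −3 dB point to
within 2 %.

NPo uses half-amplitude idealisation between adjacent fitted means;
each sample contributes weight (μ_level − μ_c)/(μ_o − μ_c), so
sublevels count in proportion to their amplitude — a declared
convention, since no standard exists for sublevel weighting in NPo.

Gating simulation is an exact Gillespie jump chain sampled on the
acquisition grid; occupancy statistics therefore converge to the
analytic stationary distribution of the rate matrix, which the tests
check at total-variation distance < 0.02 over 10⁶ samples.

## Whole-cell analysis

I–V curves come from linear interpolation of current against the
monotonic ramp command, restricted to the −130…+80 mV protocol range.
"Net" current density is stimulated minus the mean over a pre-stimulus
baseline window at the same potential — a declared convention.
Reversal potentials require a unique zero crossing (optional Gaussian
smoothing of the IV curve suppresses noise-induced extras) and are
located by local linear interpolation.

The bi-ionic divalent/monovalent relation
P_X/P_M = [M]ᵢ·ξ·(1+ξ)/(4[X]ₒ), ξ = exp(E_rev F/RT), is the standard
GHK-derived form for an external divalent carried against an internal
monovalent. It neglects activity coefficients and residual monovalent
permeation, and its inversion for E_rev is the closed-form positive
root of the quadratic in ξ. Temperature defaults to 295 K (room
temperature). Pore-size inference from large organic cation permeation
is out of scope — it is a qualitative comparison, not a computation.

## Numerical conventions and degenerate inputs

- Strict inequalities at every cutoff (contact, formed fraction).
- Empty tables, zero-length windows, windows outside the data span,
  non-monotonic ramps, non-conservative rate matrices and zero
  capacitance all raise `ValueError` rather than degrade.
- A pipeline run whose persistence filter removes every event returns
  an explicit empty result with a notice instead of raising.
- Seeds: every generator consumes a single integer seed through
  `numpy.random.SeedSequence`; repeats spawn child sequences, so equal
  seeds give bit-identical outputs and repeats are independent.

## Known limitations

- The contact generator's bound-state distances are drawn, not derived
  from geometry, so the planar track and the footprint distances are
  consistent only at the "bound lipid sits at its site" level.
- The amplitude fit estimates event fractions from all-points
  histogram areas; brief transitions smear between components when
  gating approaches the filter's rise time.
- No dwell-time fitting, burst analysis or hidden-Markov idealisation;
  NPo is the only open-probability summary.
- ABF input requires the optional pyabf package at runtime; the
  tabular and .npz containers are the supported interchange formats.
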