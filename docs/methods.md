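# Methods

`oilcluster` post-processes particle trajectories of small hydrophobic
solutes (terpenoid essential-oil ingredients such as carvacrol) and
hyperbranched polymer carriers (a partially protonated polyelectrolyte like
HBPEI, or a neutral amphiphile like HPG) in periodic orthorhombic cells.
All analyses operate on molecular centers of mass in nm/ps units; reported
lengths can be relabeled in Å at the presentation boundary only.

## Geometry under periodic boundaries

Minimum-image displacements are computed per axis as
`d − L·floor(d/L + 1/2)`, giving components in `[−L/2, L/2)`.  Molecules are
made contiguous by reference-atom chaining: the first atom anchors the
molecule and each subsequent atom is placed at its minimum image relative to
the previously placed atom.  Atom order within a molecule is contiguous in
GRO files, so this reconstruction is deterministic and needs no bond graph;
it fails (with a warning) only for conformations genuinely stretched beyond
half a box edge between consecutive atoms.  Centers of mass are taken on
the reassembled coordinates and wrapped back into the primary cell.
Unwrapping a wrapped series assumes that no molecule truly moves L/2 or
more between saved frames; under that assumption the frame-to-frame
displacement equals the minimum image of the wrapped difference and the
reconstruction is exact.  The assumption is not checked or repaired at run
time — with typical save intervals it holds by a wide margin, and a
violation would require frame spacing so coarse that every dynamic analysis
downstream would be meaningless anyway.

## Clustering and swarm size

Cluster populations use DBSCAN with the minimum-image metric
(scikit-learn on a precomputed distance matrix).  Defaults: `eps = 0.65 nm`
— a close-contact COM distance for molecules of terpenoid size; prefer the
measured first-shell boundary of the species' own rdf when the system shows
one — and `min_samples = 2`.  With `min_samples = 2` every non-noise point
is a core point, so the labeling is exactly the set of connected components
of the eps-neighborhood graph: a molecule is either clustered or freely
floating, with no order-dependent border-point ambiguity.  Labels are
canonicalized by ascending smallest member index, making results
permutation-consistent and reproducible.  `eps` must stay below half the
smallest box edge or the neighborhood is ill-defined on the torus.

The swarm radius of gyration condenses the whole solute population into one
scalar.  A translation-equivariant center is obtained per axis by circular
statistics (map positions to phases `θ = 2πx/L`, average the unit vectors,
invert); all points are then brought to their minimum images about that
center, and the radius of gyration is taken about the mean of those images.
For any swarm compact relative to the cell — including one straddling a
corner — this equals the unwrapped radius of gyration to machine precision,
and it is exactly invariant under lattice translations.  Molecules enter
with equal weight (the quantity counts molecules, not mass).

## Pair structure

The rdf estimator histograms minimum-image COM distances over ordered pairs
and normalizes each bin by the ideal-gas expectation
`T · N_α · ρ_β · V_shell`, with self-pairs excluded for like species
(`ρ_β = (N−1)/V`).  Inside half the smallest box edge the shell is a full
sphere and the analytic volume is used.  Beyond — up to the maximal
minimum-image distance `√3·L/2` of a cubic cell — the effective shell
volume is the intersection of the shell with the Wigner–Seitz cell.  It is
estimated once per (box, binning) and cached: directions `u` are sampled
isotropically (fixed seed 12345, 10⁷ samples) and the cell-limited radial
extent `ρ(u) = min_i (L_i/2)/|u_i|` gives the cumulative volume
`V(r) = (4π/3)·E[min(r, ρ(u))³]` exactly per direction.  Because every
sample contributes its full radial profile, the estimate stays accurate in
the corner tail where naive point-counting starves; the validation suite
checks a uniform ideal gas stays within 2% of g = 1 on every bin up to
`√3·L/2` (with 0.4 nm validation bins, coarse enough that pair-count
Poisson noise at the validation sample sizes — 500 molecules, 200 frames —
sits below that band).

Coordination numbers n(r) are reported from the cumulative per-reference
neighbor count.  Within half the box edge this is the binned form of the
textbook integral `∫ 4πs²ρ g(s) ds`; beyond, where shells are truncated by
the cell, the count form remains exact and saturates at `N_β − δ_αβ` at the
cell diagonal.

First coordination shells are detected on a 5-point moving average of g(r):
the first peak must clear a prominence threshold (default 0.2), and the
boundary is the leftmost minimum between the first and second peaks.  A
boundary maximum (a condensed aggregate whose COM rdf decays monotonically
from r = 0) counts as a peak; if no second peak exists the shell ends at
the leftmost point of the post-peak floor.  Structureless curves return an
explicit no-shell result rather than a number.

For a reference point on the surface of a spherical cluster of radius R,
the locus of cluster points at probe distance x is a spherical cap of area
`A(x) = 2πx²(1 − x/(2R))`, which rises to a maximum at `x = 4R/3` and
vanishes at `x = 2R`.  The model predicts where a surface-bound carrier's
rdf against interior solute should peak if the droplet were uniform; both
extrema are exposed (`cap_argmax` solves dA/dx = 0 by bracketing,
`cap_roots` brackets sign changes of A itself) and are pinned exactly by
the acceptance checks.

## Dynamics

MSD is averaged over all molecules and multiple time origins (default
stride 10 frames) on unwrapped series; wrapped input is rejected rather
than silently producing bounded displacements.  The Einstein relation
`MSD = 6Dt` gives D as slope/6 from a least-squares line over a lag window,
by default 10–50% of the maximum lag — past short-time noise, before the
origin-starved tail.  The fit reports R² and the log–log slope α; a window
with |α − 1| > 0.1 is flagged non-diffusive (ballistic or trapped) instead
of returning a silently meaningless D.  Unit chain: 1 nm²/ps = 10⁻¹⁸ m² /
10⁻¹² s = 10⁻⁶ m²/s = 10⁻² cm²/s.

The self van Hove part is presented as `4πr²G_s(r;t)`: the normalized
distribution of displacement magnitudes per lag (Σ P·Δr = 1 to 10⁻⁶).  It
uses unwrapped displacements — the same data as MSD, whose second moment it
reproduces to machine precision because the moment is taken on the raw
displacements, not the binned histogram.  The distinct part uses wrapped
coordinates and minimum-image distances between molecule i at the origin
frame and j ≠ i at the lagged frame, shell-normalized exactly like the rdf
and divided by the partner density; its zero-lag curve therefore equals
g(r) bin for bin (shared estimator code path), and an uncorrelated system
sits at 1 for every lag.  Structural decorrelation is summarized by the
first-shell maximum of `G_d/ρ` relative to its zero-lag value; the search
window is the first-shell boundary of the t = 0 curve, and a structureless
t = 0 curve flags the series "no peak" rather than tracking noise.

## Hydrogen bonds

A bond is the triple (donor, hydrogen, acceptor) with minimum-image
donor–acceptor distance ≤ 0.35 nm and H–D–A angle ≤ 30° (the GROMACS
convention; both cutoffs configurable).  Donor/acceptor/hydrogen atom names
are declared per species in the species map, so species without hydroxyl
groups (p-cymene, γ-terpinene) simply contribute nothing.  Intramolecular
pairs are excluded — the quantity of interest is intermolecular
association.  Bonds are classified polymer–polymer, compound–compound,
polymer–compound, or other, by the roles of the donor and acceptor
molecules.

Bond presence sampled at the saved frames defines the intermittent 0/1
process h(t) per bond identity.  The autocorrelation
`C(t) = ⟨h(t₀+t)h(t₀)⟩ / ⟨h(t₀)²⟩` pools all identities of a class and all
origins; C(0) = 1 by construction, and for a stationary two-state process
with rates k_on, k_off it equals `p + (1−p)·exp(−(k_on+k_off)t)` with
`p = k_on/(k_on+k_off)` — the closed form the synthetic oracle checks to
0.02.  The associated timescale τ is the trapezoidal integral of C up to
its first drop below 0.01 (configurable): a raw integral diverges for any
nonzero plateau, so a plateau that never reaches the cutoff integrates over
the whole window and is flagged truncated rather than passed off as
converged.

## Synthetic generators

The generators are pure functions of (parameters, seed) and define the
conditions under which every analysis is validated:

* **Ideal gas** — i.i.d. uniform points per frame; flat g(r), Poisson
  coordination; the null model for shell normalization and peak detection.
* **Brownian walkers** — Gaussian increments of variance 2D·dt per axis,
  emitted as an exact unwrapped series plus (optionally) its wrapped twin,
  so unwrap∘wrap identity, the Einstein slope, and the self van Hove mode
  at `2√(Dt)` are all checked against known D.
* **Planted clusters** — Gaussian blobs with pairwise center separations of
  at least 5×(spread + eps), one blob pinned at the cell corner; the
  clustering ground truth is exact by construction.
* **Two-state bonds** — independent stationary on/off chains stepped with
  the exact two-state propagator, carrying their closed-form C(t).
* **Aggregation** — overdamped Langevin dynamics (`x ← x + D·dt·F + √(2D·dt)·ξ`,
  kT = 1) of 60 solutes and 8 carriers in a 6.5 nm cubic cell.  Solute–solute
  and solute–carrier pairs share a smoothed square-well attraction (depth
  6 kT, range 1.2 nm; the cubic switch spans the outer half of the well so
  the rim force stays small against the step size — a narrower switch makes
  the Euler–Maruyama drift overshoot the rim and destroys binding).  A
  bounded soft-core repulsion with pair-additive radii (0.35 nm solute,
  0.7 nm carrier contact diameters) sets contact distances and emulates the
  carrier's bulk.  The charged-carrier variant adds a screened repulsion
  `A·exp(−r/λ)` (12 kT, λ = 1.8 nm) between carriers only.  With dt = 0.02 ps
  and 45000 steps (900 ps, 201 saved frames), the neutral preset condenses
  ≥ 93% of solutes into one carrier-decorated droplet on every calibration
  seed, while the screened preset arrests coarsening at dispersed clusters
  holding ≤ ~45% — the two morphologies observed for neutral vs
  polyelectrolyte carriers.  These parameters were fixed by calibration on
  the generator itself and then frozen.

What the generators do *not* emulate: atomistic packing and force fields,
explicit solvent and hydrophilic/hydrophobic asymmetry (carriers attach to
the droplet but are not strictly confined to its outer surface),
hydrodynamic coupling, and electrostatics beyond the single screened
repulsion toggle.  Passing tests therefore demonstrate that the estimators
are correct on processes with known structure and kinetics — not that any
particular MD observable (peak positions, lifetimes, diffusivities) is
reproduced at molecular resolution.

## Numerical and interface choices

* rdf bin width default 0.02 nm; validation of the long-range normalization
  uses 0.4 nm bins.  Ties in valley detection resolve leftmost.
* Equilibration handling: a configurable leading-fraction discard,
  default 0.5 of the frames.
* The composition fixtures store γ-terpinene with 22 atoms/molecule in the
  pure-solution series and 26 in the polymer series, as tabulated; the two
  values are chemically inconsistent (C₁₀H₁₆ has 26 atoms) but both totals
  are honored per table and no correction is guessed.
* Orthorhombic cells only; triclinic input is rejected explicitly.
* I/O: GRO/XTC via MDAnalysis (Å↔nm converted at the boundary); a
  fixed-column block reader handles multi-frame GRO fallback; tables
  persist as CSV or HDF5.

## Known limitations

* Unwrapping and the distinct van Hove assume save intervals short against
  L/2 motion and a (near-)constant box; NPT box fluctuations are averaged
  for normalization, not tracked per bin.
* DBSCAN with `min_samples > 2` reintroduces border-point semantics; the
  package canonicalizes labels but border assignment then follows
  scikit-learn's processing order.
* The H-bond ACF pools bond identities; per-pair averaging would weight
  rare long-lived bonds differently.
* The aggregation model's droplets are liquid-like blobs of point
  particles; their internal density profile is not meant to match an
  atomistic nanodroplet.
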