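# Methods

## The pit energy model

A clathrin-coated pit (CCP) is idealized as a spherical cap of surface area
*A* (nm²) and radius of curvature *R* (nm) rising above a flat plasma
membrane; the closed coated vesicle is the limiting cap with *A* = 4πR².
Its total energy is the sum of four terms (all energies in k_BT):

    E_CCP = E_memb-bend + E_memb-tension + E_clath-bend + E_clath-poly

* **Membrane bending** — Helfrich bending of the membrane patch out of its
  preferred shape: `A·(κ_memb/2)·(2/R − 2/R_memb)²`. With a flat intrinsic
  membrane (R_memb → ∞, the default) this equals `4π·κ_memb·(h/R)`: it
  depends on the cap only through its aspect ratio, and every closed
  vesicle costs the size-independent `8π·κ_memb ≈ 377 k_BT`.
* **Membrane tension** — the work of pulling membrane area into the bud:
  `γ·A²/(4πR²)`, identically `γ·π·h²` (the projected in-plane area a cap
  of height h removes is πh²).
* **Coat bending** — the same Helfrich form for the clathrin lattice with
  its intrinsic curvature `R_clath`: `A·(κ_clath/2)·(2/R − 2/R_clath)²`,
  zero only at R = R_clath. A lattice held flatter than its intrinsic
  curvature is *elastically loaded*.
* **Polymerization** — the assembly gain, `−a·A/A_clath`, i.e. −a per
  arm–arm interaction with each interaction sustaining `A_clath` of lattice
  area. An optional open-arm correction `−a·(A/A_clath − N_open)` accounts
  for unpaired boundary arms; it is negligible for lattices of more than a
  few cells and is off by default.

### Parameters

| symbol      | meaning                               | default | unit     |
|-------------|---------------------------------------|---------|----------|
| κ_memb      | membrane bending rigidity             | 15      | k_BT     |
| R_memb      | intrinsic membrane curvature radius   | ∞       | nm       |
| γ           | membrane tension                      | 0.01    | k_BT/nm² |
| κ_clath     | clathrin coat bending rigidity        | 373     | k_BT     |
| R_clath     | intrinsic clathrin curvature radius   | 40      | nm       |
| a           | polymerization energy per interaction | 30      | k_BT     |
| A_clath     | lattice area per arm–arm interaction  | 218     | nm²      |

γ = 0.01 k_BT/nm² is an intermediate value of the 10⁻⁴–1 k_BT/nm² cellular
range; R_clath ≈ 40 nm is the characteristic radius of self-assembled
clathrin cages; a ≈ 30 k_BT is the upper-bound estimate from the
bending/polymerization balance at the mean observed pit radius (see below).
All lengths are nm, energies k_BT; SI conversion (k_BT = 4.11·10⁻²¹ J at
298 K) happens only in the stiffness-to-rigidity helper.

### Constrained minimization

Only caps with A ≤ 4πR² are physical. `minimize_energy` scans a log-spaced
(A, R) grid over the valid region — augmented with the exact boundary curve
A = 4πR² at every R column, so boundary minima are representable — and
zooms locally (four refinement rounds of 41×41), which resolves the
minimizer to ≪ 0.1 nm. On the boundary the energy restricted to closed
spheres is an explicit quadratic in R and has the stationary radius

    R* = (4κ_clath/R_clath) / (2γ + 4κ_clath/R_clath² − 2a/A_clath)

(55.07 nm at the defaults); the closed form is evaluated alongside as a
cross-check and the returned result reports which branch — `boundary`,
`interior`, the `empty` A→0 reference when no pit beats E = 0 (e.g. a = 0),
or `unbounded` when the polymerization gain per unit area exceeds the
flat-lattice bending cost (a/A_clath > 2κ_clath/R_clath², detected from the
large-R, large-A density limit before any search).

`critical_tension` sweeps γ and returns the smallest grid value at which
the constrained minimizer detaches from the closed-sphere curve (~0.06
k_BT/nm² at the defaults, the tension above which vesicle closure stalls);
the result records the branch at every swept γ so the bracketing property
is checkable.

`relax_at_constant_area` is the stationary condition of the energy in 1/R
at fixed A,

    1/R = (4κ_clath/R_clath + 4κ_memb/R_memb) / (4κ_memb + 4κ_clath + γA/2π),

clamped to the sphere bound R ≥ √(A/4π). It is the state a lattice
fragment relaxes to after its architectural constraints are severed.

### Per-arm energetics and parameter estimation

`per_arm_bend_energy(R) = A_clath·(κ_clath/2)·(2/R − 2/R_clath)²` is the
coat bending cost carried by one arm–arm interaction; a flat lattice stores
~102 k_BT per interaction at the defaults. `estimate_a_from_Rmean` assumes
bending and polymerization balance at the population-mean radius (growth
from near-flat geometry remains marginally favourable) and evaluates the
per-arm curve there; at R_mean = 92 nm it returns ≈ 32 k_BT (~30 to one
significant figure). Lattice defects can only relax the true cost, so the
estimate is an upper bound on a.

`kappa_from_stiffness` converts an AFM point-load cage stiffness to a
bending rigidity with the thin-shell pair k = 4Et²/(R√(3(1−ν²))) and
κ = Et³/(12(1−ν²)), i.e. κ = kRt√3/(48√(1−ν²)). The shell thickness and
Poisson ratio are not measurable in the same experiment, so the defaults
(t = 11.5 nm, ν = 0.5) are an explicit calibration chosen such that the
measured k = 0.08 N/m on a 40-nm cage maps to κ_clath ≈ 373 k_BT; the
relation is documented rather than asserted, and alternative (t, ν) can be
passed.

## AFM morphometry

Coordinates are pixel centres, 0-based, x = column·pixel_size; heights are
nm above the zero level.

* **Leveling** sets the zero level to the median of the lowest quartile of
  heights. This lower-tail statistic ignores the protruding pits entirely;
  under Gaussian background noise it sits ≈1.15σ below the background mean
  (≈0.1 nm at typical AFM noise), which is negligible against nm-scale
  features and is characterized in the tests.
* **Registration** between frames is integer-pixel translational
  cross-correlation (drift between consecutive frames is dominated by
  in-plane translation); featureless frames fall back to the identity with
  a warning.
* **Sphere fitting** is two-stage: a linear algebraic least-squares fit of
  x²+y²+z²+Dx+Ey+Fz+G = 0 over the connected above-background region
  around the seed, then two refits restricted to points within 45° polar
  angle of the current apex. The apex-restricted refit exists because tip
  dilation corrupts the steep cap flanks but barely touches the top; the
  45° window is measured from the apex of the current sphere estimate, the
  only reference axis that serves that purpose. Cap height is the fitted
  apex height above the zero level and A = 2πRh. Fits with fewer than 12
  usable points or R outside [5, 2000] nm are failures, not records.
* **Ridge detection** subtracts a Gaussian-smoothed copy (σ = 6 px at full
  sampling, scaled with the sampling) so the pit shape drops out, then
  marks pixels that are strict 1D local maxima along either image axis —
  a separable ridge test; diagonal axes are deliberately excluded. The
  test runs at samplings 1, 0.5 and 0.25 (down-sampled passes catch the
  tops of wide flat ridges), the masks are OR-combined after upsampling,
  and two rounds of 3×3 dilation then erosion bridge single-pixel gaps
  (two rounds is the smallest count that closes them). A prominence floor
  (0.3 nm) keeps pixel noise out of the mask; all of these are exposed
  parameters.
* **Skeletonization** thins the mask to one pixel, clusters junction
  pixels within 2 px into hub nodes (AFM hub blobs span more than one
  pixel; without merging, degree-3 hubs fragment into pairs of degree-3
  pixels), prunes spurs shorter than 4 px, and simplifies every traced arc
  to its corner points (Douglas–Peucker, 2 px), so bends along boundary
  ridges become degree-2 vertices instead of being cut off. Vertex heights
  are local maxima of the topograph. Faces are the bounded faces of the
  geometrically embedded planar graph, traced with the standard
  clockwise-next half-edge rule; components without junctions (bare lines
  and closed loops) are simplified to their corners directly. Arm
  bookkeeping: N_poly = N_total − N_open by construction, where open arms
  are edges with a degree-1 end.
* **Section profiles** are bilinear height samples at 1-px spacing with a
  sliding-window algebraic (Kåsa) circle fit for local curvature, signed
  positive for upward bulges; `apex_radius` fits the contiguous region
  around the profile maximum.

## Triskelion statistics

Hubs are degree-3 skeleton vertices; arms are straight 3D chords to the
neighbouring hubs (the skeleton carries no intra-arm curvature, so chords
are the natural resolution). The three pairwise chord angles sum to 360°
for a flat hub; the flat/convex/concave classification uses a ±5° band
matching the AFM angular noise scale. Interior angles pooled per polygon
class are summarized by the maximum-likelihood normal fit (sample mean and
sd — bin-width independent; the 2° histogram is attached for plotting);
faces of size ≤4 or ≥8 are tallied but excluded from the class fits.
Angle sums are binned against pit radius (quartile bins by default, with a
per-distinct-radius fallback for discrete synthetic populations) and the
trend is reported as the Spearman rank correlation between bin radius and
mean angle sum.

## Synthetic data

The generator produces every input the pipeline needs, with ground truth:

* **Populations**: (A, R) pairs drawn with probability ∝ exp(−E_CCP/T_eff)
  over the valid region of a landscape grid. T_eff (default 300 k_BT) is
  an effective temperature controlling the spread of the cloud around the
  landscape minimum — a sampling device for producing realistic-looking
  test populations, explicitly not a physical claim about the observed
  ensemble.
* **Lattices**: generator points quasi-uniform on the full support sphere,
  Voronoi-dualized on the sphere, cells kept where the generator lies on
  the cap. Seeding uses a geodesic subdivided icosahedron (frequency
  chosen to match the target cell density for an 18-nm arm length; 20
  Lloyd relaxation steps even out cell sizes). The seeding choice is
  deliberate: a centroidal relaxation started from spiral-type point sets
  freezes in chains of pentagon–heptagon defects, whereas the geodesic
  start has Goldberg combinatorics — exactly 12 pentagonal cells on a
  closed sphere (Euler's formula for a degree-3 polyhedron), all other
  cells hexagonal, which is the defect structure of real clathrin cages.
  Pentagon count on a partial cap then scales with the subtended solid
  angle. Hubs are degree-3 by construction.
* **Rendering**: height = max(membrane 0, cap top surface, ridges raised
  2 nm above the local surface), grayscale-dilated with a spherical tip
  (ball structuring function, radius 2 nm — the standard tip-convolution
  model; dilation widens, never narrows), plus Gaussian pixel noise
  (σ = 0.1 nm). Frames default to 300×300 px at 2 nm/px, matching the
  imaging geometry emulated. The benchmark batch spans R ∈ [40, 300] nm
  (log-uniform) with aspect ratios h/R ∈ [0.25, 0.9], capped so footprints
  stay 40 nm inside the frame.
* **Nanodissection**: edge removal in the lattice graph; each resulting
  fragment keeps the faces all of whose corners it retains, is assigned
  area n_faces·3·A_clath (three arm–arm interactions per unit cell — this
  ties the dissection energetics to the polymerization bookkeeping rather
  than to mesh surface integration), and relaxes via the constant-area
  closed form. Relaxation can only lower the elastic (bending + tension)
  energy; severed interactions cost +a each in polymerization energy.

What the generator does *not* emulate: scanner line noise and feedback
artifacts, tip wear and asymmetric tips, molecular substructure of the
triskelion legs, crowded membranes with overlapping pits, and temporal
dynamics. Passing recovery tests therefore demonstrate the correctness of
the estimators under the stated imaging model, not performance on every
real-world image.

## Numerical choices

* Landscape grids are 400×400 log-spaced over A ∈ [10², 10⁵] nm²,
  R ∈ [10, 400] nm (covering the observed population and all landscape
  features); minimization uses a 200×200 scan plus refinement.
* Cap validity tolerates 10⁻⁹ relative overshoot of A ≤ 4πR²; boundary
  membership in the minimizer uses a 10⁻⁶ relative band.
* Degenerate inputs: all-equal images level to their own value; empty
  ridge masks yield empty skeletons; zero-length section lines, seeds off
  any protrusion, and sub-minimum point counts raise typed errors.
* The benchmark suite sizes (50 pits for recovery, 19-hexagon patch for
  skeleton recovery, three draped radii for the angle-sum trend) keep the
  full test suite in a few minutes on one core while leaving the medians
  statistically stable.

## Known limitations

* The thin-shell stiffness conversion is a calibrated relation, not a
  measurement; its (t, ν) defaults are stated, not derived.
* The ridge detector's prominence floor and high-pass scale are tuned for
  nm-scale ridges at 2 nm pixels; markedly different pixel sizes need the
  exposed parameters adjusted.
* Face recovery degrades gracefully but not indefinitely with noise; at
  σ comparable to the ridge height the skeleton fragments.
* The Boltzmann-style population sampler is a testing device; it is not an
  inference about the biological ensemble.
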