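# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic validation does and does not demonstrate.

## Alpha complexes

The endocast of one frame is the alpha complex of the locator cloud: of
the Delaunay tetrahedralization, keep exactly the tetrahedra whose
circumradius is `<= alpha` (the alpha-radius convention). Volume is the
sum of retained tetrahedron volumes; every connected region counts, no
holes are filled and no region is suppressed. The boundary mesh consists
of the triangles belonging to exactly one retained tetrahedron, wound
outward (normal away from the opposite vertex); it is closed in the
even-edge-count sense — a pinched edge shared by four faces can occur
where two regions touch, and the divergence-theorem volume remains valid
there.

Units: alpha is a length in the same unit as the coordinates. The package
recommends cm so volumes are ml; a `unit_scale` config entry converts
other units (e.g. 0.1 for mm).

Numerical choices:

- **Degenerate tetrahedra** (volume `<= 1e-12 ×` bounding-box diagonal³)
  are assigned circumradius `+inf` and never retained. They carry no
  volume, so the complex's volume is unaffected.
- **Co-spherical inputs** (gridded or symmetric clouds) can make the
  Delaunay triangulation ambiguous and sliver-ridden. `tetrahedralize`
  first triangulates the raw points; only if degenerate simplices appear
  does it re-triangulate after jittering all points by `1e-9 ×` the
  bounding-box diagonal with a fixed internal seed. The jitter is a
  deterministic tie-break, not a source of randomness; downstream geometry
  uses the jittered coordinates so circumradii, volumes and boundaries
  stay mutually consistent.
- **Circumradii** are computed in batch by solving the 3×3 equidistance
  system for the circumcenter. The test suite checks them against an
  independently formulated sphere-through-four-points oracle.
- **Critical alpha** is defined here as the smallest alpha at which every
  input point is a vertex of some retained tetrahedron, found by binary
  search over the sorted distinct circumradii. Points merged as exact
  duplicates by the triangulator are judged through their kept twin. This
  is a stated choice; other toolchains ("default alpha" heuristics in
  animation/math packages) may choose differently.

## Rigid kinematics

RBTs map bone-local to world coordinates, `world = R·local + t`,
right-handed, column-vector convention. `estimate_rbt` is the standard
least-squares fit: centroid alignment, SVD rotation solve, and the
proper-rotation correction (flip the smallest singular direction when the
orthogonal optimum is a reflection) — exact for noiseless rigid motion of
any non-collinear `>= 3`-marker set, and the global RMSD optimum under
noise. Collinear or too-few marker sets raise an error.

Locator placement is automated (seeded vertex-subset or greedy
farthest-point sampling over mesh vertices) where a practitioner would
place locators by hand; draws for different counts are independent, so a
smaller set is never a subset of a larger one. Midsagittal-plane locators
are parented to a static reference and use the identity transform; a
parent present in the transform table but missing a frame is an error
naming bone and frame.

## Mesh volumetrics

Closed-mesh volume is the signed divergence-theorem sum
`Σ v₁·(v₂×v₃)/6`; inward-wound meshes yield the absolute value with a
warning. Volume operations refuse meshes with open (odd-face-count)
edges, reporting the count. The gold-standard cavity volume is
`volume(wrapped) − volume(surface)` for a sealed "wrapped" mesh enclosing
solid plus cavity — mirroring how air volume is segmented out of a CT
scan — and is additive by construction. File I/O (OBJ/STL/PLY) is
delegated to `trimesh`.

## Pipeline

Per frame: alpha complex at the configured alpha; unilateral volume
`V_uni` scaled to ml; `V_bi = 2·V_uni` when one side of a symmetric
cavity is measured (bit-exact doubling). Degenerate frame clouds are
flagged and recorded as missing — never silently interpolated.

Filtering is zero-phase (forward-backward) Butterworth low-pass, order 2
by default, cutoff a required config value as a fraction of Nyquist;
a centered moving average is the fallback. Reflection padding handles the
endpoints. Below 15 frames the filter passes through with a warning — a
handful of poses cannot be filtered meaningfully, which is also why a
behavior should be captured in enough frames (50–100) to filter before
differentiating. Differentiation is central differences (one-sided at the
ends), divided by `1/frame_rate`, or by 1 for pseudo-time pose series.

Enclosed-tissue correction subtracts a constant from absolute volumes
(half of it from the unilateral column when a bilateral column exists)
and clamps negatives loudly; `dV/dt` is untouched since a constant offset
has zero derivative — the incompressibility argument for why enclosed
tissue biases absolute volume but not volume change.

Interpenetration diagnostics are Monte-Carlo: uniform samples inside the
endocast (rejection from the bounding box) tested against bone meshes by
generalized winding number (solid-angle sum), reported with a standard
error. The winding-number test is exact for closed meshes and robust to
pinched edges.

## The validation phantom

The phantom emulates a specimen CT-scanned in a pseudo time series of
poses: a hinged wedge between two rigid plates (hinge length `L`, plate
width `W`), plate A fixed, plate B opened to angle θ, with equally spaced
θ over `[θ_min, θ_max]`. Defaults (the study conditions): `L = 10` cm,
`W = 5.5` cm, θ from 17° to 57.5°, 7 poses, tissue `T = 29.4` ml, pocket
coefficient `c = 0.1173`, 4 markers per plate, marker noise σ = 0.005 cm.
These put envelope volumes at ~44–128 ml and true air volumes at ~15–108
ml — the tens-of-ml range of a real fish head — give an accuracy-law
slope of 1/(1+c) = 0.895, and use a marker noise at the scale of X-ray
marker-tracking precision (~0.05 mm). Seven poses matches a realistic
CT-pose validation budget.

Components:

- **Envelope**: triangular prism, volume exactly `½ L W² sin θ`; its
  watertight mesh is the "wrapped" gold-standard mesh.
- **Tissue**: a wedge prism of volume exactly `T` sharing the hinge,
  attached inside plate A, with a smaller opening angle than `θ_min` so it
  stays enclosed in every pose. (A flat rectangular bar of paper-scale
  tissue volume cannot fit the closed wedge, hence the wedge shape.)
- **Pocket**: `c·(V_env(θ) − V_env(θ_min))` of air the endocast cannot
  see, handled analytically rather than meshed — it models uncovered
  recesses (e.g. under bony flaps) whose growth with expansion is exactly
  what makes the method underestimate volume change.
- **Markers**: near-corner sites on each plate's inner face, observed
  with iid Gaussian noise; RBTs are re-estimated from them, so marker
  noise propagates through the whole pipeline.
- **Locator candidates**: an in-plane jittered grid on each plate's inner
  face (corners pinned, edge nodes slid along their edge). The jitter
  emulates hand placement and removes the co-circular degeneracies of an
  exact lattice; every site lies exactly on the plate surface.
- **Concave variant** (`cap_depth > 0`): the planar front cap is replaced
  by a cylindrical surface bulging inward, sampled as a polygonal arc;
  truth uses the same polygon so geometry and truth agree exactly.
  Soft-tissue locators ride the deforming cap, and a "cap bone" mesh
  occupies the bulge, so over-large alpha values bridge the concavity and
  interpenetrate it — the known failure mode of too-large alpha.

Gold truth per pose: `A = V_env − T + pocket`. Ideal-endocast algebra
gives `slope = 1/(1+c)` and `intercept = (T + c·V_env(θ_min))/(1+c)` for
the regression of endocast volume on `A`; with noiseless markers, dense
locators and alpha at twice the critical value the pipeline reproduces
both to machine precision, and any `c > 0` forces slope `< 1`.

**What the phantom does not emulate**: anatomical geometry (curved bones,
many-body kinematics), soft-tissue deformation of the cavity walls,
marker-tracking outliers, or CT segmentation error in the gold standard.
Passing tests therefore demonstrate the correctness of the machinery and
the direction/magnitude structure of the method's bias mechanism, not the
accuracy attainable on any particular animal.

## Validation statistics

Accuracy/precision is the OLS regression of endocast volume (y) on
gold-standard volume (x): slope = accuracy of volume change, R² =
precision, intercept = enclosed tissue, residuals against `y = x` =
absolute-volume bias. Confidence intervals are classical t intervals on
`n − 2` degrees of freedom (a seeded case-resampling bootstrap is
available). The regression orientation (endocast on gold) is fixed.

Sweeps share one pose series across swept values so differences are
attributable to the swept variable alone. Locator-count sweeps use
*strategic* placement: several independent candidate placements per count,
keeping the one with the best worst-frame fit (per-pose volume relative
to the best candidate at that pose) — the automated analog of placing
locators by hand and visually checking the endocast fit in every frame.
At very small counts (4 points per plate) a single random placement can
over- or under-shoot the plateau slope by chance; strategic placement
restores the rise-then-plateau shape that careful hand placement shows.
The locator sweep is evaluated at alpha = 8 cm, comfortably above every
per-set circumradius, so the sweep isolates coverage effects; at smaller
alphas the thin closed pose sheds flat tetrahedra asymmetrically and
contaminates the slope with truncation effects.

## Problem sizes

Default test and acceptance runs use 7-pose series, candidate grids of
25×14 sites per plate (700 dense locators), locator sweeps over
8–128, 100-cloud alpha-oracle sweeps at `n <= 50`, 1000-replicate rigid
fits and CI coverage runs — sizes chosen so the full validation remains a
desk-scale computation while every statistic is estimated comfortably.

## Known limitations

- The alpha-radius retention rule is one of several alpha-shape
  conventions; tools using regularized or weighted variants will differ
  near the critical alpha.
- `critical_alpha` requires every point to become a vertex of the
  retained complex; for clouds with deep interior points this can exceed
  the visually adequate alpha.
- The Monte-Carlo interpenetration fraction has `O(n^{-1/2})` error; the
  reported standard error should be honored when comparing fractions.
- Bilateral doubling assumes perfect symmetry; asymmetric cavities need
  both sides animated.
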