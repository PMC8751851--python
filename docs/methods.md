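# Methods

## The model

MREyeTrack-style model-based eye tracking treats the eye as three rigid
ellipsoids — sclera, cornea and the inner part of the lens — because these
are the structures with reliable MR contrast. Each ellipsoid is the affine
image of the unit sphere,

    x = x0 + R S u(α, β),     R = Rx(θx) · Rz(θz) · Ry(θy),
    S = diag(rx, ry, rz),

with the center `x0` in mm, rotation angles in degrees and semi-axes in mm.
Coordinates are right-handed patient coordinates (x left–right,
y anterior–posterior, z inferior–superior); `−e_y` points anteriorly, so
the cornea sits on the negative-y side of the globe.

Two anatomical constraints close the model: the cornea center is held at a
fixed 7 mm distance from the eyeball (sclera) center along a rotated
anterior axis, and the lens center is pinned to the sclera surface along
its own rotated anterior axis. A point is inside an ellipsoid when
`‖S⁻¹Rᵀ(x−x0)‖ < 1`; the outer eyeball border is the part of each of
sclera/cornea lying outside the other.

## The Normal Gradient Matching (NGM) energy

A candidate surface is scored by the mean inner product of its outward unit
normals with the image intensity gradients,

    E = (1/|Ω|) Σ_Ω  n · g,

normalized by the sample size so larger surfaces are not favored. On
T2/bSSFP contrast the vitreous is bright against a dark surround, so `g`
points inward across the outer border and E is minimized when the model
sits on it. The dark lens nucleus has the opposite edge polarity, so the
lens term enters with sign −1. Gradients are Gaussian-derivative filtered
at σ = 1 voxel and sampled off-grid by linear interpolation; points outside
the image contribute zero but still count in the normalization, so partial
occlusion degrades the energy gracefully instead of failing.

Surfaces are sampled with a Fibonacci lattice mapped through the ellipsoid
affine (near-equal-area because the globe is nearly spherical); 2000 points
per ellipsoid resolve the 0.5 mm voxels of a 24 mm globe with quadrature
error below 1% of the energy.

In the 3D stage-1 fit, outer-border sample points falling inside the lens
dilated by 1.5 mm (about the blur scale) are excluded: where the lens
crosses the outer border the edge carries no vitreous/surround contrast,
and the lens's own posterior dark→bright edge otherwise attracts the
sclera surface inward. Energy scans over (center-y, anterior semi-axis)
showed the minimum displaced by about (−0.1, −0.2) mm without the
exclusion and recentered with it. The same exclusion applied to the 2D
arcs removed too much of the anterior constraint and was left off there;
both choices are config switches.

## Optimization

The optimizer is a generalized pattern search: coordinate polling at
±mesh·scale, opportunistic acceptance, mesh doubling after a successful
poll and halving after a failed one, clamped polling at box bounds, and a
Hooke–Jeeves pattern move after each successful sweep (the accumulated
direction of recent successes is followed and doubled while it improves —
coordinate polls alone crawl along oblique valleys). Initial meshes are
1 mm / 2°, tolerances 0.01 mm / 0.05°, evaluation budget 6000. The search
is fully deterministic.

A single flat search over all stage-1 parameters proved unreliable: the
fit could bury the corneal bulge by inflating the sclera's anterior
semi-axis, or stall in the shallow valley coupling the center with the
cornea orientation (the energy along the straight line from such a stall
to the truth decreases monotonically — there is no barrier, the
coordinate polls simply fail on the valley walls). Two structural choices
remove most of these failure modes:

* the stage-1 cornea is a sphere with a single radius parameter (a free
  triaxial cornea is over-parameterized for the near-spherical corneal
  dome and lets a larger, tilted cornea mimic the bulge at a wrong
  orientation — a genuine degeneracy, observed up to 12° of orientation
  error before the change);
* semi-axes are bounded to a ±1.2 mm band around the globally fitted
  scale, the plausible asphericity range.

The stage-1 schedule is then: (a) center + global scale; (b) cornea
orientation, seeded by a ±20° grid scan over the two bulge angles;
(c) center + sclera semi-axes; (d) all parameters; (e) a multistart
refinement — the best three well-separated cornea-orientation candidates
from a fresh grid scan each launch a short full refit, and the
lowest-energy result wins; repeated while the energy improves. Stage 2
freezes the outer border and fits the lens rotation (2) and semi-axes (3)
on the lens term alone.

## Single-slice motion estimation

The imaging plane `x·n = d` is intersected with each posed ellipsoid in
closed form: the affine transform that maps the ellipsoid to the unit
sphere maps the plane to a plane at transformed distance δ; for |δ| < 1
the intersection is a circle of radius √(1−δ²) that maps back to an
ellipse given by a center and two conjugate diameters. A parameter
rotation by ½·atan2(2 v1·v2, ‖v1‖²−‖v2‖²) orthogonalizes the diameters
when principal axes are needed. Sclera/cornea curves are clipped to the
outer border by the 3D interior test; curve normals are in-plane,
oriented outward.

Per-frame motion has five parameters: in-plane translation pair,
through-plane translation (±1 mm box), and rotations about x and z with
the out-of-plane one boxed to ±5°; torsion is fixed at zero. These boxes
reflect that out-of-plane motion is not identifiable from a single slice
— the through-plane direction of the energy is nearly flat, and the
estimate simply sits somewhere in the box. Frames are tracked
sequentially, warm-starting at the previous frame's estimate; the first
frame (or independent images in the validation) gets a translation-only
prefit followed by a coarse scan of the in-plane rotation so the search
starts in the correct basin.

## Synthetic data

The generator emulates the two acquisition modes at the intensity level
only (no k-space, banding or flip-angle physics):

* volumes: 0.49 × 0.49 × 0.5 mm voxels, 1 mm through-slice sensitivity;
* slices: 0.94 mm (axial) / 1.0 mm (sagittal) pixels, 3 mm slice
  thickness, 34.8 / 37.8 ms per frame.

Rendering: exclusive region labels (lens ⊃ eye interior ⊃ surround) →
partial-volume fractions by ×4 per-axis supersampling of the indicator
over each voxel's sensitive window (the through-slice window uses the
slice thickness) → Gaussian noise with mean/SD 0.7/0.1 inside, 0.2/0.2
outside and 0.2/0.1 in the lens, blended by the partial-volume fractions →
Gaussian blur with SD of one pixel. Supersampling is restricted to voxels
near a structure border; interior/exterior voxels are pure by
construction.

Population defaults (chosen once; the source figure with the original
per-parameter histograms is not machine-readable): center N(0, 1 mm) per
axis; diameter N(24, 1) mm clipped to 20–28 mm; per-axis shape ratios
(0.97, 1.04, 0.99) with SD 2% (anterior–posterior axis longest, per ocular
biometry); globe orientation N(0°, 5°) clipped to ±20°; cornea modelled as
a sphere of radius `sclera_ry − 4.8 mm` (≈7.7 mm, keeping a 2–3 mm corneal
protrusion across eye sizes, since the 7 mm center constraint does not
scale); lens semi-axes (4.0, 1.8, 4.0) mm with 2% relative SD; cornea and
lens orientations follow the globe's anterior axis with 2° jitter
(structures are nearly coaxial; marginal SD ≈ 5.4°). Draws in which more
than 2% of the lens surface falls outside the bright sclera∪cornea
interior are rejected as non-physiologic — such configurations would leave
the lens boundary without contrast, which no real eye exhibits.

Motion for the 2D validation is uniform in ±2 mm per translation axis and
±20° per rotation axis including torsion (rendered but never estimated).
Kinematic fixtures use a raised-cosine retraction/lift pulse (peak = the
configured amplitude, FWHM = half the pulse width) and a four-parameter
sigmoid gaze step, rendered frame by frame at the slice protocol's
temporal resolution.

## Validation experiments and problem sizes

The 3D benchmark (20 eyeballs by default) renders each eye, seeds the fit
with the fast-radial-symmetry detector, runs the two-stage NGM fit and
scores: dice overlap of the outer-border voxelization (voxel centers
inside sclera ∪ corneal protrusion), and recovery of position,
orientation and diameter. "Orientation" is the physical-orientation proxy
— the two angles carrying the anterior axis to the cornea center. The
sclera ellipsoid's own per-axis angles are not scored: at 2% asphericity
the energy is flat in them (the noise-free argmin wanders by ±5°), i.e.
they are not identifiable, for the same reason torsion is not estimable
in 2D. Diameter is twice the mean sclera semi-axis. Residual SDs are the
scatter about the per-parameter regression line of estimate on truth;
systematic offsets (notably the blur/lens-induced diameter
underestimation) are reported separately as biases.

The 2D benchmark (20 eyeballs × 25 poses × 2 planes = 1000 images by
default, a reduced version of the original 20 000) places an axial and a
sagittal slice through each eye's rest-pose lens center, renders each
random pose and estimates it from scratch (translation prefit + in-plane
rotation scan at 4° steps). In-plane translation and rotation residual
SDs are pooled over planes; out-of-plane components are reported
separately.

## Known limitations

* With the population above, single-slice in-plane rotation estimates
  degrade sharply when the posed lens leaves the 3 mm slab (an
  out-of-plane rotation near ±20° displaces the lens by ~4 mm
  through-plane; roughly 10% of validation images). In those images the
  lens and most of the corneal bulge are invisible, the nearly spherical
  sclera section provides no rotational anchor, and the energy genuinely
  prefers a wrong in-plane rotation that compensates the clamped
  out-of-plane mismatch — errors can reach tens of degrees. The pooled
  in-plane rotation SD is therefore dominated by these images. A more
  aspheric globe population, or slices thick enough to retain the lens,
  would remove the degeneracy; with the present conditions it is a
  property of the task, not of the optimizer (checked by comparing the
  energy at the estimate against the truth-derived pose).
* The fitted edge localization is less biased than the original
  analysis's: the diameter underestimation is ~0.06 mm (vs. the reported
  0.33 mm) and mean dice overlap correspondingly higher (~99.2% vs.
  98.2%). Widening the gradient scale reproduces the larger bias but
  destroys position/orientation precision, so the finer scale is kept.
* Eyeball-center recovery carries a per-instance systematic component of
  roughly ±0.07 mm (it persists on noise-free renders, is unchanged by
  tripling the surface sample, and varies with the draw's lens/cornea
  geometry) — the anterior region's partial-volume structure interacts
  with the border model. Position residual SDs therefore sit near
  0.07 mm rather than the few-hundredths-of-a-millimetre regime the
  noise level alone would allow.
* Passing these simulations shows correctness of the geometry, energy,
  optimizer and scoring under the stated intensity model. Real data adds
  eyelid/muscle structure, intensity inhomogeneity, banding and motion
  artifacts that the generator deliberately does not emulate.
* Out-of-plane translation/rotation estimates are reported but sit
  anywhere inside their ±1 mm/±5° boxes; only in-plane components are
  meaningful, as in the original method.
* Head motion is corrected for translation only; rotational head motion
  and Eyelink EDF binary parsing are out of scope.
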