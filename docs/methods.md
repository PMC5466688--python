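# Methods

This note documents the models, conventions and numerical choices behind
`axdt`, and what the synthetic studies do and do not demonstrate.

## Pose geometry

A pose is a triple of Euler angles `x = (ψ, θ, ϕ)` applied as an intrinsic
y–z′–y′ rotation, `R(x) = R_y(ψ)·R_z(θ)·R_y(ϕ)`, with right-handed rotation
matrices

    R_y(γ) = [[cos γ, 0, sin γ], [0, 1, 0], [−sin γ, 0, cos γ]]
    R_z(γ) = [[cos γ, −sin γ, 0], [sin γ, cos γ, 0], [0, 0, 1]]

Angles are stored in degrees, normalized to `(−180, 180]`.  The axis order
is fixed by the cradle hardware; the *signs* are a package convention,
chosen so that the base circle `A(0, 0, N)` with horizontal gratings
(`S = [0,1,0]`) holds `s(x) = [0,1,0]` fixed and `A(0, 90, N)` yields a
vertical sensitivity — i.e. the convention reproduces the qualitative
sphere-coverage patterns expected for the three standard grating
alignments.  No other claim depends on the sign choice.

**Euler decomposition.**  `decompose_euler` recovers `(ψ, θ, ϕ)` from a
rotation matrix through the quaternion half-angle form (`w = cos(θ/2)cos σ`,
`y = cos(θ/2)sin σ`, `x = sin(θ/2)sin δ`, `z = sin(θ/2)cos δ` with
`σ = (ψ+ϕ)/2`, `δ = (ψ−ϕ)/2`), which stays well-conditioned at the gimbal
degeneracies `θ → 0, 180°` where the direct arctangent formulas divide
noise by noise.  Of the two valid y–z–y branches — `(ψ, θ, ϕ)` and
`(ψ+180°, −θ, ϕ+180°)` — the one with smaller `|ψ|` is returned, keeping
poses as close as possible to the mechanically reachable range of the first
cradle circle.  At `θ ≈ 0` (`sin(θ/2) < 10⁻¹²`) the whole y-rotation goes
into `ϕ` and `ψ = 0`, the `|ψ|`-minimizing choice.  Round-tripping holds to
1e−8 across the gimbal region.

**Minimal rotation.**  `M(v₁, v₂)` is the Rodrigues rotation about
`v₁ × v₂` by the enclosed angle (never more than 180°).  For antipodal
inputs the axis is the normalized rejection of `[1,0,0]` from `v₁` (or of
`[0,1,0]` when `v₁` is collinear with `[1,0,0]`), so scheme construction is
deterministic.

## Trajectory design

The design goal is a set of `N` poses all probing the same scattering
orientation `q` (`s(y_i) = q`) while the integration directions `t(y_i)`
sweep a full circle — the condition under which one component of the
anisotropic signal is rotation-invariant and admits classical tomographic
recovery.  The implementation maps each base pose `x_i ∈ A(0,0,N)` to

    R_final(x_i) = M([0,1,0], q) · R(x_i) · M(S, [0,1,0])

The right factor aligns the physical sensitivity `S` with the y axis, the
base rotation then spins about that axis (leaving the sensitivity fixed and
moving the beam around the great circle), and the left factor transports
the whole construction to the target `q`.  This yields `s(y_i) = q` exactly
and `N` tomographic vectors uniformly spaced by `180°/N` on the great
circle orthogonal to `q` (both hold to ~1e−13 before Euler re-encoding and
to better than 1e−8 after it).  An equivalent form computes
`R_int = M([0,1,0],q)·R(x)`, `u = R_int·S` and left-multiplies by
`M(u, q)`; the two agree by the rotation-equivariance of the minimal
rotation.  Only the sensitivity *axis* is meaningful (the model is
antipodally symmetric), so `s = ±q` are equally valid; the construction
lands on `+q`.

The full design `Z(S, N)` concatenates one trajectory per direction of the
28-orientation hemisphere set (L·N poses); the legacy grid `W(N)` and the
single circle `A(ψ, θ, N)` are provided for comparison.  Feasibility
truncation keeps poses with `|ψ| ≤ ψ_max` inclusive, after rounding `ψ` to
1e−6 degrees so boundary membership does not depend on floating-point
branch noise.

## The bundled direction set

The 28 target orientations are one hemisphere of a *symmetric spherical
9-design with 56 points* shipped as a plain-text table
(`src/axdt/data/tdesign56.txt`).  The table is **synthetic**: it was
computed by this package by minimizing the even-degree harmonic moments
(degrees 2–8; odd degrees vanish by antipodal symmetry) of 28 antipodal
pairs with L-BFGS from a seeded random start, to a residual where every
degree-1..9 harmonic averages below 1e−8 over the set.  The test suite
verifies the 9-design property.

Published 56-point design tables exist, but a t-design is not unique and is
in any case only defined up to a global rotation — and the *absolute
counts* of poses surviving the `|ψ| ≤ 40°` cut depend on how the design is
oriented relative to the setup axes.  With this package's table the
truncated `N = 100` designs contain 1718 (diagonal), 1200 (horizontal) and
1259 (vertical) poses; tables with a different orientation shift these
counts by a few percent while leaving every structural result unchanged
(the 2800-pose total, the diagonal > vertical > horizontal ordering of
measurable fractions, and all reconstruction and ranking behavior, which
depend only on the uniformity of the direction set).

**Grating angle.**  `sensitivity_from_alpha` parametrizes the sensitivity
as `S(α) = [cos α, −sin α, 0]`; the inner product with the vertical axis
fixes only `cos α`, and the negative y-component is chosen so `α = 45°`
gives the diagonal sensitivity `[0.7071, −0.7071, 0]` in the convention
above.

## Spherical harmonics

Real, orthonormal, Condon–Shortley-free harmonics built from the complex
orthonormal ones (`√2·(−1)^m Re/Im` combinations).  Any fixed orthonormal
convention yields the same physics; pinning one makes coefficients
reproducible.  Only even degrees are carried — the dark-field signal is
antipodally symmetric — so the `K = 4` basis has 15 functions (the `2^K − 1`
factor by which the coupled system exceeds a scalar CT problem).
Quadrature for expansions is a product Gauss–Legendre × uniform-azimuth
grid, exact to the requested degree (2K = 8 by default, 45 nodes), computed
at runtime rather than bundled: exactness is then guaranteed by
construction and independent of the bundled design's t-strength.

## Forward model

The measurement model is

    d(x) = exp(−(1/4π) Σ_{k even ≤ 4} Σ_m h_k^m(s(x), t(x)) ∫_{T(x)} η_k^m(r) dr)

with `p = −ln d` linear in the 15 coefficient volumes, `p = A η`.

**Weighting function.**  The default is
`h(q, s, t) = ⟨q,s⟩²·(1 − ⟨q,t⟩²)`: equal to 1 for scattering along the
sensitivity direction, 0 along the beam, nonnegative, and a degree-4
polynomial in `q` — so `K = 4` represents it *exactly* and the band limit
of the model is not an approximation.  The physically calibrated kernel of
a real interferometer may differ; the form is pluggable
(`WeightModel(form=...)`), and all tests assert declared properties
(maximum along `s`, zero along `t`, rotation-invariant mean) rather than
hard-coded values.  Its coefficients are computed per pose by exact
quadrature; the `1/4π` stays in the operator, not in `h`, so coefficient
fields are comparable across weighting forms.

**Projector.**  Joseph-style interpolating parallel-beam ray tracing: the
sample stays fixed while rays (one per detector pixel, along
`t(x) = R(x)·[0,0,1]`, detector axes `R(x)·[1,0,0]` and `R(x)·[0,1,0]`)
step through the volume slab-by-slab along the principal ray axis with
bilinear transverse interpolation and path-length weight `h/|t₀|`.  The
backprojector reuses the identical interpolation weights, so the pair
passes the adjoint dot-product identity at machine precision (~1e−15
relative; the test threshold is 1e−8).  The detector reference frame is a
package convention (any orthonormal completion of the beam is equivalent).

**Operator application.**  Since `h_k^m` is constant per pose, the 15
coefficient volumes are contracted into a single scalar volume per pose
before projecting (`Σ_km h_km P η_km = P (Σ_km h_km η_km)`), and the
adjoint accumulates backprojections through one chunked rank-15 GEMM per 64
poses.  This makes the 2800-pose, 32³/48² operator apply in a few seconds
single-threaded; kernels are numba-compiled at first use.

## Reconstruction

CGLS — conjugate gradients on the normal equations — with defaults of 50
iterations, relative gradient tolerance 1e−6, no regularization: the solver
is deliberately plain least squares.  An optional, off-by-default
nonnegativity correction (`project_nonnegative`) lifts each voxel's
isotropic coefficient just enough to make its spherical function
nonnegative, preserving the anisotropy.  CGLS is deterministic for a fixed
scheme, data and configuration, and its data residual is non-increasing;
residual growth beyond 10× raises instead of silently diverging.  A dense
pseudoinverse cross-check on a tiny system (27 unknowns, 2 poses) pins the
solution to the minimum-norm least-squares solution at 1e−8.

## Null-space probing

One kernel component is probed by minimizing `‖Av‖²` (CGLS with target
`p = 0`) from the uniform isotropic start `η₀⁰ = 0.01` in every voxel, all
other coefficients zero — a flat spherical function everywhere, the natural
neutral probe.  The probing geometry defaults to a 50³ volume and 100²
detector.  Per-orientation maps evaluate the probe field's spherical
function at each of the 28 target orientations and average over y (one x–z
image per orientation).

Two numerical facts shape the comparison between truncated and untruncated
schemes.  First, the iterate after *one* CG step equals
`v₀ − α·AᵀA v₀`, which is dominated by the smooth radial structure of the
backprojection response; its deviation-from-mean energy is nearly identical
for the truncated and untruncated `Z_D(100)` (ratio ≈ 0.99) and does not
yet expose the kernel difference.  The one-step iterate is therefore kept
only for visualization.  Second, after the recoverable components have been
suppressed — five CG iterations at the default geometry — the truncated
scheme's maps retain ≈ 1.7× the deviation-from-mean energy of the
untruncated scheme's: the missing wedges cut by the `|ψ| ≤ 40°` limit
leave per-orientation structure that no amount of iteration removes.  The
five-iteration comparison point is a package choice; the comparison is
qualitative (greater-than), not a calibrated magnitude.

## Phantoms and what the synthetic studies show

Fiber regions carry the girdle profile `c₀ + c₂(1 − ⟨q,f⟩²)` (defaults
`c₀ = 0.05`, `c₂ = 0.10` in reciprocal voxel-length units, giving dark-field
transmissions of roughly 0.3–0.9 over ~20-voxel paths).  The profile is
exactly degree 2, strictly inside the `K = 4` model space, so noiseless
full-coverage recovery is limited only by solver accuracy and phantom
studies isolate *acquisition-scheme* effects from model error; a degree-4
variant exists for stress tests.  The weld-line preset places two bulk
fiber populations (along z, and 60° away in the y–z plane) separated by a
2-voxel weld plane with fibers along x; all regions share `c₀ + 2c₂/3`, so
the isotropic coefficient is uniform and the weld is an orientation-only
feature.  Optional measurement noise is zero-mean Gaussian on `p` (the
domain where the model is linear), seeded.

Default desk-scale study conditions: 32³ voxels, 48² detector pixels (unit
spacings), `N = 20` with `L = 28` (560 poses before truncation) for the
scheme-comparison experiments, `N = 100` for the reference design, 60 CGLS
iterations for the untruncated-recovery experiment and 50 elsewhere, and
the 50³/100² probing geometry for null-space runs.  These sizes keep a full
experiment in minutes on one CPU while leaving the phantom well-resolved
(the weld plane is two voxels; orientation extraction uses a 2000-point
hemisphere grid whose ~3° spacing sits comfortably under the 5° acceptance
band).

What passing tests show: the trajectory constructions satisfy their
invariants exactly; the forward/adjoint pair and the two measurement-model
code paths agree; orientation recovery and scheme rankings behave as the
theory predicts *under the model's own assumptions*.  What they do not
show: performance on real interferometer data — no phase-stepping,
visibility, beam-hardening, edge-scattering (pore artifacts) or detector
physics is simulated, the weighting kernel is a documented stand-in, and
real fiber composites are not two-population box phantoms.

## Orientation extraction and metrics

Extraction evaluates each voxel's spherical function on a dense
quasi-uniform hemisphere grid (golden-angle lattice, 2000 points by
default) and takes the arg-extremum: the minimizer in `structure` mode
(fibers scatter least along their axis — the default, matching fiber-axis
visualization), the maximizer in `scattering` mode.  Both modes exist
because either convention appears in practice; grid extremization with
first-index tie-breaking is deterministic and adequate at the 5° tolerance
of the recovery experiments.  Voxels whose function is constant within
1e−9 over the grid are masked undefined.

The experimental metric `EM = (1/I) Σ |⟨U_i(X), U_i(ref)⟩|` is symmetric,
sign-invariant and bounded in [0, 1]; on the weld-line studies the
reference is the truncated `Z_D(100)` reconstruction, mirroring the
published comparison protocol.

The coverage surrogate stands in for a previously published coverage
metric whose formula is not restated here: poses are binned by sensitivity
direction onto the 28 design orientations, each bin's great circle is split
into 18 sectors of 10° (axial, since `t` and `−t` are equivalent), and the
score is the mean covered-sector fraction.  It is monotone under adding
poses and reproduces the published *ranking* (diagonal ≥ horizontal,
vertical, legacy); its absolute values are package-specific and
intentionally not compared against published ones.

## Known limitations

* Absolute truncated pose counts depend on the bundled direction table's
  global orientation (see above); cross-package comparisons should compare
  fractions, not counts.
* The projector assumes parallel beams and an isotropic voxel grid; cone
  beam and anisotropic spacing are out of scope.
* Null-space probing explores a single kernel component per starting
  guess; it characterizes, not exhausts, `ker(A)`.
* The CLI's `run` pipeline executes stages sequentially in one process;
  there is no parallelism beyond BLAS threading.
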