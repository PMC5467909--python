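# Methods

`ttfield` computes the electric field that scalp electrode arrays induce in a
multi-tissue head volume conductor, and summarises it with the dose metrics
used in treatment-field planning. This note records the model, the synthetic
data it runs on, the numerical choices, and what the validation suite does
and does not establish.

## Forward model

At the intermediate frequencies used for tumor treating fields (~200 kHz),
tissue dimensions are far below the electromagnetic wavelength and the
permittivity contribution to the admittance is negligible, so the field at
each instant obeys the electrostatic volume-conduction equation

    div( sigma grad V ) = 0,

with `sigma` a symmetric positive-definite 3x3 conductivity tensor per
element. Electrodes are ideal Dirichlet boundaries: all nine discs of an
array are held at one common potential (the device drives each array from a
single source). The two arrays of a montage are set to +-0.5 V — the values
are arbitrary, because the linear solution is afterwards rescaled so that the
prescribed peak current (default 0.9 A, i.e. 1.8 A peak-to-peak alternating)
flows through the source array.

Discretisation is first-order (P1) tetrahedral finite elements, so the field
`E = -grad V` and current density `J = sigma E` are constant per element.
Electrode current is measured as the sum, over an array's Dirichlet nodes, of
the residuals of the unconstrained equations — the discretely exact boundary
flux, which makes source/sink cancellation and the rescaling identity hold to
solver precision rather than to quadrature accuracy.

The linear system is solved with Jacobi-preconditioned conjugate gradients to
a relative residual below 1e-9 (configurable; a sparse-LU `direct` mode is
available and verified against the same residual bound). The residual
tolerance is interpreted relative to the right-hand-side norm. All FEM
arithmetic is in SI units; mesh coordinates are millimetres at every I/O
boundary and converted internally.

## Synthetic phantoms

No subject data is used; every geometry is generated.

* **Head phantom** — five strictly nested ellipsoidal compartments (skin,
  bone, CSF, grey matter, white matter). Outer semi-axes default to
  (75, 95, 85) mm, i.e. 150 mm left/right by 190 mm anterior/posterior, the
  adult head extents the montage geometry assumes; shell thicknesses default
  to skin 6, bone 7, CSF 3, GM 4 mm (representative adult values, exposed as
  config, not anatomical ground truth). The phantom has no gyri or sulci: a
  sulcus is emulated separately as a CSF-filled slot in a slab.
* **Slab and box phantoms** — layered stacks and homogeneous boxes with plate
  electrodes on the z faces, used wherever a closed-form solution exists.
* **Tumours** — two-compartment spheres, outer diameter 20 mm with a 14 mm
  necrotic core (isotropic 1.00 S/m) inside a 3 mm active shell (0.24 S/m),
  or solid shell tissue throughout. Placement must keep the whole sphere
  inside the brain compartments; on head phantoms this is enforced by a
  resolution-independent geometric rule (centre inside the grey-matter
  ellipsoid shrunk by the tumour radius) plus a label check on the mesh.
* **Fibre fields** — synthetic stand-ins for diffusion-MRI tensors: prolate
  (two equal minor eigenvalues), unit geometric-mean eigenvalue, principal
  direction following a `uniform`, `radial` or `tangential_shells` pattern,
  with the fractional anisotropy prescribed exactly. Default for anisotropic
  runs: uniform anterior/posterior orientation at FA 0.6, emulating the
  dominant deep white-matter tract direction (and hence a low left/right
  brain conductivity).

### Meshing

All phantoms are meshed on a rectilinear (tensor-product) lattice whose boxes
are split into six tetrahedra with the Kuhn pattern. Two properties were the
reason for this choice over an octree or an external mesher:

* **Conformity by construction.** The same split in every box keeps the
  triangulation watertight, including between regions of different spacing
  along an axis, so the lattice can be *graded*: fine spacing (default 2 mm)
  in a window around the tumour — enough to resolve the 3 mm shell — and
  coarse spacing (default 7 mm) elsewhere, with geometric transition. No
  hanging-node machinery is needed.
* **Mirror symmetry.** The raw Kuhn split is chiral; cells on the negative
  side of each coordinate plane therefore use the reflected pattern, which
  still conforms across the mid-planes (shared faces are perpendicular to
  the flipped axis, whose diagonals are mirror-invariant). A symmetric
  phantom then yields a mirror-symmetric mesh, and left/right electrode
  arrays land symmetrically to ~1e-9 mm rather than to one cell size.

Elements are labelled by centroid membership (ties on a compartment surface
belong to the inner compartment). Labelled volumes converge to the analytic
compartment volumes as O(h); at the default tumour-window resolution the
voxelised tumour volume is within ~2% of the exact sphere and the core
fraction within ~0.02 of (7/10)^3 = 0.343. The voxelised interface is also
the dominant FEM error source: sphere-in-box cross-checks converge to the
closed forms at O(h) (2-3% at 0.8-1.25 mm), not at the O(h^2) of a
body-fitted mesh. The meshing is fully deterministic; no randomised jitter is
applied (the seed recorded in metadata exists for forward compatibility).

## Conductivity models

Isotropic defaults (S/m): skin 0.465, bone 0.010, CSF 1.654, tumour shell
0.24, necrotic core 1.00. Grey/white matter scalar references default to
0.275 / 0.126 S/m; these are literature-typical stand-ins, deliberately
surfaced in the config, and results are sensitive to them in absolute terms
(the trend statements below are not).

Anisotropy uses *direct mapping*: the conductivity tensor of a brain element
shares the eigenvector frame of the local diffusion-like tensor, eigenvalues
rescaled so their geometric mean equals the tissue's scalar reference
("volume-normalised" mapping — it keeps the effective tissue conductivity
consistent with the isotropic table; an unnormalised global-scale variant is
behind a flag). Eigenvalues are floored at 1e-6 S/m to keep the system
definite. The *mean conductivity* (MC) surrogate replaces each tensor by the
arithmetic mean of its eigenvalues times the identity; comparing direct-mapped
against MC isolates the effect of anisotropy at fixed mean conductivity.
Exactly isotropic tensors pass through MC bit-identically, so an FA=0
pipeline reproduces the isotropic pipeline exactly.

## Dose metrics

Dose in a region of interest is the volume-weighted median of |E| and, as the
uniformity measure, the interquartile range (IQR). Quantiles use the
volume-mass convention: each element is an atom of probability proportional
to its volume; a quantile falling strictly inside an element's cumulative
span returns that element's value, and one landing exactly on a boundary
returns the midpoint of the adjacent values (with equal volumes this is the
ordinary sample median). Unweighted numpy-style sample quantiles are
available as a mode. Tumour dose is reported for the *active* tumour tissue
(the shell label; a solid tumour is shell throughout): the necrotic core is
fluid, not treatment target, and its high conductivity depresses its own
interior field, which would otherwise drag the whole-lesion median down by
~25% while the active-tissue medians of necrotic and solid lesions agree
within ~10%.

Hot spots are the elements strictly above a volume-weighted percentile of
|E|; for a perfectly uniform field any positive percentile returns the empty
set. Pairwise montage comparisons report the volume fraction where one
montage's |E| is equal to or higher than the other's (ties count in favour).

## Closed-form oracles

Three references validate the solver end to end:

* layered slab: `J = dV / sum(d_i / sigma_i)`, `E_i = J / sigma_i`;
* Maxwell sphere: `E_in = 3 sigma_e / (sigma_i + 2 sigma_e) E0`, uniform;
* coated sphere: equivalent homogeneous conductivity
  `sigma_eq = sigma_s [s_c + 2 s_s + 2v(s_c - s_s)] / [s_c + 2 s_s - v(s_c - s_s)]`
  with `v = (r_core/r_outer)^3` (Maxwell-Garnett), plus the exact uniform
  core field
  `E_core = 9 s_s s_e E0 / [(s_c + 2 s_s)(s_s + 2 s_e) + 2v(s_c - s_s)(s_s - s_e)]`.
  The exact core coefficient is used rather than nesting the
  homogeneous-sphere transmission twice; the nested product ignores the
  finite shell thickness and is ~30% off at the default tumour geometry,
  while the exact value agrees with FEM to discretisation accuracy. For the
  default tumour (1.00/0.24 S/m, 7/10 mm) `sigma_eq = 0.394` S/m.

The sphere formulas assume an infinite exterior; FEM cross-checks use a box
at least 5 sphere diameters wide (residual boundary bias ~0.5%, small
against the staircase error). The interior field is measured by a
least-squares linear fit of the potential over nodes well inside the sphere —
the interior potential is exactly linear in the continuum — because
per-element gradients adjacent to the voxelised interface carry the
staircase noise. The volume-averaged axial field over the whole composite
sphere is compared directly against the equivalent-sphere interior field;
that identity is exact in the continuum (the exterior solutions coincide on
and outside the outer radius, and the interior average is determined by the
boundary potential).

## Experiments and their scope

The experiment driver sweeps tumour positions along the montage axes
(defaults: the eight lateral translations of the clinical study layout,
x = 30 to 50 mm around a mid-hemispheric centre at (40, 0, 0); the most
lateral position violates containment on the ellipsoid phantom and is
reported as skipped). Per position it solves both montages for necrotic and
solid tumours under the selected conductivity models, re-grading the lattice
around each tumour centre. Everything is deterministic given the
configuration; sweep tables are written with fixed float formatting so
repeated runs are byte-identical, and run metadata carries a config hash.

On the default phantom the suite asserts the *directions* of the clinically
reported effects, not their magnitudes:

* necrotic tumours show a much larger field IQR than solid ones at every
  position and montage, while active-tissue medians agree within 15%;
* the necrotic core's field enhancement concentrates at the tumour
  boundaries perpendicular to the applied field (pole-alignment of the
  hot-spot set);
* a CSF-filled slot funnels current and deposits the hot spot at its
  terminus inside the white matter;
* for deep tumours the left/right montage delivers a higher median than
  anterior/posterior, and with anterior/posterior-oriented fibres the
  direct-mapped model exceeds MC in white matter for the L/R montage (the
  brain conductivity along the field direction falls below the eigenvalue
  mean), with the sign reversing for A/P.

What passing these tests does *not* show: agreement with any subject-specific
head-model numbers. The ellipsoid phantom has no gyri, ventricles or
anatomical fibre architecture, and the printed clinical-study field strengths
were computed on a real MRI-derived mesh whose tumour placements are only
partially parameterised. External tetrahedral meshes (Gmsh MSH 2.2 or legacy
VTK with a `tissue` cell array) can be loaded and run through the identical
pipeline when such data is available.

## Default problem sizes

The validation suite and `scripts/acceptance.py` use: 1 mm slabs (~24k
elements), sphere-in-box cross-checks at 0.8-1.25 mm interface resolution
(~0.35-0.85M elements, Jacobi-CG solves of 60-150k unknowns in seconds), and
head sweeps at 7 mm coarse / 2 mm tumour-window resolution (~0.2M elements,
~40k nodes per solve). These sizes were chosen so the full suite runs on one
CPU in a few minutes while keeping every oracle comparison inside its stated
tolerance band; halving the fine resolutions roughly halves the oracle
errors at ~8x the cost, without changing any trend result.

## Known limitations

* Voxelised (staircase) tissue interfaces: O(h) field accuracy near label
  boundaries; no body-fitted or interface-homogenised elements.
* Ideal equipotential electrodes: no gel/ceramic layer, no contact impedance,
  no per-disc current balancing (the device's internal behaviour is not
  public; the equipotential choice follows the fixed-potential formulation).
* Disc footprints use Euclidean, not geodesic, radius on the curved scalp.
* Electrostatic only: no permittivity/frequency dependence, no thermal
  model, no duty-cycle switching between montages.
* The GM/WM scalar conductivity references and the direct-mapping
  normalisation are modelling choices with acknowledged sensitivity; absolute
  field magnitudes should not be read as patient-applicable dose.
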