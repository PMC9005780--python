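# Methods

This note documents the models, algorithms and numerical choices behind
`afmfibril`, and what its synthetic tests do and do not establish about
real data.

## Coordinate conventions and units

All lengths are nanometres. MRC/CCP4 headers carry Ångströms and are
converted on read (1 Å = 0.1 nm); voxels must be isotropic within 1%.
Cryo-EM surfaces live in an axis-aligned frame with the fibril screw
axis on z. Imaging uses a rotated frame, (x, y, z) → (x, −z, y), so the
filament axis runs along the image y-axis and the substrate is the
plane z = 0 with the surface resting on it. Helical parameters are
(twist per subunit in degrees, rise per subunit in nm, handedness ±1,
C_n symmetry order); internally a left-handed filament has negative
twist, and metadata adapters normalise other sign conventions. The
rotation rate of the cross-section along the axis is
ω = deg2rad(twist)/rise; the apparent cross-over distance of a C_n
filament is cod = pitch/n, because an n-fold symmetric section repeats
its appearance after 2π/n of rotation.

## Tip model and contact imaging

The probe is a sphere-capped cone: apex radius R (nm), cone half-angle
α from the vertical, with the sphere–cone junction at lateral distance
d_t = R·cos α chosen so the profile is tangent-continuous. Defaults
follow a generic sharpened probe (α = 18°); both parameters are inputs,
not constants. A topograph is the grey-scale dilation of the sample's
top surface by the reflected tip: pixel height = max over surface
points p of p_z − tip_z(lateral distance), clipped at the substrate.
The implementation stamps each surface point's contact cap onto the
pixel grid (numba kernels; a per-pixel scan over all points gives
bit-identical values and serves as the test oracle). Accuracy depends
only on surface sampling density; mesh surfaces are subdivided to an
edge length of half a pixel before imaging, and generated point clouds
are built at that density directly.

Tip deconvolution is the morphological adjoint: grey-scale erosion by
the same reflected tip recovers the contact-point surface exactly
wherever the tip touched the sample. Erosion is a windowed minimum, so
uncorrelated pixel noise biases it downward by a couple of noise
standard deviations; images whose substrate noise (robust MAD estimate
on below-10%-of-peak pixels) exceeds 2% of the peak height are smoothed
with a 1-pixel Gaussian first. Noise-free simulations pass through
untouched.

## Tip radius estimation

The apex radius is fitted by least squares to the mean transverse
cross-section of a straightened fibril: the model is a cylinder of
radius a resting on the substrate imaged by a candidate tip, with
(R, a, lateral centre) free. On simulated cylinder images the recovery
is essentially exact for R between 2 and 20 nm; estimates at a search
bound raise a warning. Real fibrils are not cylinders, so on
experimental data this is a working-radius estimate, adequate because
simulation and deconvolution use the same tip model either way.

## Screw-axis fitting

A helical filament maps onto itself under the screw operation. The axis
position (xy offset, two small tilts) is found by maximising the
overlap between the voxelised iso-surface and its screw-transformed
copy. Two numerical choices matter:

- **Amplified operation.** For per-subunit twists around one degree a
  single screw step is nearly a pure z-translation and carries almost
  no information about the axis position, so the fitted operation is
  the k-fold composition with k ≈ 90°/|twist|, capped so the axial
  shift stays under 40% of the segment; overlap is evaluated on the
  common z-window only.
- **Smooth objective.** A hard voxel Jaccard is piecewise constant in
  the pose and stalls derivative-free optimisation. The optimiser
  therefore maximises a fuzzy Jaccard — Σ min / Σ max of trilinearly
  splatted occupancy grids — which is continuous in the pose; the
  reported `overlap_score` is the hard Jaccard at the optimum, and
  values below 0.5 raise an error (map and metadata inconsistent).

Optimisation runs Nelder–Mead from the best of a coarse ±2-voxel offset
grid (the centre-of-mass start can sit well off the axis when the
cross-section centroid does), with an explicit initial simplex of one
voxel / one degree. A staged mode (tilt, then offset, then joint
polish) is available for maps where joint optimisation is fragile.
Planted axis offsets up to 3 nm are recovered to well under 0.5 nm on
phantoms.

## Envelope reconstruction and symmetry identification

Reconstruction of a straightened topograph proceeds: (1) tip
deconvolution by erosion; (2) axis estimation — lateral position from
the height-weighted footprint centroid, elevation a from half the
robust (98th percentile) peak of per-row maxima, since a rigid filament
resting on a flat support has axis height equal to its maximal radius
and therefore peak height 2·r_max; (3) phase mapping — the deconvolved
pixels above the axis plane at image row y are treated as samples of
the base cross-section rotated by ±2π·y/(n·cod); (4) accumulation into
angular bins over one symmetric sector [0, 2π/n), keeping all samples
per bin. Bin width defaults to 1° but is coarsened on sparsely sampled
images so bins average at least ~8 samples; more than 10% empty bins,
or an image shorter than one cross-over, raises a coverage error. The
mean radial curve, its n-fold replication, and per-bin 2.5/97.5
percentile curves form the cross-section product. Only pixels above the
axis plane are used because the flanks are dominated by tip convolution
against the substrate.

Symmetry identification reconstructs an envelope under each candidate
C_n, re-simulates its topograph with the same tip on the same grid, and
scores agreement with the input. The axially invariant height profile
is identical for every candidate, so both scores are computed on the
twist modulation (each column's mean along the axis removed): a
normalised cross-correlation over the fibril footprint, and the
correlation of 2D Fourier magnitude spectra, averaged. The wrong
symmetry assumes the wrong rotation rate, smears the accumulated
section towards a surface of revolution and re-simulates with weak,
misplaced modulation. Candidates scoring within 1% of each other flag
the result ambiguous.

## Morphometrics

The tip-accessible cross-section of a point cloud is its 2D alpha shape
with alpha radius equal to the tip radius (Delaunay triangles with
circumradius below alpha; boundary edges walked into rings; the
largest-area ring returned, which also suppresses interior holes).
Concavities narrower than the probe are bridged over, which is exactly
the comparability argument for putting cryo-EM sections and
AFM-envelope sections through the same operation before comparison.
One geometric caveat: points lying exactly on a circle are co-circular,
so every Delaunay triangle has circumradius equal to that circle's
radius; thin near-circular curves can therefore defeat the alpha shape
when the tip radius is smaller than the curve radius. Untwisted map
clouds are thick bands and unaffected; for envelope mean curves the
pipeline falls back to the curve itself (already a contact surface) if
the alpha shape degenerates.

Rotational alignment resamples both closed curves to 360 points by arc
length, centres them on their polygon centroids, and scans rotations of
the first curve in 1° steps, minimising the symmetric
point-to-nearest-point RMSD; ties resolve to the smallest angle.
Cross-sectional area is the enclosed polygon area (shoelace, via
shapely). The cross-sectional difference area is defined here as the
symmetric-difference area of the two enclosed regions after centroid
and best-rotation alignment — the source supplementary definition was
not available, so this operationalisation is the package's own and is
stated wherever csd is reported.

## Similarity scoring

d_img = 1 − r, the Pearson correlation distance over the experimental
pixels strictly above the fibril-axis height (the flanks carry
compounded convolution effects). Before scoring, the candidate's
simulated image — helically extended to twice the data length — is
registered to the data by a global axial scale factor constrained to
[0.5, 2] (filament twist varies within a polymorph; the deposited
average need not match an individual) together with an axial shift of
up to one cross-over (the simulated helix starts at an arbitrary
phase). Scale is searched on a 0.02 grid refined to 0.002, shift at
whole pixels. The bounded interval is interpreted as a global scale,
not a per-pixel warp.

Morphometric distances are |candidate − reference| normalised by the
maximum absolute difference across the candidate panel (theoretical
norm 2 for handedness, so opposite handedness scores exactly 1); csd is
normalised by the panel's maximum csd. Scores are therefore
panel-relative: adding a candidate can change the others' distances,
but cannot un-rank a candidate that matches the reference exactly.
d_Σ is the plain six-component sum; ranking is ascending with
deterministic tie-breaks (d_img, then label). Candidates whose pipeline
fails are excluded with the reason recorded in the report, never
silently dropped.

## Synthetic phantoms

Phantoms sweep a star-shaped parametric cross-section (ellipse, or a
truncated Fourier radius r(θ) with harmonic orders restricted to
multiples of the symmetry order) helically along z, at point spacings
of half a voxel. Density maps are binary solids softened by a 1-voxel
Gaussian — sufficient because the pipeline consumes iso-surfaces, not
densities — so the 0.5 iso-surface reproduces the boundary to within a
voxel. Truth records carry symmetry, handedness, twist, rise,
cod = pitch/n, the analytic section area, and the resting axis height
r_max. Default study conditions mirror a tau-like regime: rise
0.47 nm, cross-overs 35–75 nm, section radii 2–5 nm, peak
signal-to-noise 10 (additive Gaussian pixel noise with optional
per-scan-line offsets), 1 nm pixels. The decoy panel stratifies size
and cross-over deterministically across its entries (no two decoys are
near-duplicates, per its spanning contract), alternates C1/C2 and
mixes handedness.

What phantoms do not emulate: bundling and lateral association,
substrate-induced deformation, scanner drift and feedback artefacts,
density-dependent iso-surface detail, and intra-filament twist
variation beyond a global scale. Passing the synthetic acceptance
checks therefore demonstrates the correctness and self-consistency of
the geometry pipeline under the stated conditions, not instrument-level
realism.

## Problem sizes and determinism

The shipped tests and the acceptance script use 1 nm pixels, ~30–40 nm
phantom segments extended to 2.3–2.5 cross-overs, a 20-phantom symmetry
panel, and 20 ranking repeats against a 6-map panel — sizes chosen so a
full run completes in minutes on one CPU while every stage of the
method is exercised end to end. All randomness flows from explicit
seeds; identical seeds reproduce identical images, truth records and
reports byte for byte.

## Known limitations

- Reconstruction models the envelope as axially invariant r(θ); real
  filaments modulate along the axis, and only the tip-accessible
  contact surface is recoverable in principle.
- The erosion-based deconvolution trusts the tip model; blunter or
  contaminated tips produce envelopes biased accordingly.
- Ridge tracing is a functional centre-line follower validated on
  phantoms; heavily curved, crossing or bundled fibrils need manual
  seed placement and inspection.
- Cross-over measurement assumes the dominant spectral peak is the
  cross-over periodicity; C1 fibrils with a nearly symmetric section
  can present a dominant half-period instead.
- Validation against deposited cryo-EM maps requires those maps
  locally; without them the equivalent round trips run on phantoms.
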