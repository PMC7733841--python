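# Methods

This note records the models, conventions and numerical choices behind
`axialfil`, in the order the pipeline applies them.

## Coordinates, units, symmetry

All coordinates are Cartesian nanometres; ångström values are converted at
the I/O boundary (PDB/mmCIF store Å) and distances in the geometry reports
are printed in Å, following crystallographic convention. The
orthogonalization convention places the *a*-axis along x and *b* in the
xy-plane, so for the hexagonal cell the *c*-axis is the Cartesian z — this
makes the [001] and [100] viewing geometries unambiguous. Fractional
wrapping uses the half-open interval [0, 1).

Only P1 and P3₁21 (International Tables #152) are supported. The six
P3₁21 operators are hard-coded from the International Tables general
positions rather than pulled from a symmetry library: the table is six
entries, auditable by eye, and the tests verify closure under composition
and agreement with gemmi's operator set. Expansion to P1 wraps each
symmetry copy into the cell by its molecular centroid (per chain), never
atom-by-atom, so monomers stay chemically intact for packing distances and
projections. Coinciding copies (special positions) are reported with a
warning, not merged — the silicatein molecule occupies a general position.

Periodic minimum-image distances are computed from the wrapped fractional
difference. For a non-orthogonal cell this is exact only while the
distances of interest are below half the smallest cell height; every
constraint in this pipeline (≤ 0.4 nm) is far below that bound for the
cells in play (heights ≥ 1.7 nm), and the verifier asserts the condition.

## Amorphous-silica packing

The hybrid model realizes "silica dispersed through the void" as random
sequential insertion of independent Si and O atoms at exact 1:2
stoichiometry, under hard minimum-distance constraints:

| parameter            | default      | meaning                                   |
|----------------------|--------------|-------------------------------------------|
| `protein_exclusion`  | 0.4 nm       | filler centre to nearest protein centre    |
| `si_si_min`          | 0.26 nm      | filler Si–Si minimum                       |
| `si_o_min`           | 0.15 nm      | filler Si–O minimum                        |
| `o_o_min`            | 0.22 nm      | filler O–O minimum                         |
| `target_density`     | 2.2 g/cm³    | SiO₂ mass over the whole cell volume       |

"Distance to the protein surface" is interpreted as centre-to-centre
distance to the nearest protein atom: the source imaging study states the
4 Å constraint without defining a surface, and centre-to-centre is
unambiguous and directly verifiable. The target density is the amorphous-
silica literature value; no density is stated for the original model.

The filler–filler minima deserve a comment. Real a-SiO₂ reaches
2.2 g/cm³ as a *bonded* network whose nonbonded pair minima are larger
(Si–Si ≈ 0.30, O–O ≈ 0.26 nm); imposing those as hard-sphere constraints
on *all* pairs puts random insertion past its jamming limit — measured
saturation is ≈ 1.8 g/cm³, 20 % short of target. Since projections and
multislice contrast at this resolution depend only on species and
positions, not bond topology, the defaults are set slightly smaller so
that insertion saturates comfortably above the target density (measured
≈ 99.5 % of 2.2 g/cm³ in protein-free cells). All values are
configurable.

Insertion is transactional per SiO₂ unit (Si, O, O all placed or none), so
the stoichiometry is exact; packing stops after 50 consecutive failed
units or when the target count is reached. Candidate sites are screened
with a periodic cell-list grid in fractional space; the independent check
is `verify_packing`, an all-pairs brute-force verifier that recomputes
every filler–filler and filler–protein distance. Packing is bit-for-bit
reproducible from (model, config): one `numpy` PCG64 stream seeded from
`config.seed`. The reported void fraction is a Monte-Carlo estimate
(2000 probes, seeded from `config.seed + 1`).

Hydrogens, silanol chemistry and hydration water are not modelled; they
are invisible at the simulated contrast.

## Zone-axis geometry

Multislice needs a periodic rectangular raster, but the cell is hexagonal.
The pipeline re-expresses the content on the orthohexagonal sublattice —
an a × √3·a × c box holding two hexagonal cells (the box vectors a₁,
a₁+2a₂, c are all crystal lattice vectors, so per-coordinate wrapping is
exact). Supported zone axes are then pure axis permutations: [001] views
down c with an (a, √3·a) image plane; [100] views down the Cartesian image
of a with a (√3·a, c) image plane and beam period a. This treats the
oblique γ = 120° geometry exactly rather than approximating b as
orthogonal to a.

Two sampling rules matter:

* the raster is locked to the single box *before* in-plane tiling, so the
  tiled grid is commensurate with the lattice — on an incommensurate grid
  the bilinear deposition pattern differs from tile to tile and the strong
  low-pass filter amplifies the resulting beat into spurious
  low-frequency peaks;
* atom deposition is bilinear with a Fourier-domain gridding correction
  (division by the tent-kernel transform), which makes single-atom
  potentials sampling-accurate to well below 1 %.

## Projected potential and multislice

Electron scattering factors are a five-Gaussian parameterization
f_e(s) = Σ aᵢ·exp(−bᵢs²) (s = sinθ/λ in Å⁻¹), tabulated in-repo for H, C,
N, O, S, Si; the zero-angle values reproduce the published electron
scattering factors (C 2.509 Å, O 1.983 Å, Si 5.828 Å, …). The projected
potential of a slice is synthesized in Fourier space,
Ṽ(k) = (h²/2πm₀e) Σ f_e(k)·e^(−2πik·r), giving volt·nm on the raster; its
plane integral equals the sum of single-atom integrals, which the tests
assert.

Multislice alternates pure-phase transmission t = exp(iσv_z) — σ the
relativistic interaction parameter computed from physical constants — with
the unitary Fresnel propagator exp(−iπλΔz·k²). Slices are commensurate
with the cell: the default slice thickness is the cell depth divided to
≈ 2 nm, which yields c/6 = 1.94 nm for the silicatein cell viewed down
[001] and a/3 = 1.99 nm down [100]; atoms are assigned to slices by
centre. Thickness beyond one cell period is reached by cycling the
per-cell slice sequence — exactly equivalent to an explicit beam-direction
supercell (the structure is periodic in z) at a fraction of the cost; the
explicit supercell remains available through `build_supercell`.

With pure-phase transmission total intensity is conserved to machine
precision, slice by slice. When the phase grating carries significant
power beyond ⅔ Nyquist, a bandlimiting antialias mask is applied with a
warning (`antialias="auto"`); this deliberately absorbs a little intensity,
and `antialias="off"` preserves strict unitarity.

## CTF, envelopes, bandpass

The aberration phase is χ(k) = πλk²(½C_sλ²k² − Δf), underfocus negative
(Δf = −2300 nm by default), applied as exp(−iχ). Partial coherence is
multiplicative (quasi-coherent approximation): a temporal envelope
exp(−½(πλΔ·k²)²) from the defocus spread Δ and a spatial envelope
exp(−(πα)²(C_sλ²k³ − Δf·k)²) from the convergence semi-angle α. At large
defocus χ oscillates faster than any affordable raster can sample at high
k, but there the envelopes have already extinguished the transfer; the
sampling check therefore requires χ to step < π per frequency pixel only
up to the frequency where the combined envelope exceeds 10⁻³, and
`simulate_zone_axis` tiles the field of view until that holds (≈ 28 nm at
the default optics).

The detected image is |ψ|² followed by the low-pass "bandpass": gain 1 on
[0, f_c], exp(−(f−f_c)/f_d) beyond, with f_c = 0.0035 of the raster
Nyquist frequency and f_d defaulting to f_c (no decay constant is stated
in the source description; both are configurable). The filter has DC gain
1 and preserves the image mean exactly. Because the cutoff is tied to
Nyquist, changing the pixel size changes the physical filter — comparisons
across samplings must scale the fraction accordingly.

The independent cross-check for the whole imaging chain is the weak-phase
object model, I = 1 + 2σ·F⁻¹[F[v_z]·sinχ·E], referenced to the specimen
mid-plane (the multislice exit wave sits half the depth downstream of a
thin specimen) and sharing the antialias band. For a single carbon atom in
a 0.5 nm slice the two agree to < 2 % RMS of the contrast.

No Debye–Waller damping is applied by default (a static heavy-atom model
imaged in cryo conditions); detector MTF, inelastic and thermal-diffuse
scattering are out of scope.

## Image comparison and lattice detection

Registration is exhaustive cyclic cross-correlation of unit-variance
images, so the reported NCC is exact at the best shift and invariant to
affine intensity rescaling. Lattice detection finds local maxima of the
lightly smoothed (σ = 1 px) Hann-windowed power spectrum that exceed 3×
the median of their frequency annulus, keeps the six lowest-order ones,
refines them by parabolic interpolation, and inverts the two shortest
independent reciprocal vectors to real-space lattice vectors. Because a
white-noise spectrum produces occasional 3–4× excursions, a candidate
basis is accepted only if *every* low-order peak indexes on it to within
0.12 of integer coordinates — random maxima essentially never do, and a
noise image yields "no lattice" rather than an exception. Declared
agreement policy for "simulation matches reference": detected lattice
constant within 3 % and NCC ≥ 0.5 after registration.

## Synthetic data: what it does and does not emulate

The toy crystal is a self-avoiding pseudo-residue polymer (N, CA, C, O, CB
per residue, fixed local geometry, random torsions with clash rejection)
placed at the general position of the default 2 × 2 × 4 nm hexagonal cell
that maximizes the minimum inter-copy distance of the P3₁21 orbit (found
once by grid search). Generation verifies, after expansion, that no two
symmetry copies clash, retrying a bounded number of rigid re-orientations.
It reproduces the *structural* features the pipeline depends on — correct
space-group orbit, molecule-scale voids, planted triad geometry with both
the as-built Ser-OG→ring distance (3.6 Å) and the χ₁-reachable minimum
(2.9 Å) hand-set by closed-form construction on the χ₁ circle — but not
protein folds, sequence realism, or solvent. Passing tests therefore
demonstrate that the machinery recovers known ground truth from
coordinates, not that any particular biological structure is correct.

Comparator stand-ins follow the same philosophy: a 218-residue Cα trace
whose partner is a random rigid transform plus isotropic noise of known
RMS with 19 displaced outliers (so trimming at 2 Å leaves ≈ 199 matched
positions), and sequence pairs mutated to a prescribed identity. The
deposited silicatein and cathepsin L structures can be run through the
identical code paths when files for them are available locally.

## Problem sizes and determinism

Default test and acceptance runs use the toy cell for end-to-end smoke
(≈ 5 s), a 4 × 4 × 4 nm protein-free cube for density convergence
(≈ 1400 SiO₂ units), and a silicatein-cell-sized toy (150 pseudo-residues,
≈ 7200 SiO₂ units, ≈ 600² raster, 35 slices) for the [001] lattice
recovery; the acceptance script completes in about two minutes on one
CPU. Every stochastic component draws from a seeded PCG64 generator;
identical config + seed gives byte-identical model files and JSON reports
(provenance files additionally carry wall-clock timings, which vary).

## Known limitations

* Only P1 and P3₁21; only the [001] and [100] zone axes; hexagonal or
  orthogonal cells.
* The silica phase is geometric, not chemical: no Si–O bonding network,
  no silanol termination, no density gradient at the protein interface.
* Quasi-coherent envelopes rather than explicit focal/beam-tilt
  averaging; the two differ at frequencies the default bandpass removes.
* Agreement with experimental micrographs is assessed at the level of
  lattice geometry and correlation, not pixelwise contrast — absolute
  contrast depends on instrument details (detector response, exact
  envelope forms) outside the model.
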