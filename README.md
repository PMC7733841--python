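# axialfil

Modelling and HRTEM contrast simulation of the hybrid silica/protein
crystal that forms the axial filament of demosponge spicules.

## The problem

Needle-shaped spicules of demosponges such as *Tethya aurantium* are grown
around an axial filament: a slender protein crystal of silicatein, the
enzyme that catalyzes silica polycondensation. In vivo the filament is a
*hybrid* crystal — silicatein molecules packed on a hexagonal lattice
(space group P3₁21, a = 5.96 nm, c = 11.63 nm, six molecules per cell)
with disordered amorphous silica filling the space between them. Cross-
sectional HRTEM shows the signature of this arrangement: a bright organic
honeycomb meshing dark silica inclusions.

`axialfil` rebuilds that picture as a reproducible computational pipeline,
for structural biologists and electron microscopists who want to go from an
asymmetric unit to a simulated micrograph and quantitative structure
reports:

1. **structio** — mmCIF/PDB I/O (via gemmi), occupancy filtering,
   fractional/Cartesian conversion. Internal unit: nm.
2. **symmetry** — hard-coded P3₁21 operators
   (x,y,z; −y,x−y,z+⅓; −x+y,−x,z+⅔; y,x,−z; x−y,−y,−z+⅔; −x,−x+y,−z+⅓),
   asymmetric-unit → P1 expansion keeping molecules whole, supercells.
3. **silicapack** — random sequential insertion of Si and O atoms (1:2)
   into the void under hard minimum-distance constraints, most importantly
   ≥ 4 Å from every protein atom; an independent brute-force verifier.
4. **geometry** — catalytic-triad distances (Ser-OG → His imidazole ring),
   a χ₁ rotamer scan of the serine, Kabsch Cα superposition with iterative
   trimming, and global-alignment sequence identity.
5. **emsim** — zone-axis projections and multislice image simulation:
   phase-grating transmission + Fresnel propagation, CTF
   χ(k) = πλk²(½C_sλ²k² − Δf) with partial-coherence envelopes, and the
   low-pass "bandpass" filter (unit gain to a cutoff expressed as a
   fraction of Nyquist, exponential decay beyond). Defaults: 200 kV,
   C_s = 1.0 mm, Δf = −2300 nm, defocus spread 2 nm, convergence
   0.15 mrad, thickness 70 nm, cutoff 0.0035 · Nyquist.
6. **compare** — cyclic registration with normalized cross-correlation and
   lattice detection from power-spectrum peaks.
7. **synthetic** — deterministic desk-scale fixtures: a toy P3₁21 crystal
   with an optional planted Ser/His/Asn triad, noisy reference images, and
   comparator stand-ins with planted ground truth, so the full pipeline
   builds and tests without any downloads.
8. **pipeline** — end-to-end orchestration with JSON reports and
   provenance.

## Worked example

```python
import axialfil as af

spec  = af.ToyCrystalSpec(seed=1, include_triad=True)   # 2 x 2 x 4 nm toy cell
asu   = af.make_toy_crystal(spec)                       # 118 atoms, chain A
cell  = af.expand_to_p1(asu, af.get_space_group("P3121"))
print(len(asu), "->", len(cell))                        # 118 -> 708

hybrid, report = af.pack_silica(cell, af.FillConfig(protein_exclusion=0.2, seed=5))
print(report.n_si, report.n_o, af.verify_packing(hybrid, af.FillConfig(protein_exclusion=0.2, seed=5)).n_violations)
# 250 500 0       -- 250 SiO2 units placed, verifier finds no constraint violations

ids = af.toy_triad_ids(spec)
print(af.min_ring_distance(asu, ("A", ids["SER"], "OG"), ("A", ids["HIS"])))
# 3.599999...     -- Ser26 OG to the His165 imidazole ring, in angstroms
scan = af.scan_chi1(asu, ("A", ids["SER"]), ("A", ids["HIS"]), step=1.0)
print(round(scan.best_distance, 2), scan.best_angle)
# 2.9 303.0       -- rotating chi1 by 303 deg brings OG to 2.9 A of the ring

sim = af.simulate_zone_axis(hybrid, "001", af.MicroscopeParams(), 0.05)
lat = af.detect_lattice(sim, expected_cell=hybrid.cell)
print([tuple(round(x, 3) for x in v) for v in lat.lattice_vectors_detected])
# [(1.732, -1.0), (1.732, 1.0)]   -- both of length 2.0 nm, the toy lattice constant
```

The 3.6 Å distance is the inactive-conformation Ser→His separation of the
silicatein catalytic triad; the 2.9 Å scan minimum is the hypothesized
activated rotamer. In the toy crystal both are planted ground truth that
the analysis recovers from raw coordinates.

The same chain runs from the command line:

```sh
axialfil synth crystal --seed 1 --out toy.cif
axialfil expand --in toy.cif --sg P3121 --out cell.cif
axialfil pack --in cell.cif --exclusion 0.2 --seed 2 --out hybrid.cif
axialfil triad --in toy.cif --ser A/26 --his A/165
axialfil simulate --in hybrid.cif --zone 001 --out sim001.mrc
axialfil run --config run.yaml        # full pipeline with JSON reports
```

A deposited silicatein entry (mmCIF with cell and space group) can be fed
to the identical pipeline through `input_path` / the `--in` options.

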