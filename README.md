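# axotomo

Quantitative cryo-electron tomography analysis of microtubules in
regenerating axons.

After an axon is cut, regrowth is driven by rapidly polymerizing
microtubule "shoots" fed by transported tubulin — and the tomograms of
that process hold a set of measurable signatures: the particles inside
the microtubule lumen (MIPs, microtubule inner proteins, normally spaced
~18.5 nm and depleted in freshly grown shoots), spiral tubulin oligomers
(~37.8 nm coils of single protofilaments that act as a precursor pool),
uniform plus-end-out polarity, a stretched tubulin lattice under
stabilizing drugs (dimer repeat ~83.3 Å vs 81.8 Å for dynamic
microtubules), and anterograde transport of tubulin clusters toward the
injury site. `axotomo` implements the measurement side of that story as
a reusable, tested pipeline for structural biologists and image
analysts:

* **Filament tracing** — hollow-cylinder matched filter (100 nm length,
  7/15 nm lumen/outer radii) over ~100 orientations, skeleton linking,
  sub-voxel axis refinement, cubic arc-length resampling; or injection
  of known centerlines.
* **Luminal particle picking** — Gaussian pre-filter (σ = 0.5 px),
  greyscale minima in lumen/shell masks built by exact
  distance-to-centerline, 0-dimensional topological persistence
  (union-find), an adaptive threshold calibrated so the shell retains
  0.006 minima/nm³, and flat-kernel mean shift at 5 nm bandwidth.
* **MIP occupancy** — arc-length projection, per-filament median
  spacing, sparse (> 50 nm) / dense / empty classification, population
  fractions.
* **Spiral geometry** — line-scan peak spacing, plane + circle fits for
  diameter, cross-profile FWHM width.
* **Polarity** — axial (doubled-angle) reference axis per image,
  normalized segment angles, parallel/antiparallel filament calls.
* **Lattice spacing** — rigid per-monomer fitting into density,
  median corresponding-Cα distances over conserved residues 1–37 ∪
  48–170 for chain pairs A–B, B–C and A–C (intra-dimer, interface,
  dimer repeat).
* **Transport** — net-displacement classification of tubulin-cluster
  tracks (> 5 µm anterograde / within 1 µm / retrograde / intermediate)
  and densities per 100 µm of axon.
* **Synthetic scenes** — a seeded generator for every structure above
  (textured 13-protofilament walls, luminal particles, spirals, actin
  controls, pseudo-atomic lattices, rotation and track tables) with
  ground truth, so the whole pipeline is testable without tomogram
  downloads.

Volumes are MRC2014 (mode 2), models PDB/mmCIF (via gemmi), tables
CSV/TSV with documented schemas, configuration YAML. Internal unit is
nm; lattice distances are reported in Å. See `docs/methods.md` for the
algorithms, parameter defaults and the generator's design.

## Worked example

Simulate a 500 nm microtubule with luminal particles at the control
spacing (SNR 2), trace it, pick its MIPs and classify occupancy, all
from the command line:

```
$ axotomo run --seed 3 --out demo/
{"n_traces": 1, "fraction_sparse": 0.0}

$ cat demo/calibration.csv
filament_id,threshold,achieved_density
0,0.5858650505542755,0.005999102005521003

$ cat demo/profiles.csv
filament_id,n_particles,median_spacing_nm,occupancy_class,statistic
0,22,18.266116967440126,dense,median
```

Reading: the adaptive persistence threshold (0.586 intensity units for
this tomogram's contrast) retained shell minima at 0.005999 /nm³ —
the 0.006 target to within one minimum. Along the traced filament, 22
picked particles have a median spacing of 18.3 nm, within the axial
placement jitter of the 18.5 nm ground truth, and the filament is
classified dense (≤ 50 nm), as a control-like microtubule should be.
The run directory also contains the scene (`scene.mrc`), the trace, an
occupancy summary and a manifest with config, seed and output checksums
for exact replay.

The same stages are available individually (`axotomo simulate | trace |
pick | quantify-mips | measure-spirals | polarity | lattice-fit |
transport`), and as a library:

```python
from axotomo.synthetic import SceneSpec, straight_mt, make_microtubule_scene
from axotomo.tracing import trace_filaments
from axotomo.picking import pick_luminal_particles
from axotomo.mip_stats import project_to_centerline, classify_occupancy

spec = SceneSpec(box_shape=(512, 44, 44),
                 microtubules=[straight_mt([21.6, 21.4, 5], [21.6, 21.4, 505])],
                 noise_snr=2.0, seed=3)
volume, truth = make_microtubule_scene(spec)
trace = trace_filaments(volume)[0]
particles = pick_luminal_particles(volume, trace)
profile = project_to_centerline(particles, trace)
print(len(particles), profile.median_spacing_nm, classify_occupancy(profile))
# 22 18.266116967440126 dense
```

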