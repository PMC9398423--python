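# cryoscreen

Hardware-free automation engine for cryo-EM specimen **screening** and
**data collection**, built around a synthetic specimen simulator so that
every stage of the pipeline is testable on a desk, with no microscope and
no downloads.

## Who this is for

Single-particle cryo-EM sessions start with a navigation problem: a
stitched low-magnification *atlas* of the grid is searched for usable mesh
*squares* (windows), each selected window is imaged and searched for the
*holes* of the holey support film, and a subset of holes is exposed at high
magnification. Doing this by hand dominates screening time. `cryoscreen`
implements the full decision chain — detection, classification, clustering,
selection, beam-image-shift (BIS) planning, tilt correction and the
acquisition workflow itself — as a library plus CLI, with a mock microscope
standing in for the hardware.

## What is inside

| module | role |
|---|---|
| `cryoscreen.simulate` | synthetic atlases, square views and high-mag exposures with full ground truth |
| `cryoscreen.atlas` | tile stitching, pixel ↔ stage-µm affine transforms, partial (center-out) atlases |
| `cryoscreen.squares` | classical window detector + six-class quality classifier (good / small / cracked / dry / contaminated / partial) |
| `cryoscreen.holes` | matched-filter hole detector with lattice snapping, contaminant flagging, per-hole median intensity |
| `cryoscreen.select` | deterministic 1-D k-means, diversity-maximizing square/hole selection, random in-hole offsets, rolling defocus |
| `cryoscreen.bis` | greedy maximum-coverage BIS grouping under a radius constraint, tilt geometry (z = v·sin θ, foreshortening v·cos θ) |
| `cryoscreen.session` | workflow engine, mock microscope, asynchronous FIFO processing queue, STAR/JSON export |

The core quantitative ideas:

* **Ice thickness from intensity.** The median gray level of a hole is a
  proxy for ice thickness (higher gray = more transmission = thinner ice).
  Holes are clustered 1-D on this value with a deterministic
  quantile-initialized k-means; the darkest cluster is rejected by default.
* **BIS planning as disk cover.** Given selected holes and an image-shift
  radius r, the planner greedily picks the hole whose r-disk covers the
  most ungrouped holes, stopping below a minimum group size. An exact
  integer-program oracle bounds its suboptimality on small instances
  (greedy ≤ optimal + 1 in the shipped tests).
* **Tilted acquisition.** For a specimen tilted by θ about an in-plane
  axis, a target at signed perpendicular distance v from the axis rises by
  z = v·sin θ and its in-plane coordinate foreshortens by cos θ; per-target
  defocus is referenced to the group's autofocused center hole:
  `defocus = nominal − (z_hole − z_center)`.

## Worked example

```python
import cryoscreen as cs

spec = cs.SyntheticSpec(seed=3, contaminant_density=2.0)
cfg = cs.SessionConfig(
    grids=[cs.GridDescriptor(name="g1", spec=spec)],
    mode="collection",                      # TOI = 0: acquire every included hole
    policy=cs.SelectionPolicy(n_squares=2, seed=7),
    bis_radius_um=4.0, min_group_size=4,    # typical collection settings
    seed=11,
)
record = cs.run_session(cfg)
report = cs.export_report(record)
print(report["grids"][0])
```

prints (abridged):

```
{'name': 'g1', 'n_squares_detected': 80,
 'square_class_counts': {'partial': 5, 'good': 48, 'contaminated': 8,
                         'cracked': 3, 'dry': 10, 'small': 6},
 'n_squares_selected': 2, 'n_holes_detected': 583, 'n_contaminants': 6,
 'n_holes_rejected': 51, 'n_holes_selected': 502,
 'n_bis_groups': 62, 'n_acquisitions': 502}
```

80 windows were found on the atlas and classified; the 48 good ones were
clustered by size and 2 representatives visited. 583 hole candidates were
detected in those two squares, 6 flagged as contaminants, 51 rejected as
the darkest intensity cluster (thick ice), and each of the 502 remaining
holes was acquired exactly once from 62 beam-image-shift groups of ≥ 4
holes. `cs.export_star(record)` serializes squares, holes and acquisitions
as STAR loop tables that re-parse byte-identically.

The same flow is available from the shell:

```bash
cryoscreen simulate --spec spec.yaml --out sim/ --seed 3
cryoscreen collect  --config session.yaml --out run/
```

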