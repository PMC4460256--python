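# acuhead

Localization of the 65 standardized head acupuncture points on 3D surface
models. The pipeline reconstructs skin/skull surfaces from a voxel stack
(thresholding, hole filling, marching cubes, normal averaging), fits
anatomical reference frames (midsagittal, coronal, transverse planes plus a
centred/scaled model frame), and positions three classes of points:

- **anatomical** (34): annotated manually (or supplied by the built-in
  phantom generator) and loaded from a JSON/CSV annotation file;
- **proportional** (24): solved from angle ratios at the TE20 midpoint and
  coordinate constraints between known points, averaged over a thin surface
  selection band and snapped to the mesh;
- **morphological** (7): solved by minimizing a distance functional along a
  surface curve between two control points against a bundled
  standard-source model.

A synthetic two-shell head phantom (skin intensity ≥ 10, skull ≥ 110) with
analytically known landmark positions makes the whole pipeline testable
without any imaging data.

## CLI

```sh
# synthetic head: BMP slice stack + ground-truth annotation skeleton
acuhead phantom --out work/phantom --seed 1

# skin surface (threshold 10; use 110 for the skull)
acuhead reconstruct --input work/phantom/stack --threshold 10 \
    --output work/skin.ply --frame-out work/frame.json

# anatomical planes from the annotation
acuhead frames --landmarks work/phantom/annotation.json --frame work/frame.json

# all 65 standard points (CSV: name,side,category,x,y,z,status in model frame)
acuhead position --mesh work/skin.ply \
    --landmarks work/phantom/annotation.json --frame work/frame.json \
    --out work/points.csv --report work/report.json \
    --dump-curves work/curves.json
```

Every command accepts `--config <yaml>` (see `acuhead.cli.RunConfig` for the
keys: thresholds, the model-frame scale alpha, selection-band tolerances,
phantom geometry, seed) and embeds the config hash in its outputs.

## Layout

- `src/acuhead/phantom.py` — voxel volume types, phantom generator, binarize /
  fill_holes / extract_boundary, BMP stack I/O
- `src/acuhead/surface.py` — marching cubes, normal smoothing, PLY/OBJ I/O
- `src/acuhead/frames.py` — model frame and anatomical planes
- `src/acuhead/catalog.py` + `data/catalog.json` — point registry, proportional
  rules, morphological rules with standard-source coordinates
- `src/acuhead/proportional.py` — angle machinery and band solvers
- `src/acuhead/morphological.py` — curve extraction and distance minimization
- `src/acuhead/cli.py` — commands `phantom`, `reconstruct`, `frames`, `position`
- `scripts/build_catalog.py` — regenerates the bundled catalog JSON
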