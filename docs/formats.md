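# File formats

All interchange formats are plain text except raw volume payloads.

## Dwell plan dialect

One record per line; `#` starts a comment.  BNF:

```
plan      ::= { record NEWLINE }
record    ::= meta | dwell | empty
meta      ::= key SP number
key       ::= "sk_u" | "prescription_gy" | "fractions"
dwell     ::= number SP number SP number SP number   ; x_mm y_mm z_mm time_s
```

Missing metadata defaults to S_k = 40000 U, 34 Gy in 10 fractions.
`save_dwell_plan` writes full-precision floats (`repr`), so a
write→read round trip is bit-exact.  Example:

```
sk_u 40000.0
prescription_gy 34.0
fractions 10
-12.0 0.0 30.0 1.73
-7.0 0.0 30.0 2.10
```

A best-effort DICOM RT Plan importer (`brachykerma.dicom.load_dicom_plan`,
requires pydicom) extracts only dwell positions/times and the reference
air-kerma rate.

## Volumes (HU, masks, dose)

Raw little-endian binary (C order) next to a `.hdr` sidecar of
`key value...` lines:

```
shape 80 80 70
voxel_size_mm 2.0 2.0 2.0
origin_mm -79.0 -79.0 -54.0
dtype float64
order C
```

`origin_mm` is the center of voxel (0, 0, 0) in patient coordinates.
Masks use dtype `uint8` with 0/1 voxels.  A `.raw.gz` suffix gzips the
payload.  Dose volumes add `scheme`, `n_histories`, `n_batches`, `seed`
keys.

## Structure sets

Per-slice closed polygons; multiple polygons on one slice combine under
the even-odd rule (holes supported):

```
structure PTV
slice 12.0
-10.0,-10.0
10.0,-10.0
10.0,10.0
-10.0,10.0
```

Rasterization uses the voxel-center rule (center on a contour counts as
inside).  `write_structures` serializes a binary mask as one thin
rectangle per contiguous voxel row-run, which rasterizes back to the
identical mask.

## Materials and calibration

`materials.txt`: blocks of `material <name> density <g/cm3>` followed by
`<element> <mass fraction>` lines.  `hu_calibration.txt`: one
`hu density material` anchor per line, strictly increasing HU.  Both are
user-replaceable via `load_materials(path)` /
`load_calibration_curve(path)`.

## Cross-section tables

`data/elements/Z??_<symbol>.txt`: commented header plus columns
`energy_keV mu_pe mu_incoh mu_coh mu_total mu_en` (cm²/g), regenerable
with `scripts/build_xs_tables.py`.
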