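# fairomics

Radiomics feature extraction from DICOM-RT with ontology-annotated,
queryable output.

Radiomics converts delineated tumor volumes in medical images (CT, PET,
MR) into quantitative features — intensity statistics, morphology, and
gray-level texture — for phenotyping and outcome modelling. Two practical
obstacles keep such features from being comparable across centers: feature
*names* do not identify what was computed (an "entropy" may be the
intensity-histogram entropy or the co-occurrence joint entropy, under any
of several binning schemes), and flat value tables drop the preprocessing
provenance (resampling, re-segmentation, discretization, software version)
that changes the numbers. `fairomics` addresses both ends of the pipeline:

* **Input**: native DICOM image series plus the RTSTRUCT contour file, as
  produced in radiotherapy practice. Contours are rasterized to binary
  voxel masks on the image grid (voxel-center, even-odd fill).
* **Features**: a fixed default panel of **105 features** in seven
  families — first-order (18), shape (14), GLCM (22), GLRLM (16),
  GLSZM (16), GLDM (14), NGTDM (5) — with formulas aligned to the Image
  Biomarker Standardisation Initiative (IBSI) conventions.
* **Output**: a semantic RDF graph in which every feature value is typed
  by an ontology identifier (IBSI codes where established, deterministic
  local IRIs otherwise) and linked to its VOI, patient, software and
  extraction-settings nodes — so two runs of "entropy" remain
  distinguishable — plus a flat CSV for convenience. Graphs serialize to
  Turtle/N-Triples for any triple store, and a built-in basic-graph-pattern
  engine answers conjunctive queries directly.

A synthetic phantom generator writes valid DICOM series and RTSTRUCT
files with analytically known geometry, so the whole pipeline is testable
without clinical data.

## Core definitions

For masked voxel intensities discretized to levels `1..Ng` by fixed bin
width `w` anchored at the region minimum, `level(x) = ⌊(x − min)/w⌋ + 1`:

* Intensity-histogram entropy: `H = −Σᵢ pᵢ log₂ pᵢ` (IBSI TLU2)
* GLCM joint entropy: `−Σᵢⱼ p(i,j) log₂ p(i,j)` (IBSI TU9B), with one
  symmetric distance-1 co-occurrence matrix per each of the 13 unique 3-D
  directions, features averaged over directions
* Sphericity: `(36π V²)^⅓ / A`, with `V`, `A` from the triangulated 0.5
  iso-surface of the mask
* Mask agreement (Dice): `D = 2|A∩B| / (|A| + |B|)`
* Concordance correlation:
  `CCC = 2 cov(x,y) / (var x + var y + (mean x − mean y)²)`

## Worked example

```bash
# write 3 synthetic phantom cases (DICOM series + RTSTRUCT each)
fairomics phantom --out cases --cases 3 --seed 7

# run the full pipeline: match, rasterize, extract, publish
fairomics extract cases --out out --format both
# -> cases: 3 attempted, 3 succeeded, 0 failed; outputs: out/features.ttl, out/features.csv
```

`out/features.csv` holds one row per (patient, VOI, feature):

```
patient_id,voi,family,name,ibsi_code,value
PHANTOM-000,roi_000,firstorder,Energy,,672500.0
PHANTOM-000,roi_000,firstorder,Total Energy,,1345000.0
...
```

The RDF graph carries the same values with full provenance. Ask which
patients are in the graph:

```bash
fairomics query out/features.ttl '?p fo:patientID ?pid . ?v fo:ofPatient ?p'
```

prints one binding row per patient/VOI pair (`PHANTOM-000` … `PHANTOM-002`).
A five-variable provenance query — label, value, software version,
programming language, patient ID — attributes every value to the software
run that produced it, which is how merged multi-center graphs are audited:

```bash
fairomics ccc groupA.csv groupB.csv   # concordance between two value columns
```

From Python:

```python
from fairomics import (read_series, read_structset, rasterize, extract_all)
vol = read_series("cases/case_000/series")
roi = read_structset("cases/case_000/rtstruct.dcm").rois[0]
mask = rasterize(roi, vol)          # binary mask on the image grid
feats = extract_all(vol, mask)      # 105 FeatureResult records
```

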