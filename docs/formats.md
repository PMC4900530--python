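# File formats

All text outputs use `.` as the decimal separator regardless of locale.
Every CSV written by the CLI starts with a provenance comment line
`# aperturekit <version> config=<hash>`.

## PLY shell mesh (read/write)

ASCII PLY, elements `vertex` (properties x, y, z; millimetres) then
`face` (quad index lists). Vertices are row-major by aperture ring:
vertex `i*Y + j` is vertex j of ring i, ring 0 earliest. Export writes
`comment aperturekit ring_size=<Y>`; import honours it, a
`ring_size_hint` argument, or infers Y from connectivity. Triangle
pairs forming grid quads are accepted on input. Binary PLY is rejected.

## Profile CSV (`<shell>_profile.csv`)

One row per aperture: `aperture_index`, `arc_length_mm`, `curvature`,
`torsion` (mm⁻¹), `aperture_size` (perimeter, mm), `shape_score_1` …
`shape_score_k` (retained pooled-PCA scores), and `volume_mm3`
(constant per shell) when volume was computed.

## EFA CSV (`<shell>_efa.csv`)

Second comment line `# normalised=true`. Columns: `ring_index`,
`perimeter_mm`, then the normalised coefficient block
`a1x,b1x,a1y,b1y,a1z,b1z,…` — 6·n_harmonics columns (30 at the default
five harmonics).

## Shape PCA report (`shape_pca_report.csv`)

`component`, `explained_variance_fraction`, `retained` (True for the
components kept under the >90% cumulative-variance rule).

## PDC outputs (`pdc_<run>.{csv,nwk,png}`)

One set per run (`all`, `torsion`, `curvature`, `size`, `shape`, or
`subset` with `--vars`). The CSV is the square dissimilarity matrix
with a leading `shell_id` column and shell ids as remaining headers.
The `.nwk` file is the single-linkage dendrogram in Newick form with
branch lengths derived from merge heights; the `.png` is its figure.

## Theoretical-morphology exports

`export_theoretical_datasets` writes three CSVs per shell:

- `<shell>_generating_curve.csv` — `ring_index`, `vertex_index`,
  `x_mm`, `y_mm`, `z_mm` (X·Y rows): aperture outlines for
  generating-curve models;
- `<shell>_ontogeny_axes.csv` — `marker_index`, `ring_index`, `x_mm`,
  `y_mm`, `z_mm`: one or several vertex trajectories for helicospiral
  models;
- `<shell>_growth_vectors.csv` — `ring_index`, `vertex_index`,
  `dx_mm`, `dy_mm`, `dz_mm` ((X−1)·Y rows): ring-to-ring displacement
  vectors for growth-vector models.

## Config file (YAML)

Keys (all optional): `q_fraction` (default 0.10), `q` (explicit
half-window, overrides the fraction), `n_harmonics` (5), `resample_k`
(50), `m` (5), `t` (1), `alpha` (0.5), `linkage` (`single`),
`marker_index` (0), `variables`, `seed`. Unknown keys are rejected.

## Acceptance JSON (`scripts/acceptance.py --out`)

`{"t3": {"value": <mean curvature, mm^-1>, "n": 50},
  "t4": {"value": <mean torsion, mm^-1>, "n": 200}}` — the estimator's
output on a straight axis and a planar spiral, both of which have true
value 0.
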