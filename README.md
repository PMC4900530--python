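# aperturekit

Quantification, visualisation and comparison of gastropod shell form
through **aperture ontogeny profiles**.

Gastropod shells grow accretionarily: new material is deposited only at
the aperture, so the sequence of aperture outlines through ontogeny is a
complete, landmark-free record of shell form that can be compared across
any taxa — regularly coiled, distorted or openly coiled alike.
`aperturekit` takes *retopologised* shell meshes — an ordered stack of X
aperture rings with Y vertices each, as produced by tracing growth lines
on a micro-CT model — and computes, per aperture:

- **growth-trajectory geometry** — the ontogeny axis is the 3D space
  curve traced by a marker vertex of the aperture; its local curvature
  κ = |r′×r″|/|r′|³ (mm⁻¹, κ ≥ 0; tighter coiling → larger κ) and
  torsion τ = det(r′,r″,r‴)/|r′×r″|² (mm⁻¹; τ = 0 planispiral, τ < 0
  left-handed coiling) are estimated by weighted least-squares local
  polynomial fits, together with cumulative axis length;
- **aperture size** — the outline perimeter (mm);
- **aperture shape** — 3D elliptic Fourier coefficients (5 harmonics ×
  6 coefficients), normalised for size, orientation and starting
  vertex, summarised by pooled PCA into aperture shape scores.

Profiles are standardised to 50 equal fractions of each shell's own
ontogeny-axis length and compared with **permutation distribution
clustering** (PDC): each 50-point series is reduced to the frequency
distribution of ordinal patterns of its length-5 embedded windows,
distributions are compared with the symmetric α-divergence
(α = 0.5: D = 4(1 − Σᵢ√(pᵢqᵢ))), summed over variables, and shells are
grouped by single-linkage clustering. Because ordinal patterns ignore
scale, PDC compares *trends*, not magnitudes — shells differing only in
size are identical to it.

A synthetic helicospiral generator with exact analytic curvature,
torsion and arc length makes every stage testable without any scan
data, and doubles as a source of idealised study sets (affine-scaled
variants, two-shell composites).

## Worked example

```python
import aperturekit as ak

meshes = ak.reference_shell_set(seed=0)          # 8 synthetic shells
prof = ak.build_profile(meshes[0])               # shell_A_regular, 90 rings
print(prof.volume_mm3, prof.arc_length[-1])      # 305.03 mm^3, 78.63 mm

built = [ak.build_profile(m, with_volume=False) for m in meshes]
scored, pca = ak.attach_shape_scores(built)      # pooled shape PCA
print(pca.explained_variance_fractions[0])       # 0.999 -> 1 PC retained

resampled = [ak.resample_profile(p, 50) for p in scored]
dm = ak.pdc_matrix(resampled)                    # all four variables
tree = ak.single_linkage(dm)
print(tree.to_newick())
```

On the bundled eight-shell reference set this prints a dissimilarity
matrix in which the half-size copy of shell A sits at distance 0.00
from its original (pure scaling is invisible to trend comparison) and
the two-shell composite is the most dissimilar shell (minimum distance
1.22 to anything else); the dendrogram joins `shell_A_regular` with
`shell_A_half` first and splits `shell_D_composite` off last.

The same pipeline is available from the shell:

```sh
aperturekit synth   --out shells/ --seed 0          # write 8 PLY meshes
aperturekit profile shells/*.ply --out results/     # CSVs + 4-panel plots
aperturekit compare shells/*.ply --out results/     # 5 PDC runs + dendrograms
aperturekit volume  shells/*.ply                    # capped-mesh volumes
```

`compare` performs the five standard runs: all four variables combined,
then torsion, curvature, aperture size and shape score separately.

## Layout

- `aperturekit.mesh_io` — ASCII PLY ring-grid reader/writer, validation,
  capped-mesh shell volume
- `aperturekit.trajectory` — ontogeny axis, curvature/torsion estimator,
  convergence scan
- `aperturekit.aperture` — perimeter, 3D elliptic Fourier analysis and
  normalisation, outline reconstruction
- `aperturekit.profiles` — profile assembly, pooled shape PCA,
  50-point standardisation, four-panel plots
- `aperturekit.pdc` — permutation distributions, symmetric α-divergence,
  dissimilarity matrices, single-linkage dendrograms
- `aperturekit.synth` — helicospiral generator with analytic truth,
  affine transforms, composites, theoretical-morphology exports
- `aperturekit.cli` — the `aperturekit` command

See `docs/methods.md` for the model and estimator details and
`docs/formats.md` for every file format written.
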