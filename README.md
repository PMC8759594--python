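# chromodisp

Quantification of chromatin dispersion from fluorescence microscopy, for
cell biologists studying how chromatin organization changes during stable
cell-cycle exit (e.g. under constitutively active RB, CDK4/6 inhibition, or
irradiation-induced senescence).

FISH probes against large chromosomal regions produce foci whose appearance
ranges from compact bright spots to scattered, punctate clouds. The package
turns that visual phenotype into numbers and carries the downstream analyses:

* **Skeleton dot length** — the dispersion metric for a FISH focus: the
  image is binarized, dilated three times with a 3×3 square element, and
  thinned to a one-pixel skeleton; the focus's score is the total calibrated
  skeleton length (orthogonal steps 1 px, diagonal steps √2 px, converted to
  µm), plus a branch count per focus.
* **Category classification** — probe-class-specific cutoffs partition the
  length axis: heterochromatin foci are *compact* (< 0.75 µm), *diffused*
  (0.75–1.25 µm) or *dispersed* (> 1.25 µm); euchromatin foci are
  *compact/diffused* (< 1.5 µm), *dispersed* (1.5–2.5 µm) or *scattered*
  (> 2.5 µm). Conditions are summarized as mean ± SEM and category
  percentages, and alleles are ranked as high/medium/low dispersers against
  reference conditions.
* **Spatial context** — shortest edge-to-edge distance from each FISH signal
  to the nearest nucleolus.
* **Puncta and PLA quantification** — LC3B (autophagosome) puncta per cell
  with sub-micrometre outlier removal; DAPI-based nucleus segmentation with
  size/circularity/border filters; proximity-ligation-assay foci per nucleus;
  EdU/DAPI cell-cycle classification (S vs G1/G2).
* **3C-qPCR quantification** — per-sample mean-centering of crossing points
  and fold-change `2^(Cp − Cp_origin)` over the origin self-ligation product,
  with replicate aggregation and condition comparison.
* **Statistics** — two-tailed Mann–Whitney U (exact for small tie-free
  samples), Kruskal–Wallis with Dunn's post hoc, per-pair Welch t tests with
  Holm–Šídák correction, and the standard star coding (ns > 0.05 … **** ≤ 0.0001).
* **Correlation screen** — Pearson correlation of every transcript in an
  expression matrix against a per-allele dispersion ranking, with hits at
  r > 0.6 / r < −0.6.
* **Synthetic data** — a generator producing images and tables with recorded
  ground truth for every input above, so the whole pipeline is testable
  without microscope data.

## Worked example

Measure two synthetic conditions — near-compact foci versus strongly
dispersed foci (sub-puncta spread 0.1 µm vs 1.2 µm) — and compare them:

```python
import numpy as np
from chromodisp import (SyntheticSceneParams, generate_fish_scene, ProjectedImage,
                        skeleton_dot_length_pipeline, total_skeleton_length,
                        CategoryCutoffs, summarize_condition, mann_whitney_u)

cutoffs = CategoryCutoffs.heterochromatin()
conditions = {}
for name, spread in [("control", 0.1), ("active_rb", 1.2)]:
    lengths = []
    for s in range(30):
        scene = generate_fish_scene(SyntheticSceneParams(
            n_nuclei=1, foci_per_nucleus=1, focus_spread_um=spread, seed=100 + s))
        foci = skeleton_dot_length_pipeline(ProjectedImage(scene.image, scene.pixel_size_um))
        lengths.append(total_skeleton_length(foci))
    conditions[name] = summarize_condition(lengths, cutoffs, condition=name)

for s in conditions.values():
    pcts = ", ".join(f"{k} {v:.0f}%" for k, v in s.category_percentages.items())
    print(f"{s.condition}: n={s.n_foci} mean={s.mean_length_um:.2f} um (SEM {s.sem_length_um:.2f}); {pcts}")

res = mann_whitney_u(conditions["control"].lengths_um, conditions["active_rb"].lengths_um)
print(f"Mann-Whitney U={res.statistic:.0f}, p={res.p_value:.2e} {res.stars}")
```

prints

```
control: n=30 mean=0.13 um (SEM 0.02); compact 100%, diffused 0%, dispersed 0%
active_rb: n=30 mean=15.52 um (SEM 0.59); compact 0%, diffused 0%, dispersed 100%
Mann-Whitney U=0, p=2.61e-11 ****
```

Compact foci collapse to near-point skeletons (mean 0.13 µm, all below the
0.75 µm compact cutoff), while dispersed foci yield long branched skeletons;
the Mann–Whitney test confirms the separation. Note that the synthetic
dispersion knob was deliberately driven far beyond the compact regime here,
so the dispersed condition's mean exceeds what real probes typically show.

A command-line interface exposes the same stages
(`chromodisp simulate|measure|classify|nucleolar-distance|puncta|pla|stats|threec|correlate|run`);
see `chromodisp --help`.

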