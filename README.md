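# hippostereo

Design-based stereology of the hippocampal dentate gyrus (DG) and CA3 in a
four-arm diabetic-rat study design, implemented as a fully testable pipeline
on synthetic tissue phantoms with known ground truth.

In experimental models of type-1 diabetes, hyperglycemia drives both
volumetric atrophy and apoptotic neuronal loss in the hippocampus. Because
DG and CA3 form one directly connected circuit, the two subfields can be
treated as a single anatomical module and summarised by a **response
index** — the ratio of a DG quantity to the matching CA3 quantity — rather
than by analysing each region in isolation. This package implements the
full measurement chain behind that analysis:

- **Cavalieri volume estimation** on systematically sampled serial coronal
  sections: `V = T · (a/p) · Σp`, where `T` is the effective slab thickness
  per sampled section, `a/p` the area of one test point of a uniformly
  random square lattice, and `Σp` the total number of points hitting the
  region profiles.
- **Physical-dissector density estimation** of apoptotic (TUNEL-labelled)
  neurons with an unbiased counting frame:
  `N_v = ΣQ / (a · h · ΣP)`, with `a` the frame area, `h` the distance
  between the paired sections, `ΣQ` the dissector count and `ΣP` the number
  of frames applied.
- **Response indices** `RI_V = V_DG / V_CA3` and `RI_ND = ND_DG / ND_CA3`
  per treatment arm (Con, Ins, VitC, Dia), least-squares index curves across
  the arm coding Con=1 … Dia=4, and the **critical point** where the volume
  curve and the apoptosis curve intersect.
- **Group statistics**: one-way ANOVA with Tukey's HSD post hoc test, and
  Pearson correlations between region quantities and the covariates blood
  glucose and plasma Cu.

Because no per-animal data are published for this design, the package ships
a phantom generator: per-animal region solids with closed-form volumes,
apoptotic markers seeded as a homogeneous Poisson process at known
intensity, and covariates drawn jointly through a Gaussian copula. Every
estimator is therefore validated against exact ground truth.

## Worked example

```python
import hippostereo as hs
from hippostereo import pipeline

# reproduce the published DG/CA3 response-index table from printed group means
rep = pipeline.reproduce_table1()
print(rep.table.means.round(2))
#           Con   Ins  VitC   Dia
# volume   0.63  0.65   0.8  0.80
# density  1.54  1.74   1.4  0.53
print(rep.flags[0])
# volume/Ins: ratio-of-means 0.65 differs from published 0.64 (per-animal ratio data unpublished)

# one full simulated study: N = 10/group, 10 um volume sections, 5 um dissector sections
report = pipeline.run_study(pipeline.RunConfig(seed=11))
print(report.group_summary.loc["Dia", ["V_DG_mean", "ND_DG_mean"]])
# V_DG_mean        1.585700
# ND_DG_mean    9312.635589
print(report.critical)
# CriticalPoint(x_star=3.836094023276416, y_star=0.8042802018497179)
```

The two density index cells 1.54 (control) and 0.53 (diabetic) show the
apoptotic burden flipping from DG-dominant to CA3-dominant under untreated
diabetes, while the volume index rises from 0.63 to 0.80; the fitted curves
for the two indices meet near an index value of 0.8 — the point at which
volumetric change and neuronal loss become coincident.

The same pipeline is scriptable from the shell:

```
hippostereo reproduce-table1
hippostereo report --seed 11 --outdir out/
hippostereo generate --seed 1 --outdir out/   # phantoms + ground truth
```

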