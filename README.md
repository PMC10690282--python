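# paralogscope

Quantifies how yeast paralogs respond to the loss of their sister gene,
from single-plane fluorescence micrographs to compensation/dependency
calls. It is aimed at high-content screening groups who image GFP-tagged
proteins in wild-type and paralog-deletion backgrounds and want a tested,
deterministic pipeline for the downstream quantification.

## What it computes

**Segmentation.** Ground-truth cell stencils are eroded with the minimal
cross (4-neighborhood) so touching cells separate, then turned into a soft
training target

&nbsp;&nbsp;&nbsp;&nbsp;T = w·B + (1 − w)·min(EDT(B), d_clip)/d_clip,&nbsp;&nbsp;w = 0.8, d_clip = 20 px,

where B is the eroded binary mask and EDT the Euclidean distance to the
nearest background pixel; border pixels score 0.81 (≈ 0.8), rising to 1.0
at depth ≥ 20 px. Probability maps (from any backend satisfying the
image → [0, 1] map contract; deterministic oracle and Otsu-based reference
backends are included) are post-processed with a seeded watershed: seed
components at probability ≥ 0.8, boundaries at ≥ 0.5, objects outside
(256, 8192) px removed.

**Redistribution.** Each cell becomes a 64 × 64 frame and a 128-dimensional
feature vector (a deterministic, documented reference extractor standing in
for a learned embedding). For gene *g*, cells pooled across replicates give
one feature centroid per background, and

&nbsp;&nbsp;&nbsp;&nbsp;redistribution score = ‖ c̄(g, wt) − c̄(g, Δparalog) ‖₂ .

A classification threshold is chosen by ROC analysis against true cases and
random-pair negative controls, minimizing the false-positive rate; genes
strictly above the threshold are called redistributed.

**Abundance.** The abundance score of a condition is the mean raw pixel
intensity over all frames; the relative change is
lfc = log₂(s_Δ + 1) − log₂(s_wt + 1), tested with a two-sided
Mann–Whitney U on per-cell means and corrected with Benjamini–Hochberg.
Calls: increased if lfc ≥ 0.2 and q < 0.05, decreased if lfc ≤ −0.2 and
q < 0.05. Compensation = abundance increase or relocalization into the
paralog's compartment; dependency = decrease or relocalization elsewhere.

**Network context.** Shared-interactor counts (binned at the cohort
median), shortest-path bins (1 vs 1+), genetic-interaction stringency
classes (lenient p < 0.05; intermediate |ε| > 0.08; stringent ε > 0.16 or
ε < −0.12; synthetic lethal ε < −0.35), colocalization Jaccard
(100·|A∩B|/|A∪B| ≥ 50), and Fisher-exact enrichment of private
interactors in the sister's compartment.

**Compartment quantification.** Two-channel per-cell ER vs cytoplasm
abundances: edge cells removed within the median major-axis length,
backgrounds QC'ed at mean ± sd per replicate, ER pixels at the ≥ 0.975
within-cell reporter quantile, cytoplasm < 0.973, cells with < 100 ER
pixels discarded, abundances as background-normalized medians.

Because screen-scale imaging data of this kind are not publicly
deposited, the package ships a first-class synthetic-data generator:
fields of non-overlapping elliptical cells with parametric localization
classes, programmed abundance fold changes and relocalization fractions,
replicate/field structure and ground-truth label maps, all reproducible
from one seed.

## Worked example

```python
import paralogscope as ps

pairs = [
    ps.ParalogPair(
        "CUE4", "CUE1", "cytoplasm", "ER",
        effect_a=ps.EffectSpec(gene="CUE4", background="deletion",
                               abundance_lfc=0.5, reloc_fraction=0.6,
                               reloc_target="ER"),
    ),
    ps.synthetic.null_pair("RND1", "RND2", "nucleus", "vacuole"),
]
cfg = ps.GeneratorConfig(n_cells=40, shape=(360, 360))
scenes, meta = ps.generate_strain_panel(pairs, replicates=3,
                                        fields_per_replicate=4, seed=7,
                                        config=cfg)
result = ps.run_screen(scenes, meta, ps.RunConfig(),
                       positive_genes=["CUE4"],
                       negative_genes=["RND1", "RND2"])
print(result.redistribution[["gene", "paralog", "score", "threshold",
                             "redistributed"]].round(3).to_string(index=False))
print(result.abundance[["gene", "lfc", "p", "q", "direction"]]
      .round(4).to_string(index=False))
```

prints

```
gene paralog  score  threshold  redistributed
CUE4    CUE1  0.852      0.539           True
CUE1    CUE4  0.147      0.539          False
RND1    RND2  0.226      0.539          False
RND2    RND1  0.221      0.539          False

gene     lfc      p      q direction
CUE1  0.0016 0.9422 0.9422      none
CUE4  0.4954 0.0000 0.0000 increased
RND1 -0.0169 0.5806 0.8899      none
RND2  0.0203 0.6675 0.8899      none
```

CUE4 carries a programmed deletion-background effect (log2 fold change
+0.5, 60 % of its signal relocated to the ER): its redistribution score
(0.852) stands far above the null genes (≤ 0.226), the ROC threshold
selected from the controls separates it cleanly, and its estimated fold
change (0.4954) recovers the programmed +0.5. The genes without
programmed effects are classified as unchanged.

A `paralogscope` console command exposes the same stages
(`simulate`, `segment`, `features`, `screen`, `quantify-compartments`,
`report`); see `paralogscope --help`.

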