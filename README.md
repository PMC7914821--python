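# pollenfoci

Quantitative image analysis of heat-stress-induced protein clustering and
protein–protein colocalization in confocal z-stacks of mature pollen, plus
the accompanying RT-qPCR relative-expression statistics.

Under heat stress, RNA-binding proteins such as the ALBA family and the
poly(A)-binding protein PABP3 redistribute from a diffuse cytoplasmic signal
into bright foci interpreted as mRNP granules. `pollenfoci` implements the
two statistics used to quantify that behaviour, the group comparison applied
to them, and a ground-truthed simulator of pollen-like fluorescence stacks
so every stage can be validated without access to microscope data.

## The statistics

**Clustering — coefficient of variation.** For one optical section with
in-mask, background-subtracted pixel intensities *I₁…I_N*,

&nbsp;&nbsp;&nbsp;&nbsp;CV = σ(I) / ⟨I⟩

with the population (N-denominator) standard deviation. A homogeneous
cytoplasm gives a small CV; the same total signal concentrated in foci gives
a large one. Only nucleus-free cytoplasmic sections enter the analysis (a
section is excluded when the dilated DAPI nucleus region exceeds a fraction
τ = 0.01 of the pollen region); the stack-level CV is the unweighted mean
over included sections.

**Colocalization — above-threshold Pearson correlation.** For two channels
with per-channel thresholds t₁, t₂ (Otsu on pooled in-mask intensities, once
per stack), the per-section statistic is the Pearson correlation R of the
paired intensities over in-mask pixels above threshold in at least one
channel (union rule; intersection available). The stack aggregate is the
mean over sections with a defined R.

**Group comparison.** Per-stack aggregates are compared across conditions
with the Kruskal–Wallis one-way ANOVA on ranks followed by Dunn's pairwise
post hoc (tie-corrected, Bonferroni-adjusted), labelled `***` (p < 0.001),
`*` (p < 0.05) or `NS`.

**qPCR.** Relative expression by ΔΔCt with two reference genes (*GAPC1*,
*EIF1a4*): ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2), calibrated against
matched-timepoint untreated controls, efficiency 2. Treated vs control is
tested with Welch's t when both groups pass Shapiro–Wilk, otherwise the
Wilcoxon rank-sum test.

**Simulator.** An ellipsoidal grain whose cytoplasm carries diffuse signal
plus Poisson-count Gaussian foci (optionally enriched near the male germ
unit), one vegetative and two sperm nuclei in the DAPI channel, a second
fluorophore channel sharing a controllable fraction ρ of foci, Gaussian PSF,
Poisson shot noise, Gaussian read noise and a background offset. The
clustered-signal fraction *f* redistributes a fixed signal total, so CV
responds to clustering and not to brightness. Every draw is recorded as
ground truth.

## Worked example

Run the heat-stress clustering design end to end (simulation → masking →
CV → statistics). Conditions carry clustered-signal fractions 0.1 (control),
0.5 (1 h post-stress), 0.3 (24 h post-stress):

```python
from pollenfoci import ExperimentConfig, run_clustering_experiment

cfg = ExperimentConfig(
    kind="clustering", out_dir="demo_run", seed=11,
    conditions={"control": 0.1, "HS37_1h": 0.5, "HS37_24h": 0.3},
    n_replicates=5, min_group_size=5,
)
bundle = run_clustering_experiment(cfg)
```

which prints (via the `compare`-style summary of `bundle["comparison"]`):

```
control: mean CV = 0.840  (n=5)
HS37_1h: mean CV = 3.050  (n=5)
HS37_24h: mean CV = 1.820  (n=5)
omnibus Kruskal-Wallis: p = 0.00193
  control vs HS37_1h: p = 0.00122 [*]
  control vs HS37_24h: p = 0.231 [NS]
  HS37_1h vs HS37_24h: p = 0.231 [NS]
```

The CV roughly triples one hour after stress and relaxes by 24 h, mirroring
the programmed clustering fractions; with five replicates per group only the
largest contrast survives Bonferroni adjustment (the study designs use 25).
Outputs land in `demo_run/`: `cv_results.csv` (one row per stack,
per-section CVs semicolon-joined), `comparison.csv`, a box plot, and
`run_log.json` with the config hash and master seed.

The same flow is available from a shell:

```bash
pollenfoci simulate --seed 1 --n 3 --out sims      # stacks + ground-truth sidecars
pollenfoci mask sims/sim_000.tif                   # → "5/10 sections included"
pollenfoci cv sims/*.tif --out cv.csv              # → "sim_000: CV = 0.8607 over 5 sections"
pollenfoci coloc sims/*.tif --out coloc.csv
pollenfoci compare cv.csv
pollenfoci run config.yaml                         # end-to-end from YAML
```

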