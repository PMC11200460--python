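# presympto

Presymptomatic disease detection from multi-region brain activity, as a
tested, reusable analysis pipeline. The scientific setting: a cohort of
mice — a disease-model line and wild-type controls — with local field
potentials (LFP) recorded from seven brain regions (thalamus THL,
periaqueductal gray PAG, prelimbic cortex PL, amygdala AMY, somatosensory
cortex S1, anterior cingulate ACC, nucleus accumbens NAc) plus neck EMG and
a respiration channel (BR). Some animals are missing entire region channels
(electrode failures), and the question is which regions carry enough
disease signal to classify animals *before* symptoms appear.

The chain, end to end:

1. **Band-power features.** Each 60-s Hamming-tapered window of each region
   signal yields six features: the FFT amplitude and spectral ratio of the
   delta (1–4 Hz), theta (6–10 Hz) and gamma (40–100 Hz) bands. One hour of
   recording gives 60 windows; three sessions give 180 samples per mouse.
2. **Completion of missing regions.** The feature matrix
   X ∈ ℝ^{N×(D·M)} (D = 6 features, M = 9 sources) has whole missing
   (mouse, region) blocks. They are imputed by a bias-regularized
   factorization x̂_ij = μ + b_mouse,i + b_brain,j + p_iᵀq_j fitted by SGD
   on observed entries (α = 2·10⁻⁵, λ = 10⁻⁵ at recording scale); observed
   entries are never altered.
3. **Supervised multiview CCA.** The M region views plus a one-hot class
   view Z_l (D_l = 2) are projected jointly by solving the generalized
   eigenproblem C̄V = ε(C̲ + ηI)V (η = 0.01). Regions are ranked by their
   cross-loading CL_m — the mean |Pearson correlation| between a region's
   features and the leading projected label variate.
4. **Leave-mouse-out classification.** The projections of the R top-ranked
   regions feed LDA, KNN (k = 9), linear SVM and an extreme learning
   machine; each fold holds out every window of one mouse, and R sweeps
   1..9 to find how many regions help.

The recorded data cannot be released, so the package ships a synthetic
cohort generator (`presympto.cohort`) that reproduces the study's
*structure* — 15 diseased / 10 wild mice, nine sources, three sessions,
~11.6% of mouse×region cells missing, class-dependent band-power gains in
configurable informative regions, realistic per-mouse / per-session /
per-window power heterogeneity — with known ground truth, so every claim
the pipeline makes is testable as a recovery property.

## Worked example

The numbered drivers under `analysis/` run the full chain on the default
demo cohort (full study design at a reduced recording scale, 400 Hz ×
600-s sessions) and write small tables to `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/04_rank_regions.py
python analysis/05_classify_sweep.py
```

`01` reports the missingness structure:

```
cohort: 25 mice, 26 of 225 (mouse, region) cells missing (11.6%)
```

`04` prints the cross-loading table; with the demo cohort's graded effects
(in the seven brain regions, none in NAc/EMG) the informative regions
occupy the top seven ranks:

```
 rank region       CL
    1    AMY 0.729509
    2    THL 0.695320
    3     PL 0.685018
    4    PAG 0.649409
    5    ACC 0.622787
    6     S1 0.617189
    7     BR 0.346736
    8    EMG 0.151125
    9    NAc 0.092626
```

meaning: these regions' features correlate strongly with the disease axis
of the shared latent space, while the two non-neural channels carry
essentially none of it (the order among the informative regions reflects
their configured gains plus per-mouse heterogeneity). `05` prints the mean
leave-mouse-out accuracy for each classifier as R grows; the demo effects
are strong enough that every classifier saturates within the first two
regions, and only KNN is visibly dragged down again once the noise
channels enter:

```
classifier R=1 R=2 R=3 R=4 R=5 R=6 R=7 R=8 R=9
       lda 0.996 1.000 1.000 1.000 1.000 1.000 1.000 1.000 1.000  (best 1.000 at R=2)
       knn 0.999 1.000 1.000 1.000 1.000 1.000 0.991 0.984 0.968  (best 1.000 at R=2)
       svm 0.997 1.000 1.000 1.000 1.000 1.000 1.000 1.000 1.000  (best 1.000 at R=2)
       elm 0.999 1.000 1.000 1.000 1.000 1.000 1.000 1.000 1.000  (best 1.000 at R=2)
```

`06` replicates the two recovery experiments at reduced replicate counts:
cohorts with two strongly informative regions rank them top-2, and under
the harder peak-recovery conditions (seven equally informative regions,
two drifting noise channels, strict per-fold refits) the accuracy-vs-R
curves of the four classifiers peak at R = 7.

Equivalent shell interface: `presympto simulate|extract|complete|analyze|
classify|run --help` (exit codes 2/3/4 distinguish config, data and
numerical errors). A single `presympto run --config cfg.yaml --out DIR`
executes the whole chain and writes a reproducibility manifest (config
hash, derived stage seeds, output digests).

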