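# qustex

Quantitative-ultrasound (QUS) spectral parametric imaging, texture radiomics
and benign/malignant lesion classification from beamformed RF data — with a
point-scatterer speckle simulator providing ground-truth-known inputs for
every stage.

The pipeline:

1. **RF studies** (`qustex.data_model`) — float32 frame files + JSON sidecars,
   physical-coordinate geometry, polygon ROI rasterization and geometric
   5-mm margin construction.
2. **Spectral estimation** (`qustex.spectral`) — Hanning-gated line-averaged
   power spectra; reference-phantom normalization into attenuation-corrected
   backscatter coefficients; spectral-difference local attenuation estimation
   (ACE); linear fits (MBF / SS / SI) and spherical-Gaussian form-factor fits
   (ASD / AAC).
3. **Parametric imaging** (`qustex.parametric`) — 2 mm × 2 mm sliding-window
   kernel (94 % overlap at full scale) producing five co-registered maps;
   core/margin region summaries and the CMR / CMCR image-quality features.
4. **Texture features** (`qustex.texture`) — 16-level quantization and
   mask-aware GLCM (4 features, 5 distances × 4 angles), GRLM (14 features,
   4 directions) and GLSZM (14 features, direction-independent) matrices;
   cohort feature tables of 25/60 (GLCM) or 75/160 (GRLM/GLSZM) columns.
5. **Screening** (`qustex.screening`) — Shapiro-Wilk-gated t-test /
   Mann-Whitney per feature with */**/*** significance tiers.
6. **Classification** (`qustex.classify`, `qustex.ann`) — forward SFS (max 10
   features, training F1), LDA / KNN / SVM-RBF / Levenberg-Marquardt ANN,
   LOOCV and repeated stratified 70/30 hold-out (ANN: 70/15/15), reporting
   sensitivity, specificity, accuracy, AUC, PPV and NPV.
7. **Simulation** (`qustex.simulate`) — seeded point-scatterer RF frames with
   controllable scatterer size/concentration/attenuation per region, a
   0.786 dB/cm/MHz reference phantom whose analytic backscatter curve closes
   the normalization exactly, Gaussian-random-field heterogeneity, and
   two-class synthetic cohorts with stored ground truth.

## CLI

```sh
qustex simulate --spec cohort.yaml --out cohort/ --seed 1
qustex extract-features --cohort cohort/ --method glszm --region both \
    --out features.csv
qustex screen --table features.csv --out screening.csv
qustex classify --table features.csv --classifier svm --validation loocv \
    --seed 1 --out report.json
```

`cohort.yaml` may override class-conditional lesion distributions
(`benign:`/`malignant:` mappings with `asd_um_mean`, `aac_db_mean`,
`correlation_length_mm`, `field_sd_aac_db`, …), cohort sizes and geometry.

## File formats

All artifacts are plain text or raw little-endian float32: study directories
(`frame_XXX.bin`, `study.json`, `rois.json`), phantom metadata, feature
tables as CSV, reports as JSON.
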