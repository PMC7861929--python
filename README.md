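# ecgstack

Single-lead heartbeat classification toolkit: wavelet preprocessing,
Pan-Tompkins R-peak detection, fixed-window beat segmentation, fiducial-point
feature extraction (10 features), distance-weighted KNN (DWKNN), a ten-fold
stacked DWKNN ensemble, and the four-class (N/S/V/F) evaluation calculus.
Everything runs end-to-end on synthetic annotated ECG — no external data
downloads are required by the tests or the CLI defaults.

## Layout

| Module | Purpose |
| --- | --- |
| `ecgstack.dataio` | WFDB record/annotation I/O (formats 212/16 + binary annotation streams + CSV), AAMI symbol mapping, stratified train/test split |
| `ecgstack.preprocess` | Continuous wavelet transform, DWT denoising (db6, baseline + high-frequency bands), 235-sample beat segmentation (R at offset 90) |
| `ecgstack.qrs` | Pan-Tompkins detector, greedy detection matching (150 ms rule), Fdr/Se/+p/Acc detection metrics |
| `ecgstack.delineate` | P/QRS/T onset/peak/offset location by a slope-threshold rule |
| `ecgstack.features` | Feature extraction, group stitching (Morph ‖ Inter ‖ Amp), median imputation, min-max normalization |
| `ecgstack.dwknn` | Distance-weighted KNN: weight 1/(distance + const), weighted majority vote |
| `ecgstack.stacking` | Four base DWKNNs × ten stratified folds, one-hot out-of-fold meta-features, DWKNN meta-classifier, fold-averaged test predictions |
| `ecgstack.evaluate` | 4×4 confusion matrix, per-class Se/Sp/+p/Acc, overall (micro) accuracy, reports |
| `ecgstack.synth` | Gaussian-bump synthetic ECG with full fiducial ground truth; labeled Gaussian-blob feature tables |
| `ecgstack.pipeline` / `ecgstack.cli` | End-to-end orchestration, feature-combination and K sweeps, `ecgstack` CLI |
| `ecgstack.benchmarks` | Published benchmark confusion matrices used as fixed inputs by golden tests and the acceptance report |

## CLI

```bash
ecgstack simulate --out /tmp/demo --n-beats 200 --seed 0        # synthetic record
ecgstack detect /tmp/demo/syn0 --annotations /tmp/demo/syn0_annotations.csv
ecgstack features /tmp/demo/syn0 --annotations /tmp/demo/syn0_annotations.csv \
    --out /tmp/demo/features.csv
ecgstack train --classifier stacking --n-beats 400 --seed 0 --out /tmp/demo/run
ecgstack evaluate --confusion /tmp/demo/run/confusion.csv
ecgstack sweep --mode combos --n-beats 200 --seed 0             # 7 feature combos
ecgstack sweep --mode k --ks 1,2,3,4,5,6,7,8,9,10 --n-beats 200 --seed 0
```

All commands default to the synthetic generator; pass `--record` (a WFDB
base path) plus `--annotations` to run on real records instead. Reproducing
the published per-record numbers requires the external arrhythmia database
and is an optional workflow, never a test dependency. Note the AAMI symbol
grouping used here (EC57 convention) may make per-class counts differ
slightly from published tallies.

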