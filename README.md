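# neuroxent

Cross-entropy EEG channel-coupling analysis: band-limited Cross-ApEn /
Cross-SampEn coupling matrices, nonparametric connection screening with FDR
control, (metric, m, r) parameter-grid selection, FCBF feature selection, and
QDA / polynomial-SVM / decision-tree classification — plus a synthetic
three-group (HC / MCI / AD) cohort generator so the entire pipeline can be
exercised and validated without clinical data.

## What it does

For each subject, multichannel recordings are decomposed into six canonical
EEG bands (delta 1–4, theta 4–8, alpha 8–13, beta1 13–19, beta2 19–30,
gamma 30–70 Hz) with zero-phase FIR filters and cut into epochs.  Every
unordered channel pair in every band gets a cross-entropy coupling value
(higher = less shared temporal structure), averaged over epochs into one
subject-level coupling matrix per band.

The analysis then:

1. screens every (band, channel-pair) connection with a Kruskal–Wallis test
   across the three groups and Benjamini–Hochberg FDR correction,
2. repeats the screening for every cell of a (metric, m, r) grid on the
   training set and selects the cell with the most significant connections,
3. treats each connection as a feature and selects a compact subset per
   binary contrast (HC vs MCI, HC vs AD) with the fast correlation-based
   filter (FCBF),
4. trains QDA, polynomial-kernel SVM, and decision-tree models on the
   selected features and reports Acc / Se / Sp / PPV / NPV on the held-out
   test subjects.

The train/test boundary is structural: epoch sets and feature tables carry a
`split` tag, and grid search / feature selection refuse test-tagged data.

## Quick start

Library:

```python
from neuroxent import cross_sampen, PipelineConfig, run_pipeline
from neuroxent.simulate import SyntheticCohortSpec

value = cross_sampen(u, v, m=1, r=0.2)   # u, v: equal-length 1-D arrays

config = PipelineConfig(
    seed=42,
    cohort=SyntheticCohortSpec(seed=42, n_train=(8, 8, 8), n_test=(4, 4, 4),
                               fs=100.0, n_channels=5,
                               epoch_duration_s=2.0, epochs_per_subject=10),
    band_names=("delta", "theta", "alpha", "beta1", "beta2"),
    epoch_duration_s=2.0,
)
result = run_pipeline(config, outdir="results/run42")
print(result.grid.selected, result.reports["HC_vs_AD"]["svm_poly"])
```

Command line:

```bash
neuroxent simulate --seed 42 --outdir cohort/ --n-train 4 --n-test 2 --epochs 4
neuroxent decompose cohort/train/train-HC-00.tsv --outdir bands/
neuroxent coupling cohort/train/train-HC-00.tsv --metric cross_sampen --outdir mats/
neuroxent run-all --config config.yaml --outdir results/
```

## Validation

```bash
pytest                                                  # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion (oracle
equivalence of the optimized counting path, analytic entropy cases,
statistical correctness, parameter recovery and end-to-end group ordering on
simulated cohorts, confusion-metric arithmetic); `scripts/acceptance.py`
recomputes the same quantities and writes them as JSON.  The
simulation-based checks use reduced problem sizes chosen for single-CPU
runtime; see `docs/methods.md` for all numerical conventions and design
choices.

## Layout

- `src/neuroxent/entropy.py` — Cross-ApEn / Cross-SampEn definitions
- `src/neuroxent/_kernels.py` — numba counting kernels (one pass serves the
  whole parameter grid)
- `src/neuroxent/oracle.py` — brute-force reference implementation
- `src/neuroxent/preprocessing.py` — FIR band filters, notch, epoching
- `src/neuroxent/coupling.py` — per-subject coupling matrices
- `src/neuroxent/stats.py` — Kruskal–Wallis / Mann–Whitney / BH-FDR screening
  and grid selection
- `src/neuroxent/features.py` — FCBF with symmetrical uncertainty
- `src/neuroxent/classify.py` — QDA / SVM / decision tree + reports
- `src/neuroxent/simulate.py` — synthetic coupled-channel cohort generator
- `src/neuroxent/pipeline.py`, `cli.py` — end-to-end driver and CLI
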