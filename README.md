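# fcnet

Graph-theoretic analysis of resting-state functional brain networks, as a
tested, reusable pipeline:

ROI time series → Pearson correlation matrix → sparsity-thresholded binary
networks (0.10–0.34, step 0.01 by default) → global metrics (Cp, Lp, γ, λ, σ,
E_glob, E_loc) and nodal metrics (degree, efficiency, betweenness) with
degree-preserving rewired null normalization → trapezoidal AUC over the
sparsity grid → covariate-adjusted permutation group comparison with
Benjamini–Hochberg FDR → clinical partial correlations (age/sex adjusted),
plus demographics tests (exact test for sex, two-sample t-tests).

Because no subject-level imaging data is distributable, the package includes a
first-class synthetic cohort generator: a Watts–Strogatz ground-truth network,
band-limited (0.01–0.08 Hz at TR = 2 s) Gaussian BOLD-like signals whose
covariance is `expm(coupling · A)` (positive definite for any coupling, with a
closed analytic form used as a test oracle), group effects injected as extra
coupling on edges incident to designated nodes, and clinical variables with a
calibrated correlation to the injected coupling.

## CLI

All stages are subcommands of `fcnet`; plain-text TSV/CSV in and out.

```bash
fcnet simulate  --out-dir run/sim --seed 7            # synthetic cohort
fcnet prep      --in-dir run/sim/timeseries --out-dir run/prep \
                --discard 10 --low-hz 0.01 --high-hz 0.08
fcnet build     --in-dir run/prep --out-dir run/mats  # correlation matrices
fcnet metrics   --in-dir run/mats --out run/metrics.tsv \
                --sparsity-min 0.10 --sparsity-max 0.34 --sparsity-step 0.01
fcnet auc       --metrics run/metrics.tsv --out run/auc.tsv
fcnet compare   --auc run/auc.tsv --cohort run/sim/cohort.csv \
                --out run/comparison.tsv --n-perm 10000 --fdr-q 0.05
fcnet correlate --auc run/auc.tsv --cohort run/sim/cohort.csv \
                --out run/correlations.tsv --clinical bmi
```

or everything at once, driven by a YAML config (see `fcnet.config.RunConfig`
for keys; every run writes its resolved config next to its outputs):

```bash
fcnet run --config config.yaml --out-dir run/
```

Runs are fully deterministic given the config seed.

## Layout

- `src/fcnet/synthetic.py` — ground-truth graphs, BOLD simulation, cohort tables
- `src/fcnet/prep.py` — discard / detrend / band-pass / nuisance regression
- `src/fcnet/connectome.py` — correlation matrices, binarization, sparsity-grid selection
- `src/fcnet/metrics.py` — global/nodal graph metrics, Maslov–Sneppen nulls (numba kernel in `_rewire.py`)
- `src/fcnet/auc.py` — trapezoidal AUC over the sparsity grid
- `src/fcnet/inference.py` — residualization, permutation tests, BH-FDR, partial correlations, demographics
- `src/fcnet/pipeline.py`, `config.py`, `cli.py`, `io.py` — orchestration, config, CLI, plain-text I/O
- `tests/` — unit + property tests with independent brute-force oracles
  (`tests/oracles.py`), and `tests/test_acceptance.py` (one test per criterion)
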