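# pvcircuit

Analysis pipeline and network model for functionally specific connectivity
between parvalbumin-expressing (PV+) interneurons and pyramidal cells:

- **synthgen** — seeded synthetic datasets: ground-truth tuned cells,
  trial-resolved dF/F tensors over a 6 SF x 6 TF x 8 direction grating
  ensemble, and directed PV/pyramidal synaptic measurements whose log
  strength tracks response similarity with a configurable coupling.
- **preprocess** — fluorescence conditioning (running-percentile detrend,
  two-Gaussian F0 estimate, dF/F) and 3-D affine control-point registration.
- **tuning** — responsiveness (stimulus-explained variance), selectivity
  (response skewness), and the constrained 9-parameter direction x SF/TF
  tuning model with FWHM-based tuned/untuned classification.
- **similarity** — pairwise metrics: response similarity (cosine of
  trial-average responses), total similarity (per-segment single-trial
  cosine), signal/total correlations, per-feature preference differences,
  marginal tuning correlations, and the overlapping-ROI pair filter.
- **synaptic** — PSP amplitude and paired-pulse measurement,
  multiexponential kinetics fits, reciprocal E/I strength correlation,
  within-PV-cell geometric-mean normalization with the within-cell
  permutation test, logistic connection-probability models, and partial
  correlations controlling for distance.
- **netsim** — structured recurrent E/I spiking network: von-Mises-shaped
  connection kernels over two tuning dimensions, specificity-weighted block
  weight matrix, LIF neurons with alpha-conductance synapses (self-contained
  exponential-Euler integrator), stimulus battery, stability analysis,
  cohort perturbation, and conductance co-tuning analyses.
- **workbench** — pipeline orchestration with a reproducibility manifest.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (printed-value
arithmetic, parameter recovery, statistical calibration, pipeline recovery,
and scaled-down network-regime replications); the simulation-based tests
take a few minutes.

## CLI

```bash
pvcircuit synth --config cfg.yaml --seed 1 --out data/
pvcircuit tuning --in data/ --out out/ --seed 1
pvcircuit similarity --in data/ --out out/
pvcircuit simulate --config net.yaml --protocol battery|stability|perturb --seed 1
pvcircuit run --config cfg.yaml          # full pipeline + report
```

Network configs use the parameter-table keys (`N`, `wE`, `wI`, `fI`, `dIE`,
`sE`, `sI`, `kEE`, `kEI`, `kIE`, `kII`); `pvcircuit.netsim.reference_config(n)`
returns weight presets re-calibrated for scaled-down network sizes.

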