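# stimvarx

Multivariate autoregressive modeling with an exogenous stimulus input
(MVARX) for multichannel electrophysiology recorded during direct
electrical stimulation. Each channel's present value is modeled as a
linear combination of all channels' pasts, a filtered stimulus trigger
(one FIR filter per channel), and Gaussian innovation noise:

    y[n] = sum_{i=1..p} A_i y[n-i] + sum_{i=0..ell} b_i x[n-i] + w[n]

The package covers the full analysis chain on synthetic or recorded
sessions:

- **synthdata** — ground-truth MVARX systems with an exact spectral-radius
  target, forward simulation of stimulation sessions (with the evoked /
  spontaneous decomposition stored as truth), injectable outlier epochs,
  and high-rate raw sessions with conduction artifacts.
- **preprocessing** — Tukey-windowed median-filter artifact removal,
  linear-phase anti-alias lowpass + decimation (zero net delay), and
  stimulus-aligned epoch segmentation.
- **outliers** — leave-one-out Mahalanobis rejection of deviant epochs and
  merging of surviving epochs into maximal contiguous segments.
- **core** — the model container, joint OLS estimation of coupling,
  input filters and innovation covariance, evoked simulation, one-step
  prediction, and JSON model serialization.
- **order_selection** — cross-validated AR-order choice combining
  one-step prediction error with average-evoked-response error,
  median-normalized.
- **diagnostics** — kernel-weighted portmanteau residual whiteness test
  (Bartlett lag window, width `L = ceil(3 Nc^0.3)`), two-phase averaged
  CV responses, and the fit metrics NMSD / RRMS / NMRD / NMSE, plus the
  unconnected (per-channel univariate) comparison model.
- **integration** — stationary/lagged moments via the companion-form
  Lyapunov equation, past-given-present conditional covariances,
  effective information over bipartitions, the minimum-information
  bipartition, integrated-information profiles over lags, and a
  rank-sum comparison between conditions.
- **io / pipeline / cli** — HDF5 and CSV session containers, a flat
  text pipeline configuration, and an end-to-end runner.

## CLI

All stages are exposed as subcommands of `stimvarx`:

```sh
stimvarx synth -d 10 -p 5 --seed 1 --out session.h5 --model-out truth.json
stimvarx preprocess --input raw.h5 --out clean.h5
stimvarx reject --input session.h5 --out outliers.tsv
stimvarx cv --input session.h5 --out cv.tsv --p-max 30
stimvarx fit --input session.h5 --p 12 --model-out model.json
stimvarx whiteness --input session.h5 --model model.json
stimvarx metrics --input session.h5 --model model.json --out metrics.tsv
stimvarx phi --model model.json --out phi.tsv --tau-ms-max 300
stimvarx run --config pipeline.cfg
```

`stimvarx run` chains preprocess → reject → cv → fit → whiteness →
metrics → phi from a key-value config file (see
`stimvarx.pipeline.PipelineConfig` for the keys) and writes every stage's
output under the configured directory.

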