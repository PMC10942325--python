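# tachy

Chronometric analysis of urgent pro/antisaccade choices: from per-trial
eye-movement records (or raw gaze traces) to tachometric curves, sigmoid-derived
rise points, exogenous-capture and endogenous-bias metrics, and
resampling-based inference — plus a trial simulator with known ground truth so
every stage supports parameter-recovery testing.

## What it computes

- **Trial tables** (`tachy.io`): canonical CSV schema
  (`participant,experiment,trial_type,cue_side,gap,rt,choice_side,correct,excluded,exclusion_reason`),
  validation with per-line error reports, declarative filtering
  (urgent `gap >= 0` vs easy `gap < 0`, rpt windows, participants), and a YAML
  analysis config. The raw processing time is always recomputed as
  `rpt = rt - gap`.
- **Saccade detection** (`tachy.saccades`): 40 deg/s speed-threshold detection
  (central differences on lightly smoothed 1 kHz position), trial scoring from
  the first post-go saccade, near-vertical (> 60 deg) and blink/abort
  exclusions.
- **Tachometric curves** (`tachy.tachometric`): fraction correct vs rpt in
  sliding bins (default width 31 ms aggregate / 41 ms single participant,
  1 ms step) with exact Clopper-Pearson binomial CIs; pooling at the trial
  level.
- **Sigmoid fits** (`tachy.sigmoid`): four-parameter logistic
  `s(x) = B + (A - B) / (1 + exp(-(x - C)/D))` fitted by mean-absolute-error
  minimization (multi-start Nelder-Mead), rise point `C`, rpt-at-criterion
  (default theta = 0.7), modulation/fit-error gate (ratio > 2.5), and
  percentile bootstrap CIs from trial resampling.
- **Attention metrics** (`tachy.metrics`): exogenous-capture fractions in the
  83-124 ms window (and data-driven window derivation from mirrored pro/anti
  curves), guessing bias toward the cue at rpt <= 75 ms, motor bias
  (`B_pro - B_anti`), antisaccade processing-time cost at the shared halfway
  criterion, four-range (G/C/T/A) performance summaries, and the easy-trial
  performance screen for reliable performers.
- **Inference** (`tachy.stats`): paired permutation and randomization tests
  (exhaustive when cheap, Monte Carlo with +1 correction otherwise), exact
  binomial tests, Pearson correlation with permutation p-values, OLS.
- **Simulator** (`tachy.synth`): trials drawn from a composable accuracy model
  (biased guessing baseline + Gaussian capture bump + sigmoidal endogenous
  rise, defaults `C_pro = 165`, `C_anti = 195` ms) under four luminance
  conditions, plus minimum-jerk gaze traces with recorded ground truth.

## CLI

```sh
tachy simulate --experiment 3 --n 20000 --seed 7 --capture-amp 0.25 --out trials.csv
tachy curve trials.csv --trial-type pro --bin-width 31 --out curve_pro.csv
tachy fit trials.csv --trial-type anti --bootstrap 1000 --out fit_anti.json
tachy metrics trials.csv --out metrics.csv
tachy report trials.csv --out report.json          # headline quantities
tachy run-all --experiment 3 --n 20000 --seed 7 --out-dir run/
tachy stats --binomial 9 11 --alternative greater  # exact binomial test
```

Exit codes: 0 success, 2 usage error, 3 data error, 4 fit failure.
`run-all` writes a manifest with config snapshot, seeds and output hashes;
reruns with the same seed are byte-identical.

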