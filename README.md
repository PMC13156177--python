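# dyadsync

Dyadic biobehavioral synchrony analysis: second-by-second respiratory sinus
arrhythmia (RSA) estimation from interbeat intervals, dyadic RSA and
positive-affect synchrony metrics, and moderation models of child symptom
scores probed with simple slopes and Johnson–Neyman regions of significance —
plus a synthetic dyad generator so the whole pipeline is testable end to end
without any external data.

## Package layout

| module | what it does |
| --- | --- |
| `dyadsync.types` | Domain types: `IBISeries`, `CodedStream`, `RSASeries`, `DiffSeries`, `DyadRecord` |
| `dyadsync.io` | Delimited-text readers/writers and dyad assembly from a manifest |
| `dyadsync.rsa` | 4 Hz cubic-spline resampling, 32 s multitaper short-time band power, ±3 SD cleaning, first differencing |
| `dyadsync.behavior` | Shared-positive-affect and unsupportive-ERSB indicators, time-unit Cohen's kappa |
| `dyadsync.synchrony` | Lag-0 Pearson correlation of differenced RSA, Fisher z, dyad-level outlier screening |
| `dyadsync.moderation` | Interaction model fits (OLS/logistic), simple slopes, regions of significance |
| `dyadsync.simulate` | Coupled-envelope IBI generator, coupled Markov affect streams, outcome model with planted interactions |
| `dyadsync.pipeline` / `dyadsync.cli` | simulate / process / analyze orchestration from one YAML config |

## Method summary

**RSA estimation.** Interbeat intervals (ms) are cubic-spline interpolated at
4 Hz against beat time. For every second with a full surrounding 32 s window,
the windowed segment is demeaned, linearly detrended, tapered (DPSS
multitaper, K=3, NW=2 by default; single Hann available), tapered
periodograms are averaged, and the one-sided PSD is integrated over the
respiration band (adults 0.12–0.40 Hz; the child band must be configured
explicitly — there is no safe default). Output is ln(band power in ms²)
assigned to the window's central second; seconds without a full valid window
are invalid. Values ≥ 3 SD from the person's task mean are removed
(two-sided by default), and the series is first-differenced.

**Synchrony.** Dyadic RSA synchrony is the lag-0 Pearson correlation of the
two members' differenced RSA over jointly valid seconds (min. overlap 30),
Fisher transformed (z = atanh r). Dyads with |z − mean| > 3.92 SD are
screened out before analysis. Positive affect synchrony is whether the dyad
shows any second of simultaneous positive/warm affect; dyads with more than
50% uncodable affect in either member are missing on affect synchrony.

**Moderation.** Outcome ~ focal + moderator + focal×moderator + covariates,
fit by ML on complete cases with continuous predictors grand-mean-centered.
Simple slopes `b_focal + m·b_int` are probed at both levels of binary
moderators and at −1 SD / mean / +1 SD of continuous ones; Johnson–Neyman
boundaries solve |slope(m)/se(m)| = critical value and are clipped to ±2 SD.

## CLI

```bash
dyadsync all --config config.yaml            # simulate + process + analyze
dyadsync simulate --config config.yaml --seed 7
dyadsync process  --config config.yaml --outdir runs/x
dyadsync analyze  --config config.yaml
```

Minimal config:

```yaml
seed: 1
outdir: runs/demo
task_s: 300
child_band: [0.12, 0.40]   # required for child RSA; no default
simulate:
  n_dyads: 80
  rsa_change_coupling: 0.3
```

Outputs under `outdir/`: `data/` (per-dyad CSVs + manifest + outcome table),
`processed/rsa_series.csv` (dyad_id, person, second, rsa, valid),
`processed/synchrony.csv` (dyad_id, r, z, n_pairs, excluded_flag, reason),
`processed/dyads.csv` (analysis table), `analysis/models.json`,
`analysis/probes.csv`, `report.json` (config echo, seed, per-stage counts
with exclusion reasons that reconcile), `ground_truth.json`.

## File formats

* **IBI table** — columns `beat_time_s` and/or `ibi_ms`; if only intervals
  are given, beat times are reconstructed by cumulative sum from 0.
  Non-positive intervals are dropped with a logged line number; non-monotone
  beat times are an error.
* **Coded stream** — tall table `second,code`; 0-based seconds, gaps filled
  with `uncodable`. Affect alphabet: `positive_warm`, `dysphoric`,
  `angry_aggressive`, `neutral`, `uncodable`. ERSB alphabet: `supportive`,
  `dismissing`, `mild_rejection`, `firm_rejection`, `none`, `uncodable`.
* **Manifest** — `dyad_id` plus relative paths `parent_ibi, child_ibi,
  parent_affect, child_affect, parent_ersb` (empty cell = missing component).
* **Outcome table** — `dyad_id`, covariates (`child_medication`,
  `pubertal_status`, `pandemic_cohort`, each 0/1/missing), T-scores
  (`parent_dep_T`, `child_dep_T`, optional `child_internalizing_T`,
  `child_total_T`).

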