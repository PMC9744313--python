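# crpseq

Forgetful hierarchical Chinese restaurant process (CRP) sequence modelling of
serial reaction time behavior, built around the Alternating Serial Reaction
Time (ASRT) task. The package provides, end to end on synthetic data:

- **`crpseq.asrt`** — ASRT trial-stream generation and labelling: cyclic
  second-order patterns (6 rotation-unique permutations), alternating
  deterministic/random states, `d`/`rH`/`rL` trigram labels, the
  adjacent-element interference swap (changes 3 of 4 second-order pairs), and
  the old/new alternation schedule.
- **`crpseq.restaurant`** — a single distance-dependent ("forgetful") Chinese
  restaurant: exponentially decayed seat weights, predictive mixtures, and
  stochastic recognition seating with a back-off signal. `decay = 0` recovers
  the classic count-based CRP exactly.
- **`crpseq.hcrp`** — the hierarchy: per-context restaurants on levels
  0..N, recursive back-off prediction, recognition updates, online parsing
  with multiple seating samples, per-level prediction decompositions, and
  KL-based context-gain diagnostics.
- **`crpseq.response`** — the linear reaction-time model: surprise of the
  pressed key plus low-level effects (spatial distance, response repetition,
  error, post-error), Gaussian likelihood on log RTs, OLS subfit.
- **`crpseq.fitting`** — ABC-style random-search fitting of the
  hyperparameters with per-iteration OLS for the response coefficients,
  sequential (bin-by-bin) priors, seating carry-over between bins, and
  held-out middle-segment evaluation.
- **`crpseq.agents`** — synthetic participants generated from known
  parameters (including expectation-driven errors), plus a parameter-recovery
  harness.
- **`crpseq.analysis`** — trial-type contrasts, the standardized (>2)-order
  effect, pattern/recency/other error typing, and a generic per-participant
  correlation utility.

## CLI

```bash
# generate a labelled trial schedule (default: 9 x 2125 + 1700 trials)
crpseq generate --pattern-id 0 --seed 1 --out trials.csv

# simulate an agent on it
crpseq simulate --agent agent.yaml --trials trials.csv --seed 1 --out behavior.csv

# fit hyperparameters bin by bin
crpseq fit --trials trials.csv --behavior behavior.csv --config priors.yaml --seed 1 --out fits/

# descriptive + model-based diagnostics
crpseq analyze --trials trials.csv --behavior behavior.csv --out report/

# relate fitted parameters to external per-participant covariates
crpseq correlate --left fits.csv --right spans.csv --out corr.csv
```

Example `agent.yaml`:

```yaml
hcrp: {depth: 2, alpha: [1.0, 1.0, 1.0], decay: [0.001, 0.001, 0.01]}
rho: {intercept: 400.0, w_seq: 30.0, sigma: 0.05}
error_rate: 0.1
```

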