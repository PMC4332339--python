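# minifract

Fractal analysis and simulation of spontaneous quantal release at synapses.

Miniature postsynaptic currents ("minis") mark the spontaneous fusion of
single neurotransmitter vesicles.  Their timing is often assumed Poisson,
but in some states the event rate fluctuates with a `1/f^α` power law —
long-range temporal correlations whose strength α tracks the release
probability of docked vesicles.  `minifract` provides the computational
tool-chain for studying this phenomenon:

* **Fractal exponent estimation** of an event train by the count-based
  periodogram (PG) — `α = −slope` of `log₁₀ S(f)` vs `log₁₀ f` below a
  0.3 Hz cut-off, with `S(f)` the window-averaged `|W(f)|²/M` of 10 ms
  count series — and by the Allan factor (AF) —
  `AF(τ) = E[(Z_{k+1}−Z_k)²] / 2E[Z_k]`, with `α = slope` of `log₁₀ AF` vs
  `log₁₀ τ` from the fractal onset time τ₀ = 1 s.  A Poisson train gives
  α ≈ 0 under both.
* **Monte-Carlo significance**: the observed α is ranked against α from
  simulated homogeneous-Poisson trains matched in duration and event count;
  `p = #{α_null ≥ α_obs}/n_sim`.
* **A pre-docking release simulator**: at each of N independent sites the
  inter-event interval is the first-return time of a ±0.5 nm random walk at
  90 nm/s (heavy-tailed, the 1/f source) plus an exponential fusion delay
  with rate λ; the observable train is the superposition over sites.
  Parameter sweeps reproduce the signature of the model: α rises steeply
  with λ to a plateau near 0.9 and is nearly blind to N.
* **A wavelet mini detector**: 2 Hz zero-phase high-pass, 5-level
  stationary reverse-biorthogonal (rbio2.2) decomposition with per-level
  thresholding, slope-dip candidates, and joint multi-event template fits
  for onset timing; plus a simulated sensitivity assay (sequences of 100
  bi-exponential minis at SNR 3, 20 kHz) scored against ground truth at a
  0.6 ms tolerance.

## Worked example

Simulate one hour-equivalent of release from 50 sites at a high fusion rate,
then analyze it:

```
$ minifract simulate --n-sites 50 --lam 10 --duration 600 --seed 7 --out events.csv
wrote 14476 events to events.csv

$ minifract analyze --events events.csv --n-sim 200 --seed 1
{
  "input_id": "events.csv",
  "n_events": 14476,
  "span": 600.0,
  "alpha_pg": 0.8136,
  "alpha_af": 0.8221,
  "p_pg": 0.0,
  "p_af": 0.0,
  "n_sim": 200,
  ...
}
```

Both estimators agree that this train is strongly fractal (α ≈ 0.81–0.82): its
rate fluctuations follow a `1/f^0.8` spectrum, far from the flat spectrum of
a Poisson process — none of the 200 matched Poisson surrogates reached the
observed α, so `p < 1/200`.  Dropping `--lam` to 0.1 makes the exponential
fusion delay dominate the intervals and α falls to ≈ 0: the fractal
signature appears only when release is fast enough to expose the
random-walk docking dynamics, which is the model's central prediction.

Other subcommands: `sweep` (the (N, λ) grid), `synth` (ground-truth mEPSC
recordings), `detect` (run the detector on a trace), `assay` (the detector
sensitivity table), `mc-test`, and `fig5` (sweep plus fits and correlation
summaries).  Python API mirrors the CLI; see the module docstrings.

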