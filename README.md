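# rqalen

**How long must a recording be before recurrence-quantification features can
be trusted?** `rqalen` measures the estimation error of the four
diagonal-line RQA features — determinism (*DET*), maximal line length
(*L*max), average line length (*L*) and line-length entropy (*ENTR*) — as a
function of time-series length, and derives minimal-length requirements.
It targets quasi-periodic physiological signals (photoplethysmograms, PPG)
and ships the two benchmark generators the analysis is exercised on: a
chaotic Rössler system with adjustable measurement noise, and a synthetic
PPG generator.

It is intended for researchers applying nonlinear time-series analysis to
short physiological recordings, where "is this recording long enough?" is
usually answered by folklore rather than measurement.

## Method

A scalar series $\{x_i\}_{i=1}^{n}$ is delay-embedded,

$$X_j = (x_j, x_{j+\tau}, \dots, x_{j+(m-1)\tau}), \qquad N = n-(m-1)\tau,$$

with $\tau$ the first lag at which the autocorrelation falls below $1/e$.
The recurrence plot marks close pairs, $R_{i,j} = 1$ iff
$\lVert X_i - X_j \rVert < \varepsilon$, with $\varepsilon$ set to 10% of
the attractor diameter $\max_{i,j} \lVert X_i - X_j \rVert$. From the
histogram $P(l)$ of maximal diagonal lines (Theiler window excludes the
line of identity):

$$DET = \frac{\sum_{l \ge l_{min}} l\,P(l)}{\sum_{l \ge 1} l\,P(l)}, \quad
L = \frac{\sum_{l \ge l_{min}} l\,P(l)}{\sum_{l \ge l_{min}} P(l)}, \quad
ENTR = -\sum_{l} p(l) \ln p(l),$$

with $p(l) = P(l)/N_l$ and $L_{max}$ the longest line. The length scan
computes reference values $S_T$ from a long segment ($T$, ideally >100
average cycles of the trajectory), then draws random segments of each
tested length $l$, quantifies them with the *same* $\tau$ and
$\varepsilon$, and averages the relative error

$$E_l = \frac{|S_l - S_T|}{S_T} \times 100\%.$$

The minimal usable length for a feature at an error budget (5% or 1%) is
the smallest tested length whose mean error is at or below the budget and
stays below it at every longer tested length.

## Worked example

```sh
rqalen simulate-rossler --theta 0 --n-out 20000 --seed 1 -o rossler.csv
rqalen rqa rossler.csv -m 3
```

prints (abridged):

```json
{
  "det": 0.9999993353530624,
  "lmax": 19559,
  "mean_line": 488.0489165693525,
  "entr": 6.563706634607945,
  "n_lines": 30828,
  "tau": 220,
  "epsilon_absolute": 2.469493989778362,
  "dimension": 3
}
```

The clean Rössler trajectory is almost perfectly deterministic
(`det` ≈ 1: virtually every recurrent point lies on a diagonal line), the
longest line spans nearly the whole recording, and the threshold resolved
to 10% of the attractor diameter (≈ 2.47 signal units). Then scan lengths:

```sh
rqalen length-scan rossler.csv -m 3 --lengths 1500,4000,8000,20000 \
    --n-segments 20 -O scan/
rqalen report scan/
```

`scan/scan_errors.csv` holds mean relative error per feature and length —
*DET* error is already below 0.001% at 1,500 points, while *L*max is
still 95% off there — and `scan/scan_lower_limits.csv` the minimal lengths
at the 5% and 1% budgets (*DET*: 1,500 points; *ENTR* at 5%: 8,000; *L*
and *L*max only converge at the reference length on this short demo
series). A synthetic 5-minute PPG at 409.6 Hz comes from
`rqalen simulate-ppg -o ppg.csv`; use `--decimate 2` or `4` for
lower-rate variants.

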