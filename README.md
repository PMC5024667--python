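# popcode

Population coding and decoding models of human orientation perception at
low contrast.

When a faint oriented stimulus is encoded in the Poisson spiking of an
orientation-tuned neural population and read out by a maximum
a-posteriori (MAP) decoder, the distribution of estimation errors is
**not** circular normal: at low gain it develops a sharp peak with long
tails, and in the limit of no spikes it becomes uniform.  `popcode`
implements that account end to end for researchers in visual
psychophysics and computational neuroscience: the encoder and decoder,
the analytic error distribution, maximum-likelihood fits of the model
(and of two rival accounts) to trial-level estimation data, predicted
two-alternative forced-choice (2AFC) detection thresholds, and the
relationship between decoding reliability and subjective confidence —
plus a synthetic-data generator with the structure of the behavioural
study, so the whole pipeline is testable without any data download.

## The model in brief

M neurons with Von Mises tuning (concentration κ, preferred orientations
φᵢ evenly spaced on the doubled orientation circle) fire as independent
Poisson processes at rates

    rᵢ(θ, c) = η + g(c) · γ · e^{κ cos(θ − φᵢ)} / (M I₀(κ)),
    g(c) = cᵅ / (cᵅ + σ_cᵅ),

so the expected total spike count in a decode window T is
ξ = T(γ g(c) + Mη).  MAP decoding with a uniform prior makes the decoded
orientation the resultant direction of the spike-weighted preferred
orientations, and the error Δθ the resultant direction of an m-step Von
Mises random walk.  Marginalising over the walk's resultant length r and
the Poisson count m gives the analytic error density

    p(Δθ) = e^{−ξ}/2π + Σ_m Pois(m; ξ) · E_r[ VM(Δθ; 0, κr) ],

an infinite mixture of circular normals of different widths — hence the
non-normality at low ξ.  The same spiking model yields a closed-form 75%
2AFC detection threshold, g(c*) = ln 2/(γT), and a per-trial posterior
precision that rises with the total spike count, providing a neural
basis for confidence.  Details, numerical scheme and design decisions
are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from popcode import PopulationParams, PopulationCodingModel
from popcode.detection import threshold_closed_form
from popcode.synthetic_data import generate_subject_trials
from popcode.analysis import precision_by_contrast

params = PopulationParams()          # group-mean ML parameters
print("75%-correct threshold contrast:", round(threshold_closed_form(params), 4))
rng = np.random.default_rng(0)
trials = generate_subject_trials(params, 1600, rng, balanced=True)
print(precision_by_contrast(trials).round(3).to_string(index=False))
res = PopulationCodingModel(trials).fit(seed=0)
print(res.summary())
```

prints

```
75%-correct threshold contrast: 0.0902
 contrast_rel   n  precision    se  chance
          0.5 400      0.141 0.031   0.151
          1.0 400      0.564 0.054   0.161
          2.0 400     21.780 2.265   0.163
          4.0 400     29.815 2.332   0.158
population coding fit
==========================================================
observations                1600
free parameters                5
log-likelihood             -1213.314
AICc                        2436.666
BIC                         2463.517
converged                   True
----------------------------------------------------------
parameter         estimate     std err
gamma                104.8        29.6
kappa                3.741      0.6303
beta              -0.05294    0.006825
alpha                5.882      0.6223
sigma_c             0.1442     0.01019
```

Reading the output: the model observer with a 145 Hz population gain
detects this stimulus at ~9% contrast.  Response precision (1/σ², Fisher
circular SD) is at chance at 50% of that threshold, barely above chance
at threshold, and high at 200–400% — the hallmark contrast dependence.
The five-parameter maximum-likelihood refit recovers the generating
parameters up to the model's well-known gain/tuning-width trade-off
(γ·A(κ)·κ sets precision; γ = 104.8 with κ = 3.74 lies on the same
likelihood ridge as the generating γ = 145, κ = 2.40, and the standard
errors reflect that).  Rival models fit with the same interface
(`ThresholdModel`, `TwoStageModel`) and are compared with
`compare_models` (AICc/BIC).

A thin CLI wraps the main entry points:

```
popcode synth  --out trials.csv --truth truth.json --seed 1
popcode detect --mode closed
popcode analyze --trials trials.csv --out report/
```

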