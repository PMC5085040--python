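# txinit

Inference of the rate-limiting steps of bacterial transcription initiation
from censored single-cell RNA production intervals.

Time-lapse single-RNA microscopy (e.g. MS2-GFP tagging in *Escherichia
coli*) yields, for each cell, the durations between consecutive RNA
production events — observed only up to the sampling resolution of the
movie (60 s frames) and cut short by the end of each cell's observation
window. `txinit` fits stochastic models of initiation to such interval
tables, decides how many steps are rate limiting and whether on/off
promoter switching matters, resolves how each step responds to
temperature, and splits the mean interval into its RNA-polymerase-dependent
(pre-commit) and independent (post-commit) parts. It is aimed at
single-cell transcription labs and modelers who have interval tables (or
want realistic synthetic ones) rather than raw images.

## Model

The promoter is a telegraph switch in series with up to three sequential
steps,

    P_off <-- k_off / k_on --> P_on --k1--> I1 --k2--> I2 --k3--> RNA,

so the inter-production interval follows a phase-type distribution with
sub-generator T: density f(t) = α·exp(Tt)·t₀, mean
(1 + k_on⁻¹/k_off⁻¹)·k1⁻¹ + k2⁻¹ + k3⁻¹. Records enter the likelihood as
interval probabilities — log[F(ub) − F(lb)] for grid-bounded records (by
default in a detection-phase-averaged form that is exact for grid data,
see `docs/methods.md`) and log[1 − F(lb)] for right-censored ones. Model
structure is chosen by BIC with censored samples worth 0.5 exact samples,
plus a worst-case ΔBIC lower bound over that worth; temperature enters
through polynomial inverse-rate laws k_x(T)⁻¹ = A·T² + B·T + C; fit
adequacy is checked by a parametric bootstrap.

## Worked example

Simulate one bursty condition under the study's observation design (120 min
movies, 60 s sampling) and ask which scheme the data support:

```python
import numpy as np
from txinit import InitiationModel, ObservationDesign, select_structure, burst_statistics
from txinit.simulate import ConditionMeta, simulate_condition

model = InitiationModel((1 / 5,), k_on=1 / 2000, k_off=1 / 10)  # rates in 1/s
design = ObservationDesign(movie_length=7200, sampling_interval=60, n_cells=300)
records = simulate_condition(model, design, ConditionMeta("C1"),
                             np.random.default_rng(42))

comp = select_structure(records, n_starts=5, seed=0)
print(comp.to_frame().to_string(index=False, float_format=lambda v: f"{v:.2f}"))

best = comp.best_fit
print({k: round(float(v), 1) for k, v in zip(best.param_names, 1 / np.exp(best.estimates))})
print({k: round(float(v), 4) for k, v in burst_statistics(best.model).items()})
```

Output:

```
   structure  p   loglik      BIC  delta_BIC  delta_BIC_LB evidence
on/off+1step  3 -4707.66  9438.92       0.00          0.00     weak
on/off+2step  4 -4707.66  9446.79       7.87          7.81   strong
on/off+3step  5 -4707.66  9454.66      15.74         15.63   strong
       1step  1 -8110.79 16229.45    6790.53       6790.42   strong
       2step  2 -8112.64 16241.03    6802.11       6802.05   strong
       3step  3 -8114.50 16252.61    6813.69       6813.69   strong
{'k_on': 1979.7, 'k_off': 14.7, 'k1': 7.3}
{'duty_cycle': 0.0074, 'mean_burst_size': 2.0196, 'mean_burst_interval': 1979.6515}
```

The on/off + single-step scheme wins decisively over the purely sequential
candidates (ΔBIC > 6000: the data are super-Poissonian, so switching is
essential), while the extra sequential steps buy no likelihood and lose on
the parameter penalty. The recovered inverse rates (k_on⁻¹ ≈ 1980 s,
k_off⁻¹ ≈ 15 s, k1⁻¹ ≈ 7 s against the generating 2000/10/5 s) describe a
promoter that is off most of the time (duty cycle 0.7%) and fires bursts of
about two initiations when it switches on.

The same analyses run from the shell on conditions/intervals CSV tables:

```sh
txinit simulate --config examples/config.yaml --out data/
txinit select --conditions data/conditions.csv --intervals data/intervals.csv
txinit fit-temperature --conditions data/conditions.csv --intervals data/intervals.csv
txinit gof --conditions data/conditions.csv --intervals data/intervals.csv
txinit split --activity activity.csv
txinit report --config examples/config.yaml --out out/   # full pipeline + summary.json
```

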