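# barknarx

Bark-thickness modelling along tree stems for forest biometrics: a recurrent
(NARX) neural-network model of double bark thickness, two polynomial
bark-taper baselines, the accuracy statistics to compare them, and a
synthetic stem-measurement generator so the whole pipeline can be exercised
and validated without field data.

**Who it is for.** Forest mensurationists and biometricians who need bark
thickness at arbitrary stem heights — for under-bark volume in inventories
and log trade — and want to compare a data-driven recurrent model against
the classical regression equations on their own sectional measurements.

## The models

Felled trees are measured at sections `Hb = 0.0, 0.5, 1.3, 2.0 m` and then
every 2 m to the tip: outside-bark diameter `avg_d` (cm, mean of two
perpendicular caliper readings) and two perpendicular bark-gauge readings
`k1, k2` (cm). The target is the **double bark thickness** `DBT = k1 + k2`.

*Recurrent model.* All sections are flattened tree-by-tree into one series
indexed by `k`; within each tree the distance to the top `DTT = H − Hb`
decreases, so the series is a train of descending ramps. A NARX network

    y(k) = F( y(k−1),…,y(k−N), u(k−1),…,u(k−M) ) + ε(k),
    u(k) = [avg_d(k), DTT(k)],   y(k) = DBT(k),   N = M = delay

with one sigmoidal hidden layer and a linear output (`2(delay)-h-1`
architecture) is trained in open-loop (series–parallel) form on
Min–Max-scaled data, with Nguyen–Widrow starting weights and one of three
optimizers: Levenberg–Marquardt (LM), Bayesian regularization (BR, no
validation stop) or Møller's scaled conjugate gradient (SCG). Data are
split 70/15/15 into training/validation/test by random subsampling.

*Polynomial baselines.* Two bark-taper equations of the Cao–Pepper /
Li–Weiskittel family, with `q = Hb/H`:

    STAT1:  DBT = avg_d (b1 + b2 q + b3 q² + b4 H) + b5
    STAT2:  DBT = avg_d (c1 + c2 q + c3 q² + c4 H + c5 ρ) + c6

where `ρ` is the inside/outside-bark diameter ratio at breast height
(1.3 m). Published coefficient sets for Scots pine and common oak ship with
the package; both models are linear in their coefficients and can be refit
by ordinary least squares.

*Comparison statistics.* RMSE, mean error `ME = Σ(obs − pred)/K`
(positive = underestimation), MAE, and the model-efficiency coefficient EF
(conventional observed-mean denominator by default; the predicted-mean
variant is selectable).

## Worked example

```python
from barknarx import NarxConfig, build_series, series_to_frame, split_series
from barknarx.pipeline import train_restarts
from barknarx.synthetic import SyntheticProfile, generate_dataset

gen = generate_dataset(SyntheticProfile(species="pine", truth="stat1",
                                        noise_sd=0.1), n_trees=80, seed=3)
frame = series_to_frame(build_series(gen.dataset))
split = split_series(len(frame), seed=3)
config = NarxConfig(n_hidden=20, delay=1, trainer="BR", max_epochs=300)
results, chosen = train_restarts(frame, split, config, restarts=5, seed=3)
```

prints (via `examples/train_network.py`):

```
2(1)-20-1 BR: restart 5/5, stopped after 300 epochs (max_epochs)
  training   MSE = 0.180 cm^2   R = 0.962
  validation MSE = 0.000 cm^2   R = 0.000
  testing    MSE = 0.220 cm^2   R = 0.950
```

Training/testing MSE are in cm² of double bark thickness and R is the
measured-vs-predicted correlation; the validation row reads zero by
convention because BR pools the validation samples into training and needs
no early stop. The other scripts in `examples/` walk through simulation
(`simulate_stems.py`), the polynomial baselines and their least-squares
refit (`taper_baselines.py`) and the three-model accuracy table
(`compare_models.py`). A thin CLI wraps the same calls:

```sh
barknarx simulate --species pine --n-trees 100 --seed 1 -o stems.csv
barknarx fit --data stems.csv --hidden 20 --delay 1 --trainer br -o model.json
barknarx grid --data stems.csv -o tables/
barknarx compare --data stems.csv --model model.json -o accuracy.csv
```

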