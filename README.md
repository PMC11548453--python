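# solestep

Multi-activity step counting from a single IMU embedded in a shoe sole.

Most pedometer algorithms are tuned for steady walking and degrade when
the wearer mixes activities — running, stomping, high knees, butt kicks,
stair descent — with speed changes and transitions in between. `solestep`
implements a different strategy aimed exactly at that regime: instead of
thresholding acceleration peaks, it detects the **foot-flat phase** of
each stance (the sub-phase in which the sole is stationary on the ground)
with a small recurrent classifier, then converts the detected phases into
step events with a refractory rule. It is written for movement-science
and digital-health researchers who want a tested, end-to-end reference
pipeline — including a synthetic multi-activity cohort generator, since
datasets of this kind are rarely public.

## Method

For each 200 Hz IMU sample *t*, a many-to-one LSTM reads a 125 ms window
of anterior data from the three informative channels — the gyroscope norm
‖ω‖, the acceleration norm ‖a‖, and the vertical acceleration a_z,
selected by the Pearson-correlation cut |r(x, flat)| ≥ 0.1 — and emits

  p_t = P(foot flat at t | x_{t−w+1..t}),  ŝ_t = 1{p_t ≥ 0.5}.

A step is registered at each 0→1 onset of ŝ, except onsets falling within
the **rest delay** RD after the previously registered onset:

  steps = #{ t : ŝ_{t−1}=0, ŝ_t=1, t − t_last ≥ RD },

with RD chosen on a 25:25:1000 ms grid. Accuracy is reported subject-wise
(no person contributes to both training and evaluation) as

  MAPE_G = |n_steps,pred − n_steps,obs| / n_steps,obs,
  MAPE_DL = |n_flat,pred − n_flat,obs| / n_flat,obs.

The default model configuration is the tuned operating point: 2 LSTM
layers × 32 units, tanh activation, no intermediate dense layer, dropout
0.2, learning rate 1e-2, batch 1024, trained with Adam on binary
cross-entropy under early stopping (patience 10, 5-minute budget). The
network itself is a compact, fully tested NumPy implementation (forward
pass + backpropagation through time). See `docs/methods.md` for the
model, the synthetic-cohort design and its calibration, and all numerical
choices.

## Worked example

```python
from solestep.gait_synth import simulate_cohort
from solestep.pipeline import prepare_cohort, single_split_experiment
from solestep.feature_select import select_channels

# 21 simulated subjects, ~191 steps each, multi-activity track
cohort = prepare_cohort(simulate_cohort(21, seed=1))

ranking = select_channels([s.enriched for s in cohort])
print(ranking.magnitudes.round(3).to_dict())
print("retained:", ranking.retained)

res = single_split_experiment(seed=1)   # trains on 18 subjects, tests on 3
print(f"MAPE_G = {100 * res['mape_g']:.2f}% at RD = {res['rd_ms']:.0f} ms")
```

Output from this exact run:

```
{'gyro_norm': 0.646, 'acc_norm': 0.401, 'acc_z': 0.147, 'gyro_y': 0.01,
 'gyro_z': 0.009, 'gyro_x': 0.007, 'acc_x': 0.002, 'acc_y': 0.001}
retained: ['gyro_norm', 'acc_norm', 'acc_z']
MAPE_G = 0.00% at RD = 25 ms
```

The ranking says the gyroscope norm is by far the most label-informative
channel (|r| ≈ 0.65), the acceleration norm second (≈ 0.40), vertical
acceleration a distant third (≈ 0.15), and every individual axis is
uninformative (< 0.1) — so the selector keeps exactly three of eight
channels. On the held-out subjects the predicted step count matches the
573 true steps exactly across the whole low end of the rest-delay grid
(the tie-break then reports the smallest delay), while a 1000 ms delay
suppresses genuine steps of the fast activities and drives the error
above 30%.

A command-line interface mirrors the library
(`solestep simulate | preprocess | select | count | split | tune | run`),
e.g.:

```bash
solestep simulate --subjects 21 --seed 1 --out cohort/
solestep preprocess --imu cohort/subject00_imu.csv \
    --annotation cohort/subject00_annotation.csv --out enriched00.csv
solestep split --seed 1
```

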