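# blapipe

Statistical pipeline for studies of genetically defined basolateral-amygdala
(BLA) neuron populations, combining single-cell-resolution calcium imaging
in freely moving mice with single-nucleus transcriptomics and multiplexed
smFISH.  It answers three kinds of question:

1. **Distance tuning** — is a neuron's firing tuned to the animal's distance
   from a target (food container, caged conspecific)?  Firing is binned over
   31 normalized-distance bins; the statistic max<sub>b</sub> r̄<sub>b</sub>
   is tested against a null of 1000 *rotary shuffles* (circular shifts of
   the neuron's own deconvolved spike train, preserving its values and
   autocorrelation), with Benjamini–Hochberg control at FDR 5%.  Each
   neuron's peak bin sorts it into pro / neutral / anti zones (5/17 cm for
   food, 10/20 cm for social targets), and a pooled-resampling composition
   test asks whether a population holds more (or fewer) pro/anti neurons
   than drawing the same number from all populations pooled (2.5% tails).
2. **Event responses** — the shock response score
   SRC = (F<sub>during</sub> − F<sub>before</sub>) / (F<sub>during</sub> +
   F<sub>before</sub>) over 2-s windows around footshock onsets (averaged
   over shocks), and its analogues for freezing bouts and social-engagement
   frames (SoRC), all bounded in [−1, 1]; responders are classified against
   a rotary-shuffle null of the mean SRC.
3. **Spatial mapping** — AUROC one-vs-rest marker screening
   (auc > 0.5, pct_in ≥ 20, pct_out ≤ 20), per-cluster marker profiles
   max-scaled to [0, 1], positive-cell fractions over the eight BLA
   subregions (aLA, pLA, ppLA, amBA, alBA, acBA, pBA, ppBA), eigen-image
   PCA of rasterized marker maps, and assignment of each smFISH cell to the
   transcriptomic cluster with the highest Pearson correlation.

A seeded synthetic-data module generates every input the pipeline consumes
(arena trajectories at 15 frames/s, tuned/event-locked Poisson spike
trains, negative-binomial expression counts, 2-D smFISH layouts) with
ground truth attached, so the whole pipeline is testable offline.
See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import pandas as pd
from blapipe import simdata, disttuning, eventresp
from blapipe.disttuning import TuningConfig

arena = simdata.feeding_arena()                      # 20 x 32.5 cm cage, food in a corner
traj = simdata.gen_trajectory(arena, 9000, 1.5, seed=1)   # 10 min at 15 fps
truth = simdata.make_tuning_truth(6, frac_tuned=0.5, baseline=0.2,
                                  amplitude=0.6, seed=2)  # 3 tuned, 3 flat neurons
spikes = simdata.gen_tuned_spikes(traj, arena, truth, seed=3)
res = disttuning.analyze_tuning(spikes, traj, arena, TuningConfig(seed=4))
print(res.table.to_string(index=False))
```

```text
neuron_id  peak_bin  peak_distance_cm    zone  p_value  significant
    n0000        10          5.504032 neutral 0.000999         True
    n0001         9          4.979839     pro 0.000999         True
    n0002        22         11.794355 neutral 0.000999         True
    n0003         5          2.883065     pro 0.934066        False
    n0004         0          0.262097     pro 0.379620        False
    n0005        16          8.649194 neutral 0.992008        False
```

The three planted tuned neurons (n0000–n0002) are flagged at the p-value
floor 1/1001 and their peak distances land within a bin of the planted
preferences (e.g. n0000 prefers normalized distance 0.309 ≙ 5.0 cm,
estimated 5.5 cm); the three untuned neurons are not flagged.  `zone` is
read off the peak bin — only flagged neurons would be carried into the
population composition test.

The same session style works for footshock responders — one neuron each
with event gain 3 (activated), 1 (unmodulated) and 0 (silenced during
shocks):

```python
ev = simdata.EventTimeline(pd.DataFrame(
    {"onset_s": [198., 278., 358.], "offset_s": [200., 280., 360.], "label": "shock"}))
sm = simdata.gen_event_spikes(6000, 15.0, ev, baseline=0.3, gain=[3.0, 1.0, 0.0], seed=5)
print(eventresp.classify_shock_responders(sm, ev, 15.0, TuningConfig(seed=6)).to_string(index=False))
```

```text
neuron_id     score   class  null_lower  null_upper
    n0000  0.615756     pro   -0.316760    0.333431
    n0001 -0.016667 neutral   -0.260254    0.266460
    n0002 -1.000000    anti   -0.318929    0.305101
```

The mean SRC of the planted responder (0.62) clears the upper 2.5% null
quantile; the silenced neuron's SRC of −1.0 (no spikes during any shock)
falls below the lower quantile.

A full demo run over every stage (simulate → markers → spatial → tuning →
events), writing result tables plus a reproducibility manifest:

```sh
blapipe run --config examples/demo_config.yaml
```

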