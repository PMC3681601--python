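# spindlequant

Quantitative analysis of fluorescence measurements on acentrosomal
(oocyte meiotic) spindles, built around three workflows:

1. **FRAP turnover kinetics** — correct fluorescence-recovery-after-
   photobleaching traces for acquisition-induced photobleaching against
   non-bleached control spindles, normalize them between the pre-bleach
   level and the bleach floor, pool replicate oocytes, and fit a family
   of recovery models to measure how stably a protein (e.g. the
   microtubule-nucleating Augmin complex) is associated with the spindle.
2. **Axial intensity profiling** — pole-to-pole line scans of spindle
   fluorescence, normalized in position and intensity, reduced to medians
   over 10 axial bins, and summarized by a sub-polar/equator ratio that
   is compared between genotypes with a Wilcoxon rank-sum test.
3. **Pole intensity vs chromosome congression** — background-subtracted
   per-pixel pole fluorescence from nested ROIs, the axial spread of the
   chromosome mass, and the Pearson correlation of spread with log pole
   intensity across oocytes.

A synthetic-data module generates FRAP traces, two-channel spindle
images, and congression datasets with known ground truth, so the entire
pipeline is testable end-to-end without microscopy data.

## The recovery model

Normalized recovery after bleaching at `t = 0` is modelled as up to two
exponentially recovering populations with half-recovery times
parameterized directly (rate `k = ln 2 / t½`):

```
F(t) = f · (1 − 2^(−t / tf½)) + s · (1 − 2^(−t / ts½))
```

where `f` and `s` are the fast and slow population fractions. Three
nested variants are fitted by bounded multistart least squares and
compared by AICc:

| model kind             | free parameters        | interpretation |
|------------------------|------------------------|----------------|
| `full_single`          | `t½`                   | one population, full recovery |
| `single_plus_immobile` | `f, t½`                | one turnover population + immobile rest |
| `two_population`       | `f, tf½, ts½` (f+s=1)  | fast and slow turnover populations |

In oocytes this distinguishes a dominant slow population (t½ of
minutes) from a small fast one (t½ of seconds), while mitotic
syncytial-embryo spindles are better described by a single fast
turnover population plus an immobile remainder.

## Worked example

Simulate 15 metaphase-I-like oocyte FRAP experiments and fit them:

```
$ spindlequant simulate traces --condition oocyte_metaphase_I --n 15 --seed 1 --out oocyte.csv
wrote 30 traces (15 sample/control pairs) to oocyte.csv
$ spindlequant frap-fit oocyte.csv --model auto --seed 1 --out fit.json
wrote fit report to fit.json
```

`fit.json` then contains (abridged):

```
selected: two_population
full_single           rss 0.094  aicc -195.7
single_plus_immobile  rss 0.021  aicc -244.9
two_population        f=0.147 tf½=7.0 s  s=0.853 ts½=294.1 s  rss 0.009  aicc -272.1
```

The two-population model wins by a wide AICc margin, and the fit
recovers the generating truth: 85% of the protein in a slow pool with a
half-recovery time near 5 minutes (294 s) and 15% in a fast pool with a
half-recovery time near 8 s. The one-population alternatives leave an
order of magnitude more residual, which is the quantitative form of
"did not fit satisfactorily".

The same can be done from Python:

```python
from spindlequant import CONDITIONS, TraceSimConfig, gen_trace_ensemble
from spindlequant.pipeline import normalize_ensemble
from spindlequant import fit_recovery

cfg = TraceSimConfig(params=CONDITIONS["oocyte_metaphase_I"], seed=1)
pooled, sem = normalize_ensemble(gen_trace_ensemble(cfg, 15))
print(fit_recovery(pooled, "two_population").params)
```

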