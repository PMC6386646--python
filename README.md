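# har — adaptive-window human activity recognition

`har` is a toolkit for recognising physical activities (sitting, standing,
lying, walking, stairs, running) from body-worn triaxial accelerometer and
gyroscope streams. It is aimed at digital-health researchers who need
time-resolved activity traces from smartwatch or smartphone sensors — for
example to relate activity bouts to symptoms or exposures — and who face the
classic windowing dilemma: a small fixed analysis window gives noisy
predictions, a large one misses short activity bursts.

The package's answer is **adaptive windowing by multivariate change-point
detection**. Instead of fixed-size windows, segment boundaries are placed
where the joint statistics of the 6-channel signal change, using **greedy
Gaussian segmentation (GGS)**: within segment *i* the samples
*x<sub>t</sub>* ∈ ℝ<sup>m</sup> (m = 6) are modelled as i.i.d.
MVN(µ<sub>i</sub>, Σ<sub>i</sub>), and the breakpoints
*b<sub>1</sub> < … < b<sub>K</sub>* maximise the covariance-regularised
log-likelihood

&nbsp;&nbsp;&nbsp;&nbsp;Φ(b) = Σ<sub>i</sub> ψ<sub>i</sub>,&nbsp;&nbsp;
ψ<sub>i</sub> = −(n<sub>i</sub>/2)·(m ln 2π + ln det Σ̂<sub>i</sub> +
tr(Σ̂<sub>i</sub><sup>−1</sup> S<sub>i</sub>)),&nbsp;&nbsp;
Σ̂<sub>i</sub> = S<sub>i</sub> + (λ/n<sub>i</sub>)·I,

with S<sub>i</sub> the segment's sample covariance and λ ≥ 0 a
regularisation weight. A greedy heuristic adds one breakpoint at a time at
the position of largest Φ gain, then repeatedly re-optimises each breakpoint
between its neighbours until a full sweep changes nothing. The Φ-versus-K
curve exposes an elbow at the true number of activity bouts and guides the
choice of K.

Around the segmenter sits a complete pipeline:

1. **sensor_io** — read raw per-sensor files, snap both sensors onto an
   exact 50 Hz grid, fill holes with local least-squares lines, truncate
   gaps longer than 10 s;
2. **preprocess** — median filter (kernel 3), zero-phase third-order
   Butterworth low-pass, Welch PSD for cutoff selection;
3. **features** — augment 6 channels to 14 (jerks + sensor norms), extract
   6 statistics × 14 signals × 2 domains = **168 features** per segment;
4. **classify** — XGBoost multiclass model (200 trees, learning rate 0.1)
   on segment features; segment predictions broadcast to every sample
   ("instantaneous" predictions);
5. **evaluate** — confusion matrices and accuracy on instantaneous
   predictions, so adaptive and fixed windows are scored on the identical
   denominator;
6. **synthetic** — a simulator that generates labeled streams with the
   statistical structure above, shuffles activity bouts into unequal
   durations, and injects timestamp jitter / missing spans.

## Worked example

```python
import har
from har.pipeline import PROFILES, preprocess_stream
from har import evaluate

profile = PROFILES["desk_shuffled"]
pairs = []
for i in range(14):
    stream, labels = har.simulate_activity_stream(har.default_protocol("desk"), seed=1000 + i)
    stream, labels = har.shuffle_bouts(stream, labels, n_sub=10, seed=1500 + i)
    pairs.append((preprocess_stream(stream, profile), labels))

table = evaluate.window_size_sweep(pairs[:12], pairs[12:], profile)
print(table.to_string(index=False))
```

```
method  size_s  accuracy_pct
 fixed     0.8     91.704545
 fixed     3.0     87.621212
 fixed     8.0     74.257576
 fixed    30.0     52.651515
   ggs     NaN     95.303030
```

Each row is the instantaneous accuracy of one windowing scheme on the two
held-out streams (13 200 samples): fixed windows of 0.8–30 s versus GGS.
With unequal (shuffled) activity bouts the adaptive segmentation beats every
fixed size — short windows are statistically noisy, long windows straddle
bout boundaries — whereas on unshuffled equal-bout sessions the best fixed
window is on par with GGS. This is the qualitative fingerprint of
adaptive windowing.

The same stages are scriptable from the shell:

```bash
har simulate --profile desk --shuffle-bouts --seed 7 -o exp01/
har segment ggs --stream exp01/stream.tsv --k 60 --lambda 1e-3 -o exp01/seg.tsv
har featurize --stream exp01/stream.tsv --segments exp01/seg.tsv -o exp01/features.tsv
```

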