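# jointkal

Correction of depth-sensor skeleton joint trajectories by reliability
classification, extended Kalman smoothing, and bone-length-constrained
prediction.

Consumer depth sensors (Kinect v2 and similar) track 25 named 3-D skeleton
joints at 30 Hz. The stream suffers from two distinct defects: small-amplitude
sensor jitter on every frame, and gross estimation failures — typically under
occlusion — in which the reported joint position departs from the true one by
tens of centimeters while vibrating at high frequency. Smoothing filters handle
the first defect but smear the second into the surrounding frames. `jointkal`
is for anyone who consumes skeleton streams quantitatively (rehabilitation
assessment, ergonomics, human–robot interaction) and needs both defects
handled.

## Method

Each joint trajectory p(f) is processed in three stages:

1. **Vibration-degree classification.** Displacement vectors
   d(f) = p(f+1) − p(f) are formed; the angle θ(f) between consecutive
   displacements (evaluated only when both magnitudes exceed d_min = 0.02 m)
   is mapped to a reliability

       R(f) = 1 − [ min(θ, θ_max) − θ_min ]₊ / (θ_max − θ_min),

   with θ_min = 45°, θ_max = 135°. Frames with R < 0.70 (or a missing
   position) are *erroneous*; the rest are *noise* frames. The 0.70 threshold
   can be re-calibrated against manual annotation by bisection on the flagged
   count.

2. **Extended Kalman smoothing of noise frames.** State
   X = [x, y, z, ẋ, ẏ, ż]ᵀ with constant-velocity dynamics X_{k+1} = F X_k + w;
   measurement Y = [x, y, z, arctan(x/z)]ᵀ, where the fourth component is the
   subject bearing from the sensor's microphone array. The bearing row is
   nonlinear, so the update linearizes it about the prediction (EKF). Without
   a bearing channel the filter reduces to the traditional linear Kalman
   filter.

3. **Constrained correction of erroneous frames.** The erroneous observation
   is discarded. The state is advanced by prediction only, and the predicted
   position P̃ is projected onto the sphere of radius l_AB (the constant bone
   length) centered at the trusted parent joint A:

       B̂ = A + l_AB · (P̃ − A) / ‖P̃ − A‖,

   the nearer of the two intersections of the sphere with the line through A
   and P̃.

A synthetic generator reproduces the evaluation protocol — a wrist traversing
a quarter-circle arc of known radius in the (x, z) plane with an occlusion
window of corrupted frames — so the whole method is testable without hardware.
Accuracy is scored as the mean planar error
E = (1/n) Σ √((x−x₀)² + (z−z₀)²) against the arc, and compared with a moving
mean filter and the traditional Kalman filter.

## Worked example

```sh
jointkal simulate --seed 3 --out scene/
jointkal filter --in scene/observed.csv --topo scene/topology.yaml --out corrected.csv
jointkal evaluate --est corrected.csv --truth scene/truth.csv \
                  --observed scene/observed.csv --joint wrist
```

prints

```
     method  mean_error_m  sd_m  n_runs
        raw         0.054   0.0       1
moving_mean         0.015   0.0       1
     kalman         0.014   0.0       1
       ours         0.005   0.0       1
improvement of moving_mean vs raw: 71.3%
improvement of kalman vs raw: 74.7%
improvement of ours vs raw: 90.7%
```

Reading: the raw observed wrist deviates from the true arc by 54 mm on
average (dominated by the 1-second occlusion window); the moving-mean and
Kalman baselines smooth this to 14–15 mm but cannot reject the gross errors
they average over; the full pipeline detects the occluded frames, replaces
them with constrained predictions, and lands at 5 mm — a 90.7 % improvement
over the raw stream.

The same is available as a library:

```python
from jointkal import SceneConfig, generate_quarter_circle, run_pipeline, mean_planar_error

scene = generate_quarter_circle(SceneConfig(seed=3))
result = run_pipeline(scene.observed, scene.topology())
print(mean_planar_error(result.corrected.joint("wrist"), scene.truth.joint("wrist")))
```

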