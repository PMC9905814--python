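# dynifs

Dynamic bone-to-bone distance from optical motion capture and
subject-specific bone meshes — built around the in vivo measurement of
the **ischiofemoral space (IFS)**: the shortest distance between the
lateral cortex of the ischial tuberosity (pelvis) and the medial cortex
of the lesser trochanter (femur), tracked continuously over the gait
cycle.

It is aimed at musculoskeletal biomechanics researchers who have (a)
neutral-position bone/skin landmark coordinates and bone meshes from
imaging and (b) skin-marker trajectories and ground-reaction forces from
a gait laboratory, and who want radiation-free, subject-specific
dynamic bone-to-bone distance curves and a principled waveform-level
group comparison.

## Method

**Registration.** For corresponded landmark sets P (imaging frame) and
Q (lab frame, one capture frame) the rigid pose minimizing
Σᵢ‖R pᵢ + t − qᵢ‖² is closed-form: with centroids μ_P, μ_Q and
decentred sets P′, Q′, form H = P′Q′ᵀ, take the SVD H = U S Vᵀ, set
R = VUᵀ (negating the last column of V if det(VUᵀ) < 0, so R is never a
reflection) and t = −RμP + μQ. Bone landmarks A are then mapped into
the lab frame per frame as **B = RA + t**, posing the bone mesh.

**Distance.** The IFS at a frame is the minimum point-to-triangle
distance between the two posed cortical regions of interest (both
directions), computed exactly with a bounding-sphere pruning step.
Curves are resampled to 101 nodes (0–100 % of the heel-strike to
heel-strike cycle, events from a 10 N vertical-GRF threshold).

**Validation metrics.** Against a ground-truth trajectory source the
package reports RMSE of distance (mm) and of cluster orientation
(geodesic angle, degrees), between-session coefficient of multiple
correlation (CMC), and linear-fit-method validity (slope a₁, intercept
a₀, R²).

**Inference.** Cohort IFS waveforms are compared with SPM{t}/SnPM{t}:
a pointwise t field over the 101 nodes with a field-wise critical
threshold, from the 1D Euler-characteristic approximation (SPM) or the
permutation distribution of the max-over-nodes |t| (SnPM), gated by a
pointwise normality test. Supra-threshold clusters are reported with
interpolated endpoints (percent of cycle) and cluster p-values.

A sphere-phantom generator replicates the physical validation protocol
(five surface/bone landmark pairs with distinct offsets, a 30 cm
oblique slide and a 90° rotation) with exact ground truth.

## Worked example

```python
import numpy as np
from dynifs.phantom import PhantomSpec, simulate_slide
from dynifs.kinematics import bone_landmark_trajectories, fit_frame_transforms
from dynifs.metrics import rmse_distance

spec = PhantomSpec(noise_sd_mm=0.2, seed=1)        # slide, 990 frames @100 Hz
markers, truth, model = simulate_slide(spec)
series = fit_frame_transforms(markers, model.surface_landmarks)
_, A = model.landmark_array("bone")
B = bone_landmark_trajectories(series, A)

disp = np.linalg.norm(B[-1] - B[0], axis=1)
print(f"net displacement {disp.mean():.3f} mm")
print(f"trajectory RMSE  {rmse_distance(B, truth.bone_trajectories):.3f} mm")
```

prints

```
net displacement 300.005 mm
trajectory RMSE  0.200 mm
```

i.e. the commanded 300 mm slide is recovered through the full
marker-to-bone registration, and with 0.2 mm optical noise on the skin
markers the reconstructed bone-landmark trajectories deviate from the
ground truth by about the injected noise level.

The same pipeline is available from the shell:

```sh
dynifs phantom --motion slide --frames 990 --noise-sd 0 --seed 1 --out run/
dynifs register --markers run/markers.tsv --landmarks run/landmarks.json --out run/tf.csv
```

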