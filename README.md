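# lssdmap

Localized signed surface distance (LSSD) maps for consensus-based contour
training in radiotherapy.

Delineating targets and organs at risk on CT is subject to large inter- and
intra-observer variability, and training contourers traditionally requires a
radiation oncologist to review each attempt. `lssdmap` implements the
computational core of a real-time feedback loop: a trainee's contour of a
structure (e.g. the heart or left ventricle) is compared against a consensus
reference fused from a panel of expert contours, and the disagreement is
localized per CT slice and per angular sector as a signed surface distance,
so the trainee can see *where* they over- or under-contour, not just by how
much overall.

## The metric

For one structure on one axial slice, let R be the reference contour and T
the trainee contour. The slice plane is divided into N = 360°/Δθ angular
sectors about the geometric centre of R (in a head-first-supine setup,
θ = 0°, 90°, 180°, 270° point patient-left, anterior, right, posterior). In
each sector, with ΔR and ΔT the pieces of each boundary falling in the
sector, the symmetric mean surface distance is

    |Δd| = (Δd_RT + Δd_TR) / 2,
    Δd_RT = (1/|ΔR|) Σ_{r∈ΔR} min_{t∈ΔT} d(r, t),   Δd_TR symmetrically,

and the enclosed regions clipped to the sector wedge give the sensitivity
P = A(R∩T)/A(R) and specificity Q = A(R∩T)/A(T). The sector value is signed

    Δd = +|Δd|  if P ≥ Q   (trainee extends beyond the reference: over-contoured)
    Δd = −|Δd|  if P < Q   (trainee inside the reference: under-contoured).

All sectors and slices assemble into the **LSSD map** (rows = slices,
columns = sectors), rendered green at 0, saturating red at ≥ +3 mm and blue
at ≤ −3 mm. The reference R is the STAPLE (EM label fusion) consensus of the
trainee contour plus the expert panel, re-fused on every update, so a
trainee close to the experts earns weight in the consensus while a deviant
trainee barely moves it. A session is summarized by the mean and standard
deviation of the map cells (LSSD_AVG, LSSD_SD); the training effect is
ΔLSSD_SD = LSSD_SD(initial) − LSSD_SD(final), tested with a two-tailed
variance F test at the 95% level.

## Worked example

No clinical data is required — synthetic phantoms drive everything:

```python
import numpy as np
from lssdmap import make_tube, make_rater_ensemble, perturb, TrainingSession
from lssdmap.stats import SessionRecord, session_trajectory

truth = make_tube("circle", radii=40.0, z_range=(0.0, 15.0),
                  slice_spacing=3.0, label="Heart")
experts = make_rater_ensemble(truth, n_raters=8, per_rater_noise_sd=1.0, seed=11)
session = TrainingSession(experts, delta_theta=10.0)
record = SessionRecord()
rng = np.random.default_rng(5)
for noise in (3.0, 1.5, 0.75, 0.4):       # the trainee improves each update
    trainee = perturb(truth, noise, rng=rng)
    record.append(session.submit(trainee))
print(session_trajectory(record).to_string(index=False))
d = record.delta()
print(f"delta_sd = {d.delta_sd:.2f} mm, F = {d.f_statistic:.2f}, p = {d.p_value:.2e}")
```

prints

```
 sequence_index  lssd_avg_mm  lssd_sd_mm  n_cells  is_final
              0     0.243936    2.604006      216     False
              1     0.278791    1.472140      216     False
              2     0.234215    0.733186      216     False
              3     0.226529    0.408811      216      True
delta_sd = 2.20 mm, F = 40.57, p = 0.00e+00
```

Each row is one map update of a 6-slice, 36-sector session: as the simulated
trainee converges on the truth, the map spread LSSD_SD falls from 2.6 mm to
0.4 mm, and the 2.2 mm ΔLSSD_SD is highly significant — the signature of a
successful training session.

A command-line interface mirrors the library
(`lssd compute | staple | stats | render | simulate`); contours interchange
as JSON or DICOM RT-STRUCT, masks as NIfTI, maps as CSV (lossless) or PNG
(rendered).

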