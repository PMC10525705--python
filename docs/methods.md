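# Methods

This note records the model behind `lssdmap`, the numerical choices made
where the design was genuinely open, and what the synthetic phantoms do and
do not demonstrate about real contouring data.

## Sector signed surface distance

The disagreement between a trainee contour T and a reference contour R is
examined slice by slice. On each slice the plane is partitioned into
N = 360°/Δθ half-open angular sectors `[kΔθ, (k+1)Δθ)` about the geometric
centre of the *reference* contour — always the reference, never the trainee,
so the sector frame does not move with the trainee's errors. Sector angles
use θ = atan2(−(y−y₀), x−x₀) mapped to [0°, 360°): with DICOM head-first
supine axes (+x patient-left, +y posterior) this puts 0° at patient-left and
90° anterior, the convention a clinician expects when reading the map. This
is the single place the patient frame is interpreted
(`geometry.point_angles`).

Δθ is restricted to integer divisors of 360 (default 10°, N = 36). A
non-divisor width would leave a partial sector at the wrap-around whose
statistics differ systematically from its neighbours; restricting the choice
sidesteps the ambiguity at no practical cost.

Within a sector, both boundaries are resampled to ≤ 0.25 mm spacing
(vertices preserved, chords subdivided) and each contour's points falling in
the sector form ΔR and ΔT. The sector magnitude is the symmetric mean
surface distance |Δd| = (Δd_RT + Δd_TR)/2 with exact nearest-neighbour
queries (cKDTree). The 0.25 mm default makes the discretization error of the
mean distance well below the 0.1 mm tolerances used in the tests; a coarser
spacing is configurable and degrades accuracy roughly linearly.

**Neighbour pool.** Nearest distances are taken against the other contour's
points *within the same sector* when that set is non-empty. If the other
contour has no boundary points in the sector but still exists on the slice,
the pool falls back to that contour's full slice boundary. Without the
fallback, a contour grazing a sector boundary would contribute artificially
inflated distances measured to a nearly empty sliver of points.

**Sign.** The enclosed regions are clipped to the (convex) sector wedge and
the per-sector sensitivity P = A(R∩T)/A(R) and specificity Q = A(R∩T)/A(T)
are formed from the clipped areas. P ≥ Q gives +|Δd| (over-contoured),
P < Q gives −|Δd|; ties take the positive sign. Because the ratios share the
numerator, the comparison reduces to comparing the clipped trainee and
reference areas whenever the intersection is nonzero, which is why per-slice
areas and thin-slab volumes give the same sign for uniform slice thickness.

**Empty sectors.** Where one region is entirely absent from the wedge the
ratios are undefined (division by zero area); the sign is then forced by the
geometry: reference present / trainee absent ⇒ negative with magnitude the
mean distance from the sector's reference points to the full trainee
boundary, and mirrored for the opposite case. Sectors where both regions
miss the wedge are masked invalid and excluded from every statistic. Slices
present in only one structure beyond the other's superior/inferior extent
produce whole rows with the corresponding forced sign and magnitude equal to
the z-overshoot (slice spacing × number of slices beyond the other's
extent), with a dedicated row status so axial over/undershoot is visible in
the map rather than silently dropped. A missing *interior* slice, by
contrast, is a genuine grid mismatch and raises an error naming the z.

**Limitations.** The sector decomposition assumes the structure is
star-shaped enough that its centroid lies inside the contour; branched
structures (optic chiasm, brachial plexus) are out of scope. If the
reference centroid falls outside the reference region on a slice, the slice
is still processed but flagged in the map metadata. Only axial contours are
supported. A sector wedge may intersect a non-convex region in several
pieces; areas and boundary points are pooled over all pieces.

Map values are stored unclipped; the ±3 mm saturation exists only in
rendering.

## Reference fusion (STAPLE)

The reference is not a gold standard: it is the STAPLE consensus of the
trainee contour fused together with the expert panel, recomputed on every
map update. Binary STAPLE EM is implemented directly on the rater decision
matrix (log-space E-step, closed-form M-step; `staple.py` documents the
update equations). Choices:

- **Initialization** p_j = q_j = 0.99999; **convergence** when the relative
  change of ΣW falls below 1e-6, max 100 iterations. On the test phantoms
  convergence takes well under 10 iterations and the log-likelihood is
  checked non-decreasing.
- **Prior** γ: "auto" = mean foreground fraction of the rater masks over the
  working region; a fixed value can be supplied (γ = 0.5 reproduces majority
  voting for equal-performance raters).
- **Working region**: union of rater foregrounds dilated by 5 voxels.
  Estimating specificity against an entire scan volume inflates q_j toward 1
  and degrades the consensus — a known STAPLE pitfall; restricting the
  region keeps the background relevant. Consensus probability outside the
  region is 0.
- **Rasterization**: contours are rasterized at 1×1 mm in-plane (voxel-centre
  point-in-polygon tests) at the native slice spacing; the consensus is
  thresholded at 0.5 and traced back to polygons by marching squares at the
  iso-0.5 level. STAPLE is run once in 3D per structure rather than per
  slice: a single performance estimate per rater is the natural reading of
  one expert delineating one organ, and it shares strength across slices.
  SimpleITK's independent STAPLE filter agrees with this implementation on
  voxel-flip phantoms (cross-checked in the test suite).
- The session object keeps the fused reference and the expert panel private;
  the only artifact returned to the trainee path is the LSSD map, mirroring
  the training protocol in which neither expert contours nor the reference
  are ever displayed.

At least three expert raters are required; with eight identical experts and
one deviant trainee the consensus Dice against the experts' contour exceeds
0.99, i.e. a far-off trainee cannot drag the reference toward themselves.

## Session statistics

Each map is summarized by the mean and sample standard deviation (n−1
denominator; the population/sample choice is unstated in common practice and
immaterial at hundreds of cells, but it is fixed and documented here) of its
valid cells, plus a histogram with 0.5 mm bins, one bin centred on zero
(cosmetic only — statistics use the raw values). ΔLSSD_SD = SD(initial) −
SD(final) is tested with a two-tailed F test: F is the larger sample
variance over the smaller with matching (n−1, n−1) degrees of freedom and
p = 2·min(CDF, 1−CDF), significant at p < 0.05. Treating map cells as
independent observations overstates the effective sample size — neighbouring
sectors share contouring errors — and is reproduced deliberately because the
feedback protocol defines its training-effect measure this way; the p-values
should be read as descriptive of the protocol, not as rigorous spatial
inference. Zero-variance maps make F degenerate and are flagged rather than
tested. Aggregation across cases/trainees pools all valid cells into one
distribution.

## Synthetic phantoms

The generator produces what the analysis needs and nothing it cannot verify:

- `make_tube`: circular/elliptical tubes as 128-gons (area within 0.2% of
  the analytic value), default cross-sections of 25–50 mm radius at 3 mm
  slice spacing — the scale of a heart or left ventricle on chest CT.
- `perturb`: smooth radial noise, a random Fourier series in the boundary
  angle with harmonics 1..3 and coefficients scaled so the pooled radial
  deviation SD equals the requested amplitude. Low harmonics emulate the
  smooth, spatially correlated disagreement of human raters rather than
  white vertex jitter. Expert panels default to 1–1.5 mm radial SD and
  trainee noise starts at 3 mm, matching the few-mm initial LSSD_SD spread a
  feedback session is meant to reduce.
- voxel-flip raters (`flip_rates`/`flip_raters_from_mask`): i.i.d. voxel
  flips realizing exact sensitivity/specificity, the regime in which STAPLE
  parameter recovery has a known answer (0.95/0.98 on a 64×64×16 grid in the
  recovery studies).
- `simulate_session`: a trainee whose radial noise decays geometrically
  (default factor 0.5 over 6 updates) against a fixed 8-expert panel, with
  the reference re-fused per update — the converging-session trajectory; a
  decay of 1 models a non-improving trainee and yields no significant
  ΔLSSD_SD.

What passing these tests shows: the sector metric, sign rule, fusion and
statistics behave exactly as specified on geometry with known answers. What
it does not show: performance on real anatomies with ambiguous image
contrast, raters with spatially structured (non-stationary, correlated)
error, or non-star-shaped structures — none of which the phantoms emulate.
Test problem sizes (single- to 10-slice tubes, 64×64×16 fusion grids, 20
oracle cases) were chosen as the smallest geometries on which every property
is non-trivially exercised.

## Numerical notes

- Sector wedges are built as convex polygons with the arc chords placed
  slightly beyond the needed radius so clipping is conservative; the
  brute-force validator instead clips with exact half-planes
  (Sutherland–Hodgman) and the two routes agree to < 1e-9 mm on the
  distances.
- Sector membership is half-open in angle; a boundary point exactly at the
  origin is assigned sector 0 with a warning.
- Degenerate rings (< 3 vertices or near-zero area) are rejected at
  construction; self-intersections are cleaned via buffer(0).
- CSV map serialization is lossless for values and validity; the JSON
  sidecar carries Δθ, labels, per-cell statuses and the session sequence
  index.
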