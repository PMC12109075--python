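# Methods

## Signal model and conventions

A CINE-PC acquisition is modelled as 32 magnitude/phase image pairs over
one cardiac cycle, indexed `(frame, row, col)` with frame 0 at the R-wave.
Through-plane velocity is linear in phase, `φ = π·v/Venc`, wrapped to
[−π, π); flow toward the heart is positive, so ascending arteries carry
negative velocities and are re-oriented positive at the flow-curve stage.
The unit constant 0.6 (cm/s·mm² → mL/min) is computed exactly as
`10 mm/s · 60 s/min / 1000 mm³/mL`.

Native storage is a pair of 4D NIfTI volumes plus a JSON sidecar
(`venc_cm_s`, `pixel_area_mm2`, `rr_ms`, `plane`). Vendor DICOM phase
dialects are out of scope; the linear π-mapping is the package's canonical
phase convention.

## Phantom generator

The generator emulates the features of real neck/head CINE-PC that the
analysis must survive, with exact ground truth:

* **Vessels** are circular cross-sections rasterised on a 4× supersampled
  grid and averaged down, so edge pixels carry the correct lumen coverage
  and the pixel velocity is the lumen-mean velocity scaled by coverage
  (plug-flow approximation). Default grid 96×96 px of 1×1 mm².
* **Waveforms** prescribe the lumen-mean velocity at each of the 32 frames.
  The arterial shape is a narrow systolic Gaussian (peak near frame 8 of
  32) plus a small dicrotic bump; the venous shape is a gentle
  quasi-sinusoid with a mild second harmonic. Both are scaled so the
  implied flow curve attains the requested mean flow and pulsatility index
  exactly; a PI so large that flow would reverse is rejected as infeasible.
* **Background offset**: a temporally static, spatially smooth 2D
  polynomial velocity offset (eddy-current-like), expressed directly in
  cm/s, bounded by ~0.05·Venc in the presets.
* **Noise**: independent Gaussian noise on the two complex channels at the
  requested SNR (lumen magnitude 1.0, tissue 0.6), giving Rician magnitude
  and phase-derived velocity noise. Note that tissue pixels, having lower
  magnitude, carry ~1.7× the velocity noise of lumen pixels — this drives
  the segmentation design below.
* **Wrapping**: phase is wrapped to [−π, π), so velocities above Venc alias
  with opposite sign, exactly as acquired data would.
* **Cohorts**: per-vessel mean flows are drawn from truncated normals
  (floor 5 mL/min) with published healthy-adult moments per plane
  (e.g. right ICA 288 ± 47 mL/min cervically, right IJV 329 ± 168,
  left IJV 207 ± 134); epidural veins are present with probability 28/36
  (right) and 27/36 (left); vessel centers get ±0.5 px sub-pixel jitter
  (vessels are never pixel-aligned in vivo). Published tables do not
  report lumen areas, so preset radii are a modelling choice derived from
  those flows and typical lumen-mean velocities (arterial means
  ~10–20 cm/s, peaks of a few tens of cm/s); the independent left/right
  jugular sampling spreads subjects across all three dominance classes.
* The ground-truth lumen mask uses a coverage threshold of 0.3 — the same
  relative boundary the default segmentation recovers — so that noiseless
  segmentation and the truth mask agree at a supersampling-consistent
  boundary. True curves are waveform × rendered lumen area (coverage sum),
  which matches π·r² to well under 1 %.

What the phantom does **not** model: k-space/coil effects, vessel wall
motion and caliber change over the cycle, non-circular lumina, laminar
velocity profiles (plug flow only), respiration, and motion artifacts.
Passing tests therefore demonstrate correctness of the *processing* under
realistic noise, offsets, partial volume and aliasing — not robustness to
every in-vivo confound.

## Segmentation

A pixel belongs to a vessel if its velocity waveform carries cardiac-
frequency power: the criterion map is the fundamental DFT amplitude
`A = 2|DFT₁(v)|/32` (optionally root-sum-square of the first harmonics; DC
excluded). From one operator seed, a single 4-connected region grows over
pixels whose score reaches `rel_threshold` (default 0.3) of the region's
maximum score. Details that matter:

* The region maximum is read off a 3×3-mean-smoothed map. The lumen
  interior is a plateau, so this estimate is unbiased while suppressing
  the upward bias of a pointwise max under noise, which would otherwise
  silently raise the effective threshold and shave partial-volume edge
  pixels (a few percent of flow).
* The running maximum is monotone non-decreasing across growth iterations,
  so the procedure converges and the final mask is a property of the
  vessel, not of the seed position — the basis of the operator-robustness
  bound.
* An absolute floor of 2× the amplitude-noise scale (estimated from the
  map median via Rayleigh statistics) prevents growth through background;
  occasional accreted noise pixels are harmless for flow because they
  carry ≈ zero net velocity.
* **Low-pulsatility fallback.** When the seed's spectral amplitude is
  below 6× the noise scale, a partial-volume edge pixel is statistically
  indistinguishable from background on the amplitude map, and no threshold
  can be both inclusive and flood-safe. Such vessels (low-PI veins) are
  grown instead on |temporal-mean velocity| flattened by a 25×25 median
  filter — the local flattening removes the smooth background offset so it
  can neither flood the growth nor shift the threshold. The ROI records
  which criterion was used. A seed with neither spectral amplitude nor
  mean velocity above the floors raises "no vessel at seed"; the pipeline
  records such vessels as undetected (they contribute zero flow and are
  flagged missing), mirroring how anatomically absent or sub-threshold
  veins appear in real cohorts.
* Masks are fixed across all 32 frames by design; per-frame contours are a
  non-goal.

## Aliasing correction

Within an ROI of known dominant direction, samples of opposite sign are
shifted by 2·Venc toward the dominant direction when the candidate lands in
(Venc, 2·Venc]. Double wrapping is out of contract (such an acquisition
must be repeated at higher Venc). Two refinements:

* `min_opposing_frac` (pipeline default 0.2): opposing samples with
  |v| ≤ 0.2·Venc are treated as genuine near-zero flow. Without the guard,
  a noise sample crossing zero in a slow vein is moved by 2·Venc — a
  catastrophic single-sample bias; any truly wrapped peak below
  1.8·Venc still clears the guard. The plain sign rule is the
  `min_opposing_frac = 0` limit.
* Wrap-around near the systolic peak can *suppress* a pixel's cardiac
  amplitude (the wrapped frames interfere destructively with the
  fundamental), so the first-pass mask may miss aliased lumen pixels. The
  pipeline therefore unaliases a 2-px dilation of each ROI and re-grows
  any vessel whose samples changed, on the corrected field.

## Background correction

Static reference tissue is sought in a Chebyshev annulus (default 3–10 px)
around the ROI bounding box: temporal-mean magnitude ≥ 0.3× the median
in-ROI magnitude (excludes air) and temporal velocity SD ≤ 0.05·Venc
(excludes flowing blood); all vessel ROIs, dilated by 2 px to cover the
partial-volume halo, are excluded. Fewer than 20 qualifying pixels is an
error. The mask's mean velocity is subtracted everywhere, making static
tissue the exact zero reference; re-estimation on the corrected series
returns ≈ 0.

The pipeline applies this **per vessel** (annulus around each vessel,
other ROIs excluded) rather than once per slice: a spatially varying
offset differs between vessel sites by up to a few cm/s across the slice,
which alone would exceed the accuracy budget of slow veins, while a local,
roughly symmetric annulus also cancels the linear component of the offset
gradient. The function itself accepts any ROI list, so a single
slice-level scalar remains available.

Order contract: unalias before offset estimation (the estimate assumes an
unwrapped field near the vessels).

## Flow, compartments, dominance

Flow curves integrate the corrected velocity over the fixed mask. The PI
uses signed flows; non-positive-mean curves are rejected rather than
silently flipped (`negate` orients arteries positive). Compartments are
framewise sums; members without a measured curve contribute zero and are
flagged missing, never imputed. Dominance ratios divide the pathway mean
(jugulars extracranially; straight + superior sagittal sinus
intracranially) by the **arterial** compartment mean by default — the
venous-denominator variant is exposed as an option since both conventions
circulate. Boundary ratios of exactly 0.40 or 0.60 classify as balanced
(the 40–60 % band is read as inclusive; only measure-zero inputs are
affected). Group comparisons use the pooled-variance two-sample t-test
(df = n_a + n_b − 2, two-sided) with no multiple-comparison correction, by
design.

## Numerical and design choices

* Truncated-normal flow sampling floors at 5 mL/min; a sampled vein too
  slow to detect at the plane's Venc is a realistic outcome, handled as
  undetected rather than an error.
* Region growth iterates to a fixed point with a hard cap of 20
  iterations (always converges far earlier).
* `flow_curve` sums are float64; "exact" linearity holds up to summation
  order (~1e-13 relative).
* Direction sign ties (ROI-mean velocity exactly 0) resolve to +1.
* All randomness flows through `numpy.random.SeedSequence` spawning, so
  subjects are independent and every result is bit-reproducible given the
  seed.

## Benchmarks and problem sizes

The validation benchmark (`cineflow.validation`, used by
`scripts/acceptance.py` and the acceptance tests) renders four-vessel
subjects at Venc 60 cm/s, SNR 15: one artery with wrapped systolic peaks
(~60–85 cm/s), one unwrapped artery, a large and a small vein
(PI 0.5–0.7, mean velocities 8–13 cm/s), radii drawn from 3–6 px, and
polynomial offsets bounded by 0.05·Venc. Velocity ranges follow the
matched-Venc acquisition logic (a vein read at Venc 5 in practice is
represented at a velocity measurable at the rendered Venc). Accuracy uses
100 subjects (worst-vessel mean-flow error vs truth, observed ≈ 7–8 %,
dominated by partial-volume edge pixels); operator robustness uses 20
subjects × 5 random in-lumen seeds (worst spread ≈ 2–4 %). Cohort-level
tests use 200 subjects for distributional checks and ~40 for end-to-end
classification agreement; these sizes keep the full suite within a few
minutes on one CPU while leaving the statistics stable across seeds.

## Known limitations

* Fixed plug-flow phantoms cannot probe errors from intra-lumen velocity
  profiles or vessel motion; the fixed-ROI method is known to be biased
  low by partial volume for small vessels (visible in the benchmarks).
* The sign-based aliasing rule assumes a vessel does not genuinely reverse
  beyond `min_opposing_frac`·Venc during the cycle.
* The static-tissue criteria assume some tissue within the annulus; a
  vessel surrounded by air (or other vessels) raises an explicit error.
* No multi-wrap unwrapping, no spatial phase-unwrapping, no per-frame
  contours, no k-space simulation.
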