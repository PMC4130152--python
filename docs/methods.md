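# Methods

This note records the model, the parameter choices, the numerical
conventions, and the known limits of `wmh3d` — the things a maintainer
would want explained rather than re-derived.

## The detection model

The pipeline treats a 3D FLAIR volume `v(x)` as

    v(x) = b(x) · t(x) + n(x)

with `b` a smooth multiplicative bias field (mean ≈ 1), `t` the piecewise
tissue signal (CSF ≪ WM < GM ≤ lesion), and `n` additive Gaussian noise.
Lesions are bright, blob-like, and embedded in WM; the two systematic
confounds are the bias field and thin bright cortical GM.

**Bias correction (homodyne).** `b` is estimated as the slice-wise
k-space Hanning low-pass of the edge-extrapolated image, normalised by
the modal brain intensity κ of that low-pass image, so `b ≈ 1` in modal
tissue and `u = v/b` keeps the scanner intensity scale. The
extrapolation (20 iterations of in-plane 3×3 grayscale dilation beyond
the brain edge) suppresses the ringing a hard brain/air edge would
inject. Homodyne filtering is cheap and deterministic, but it is *not*
anatomy-blind: dark CSF and bright lesions leak into the low-pass
estimate. On the structureless uniform head (where the field is the
only smooth modulation) the estimate correlates with the truth field at
≈ 0.99; on the full anatomy phantom the correlation drops to ≈ 0.85
over WM (≈ 0.6 over the whole brain, where ventricular CSF dominates
the error). The residual expresses itself as a halo of over-corrected
WM around the ventricles; two downstream guards (the small-path CSF
distance rule and the region-growing cap, below) exist specifically to
keep that halo out of the lesion map. Iterative estimators (N3/N4) are
deliberately out of scope.

**Gray-matter suppression.** Thin structures live at high spatial
frequency, so `u' = u − λ·HP(u)` with `HP = I − LPF_hann` damps the GM
ribbon much more than lesion interiors (measured on the phantom: ~35%
mean drop over GM vs ~5% over a 10 mm lesion interior). Window sizes
are quoted in k-space pixels on the acquisition's 512 in-plane matrix
and scaled proportionally to other grids; the filter is applied per
slice. The operating point (window 130 px, λ = 1.2, threshold factor
p = 1.2) is the operating point the similarity-index sweep
(`evaluation.parameter_sweep`) selects; λ = 1.4 pairs with p = 1.0,
other λ values keep p = 1.2.

**Detection threshold.** `T = p·S_WM + 4·σ_WM`. `S_WM` is the mean of
brain-minus-CSF voxels within ±20% of the modal parenchymal intensity
(the mode-band rule makes "the WM over the entire brain" deterministic
and lesion/GM-robust). `σ_WM` is the *noise* standard deviation,
estimated as `1.4826·MAD/√2` of first differences between in-plane
neighbour pairs inside the band. The differencing matters: a plain
robust SD of the band conflates residual bias inhomogeneity with noise
(it reads ≈ 8 on a σ = 5 phantom after correction), which inflates the
threshold and fragments true lesions; the difference estimator recovers
σ to within ~1%. The 4σ multiplier is deliberately conservative —
smaller multiples admit noise tails.

**Shape and distance filters.** Candidates are removed if: smaller
than `min_lesion_vox` (10 voxels = 0.0025 mL — at a 4σ threshold over
~10⁶ brain voxels, isolated suprathreshold specks are *expected* by
chance, so a noise-size floor is a precondition for a zero-FP
specificity claim; 3 mm is also the conventional minimum lesion
diameter in MS reporting); closer than 2.0 mm to sulcal CSF (GM
remnants hug the sulci); or with FA > 0.6. FA here is the fractional
anisotropy of the intensity-weighted second-moment (inertia) tensor in
mm coordinates — 0 for blobs, → 1 for rods/sheets (a sheet scores
≈ 0.71) — computed about the weighted centroid with the standard
eigenvalue-dispersion normalisation; a single voxel is isotropic by
convention (FA = 0). All cut-offs use strict inequalities, following
their "less than" definitions.

**Small-lesion path.** Sub-0.025 mL (100 voxel) lesions are
intrinsically high-frequency and are destroyed by the suppression
filter, so they are re-detected at the same threshold in the
*unsuppressed* `u` and passed through the same filters, with one
difference: the distance rule uses sulcal ∪ ventricular CSF. This path
sees raw noise and the ventricle-wall halo, and the union rule removes
both; the cost — a genuine lesion touching the ventricle cannot enter
through the small path — is intrinsic to any CSF-distance rule and
accepted here. Components ≥ 100 voxels in this path belong to the large
path and are skipped; a voxel claimed by both paths keeps its
large-path label.

**Region growing.** Thresholding `u'` eats a rim roughly as thick as
the high-pass kernel (~1.5–2 mm), so each surviving seed is grown back
by a deterministic synchronous flood fill. Label `l` accretes
26-adjacent brain voxels with

    u ≥ max(S_WM + 2σ_WM,  S_WM + 0.4·(max_l(u) − S_WM))

within 3.0 mm of the seed. The per-seed half-max-style floor stops
growth at the lesion/WM boundary without descending into residual-bias
elevations of surrounding WM; the 3 mm reach cap encodes that growth is
*edge recovery*, not flood fill — without it a single spurious seed can
percolate through the ventricle halo (observed: 6 mL from one voxel).
Conflicts within a round resolve to the smallest label, so labels never
merge and shared plateaus partition deterministically; seeds are always
kept, and because the per-seed peak is non-decreasing under accretion,
re-growing a converged map is a no-op.

**Classification.** PVH ⇔ minimum lesion-edge distance to the
ventricular mask < 3.0 mm (strict), computed on the anisotropy-aware
Euclidean distance transform; an empty ventricle mask (extraction
failure) is a warning, not an error — every lesion then reports
distance ∞ and class DWMH.

## Parameters that matter

| parameter | default | unit | notes |
|---|---|---|---|
| LPF window (bias) | 32 | k-px @512 | smaller = smoother field estimate |
| dilation iterations | 20 | — | ×3×3 in-plane; ~10 mm extrapolation at 0.5 mm |
| κ bins | 256 | — | mode of 1st–99th percentile histogram; ties → lowest bin |
| HP window | 130 | k-px @512 | suppression filter; the calibrated optimum |
| λ | 1.2 | — | suppression weight; pairs with p |
| p | 1.2 | — | WM baseline factor in the threshold |
| noise multiplier | 4 | σ | conservative, per the threshold design |
| FA cut | 0.6 | — | rods/sheets removed above this |
| sulcal distance cut | 2.0 | mm | strict `<` |
| PVH distance | 3.0 | mm | strict `<` |
| small-lesion gate | 100 | voxels | = 0.025 mL at 0.5×0.5×1.0 mm |
| min lesion size | 10 | voxels | noise floor, both paths |
| erosion radius | 25 | mm | ventricle isolation (= 50 px at 0.5 mm) |
| growth floor | 2σ / 40% peak | — | whichever is higher |
| growth reach | 3.0 | mm | suppression-rim thickness bound |

## Numerical conventions

- All morphology with mm radii is realised through the Euclidean
  distance transform with anisotropic sampling (exact up to
  voxel-centre discretisation); connected components use 6-connectivity
  for CSF/ventricles (conservative against diagonal leakage) and
  26-connectivity for lesions (blobs should not fragment).
- The Hanning windows are raised cosines centred exactly on the DC bin
  (gain exactly 1 there), zero outside their full width; constant
  images are therefore exact fixed points of both filters and of the
  bias correction on a full-grid mask.
- Otsu thresholds maximise between-class variance on a 256-bin
  histogram and return the first bin edge of the maximal plateau (the
  criterion is exactly flat across empty bins between classes; a
  relative-tolerance tie rule keeps the choice independent of float
  summation order).
- Candidate labels are ordered by decreasing size (stable for ties);
  "largest component" ties resolve to the lowest label id.
- `b` is floored at 0.05 before division — this only binds outside the
  dilated band and keeps `u` finite everywhere.
- Every stage is a pure function of (input, config); identical inputs
  give byte-identical outputs, and all stochastic inputs (phantoms)
  are seeded.

## The phantom, and what passing it does not show

`phantom.generate_phantom` builds an ellipsoidal head (default
160×160×96 at 0.5×0.5×1.0 mm — the target acquisition's in-plane
resolution at desk scale) with: narrow radial sulcal CSF fissures
(2.4 mm wide, 4 mm deep, a quarter of each angular period — real sulci
are narrow relative to gyri, and an unbroken dark shell would make any
intensity-based brain mask impossible); a 1.5 mm GM ribbon lining the
outer surface and fissure walls; a central connected ventricular
ellipsoid; planted ellipsoidal lesions (defaults: five ≥ 0.05 mL, two
of them periventricular at 1 mm gap, plus one 0.012 mL small-path
lesion); a mean-1 smoothed-noise bias field (amplitude 0.2, scale
40 mm); and additive Gaussian noise (σ = 5 against WM = 100, CSF = 40,
GM = 130, lesions = 180). Lesion placement is validated at generation
time (inside deep WM, pairwise disjoint, > 2 mm from sulcal CSF) so the
ground truth is never ambiguous under the pipeline's own removal rules.
`phantom.uniform_head` is the structureless variant used for
bias-estimator consistency checks.

What the phantom does *not* emulate: cortical folding beyond wedge
fissures, partial-volume voxels (lesion edges are hard), Rician noise
statistics, MR contrast physics (TR/TE/TI), motion, and pathology
heterogeneity. Passing the phantom suite therefore demonstrates the
algorithm's internal correctness and its robustness to the modelled
confounds (bias, noise, bright thin GM, dark CSF) — it does not certify
clinical-grade accuracy on scanner data, where skull stripping, subtler
contrast and partial volume dominate the error budget.

## Known limitations

- The brain-extraction surrogate assumes skull-free or
  high-brain/background-contrast data; real acquisitions should supply
  a mask from a dedicated tool (`--brain-mask`).
- Homodyne bias estimation is anatomy-confounded near CSF and lesions
  (see above); the guards contain, not remove, the effect.
- Lesions adjacent to CSF can be falsely removed by the distance rules,
  and small lesions touching the ventricle are unrecoverable by the
  small-lesion path.
- The 25 mm erosion assumes an adult-scale head; small heads lose the
  ventricle mask and degrade to all-DWMH (by design, with a warning).
- Filter windows scale with the in-plane matrix, but the operating
  point (130 px, λ = 1.2) was tuned for the target acquisition; a
  different protocol warrants re-running the sweep.
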