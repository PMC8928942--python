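# Methods

This note records the model, the conventions, the tunable parameters, the
numerical choices, and what the synthetic generators do and do not emulate.

## Conventions

* Images are m×m float arrays; row = y (down), column = x (right).
* The rotation/polar center is the pixel at 0-based index (m//2, m//2) on
  both axes, so the translational correlation of an image with itself peaks
  exactly at the center position and maps to zero shift.
* Positive angles rotate counter-clockwise in the y-up mathematical frame.
* Translation is implemented as Fourier phase modulation: exact for
  band-limited content, circular at borders (integer shifts equal `np.roll`).
  Rotation is real-space bilinear resampling with zero fill.
* `estimate_rotation(ref, img)` / `estimate_shift(ref, img)` return the
  *correction* — the parameters that warp `img` onto `ref` — which is what
  the joint loop consumes.

## Rotational alignment

The polar resampling uses radii 1..m//2 (the center pixel carries no angular
information) at 1° steps, bilinear, zero outside the image; this covers
exactly the inscribed disc, which is the rotation-invariant region of a
square image. Both polar maps are 2-D FFT'd, multiplied (one conjugated),
inverse-transformed, and the absolute value taken. The radial axis of the
correlation surface is circularly shifted by half its length to center the
energy; the angle is read from the *column* of the peak, which is left
uncentered so column 0 is 0°. Raw angles fold into [−180°, 180°]
(values above 180° have 360° subtracted).

The cross-correlation uses the raw spectra, not phase-only normalization —
the printed form of the method. Consequences are discussed under
*Limitations*.

## Translational alignment

Plain FFT cross-correlation with the real part taken (the imaginary part of
the inverse transform is floating-point noise for real inputs) and
`fftshift` centering. The 1-based peak position (x, y) maps to displacements
δx = ⌊m/2⌋ − x + 1 (and likewise δy); the sign convention is such that the
raw value is the displacement of the test image, and its negation is the
correction returned.

## Peak refinement

An 11×11 patch centered on the integer argmax (ties: smallest row, then
column) is interpolated onto a 101×101 grid — i.e. 0.1-unit steps — with a
tensor-product not-a-knot cubic spline (`CubicSpline` per axis), the same
interpolant family as MATLAB's `interp2(..., 'spline')`. The angular axis
wraps circularly; on non-periodic axes the window slides inward at borders
(a translational peak near the border would mean a shift near m/2, far
outside the supported range). Interpolated estimates are therefore exact
multiples of 0.1. A perfectly flat patch is reported degenerate and the
coarse peak is kept. If spline overshoot ever placed the patch argmax
further than 0.5 grid units from the coarse peak, the search falls back to
the ±0.5 window around it — never observed on real correlation surfaces, but
it makes the refinement contract ("within half a grid unit of the coarse
peak") unconditional.

## Joint alignment

Per iteration: estimate δθ, rotate the working copy; estimate (δx, δy),
shift it. Accumulation rotates the running shift vector by each new δθ
before adding the new correction, so that one final composition
`shift(rotate(M, Δθ), Δx, Δy)` applied to the original image reproduces the
iteratively warped copy without stacking interpolation error. The loop stops
early when consecutive corrections are identical (at 0.1 resolution,
|change| < 1e-6 is equality), or after `max_iter` = 10 iterations. On
structured 256×256 test images the loop converges in 4–7 iterations.

## Classification

* **Similarity** (Pearson over all pixels) is computed after jointly
  aligning each pair; the matrix is symmetric with unit diagonal. The
  correlation is undefined when either image is constant, and the code
  raises in that case.
* **k** is chosen adaptively as ⌊√N⌋ + NS, capped at N − 1, with NS = 5.
  (The printed adaptive rule in the source method is not usable verbatim —
  it exceeds N — so the standard √N form is used and exposed as
  `k_override`.)
* **SNN graph**: KNN(i) excludes i itself (self-similarity would consume one
  slot identically for every image); counts(i,j) = |KNN(i) ∩ KNN(j)|; an
  edge requires *strictly more than* NS shared neighbors.
* **Spectral step**: symmetric-normalized affinity D^{−1/2}AD^{−1/2} of the
  non-isolated subgraph, eigenvectors of the n_classes largest eigenvalues,
  row-normalized, clustered by k-means with a fixed seed (n_init = 10), so
  the partition is deterministic given the seed. Isolated vertices make the
  normalized Laplacian undefined, so they are attached afterward to the
  class of their most similar clustered image.
* **Averaging**: members are re-aligned onto the class medoid (the member
  with the largest within-class similarity sum). Weights are the
  post-alignment similarities to the medoid, the medoid itself enters with
  weight 1, and the default denominator 1 + ΣS makes the weights a convex
  combination (a singleton class returns its medoid exactly). The
  non-normalizing literal denominator ΣS is available as `eq9_literal=True`.

## Synthetic data — what it emulates, what it does not

* `make_phantom` stands in for a natural 256×256 test photograph: a faint
  planar gradient (±0.05 across the image) plus two weak broad Gaussian
  blobs (σ ≈ m/20–m/12) and ten narrow ones (σ ≈ m/80–m/30, floored at 2 px
  so small images stay resolvable), all inside 0.35·m of the center. The
  mixture of scales matters: fine detail makes the rotational
  autocorrelation drop below 0.95 for every rotation in 5°–355° (each trial
  has a unique answer), while the coarse blobs stabilize the first rotation
  estimate when the image is also shifted. All-narrow phantoms met the
  asymmetry bound but produced occasional gross joint-alignment failures.
* `project_volume` projects an asymmetric anisotropic 3-D Gaussian mixture
  analytically (a rotated Gaussian marginalizes to the xy block of its
  rotated covariance), so clean projections are exact — no voxel grid, no
  projection interpolation. Uniform SO(3) rotations come from normalized
  quaternions.
* `add_noise` implements SNR = var(signal)/var(noise) with white Gaussian
  noise; SNR 0.1 means noise variance ten times the clean image's.
* Not emulated: CTF, detector/ice statistics, correlated noise, particle-
  picking offsets beyond the stated shift ranges, and the scale of real
  datasets (10⁴ images). A green planted-view test therefore establishes the
  pipeline's correctness, not its behavior on real micrographs.

## Known limitations

* **Background-gradient translation bias.** The translational correlation is
  unnormalized, and rotation zero-fills corners. When a test image is
  rotated, the corners of the square reference have no counterpart in the
  warped copy; any strong planar background there pulls the correlation
  peak, producing a constant ~0.5 px bias along the gradient direction
  (observed with a ±0.15 gradient; negligible at ±0.05). Natural photographs
  and background-subtracted particles have weak planar components, so the
  effect is mostly a synthetic-image hazard; masking or phase-only
  correlation would remove it but are not part of the method.
* **Joint trials can hit a wrong rotation optimum** (≈0–4 per 100 trials
  depending on the phantom realization) when fine structure offers a
  competing alignment; errors are then large (tens of degrees), not
  marginal. The source method reports the same failure mode on real data.
* Fractional Fourier shifts project the Nyquist bin onto its real part, so
  shift(+v) followed by shift(−v) reproduces the input only to ~1e-3 of the
  dynamic range, not bitwise.
* The all-pairs similarity matrix is O(N²) joint alignments; at N = 10⁴ a
  reference- or landmark-based scheme would be required. `run_pipeline` is
  intended for desk-scale stacks (N ≲ a few hundred).
* Labels are 0-based; empty classes are possible (k-means may leave a
  centroid unused) and are reported rather than repaired.
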