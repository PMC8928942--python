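# freqalign

Frequency-domain image alignment and spectral-clustering 2-D class averaging
for single-particle cryo-EM projection images.

## The problem

Single-particle cryo-EM records thousands of extremely noisy 2-D projections
of the same macromolecule from unknown directions. Before any 3-D
reconstruction, images that show (nearly) the same view must be found,
brought into register — estimating an in-plane rotation Δθ and translations
(Δx, Δy) for every image — and averaged, so that independent background noise
cancels and the common signal is reinforced. Exhaustive real-space alignment
is accurate only to the search step and far too slow for large stacks.

`freqalign` is for method developers and practitioners who need fast,
subpixel/subangle 2-D alignment and a simple, single-pass classification
pipeline that runs on a laptop, plus fully seeded synthetic data to validate
every stage without downloading a map.

## The method

**Rotation.** An m×m image `M` is resampled onto a polar grid
(⌊m/2⌋ radii × 360 angles); a rotation of the image becomes a circular shift
along the angular axis. With `F_i = fft2(polar(M_i))`, the correlation
surface

```
C = abs(ifft2(F_i · conj(F_j)))
```

peaks at the column encoding the relative rotation (read at 1° resolution).

**Translation.** Standard phase-correlation: `C = Re ifft2(fft2(M_i) ·
conj(fft2(M_j)))`, fftshift-centered; the peak offset from the center
position (⌊m/2⌋+1, ⌊m/2⌋+1) is the integer-pixel shift.

**Subgrid refinement.** The 11×11 patch around either peak is interpolated
with a not-a-knot bicubic spline onto a 101×101 grid (0.1-unit steps); the
interpolated argmax gives 0.1° / 0.1 px estimates. With refinement the
estimator is called *interpolated* (`interpolate=True`, the default);
without it, estimates are integers.

**Joint alignment.** Rotation and translation are coupled, so the two
estimates alternate (rotate-correct, then shift-correct) for at most 10
iterations, stopping early when the per-iteration corrections stop changing.
Parameters are accumulated so the final aligned image is produced from the
*original* input by a single `shift(rotate(M, Δθ), Δx, Δy)` — no stacked
interpolation blur.

**Classification.** All pairs are aligned to build a Pearson similarity
matrix S; each image keeps its k = ⌊√N⌋ + NS nearest neighbors (NS = 5);
pairs sharing more than NS neighbors become edges of a binary graph; the
normalized spectral clustering algorithm (symmetric-normalized affinity,
top-k eigenvectors, seeded k-means) partitions the graph; every class is
re-aligned onto its medoid and averaged with similarity weights
`(Σ_i S(i,j)·M_i + M_j) / (1 + Σ_i S(i,j))`.

## Worked example

```python
from freqalign import make_phantom, perturb, joint_align, similarity

ref = make_phantom(m=256, n_blobs=12, seed=0)       # structured test image
test = perturb(ref, theta=25.0, dx=3.0, dy=-2.0)    # shift first, then rotate

params, aligned = joint_align(ref, test)
print(params)
print(similarity(ref, test), similarity(ref, aligned))
```

prints

```
AlignmentParams(theta=-25.0, dx=-2.9930004201429234, dy=2.110459769561252,
                n_iter=4, converged=True)
0.4743444938537267 0.7846437690384537
```

The estimator recovers the exact inverse rotation (−25.0°), the x-shift to
0.007 px and the y-shift to 0.11 px in 4 iterations, and raises the
correlation with the reference from 0.47 to 0.78 (the residual is the
interpolation loss and the zero-filled corners, not misalignment).

The same works from the shell:

```bash
freqalign simulate --mode both --m 256 --n 100 --seed 0 --out trials.csv
freqalign make-stack --views 3 --per-view 30 --snr 0.5 --out stack.mrcs
freqalign classify --stack stack.mrcs --n-classes 3 --out-dir results/
```

`freqalign benchmark` prints the absolute-error frequency tables for all
three simulations (rotation-only, shift-only, shift-then-rotate), with and
without spline refinement.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the structured phantom from the given seed, reruns the three
simulations (100 one-decimal trials each: rotations uniform in [−180°, 180°],
shifts uniform in [−m/10, m/10], joint trials shifted in [−m/20, m/20] then
rotated), and writes, per experiment, the count of trials whose interpolated
estimate lands in the [0, 0.5) absolute-error bin (rotation angle; x and y
shift; joint-trial angle and x shift).

See `docs/methods.md` for assumptions, parameter choices, numerical details
and known limitations.
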