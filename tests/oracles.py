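"""Independent real-space oracles used only by the tests.

These are the brute-force exhaustive searches: rotate or roll the test image
through every candidate on a 1-degree / 1-pixel grid and pick the best
Pearson correlation. Deliberately slow and simple: they share no code path
with the frequency-domain estimators they check.
"""

import numpy as np

from freqalign.imageops import rotate_image


def pearson(a, b) -> float:
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])


def exhaustive_rotation(ref, img, step: float = 1.0):
    """Angle in [-180, 180) maximizing real-space correlation after rotation."""
    best, barg = -np.inf, None
    for d in np.arange(-180.0, 180.0, step):
        c = pearson(ref, rotate_image(img, float(d)))
        if c > best:
            best, barg = c, float(d)
    return barg


def exhaustive_shift(ref, img):
    """Integer (dx, dy) maximizing correlation over all circular rolls."""
    ref = np.asarray(ref)
    m = ref.shape[0]
    best, barg = -np.inf, None
    for dy in range(-m // 2, m // 2):
        rolled_y = np.roll(img, dy, axis=0)
        for dx in range(-m // 2, m // 2):
            c = pearson(ref, np.roll(rolled_y, dx, axis=1))
            if c > best:
                best, barg = c, (dx, dy)
    return barg
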