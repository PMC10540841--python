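"""Independent brute-force reference implementations used only by tests.

These deliberately use naive per-pixel / per-cell Python loops and share no
code with the package internals.
"""

import math

import numpy as np


def hog_bruteforce(image, cell=8, block=2, nbins=9, clip=0.2):
    """Naive HOG: per-pixel gradient votes, per-block L2-Hys, loops only."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    ncy, ncx = h // cell, w // cell

    def px(i, j):
        return image[min(max(i, 0), h - 1), min(max(j, 0), w - 1)]

    hist = np.zeros((ncy, ncx, nbins))
    binw = math.pi / nbins
    for i in range(ncy * cell):
        for j in range(ncx * cell):
            gx = 0.5 * (px(i, j + 1) - px(i, j - 1))
            gy = 0.5 * (px(i + 1, j) - px(i - 1, j))
            mag = math.hypot(gx, gy)
            ang = math.atan2(gy, gx) % math.pi
            f = ang / binw
            i0 = int(math.floor(f))
            frac = f - i0
            hist[i // cell, j // cell, i0 % nbins] += mag * (1.0 - frac)
            hist[i // cell, j // cell, (i0 + 1) % nbins] += mag * frac

    out = []
    for by in range(ncy - block + 1):
        for bx in range(ncx - block + 1):
            v = []
            for cy in range(block):
                for cx in range(block):
                    v.extend(hist[by + cy, bx + cx])
            v = np.array(v)
            n1 = math.sqrt(float((v**2).sum()))
            if n1 < 1e-12:
                v = np.zeros_like(v)
            else:
                v = v / n1
                v = np.minimum(v, clip)
                n2 = math.sqrt(float((v**2).sum()))
                v = np.zeros_like(v) if n2 < 1e-12 else v / n2
            out.extend(v)
    return np.array(out)


def yates_chi2_bruteforce(table):
    """Sum over cells of (max(|O-E|-0.5, 0))^2 / E, p from chi2(1)."""
    from scipy.stats import chi2

    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            stat += max(abs(obs[i, j] - e) - 0.5, 0.0) ** 2 / e
    return stat, float(chi2.sf(stat, 1))
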