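"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
scans, all-pairs distances, closed forms) rather than calling the code
paths they check.
"""

from __future__ import annotations

import numpy as np


def moments_oracle(counts: np.ndarray) -> int:
    """Exhaustive moment-preserving threshold.

    For each cut the class fractions are fixed by the cumulative
    histogram and the two surrogate levels are solved so the first two
    moments match exactly; the score is the squared mismatch of the
    third moment.  At the moment-preserving cut all three moments match,
    so the argmin is the threshold.
    """
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    i = np.arange(counts.size, dtype=float)
    m1 = (p * i).sum()
    m2 = (p * i**2).sum()
    m3 = (p * i**3).sum()
    var = m2 - m1 * m1
    cum = np.cumsum(p)
    best, arg = None, None
    for t in range(counts.size - 1):
        q0 = cum[t]
        q1 = 1.0 - q0
        if q0 <= 0 or q1 <= 0:
            continue
        z0 = m1 - np.sqrt(q1 / q0 * var)
        z1 = m1 + np.sqrt(q0 / q1 * var)
        mis = (q0 * z0**3 + q1 * z1**3 - m3) ** 2
        if best is None or mis < best:
            best, arg = mis, t
    return arg


def li_oracle(counts: np.ndarray) -> int:
    """Exhaustive minimiser of the Li cross-entropy objective."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    u = np.arange(1, counts.size + 1, dtype=float)
    best, arg = None, None
    for t in range(counts.size - 1):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 1e-12 or w1 <= 1e-12:
            continue
        mu0 = (p[: t + 1] * u[: t + 1]).sum() / w0
        mu1 = (p[t + 1 :] * u[t + 1 :]).sum() / w1
        eta = -(p[: t + 1] * u[: t + 1]).sum() * np.log(mu0) \
              - (p[t + 1 :] * u[t + 1 :]).sum() * np.log(mu1)
        if best is None or eta < best:
            best, arg = eta, t
    return arg


def random_bimodal_histogram(rng: np.random.Generator, nbins: int = 256):
    """A noisy two-population histogram, as punctate images produce."""
    x = np.arange(nbins)
    mu1 = rng.uniform(20, 90)
    mu2 = rng.uniform(140, 230)
    s1 = rng.uniform(5, 25)
    s2 = rng.uniform(5, 30)
    w = rng.uniform(0.2, 0.8)
    h = w * np.exp(-((x - mu1) ** 2) / (2 * s1**2)) \
        + (1 - w) * np.exp(-((x - mu2) ** 2) / (2 * s2**2))
    return np.round(h * 1000 + rng.uniform(0, 3, nbins))


def brute_force_neighbors(psd_xy, astro_xy, k=10, radius=3.0):
    """All-pairs nearest-neighbour distances and closed-radius counts."""
    psd_xy = np.asarray(psd_xy, float).reshape(-1, 2)
    astro_xy = np.asarray(astro_xy, float).reshape(-1, 2)
    out = []
    for p in psd_xy:
        d = np.sort(np.hypot(*(astro_xy - p).T))
        kk = min(k, d.size)
        row = list(d[:kk]) + [float("nan")] * (k - kk)
        out.append((row, int((d <= radius).sum())))
    return out


def pearson_chi2_2x2(a, b, c, d):
    """Hand-expanded 2x2 Pearson statistic (ad−bc)²·n / margin product."""
    n = a + b + c + d
    return ((a * d - b * c) ** 2 * n) / ((a + b) * (c + d) * (a + c) * (b + d))
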