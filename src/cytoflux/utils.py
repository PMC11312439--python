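"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde


def find_valley(
    values: np.ndarray,
    grid_size: int = 256,
    min_prominence: float = 0.005,
    min_bandwidth: float = 0.25,
    min_peak_distance: float = 0.8,
    max_valley_ratio: float = 0.8,
    max_points: int = 20000,
    rng_seed: int = 0,
    side: str | None = None,
) -> float | None:
    """Valley between the two dominant modes of a 1-D distribution.

    A Gaussian KDE (bandwidth floored at ``min_bandwidth`` so that the
    discrete spikes of low Poisson ion counts do not masquerade as modes) is
    evaluated on a regular grid.  The split is accepted only when two peaks
    of relative prominence ``min_prominence`` lie at least
    ``min_peak_distance`` apart and the density at the valley drops below
    ``max_valley_ratio`` of the smaller peak; otherwise ``None`` is returned
    and the caller falls back to a quantile rule.  Large inputs are
    subsampled for speed.

    ``side`` constrains the secondary mode relative to the dominant one:
    ``"above"`` looks for a valley above the main mode (e.g. a doublet or
    bead shoulder), ``"below"`` for one below it (e.g. debris or a
    marker-negative population); ``None`` takes the two most prominent
    peaks wherever they lie.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10 or np.ptp(x) == 0:
        return None
    if x.size > max_points:
        rng = np.random.default_rng(rng_seed)
        x = rng.choice(x, size=max_points, replace=False)
    sd = x.std()
    if sd == 0:
        return None
    try:
        kde = gaussian_kde(x)
        if kde.factor * sd < min_bandwidth:
            kde.set_bandwidth(min_bandwidth / sd)
    except np.linalg.LinAlgError:
        return None
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    # zero-pad so modes at the grid boundary register as peaks
    padded = np.concatenate([[0.0], dens, [0.0]])
    peaks, props = find_peaks(padded, prominence=min_prominence * dens.max())
    peaks = peaks - 1
    if len(peaks) < 2:
        return None
    prom = props["prominences"]
    if side is None:
        top2 = peaks[np.argsort(prom)[-2:]]
    else:
        main = peaks[int(np.argmax(dens[peaks]))]
        if side == "above":
            cand = [(pk, pr) for pk, pr in zip(peaks, prom) if pk > main]
        elif side == "below":
            cand = [(pk, pr) for pk, pr in zip(peaks, prom) if pk < main]
        else:
            raise ValueError(f"unknown side {side!r}")
        if not cand:
            return None
        second = max(cand, key=lambda c: c[1])[0]
        top2 = np.array([main, second])
    lo, hi = sorted(int(p) for p in top2)
    if grid[hi] - grid[lo] < min_peak_distance:
        return None
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    if dens[valley] > max_valley_ratio * min(dens[lo], dens[hi]):
        return None
    return float(grid[valley])


def two_means_split(
    values: np.ndarray, min_gap: float = 1.0
) -> float | None:
    """Midpoint between the two 1-D k-means centers, if they are separated.

    Returns ``None`` when the two centers are closer than ``min_gap`` (the
    sample looks unimodal at the relevant scale) or fewer than 2 values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 2 or np.ptp(x) == 0:
        return None
    # exact 1-D 2-means: best split minimizes within-group sum of squares
    best = None
    for cut in range(1, x.size):
        a, b = x[:cut], x[cut:]
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if best is None or ss < best[0]:
            best = (ss, a.mean(), b.mean())
    _, c_lo, c_hi = best
    if c_hi - c_lo < min_gap:
        return None
    return float((c_lo + c_hi) / 2.0)
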