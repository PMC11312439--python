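"""Bead-based correction of time-varying instrument sensitivity.

EQ calibration beads spiked into every sample carry a fixed metal content,
so any temporal trend in their measured intensities reflects instrument
drift.  The correction model is multiplicative: sliding-window medians of
the bead channels are regressed through the origin against the run-global
baseline medians, giving one sensitivity slope per window; slopes are
interpolated (and linearly extended to the run boundaries) and every mass
channel is divided by the interpolated sensitivity at its event's
acquisition time.  A through-origin fit is required because zero ion counts
must map to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import (
    MASS_ROLES,
    ROLE_BEAD,
    ROLE_CERIUM,
    ROLE_DNA,
    EventTable,
)
from .panel import DEFAULT_COFACTOR
from .utils import find_valley

#: Smallest sensitivity the model will report; guards against division blow-up.
MIN_SLOPE = 0.05


class NormalizationError(ValueError):
    pass


@dataclass
class DriftModel:
    """Piecewise-linear multiplicative sensitivity over acquisition time.

    ``slope(t)`` is the fitted instrument sensitivity (1 = baseline);
    the correction factor applied to intensities is ``1 / slope(t)``.
    """

    knot_times: np.ndarray
    knot_slopes: np.ndarray
    baseline: dict[str, float]
    window: int
    bead_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.knot_times = np.asarray(self.knot_times, dtype=float)
        self.knot_slopes = np.asarray(self.knot_slopes, dtype=float)
        if np.any(self.knot_slopes <= 0):
            raise NormalizationError("sensitivity slopes must be > 0")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knot_times[0]), float(self.knot_times[-1])

    def slope_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.span
        if t.size and (t.min() < lo or t.max() > hi):
            warnings.warn(
                "event times outside the fitted drift span; "
                "clamping to the nearest endpoint"
            )
        return np.interp(np.clip(t, lo, hi), self.knot_times, self.knot_slopes)

    def correction_at(self, t: np.ndarray) -> np.ndarray:
        return 1.0 / self.slope_at(t)

    @classmethod
    def identity(cls, t0: float = 0.0, t1: float = 1.0) -> "DriftModel":
        return cls(np.array([t0, t1]), np.array([1.0, 1.0]), {}, 0)


def bead_gate_channels(table: EventTable) -> list[str]:
    """The four bead channels: Ce140 plus the three other EQ elements."""
    return table.channels(ROLE_CERIUM) + table.channels(ROLE_BEAD)


def identify_bead_events(
    table: EventTable,
    cofactor: float = DEFAULT_COFACTOR,
    fallback_quantile: float = 0.95,
) -> np.ndarray:
    """Flag EQ calibration-bead events.

    An event is flagged when it is positive on all four bead channels, with
    per-channel thresholds at the valley of the bimodal arcsinh intensity
    distribution (falling back to the given quantile when no valley is
    found).  Flagged events that look like bead-cell doublets — DNA-positive
    or antibody-positive on a majority of marker channels — are excluded.
    """
    channels = bead_gate_channels(table)
    if not channels:
        raise NormalizationError("no bead channels present in channel_meta")
    n = table.n_events
    mask = np.ones(n, dtype=bool)
    for ch in channels:
        x = np.arcsinh(table.data[ch].to_numpy(dtype=float) / cofactor)
        thr = find_valley(x)
        if thr is None:
            thr = float(np.quantile(x, fallback_quantile))
        mask &= x > thr
    if not mask.any():
        return mask

    # bead-cell doublets: beads carry no DNA intercalator and no antibody
    dna = table.channels(ROLE_DNA)
    if dna:
        x = np.arcsinh(table.data[dna[0]].to_numpy(dtype=float) / cofactor)
        thr = find_valley(x)
        if thr is not None:
            mask &= x <= thr
    markers = table.marker_channels
    if markers:
        vals = table.data[markers].to_numpy(dtype=float)
        cuts = np.quantile(vals, 0.75, axis=0)
        positive_frac = (vals > cuts).mean(axis=1)
        mask &= positive_frac <= 0.5
    return mask


def fit_drift(
    table: EventTable,
    bead_mask: np.ndarray,
    window: int = 500,
    step: int | None = None,
) -> DriftModel:
    """Fit the sensitivity curve from bead events.

    Sliding windows of ``window`` bead events (advancing by ``step``,
    default half a window) give per-channel medians; each window's
    sensitivity is the least-squares through-origin slope of its median
    vector against the global baseline medians.  Slopes are extended to the
    full acquisition span by linear extrapolation from the edge windows.
    """
    bead_mask = np.asarray(bead_mask, dtype=bool)
    channels = bead_gate_channels(table)
    if not channels:
        raise NormalizationError("no bead channels present")
    if step is None:
        step = max(window // 2, 1)
    n_beads = int(bead_mask.sum())
    if n_beads < 2 * window:
        raise NormalizationError(
            f"only {n_beads} bead events for window={window}; need at least "
            f"{2 * window} — enlarge the window or spike more beads"
        )
    tc = table.time_channel
    if tc is None:
        raise NormalizationError("no acquisition-time channel")
    t = table.data[tc].to_numpy(dtype=float)[bead_mask]
    B = table.data[channels].to_numpy(dtype=float)[bead_mask]
    order = np.argsort(t, kind="stable")
    t, B = t[order], B[order]

    baseline = np.median(B, axis=0)
    if np.any(baseline <= 0):
        bad = [c for c, b in zip(channels, baseline) if b <= 0]
        raise NormalizationError(f"bead channels with zero baseline: {bad}")

    starts = list(range(0, n_beads - window + 1, step))
    if starts[-1] != n_beads - window:
        starts.append(n_beads - window)
    knot_t, knot_s = [], []
    denom = float(baseline @ baseline)
    for s in starts:
        sl = slice(s, s + window)
        med = np.median(B[sl], axis=0)
        slope = float(med @ baseline) / denom
        knot_t.append(float(np.median(t[sl])))
        knot_s.append(max(slope, MIN_SLOPE))
    knot_t = np.asarray(knot_t)
    knot_s = np.asarray(knot_s)

    # extend to the full run span by linear extrapolation from edge windows
    t_all = table.data[tc].to_numpy(dtype=float)
    t_lo, t_hi = float(t_all.min()), float(t_all.max())
    if len(knot_t) >= 2:
        def _extrap(tq, i0, i1):
            dt = knot_t[i1] - knot_t[i0]
            if dt == 0:
                return knot_s[i0]
            return knot_s[i0] + (knot_s[i1] - knot_s[i0]) * (
                (tq - knot_t[i0]) / dt
            )
        lo_s = max(float(_extrap(t_lo, 0, 1)), MIN_SLOPE)
        hi_s = max(float(_extrap(t_hi, -2, -1)), MIN_SLOPE)
    else:
        lo_s = hi_s = float(knot_s[0])
    times = np.concatenate([[t_lo], knot_t, [t_hi]])
    slopes = np.concatenate([[lo_s], knot_s, [hi_s]])
    keep = np.concatenate(
        [[True], (knot_t > t_lo) & (knot_t < t_hi), [True]]
    )
    return DriftModel(
        times[keep], slopes[keep],
        dict(zip(channels, baseline.tolist())),
        window, list(channels),
    )


def apply_normalization(table: EventTable, model: DriftModel) -> EventTable:
    """Divide every mass channel by the fitted sensitivity at its event time.

    Event order and non-mass roles are unchanged; corrected intensities stay
    non-negative because sensitivity slopes are positive.
    """
    out = table.copy()
    tc = out.time_channel
    if tc is None:
        raise NormalizationError("no acquisition-time channel")
    corr = model.correction_at(out.data[tc].to_numpy(dtype=float))
    mass = out.mass_channels
    out.data[mass] = out.data[mass].to_numpy(dtype=float) * corr[:, None]
    out.sample_meta["bead_normalized"] = True
    return out


def bead_channel_cv(
    table: EventTable, bead_mask: np.ndarray, n_slices: int = 10
) -> float:
    """Temporal coefficient of variation of bead-channel medians.

    The run is cut into ``n_slices`` equal-count bead slices; the CV of the
    per-slice median is averaged over bead channels.  Used to quantify how
    flat the bead signal is before vs after normalization.
    """
    bead_mask = np.asarray(bead_mask, dtype=bool)
    channels = bead_gate_channels(table)
    tc = table.time_channel
    t = table.data[tc].to_numpy(dtype=float)[bead_mask]
    B = table.data[channels].to_numpy(dtype=float)[bead_mask]
    order = np.argsort(t, kind="stable")
    B = B[order]
    slices = np.array_split(np.arange(B.shape[0]), n_slices)
    cvs = []
    for j in range(B.shape[1]):
        meds = np.array([np.median(B[s, j]) for s in slices if len(s)])
        cvs.append(meds.std() / meds.mean())
    return float(np.mean(cvs))
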