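"""Sequential clean-up gating to isolate viable single cells.

The gate chain reproduces the study's manual clean-up sequence:
debarcode-confidence filtering (see :mod:`cytoflux.debarcode`), then

1. **singlets** — joint density core of Event_length vs Center;
2. **viability** — DNA-intercalator-positive interval (debris below,
   aggregates above);
3. **bead residual** — remove Ce140-high events (beads that survived
   normalization);
4. **microglia** — CD11b/CD45 double-positive quadrant;
5. **GFAP-negative** — drop residual astrocyte contaminants.

Astrocytes are isolated by the complementary GFAP-positive gate applied
after the first three gates.  Thresholds default to automatic valley
detection on the arcsinh scale with quantile fallbacks; ``resolve_gate``
freezes them into concrete, idempotent specs, and every resolved threshold
is recorded in the gate report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import (
    ROLE_CENTER,
    ROLE_CERIUM,
    ROLE_DNA,
    ROLE_EVENT_LENGTH,
    EventTable,
)
from .panel import DEFAULT_COFACTOR
from .utils import find_valley

RULE_INTERVAL = "interval"
RULE_QUANTILE_INTERVAL = "quantile-interval"
RULE_DENSITY_CORE = "2D-density-core"
RULE_ABOVE = "threshold-above"
RULE_BELOW = "threshold-below"


class GateError(ValueError):
    pass


@dataclass(frozen=True)
class GateSpec:
    """One gate: named rule over one or two channels with parameters.

    ``params`` may contain ``"auto"`` thresholds (valley detection with
    quantile fallback); :func:`resolve_gate` replaces them with numbers.
    A spec whose params are all numeric applies idempotently.
    """

    name: str
    channels: tuple[str, ...]
    rule: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channels": list(self.channels),
            "rule": self.rule,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateSpec":
        return cls(
            d["name"], tuple(d["channels"]), d["rule"], dict(d.get("params", {}))
        )


@dataclass
class GateReport:
    """Telescoping per-gate event accounting."""

    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, resolved: dict) -> None:
        self.rows.append(
            {
                "gate": name,
                "events_in": int(n_in),
                "events_out": int(n_out),
                "fraction_removed": (
                    0.0 if n_in == 0 else 1.0 - n_out / n_in
                ),
                "resolved_params": resolved,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {k: v for k, v in row.items() if k != "resolved_params"}
                for row in self.rows
            ]
        )


def _asinh(table: EventTable, channel: str, cofactor: float) -> np.ndarray:
    x = table.data[channel].to_numpy(dtype=float)
    if table.sample_meta.get("arcsinh_cofactor"):
        return x  # already transformed upstream
    return np.arcsinh(x / cofactor)


def _auto_threshold(
    values: np.ndarray, fallback_quantile: float, side: str | None = None
) -> tuple[float, str]:
    thr = find_valley(values, side=side)
    if thr is not None:
        return thr, "valley"
    return float(np.quantile(values, fallback_quantile)), "quantile"


def _require(table: EventTable, channels: tuple[str, ...], gate: str) -> None:
    missing = [c for c in channels if c not in table.data.columns]
    if missing:
        raise GateError(f"gate {gate!r}: missing channels {missing}")


# ---------------------------------------------------------------------------
# Default specs
# ---------------------------------------------------------------------------

def default_singlet_spec() -> GateSpec:
    # Event_length carries the quantile core (1st-95th); Center trims only
    # when a second (doublet) mode is actually present
    return GateSpec(
        "singlets", ("Event_length", "Center"), RULE_DENSITY_CORE,
        {
            "lo_quantiles": (0.01, 0.0),
            "hi_quantiles": (0.95, 1.0),
            "upper": ("auto", "auto"),  # valley if bimodal, else hi quantile
        },
    )


def default_viability_spec(channel: str = "Ir191") -> GateSpec:
    return GateSpec(
        "viability", (channel,), RULE_INTERVAL,
        {"low": "auto", "high": "auto", "low_fallback_q": 0.005,
         "high_q": 0.995},
    )


def default_bead_residual_spec(channel: str = "Ce140") -> GateSpec:
    return GateSpec(
        "bead_residual", (channel,), RULE_BELOW,
        {"threshold": "auto", "fallback_q": 0.995},
    )


def default_microglia_spec() -> GateSpec:
    return GateSpec(
        "microglia", ("CD11b", "CD45"), RULE_ABOVE,
        {"thresholds": ("auto", "auto"), "fallback_q": 0.02},
    )


def default_gfap_negative_spec() -> GateSpec:
    return GateSpec(
        "gfap_negative", ("GFAP",), RULE_BELOW,
        {"threshold": "auto", "fallback_q": 0.98},
    )


def default_astrocyte_spec() -> GateSpec:
    return GateSpec(
        "astrocytes", ("GFAP",), RULE_ABOVE,
        {"thresholds": ("auto",), "fallback_q": 0.995},
    )


# ---------------------------------------------------------------------------
# Resolution and application
# ---------------------------------------------------------------------------

def resolve_gate(
    table: EventTable, spec: GateSpec, cofactor: float = DEFAULT_COFACTOR
) -> GateSpec:
    """Freeze auto/quantile parameters into concrete arcsinh-scale numbers.

    Resolved specs are idempotent: applying one twice equals applying it
    once.  Thresholds for mass channels are on the arcsinh scale; the
    singlet gate operates on the untransformed instrument summaries.
    """
    _require(table, spec.channels, spec.name)
    p = dict(spec.params)
    if spec.rule == RULE_DENSITY_CORE:
        lo_q = p.get("lo_quantiles", (0.01, 0.01))
        hi_q = p.get("hi_quantiles", (0.95, 0.99))
        bounds = []
        for ch, lq, hq, up in zip(
            spec.channels, lo_q, hi_q, p.get("upper", ("auto", "auto"))
        ):
            x = table.data[ch].to_numpy(dtype=float)
            lo = float(np.quantile(x, lq))
            if up == "auto":
                valley = find_valley(x, side="above")
                hi = valley if valley is not None else float(np.quantile(x, hq))
            elif isinstance(up, (int, float)):
                hi = float(up)
            else:
                hi = float(np.quantile(x, hq))
            bounds.append((lo, float(hi)))
        return replace(spec, params={"bounds": tuple(bounds)})
    if spec.rule == RULE_INTERVAL:
        (ch,) = spec.channels
        if "bounds" in p:
            return spec
        x = _asinh(table, ch, cofactor)
        low, high = p.get("low", "auto"), p.get("high", "auto")
        if low == "auto":
            valley = find_valley(x, side="below")
            low = (
                valley
                if valley is not None
                else float(np.quantile(x, p.get("low_fallback_q", 0.005)))
            )
        if high == "auto":
            high = float(np.quantile(x, p.get("high_q", 0.995)))
        return replace(
            spec, params={"bounds": ((float(low), float(high)),)}
        )
    if spec.rule == RULE_BELOW:
        (ch,) = spec.channels
        if isinstance(p.get("threshold"), (int, float)):
            return spec
        x = _asinh(table, ch, cofactor)
        thr, how = _auto_threshold(x, p.get("fallback_q", 0.995),
                                   side="above")
        return replace(spec, params={"threshold": thr, "resolved_by": how})
    if spec.rule == RULE_ABOVE:
        thrs = p.get("thresholds", tuple("auto" for _ in spec.channels))
        out = []
        how_all = []
        for ch, thr in zip(spec.channels, thrs):
            if isinstance(thr, (int, float)):
                out.append(float(thr))
                how_all.append("given")
                continue
            x = _asinh(table, ch, cofactor)
            valley = find_valley(x)
            if valley is not None:
                out.append(valley)
                how_all.append("valley")
            else:
                out.append(float(np.quantile(x, p.get("fallback_q", 0.02))))
                how_all.append("quantile")
        return replace(
            spec,
            params={"thresholds": tuple(out), "resolved_by": tuple(how_all)},
        )
    if spec.rule == RULE_QUANTILE_INTERVAL:
        (ch,) = spec.channels
        x = _asinh(table, ch, cofactor)
        lo = float(np.quantile(x, p.get("lo_q", 0.0)))
        hi = float(np.quantile(x, p.get("hi_q", 1.0)))
        return replace(
            spec, params={"bounds": ((lo, hi),)}, rule=RULE_INTERVAL
        )
    raise GateError(f"unknown gate rule {spec.rule!r}")


def apply_gate(
    table: EventTable, spec: GateSpec, cofactor: float = DEFAULT_COFACTOR
) -> np.ndarray:
    """Boolean keep-mask for a resolved (or resolvable) spec."""
    if _needs_resolution(spec):
        spec = resolve_gate(table, spec, cofactor)
    _require(table, spec.channels, spec.name)
    n = table.n_events
    mask = np.ones(n, dtype=bool)
    if spec.rule == RULE_DENSITY_CORE:
        for ch, (lo, hi) in zip(spec.channels, spec.params["bounds"]):
            x = table.data[ch].to_numpy(dtype=float)
            mask &= (x >= lo) & (x <= hi)
        return mask
    if spec.rule == RULE_INTERVAL:
        ((lo, hi),) = spec.params["bounds"]
        x = _asinh(table, spec.channels[0], cofactor)
        return (x >= lo) & (x <= hi)
    if spec.rule == RULE_BELOW:
        x = _asinh(table, spec.channels[0], cofactor)
        return x <= float(spec.params["threshold"])
    if spec.rule == RULE_ABOVE:
        for ch, thr in zip(spec.channels, spec.params["thresholds"]):
            x = _asinh(table, ch, cofactor)
            mask &= x > float(thr)
        return mask
    raise GateError(f"unknown gate rule {spec.rule!r}")


def _needs_resolution(spec: GateSpec) -> bool:
    if spec.rule == RULE_QUANTILE_INTERVAL:
        return True
    p = spec.params
    if spec.rule == RULE_DENSITY_CORE:
        return "bounds" not in p
    if spec.rule == RULE_INTERVAL:
        return "bounds" not in p
    if spec.rule == RULE_BELOW:
        return not isinstance(p.get("threshold"), (int, float))
    if spec.rule == RULE_ABOVE:
        thrs = p.get("thresholds")
        return thrs is None or not all(
            isinstance(t, (int, float)) for t in thrs
        )
    return True


# Named gate operations (thin wrappers fixing the spec family) --------------

def gate_singlets(table, spec=None, cofactor=DEFAULT_COFACTOR):
    spec = spec or default_singlet_spec()
    _require(table, spec.channels, spec.name)
    return apply_gate(table, spec, cofactor)


def gate_viability(table, spec=None, cofactor=DEFAULT_COFACTOR):
    if spec is None:
        dna = table.channels(ROLE_DNA)
        if not dna:
            raise GateError("gate 'viability': no DNA channels present")
        spec = default_viability_spec(dna[0])
    return apply_gate(table, spec, cofactor)


def gate_bead_residual(table, spec=None, cofactor=DEFAULT_COFACTOR):
    if spec is None:
        ce = table.channels(ROLE_CERIUM)
        if not ce:
            raise GateError("gate 'bead_residual': Ce140 channel missing")
        spec = default_bead_residual_spec(ce[0])
    return apply_gate(table, spec, cofactor)


def gate_microglia(table, spec=None, cofactor=DEFAULT_COFACTOR):
    spec = spec or default_microglia_spec()
    return apply_gate(table, spec, cofactor)


def gate_gfap_negative(table, spec=None, cofactor=DEFAULT_COFACTOR):
    spec = spec or default_gfap_negative_spec()
    return apply_gate(table, spec, cofactor)


def gate_astrocytes(table, spec=None, cofactor=DEFAULT_COFACTOR):
    spec = spec or default_astrocyte_spec()
    return apply_gate(table, spec, cofactor)


def default_gate_chain(table: EventTable) -> list[GateSpec]:
    dna = table.channels(ROLE_DNA)
    ce = table.channels(ROLE_CERIUM)
    return [
        default_singlet_spec(),
        default_viability_spec(dna[0] if dna else "Ir191"),
        default_bead_residual_spec(ce[0] if ce else "Ce140"),
        default_microglia_spec(),
        default_gfap_negative_spec(),
    ]


def run_gate_chain(
    table: EventTable,
    specs: list[GateSpec] | None = None,
    cofactor: float = DEFAULT_COFACTOR,
) -> tuple[np.ndarray, GateReport]:
    """Apply gates sequentially; thresholds resolve on the events entering
    each gate.  Returns the overall keep mask and the telescoping report."""
    if specs is None:
        specs = default_gate_chain(table)
    keep = np.ones(table.n_events, dtype=bool)
    report = GateReport()
    current = table
    for spec in specs:
        resolved = resolve_gate(current, spec, cofactor)
        mask = apply_gate(current, resolved, cofactor)
        n_in = current.n_events
        current = current.subset(mask)
        idx = np.flatnonzero(keep)
        keep[idx[~mask]] = False
        report.add(spec.name, n_in, current.n_events, resolved.params)
    return keep, report
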