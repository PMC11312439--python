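"""Event-level container for mass-cytometry data.

An :class:`EventTable` holds the events x channels intensity matrix of one
acquisition (or one debarcoded sample), per-channel roles, per-event
annotations accumulated by pipeline stages (barcode assignment, doublet
scores, gate flags, cluster labels), and sample-level metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Channel roles
ROLE_MARKER = "marker"
ROLE_PALLADIUM = "palladium"
ROLE_BEAD = "bead"
ROLE_DNA = "dna"
ROLE_CERIUM = "cerium"
ROLE_EVENT_LENGTH = "event_length"
ROLE_CENTER = "center"
ROLE_TIME = "time"
ROLE_UNASSIGNED = "unassigned"

#: Roles measured by the mass channel (subject to sensitivity drift and the
#: arcsinh transform); Event_length / Center / Time are instrument summaries.
MASS_ROLES = frozenset(
    {ROLE_MARKER, ROLE_PALLADIUM, ROLE_BEAD, ROLE_DNA, ROLE_CERIUM}
)

VALID_ROLES = MASS_ROLES | {
    ROLE_EVENT_LENGTH,
    ROLE_CENTER,
    ROLE_TIME,
    ROLE_UNASSIGNED,
}


class EventTableError(ValueError):
    """Raised when an EventTable violates its invariants."""


@dataclass
class EventTable:
    """Events x channels intensity matrix with channel roles and annotations.

    Parameters
    ----------
    data:
        Intensity matrix, one row per event, one named column per channel.
        Ion counts are non-negative; stored as floats.
    roles:
        Mapping channel name -> role (see module constants).
    annotations:
        Per-event columns appended by pipeline stages.  Always index-aligned
        with ``data``.
    sample_meta:
        Free-form sample metadata (condition, stimulus, timepoint_h,
        replicate, provenance such as the arcsinh cofactor used).
    """

    data: pd.DataFrame
    roles: dict[str, str]
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if self.annotations is None or len(self.annotations.columns) == 0:
            self.annotations = pd.DataFrame(index=self.data.index)
        else:
            self.annotations = self.annotations.reset_index(drop=True)
        unknown = set(self.data.columns) - set(self.roles)
        if unknown:
            raise EventTableError(f"channels without a role: {sorted(unknown)}")
        bad = {c: r for c, r in self.roles.items() if r not in VALID_ROLES}
        if bad:
            raise EventTableError(f"invalid channel roles: {bad}")

    # -- basic introspection -------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channel_names(self) -> list[str]:
        return list(self.data.columns)

    def channels(self, *roles: str) -> list[str]:
        """Channel names with any of the given roles, in data order."""
        want = set(roles)
        return [c for c in self.data.columns if self.roles.get(c) in want]

    @property
    def marker_channels(self) -> list[str]:
        return self.channels(ROLE_MARKER)

    @property
    def pd_channels(self) -> list[str]:
        return self.channels(ROLE_PALLADIUM)

    @property
    def mass_channels(self) -> list[str]:
        return self.channels(*MASS_ROLES)

    @property
    def time_channel(self) -> str | None:
        t = self.channels(ROLE_TIME)
        return t[0] if t else None

    # -- manipulation --------------------------------------------------------
    def copy(self) -> "EventTable":
        return EventTable(
            self.data.copy(),
            dict(self.roles),
            self.annotations.copy(),
            dict(self.sample_meta),
        )

    def subset(self, mask: Iterable[bool] | np.ndarray) -> "EventTable":
        """Row-subset by boolean mask; index is reset."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_events,):
            raise EventTableError(
                f"mask length {mask.shape} != n_events {self.n_events}"
            )
        return EventTable(
            self.data.loc[mask].reset_index(drop=True),
            dict(self.roles),
            self.annotations.loc[mask].reset_index(drop=True),
            dict(self.sample_meta),
        )

    def with_annotation(self, name: str, values) -> "EventTable":
        values = np.asarray(values)
        if values.shape[0] != self.n_events:
            raise EventTableError(
                f"annotation {name!r} has {values.shape[0]} values for "
                f"{self.n_events} events"
            )
        out = self.copy()
        out.annotations[name] = values
        return out

    # -- validation ----------------------------------------------------------
    def validate(self) -> "EventTable":
        """Check invariants; return self so calls can be chained."""
        vals = self.data.to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise EventTableError("intensities contain non-finite values")
        mass = self.data[self.mass_channels].to_numpy(dtype=float)
        if mass.size and mass.min() < 0:
            raise EventTableError("mass-channel intensities must be >= 0")
        tc = self.time_channel
        if tc is not None and self.n_events > 1:
            t = self.data[tc].to_numpy()
            if np.any(np.diff(t) < 0):
                raise EventTableError(
                    "acquisition-time channel is not non-decreasing"
                )
        if len(self.annotations) != self.n_events:
            raise EventTableError("annotations not aligned with events")
        return self


def concat_tables(tables: list[EventTable]) -> EventTable:
    """Concatenate event tables sharing the same channels and roles."""
    if not tables:
        raise EventTableError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if list(t.data.columns) != list(first.data.columns):
            raise EventTableError("channel sets differ between tables")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    ann = pd.concat([t.annotations for t in tables], ignore_index=True)
    meta: dict = {}
    for t in tables:
        for k, v in t.sample_meta.items():
            if k in meta and meta[k] != v:
                meta[k] = None  # mixed across pooled samples
            else:
                meta.setdefault(k, v)
    return EventTable(data, dict(first.roles), ann, meta)


def infer_channel_roles(
    names: Iterable[str],
    panel=None,
    pd_channels: Iterable[str] = (),
    bead_channels: Iterable[str] = (),
    dna_channels: Iterable[str] = (),
    cerium_channel: str = "Ce140",
) -> dict[str, str]:
    """Infer channel roles from channel names.

    Matching order: instrument parameters by name, then palladium/bead/DNA/
    cerium channel lists, then panel metal tag, then panel marker name.
    Unmatched channels get the role ``unassigned`` and are carried but
    excluded from analysis.
    """
    pd_set = set(pd_channels)
    bead_set = set(bead_channels)
    dna_set = set(dna_channels)
    metal_to_marker = {}
    marker_names = set()
    if panel is not None:
        metal_to_marker = {m.metal: m.name for m in panel.markers}
        marker_names = {m.name for m in panel.markers}
    roles: dict[str, str] = {}
    for name in names:
        low = name.lower()
        if low == "time":
            roles[name] = ROLE_TIME
        elif low in ("event_length", "eventlength", "event length"):
            roles[name] = ROLE_EVENT_LENGTH
        elif low == "center":
            roles[name] = ROLE_CENTER
        elif name in pd_set:
            roles[name] = ROLE_PALLADIUM
        elif name in bead_set:
            roles[name] = ROLE_BEAD
        elif name in dna_set:
            roles[name] = ROLE_DNA
        elif name == cerium_channel:
            roles[name] = ROLE_CERIUM
        elif name in metal_to_marker or name in marker_names:
            roles[name] = ROLE_MARKER
        else:
            roles[name] = ROLE_UNASSIGNED
    return roles
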