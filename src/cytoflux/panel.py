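"""Panel and barcode-key configuration, and the arcsinh transform.

The antibody panel comprises 33 metal-conjugated markers (21 signaling + 12
identity).  Two marker subsets drive the two clustering rounds:

* round 1 (identity clustering) uses a fixed 13-marker set — the 12
  identity-class markers plus CD40, an activation-capable marker that also
  informs cell identity;
* round 2 (signaling clustering) uses every panel marker except CD11b, CD45,
  GFAP and Olig2, which only encode lineage.

Samples are multiplexed with a 6-choose-3 palladium barcode: each sample
carries exactly 3 of the 6 Pd isotopes, giving C(6,3) = 20 possible codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .events import (
    MASS_ROLES,
    ROLE_CENTER,
    ROLE_EVENT_LENGTH,
    ROLE_TIME,
    EventTable,
)

CLASS_SIGNALING = "signaling"
CLASS_IDENTITY = "identity"

#: The six palladium barcoding channels, in index order.
PD_CHANNELS: tuple[str, ...] = (
    "Pd102", "Pd104", "Pd105", "Pd106", "Pd108", "Pd110",
)
#: Iridium DNA-intercalator channels (viability / debris discrimination).
DNA_CHANNELS: tuple[str, ...] = ("Ir191", "Ir193")
#: EQ four-element calibration-bead channels besides Ce140.
BEAD_CHANNELS: tuple[str, ...] = ("Eu151", "Ho165", "Lu175")
#: Cerium bead channel, also used for the residual-bead clean-up gate.
CERIUM_CHANNEL = "Ce140"

#: The 13-marker identity-clustering (round 1) set.
ROUND1_MARKERS: tuple[str, ...] = (
    "Olig2", "CD11b", "Fibronectin", "GFAP", "CD68", "F480", "CD45",
    "Ly6C", "Sox2", "CD40", "Galectin-1", "Cx3CR1", "CD86",
)
#: Lineage-only markers excluded from round-2 (signaling) clustering.
ROUND2_EXCLUDED: tuple[str, ...] = ("CD11b", "CD45", "GFAP", "Olig2")

DEFAULT_COFACTOR = 5.0

EXPECTED_TOTAL = 33
EXPECTED_SIGNALING = 21
EXPECTED_IDENTITY = 12
MAX_BARCODED_SAMPLES = 20  # C(6,3)


class PanelError(ValueError):
    """Raised for invalid panel or barcode-key configurations."""


@dataclass(frozen=True)
class Marker:
    name: str
    metal: str
    marker_class: str
    in_round1: bool
    in_round2: bool


@dataclass(frozen=True)
class Panel:
    """Ordered marker list; counts are derived, never stored."""

    markers: tuple[Marker, ...]

    @property
    def total(self) -> int:
        return len(self.markers)

    @property
    def n_signaling(self) -> int:
        return sum(m.marker_class == CLASS_SIGNALING for m in self.markers)

    @property
    def n_identity(self) -> int:
        return sum(m.marker_class == CLASS_IDENTITY for m in self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def round1_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.in_round1]

    @property
    def round2_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.in_round2]

    def __getitem__(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def validate(self) -> "Panel":
        names = [m.name for m in self.markers]
        metals = [m.metal for m in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate marker names: {dup}")
        if len(set(metals)) != len(metals):
            dup = sorted({n for n in metals if metals.count(n) > 1})
            raise PanelError(f"duplicate metal tags: {dup}")
        missing_r1 = sorted(set(ROUND1_MARKERS) - set(names))
        if missing_r1:
            raise PanelError(
                f"panel missing round-1 identity-clustering markers: {missing_r1}"
            )
        missing_r2 = sorted(set(ROUND2_EXCLUDED) - set(names))
        if missing_r2:
            raise PanelError(
                f"panel missing round-2 exclusion markers: {missing_r2}"
            )
        for m in self.markers:
            if m.marker_class not in (CLASS_SIGNALING, CLASS_IDENTITY):
                raise PanelError(
                    f"marker {m.name}: invalid class {m.marker_class!r}"
                )
            if m.in_round1 != (m.name in ROUND1_MARKERS):
                raise PanelError(f"marker {m.name}: wrong in_round1 flag")
            if m.in_round2 != (m.name not in ROUND2_EXCLUDED):
                raise PanelError(f"marker {m.name}: wrong in_round2 flag")
        if self.total != EXPECTED_TOTAL:
            raise PanelError(
                f"panel has {self.total} markers, expected {EXPECTED_TOTAL}"
            )
        if self.n_signaling != EXPECTED_SIGNALING:
            raise PanelError(
                f"panel has {self.n_signaling} signaling markers, "
                f"expected {EXPECTED_SIGNALING}"
            )
        if self.n_identity != EXPECTED_IDENTITY:
            raise PanelError(
                f"panel has {self.n_identity} identity markers, "
                f"expected {EXPECTED_IDENTITY}"
            )
        return self


def _panel_from_entries(entries: Sequence[Mapping]) -> Panel:
    markers = []
    for e in entries:
        name = str(e["name"])
        markers.append(
            Marker(
                name=name,
                metal=str(e["metal"]),
                marker_class=str(e.get("class", e.get("marker_class"))),
                in_round1=name in ROUND1_MARKERS,
                in_round2=name not in ROUND2_EXCLUDED,
            )
        )
    return Panel(tuple(markers)).validate()


def load_panel(path) -> Panel:
    """Load and validate a panel YAML (``markers: [{name, metal, class}]``)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "markers" not in cfg:
        raise PanelError("panel config must have a top-level 'markers' list")
    return _panel_from_entries(cfg["markers"])


def default_panel() -> Panel:
    """The packaged 33-marker panel."""
    ref = resources.files("cytoflux.data").joinpath("panel.yaml")
    with resources.as_file(ref) as p:
        return load_panel(p)


# ---------------------------------------------------------------------------
# Barcode key
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeKey:
    """Mapping sample_id -> 3-subset of the 6 palladium channels.

    Codes are stored as frozensets of channel indices into ``pd_channels``.
    """

    codes: Mapping[str, frozenset[int]]
    pd_channels: tuple[str, ...] = PD_CHANNELS

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes)

    def code_channels(self, sample_id: str) -> list[str]:
        return [self.pd_channels[i] for i in sorted(self.codes[sample_id])]

    def code_lookup(self) -> dict[frozenset[int], str]:
        return {code: sid for sid, code in self.codes.items()}

    def validate(self) -> "BarcodeKey":
        if len(self.pd_channels) != 6:
            raise PanelError("exactly 6 palladium channels required")
        if len(self.codes) > MAX_BARCODED_SAMPLES:
            raise PanelError(
                f"{len(self.codes)} samples exceed the "
                f"{MAX_BARCODED_SAMPLES} possible 3-of-6 codes"
            )
        seen: dict[frozenset[int], str] = {}
        for sid, code in self.codes.items():
            code = frozenset(code)
            if len(code) != 3:
                raise PanelError(
                    f"sample {sid!r}: code has cardinality {len(code)}, "
                    "expected exactly 3"
                )
            if not code <= set(range(6)):
                raise PanelError(f"sample {sid!r}: channel index out of range")
            if code in seen:
                raise PanelError(
                    f"duplicate barcode: samples {seen[code]!r} and {sid!r}"
                )
            seen[code] = sid
        return self


def _parse_code(entry, pd_channels: Sequence[str]) -> frozenset[int]:
    idx = []
    for item in entry:
        if isinstance(item, str):
            if item not in pd_channels:
                raise PanelError(f"unknown palladium channel {item!r}")
            idx.append(list(pd_channels).index(item))
        else:
            idx.append(int(item))
    return frozenset(idx)


def load_barcode_key(path) -> BarcodeKey:
    """Load a barcode-key YAML (``codes: {sample: [Pd..., ...]}``)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "codes" not in cfg:
        raise PanelError("barcode key must have a top-level 'codes' mapping")
    pd_channels = tuple(cfg.get("pd_channels", PD_CHANNELS))
    codes = {
        str(sid): _parse_code(entry, pd_channels)
        for sid, entry in cfg["codes"].items()
    }
    return BarcodeKey(codes, pd_channels).validate()


def default_barcode_key(n_samples: int = 9, prefix: str = "S") -> BarcodeKey:
    """A balanced set of ``n_samples`` 3-of-6 codes.

    Codes are taken in complementary pairs (each pair covers all six
    palladium channels), so channel usage stays as even as possible and
    every channel carries positives even for small sample sets — a
    requirement for the robust-range rescaling used in debarcoding.
    """
    if not 1 <= n_samples <= MAX_BARCODED_SAMPLES:
        raise PanelError(
            f"n_samples must be in [1, {MAX_BARCODED_SAMPLES}]"
        )
    ordered: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    for c in combinations(range(6), 3):
        code = frozenset(c)
        if code in seen:
            continue
        comp = frozenset(range(6)) - code
        ordered.extend([code, comp])
        seen.update([code, comp])
    codes = {
        f"{prefix}{i + 1:02d}": code
        for i, code in enumerate(ordered[:n_samples])
    }
    return BarcodeKey(codes).validate()


# ---------------------------------------------------------------------------
# arcsinh transform
# ---------------------------------------------------------------------------

def arcsinh_transform(
    table: EventTable, cofactor: float = DEFAULT_COFACTOR
) -> EventTable:
    """Variance-stabilizing transform x -> asinh(x / cofactor).

    Applies to all mass channels (markers, palladium, DNA, beads, Ce140);
    Event_length, Center and Time are untouched.  Strictly increasing and
    maps 0 -> 0 for every cofactor > 0.
    """
    if not cofactor > 0:
        raise ValueError(f"cofactor must be > 0, got {cofactor}")
    out = table.copy()
    cols = out.mass_channels
    out.data[cols] = np.arcsinh(out.data[cols].to_numpy(dtype=float) / cofactor)
    out.sample_meta["arcsinh_cofactor"] = float(cofactor)
    return out
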