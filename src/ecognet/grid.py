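"""Electrode-grid geometry.

Subdural ECoG arrays are rectangular grids of square contacts with a fixed
center-to-center pitch (2.5 mm for the arrays this package emulates: an
8 x 16 temporal-cortex array and an 8 x 8 prefrontal array).  All spatial
bookkeeping downstream -- searchlight neighborhoods, component topographies,
vertical bipolar derivation -- is expressed in the (row, col) frame defined
here.  Row 0 is the dorsal edge of an array by convention; users with a
different physical layout can flip rows before constructing the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ElectrodeGrid", "GridSet", "make_grid"]


@dataclass
class ElectrodeGrid:
    """A single rectangular electrode array.

    Channels are numbered row-major within the array: channel ``r * cols + c``
    sits at row ``r`` (0 = dorsal), column ``c``.

    Parameters
    ----------
    rows, cols:
        Grid dimensions; the array has ``rows * cols`` channels.
    pitch:
        Center-to-center contact distance in millimeters.
    array_id:
        Label of the array (e.g. ``"TC"``, ``"dmPFC"``).
    location_flag:
        Per-channel ``"surface"`` or ``"sulcal"`` flag.
    region_label:
        Free-text per-channel anatomical label (e.g. ``"ITC"``, ``"STSv"``).
    """

    rows: int
    cols: int
    pitch: float = 2.5
    array_id: str = "array"
    location_flag: list[str] = field(default_factory=list)
    region_label: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(
                f"grid dimensions must be positive, got {self.rows} x {self.cols}"
            )
        n = self.rows * self.cols
        if not self.location_flag:
            self.location_flag = ["surface"] * n
        if not self.region_label:
            self.region_label = [self.array_id] * n
        if len(self.location_flag) != n or len(self.region_label) != n:
            raise ValueError("per-channel metadata length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_index(self, row: int, col: int) -> int:
        """Local channel id of the contact at (row, col)."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"({row}, {col}) outside {self.rows} x {self.cols} grid")
        return row * self.cols + col

    def position(self, channel: int) -> tuple[int, int]:
        """(row, col) of a local channel id."""
        if not (0 <= channel < self.n_channels):
            raise IndexError(f"channel {channel} outside array {self.array_id}")
        return divmod(channel, self.cols)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "pitch": self.pitch,
            "array_id": self.array_id,
            "location_flag": list(self.location_flag),
            "region_label": list(self.region_label),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGrid":
        return cls(**d)


def make_grid(rows: int, cols: int, pitch: float = 2.5, array_id: str = "array") -> ElectrodeGrid:
    """Build a rectangular array with row-major channel ids.

    ``make_grid(8, 16, 2.5, "TC")`` yields the 128-channel temporal-cortex
    layout; ``make_grid(8, 8, 2.5, "dmPFC")`` the 64-channel prefrontal one.
    """
    return ElectrodeGrid(rows=rows, cols=cols, pitch=pitch, array_id=array_id)


class GridSet:
    """An ordered collection of arrays sharing one global channel numbering.

    Global channels are the concatenation of the arrays' local channels in
    the order the arrays are given, so a TC (128 ch) + dmPFC (64 ch) session
    has global channels 0..191.
    """

    def __init__(self, grids: Sequence[ElectrodeGrid]):
        if not grids:
            raise ValueError("GridSet requires at least one array")
        ids = [g.array_id for g in grids]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate array ids: {ids}")
        self.grids: list[ElectrodeGrid] = list(grids)
        self._offsets: dict[str, int] = {}
        off = 0
        for g in self.grids:
            self._offsets[g.array_id] = off
            off += g.n_channels
        self._n_channels = off

    @property
    def n_channels(self) -> int:
        return self._n_channels

    @property
    def array_ids(self) -> list[str]:
        return [g.array_id for g in self.grids]

    def grid(self, array_id: str) -> ElectrodeGrid:
        for g in self.grids:
            if g.array_id == array_id:
                return g
        raise KeyError(array_id)

    def offset(self, array_id: str) -> int:
        return self._offsets[array_id]

    def array_of(self, channel: int) -> ElectrodeGrid:
        """Array containing a global channel id."""
        if not (0 <= channel < self._n_channels):
            raise IndexError(f"global channel {channel} out of range")
        for g in self.grids:
            off = self._offsets[g.array_id]
            if off <= channel < off + g.n_channels:
                return g
        raise IndexError(channel)  # pragma: no cover

    def position(self, channel: int) -> tuple[str, int, int]:
        """(array_id, row, col) of a global channel id."""
        g = self.array_of(channel)
        r, c = g.position(channel - self._offsets[g.array_id])
        return g.array_id, r, c

    def global_channel(self, array_id: str, row: int, col: int) -> int:
        g = self.grid(array_id)
        return self._offsets[array_id] + g.channel_index(row, col)

    def channels_of(self, array_id: str) -> np.ndarray:
        g = self.grid(array_id)
        off = self._offsets[array_id]
        return np.arange(off, off + g.n_channels)

    def array_membership(self) -> np.ndarray:
        """Array id of every global channel, as an object array."""
        out = np.empty(self._n_channels, dtype=object)
        for g in self.grids:
            out[self.channels_of(g.array_id)] = g.array_id
        return out

    def to_json(self) -> str:
        return json.dumps({"grids": [g.to_dict() for g in self.grids]})

    @classmethod
    def from_json(cls, s: str) -> "GridSet":
        d = json.loads(s)
        return cls([ElectrodeGrid.from_dict(g) for g in d["grids"]])

    @classmethod
    def coerce(cls, obj: "GridSet | ElectrodeGrid | Iterable[ElectrodeGrid]") -> "GridSet":
        if isinstance(obj, GridSet):
            return obj
        if isinstance(obj, ElectrodeGrid):
            return cls([obj])
        return cls(list(obj))


def default_grids() -> GridSet:
    """The emulated recording layout: 8x16 TC array plus 8x8 dmPFC array."""
    return GridSet([make_grid(8, 16, 2.5, "TC"), make_grid(8, 8, 2.5, "dmPFC")])
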