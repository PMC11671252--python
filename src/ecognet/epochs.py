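"""Trial-epoched multichannel voltage data and its HDF5 container.

:class:`TrialEpochs` is the exchange object between every pipeline stage:
a ``(trials, channels, samples)`` voltage array with a uniform time axis
relative to stimulus onset, per-trial category labels, a reference to the
electrode geometry, and a free-text provenance log that each processing
stage appends to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .grid import GridSet

__all__ = ["TrialEpochs", "save_epochs", "load_epochs"]

ANIMATE = "animate"
INANIMATE = "inanimate"


@dataclass
class TrialEpochs:
    """Trial-epoched multichannel field potentials.

    Parameters
    ----------
    data:
        ``(n_trials, n_channels, n_samples)`` voltages, arbitrary units.
    fs:
        Sampling rate in Hz.
    times:
        Sample times in seconds relative to stimulus onset; uniform spacing
        ``1/fs``, same length as the last data axis.
    labels:
        Per-trial category, ``"animate"`` or ``"inanimate"``.
    grid:
        Electrode geometry for the channel axis (optional for derived
        channel sets such as sources or bipolar sites).
    provenance:
        Ordered log of the processing applied so far.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    labels: np.ndarray
    grid: GridSet | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (trials, channels, samples), got {self.data.shape}")
        if self.times.shape[0] != self.data.shape[2]:
            raise ValueError("times length must equal sample count")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced at 1/fs")
        if self.grid is not None and self.grid.n_channels != self.data.shape[1]:
            raise ValueError(
                f"grid has {self.grid.n_channels} channels, data has {self.data.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy_with(self, data: np.ndarray, *, fs: float | None = None,
                  times: np.ndarray | None = None, grid: GridSet | None = None,
                  keep_grid: bool = True, note: str | None = None) -> "TrialEpochs":
        """New epochs sharing labels/provenance, with replaced data."""
        out = TrialEpochs(
            data=data,
            fs=self.fs if fs is None else fs,
            times=self.times if times is None else times,
            labels=self.labels.copy(),
            grid=(self.grid if (grid is None and keep_grid) else grid),
            provenance=list(self.provenance),
        )
        if note:
            out.log(note)
        return out

    def time_indices(self, window: tuple[float, float], inclusive: bool = True) -> np.ndarray:
        """Sample indices whose times fall in ``window`` (endpoints included
        by default, with half-sample tolerance)."""
        tol = 0.5 / self.fs
        lo, hi = window
        if inclusive:
            mask = (self.times >= lo - tol) & (self.times <= hi + tol)
        else:
            mask = (self.times >= lo) & (self.times < hi)
        return np.flatnonzero(mask)


def save_epochs(epochs: TrialEpochs, path: str) -> None:
    """Write epochs to HDF5 (data, times, labels, fs; grid and provenance
    serialized to JSON/UTF-8 attributes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=np.array([str(l) for l in epochs.labels], dtype="S32"))
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["provenance"] = "\n".join(epochs.provenance)
        if epochs.grid is not None:
            f.attrs["grid_json"] = epochs.grid.to_json()


def load_epochs(path: str) -> TrialEpochs:
    """Read epochs written by :func:`save_epochs`."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        labels = np.array([s.decode() for s in f["labels"][()]])
        fs = float(f.attrs["fs"])
        prov = [s for s in str(f.attrs.get("provenance", "")).split("\n") if s]
        grid = None
        if "grid_json" in f.attrs:
            grid = GridSet.from_json(str(f.attrs["grid_json"]))
    return TrialEpochs(data=data, fs=fs, times=times, labels=labels, grid=grid,
                       provenance=prov)
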