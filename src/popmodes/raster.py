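"""Spike-train binning, binary rasters, and word statistics.

The observable throughout the package is an N x T binary matrix: one row per
cell, one column per time bin, entry 1 iff the cell fired at least once in
that bin.  Bins are half-open intervals ``[t*dt, (t+1)*dt)``; a spike landing
exactly on the final boundary is dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "BinaryRaster",
    "RepeatSet",
    "bin_spikes",
    "circular_shuffle",
    "word_frequencies",
    "words_to_strings",
    "read_spike_csv",
    "read_raster_tsv",
    "write_raster_tsv",
]


@dataclass
class SpikeTrainSet:
    """Per-cell spike times in seconds.

    Parameters
    ----------
    spikes
        One array of non-negative, sorted spike times per cell.
    duration
        Recording length in seconds; all spikes must fall in ``[0, duration)``.
    """

    spikes: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for i, s in enumerate(self.spikes):
            if s.size and (s.min() < 0 or s.max() >= self.duration):
                raise ValueError(
                    f"cell {i}: spike times must lie in [0, duration)"
                )
            if np.any(np.diff(s) < 0):
                raise ValueError(f"cell {i}: spike times must be sorted")

    @property
    def n_cells(self) -> int:
        return len(self.spikes)


@dataclass
class BinaryRaster:
    """N x T binary matrix of population activity with its bin width."""

    data: np.ndarray
    bin_width: float
    cell_ids: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D (cells x bins)")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.data = self.data.astype(np.uint8)
        if self.cell_ids is None:
            self.cell_ids = list(range(self.data.shape[0]))

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


@dataclass
class RepeatSet:
    """R aligned rasters recorded under identical repeated stimulation."""

    rasters: list[BinaryRaster] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rasters:
            raise ValueError("RepeatSet needs at least one raster")
        n, t, dt = (
            self.rasters[0].n_cells,
            self.rasters[0].n_bins,
            self.rasters[0].bin_width,
        )
        for r in self.rasters[1:]:
            if r.n_cells != n or r.n_bins != t or r.bin_width != dt:
                raise ValueError("all repeats must share N, T and bin width")

    @property
    def n_repeats(self) -> int:
        return len(self.rasters)

    @property
    def n_cells(self) -> int:
        return self.rasters[0].n_cells

    @property
    def n_bins(self) -> int:
        return self.rasters[0].n_bins

    def stack(self) -> np.ndarray:
        """Return an R x N x T array."""
        return np.stack([r.data for r in self.rasters])


def bin_spikes(spikes: SpikeTrainSet, bin_width: float = 0.020) -> BinaryRaster:
    """Bin spike trains into a binary raster.

    Entry (i, t) is 1 iff cell i fired at least once in ``[t*dt, (t+1)*dt)``.
    Multiple spikes in one bin still give 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if spikes.n_cells == 0:
        raise ValueError("no cells")
    n_bins = int(np.ceil(spikes.duration / bin_width))
    data = np.zeros((spikes.n_cells, n_bins), dtype=np.uint8)
    for i, times in enumerate(spikes.spikes):
        idx = np.floor(times / bin_width).astype(int)
        idx = idx[idx < n_bins]  # boundary spikes at duration edge dropped
        data[i, idx] = 1
    return BinaryRaster(data, bin_width)


def circular_shuffle(raster: BinaryRaster, seed: int) -> BinaryRaster:
    """Independently circularly shift each cell's row by a random offset.

    Destroys cross-cell correlation while preserving every per-cell spike
    count and (circular) autocorrelation exactly.
    """
    if raster.n_bins < 2:
        raise ValueError("need at least 2 bins")
    rng = np.random.default_rng(seed)
    out = np.empty_like(raster.data)
    shifts = rng.integers(0, raster.n_bins, size=raster.n_cells)
    for i, s in enumerate(shifts):
        out[i] = np.roll(raster.data[i], int(s))
    return BinaryRaster(out, raster.bin_width, list(raster.cell_ids))


def words_to_strings(words: np.ndarray) -> list[str]:
    """Encode binary words (columns of an N x K array) as 0/1 strings.

    Cell 0 is the leftmost (most significant) character.
    """
    words = np.asarray(words)
    if words.ndim == 1:
        words = words[:, None]
    return ["".join("1" if b else "0" for b in words[:, k]) for k in range(words.shape[1])]


def word_frequencies(raster: BinaryRaster) -> pd.DataFrame:
    """Tabulate the distinct population words of a raster.

    Returns a DataFrame with columns ``word`` (0/1 string, cell 0 first),
    ``count`` and ``frequency``, sorted by decreasing count then word.
    """
    uniq, counts = np.unique(raster.data, axis=1, return_counts=True)
    words = words_to_strings(uniq)
    df = pd.DataFrame(
        {
            "word": words,
            "count": counts,
            "frequency": counts / raster.n_bins,
        }
    )
    df = df.sort_values(
        ["count", "word"], ascending=[False, True], ignore_index=True
    )
    return df


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_spike_csv(path) -> SpikeTrainSet:
    """Read a ``cell_id,time_s`` CSV into a SpikeTrainSet.

    Duration is taken as the latest spike time plus one microsecond unless
    the file is empty.
    """
    df = pd.read_csv(path)
    if not {"cell_id", "time_s"}.issubset(df.columns):
        raise ValueError("spike CSV must have columns cell_id,time_s")
    n_cells = int(df["cell_id"].max()) + 1 if len(df) else 0
    if n_cells == 0:
        raise ValueError("no cells")
    spikes = [
        np.sort(df.loc[df["cell_id"] == i, "time_s"].to_numpy())
        for i in range(n_cells)
    ]
    duration = float(df["time_s"].max()) + 1e-6
    return SpikeTrainSet(spikes, duration)


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_raster_tsv(raster: BinaryRaster, path) -> None:
    """Write a raster as TSV: one row per cell, 0/1 values, no header."""
    with _open_text(path, "w") as fh:
        for row in raster.data:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_raster_tsv(path, bin_width: float = 0.020) -> BinaryRaster:
    with _open_text(path, "r") as fh:
        rows = [
            [int(v) for v in line.split()] for line in fh if line.strip()
        ]
    return BinaryRaster(np.array(rows, dtype=np.uint8), bin_width)
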