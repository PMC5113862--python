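"""Post-fit structural analyses of a fitted mode model.

Transition entropies, dwell-time statistics of a decoded path, threshold
curves of cell participation in modes, and pairwise Fisher-LDA
discriminability of the word clouds assigned to each mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hmm import HMMParams, ModePath
from .raster import BinaryRaster
from .tree import TreeEmission

__all__ = [
    "DiscriminabilityReport",
    "transition_entropy",
    "dwell_times",
    "mode_participation",
    "lda_dprime",
]


@dataclass
class DiscriminabilityReport:
    """Pairwise mode separability along the Fisher discriminant."""

    dprime: np.ndarray  # (M, M), symmetric, 0 diagonal, NaN for skipped modes
    nearest_neighbor: np.ndarray  # per-mode index of the closest other mode
    nearest_dprime: np.ndarray  # per-mode smallest off-diagonal d'


def transition_entropy(
    model: HMMParams, off_diagonal_only: bool = False
) -> np.ndarray:
    """Entropy (bits) of each mode's outgoing transition distribution.

    With ``off_diagonal_only`` the self-transition is removed and the
    remaining column renormalized: p~(a|b) = p(a|b) / (1 - p(b|b)).
    """
    P = model.transition
    M = model.n_modes
    out = np.empty(M)
    for b in range(M):
        col = P[:, b].copy()
        if off_diagonal_only:
            if col[b] >= 1 - 1e-15:
                raise ValueError(
                    f"mode {b}: self-transition is 1; off-diagonal "
                    "distribution undefined"
                )
            col[b] = 0.0
            col = col / col.sum()
        nz = col[col > 0]
        out[b] = float(-(nz * np.log2(nz)).sum())
    return out


def dwell_times(
    path: ModePath, bin_width: float = 0.020
) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    """Mean dwell time (seconds) and run-length lists per mode.

    A dwell is a maximal run of consecutive bins in the same mode.
    """
    p = path.path
    if p.size == 0:
        raise ValueError("empty path")
    change = np.nonzero(np.diff(p))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [p.size]])
    runs: dict[int, list[int]] = {}
    for s, e in zip(starts, ends):
        runs.setdefault(int(p[s]), []).append(e - s)
    run_lengths = {a: np.array(v) for a, v in runs.items()}
    mean_dwell = {
        a: float(v.mean() * bin_width) for a, v in run_lengths.items()
    }
    return mean_dwell, run_lengths


def mode_participation(
    emissions: list[TreeEmission], theta: float
) -> dict:
    """Cells-per-mode and modes-per-cell counts at threshold theta.

    Cell i participates in mode a iff m_ia / mbar_i >= theta, where mbar_i
    is the unweighted mean of the cell's spiking probability across modes.
    Cells with mbar_i = 0 are excluded with a warning.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    m = np.stack([e.marginals for e in emissions])  # (M, N)
    mbar = m.mean(axis=0)
    ok = mbar > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} cells have zero mean rate; excluded",
            stacklevel=2,
        )
    ratio = np.full_like(m, -np.inf)
    ratio[:, ok] = m[:, ok] / mbar[ok]
    member = ratio >= theta  # (M, N)
    cells_per_mode = member.sum(axis=1)
    modes_per_cell = member[:, ok].sum(axis=0)
    return {
        "cells_per_mode": cells_per_mode,
        "modes_per_cell": modes_per_cell,
        "mean_cells_per_mode": float(cells_per_mode.mean()),
        "mean_modes_per_cell": float(modes_per_cell.mean())
        if modes_per_cell.size
        else 0.0,
    }


def _fisher_dprime(x1: np.ndarray, x2: np.ndarray) -> float:
    """d' between two word sets (rows = words) along the Fisher direction.

    The pooled within-class covariance is shrunk by lambda*I with
    lambda = 1e-3 * trace / N to handle the rank deficiency of binary
    word clouds.
    """
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    n = x1.shape[1]
    s1 = np.cov(x1, rowvar=False, bias=True) if x1.shape[0] > 1 else np.zeros((n, n))
    s2 = np.cov(x2, rowvar=False, bias=True) if x2.shape[0] > 1 else np.zeros((n, n))
    pooled = np.atleast_2d((s1 + s2) / 2.0)
    lam = 1e-3 * max(np.trace(pooled), 1e-12) / n
    w = np.linalg.solve(pooled + lam * np.eye(n), mu1 - mu2)
    z1, z2 = x1 @ w, x2 @ w
    denom = np.sqrt((z1.var() + z2.var()) / 2.0)
    if denom == 0:
        return 0.0 if np.isclose(z1.mean(), z2.mean()) else np.inf
    return float(abs(z1.mean() - z2.mean()) / denom)


def lda_dprime(
    raster: BinaryRaster,
    path: ModePath,
    n_modes: int | None = None,
    exclude_transition_bins: bool = True,
    shuffle_control: bool = False,
    seed: int = 0,
) -> DiscriminabilityReport:
    """Pairwise Fisher-LDA d' between the word clouds of all mode pairs.

    Bins within one time bin of a mode switch are dropped (unless
    ``exclude_transition_bins`` is False); each mode contributes its set of
    *unique* words.  ``shuffle_control`` randomly permutes the bin-to-mode
    assignment (preserving per-mode bin counts) before the analysis.
    """
    data = raster.data
    p = path.path.copy()
    if n_modes is None:
        n_modes = int(p.max()) + 1
    if shuffle_control:
        rng = np.random.default_rng(seed)
        p = rng.permutation(p)
    keep = np.ones(p.size, dtype=bool)
    if exclude_transition_bins:
        switch = np.nonzero(np.diff(p))[0]
        for s in switch:
            keep[max(0, s) : min(p.size, s + 2)] = False
    word_sets: list[np.ndarray | None] = []
    for a in range(n_modes):
        idx = np.nonzero((p == a) & keep)[0]
        if idx.size == 0:
            word_sets.append(None)
            continue
        uniq = np.unique(data[:, idx], axis=1).T.astype(float)  # rows = words
        word_sets.append(uniq if uniq.shape[0] >= 2 else None)
    skipped = [a for a, w in enumerate(word_sets) if w is None]
    if skipped:
        warnings.warn(
            f"modes {skipped} have fewer than 2 unique words; excluded",
            stacklevel=2,
        )
    dp = np.full((n_modes, n_modes), np.nan)
    np.fill_diagonal(dp, 0.0)
    for a in range(n_modes):
        for b in range(a + 1, n_modes):
            if word_sets[a] is None or word_sets[b] is None:
                continue
            dp[a, b] = dp[b, a] = _fisher_dprime(word_sets[a], word_sets[b])
    nn = np.full(n_modes, -1, dtype=int)
    nn_d = np.full(n_modes, np.nan)
    for a in range(n_modes):
        off = dp[a].copy()
        off[a] = np.nan
        if np.isfinite(off).any():
            nn[a] = int(np.nanargmin(off))
            nn_d[a] = off[nn[a]]
    return DiscriminabilityReport(dprime=dp, nearest_neighbor=nn, nearest_dprime=nn_d)
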