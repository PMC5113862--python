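"""Repeat-based reliability of modes and words.

Given R aligned repeats of the same stimulus, each mode (or word) yields an
R x T binary activation matrix.  From it we measure how much of the
activation entropy is stimulus-locked (information efficiency), how often
events recur across repeats within a short window, and the trial-to-trial
Hamming noise of the raw words.  Two randomized null models — shuffled mode
means and a random deterministic word-to-mode partition — plus a
time-permutation chance baseline calibrate these numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import (
    HMMParams,
    StationaryMixture,
    refit_transition_matrix,
    viterbi,
)
from .raster import BinaryRaster, RepeatSet, words_to_strings
from .tree import TreeEmission

__all__ = [
    "ActivationMatrix",
    "mode_activation_matrices",
    "information_efficiency",
    "event_reproducibility",
    "hamming_noise",
    "shuffled_means_control",
    "random_partition_control",
    "partition_activation_matrices",
    "chance_baseline",
]


@dataclass
class ActivationMatrix:
    """R x T binary activation of one mode (or word) across repeats."""

    active: np.ndarray
    bin_width: float = 0.020

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active).astype(np.uint8)
        if self.active.ndim != 2:
            raise ValueError("activation matrix must be R x T")

    @property
    def n_repeats(self) -> int:
        return self.active.shape[0]

    def r_t(self) -> np.ndarray:
        """Fraction of repeats on which the event was active, per bin."""
        return self.active.mean(axis=0)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    q = p[mask]
    out[mask] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out


def information_efficiency(act: ActivationMatrix) -> dict[str, float]:
    """Stimulus-locked fraction of a mode's activation entropy.

    S_out is the binary entropy of the grand-mean activation rate; S_noise
    the time average of the per-bin across-repeat entropy; efficiency
    (S_out - S_noise) / S_out, defined as 0 when S_out = 0.
    """
    if act.n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    r = act.r_t()
    rbar = float(r.mean())
    s_out = float(_binary_entropy(np.array(rbar)))
    s_noise = float(_binary_entropy(r).mean())
    eff = 0.0 if s_out == 0 else (s_out - s_noise) / s_out
    return {"S_out": s_out, "S_noise": s_noise, "efficiency": eff}


def event_reproducibility(act: ActivationMatrix, window: float = 0.080) -> float:
    """Cross-repeat recurrence of an event within a +/- time window.

    For every (repeat, bin) occurrence, the fraction of the other repeats
    containing an occurrence within ``window`` seconds of that bin; averaged
    over all occurrences.  Default 80 ms = +/-4 bins at 20 ms.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    a = act.active
    R, T = a.shape
    w_bins = int(round(window / act.bin_width))
    occ_r, occ_t = np.nonzero(a)
    if occ_r.size == 0:
        raise ValueError("event never occurs")
    # near[r, t]: repeat r has an occurrence within +/- w_bins of bin t
    near = np.zeros((R, T), dtype=bool)
    for d in range(-w_bins, w_bins + 1):
        lo, hi = max(0, -d), min(T, T - d)
        if hi <= lo:
            continue
        near[:, lo:hi] |= a[:, lo + d : hi + d].astype(bool)
    fracs = []
    for r, t in zip(occ_r, occ_t):
        others = np.delete(near[:, t], r)
        fracs.append(others.mean())
    return float(np.mean(fracs))


def hamming_noise(
    repeats: RepeatSet,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean Hamming distance between same-bin words across repeat pairs.

    Returns the per-bin mean distance and a table aggregating it against
    the mean spike count k of each bin.
    """
    stack = repeats.stack().astype(np.int64)  # (R, N, T)
    R = stack.shape[0]
    if R < 2:
        raise ValueError("need at least 2 repeats")
    total = np.zeros(stack.shape[2])
    n_pairs = 0
    for i in range(R):
        for j in range(i + 1, R):
            total += np.abs(stack[i] - stack[j]).sum(axis=0)
            n_pairs += 1
    per_bin = total / n_pairs
    k = stack.sum(axis=1).mean(axis=0)  # mean spike count per bin
    df = (
        pd.DataFrame({"k": np.round(k).astype(int), "hamming": per_bin})
        .groupby("k")["hamming"]
        .agg(["mean", "count"])
        .reset_index()
    )
    return per_bin, df


def mode_activation_matrices(
    model: HMMParams, repeats: RepeatSet
) -> list[ActivationMatrix]:
    """Viterbi-decode each repeat; one R x T activation matrix per mode."""
    paths = np.stack([viterbi(model, r).path for r in repeats.rasters])
    dt = repeats.rasters[0].bin_width
    return [
        ActivationMatrix((paths == a).astype(np.uint8), dt)
        for a in range(model.n_modes)
    ]


def shuffled_means_control(
    model: HMMParams, raster: BinaryRaster, seed: int
) -> HMMParams:
    """Null model: permute each mode's mean vector across cells, refit P.

    Requires independent (edge-free) emissions.  The permuted means are
    frozen while the transition matrix and initial vector are re-optimized
    by EM on the supplied raster.
    """
    if any(e.edges for e in model.emissions):
        raise ValueError("shuffled-means control requires independent emissions")
    rng = np.random.default_rng(seed)
    emissions = [
        TreeEmission(rng.permutation(e.marginals), [], np.empty((0, 2, 2)))
        for e in model.emissions
    ]
    shuffled = HMMParams(
        n_modes=model.n_modes,
        transition=model.transition.copy(),
        initial=model.initial.copy(),
        emissions=emissions,
        eta=model.eta,
    )
    return refit_transition_matrix(shuffled, raster)


def random_partition_control(
    word_table: pd.DataFrame,
    mode_weights: np.ndarray,
    seed: int,
) -> dict[str, int]:
    """Deterministic random mapping of words onto modes, mass-matched.

    Each mode starts with capacity equal to its weight.  Words are visited
    in decreasing probability; each goes to a uniformly random mode whose
    remaining capacity is at least the word's probability, and that capacity
    is decremented.  When no mode qualifies the word is assigned uniformly
    at random.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(mode_weights, dtype=float)
    M = weights.size
    capacity = weights.copy()
    table = word_table.sort_values(
        ["frequency", "word"], ascending=[False, True]
    )
    assignment: dict[str, int] = {}
    for word, prob in zip(table["word"], table["frequency"]):
        ok = np.nonzero(capacity >= prob)[0]
        if ok.size:
            a = int(rng.choice(ok))
            capacity[a] -= prob
        else:
            a = int(rng.integers(M))
        assignment[word] = a
    return assignment


def partition_activation_matrices(
    assignment: dict[str, int],
    n_modes: int,
    repeats: RepeatSet,
) -> list[ActivationMatrix]:
    """Activation matrices for the word-partition control modes.

    Mode a is "active" at (repeat, bin) iff the word there maps to a.
    Unseen words activate no mode.
    """
    dt = repeats.rasters[0].bin_width
    R, T = repeats.n_repeats, repeats.n_bins
    labels = np.full((R, T), -1, dtype=int)
    for r, raster in enumerate(repeats.rasters):
        for t, w in enumerate(words_to_strings(raster.data)):
            labels[r, t] = assignment.get(w, -1)
    return [
        ActivationMatrix((labels == a).astype(np.uint8), dt)
        for a in range(n_modes)
    ]


def chance_baseline(act: ActivationMatrix, seed: int) -> dict[str, float]:
    """Efficiency after independently permuting the time bins of each repeat."""
    if act.n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    rng = np.random.default_rng(seed)
    permuted = np.stack([rng.permutation(row) for row in act.active])
    return information_efficiency(ActivationMatrix(permuted, act.bin_width))
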