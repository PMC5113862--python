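"""Ground-truth generators for end-to-end testing of the pipeline.

Two generators: (1) mode-HMM populations with a dominant near-silent mode
plus active modes that each recruit a small subset of cells, with a
separation knob that interpolates from fully degenerate (all modes
identical) to strongly distinct; (2) repeat structure built by reusing one
master mode path across repeats with per-bin jitter, mimicking
stimulus-locked latent dynamics with trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import HMMParams, ModePath
from .raster import BinaryRaster, RepeatSet
from .tree import TreeEmission, floor_joint, sample_emission

__all__ = ["GroundTruth", "make_ground_truth_model", "simulate_repeats"]


@dataclass
class GroundTruth:
    """A generated model together with the data sampled from it."""

    model: HMMParams
    mode_paths: list[ModePath]
    rasters: RepeatSet
    provenance: dict = field(default_factory=dict)


def _chain_tree(
    marginals: np.ndarray, corr: float, rng: np.random.Generator, eps: float = 1e-6
) -> TreeEmission:
    """Random chain tree with uniform positive edge correlation ``corr``."""
    n = marginals.size
    if n == 1 or corr == 0:
        return TreeEmission(marginals, [], np.empty((0, 2, 2)))
    order = rng.permutation(n)
    edges = [tuple(sorted((int(order[k]), int(order[k + 1])))) for k in range(n - 1)]
    joints = np.empty((len(edges), 2, 2))
    for e, (i, j) in enumerate(edges):
        mi, mj = marginals[i], marginals[j]
        p11 = mi * mj + corr * np.sqrt(mi * (1 - mi) * mj * (1 - mj))
        joints[e] = floor_joint(mi, mj, p11, eps)
    return TreeEmission(marginals, edges, joints)


def make_ground_truth_model(
    n_cells: int,
    n_modes: int,
    separation: float = 1.0,
    self_transition: float = 0.7,
    seed: int = 0,
    active_cells_per_mode: int = 10,
    edge_corr: float = 0.2,
) -> HMMParams:
    """Generate a mode HMM with controllable mode separation.

    Mode 0 is near-silent (all marginals <= 0.01).  Each remaining mode
    lifts the rates of a random ~``active_cells_per_mode``-cell subset by an
    amount proportional to ``separation``; at separation 0 every mode
    collapses onto the common baseline and the modes are identical.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if not 0 <= separation <= 1 or not 0 <= self_transition <= 1:
        raise ValueError("separation and self_transition must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(0.002, 0.01, size=n_cells)
    emissions = [
        _chain_tree(baseline.copy(), 0.0, rng)  # silent mode: independent
    ]
    for _ in range(1, n_modes):
        active = rng.choice(
            n_cells, size=min(active_cells_per_mode, n_cells), replace=False
        )
        m = baseline.copy()
        m[active] += separation * rng.uniform(0.35, 0.65, size=active.size)
        emissions.append(_chain_tree(m, edge_corr * separation, rng))
    # transition: fixed diagonal, Dirichlet off-diagonal mass per column
    P = np.zeros((n_modes, n_modes))
    for b in range(n_modes):
        if n_modes == 1:
            P[b, b] = 1.0
            continue
        off = rng.dirichlet(np.ones(n_modes - 1)) * (1 - self_transition)
        col = np.insert(off, b, self_transition)
        P[:, b] = col
    initial = np.full(n_modes, 1.0 / n_modes)
    model = HMMParams(
        n_modes=n_modes,
        transition=P,
        initial=initial,
        emissions=emissions,
        meta={
            "generator": "make_ground_truth_model",
            "seed": seed,
            "separation": separation,
            "self_transition": self_transition,
        },
    )
    model.validate()
    return model


def _sample_chain(model: HMMParams, T: int, rng: np.random.Generator) -> np.ndarray:
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transition, axis=0)
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    path[0] = np.searchsorted(cum_init, u[0])
    for t in range(1, T):
        path[t] = np.searchsorted(cum_trans[:, path[t - 1]], u[t])
    return path


def _emit_words(
    model: HMMParams, path: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    data = np.zeros((model.n_cells, path.size), dtype=np.uint8)
    for a in range(model.n_modes):
        idx = np.nonzero(path == a)[0]
        if idx.size:
            data[:, idx] = sample_emission(model.emissions[a], idx.size, rng)
    return data


def simulate_repeats(
    model: HMMParams,
    T: int,
    n_repeats: int,
    jitter: float = 0.0,
    seed: int = 0,
    bin_width: float = 0.020,
) -> GroundTruth:
    """Sample repeat rasters sharing one stimulus-locked master mode path.

    A single master path is drawn from the chain.  Each repeat copies it but,
    independently at each bin with probability ``jitter``, resamples the
    bin's mode from the transition distribution conditioned on the repeat's
    previous bin.  jitter 0 gives identical paths with independent emission
    noise; jitter 1 gives fully independent chain draws.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not 0 <= jitter <= 1:
        raise ValueError("jitter must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    master = _sample_chain(model, T, rng)
    cum_trans = np.cumsum(model.transition, axis=0)
    paths, rasters = [], []
    for _r in range(n_repeats):
        path = master.copy()
        flips = rng.random(T) < jitter
        u = rng.random(T)
        for t in np.nonzero(flips)[0]:
            if t == 0:
                path[t] = np.searchsorted(np.cumsum(model.initial), u[t])
            else:
                path[t] = np.searchsorted(cum_trans[:, path[t - 1]], u[t])
        paths.append(ModePath(path))
        rasters.append(BinaryRaster(_emit_words(model, path, rng), bin_width))
    return GroundTruth(
        model=model,
        mode_paths=paths,
        rasters=RepeatSet(rasters),
        provenance={
            "seed": seed,
            "T": T,
            "n_repeats": n_repeats,
            "jitter": jitter,
            "master_path": master.tolist(),
        },
    )
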