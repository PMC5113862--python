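"""Hidden Markov model over latent population modes.

The latent state ("mode") evolves as a stationary Markov chain with
column-stochastic transition matrix P[a, b] = P(mode a at t | mode b at
t-1); each mode emits the binary population word of a time bin from its own
tree-structured distribution (:mod:`popmodes.tree`).

Fitting is Baum-Welch EM with an M-step adapted to the tree emissions:
mode-conditional marginal and pairwise tables are estimated from the
posterior responsibilities, shrunk toward the global (mode-independent)
tables with weight ``eta``, and the spanning tree of each mode is re-selected
from the shrunk statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from . import _chain
from .raster import BinaryRaster, words_to_strings
from .tree import (
    DEFAULT_EPS,
    TreeEmission,
    emission_logprob,
    pairwise_tables,
    sample_emission,
    tree_from_tables,
)

__all__ = [
    "HMMParams",
    "Posteriors",
    "ModePath",
    "StationaryMixture",
    "forward_backward",
    "baum_welch_fit",
    "refit_transition_matrix",
    "viterbi",
    "stationary_weights",
    "static_log_likelihood",
    "select_num_modes",
    "sample_hmm",
]

DEFAULT_ETA = 0.002


@dataclass
class HMMParams:
    """Parameters of the mode HMM."""

    n_modes: int
    transition: np.ndarray  # (M, M), columns sum to 1
    initial: np.ndarray  # (M,)
    emissions: list[TreeEmission]
    eta: float = DEFAULT_ETA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.emissions[0].n_cells

    def validate(self, atol: float = 1e-10) -> None:
        m = self.n_modes
        if m < 1 or len(self.emissions) != m:
            raise ValueError("n_modes / emissions mismatch")
        if self.transition.shape != (m, m):
            raise ValueError("transition matrix has wrong shape")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValueError("negative probabilities")
        if not np.allclose(self.transition.sum(axis=0), 1, atol=atol):
            raise ValueError("transition columns must sum to 1")
        if not np.isclose(self.initial.sum(), 1, atol=atol):
            raise ValueError("initial distribution must sum to 1")
        for em in self.emissions:
            em.validate()

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "n_modes": self.n_modes,
            "eta": self.eta,
            "transition": self.transition.ravel().tolist(),
            "initial": self.initial.tolist(),
            "emissions": [e.to_dict() for e in self.emissions],
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "HMMParams":
        with open(path) as fh:
            obj = json.load(fh)
        m = obj["n_modes"]
        return cls(
            n_modes=m,
            transition=np.array(obj["transition"]).reshape(m, m),
            initial=np.array(obj["initial"]),
            emissions=[TreeEmission.from_dict(d) for d in obj["emissions"]],
            eta=obj.get("eta", DEFAULT_ETA),
            meta=obj.get("meta", {}),
        )


@dataclass
class Posteriors:
    """E-step output: per-bin and pairwise mode posteriors."""

    gamma: np.ndarray  # (T, M)
    xi: np.ndarray  # (T-1, M, M); xi[t, a, b] = P(z_{t+1}=a, z_t=b | data)
    loglik: float


@dataclass
class ModePath:
    """Decoded mode index per time bin."""

    path: np.ndarray

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.int64)

    def __len__(self) -> int:
        return self.path.size


@dataclass
class StationaryMixture:
    """Static word distribution: mode weights solving w = P w."""

    weights: np.ndarray
    emissions: list[TreeEmission]

    def log_word_prob(self, words: np.ndarray) -> np.ndarray:
        """Natural-log mixture probability of words (N x K)."""
        logq = np.stack(
            [emission_logprob(e, words) for e in self.emissions]
        )  # (M, K)
        return logsumexp(logq + np.log(self.weights)[:, None], axis=0)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _as_data(raster) -> np.ndarray:
    return raster.data if isinstance(raster, BinaryRaster) else np.asarray(raster)


def emission_log_matrix(model: HMMParams, data: np.ndarray) -> np.ndarray:
    """logB[a, t] = log Q_a(word at bin t); shape (M, T)."""
    return np.stack([emission_logprob(e, data) for e in model.emissions])


def _scaled_B(logB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    offsets = logB.max(axis=0)
    return np.exp(logB - offsets), offsets


def forward_backward(model: HMMParams, raster) -> Posteriors:
    """Exact posteriors and sequence log-likelihood via scaled recursions."""
    if not np.allclose(model.transition.sum(axis=0), 1, atol=1e-8):
        raise ValueError("transition matrix columns must sum to 1")
    data = _as_data(raster)
    logB = emission_log_matrix(model, data)
    B, offsets = _scaled_B(logB)
    alpha, c = _chain.forward(model.transition, B, model.initial)
    beta = _chain.backward(model.transition, B, c)
    gamma = (alpha * beta).T
    gamma /= gamma.sum(axis=1, keepdims=True)
    T = data.shape[1]
    xi = np.empty((T - 1, model.n_modes, model.n_modes))
    for t in range(T - 1):
        x = (
            model.transition
            * alpha[:, t][None, :]
            * (B[:, t + 1] * beta[:, t + 1] / c[t + 1])[:, None]
        )
        xi[t] = x / x.sum()
    loglik = float(np.log(c).sum() + offsets.sum())
    return Posteriors(gamma=gamma, xi=xi, loglik=loglik)


def viterbi(model: HMMParams, raster) -> ModePath:
    """Most probable full mode sequence; ties go to the lower mode index."""
    data = _as_data(raster)
    logB = emission_log_matrix(model, data)
    with np.errstate(divide="ignore"):
        logP = np.log(model.transition)
        logpi = np.log(model.initial)
    return ModePath(_chain.viterbi_path(logP, logB, logpi))


def stationary_weights(model: HMMParams) -> StationaryMixture:
    """Solve w = P w for the unique stationary mode distribution.

    Raises if the chain is reducible (multiple strongly connected
    components), in which case the stationary distribution is not unique.
    """
    P = model.transition
    n_comp, _ = connected_components(csr_matrix(P > 0), connection="strong")
    if n_comp > 1:
        raise ValueError("no unique stationary distribution")
    m = model.n_modes
    A = np.vstack([P - np.eye(m), np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    w, *_ = np.linalg.lstsq(A, b, rcond=None)
    w = np.clip(w, 0, None)
    w /= w.sum()
    return StationaryMixture(weights=w, emissions=model.emissions)


def static_log_likelihood(
    mixture: StationaryMixture, raster, min_count: int = 1
) -> tuple[pd.DataFrame, float]:
    """Per-word mixture log-probabilities and the summary statistic

        L = sum_w f_emp(w) ln P_mix(w),

    restricted to words observed at least ``min_count`` times (frequencies
    stay normalized over *all* observed words).  L is the mean per-bin
    natural-log likelihood when ``min_count`` is 1.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    data = _as_data(raster)
    uniq, counts = np.unique(data, axis=1, return_counts=True)
    freq = counts / data.shape[1]
    logp = mixture.log_word_prob(uniq)
    table = pd.DataFrame(
        {
            "word": words_to_strings(uniq),
            "count": counts,
            "frequency": freq,
            "log_pmodel": logp,
        }
    )
    keep = counts >= min_count
    L = float((freq[keep] * logp[keep]).sum())
    return table, L


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _estep_sums(model: HMMParams, data: np.ndarray):
    """Gamma, summed xi and log-likelihood without materializing full xi."""
    logB = emission_log_matrix(model, data)
    B, offsets = _scaled_B(logB)
    alpha, c = _chain.forward(model.transition, B, model.initial)
    beta = _chain.backward(model.transition, B, c)
    gamma = (alpha * beta).T
    gamma /= gamma.sum(axis=1, keepdims=True)
    xs = _chain.xi_sums(model.transition, B, c, alpha, beta)
    loglik = float(np.log(c).sum() + offsets.sum())
    return gamma, xs, loglik


def _emissions_from_responsibilities(
    data: np.ndarray,
    gamma: np.ndarray,
    eta: float,
    eps: float,
    tree: bool,
    global_tables: tuple[np.ndarray, np.ndarray],
) -> list[TreeEmission]:
    g_m, g_p11 = global_tables
    fdata = data.astype(float)
    emissions = []
    for a in range(gamma.shape[1]):
        w = gamma[:, a]
        tot = w.sum()
        if tot <= 0:
            m, p11 = g_m, g_p11
        else:
            m = fdata @ w / tot
            p11 = (fdata * w) @ fdata.T / tot
        m = (1 - eta) * m + eta * g_m
        p11 = (1 - eta) * p11 + eta * g_p11
        emissions.append(tree_from_tables(m, p11, eps=eps, tree=tree))
    return emissions


def _transition_from_xi(xs: np.ndarray) -> np.ndarray:
    col = xs.sum(axis=0)
    P = np.where(col > 0, xs / np.where(col > 0, col, 1.0), 1.0 / xs.shape[0])
    return P


def baum_welch_fit(
    raster,
    n_modes: int,
    eta: float = DEFAULT_ETA,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    tree: bool = True,
    eps: float = DEFAULT_EPS,
) -> HMMParams:
    """Fit the mode HMM by EM with multiple seeded restarts.

    Each restart assigns every bin a uniformly random mode, runs an M-step
    from those hard responsibilities, then iterates E/M until the relative
    training log-likelihood improvement drops below ``tol``.  The restart
    with the best final training log-likelihood wins.

    Set ``tree=False`` for independent (edge-free) emission distributions.
    """
    data = _as_data(raster)
    n, T = data.shape
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if T <= n_modes:
        raise ValueError("need more bins than modes")
    rng = np.random.default_rng(seed)
    global_tables = pairwise_tables(data, np.ones(T))
    best: HMMParams | None = None
    for _ in range(max(1, n_restarts)):
        labels = rng.integers(0, n_modes, size=T)
        gamma = np.zeros((T, n_modes))
        gamma[np.arange(T), labels] = 1.0
        counts = np.full((n_modes, n_modes), 0.1)
        np.add.at(counts, (labels[1:], labels[:-1]), 1.0)
        model = HMMParams(
            n_modes=n_modes,
            transition=counts / counts.sum(axis=0, keepdims=True),
            initial=np.full(n_modes, 1.0 / n_modes),
            emissions=_emissions_from_responsibilities(
                data, gamma, eta, eps, tree, global_tables
            ),
            eta=eta,
        )
        history: list[float] = []
        prev = -np.inf
        for _it in range(max_iter):
            gamma, xs, loglik = _estep_sums(model, data)
            history.append(loglik)
            if np.isfinite(prev) and loglik - prev < tol * abs(prev):
                break
            prev = loglik
            model = HMMParams(
                n_modes=n_modes,
                transition=_transition_from_xi(xs),
                initial=gamma[0] / gamma[0].sum(),
                emissions=_emissions_from_responsibilities(
                    data, gamma, eta, eps, tree, global_tables
                ),
                eta=eta,
            )
        model.meta = {
            "train_loglik": history[-1],
            "loglik_history": history,
            "n_iter": len(history),
            "seed": seed,
            "n_cells": n,
            "n_bins": T,
        }
        if best is None or model.meta["train_loglik"] > best.meta["train_loglik"]:
            best = model
    return best


def refit_transition_matrix(
    model: HMMParams,
    raster,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> HMMParams:
    """EM that re-estimates only the transition matrix and initial vector.

    Emission distributions are held fixed; used by the shuffled-means
    control.
    """
    data = _as_data(raster)
    cur = HMMParams(
        n_modes=model.n_modes,
        transition=model.transition.copy(),
        initial=model.initial.copy(),
        emissions=model.emissions,
        eta=model.eta,
    )
    prev = -np.inf
    for _ in range(max_iter):
        gamma, xs, loglik = _estep_sums(cur, data)
        if np.isfinite(prev) and loglik - prev < tol * abs(prev):
            break
        prev = loglik
        cur = HMMParams(
            n_modes=cur.n_modes,
            transition=_transition_from_xi(xs),
            initial=gamma[0] / gamma[0].sum(),
            emissions=cur.emissions,
            eta=cur.eta,
        )
    cur.meta = dict(model.meta, refit_loglik=prev)
    return cur


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def select_num_modes(
    raster,
    candidates,
    n_folds: int = 2,
    eta: float = DEFAULT_ETA,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, int]:
    """Choose the number of modes by contiguous-block cross-validation.

    The raster is cut into ``n_folds`` contiguous time blocks; for each
    candidate M the model is trained on all-but-one block and scored on the
    held-out block with the per-bin static mixture log-likelihood.  Returns
    the per-M table and the argmax M.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate mode counts")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    data = _as_data(raster)
    T = data.shape[1]
    bounds = np.linspace(0, T, n_folds + 1).astype(int)
    blocks = [(bounds[i], bounds[i + 1]) for i in range(n_folds)]
    if min(b - a for a, b in blocks) < 2:
        raise ValueError("fold blocks must span at least 2 bins")
    rows = []
    for m in candidates:
        fold_lls = []
        for k, (a, b) in enumerate(blocks):
            train = np.concatenate([data[:, : a], data[:, b:]], axis=1)
            test = data[:, a:b]
            model = baum_welch_fit(
                train, m, eta=eta, seed=seed + 1000 * k, **fit_kwargs
            )
            mixture = stationary_weights(model)
            _, ll = static_log_likelihood(mixture, test, min_count=1)
            fold_lls.append(ll)
        rows.append(
            {"n_modes": m, "cv_loglik": float(np.mean(fold_lls)),
             **{f"fold{k}": v for k, v in enumerate(fold_lls)}}
        )
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["cv_loglik"].idxmax(), "n_modes"])
    return table, chosen


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_hmm(
    model: HMMParams,
    T: int,
    seed: int | np.random.Generator,
    bin_width: float = 0.020,
) -> tuple[BinaryRaster, ModePath]:
    """Sample a mode chain and the corresponding words."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    M = model.n_modes
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transition, axis=0)  # per column
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    path[0] = np.searchsorted(cum_init, u[0])
    for t in range(1, T):
        path[t] = np.searchsorted(cum_trans[:, path[t - 1]], u[t])
    data = np.zeros((model.n_cells, T), dtype=np.uint8)
    for a in range(M):
        idx = np.nonzero(path == a)[0]
        if idx.size:
            data[:, idx] = sample_emission(model.emissions[a], idx.size, rng)
    return BinaryRaster(data, bin_width), ModePath(path)
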