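"""Tree-structured emission distributions over binary population words.

Each latent mode emits words from a Chow-Liu dependence tree: the joint
distribution factorizes into per-cell marginals times pairwise correction
factors on the edges of a spanning tree,

    Q({s}) = prod_i p(s_i) * prod_{<i,j> in edges} p(s_i, s_j) / (p(s_i) p(s_j)).

The tree topology is the maximum spanning tree on pairwise mutual
information, which is the maximum-likelihood tree-structured model for the
(weighted) empirical statistics.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TreeEmission",
    "chow_liu_fit",
    "independent_fit",
    "emission_logprob",
    "sample_emission",
    "emission_entropy",
    "max_entropy_bound",
    "spike_count_distribution",
    "pairwise_tables",
    "floor_joint",
]

DEFAULT_EPS = 1e-6


@dataclass
class TreeEmission:
    """One mode's emission distribution.

    Parameters
    ----------
    marginals
        Length-N vector of per-cell spiking probabilities.
    edges
        Unordered cell pairs (i < j) forming a spanning tree (or, internally,
        a forest; an empty list gives an independent-cell model).
    edge_joints
        For each edge an array ``J[si, sj]`` of joint probabilities, 2x2,
        summing to 1 and consistent with the marginals of cells i and j.
    """

    marginals: np.ndarray
    edges: list[tuple[int, int]]
    edge_joints: np.ndarray

    def __post_init__(self) -> None:
        self.marginals = np.asarray(self.marginals, dtype=float)
        self.edges = [(int(i), int(j)) for i, j in self.edges]
        self.edge_joints = np.asarray(self.edge_joints, dtype=float).reshape(
            len(self.edges), 2, 2
        )

    @property
    def n_cells(self) -> int:
        return self.marginals.size

    def validate(self, atol: float = 1e-9) -> None:
        n = self.n_cells
        if np.any(self.marginals <= 0) or np.any(self.marginals >= 1):
            raise ValueError("marginals must lie strictly in (0, 1)")
        seen: set[tuple[int, int]] = set()
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (i, j), joint in zip(self.edges, self.edge_joints):
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bad edge ({i},{j})")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
            ri, rj = find(i), find(j)
            if ri == rj:
                raise ValueError("edge set contains a cycle")
            parent[ri] = rj
            if abs(joint.sum() - 1) > atol:
                raise ValueError("edge joint does not sum to 1")
            if abs(joint[1].sum() - self.marginals[i]) > 1e-9:
                raise ValueError("edge joint inconsistent with marginal i")
            if abs(joint[:, 1].sum() - self.marginals[j]) > 1e-9:
                raise ValueError("edge joint inconsistent with marginal j")
            if np.any(joint <= 0):
                raise ValueError("edge joint has non-positive entries")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "marginals": self.marginals.tolist(),
            "edges": [list(e) for e in self.edges],
            # order p00, p01, p10, p11
            "edge_joints": [j.ravel().tolist() for j in self.edge_joints],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeEmission":
        joints = np.array(d["edge_joints"], dtype=float).reshape(-1, 2, 2)
        return cls(
            np.array(d["marginals"], dtype=float),
            [tuple(e) for e in d["edges"]],
            joints,
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def pairwise_tables(
    data: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted marginals and pairwise joint-spiking probabilities.

    Returns ``(m, p11)`` with ``m[i] = P(s_i = 1)`` and
    ``p11[i, j] = P(s_i = 1, s_j = 1)`` under the weighted empirical measure.
    """
    data = np.asarray(data, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    m = data @ weights / total
    p11 = (data * weights) @ data.T / total
    return m, p11


def floor_joint(mi: float, mj: float, p11: float, eps: float) -> np.ndarray:
    """Build a strictly positive 2x2 joint consistent with (mi, mj).

    p11 is clipped to the interior of its Frechet bounds so that all four
    entries are positive while the row/column sums match the (already
    floored) marginals exactly.
    """
    lo = max(0.0, mi + mj - 1.0)
    hi = min(mi, mj)
    pad = eps * (hi - lo)
    p11 = float(np.clip(p11, lo + pad, hi - pad))
    return np.array(
        [
            [1.0 - mi - mj + p11, mj - p11],
            [mi - p11, p11],
        ]
    )


def _table_mi(joint: np.ndarray) -> float:
    """Mutual information (bits) of a 2x2 joint table."""
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / np.outer(pi, pj))
    return float(np.nansum(term))


def _max_spanning_tree(mi: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal maximum spanning tree; ties broken by lexicographic edge."""
    n = mi.shape[0]
    if n <= 1:
        return []
    cand = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (-mi[e[0], e[1]], e[0], e[1]),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int]] = []
    for i, j in cand:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return edges


def _assemble(
    m: np.ndarray,
    p11: np.ndarray,
    edges: list[tuple[int, int]],
    eps: float,
) -> TreeEmission:
    joints = np.empty((len(edges), 2, 2))
    for e, (i, j) in enumerate(edges):
        joints[e] = floor_joint(m[i], m[j], p11[i, j], eps)
    return TreeEmission(m, edges, joints)


def chow_liu_fit(
    data: np.ndarray,
    weights: np.ndarray | None = None,
    eps: float = DEFAULT_EPS,
) -> TreeEmission:
    """Fit the maximum-likelihood tree model to weighted binary words.

    Parameters
    ----------
    data
        N x T binary matrix (cells x bins).
    weights
        Per-bin non-negative weights (e.g. mode responsibilities);
        defaults to uniform.
    eps
        Probability floor applied to marginals and joint tables so that all
        log-probabilities are finite.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n == 0:
        raise ValueError("no cells")
    if weights is None:
        weights = np.ones(data.shape[1])
    m, p11 = pairwise_tables(data, weights)
    m = np.clip(m, eps, 1 - eps)
    if n == 1:
        return TreeEmission(m, [], np.empty((0, 2, 2)))
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = _table_mi(floor_joint(m[i], m[j], p11[i, j], eps))
    edges = _max_spanning_tree(mi)
    return _assemble(m, p11, edges, eps)


def independent_fit(
    data: np.ndarray,
    weights: np.ndarray | None = None,
    eps: float = DEFAULT_EPS,
) -> TreeEmission:
    """Fit an edge-free (independent-cells) emission model."""
    data = np.asarray(data)
    if data.shape[0] == 0:
        raise ValueError("no cells")
    if weights is None:
        weights = np.ones(data.shape[1])
    m, _ = pairwise_tables(data, weights)
    m = np.clip(m, eps, 1 - eps)
    return TreeEmission(m, [], np.empty((0, 2, 2)))


def tree_from_tables(
    m: np.ndarray, p11: np.ndarray, eps: float = DEFAULT_EPS, tree: bool = True
) -> TreeEmission:
    """Build a TreeEmission from marginal/pairwise tables.

    Used by the EM M-step after shrinkage; re-selects the maximum-MI
    spanning tree unless ``tree`` is False (independent model).
    """
    m = np.clip(np.asarray(m, dtype=float), eps, 1 - eps)
    n = m.size
    if not tree or n == 1:
        return TreeEmission(m, [], np.empty((0, 2, 2)))
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = _table_mi(floor_joint(m[i], m[j], p11[i, j], eps))
    edges = _max_spanning_tree(mi)
    return _assemble(m, p11, edges, eps)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def emission_logprob(model: TreeEmission, words: np.ndarray) -> np.ndarray | float:
    """Log-probability of one word (shape N) or a batch (shape N x K)."""
    words = np.asarray(words)
    scalar = words.ndim == 1
    if scalar:
        words = words[:, None]
    if words.shape[0] != model.n_cells:
        raise ValueError(
            f"word length {words.shape[0]} != n_cells {model.n_cells}"
        )
    w = words.astype(np.int64)
    m = model.marginals
    p_cell = np.where(w == 1, m[:, None], 1 - m[:, None])
    logp = np.log(p_cell).sum(axis=0)
    for (i, j), joint in zip(model.edges, model.edge_joints):
        si, sj = w[i], w[j]
        pij = joint[si, sj]
        pi = np.where(si == 1, m[i], 1 - m[i])
        pj = np.where(sj == 1, m[j], 1 - m[j])
        logp += np.log(pij) - np.log(pi) - np.log(pj)
    return float(logp[0]) if scalar else logp


def _rooted_forest(
    model: TreeEmission,
) -> list[tuple[int, list[tuple[int, int, np.ndarray]]]]:
    """Root each tree component at its lowest cell index.

    Returns a list of (root, ordered_edges) where ordered_edges are
    (parent, child, cond) tuples in BFS order and ``cond[sp, sc]`` is the
    conditional P(s_child = sc | s_parent = sp).
    """
    n = model.n_cells
    adj: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(n)}
    for (i, j), joint in zip(model.edges, model.edge_joints):
        cond_j = joint / joint.sum(axis=1, keepdims=True)  # P(sj | si)
        cond_i = joint.T / joint.sum(axis=0, keepdims=True).T  # P(si | sj)
        adj[i].append((j, cond_j))
        adj[j].append((i, cond_i))
    visited = np.zeros(n, dtype=bool)
    components = []
    for root in range(n):
        if visited[root]:
            continue
        visited[root] = True
        order: list[tuple[int, int, np.ndarray]] = []
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v, cond in adj[u]:
                if not visited[v]:
                    visited[v] = True
                    order.append((u, v, cond))
                    queue.append(v)
        components.append((root, order))
    return components


def sample_emission(
    model: TreeEmission, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n words by exact ancestral sampling; returns an N x n array."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = np.zeros((model.n_cells, n), dtype=np.uint8)
    u = rng.random((model.n_cells, n))
    for root, order in _rooted_forest(model):
        out[root] = u[root] < model.marginals[root]
        for parent, child, cond in order:
            p1 = cond[out[parent].astype(np.int64), 1]
            out[child] = u[child] < p1
    return out


def emission_entropy(model: TreeEmission) -> float:
    """Closed-form entropy (bits) of the tree distribution."""
    m = model.marginals
    h = float(-(m * np.log2(m) + (1 - m) * np.log2(1 - m)).sum())
    for (i, j), joint in zip(model.edges, model.edge_joints):
        h -= _table_mi(joint)
    return h


def max_entropy_bound(n_cells: int, k: float) -> float:
    """Entropy (bits) of the uniform distribution over words with mean count k.

    Equals log2 C(N, k) for integer k, extended to real k by the Gamma
    function.
    """
    if not 0 <= k <= n_cells:
        raise ValueError("k must lie in [0, n_cells]")
    return float(
        (gammaln(n_cells + 1) - gammaln(n_cells - k + 1) - gammaln(k + 1))
        / np.log(2)
    )


def spike_count_distribution(model: TreeEmission) -> np.ndarray:
    """Exact distribution of the population spike count k = sum_i s_i.

    Computed by dynamic programming over the tree: each node passes up a
    per-state count distribution for its subtree; children combine by
    convolution.  No sampling involved.
    """
    n = model.n_cells
    children: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(n)}
    roots = []
    for root, order in _rooted_forest(model):
        roots.append(root)
        for parent, child, cond in order:
            children[parent].append((child, cond))

    def subtree_message(v: int) -> np.ndarray:
        """msg[sv, k]: P(count in subtree(v) = k | s_v = sv), incl. v."""
        msg = np.zeros((2, 1))
        msg[0, 0] = 1.0
        msg[1, 0] = 1.0
        for child, cond in children[v]:
            cm = subtree_message(child)
            # marginalize child state given parent state sv
            contrib = np.stack(
                [cond[sv, 0] * cm[0] + cond[sv, 1] * cm[1] for sv in (0, 1)]
            )
            msg = np.stack(
                [np.convolve(msg[sv], contrib[sv]) for sv in (0, 1)]
            )
        # account for v's own spike: shift the sv=1 row by one count
        out = np.zeros((2, msg.shape[1] + 1))
        out[0, : msg.shape[1]] = msg[0]
        out[1, 1:] = msg[1]
        return out

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 100))
    try:
        total = np.ones(1)
        for root in roots:
            msg = subtree_message(root)
            p_root = np.array([1 - model.marginals[root], model.marginals[root]])
            comp = p_root @ msg
            total = np.convolve(total, comp)
    finally:
        sys.setrecursionlimit(old_limit)
    out = np.zeros(n + 1)
    out[: total.size] = total
    return out / out.sum()
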