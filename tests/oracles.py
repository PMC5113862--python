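"""Independent brute-force oracles used to check the package's fast paths.

Everything here works by explicit enumeration at tiny sizes and deliberately
avoids the library's own vectorized/DP implementations.
"""

import itertools
import math

import numpy as np


def all_words(n_cells: int) -> np.ndarray:
    """All 2^N binary words as an N x 2^N array (cell 0 most significant)."""
    words = np.array(
        list(itertools.product([0, 1], repeat=n_cells)), dtype=np.uint8
    ).T
    return words


def tree_word_prob(model, word) -> float:
    """Direct evaluation of the tree factorization for one word."""
    p = 1.0
    for i, m in enumerate(model.marginals):
        p *= m if word[i] == 1 else 1 - m
    for (i, j), joint in zip(model.edges, model.edge_joints):
        pi = model.marginals[i] if word[i] == 1 else 1 - model.marginals[i]
        pj = model.marginals[j] if word[j] == 1 else 1 - model.marginals[j]
        p *= joint[word[i], word[j]] / (pi * pj)
    return p


def tree_distribution(model) -> np.ndarray:
    """Probability of every word of the tree model, by enumeration."""
    words = all_words(model.n_cells)
    return np.array([tree_word_prob(model, words[:, k]) for k in range(words.shape[1])])


def tree_entropy_bits(model) -> float:
    probs = tree_distribution(model)
    probs = probs[probs > 0]
    return float(-(probs * np.log2(probs)).sum())


def tree_count_distribution(model) -> np.ndarray:
    words = all_words(model.n_cells)
    probs = tree_distribution(model)
    out = np.zeros(model.n_cells + 1)
    for k in range(words.shape[1]):
        out[int(words[:, k].sum())] += probs[k]
    return out


def hmm_sequence_loglik(model, data) -> float:
    """log P(data) by summing over every mode sequence explicitly."""
    T = data.shape[1]
    M = model.n_modes
    emis = [
        [tree_word_prob(model.emissions[a], data[:, t]) for a in range(M)]
        for t in range(T)
    ]
    total = 0.0
    for seq in itertools.product(range(M), repeat=T):
        p = model.initial[seq[0]] * emis[0][seq[0]]
        for t in range(1, T):
            p *= model.transition[seq[t], seq[t - 1]] * emis[t][seq[t]]
        total += p
    return math.log(total)


def hmm_best_path(model, data) -> np.ndarray:
    """Most probable mode sequence by exhaustive search (ties: first found,
    i.e. lexicographically smallest sequence)."""
    T = data.shape[1]
    M = model.n_modes
    best_p, best_seq = -1.0, None
    for seq in itertools.product(range(M), repeat=T):
        p = model.initial[seq[0]] * tree_word_prob(
            model.emissions[seq[0]], data[:, 0]
        )
        for t in range(1, T):
            p *= model.transition[seq[t], seq[t - 1]] * tree_word_prob(
                model.emissions[seq[t]], data[:, t]
            )
        if p > best_p:
            best_p, best_seq = p, seq
    return np.array(best_seq)


def tree_train_loglik(data, edges) -> float:
    """Exact ML log-likelihood of a fixed tree topology on binary data.

    Marginals and edge joints are the empirical tables; likelihood is the
    sum over samples of the log factorized probability.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[1]
    m = data.mean(axis=1)
    ll = 0.0
    for t in range(data.shape[1]):
        w = data[:, t]
        for i, mi in enumerate(m):
            ll += math.log(mi if w[i] == 1 else 1 - mi)
        for i, j in edges:
            joint = np.zeros((2, 2))
            for tt in range(T):
                joint[int(data[i, tt]), int(data[j, tt])] += 1
            joint /= T
            pi = m[i] if w[i] == 1 else 1 - m[i]
            pj = m[j] if w[j] == 1 else 1 - m[j]
            ll += math.log(joint[int(w[i]), int(w[j])] / (pi * pj))
    return ll
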