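"""Discrete-trait CTMC on a time tree: likelihood, ML rates, marginals.

A character with a small state set (by default three habitat classes)
evolves along the tree under a continuous-time Markov chain with an
asymmetric generator Q (off-diagonal rates free and nonnegative, rows
summing to zero) scaled by a strict-clock rate multiplier.  Tip states are
single-valued.  The likelihood is computed by Felsenstein pruning with
per-branch transition matrices exp(Q t); marginal ancestral state
probabilities use the standard up-down (outside) pass.  Rate fitting is
maximum likelihood over log-parameterized off-diagonal rates from a fixed
start grid, so results are deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .treeio import UltrametricTree

__all__ = [
    "TraitModel",
    "AncestralReconstruction",
    "ctmc_loglik",
    "fit_and_reconstruct",
    "marginal_reconstruction",
    "stationary_distribution",
]

DEFAULT_STATES = ("mountain", "forest", "savannah")


@dataclass
class TraitModel:
    """CTMC trait model.

    ``rates`` is the k x k matrix of infinitesimal transition rates; its
    off-diagonal entries are the free parameters (>= 0) and the diagonal is
    ignored on input (recomputed so rows of Q sum to zero).  ``multiplier``
    is an overall strict-clock scaling.  ``root`` selects the root state
    distribution: "uniform" (default), or "fixed" with ``root_probs``.
    """

    states: tuple[str, ...] = DEFAULT_STATES
    rates: Optional[np.ndarray] = None
    multiplier: float = 1.0
    root: str = "uniform"
    root_probs: Optional[np.ndarray] = None

    def __post_init__(self):
        k = len(self.states)
        if self.rates is None:
            self.rates = np.ones((k, k))
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (k, k):
            raise ValueError("rates matrix shape does not match state count")
        off = self.rates[~np.eye(k, dtype=bool)]
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be nonnegative")
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be positive")
        if self.root == "fixed":
            if self.root_probs is None:
                raise ValueError("root='fixed' requires root_probs")
            self.root_probs = np.asarray(self.root_probs, dtype=float)
            if not np.isclose(self.root_probs.sum(), 1.0):
                raise ValueError("root_probs must sum to 1")
        elif self.root != "uniform":
            raise ValueError(f"unknown root option {self.root!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def Q(self) -> np.ndarray:
        """Generator: off-diagonal rates times the multiplier, zero row sums."""
        q = self.rates.copy() * self.multiplier
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def root_distribution(self) -> np.ndarray:
        if self.root == "fixed":
            return np.asarray(self.root_probs, dtype=float)
        return np.full(self.n_states, 1.0 / self.n_states)

    def to_json_dict(self) -> dict:
        return {
            "states": list(self.states),
            "Q": self.Q.tolist(),
            "rates": self.rates.tolist(),
            "multiplier": self.multiplier,
            "root": self.root,
            "root_probs": self.root_distribution().tolist(),
        }


@dataclass
class AncestralReconstruction:
    """Marginal ancestral state probabilities at the internal nodes."""

    states: tuple[str, ...]
    probs: pd.DataFrame  # index node_id, one column per state
    map_state: dict[str, str]
    loglik: float

    def to_frame(self) -> pd.DataFrame:
        df = self.probs.copy()
        df.insert(0, "node_id", df.index)
        df["map_state"] = [self.map_state[n] for n in df.index]
        return df.reset_index(drop=True)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (left null vector of Q)."""
    k = Q.shape[0]
    a = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


# ---------------------------------------------------------------------------


def _tip_vectors(
    tree: UltrametricTree, tips: Mapping[str, str], states: Sequence[str]
) -> dict[str, np.ndarray]:
    index = {s: i for i, s in enumerate(states)}
    missing = sorted(set(tree.tip_labels) - set(tips))
    if missing:
        raise ValueError(f"tips without a state: {missing}")
    out = {}
    for label in tree.tip_labels:
        s = tips[label]
        if s not in index:
            raise ValueError(f"unknown state {s!r} for tip {label!r}")
        v = np.zeros(len(states))
        v[index[s]] = 1.0
        out[label] = v
    return out


def _branch_matrices(tree: UltrametricTree, Q: np.ndarray) -> np.ndarray:
    """exp(Q * t) for every node's subtending branch, indexed by node.index."""
    lengths = np.array([n.length for n in tree.nodes])
    return expm(Q[None, :, :] * lengths[:, None, None])


def _pruning(
    tree: UltrametricTree,
    tipvec: dict[str, np.ndarray],
    Q: np.ndarray,
    root_dist: np.ndarray,
):
    """Up pass.  Returns (loglik, up, up_msg, P, log_scale) where up[i] is the
    scaled conditional likelihood at node i and up_msg[i] the message through
    node i's branch to its parent."""
    k = Q.shape[0]
    P = _branch_matrices(tree, Q)
    n = len(tree.nodes)
    up = np.zeros((n, k))
    up_msg = np.zeros((n, k))
    log_scale = 0.0
    for node in tree.nodes:  # postorder
        i = node.index
        if node.is_leaf:
            up[i] = tipvec[node.label]
        else:
            prod = np.ones(k)
            for c in node.children:
                prod *= up_msg[c.index]
            s = prod.max()
            if s <= 0:
                return -np.inf, up, up_msg, P, log_scale
            log_scale += np.log(s)
            up[i] = prod / s
        if node.parent is not None:
            up_msg[i] = P[i] @ up[i]
    lik = float(root_dist @ up[tree.root.index])
    if lik <= 0:
        return -np.inf, up, up_msg, P, log_scale
    return float(np.log(lik) + log_scale), up, up_msg, P, log_scale


def ctmc_loglik(
    tree: UltrametricTree, tips: Mapping[str, str], model: TraitModel
) -> float:
    """Log-likelihood of the tip states under the model (pruning)."""
    tipvec = _tip_vectors(tree, tips, model.states)
    ll, *_ = _pruning(tree, tipvec, model.Q, model.root_distribution())
    return ll


def marginal_reconstruction(
    tree: UltrametricTree, tips: Mapping[str, str], model: TraitModel
) -> AncestralReconstruction:
    """Marginal state probabilities at every internal node (up-down pass)."""
    tipvec = _tip_vectors(tree, tips, model.states)
    root_dist = model.root_distribution()
    ll, up, up_msg, P, _ = _pruning(tree, tipvec, model.Q, root_dist)
    if not np.isfinite(ll):
        raise ValueError("data have zero likelihood under the model")
    k = model.n_states
    n = len(tree.nodes)
    out = np.zeros((n, k))
    out[tree.root.index] = root_dist
    # preorder: parent's outside vector combined with the sibling's message
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        a, b = node.children
        for child, sib in ((a, b), (b, a)):
            pre = out[node.index] * up_msg[sib.index]
            v = pre @ P[child.index]
            top = v.max()
            out[child.index] = v / top if top > 0 else v
            stack.append(child)
    rows = {}
    map_state = {}
    for node in tree.internal_nodes:
        m = out[node.index] * up[node.index]
        m = m / m.sum()
        rows[node.label] = m
        map_state[node.label] = model.states[int(np.argmax(m))]
    probs = pd.DataFrame.from_dict(rows, orient="index", columns=list(model.states))
    return AncestralReconstruction(model.states, probs, map_state, ll)


# ---------------------------------------------------------------------------


def fit_and_reconstruct(
    tree: UltrametricTree,
    tips: Mapping[str, str],
    *,
    states: Optional[Sequence[str]] = None,
    root: str = "uniform",
) -> tuple[TraitModel, AncestralReconstruction]:
    """ML fit of the asymmetric rates followed by marginal reconstruction.

    The k(k-1) off-diagonal rates are optimized on the log scale with
    L-BFGS-B from a small fixed grid of starting rates (multiples of a
    parsimony-flavoured change density), so the result is deterministic.
    If all tips share one state the model degenerates to zero rates with a
    warning and an all-certain reconstruction.
    """
    if states is None:
        states = tuple(sorted(set(tips[t] for t in tree.tip_labels)))
        if len(states) < 2:
            states = tuple(states)
    states = tuple(states)
    observed = set(tips[t] for t in tree.tip_labels)
    if len(observed) < 2:
        warnings.warn(
            "all tips share one state; returning a zero-rate model",
            stacklevel=2,
        )
        only = next(iter(observed))
        if only not in states:
            states = (only,) + tuple(s for s in states if s != only)
        k = len(states)
        probs_row = np.zeros(k)
        probs_row[states.index(only)] = 1.0
        model = TraitModel(
            states=states,
            rates=np.zeros((k, k)),
            root="fixed",
            root_probs=probs_row,
        )
        rows = {n.label: probs_row for n in tree.internal_nodes}
        probs = pd.DataFrame.from_dict(rows, orient="index", columns=list(states))
        recon = AncestralReconstruction(
            states, probs, {n.label: only for n in tree.internal_nodes}, 0.0
        )
        return model, recon

    k = len(states)
    tipvec = _tip_vectors(tree, tips, states)
    root_dist = np.full(k, 1.0 / k)
    off = ~np.eye(k, dtype=bool)
    total_len = sum(n.length for n in tree.nodes)
    # crude change-density scale: observed state count over total tree length
    r0 = max(len(observed) - 1, 1) / total_len

    def neg_loglik(x: np.ndarray) -> float:
        rates = np.zeros((k, k))
        rates[off] = np.exp(x)
        q = rates
        np.fill_diagonal(q, -q.sum(axis=1) + np.diag(q))
        ll, *_ = _pruning(tree, tipvec, q, root_dist)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    # rates are bounded above by 5x the parsimony change density: beyond
    # that the flat likelihood surface admits high-rate solutions whose
    # stationary marginals erase the ancestral signal
    bounds = [(np.log(r0) - 14.0, np.log(r0 * 5.0))] * int(off.sum())
    for mult in (1.0, 0.2):
        x0 = np.full(int(off.sum()), np.log(r0 * mult))
        res = minimize(
            neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    rates = np.zeros((k, k))
    rates[off] = np.exp(best.x)
    model = TraitModel(states=states, rates=rates, root=root)
    recon = marginal_reconstruction(tree, tips, model)
    return model, recon


def write_model_json(model: TraitModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_json_dict(), fh, indent=1)
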