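"""Simulators with the statistical structure the delimitation model assumes.

Trees are generated as a Yule (pure-birth) species process above a fixed
threshold age T with Kingman-style neutral coalescents grafted below T
inside each species, so that exactly S branches cross T; sequences evolve
along the tree under the Kimura two-parameter substitution model; discrete
traits evolve under an arbitrary CTMC generator.  Every generator takes an
explicit seed (one RNG per call, no hidden state), making all downstream
recovery experiments reproducible.

The ``nannomys_like`` preset mirrors the empirical regime the package is
aimed at: 27 species, 1-12 mitochondrial sequences each, 741 bp, a
speciation-coalescence threshold of 0.46 time units (Mya), and a
substitution rate placing between-species K2P distances in the ~3-21% band
and within-species distances below ~2.4%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .genetic_distance import Alignment
from .treeio import Node, UltrametricTree

__all__ = [
    "SimConfig",
    "nannomys_like",
    "sim_species_tree",
    "sim_full_tree",
    "sim_k2p_alignment",
    "sim_traits",
    "scale_rates_to_expected_changes",
]

_DEFAULT_TRAIT_RATES = np.array(
    [
        [0.0, 1.0, 0.5],
        [0.5, 0.0, 1.0],
        [1.0, 0.5, 0.0],
    ]
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Rates are per time unit; ``lam_coal`` is the pairwise coalescence rate,
    so n within-species lineages coalesce at total rate lam_coal * n(n-1)
    (matching the delimitation model's rate law).  ``samples_per_species``
    is a fixed count or an inclusive (lo, hi) range.  ``sub_rate`` is in
    substitutions/site/time; ``kappa`` is the transition/transversion rate
    ratio.  ``trait_rates`` is the trait generator's off-diagonal rate
    matrix (diagonal ignored), scaled by ``trait_rate_multiplier``.
    """

    n_species: int = 20
    lam_spec: float = 1.0
    threshold: float = 1.0
    samples_per_species: Union[int, tuple[int, int]] = 4
    lam_coal: float = 50.0
    seq_length: int = 1000
    kappa: float = 4.0
    sub_rate: float = 0.01
    trait_states: tuple[str, ...] = ("mountain", "forest", "savannah")
    trait_rates: np.ndarray = field(default_factory=lambda: _DEFAULT_TRAIT_RATES.copy())
    trait_rate_multiplier: float = 1.0
    trait_root_state: Optional[str] = "mountain"
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if min(self.lam_spec, self.lam_coal, self.sub_rate, self.kappa) <= 0:
            raise ValueError("rates must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold age must be positive")
        if self.seq_length < 1:
            raise ValueError("sequence length must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sample_count(self, rng: np.random.Generator) -> int:
        if isinstance(self.samples_per_species, tuple):
            lo, hi = self.samples_per_species
            return int(rng.integers(lo, hi + 1))
        return int(self.samples_per_species)


def nannomys_like(seed: int = 0, **overrides) -> SimConfig:
    """Preset emulating a pan-African pygmy-mouse style dataset.

    27 species, 1-12 samples each, 741 bp, threshold 0.46 Mya, CYTB-like
    substitution rate 0.02 subs/site/Mya and transition bias kappa=5; the
    Yule rate puts the root a few Mya above the threshold so between-species
    K2P distances span roughly 3-21% while within-species distances stay
    below ~2.4%.
    """
    cfg = SimConfig(
        n_species=27,
        lam_spec=0.55,
        threshold=0.46,
        samples_per_species=(1, 12),
        lam_coal=10.0,
        seq_length=741,
        kappa=5.0,
        sub_rate=0.02,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# trees


class _Lineage:
    __slots__ = ("node",)

    def __init__(self, node: Node):
        self.node = node


def _yule_split_ages(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Split ages (descending) of a Yule tree with S tips whose youngest
    split sits a fresh Exp(lam*S) above the threshold age."""
    S = cfg.n_species
    waits = np.array(
        [rng.exponential(1.0 / (cfg.lam_spec * k)) for k in range(2, S + 1)]
    )
    # youngest split at threshold + waits[-1]; each older split adds the
    # waiting time of the corresponding lineage count
    ages = cfg.threshold + np.cumsum(waits[::-1])
    return ages  # ascending: youngest .. root


def sim_species_tree(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[UltrametricTree, np.ndarray]:
    """Yule species tree with all tips extended to the present.

    Returns the tree (tips ``S1..S<n>`` in Newick order) and the split ages
    (ascending; the youngest exceeds ``cfg.threshold``).
    """
    if rng is None:
        rng = cfg.rng()
    ages = _yule_split_ages(cfg, rng)
    root_age = float(ages[-1])
    split_ages = ages[::-1]  # descending: root first

    root = Node()
    root.age = root_age
    a, b = Node(), Node()
    for c in (a, b):
        c.parent = root
        root.children.append(c)
    active = [a, b]
    for age in split_ages[1:]:
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.age = float(age)
        x, y = Node(), Node()
        for c in (x, y):
            c.parent = node
            node.children.append(c)
        active.extend([x, y])
    for k, leaf in enumerate(active, start=1):
        leaf.label = f"S{k}"
        leaf.age = 0.0

    def fix_lengths(node: Node) -> None:
        for c in node.children:
            c.length = node.age - c.age
            fix_lengths(c)

    fix_lengths(root)
    tree = UltrametricTree(root)
    return tree, ages


def _coalescent_times(
    n: int, lam: float, limit: float, rng: np.random.Generator, max_tries: int = 1000
) -> list[float]:
    """Coalescence ages (ascending) of n lineages with pairwise rate lam,
    conditioned on the MRCA being younger than ``limit`` by rejection."""
    if n == 1:
        return []
    for _ in range(max_tries):
        t = 0.0
        times = []
        for j in range(n, 1, -1):
            t += rng.exponential(1.0 / (lam * j * (j - 1)))
            times.append(t)
        if times[-1] < limit:
            return times
    raise RuntimeError(
        f"could not place a {n}-lineage coalescent below {limit} in "
        f"{max_tries} attempts; increase lam_coal or the threshold"
    )


def _coalescent_subtree(
    species: str, n: int, times: list[float], rng: np.random.Generator
) -> Node:
    """Random-topology Kingman subtree over ``n`` tips with given event ages."""
    active = []
    for j in range(1, n + 1):
        leaf = Node(label=f"{species}_{j}")
        leaf.age = 0.0
        active.append(leaf)
    for t in times:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        node = Node()
        node.age = float(t)
        for c in (a, b):
            c.parent = node
            node.children.append(c)
        active.append(node)
    return active[0]


def sim_full_tree(cfg: SimConfig) -> tuple[UltrametricTree, pd.DataFrame]:
    """Species tree plus within-species coalescents below the threshold.

    Returns the sample-level ultrametric tree and a truth table with columns
    tip_id, species.  By construction ``lineages_at(tree, threshold)`` equals
    the species count: every within-species coalescence is younger than the
    threshold (enforced by rejection) and every speciation older.
    """
    rng = cfg.rng()
    species_tree, _ = sim_species_tree(cfg, rng)
    rows = []
    for leaf in list(species_tree.tips):
        sp = leaf.label
        n = cfg.sample_count(rng)
        times = _coalescent_times(n, cfg.lam_coal, cfg.threshold, rng)
        sub = _coalescent_subtree(sp, n, times, rng)
        parent = leaf.parent
        idx = parent.children.index(leaf)
        sub.parent = parent
        sub.length = parent.age - sub.age
        parent.children[idx] = sub
        for j in range(1, n + 1):
            rows.append((f"{sp}_{j}", sp))

    def fix_lengths(node: Node) -> None:
        for c in node.children:
            c.length = node.age - c.age
            fix_lengths(c)

    fix_lengths(species_tree.root)
    tree = UltrametricTree(species_tree.root)
    truth = pd.DataFrame(rows, columns=["tip_id", "species"])
    return tree, truth


# ---------------------------------------------------------------------------
# sequences

# encoding: A=0, G=1, C=2, T=3; s ^ 1 is the transition partner,
# s ^ 2 and s ^ 3 the transversion partners
_ALPHABET = np.array(list("AGCT"))


def _k2p_branch_probs(t: float, cfg: SimConfig) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after time t under K2P."""
    beta = cfg.sub_rate / (cfg.kappa + 2.0)
    alpha = cfg.kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def sim_k2p_alignment(
    tree: UltrametricTree,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Alignment:
    """Evolve sequences down the tree under the K2P model.

    The root sequence is uniform over A/C/G/T; each branch applies the
    closed-form K2P transition probabilities site by site.
    """
    if rng is None:
        rng = cfg.rng()
    L = cfg.seq_length
    seqs: dict[int, np.ndarray] = {}
    seqs[tree.root.index] = rng.integers(0, 4, size=L, dtype=np.int64)

    order = [tree.root]
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for c in node.children:
            order.append(c)
            stack.append(c)

    for node in order:
        if node.parent is None:
            continue
        parent_seq = seqs[node.parent.index]
        p_ts, p_tv = _k2p_branch_probs(node.length, cfg)
        u = rng.random(L)
        child = parent_seq.copy()
        same = 1.0 - p_ts - 2.0 * p_tv
        mask_ts = (u >= same) & (u < same + p_ts)
        mask_tv1 = (u >= same + p_ts) & (u < same + p_ts + p_tv)
        mask_tv2 = u >= same + p_ts + p_tv
        child[mask_ts] ^= 1
        child[mask_tv1] ^= 2
        child[mask_tv2] ^= 3
        seqs[node.index] = child

    ids = []
    out = []
    for leaf in tree.tips:
        ids.append(leaf.label)
        out.append("".join(_ALPHABET[seqs[leaf.index]]))
    return Alignment(ids, out)


# ---------------------------------------------------------------------------
# traits


def _trait_generator(cfg: SimConfig) -> np.ndarray:
    q = np.asarray(cfg.trait_rates, dtype=float).copy() * cfg.trait_rate_multiplier
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def scale_rates_to_expected_changes(
    tree: UltrametricTree, rates: np.ndarray, n_changes: float
) -> float:
    """Multiplier putting the expected number of trait changes on the tree
    near ``n_changes`` (uniformization with the mean exit rate)."""
    q = np.asarray(rates, dtype=float).copy()
    np.fill_diagonal(q, 0.0)
    exit_rates = q.sum(axis=1)
    mean_exit = float(exit_rates.mean())
    total_len = sum(n.length for n in tree.nodes)
    return n_changes / (mean_exit * total_len)


def sim_traits(
    tree: UltrametricTree,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Evolve a discrete trait down the tree by Gillespie simulation.

    Returns (tip states, internal-node truth states), both keyed by node
    label.  With a zero generator all nodes inherit the root state.
    """
    if rng is None:
        rng = cfg.rng()
    states = cfg.trait_states
    q = _trait_generator(cfg)
    k = len(states)
    if cfg.trait_root_state is not None:
        root_state = states.index(cfg.trait_root_state)
    else:
        root_state = int(rng.integers(k))

    node_state: dict[int, int] = {tree.root.index: root_state}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        s = node_state[node.index]
        for c in node.children:
            sc = s
            remaining = c.length
            while True:
                exit_rate = -q[sc, sc]
                if exit_rate <= 0:
                    break
                wait = rng.exponential(1.0 / exit_rate)
                if wait >= remaining:
                    break
                remaining -= wait
                probs = q[sc].copy()
                probs[sc] = 0.0
                probs /= probs.sum()
                sc = int(rng.choice(k, p=probs))
            node_state[c.index] = sc
            stack.append(c)

    tip_states = {leaf.label: states[node_state[leaf.index]] for leaf in tree.tips}
    internal = {
        n.label: states[node_state[n.index]] for n in tree.internal_nodes
    }
    return tip_states, internal
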