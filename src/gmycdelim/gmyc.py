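"""Single-threshold GMYC model: likelihood, threshold scan, supports.

The model reads an ultrametric single-locus tree as two superimposed pure
branching processes separated by a threshold age T: nodes at age >= T are
speciation events of a Yule-type diversification process with per-interval
rate ``lam_spec * k**p_spec`` (k = diversification lineages alive in the
interval; the diversification process stops at T), and nodes younger than T
are coalescent events inside their entity (the clade subtended by a branch
crossing T) with per-interval rate ``lam_coal * (n(n-1))**p_coal`` summed
over entities, n being the entity's lineage count in the interval.  The
log-likelihood is the joint density of the labeled tree: the usual
inhomogeneous-Poisson waiting-time terms plus, for every event, the
ranked-topology factor 1/C(k,2) over the lineage pairs on its tipward side
(Yule and Kingman both induce the uniform distribution on ranked labeled
histories).  The one-process null is the same kind of density with a single
``lam (n(n-1))**p`` law over the whole tree, so the likelihood-ratio test
compares like with like.  With exponents fixed, the two rates enter as
independent Poisson-exposure parameters and their MLEs are events/exposure
in closed form.

Candidate thresholds are scanned (distinct internal-node ages by default,
a candidate at a node's age placing that node in the diversification
process, so the diversification exposure ends exactly at the youngest
speciation event), compared by AIC with a common parameter count of 3, and
converted to Akaike weights.  Per-split supports follow the older-or-equal
bookkeeping: the coalescence support of a node at age a is the summed
weight of thresholds >= a, the speciation support the summed weight of
thresholds < a, and the two add to 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .treeio import Node, UltrametricTree

__all__ = [
    "GmycConfig",
    "GmycFit",
    "EntityPartition",
    "gmyc_loglik",
    "fit_gmyc",
    "split_supports",
    "entity_partition",
    "single_process_loglik",
]


@dataclass(frozen=True)
class GmycConfig:
    """Tuning knobs of the GMYC scan.

    p_spec / p_coal generalize the rate laws (1 = pure Yule / pure neutral
    coalescent).  ``threshold_rule`` chooses candidate thresholds: distinct
    internal-node ages excluding the root age ("node-ages", default) or
    midpoints between consecutive distinct ages ("midpoints").  ``ci_rule``
    picks the confidence set of thresholds: all within 2 log-likelihood
    units of the maximum ("loglik-2-units", default) or the smallest set of
    highest Akaike weights reaching 0.95 ("cumulative-weight-0.95").
    """

    p_spec: float = 1.0
    p_coal: float = 1.0
    threshold_rule: str = "node-ages"
    ci_rule: str = "loglik-2-units"

    def __post_init__(self):
        if self.p_spec <= 0 or self.p_coal <= 0:
            raise ValueError("rate-law exponents must be positive")
        if self.threshold_rule not in ("node-ages", "midpoints"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.ci_rule not in ("loglik-2-units", "cumulative-weight-0.95"):
            raise ValueError(f"unknown ci_rule {self.ci_rule!r}")


@dataclass
class EntityPartition:
    """Tips grouped into GMYC entities at a threshold age.

    Entities are the branches crossing the threshold; each is a clade.
    ``entities`` maps entity id -> dict with keys tips, root_node, singleton,
    basal_age (age of the entity's basal split; None for singletons).
    """

    threshold: float
    tip_to_entity: dict[str, str]
    entities: dict[str, dict]

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    def to_frame(self) -> pd.DataFrame:
        rows = [(tip, ent) for tip, ent in self.tip_to_entity.items()]
        return pd.DataFrame(rows, columns=["tip_id", "entity_id"])


@dataclass
class GmycFit:
    """Result of a GMYC threshold scan.

    Arrays are aligned over candidate thresholds (ascending age).  The
    threshold/entity-count ranges come from the config's ci_rule; the
    threshold range's lower end is extended to the next node age below the
    youngest qualifying candidate because the induced classification is
    constant on (a_{j-1}, a_j].
    """

    config: GmycConfig
    thresholds: np.ndarray
    loglik: np.ndarray
    lam_spec: np.ndarray
    lam_coal: np.ndarray
    n_entities: np.ndarray
    aic: np.ndarray
    weights: np.ndarray
    best_index: int
    null_loglik: float
    null_rate: float
    lrt: float
    lrt_df: int
    lrt_pvalue: float
    partition: EntityPartition
    entity_count_range: tuple[int, int]
    threshold_range: tuple[float, float]
    excluded: list[float] = field(default_factory=list)
    _tree: Optional[UltrametricTree] = None

    @property
    def threshold(self) -> float:
        """ML threshold age T*."""
        return float(self.thresholds[self.best_index])

    @property
    def max_loglik(self) -> float:
        return float(self.loglik[self.best_index])

    @property
    def n_entities_best(self) -> int:
        return int(self.n_entities[self.best_index])

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "threshold_range": list(self.threshold_range),
            "n_entities": self.n_entities_best,
            "entity_count_range": list(self.entity_count_range),
            "max_loglik": self.max_loglik,
            "null_loglik": self.null_loglik,
            "lrt": self.lrt,
            "lrt_df": self.lrt_df,
            "lrt_pvalue": self.lrt_pvalue,
            "candidates": [
                {
                    "threshold": float(t),
                    "loglik": float(l),
                    "lam_spec": float(ls),
                    "lam_coal": float(lc),
                    "aic": float(a),
                    "weight": float(w),
                    "n_entities": int(k),
                }
                for t, l, ls, lc, a, w, k in zip(
                    self.thresholds,
                    self.loglik,
                    self.lam_spec,
                    self.lam_coal,
                    self.aic,
                    self.weights,
                    self.n_entities,
                )
            ],
            "excluded_thresholds": [float(t) for t in self.excluded],
            "config": {
                "p_spec": self.config.p_spec,
                "p_coal": self.config.p_coal,
                "threshold_rule": self.config.threshold_rule,
                "ci_rule": self.config.ci_rule,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# sufficient statistics


@dataclass
class _ThresholdStats:
    """Per-threshold sufficient statistics of the two-process likelihood."""

    n_spec_events: int
    spec_exposure: float  # integral of k**p_spec dt above T
    spec_log_terms: float  # sum over speciation events of p_spec*log(k)
    n_coal_events: int
    coal_exposure: float  # integral of sum_c (n(n-1))**p_coal dt below T
    coal_log_terms: float  # sum over coalescences of p_coal*log(n(n-1))


def _entity_roots(tree: UltrametricTree, T: float) -> list[Node]:
    """Branches crossing the threshold: nodes with age < T <= parent age.

    (A node at exactly T is a speciation event, so its children subtend
    entities of their own.)"""
    return [
        n
        for n in tree.nodes
        if n.parent is not None and n.age < T <= n.parent.age
    ]


def _subtree_internal_ages(node: Node) -> list[float]:
    out: list[float] = []
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.is_leaf:
            out.append(n.age)
            stack.extend(n.children)
    return out


def _subtree_tip_count(node: Node) -> int:
    count = 0
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            count += 1
        else:
            stack.extend(n.children)
    return count


def _threshold_stats(tree: UltrametricTree, T: float, cfg: GmycConfig) -> _ThresholdStats:
    ps, pc = cfg.p_spec, cfg.p_coal

    # --- diversification process (nodes at age >= T) ------------------------
    # deterministic event order: descending age (ties processed arbitrarily;
    # zero-length intervals add no exposure).  The i-th oldest event carries
    # its waiting-time factor lam_spec * i**ps (i lineages on its rootward
    # side) and its ranked-topology factor 1/C(i+1, 2): Yule and Kingman
    # both induce the uniform distribution on ranked labeled histories, so
    # with these factors every process (and the one-process null) is a
    # normalized density of the labeled tree and likelihoods are comparable.
    spec_ages = sorted(
        (n.age for n in tree.internal_nodes if n.age >= T), reverse=True
    )
    m = len(spec_ages)
    spec_log = 0.0
    if m:
        i = np.arange(1, m + 1, dtype=float)
        spec_log = float(np.sum(ps * np.log(i) - np.log(i * (i + 1) / 2.0)))
    # the interval below the (i+1)-th oldest event carries i+2 lineages
    exposure_s = 0.0
    times = spec_ages + [T]
    for i in range(m):
        exposure_s += ((i + 2.0) ** ps) * (times[i] - times[i + 1])

    # --- coalescent processes (entities below T) -----------------------------
    n_coal = 0
    exposure_c = 0.0
    coal_log = 0.0
    for root in _entity_roots(tree, T):
        n_c = _subtree_tip_count(root)
        if n_c < 2:
            continue
        ages = sorted(_subtree_internal_ages(root))  # ascending, q = n_c - 1
        q = len(ages)
        n_coal += q
        # event j (ascending) has n_c - j + 1 lineages on its younger side:
        # waiting-time factor lam_coal * (n(n-1))**pc times the topology
        # factor 1/C(n, 2) for the specific pair that coalesced
        for j in range(1, q + 1):
            n = n_c - j + 1
            coal_log += np.log(2.0) + (pc - 1.0) * float(np.log(n * (n - 1)))
        # exposure: (0, e_1) with n_c lineages, (e_j, e_{j+1}) with n_c - j
        bounds = [0.0] + ages + [T]
        for j in range(q + 1):
            n = n_c - j
            if n >= 2:
                exposure_c += ((n * (n - 1.0)) ** pc) * (bounds[j + 1] - bounds[j])

    return _ThresholdStats(m, exposure_s, spec_log, n_coal, exposure_c, coal_log)


# ---------------------------------------------------------------------------
# likelihood


def gmyc_loglik(
    tree: UltrametricTree,
    T: float,
    lam_spec: float,
    lam_coal: float,
    cfg: GmycConfig = GmycConfig(),
) -> float:
    """GMYC log-likelihood at threshold ``T`` with given process rates."""
    if not (0.0 < T < tree.root_age):
        raise ValueError(
            f"threshold T={T} must lie strictly inside (0, root age={tree.root_age})"
        )
    if lam_spec <= 0 or lam_coal <= 0:
        raise ValueError("rates must be positive")
    s = _threshold_stats(tree, T, cfg)
    ll = (
        s.n_spec_events * np.log(lam_spec)
        + s.spec_log_terms
        - lam_spec * s.spec_exposure
    )
    ll += (
        s.n_coal_events * np.log(lam_coal)
        + s.coal_log_terms
        - lam_coal * s.coal_exposure
    )
    return float(ll)


def _ml_at_threshold(s: _ThresholdStats) -> tuple[float, float, float]:
    """Closed-form rate MLEs (events/exposure) and the maximized loglik.

    Each process is a Poisson-exposure model, concave in log rate, so the
    method-of-moments estimate is the exact maximizer.
    """
    if s.n_spec_events == 0 or s.spec_exposure <= 0:
        raise FloatingPointError("speciation process has no events/exposure")
    if s.n_coal_events == 0 or s.coal_exposure <= 0:
        raise FloatingPointError("coalescent process has no events/exposure")
    lam_s = s.n_spec_events / s.spec_exposure
    lam_c = s.n_coal_events / s.coal_exposure
    ll = (
        s.n_spec_events * (np.log(lam_s) - 1.0)
        + s.spec_log_terms
        + s.n_coal_events * (np.log(lam_c) - 1.0)
        + s.coal_log_terms
    )
    return lam_s, lam_c, float(ll)


def single_process_loglik(
    tree: UltrametricTree, p: float = 1.0
) -> tuple[float, float]:
    """Null model: one branching process over the whole tree.

    All n-1 nodes are events of a single process with rate law
    ``lam * (n(n-1))**p`` over the joint lineage count; returns the
    maximized log-likelihood and the rate MLE.
    """
    ages = sorted(n.age for n in tree.internal_nodes)  # ascending
    ntips = tree.n_tips
    log_terms = 0.0
    exposure = 0.0
    bounds = [0.0] + ages
    for j in range(1, ntips):  # event j (ascending) has ntips - j + 1 below
        n = ntips - j + 1
        log_terms += np.log(2.0) + (p - 1.0) * float(np.log(n * (n - 1)))
        exposure += ((n * (n - 1.0)) ** p) * (bounds[j] - bounds[j - 1])
    lam = (ntips - 1) / exposure
    ll = (ntips - 1) * (np.log(lam) - 1.0) + log_terms
    return float(ll), float(lam)


# ---------------------------------------------------------------------------
# partition


def entity_partition(tree: UltrametricTree, T: float) -> EntityPartition:
    """GMYC entities (branches crossing ``T``) as a tip partition.

    Entity ids are assigned in tip order of first occurrence.
    """
    if not (0.0 < T < tree.root_age):
        raise ValueError("threshold outside (0, root age)")
    roots = _entity_roots(tree, T)
    # order entities by the tree's tip order
    tip_rank = {label: i for i, label in enumerate(tree.tip_labels)}
    keyed = sorted(roots, key=lambda n: min(tip_rank[t] for t in tree.clade_tips(n)))
    tip_to_entity: dict[str, str] = {}
    entities: dict[str, dict] = {}
    for k, root in enumerate(keyed, start=1):
        ent = f"E{k}"
        tips = tree.clade_tips(root)
        for t in tips:
            tip_to_entity[t] = ent
        entities[ent] = {
            "tips": tips,
            "root_node": root.label,
            "singleton": root.is_leaf,
            "basal_age": None if root.is_leaf else float(root.age),
        }
    return EntityPartition(float(T), tip_to_entity, entities)


# ---------------------------------------------------------------------------
# scan


def _candidates(tree: UltrametricTree, rule: str) -> np.ndarray:
    ages = tree.internal_ages(distinct=True)  # ascending, includes root age
    if rule == "node-ages":
        # the youngest age yields no coalescent event and the root age no
        # diversification exposure, so both are structurally degenerate
        return ages[1:-1]
    mids = 0.5 * (ages[:-1] + ages[1:])
    return mids


def fit_gmyc(tree: UltrametricTree, cfg: GmycConfig = GmycConfig()) -> GmycFit:
    """Scan candidate thresholds, maximize rates at each, and assemble the
    fit: Akaike weights, ML threshold and partition, confidence ranges, and
    the likelihood-ratio test against the one-process null."""
    if tree.n_tips < 4:
        raise ValueError("GMYC needs at least 4 tips")
    cand = _candidates(tree, cfg.threshold_rule)
    rows = []
    excluded: list[float] = []
    for T in cand:
        try:
            s = _threshold_stats(tree, float(T), cfg)
            lam_s, lam_c, ll = _ml_at_threshold(s)
        except FloatingPointError as exc:
            warnings.warn(
                f"candidate threshold {T:.6g} excluded: {exc}", stacklevel=2
            )
            excluded.append(float(T))
            continue
        rows.append((float(T), ll, lam_s, lam_c, s.n_spec_events + 1))
    if not rows:
        raise RuntimeError("no candidate threshold could be fitted")

    thresholds = np.array([r[0] for r in rows])
    loglik = np.array([r[1] for r in rows])
    lam_spec = np.array([r[2] for r in rows])
    lam_coal = np.array([r[3] for r in rows])
    n_entities = np.array([r[4] for r in rows], dtype=int)

    aic = 2.0 * 3 - 2.0 * loglik
    delta = aic - aic.min()
    w = np.exp(-0.5 * delta)
    weights = w / w.sum()
    best = int(np.argmax(loglik))

    null_ll, null_rate = single_process_loglik(tree, p=cfg.p_coal)
    lrt = 2.0 * (float(loglik[best]) - null_ll)
    lrt_df = 2
    lrt_p = float(chi2.sf(max(lrt, 0.0), lrt_df))

    if cfg.ci_rule == "loglik-2-units":
        in_ci = loglik >= loglik[best] - 2.0
    else:
        order = np.argsort(weights)[::-1]
        cum = np.cumsum(weights[order])
        take = order[: int(np.searchsorted(cum, 0.95) + 1)]
        in_ci = np.zeros(len(weights), dtype=bool)
        in_ci[take] = True
    count_range = (int(n_entities[in_ci].min()), int(n_entities[in_ci].max()))
    t_lo_cand = float(thresholds[in_ci].min())
    t_hi = float(thresholds[in_ci].max())
    # the induced classification is constant for T in (a_{j-1}, a_j], so the
    # range extends down to the next node age below the youngest qualifying
    # candidate (or to 0)
    all_ages = tree.internal_ages(distinct=True)
    younger = all_ages[all_ages < t_lo_cand]
    t_lo = float(younger.max()) if younger.size else 0.0
    part = entity_partition(tree, float(thresholds[best]))

    return GmycFit(
        config=cfg,
        thresholds=thresholds,
        loglik=loglik,
        lam_spec=lam_spec,
        lam_coal=lam_coal,
        n_entities=n_entities,
        aic=aic,
        weights=weights,
        best_index=best,
        null_loglik=null_ll,
        null_rate=null_rate,
        lrt=lrt,
        lrt_df=lrt_df,
        lrt_pvalue=lrt_p,
        partition=part,
        entity_count_range=count_range,
        threshold_range=(t_lo, t_hi),
        excluded=excluded,
        _tree=tree,
    )


# ---------------------------------------------------------------------------
# supports


def split_supports(fit: GmycFit, *, strong_cutoff: float = 0.95) -> pd.DataFrame:
    """Per-split support statistics from the Akaike weights.

    For each internal node at age a the coalescence support is the summed
    weight of thresholds >= a and the speciation support the summed weight of
    thresholds < a (they add to 1).  The node's role at the ML threshold is
    also reported: "speciation" for nodes older than T*, "coalescence_basal"
    for an entity's basal split, "coalescence" otherwise.  ``strong`` flags
    nodes whose role-matching support reaches ``strong_cutoff``.
    """
    tree = fit._tree
    if tree is None:
        raise ValueError("fit does not carry its tree")
    T = fit.threshold
    basal_nodes = {
        info["root_node"]
        for info in fit.partition.entities.values()
        if not info["singleton"]
    }
    rows = []
    for node in tree.internal_nodes:
        a = node.age
        coal = float(fit.weights[fit.thresholds >= a].sum())
        spec = float(fit.weights[fit.thresholds < a].sum())
        if a >= T:
            role = "speciation"
            role_support = spec
        elif node.label in basal_nodes:
            role = "coalescence_basal"
            role_support = coal
        else:
            role = "coalescence"
            role_support = coal
        rows.append(
            (node.label, float(a), coal, spec, role, role_support,
             role_support >= strong_cutoff)
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "node_id",
            "age",
            "coalescence_support",
            "speciation_support",
            "role",
            "role_support",
            "strong",
        ],
    )
    return df.sort_values("age", ascending=False, kind="stable").reset_index(drop=True)
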