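"""Kimura two-parameter (K2P) distances, group summaries, haplotypes.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the observed transition and transversion proportions over the
sites compared, the corrected distance (substitutions/site) is

    d = 1/2 ln(1 / (1 - 2P - Q)) + 1/4 ln(1 / (1 - 2Q))

Sites containing a gap or any non-ACGT code in either sequence are dropped
pair by pair (pairwise deletion); IUPAC partial ambiguities are treated as
missing rather than probabilistically resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "SaturatedPairError",
    "k2p",
    "k2p_counts",
    "k2p_variance",
    "k2p_matrix",
    "group_distance_summary",
    "GroupDistanceSummary",
    "collapse_haplotypes",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

# encoding: A=0, G=1, C=2, T=3 -> s ^ 1 is the transition partner
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_LETTERS = np.array(list("AGCT"))


class SaturatedPairError(ValueError):
    """The observed P/Q proportions put the K2P logarithms out of domain."""

    def __init__(self, p: float, q: float):
        self.p = p
        self.q = q
        super().__init__(
            f"saturated pair: P={p:.4f}, Q={q:.4f} leave the K2P correction "
            "undefined (1-2P-Q <= 0 or 1-2Q <= 0)"
        )


@dataclass
class Alignment:
    """A DNA multiple alignment: equal-length uppercase sequences.

    ``ids`` are unique; IUPAC codes and gap characters are allowed and are
    handled downstream by pairwise deletion.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0]) if self.seqs else 0

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{seq}\n")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def k2p_counts(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(shared unambiguous sites, transitions, transversions) for a pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a = _encode(seq_a)
    b = _encode(seq_b)
    ok = (a != 255) & (b != 255)
    a = a[ok]
    b = b[ok]
    diff = a != b
    transitions = int(np.sum(diff & ((a ^ b) == 1)))
    transversions = int(np.sum(diff) - transitions)
    return int(ok.sum()), transitions, transversions


def _k2p_from_pq(p: float, q: float) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedPairError(p, q)
    return 0.5 * float(np.log(1.0 / w1)) + 0.25 * float(np.log(1.0 / w2))


def k2p(seq_a: str, seq_b: str) -> float:
    """K2P distance between two aligned sequences (pairwise deletion).

    Raises
    ------
    ValueError
        If no unambiguous A/C/G/T site is shared.
    SaturatedPairError
        If the observed proportions saturate the correction.
    """
    n, ts, tv = k2p_counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable (unambiguous) sites shared by the pair")
    return _k2p_from_pq(ts / n, tv / n)


def k2p_variance(p: float, q: float, n_sites: int) -> float:
    """Large-sample variance of the K2P distance (Kimura's delta-method
    formula), useful for standard-error bands in simulation checks."""
    c1 = 1.0 / (1.0 - 2.0 * p - q)
    c2 = 1.0 / (1.0 - 2.0 * q)
    c3 = 0.5 * (c1 + c2)
    return (c1 * c1 * p + c3 * c3 * q - (c1 * p + c3 * q) ** 2) / n_sites


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts.

    Saturated pairs are stored as NaN ("undefined") rather than raising,
    so a single bad pair does not sink a whole matrix.  ``groups`` optionally
    maps each id to a group label (e.g. a GMYC entity).
    """

    ids: list[str]
    values: np.ndarray
    n_sites: Optional[np.ndarray] = None
    groups: Optional[dict[str, str]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.ids)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, groups: Optional[dict[str, str]] = None) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        ids = [str(i) for i in df.index]
        if ids != list(df.columns):
            raise ValueError("distance TSV must have identical row/column ids")
        return cls(ids, df.to_numpy(dtype=float), groups=groups)


def k2p_matrix(
    aln: Alignment, groups: Optional[Mapping[str, str]] = None
) -> DistanceMatrix:
    """All-pairs K2P distances for an alignment.

    Saturated or incomparable pairs become NaN with a warning.
    """
    m = len(aln)
    enc = [_encode(s) for s in aln.seqs]
    values = np.zeros((m, m))
    sites = np.zeros((m, m), dtype=int)
    bad: list[tuple[str, str]] = []
    for i in range(m):
        sites[i, i] = int(np.sum(enc[i] != 255))
        for j in range(i + 1, m):
            a, b = enc[i], enc[j]
            ok = (a != 255) & (b != 255)
            n = int(ok.sum())
            sites[i, j] = sites[j, i] = n
            if n == 0:
                values[i, j] = values[j, i] = np.nan
                bad.append((aln.ids[i], aln.ids[j]))
                continue
            aa, bb = a[ok], b[ok]
            diff = aa != bb
            ts = int(np.sum(diff & ((aa ^ bb) == 1)))
            tv = int(np.sum(diff) - ts)
            try:
                d = _k2p_from_pq(ts / n, tv / n)
            except SaturatedPairError:
                d = np.nan
                bad.append((aln.ids[i], aln.ids[j]))
            values[i, j] = values[j, i] = d
    if bad:
        warnings.warn(
            f"{len(bad)} pair(s) undefined (saturated or no shared sites): "
            f"{bad[:5]}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
    g = dict(groups) if groups is not None else None
    return DistanceMatrix(list(aln.ids), values, n_sites=sites, groups=g)


@dataclass
class GroupDistanceSummary:
    """Group-level distance summary.

    ``table`` has one row per group pair (kind="between") and per group with
    >= 2 members (kind="within"), with mean/min/max and pair counts;
    ``within_range`` and ``between_range`` are the global (min, max) over the
    corresponding pair sets, or None if empty.
    """

    table: pd.DataFrame
    within_range: Optional[tuple[float, float]]
    between_range: Optional[tuple[float, float]]
    notes: list[str] = field(default_factory=list)


def group_distance_summary(
    dm: DistanceMatrix, groups: Optional[Mapping[str, str]] = None
) -> GroupDistanceSummary:
    """Mean/min/max of within- and between-group distances.

    Groups with a single member get no within-group row (a note records
    them).  NaN (undefined) pairs are excluded from the statistics.
    """
    if groups is None:
        groups = dm.groups
    if not groups:
        raise ValueError("no group labels provided")
    missing = [i for i in dm.ids if i not in groups]
    if missing:
        raise ValueError(f"ids without group labels: {missing}")

    members: dict[str, list[int]] = {}
    for idx, sid in enumerate(dm.ids):
        members.setdefault(groups[sid], []).append(idx)
    names = sorted(members)

    rows = []
    notes = []
    within_all: list[np.ndarray] = []
    between_all: list[np.ndarray] = []

    def stats(vals: np.ndarray) -> Optional[tuple[float, float, float, int]]:
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return None
        return float(vals.mean()), float(vals.min()), float(vals.max()), int(vals.size)

    for g in names:
        idx = members[g]
        if len(idx) < 2:
            notes.append(f"group {g!r} has a single member; within-group row omitted")
            continue
        sub = dm.values[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        st = stats(vals)
        if st:
            rows.append(("within", g, g, *st))
            within_all.append(vals[~np.isnan(vals)])
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            vals = dm.values[np.ix_(members[ga], members[gb])].ravel()
            st = stats(vals)
            if st:
                rows.append(("between", ga, gb, *st))
                between_all.append(vals[~np.isnan(vals)])

    table = pd.DataFrame(
        rows, columns=["kind", "group_a", "group_b", "mean", "min", "max", "n_pairs"]
    )

    def global_range(chunks: list[np.ndarray]) -> Optional[tuple[float, float]]:
        if not chunks:
            return None
        allv = np.concatenate(chunks)
        return (float(allv.min()), float(allv.max())) if allv.size else None

    return GroupDistanceSummary(
        table, global_range(within_all), global_range(between_all), notes
    )


_AMBIGUOUS = frozenset("RYSWKMBDHVN-?.")


def collapse_haplotypes(
    aln: Alignment, *, exclude_ambiguous_columns: bool = False
) -> pd.DataFrame:
    """Collapse identical sequences into haplotypes.

    By default identity is exact full-string equality over all columns (gaps
    and ambiguity codes compared as literal characters), which keeps the
    equivalence relation transitive.  With ``exclude_ambiguous_columns=True``,
    columns containing a gap or ambiguity code in *any* sequence are removed
    first, then exact matching is applied.

    Returns a DataFrame with columns haplotype_id, count, member_ids
    (comma-joined, input order), one row per haplotype, in order of first
    occurrence.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    seqs = aln.seqs
    if exclude_ambiguous_columns and aln.length:
        cols = np.array([[c in _AMBIGUOUS for c in s] for s in seqs])
        keep = ~cols.any(axis=0)
        seqs = ["".join(np.array(list(s))[keep]) for s in seqs]
    table: dict[str, list[str]] = {}
    for sid, seq in zip(aln.ids, seqs):
        table.setdefault(seq, []).append(sid)
    rows = [
        (f"H{k + 1}", len(ids), ",".join(ids))
        for k, ids in enumerate(table.values())
    ]
    return pd.DataFrame(rows, columns=["haplotype_id", "count", "member_ids"])
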