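"""Homology-aware cross-validation partitions.

Random row splits leak information when a dataset contains homologous
sequences: near-identical proteins end up on both sides of a train/test
boundary and the measured performance is inflated.  The protocol implemented
here first groups sequences into similarity clusters (CD-HIT ``.clstr`` files,
or the internal greedy clusterer) and then deals whole clusters round-robin
into *k* subsets — cluster 1 to subset 1, cluster 2 to subset 2, ..., cluster
k+1 back to subset 1.  Positive and negative sequences are clustered and dealt
independently and the subsets are zipped by index, so every fold tests on one
positive and one negative subset while no two subsets share a cluster.

With clusters built at an identity threshold *t*, no two sequences in
different subsets can be more than *t* similar (on data whose families are
mutually dissimilar below *t*), which is the guarantee the whole evaluation
rests on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align
from sklearn.model_selection import BaseCrossValidator

from .seqio import ProteinRecord


class ClstrParseError(ValueError):
    """Malformed CD-HIT .clstr input."""


@dataclass(frozen=True)
class Cluster:
    """One similarity cluster: 1-based index, members with representative first."""

    index: int
    members: tuple[str, ...]

    @property
    def representative(self) -> str:
        return self.members[0]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterSet:
    """An ordered list of disjoint clusters covering a dataset."""

    clusters: tuple[Cluster, ...]

    def __post_init__(self) -> None:
        for pos, cluster in enumerate(self.clusters, start=1):
            if cluster.index != pos:
                raise ValueError(
                    f"cluster indices must be contiguous from 1; found {cluster.index} "
                    f"at position {pos}"
                )
        ids = [m for c in self.clusters for m in c.members]
        if len(ids) != len(set(ids)):
            raise ValueError("a sequence id appears in more than one cluster")

    @property
    def ids(self) -> list[str]:
        return [m for c in self.clusters for m in c.members]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class FoldAssignment:
    """A map from subset index (1..k) to the sequence ids it holds."""

    k: int
    assignment: dict[int, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.assignment) != set(range(1, self.k + 1)):
            raise ValueError(f"assignment must cover subsets 1..{self.k}")
        ids = [i for members in self.assignment.values() for i in members]
        if len(ids) != len(set(ids)):
            raise ValueError("subsets are not disjoint")

    @property
    def ids(self) -> list[str]:
        return [i for members in self.assignment.values() for i in members]

    def subset_of(self, seq_id: str) -> int:
        for subset, members in self.assignment.items():
            if seq_id in members:
                return subset
        raise KeyError(seq_id)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"k": self.k, "subsets": {str(s): list(m) for s, m in self.assignment.items()}},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "FoldAssignment":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(
            k=int(data["k"]),
            assignment={int(s): tuple(m) for s, m in data["subsets"].items()},
        )


def parse_clstr(path: str | Path) -> ClusterSet:
    """Parse a CD-HIT ``.clstr`` file into a ClusterSet.

    Clusters keep file order but are re-indexed 1-based; within a cluster the
    representative (the member line marked ``*``) is listed first, the rest in
    file order.
    """
    path = Path(path)
    raw: list[tuple[str | None, list[str]]] = []  # (representative, others)
    current: tuple[str | None, list[str]] | None = None
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                current = (None, [])
                raw.append(current)
                continue
            if current is None:
                raise ClstrParseError(
                    f"{path}: line {lineno}: member line before any '>Cluster' header"
                )
            start = line.find(">")
            if start == -1:
                raise ClstrParseError(f"{path}: line {lineno}: no '>' in member line")
            end = line.find("...", start)
            if end == -1:
                raise ClstrParseError(
                    f"{path}: line {lineno}: member id not terminated by '...'"
                )
            member = line[start + 1 : end]
            if line.rstrip().endswith("*"):
                if current[0] is not None:
                    raise ClstrParseError(
                        f"{path}: line {lineno}: second representative in one cluster"
                    )
                raw[-1] = (member, current[1])
                current = raw[-1]
            else:
                current[1].append(member)
    clusters = []
    for pos, (rep, others) in enumerate(raw, start=1):
        members = ([rep] if rep is not None else []) + others
        if not members:
            raise ClstrParseError(f"{path}: cluster {pos} has no members")
        clusters.append(Cluster(index=pos, members=tuple(members)))
    if not clusters:
        raise ClstrParseError(f"{path}: no clusters found")
    return ClusterSet(tuple(clusters))


def write_clstr(clusters: ClusterSet, path: str | Path,
                lengths: dict[str, int] | None = None) -> None:
    """Write a ClusterSet in CD-HIT ``.clstr`` layout (representative marked *)."""
    with Path(path).open("w") as handle:
        for cluster in clusters.clusters:
            handle.write(f">Cluster {cluster.index - 1}\n")
            for i, member in enumerate(cluster.members):
                length = (lengths or {}).get(member, 0)
                mark = "*" if i == 0 else "at 100.00%"
                handle.write(f"{i}\t{length}aa, >{member}... {mark}\n")


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _identity_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matched positions / alignment columns, in [0, 1]."""
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def greedy_cluster(
    records: Sequence[ProteinRecord], identity_threshold: float = 0.4
) -> ClusterSet:
    """Greedy length-sorted single-linkage-to-representative clustering.

    Records are sorted by length descending (ties keep input order, matching
    CD-HIT's processing order); each record joins the first existing cluster
    whose representative aligns at >= ``identity_threshold`` identity,
    otherwise it founds a new cluster.  This approximates CD-HIT's behaviour
    without its word filtering and banded alignment; parsing a real ``.clstr``
    file is the faithful route when CD-HIT output is available.
    """
    if not records:
        raise ValueError("greedy_cluster requires at least one record")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    ordered = sorted(records, key=lambda r: -len(r.sequence))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for idx, rep in enumerate(reps):
            if pairwise_identity(rec.sequence, rep.sequence) >= identity_threshold:
                members[idx].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return ClusterSet(
        tuple(
            Cluster(index=i + 1, members=tuple(m)) for i, m in enumerate(members)
        )
    )


def round_robin_split(clusters: ClusterSet, k: int = 5) -> FoldAssignment:
    """Deal clusters round-robin into k subsets: cluster i -> subset ((i-1) mod k)+1.

    All members of a cluster land in the same subset.  If there are fewer
    clusters than subsets a warning is issued and the surplus subsets are
    empty.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(clusters):
        warnings.warn(
            f"only {len(clusters)} cluster(s) for {k} subsets; some subsets will be empty",
            stacklevel=2,
        )
    subsets: dict[int, list[str]] = {s: [] for s in range(1, k + 1)}
    for cluster in clusters.clusters:
        subsets[(cluster.index - 1) % k + 1].extend(cluster.members)
    return FoldAssignment(k=k, assignment={s: tuple(m) for s, m in subsets.items()})


def make_cv_folds(
    pos: FoldAssignment, neg: FoldAssignment
) -> list[tuple[list[str], list[str]]]:
    """Zip positive and negative subset j into test fold j; train is the rest.

    Every id appears in a test set exactly once across the k folds, and train
    and test are disjoint within each fold.
    """
    if pos.k != neg.k:
        raise ValueError(f"subset counts differ: positive k={pos.k}, negative k={neg.k}")
    folds = []
    for j in range(1, pos.k + 1):
        test = list(pos.assignment[j]) + list(neg.assignment[j])
        train = [
            i
            for s in range(1, pos.k + 1)
            if s != j
            for i in list(pos.assignment[s]) + list(neg.assignment[s])
        ]
        folds.append((train, test))
    return folds


def dedupe(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop records whose exact sequence was already seen (keep first occurrence)."""
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def max_inter_subset_identity(
    assignment: FoldAssignment, records: Sequence[ProteinRecord]
) -> float:
    """Largest pairwise identity between sequences placed in different subsets.

    This is the leakage audit: with clustering at threshold t on data whose
    families are mutually dissimilar below t, the value stays <= t.
    """
    by_id = {r.id: r.sequence for r in records}
    groups = [
        [by_id[i] for i in assignment.assignment[s]] for s in range(1, assignment.k + 1)
    ]
    best = 0.0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            for seq_a in groups[a]:
                for seq_b in groups[b]:
                    best = max(best, pairwise_identity(seq_a, seq_b))
    return best


class RoundRobinGroupKFold(BaseCrossValidator):
    """Cross-validator dealing whole similarity clusters round-robin into folds.

    Groups (cluster labels) are ordered by first appearance; when ``y`` is
    given, each class's clusters are enumerated and dealt independently and
    the per-class subsets are zipped by index, mirroring the id-level
    :func:`round_robin_split` / :func:`make_cv_folds` pipeline at the level of
    row indices, so it plugs directly into scikit-learn model selection.
    """

    def __init__(self, n_splits: int = 5):
        self.n_splits = n_splits

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def _iter_test_masks(self, X=None, y=None, groups=None) -> Iterator[np.ndarray]:
        if groups is None:
            raise ValueError("RoundRobinGroupKFold requires the groups argument")
        groups = np.asarray(groups)
        n = len(groups)
        if y is None:
            strata = [np.arange(n)]
        else:
            y = np.asarray(y)
            strata = [np.flatnonzero(y == cls) for cls in np.unique(y)]
        subset = np.empty(n, dtype=int)
        for idx in strata:
            order: dict = {}
            for i in idx:
                order.setdefault(groups[i], len(order))
            for i in idx:
                subset[i] = order[groups[i]] % self.n_splits
        for fold in range(self.n_splits):
            yield subset == fold
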