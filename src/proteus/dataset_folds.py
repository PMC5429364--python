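"""Cluster-grouped cross-validation folds.

Homologous sequences must never straddle a train/test boundary, so folds are
built on sequence-similarity clusters, not on individual proteins: clusters
are assigned whole to folds, balancing folds by protein count (largest
cluster first, each cluster to the currently smallest fold).

Cluster assignments normally come from an external clustering tool's output
file (30% identity over 50% coverage is the convention for this corpus);
:func:`greedy_cluster` is a self-contained approximation for when no such
file is available: single-linkage over a k-mer-seeded gapless-diagonal
identity measure.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_tracks import ClusterAssignment, ProteinData, SequenceRecord


@dataclass
class FoldAssignment:
    """protein_id -> fold index in {0..k-1}; clusters never span folds."""

    mapping: dict[str, int]
    k: int

    def fold_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {f: [] for f in range(self.k)}
        for pid, f in self.mapping.items():
            out[f].append(pid)
        return out

    def __getitem__(self, protein_id: str) -> int:
        return self.mapping[protein_id]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _diagonal_identity(a: str, b: str, k: int = 5) -> tuple[float, float]:
    """Best gapless-diagonal (identity, coverage-of-shorter) between two sequences.

    Diagonals are seeded by shared k-mers; identity is matches over the
    diagonal overlap, coverage is overlap length over the shorter sequence.
    """
    if len(a) > len(b):
        a, b = b, a
    kmers: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        kmers.setdefault(a[i : i + k], []).append(i)
    shifts: set[int] = set()
    for j in range(len(b) - k + 1):
        for i in kmers.get(b[j : j + k], ()):
            shifts.add(j - i)
    if not shifts:
        return 0.0, 0.0
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    best = (0.0, 0.0)
    for shift in shifts:
        lo_a = max(0, -shift)
        hi_a = min(len(a), len(b) - shift)
        if hi_a <= lo_a:
            continue
        seg_a = arr_a[lo_a:hi_a]
        seg_b = arr_b[lo_a + shift : hi_a + shift]
        overlap = hi_a - lo_a
        ident = float((seg_a == seg_b).sum()) / overlap
        cov = overlap / len(a)
        if (ident, cov) > best:
            best = (ident, cov)
    return best


def greedy_cluster(
    sequences: Sequence[SequenceRecord],
    identity_threshold: float = 0.30,
    coverage_threshold: float = 0.50,
    kmer: int = 5,
) -> ClusterAssignment:
    """Single-linkage clustering on gapless k-mer-seeded identity.

    An edge joins two sequences when some shared-k-mer diagonal reaches
    ``identity_threshold`` identity over at least ``coverage_threshold`` of
    the shorter sequence. Deterministic: cluster ids follow input order.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    n = len(sequences)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident, cov = _diagonal_identity(sequences[i].sequence, sequences[j].sequence, kmer)
            if ident >= identity_threshold and cov >= coverage_threshold:
                uf.union(i, j)
    roots: dict[int, int] = {}
    mapping: dict[str, int] = {}
    for i, rec in enumerate(sequences):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots)
        mapping[rec.id] = roots[r]
    return ClusterAssignment(mapping)


def build_folds(
    clusters: ClusterAssignment, k: int = 5, seed: int | None = None
) -> FoldAssignment:
    """Assign whole clusters to k folds, balancing protein counts.

    Clusters are taken largest first (ties by cluster id, optionally
    shuffled within equal sizes by ``seed``) and each goes to the currently
    smallest fold, so the max-min fold-size gap never exceeds the largest
    cluster.
    """
    members = clusters.members()
    if k > len(members):
        raise ValueError(f"cannot build {k} folds from {len(members)} clusters")
    order = sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    if seed is not None:
        rng = random.Random(seed)
        i = 0
        shuffled: list[tuple[int, list[str]]] = []
        while i < len(order):
            j = i
            while j < len(order) and len(order[j][1]) == len(order[i][1]):
                j += 1
            block = order[i:j]
            rng.shuffle(block)
            shuffled.extend(block)
            i = j
        order = shuffled
    sizes = [0] * k
    mapping: dict[str, int] = {}
    for _, pids in order:
        target = min(range(k), key=lambda f: (sizes[f], f))
        for pid in pids:
            mapping[pid] = target
        sizes[target] += len(pids)
    return FoldAssignment(mapping, k)


def split(
    dataset: Sequence[ProteinData], folds: FoldAssignment, test_fold: int
) -> tuple[list[ProteinData], list[ProteinData]]:
    """Partition a corpus into (train, test) for one cross-validation rotation."""
    if not 0 <= test_fold < folds.k:
        raise ValueError(f"test fold {test_fold} outside [0, {folds.k})")
    train = [p for p in dataset if folds[p.id] != test_fold]
    test = [p for p in dataset if folds[p.id] == test_fold]
    return train, test
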