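"""Pairwise-identity species demarcation and rank placement.

The engine follows the PASC idea: compute all-against-all pairwise
identities, cluster sequences at a demarcation threshold (e.g. 90% for
partiti-like RdRps, 50% for narna-like ones), and place query sequences
against the identity distributions observed within and between
established genera.  Identity is measured on a Needleman–Wunsch global
alignment (BLOSUM62, gap open 11 / extend 1); terminal-gap columns are
excluded from the denominator, internal gaps count as mismatches.

A neighbor-joining tree over ``100 − identity`` distances is provided as
lightweight plumbing for visual inspection; it is not a substitute for
maximum-likelihood phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .homology_search import _get_aligner


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # percent, square, symmetric, diagonal 100

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


@dataclass
class RankDistributions:
    """Reference identity samples within and between genera."""

    intra_genus: list[float]
    inter_genus: list[float]

    def __post_init__(self) -> None:
        if not self.intra_genus or not self.inter_genus:
            raise ValueError("both rank distributions must be nonempty")


@dataclass
class DemarcationResult:
    threshold: float
    clusters: list[list[str]]
    verdicts: dict[str, str] = field(default_factory=dict)


def global_identity(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Percent identity on the optimal global alignment of two proteins.

    Columns inside terminal gaps are trimmed before counting; identity is
    ``identical columns / remaining columns × 100``.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if (len(b), b) < (len(a), a):
        # Co-optimal alignments can differ with argument order; canonical
        # ordering keeps identity exactly symmetric.
        a, b = b, a
    aligner = _get_aligner(matrix, gap_open, gap_extend, "global")
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    n = len(row_a)
    lo = 0
    while lo < n and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 0.0
    matches = sum(
        1 for x, y in zip(row_a[lo:hi], row_b[lo:hi]) if x == y and x != "-"
    )
    return 100.0 * matches / (hi - lo)


def identity_matrix(seqs: Sequence[tuple[str, str]]) -> IdentityMatrix:
    """All-against-all percent identity for labeled sequences."""
    labels = [lab for lab, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("sequence labels must be unique")
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_identity(seqs[i][1], seqs[j][1])
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(labels=labels, values=values)


def cluster_species(matrix: IdentityMatrix, threshold: float) -> list[list[str]]:
    """Single-linkage clusters: any pair with identity ≥ threshold is
    linked.  Output clusters are ordered by first-seen label; members
    keep input order.  Order-invariant up to that canonical ordering."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    n = len(matrix.labels)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(matrix.labels[i])
    return [groups[root] for root in sorted(groups)]


def place_rank(
    query_identities: Sequence[float],
    dists: RankDistributions,
    intra_quantile: float = 0.05,
) -> tuple[str, dict[str, dict[str, float]]]:
    """Place a query against intra/inter-genus identity distributions.

    * ``new_genus_candidate`` — the query's best identity falls below
      every intra-genus sample,
    * ``existing_taxon`` — the best identity reaches the lower
      ``intra_quantile`` of the intra-genus distribution,
    * ``new_species`` — in between: intra-genus-like but distinct.
    """
    if not query_identities:
        raise ValueError("need at least one query identity")
    best = max(query_identities)
    intra = np.asarray(dists.intra_genus, dtype=float)
    inter = np.asarray(dists.inter_genus, dtype=float)
    if best < intra.min():
        verdict = "new_genus_candidate"
    elif best >= float(np.quantile(intra, intra_quantile)):
        verdict = "existing_taxon"
    else:
        verdict = "new_species"
    summary = {
        "query": _summary(np.asarray(query_identities, dtype=float)),
        "intra_genus": _summary(intra),
        "inter_genus": _summary(inter),
    }
    return verdict, summary


def _summary(x: np.ndarray) -> dict[str, float]:
    return {"min": float(x.min()), "median": float(np.median(x)), "max": float(x.max())}


def demarcate(
    seqs: Sequence[tuple[str, str]],
    threshold: float,
    dists: Optional[RankDistributions] = None,
) -> DemarcationResult:
    """Identity matrix → threshold clustering (→ optional rank verdicts)."""
    matrix = identity_matrix(seqs)
    clusters = cluster_species(matrix, threshold)
    verdicts: dict[str, str] = {}
    if dists is not None:
        for i, label in enumerate(matrix.labels):
            others = np.delete(matrix.values[i], i)
            if len(others):
                verdicts[label], _ = place_rank(list(others), dists)
    result = DemarcationResult(threshold=threshold, clusters=clusters, verdicts=verdicts)
    result.matrix = matrix  # attached for reporting
    return result


def nj_tree(matrix: IdentityMatrix) -> str:
    """Neighbor-joining newick tree on ``100 − identity`` distances."""
    if len(matrix.labels) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    dist = 100.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix((dist + dist.T) / 2.0, matrix.labels)
    tree = _skbio_nj(dm)
    return str(tree).strip()


def nj_tree_from_distances(labels: Sequence[str], distances: np.ndarray) -> str:
    """Neighbor joining on an explicit distance matrix (testing hook)."""
    dm = DistanceMatrix(np.asarray(distances, dtype=float), list(labels))
    return str(_skbio_nj(dm)).strip()
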