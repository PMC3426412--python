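"""Distance phylogeny over gapless protein alignments.

The tree-building route mirrors the classic desk workflow: strip every
column that contains a gap, compute pairwise distances, and run
Saitou-Nei neighbor joining.  Two distance models are provided --
uncorrected p-distance and its Poisson correction ``-ln(1 - p)`` -- as
documented stand-ins for Protdist's JTT model: the downstream question
(do tips cluster by phylum?) depends on relative, not absolute, distances.

The phylum-clustering score quantifies a qualitative claim: the fraction
of tips whose nearest tip by patristic (path-length) distance carries the
same phylum label.  It is an invented summary statistic and is labelled as
such in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a model tag.

    ``saturated`` flags pairs whose corrected distance is infinite
    (p-distance >= 1 under the Poisson correction).
    """

    ids: list[str]
    matrix: np.ndarray
    model: str
    saturated: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite.T], atol=1e-9):
            raise ValueError("matrix must be symmetric")
        self.matrix = m


def strip_gap_columns(records: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Remove every alignment column containing a gap in any record.

    Idempotent; raises if no column survives.
    """
    if not records:
        raise ValueError("empty alignment")
    length = len(records[0][1])
    if any(len(seq) != length for _id, seq in records):
        raise ValueError("aligned sequences must have equal length")
    keep = [
        j for j in range(length)
        if not any(seq[j] in GAP_CHARS for _id, seq in records)
    ]
    if not keep:
        raise ValueError("no gap-free columns remain")
    return [(rid, "".join(seq[j] for j in keep)) for rid, seq in records]


def distances(
    records: Sequence[tuple[str, str]], model: str = "p_distance"
) -> DistanceMatrix:
    """Pairwise distances over a gapless alignment.

    ``p_distance`` is mismatches/length; ``poisson_corrected`` is
    ``-ln(1 - p)``, infinite (and flagged) when p reaches 1.
    """
    if model not in {"p_distance", "poisson_corrected"}:
        raise ValueError(f"unknown distance model {model!r}")
    if not records:
        raise ValueError("empty alignment")
    ids = [rid for rid, _ in records]
    seqs = [seq.upper() for _, seq in records]
    length = len(seqs[0])
    if length == 0 or any(len(s) != length for s in seqs):
        raise ValueError("sequences must be gapless, equal, nonzero length")
    if any(c in GAP_CHARS for s in seqs for c in s):
        raise ValueError("alignment still contains gaps; strip columns first")
    arr = np.array([list(s) for s in seqs])
    n = len(ids)
    p = np.zeros((n, n))
    for i in range(n):
        mism = (arr[i] != arr[i + 1 :]).mean(axis=1) if i + 1 < n else []
        for k, v in enumerate(mism, start=i + 1):
            p[i, k] = p[k, i] = v
    saturated = np.zeros((n, n), bool)
    if model == "p_distance":
        d = p
    else:
        saturated = (p >= 1.0) & ~np.eye(n, dtype=bool)
        with np.errstate(divide="ignore"):
            d = -np.log(np.clip(1.0 - p, 0.0, None))
    return DistanceMatrix(ids=ids, matrix=d, model=model, saturated=saturated)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on the Q-criterion.

    Ties in Q are broken by the smallest (i, j) pair in the current node
    ordering (insertion order: input taxa first, then created internal
    nodes), which makes the output independent of floating-point
    coincidences.  Negative branch-length estimates are clamped to zero
    with a warning.  Additive matrices are recovered exactly.  The result
    is an unrooted tree written with a trifurcating root node.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("distance matrix contains non-finite entries")
    d = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=str(name)) for name in dm.ids]
    clamped = 0

    def attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        child.length = float(length)
        parent.append(child)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among minimal Q values (argwhere is row-major, so
        # the first upper-triangle candidate is the lexicographic minimum)
        qmin = q.min()
        ii = jj = -1
        for i, j in np.argwhere(q <= qmin + 1e-12):
            if i < j:
                ii, jj = int(i), int(j)
                break
        li = 0.5 * d[ii, jj] + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = d[ii, jj] - li
        parent = TreeNode()
        attach(parent, nodes[ii], li)
        attach(parent, nodes[jj], lj)
        dnew = 0.5 * (d[ii, :] + d[jj, :] - d[ii, jj])
        keep = [k for k in range(m) if k not in (ii, jj)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join
    root = TreeNode()
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        attach(root, node, length)
    if clamped:
        warnings.warn(
            f"{clamped} negative branch length estimate(s) clamped to 0",
            stacklevel=2,
        )
    return root


def path_length_matrix(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Tip ids and the patristic (path-length) distance matrix."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data


def phylum_clustering_score(tree: TreeNode, labels: Mapping[str, str]) -> float:
    """Fraction of tips whose nearest tip (patristic distance) shares its
    phylum label.  Ties are broken by the lexicographically smallest tip id.
    """
    ids, mat = path_length_matrix(tree)
    missing = [tid for tid in ids if tid not in labels]
    if missing:
        raise ValueError(f"missing phylum labels for: {missing[:5]}")
    order = np.argsort(ids)  # lexicographic tie-break
    matches = 0
    for i, tid in enumerate(ids):
        best = None
        for j in order:
            if j == i:
                continue
            key = (mat[i, j], ids[j])
            if best is None or key < best[0]:
                best = (key, ids[j])
        matches += labels[best[1]] == labels[tid]
    return matches / len(ids)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
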