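"""Pairwise sequence / structure / dynamics similarity matrices.

Sequence similarity between two members is the identity fraction ``f`` over
the aligned non-gap columns of their pairwise global alignment (the
normalized Hamming distance is ``1 - f``).  Structural similarity is the Cα
RMSD after a fresh pairwise superposition.  Dynamics similarity (the
spectral-distance matrix) lives in :mod:`sigdyn.signature_dynamics`; all
three share the :class:`DistanceMatrix` container and the sequence-cluster
ordering produced here, so heatmaps of the three spaces can be displayed in
a common member order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .ensemble_align import (
    DEFAULT_MIN_IDENTITY,
    MappedEnsemble,
    kabsch_superpose,
    map_to_reference,
)
from .structure_io import StructureRecord

log = logging.getLogger(__name__)

_METRICS = ("seq_identity", "rmsd", "spectral_distance")


@dataclass
class DistanceMatrix:
    member_ids: list[str]
    values: np.ndarray  # (M, M)
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        m = len(self.member_ids)
        if self.values.shape != (m, m):
            raise ValueError("values must be square over member_ids")

    def validate(self) -> None:
        v = self.values
        finite = np.isfinite(v)
        assert np.allclose(v[finite], v.T[finite.T], atol=1e-10), "matrix not symmetric"
        diag_expect = 1.0 if self.metric == "seq_identity" else 0.0
        assert np.allclose(np.diag(v), diag_expect, atol=1e-10)
        if self.metric == "seq_identity":
            assert (v[finite] >= -1e-12).all() and (v[finite] <= 1 + 1e-12).all()
        elif self.metric == "rmsd":
            assert (v[finite] >= -1e-12).all()
        else:
            assert (v[finite] >= -1e-12).all() and (v[finite] <= np.pi / 2 + 1e-9).all()


def sequence_identity_matrix(
    records: list[StructureRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> DistanceMatrix:
    """All-pairs sequence identity fractions from pairwise global alignments.

    Entry (a, b) is the fraction of identical residues over the aligned
    non-gap columns of the a-vs-b alignment; the diagonal is 1.  Pairs whose
    identity falls below ``min_identity`` are marked missing (NaN).
    """
    m = len(records)
    values = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            amap = map_to_reference(records[a], records[b], min_identity=min_identity)
            if not amap.mappable:
                log.warning("pair (%s, %s) unmappable; identity entry missing",
                            records[a].member_id, records[b].member_id)
                values[a, b] = values[b, a] = np.nan
            else:
                values[a, b] = values[b, a] = amap.identity_fraction
    mat = DistanceMatrix([r.member_id for r in records], values, "seq_identity")
    mat.validate()
    return mat


def rmsd_matrix(ensemble: MappedEnsemble) -> DistanceMatrix:
    """All-pairs Cα RMSD after fresh pairwise Kabsch superposition.

    Each pair is compared over the positions resolved in both members; pairs
    sharing fewer than 3 positions are marked missing.
    """
    if not ensemble.superposed:
        raise ValueError("rmsd_matrix requires a superposed ensemble")
    m = ensemble.n_members
    values = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            shared = ensemble.mask[a] & ensemble.mask[b]
            if shared.sum() < 3:
                log.warning("pair (%s, %s): <3 shared positions, RMSD missing",
                            ensemble.member_ids[a], ensemble.member_ids[b])
                values[a, b] = values[b, a] = np.nan
                continue
            _, _, rmsd = kabsch_superpose(
                ensemble.coords[a][shared], ensemble.coords[b][shared]
            )
            values[a, b] = values[b, a] = rmsd
    mat = DistanceMatrix(list(ensemble.member_ids), values, "rmsd")
    mat.validate()
    return mat


def cluster_order(matrix: DistanceMatrix) -> np.ndarray:
    """Leaf order of average-linkage hierarchical clustering of the matrix.

    Sequence-identity matrices are converted to distances as ``1 - f``; the
    RMSD and spectral-distance matrices are used as-is.  scipy's
    deterministic merge order provides the tie-break, so identical all-pairs
    distances preserve input order.
    """
    v = matrix.values
    if np.isnan(v).any():
        raise ValueError("cluster_order requires a complete matrix")
    if len(matrix.member_ids) == 1:
        return np.array([0])
    dist = 1.0 - v if matrix.metric == "seq_identity" else v.copy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    # canonical leaf order: each internal node lists the subtree containing
    # the smaller original index first, so ties preserve input order
    m = len(matrix.member_ids)
    children = {m + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(tree)}

    def leaves(node: int) -> list[int]:
        if node < m:
            return [node]
        left, right = (leaves(c) for c in children[node])
        return left + right if min(left) <= min(right) else right + left

    return np.asarray(leaves(2 * m - 2))


def reorder(matrix: DistanceMatrix, order: np.ndarray) -> DistanceMatrix:
    """Apply a member permutation (e.g. the sequence-cluster order) to a matrix."""
    order = np.asarray(order, dtype=int)
    return DistanceMatrix(
        [matrix.member_ids[i] for i in order],
        matrix.values[np.ix_(order, order)],
        matrix.metric,
    )
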