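"""Mapping members onto a reference, occupancy filtering, and superposition.

Every member chain is mapped position-by-position onto the reference chain by
global sequence alignment (BLOSUM62, affine gaps).  Reference positions with
too few members resolved are discarded, members covering too little of the
retained positions are discarded, and the surviving coordinate array is
rigid-body superposed (weighted Kabsch) iteratively onto the running ensemble
mean.  The result is the ``MappedEnsemble`` every downstream analysis
(pairwise RMSD, PCA, elastic network modes) operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import StructureRecord, record_sequence

log = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.20
DEFAULT_OCCUPANCY = 0.90
DEFAULT_COVERAGE = 0.80


@dataclass
class AlignmentMap:
    """Residue-index pairing of one member against the reference."""

    member_id: str
    pairs: np.ndarray  # (n_pairs, 2): member index, reference index
    identity_fraction: float
    mappable: bool = True

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(self.pairs) > 1:
            d = np.diff(self.pairs, axis=0)
            if not (d > 0).all():
                raise ValueError(f"{self.member_id}: alignment pairs not colinear")


@dataclass
class MappedEnsemble:
    """M members × N reference positions × 3 Cα coordinates, with mask.

    ``coords`` are finite wherever ``mask`` is true and NaN elsewhere until
    :func:`impute_missing` fills unresolved positions with the ensemble mean.
    ``occupancy[j]`` is the fraction of members resolving position ``j``.
    """

    reference_id: str
    member_ids: list[str]
    position_ids: list[str]
    coords: np.ndarray  # (M, N, 3) Å
    mask: np.ndarray    # (M, N) bool
    occupancy: np.ndarray  # (N,)
    labels: list[str]
    species: list[str]
    superposed: bool = False
    imputed: bool = False
    segments: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_positions(self) -> int:
        return len(self.position_ids)

    def validate(self, occupancy_threshold: float | None = None) -> None:
        assert self.coords.shape == (self.n_members, self.n_positions, 3)
        assert self.mask.shape == (self.n_members, self.n_positions)
        np.testing.assert_allclose(self.occupancy, self.mask.mean(axis=0), atol=1e-12)
        assert np.isfinite(self.coords[self.mask]).all()
        if occupancy_threshold is not None:
            assert (self.occupancy >= occupancy_threshold).all()

    def member_index(self, member_id: str) -> int:
        return self.member_ids.index(member_id)


def _aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def map_to_reference(
    record: StructureRecord,
    reference: StructureRecord,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> AlignmentMap:
    """Global alignment of the member sequence onto the reference sequence.

    Aligned non-gap columns become (member, reference) index pairs;
    ``identity_fraction`` is the fraction of identical aligned pairs.  A
    member whose identity falls below ``min_identity`` is flagged unmappable.
    """
    seq_m = record_sequence(record)
    seq_r = record_sequence(reference)
    alignment = _aligner().align(seq_m, seq_r)[0]
    blocks_m, blocks_r = alignment.aligned
    pairs = np.concatenate(
        [
            np.column_stack([np.arange(am, bm), np.arange(ar, br)])
            for (am, bm), (ar, br) in zip(blocks_m, blocks_r)
        ]
    ) if len(blocks_m) else np.empty((0, 2), dtype=int)
    if len(pairs) == 0:
        return AlignmentMap(record.member_id, pairs, 0.0, mappable=False)
    same = sum(seq_m[i] == seq_r[j] for i, j in pairs)
    identity = same / len(pairs)
    mappable = identity >= min_identity
    if not mappable:
        log.warning(
            "member %s: identity %.3f below floor %.2f, flagged unmappable",
            record.member_id, identity, min_identity,
        )
    return AlignmentMap(record.member_id, pairs, identity, mappable=mappable)


def build_mapped_ensemble(
    records: list[StructureRecord],
    reference: StructureRecord,
    occupancy_threshold: float = DEFAULT_OCCUPANCY,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    coverage_floor: float = DEFAULT_COVERAGE,
    drop_log: list[dict] | None = None,
) -> MappedEnsemble:
    """Assemble the member × reference-position coordinate array.

    Reference positions resolved in fewer than ``occupancy_threshold`` of the
    members are dropped; members resolving fewer than ``coverage_floor`` of
    the retained positions are dropped; both filters are re-applied until
    stable so the stated occupancy invariant holds on the final ensemble.
    """
    n_ref = len(reference)
    kept: list[tuple[StructureRecord, AlignmentMap]] = []
    for rec in records:
        amap = map_to_reference(rec, reference, min_identity=min_identity)
        if not amap.mappable:
            if drop_log is not None:
                drop_log.append({"member_id": rec.member_id, "reason": "unmappable",
                                 "detail": f"identity {amap.identity_fraction:.3f}"})
            log.warning("member %s dropped: unmappable", rec.member_id)
            continue
        kept.append((rec, amap))
    if len(kept) < 2:
        raise ValueError(f"need at least 2 mappable members, got {len(kept)}")

    m = len(kept)
    coords = np.full((m, n_ref, 3), np.nan)
    mask = np.zeros((m, n_ref), dtype=bool)
    for k, (rec, amap) in enumerate(kept):
        mi, ri = amap.pairs[:, 0], amap.pairs[:, 1]
        coords[k, ri] = rec.ca_coords[mi]
        mask[k, ri] = True

    member_keep = np.ones(m, dtype=bool)
    pos_keep = np.ones(n_ref, dtype=bool)
    while True:
        occ = mask[member_keep][:, pos_keep].mean(axis=0)
        pos_drop = occ < occupancy_threshold
        if pos_drop.any():
            pos_keep[np.flatnonzero(pos_keep)[pos_drop]] = False
            continue
        coverage = mask[:, pos_keep].mean(axis=1)
        low = member_keep & (coverage < coverage_floor)
        if low.any():
            for k in np.flatnonzero(low):
                if drop_log is not None:
                    drop_log.append({"member_id": kept[k][0].member_id,
                                     "reason": "low_coverage",
                                     "detail": f"coverage {coverage[k]:.3f}"})
                log.warning("member %s dropped: coverage %.3f < %.2f",
                            kept[k][0].member_id, coverage[k], coverage_floor)
            member_keep[low] = False
            if member_keep.sum() < 2:
                raise ValueError("fewer than 2 members survive coverage filtering")
            continue
        break

    mk, pk = np.flatnonzero(member_keep), np.flatnonzero(pos_keep)
    sub_mask = mask[np.ix_(mk, pk)]
    segments = [reference.segments[j] for j in pk] if reference.segments else []
    ens = MappedEnsemble(
        reference_id=reference.member_id,
        member_ids=[kept[k][0].member_id for k in mk],
        position_ids=[reference.residue_ids[j] for j in pk],
        coords=coords[np.ix_(mk, pk)],
        mask=sub_mask,
        occupancy=sub_mask.mean(axis=0),
        labels=[kept[k][0].state_label for k in mk],
        species=[kept[k][0].species for k in mk],
        segments=segments,
    )
    ens.validate(occupancy_threshold)
    return ens


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD.
    The rotation is proper (det = +1); reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    wn = w / w.sum()

    cm = wn @ mobile
    ct = wn @ target
    x = mobile - cm
    y = target - ct
    h = (x * wn[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate point set (collinear): rotation not determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    moved = x @ rot.T
    rmsd = float(np.sqrt((wn[:, None] * (moved - y) ** 2).sum()))
    return rot, trans, rmsd


def pairwise_rmsd(
    a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Minimum RMSD between two coordinate sets after Kabsch superposition."""
    return kabsch_superpose(a, b, weights)[2]


def iterative_superpose(
    ensemble: MappedEnsemble,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> MappedEnsemble:
    """Superpose all members onto the reference, then onto the running mean.

    Each member is aligned on its resolved positions (mask-weighted Kabsch),
    first to the reference member, then repeatedly to the occupancy-weighted
    ensemble mean until the mean moves less than ``tol`` Å RMSD or
    ``max_iter`` is reached.
    """
    coords = ensemble.coords.copy()
    mask = ensemble.mask
    try:
        ref_idx = ensemble.member_index(ensemble.reference_id)
    except ValueError:
        ref_idx = 0
        log.warning("reference %s not among members; superposing onto member %s",
                    ensemble.reference_id, ensemble.member_ids[0])

    def _superpose_onto(target: np.ndarray, target_mask: np.ndarray) -> None:
        for k in range(len(coords)):
            shared = mask[k] & target_mask
            if shared.sum() < 3:
                raise ValueError(
                    f"member {ensemble.member_ids[k]}: fewer than 3 positions "
                    "shared with the superposition target"
                )
            rot, trans, _ = kabsch_superpose(
                coords[k][shared], target[shared]
            )
            resolved = mask[k]
            coords[k][resolved] = coords[k][resolved] @ rot.T + trans

    _superpose_onto(coords[ref_idx], mask[ref_idx])

    def _mean() -> np.ndarray:
        cnt = mask.sum(axis=0)[:, None].astype(float)
        tot = np.where(mask[:, :, None], coords, 0.0).sum(axis=0)
        return tot / np.maximum(cnt, 1)

    mean = _mean()
    mean_mask = mask.any(axis=0)
    for _ in range(max_iter):
        _superpose_onto(mean, mean_mask)
        new_mean = _mean()
        shift = float(np.sqrt(((new_mean - mean)[mean_mask] ** 2).sum(axis=-1).mean()))
        mean = new_mean
        if shift < tol:
            break

    out = replace(ensemble, coords=coords, superposed=True)
    return out


def impute_missing(ensemble: MappedEnsemble) -> MappedEnsemble:
    """Fill unresolved (mask-false) positions with the per-position mean.

    Requires a superposed ensemble; the mask is retained so downstream
    reports can flag imputed positions.
    """
    if not ensemble.superposed:
        raise ValueError("impute_missing requires a superposed ensemble")
    coords = ensemble.coords.copy()
    cnt = ensemble.mask.sum(axis=0)
    if (cnt == 0).any():
        raise ValueError("positions resolved in no member cannot be imputed")
    mean = np.where(ensemble.mask[:, :, None], coords, 0.0).sum(axis=0) / cnt[:, None]
    miss = ~ensemble.mask
    coords[miss] = np.broadcast_to(mean, coords.shape)[miss]
    return replace(ensemble, coords=coords, imputed=True)
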