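"""Synthetic fixtures: toy helix bundles, planted-mode ensembles, sequences.

The toy structure is an idealized seven-helix transmembrane-like bundle
(antiparallel ideal α-helices on a circle, joined by semicircular loop
arcs), standing in for the 7-TM fold.  Conformational ensembles are built
from a template plus Gaussian displacements along a few planted orthonormal
collective modes with prescribed variances plus isotropic noise — a
linear-Gaussian model whose PCA ground truth is exact, which makes
parameter-recovery tests sharp.  A labeled two-state variant shifts the two
states apart along one collective mode localized to a contiguous loop
segment (an "ICL3-like" region, mimicking the cytoplasmic TM5–TM6 opening
upon receptor activation) and gives the "inactive" state extra noise on
that segment.  All generators are fully deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .ensemble_align import MappedEnsemble
from .structure_io import StructureRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal α-helix Cα geometry
HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å
MIN_CA_DIST = 2.0      # Å, clash floor


@dataclass
class BundleSpec:
    """Geometry of the idealized seven-helix bundle."""

    n_helices: int = 7
    residues_per_helix: int = 25
    loop_length: int = 6
    bundle_radius: float = 12.0
    seed: int = 0

    @property
    def total_length(self) -> int:
        return (
            self.n_helices * self.residues_per_helix
            + (self.n_helices - 1) * self.loop_length
        )


@dataclass
class PlantedEnsembleSpec:
    """Template + orthonormal collective modes with prescribed variances."""

    template: StructureRecord
    modes: np.ndarray       # (K, 3N) orthonormal rows
    variances: np.ndarray   # (K,) Å², positive descending
    noise_sd: float = 0.1   # Å isotropic per coordinate
    n_members: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.modes.ndim != 2 or self.modes.shape[1] != 3 * len(self.template):
            raise ValueError("modes must be (K, 3N) for the template length")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-8):
            raise ValueError("planted modes must be mutually orthonormal")
        if (self.variances <= 0).any() or (np.diff(self.variances) > 0).any():
            raise ValueError("variances must be positive and descending")


@dataclass
class TwoStateSpec:
    """Two labeled states separated along a segment-localized shift mode.

    The shift mode (by default an ICL3-like loop bump, see
    :func:`segment_shift_mode`) carries a between-state displacement of
    ``shift_amplitude`` Å (projections of the two states differ by this
    amount); the "inactive" state additionally receives isotropic noise of
    ``segment_noise_sd`` Å on the segment positions, emulating the broader
    conformational variance of inactive receptors at the cytoplasmic loop.
    """

    template: StructureRecord
    modes: np.ndarray
    variances: np.ndarray
    shift_mode: np.ndarray         # (3N,) unit vector, segment-localized
    segment: tuple[int, int]       # [start, stop) position range
    shift_amplitude: float = 6.0   # Å along the unit shift mode
    segment_noise_sd: float = 2.0  # Å extra per coordinate on segment, state B
    noise_sd: float = 0.2
    m_per_state: int = 20
    seed: int = 0
    state_labels: tuple[str, str] = ("active", "inactive")


def _ideal_helix(n: int, direction: float, phase: float) -> np.ndarray:
    """Cα trace of an ideal helix along ±z in its local frame."""
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i + phase
    z = direction * HELIX_RISE * i
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), z]
    )


LOOP_SPACING = 3.0  # Å target Cα–Cα step along loop arcs


def _loop_arc(p0: np.ndarray, p1: np.ndarray, bulge_dir: np.ndarray, n: int) -> np.ndarray:
    """n points on a circular arc from p0 to p1 bulging along bulge_dir.

    The arc's subtended angle is chosen so consecutive points (endpoints
    included) sit ``LOOP_SPACING`` apart along the arc, keeping short-chord
    loops from bunching below the clash floor.
    """
    from scipy.optimize import brentq

    chord = p1 - p0
    mid = 0.5 * (p0 + p1)
    e1 = chord / np.linalg.norm(chord)
    normal = bulge_dir - (bulge_dir @ e1) * e1
    e2 = normal / np.linalg.norm(normal)
    r = 0.5 * np.linalg.norm(chord)
    arc_length = max((n + 1) * LOOP_SPACING, 2.0 * r * 1.01)
    # solve sin(a)/a = 2r/L for the half-angle a of the subtending sector
    ratio = 2.0 * r / arc_length
    alpha = brentq(lambda a: np.sin(a) / a - ratio, 1e-9, np.pi - 1e-9)
    radius = r / np.sin(alpha)
    center = mid - radius * np.cos(alpha) * e2
    phi = -alpha + 2.0 * alpha * np.arange(1, n + 1) / (n + 1)
    return center + radius * (np.outer(np.sin(phi), e1) + np.outer(np.cos(phi), e2))


def make_bundle(spec: BundleSpec) -> StructureRecord:
    """Deterministic idealized Cα bundle with helix/loop segment annotation.

    Helices run antiparallel (alternating ±z) at equal angles on a circle of
    ``bundle_radius``; consecutive helices are joined by semicircular loop
    arcs bulging axially outward.  Sequence is drawn uniformly from the 20
    amino acids under the spec seed.  Raises if any inter-Cα distance falls
    below 2.0 Å.
    """
    rng = np.random.default_rng(spec.seed)
    coords: list[np.ndarray] = []
    segments: list[str] = []
    helix_spans: list[tuple[int, int]] = []
    loop_spans: list[tuple[int, int]] = []

    centers = []
    for h in range(spec.n_helices):
        phi = 2.0 * np.pi * h / spec.n_helices
        centers.append(
            np.array([spec.bundle_radius * np.cos(phi), spec.bundle_radius * np.sin(phi), 0.0])
        )

    height = HELIX_RISE * (spec.residues_per_helix - 1)
    pos = 0
    for h in range(spec.n_helices):
        direction = 1.0 if h % 2 == 0 else -1.0
        local = _ideal_helix(spec.residues_per_helix, direction, phase=0.3 * h)
        z0 = 0.0 if direction > 0 else height
        helix = local + centers[h] + np.array([0.0, 0.0, z0])
        coords.append(helix)
        helix_spans.append((pos, pos + spec.residues_per_helix))
        segments.extend(["H"] * spec.residues_per_helix)
        pos += spec.residues_per_helix
        if h < spec.n_helices - 1:
            p0 = helix[-1]
            direction_next = 1.0 if (h + 1) % 2 == 0 else -1.0
            local_next = _ideal_helix(spec.residues_per_helix, direction_next, phase=0.3 * (h + 1))
            z0n = 0.0 if direction_next > 0 else height
            next_helix = local_next + centers[h + 1] + np.array([0.0, 0.0, z0n])
            p1 = next_helix[0]
            # bulge away from the membrane: +z at the top crossing, −z at the bottom
            axial = np.array([0.0, 0.0, 1.0 if p0[2] > height / 2 else -1.0])
            radial = 0.5 * (centers[h] + centers[h + 1])
            radial = radial / np.linalg.norm(radial)
            bulge = axial + 0.4 * radial
            coords.append(_loop_arc(p0, p1, bulge, spec.loop_length))
            loop_spans.append((pos, pos + spec.loop_length))
            segments.extend(["L"] * spec.loop_length)
            pos += spec.loop_length

    xyz = np.vstack(coords)
    if pdist(xyz).min() < MIN_CA_DIST:
        raise ValueError(
            f"bundle geometry has Cα–Cα clash below {MIN_CA_DIST} Å; adjust spec"
        )
    n = len(xyz)
    seq = "".join(rng.choice(list(AA20), size=n))
    record = StructureRecord(
        member_id=f"bundle-{spec.seed}",
        chain_id="A",
        residue_ids=[str(i + 1) for i in range(n)],
        residue_codes=seq,
        ca_coords=xyz,
        segments=segments,
    )
    record.helix_spans = helix_spans  # type: ignore[attr-defined]
    record.loop_spans = loop_spans    # type: ignore[attr-defined]
    return record


def icl3_like_segment(record: StructureRecord, pad: int = 5) -> tuple[int, int]:
    """Position range of the loop between helices 5 and 6 plus flanking ends.

    Mirrors the intracellular loop 3 of the 7-TM fold (between TM5 and TM6);
    ``pad`` residues of the adjoining helix ends are included, as the
    cytoplasmic helix ends move together with the loop upon activation.
    """
    loop_spans = getattr(record, "loop_spans", None)
    if not loop_spans or len(loop_spans) < 5:
        raise ValueError("record lacks bundle loop annotation")
    start, stop = loop_spans[4]  # loop joining the 5th and 6th helices
    return max(0, start - pad), min(len(record), stop + pad)


def _translation_basis(n: int) -> np.ndarray:
    basis = np.zeros((3, 3 * n))
    for d in range(3):
        basis[d, d::3] = 1.0
    return basis / np.sqrt(n)


def segment_shift_mode(record: StructureRecord, segment: tuple[int, int]) -> np.ndarray:
    """Unit 3N-vector displacing a contiguous segment radially outward.

    A smooth cosine window over the segment multiplies each position's
    radial (xy, away from the bundle axis) unit direction; the result is
    orthogonalized against rigid translations and normalized, so planting
    it in an ensemble adds no net translation.
    """
    n = len(record)
    start, stop = segment
    if not (0 <= start < stop <= n):
        raise ValueError(f"segment {segment} outside template of length {n}")
    center = record.ca_coords.mean(axis=0)
    vec = np.zeros((n, 3))
    width = stop - start
    for k, i in enumerate(range(start, stop)):
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (k + 0.5) / width))  # Hann window
        radial = record.ca_coords[i] - center
        radial[2] = 0.0
        norm = np.linalg.norm(radial)
        if norm < 1e-9:
            continue
        vec[i] = w * radial / norm
    flat = vec.reshape(-1)
    for t in _translation_basis(n):
        flat = flat - (flat @ t) * t
    nrm = np.linalg.norm(flat)
    if nrm < 1e-12:
        raise ValueError("segment shift mode vanished after orthogonalization")
    return flat / nrm


def smooth_random_modes(
    record: StructureRecord, k: int, seed: int = 0, smooth_window: int = 9
) -> np.ndarray:
    """k orthonormal smoothly varying 3N-vectors, orthogonal to translations.

    Gaussian coefficients are smoothed along the chain (moving average) so
    the planted collective motions are spatially coherent like low-frequency
    normal modes, then Gram–Schmidt orthonormalized.
    """
    rng = np.random.default_rng(seed)
    n = len(record)
    base = _translation_basis(n)
    modes = []
    kernel = np.ones(smooth_window) / smooth_window
    while len(modes) < k:
        raw = rng.standard_normal((n, 3))
        for d in range(3):
            raw[:, d] = np.convolve(raw[:, d], kernel, mode="same")
        flat = raw.reshape(-1)
        for prev in list(base) + modes:
            flat = flat - (flat @ prev) * prev
        nrm = np.linalg.norm(flat)
        if nrm < 1e-8:
            continue
        modes.append(flat / nrm)
    return np.vstack(modes)


def _ensemble_from_coords(
    template: StructureRecord,
    coords: np.ndarray,
    member_ids: list[str],
    labels: list[str],
) -> MappedEnsemble:
    m, n = coords.shape[:2]
    mask = np.ones((m, n), dtype=bool)
    return MappedEnsemble(
        reference_id=template.member_id,
        member_ids=member_ids,
        position_ids=list(template.residue_ids),
        coords=coords,
        mask=mask,
        occupancy=mask.mean(axis=0),
        labels=labels,
        species=["synthetic"] * m,
        superposed=True,  # members are generated in the template frame
        imputed=True,     # no unresolved positions
        segments=list(template.segments),
    )


def plant_ensemble(spec: PlantedEnsembleSpec) -> MappedEnsemble:
    """Ensemble of template + Gaussian mode displacements + isotropic noise.

    Member m is ``template + Σ_k z_mk √(variance_k) mode_k + ε`` with z and
    ε standard normal under the spec seed; occupancy is 1 everywhere and
    labels are ``none``.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.template)
    flat0 = spec.template.ca_coords.reshape(-1)
    z = rng.standard_normal((spec.n_members, len(spec.variances)))
    disp = (z * np.sqrt(spec.variances)) @ spec.modes
    noise = spec.noise_sd * rng.standard_normal((spec.n_members, 3 * n))
    coords = (flat0 + disp + noise).reshape(spec.n_members, n, 3)
    ids = [f"synth-{i:04d}" for i in range(spec.n_members)]
    ens = _ensemble_from_coords(spec.template, coords, ids, ["none"] * spec.n_members)
    ens.validate()
    return ens


def plant_two_state(spec: TwoStateSpec) -> MappedEnsemble:
    """Labeled two-state ensemble with a segment-localized activation shift.

    Both states share the background planted modes and isotropic noise;
    state A is displaced +shift/2 and state B −shift/2 along the unit shift
    mode, and state B receives extra isotropic noise of ``segment_noise_sd``
    on the segment positions only.
    """
    shift = np.asarray(spec.shift_mode, dtype=float).ravel()
    n = len(spec.template)
    if shift.shape != (3 * n,):
        raise ValueError("shift mode must be a 3N-vector for the template")
    if abs(np.linalg.norm(shift) - 1.0) > 1e-8:
        raise ValueError("shift mode must be unit length")
    start, stop = spec.segment
    if not (0 <= start < stop <= n):
        raise ValueError(f"segment {spec.segment} outside template")
    base = PlantedEnsembleSpec(
        template=spec.template,
        modes=spec.modes,
        variances=spec.variances,
        noise_sd=spec.noise_sd,
        n_members=2 * spec.m_per_state,
        seed=spec.seed,
    )
    ens = plant_ensemble(base)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    coords = ens.coords.reshape(ens.n_members, -1)
    half = spec.m_per_state
    coords[:half] += 0.5 * spec.shift_amplitude * shift
    coords[half:] -= 0.5 * spec.shift_amplitude * shift
    coords = coords.reshape(ens.n_members, n, 3)
    if spec.segment_noise_sd > 0:
        extra = spec.segment_noise_sd * rng.standard_normal((half, stop - start, 3))
        coords[half:, start:stop] += extra
    la, lb = spec.state_labels
    labels = [la] * half + [lb] * half
    ids = [f"{lab}-{i:03d}" for i, lab in enumerate(labels)]
    out = _ensemble_from_coords(spec.template, coords, ids, labels)
    out.validate()
    return out


def mutate_sequences(
    reference: str, target_identities: list[float], seed: int = 0
) -> list[str]:
    """Sequences at exact target identities to the reference.

    Each output substitutes a seeded random position set of size
    ``round((1 - identity) * len)`` with a different residue, so the
    realized identity is exact after rounding.
    """
    rng = np.random.default_rng(seed)
    n = len(reference)
    out = []
    for ident in target_identities:
        if not (0.0 < ident <= 1.0):
            raise ValueError(f"identity {ident} outside (0, 1]")
        n_sub = round((1.0 - ident) * n)
        if n - n_sub < 1:
            raise ValueError(f"identity {ident} too low for length {n}")
        positions = rng.choice(n, size=n_sub, replace=False)
        seq = list(reference)
        for p in positions:
            choices = [a for a in AA20 if a != seq[p]]
            seq[p] = choices[rng.integers(len(choices))]
        out.append("".join(seq))
    return out


def ground_truth_json(spec: TwoStateSpec) -> str:
    """Serialized planted ground truth (modes, variances, shift, segment)."""
    payload = {
        "segment": list(spec.segment),
        "shift_amplitude": spec.shift_amplitude,
        "segment_noise_sd": spec.segment_noise_sd,
        "noise_sd": spec.noise_sd,
        "variances": spec.variances.tolist(),
        "shift_mode": np.asarray(spec.shift_mode).tolist(),
        "modes": np.asarray(spec.modes).tolist(),
        "m_per_state": spec.m_per_state,
        "seed": spec.seed,
    }
    return json.dumps(payload, indent=1)


def default_two_state_spec(seed: int = 0, m_per_state: int = 20, **overrides) -> TwoStateSpec:
    """The standard labeled synthetic study conditions used throughout.

    Seven-helix bundle template; three smooth background modes with
    variances 4, 2, 1 Å² (kept below the activation shift so the shift is
    the leading variance direction, as in the receptor family emulated);
    0.2 Å isotropic noise; a 6 Å activation-like shift on the ICL3-like
    loop segment; 2 Å extra inactive-state segment noise (the inactive
    loop is effectively disordered, so its excursions are on the scale of
    the loop geometry itself); 20 members per state.
    """
    bundle = make_bundle(BundleSpec(seed=seed))
    segment = icl3_like_segment(bundle)
    shift = segment_shift_mode(bundle, segment)
    modes = smooth_random_modes(bundle, k=3, seed=seed)
    # keep background modes orthogonal to the planted shift direction
    modes = modes - np.outer(modes @ shift, shift)
    modes = np.vstack([m / np.linalg.norm(m) for m in modes])
    # re-orthonormalize after the projection
    q, _ = np.linalg.qr(modes.T)
    modes = q.T
    spec = TwoStateSpec(
        template=bundle,
        modes=modes,
        variances=np.array([4.0, 2.0, 1.0]),
        shift_mode=shift,
        segment=segment,
        seed=seed,
        m_per_state=m_per_state,
    )
    return dataclasses.replace(spec, **overrides) if overrides else spec
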