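"""Signature dynamics across an ensemble of homologous structures.

Each member gets its own GNM on the common mapped position set.  Because
eigenvector sign and the ordering of near-degenerate eigenvalues are
arbitrary, member modes are matched to the modes of a chosen reference
spectrum (greedy, in ascending reference-mode order, by absolute inner
product) before family-level statistics are formed.  Similarity between two
members' mode spectra is the covariance (spectral) overlap over a mode
window, with the spectral distance arccos(overlap) used for the dynamics
heatmap; signature profiles are the per-residue mean/variance/min/max of
mode-regime MSFs over the ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .enm import DEFAULT_GAMMA, DEFAULT_GNM_CUTOFF, build_gnm
from .ensemble_align import MappedEnsemble
from .similarity import DistanceMatrix

log = logging.getLogger(__name__)

#: mode regimes (1-based inclusive ranges over nonzero modes); "fastest" is
#: each member's 10 highest-frequency modes and needs no matching.
REGIMES: dict[str, tuple[int, int] | None] = {
    "global": (1, 3),
    "lf": (4, 20),
    "ltif": (21, 60),
    "fastest": None,
}
N_FASTEST = 10


@dataclass
class ModeSpectrum:
    """Nonzero GNM modes of one member, optionally matched to a reference.

    ``matched_order[r]`` is the local (0-based) mode index assigned to
    reference mode ``r``; ``match_signs[r]`` flips the local eigenvector so
    its overlap with the reference mode is positive.
    """

    member_id: str
    eigenvalues: np.ndarray   # ascending positive, (K,)
    eigenvectors: np.ndarray  # (K, N)
    matched_order: np.ndarray | None = None
    match_signs: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_positions(self) -> int:
        return self.eigenvectors.shape[1]

    def matched_mode(self, ref_index: int) -> tuple[float, np.ndarray]:
        """Eigenvalue and sign-corrected eigenvector matched to a 0-based reference mode."""
        if self.matched_order is None:
            raise ValueError(f"spectrum {self.member_id} is unmatched")
        k = self.matched_order[ref_index]
        return float(self.eigenvalues[k]), self.match_signs[ref_index] * self.eigenvectors[k]


@dataclass
class SignatureProfile:
    """Per-residue distribution of mode-regime MSFs across the ensemble."""

    regime: str
    mean_msf: np.ndarray
    variance_msf: np.ndarray
    min_msf: np.ndarray
    max_msf: np.ndarray
    n_members: int = 0

    def validate(self) -> None:
        assert (self.min_msf <= self.mean_msf + 1e-12).all()
        assert (self.mean_msf <= self.max_msf + 1e-12).all()
        assert (self.variance_msf >= -1e-15).all()


def ensemble_gnm(
    ensemble: MappedEnsemble,
    cutoff: float = DEFAULT_GNM_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    on_disconnected: str = "drop",
) -> list[ModeSpectrum]:
    """One GNM spectrum per member on the common (imputed) position set.

    Members whose contact graph is disconnected at this cutoff are dropped
    with a warning (or raise, with ``on_disconnected='error'``).
    """
    if not ensemble.superposed:
        raise ValueError("ensemble_gnm requires a superposed ensemble")
    if not (ensemble.imputed or ensemble.mask.all()):
        raise ValueError("ensemble has unresolved positions; run impute_missing first")
    spectra = []
    for k, mid in enumerate(ensemble.member_ids):
        try:
            model = build_gnm(ensemble.coords[k], cutoff=cutoff, gamma=gamma)
        except ValueError as exc:
            if on_disconnected == "error":
                raise
            log.warning("member %s dropped from GNM ensemble: %s", mid, exc)
            continue
        spectra.append(
            ModeSpectrum(
                member_id=mid,
                eigenvalues=model.eigenvalues,
                eigenvectors=model.eigenvectors,
            )
        )
    return spectra


def reference_spectrum(
    reference,  # StructureRecord
    ensemble: MappedEnsemble,
    cutoff: float = DEFAULT_GNM_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> ModeSpectrum:
    """GNM spectrum of the reference structure on the ensemble's positions.

    The reference coordinates are restricted to the retained reference
    positions so every member's modes can be matched against a common,
    member-independent target.
    """
    index = {rid: i for i, rid in enumerate(reference.residue_ids)}
    try:
        rows = [index[rid] for rid in ensemble.position_ids]
    except KeyError as exc:
        raise ValueError(f"ensemble position {exc} absent from reference") from exc
    model = build_gnm(reference.ca_coords[rows], cutoff=cutoff, gamma=gamma)
    return ModeSpectrum(
        member_id=reference.member_id,
        eigenvalues=model.eigenvalues,
        eigenvectors=model.eigenvectors,
    )


def match_modes(
    spectrum: ModeSpectrum,
    reference_spectrum: ModeSpectrum,
    k_max: int = 60,
    method: str = "greedy",
) -> ModeSpectrum:
    """Match a member's modes to the reference spectrum's modes.

    Greedy scheme: reference modes are visited in ascending order and each
    takes the still-unassigned local mode with the largest absolute overlap;
    signs are flipped so matched overlaps are positive.  ``method='optimal'``
    solves the assignment problem maximizing total |overlap| instead.
    """
    if spectrum.n_positions != reference_spectrum.n_positions:
        raise ValueError("spectra live on different position sets")
    k = min(k_max, spectrum.n_modes, reference_spectrum.n_modes)
    if k < k_max:
        log.warning("k_max=%d exceeds available modes; matching %d", k_max, k)
    overlaps = spectrum.eigenvectors @ reference_spectrum.eigenvectors[:k].T  # (K_local, k)
    if method == "optimal":
        rows, cols = linear_sum_assignment(-np.abs(overlaps[:, :k]).T)
        order = np.asarray(cols)  # rows come back sorted 0..k-1
    elif method == "greedy":
        order = np.empty(k, dtype=int)
        taken = np.zeros(spectrum.n_modes, dtype=bool)
        for r in range(k):
            cand = np.abs(overlaps[:, r]).copy()
            cand[taken] = -1.0
            best = int(np.argmax(cand))
            order[r] = best
            taken[best] = True
    else:
        raise ValueError("method must be 'greedy' or 'optimal'")
    signs = np.sign(overlaps[order, np.arange(k)])
    signs[signs == 0] = 1.0
    return replace(spectrum, matched_order=order, match_signs=signs)


def spectral_overlap(a: ModeSpectrum, b: ModeSpectrum, i: int = 1, j: int = 20) -> float:
    """Covariance overlap of two mode spectra over 1-based mode window i..j.

    With per-mode variances σ_k = 1/λ_k,
    SO = 1 − sqrt[(Σσ_A + Σσ_B − 2 Σ_{k,l} sqrt(σ_Ak σ_Bl)(u_k·v_l)²)
                  / (Σσ_A + Σσ_B)],
    clipped into [0, 1].  Identical spectra give 1; orthogonal equal-variance
    single modes give 0.
    """
    if a.n_positions != b.n_positions:
        raise ValueError("spectra live on different position sets")
    if not (1 <= i <= j <= min(a.n_modes, b.n_modes)):
        raise ValueError(f"invalid mode window {i}..{j}")
    sl = slice(i - 1, j)
    sa = 1.0 / a.eigenvalues[sl]
    sb = 1.0 / b.eigenvalues[sl]
    dots2 = (a.eigenvectors[sl] @ b.eigenvectors[sl].T) ** 2
    cross = (np.sqrt(np.outer(sa, sb)) * dots2).sum()
    denom = sa.sum() + sb.sum()
    inner = (denom - 2.0 * cross) / denom
    so = 1.0 - np.sqrt(max(inner, 0.0))
    return float(min(max(so, 0.0), 1.0))


def spectral_distance_matrix(
    spectra: list[ModeSpectrum], i: int = 1, j: int = 20
) -> DistanceMatrix:
    """All-pairs arccos(covariance overlap) over the mode window i..j."""
    m = len(spectra)
    values = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            so = spectral_overlap(spectra[a], spectra[b], i, j)
            values[a, b] = values[b, a] = np.arccos(so)
    mat = DistanceMatrix([s.member_id for s in spectra], values, "spectral_distance")
    mat.validate()
    return mat


def regime_msf(
    spectrum: ModeSpectrum,
    regime: str,
    normalize: bool = True,
) -> np.ndarray:
    """One member's MSF profile for a mode regime.

    Matched regimes (global / lf / ltif) use the local modes assigned to the
    reference modes of the regime window; the "fastest" regime uses the
    member's own 10 highest-frequency modes and needs no matching.  With
    ``normalize`` the profile is scaled to unit sum (γ-relative mode scales
    are arbitrary across members, so only the shape is comparable).
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {sorted(REGIMES)}")
    if regime == "fastest":
        local = np.argsort(spectrum.eigenvalues)[-N_FASTEST:]
    else:
        lo, hi = REGIMES[regime]
        if spectrum.matched_order is None:
            raise ValueError("matched spectrum required for regime " + regime)
        if hi > len(spectrum.matched_order):
            raise ValueError(
                f"regime {regime} needs {hi} matched modes, "
                f"have {len(spectrum.matched_order)}"
            )
        local = spectrum.matched_order[lo - 1 : hi]
    u = spectrum.eigenvectors[local]
    lam = spectrum.eigenvalues[local]
    msf = (u ** 2 / lam[:, None]).sum(axis=0)
    if normalize:
        msf = msf / msf.sum()
    return msf


def signature_profile(
    spectra: list[ModeSpectrum],
    regime: str,
    normalize: bool = True,
) -> SignatureProfile:
    """Elementwise mean/variance/min/max of regime MSFs across members.

    Members whose spectra cannot cover the regime are skipped with a
    warning; the variance uses the population divisor M (a descriptive
    envelope, not an inferential estimate).
    """
    profiles = []
    for s in spectra:
        try:
            profiles.append(regime_msf(s, regime, normalize=normalize))
        except ValueError as exc:
            log.warning("member %s skipped for regime %s: %s", s.member_id, regime, exc)
    if not profiles:
        raise ValueError(f"no member covers regime {regime}")
    arr = np.vstack(profiles)
    prof = SignatureProfile(
        regime=regime,
        mean_msf=arr.mean(axis=0),
        variance_msf=arr.var(axis=0),
        min_msf=arr.min(axis=0),
        max_msf=arr.max(axis=0),
        n_members=len(profiles),
    )
    prof.validate()
    return prof
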