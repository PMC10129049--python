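"""Ensemble principal component analysis of Cα coordinates.

Members of a superposed (and, if needed, mean-imputed) ensemble are treated
as points in 3N-dimensional coordinate space.  The eigenvectors of the
sample covariance about the ensemble mean are the principal components of
structural variation; their eigenvalues (Å²) give the variance each
direction accounts for, and per-residue displacement magnitudes along a
component give its mobility profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_align import MappedEnsemble

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Top-k eigenpairs of the 3N × 3N coordinate covariance (divisor M−1)."""

    eigenvalues: np.ndarray       # (K,) Å², non-increasing
    components: np.ndarray        # (K, 3N), orthonormal rows
    variance_fraction: np.ndarray  # (K,), eigenvalue / total variance
    projections: np.ndarray       # (M, K) Å
    mean_coords: np.ndarray       # (N, 3)
    total_variance: float

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_positions(self) -> int:
        return len(self.mean_coords)


@dataclass
class ResidueMobilityProfile:
    """Per-residue displacement amplitude along one principal component."""

    component: int
    values: np.ndarray  # (N,) nonnegative, Å (scaled by sqrt eigenvalue)
    low_occupancy: np.ndarray | None = None  # (N,) bool flag for imputed positions


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(len(components)), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def ensemble_pca(ensemble: MappedEnsemble, k: int = 20) -> PCAResult:
    """PCA of member coordinate vectors about the ensemble mean.

    The full symmetric eigendecomposition of the (M−1)-divisor covariance is
    computed; the top-``k`` components are returned with a deterministic
    sign convention (largest-magnitude entry positive).  ``k`` is truncated
    to the covariance rank bound min(3N, M−1) with a warning.
    """
    if not ensemble.superposed:
        raise ValueError("ensemble_pca requires a superposed ensemble")
    if not (ensemble.imputed or ensemble.mask.all()):
        raise ValueError("ensemble has unresolved positions; run impute_missing first")
    m, n = ensemble.n_members, ensemble.n_positions
    if m < 2:
        raise ValueError("PCA needs at least 2 members")
    k_max = min(3 * n, m - 1)
    if k > k_max:
        log.warning("k=%d exceeds covariance rank bound %d; truncating", k, k_max)
        k = k_max

    x = ensemble.coords.reshape(m, 3 * n)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (m - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(evals.sum())

    components = _fix_signs(evecs[:, :k].T.copy())
    projections = xc @ components.T
    return PCAResult(
        eigenvalues=evals[:k],
        components=components,
        variance_fraction=evals[:k] / total if total > 0 else np.zeros(k),
        projections=projections,
        mean_coords=mean.reshape(n, 3),
        total_variance=total,
    )


def mobility_profile(
    result: PCAResult,
    component: int,
    ensemble: MappedEnsemble | None = None,
) -> ResidueMobilityProfile:
    """Per-residue displacement magnitude along one component (0-based index).

    The component's per-residue (x, y, z) triplet norm is scaled by the
    square root of its eigenvalue, so profiles of successive components are
    on a common Å amplitude scale.
    """
    if not 0 <= component < result.n_components:
        raise ValueError(
            f"component {component} out of range 0..{result.n_components - 1}"
        )
    vec = result.components[component].reshape(-1, 3)
    values = np.linalg.norm(vec, axis=1) * np.sqrt(result.eigenvalues[component])
    low_occ = None
    if ensemble is not None:
        low_occ = ensemble.occupancy < 1.0
    return ResidueMobilityProfile(component=component, values=values, low_occupancy=low_occ)


def project_members(
    result: PCAResult,
    ensemble: MappedEnsemble,
    components: list[int] | None = None,
) -> pd.DataFrame:
    """Member projections onto selected components, labeled for plotting.

    Columns ``PC1..PCk`` (1-based naming) hold the centered-coordinate dot
    products with each component; member id, state label and species are
    attached.  Each projection column has zero mean by construction.
    """
    if components is None:
        components = list(range(result.n_components))
    if any(c < 0 or c >= result.n_components for c in components):
        raise ValueError("component index out of range")
    m, n = ensemble.n_members, ensemble.n_positions
    if 3 * n != result.components.shape[1]:
        raise ValueError("ensemble positions do not match PCA dimensionality")
    xc = ensemble.coords.reshape(m, 3 * n) - result.mean_coords.reshape(-1)
    proj = xc @ result.components[components].T
    df = pd.DataFrame(proj, columns=[f"PC{c + 1}" for c in components])
    df.insert(0, "member_id", ensemble.member_ids)
    df.insert(1, "state_label", ensemble.labels)
    df.insert(2, "species", ensemble.species)
    return df
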