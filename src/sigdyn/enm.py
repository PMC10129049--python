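"""Elastic network models on Cα traces.

The Gaussian Network Model (GNM) places identical springs between residue
pairs within a distance cutoff; its Kirchhoff (contact-graph Laplacian)
matrix Γ determines isotropic fluctuations, with residue mean-square
fluctuations accumulating u_k[i]²/λ_k over chosen nonzero modes (kT/γ
prefactor omitted — spectra are in relative units).  The Anisotropic
Network Model (ANM) builds the 3N × 3N Hessian from per-contact directional
blocks; its six zero modes are rigid-body motions, and its slow nonzero
modes are the directional collective motions compared against ensemble
principal components via the correlation cosine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

DEFAULT_GNM_CUTOFF = 10.0
DEFAULT_ANM_CUTOFF = 15.0
DEFAULT_GAMMA = 1.0
DEFAULT_ZERO_TOL = 1e-8


@dataclass
class GNMModel:
    kirchhoff: np.ndarray      # (N, N)
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray    # (N-1,) ascending, nonzero modes
    eigenvectors: np.ndarray   # (N-1, N), row k = mode k (1-based mode k+1)

    @property
    def n_nodes(self) -> int:
        return self.kirchhoff.shape[0]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ANMModel:
    hessian: np.ndarray        # (3N, 3N)
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray    # ascending, six zero modes removed
    eigenvectors: np.ndarray   # (3N-6, 3N)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def _contact_map(coords: np.ndarray, cutoff: float) -> np.ndarray:
    d = squareform(pdist(coords))
    contact = (d > 0) & (d <= cutoff)
    return contact


def build_gnm(
    coords: np.ndarray,
    cutoff: float = DEFAULT_GNM_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> GNMModel:
    """Kirchhoff matrix and full mode spectrum of the contact network.

    Γ_ij = −γ for 0 < |r_i − r_j| ≤ cutoff, with diagonal entries the
    negative row sums.  Eigenvalues below ``zero_tol · max(λ)`` are treated
    as zero modes and removed; a connected contact graph has exactly one.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n < 3:
        raise ValueError("GNM needs at least 3 nodes")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    contact = _contact_map(coords, cutoff)
    kirchhoff = -gamma * contact.astype(float)
    np.fill_diagonal(kirchhoff, gamma * contact.sum(axis=1))

    evals, evecs = np.linalg.eigh(kirchhoff)
    tol = zero_tol * max(evals[-1], 0.0)
    zero = evals < tol
    if zero.sum() != 1:
        raise ValueError(
            f"contact graph disconnected ({int(zero.sum())} zero modes); "
            f"increase the cutoff (currently {cutoff} Å)"
        )
    return GNMModel(
        kirchhoff=kirchhoff,
        cutoff=cutoff,
        gamma=gamma,
        eigenvalues=evals[~zero],
        eigenvectors=evecs[:, ~zero].T.copy(),
    )


def gnm_msf(model: GNMModel, mode_indices: list[int] | np.ndarray) -> np.ndarray:
    """Per-residue mean-square fluctuations from a subset of nonzero modes.

    ``mode_indices`` are 1-based over the nonzero spectrum (mode 1 = slowest
    nonzero mode); MSF_i = Σ_k u_k[i]² / λ_k in units of 1/γ.
    """
    idx = np.asarray(mode_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("mode subset must be nonempty")
    if (idx < 1).any() or (idx > model.n_modes).any():
        raise ValueError(f"mode indices must lie in 1..{model.n_modes}")
    u = model.eigenvectors[idx - 1]
    lam = model.eigenvalues[idx - 1]
    return (u ** 2 / lam[:, None]).sum(axis=0)


def build_anm(
    coords: np.ndarray,
    cutoff: float = DEFAULT_ANM_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> ANMModel:
    """ANM Hessian and mode spectrum with the six rigid-body modes removed.

    For each contact pair (i, j) the off-diagonal 3×3 super-element is
    −γ (d dᵀ)/|d|² with d the separation vector; diagonal blocks are the
    negative sums of the off-diagonal blocks in their row.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n < 3:
        raise ValueError("ANM needs at least 3 nodes")
    contact = _contact_map(coords, cutoff)
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, 1))
    for i, j in zip(ii, jj):
        d = coords[j] - coords[i]
        block = -gamma * np.outer(d, d) / (d @ d)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block

    evals, evecs = np.linalg.eigh(hessian)
    tol = zero_tol * max(evals[-1], 0.0)
    zero = evals < tol
    if zero.sum() != 6:
        raise ValueError(
            f"expected 6 rigid-body modes, found {int(zero.sum())}: "
            "degenerate geometry or disconnected contact graph"
        )
    return ANMModel(
        hessian=hessian,
        cutoff=cutoff,
        gamma=gamma,
        eigenvalues=evals[~zero],
        eigenvectors=evecs[:, ~zero].T.copy(),
    )


def anm_pc_correlation(anm_mode: np.ndarray, pc_component: np.ndarray) -> float:
    """Correlation cosine |u·v| between an ANM mode and a principal component.

    Both 3N-vectors are normalized first; the absolute value is used because
    eigenvector signs are arbitrary.
    """
    a = np.asarray(anm_mode, dtype=float).ravel()
    b = np.asarray(pc_component, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    return float(abs(a @ b) / (na * nb))
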