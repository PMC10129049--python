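import numpy as np
import pytest

from sigdyn.signature_dynamics import ensemble_gnm, match_modes, reference_spectrum
from sigdyn.synthetic_data import (
    BundleSpec,
    default_two_state_spec,
    make_bundle,
    plant_two_state,
)


@pytest.fixture(scope="session")
def bundle():
    """Default idealized 7-helix bundle template (211 positions)."""
    return make_bundle(BundleSpec())


@pytest.fixture(scope="session")
def two_state():
    """Standard labeled synthetic study conditions, seed 0, with matched spectra."""
    spec = default_two_state_spec(seed=0, m_per_state=20)
    ens = plant_two_state(spec)
    spectra = ensemble_gnm(ens)
    ref = reference_spectrum(spec.template, ens)
    matched = [match_modes(s, ref, k_max=60) for s in spectra]
    return spec, ens, matched


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def quaternion_superposition_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Independent quaternion-eigenproblem (Kearsley) superposition oracle.

    The minimum RMSD equals sqrt(lambda_min / n) where lambda_min is the
    smallest eigenvalue of the 4x4 Kearsley key matrix of the centered
    coordinate sets.
    """
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    xm, ym, zm = (x - y).T
    xp, yp, zp = (x + y).T
    key = np.empty((4, 4))
    key[0, 0] = (xm**2 + ym**2 + zm**2).sum()
    key[1, 1] = (yp**2 + zp**2 + xm**2).sum()
    key[2, 2] = (xp**2 + zp**2 + ym**2).sum()
    key[3, 3] = (xp**2 + yp**2 + zm**2).sum()
    key[0, 1] = key[1, 0] = (yp * zm - ym * zp).sum()
    key[0, 2] = key[2, 0] = (xm * zp - xp * zm).sum()
    key[0, 3] = key[3, 0] = (xp * ym - xm * yp).sum()
    key[1, 2] = key[2, 1] = (xm * ym - xp * yp).sum()
    key[1, 3] = key[3, 1] = (xm * zm - xp * zp).sum()
    key[2, 3] = key[3, 2] = (ym * zm - yp * zp).sum()
    lam = np.linalg.eigvalsh(key)[0]
    return float(np.sqrt(max(lam, 0.0) / len(x)))


def covariance_overlap_bruteforce(eva, vca, evb, vcb) -> float:
    """Double-loop evaluation of the covariance-overlap formula (oracle)."""
    sa = [1.0 / l for l in eva]
    sb = [1.0 / l for l in evb]
    cross = 0.0
    for k in range(len(sa)):
        for l in range(len(sb)):
            cross += np.sqrt(sa[k] * sb[l]) * float(vca[k] @ vcb[l]) ** 2
    denom = sum(sa) + sum(sb)
    return 1.0 - np.sqrt(max((denom - 2 * cross) / denom, 0.0))
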