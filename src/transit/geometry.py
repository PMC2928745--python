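"""Rigid-body superposition, best-fit RMSD, and its analytic gradient.

The RMSD used by the biasing potential is the best-fit (Kabsch) RMSD,
recomputed at every evaluation: the reference is optimally superposed onto
the mobile coordinates before the deviation is measured.  This convention
removes spurious net forces and torques from the bias.

The gradient of the best-fit RMSD with respect to the mobile coordinates is
the standard targeted-MD result: with the optimal rotation treated as
stationary (an application of the envelope theorem at the optimum),

    dRMSD/dx_i = (x_i - xhat_i) / (N * RMSD)

where ``xhat`` is the optimally superposed reference.  Because the optimal
fit matches centroids and zeroes the cross torque, the per-point gradient
vectors sum to zero and exert no net torque.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["Superposition", "kabsch_superpose", "superposed_reference",
           "best_fit_rmsd", "rmsd_gradient"]

#: Below this RMSD (Å) the structures are considered "at target" and the
#: (undefined) gradient is reported as zero with a flag.
AT_TARGET_RMSD = 1e-6

_DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map of a mobile point set onto a reference.

    ``transform`` applies ``x -> R (x - mobile_centroid) + reference_centroid``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return (coords - self.mobile_centroid) @ self.rotation.T \
            + self.reference_centroid


def _check_pair(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinates must have shape (n, 3)")
    if mobile.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a rigid fit")
    return mobile, reference


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Uses the Kabsch/SVD construction with reflection correction.  Raises
    :class:`DegenerateGeometryError` when either point set is (near-)
    collinear, in which case the rotation is not unique.
    """
    mobile, reference = _check_pair(mobile, reference)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    scale = max(np.linalg.norm(p), np.linalg.norm(q), 1.0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    # Collinearity: the two largest principal extents of either cloud must be
    # non-negligible, otherwise rotation about the line is arbitrary.
    for cloud in (p, q):
        sv = np.linalg.svd(cloud, compute_uv=False)
        if sv[1] <= _DEGENERACY_RTOL * scale:
            raise DegenerateGeometryError(
                "point set is collinear (or coincident); superposition "
                "rotation is not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=cr - rot @ cm, rmsd=rmsd,
                         mobile_centroid=cm, reference_centroid=cr)


def superposed_reference(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reference coordinates optimally fitted onto the mobile frame."""
    sup = kabsch_superpose(reference, mobile)
    return sup.transform(np.asarray(reference, dtype=float))


def best_fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between two point sets over all rigid motions."""
    return kabsch_superpose(mobile, reference).rmsd


def rmsd_gradient(mobile: np.ndarray,
                  reference: np.ndarray) -> tuple[np.ndarray, bool]:
    """Gradient of the best-fit RMSD with respect to mobile coordinates.

    Returns ``(gradient, at_target)``.  When the RMSD is below
    ``AT_TARGET_RMSD`` the gradient is undefined; a zero array is returned
    with ``at_target=True``.
    """
    mobile, reference = _check_pair(mobile, reference)
    xhat = superposed_reference(mobile, reference)
    diff = mobile - xhat
    n = mobile.shape[0]
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    if rmsd < AT_TARGET_RMSD:
        return np.zeros_like(mobile), True
    return diff / (n * rmsd), False
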