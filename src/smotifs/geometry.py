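"""Internal-coordinate geometry of Smotifs.

An element's orientation is its principal inertia axis computed from the
Cα trace (unit masses).  For a Smotif the anchor points are P1 = Cα of the
last residue of SS1 and P2 = Cα of the first residue of SS2, L = P2 - P1.

Frame convention.  With e1 = M1, the plane Π is spanned by M1 and L and
the plane Γ by M1 and the normal of Π.  We take

    e2 = normalised component of L orthogonal to e1   (in Π),
    e3 = e1 × e2                                      (normal of Π; Γ = span(e1, e3)),

and define the meridian as the azimuth rho = atan2(M2·e2, M2·e3) mapped to
[0, 360).  A signed azimuth is the only reading of a 0-360 meridian span;
the zero lies in the Γ plane.  When L is (anti)parallel to M1 the frame is
undefined; such Smotifs are flagged ``degenerate`` and given rho = 0.
"""

from __future__ import annotations

import numpy as np

from .core import Smotif, SmotifGeometry, SSElement

__all__ = [
    "principal_axis",
    "geometry_frame",
    "compute_geometry",
    "superpose_rmsd",
    "DEGENERATE_TOL_DEG",
]

#: below this angular separation between L and M1 the Π plane is undefined
DEGENERATE_TOL_DEG = 1.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero vector has no direction")
    return v / n


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = np.clip(np.dot(_unit(a), _unit(b)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def principal_axis(elem: SSElement) -> np.ndarray:
    """Long axis of an element from the inertia tensor of its Cα trace.

    Returns the unit eigenvector of the smallest principal moment, with
    its sign fixed so that it points N- to C-terminal (positive dot
    product with last Cα − first Cα).

    Raises ``ValueError`` for fewer than 3 Cα or coincident points.
    """
    if elem.ca_coords is None:
        raise ValueError("element has no Cα coordinates")
    X = np.asarray(elem.ca_coords, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("principal axis needs at least 3 Cα positions")
    C = X - X.mean(axis=0)
    if np.allclose(C, 0.0):
        raise ValueError("all Cα coincide: inertia tensor degenerate")
    # inertia tensor with unit masses: I = sum(|r|^2) E - sum(r r^T)
    r2 = np.einsum("ij,ij->", C, C)
    inertia = r2 * np.eye(3) - C.T @ C
    w, v = np.linalg.eigh(inertia)
    axis = v[:, np.argmin(w)]
    direction = X[-1] - X[0]
    if np.linalg.norm(direction) > 0 and np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def geometry_frame(ss1: SSElement, ss2: SSElement):
    """Anchors, axes and the (e1, e2, e3) frame for a Smotif pair.

    Returns ``(P1, P2, L, M1, M2, frame)`` where ``frame`` is the 3x3
    matrix with rows e1, e2, e3, or ``None`` when Π is degenerate.
    """
    if ss1.ca_coords is None or ss2.ca_coords is None:
        raise ValueError("both elements need Cα coordinates")
    P1 = np.asarray(ss1.ca_coords[-1], dtype=float)
    P2 = np.asarray(ss2.ca_coords[0], dtype=float)
    L = P2 - P1
    if np.linalg.norm(L) == 0.0:
        raise ValueError("anchor points coincide: D undefined")
    M1 = principal_axis(ss1)
    M2 = principal_axis(ss2)
    delta = _angle_deg(L, M1)
    if delta < DEGENERATE_TOL_DEG or delta > 180.0 - DEGENERATE_TOL_DEG:
        return P1, P2, L, M1, M2, None
    e1 = M1
    e2 = _unit(L - np.dot(L, e1) * e1)
    e3 = np.cross(e1, e2)
    return P1, P2, L, M1, M2, np.vstack([e1, e2, e3])


def compute_geometry(ss1: SSElement, ss2: SSElement) -> SmotifGeometry:
    """The (D, delta, theta, rho) internal coordinates of an element pair.

    Invariant under any rigid motion applied to both elements; a mirror
    reflection maps rho to 360 − rho while preserving D, delta, theta.
    """
    P1, P2, L, M1, M2, frame = geometry_frame(ss1, ss2)
    D = float(np.linalg.norm(L))
    delta = _angle_deg(L, M1)
    theta = _angle_deg(M1, M2)
    if frame is None:
        return SmotifGeometry(D=D, delta=delta, theta=theta, rho=0.0, degenerate=True)
    _, e2, e3 = frame
    rho = float(np.degrees(np.arctan2(np.dot(M2, e2), np.dot(M2, e3)))) % 360.0
    if rho >= 360.0:  # guard against float wrap at exactly 360
        rho = 0.0
    return SmotifGeometry(D=D, delta=delta, theta=theta, rho=rho)


def _paired_cas(a: Smotif, b: Smotif) -> tuple[np.ndarray, np.ndarray]:
    """Loop-junction-anchored Cα pairing of two Smotifs.

    SS1 atoms are aligned at their C-terminus, SS2 atoms at their
    N-terminus, each trimmed to the shorter element; loop residues are
    excluded.  This anchors the comparison at the loop junction, the
    feature the geometry coordinates describe.
    """
    if any(s.ss1.ca_coords is None or s.ss2.ca_coords is None for s in (a, b)):
        raise ValueError("superposition needs Cα coordinates on both Smotifs")
    n1 = min(a.ss1.length, b.ss1.length)
    n2 = min(a.ss2.length, b.ss2.length)
    pa = np.vstack([a.ss1.ca_coords[-n1:], a.ss2.ca_coords[:n2]])
    pb = np.vstack([b.ss1.ca_coords[-n1:], b.ss2.ca_coords[:n2]])
    return pa, pb


def superpose_rmsd(a: Smotif, b: Smotif) -> float:
    """Minimum Cα RMSD of two Smotifs after optimal rigid superposition.

    Kabsch least-squares fit on the anchored pairing of ``_paired_cas``.
    """
    pa, pb = _paired_cas(a, b)
    if pa.shape[0] < 3:
        raise ValueError("need at least 3 paired Cα atoms")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    # Kabsch via SVD of the covariance, proper rotation enforced
    H = pb.T @ pa
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    S_corr = np.array([1.0, 1.0, d])
    # minimised squared deviation without forming the rotation explicitly
    msd = (np.einsum("ij,ij->", pa, pa) + np.einsum("ij,ij->", pb, pb)
           - 2.0 * np.dot(S, S_corr)) / pa.shape[0]
    return float(np.sqrt(max(msd, 0.0)))
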