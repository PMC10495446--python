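"""Spherical head geometry: standard montage positions, sphere fitting,
spherical-spline interpolation and the analytic three-shell forward model.

All positions are head RAS in meters (+x right, +y anterior, +z superior),
with the sphere centre at the origin.

The forward model is a concentric three-shell (brain / skull / scalp)
conductor solved per spherical-harmonic degree by matching potential and
radial current at the shell interfaces, with a zero-flux outer boundary.
It is a closed-form, testable stand-in for template BEM head models.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg

HEAD_RADIUS_M = 0.095

#: relative shell radii (brain, skull outer, scalp outer) and conductivities (S/m)
SHELL_RADII = (0.87, 0.92, 1.0)
SHELL_SIGMA = (0.33, 0.0042, 0.33)


# ---------------------------------------------------------------------------
# standard montage
# ---------------------------------------------------------------------------

def _sph(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from polar angle (from vertex) and azimuth (0 = front,
    counted clockwise toward the right ear when viewed from above)."""
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    w = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if w < 1e-12:
        return a.copy()
    return (np.sin((1 - f) * w) * a + np.sin(f * w) * b) / np.sin(w)


def standard_positions(radius: float = HEAD_RADIUS_M) -> dict[str, np.ndarray]:
    """Idealized 10-20 / 10-10 electrode positions on a sphere.

    Constructed the way the system is defined: 10 %/20 % fractions along the
    nasion-inion midline arc, the preauricular coronal arc, the 10 % ring, and
    great-circle arcs between those anchor points.
    """
    pos: dict[str, np.ndarray] = {}
    # midline arc, nasion (front, polar 90) to inion: 10% steps of the 180 deg arc
    midline = ["Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"]
    for i, name in enumerate(midline):
        frac = 0.1 + 0.1 * i          # fraction of nasion->inion arc
        ang = 180 * frac              # degrees from nasion
        polar = abs(90 - ang)
        azim = 0.0 if ang <= 90 else 180.0
        pos[name] = _sph(polar, azim)
    # coronal arc through the vertex (left preauricular -> right)
    coronal = ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]
    for i, name in enumerate(coronal):
        frac = 0.1 + 0.1 * i
        ang = 180 * frac
        polar = abs(90 - ang)
        azim = -90.0 if ang <= 90 else 90.0
        pos[name] = _sph(polar, azim)
    # 10% ring (polar 72 deg): angles measured from the front midline
    ring = {
        "Fp1": -18, "Fp2": 18, "AF7": -36, "AF8": 36, "F7": -54, "F8": 54,
        "FT7": -72, "FT8": 72, "P7": -126, "P8": 126, "TP7": -108, "TP8": 108,
        "PO7": -144, "PO8": 144, "O1": -162, "O2": 162,
    }
    for name, az in ring.items():
        pos[name] = _sph(72, az)
    # interior electrodes: midway along great-circle arcs ring <-> midline
    arcs = {
        "F3": ("F7", "Fz"), "F4": ("F8", "Fz"),
        "P3": ("P7", "Pz"), "P4": ("P8", "Pz"),
        "AF3": ("AF7", "AFz"), "AF4": ("AF8", "AFz"),
        "PO3": ("PO7", "POz"), "PO4": ("PO8", "POz"),
        "FC3": ("FT7", "FCz"), "FC4": ("FT8", "FCz"),
        "CP3": ("TP7", "CPz"), "CP4": ("TP8", "CPz"),
    }
    for name, (a, b) in arcs.items():
        pos[name] = _slerp(pos[a], pos[b], 0.5)
    quarter = {
        "F5": ("F7", "Fz", 0.25), "F1": ("F7", "Fz", 0.75),
        "F6": ("F8", "Fz", 0.25), "F2": ("F8", "Fz", 0.75),
        "P5": ("P7", "Pz", 0.25), "P1": ("P7", "Pz", 0.75),
        "P6": ("P8", "Pz", 0.25), "P2": ("P8", "Pz", 0.75),
        "FC5": ("FT7", "FCz", 0.25), "FC1": ("FT7", "FCz", 0.75),
        "FC6": ("FT8", "FCz", 0.25), "FC2": ("FT8", "FCz", 0.75),
        "CP5": ("TP7", "CPz", 0.25), "CP1": ("TP7", "CPz", 0.75),
        "CP6": ("TP8", "CPz", 0.25), "CP2": ("TP8", "CPz", 0.75),
    }
    for name, (a, b, f) in quarter.items():
        pos[name] = _slerp(pos[a], pos[b], f)
    return {k: radius * v for k, v in pos.items()}


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit; returns (center, radius).

    Linearized: |p|^2 = 2 c.p + (R^2 - |c|^2).
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < 4:
        # underdetermined: assume origin-centred
        return np.zeros(3), float(np.mean(np.linalg.norm(pts, axis=1)))
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("electrode cloud is not fittable to a sphere")
    return c, float(np.sqrt(r2))


# ---------------------------------------------------------------------------
# spherical splines (Perrin et al. style, stiffness m=4)
# ---------------------------------------------------------------------------

def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m / (4 * np.pi)
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coef)


def spline_interp_weights(pos_from: np.ndarray, pos_to: np.ndarray,
                          m: int = 4, n_terms: int = 50,
                          reg: float = 1e-5) -> np.ndarray:
    """Weight matrix W (n_to x n_from) so that  data_to = W @ data_from.

    Spherical-spline interpolation with a constant term; positions are
    projected onto their best-fit sphere before the angular kernel is built.
    """
    pf = np.asarray(pos_from, float)
    pt = np.asarray(pos_to, float)
    allp = np.vstack([pf, pt])
    c, r = fit_sphere(allp)
    uf = (pf - c) / np.linalg.norm(pf - c, axis=1, keepdims=True)
    ut = (pt - c) / np.linalg.norm(pt - c, axis=1, keepdims=True)
    G = _g_matrix(uf @ uf.T, m, n_terms)
    G = G + reg * np.eye(len(uf))
    # bordered system enforcing sum of spline coefficients == 0
    k = len(uf)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    Gt = _g_matrix(ut @ uf.T, m, n_terms)
    B = np.hstack([Gt, np.ones((len(ut), 1))])
    # W = B @ inv(A) restricted to data rows
    sol = np.linalg.solve(A.T, B.T).T          # B @ inv(A)
    return sol[:, :k]


# ---------------------------------------------------------------------------
# three-shell analytic forward model
# ---------------------------------------------------------------------------

def _shell_response(n_max: int, radii: tuple[float, float, float],
                    sigma: tuple[float, float, float]) -> np.ndarray:
    """Per-degree scalp response factors S_n.

    For each degree n the infinite-medium source term c_n / r^(n+1) inside the
    brain shell is continued through skull and scalp; S_n is the value that
    replaces r^(-(n+1)) at the outer radius, i.e. the bounded-conductor
    potential per unit source coefficient.
    """
    r1, r2, R = radii
    s1, s2, s3 = sigma
    S = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # V continuity at r1:  A1 r1^n - A2 r1^n - B2 r1^-(n+1) = -r1^-(n+1)
        M[0] = [r1 ** n, -r1 ** n, -r1 ** -(n + 1), 0, 0]
        rhs[0] = -r1 ** -(n + 1)
        # current continuity at r1
        M[1] = [s1 * n * r1 ** (n - 1),
                -s2 * n * r1 ** (n - 1),
                s2 * (n + 1) * r1 ** -(n + 2), 0, 0]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # V continuity at r2
        M[2] = [0, r2 ** n, r2 ** -(n + 1), -r2 ** n, -r2 ** -(n + 1)]
        # current continuity at r2
        M[3] = [0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
                -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)]
        # zero radial current at R
        M[4] = [0, 0, 0, n * R ** (n - 1), -(n + 1) * R ** -(n + 2)]
        sol = np.linalg.solve(M, rhs)
        A3, B3 = sol[3], sol[4]
        S[n] = A3 * R ** n + B3 * R ** -(n + 1)
    return S


def _dipole_potential_series(dip_pos: np.ndarray, elec_unit: np.ndarray,
                             S: np.ndarray, sigma_in: float) -> np.ndarray:
    """Gain matrix (n_elec x 3) from the harmonic expansion of a dipole.

    ``S[n]`` carries the radial dependence at the electrode radius (for the
    free medium it is simply r_e^-(n+1)); electrodes are given as unit
    directions. The expansion is
    V = 1/(4 pi s) * sum_n S_n b^(n-1) [ n m_r P_n(x) + m_t P_n'(x) sqrt(1-x^2) ]
    with x the cosine of the dipole-electrode angle.
    """
    n_max = len(S) - 1
    b = np.linalg.norm(dip_pos)
    if b < 1e-12:
        # central dipole: only n=1 term survives, direction-independent geometry
        p_hat = np.array([0.0, 0.0, 1.0])
        b_pow = np.zeros(n_max + 1)
        b_pow[1] = 1.0
    else:
        p_hat = dip_pos / b
        n_arr = np.arange(n_max + 1)
        b_pow = np.where(n_arr >= 1, b ** np.maximum(n_arr - 1, 0), 0.0)

    x = np.clip(elec_unit @ p_hat, -1.0, 1.0)
    # e_perp: unit component of the electrode direction orthogonal to p_hat
    perp = elec_unit - np.outer(x, p_hat)
    pn = np.linalg.norm(perp, axis=1)
    safe = pn > 1e-12
    perp[safe] /= pn[safe, None]
    perp[~safe] = 0.0

    n_arr = np.arange(n_max + 1)
    rad_coef = np.zeros(n_max + 1)
    rad_coef[1:] = S[1:] * b_pow[1:] * n_arr[1:]
    tan_coef = S * b_pow

    P_rad = npleg.legval(x, rad_coef)                       # sum_n c_n P_n(x)
    dtan = npleg.legder(tan_coef)                           # derivative series
    P_tan = npleg.legval(x, dtan) * np.sqrt(np.maximum(1 - x ** 2, 0.0))

    # V(e) = k * [ (m . p_hat) P_rad(e) + (m . perp_e) P_tan(e) ]
    k = 1.0 / (4 * np.pi * sigma_in)
    gain = k * (np.outer(P_rad, p_hat) + P_tan[:, None] * perp)
    return gain


def leadfield_free_medium(dip_pos: np.ndarray, elec_pos: np.ndarray,
                          sigma: float = 0.33) -> np.ndarray:
    """Closed-form infinite-medium dipole gain (n_elec x 3); test oracle."""
    d = np.asarray(elec_pos, float) - np.asarray(dip_pos, float)
    r = np.linalg.norm(d, axis=1, keepdims=True)
    return d / (4 * np.pi * sigma * r ** 3)


def leadfield_free_medium_series(dip_pos: np.ndarray, elec_pos: np.ndarray,
                                 sigma: float = 0.33,
                                 n_terms: int = 60) -> np.ndarray:
    """Same free-medium gain through the harmonic series (series validation)."""
    elec = np.asarray(elec_pos, float)
    re = np.linalg.norm(elec, axis=1)
    if not np.allclose(re, re[0], rtol=1e-6):
        raise ValueError("series form requires electrodes on a common sphere")
    S = np.zeros(n_terms + 1)
    n = np.arange(1, n_terms + 1)
    S[1:] = re[0] ** -(n + 1)
    return _dipole_potential_series(np.asarray(dip_pos, float), elec / re[:, None],
                                    S, sigma)


class ThreeShellModel:
    """Concentric three-shell conductor fitted to an electrode cloud."""

    def __init__(self, elec_pos: np.ndarray, n_terms: int = 60,
                 radii: tuple[float, float, float] = SHELL_RADII,
                 sigma: tuple[float, float, float] = SHELL_SIGMA):
        elec_pos = np.asarray(elec_pos, float)
        if not np.all(np.isfinite(elec_pos)):
            raise ValueError("non-finite electrode positions")
        self.center, self.scalp_radius = fit_sphere(elec_pos)
        rel = elec_pos - self.center
        d = np.linalg.norm(rel, axis=1)
        if np.any(d < 1e-9):
            raise ValueError("electrode at sphere centre; cloud not fittable")
        resid = np.std(d) / np.mean(d)
        extent = np.max(np.linalg.norm(elec_pos - elec_pos.mean(axis=0), axis=1))
        if resid > 0.05 or self.scalp_radius > 2.0 * extent:
            raise ValueError(
                "electrode cloud is not fittable to a head-sized sphere "
                f"(radial fit residual {resid:.3f}, fitted radius "
                f"{self.scalp_radius:.3f} m vs cloud extent {extent:.3f} m)")
        self.elec_unit = rel / d[:, None]
        self.radii = tuple(r * self.scalp_radius for r in radii)
        self.sigma = sigma
        self.n_terms = n_terms
        self._S = _shell_response(n_terms, self.radii, sigma)

    def gain(self, dip_pos: np.ndarray) -> np.ndarray:
        """(n_elec x 3) scalp potential per unit dipole moment at ``dip_pos``."""
        p = np.asarray(dip_pos, float) - self.center
        b = np.linalg.norm(p)
        if b >= self.radii[0]:
            raise ValueError("dipole outside the brain shell")
        return _dipole_potential_series(p, self.elec_unit, self._S, self.sigma[0])
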