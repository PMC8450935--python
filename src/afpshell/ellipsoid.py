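"""Protein-shape ellipsoid model and its distance/volume geometry.

The hydration-shell analysis references every solvent position to a single
smooth surface: an ellipsoid fitted to the protein heavy atoms.  Distances
from that surface define the density profiles, and the volumes of its
parallel (offset) bodies define the geometric slab volumes used to turn
water counts into densities.

The fit maps the weighted gyration tensor of the atom cloud onto a uniform
solid ellipsoid: eigenvalues lambda_i of the gyration tensor correspond to
semi-axes a_i = sqrt(5 * lambda_i).  This is parameter-free and exact for a
uniformly filled ellipsoid; the downstream ratio normalisation
(rho / rho_b,fict) makes the shell statistics insensitive to the precise
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "EllipsoidModel",
    "fit_ellipsoid",
    "signed_surface_distance",
    "parallel_body_volume",
    "steiner_coefficients",
]


@dataclass(frozen=True)
class EllipsoidModel:
    """Fitted ellipsoid: center, orthonormal axes (rows = principal axes),
    semi-axes (a >= b >= c > 0), all lengths in nm."""

    center: np.ndarray          # (3,)
    axes: np.ndarray            # (3, 3) rotation matrix, rows are axes
    semi_axes: np.ndarray       # (3,), descending

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        semi = np.asarray(self.semi_axes, dtype=float).reshape(3)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-10):
            raise ValueError("axes must be orthonormal (R @ R.T = I within 1e-10)")
        if not (semi[0] >= semi[1] >= semi[2] > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {semi}")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "semi_axes", semi)

    @property
    def volume(self) -> float:
        """Ellipsoid volume (4pi/3) a b c in nm^3."""
        a, b, c = self.semi_axes
        return 4.0 * np.pi / 3.0 * a * b * c

    @property
    def is_sphere(self) -> bool:
        a, _, c = self.semi_axes
        return (a - c) < 1e-12 * max(a, 1.0)

    def to_body_frame(self, points: np.ndarray) -> np.ndarray:
        """Map lab-frame points (N,3) into the ellipsoid's principal frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ self.axes.T

    # -- serialisation (small text record for reproducibility) --------------

    def to_dict(self) -> dict:
        return {
            "center": [float(x) for x in self.center],
            "axes": [[float(x) for x in row] for row in self.axes],
            "semi_axes": [float(x) for x in self.semi_axes],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "EllipsoidModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            center=np.array(d["center"], dtype=float),
            axes=np.array(d["axes"], dtype=float),
            semi_axes=np.array(d["semi_axes"], dtype=float),
        )


def fit_ellipsoid(coords: np.ndarray, weights: np.ndarray | None = None) -> EllipsoidModel:
    """Fit the protein ellipsoid from atom coordinates.

    Parameters
    ----------
    coords : (N, 3) array, nm
        Atom positions (heavy atoms by convention).
    weights : (N,) array, optional
        Per-atom weights (masses); unit weights if omitted.

    Returns
    -------
    EllipsoidModel
        center = weighted centroid; axes = gyration-tensor eigenvectors
        (right-handed); semi-axes a_i = sqrt(5 lambda_i), descending.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    n = coords.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 atoms to fit an ellipsoid, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must match number of atoms")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    center = (w[:, None] * coords).sum(axis=0) / wsum
    d = coords - center
    gyr = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / wsum
    lam, vec = np.linalg.eigh(gyr)           # ascending
    scale = float(np.trace(gyr))
    if lam[0] <= 1e-12 * max(scale, 1e-30) or scale <= 0:
        rank = int(np.sum(lam > 1e-12 * max(scale, 1e-30)))
        raise ValueError(
            f"degenerate atom cloud: gyration tensor rank {rank} < 3 "
            "(coplanar or collinear coordinates)"
        )
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    axes = vec[:, order].T                   # rows = axes, descending eigenvalue
    if np.linalg.det(axes) < 0:              # enforce right-handedness
        axes[2] *= -1.0
    semi = np.sqrt(5.0 * lam)
    return EllipsoidModel(center=center, axes=axes, semi_axes=semi)


def _root_bracketed(u: np.ndarray, a2: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                    iters: int = 70) -> np.ndarray:
    """Vectorised bisection for F(t) = sum a_i^2 u_i^2 / (a_i^2 + t)^2 - 1 = 0.

    F is strictly decreasing on (-c^2, inf); lo/hi must bracket the root.
    """
    lo = lo.copy()
    hi = hi.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f = (a2 * u * u / (a2 + mid[:, None]) ** 2).sum(axis=1) - 1.0
        take_lo = f > 0
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def signed_surface_distance(points: np.ndarray, ellipsoid: EllipsoidModel) -> np.ndarray:
    """Euclidean distance from point(s) to the ellipsoid surface, negative inside.

    Exact for spheres.  For general ellipsoids the nearest surface point
    x_i = a_i^2 u_i / (a_i^2 + t) is found by solving the orthogonality
    condition for t with bracketed bisection (|Delta d| converges well below
    1e-6 nm).  For interior points lying exactly on a principal plane the
    nearest point is taken within that plane (the symmetric solution); at the
    exact center the distance is -c (nearest along the shortest axis).

    Accepts a single (3,) point or an (N, 3) array; returns scalar or (N,).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    u = np.abs(ellipsoid.to_body_frame(pts))
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite point coordinates")
    a = ellipsoid.semi_axes
    a2 = a * a
    if ellipsoid.is_sphere:
        d = np.linalg.norm(u, axis=1) - a[0]
        return float(d[0]) if single else d

    n = u.shape[0]
    dist = np.empty(n)
    f0 = (u * u / a2).sum(axis=1)            # <1 inside, >1 outside
    inside = f0 < 1.0
    r = np.linalg.norm(u, axis=1)

    out = ~inside
    if out.any():
        uo = u[out]
        ro = r[out]
        lo = np.zeros(out.sum())
        hi = a[0] * ro + a2[0]               # F(hi) < 1 guaranteed
        t = _root_bracketed(uo, a2, lo, hi)
        x = a2 * uo / (a2 + t[:, None])
        dist[out] = np.linalg.norm(uo - x, axis=1)

    if inside.any():
        ui = u[inside]
        m = ui.shape[0]
        lo = np.full(m, -a2[2] * (1.0 - 1e-12))
        hi = np.zeros(m)
        t = _root_bracketed(ui, a2, lo, hi)
        x = a2 * ui / (a2 + t[:, None])
        d = np.linalg.norm(ui - x, axis=1)
        # exact center: bisection degenerates; nearest surface point is at
        # the end of the shortest axis
        at_center = (ui * ui).sum(axis=1) < 1e-24
        d = np.where(at_center, a[2], d)
        dist[inside] = -d

    return float(dist[0]) if single else dist


def steiner_coefficients(ellipsoid: EllipsoidModel, n_theta: int = 256,
                         n_phi: int = 256) -> tuple[float, float]:
    """Surface area S and integrated mean curvature M of the ellipsoid.

    Both are evaluated by quadrature over the standard parametrisation
    (Gauss–Legendre in theta, trapezoid in the periodic phi), using the
    first and second fundamental forms.  For a sphere of radius r this
    returns (4 pi r^2, 4 pi r) to machine precision at these grid sizes.
    """
    a, b, c = ellipsoid.semi_axes
    nodes, wts = np.polynomial.legendre.leggauss(n_theta)
    theta = 0.5 * np.pi * (nodes + 1.0)      # map [-1,1] -> [0, pi]
    wt = 0.5 * np.pi * wts
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    wp = 2.0 * np.pi / n_phi

    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    sp, cp = np.sin(phi)[None, :], np.cos(phi)[None, :]

    r_t = np.stack([a * ct * cp, b * ct * sp, -c * st * np.ones_like(cp)], axis=-1)
    r_p = np.stack([-a * st * sp, b * st * cp, np.zeros_like(st * cp)], axis=-1)
    r_tt = np.stack([-a * st * cp, -b * st * sp, -c * ct * np.ones_like(cp)], axis=-1)
    r_tp = np.stack([-a * ct * sp, b * ct * cp, np.zeros_like(st * cp)], axis=-1)
    r_pp = np.stack([-a * st * cp, -b * st * sp, np.zeros_like(st * cp)], axis=-1)

    cross = np.cross(r_t, r_p)
    dA = np.linalg.norm(cross, axis=-1)
    ok = dA > 1e-300
    nrm = np.where(ok[..., None], cross / np.where(ok, dA, 1.0)[..., None], 0.0)

    E = (r_t * r_t).sum(-1)
    F = (r_t * r_p).sum(-1)
    G = (r_p * r_p).sum(-1)
    L = (r_tt * nrm).sum(-1)
    Mf = (r_tp * nrm).sum(-1)
    N = (r_pp * nrm).sum(-1)
    denom = E * G - F * F
    H = np.where(ok, (E * N - 2.0 * F * Mf + G * L) / np.where(ok, 2.0 * denom, 1.0), 0.0)
    # with the r_t x r_p normal (outward) H comes out negative for a convex
    # body in this convention; the Steiner coefficient is the outward one
    w2d = wt[:, None]
    S = float((dA * w2d).sum() * wp)
    M = float((-H * dA * w2d).sum() * wp)
    return S, M


def parallel_body_volume(ellipsoid: EllipsoidModel, t: float,
                         method: str = "steiner",
                         n_qmc: int = 1 << 20, seed: int = 0) -> float:
    """Volume (nm^3) of the parallel body {x : dist(x, surface) <= t}, t >= 0.

    method="steiner" evaluates V + S t + M t^2 + (4 pi / 3) t^3, which is
    exact for a convex body, with S and M from numerical quadrature.
    method="qmc" integrates the indicator over the bounding box with a
    scrambled Sobol sequence (relative error well below 0.2% at the default
    point count) and exists as an independent cross-check.
    """
    if t < 0:
        raise ValueError(f"offset t must be >= 0, got {t}")
    if method == "steiner":
        S, M = steiner_coefficients(ellipsoid)
        return ellipsoid.volume + S * t + M * t * t + 4.0 * np.pi / 3.0 * t ** 3
    if method == "qmc":
        from scipy.stats import qmc

        a = ellipsoid.semi_axes
        half = a + t
        sampler = qmc.Sobol(d=3, scramble=True, rng=seed)
        pts = sampler.random(n_qmc) * 2.0 * half - half     # body frame
        lab = pts @ ellipsoid.axes + ellipsoid.center
        d = signed_surface_distance(lab, ellipsoid)
        frac = float(np.mean(d <= t))
        return frac * float(np.prod(2.0 * half))
    raise ValueError(f"unknown method {method!r}")
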