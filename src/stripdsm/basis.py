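"""Spline bases and roughness penalties for abundance smooths.

Two families are provided:

* a cubic regression spline (B-spline basis with knots at data quantiles
  and an exact second-derivative penalty) for univariate covariates such
  as mean elevation or distance to coast, and
* a low-rank isotropic radial smoother (Gaussian kernel at deterministic
  farthest-point knots, with an unpenalized polynomial part) for the
  bivariate geographic-location term and the optional joint
  location-by-covariate term.

Every term absorbs a sum-to-zero identifiability constraint over the data
it was built on, so a model intercept can be estimated separately; a term
of nominal dimension ``k`` therefore contributes ``k - 1`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SmoothTerm", "build_univariate_smooth", "build_location_smooth"]

K_MIN = 4
K_MAX = 20


@dataclass
class SmoothTerm:
    """A smooth model term: constrained design columns plus quadratic penalty.

    Attributes
    ----------
    names : tuple of str
        Covariate name(s) the term consumes, in evaluation order.
    kind : str
        ``"cubic"`` for the univariate spline, ``"radial"`` for the
        isotropic multivariate smoother.
    k : int
        Nominal basis dimension before the sum-to-zero constraint.
    knots : ndarray
        Knot vector (cubic) or knot coordinates, one row per knot (radial).
    X : ndarray, shape (n, k-1)
        Constrained design evaluated at the training data.
    S : ndarray, shape (k-1, k-1)
        Constrained penalty matrix, symmetric positive semidefinite,
        rescaled to unit Frobenius norm so smoothing parameters are
        dimensionless whatever the covariate units; ``penalty_scale``
        holds the factor, i.e. ``S * penalty_scale`` is the raw roughness
        Gram matrix (integrated squared second derivative for cubic
        terms).
    null_dim : int
        Dimension of the penalty null space *before* the constraint
        (2 for cubic: constant + linear; 1 + d for radial: constant +
        linear polynomial in each input).
    """

    names: tuple[str, ...]
    kind: str
    k: int
    knots: np.ndarray
    X: np.ndarray
    S: np.ndarray
    null_dim: int
    constraint: np.ndarray
    Z: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(1))
    scale: np.ndarray = field(default_factory=lambda: np.ones(1))
    lengthscale: float = 1.0
    penalty_scale: float = 1.0
    data_min: np.ndarray | None = None
    data_max: np.ndarray | None = None

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def design(self, values: np.ndarray) -> np.ndarray:
        """Evaluate the constrained design columns at new covariate values.

        ``values`` is a 1-D array for cubic terms, an (n, d) array for
        radial terms. Beyond the training range a cubic smooth is continued
        constant at its boundary value (cubic polynomial extrapolation is
        unbounded and such cells are flagged as extrapolation anyway);
        radial terms decay naturally to their polynomial part.
        """
        if self.kind == "cubic":
            x = np.asarray(values, dtype=float).ravel()
            x = np.clip(x, self.knots[0], self.knots[-1])
            raw = BSpline.design_matrix(x, self.knots, 3).toarray()
        else:
            pts = np.atleast_2d(np.asarray(values, dtype=float))
            z = (pts - self.center) / self.scale
            raw = _radial_design(z, self.knots, self.lengthscale)
        return raw @ self.Z

    def extrapolated(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of rows lying outside the training covariate range."""
        if self.data_min is None:
            return np.zeros(np.atleast_2d(values).shape[0], dtype=bool)
        pts = np.asarray(values, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        return np.any((pts < self.data_min) | (pts > self.data_max), axis=1)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "kind": self.kind,
            "k": self.k,
            "knots": self.knots.tolist(),
            "null_dim": self.null_dim,
            "constraint": self.constraint.tolist(),
            "Z": self.Z.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "lengthscale": self.lengthscale,
            "penalty_scale": self.penalty_scale,
            "data_min": None if self.data_min is None else self.data_min.tolist(),
            "data_max": None if self.data_max is None else self.data_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothTerm":
        return cls(
            names=tuple(d["names"]),
            kind=d["kind"],
            k=d["k"],
            knots=np.asarray(d["knots"], dtype=float),
            X=np.zeros((0, np.asarray(d["Z"]).shape[1])),
            S=np.zeros((np.asarray(d["Z"]).shape[1],) * 2),
            null_dim=d["null_dim"],
            constraint=np.asarray(d["constraint"], dtype=float),
            Z=np.asarray(d["Z"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            lengthscale=d["lengthscale"],
            penalty_scale=d.get("penalty_scale", 1.0),
            data_min=None if d["data_min"] is None else np.asarray(d["data_min"]),
            data_max=None if d["data_max"] is None else np.asarray(d["data_max"]),
        )


def _constraint_null_basis(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the row vector c (k x (k-1))."""
    k = c.size
    # Householder: full QR of c as a column, drop the first column of Q.
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(k)[:, : k - 1]]))
    z = q[:, 1:]
    # Sign convention for reproducibility across BLAS implementations.
    signs = np.sign(np.sum(z, axis=0))
    signs[signs == 0] = 1.0
    return z * signs


def _apply_constraint(X: np.ndarray, S: np.ndarray):
    c = X.sum(axis=0)
    if np.linalg.norm(c) < 1e-12:  # already centered
        c = np.eye(X.shape[1])[0]
    Z = _constraint_null_basis(c / np.linalg.norm(c))
    Sc = Z.T @ S @ Z
    scale = float(np.linalg.norm(Sc, "fro"))
    if scale > 0:
        Sc = Sc / scale
    return X @ Z, Sc, c, Z, scale


def build_univariate_smooth(values: np.ndarray, k: int, name: str = "x") -> SmoothTerm:
    """Cubic regression spline with knots at data quantiles.

    The penalty is the exact integrated squared second derivative of the
    spline over the data range, computed by Gauss-Legendre quadrature on
    each knot span (the integrand is piecewise quadratic, so two nodes per
    span are exact). The null space of the unconstrained penalty is the
    span of constant and linear functions.

    Parameters
    ----------
    values : array
        Training covariate values; must contain at least ``k`` distinct values.
    k : int
        Basis dimension, between 4 and 20.
    """
    if not (K_MIN <= k <= K_MAX):
        raise ValueError(f"k must lie in [{K_MIN}, {K_MAX}], got {k}")
    x = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(x)
    if uniq.size < k:
        raise ValueError(f"need at least k={k} distinct values, got {uniq.size}")

    lo, hi = uniq[0], uniq[-1]
    n_interior = k - 4
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(uniq, probs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])

    X = BSpline.design_matrix(x, t, 3).toarray()
    S = _bspline_curvature_penalty(t, k)
    Xc, Sc, c, Z, scale = _apply_constraint(X, S)
    return SmoothTerm(
        names=(name,), kind="cubic", k=k, knots=t, X=Xc, S=Sc, null_dim=2,
        constraint=c, Z=Z, penalty_scale=scale,
        data_min=np.array([lo]), data_max=np.array([hi]),
    )


def _second_derivative_operator(t: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient map L so that the 2nd derivative of spline(t, c, 3) is
    spline(t[2:-2], L @ c, 1); returns (t[2:-2], L)."""
    L1 = np.zeros((k - 1, k))
    for i in range(k - 1):
        dt = t[i + 4] - t[i + 1]
        L1[i, i], L1[i, i + 1] = -3.0 / dt, 3.0 / dt
    L2 = np.zeros((k - 2, k - 1))
    for i in range(k - 2):
        dt = t[i + 4] - t[i + 2]
        L2[i, i], L2[i, i + 1] = -2.0 / dt, 2.0 / dt
    return t[2:-2], L2 @ L1


def _bspline_curvature_penalty(t: np.ndarray, k: int) -> np.ndarray:
    """Exact Gram matrix of second derivatives of the k cubic B-splines on t.

    The second derivative is piecewise linear, so its pairwise products are
    quadratic and two-point Gauss-Legendre per knot span integrates exactly.
    """
    t2, L = _second_derivative_operator(t, k)
    spans = np.unique(t)
    gn = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    S = np.zeros((k, k))
    for a, b in zip(spans[:-1], spans[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        pts = mid + half * gn
        D = BSpline.design_matrix(pts, t2, 1).toarray() @ L
        S += half * D.T @ D
    return 0.5 * (S + S.T)


def _radial_design(z: np.ndarray, knots: np.ndarray, ell: float) -> np.ndarray:
    """Unconstrained radial design [1 | z | kernel(z, knots)]."""
    d2 = ((z[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * d2 / ell**2)
    return np.column_stack([np.ones(z.shape[0]), z, K])


def _farthest_point_knots(z: np.ndarray, m: int) -> np.ndarray:
    """Deterministic farthest-point subsample of m rows of z.

    Starts from the point nearest the centroid; ties broken by row index.
    Prefixes are nested, so knot sets for increasing k are nested too.
    """
    n = z.shape[0]
    centroid = z.mean(axis=0)
    start = int(np.argmin(((z - centroid) ** 2).sum(axis=1)))
    chosen = [start]
    mind = ((z - z[start]) ** 2).sum(axis=1)
    while len(chosen) < m:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, ((z - z[nxt]) ** 2).sum(axis=1))
    return z[chosen]


def build_location_smooth(points: np.ndarray, k: int,
                          names: tuple[str, ...] = ("x", "y")) -> SmoothTerm:
    """Isotropic radial smooth of geographic location (or location x covariate).

    Coordinates are standardized (centered, scaled by standard deviation)
    so meter-scale inputs are well conditioned; the basis is a Gaussian
    radial kernel at ``k - 1 - d`` farthest-point knots plus an unpenalized
    linear polynomial, giving a penalty null space of dimension ``1 + d``
    (constant plus a plane for d = 2). The penalty is the kernel Gram
    matrix at the knots, positive semidefinite by construction. The kernel
    lengthscale is the median inter-knot distance.

    Raises ``ValueError`` when the points are collinear (rank-deficient
    polynomial part) or fewer than ``k`` distinct points exist.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts.shape[1]
    if not (1 + d + 1 <= k <= K_MAX):
        raise ValueError(f"k must lie in [{d + 2}, {K_MAX}] for a {d}-input smooth")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < k:
        raise ValueError(f"need at least k={k} distinct points, got {uniq.shape[0]}")
    center = pts.mean(axis=0)
    scale = pts.std(axis=0)
    if np.any(scale < 1e-12) or np.linalg.matrix_rank(pts - center, tol=1e-9 * max(1.0, np.abs(pts).max())) < d:
        raise ValueError("points are collinear; location smooth is rank deficient")
    z = (pts - center) / scale

    m = k - 1 - d  # number of radial knots
    zu = np.unique(z, axis=0)
    knots = _farthest_point_knots(zu, m)
    dk = np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2))
    ell = float(np.median(dk[np.triu_indices(m, 1)])) if m > 1 else 1.0
    ell = max(ell, 1e-6)

    X = _radial_design(z, knots, ell)
    S = np.zeros((k, k))
    K = np.exp(-0.5 * (dk / ell) ** 2)
    S[1 + d:, 1 + d:] = K + 1e-10 * np.eye(m)
    Xc, Sc, c, Z, pscale = _apply_constraint(X, S)
    return SmoothTerm(
        names=tuple(names), kind="radial", k=k, knots=knots, X=Xc, S=Sc,
        null_dim=1 + d, constraint=c, Z=Z, center=center, scale=scale,
        lengthscale=ell, penalty_scale=pscale,
        data_min=pts.min(axis=0), data_max=pts.max(axis=0),
    )
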