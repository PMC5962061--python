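"""Penalized Tweedie regression for segment counts (the abundance model).

Counts per transect segment are modelled as

    y_i ~ Tweedie(mu_i, phi, p),   log mu_i = beta0 + sum_j f_j(z_ij) + log A_i

with segment effort area ``A_i`` (km^2) entering as an offset so the
intercept lives on the density-per-km^2 scale, smooth effects ``f_j``
represented by the penalized bases in :mod:`stripdsm.basis`, and Tweedie
power ``1 < p < 2`` (compound Poisson-gamma: overdispersed, zero-inflated
group counts). Coefficients minimize the penalized deviance via IRLS;
smoothing parameters minimize a Laplace-approximate restricted marginal
likelihood (REML-type) score with the dispersion profiled out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .basis import SmoothTerm, build_location_smooth, build_univariate_smooth

__all__ = [
    "TermSpec", "ModelSpec", "FittedDSM", "tweedie_deviance",
    "fit_penalized", "reml_score", "optimize_smoothing", "deviance_explained",
]

IRLS_TOL = 1e-8
IRLS_MAXIT = 200


class ConvergenceError(RuntimeError):
    """IRLS or smoothing-parameter iteration failed to converge."""


# ---------------------------------------------------------------------------
# deviance


def tweedie_unit_deviance(y: np.ndarray, mu: np.ndarray, p: float) -> np.ndarray:
    """Tweedie unit deviance d(y, mu) for power p in [1, 2].

    For 1 < p < 2:
        d = 2 [ y^(2-p) / ((1-p)(2-p)) - y mu^(1-p) / (1-p) + mu^(2-p) / (2-p) ]
    The boundaries are the continuous limits: Poisson deviance at p = 1 and
    gamma deviance at p = 2 (the latter requires y > 0).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("Tweedie deviance requires mu > 0")
    if np.any(y < 0):
        raise ValueError("Tweedie deviance requires y >= 0")
    if not (1.0 <= p <= 2.0):
        raise ValueError("Tweedie power p must lie in [1, 2]")
    if p == 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        return 2.0 * (ylogy - (y - mu))
    if p == 2.0:
        if np.any(y <= 0):
            raise ValueError("gamma deviance (p = 2) requires y > 0")
        return 2.0 * ((y - mu) / mu - np.log(y / mu))
    term1 = np.power(y, 2.0 - p) / ((1.0 - p) * (2.0 - p))
    term2 = y * np.power(mu, 1.0 - p) / (1.0 - p)
    term3 = np.power(mu, 2.0 - p) / (2.0 - p)
    return 2.0 * (term1 - term2 + term3)


def tweedie_deviance(y: np.ndarray, mu: np.ndarray, p: float) -> float:
    """Total Tweedie deviance, the sum of unit deviances."""
    return float(np.sum(tweedie_unit_deviance(y, mu, p)))


# ---------------------------------------------------------------------------
# model specification


@dataclass
class TermSpec:
    """Descriptor of one smooth term before it is bound to data.

    ``covariates`` names the segment-table columns the term consumes
    (one name -> cubic spline; two or three -> isotropic radial smooth).
    """

    covariates: tuple[str, ...]
    k: int = 10

    @property
    def label(self) -> str:
        return "s(" + ",".join(self.covariates) + ")"


@dataclass
class ModelSpec:
    """A candidate abundance-model structure.

    Attributes
    ----------
    terms : list of TermSpec
        Smooth terms; empty list gives the intercept-only (null) model.
    p : float
        Tweedie power, strictly inside (1, 2) (p = 1 selects the Poisson
        boundary, used for oracle checks).
    label : str
        Display label, e.g. ``"AA+GL"``.
    """

    terms: list[TermSpec] = field(default_factory=list)
    p: float = 1.5
    label: str = ""

    def __post_init__(self):
        if not (1.0 <= self.p < 2.0):
            raise ValueError("Tweedie power must satisfy 1 <= p < 2")
        if not self.label:
            self.label = "+".join(t.label for t in self.terms) or "1"

    def build_terms(self, data: pd.DataFrame, k_override: Sequence[int] | None = None) -> list[SmoothTerm]:
        terms = []
        for j, ts in enumerate(self.terms):
            k = ts.k if k_override is None else k_override[j]
            if len(ts.covariates) == 1:
                terms.append(build_univariate_smooth(
                    data[ts.covariates[0]].to_numpy(), k, ts.covariates[0]))
            else:
                pts = data[list(ts.covariates)].to_numpy()
                terms.append(build_location_smooth(pts, k, tuple(ts.covariates)))
        return terms


def _assemble_design(terms: list[SmoothTerm], n: int):
    """Stack intercept + term columns; return (X, per-term column slices,
    embedded penalty list, total penalty-null-space dimension)."""
    cols = [np.ones((n, 1))] + [t.X for t in terms]
    X = np.hstack(cols)
    q = X.shape[1]
    slices, penalties = [], []
    start = 1
    null_dim = 1  # intercept
    for t in terms:
        sl = slice(start, start + t.n_columns)
        S = np.zeros((q, q))
        S[sl, sl] = t.S
        slices.append(sl)
        penalties.append(S)
        # one null-space direction absorbed by the sum-to-zero constraint
        null_dim += t.null_dim - 1
        start += t.n_columns
    return X, slices, penalties, null_dim


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedDSM:
    """Fitted state of a density surface model.

    Carries everything needed to predict densities at new covariate values
    and to propagate coefficient uncertainty (covariance conditional on the
    selected smoothing parameters).
    """

    spec: ModelSpec
    terms: list[SmoothTerm]
    beta: np.ndarray
    lam: np.ndarray
    k_chosen: list[int]
    p: float
    phi: float
    reml: float
    deviance: float
    null_deviance: float
    edf: float
    edf_terms: list[float]
    Vb: np.ndarray
    fitted: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    slices: list[slice] = field(default_factory=list)
    rho: float = 0.0

    @property
    def deviance_explained(self) -> float:
        """Percent of null deviance explained, in [0, 100] for sane fits."""
        if self.null_deviance == 0:
            raise ZeroDivisionError("null deviance is zero; explained deviance undefined")
        return 100.0 * (self.null_deviance - self.deviance) / self.null_deviance

    def linear_predictor(self, data: pd.DataFrame,
                         offset: np.ndarray | None = None) -> np.ndarray:
        """Evaluate eta = beta0 + sum_j f_j + offset at new covariates."""
        X = self.design(data)
        eta = X @ self.beta
        if offset is not None:
            eta = eta + offset
        return eta

    def design(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        cols = [np.ones((n, 1))]
        for ts, term in zip(self.spec.terms, self.terms):
            if len(ts.covariates) == 1:
                vals = data[ts.covariates[0]].to_numpy()
            else:
                vals = data[list(ts.covariates)].to_numpy()
            cols.append(term.design(vals))
        return np.hstack(cols)

    def extrapolation_mask(self, data: pd.DataFrame) -> np.ndarray:
        """Rows whose covariates fall outside the training range of any term."""
        n = len(data)
        mask = np.zeros(n, dtype=bool)
        for ts, term in zip(self.spec.terms, self.terms):
            if len(ts.covariates) == 1:
                vals = data[ts.covariates[0]].to_numpy()
            else:
                vals = data[list(ts.covariates)].to_numpy()
            mask |= term.extrapolated(vals)
        return mask

    def term_pvalues(self) -> list[float]:
        """Approximate Wald p-value per smooth term (chi-square on the
        term's effective degrees of freedom, coefficients vs conditional
        covariance)."""
        from scipy.stats import chi2
        out = []
        for sl, edf in zip(self.slices, self.edf_terms):
            b = self.beta[sl]
            V = self.Vb[sl, sl]
            stat = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b)
            df = max(edf, 1e-3)
            out.append(float(chi2.sf(stat, df)))
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "label": self.spec.label,
            "p": self.p,
            "term_specs": [{"covariates": list(t.covariates), "k": t.k}
                           for t in self.spec.terms],
            "terms": [t.to_dict() for t in self.terms],
            "beta": self.beta.tolist(),
            "lam": self.lam.tolist(),
            "k_chosen": self.k_chosen,
            "phi": self.phi,
            "reml": self.reml,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "edf": self.edf,
            "edf_terms": self.edf_terms,
            "Vb": self.Vb.tolist(),
            "rho": self.rho,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedDSM":
        d = json.loads(text)
        spec = ModelSpec(
            terms=[TermSpec(tuple(t["covariates"]), t["k"]) for t in d["term_specs"]],
            p=d["p"], label=d["label"])
        terms = [SmoothTerm.from_dict(t) for t in d["terms"]]
        beta = np.asarray(d["beta"])
        slices, start = [], 1
        for t in terms:
            slices.append(slice(start, start + t.Z.shape[1]))
            start += t.Z.shape[1]
        return cls(
            spec=spec, terms=terms, beta=beta, lam=np.asarray(d["lam"]),
            k_chosen=d["k_chosen"], p=d["p"], phi=d["phi"], reml=d["reml"],
            deviance=d["deviance"], null_deviance=d["null_deviance"],
            edf=d["edf"], edf_terms=d["edf_terms"], Vb=np.asarray(d["Vb"]),
            fitted=np.zeros(0), y=np.zeros(0), offset=np.zeros(0),
            slices=slices, rho=d["rho"])


# ---------------------------------------------------------------------------
# AR(1) whitening


def _ar1_whiten(M: np.ndarray, rho: float, blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Left-multiply rows of M by the inverse Cholesky factor of an AR(1)
    correlation, independently within each block of row indices (segments
    in along-track order within one transect)."""
    if rho == 0.0:
        return M
    out = M.astype(float).copy()
    s = np.sqrt(1.0 - rho * rho)
    for idx in blocks:
        if len(idx) < 2:
            continue
        rows = M[idx]
        w = rows.copy()
        w[1:] = (rows[1:] - rho * rows[:-1]) / s
        out[idx] = w
    return out


# ---------------------------------------------------------------------------
# fitting


def _segments_to_arrays(segments: pd.DataFrame):
    seg = segments
    if "excluded" in seg.columns:
        seg = seg.loc[~seg["excluded"].astype(bool)]
    y = seg["count"].to_numpy(dtype=float)
    area = seg["area"].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ValueError("segments must have positive effort areas")
    return seg.reset_index(drop=True), y, np.log(area)


def _transect_blocks(seg: pd.DataFrame) -> list[np.ndarray]:
    if "transect" not in seg.columns:
        return []
    blocks = []
    order_col = "order" if "order" in seg.columns else None
    for _, grp in seg.groupby("transect", sort=True):
        if order_col is not None:
            grp = grp.sort_values(order_col)
        blocks.append(grp.index.to_numpy())
    return blocks


def _pirls(X, y, offset, penalties, lam, p, rho=0.0, blocks=(),
           tol=IRLS_TOL, maxit=IRLS_MAXIT):
    """Penalized IRLS on the log link. Returns (beta, mu, deviance, W, H)."""
    n, q = X.shape
    S_lam = sum(l * S for l, S in zip(lam, penalties)) if penalties else np.zeros((q, q))
    mu = (y + np.mean(y)) / 2.0
    mu = np.maximum(mu, 1e-8)
    eta = np.log(mu)
    dev = tweedie_deviance(y, mu, p) if p > 1 else tweedie_deviance(y, mu, 1.0)
    beta = None
    for _ in range(maxit):
        w = np.power(mu, 2.0 - p)
        z = eta - offset + (y - mu) / mu
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        zw = z * sw
        if rho != 0.0 and len(blocks):
            Xw = _ar1_whiten(Xw, rho, blocks)
            zw = _ar1_whiten(zw[:, None], rho, blocks).ravel()
        H = Xw.T @ Xw + S_lam
        try:
            beta_new = np.linalg.solve(H, Xw.T @ zw)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular penalized system: {e}") from e
        # step-halving on the penalized deviance
        step = 1.0
        beta_old = beta if beta is not None else beta_new
        for _ in range(30):
            b_try = beta_old + step * (beta_new - beta_old)
            eta_try = np.clip(X @ b_try + offset, -300.0, 300.0)
            mu_try = np.exp(eta_try)
            dev_try = tweedie_deviance(y, mu_try, p)
            pen_try = dev_try + float(b_try @ S_lam @ b_try)
            pen_cur = dev + float((beta_old @ S_lam @ beta_old) if beta is not None else np.inf)
            if np.isfinite(pen_try) and (beta is None or pen_try <= pen_cur + 1e-12):
                break
            step *= 0.5
        dbeta = np.max(np.abs(b_try - beta_old)) if beta is not None else np.inf
        beta, eta, mu, dev_new = b_try, eta_try, mu_try, dev_try
        if (abs(dev_new - dev) < tol * (abs(dev_new) + 0.1)
                and dbeta < 1e-8 * (1.0 + np.max(np.abs(beta)))):
            dev = dev_new
            break
        dev = dev_new
    else:
        raise ConvergenceError(
            f"penalized IRLS did not converge in {maxit} iterations "
            f"(last deviance {dev:.6g})")
    w = np.power(mu, 2.0 - p)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    if rho != 0.0 and len(blocks):
        Xw = _ar1_whiten(Xw, rho, blocks)
    H = Xw.T @ Xw + S_lam
    return beta, mu, dev, Xw, H, S_lam


def fit_penalized(spec: ModelSpec, segments: pd.DataFrame,
                  lam: Sequence[float] | None = None,
                  rho: float = 0.0,
                  terms: list[SmoothTerm] | None = None) -> FittedDSM:
    """Fit the penalized Tweedie model at fixed smoothing parameters.

    Parameters
    ----------
    spec : ModelSpec
        Model structure (smooth terms, Tweedie power).
    segments : DataFrame
        Segment table with columns ``count``, ``area`` (km^2), the term
        covariates, optionally ``transect``/``order`` (needed when
        ``rho != 0``) and ``excluded`` (excluded rows are dropped).
    lam : sequence of float
        One smoothing parameter per term; zeros give the unpenalized fit.
    rho : float
        AR(1) working correlation among consecutive segments within a
        transect; 0 recovers the independent fit exactly.
    """
    seg, y, offset = _segments_to_arrays(segments)
    if y.sum() == 0:
        raise ValueError("all segment counts are zero; intercept diverges to -inf")
    if not (-1.0 < rho < 1.0):
        raise ValueError("AR(1) rho must lie in (-1, 1)")
    if terms is None:
        terms = spec.build_terms(seg)
    X, slices, penalties, null_dim = _assemble_design(terms, len(seg))
    if lam is None:
        lam = np.ones(len(terms))
    lam = np.asarray(lam, dtype=float)
    if lam.size != len(terms):
        raise ValueError("need one smoothing parameter per term")
    blocks = _transect_blocks(seg) if rho != 0.0 else []
    if rho != 0.0 and not blocks:
        raise ValueError("AR(1) correction requires a 'transect' column")

    beta, mu, dev, Xw, H, S_lam = _pirls(
        X, y, offset, penalties, lam, spec.p, rho=rho, blocks=blocks)

    Hinv = np.linalg.inv(H)
    F = Hinv @ (Xw.T @ Xw)  # edf matrix
    edf = float(np.trace(F))
    edf_terms = [float(np.trace(F[sl, sl])) for sl in slices]
    pearson = float(np.sum((y - mu) ** 2 / np.power(mu, spec.p)))
    phi = pearson / max(len(y) - edf, 1.0)
    Vb = phi * Hinv

    null_dev = _null_deviance(y, offset, spec.p)
    fit = FittedDSM(
        spec=spec, terms=terms, beta=beta, lam=lam,
        k_chosen=[t.k for t in terms], p=spec.p, phi=phi, reml=np.nan,
        deviance=dev, null_deviance=null_dev, edf=edf, edf_terms=edf_terms,
        Vb=Vb, fitted=mu, y=y, offset=offset, slices=slices, rho=rho)
    fit.reml = _reml_from_state(fit, H, S_lam, penalties, lam, null_dim, len(y))
    return fit


def _null_deviance(y, offset, p):
    """Deviance of the intercept + offset model (closed-form optimum).

    With log link and offset o_i, the Tweedie deviance in beta0 has
    stationary point sum(y exp((1-p)(b+o))) = sum(exp((2-p)(b+o))); solved
    by 1-D Newton on b.
    """
    b = np.log(np.sum(y) / np.sum(np.exp(offset)))
    for _ in range(100):
        e1 = np.exp((1.0 - p) * (b + offset))
        e2 = np.exp((2.0 - p) * (b + offset))
        g = -np.sum(y * e1) + np.sum(e2)
        h = -(1.0 - p) * np.sum(y * e1) + (2.0 - p) * np.sum(e2)
        if abs(h) < 1e-300:
            break
        step = g / h
        b -= step
        if abs(step) < 1e-12:
            break
    mu0 = np.exp(b + offset)
    return tweedie_deviance(y, mu0, p)


def _reml_from_state(fit: FittedDSM, H, S_lam, penalties, lam, null_dim, n):
    """Laplace/extended-quasi-likelihood REML-type score; lower is better.

    score = Dp/(2 phi) + (1/2) sum log(2 pi phi (y_i + 1/6)^p)
            + (1/2) log|H| - (1/2) log+|S_lam| - (M0/2) log phi
    with Dp the penalized deviance and phi profiled as Dp/(n - M0),
    M0 the total penalty-null-space dimension (unpenalized coefficients).
    """
    Dp = fit.deviance + float(fit.beta @ S_lam @ fit.beta)
    M0 = null_dim
    phi = max(Dp / max(n - M0, 1), 1e-12)
    y = fit.y
    sat = 0.5 * np.sum(np.log(2.0 * np.pi * phi * np.power(y + 1.0 / 6.0, fit.p)))
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("penalized Hessian not positive definite")
    logdet_S = 0.0
    for l, S in zip(lam, penalties):
        if l <= 0:
            continue
        ev = np.linalg.eigvalsh(S)
        pos = ev[ev > 1e-10 * max(ev.max(), 1e-300)]
        logdet_S += pos.size * np.log(l) + float(np.sum(np.log(pos)))
    return float(Dp / (2.0 * phi) + sat + 0.5 * logdet_H - 0.5 * logdet_S
                 - 0.5 * M0 * np.log(phi))


def reml_score(spec: ModelSpec, segments: pd.DataFrame,
               lam: Sequence[float], rho: float = 0.0,
               terms: list[SmoothTerm] | None = None) -> float:
    """REML-type score of the model at the given smoothing parameters."""
    return fit_penalized(spec, segments, lam, rho=rho, terms=terms).reml


# ---------------------------------------------------------------------------
# smoothing-parameter and basis-dimension selection

LAMBDA_GRID = np.logspace(-3, 5, 7)
LOG_LAMBDA_BOUNDS = (np.log(1e-6), np.log(1e8))


def _optimize_lambda(spec, segments, terms, rho):
    """Log-scale grid multistart followed by Nelder-Mead polish."""
    m = len(terms)
    if m == 0:
        return np.zeros(0), fit_penalized(spec, segments, [], rho=rho, terms=terms)

    cache: dict[tuple, float] = {}

    def score(loglam):
        # clip to a well-conditioned range; the criterion is flat beyond
        # full shrinkage, so the bound never moves a genuine optimum
        loglam = np.clip(loglam, *LOG_LAMBDA_BOUNDS)
        key = tuple(np.round(loglam, 10))
        if key not in cache:
            try:
                cache[key] = reml_score(spec, segments, np.exp(loglam),
                                        rho=rho, terms=terms)
            except (ConvergenceError, np.linalg.LinAlgError):
                cache[key] = np.inf
        return cache[key]

    # multistart: same grid value for every term (keeps the search cheap and
    # deterministic), best point seeds the simplex
    best_ll, best_s = None, np.inf
    for g in LAMBDA_GRID:
        ll = np.full(m, np.log(g))
        s = score(ll)
        if s < best_s:
            best_ll, best_s = ll, s
    res = minimize(score, best_ll, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200 * m})
    ll = res.x if res.fun <= best_s else best_ll
    lam = np.exp(np.clip(ll, *LOG_LAMBDA_BOUNDS))
    return lam, fit_penalized(spec, segments, lam, rho=rho, terms=terms)


def optimize_smoothing(spec: ModelSpec, segments: pd.DataFrame,
                       k_grid: Sequence[int] | None = None,
                       rho: float = 0.0) -> FittedDSM:
    """Select smoothing parameters (and optionally basis dimensions) by REML.

    For each candidate basis dimension (coordinate-wise over terms when a
    ``k_grid`` is supplied, otherwise the ``k`` fixed in the spec), the
    smoothing parameters are chosen by a 7-point log-spaced multistart on a
    shared grid followed by Nelder-Mead. The candidate with the lowest
    REML-type score wins; everything is deterministic.
    """
    seg, _, _ = _segments_to_arrays(segments)
    k_current = [t.k for t in spec.terms]
    best = None

    def try_ks(ks):
        nonlocal best
        try:
            terms = spec.build_terms(seg, k_override=ks)
        except ValueError:
            return
        try:
            _, fit = _optimize_lambda(spec, seg, terms, rho)
        except (ConvergenceError, np.linalg.LinAlgError):
            return
        fit.k_chosen = list(ks)
        if best is None or fit.reml < best.reml - 1e-10 or (
                abs(fit.reml - best.reml) <= 1e-10 and fit.edf < best.edf):
            best = fit

    if k_grid is None or not spec.terms:
        try_ks(k_current)
    else:
        ks = list(k_current)
        for j in range(len(spec.terms)):
            for k in k_grid:
                trial = list(ks)
                trial[j] = k
                try_ks(trial)
            if best is not None:
                ks[j] = best.k_chosen[j]
    if best is None:
        raise ConvergenceError(f"no candidate fit converged for {spec.label}")
    return best


def deviance_explained(fit: FittedDSM) -> float:
    """Percent deviance explained relative to the intercept+offset null model."""
    return fit.deviance_explained
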