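"""Marker-based models: genomic relationships, REML heritability, RR-BLUP.

The three classical ingredients of genomic prediction:

* :func:`compute_grm` — VanRaden method-1 genomic relationship matrix,
  K = W Wᵀ / (2 Σ pⱼ(1-pⱼ)) with W the allele-frequency-centered dosages;
* :func:`reml_single_component` — restricted maximum likelihood for the
  single-GRM animal model y = μ1 + g + e, g ~ N(0, σ²g K), e ~ N(0, σ²e I),
  profiled over h² = σ²g/(σ²g+σ²e) via the eigendecomposition of K;
* :func:`fit_rrblup` / :func:`predict_rrblup` — ridge-regression BLUP with
  the ridge ratio λ = σ²e/σ²u estimated by REML on the n x n kernel system.

All REML computations use the spectral trick: after rotating by the
eigenvectors of the relationship kernel the covariance is diagonal, so each
likelihood evaluation is O(n) and a bounded 1-D Brent search is enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import GenotypeMatrix

__all__ = [
    "GRM",
    "GRMEigen",
    "VarianceComponents",
    "RRBLUPFit",
    "compute_grm",
    "grm_eigendecomposition",
    "reml_single_component",
    "fit_rrblup",
    "predict_rrblup",
]

_PSD_TOL = -1e-8
_H2_EPS = 1e-6


@dataclass
class GRM:
    """Genomic relationship matrix over k lines."""

    line_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        k = len(self.line_ids)
        if self.K.shape != (k, k):
            raise ValueError(f"K has shape {self.K.shape} for {k} lines")
        if not np.allclose(self.K, self.K.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")


@dataclass
class GRMEigen:
    """Cached eigendecomposition of a GRM (reused across many traits)."""

    eigenvalues: np.ndarray   # ascending, clipped at 0
    eigenvectors: np.ndarray  # columns


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    at_boundary: bool = False


@dataclass
class RRBLUPFit:
    mu: float
    beta: np.ndarray            # (m,) marker effects
    lam: float                  # ridge ratio sigma2_e / sigma2_u
    sigma2_u: float
    sigma2_e: float
    marker_centering: np.ndarray  # (m,) per-marker means used
    marker_ids: list[str] | None = None
    loglik: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def compute_grm(G: GenotypeMatrix, method: str = "centered") -> GRM:
    """VanRaden method-1 GRM from 0/1/2 dosages."""
    if method != "centered":
        raise ValueError(f"unknown GRM method {method!r}")
    p = G.allele_freq
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; the GRM is undefined")
    W = G.dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return GRM(list(G.line_ids), (W @ W.T) / denom)


def grm_eigendecomposition(K: GRM | np.ndarray) -> GRMEigen:
    Kmat = K.K if isinstance(K, GRM) else np.asarray(K, dtype=float)
    vals, vecs = np.linalg.eigh(Kmat)
    if vals[0] < _PSD_TOL * max(1.0, abs(vals[-1])):
        raise ValueError(
            f"relationship matrix is not positive semidefinite (min eigenvalue {vals[0]:.3g})"
        )
    return GRMEigen(np.clip(vals, 0.0, None), vecs)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _restricted_loglik(theta: float, lam_eigs: np.ndarray, yt: np.ndarray,
                       ot: np.ndarray, mix: str) -> tuple[float, float, float]:
    """Profiled restricted log-likelihood on the rotated scale.

    ``mix='h2'``: diag weights d = theta*lam + (1-theta) (total variance
    profiled out). ``mix='lambda'``: d = lam + theta (genetic variance
    profiled out). Returns (loglik, mu_gls, profiled variance).
    """
    if mix == "h2":
        d = theta * lam_eigs + (1.0 - theta)
    else:
        d = lam_eigs + theta
    d = np.maximum(d, 1e-12)
    w = 1.0 / d
    oto = float(np.sum(ot * ot * w))
    mu = float(np.sum(ot * yt * w)) / oto
    resid = yt - mu * ot
    n = len(yt)
    rss = float(np.sum(resid * resid * w))
    sigma2 = rss / (n - 1)
    if sigma2 <= 0:
        return -np.inf, mu, 0.0
    ll = -0.5 * (np.sum(np.log(d)) + np.log(oto) + (n - 1) * (np.log(sigma2) + 1.0))
    return ll, mu, sigma2


def _maximize_1d(neg_ll, lo: float, hi: float, coarse: int = 41,
                 xatol: float = 1e-8) -> float:
    """Coarse grid then bounded Brent refinement (guards multimodality)."""
    grid = np.linspace(lo, hi, coarse)
    vals = [neg_ll(g) for g in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, coarse - 1)]
    res = minimize_scalar(neg_ll, bounds=(a, b), method="bounded",
                          options={"xatol": xatol})
    # the bracket endpoints may themselves be the bound optimum
    cands = [res.x, grid[i], lo, hi]
    return float(min(cands, key=neg_ll))


def reml_single_component(
    y: np.ndarray,
    K: GRM | GRMEigen,
    eig: GRMEigen | None = None,
) -> VarianceComponents:
    """GREML heritability for one phenotype vector.

    Maximizes the restricted likelihood over h² in [0, 1]; boundary optima
    are reported with ``at_boundary=True``, interior estimates are clipped
    away from the exact boundary.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype vector is constant; heritability undefined")
    if isinstance(K, GRMEigen):
        eig = K
    elif eig is None:
        eig = grm_eigendecomposition(K)
    if len(y) != len(eig.eigenvalues):
        raise ValueError("phenotype length does not match the GRM")
    S = eig.eigenvectors
    yt = S.T @ y
    ot = S.T @ np.ones(len(y))

    def neg_ll(h2: float) -> float:
        return -_restricted_loglik(h2, eig.eigenvalues, yt, ot, "h2")[0]

    h2_hat = _maximize_1d(neg_ll, 0.0, 1.0)
    ll, _, sigma2 = _restricted_loglik(h2_hat, eig.eigenvalues, yt, ot, "h2")
    at_boundary = h2_hat <= _H2_EPS or h2_hat >= 1.0 - _H2_EPS
    if not at_boundary:
        h2_hat = float(np.clip(h2_hat, _H2_EPS, 1.0 - _H2_EPS))
    return VarianceComponents(
        sigma2_g=h2_hat * sigma2,
        sigma2_e=(1.0 - h2_hat) * sigma2,
        h2=h2_hat,
        loglik=ll,
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# RR-BLUP
# ---------------------------------------------------------------------------

@dataclass
class KernelEigen:
    """Cached spectral pieces of the centered-dosage kernel M Mᵀ."""

    centering: np.ndarray     # (m,)
    Mc: np.ndarray            # (n, m) centered dosages
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


def kernel_eigendecomposition(M: np.ndarray) -> KernelEigen:
    M = np.asarray(M, dtype=float)
    centering = M.mean(axis=0)
    Mc = M - centering
    vals, vecs = np.linalg.eigh(Mc @ Mc.T)
    return KernelEigen(centering, Mc, np.clip(vals, 0.0, None), vecs)


def fit_rrblup(
    y: np.ndarray,
    M: np.ndarray | KernelEigen,
    lam: float | None = None,
    marker_ids: list[str] | None = None,
    log_lambda_bounds: tuple[float, float] = (-10.0, 10.0),
) -> RRBLUPFit:
    """Fit y = μ1 + M u + e with i.i.d. normal marker effects.

    Markers are centered internally (centering stored for prediction). The
    ridge ratio λ = σ²e/σ²u is REML-estimated over log λ in
    ``log_lambda_bounds`` unless ``lam`` is given. A precomputed
    :class:`KernelEigen` may be passed instead of the dosage matrix to reuse
    the n x n eigendecomposition across many phenotypes.
    """
    y = np.asarray(y, dtype=float)
    ke = M if isinstance(M, KernelEigen) else kernel_eigendecomposition(M)
    n = ke.Mc.shape[0]
    if len(y) != n:
        raise ValueError("phenotype length does not match the marker matrix")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype vector is constant; the model is undefined")
    S = ke.eigenvectors
    yt = S.T @ y
    ot = S.T @ np.ones(n)

    if lam is None:
        def neg_ll(log_lam: float) -> float:
            return -_restricted_loglik(np.exp(log_lam), ke.eigenvalues, yt, ot,
                                       "lambda")[0]
        lam = float(np.exp(_maximize_1d(neg_ll, *log_lambda_bounds)))
    if lam <= 0:
        raise ValueError("lambda must be positive")
    ll, mu, sigma2_u = _restricted_loglik(lam, ke.eigenvalues, yt, ot, "lambda")
    # beta = Mᵀ (M Mᵀ + λI)⁻¹ (y - μ1), via the rotated diagonal system
    alpha_t = (yt - mu * ot) / (ke.eigenvalues + lam)
    beta = ke.Mc.T @ (S @ alpha_t)
    return RRBLUPFit(
        mu=mu, beta=beta, lam=lam,
        sigma2_u=sigma2_u, sigma2_e=lam * sigma2_u,
        marker_centering=ke.centering.copy(), marker_ids=marker_ids, loglik=ll,
    )


def predict_rrblup(fit: RRBLUPFit, M_new: np.ndarray,
                   marker_ids: list[str] | None = None) -> np.ndarray:
    """Predict new lines: ŷ = μ + (M_new − centering) β."""
    M_new = np.asarray(M_new, dtype=float)
    if M_new.ndim == 1:
        M_new = M_new[None, :]
    if M_new.shape[1] != len(fit.beta):
        raise ValueError(
            f"marker mismatch: model has {len(fit.beta)} markers, input has "
            f"{M_new.shape[1]}"
        )
    if marker_ids is not None and fit.marker_ids is not None:
        if list(marker_ids) != list(fit.marker_ids):
            raise ValueError("marker ids/order do not match the fitted model")
    return fit.mu + (M_new - fit.marker_centering) @ fit.beta
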