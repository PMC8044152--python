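"""Numerical statistics shared across the pipeline.

Tail probabilities of weighted chi-square mixtures (the null distribution of
variance-component score statistics), the Hardy-Weinberg exact test used in
variant QC, a Firth-penalized logistic fit used as a fallback under
separation, and fixed-effect meta-analysis with Cochran's Q / I-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats


# ----------------------------------------------------------------------
# Weighted chi-square mixture tail probability


@dataclass
class QuadFormPValue:
    p: float
    method: str  # "davies" or "liu"


def davies_pvalue(lambdas, q: float) -> QuadFormPValue:
    """P(sum_i lambda_i * chi2_1 >= q) by characteristic-function inversion.

    Uses Imhof's real-integral form of the inversion,

        P(Q > q) = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u * rho(u)) du,

    with ``theta(u) = 0.5 * sum arctan(lambda_i u) - q u / 2`` and
    ``rho(u) = prod (1 + lambda_i^2 u^2)^{1/4}``.  The integral is evaluated
    with panel-wise Gauss-Legendre quadrature on panels shorter than a
    quarter oscillation, truncated at a point where the integration-by-parts
    tail correction ``f(U) cos(theta(U)) / theta'(U)`` has a provably small
    remainder.  Falls back to the Liu moment-matching approximation when
    truncation cannot be certified.  Returns the p-value clipped to (0, 1]
    and the method used.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 0:
        raise ValueError("lambdas must be non-empty")
    if np.any(lam <= 0):
        raise ValueError("lambdas must be positive")
    if q < 0:
        raise ValueError("quadratic-form statistic must be non-negative")
    if q == 0:
        return QuadFormPValue(1.0, "davies")
    p = _imhof_p(lam, float(q))
    if p is None or not np.isfinite(p):
        return QuadFormPValue(liu_pvalue(lam, q), "liu")
    return QuadFormPValue(float(min(max(p, 1e-300), 1.0)), "davies")


def _imhof_theta_rho(lam: np.ndarray, u: np.ndarray, q: float):
    """Phase theta(u) and log of the envelope denominator log(rho(u))."""
    lu = np.multiply.outer(lam, u)
    theta = 0.5 * np.arctan(lu).sum(axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.log1p(lu**2).sum(axis=0)
    return theta, log_rho


def _imhof_p(lam: np.ndarray, q: float, eps: float = 1e-11) -> float | None:
    # the integral is invariant to a common rescaling of (lambdas, q)
    scale = float(lam.max())
    lam = lam / scale
    q = q / scale
    k = lam.size

    def envelope(u: float) -> float:
        return math.exp(-(0.25 * np.sum(np.log1p((lam * u) ** 2)))) / u

    def dtheta(u: float) -> float:
        return 0.5 * float(np.sum(lam / (1 + (lam * u) ** 2))) - 0.5 * q

    # truncation point: either the oscillatory tail correction is certified
    # small, or (k > 2) the absolute envelope tail already is
    U = max(16.0 / max(q, np.sum(lam)), 1.0)
    ok = False
    for _ in range(60):
        f_u = envelope(U)
        dth = dtheta(U)
        osc_ok = dth < -1e-12 and (
            f_u / (dth**2) * ((1 + k / 2) / U * abs(dth) + q / 2 * f_u) < eps
            or f_u / abs(dth) * ((1 + k / 2) / U) / abs(dth) < eps
        )
        abs_ok = k > 2 and f_u * U * 2.0 / (k - 2 + 1e-9) < eps
        if osc_ok or abs_ok:
            ok = True
            break
        U *= 1.6
        if U > 1e8:
            break
    if not ok:
        return None

    # panel edges adapted to the local phase speed |theta'(u)| (decreasing
    # in u), each panel shorter than a quarter oscillation
    edges_list = [0.0]
    u = 0.0
    max_panels = 300_000
    while u < U and len(edges_list) <= max_panels:
        w_loc = 0.5 * float(np.sum(lam / (1 + (lam * u) ** 2))) + 0.5 * q
        u = min(U, u + (math.pi / 2.0) / max(w_loc, 1e-9))
        edges_list.append(u)
    if len(edges_list) > max_panels:
        return None
    edges = np.asarray(edges_list)
    n_panels = edges.size - 1
    nodes, wts = np.polynomial.legendre.leggauss(24)
    total = 0.0
    chunk = max(1, 5_000_000 // (24 * max(k, 1)))
    for start in range(0, n_panels, chunk):
        end = min(start + chunk, n_panels)
        lo = edges[start:end]
        hi = edges[start + 1 : end + 1]
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        u_nodes = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
        theta, log_rho = _imhof_theta_rho(lam, u_nodes, q)
        vals = np.sin(theta) * np.exp(-log_rho - np.log(u_nodes))
        total += float((vals.reshape(-1, 24) @ wts * half).sum())
    # first-order oscillatory tail correction
    thU, log_rhoU = _imhof_theta_rho(lam, np.array([U]), q)
    total += float(np.cos(thU[0]) * math.exp(-log_rhoU[0] - math.log(U)) / dtheta(U))
    return 0.5 + total / math.pi


def liu_pvalue(lambdas, q: float) -> float:
    """Liu-Tang-Zhang moment-matched chi-square approximation of the tail."""
    lam = np.asarray(lambdas, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = math.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    if s1**2 > s2:
        a = 1 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1 / s2
        a = math.sqrt(df)
    mu_x = df + delta
    sigma_x = math.sqrt(2) * a
    p = stats.ncx2.sf(t_star * sigma_x + mu_x, df, delta)
    return float(min(max(p, 1e-300), 1.0))


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test (conditional on allele counts)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p-value: total probability of heterozygote counts no more
    likely than the observed one, conditional on the allele counts.

    Monomorphic variants return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # probabilities over het counts of the same parity, via the standard
    # recurrence P(h+2)/P(h) = 4*(n_r - h)/2 * (n_c - h)/2 / ((h+2)(h+1))
    # where n_r, n_c are rare/common allele counts.
    n_r, n_c = n_rare, 2 * n - n_rare
    h_min = n_r % 2
    h_max = min(n_r, n_c)
    hets = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for i in range(1, hets.size):
        h = hets[i - 1]
        probs[i] = probs[i - 1] * ((n_r - h) * (n_c - h)) / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[(n_het - h_min) // 2]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# Firth-penalized logistic regression (fallback under separation)


@dataclass
class FirthFit:
    params: np.ndarray
    bse: np.ndarray
    converged: bool
    n_iter: int


def firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 100,
                tol: float = 1e-8) -> FirthFit:
    """Jeffreys-prior penalized logistic regression via modified scoring.

    The penalty keeps estimates finite under complete or quasi-complete
    separation; standard errors come from the penalized information matrix.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # dampen huge steps
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    cov = np.linalg.pinv(info)
    return FirthFit(beta, np.sqrt(np.diag(cov)), converged, it)


# ----------------------------------------------------------------------
# Fixed-effect meta-analysis and heterogeneity


@dataclass
class HeterogeneityStats:
    q: float
    df: int
    i2: float
    p_het: float
    pooled_effect: float
    pooled_se: float


def fixed_effect_meta(effects, ses) -> HeterogeneityStats:
    """Inverse-variance pooled effect with Cochran's Q and I-squared.

    I2 = max(0, (Q - df) / Q): the share of between-stratum variability in
    the effect estimates beyond sampling error.
    """
    b = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if b.size != se.size or b.size == 0:
        raise ValueError("effects and ses must be equal-length, non-empty")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - pooled) ** 2))
    df = int(b.size - 1)
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q)
    p_het = 1.0 if df == 0 else float(stats.chi2.sf(q, df))
    return HeterogeneityStats(q, df, i2, p_het, pooled, pooled_se)
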