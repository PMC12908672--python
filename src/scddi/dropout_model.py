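"""Poisson–negative binomial (PNB) mixture model for dropout detection.

Each gene's counts across cells are modelled as a two-component mixture:
a low-mean Poisson component generating dropout events and a negative
binomial component generating genuine expression,

    f(y_j) = pi_j * Pois(y_j; lambda_j) + (1 - pi_j) * NB(y_j; mu_j, phi),

with per-cell parameters tied to the cell's library size L_j through
generalized linear links: logit(pi_j), log(lambda_j) and log(mu_j) are
each linear in log L_j (centered), and the NB dispersion phi is shared
within a gene (Var = mu + mu^2/phi).  Parameters are estimated by an EM
algorithm whose M-step performs damped Newton updates of the three
2-parameter GLMs and a one-dimensional update of phi; the observed-data
log-likelihood is non-decreasing across iterations.

The posterior probability that an observed count arose from the Poisson
(dropout) component,

    d_j = pi_j Pois(y_j) / (pi_j Pois(y_j) + (1 - pi_j) NB(y_j)),

is the dropout probability; entries with d > tau (default 0.5) are
flagged for imputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit, gammaln, logit, polygamma

PI_EPS = 1e-6          # guard: pi in [PI_EPS, 1 - PI_EPS]
PHI_MIN, PHI_MAX = 1e-3, 1e6
_ETA_MAX = 30.0        # cap on log-link linear predictors


class DomainError(ValueError):
    """A mixture parameter is outside its admissible domain."""


def _pois_logpmf(y, lam):
    return y * np.log(lam) - lam - gammaln(y + 1.0)


def _nb_logpmf(y, mu, phi):
    return (
        gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )


def pnb_log_density(y, pi, lam, mu, phi):
    """Log of the PNB mixture density, evaluated stably in log space."""
    y = np.asarray(y, dtype=np.float64)
    pi, lam, mu, phi = (np.asarray(v, dtype=np.float64) for v in (pi, lam, mu, phi))
    if np.any((pi < 0) | (pi > 1)):
        raise DomainError("pi must lie in [0, 1]")
    if np.any(lam <= 0) or np.any(mu <= 0) or np.any(phi <= 0):
        raise DomainError("lambda, mu and phi must be positive")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise DomainError("y must be a nonnegative integer")
    lp = _pois_logpmf(y, lam)
    ln = _nb_logpmf(y, mu, phi)
    with np.errstate(divide="ignore"):
        a = np.log(pi) + lp
        b = np.log1p(-pi) + ln
    out = np.logaddexp(a, b)
    # pure components: logaddexp with -inf handles these already
    return out


@dataclass
class PNBGeneFit:
    """Fitted PNB mixture for one gene.

    Link coefficients are expressed in the centered covariate
    x = log L - ``logL_center``; apply :meth:`cell_params` to recover the
    per-cell (pi, lambda, mu).
    """

    pi_coef: np.ndarray
    lambda_coef: np.ndarray
    mu_coef: np.ndarray
    phi: float
    loglik: float
    n_iter: int
    converged: bool
    logL_center: float
    failed: bool = False
    loglik_trace: np.ndarray | None = None

    def cell_params(self, L):
        """Per-cell (pi, lambda, mu) for library sizes ``L``."""
        x = np.log(np.asarray(L, dtype=np.float64)) - self.logL_center
        pi = expit(self.pi_coef[0] + self.pi_coef[1] * x)
        pi = np.clip(pi, PI_EPS, 1.0 - PI_EPS)
        lam = np.exp(np.clip(self.lambda_coef[0] + self.lambda_coef[1] * x,
                             -_ETA_MAX, _ETA_MAX))
        mu = np.exp(np.clip(self.mu_coef[0] + self.mu_coef[1] * x,
                            -_ETA_MAX, _ETA_MAX))
        return pi, lam, mu


def dropout_posterior(y, fit: PNBGeneFit, L):
    """Per-cell posterior dropout probabilities d_j for one gene."""
    y = np.asarray(y, dtype=np.float64)
    pi, lam, mu = fit.cell_params(L)
    if fit.failed:
        return np.where(y == 0, 1.0, 0.0)
    a = np.log(pi) + _pois_logpmf(y, lam)
    b = np.log1p(-pi) + _nb_logpmf(y, mu, fit.phi)
    return expit(a - b)


# ---------------------------------------------------------------------------
# batched EM
# ---------------------------------------------------------------------------

def _solve2(g0, g1, h00, h01, h11):
    """Solve the per-gene 2x2 Newton systems H d = g (H positive)."""
    det = h00 * h11 - h01 * h01
    ok = det > 1e-12
    det = np.where(ok, det, 1.0)
    d0 = np.where(ok, (h11 * g0 - h01 * g1) / det, 0.0)
    d1 = np.where(ok, (h00 * g1 - h01 * g0) / det, 0.0)
    return d0, d1


def _backtrack_2param(coef, d0, d1, qfun, max_halve=12):
    """Damped Newton: halve per-gene steps until the objective does not drop."""
    q_old = qfun(coef[:, 0], coef[:, 1])
    scale = np.ones_like(q_old)
    for _ in range(max_halve):
        c0 = coef[:, 0] + scale * d0
        c1 = coef[:, 1] + scale * d1
        q_new = qfun(c0, c1)
        bad = q_new < q_old - 1e-10
        if not bad.any():
            coef[:, 0], coef[:, 1] = c0, c1
            return coef
        scale = np.where(bad, scale * 0.5, scale)
        if (scale < 1e-8).all():
            break
    # accept only genes whose final damped step improves
    c0 = coef[:, 0] + scale * d0
    c1 = coef[:, 1] + scale * d1
    q_new = qfun(c0, c1)
    good = q_new >= q_old - 1e-10
    coef[:, 0] = np.where(good, c0, coef[:, 0])
    coef[:, 1] = np.where(good, c1, coef[:, 1])
    return coef


def _eta(coef, x):
    return np.clip(coef[:, [0]] + coef[:, [1]] * x[None, :], -_ETA_MAX, _ETA_MAX)


def fit_pnb_batch(
    Y: np.ndarray,
    L: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    keep_trace: bool = False,
) -> list[PNBGeneFit]:
    """Fit the PNB mixture independently for every row (gene) of ``Y``.

    All genes share the covariate x = log L - mean(log L); the EM runs
    vectorized across genes but each gene's updates depend only on its own
    row, so the result is identical to fitting genes one at a time.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[None, :]
    L = np.asarray(L, dtype=np.float64)
    G, C = Y.shape
    if C < 20:
        raise ValueError(f"need at least 20 cells to fit the mixture, got {C}")
    if np.any(L <= 0):
        raise ValueError("library sizes must be positive")
    logL = np.log(L)
    center = float(logL.mean())
    x = logL - center

    # degenerate genes: constant counts carry no mixture information
    degenerate = Y.max(axis=1) == Y.min(axis=1)

    zero_frac = (Y == 0).mean(axis=1)
    pi0 = np.clip(zero_frac, 0.05, 0.95)
    a = np.column_stack([logit(pi0), np.zeros(G)])
    b = np.column_stack([np.full(G, math.log(0.1)), np.zeros(G)])
    nz_mean = np.empty(G)
    nz_var = np.empty(G)
    nz = Y > 0
    n_nz = nz.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nz_mean = np.where(n_nz > 0, (Y * nz).sum(axis=1) / np.maximum(n_nz, 1), 1.0)
        ex2 = np.where(n_nz > 0, (Y * Y * nz).sum(axis=1) / np.maximum(n_nz, 1), 1.0)
    nz_var = np.maximum(ex2 - nz_mean**2, 1e-8)
    mu0 = np.maximum(nz_mean, 0.1)
    phi = np.clip(mu0**2 / np.maximum(nz_var - mu0, 1e-6), PHI_MIN, PHI_MAX)
    c = np.column_stack([np.log(mu0), np.zeros(G)])

    act = np.flatnonzero(~degenerate)
    n_iter = np.zeros(G, dtype=np.int64)
    converged = np.zeros(G, dtype=bool)
    ll_final = np.full(G, -np.inf)
    traces: list[list[float]] = [[] for _ in range(G)] if keep_trace else []

    def loglik(idx, a_, b_, c_, phi_):
        pi = np.clip(expit(_eta(a_, x)), PI_EPS, 1 - PI_EPS)
        lam = np.exp(_eta(b_, x))
        mu = np.exp(_eta(c_, x))
        lp = _pois_logpmf(Y[idx], lam)
        ln = _nb_logpmf(Y[idx], mu, phi_[:, None])
        lf = np.logaddexp(np.log(pi) + lp, np.log1p(-pi) + ln)
        return lf.sum(axis=1), np.exp(np.log(pi) + lp - lf)

    prev_ll = np.full(G, np.nan)
    for it in range(max_iter):
        if act.size == 0:
            break
        Ya = Y[act]
        aa, ba, ca, pa = a[act], b[act], c[act], phi[act]

        # E-step + current log-likelihood (at the params entering this iter)
        ll, R = loglik(act, aa, ba, ca, pa)
        if keep_trace:
            for k, g in enumerate(act):
                traces[g].append(float(ll[k]))
        ll_final[act] = ll
        n_iter[act] = it + 1
        pl = prev_ll[act]
        done = ~np.isnan(pl) & (np.abs(ll - pl) <= tol * (np.abs(pl) + 1e-10))
        converged[act[done]] = True
        prev_ll[act] = ll
        keep = ~done
        act = act[keep]
        if act.size == 0:
            break
        Ya, aa, ba, ca, pa, R = (
            Ya[keep], aa[keep], ba[keep], ca[keep], pa[keep], R[keep]
        )
        W = 1.0 - R

        # --- logistic update of pi coefficients ---
        def q_logit(c0, c1, R=R, Ya=Ya):
            p = np.clip(expit(np.clip(c0[:, None] + c1[:, None] * x,
                                      -_ETA_MAX, _ETA_MAX)), PI_EPS, 1 - PI_EPS)
            return (R * np.log(p) + (1 - R) * np.log1p(-p)).sum(axis=1)

        p = np.clip(expit(_eta(aa, x)), PI_EPS, 1 - PI_EPS)
        res = R - p
        w = p * (1 - p)
        d0, d1 = _solve2(res.sum(1), (res * x).sum(1),
                         w.sum(1), (w * x).sum(1), (w * x * x).sum(1))
        aa = _backtrack_2param(aa, d0, d1, q_logit)

        # --- Poisson update of lambda coefficients (weights R) ---
        def q_pois(c0, c1, R=R, Ya=Ya):
            eta = np.clip(c0[:, None] + c1[:, None] * x, -_ETA_MAX, _ETA_MAX)
            return (R * (Ya * eta - np.exp(eta))).sum(axis=1)

        lam = np.exp(_eta(ba, x))
        res = R * (Ya - lam)
        w = R * lam
        d0, d1 = _solve2(res.sum(1), (res * x).sum(1),
                         w.sum(1), (w * x).sum(1), (w * x * x).sum(1))
        ba = _backtrack_2param(ba, d0, d1, q_pois)

        # --- NB mean update (weights 1-R, Fisher scoring at fixed phi) ---
        def q_nb(c0, c1, W=W, Ya=Ya, pa=pa):
            eta = np.clip(c0[:, None] + c1[:, None] * x, -_ETA_MAX, _ETA_MAX)
            mu = np.exp(eta)
            ph = pa[:, None]
            return (W * (Ya * (eta - np.log(ph + mu))
                         - ph * np.log(ph + mu))).sum(axis=1)

        mu = np.exp(_eta(ca, x))
        ph = pa[:, None]
        res = W * (Ya - mu) * ph / (ph + mu)
        w = W * mu * ph / (mu + ph)
        d0, d1 = _solve2(res.sum(1), (res * x).sum(1),
                         w.sum(1), (w * x).sum(1), (w * x * x).sum(1))
        ca = _backtrack_2param(ca, d0, d1, q_nb)

        # --- phi update (Newton in log phi with backtracking) ---
        mu = np.exp(_eta(ca, x))

        def q_phi(theta, W=W, Ya=Ya, mu=mu):
            ph = np.exp(theta)[:, None]
            return (W * (gammaln(Ya + ph) - gammaln(ph)
                         + ph * np.log(ph) - (Ya + ph) * np.log(ph + mu))).sum(axis=1)

        theta = np.log(pa)
        ph = pa[:, None]
        dl = (polygamma(0, Ya + ph) - polygamma(0, ph)
              + np.log(ph) + 1.0 - np.log(ph + mu) - (Ya + ph) / (ph + mu))
        d2l = (polygamma(1, Ya + ph) - polygamma(1, ph)
               + 1.0 / ph - 2.0 / (ph + mu) + (Ya + ph) / (ph + mu) ** 2)
        g = pa * (W * dl).sum(axis=1)
        h = pa**2 * (W * d2l).sum(axis=1) + g
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(h < -1e-12, -g / h, np.sign(g) * 0.5)
        step = np.clip(step, -2.0, 2.0)
        q0 = q_phi(theta)
        scale = np.ones_like(step)
        for _ in range(12):
            t_new = np.clip(theta + scale * step,
                            math.log(PHI_MIN), math.log(PHI_MAX))
            q1 = q_phi(t_new)
            bad = q1 < q0 - 1e-10
            if not bad.any():
                theta = t_new
                break
            scale = np.where(bad, scale * 0.5, scale)
        else:
            t_new = np.clip(theta + scale * step,
                            math.log(PHI_MIN), math.log(PHI_MAX))
            q1 = q_phi(t_new)
            theta = np.where(q1 >= q0 - 1e-10, t_new, theta)
        pa = np.exp(theta)

        a[act], b[act], c[act], phi[act] = aa, ba, ca, pa

    # final log-likelihood for genes that ran out of iterations
    rest = np.flatnonzero(~degenerate & ~converged)
    if rest.size:
        ll_final[rest] = loglik(rest, a[rest], b[rest], c[rest], phi[rest])[0]
        if keep_trace:
            for k, g in enumerate(rest):
                traces[g].append(float(ll_final[g]))

    fits = []
    for g in range(G):
        fits.append(PNBGeneFit(
            pi_coef=a[g].copy(),
            lambda_coef=b[g].copy(),
            mu_coef=c[g].copy(),
            phi=float(phi[g]),
            loglik=float(ll_final[g]),
            n_iter=int(n_iter[g]),
            converged=bool(converged[g]) and not degenerate[g],
            logL_center=center,
            failed=bool(degenerate[g]),
            loglik_trace=(np.array(traces[g]) if keep_trace else None),
        ))
    return fits


def fit_pnb_em(
    y, L, max_iter: int = 200, tol: float = 1e-6, keep_trace: bool = False
) -> PNBGeneFit:
    """Fit the PNB mixture for a single gene's counts ``y``."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("y must be a 1-d count vector")
    return fit_pnb_batch(y[None, :], L, max_iter=max_iter, tol=tol,
                         keep_trace=keep_trace)[0]


# ---------------------------------------------------------------------------
# dropout probability matrix
# ---------------------------------------------------------------------------

@dataclass
class DropoutMatrix:
    """Per-entry dropout posteriors with threshold calls.

    ``calls[i, j]`` is true exactly when ``probs[i, j] > tau``.
    """

    probs: np.ndarray
    tau: float
    fits: list
    gene_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None
    calls: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.size and (p.min() < -1e-12 or p.max() > 1 + 1e-12):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        self.probs = np.clip(p, 0.0, 1.0)
        self.calls = self.probs > self.tau

    @property
    def n_failed(self) -> int:
        return sum(1 for f in self.fits if getattr(f, "failed", False))


def _fit_logistic_zero_curve(mean_log, zero_frac):
    """Least-squares logistic fit of zero fraction against log2 gene mean."""

    def f(m, s, mid):
        return expit(-s * (m - mid))

    s0, mid0 = 1.0, float(np.median(mean_log))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                f, mean_log, zero_frac, p0=(s0, mid0),
                bounds=([1e-3, mean_log.min() - 10], [100.0, mean_log.max() + 10]),
                maxfev=2000,
            )
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        return s0, mid0


def dropout_matrix(
    E_fit,
    tau: float = 0.5,
    model: str = "pnb",
    max_iter: int = 200,
    tol: float = 1e-6,
) -> DropoutMatrix:
    """Dropout posteriors for every entry of a (QC'd) count matrix.

    ``model="pnb"`` fits every gene's mixture by EM; genes whose fit is
    degenerate fall back to probability 1 at zeros and 0 elsewhere and are
    flagged on their fit record.  ``model="logistic"`` is the ablation
    surrogate: a single logistic curve of zero probability against log2
    gene mean, applied only at observed zeros.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    Y = np.asarray(E_fit.values, dtype=np.float64)
    L = np.asarray(E_fit.library_sizes, dtype=np.float64)
    G, C = Y.shape
    if model == "pnb":
        fits = fit_pnb_batch(Y, L, max_iter=max_iter, tol=tol)
        n_failed = sum(f.failed for f in fits)
        if n_failed > 0.5 * G:
            raise RuntimeError(
                f"{n_failed}/{G} gene fits failed; matrix unsuitable for the "
                "mixture model"
            )
        probs = np.empty((G, C))
        for g, f in enumerate(fits):
            probs[g] = dropout_posterior(Y[g], f, L)
    elif model == "logistic":
        mean_log = np.log2(Y.mean(axis=1) + 1.0)
        zero_frac = (Y == 0).mean(axis=1)
        s, mid = _fit_logistic_zero_curve(mean_log, zero_frac)
        p_gene = expit(-s * (mean_log - mid))
        probs = np.where(Y == 0, p_gene[:, None], 0.0)
        fits = [("logistic", s, mid)] * G
    else:
        raise ValueError(f"unknown dropout model {model!r}")
    return DropoutMatrix(
        probs=probs, tau=tau, fits=fits,
        gene_ids=getattr(E_fit, "gene_ids", None),
        cell_ids=getattr(E_fit, "cell_ids", None),
    )


def write_dropout(D: DropoutMatrix, outdir) -> None:
    """Export probabilities, calls and the per-gene fit table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idx = D.gene_ids if D.gene_ids is not None else np.arange(D.probs.shape[0])
    cols = D.cell_ids if D.cell_ids is not None else np.arange(D.probs.shape[1])
    pd.DataFrame(D.probs, index=idx, columns=cols).to_csv(
        outdir / "dropout_probs.csv", float_format="%.6g")
    pd.DataFrame(D.calls.astype(int), index=idx, columns=cols).to_csv(
        outdir / "dropout_calls.csv")
    rows = []
    for g, f in zip(idx, D.fits):
        if isinstance(f, PNBGeneFit):
            rows.append({
                "gene": g,
                "pi_intercept": f.pi_coef[0], "pi_slope": f.pi_coef[1],
                "lambda_intercept": f.lambda_coef[0], "lambda_slope": f.lambda_coef[1],
                "mu_intercept": f.mu_coef[0], "mu_slope": f.mu_coef[1],
                "phi": f.phi, "loglik": f.loglik, "n_iter": f.n_iter,
                "converged": f.converged, "failed": f.failed,
            })
        else:
            rows.append({"gene": g, "model": "logistic",
                         "shape": f[1], "midpoint": f[2]})
    pd.DataFrame(rows).to_csv(outdir / "gene_fits.tsv", sep="\t", index=False)
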