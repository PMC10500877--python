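"""Average-information REML for variance components of the generation proxy.

Two models are provided, statsmodels-style (construct, then ``fit()``):

* :class:`AgeVarianceModel` — univariate ``y = 1 mu + g + e`` with
  ``g ~ N(0, G sigma2_g)`` and ``e ~ N(0, I sigma2_e)``. The quantity of
  interest is PVE = sigma2_g / (sigma2_g + sigma2_e), the proportion of
  variance in AGE captured by genome-wide SNPs. Because a GRM eigenbasis
  diagonalises every candidate covariance ``sigma2_g G + sigma2_e I``, the
  model is rotated once and each REML iteration costs O(n).

* :class:`BivariateAgeModel` — two populations measured for the same proxy,
  sharing one GRM across the union sample, with genetic covariance
  ``sigma_g12`` and zero residual covariance (no individual has records in
  both populations). The genetic correlation is
  ``r_G = sigma_g12 / sqrt(sigma2_g1 * sigma2_g2)``.

Both fits run Newton steps with the average-information matrix, fall back to
EM-style or damped (step-halved) updates whenever an AI step would leave the
parameter space or decrease the restricted likelihood, and report standard
errors from the inverse AI matrix at convergence (delta method for PVE and
r_G). Likelihood-ratio tests for a variance component on the boundary use
the 50:50 mixture of chi2(0) and chi2(1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .grm import KinshipMatrix

logger = logging.getLogger(__name__)

PSD_EIG_FLOOR = 1e-8


def _as_grm_values(grm) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(grm, KinshipMatrix):
        return grm.values, list(grm.sample_ids)
    return np.asarray(grm, dtype=np.float64), None


def _boundary_lrt_p(lr: float) -> float:
    """P-value for a variance component on the boundary (chi2 0/1 mixture)."""
    if lr <= 0:
        return 1.0
    return 0.5 * stats.chi2.sf(lr, df=1)


# ---------------------------------------------------------------------------
# univariate model in the GRM eigenbasis
# ---------------------------------------------------------------------------

@dataclass
class VarCompResults:
    """Univariate REML estimates for the generation-proxy model."""

    sigma2_g: float
    sigma2_e: float
    se_sigma2_g: float
    se_sigma2_e: float
    pve: float
    se_pve: float
    loglik: float
    loglik_null: float
    lrt_p: float
    n_iter: int
    converged: bool
    n: int
    model: "AgeVarianceModel" = field(repr=False)

    def summary(self) -> str:
        lines = [
            "Univariate variance components (AI-REML)",
            "=" * 44,
            f"n records            {self.n:>12d}",
            f"sigma2_g (months^2)  {self.sigma2_g:>12.4f}  (SE {self.se_sigma2_g:.4f})",
            f"sigma2_e (months^2)  {self.sigma2_e:>12.4f}  (SE {self.se_sigma2_e:.4f})",
            f"PVE                  {self.pve:>12.4f}  (SE {self.se_pve:.4f})",
            f"restricted logL      {self.loglik:>12.4f}",
            f"LRT p (sigma2_g = 0) {self.lrt_p:>12.3e}",
            f"iterations           {self.n_iter:>12d}  converged={self.converged}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd
        return pd.DataFrame([{
            "n": self.n, "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e, "pve": self.pve,
            "se_pve": self.se_pve, "loglik": self.loglik,
            "lrt_p": self.lrt_p, "converged": self.converged,
        }])


class AgeVarianceModel:
    """REML model for the variance in AGE explained by genome-wide SNPs."""

    def __init__(self, y, grm):
        values, ids = _as_grm_values(grm)
        y = np.asarray(y, dtype=np.float64).ravel()
        n = y.size
        if values.shape != (n, n):
            raise ValueError(f"GRM is {values.shape} but y has length {n}")
        self.y = y
        self.sample_ids = ids
        d, U = linalg.eigh(values)
        n_clipped = int((d < PSD_EIG_FLOOR).sum())
        if n_clipped:
            logger.info("clipped %d GRM eigenvalues below %.1e", n_clipped,
                        PSD_EIG_FLOOR)
        self.eigenvalues = np.maximum(d, PSD_EIG_FLOOR)
        self.eigenvectors = U
        self.yr = U.T @ y
        self.Xr = U.T @ np.ones((n, 1))

    # -- internals, all O(n) -------------------------------------------------
    def _core(self, theta):
        """GLS pieces at theta = (sigma2_g, sigma2_e) in the eigenbasis."""
        sg, se = theta
        v = sg * self.eigenvalues + se
        a = 1.0 / v
        Xa = self.Xr * a[:, None]
        XtViX = self.Xr.T @ Xa
        beta = linalg.solve(XtViX, Xa.T @ self.yr, assume_a="pos")
        Py = a * (self.yr - (self.Xr @ beta).ravel())
        return v, a, Xa, XtViX, Py

    def _loglik(self, theta) -> float:
        v, a, Xa, XtViX, Py = self._core(theta)
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (np.log(v).sum() + logdet_x + float(self.yr @ Py))

    def _proj(self, z, a, Xa, XtViX):
        """P z for a vector z, using the diagonal V in the eigenbasis."""
        az = a * z
        return az - (Xa @ linalg.solve(XtViX, Xa.T @ z)).ravel()

    def _score_ai(self, theta):
        d1 = self.eigenvalues  # dV/dsigma2_g in the eigenbasis
        v, a, Xa, XtViX, Py = self._core(theta)
        XtViX_inv = linalg.inv(XtViX)

        tr_terms = []
        for di in (d1, np.ones_like(d1)):
            # tr(P D) = tr(V^-1 D) - tr((X'V^-1X)^-1 X'V^-1 D V^-1 X)
            inner = (Xa * (di * a)[:, None]).T @ self.Xr
            tr_terms.append(float((di * a).sum() - np.trace(XtViX_inv @ inner)))

        t = [d1 * Py, Py.copy()]
        score = np.array([
            -0.5 * (tr_terms[i] - float(Py @ t[i])) for i in range(2)
        ])
        pt = [self._proj(ti, a, Xa, XtViX) for ti in t]
        ai = np.array([[0.5 * float(t[i] @ pt[j]) for j in range(2)]
                       for i in range(2)])
        return score, ai

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> VarCompResults:
        n = self.y.size
        vary = float(np.var(self.y, ddof=1))
        if vary == 0:
            raise ValueError("y has zero variance")
        floor = 1e-6 * vary
        theta = np.array([vary / 2.0, vary / 2.0])
        ll = self._loglik(theta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            score, ai = self._score_ai(theta)
            try:
                delta = linalg.solve(ai, score, assume_a="pos")
            except linalg.LinAlgError:
                delta = np.linalg.pinv(ai) @ score
            cand = theta + delta
            if np.any(cand < floor):
                # EM fallback keeps the iterate inside the parameter space
                _, a, Xa, XtViX, Py = self._core(theta)
                em = np.empty(2)
                for i, di in enumerate((self.eigenvalues, np.ones(n))):
                    tr_pd = self._trace_pd(di, a, Xa, XtViX)
                    em[i] = theta[i] + theta[i] ** 2 * (
                        float(Py @ (di * Py)) - tr_pd) / n
                cand = np.maximum(em, floor)
                delta = cand - theta
            ll_new = self._loglik(np.maximum(cand, floor))
            halvings = 0
            while ll_new < ll - 1e-12 and halvings < 30:
                delta *= 0.5
                cand = np.maximum(theta + delta, floor)
                ll_new = self._loglik(cand)
                halvings += 1
            theta = np.maximum(cand, floor)
            if abs(ll_new - ll) < tol:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        if not converged:
            warnings.warn("univariate REML did not converge; returning last "
                          "iterate", stacklevel=2)

        _, ai = self._score_ai(theta)
        try:
            cov = linalg.inv(ai)
        except linalg.LinAlgError:
            cov = np.linalg.pinv(ai)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        sg, sge = float(theta[0]), float(theta[1])
        tot = sg + sge
        pve = sg / tot
        grad = np.array([sge, -sg]) / tot**2
        se_pve = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

        loglik_null = self._null_loglik()
        lr = 2.0 * (ll - loglik_null)
        results = VarCompResults(
            sigma2_g=sg, sigma2_e=sge,
            se_sigma2_g=float(se[0]), se_sigma2_e=float(se[1]),
            pve=pve, se_pve=se_pve,
            loglik=float(ll), loglik_null=float(loglik_null),
            lrt_p=_boundary_lrt_p(lr), n_iter=it, converged=converged,
            n=n, model=self,
        )
        return results

    def _trace_pd(self, di, a, Xa, XtViX):
        inner = (Xa * (di * a)[:, None]).T @ self.Xr
        return float((di * a).sum() - np.trace(linalg.solve(XtViX, inner)))

    def _null_loglik(self) -> float:
        """Restricted likelihood with sigma2_g fixed at zero (OLS residuals)."""
        n, p = self.yr.size, self.Xr.shape[1]
        beta, *_ = np.linalg.lstsq(self.Xr, self.yr, rcond=None)
        rss = float(np.sum((self.yr - self.Xr @ beta) ** 2))
        s2 = rss / (n - p)
        return self._loglik((0.0, s2))


# ---------------------------------------------------------------------------
# bivariate model, dense AI-REML
# ---------------------------------------------------------------------------

@dataclass
class BivarResults:
    """Bivariate REML estimates: per-population variances, genetic covariance
    and the cross-population genetic correlation of the generation proxy."""

    sigma2_g1: float
    sigma2_g2: float
    sigma_g12: float
    sigma2_e1: float
    sigma2_e2: float
    se: dict
    r_g: float
    se_rg: float
    r_g_clamped: bool
    loglik: float
    lrt_p_rg0: float
    n_iter: int
    converged: bool
    n1: int
    n2: int
    populations: tuple[str, str]

    def summary(self) -> str:
        p1, p2 = self.populations
        lines = [
            "Bivariate variance components (AI-REML)",
            "=" * 46,
            f"populations          {p1} (n={self.n1}), {p2} (n={self.n2})",
            f"sigma2_g [{p1}]      {self.sigma2_g1:>10.4f}  (SE {self.se['sigma2_g1']:.4f})",
            f"sigma2_g [{p2}]      {self.sigma2_g2:>10.4f}  (SE {self.se['sigma2_g2']:.4f})",
            f"sigma_g12            {self.sigma_g12:>10.4f}  (SE {self.se['sigma_g12']:.4f})",
            f"sigma2_e [{p1}]      {self.sigma2_e1:>10.4f}",
            f"sigma2_e [{p2}]      {self.sigma2_e2:>10.4f}",
            f"r_G                  {self.r_g:>10.4f}  (SE {self.se_rg:.4f})",
            f"restricted logL      {self.loglik:>10.4f}",
            f"LRT p (sigma_g12=0)  {self.lrt_p_rg0:>10.3e}",
            f"iterations           {self.n_iter:>10d}  converged={self.converged}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd
        p1, p2 = self.populations
        return pd.DataFrame([{
            "population_1": p1, "population_2": p2,
            "n_1": self.n1, "n_2": self.n2,
            "sigma2_g1": self.sigma2_g1, "sigma2_g2": self.sigma2_g2,
            "sigma_g12": self.sigma_g12, "r_g": self.r_g,
            "se_rg": self.se_rg, "lrt_p_rg0": self.lrt_p_rg0,
            "converged": self.converged,
        }])


class _DenseREML:
    """Generic dense AI-REML: V = sum_i theta_i C_i, X fixed effects."""

    def __init__(self, y, X, components, var_idx, floor):
        self.y = np.asarray(y, dtype=np.float64).ravel()
        self.X = np.asarray(X, dtype=np.float64)
        self.components = components
        self.var_idx = var_idx  # indices of theta constrained to be >= floor
        self.floor = floor

    def _pieces(self, theta):
        V = sum(t * C for t, C in zip(theta, self.components))
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        Vinv = linalg.cho_solve((c, low), np.eye(len(self.y)),
                                check_finite=False)
        B = Vinv @ self.X
        XtViX = self.X.T @ B
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        beta = linalg.solve(XtViX, B.T @ self.y)
        Py = Vinv @ self.y - B @ beta
        ll = -0.5 * (logdet_v + logdet_x + float(self.y @ Py))
        return V, Vinv, B, XtViX, Py, ll

    def _loglik(self, theta) -> float:
        pieces = self._pieces(theta)
        return -np.inf if pieces is None else pieces[-1]

    def _score_ai(self, pieces):
        _, Vinv, B, XtViX, Py, _ = pieces
        k = len(self.components)
        t = [C @ Py for C in self.components]
        tr_pd = []
        for C in self.components:
            inner = B.T @ C @ B
            tr_pd.append(float(np.sum(Vinv * C) -
                               np.trace(linalg.solve(XtViX, inner))))
        score = np.array([-0.5 * (tr_pd[i] - float(Py @ t[i]))
                          for i in range(k)])
        pt = [Vinv @ ti - B @ linalg.solve(XtViX, B.T @ ti) for ti in t]
        ai = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(t[i] @ pt[j])
        return score, ai

    def _clamp(self, theta):
        theta = theta.copy()
        theta[self.var_idx] = np.maximum(theta[self.var_idx], self.floor)
        return theta

    def fit(self, start, max_iter=100, tol=1e-8):
        theta = self._clamp(np.asarray(start, dtype=float))
        pieces = self._pieces(theta)
        if pieces is None:
            raise ValueError("starting covariance matrix is not positive definite")
        ll = pieces[-1]
        converged, it = False, 0
        for it in range(1, max_iter + 1):
            score, ai = self._score_ai(pieces)
            try:
                delta = linalg.solve(ai, score, assume_a="pos")
            except linalg.LinAlgError:
                delta = np.linalg.pinv(ai) @ score
            cand = self._clamp(theta + delta)
            ll_new = self._loglik(cand)
            halvings = 0
            while ll_new < ll - 1e-12 and halvings < 30:
                delta *= 0.5
                cand = self._clamp(theta + delta)
                ll_new = self._loglik(cand)
                halvings += 1
            if not np.isfinite(ll_new):
                break
            theta = cand
            pieces = self._pieces(theta)
            if abs(ll_new - ll) < tol:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        _, ai = self._score_ai(pieces)
        try:
            cov = linalg.inv(ai)
        except linalg.LinAlgError:
            cov = np.linalg.pinv(ai)
        return theta, ll, cov, it, converged


class BivariateAgeModel:
    """Bivariate REML model for the generation proxy in two populations."""

    def __init__(self, y, grm, populations, min_group: int = 30):
        values, ids = _as_grm_values(grm)
        y = np.asarray(y, dtype=np.float64).ravel()
        populations = np.asarray(populations)
        n = y.size
        if values.shape != (n, n) or populations.size != n:
            raise ValueError("y, GRM and population labels must align")
        labels = list(dict.fromkeys(populations.tolist()))
        if len(labels) != 2:
            raise ValueError(f"exactly two populations required, got {labels}")
        if labels[0] == labels[1]:
            raise ValueError("the two populations must differ")
        if ids is not None:
            seen = {}
            for sid, pop in zip(ids, populations):
                if sid in seen and seen[sid] != pop:
                    raise ValueError(
                        f"sample {sid} appears in both populations")
                seen[sid] = pop
        m1 = populations == labels[0]
        m2 = ~m1
        self.small_groups = []
        for lab, m in zip(labels, (m1, m2)):
            if m.sum() < min_group:
                self.small_groups.append(lab)
                warnings.warn(f"population {lab!r} has only {int(m.sum())} "
                              "samples; estimates will be unstable",
                              stacklevel=2)

        d, U = linalg.eigh(values)
        G = (U * np.maximum(d, PSD_EIG_FLOOR)) @ U.T

        f1 = m1.astype(float)
        f2 = m2.astype(float)
        C_g1 = G * np.outer(f1, f1)
        C_g2 = G * np.outer(f2, f2)
        C_g12 = G * (np.outer(f1, f2) + np.outer(f2, f1))
        C_e1 = np.diag(f1)
        C_e2 = np.diag(f2)
        X = np.column_stack([f1, f2])  # separate intercepts

        self.y = y
        self.labels = (str(labels[0]), str(labels[1]))
        self.masks = (m1, m2)
        self._components = [C_g1, C_g2, C_g12, C_e1, C_e2]
        self._X = X

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> BivarResults:
        y, (m1, m2) = self.y, self.masks
        v1 = float(np.var(y[m1], ddof=1))
        v2 = float(np.var(y[m2], ddof=1))
        floor = 1e-6 * float(np.var(y, ddof=1))
        start = [v1 / 2, v2 / 2, 0.0, v1 / 2, v2 / 2]

        full = _DenseREML(y, self._X, self._components,
                          var_idx=np.array([0, 1, 3, 4]), floor=floor)
        theta, ll, cov, it, converged = full.fit(start, max_iter, tol)

        g1, g2, g12, e1, e2 = map(float, theta)
        r_g = g12 / np.sqrt(g1 * g2)
        clamped = abs(r_g) > 1.0
        if clamped:
            warnings.warn(f"r_G = {r_g:.3f} outside [-1, 1]; clamped",
                          stacklevel=2)
            r_g = float(np.clip(r_g, -1.0, 1.0))
        grad = np.array([-r_g / (2 * g1), -r_g / (2 * g2),
                         1.0 / np.sqrt(g1 * g2)])
        cov_g = cov[np.ix_([0, 1, 2], [0, 1, 2])]
        se_rg = float(np.sqrt(max(grad @ cov_g @ grad, 0.0)))

        # constrained fit with sigma_g12 = 0 (interior point -> plain chi2_1)
        comps0 = [self._components[i] for i in (0, 1, 3, 4)]
        null = _DenseREML(y, self._X, comps0,
                          var_idx=np.array([0, 1, 2, 3]), floor=floor)
        _, ll0, *_ = null.fit([v1 / 2, v2 / 2, v1 / 2, v2 / 2],
                              max_iter, tol)
        lr = max(2.0 * (ll - ll0), 0.0)
        lrt_p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0

        se_names = ["sigma2_g1", "sigma2_g2", "sigma_g12",
                    "sigma2_e1", "sigma2_e2"]
        se = {nm: float(np.sqrt(max(cov[i, i], 0.0)))
              for i, nm in enumerate(se_names)}
        return BivarResults(
            sigma2_g1=g1, sigma2_g2=g2, sigma_g12=g12,
            sigma2_e1=e1, sigma2_e2=e2, se=se,
            r_g=r_g, se_rg=se_rg, r_g_clamped=clamped,
            loglik=float(ll), lrt_p_rg0=lrt_p,
            n_iter=it, converged=converged,
            n1=int(m1.sum()), n2=int(m2.sum()),
            populations=self.labels,
        )
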