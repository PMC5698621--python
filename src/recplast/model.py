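"""Mixed-model test of recombination-rate plasticity.

The response is the fine-scale recombination rate (cM/Mb) at the
female x interval x brood level.  Fixed effects are the full three-way
factorial of genomic position, temperature treatment and day (brood), all
categorical; a random intercept per replicate vial absorbs the
non-independence of pseudo-replicate F1 females sharing a source vial.

    y_{gi} = x_{gi}' beta + u_g + e_{gi},   u_g ~ N(0, sigma_rep^2),
                                            e_{gi} ~ N(0, sigma^2)

The model is fitted by REML (ML log-likelihoods are kept for the
likelihood-ratio test against the intercept + random-intercept null).  For
a single random intercept the covariance of each replicate block is
``sigma^2 (I + lambda J)`` with ``lambda = sigma_rep^2 / sigma^2``, whose
inverse and determinant are closed forms (Woodbury); beta and sigma^2 are
profiled out and the REML criterion is optimised over lambda alone.  All
likelihood evaluations reduce to per-replicate sufficient statistics
(X'X, X'1, X'y, 1'y, y'y), so fitting is fast even with hundreds of fixed
effects.

Inference follows the lmerTest/emmeans conventions:

* Type-III F tests per fixed term (sum-to-zero factor coding, so testing a
  term's coefficients against zero is the Type-III hypothesis), with
  Satterthwaite denominator degrees of freedom obtained from the gradient
  of the contrast variance with respect to the variance parameters and the
  asymptotic covariance of the REML variance estimates.
* Estimated marginal (least-squares) means on the full position x day x
  temperature grid, with between-temperature contrasts within each
  (position, day) cell, Satterthwaite df, and Benjamini-Hochberg adjustment
  across the position x day family by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrices
from scipy import optimize, stats

__all__ = ["PlasticityModel", "PlasticityResults", "fit_plasticity_lmm"]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when the (RE)ML optimiser fails to converge."""


# ---------------------------------------------------------------------------
# sufficient statistics and likelihoods for the random-intercept model
# ---------------------------------------------------------------------------


@dataclass
class _Suffstats:
    """Per-group sufficient statistics for a random-intercept LMM."""

    n: int
    p: int
    n_g: np.ndarray  # (G,) group sizes
    Sxx: np.ndarray  # (G, p, p) X_g' X_g
    sx: np.ndarray  # (G, p) X_g' 1
    sxy: np.ndarray  # (G, p) X_g' y
    sy: np.ndarray  # (G,) 1' y
    syy: np.ndarray  # (G,) y' y

    @classmethod
    def build(cls, X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> "_Suffstats":
        labels, codes = np.unique(groups, return_inverse=True)
        G = len(labels)
        n, p = X.shape
        Sxx = np.zeros((G, p, p))
        sx = np.zeros((G, p))
        sxy = np.zeros((G, p))
        sy = np.zeros(G)
        syy = np.zeros(G)
        n_g = np.zeros(G, dtype=int)
        for g in range(G):
            m = codes == g
            Xg, yg = X[m], y[m]
            Sxx[g] = Xg.T @ Xg
            sx[g] = Xg.sum(axis=0)
            sxy[g] = Xg.T @ yg
            sy[g] = yg.sum()
            syy[g] = yg @ yg
            n_g[g] = m.sum()
        return cls(n=n, p=p, n_g=n_g, Sxx=Sxx, sx=sx, sxy=sxy, sy=sy, syy=syy)

    def gls_pieces(self, lam: float):
        """M(lambda) = X'W X, b = X'W y, q = y'W y with W = I - c J per group."""
        c = lam / (1.0 + self.n_g * lam)  # (G,)
        M = self.Sxx.sum(axis=0) - np.einsum("g,gi,gj->ij", c, self.sx, self.sx)
        b = self.sxy.sum(axis=0) - (c * self.sy) @ self.sx
        q = self.syy.sum() - np.sum(c * self.sy**2)
        return M, b, q

    def profiled_neg2(self, lam: float, reml: bool):
        """-2 log-likelihood profiled over beta and sigma^2, plus byproducts."""
        M, b, q = self.gls_pieces(lam)
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf, None, None
        beta = np.linalg.solve(M, b)
        rss = q - b @ beta
        if rss <= 0:
            return np.inf, None, None
        S = np.sum(np.log1p(self.n_g * lam))
        if reml:
            dof = self.n - self.p
            sigma2 = rss / dof
            crit = dof * (_LOG2PI + np.log(sigma2)) + S + logdetM + dof
        else:
            sigma2 = rss / self.n
            crit = self.n * (_LOG2PI + np.log(sigma2)) + S + self.n
        return crit, beta, sigma2

    def neg2_full(self, sigma2_rep: float, sigma2: float, reml: bool) -> float:
        """-2 log-likelihood at given variance parameters (beta profiled)."""
        if sigma2 <= 0 or sigma2_rep < 0:
            return np.inf
        lam = sigma2_rep / sigma2
        M, b, q = self.gls_pieces(lam)
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(M, b)
        rss = q - b @ beta
        S = np.sum(np.log1p(self.n_g * lam))
        if reml:
            dof = self.n - self.p
            return dof * (_LOG2PI + np.log(sigma2)) + S + logdetM + rss / sigma2
        return self.n * (_LOG2PI + np.log(sigma2)) + S + rss / sigma2

    def beta_cov(self, lam: float, sigma2: float):
        """beta-hat and Cov(beta-hat) = sigma^2 M(lambda)^{-1}."""
        M, b, _ = self.gls_pieces(lam)
        Minv = np.linalg.inv(M)
        return Minv @ b, sigma2 * Minv


def _optimise_lambda(ss: _Suffstats, reml: bool):
    """Maximise the profiled criterion over lambda >= 0 (log-scale Brent)."""

    def crit(t):
        return ss.profiled_neg2(np.exp(t), reml)[0]

    res = optimize.minimize_scalar(crit, bounds=(-15.0, 12.0), method="bounded",
                                   options={"xatol": 1e-12})
    if not np.isfinite(res.fun):
        raise ConvergenceError("profiled likelihood not finite at optimum; "
                               f"optimizer result: {res}")
    lam_int = float(np.exp(res.x))
    c0 = ss.profiled_neg2(0.0, reml)[0]
    if c0 <= res.fun + 1e-10 or res.x < -14.0:
        return 0.0, c0
    return lam_int, float(res.fun)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


@dataclass
class PlasticityResults:
    """Fitted plasticity mixed model: estimates, variances, inference.

    Attributes
    ----------
    fe_params : pandas.Series
        Fixed-effect estimates (REML), indexed by design column name.
    cov_params : pandas.DataFrame
        REML covariance of the fixed effects.
    sigma2, sigma2_rep : float
        Residual and replicate-intercept variances (REML).
    llf_reml, llf_ml : float
        Restricted and full maximum log-likelihoods.
    """

    model: "PlasticityModel"
    fe_params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    sigma2_rep: float
    llf_reml: float
    llf_ml: float
    converged: bool = True
    boundary: bool = field(default=False)  # sigma2_rep estimated at 0

    # --- Satterthwaite machinery -------------------------------------------------

    def _vc_cov(self):
        """Asymptotic covariance of (sigma2_rep, sigma2) from the REML Hessian."""
        ss = self.model._suffstats
        th = np.array([self.sigma2_rep, self.sigma2])
        h = np.maximum(1e-3 * th, 1e-6 * self.sigma2)
        if self.boundary:
            return None  # handled by the residual-df fallback

        def f(t1, t2):
            return -0.5 * ss.neg2_full(t1, t2, reml=True)

        f0 = f(*th)
        H = np.empty((2, 2))
        for i in range(2):
            e = np.zeros(2)
            e[i] = h[i]
            H[i, i] = (f(*(th + e)) - 2 * f0 + f(*(th - e))) / h[i] ** 2
        H[0, 1] = H[1, 0] = (
            f(th[0] + h[0], th[1] + h[1])
            - f(th[0] + h[0], th[1] - h[1])
            - f(th[0] - h[0], th[1] + h[1])
            + f(th[0] - h[0], th[1] - h[1])
        ) / (4 * h[0] * h[1])
        try:
            A = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(-H)
        if not np.all(np.isfinite(A)) or A[0, 0] < 0 or A[1, 1] < 0:
            return None
        return A, h

    def _satterthwaite_dfs(self, Lmat: np.ndarray) -> np.ndarray:
        """Satterthwaite df for each row-contrast of Lmat.

        df = 2 g^2 / (grad g' A grad g) with g(theta) = l' C(theta) l,
        C(theta) = sigma^2 M(sigma2_rep/sigma2)^{-1}; gradients by central
        differences using cached C at the stencil points.  When the
        replicate variance sits on the zero boundary the model collapses to
        OLS and the classical residual df n - p is exact.
        """
        ss = self.model._suffstats
        resid_df = ss.n - ss.p
        vc = self._vc_cov()
        if vc is None:
            return np.full(len(Lmat), float(resid_df))
        A, h = vc
        th = np.array([self.sigma2_rep, self.sigma2])

        def cov_at(t1, t2):
            _, C = ss.beta_cov(t1 / t2, t2)
            return C

        C0 = self.cov_params.to_numpy()
        g0 = np.einsum("ij,jk,ik->i", Lmat, C0, Lmat)
        grads = np.empty((2, len(Lmat)))
        for i in range(2):
            e = np.zeros(2)
            e[i] = h[i]
            Cp = cov_at(*(th + e))
            Cm = cov_at(*(th - e))
            grads[i] = np.einsum("ij,jk,ik->i", Lmat, (Cp - Cm), Lmat) / (2 * h[i])
        var_g = (
            A[0, 0] * grads[0] ** 2
            + 2 * A[0, 1] * grads[0] * grads[1]
            + A[1, 1] * grads[1] ** 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * g0**2 / var_g
        df = np.where(np.isfinite(df) & (df > 1e-8), df, float(resid_df))
        # a Satterthwaite df cannot meaningfully exceed the residual df here
        return np.minimum(df, float(resid_df))

    # --- public inference --------------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Type-III ANOVA with Satterthwaite denominator df.

        One row per fixed term (intercept excluded) with sum of squares,
        mean square, numerator df, denominator df, F and p.  Sums of squares
        are scaled so that F = MS / sigma^2.
        """
        info = self.model._design_info
        beta = self.fe_params.to_numpy()
        C = self.cov_params.to_numpy()
        rows = []
        for term, sl in info.term_name_slices.items():
            if term == "Intercept":
                continue
            idx = np.arange(sl.start, sl.stop)
            q = len(idx)
            L = np.zeros((q, len(beta)))
            L[np.arange(q), idx] = 1.0
            Phi = L @ C @ L.T
            Lb = L @ beta
            evals, evecs = np.linalg.eigh(Phi)
            keep = evals > max(1e-12, 1e-10 * evals.max())
            evals, evecs = evals[keep], evecs[:, keep]
            contrasts = evecs.T @ L  # one-df contrasts spanning the term
            t2 = (contrasts @ beta) ** 2 / evals
            F = float(t2.sum() / q)
            nus = self._satterthwaite_dfs(contrasts)
            ok = nus > 2.0
            if ok.any():
                E = float(np.sum(nus[ok] / (nus[ok] - 2.0)))
                den_df = 2.0 * E / (E - q) if E > q else float(self.model._suffstats.n - self.model._suffstats.p)
            else:
                den_df = float(self.model._suffstats.n - self.model._suffstats.p)
            ssq = F * q * self.sigma2
            rows.append(
                {
                    "term": self.model._friendly_term(term),
                    "sum_sq": ssq,
                    "mean_sq": ssq / q,
                    "num_df": q,
                    "den_df": den_df,
                    "F": F,
                    "p_value": float(stats.f.sf(F, q, den_df)),
                }
            )
        return pd.DataFrame(rows).set_index("term")

    def lrt_vs_null(self):
        """Likelihood-ratio test of all fixed effects against the
        intercept + random-intercept null, using ML log-likelihoods.

        Returns (statistic, df, p).
        """
        null = self.model._null_model().fit()
        stat = 2.0 * (self.llf_ml - null.llf_ml)
        if stat < -1e-6:
            raise ConvergenceError(
                f"full-model ML log-likelihood ({self.llf_ml:.6f}) below the "
                f"null's ({null.llf_ml:.6f}); optimizer failure"
            )
        stat = max(stat, 0.0)
        df = len(self.fe_params) - 1
        return float(stat), int(df), float(stats.chi2.sf(stat, df))

    def emmeans(self) -> pd.DataFrame:
        """Estimated marginal means on the position x day x temperature grid."""
        grid, X, observed = self.model._reference_grid()
        beta = self.fe_params.to_numpy()
        C = self.cov_params.to_numpy()
        est = X @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, C, X))
        out = grid.copy()
        out["emmean"] = est
        out["se"] = se
        out["estimable"] = observed
        return out

    def contrasts(self, adjust: str = "bh") -> pd.DataFrame:
        """Temperature contrasts within each (position, day) cell.

        The estimate is the difference in estimated marginal means between
        the two temperature levels (first minus second in sorted order) at
        each position x day cell; SE from the fixed-effect covariance, df by
        Satterthwaite, with Benjamini-Hochberg adjustment across the whole
        position x day family by default (``adjust="none"`` for raw p).
        Cells with no observed data in either temperature are flagged
        non-estimable and excluded from the adjustment family.
        """
        if adjust not in ("bh", "none"):
            raise ValueError(f"unknown adjustment {adjust!r}")
        t_levels = self.model._levels["temperature"]
        if len(t_levels) != 2:
            raise ValueError("temperature contrasts require exactly 2 treatment levels")
        grid, X, observed = self.model._reference_grid()
        beta = self.fe_params.to_numpy()
        C = self.cov_params.to_numpy()
        key = ["position", "day"]
        rows, Ls = [], []
        for (pos, day), sub in grid.groupby(key, sort=True, observed=True):
            i1 = sub.index[sub["temperature"] == t_levels[0]][0]
            i2 = sub.index[sub["temperature"] == t_levels[1]][0]
            est_ok = bool(observed[i1] and observed[i2])
            Ls.append(X[i1] - X[i2])
            rows.append({"position": pos, "day": day, "estimable": est_ok})
        Lmat = np.asarray(Ls)
        est = Lmat @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", Lmat, C, Lmat))
        dfs = self._satterthwaite_dfs(Lmat)
        tvals = est / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
        out = pd.DataFrame(rows)
        out["contrast"] = f"{t_levels[0]} - {t_levels[1]}"
        out["estimate"] = est
        out["se"] = se
        out["df"] = dfs
        out["t"] = tvals
        out["p_value"] = pvals
        mask = out["estimable"].to_numpy()
        adj = np.full(len(out), np.nan)
        if adjust == "bh" and mask.any():
            adj[mask] = stats.false_discovery_control(pvals[mask], method="bh")
        elif adjust == "none":
            adj[mask] = pvals[mask]
        out["p_adjusted"] = adj
        return out

    def summary(self) -> str:
        """Plain-text summary in the statsmodels style."""
        ss = self.model._suffstats
        lines = [
            "Recombination-rate plasticity mixed model (REML)",
            "=" * 58,
            f"observations: {ss.n}   fixed effects: {ss.p}   replicates: {len(ss.n_g)}",
            f"residual variance:  {self.sigma2:.6g}",
            f"replicate variance: {self.sigma2_rep:.6g}"
            + ("  (boundary)" if self.boundary else ""),
            f"log-likelihood (REML): {self.llf_reml:.4f}   (ML): {self.llf_ml:.4f}",
            "",
            "Type-III ANOVA (Satterthwaite df)",
            "-" * 58,
            self.anova().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        try:
            stat, df, p = self.lrt_vs_null()
            lines += ["", f"LRT vs intercept-only null: chi2({df}) = {stat:.3f}, p = {p:.4g}"]
        except ConvergenceError:
            pass
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------


class PlasticityModel:
    """Linear mixed model of cM/Mb on position x temperature x day.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per female x interval x brood observation.
    response, position, temperature, day, group : str
        Column names for the response and the three factors plus the
        replicate grouping column.

    All three factors are treated as categorical (the design of the
    factorial experiment); the replicate column defines the random
    intercept.  Use :meth:`from_rate_table` for pipeline rate tables.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "cM_per_Mb",
        position: str = "midpoint_mb",
        temperature: str = "treatment",
        day: str = "brood",
        group: str = "replicate_id",
        _null: bool = False,
    ):
        cols = {response: "y", position: "position", temperature: "temperature", day: "day"}
        missing = [c for c in list(cols) + [group] if c not in data.columns]
        if missing:
            raise ValueError(f"data missing columns: {missing}")
        df = data[list(cols) + [group]].rename(columns=cols).dropna(subset=["y"]).copy()
        if df.empty:
            raise ValueError("no non-missing response rows")
        groups = df[group].to_numpy()
        if len(np.unique(groups)) < 2:
            raise ValueError(
                "at least 2 replicates are required: the replicate-intercept "
                "variance is unidentifiable with a single replicate"
            )
        self._is_null = _null
        self._group_col = group
        self._levels = {
            "position": np.sort(df["position"].unique()),
            "temperature": np.sort(df["temperature"].unique()),
            "day": np.sort(df["day"].unique()),
        }
        formula = (
            "y ~ 1"
            if _null
            else "y ~ C(position, Sum) * C(temperature, Sum) * C(day, Sum)"
        )
        ymat, X = dmatrices(formula, df, return_type="dataframe")
        self._design_info = X.design_info
        Xa = X.to_numpy()
        if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
            raise ValueError(
                "fixed-effect design is rank deficient (empty factor cells?)"
            )
        self._X = Xa
        self._colnames = list(X.columns)
        self._y = ymat.to_numpy().ravel()
        self._groups = groups
        self._data = df
        self._suffstats = _Suffstats.build(self._X, self._y, groups)

    @classmethod
    def from_rate_table(cls, rates: pd.DataFrame, **kwargs) -> "PlasticityModel":
        """Build from a long-format rate table (pipeline columns)."""
        return cls(rates, **kwargs)

    def _null_model(self) -> "PlasticityModel":
        df = self._data.rename(
            columns={"y": "cM_per_Mb", "position": "midpoint_mb",
                     "temperature": "treatment", "day": "brood"}
        )
        return PlasticityModel(df, group=self._group_col, _null=True)

    def _friendly_term(self, term: str) -> str:
        for raw, nice in [
            ("C(position, Sum)", "position"),
            ("C(temperature, Sum)", "temperature"),
            ("C(day, Sum)", "day"),
        ]:
            term = term.replace(raw, nice)
        return term.replace(":", " x ")

    def _reference_grid(self):
        """Full factor grid, its design matrix, and an observed-cell mask."""
        pos, trt, day = (self._levels[k] for k in ("position", "temperature", "day"))
        grid = pd.DataFrame(
            [(p, d, t) for p in pos for d in day for t in trt],
            columns=["position", "day", "temperature"],
        )
        (X,) = build_design_matrices([self._design_info], grid)
        seen = set(map(tuple, self._data[["position", "day", "temperature"]].to_numpy()))
        observed = np.array([tuple(r) in seen for r in grid.to_numpy()])
        return grid, np.asarray(X), observed

    def fit(self, fix_lambda: float | None = None) -> PlasticityResults:
        """Fit by REML (point estimates, variances) and ML (for the LRT).

        ``fix_lambda`` fixes the variance ratio sigma_rep^2/sigma^2 instead
        of estimating it (0 forces the OLS degenerate limit; used for
        diagnostics and oracle comparisons).
        """
        ss = self._suffstats
        if fix_lambda is not None:
            lam = float(fix_lambda)
            crit_reml = ss.profiled_neg2(lam, reml=True)[0]
        else:
            lam, crit_reml = _optimise_lambda(ss, reml=True)
        _, beta, sigma2 = ss.profiled_neg2(lam, reml=True)
        if beta is None:
            raise ConvergenceError("REML criterion not finite at the optimum")
        if fix_lambda is not None:
            crit_ml = ss.profiled_neg2(lam, reml=False)[0]
        else:
            _, crit_ml = _optimise_lambda(ss, reml=False)
        _, C = ss.beta_cov(lam, sigma2)
        return PlasticityResults(
            model=self,
            fe_params=pd.Series(beta, index=self._colnames),
            cov_params=pd.DataFrame(C, index=self._colnames, columns=self._colnames),
            sigma2=float(sigma2),
            sigma2_rep=float(lam * sigma2),
            llf_reml=-0.5 * crit_reml,
            llf_ml=-0.5 * crit_ml,
            boundary=(lam == 0.0),
        )


def fit_plasticity_lmm(rates: pd.DataFrame, **kwargs) -> PlasticityResults:
    """Convenience wrapper: build the model from a rate table and fit."""
    return PlasticityModel.from_rate_table(rates, **kwargs).fit()
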