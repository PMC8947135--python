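"""Random-intercept linear mixed models with stratified residual variances.

The inference engine for the flight-performance analysis: a Gaussian
linear mixed model

    y_ij = x_ij' beta + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_{g(ij)}^2),

where i indexes bees (the random intercept) and g(ij) assigns each
observation to a residual-variance stratum — the varIdent-style
structure in which residual spread may differ between levels of one or
more experimental factors ("homoskedastic" means a single stratum).
Variance parameters are estimated by maximizing the restricted (REML)
or full (ML) log-likelihood of the marginal model
``y ~ N(X beta, Z sigma_b^2 Z' + D)``; the fixed effects are profiled
out by GLS at each evaluation.

AIC is ``-2 loglik + 2 (p_fixed + n_variance_params)`` under either
criterion.  REML AICs are comparable only between models with the same
fixed-effects design; ranking across different fixed structures should
use ML fits.

Denominator degrees of freedom for Wald F/t tests follow the
containment method: a term whose columns are constant within every
group is tested against ``n_groups - p_between`` df, any other term
against ``n_obs - n_groups - p_within`` df, matching the convention of
classic nested-ANOVA mixed-model software.

Example
-------
>>> model = HeteroskedasticLMM.from_formula(
...     "speed ~ route * wind * direction", data, groups="bee_id",
...     variance_strata=["field_height"])
>>> res = model.fit()          # REML
>>> res.anova()                # containment-df F table
>>> res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = ["HeteroskedasticLMM", "HeteroskedasticLMMResults", "ConvergenceWarning"]


class ConvergenceWarning(UserWarning):
    pass


def _group_blocks(groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    blocks = np.split(order, boundaries[1:])
    return blocks


class HeteroskedasticLMM:
    """Random-intercept LMM with per-stratum residual variances.

    Parameters
    ----------
    endog : (n,) response (already transformed as needed)
    exog : (n, p) fixed-effects design matrix
    groups : (n,) random-intercept grouping labels (bee identities)
    strata : (n,) residual-variance stratum labels, or None for a single
        homoskedastic stratum
    exog_names : column names for reporting
    """

    def __init__(self, endog, exog, groups, strata=None, exog_names=None,
                 design_info=None, data=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        n, p = self.exog.shape
        if len(self.endog) != n:
            raise ValueError("endog/exog length mismatch")
        self.groups = np.asarray(groups)
        if strata is None:
            strata = np.zeros(n, dtype=int)
        strata = np.asarray(strata)
        self.strata_labels, self.strata_codes = np.unique(strata, return_inverse=True)
        counts = np.bincount(self.strata_codes)
        if np.any(counts < 2):
            raise ValueError("every variance stratum needs >= 2 observations")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(p)]
        self.design_info = design_info
        self.data = data
        self._blocks = _group_blocks(self.groups)

    # -- construction -------------------------------------------------
    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups: str,
                     variance_strata=None) -> "HeteroskedasticLMM":
        """Build from a patsy formula; ``groups`` and ``variance_strata``
        name columns of ``data``."""
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        idx = X.index
        strata = None
        if variance_strata:
            cols = [variance_strata] if isinstance(variance_strata, str) else list(variance_strata)
            strata = data.loc[idx, cols].astype(str).agg("/".join, axis=1).to_numpy()
        return cls(endog=y.to_numpy().ravel(), exog=X.to_numpy(),
                   groups=data.loc[idx, groups].to_numpy(), strata=strata,
                   exog_names=list(X.columns),
                   design_info=X.design_info, data=data.loc[idx])

    # -- likelihood ---------------------------------------------------
    def _profile(self, theta, reml: bool):
        """Profiled log-likelihood at variance params; returns
        (loglik, beta, cov_beta)."""
        sigma_b2 = np.exp(2.0 * theta[0])
        sigma_g2 = np.exp(2.0 * theta[1:])
        X, y = self.exog, self.endog
        p = X.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        parts = []
        for idx in self._blocks:
            Xi, yi = X[idx], y[idx]
            d = sigma_g2[self.strata_codes[idx]]
            Vi = np.full((len(idx), len(idx)), sigma_b2) + np.diag(d)
            cf = cho_factor(Vi, lower=True)
            logdet += 2.0 * np.sum(np.log(np.diag(cf[0])))
            ViX = cho_solve(cf, Xi)
            Viy = cho_solve(cf, yi)
            XtVX += Xi.T @ ViX
            XtVy += Xi.T @ Viy
            parts.append((idx, cf, yi, Xi))
        cov_beta = np.linalg.inv(XtVX)
        beta = cov_beta @ XtVy
        quad = 0.0
        for idx, cf, yi, Xi in parts:
            ri = yi - Xi @ beta
            quad += ri @ cho_solve(cf, ri)
        n = len(y)
        if reml:
            sign, logdet_X = np.linalg.slogdet(XtVX)
            ll = -0.5 * (logdet + quad + logdet_X + (n - p) * np.log(2 * np.pi))
        else:
            ll = -0.5 * (logdet + quad + n * np.log(2 * np.pi))
        return ll, beta, cov_beta

    def fit(self, method: str = "reml", start=None,
            maxiter: int = 500) -> "HeteroskedasticLMMResults":
        """Estimate variance parameters by numerical REML/ML and return results."""
        reml = method.lower() == "reml"
        n_strata = len(self.strata_labels)
        if start is None:
            resid = self.endog - self.exog @ np.linalg.lstsq(
                self.exog, self.endog, rcond=None)[0]
            s = max(np.std(resid), 1e-6)
            start = np.log(np.r_[s / 2.0, np.full(n_strata, s)])

        def negll(theta):
            try:
                ll, _, _ = self._profile(theta, reml)
            except np.linalg.LinAlgError:
                return 1e12
            return -ll

        opt = optimize.minimize(negll, start, method="L-BFGS-B",
                                bounds=[(-12.0, 12.0)] * (1 + n_strata),
                                options={"maxiter": maxiter, "ftol": 1e-12})
        ll, beta, cov_beta = self._profile(opt.x, reml)
        p = self.exog.shape[1]
        n_var = 1 + n_strata
        return HeteroskedasticLMMResults(
            model=self, method="reml" if reml else "ml",
            params=beta, cov_params=cov_beta,
            sigma_b=float(np.exp(opt.x[0])),
            sigma_strata=dict(zip((str(s) for s in self.strata_labels),
                                  np.exp(opt.x[1:]).tolist())),
            llf=float(ll),
            aic=float(-2.0 * ll + 2.0 * (p + n_var)),
            converged=bool(opt.success),
            optimizer_message=str(opt.message),
        )

    # -- containment df helpers --------------------------------------
    def _between_columns(self) -> np.ndarray:
        """Boolean mask: column constant within every group."""
        X = self.exog
        out = np.ones(X.shape[1], dtype=bool)
        for idx in self._blocks:
            out &= np.all(np.abs(X[idx] - X[idx][0]) < 1e-10, axis=0)
        return out

    def containment_df(self, cols) -> float:
        """Denominator df for a hypothesis on the given design columns."""
        between = self._between_columns()
        n_groups = len(self._blocks)
        n = len(self.endog)
        p_between = int(np.sum(between))
        p_within = self.exog.shape[1] - p_between
        if all(between[c] for c in cols):
            return float(n_groups - p_between)
        return float(n - n_groups - p_within)


@dataclass
class HeteroskedasticLMMResults:
    """Estimates, uncertainties and diagnostics of one fitted LMM."""

    model: HeteroskedasticLMM
    method: str
    params: np.ndarray
    cov_params: np.ndarray
    sigma_b: float
    sigma_strata: dict[str, float]
    llf: float
    aic: float
    converged: bool
    optimizer_message: str = ""
    _ml_twin: "HeteroskedasticLMMResults | None" = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def n_obs(self) -> int:
        return len(self.model.endog)

    @property
    def n_groups(self) -> int:
        return len(self.model._blocks)

    @property
    def aic_ml(self) -> float:
        """ML-based AIC (refit if this fit is REML); valid for comparing
        models with different fixed effects."""
        if self.method == "ml":
            return self.aic
        if self._ml_twin is None:
            self._ml_twin = self.model.fit(method="ml")
        return self._ml_twin.aic

    # -- diagnostics --------------------------------------------------
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params

    def standardized_residuals(self) -> np.ndarray:
        """Marginal residuals scaled by their stratum residual sd."""
        resid = self.model.endog - self.fittedvalues()
        scale = np.array([self.sigma_strata[str(self.model.strata_labels[c])]
                          for c in self.model.strata_codes])
        return resid / scale

    # -- inference ----------------------------------------------------
    def anova(self) -> pd.DataFrame:
        """Wald F-tests per model term with containment denominator df."""
        if self.model.design_info is None:
            raise ValueError("anova() needs a formula-built model")
        rows = []
        di = self.model.design_info
        for term, sl in di.term_name_slices.items():
            if term == "Intercept":
                continue
            cols = list(range(sl.start, sl.stop))
            L = np.zeros((len(cols), len(self.params)))
            for i, c in enumerate(cols):
                L[i, c] = 1.0
            est = L @ self.params
            cov = L @ self.cov_params @ L.T
            q = len(cols)
            F = float(est @ np.linalg.solve(cov, est) / q)
            den = self.model.containment_df(cols)
            rows.append({"term": term, "num_df": q, "den_df": den, "F": F,
                         "p": float(f_dist.sf(F, q, den))})
        return pd.DataFrame(rows)

    def t_test(self, L) -> tuple[float, float, float]:
        """Single-row contrast: returns (estimate, t, p) with containment df."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.params)
        se = float(np.sqrt(L @ self.cov_params @ L))
        cols = list(np.flatnonzero(np.abs(L) > 1e-12))
        df = self.model.containment_df(cols)
        t = est / se
        return est, t, 2.0 * float(t_dist.sf(abs(t), df))

    def summary(self) -> str:
        lines = [
            "Heteroskedastic random-intercept LMM"
            f" ({self.method.upper()})",
            "=" * 64,
            f"No. observations: {self.n_obs:5d}   Groups: {self.n_groups}",
            f"Log-likelihood:   {self.llf:10.3f}   AIC: {self.aic:.3f}",
            f"Converged:        {self.converged}",
            "-" * 64,
            f"{'coef':>32} {'estimate':>10} {'std err':>9} {'t':>8}",
        ]
        for name, b, se in zip(self.model.exog_names, self.params, self.bse):
            lines.append(f"{name[:32]:>32} {b:10.4f} {se:9.4f} {b / se:8.3f}")
        lines.append("-" * 64)
        lines.append(f"Random intercept sd (sigma_b): {self.sigma_b:.4f}")
        for k, v in self.sigma_strata.items():
            lines.append(f"Residual sd [{k}]: {v:.4f}")
        return "\n".join(lines)
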