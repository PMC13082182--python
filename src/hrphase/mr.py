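"""One-sample Mendelian randomization by two-stage residual inclusion.

The genotype dosage of a single variant instruments the exposure
(heart-rate phase).  Stage 1 regresses the exposure on the instrument
and exogenous covariates by OLS; the instrument strength is summarised
by the Wald F of the instrument coefficient (F < 10 flags a weak
instrument) and the stage-1 R^2.  Stage 2 is a logistic regression of
the binary outcome on the stage-1 residual, the exposure and the same
exogenous covariates; the causal estimand is the stage-2 exposure
coefficient (log-odds per hour of phase), while the residual
coefficient serves as an endogeneity diagnostic.  Confidence intervals
come from a participant-level nonparametric bootstrap in which both
stages are re-fit within each resample; percentile intervals are
reported, plus both the analytic (robust z) and bootstrap p-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._glm import logit_beta, ols_beta

__all__ = ["MRResult", "TwoStageResidualInclusion", "WeakInstrumentWarning"]

MR_EXOGENOUS = ["weekly_steps", "age", "y_chromosome",
                "pc1", "pc2", "pc3", "pc4", "pc5"]


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class MRResult:
    """Results of a two-stage residual inclusion fit."""

    stage1_F: float
    stage1_r_squared: float
    stage1_beta: float          # exposure units per instrument allele
    stage2_beta: float          # log-odds per unit exposure
    stage2_se: float            # analytic robust SE
    ci_low: float
    ci_high: float
    p_analytic: float
    p_bootstrap: float
    residual_beta: float        # endogeneity diagnostic
    residual_p: float
    n: int
    n_resamples: int
    n_failed_resamples: int
    seed: int | None
    weak_instrument: bool
    bootstrap_betas: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Two-stage residual inclusion (one-sample MR)",
            "=" * 46,
            f"n participants           {self.n}",
            f"Stage 1 instrument beta  {self.stage1_beta:.4f} (exposure/allele)",
            f"Stage 1 F-statistic      {self.stage1_F:.2f}"
            + ("  [WEAK INSTRUMENT]" if self.weak_instrument else ""),
            f"Stage 1 R-squared        {self.stage1_r_squared:.4f}",
            f"Stage 2 exposure beta    {self.stage2_beta:.4f} (log-odds/unit)",
            f"  bootstrap 95% CI       [{self.ci_low:.4f}, {self.ci_high:.4f}]"
            f"  ({self.n_resamples} resamples, {self.n_failed_resamples} failed)",
            f"  odds ratio             {np.exp(self.stage2_beta):.4f}"
            f" [{np.exp(self.ci_low):.4f}, {np.exp(self.ci_high):.4f}]",
            f"  p (analytic z)         {self.p_analytic:.3g}",
            f"  p (bootstrap)          {self.p_bootstrap:.3g}",
            f"Residual (endogeneity)   beta={self.residual_beta:.4f}, p={self.residual_p:.3g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "bootstrap_betas"}
        return {k: (float(v) if isinstance(v, (np.floating, np.integer)) else v)
                for k, v in d.items()}


class TwoStageResidualInclusion:
    """Model object for one-sample MR with a binary outcome.

    Parameters
    ----------
    data : DataFrame holding outcome, exposure, instrument and
        exogenous columns; rows with missing values in any used column
        are dropped.
    outcome, exposure, instrument : column names.
    exogenous : covariate column names (defaults to steps, age,
        Y-chromosome and PC1-5).
    """

    def __init__(self, data: pd.DataFrame, outcome: str, exposure: str,
                 instrument: str, exogenous: list[str] | None = None):
        if exogenous is None:
            exogenous = [c for c in MR_EXOGENOUS if c in data.columns]
        cols = [outcome, exposure, instrument] + list(exogenous)
        df = data[cols].dropna()
        self.outcome, self.exposure, self.instrument = outcome, exposure, instrument
        self.exogenous = list(exogenous)
        self.y = df[outcome].astype(float).to_numpy()
        self.x = df[exposure].astype(float).to_numpy()
        self.z = df[instrument].astype(float).to_numpy()
        self.W = df[exogenous].astype(float).to_numpy()
        self.n = len(df)
        if np.unique(self.z).size < 2:
            raise ValueError("instrument does not vary")
        if np.unique(self.y).size < 2:
            raise ValueError("outcome does not vary")

    # -- design matrices ----------------------------------------------
    def _stage1_design(self, z: np.ndarray, W: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(z)), z, W])

    def _stage2_design(self, resid: np.ndarray, x: np.ndarray,
                       W: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(x)), resid, x, W])

    def _point_estimates(self, y, x, z, W) -> tuple[float, bool]:
        """Stage-2 exposure coefficient via fast IRLS (bootstrap path)."""
        X1 = self._stage1_design(z, W)
        b1 = ols_beta(X1, x)
        resid = x - X1 @ b1
        X2 = self._stage2_design(resid, x, W)
        b2, ok = logit_beta(X2, y)
        return float(b2[2]), ok

    def fit(self, n_resamples: int = 100_000, seed: int | None = None,
            alpha: float = 0.05, cov_type: str = "HC1") -> MRResult:
        """Fit both stages and bootstrap the stage-2 exposure coefficient.

        ``n_resamples`` participant-level resamples with replacement;
        both stages are re-fit inside each replicate.  Non-convergent
        replicates are dropped and counted.
        """
        X1 = self._stage1_design(self.z, self.W)
        s1 = sm.OLS(self.x, X1).fit()
        f_test = s1.f_test(np.eye(X1.shape[1])[1])  # instrument coefficient
        stage1_F = float(np.squeeze(f_test.fvalue))
        stage1_r2 = float(s1.rsquared)
        resid = self.x - X1 @ s1.params
        X2 = self._stage2_design(resid, self.x, self.W)
        s2 = sm.Logit(self.y, X2).fit(disp=0, cov_type=cov_type)
        beta = float(s2.params[2])
        se = float(s2.bse[2])
        p_analytic = float(s2.pvalues[2])
        resid_beta = float(s2.params[1])
        resid_p = float(s2.pvalues[1])
        weak = stage1_F < 10.0
        if weak:
            warnings.warn(
                f"weak instrument: stage-1 F = {stage1_F:.2f} < 10",
                WeakInstrumentWarning, stacklevel=2)

        rng = np.random.default_rng(seed)
        betas = np.empty(n_resamples)
        failed = 0
        k = 0
        for _ in range(n_resamples):
            idx = rng.integers(0, self.n, self.n)
            b, ok = self._point_estimates(self.y[idx], self.x[idx],
                                          self.z[idx], self.W[idx])
            if ok:
                betas[k] = b
                k += 1
            else:
                failed += 1
        betas = betas[:k]
        if k:
            lo, hi = np.percentile(betas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            # symmetric percentile bootstrap p: how extreme is 0?
            frac = np.mean(betas > 0.0)
            p_boot = float(min(1.0, 2.0 * min(frac, 1.0 - frac)))
        else:
            lo = hi = p_boot = np.nan
        return MRResult(
            stage1_F=stage1_F, stage1_r_squared=stage1_r2,
            stage1_beta=float(s1.params[1]),
            stage2_beta=beta, stage2_se=se,
            ci_low=float(lo), ci_high=float(hi),
            p_analytic=p_analytic, p_bootstrap=p_boot,
            residual_beta=resid_beta, residual_p=resid_p,
            n=self.n, n_resamples=n_resamples, n_failed_resamples=failed,
            seed=seed, weak_instrument=weak, bootstrap_betas=betas)

    def fit_naive(self, cov_type: str = "HC1"):
        """Conventional logistic fit (no residual term), for contrast."""
        X = np.column_stack([np.ones(self.n), self.x, self.W])
        fit = sm.Logit(self.y, X).fit(disp=0, cov_type=cov_type)
        return float(fit.params[1]), float(fit.bse[1])
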