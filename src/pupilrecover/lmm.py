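"""Linear mixed-effects models for cycle-wise PLR amplitudes.

Two fixed-effect specifications are supported, both with a random intercept
for group and maximum-likelihood estimation:

    base:      amplitude ~ 1 + Time + Group + (1 | Group)
    extended:  amplitude ~ 1 + Age + Time + Group + Age x Group + (1 | Group)

Time is the preceding dark duration in milliseconds; Group is a treatment
contrast with Control as the reference level, so a negative Group coefficient
means lower amplitude in AMD; Age is centered at the cohort mean.  Estimation
is ML (not REML) so AIC/BIC are comparable across fixed-effect structures.

A random intercept with only two levels sits at the boundary of the parameter
space in most data sets; the fit then degenerates gracefully to OLS-like
estimates, ``converged`` stays true and the boundary is reported.  A
``random='subject'`` sensitivity refit is available.

The API follows the Model / Results convention: build a :class:`RecoveryLMM`
from an amplitude table, call :meth:`~RecoveryLMM.fit`, and read estimates,
ANOVA and the summary off the returned :class:`RecoveryLMMResults`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "RecoveryLMM",
    "RecoveryLMMResults",
    "fit_lmm",
    "marginal_anova",
    "summarize_fit",
]

logger = logging.getLogger(__name__)

VARIANT_TERMS = {
    "base": ["Intercept", "Time", "Group[AMD]"],
    "extended": ["Intercept", "Age", "Time", "Group[AMD]", "Age:Group[AMD]"],
}

#: group-level variance below this (relative to residual) is reported as boundary
BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    variant: Literal["base", "extended"] = "base"
    random: Literal["group", "subject"] = "group"
    normalize: bool = False
    phases: tuple[str, ...] = ("ramp",)  # only ramp cycles feed the model

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_TERMS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.random not in ("group", "subject"):
            raise ValueError(f"unknown random structure {self.random!r}")

    @property
    def fixed_terms(self) -> list[str]:
        return list(VARIANT_TERMS[self.variant])


class RecoveryLMM:
    """Mixed model for an amplitude table (one row per subject x cycle)."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        self.table = self._prepare(table)
        self.exog, self.term_names = self._design(self.table)
        self.endog = self.table["amplitude"].to_numpy(dtype=float)
        self.groups = (
            self.table["group"].to_numpy()
            if self.spec.random == "group"
            else self.table["subject_id"].to_numpy()
        )
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            aliased = self._aliased_terms()
            raise ValueError(f"rank-deficient fixed design; aliased terms: {aliased}")

    @classmethod
    def from_table(cls, table: pd.DataFrame, variant: str = "base", **kw) -> "RecoveryLMM":
        return cls(table, ModelSpec(variant=variant, **kw))

    @classmethod
    def from_csv(cls, path, variant: str = "base", **kw) -> "RecoveryLMM":
        from .amplitude import read_amplitude_table
        return cls(read_amplitude_table(path), ModelSpec(variant=variant, **kw))

    # -- construction helpers ------------------------------------------------

    def _prepare(self, table: pd.DataFrame) -> pd.DataFrame:
        df = table.copy()
        if "phase" in df.columns:
            df = df[df["phase"].isin(self.spec.phases)]
        if "missing_reason" in df.columns:
            df["missing_reason"] = df["missing_reason"].fillna("")
            n_missing = int((df["missing_reason"] != "").sum())
            if n_missing:
                logger.info("dropping %d missing amplitude rows", n_missing)
            df = df[df["missing_reason"] == ""]
        df = df.dropna(subset=["amplitude", "dark_ms", "group", "age_years"])
        if df.empty:
            raise ValueError("no usable rows in amplitude table")
        groups = sorted(df["group"].unique())
        if set(groups) - {"AMD", "Control"}:
            raise ValueError(f"unknown group labels: {sorted(set(groups) - {'AMD', 'Control'})}")
        if len(groups) < 2:
            raise ValueError(
                "design error: the Group term requires both AMD and Control rows"
            )
        if self.spec.normalize:
            if "baseline_mm" not in df.columns:
                raise ValueError("normalize=True requires a baseline_mm column")
            df["amplitude"] = df["amplitude"] / df["baseline_mm"]
        # center age at the cohort (per-subject) mean
        subj_age = df.groupby("subject_id")["age_years"].first()
        df["age_centered"] = df["age_years"] - subj_age.mean()
        return df.reset_index(drop=True)

    def _design(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        amd = (df["group"] == "AMD").to_numpy(dtype=float)
        time = df["dark_ms"].to_numpy(dtype=float)
        cols = {"Intercept": np.ones(len(df)), "Time": time, "Group[AMD]": amd}
        if self.spec.variant == "extended":
            age = df["age_centered"].to_numpy(dtype=float)
            cols = {
                "Intercept": cols["Intercept"],
                "Age": age,
                "Time": time,
                "Group[AMD]": amd,
                "Age:Group[AMD]": age * amd,
            }
        names = list(cols)
        return np.column_stack([cols[n] for n in names]), names

    def _aliased_terms(self) -> list[str]:
        aliased = []
        for j, name in enumerate(self.term_names):
            others = np.delete(self.exog, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(self.exog):
                aliased.append(name)
        return aliased

    # -- estimation ----------------------------------------------------------

    def fit(self, **fit_kw) -> "RecoveryLMMResults":
        """Maximum-likelihood fit; returns a results object.

        When the optimizer stalls with the random-intercept variance at the
        boundary (variance -> 0), the fit is replaced by the exact boundary
        ML solution (generalised least squares with zero group variance);
        ``converged`` stays true and the boundary is reported.
        """
        model = sm.MixedLM(self.endog, self.exog, groups=self.groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, **fit_kw)
        if not res.converged:
            var_re = float(np.asarray(res.cov_re)[0, 0])
            if var_re < BOUNDARY_TOL * res.scale:
                res = _BoundaryMLFit(self.endog, self.exog)
        return RecoveryLMMResults(self, res)


class _BoundaryMLFit:
    """Exact ML solution on the boundary of the variance space (sigma_b = 0).

    With the group variance pinned at zero the marginal model is ordinary
    least squares with ML residual variance; used only when the mixed-model
    optimizer stalls exactly at that boundary.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray) -> None:
        n, p = exog.shape
        beta, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        resid = endog - exog @ beta
        sigma2 = float(resid @ resid) / n  # ML, not OLS, divisor
        xtx_inv = np.linalg.inv(exog.T @ exog)
        self.fe_params = beta
        self.bse_fe = np.sqrt(np.diag(xtx_inv) * sigma2)
        self.scale = sigma2
        self.cov_re = np.zeros((1, 1))
        self.converged = True
        self.llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


class RecoveryLMMResults:
    """Estimates, uncertainties and diagnostics of a fitted RecoveryLMM."""

    def __init__(self, model: RecoveryLMM, smres) -> None:
        self.model = model
        self._smres = smres
        self.n_obs = len(model.endog)
        self.df_resid = self.n_obs - np.linalg.matrix_rank(model.exog)
        self.params = pd.Series(
            np.asarray(smres.fe_params), index=model.term_names, name="estimate"
        )
        with np.errstate(invalid="ignore"):  # sqrt warning at the variance boundary
            bse = np.asarray(smres.bse_fe)
        self.bse = pd.Series(bse, index=model.term_names, name="se")
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * scipy.stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=model.term_names,
            name="p",
        )
        self.sigma_resid = float(np.sqrt(smres.scale))
        self.random_intercept_var = float(np.asarray(smres.cov_re)[0, 0])
        self.random_intercept_sd = float(np.sqrt(self.random_intercept_var))
        self.converged = bool(smres.converged)
        self.llf = float(smres.llf)
        # ML parameter count: fixed effects + group variance + residual variance
        self.k_params = len(self.params) + 2
        self.aic = -2 * self.llf + 2 * self.k_params
        self.bic = -2 * self.llf + self.k_params * np.log(self.n_obs)
        self.at_boundary = self.random_intercept_var < BOUNDARY_TOL * smres.scale

    # -- inference -----------------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Marginal (type-III) F tests with residual degrees of freedom.

        Each fixed term is tested given all others; for single-df terms the F
        statistic is the squared coefficient t statistic.
        """
        if not self.converged:
            raise RuntimeError("cannot compute ANOVA from a non-converged fit")
        rows = []
        for name in self.model.term_names:
            f = float(self.tvalues[name] ** 2)
            p = float(scipy.stats.f.sf(f, 1, self.df_resid))
            rows.append({"term": name, "F": f, "df_num": 1,
                         "df_resid": self.df_resid, "p": p})
        return pd.DataFrame(rows)

    # -- reporting -----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variant": self.model.spec.variant,
            "random": self.model.spec.random,
            "converged": self.converged,
            "at_boundary": bool(self.at_boundary),
            "n_obs": int(self.n_obs),
            "df_resid": int(self.df_resid),
            "llf": self.llf,
            "aic": float(self.aic),
            "bic": float(self.bic),
            "sigma_resid": self.sigma_resid,
            "random_intercept_sd": self.random_intercept_sd,
            "coefficients": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "t": float(self.tvalues[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.model.term_names
            },
            "anova": self.anova().to_dict(orient="records") if self.converged else None,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({self.model.spec.variant}), ML estimation",
            f"  amplitude ~ {' + '.join(self.model.term_names)}"
            f" + (1 | {self.model.spec.random})",
            f"  n_obs = {self.n_obs}, residual df = {self.df_resid}",
        ]
        if not self.converged:
            lines.append("  *** WARNING: FIT DID NOT CONVERGE — estimates unreliable ***")
        lines.append(f"  logLik = {self.llf:.3f}  AIC = {self.aic:.2f}  BIC = {self.bic:.2f}")
        lines.append(
            f"  sigma_resid = {self.sigma_resid:.6g}  "
            f"random intercept sd = {self.random_intercept_sd:.6g}"
            + ("  (variance at boundary)" if self.at_boundary else "")
        )
        lines.append(f"  {'term':<18}{'estimate':>14}{'se':>12}{'t':>10}{'p':>12}")
        for name in self.model.term_names:
            lines.append(
                f"  {name:<18}{self.params[name]:>14.6g}{self.bse[name]:>12.4g}"
                f"{self.tvalues[name]:>10.3f}{self.pvalues[name]:>12.3g}"
            )
        if self.converged:
            lines.append("  Marginal (type-III) ANOVA:")
            for _, row in self.anova().iterrows():
                lines.append(
                    f"  {row['term']:<18}F(1, {int(row['df_resid'])}) = "
                    f"{row['F']:.3f}, p = {row['p']:.3g}"
                )
        return "\n".join(lines)


# -- functional wrappers used by the pipeline/CLI ---------------------------

def fit_lmm(
    table: pd.DataFrame, variant: str = "base", **spec_kw
) -> RecoveryLMMResults:
    return RecoveryLMM.from_table(table, variant=variant, **spec_kw).fit()


def marginal_anova(results: RecoveryLMMResults) -> pd.DataFrame:
    return results.anova()


def summarize_fit(results: RecoveryLMMResults, json_path=None) -> str:
    if json_path is not None:
        results.to_json(json_path)
    return results.summary()
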