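"""Strata-level Poisson models of fertility ideals and behavior.

Ideal family size (or, for women aged 40-49, children ever born) of woman
*i* in survey stratum *s* is modelled as a Poisson count with log mean

    log mu_{i,s} = b0 + b1[educ_i] + b2 * MYS_s + b3[educ_i] * MYS_s + U_s,

where MYS_s is the mean years of schooling of women in the stratum, educ is
the four-category attainment of the woman herself (reference: no formal
education) and U_s absorbs unobserved stratum heterogeneity.  The
interaction b3 is the quantity of interest: it measures how strongly the
fertility of women at a *given* attainment level responds to the education
of the women around them — the cross-sectional footprint of a diffusion
process.

Two treatments of U_s are provided.  ``mode="fixed"`` (default) absorbs the
strata as constants in a standard Poisson GLM; because MYS_s is itself a
stratum-level regressor, the absorbed constants are identified by the
constraint that U be orthogonal to (1, MYS) across strata — the
stratum-level trend belongs to (b0, b2), the orthogonal residual to U_s.
``mode="random"`` treats U_s as zero-mean normal and fits the mixed model
by MAP (Laplace) estimation.  Prediction curves set the stratum term to
its reference level: the mean absorbed effect (fixed, zero by
construction) or zero (random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse
from scipy.linalg import null_space
from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

from .data_model import EDUCATION_LEVELS

__all__ = ["PoissonModelFit", "InestimableContrastError",
           "SeparationError", "fit_ifs_model", "predict_curves"]

logger = logging.getLogger(__name__)

_CONTRAST_LEVELS = EDUCATION_LEVELS[1:]   # reference = "none"


class InestimableContrastError(ValueError):
    """The design matrix is rank deficient; names the offending contrasts."""


class SeparationError(ValueError):
    """An education category has an all-zero outcome (log link diverges)."""


@dataclass
class PoissonModelFit:
    """Estimated coefficients of the strata Poisson model."""

    mode: str                          # "fixed" | "random"
    outcome: str
    beta0: float                       # intercept, log scale
    beta1: dict                       # education contrasts (none = 0)
    beta2: float                       # slope on stratum MYS
    beta3: dict                       # education x MYS interactions (none = 0)
    se: dict                          # standard error per named coefficient
    urban_effect: float | None
    stratum_effects: pd.Series        # U_s per stratum (absorbed or posterior)
    stratum_reference: float          # stratum term used for predictions
    mys_range: tuple
    n_obs: int
    llf: float
    include_urban: bool
    converged: bool = True
    raw_result: object = field(default=None, repr=False)

    def coefficient(self, name: str) -> float:
        """Look up a coefficient by its design-column name."""
        table = {"beta0": self.beta0, "beta2": self.beta2}
        for e in _CONTRAST_LEVELS:
            table[f"beta1[{e}]"] = self.beta1[e]
            table[f"beta3[{e}]"] = self.beta3[e]
        if self.urban_effect is not None:
            table["urban"] = self.urban_effect
        return table[name]


def _design(df: pd.DataFrame, include_urban: bool) -> tuple[np.ndarray, list]:
    """Dense fixed-part design: intercept, contrasts, MYS, interactions."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["beta0"]
    mys = df["stratum_mys"].to_numpy(dtype=float)
    for e in _CONTRAST_LEVELS:
        cols.append((df["education"] == e).to_numpy(dtype=float))
        names.append(f"beta1[{e}]")
    cols.append(mys)
    names.append("beta2")
    for e in _CONTRAST_LEVELS:
        cols.append((df["education"] == e).to_numpy(dtype=float) * mys)
        names.append(f"beta3[{e}]")
    if include_urban:
        cols.append(df["urban"].to_numpy(dtype=float))
        names.append("urban")
    return np.column_stack(cols), names


def _check_estimable(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X.T @ X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        flagged = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            sub = X[:, keep]
            if np.linalg.matrix_rank(sub.T @ sub) == rank:
                flagged.append(names[j])
        raise InestimableContrastError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"inestimable contrasts: {flagged or names}")


def fit_ifs_model(data: pd.DataFrame, outcome: str = "ideal_family_size",
                  mode: str = "fixed", include_urban: bool = False,
                  group_col: str = "stratum_id") -> PoissonModelFit:
    """Fit the strata Poisson model of ideal or achieved family size.

    ``outcome="children_ever_born"`` restricts the sample to women aged
    40-49 with a nonmissing count, the group whose births approximate
    completed cohort fertility.  ``group_col`` selects the grouping level
    for U_s (strata by default; pass ``"cluster_id"`` for the finer level).
    """
    if outcome not in ("ideal_family_size", "children_ever_born"):
        raise ValueError(f"unknown outcome '{outcome}'")
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown mode '{mode}'")
    df = data
    if outcome == "children_ever_born":
        df = df[(df["age"] >= 40) & (df["age"] <= 49)
                & df["children_ever_born"].notna()]
    df = df[df[outcome].notna()]
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 groups (strata)")

    y = df[outcome].to_numpy(dtype=float)
    for e in EDUCATION_LEVELS:
        mask = (df["education"] == e).to_numpy()
        if mask.any() and not (y[mask] > 0).any():
            raise SeparationError(
                f"outcome '{outcome}' is all zero for education '{e}': "
                "the log-scale mean diverges")

    X, names = _design(df, include_urban)
    _check_estimable(X, names)
    groups = df[group_col].to_numpy()
    levels, group_idx = np.unique(groups, return_inverse=True)

    if mode == "fixed":
        # Absorb the strata as constants.  Stratum MYS is itself constant
        # within strata, so unrestricted dummies are collinear with the
        # intercept and the MYS slope; identification requires U to be
        # orthogonal to (1, MYS) across strata.  The dummies are therefore
        # replaced by a null-space basis of that stratum-level subspace:
        # the stratum-level part of the fit goes to (beta0, beta2) and U_s
        # is the orthogonal residual, all in one Poisson likelihood.
        group_mys = np.empty(len(levels))
        group_mys[group_idx] = df["stratum_mys"].to_numpy(dtype=float)
        basis = np.column_stack([np.ones(len(levels)), group_mys])
        z = null_space(basis.T)                       # S x (S - 2)
        dummies = sparse.csr_matrix(
            (np.ones(len(df)), (np.arange(len(df)), group_idx)),
            shape=(len(df), len(levels)))
        X_full = np.column_stack([X, dummies @ z])
        full_names = names + [f"u{j}" for j in range(z.shape[1])]
        res = sm.Poisson(y, X_full).fit(method="newton", disp=0)
        params = pd.Series(np.asarray(res.params), index=full_names)
        bse = pd.Series(np.asarray(res.bse), index=full_names)
        absorbed = pd.Series(z @ params[len(names):].to_numpy(), index=levels)
        fit_kwargs = dict(llf=float(res.llf),
                          converged=bool(res.mle_retvals.get("converged",
                                                             True)),
                          raw_result=res)
        stratum_reference = float(absorbed.mean())    # 0 by construction
    else:
        exog_vc = sparse.csr_matrix(
            (np.ones(len(df)), (np.arange(len(df)), group_idx)),
            shape=(len(df), len(levels)))
        model = PoissonBayesMixedGLM(y, X, exog_vc,
                                     ident=np.zeros(len(levels), dtype=int),
                                     fep_names=names)
        res = model.fit_map(minim_opts={"maxiter": 500})
        params = pd.Series(res.fe_mean, index=names)
        bse = pd.Series(res.fe_sd, index=names)
        absorbed = pd.Series(res.vc_mean, index=levels)
        fit_kwargs = dict(llf=float("nan"), converged=True, raw_result=res)
        stratum_reference = 0.0

    mys = df["stratum_mys"].to_numpy(dtype=float)
    return PoissonModelFit(
        mode=mode, outcome=outcome,
        beta0=float(params["beta0"]),
        beta1={"none": 0.0, **{e: float(params[f"beta1[{e}]"])
                               for e in _CONTRAST_LEVELS}},
        beta2=float(params["beta2"]),
        beta3={"none": 0.0, **{e: float(params[f"beta3[{e}]"])
                               for e in _CONTRAST_LEVELS}},
        se={name: float(bse[name]) for name in names},
        urban_effect=float(params["urban"]) if include_urban else None,
        stratum_effects=absorbed,
        stratum_reference=stratum_reference,
        mys_range=(float(mys.min()), float(mys.max())),
        n_obs=int(len(df)), include_urban=include_urban, **fit_kwargs)


def predict_curves(fit: PoissonModelFit, mys_grid: Sequence[float],
                   education: str, urban: bool = False) -> np.ndarray:
    """Predicted mean count over a grid of stratum mean years of schooling.

    Evaluates ``exp(b0 + b1[educ] + (b2 + b3[educ]) * MYS + U_ref)`` with
    the stratum term at its reference level.  Grid points outside the
    fitted MYS range trigger an extrapolation warning, not an error.
    """
    if education not in EDUCATION_LEVELS:
        raise ValueError(f"unknown education '{education}'")
    grid = np.asarray(mys_grid, dtype=float)
    lo, hi = fit.mys_range
    span = max(hi - lo, 1.0)
    if (grid < lo - 0.1 * span).any() or (grid > hi + 0.1 * span).any():
        logger.warning("MYS grid extends well beyond the fitted range "
                       "[%.2f, %.2f]: predictions are extrapolations", lo, hi)
    eta = (fit.beta0 + fit.beta1[education]
           + (fit.beta2 + fit.beta3[education]) * grid
           + fit.stratum_reference)
    if fit.include_urban and urban:
        eta = eta + fit.urban_effect
    return np.exp(eta)
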