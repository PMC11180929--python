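"""Polygenic risk scores and pairwise scaled-PRS contrasts.

A PRS is the fixed-weight sum of effect-allele dosages over the panel, using
the meta-analysis log odds ratios as weights:

    score_i = sum_j beta_meta_j * dosage_ij.

Scores are z-scored (mean 0, sd 1) over a standardization scope — by default
the union of all loaded samples, so the odds ratios of the three pairwise
contrasts are on a common scale — and each contrast is a logistic regression
of group membership on the scaled score plus PC1-5.  The reported effect is
the odds ratio per one standard deviation increase in PRS, with a Wald 95%
confidence interval.  Because the two APOE SNPs dominate the weight
distribution, every contrast is run with and without them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.api import Logit
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationError)

from .association import CONTRASTS, _contrast_labels
from .io import AD, CohortDataset, ReferencePanel, ValidationError


@dataclass
class PRSConfig:
    """Scoring options.  The weight source is fixed to ``beta_meta``."""

    include_apoe: bool = True
    #: "all" standardizes over every loaded sample; "contrast" re-standardizes
    #: within each pairwise comparison (sensitivity option).
    standardization_scope: str = "all"


@dataclass
class PRSComparison:
    """One pairwise scaled-PRS logistic contrast."""

    contrast: tuple[str, str]
    include_apoe: bool
    stratum: str  # "all" | "F" | "M"
    or_per_sd: float
    ci95: tuple[float, float]
    p_value: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "group_a": self.contrast[0], "group_b": self.contrast[1],
            "include_apoe": self.include_apoe, "stratum": self.stratum,
            "or_per_sd": self.or_per_sd, "ci_low": self.ci95[0],
            "ci_high": self.ci95[1], "p_value": self.p_value,
            "n_a": self.n_a, "n_b": self.n_b,
        }


def compute_prs(dataset: CohortDataset, panel: ReferencePanel,
                config: PRSConfig | None = None) -> pd.Series:
    """Raw weighted dosage sum per sample (missing dosages mean-imputed)."""
    config = config or PRSConfig()
    use = panel if config.include_apoe else panel.without_apoe()
    ids = [s for s in use.snp_ids if s in dataset.dosage.columns]
    if not ids:
        raise ValidationError("no panel SNPs available to score")
    weights = use.beta_meta.loc[ids]
    dosage = dataset.mean_imputed().dosage[ids]
    return pd.Series(dosage.to_numpy() @ weights.to_numpy(),
                     index=dataset.samples.index, name="prs")


def standardize_prs(raw: pd.Series, scope_mask: np.ndarray | None = None) -> pd.Series:
    """Z-score raw PRS values using mean/sd computed over ``scope_mask``.

    Samples outside the scope are transformed with the scope's mean and sd,
    so all values stay on one scale.  Zero variance within scope is an error.
    """
    values = raw.to_numpy(dtype=float)
    scope = np.ones(values.size, dtype=bool) if scope_mask is None \
        else np.asarray(scope_mask, dtype=bool)
    if not scope.any():
        raise ValidationError("standardization scope is empty")
    mu = values[scope].mean()
    sd = values[scope].std()
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("PRS has zero variance within the scope")
    return pd.Series((values - mu) / sd, index=raw.index, name="prs_z")


def compare_prs(z_scores: pd.Series, dataset: CohortDataset, contrast,
                stratum: str = "all",
                include_apoe: bool = True) -> PRSComparison:
    """Logistic contrast of group membership on scaled PRS + PC1-5.

    ``stratum`` restricts to one sex ("F"/"M"); "all" pools.  Raises
    :class:`ValidationError` on separation or non-convergence (PRS fits are
    one per contrast, so a failure is surfaced rather than flagged).
    """
    mask, y, names = _contrast_labels(dataset, contrast)
    if stratum != "all":
        sex = dataset.samples["sex"].to_numpy()
        keep = sex[mask] == stratum
        mask = mask & (sex == stratum)
        y = y[keep]
    if y.size == 0 or y.min() == y.max():
        raise ValidationError(f"both groups must be non-empty in stratum {stratum!r}")
    z = z_scores.to_numpy(dtype=float)[mask]
    pcs = dataset.pcs[mask]
    X = np.column_stack([np.ones_like(z), z, pcs])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValidationError(f"PRS contrast failed to fit: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ValidationError("PRS contrast did not converge")
    beta, se = float(res.params[1]), float(res.bse[1])
    zcrit = norm.ppf(0.975)
    return PRSComparison(
        contrast=names, include_apoe=include_apoe, stratum=stratum,
        or_per_sd=float(np.exp(beta)),
        ci95=(float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se))),
        p_value=float(res.pvalues[1]),
        n_a=int(y.sum()), n_b=int(y.size - y.sum()))


def prs_analysis(dataset: CohortDataset, panel: ReferencePanel,
                 contrasts=tuple(CONTRASTS),
                 by_sex: bool = False,
                 include_early_late: bool = True,
                 standardization_scope: str = "all") -> pd.DataFrame:
    """All pairwise contrasts x {with, without APOE} x strata, one table.

    The early-vs-late-onset sensitivity test (AD cases split at onset age
    <= 65) is appended when onset ages are available.
    """
    imputed = dataset.mean_imputed()
    strata = ["all"] + (["F", "M"] if by_sex else [])
    rows = []
    for include_apoe in (True, False):
        config = PRSConfig(include_apoe=include_apoe,
                           standardization_scope=standardization_scope)
        raw = compute_prs(imputed, panel, config)
        todo = list(contrasts)
        if include_early_late and not imputed.samples.loc[
                imputed.cohort_mask(AD), "onset_age"].isna().any():
            todo.append("early-vs-late")
        for contrast in todo:
            if standardization_scope == "contrast":
                scope, _, _ = _contrast_labels(imputed, contrast)
                z = standardize_prs(raw, scope)
            else:
                z = standardize_prs(raw)
            for stratum in strata:
                rows.append(compare_prs(z, imputed, contrast, stratum,
                                        include_apoe).to_dict())
    return pd.DataFrame(rows)
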