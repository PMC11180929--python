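"""Per-SNP logistic association, effect-size change, FDR, and sign test.

Every pairwise group contrast is an additive logistic regression of group
membership (the case-like group coded 1) on effect-allele dosage, adjusting
for the first five principal components of population stratification.  The
headline statistic is the *effect-size change*: the ratio of the observed
contrast log odds ratio to the reference clinical-discovery log odds ratio
for the same aligned effect allele,

    change = beta_obs / beta_clin.

change > 1 means the contrast amplifies the published effect (expected when
the control-like group is an extreme phenotype), 0 < change < 1 attenuation,
and change < 0 an opposite direction of effect.  A scan over the panel is
summarized by the median change and IQR, change-bin counts, and a one-tailed
binomial sign test on the number of SNPs with change > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationError)

from .io import (AD, AGE_MATCHED_CONTROL, CENTENARIAN, CohortDataset,
                 ReferencePanel, ValidationError)

#: Named contrasts: (case-like group coded 1, control-like group coded 0).
CONTRASTS = {
    "ad-vs-centenarian": (AD, CENTENARIAN),
    "ad-vs-control": (AD, AGE_MATCHED_CONTROL),
    "control-vs-centenarian": (AGE_MATCHED_CONTROL, CENTENARIAN),
}
#: Sensitivity contrast within AD cases, split at onset age <= 65.
EARLY_VS_LATE = "early-vs-late"
EARLY_ONSET_CUTOFF = 65.0


@dataclass(frozen=True)
class SNPFit:
    """Wald summary of one additive logistic fit (dosage coefficient)."""

    beta: float
    se: float
    p_value: float
    converged: bool
    message: str = ""


@dataclass
class ScanSummary:
    """Distributional summary of the change statistic over one scan.

    Boundary convention: change exactly 1 counts in the 0-1 bin and change
    exactly 0 in the opposite-direction bin (probability-zero events for
    continuous estimates).  The sign test is the exact upper-tail binomial
    probability of observing at least ``n_change_gt1`` of ``n_fit`` SNPs with
    change > 1 under a fair coin.
    """

    n_snps: int
    n_fit: int
    median_change: float
    iqr_change: tuple[float, float]
    n_change_gt1: int
    n_change_0_1: int
    n_change_lt0: int
    sign_test_p: float

    def to_dict(self) -> dict:
        return {
            "n_snps": self.n_snps, "n_fit": self.n_fit,
            "median_change": self.median_change,
            "iqr_change_low": self.iqr_change[0],
            "iqr_change_high": self.iqr_change[1],
            "n_change_gt1": self.n_change_gt1,
            "n_change_0_1": self.n_change_0_1,
            "n_change_lt0": self.n_change_lt0,
            "sign_test_p": self.sign_test_p,
        }


def fit_snp_logistic(dosage: np.ndarray, labels: np.ndarray,
                     covariates: np.ndarray | None = None) -> SNPFit:
    """Additive logistic fit of binary labels on dosage (+ covariates).

    Returns the maximum-likelihood dosage coefficient with Wald standard
    error and two-sided p-value.  Perfect separation, non-convergence, a
    constant dosage, or an empty group yield a flagged result (``converged``
    False, NaN estimates) rather than an exception, so scans can proceed.
    """
    y = np.asarray(labels, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if y.min() == y.max():
        return SNPFit(np.nan, np.nan, np.nan, False, "one group empty")
    if np.nanstd(d) == 0:
        return SNPFit(np.nan, np.nan, np.nan, False, "constant dosage")
    cols = [np.ones_like(d), d]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cols.extend(cov.T)
    X = np.column_stack(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return SNPFit(np.nan, np.nan, np.nan, False, type(exc).__name__)
    if not res.mle_retvals.get("converged", False):
        return SNPFit(np.nan, np.nan, np.nan, False, "did not converge")
    se = float(res.bse[1])
    if not np.isfinite(se) or se <= 0:
        return SNPFit(np.nan, np.nan, np.nan, False, "degenerate standard error")
    return SNPFit(float(res.params[1]), se, float(res.pvalues[1]), True)


def effect_size_change(beta_obs: float, beta_clin: float) -> float:
    """Ratio of the observed to the reference log odds ratio (aligned alleles).

    Undefined (NaN) when the reference effect is zero.
    """
    if beta_clin == 0 or not np.isfinite(beta_clin):
        return np.nan
    return float(beta_obs / beta_clin)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sign_test_binomial(k: int, n: int) -> float:
    """Exact one-tailed binomial probability P(X >= k), X ~ Binomial(n, 1/2)."""
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, 0.5))


def _contrast_labels(dataset: CohortDataset, contrast):
    """Resolve a contrast to (sample mask, binary labels, group names)."""
    if contrast == EARLY_VS_LATE:
        mask = dataset.cohort_mask(AD)
        onset = dataset.samples["onset_age"].to_numpy(dtype=float)
        if np.isnan(onset[mask]).any():
            raise ValidationError("early-vs-late requires onset_age for all AD cases")
        y = (onset <= EARLY_ONSET_CUTOFF)[mask]
        return mask, y.astype(float), ("EARLY_ONSET_AD", "LATE_ONSET_AD")
    if isinstance(contrast, str):
        try:
            group_a, group_b = CONTRASTS[contrast]
        except KeyError:
            raise ValidationError(
                f"unknown contrast {contrast!r}; expected one of "
                f"{sorted(CONTRASTS) + [EARLY_VS_LATE]}") from None
    else:
        group_a, group_b = contrast
    mask = dataset.cohort.isin([group_a, group_b]).to_numpy()
    if not dataset.cohort_mask(group_a).any() or not dataset.cohort_mask(group_b).any():
        raise ValidationError(f"contrast groups {group_a}/{group_b} not both present")
    y = (dataset.cohort[mask] == group_a).to_numpy(dtype=float)
    return mask, y, (group_a, group_b)


def run_pairwise_scan(dataset: CohortDataset, panel: ReferencePanel,
                      contrast) -> tuple[pd.DataFrame, ScanSummary]:
    """Fit every panel SNP for one group contrast and summarize the scan.

    ``contrast`` is a named contrast (``ad-vs-centenarian``, ``ad-vs-control``,
    ``control-vs-centenarian``, ``early-vs-late``) or an explicit
    ``(group_a, group_b)`` pair with the case-like group first.  Missing
    dosages are mean-imputed over the full loaded dataset before subsetting.
    BH-FDR q-values are computed per scan over the converged fits.
    """
    imputed = dataset.mean_imputed()
    mask, y, (name_a, name_b) = _contrast_labels(imputed, contrast)
    sub = imputed.subset(mask)
    pcs = sub.pcs
    n_a, n_b = int(y.sum()), int(len(y) - y.sum())
    rows = []
    for snp in panel:
        if snp.snp_id not in sub.dosage.columns:
            fit = SNPFit(np.nan, np.nan, np.nan, False, "SNP absent from dataset")
        else:
            fit = fit_snp_logistic(sub.dosage[snp.snp_id].to_numpy(), y, pcs)
        rows.append({
            "snp_id": snp.snp_id, "group_a": name_a, "group_b": name_b,
            "n_a": n_a, "n_b": n_b, "beta_obs": fit.beta, "se": fit.se,
            "p_value": fit.p_value,
            "change": effect_size_change(fit.beta, snp.beta_clin)
            if fit.converged else np.nan,
            "converged": fit.converged, "message": fit.message,
        })
    results = pd.DataFrame(rows)
    if not results["converged"].any():
        raise ValidationError("all panel SNPs failed to fit in this scan")
    q = np.full(len(results), np.nan)
    ok = results["converged"].to_numpy()
    q[ok] = bh_fdr(results.loc[ok, "p_value"].to_numpy())
    results.insert(results.columns.get_loc("p_value") + 1, "q_value", q)
    return results, summarize_scan(results)


def summarize_scan(results: pd.DataFrame) -> ScanSummary:
    """Change-statistic summary of one scan (converged fits only)."""
    changes = results.loc[results["converged"], "change"].dropna().to_numpy()
    n_fit = changes.size
    if n_fit == 0:
        raise ValidationError("no converged fits to summarize")
    lo, hi = np.percentile(changes, [25, 75])
    k_gt1 = int((changes > 1).sum())
    return ScanSummary(
        n_snps=int(len(results)), n_fit=n_fit,
        median_change=float(np.median(changes)),
        iqr_change=(float(lo), float(hi)),
        n_change_gt1=k_gt1,
        n_change_0_1=int(((changes > 0) & (changes <= 1)).sum()),
        n_change_lt0=int((changes <= 0).sum()),
        sign_test_p=sign_test_binomial(k_gt1, n_fit),
    )
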