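"""Case-control power, control-escalation, and centenarian equivalence.

The question answered here: for a SNP with a given allele frequency and true
allelic effect, how many controls of each type (age-matched vs extreme
super-controls) must be paired with a fixed number of cases for the additive
logistic test to reach a target power?  The ratio of the two requirements is
the per-SNP *equivalence ratio* — how many ordinary controls one
super-control is worth.

Analytic power is computed from the expected likelihood-ratio non-centrality
of the additive logistic test.  Under the generative model the control group
carries effect-allele frequency ``p0 = maf`` and the case group
``p1 = shifted_allele_freq(p0, exp(beta))``; genotypes are HWE within each
group.  With expected genotype counts ``w_yg = n_y * HWE_y(g)``, the
non-centrality is twice the expected log-likelihood gap between the fitted
additive model and the intercept-only null,

    ncp = 2 * (L(b0*, b1*) - L0),      power = P(chi2_1(ncp) > chi2_1,1-alpha)

where (b0*, b1*) maximize the expected log-likelihood (for exact-HWE cell
counts the additive model reproduces the cells and b1* equals the allelic
log odds ratio).  The same weighted-logistic Newton solver, applied to
*observed* multinomial genotype counts, yields a fast Monte-Carlo
likelihood-ratio test used to validate the analytic formula.

The escalation procedure scans controls in steps of 200 from 200 up to a cap
of twice the case count, returning the first count reaching the target
power, or the cap as a sentinel when no count converges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, ncx2

from .io import AGE_MATCHED_CONTROL, CENTENARIAN, ReferencePanel, ValidationError
from .simulate import shifted_allele_freq

_GENO = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class PowerQuery:
    """One analytic power evaluation / escalation request."""

    maf: float
    beta: float
    n_cases: int = 8000
    n_controls: int = 200
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValidationError("target_power must be in (0, 1)")


@dataclass(frozen=True)
class EscalationResult:
    """Outcome of the control-escalation procedure for one SNP arm."""

    snp_id: str | None
    control_type: str | None
    n_required: int  # smallest multiple of `step` reaching target, or the cap
    converged: bool
    cap: int
    power: float  # analytic power at n_required


@dataclass
class EquivalenceSummary:
    """Distribution of per-SNP equivalence ratios and the functional shortlist.

    ``ratios`` maps snp_id -> n_required(age-matched) / n_required(extreme),
    with the cap substituted for an arm that did not converge when the other
    did; SNPs converging in neither arm are excluded.  The shortlist holds
    SNPs whose ratio exceeds the threshold (default 2: one super-control
    worth more than two ordinary controls).
    """

    ratios: pd.Series
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]
    shortlist: list[str]
    n_excluded_nonconverged: int
    ratio_threshold: float = 2.0


def _hwe_probs(p):
    p = np.asarray(p, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)


def _fit_counts_logit(w1, w0, max_iter=60, tol=1e-12):
    """Newton fit of logistic y ~ genotype on 2x3 count tables (vectorized).

    ``w1``/``w0`` have shape (..., 3): counts (expected or observed) at
    genotypes 0/1/2 for the case and control group.  Returns
    ``(b0, b1, loglik)`` broadcast over the leading shape.  Tables with no
    genotype variation get b1 = 0, collapsing the LRT to zero.
    """
    w1 = np.asarray(w1, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    wt = w1 + w0
    n1 = w1.sum(-1)
    n0 = w0.sum(-1)
    b0 = np.log(n1 / n0)
    b1 = np.zeros_like(b0)
    for _ in range(max_iter):
        eta = b0[..., None] + b1[..., None] * _GENO
        mu = expit(eta)
        r = w1 - wt * mu
        s = wt * mu * (1 - mu)
        g0 = r.sum(-1)
        g1 = (r * _GENO).sum(-1)
        h00 = s.sum(-1)
        h01 = (s * _GENO).sum(-1)
        h11 = (s * _GENO ** 2).sum(-1)
        det = h00 * h11 - h01 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            db0 = (h11 * g0 - h01 * g1) / det
            db1 = (h00 * g1 - h01 * g0) / det
        ok = np.isfinite(db0) & np.isfinite(db1)
        db0 = np.where(ok, db0, 0.0)
        db1 = np.where(ok, db1, 0.0)
        b0 = b0 + db0
        b1 = b1 + db1
        if max(np.abs(db0).max(initial=0.0), np.abs(db1).max(initial=0.0)) < tol:
            break
    eta = b0[..., None] + b1[..., None] * _GENO
    loglik = (w1 * eta - wt * np.logaddexp(0.0, eta)).sum(-1)
    return b0, b1, loglik


def _null_loglik(n1, n0):
    n = n1 + n0
    return n1 * np.log(n1 / n) + n0 * np.log(n0 / n)


def analytic_power(maf, beta, n_cases, n_controls, alpha: float = 0.05):
    """Power of the additive logistic LRT via expected non-centrality.

    All arguments broadcast, so a whole escalation grid can be evaluated in
    one call.  At ``beta = 0`` the non-centrality vanishes and the power
    equals the test size ``alpha`` exactly.
    """
    maf = np.asarray(maf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    maf, beta, n_cases, n_controls = np.broadcast_arrays(maf, beta, n_cases,
                                                         n_controls)
    p1 = shifted_allele_freq(maf, np.exp(beta))
    w1 = n_cases[..., None] * _hwe_probs(p1)
    w0 = n_controls[..., None] * _hwe_probs(maf)
    _, _, l1 = _fit_counts_logit(w1, w0)
    l0 = _null_loglik(n_cases, n_controls)
    ncp = np.clip(2.0 * (l1 - l0), 0.0, None)
    crit = chi2.ppf(1.0 - alpha, 1)
    power = ncx2.sf(crit, 1, ncp)
    return float(power) if power.ndim == 0 else power


def mc_power(maf: float, beta: float, n_cases: int, n_controls: int,
             alpha: float = 0.05, n_reps: int = 20000,
             rng: np.random.Generator | int | None = None) -> float:
    """Monte-Carlo rejection rate of the additive logistic LRT.

    Independent validation route for :func:`analytic_power`: draws multinomial
    genotype counts per group under the same generative model, fits the
    additive logistic model to each replicate's observed counts, and counts
    likelihood-ratio p-values below ``alpha``.
    """
    rng = np.random.default_rng(rng)
    p1 = shifted_allele_freq(maf, float(np.exp(beta)))
    c1 = rng.multinomial(n_cases, _hwe_probs(p1), size=n_reps).astype(float)
    c0 = rng.multinomial(n_controls, _hwe_probs(maf), size=n_reps).astype(float)
    _, _, l1 = _fit_counts_logit(c1, c0)
    l0 = _null_loglik(float(n_cases), float(n_controls))
    lrt = np.clip(2.0 * (l1 - l0), 0.0, None)
    p = chi2.sf(lrt, 1)
    return float((p < alpha).mean())


def controls_needed(maf: float, beta: float, n_cases: int = 8000,
                    alpha: float = 0.05, target_power: float = 0.80,
                    step: int = 200, snp_id: str | None = None,
                    control_type: str | None = None) -> EscalationResult:
    """Smallest control count on the ``step`` grid reaching the target power.

    Scans ``step, 2*step, ...`` up to a cap of twice the case count; a SNP
    whose power never reaches the target is returned non-converged with the
    cap as sentinel count.
    """
    PowerQuery(maf=maf, beta=beta, n_cases=n_cases, alpha=alpha,
               target_power=target_power)  # validate
    cap = 2 * n_cases
    grid = np.arange(step, cap + 1, step)
    power = analytic_power(maf, beta, n_cases, grid, alpha)
    hit = power >= target_power
    if hit.any():
        idx = int(np.argmax(hit))
        return EscalationResult(snp_id, control_type, int(grid[idx]), True,
                                cap, float(power[idx]))
    return EscalationResult(snp_id, control_type, cap, False, cap,
                            float(power[-1]))


def direction_filter(scan_cc: pd.DataFrame, scan_cent: pd.DataFrame,
                     panel: ReferencePanel, maf_min: float = 0.01,
                     require_match_in: str = "both") -> list[str]:
    """Common SNPs whose observed effect direction matches the reference.

    Keeps panel SNPs with ``maf_ref > maf_min`` whose fitted ``beta_obs``
    agrees in sign with ``beta_clin`` in both scans (``require_match_in =
    "both"``) or in at least one (``"either"``).  Non-converged fits never
    match.
    """
    if require_match_in not in ("both", "either"):
        raise ValidationError("require_match_in must be 'both' or 'either'")
    cc = scan_cc.set_index("snp_id")
    cent = scan_cent.set_index("snp_id")
    keep = []
    for snp in panel:
        if snp.maf_ref <= maf_min:
            continue
        matches = []
        for scan in (cc, cent):
            if snp.snp_id not in scan.index or not bool(scan.loc[snp.snp_id, "converged"]):
                matches.append(False)
                continue
            b = float(scan.loc[snp.snp_id, "beta_obs"])
            matches.append(np.sign(b) == np.sign(snp.beta_clin) and b != 0)
        ok = all(matches) if require_match_in == "both" else any(matches)
        if ok:
            keep.append(snp.snp_id)
    return keep


def escalate_panel(panel: ReferencePanel, scan_cc: pd.DataFrame,
                   scan_cent: pd.DataFrame, eligible: list[str] | None = None,
                   n_cases: int = 8000, alpha: float = 0.05,
                   target_power: float = 0.80, step: int = 200) -> pd.DataFrame:
    """Run the escalation for both control types over the eligible SNPs.

    The assumed true effect per arm is the *observed* log odds ratio from the
    corresponding contrast (cases vs age-matched controls for the
    age-matched arm, cases vs centenarians for the centenarian arm); the
    allele frequency is the reference GWAS MAF.
    """
    if eligible is None:
        eligible = direction_filter(scan_cc, scan_cent, panel)
    cc = scan_cc.set_index("snp_id")
    cent = scan_cent.set_index("snp_id")
    rows = []
    for snp_id in eligible:
        snp = panel.get(snp_id)
        for control_type, scan in ((AGE_MATCHED_CONTROL, cc), (CENTENARIAN, cent)):
            beta = float(scan.loc[snp_id, "beta_obs"])
            res = controls_needed(snp.maf_ref, beta, n_cases, alpha,
                                  target_power, step, snp_id, control_type)
            rows.append({
                "snp_id": snp_id, "control_type": control_type,
                "maf_ref": snp.maf_ref, "beta_assumed": beta,
                "n_required": res.n_required, "converged": res.converged,
                "cap": res.cap, "power_at_n": res.power,
            })
    return pd.DataFrame(rows)


def equivalence_summary(escalations: pd.DataFrame,
                        ratio_threshold: float = 2.0) -> EquivalenceSummary:
    """Per-SNP equivalence ratios and the ratio-threshold shortlist.

    ``escalations`` is the tidy frame from :func:`escalate_panel` with both
    arms per SNP.  Ratio = required age-matched controls / required extreme
    controls; the sentinel cap stands in for a single non-converged arm, and
    SNPs non-converged in both arms are excluded from all summaries.
    """
    wide_n = escalations.pivot(index="snp_id", columns="control_type",
                               values="n_required")
    wide_c = escalations.pivot(index="snp_id", columns="control_type",
                               values="converged").astype(bool)
    for col in (AGE_MATCHED_CONTROL, CENTENARIAN):
        if col not in wide_n.columns:
            raise ValidationError(f"escalations must cover control type {col}")
    both_failed = ~wide_c[AGE_MATCHED_CONTROL] & ~wide_c[CENTENARIAN]
    included = wide_n.loc[~both_failed]
    if included.empty:
        raise ValidationError("no SNP converged in either arm")
    ratios = (included[AGE_MATCHED_CONTROL] / included[CENTENARIAN]).rename("ratio")
    lo, hi = np.percentile(ratios, [25, 75])
    shortlist = sorted(ratios.index[ratios > ratio_threshold])
    return EquivalenceSummary(
        ratios=ratios, mean=float(ratios.mean()), sd=float(ratios.std()),
        median=float(ratios.median()), iqr=(float(lo), float(hi)),
        shortlist=shortlist,
        n_excluded_nonconverged=int(both_failed.sum()),
        ratio_threshold=ratio_threshold)


def power_validation_grid(mafs=(0.05, 0.2, 0.4), ors=(1.1, 1.3, 2.0),
                          n_controls=(2000, 8000), n_cases: int = 2000,
                          alpha: float = 0.05, n_reps: int = 20000,
                          rng=None) -> pd.DataFrame:
    """Analytic-vs-Monte-Carlo power over a (maf, OR, n_controls) grid."""
    rng = np.random.default_rng(rng)
    rows = []
    for maf in mafs:
        for or_value in ors:
            for n_ctl in n_controls:
                beta = float(np.log(or_value))
                a = analytic_power(maf, beta, n_cases, n_ctl, alpha)
                m = mc_power(maf, beta, n_cases, n_ctl, alpha, n_reps, rng)
                rows.append({"maf": maf, "odds_ratio": or_value,
                             "n_cases": n_cases, "n_controls": n_ctl,
                             "analytic": float(a), "monte_carlo": m,
                             "abs_dev": abs(float(a) - m)})
    return pd.DataFrame(rows)
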