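"""Synthetic three-cohort genotype/phenotype generator.

The generator emulates the statistical structure the downstream analyses
assume: three cohorts (AD cases, age-matched controls, cognitively healthy
centenarians) genotyped on a fixed panel of independent SNPs, each SNP in
Hardy-Weinberg equilibrium within every cohort.

The generative model is allelic (per-allele odds), which keeps the truth
analytically available:

* age-matched controls draw effect-allele dosages at the panel frequency
  ``maf_ref``;
* cases draw at the frequency whose allelic odds ratio versus controls is
  ``exp(beta_clin) * case_or_multiplier``;
* centenarians draw at the frequency that makes the case-versus-centenarian
  allelic log odds ratio equal ``centenarian_change * beta_clin`` — i.e. the
  generator is parameterized directly through the effect-size-change statistic
  the association stage estimates, so parameter-recovery tests are
  self-calibrating.

Defaults mirror the study margins of the motivating design: 2281 cases /
3165 age-matched controls / 346 centenarians, female fractions 55/48/71 %,
and 971/2281 early-onset (age at onset <= 65) cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (AD, AGE_MATCHED_CONTROL, CENTENARIAN, COHORTS, PC_COLUMNS,
                 CohortDataset, ReferencePanel, ReferenceSNP, ValidationError)

#: Centenarian change factors for the two APOE SNPs that reproduce the
#: study-like carrier fractions (e4: 43/17/7 %, e2: 3/9/13 % across
#: cases/controls/centenarians) when combined with the default panel's
#: APOE maf_ref and beta_clin.
APOE_CENTENARIAN_CHANGES = {"rs429358": 1.8192, "rs7412": 1.3499}


@dataclass
class CohortSpec:
    """Study conditions for one simulated dataset.

    ``case_or_multiplier`` and ``centenarian_change`` accept either a single
    float applied to every SNP or a ``{snp_id: value}`` mapping (missing keys
    fall back to the scalar default).
    """

    n_cases: int = 2281
    n_controls: int = 3165
    n_centenarians: int = 346
    case_or_multiplier: float | Mapping[str, float] = 1.0
    centenarian_change: float | Mapping[str, float] = 2.0
    sex_fractions: Mapping[str, float] = field(default_factory=lambda: {
        AD: 0.55, AGE_MATCHED_CONTROL: 0.48, CENTENARIAN: 0.71})
    early_onset_fraction: float = 971 / 2281
    early_onset_window: tuple[float, float] = (45.0, 65.0)
    late_onset_window: tuple[float, float] = (66.0, 95.0)
    #: shift added to PC1 as +delta (cases) / 0 (controls) / -delta
    #: (centenarians); 0 = homogeneous population, no confounding.
    pc_confounding: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_centenarians"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.early_onset_fraction <= 1.0:
            raise ValidationError("early_onset_fraction must be in [0, 1]")


@dataclass
class SimulatedDataset:
    """A simulated cohort plus the per-SNP generative truth."""

    dataset: CohortDataset
    truth: pd.DataFrame  # indexed by snp_id


def shifted_allele_freq(p0, or_value):
    """Allele frequency whose allelic odds ratio versus ``p0`` is ``or_value``.

    Inverts ``OR = [p1/(1-p1)] / [p0/(1-p0)]``:
    ``p1 = OR * p0 / (1 + p0 * (OR - 1))``.  Vectorized.
    """
    p0 = np.asarray(p0, dtype=float)
    or_value = np.asarray(or_value, dtype=float)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValidationError("baseline frequency must be in (0, 1)")
    if np.any(or_value <= 0):
        raise ValidationError("odds ratio must be > 0")
    out = or_value * p0 / (1.0 + p0 * (or_value - 1.0))
    return float(out) if out.ndim == 0 else out


def sample_genotypes_hwe(freq: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` effect-allele dosages as Binomial(2, freq) (HWE hard calls)."""
    if not 0.0 < freq < 1.0:
        raise ValidationError(f"allele frequency must be in (0, 1), got {freq}")
    return rng.binomial(2, freq, size=n).astype(float)


def _per_snp(value, snp_id: str, default: float) -> float:
    if isinstance(value, Mapping):
        return float(value.get(snp_id, default))
    return float(value)


def group_frequencies(snp: ReferenceSNP, case_or_multiplier=1.0,
                      centenarian_change=2.0) -> tuple[float, float, float]:
    """Generative effect-allele frequencies (case, control, centenarian)."""
    p_ctl = snp.maf_ref
    p_case = shifted_allele_freq(p_ctl, np.exp(snp.beta_clin) * case_or_multiplier)
    p_cent = float(expit(logit(p_case) - centenarian_change * snp.beta_clin))
    for label, p in (("case", p_case), ("centenarian", p_cent)):
        if not 0.0 < p < 1.0 or not np.isfinite(p):
            raise ValidationError(
                f"{snp.snp_id}: implied {label} frequency {p} outside (0, 1) "
                f"(centenarian_change={centenarian_change}, "
                f"case_or_multiplier={case_or_multiplier})")
    return p_case, p_ctl, p_cent


def simulate_cohorts(panel: ReferencePanel, spec: CohortSpec) -> SimulatedDataset:
    """Draw a three-cohort dataset under the allelic HWE model.

    Seeded runs are bit-reproducible.  The returned truth table records the
    generative group frequencies and the implied pairwise log odds ratios.
    """
    if len(panel) == 0:
        raise ValidationError("panel must be non-empty")
    rng = np.random.default_rng(spec.seed)
    n_by_cohort = {AD: spec.n_cases, AGE_MATCHED_CONTROL: spec.n_controls,
                   CENTENARIAN: spec.n_centenarians}
    prefixes = {AD: "AD", AGE_MATCHED_CONTROL: "CTL", CENTENARIAN: "CENT"}
    sample_ids, cohorts = [], []
    for cohort in COHORTS:
        n = n_by_cohort[cohort]
        sample_ids += [f"{prefixes[cohort]}{i:05d}" for i in range(n)]
        cohorts += [cohort] * n
    index = pd.Index(sample_ids, name="sample_id")
    cohort_arr = np.asarray(cohorts)

    # genotypes: one frequency per SNP x cohort, HWE draws within cohort
    dosage = {}
    truth_rows = []
    for snp in panel:
        mult = _per_snp(spec.case_or_multiplier, snp.snp_id, 1.0)
        change = _per_snp(spec.centenarian_change, snp.snp_id, 2.0)
        p_case, p_ctl, p_cent = group_frequencies(snp, mult, change)
        col = np.empty(len(index))
        for cohort, p in ((AD, p_case), (AGE_MATCHED_CONTROL, p_ctl),
                          (CENTENARIAN, p_cent)):
            m = cohort_arr == cohort
            if m.any():
                col[m] = sample_genotypes_hwe(p, int(m.sum()), rng)
        dosage[snp.snp_id] = col
        truth_rows.append({
            "snp_id": snp.snp_id, "freq_case": p_case, "freq_control": p_ctl,
            "freq_centenarian": p_cent,
            "logor_case_control": float(logit(p_case) - logit(p_ctl)),
            "logor_case_centenarian": float(logit(p_case) - logit(p_cent)),
            "logor_control_centenarian": float(logit(p_ctl) - logit(p_cent)),
            "change_target": change, "case_or_multiplier": mult,
        })
    dosage_df = pd.DataFrame(dosage, index=index)
    truth = pd.DataFrame(truth_rows).set_index("snp_id")

    # phenotypes / covariates
    sex = np.empty(len(index), dtype=object)
    for cohort in COHORTS:
        m = cohort_arr == cohort
        f = spec.sex_fractions.get(cohort, 0.5)
        sex[m] = np.where(rng.random(int(m.sum())) < f, "F", "M")
    onset = np.full(len(index), np.nan)
    m_ad = cohort_arr == AD
    if m_ad.any():
        n_ad = int(m_ad.sum())
        early = rng.random(n_ad) < spec.early_onset_fraction
        lo_e, hi_e = spec.early_onset_window
        lo_l, hi_l = spec.late_onset_window
        ages = np.where(early, rng.uniform(lo_e, hi_e, n_ad),
                        rng.uniform(lo_l, hi_l, n_ad))
        onset[m_ad] = ages
    pcs = rng.standard_normal((len(index), 5))
    if spec.pc_confounding:
        shift = {AD: 1.0, AGE_MATCHED_CONTROL: 0.0, CENTENARIAN: -1.0}
        pcs[:, 0] += spec.pc_confounding * np.vectorize(shift.get)(cohort_arr)

    samples = pd.DataFrame({"cohort": cohort_arr, "sex": sex, "onset_age": onset},
                           index=index)
    samples[list(PC_COLUMNS)] = pcs
    return SimulatedDataset(CohortDataset(samples, dosage_df), truth)


# ---------------------------------------------------------------------------
# Default panel
# ---------------------------------------------------------------------------

def default_panel(n_snps: int = 86, seed: int = 2024,
                  include_apoe: bool = True) -> ReferencePanel:
    """A deterministic synthetic reference panel of AD-GWAS-like SNPs.

    The panel stands in for a published supplementary SNP table, which cannot
    be redistributed here; it is synthetic but calibrated to the field's
    margins.  It contains the two APOE haplotype SNPs with maf_ref/beta_clin
    solved from realistic carrier fractions (e4 risk, e2 protective), plus
    ``n_snps - 2`` synthetic loci whose clinical-discovery odds ratios span
    the range typical of common AD hits (common SNPs OR 1.08-1.30, a minority
    of low-frequency SNPs OR 1.25-1.9, mixed effect directions).  ``beta_meta``
    is an attenuated copy of ``beta_clin`` (proxy-phenotype dilution in the
    meta-analysis weights).
    """
    rng = np.random.default_rng(seed)
    snps: list[ReferenceSNP] = []
    if include_apoe:
        snps.append(ReferenceSNP(
            snp_id="rs429358", chrom="19", pos=44908684, effect_allele="C",
            other_allele="T", maf_ref=0.0890, beta_clin=1.1944,
            beta_meta=1.05, is_apoe=True))
        snps.append(ReferenceSNP(
            snp_id="rs7412", chrom="19", pos=44908822, effect_allele="T",
            other_allele="C", maf_ref=0.0461, beta_clin=-1.1463,
            beta_meta=-0.80, is_apoe=True))
    n_rest = max(n_snps - len(snps), 0)
    bases = np.array(list("ACGT"))
    n_rare = max(int(round(n_rest * 0.15)), 0)
    for i in range(n_rest):
        rare = i < n_rare
        maf = float(rng.uniform(0.01, 0.05)) if rare \
            else float(rng.uniform(0.05, 0.5))
        or_mag = float(rng.uniform(1.25, 1.9)) if rare \
            else float(rng.uniform(1.08, 1.30))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        beta_clin = sign * np.log(or_mag)
        beta_meta = beta_clin * float(rng.uniform(0.6, 0.9))
        ea, oa = rng.choice(bases, size=2, replace=False)
        snps.append(ReferenceSNP(
            snp_id=f"rs{9000001 + i}", chrom=str(1 + i % 22),
            pos=int(rng.integers(1_000_000, 240_000_000)),
            effect_allele=str(ea), other_allele=str(oa), maf_ref=maf,
            beta_clin=float(beta_clin), beta_meta=float(beta_meta)))
    return ReferencePanel(snps, name=f"synthetic-ad-panel-{n_snps}")


def null_spec(panel: ReferencePanel, **overrides) -> CohortSpec:
    """A :class:`CohortSpec` under which all three cohorts share frequencies.

    Expressed through the generator's own knobs: per-SNP
    ``case_or_multiplier = exp(-beta_clin)`` cancels the case shift and
    ``centenarian_change = 0`` pins centenarians to the case frequency.
    """
    mult = {s.snp_id: float(np.exp(-s.beta_clin)) for s in panel}
    return CohortSpec(case_or_multiplier=mult, centenarian_change=0.0,
                      **overrides)
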