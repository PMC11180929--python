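"""Reference SNP panels, cohort genotype data, and result-table input/output.

The analyses in this package revolve around a fixed panel of disease-associated
SNPs with published reference effect sizes, applied to a three-cohort
extreme-phenotype design (cases, age-matched controls, and cognitively healthy
centenarians used as super-controls).  This module defines the two central
containers — :class:`ReferencePanel` and :class:`CohortDataset` — and the
plain-text formats they travel in:

* reference panel: TSV with columns ``snp_id, chrom, pos, effect_allele,
  other_allele, maf_ref, beta_clin, beta_meta, is_apoe``;
* genotypes: VCF with a per-sample ``DS`` (dosage) FORMAT field, or a TSV
  matrix (rows = samples, columns = snp_id);
* sample table: TSV with ``sample_id, cohort, sex, onset_age, pc1..pc5``.

Genotypes are represented as continuous effect-allele dosages in [0, 2]
(imputed data), with NaN as the missing marker; hard calls are a special case.
Allele alignment uses exact string matching in either orientation — there is
deliberately no reverse-complement rescue, since silent strand flips are the
dominant corruption risk when both sides of the exchange use the same panel.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cohort labels used throughout the package.
AD = "AD"
AGE_MATCHED_CONTROL = "AGE_MATCHED_CONTROL"
CENTENARIAN = "CENTENARIAN"
COHORTS = (AD, AGE_MATCHED_CONTROL, CENTENARIAN)

#: The two APOE haplotype-defining SNPs (epsilon-4 and epsilon-2).
APOE_SNP_IDS = ("rs429358", "rs7412")

PANEL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "maf_ref", "beta_clin", "beta_meta", "is_apoe",
]

SAMPLE_COLUMNS = ["sample_id", "cohort", "sex", "onset_age",
                  "pc1", "pc2", "pc3", "pc4", "pc5"]
PC_COLUMNS = ["pc1", "pc2", "pc3", "pc4", "pc5"]


class FormatError(ValueError):
    """A file does not conform to the declared dialect (missing columns etc.)."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a domain invariant."""


class AlleleMismatchError(ValueError):
    """Observed allele pair matches the reference pair in neither orientation."""


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSNP:
    """One disease-associated variant with its reference effect sizes.

    ``beta_clin`` is the log odds ratio from the clinical-discovery case-control
    comparison (the yardstick for the effect-size-change statistic);
    ``beta_meta`` is the meta-analysis log odds ratio used as the PRS weight.
    Both are per copy of ``effect_allele``.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf_ref: float
    beta_clin: float
    beta_meta: float
    is_apoe: bool = False

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if not (0.0 < self.maf_ref <= 0.5):
            raise ValidationError(
                f"{self.snp_id}: maf_ref must be in (0, 0.5], got {self.maf_ref!r}")
        if not self.effect_allele or not self.other_allele:
            raise ValidationError(f"{self.snp_id}: alleles must be non-empty")
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.snp_id}: effect_allele equals other_allele "
                f"({self.effect_allele!r})")
        if int(self.pos) < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1 (1-based)")
        for name in ("maf_ref", "beta_clin", "beta_meta"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{self.snp_id}: {name} must be finite")


class ReferencePanel:
    """Ordered, uniquely-keyed collection of :class:`ReferenceSNP`.

    A panel that declares APOE must contain exactly the two APOE SNPs flagged;
    a panel with no ``is_apoe`` rows is also valid (APOE-free sub-panels).
    """

    def __init__(self, snps: Iterable[ReferenceSNP], name: str = ""):
        snps = list(snps)
        ids = [s.snp_id for s in snps]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicated snp_id in panel: {sorted(dupes)}")
        n_apoe = sum(s.is_apoe for s in snps)
        if n_apoe not in (0, 2):
            raise ValidationError(
                f"panel must flag exactly 0 or 2 APOE SNPs, found {n_apoe}")
        self.snps: list[ReferenceSNP] = snps
        self.name = name
        self._by_id: dict[str, ReferenceSNP] = {s.snp_id: s for s in snps}

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[ReferenceSNP]:
        return iter(self.snps)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def get(self, snp_id: str) -> ReferenceSNP:
        return self._by_id[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def apoe_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps if s.is_apoe]

    def subset(self, snp_ids: Sequence[str], name: str | None = None) -> "ReferencePanel":
        """Sub-panel restricted to ``snp_ids``, preserving panel order."""
        keep = set(snp_ids)
        missing = keep - set(self.snp_ids)
        if missing:
            raise KeyError(f"snp_ids not in panel: {sorted(missing)}")
        sub = [s for s in self.snps if s.snp_id in keep]
        # drop a dangling single APOE flag in a sub-panel
        if sum(s.is_apoe for s in sub) == 1:
            sub = [replace(s, is_apoe=False) for s in sub]
        return ReferencePanel(sub, name=name if name is not None else self.name)

    def without_apoe(self) -> "ReferencePanel":
        return ReferencePanel([s for s in self.snps if not s.is_apoe],
                              name=self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
            "effect_allele": s.effect_allele, "other_allele": s.other_allele,
            "maf_ref": s.maf_ref, "beta_clin": s.beta_clin,
            "beta_meta": s.beta_meta, "is_apoe": int(s.is_apoe),
        } for s in self.snps], columns=PANEL_COLUMNS)

    @property
    def beta_clin(self) -> pd.Series:
        return pd.Series({s.snp_id: s.beta_clin for s in self.snps}, name="beta_clin")

    @property
    def beta_meta(self) -> pd.Series:
        return pd.Series({s.snp_id: s.beta_meta for s in self.snps}, name="beta_meta")

    @property
    def maf_ref(self) -> pd.Series:
        return pd.Series({s.snp_id: s.maf_ref for s in self.snps}, name="maf_ref")


_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no", ""}


def _parse_bool(raw: str) -> bool:
    low = str(raw).strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"cannot parse boolean from {raw!r}")


def read_reference_table(path: str | Path, name: str | None = None) -> ReferencePanel:
    """Read and validate a reference panel TSV.

    Raises :class:`FormatError` on missing columns and :class:`ValidationError`
    with 1-based data-row numbers for rows violating panel invariants.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    snps, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            snps.append(ReferenceSNP(
                snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                maf_ref=float(row.maf_ref), beta_clin=float(row.beta_clin),
                beta_meta=float(row.beta_meta), is_apoe=_parse_bool(row.is_apoe)))
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return ReferencePanel(snps, name=name if name is not None else path.stem)


def write_reference_table(panel: ReferencePanel, path: str | Path) -> Path:
    path = Path(path)
    panel.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# Cohort dataset
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """Dosage matrix plus per-sample phenotype/covariate table.

    ``samples``: DataFrame indexed by sample_id with columns ``cohort``
    (one of ``AD``, ``AGE_MATCHED_CONTROL``, ``CENTENARIAN``), ``sex``
    (``F``/``M``), ``onset_age`` (years; NaN outside AD), ``pc1..pc5``.

    ``dosage``: float DataFrame on the same index, one column per panel SNP,
    values in [0, 2] counting copies of the panel's effect allele, NaN missing.
    """

    samples: pd.DataFrame
    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.dosage.index):
            raise ValidationError("samples and dosage must share the same index")
        if not self.samples.index.is_unique:
            raise ValidationError("sample_id index must be unique")
        missing_cols = [c for c in ("cohort", "sex", "onset_age", *PC_COLUMNS)
                        if c not in self.samples.columns]
        if missing_cols:
            raise ValidationError(f"sample table missing columns {missing_cols}")
        bad = set(self.samples["cohort"]) - set(COHORTS)
        if bad:
            raise ValidationError(f"unknown cohort labels {sorted(bad)}")
        vals = self.dosage.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 2)):
                raise ValidationError("dosage values outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def cohort(self) -> pd.Series:
        return self.samples["cohort"]

    @property
    def pcs(self) -> np.ndarray:
        return self.samples[list(PC_COLUMNS)].to_numpy(dtype=float)

    def cohort_mask(self, label: str) -> np.ndarray:
        return (self.samples["cohort"] == label).to_numpy()

    def counts(self) -> dict[str, int]:
        return {c: int((self.samples["cohort"] == c).sum()) for c in COHORTS}

    def mean_imputed(self) -> "CohortDataset":
        """Fill missing dosages with the per-SNP mean over the full dataset."""
        if not self.dosage.isna().any().any():
            return self
        filled = self.dosage.fillna(self.dosage.mean(axis=0))
        return CohortDataset(self.samples, filled)

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortDataset":
        if isinstance(mask, pd.Series):
            mask = mask.to_numpy()
        return CohortDataset(self.samples.loc[mask], self.dosage.loc[mask])


def read_sample_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str,
                                            "sex": str}, na_values=["NA", ""])
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicated sample_id {dup[:5]}")
    bad = set(df["cohort"]) - set(COHORTS)
    if bad:
        raise ValidationError(f"{path}: unknown cohort labels {sorted(bad)}")
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValidationError(f"{path}: sex must be F or M, found {sorted(bad_sex)}")
    df = df.set_index("sample_id")
    df["onset_age"] = pd.to_numeric(df["onset_age"], errors="raise")
    for c in PC_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return df


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

def align_to_effect_allele(record_alleles: tuple[str, str],
                           record_dosage,
                           ref: ReferenceSNP):
    """Re-express a dosage as copies of the panel's effect allele.

    ``record_alleles`` is ``(counted_allele, other_allele)`` where
    ``record_dosage`` counts copies of the first element (for VCF input the
    counted allele is ALT).  Matching is exact in either orientation; a swap
    maps ``d`` to ``2 - d``.  Aligning twice is the identity.
    """
    a, b = record_alleles
    if (a, b) == (ref.effect_allele, ref.other_allele):
        return record_dosage
    if (a, b) == (ref.other_allele, ref.effect_allele):
        return 2.0 - np.asarray(record_dosage) if not np.isscalar(record_dosage) \
            else 2.0 - record_dosage
    raise AlleleMismatchError(
        f"{ref.snp_id}: observed alleles {a}/{b} match reference "
        f"{ref.effect_allele}/{ref.other_allele} in neither orientation")


# ---------------------------------------------------------------------------
# Genotype readers / writers
# ---------------------------------------------------------------------------

def _read_vcf_dosages(path: Path, panel: ReferencePanel) -> pd.DataFrame:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for variant in vcf:
        vid = variant.ID
        if vid is None or vid not in panel:
            continue
        ref_snp = panel.get(vid)
        ds = variant.format("DS")
        if ds is None:
            raise FormatError(f"{path}: record {vid} lacks a DS FORMAT field")
        d = np.asarray(ds, dtype=float).reshape(len(sample_ids), -1)[:, 0]
        d = np.where(np.isfinite(d) & (d >= 0), d, np.nan)  # negative = missing
        alt = variant.ALT[0] if variant.ALT else ""
        try:
            aligned = align_to_effect_allele((alt, variant.REF), d, ref_snp)
        except AlleleMismatchError:
            dropped.append(vid)
            continue
        columns[vid] = np.asarray(aligned, dtype=float)
    vcf.close()
    if dropped:
        logger.warning("dropped %d SNP(s) with unalignable alleles: %s",
                       len(dropped), dropped)
    df = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    return df


def _read_tsv_dosages(path: Path, panel: ReferencePanel) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    keep = [c for c in df.columns if c in panel]
    extra = [c for c in df.columns if c not in panel]
    if extra:
        logger.warning("ignoring %d dosage column(s) not in panel: %s",
                       len(extra), extra[:5])
    # TSV matrices are declared pre-aligned: columns count the effect allele.
    return df[keep].astype(float)


def read_dosages(path: str | Path, panel: ReferencePanel,
                 samples_path: str | Path) -> CohortDataset:
    """Load genotypes (VCF with DS field, or TSV matrix) plus the sample table.

    The result is restricted to panel SNPs present in the genotype file; panel
    SNPs absent from the file are reported with a warning.  Every genotyped
    sample must appear in the sample table.
    """
    path = Path(path)
    samples = read_sample_table(samples_path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        dosage = _read_vcf_dosages(path, panel)
    else:
        dosage = _read_tsv_dosages(path, panel)
    vals = dosage.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((vals < 0) | (vals > 2)):
            raise ValidationError(f"{path}: dosage values outside [0, 2]")
    unmatched = [s for s in panel.snp_ids if s not in dosage.columns]
    if unmatched:
        logger.warning("%d panel SNP(s) absent from %s: %s",
                       len(unmatched), path.name, unmatched[:10])
    missing_samples = [s for s in dosage.index if s not in samples.index]
    if missing_samples:
        raise ValidationError(
            f"samples genotyped but absent from sample table: {missing_samples[:5]}")
    return CohortDataset(samples.loc[dosage.index], dosage)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description='
    '"Estimated effect-allele dosage in [0,2]">\n'
)


def write_vcf_dosages(dataset: CohortDataset, panel: ReferencePanel,
                      path: str | Path) -> Path:
    """Write the dataset as a plain-text VCF with a DS FORMAT field.

    REF is the panel's other allele and ALT the effect allele, so the written
    dosages count ALT copies and the file round-trips through
    :func:`read_dosages` without sign flips.
    """
    path = Path(path)
    sample_ids = list(dataset.samples.index)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for snp in panel:
            if snp.snp_id not in dataset.dosage.columns:
                continue
            d = dataset.dosage[snp.snp_id].to_numpy(dtype=float)
            cells = [("." if not np.isfinite(x) else f"{x:.6g}") for x in d]
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.other_allele}"
                     f"\t{snp.effect_allele}\t.\tPASS\t.\tDS\t"
                     + "\t".join(cells) + "\n")
    return path


def write_sample_table(dataset: CohortDataset, path: str | Path) -> Path:
    path = Path(path)
    dataset.samples.reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
    return path


def write_dataset(dataset: CohortDataset, out_dir: str | Path,
                  panel: ReferencePanel | None = None,
                  fmt: str = "tsv") -> dict[str, str]:
    """Write genotypes + sample table in the formats :func:`read_dosages` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    if fmt == "vcf":
        if panel is None:
            raise ValueError("VCF output requires the panel (alleles/positions)")
        files["dosages"] = str(write_vcf_dosages(dataset, panel, out_dir / "dosages.vcf"))
    elif fmt == "tsv":
        p = out_dir / "dosages.tsv"
        dataset.dosage.to_csv(p, sep="\t", float_format="%.10g", na_rep="NA")
        files["dosages"] = str(p)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    files["samples"] = str(write_sample_table(dataset, out_dir / "samples.tsv"))
    return files


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  summary: Mapping | None = None,
                  overwrite: bool = False) -> dict:
    """Write one TSV per named table plus a machine-readable run summary.

    Float formatting is fixed (``%.10g``) so identical inputs reproduce
    byte-identical tables.  Raises ``FileExistsError`` on collision unless
    ``overwrite`` is set.  Returns a manifest with per-file sha256 checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "summary": dict(summary or {})}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path),
                                   "n_rows": int(len(df))}
    summary_path = out_dir / "run_summary.json"
    if summary_path.exists() and not overwrite:
        raise FileExistsError(f"{summary_path} exists (pass overwrite=True)")
    with open(summary_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["summary_path"] = str(summary_path)
    return manifest
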