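"""Input/output and quality control for the screening pipeline.

Reads multi-sample VCFs (via :mod:`cyvcf2`) into a dense dosage matrix with
per-call GQ/DP, reads phenotype and variant-annotation TSVs, and applies
the screen's QC contract: per-genotype GQ >= 20 and DP >= 10 (failing calls
become missing, never deleted), variant rarity (reference-population allele
frequency strictly below 1%), and consequence-class filtering (missense /
loss-of-function by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeData",
    "VcfParseError",
    "PhenotypeError",
    "read_vcf",
    "read_phenotypes",
    "read_annotation",
    "parse_apoe",
    "apply_genotype_qc",
    "filter_by_reference_af",
    "filter_by_consequence",
    "load_qc_config",
    "KNOWN_CONSEQUENCES",
    "DEFAULT_CONSEQUENCES",
]

#: recognized consequence-class labels
KNOWN_CONSEQUENCES = frozenset(
    {
        "missense",
        "LOF",
        "synonymous",
        "splice_region",
        "inframe_indel",
        "UTR",
        "intronic",
        "intergenic",
    }
)

#: default "potentially damaging" classes retained by the screen
DEFAULT_CONSEQUENCES = frozenset({"missense", "LOF"})

_VALID_APOE_ALLELES = {"e2", "e3", "e4"}
_PHENO_COLUMNS = [
    "sample_id",
    "family_id",
    "cohort",
    "apoe",
    "diagnosis",
    "age",
    "sex",
    "ancestry",
]
_ANNOT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence", "ref_af"]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class PhenotypeError(ValueError):
    """Raised for an invalid phenotype table."""


@dataclass
class GenotypeData:
    """Dense biallelic genotype matrix with per-call quality fields.

    ``variants`` has columns chrom, pos (1-based), ref, alt, variant_id;
    ``dosage`` is (n_variants, n_samples) with values {0, 1, 2} and -1 for
    missing; ``gq`` and ``dp`` are the per-call quality and depth.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    gq: np.ndarray
    dp: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "GenotypeData":
        return GenotypeData(
            variants=self.variants.copy(),
            samples=list(self.samples),
            dosage=self.dosage.copy(),
            gq=self.gq.copy(),
            dp=self.dp.copy(),
        )

    def subset_variants(self, keep: np.ndarray | pd.Index | list) -> "GenotypeData":
        """Restrict to the given variant_ids (order preserved from self)."""
        ids = set(keep)
        mask = self.variants.variant_id.isin(ids).to_numpy()
        return GenotypeData(
            variants=self.variants.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[mask],
            gq=self.gq[mask],
            dp=self.dp[mask],
        )


def read_vcf(path: str | Path) -> GenotypeData:
    """Read a VCF v4.2 into a :class:`GenotypeData`.

    Multi-allelic rows are split into biallelic records; per-sample dosage
    is recomputed per alternate allele.  Genotypes containing any missing
    allele (``./.`` and half-calls such as ``0/.``) are treated as missing.
    Missing GQ/DP fields are read as 0 (they then fail the QC thresholds).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    dosages = []
    gqs = []
    dps = []
    n_rec = 0
    try:
        vcf = VCF(str(path), gts012=False)
        samples = list(vcf.samples)
        for v in vcf:
            n_rec += 1
            if samples:
                gts = np.array([gt[:2] for gt in v.genotypes], dtype=int)
            else:
                gts = np.empty((0, 2), dtype=int)
            gq = _format_field(v, "GQ", len(samples))
            dp = _format_field(v, "DP", len(samples))
            missing = (gts < 0).any(axis=1)
            for ai, alt in enumerate(v.ALT):
                dose = (gts == ai + 1).sum(axis=1).astype(np.int8)
                dose[missing] = -1
                rows.append(
                    {
                        "chrom": str(v.CHROM),
                        "pos": int(v.POS),
                        "ref": v.REF,
                        "alt": alt,
                    }
                )
                dosages.append(dose)
                gqs.append(gq)
                dps.append(dp)
    except FileNotFoundError:
        raise
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise VcfParseError(f"{path}: parse failure at record {n_rec + 1}: {exc}") from exc
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    variants["variant_id"] = (
        variants.chrom
        + ":"
        + variants.pos.astype(str)
        + ":"
        + variants.ref
        + ":"
        + variants.alt
    )
    n = len(variants)
    return GenotypeData(
        variants=variants,
        samples=samples,
        dosage=np.vstack(dosages) if n else np.empty((0, len(samples)), dtype=np.int8),
        gq=np.vstack(gqs) if n else np.empty((0, len(samples)), dtype=np.int16),
        dp=np.vstack(dps) if n else np.empty((0, len(samples)), dtype=np.int32),
    )


def _format_field(v, key: str, n_samples: int) -> np.ndarray:
    arr = v.format(key)
    if arr is None:
        return np.zeros(n_samples, dtype=np.int32)
    out = np.asarray(arr).reshape(n_samples, -1)[:, 0].astype(np.int64)
    out[out < 0] = 0  # cyvcf2 missing-value sentinels are negative
    return out.astype(np.int32)


def parse_apoe(s: str) -> tuple[str, str]:
    """Parse an APOE genotype string like ``'e3/e4'`` into an allele pair."""
    parts = str(s).strip().lower().replace("ε", "e").split("/")
    if len(parts) != 2 or not set(parts) <= _VALID_APOE_ALLELES:
        raise PhenotypeError(f"unknown APOE genotype string: {s!r}")
    a, b = sorted(parts)
    return a, b


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate the phenotype TSV.

    Required columns: sample_id, family_id, cohort, apoe, diagnosis, age,
    sex, ancestry.  APOE strings are validated and normalized, duplicate
    sample ids and non-positive ages are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str})
    missing = [c for c in _PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"{path}: missing columns {missing}")
    dup = df.sample_id[df.sample_id.duplicated()]
    if len(dup):
        raise PhenotypeError(
            f"{path}: duplicate sample_id {dup.iloc[0]!r} (row {int(dup.index[0]) + 2})"
        )
    for idx, s in df.apoe.items():
        try:
            a, b = parse_apoe(s)
        except PhenotypeError as exc:
            raise PhenotypeError(f"{path}: row {int(idx) + 2}: {exc}") from exc
        df.at[idx, "apoe"] = f"{a}/{b}"
    bad_age = df.age.notna() & (df.age <= 0)
    if bad_age.any():
        row = int(np.flatnonzero(bad_age)[0])
        raise PhenotypeError(f"{path}: row {row + 2}: non-positive age")
    bad_dx = ~df.diagnosis.isin(["AD", "control", "unknown"])
    if bad_dx.any():
        row = int(np.flatnonzero(bad_dx)[0])
        raise PhenotypeError(f"{path}: row {row + 2}: unknown diagnosis")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the variant annotation TSV (chrom pos ref alt gene consequence ref_af)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["variant_id"] = (
        df.chrom + ":" + df.pos.astype(int).astype(str) + ":" + df.ref + ":" + df.alt
    )
    return df


def apply_genotype_qc(
    gd: GenotypeData, gq_min: int = 20, dp_min: int = 10
) -> GenotypeData:
    """Set calls with GQ < gq_min or DP < dp_min to missing (thresholds inclusive).

    Idempotent: GQ/DP fields are preserved, only the dosage is masked.
    """
    if gq_min < 0 or dp_min < 0:
        raise ValueError("QC thresholds must be non-negative")
    out = gd.copy()
    fail = (gd.gq < gq_min) | (gd.dp < dp_min)
    out.dosage[fail] = -1
    return out


def filter_by_reference_af(
    annotation: pd.DataFrame, max_af: float = 0.01
) -> pd.DataFrame:
    """Keep variants with reference-population AF strictly below ``max_af``.

    Missing ref_af is treated as 0 (the variant is kept) with a warning:
    rare alleles absent from reference panels should not be discarded by
    the rarity filter.
    """
    af = annotation.ref_af
    n_missing = int(af.isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} variants lack ref_af; treated as 0 (kept)", stacklevel=2
        )
    return annotation.loc[af.fillna(0.0) < max_af].reset_index(drop=True)


def filter_by_consequence(
    annotation: pd.DataFrame, allowed=DEFAULT_CONSEQUENCES
) -> pd.DataFrame:
    """Keep variants whose consequence class is in ``allowed``.

    Variants with an unrecognized class label are dropped with a warning.
    """
    allowed = frozenset(allowed)
    unknown = ~annotation.consequence.isin(KNOWN_CONSEQUENCES)
    if unknown.any():
        labels = sorted(annotation.consequence[unknown].unique())
        warnings.warn(
            f"dropping {int(unknown.sum())} variants with unknown consequence "
            f"labels {labels}",
            stacklevel=2,
        )
    keep = annotation.consequence.isin(allowed & KNOWN_CONSEQUENCES)
    return annotation.loc[keep].reset_index(drop=True)


def load_qc_config(path: str | Path) -> dict:
    """Load QC settings from YAML (keys qc.gq_min, qc.dp_min, qc.max_ref_af,
    qc.consequences); absent keys take the screen's defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    qc = raw.get("qc", {})
    return {
        "gq_min": int(qc.get("gq_min", 20)),
        "dp_min": int(qc.get("dp_min", 10)),
        "max_ref_af": float(qc.get("max_ref_af", 0.01)),
        "consequences": frozenset(qc.get("consequences", DEFAULT_CONSEQUENCES)),
    }
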