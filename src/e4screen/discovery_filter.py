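"""The segregation cascade: candidate protective variants from a QC'd cohort.

Applied to rare, potentially damaging variants in a stratified cohort, the
cascade keeps a variant when (1) its alternate allele is absent from all
APOE e4 non-carriers, (2) it is carried by at least the configured fraction
(default 1%) of cognitively unaffected elderly e4 homozygotes, and (3) it
has carrier support in cognitively unaffected elderly heterozygotes.
Absence from e4-carrier AD cases is then applied either as a hard filter or
as a tier ranking (tier 1: absent in all e4 AD cases; tier 2: absent in
e4/4 AD cases only; tier 3: otherwise) -- mirroring a screen in which case
absence is a prioritization rather than an exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from e4screen.cohort_io import GenotypeData
from e4screen.stratification import (
    MAF_COLUMNS,
    align_phenotypes,
    assign_strata,
    stratum_allele_counts,
    _chrom_sort_key,
)

__all__ = [
    "CascadeConfig",
    "CascadeResult",
    "StratumError",
    "noncarrier_absence",
    "elderly_hom_carrier_fraction",
    "case_absence_flags",
    "run_cascade",
]

_CASE_ABSENCE_MODES = ("hard_all_e4_AD", "hard_hom_AD_only", "rank_only")


class StratumError(RuntimeError):
    """Raised when a stratum required by the cascade has no samples."""


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable gates of the segregation cascade."""

    min_elderly_hom_carrier_fraction: float = 0.01
    require_het_support: bool = True
    case_absence_mode: str = "hard_hom_AD_only"
    per_cohort: bool = True
    age_hom: float = 70
    age_het: float = 80
    strict_age: bool = False

    def __post_init__(self):
        if not 0.0 <= self.min_elderly_hom_carrier_fraction <= 1.0:
            raise ValueError("min_elderly_hom_carrier_fraction must lie in [0, 1]")
        if self.case_absence_mode not in _CASE_ABSENCE_MODES:
            raise ValueError(f"case_absence_mode must be one of {_CASE_ABSENCE_MODES}")


@dataclass
class CascadeResult:
    """Candidates per cohort plus (in per-cohort mode) their intersection."""

    candidates: pd.DataFrame  # pooled or concatenated per-cohort candidates
    per_cohort: dict[str, pd.DataFrame]
    intersection: pd.DataFrame  # variants present in every cohort's list


def noncarrier_absence(dosage_row: np.ndarray, noncarriers: np.ndarray) -> bool:
    """True iff the alt allele count is zero among genotyped e4 non-carriers."""
    d = np.asarray(dosage_row)[np.asarray(noncarriers, dtype=bool)]
    return int(d[d >= 0].sum()) == 0


def elderly_hom_carrier_fraction(
    dosage_row: np.ndarray, elderly_healthy_hom: np.ndarray
) -> float | None:
    """Carrier-individual fraction in the elderly unaffected e4/4 stratum.

    Individual-level (carriers / genotyped), not an allele frequency;
    ``None`` when nobody in the stratum was genotyped.
    """
    d = np.asarray(dosage_row)[np.asarray(elderly_healthy_hom, dtype=bool)]
    d = d[d >= 0]
    if d.size == 0:
        return None
    return float((d >= 1).sum() / d.size)


def case_absence_flags(
    dosage_row: np.ndarray, strata: dict[str, np.ndarray]
) -> tuple[bool, bool]:
    """(absent_in_hom_AD, absent_in_all_e4_AD) over genotyped AD carriers."""

    def absent(mask: np.ndarray) -> bool:
        d = np.asarray(dosage_row)[mask]
        return int(d[d >= 0].sum()) == 0

    absent_hom = absent(strata["hom_AD"])
    absent_all = absent_hom and absent(strata["het_AD"])
    return absent_hom, absent_all


def _cascade_one(
    gd: GenotypeData,
    pheno: pd.DataFrame,
    annotation: pd.DataFrame | None,
    config: CascadeConfig,
    cohort_mask: np.ndarray,
) -> pd.DataFrame:
    strata = {
        name: mask & cohort_mask
        for name, mask in assign_strata(
            pheno, age_hom=config.age_hom, age_het=config.age_het,
            strict_age=config.strict_age,
        ).items()
    }
    required = ["noncarrier", "elderly_healthy_hom"]
    if config.require_het_support:
        required.append("elderly_healthy_het")
    for name in required:
        if not strata[name].any():
            raise StratumError(f"required stratum {name!r} has no samples")

    gene = None
    if annotation is not None:
        gene = annotation.set_index("variant_id").gene.to_dict()

    rows = []
    for i, vid in enumerate(gd.variants.variant_id):
        dose = gd.dosage[i]
        if not noncarrier_absence(dose, strata["noncarrier"]):
            continue
        frac = elderly_hom_carrier_fraction(dose, strata["elderly_healthy_hom"])
        if frac is None or frac < config.min_elderly_hom_carrier_fraction:
            continue
        het_counts = stratum_allele_counts(
            vid, dose, strata["elderly_healthy_het"], "elderly_healthy_het"
        )
        het_support = het_counts.n_carriers >= 1
        if config.require_het_support and not het_support:
            continue
        absent_hom, absent_all = case_absence_flags(dose, strata)
        if config.case_absence_mode == "hard_all_e4_AD" and not absent_all:
            continue
        if config.case_absence_mode == "hard_hom_AD_only" and not absent_hom:
            continue
        tier = 1 if absent_all else (2 if absent_hom else 3)
        rec = {
            "variant_id": vid,
            "chrom": gd.variants.chrom.iloc[i],
            "pos": int(gd.variants.pos.iloc[i]),
            "gene": gene.get(vid, "") if gene else "",
            "tier": tier,
            "elderly_hom_fraction": frac,
            "het_support": het_support,
            "absent_in_noncarriers": True,
            "absent_in_hom_AD": absent_hom,
            "absent_in_all_e4_AD": absent_all,
        }
        for name in MAF_COLUMNS:
            sc = stratum_allele_counts(vid, dose, strata[name], name)
            rec[f"maf_{name}"] = np.nan if sc.maf is None else 100.0 * sc.maf
        rows.append(rec)

    columns = [
        "variant_id", "chrom", "pos", "gene", "tier", "elderly_hom_fraction",
        "het_support", "absent_in_noncarriers", "absent_in_hom_AD",
        "absent_in_all_e4_AD",
    ] + [f"maf_{name}" for name in MAF_COLUMNS]
    out = pd.DataFrame(rows, columns=columns)
    if out.empty:
        return out
    out["_ck"] = out.chrom.map(_chrom_sort_key)
    out = (
        out.sort_values(
            ["tier", "elderly_hom_fraction", "_ck", "pos"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    return out


def run_cascade(
    gd: GenotypeData,
    samples: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Run the segregation cascade on a QC'd, variant-filtered cohort.

    Inputs are expected to be genotype-QC'd and restricted to rare,
    potentially damaging variants (see :mod:`e4screen.cohort_io`).  In
    per-cohort mode the cascade runs independently within each cohort and
    additionally reports the variants found in every cohort.
    """
    config = config or CascadeConfig()
    pheno = align_phenotypes(gd, samples)
    cohorts = sorted(pheno.cohort.unique()) if config.per_cohort else ["__pooled__"]
    per_cohort: dict[str, pd.DataFrame] = {}
    for cohort in cohorts:
        mask = (
            np.ones(len(pheno), dtype=bool)
            if cohort == "__pooled__"
            else (pheno.cohort.to_numpy() == cohort)
        )
        per_cohort[cohort] = _cascade_one(gd, pheno, annotation, config, mask)

    frames = [
        df.assign(cohort=c) for c, df in per_cohort.items() if not df.empty
    ]
    candidates = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["variant_id", "cohort", "tier"])
    )
    if len(per_cohort) > 1:
        common = set.intersection(
            *(set(df.variant_id) for df in per_cohort.values())
        )
        inter = candidates.loc[
            candidates.variant_id.isin(common)
        ].drop_duplicates("variant_id")
    else:
        inter = next(iter(per_cohort.values()))
    return CascadeResult(
        candidates=candidates, per_cohort=per_cohort, intersection=inter
    )
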