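"""APOE x diagnosis x age strata and per-stratum allele-frequency tables.

The screen stratifies every cohort into seven groups: cognitively
unaffected "elderly" e4 homozygotes (age >= 70 at last examination) and
heterozygotes (age >= 80), all unaffected homozygotes/heterozygotes, AD
cases by e4 dosage (onset ages, no age floor), and e4 non-carriers.  The
frequency table reports, per variant and cohort, the minor allele
frequency in each of the six e4-carrier strata: alt alleles over twice the
number of successfully genotyped individuals in the stratum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from e4screen.cohort_io import GenotypeData, parse_apoe

log = logging.getLogger(__name__)

__all__ = [
    "StratumDefinition",
    "StratumCounts",
    "e4_dosage",
    "default_strata",
    "assign_strata",
    "stratum_allele_counts",
    "frequency_table",
    "align_phenotypes",
    "MAF_COLUMNS",
]

#: canonical ordering of the six carrier-stratum MAF columns
MAF_COLUMNS = [
    "elderly_healthy_hom",
    "all_healthy_hom",
    "hom_AD",
    "elderly_healthy_het",
    "all_healthy_het",
    "het_AD",
]


@dataclass(frozen=True)
class StratumDefinition:
    """One stratum: e4 dosage, diagnosis (None = any), optional age floor."""

    name: str
    e4_dosage: int
    diagnosis: str | None
    min_age: float | None = None

    def __post_init__(self):
        if self.min_age is not None and self.min_age < 0:
            raise ValueError("min_age must be >= 0")


@dataclass(frozen=True)
class StratumCounts:
    """Allele counts for one variant in one stratum."""

    variant_id: str
    stratum: str
    n_genotyped: int
    n_carriers: int
    alt_alleles: int
    maf: float | None  # None when no individual was genotyped

    def __post_init__(self):
        if not 0 <= self.n_carriers <= self.n_genotyped:
            raise ValueError("carrier count outside [0, n_genotyped]")
        if not self.n_carriers <= self.alt_alleles <= 2 * self.n_carriers:
            raise ValueError("alt_alleles inconsistent with carrier count")

    @property
    def maf_percent(self) -> float | None:
        return None if self.maf is None else 100.0 * self.maf


def _norm_allele(a) -> str:
    s = str(a).strip().lower().replace("ε", "e")
    if not s.startswith("e"):
        s = "e" + s
    if s not in {"e2", "e3", "e4"}:
        raise ValueError(f"unknown APOE allele: {a!r}")
    return s


def e4_dosage(apoe) -> int:
    """Number of e4 alleles in an APOE genotype (string ``'e3/e4'`` or pair)."""
    pair = parse_apoe(apoe) if isinstance(apoe, str) else tuple(apoe)
    if len(pair) != 2:
        raise ValueError("APOE genotype must have exactly two alleles")
    return sum(1 for a in pair if _norm_allele(a) == "e4")


def default_strata(age_hom: float = 70, age_het: float = 80) -> list[StratumDefinition]:
    """The screen's seven strata (six carrier strata + non-carriers)."""
    return [
        StratumDefinition("elderly_healthy_hom", 2, "control", age_hom),
        StratumDefinition("all_healthy_hom", 2, "control", None),
        StratumDefinition("hom_AD", 2, "AD", None),
        StratumDefinition("elderly_healthy_het", 1, "control", age_het),
        StratumDefinition("all_healthy_het", 1, "control", None),
        StratumDefinition("het_AD", 1, "AD", None),
        StratumDefinition("noncarrier", 0, None, None),
    ]


def assign_strata(
    samples: pd.DataFrame,
    defs: list[StratumDefinition] | None = None,
    age_hom: float = 70,
    age_het: float = 80,
    strict_age: bool = False,
) -> dict[str, np.ndarray]:
    """Map each sample to every stratum whose predicate it satisfies.

    Ages are floored to whole years before comparison with the (inclusive)
    threshold; ``strict_age=True`` switches to a strict ``>`` comparison.
    Samples with unknown diagnosis are excluded from diagnosis-conditioned
    strata (logged).
    """
    if defs is None:
        defs = default_strata(age_hom, age_het)
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("stratum names must be distinct")
    dosage = samples.apoe.map(e4_dosage).to_numpy()
    dx = samples.diagnosis.to_numpy()
    n_unknown = int((~np.isin(dx, ["AD", "control"])).sum())
    if n_unknown:
        log.info("%d samples with unknown diagnosis excluded from diagnosis strata", n_unknown)
    age = np.floor(samples.age.to_numpy(dtype=float))
    out: dict[str, np.ndarray] = {}
    for d in defs:
        mask = dosage == d.e4_dosage
        if d.diagnosis is not None:
            mask &= dx == d.diagnosis
        if d.min_age is not None:
            mask &= (age > d.min_age) if strict_age else (age >= d.min_age)
        out[d.name] = mask
    return out


def stratum_allele_counts(
    variant_id: str, dosage_row: np.ndarray, members: np.ndarray, stratum: str = ""
) -> StratumCounts:
    """Allele counts over the non-missing genotypes of one stratum.

    MAF = alt alleles / (2 x genotyped individuals); undefined (None, not 0)
    when the stratum has no genotyped individual.
    """
    d = np.asarray(dosage_row)[np.asarray(members, dtype=bool)]
    d = d[d >= 0]
    n_gt = int(d.size)
    alt = int(d.sum())
    return StratumCounts(
        variant_id=variant_id,
        stratum=stratum,
        n_genotyped=n_gt,
        n_carriers=int((d >= 1).sum()),
        alt_alleles=alt,
        maf=None if n_gt == 0 else alt / (2 * n_gt),
    )


def align_phenotypes(gd: GenotypeData, samples: pd.DataFrame) -> pd.DataFrame:
    """Reorder the phenotype table to the genotype sample order."""
    pheno = samples.set_index("sample_id", drop=False)
    missing = [s for s in gd.samples if s not in pheno.index]
    if missing:
        raise ValueError(f"samples missing from phenotype table: {missing[:5]}")
    return pheno.loc[gd.samples].reset_index(drop=True)


def frequency_table(
    gd: GenotypeData,
    samples: pd.DataFrame,
    age_hom: float = 70,
    age_het: float = 80,
    strict_age: bool = False,
    percent: bool = True,
) -> pd.DataFrame:
    """Per-variant, per-cohort MAFs in the six carrier strata.

    One row per (cohort, variant), ordered by (cohort, chrom, pos); MAFs in
    percent by default (NaN where the stratum has no genotyped individual).
    """
    pheno = align_phenotypes(gd, samples)
    strata = assign_strata(pheno, age_hom=age_hom, age_het=age_het, strict_age=strict_age)
    scale = 100.0 if percent else 1.0
    frames = []
    for cohort in sorted(pheno.cohort.unique()):
        in_cohort = pheno.cohort.to_numpy() == cohort
        rows = []
        for i, vid in enumerate(gd.variants.variant_id):
            rec = {"cohort": cohort, "variant_id": vid,
                   "chrom": gd.variants.chrom.iloc[i], "pos": int(gd.variants.pos.iloc[i])}
            for name in MAF_COLUMNS:
                sc = stratum_allele_counts(vid, gd.dosage[i], strata[name] & in_cohort, name)
                rec[f"maf_{name}"] = math.nan if sc.maf is None else scale * sc.maf
                rec[f"n_{name}"] = sc.n_genotyped
            rows.append(rec)
        frames.append(pd.DataFrame(rows))
    out = pd.concat(frames, ignore_index=True)
    chrom_key = out.chrom.map(_chrom_sort_key)
    return (
        out.assign(_ck=chrom_key)
        .sort_values(["cohort", "_ck", "pos"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )


def _chrom_sort_key(c: str) -> tuple[int, str]:
    c = str(c).removeprefix("chr")
    return (int(c), "") if c.isdigit() else (10**6, c)
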