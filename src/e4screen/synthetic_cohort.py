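"""Family-based cohort simulator for APOE-stratified protective-variant screens.

The generator emulates the study design of multiplex late-onset Alzheimer's
disease (AD) family cohorts: nuclear families with two founders and a
variable number of offspring, Mendelian transmission of APOE (e2/e3/e4)
and of rare coding variants, an e4-dosage-dependent AD liability with a
planted protective effect among e4 carriers, an age-at-onset delay per
protective allele, and per-genotype sequencing-quality fields (GQ/DP) at
~30x mean depth with a configurable fraction of sub-threshold calls.

The planted protective variant resides on e4 haplotype backgrounds and is
transmitted together with APOE (complete linkage).  This is the generative
counterpart of the screen's premise: a variant that segregates with e4 in
families and is therefore absent from e4 non-carriers.  Background neutral
variants are unlinked loci in Hardy-Weinberg proportions; they provide the
negatives the discovery cascade must reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from e4screen.cohort_io import GenotypeData

__all__ = [
    "SimConfig",
    "SimTruth",
    "Cohort",
    "ConfigError",
    "sample_founders",
    "transmit_alleles",
    "ad_probability",
    "assign_phenotype",
    "simulate_cohort",
    "simulate_homozygote_panel",
    "write_cohort",
]

#: internal codes for APOE alleles
_APOE_CODES = np.array([2, 3, 4], dtype=np.int8)

#: genomic anchor for the planted protective site (an FN1-like autosomal
#: missense position); background sites are scattered over the autosomes.
_PLANTED_CHROM = "2"
_PLANTED_POS = 216_225_163
_PLANTED_REF = "C"
_PLANTED_ALT = "T"
_PLANTED_GENE = "FN1"
_PLANTED_REF_AF = 0.0046  # reference-population (gnomAD-style) AF

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic family cohort.

    Defaults describe a multiplex-AD-family cohort: e4-enriched APOE allele
    frequencies, roughly half the sample affected, late onset with earlier
    onset per e4 allele, and a rare (<1%) protective allele on e4 haplotypes
    whose effect sizes match the screen's replication estimates
    (odds ratio 0.29 per allele among e4 carriers, +3.37 years of onset
    delay per allele).
    """

    seed: int = 0
    n_families: int = 400
    offspring_per_family: tuple[int, int] = (2, 6)
    #: allele frequencies of (e2, e3, e4); e4-enriched as in AD families
    apoe_allele_freqs: tuple[float, float, float] = (0.05, 0.60, 0.35)
    #: founder population frequency of the planted protective allele
    protective_af: float = 0.008
    #: multiplicative odds effect per protective allele among e4 carriers
    protective_or: float = 0.29
    #: AD probability at reference age for e4 dosage 0 / 1 / 2
    baseline_risk_by_dosage: tuple[float, float, float] = (0.15, 0.35, 0.55)
    #: mean age at onset (years) for e4 dosage 0 / 1 / 2
    aao_mean_by_dosage: tuple[float, float, float] = (78.0, 73.0, 68.0)
    #: onset delay (years) per protective allele
    aao_delay_per_allele: float = 3.37
    aao_sd: float = 6.0
    #: mean sequencing depth (reads); per-call DP ~ Poisson(mean_depth)
    mean_depth: float = 30.0
    #: per-call GQ ~ round(Normal(mean, sd)) clipped to [0, 99]
    gq_distribution: tuple[float, float] = (85.0, 10.0)
    #: fraction of genotype calls degraded below the GQ/DP thresholds
    qc_fail_fraction: float = 0.02
    #: censoring-age range (years) for unaffected individuals
    censor_age_range: tuple[float, float] = (60.0, 95.0)
    #: number of unlinked neutral background sites
    n_background: int = 200
    #: background site allele frequencies drawn log-uniform in this range
    background_af_range: tuple[float, float] = (1e-4, 9e-3)
    #: optional ascertainment: resample a family until it has at least this
    #: many affected members (0 disables ascertainment)
    min_affected_per_family: int = 0
    cohort_name: str = "SIM"
    ancestry: str = "EUR"

    def validate(self) -> None:
        f = np.asarray(self.apoe_allele_freqs, dtype=float)
        if f.shape != (3,) or np.any(f < 0) or np.any(f > 1):
            raise ConfigError("apoe_allele_freqs must be three probabilities")
        if not math.isclose(float(f.sum()), 1.0, abs_tol=1e-9):
            raise ConfigError("apoe_allele_freqs must sum to 1")
        if not 0.0 <= self.protective_af <= 1.0:
            raise ConfigError("protective_af must lie in [0, 1]")
        if self.protective_af > 0 and f[2] == 0:
            raise ConfigError("protective_af > 0 requires a nonzero e4 frequency")
        if self.protective_af > f[2]:
            raise ConfigError("protective_af may not exceed the e4 allele frequency")
        if self.protective_or <= 0:
            raise ConfigError("protective_or must be positive")
        if self.aao_sd <= 0:
            raise ConfigError("aao_sd must be positive")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ConfigError("qc_fail_fraction must lie in [0, 1]")
        lo, hi = self.offspring_per_family
        if lo < 0 or hi < lo:
            raise ConfigError("offspring_per_family must satisfy 0 <= min <= max")
        for p in self.baseline_risk_by_dosage:
            if not 0.0 < p < 1.0:
                raise ConfigError("baseline risks must lie strictly in (0, 1)")
        a_lo, a_hi = self.censor_age_range
        if not 0 < a_lo <= a_hi:
            raise ConfigError("censor_age_range must be positive and ordered")

    @property
    def e4_hap_carrier_prob(self) -> float:
        """Probability that an e4 haplotype carries the protective allele."""
        f4 = self.apoe_allele_freqs[2]
        return 0.0 if self.protective_af == 0 else self.protective_af / f4


@dataclass
class Haplotypes:
    """Phased genotypes for a set of individuals.

    ``apoe``: (n, 2) APOE allele codes in {2, 3, 4}; ``prot``: (n, 2)
    protective-allele indicator attached to the corresponding APOE
    haplotype; ``bg``: (n, n_background, 2) background-site alleles.
    """

    apoe: np.ndarray
    prot: np.ndarray
    bg: np.ndarray

    @property
    def n(self) -> int:
        return self.apoe.shape[0]

    @property
    def e4_dosage(self) -> np.ndarray:
        return (self.apoe == 4).sum(axis=1).astype(np.int8)

    @property
    def prot_dosage(self) -> np.ndarray:
        return self.prot.sum(axis=1).astype(np.int8)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort."""

    planted_variant_id: str
    planted_dosage: pd.Series  # indexed by sample_id
    protective_or: float
    aao_delay_per_allele: float
    background_variant_ids: tuple[str, ...]
    background_afs: tuple[float, ...]


@dataclass
class Cohort:
    """A simulated cohort: phenotypes, genotypes and variant annotation."""

    phenotypes: pd.DataFrame
    genotypes: GenotypeData
    annotation: pd.DataFrame
    name: str = "SIM"


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    # counter-keyed substreams: reproducible regardless of processing order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def sample_founders(
    config: SimConfig,
    rng: np.random.Generator,
    n: int = 2,
    bg_afs: np.ndarray | None = None,
) -> Haplotypes:
    """Draw ``n`` unrelated founders.

    Each founder receives two APOE alleles drawn independently from
    ``apoe_allele_freqs``; e4 haplotypes carry the protective allele with
    probability ``protective_af / freq(e4)`` so the unconditional allele
    frequency equals ``protective_af``.  Background sites are in
    Hardy-Weinberg proportions at ``bg_afs`` (drawn from
    ``background_af_range`` if not supplied).
    """
    config.validate()
    if bg_afs is None:
        bg_afs = draw_background_afs(config, rng)
    apoe = _APOE_CODES[rng.choice(3, size=(n, 2), p=np.asarray(config.apoe_allele_freqs))]
    prot = np.zeros((n, 2), dtype=np.int8)
    c = config.e4_hap_carrier_prob
    if c > 0:
        is_e4 = apoe == 4
        prot[is_e4] = rng.random(int(is_e4.sum())) < c
    bg = (rng.random((n, len(bg_afs), 2)) < bg_afs[None, :, None]).astype(np.int8)
    return Haplotypes(apoe=apoe, prot=prot, bg=bg)


def draw_background_afs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.background_af_range
    if config.n_background == 0:
        return np.empty(0)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_background))


def transmit_alleles(
    parents: Haplotypes, n_offspring: int, rng: np.random.Generator
) -> Haplotypes:
    """Mendelian transmission from a parent pair to ``n_offspring`` children.

    Each child receives one uniformly chosen haplotype per parent per locus,
    independently across loci.  APOE and the attached protective allele are
    one linked block; background loci segregate independently.
    """
    if parents.n != 2:
        raise ValueError("transmit_alleles expects exactly two parents")
    n_bg = parents.bg.shape[1]
    # haplotype choice per child per parent for the APOE block
    apoe_pick = rng.integers(0, 2, size=(n_offspring, 2))
    apoe = np.stack(
        [parents.apoe[p, apoe_pick[:, p]] for p in (0, 1)], axis=1
    )
    prot = np.stack(
        [parents.prot[p, apoe_pick[:, p]] for p in (0, 1)], axis=1
    )
    # independent choices per background locus
    bg_pick = rng.integers(0, 2, size=(n_offspring, n_bg, 2))
    bg = np.stack(
        [parents.bg[p][np.arange(n_bg)[None, :], bg_pick[:, :, p]] for p in (0, 1)],
        axis=2,
    )
    return Haplotypes(apoe=apoe.astype(np.int8), prot=prot.astype(np.int8), bg=bg)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def ad_probability(e4_dosage, prot_dosage, config: SimConfig) -> np.ndarray:
    """AD probability under the liability model.

    ``P(AD) = expit(logit(b_d) + k ln(OR) 1[d>=1])``: each protective allele
    multiplies the disease odds by ``protective_or``, among e4 carriers only.
    """
    d = np.asarray(e4_dosage, dtype=int)
    k = np.asarray(prot_dosage, dtype=float)
    base = np.asarray(config.baseline_risk_by_dosage)[d]
    eta = _logit(base) + k * np.log(config.protective_or) * (d >= 1)
    return 1.0 / (1.0 + np.exp(-eta))


def assign_phenotype(
    e4_dosage: np.ndarray,
    prot_dosage: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign (diagnosis, age) given APOE-e4 and protective-allele dosages.

    The liability model is ``P(AD) = expit(logit(b_d) + k ln(OR) 1[d>=1])``
    with ``b_d`` the baseline risk at e4 dosage ``d`` and ``k`` the
    protective dosage.  Affected individuals receive an onset age
    ``Normal(mu_d + k * delta, sd)``; unaffected individuals a censoring age
    uniform over ``censor_age_range``.  Ages are strictly positive.
    """
    d = np.asarray(e4_dosage, dtype=int)
    k = np.asarray(prot_dosage, dtype=float)
    p_ad = ad_probability(d, k, config)
    affected = rng.random(d.shape) < p_ad
    mu = np.asarray(config.aao_mean_by_dosage)[d] + k * config.aao_delay_per_allele
    onset = rng.normal(mu, config.aao_sd)
    censor = rng.uniform(*config.censor_age_range, size=d.shape)
    age = np.where(affected, onset, censor)
    age = np.maximum(age, 1.0)
    diagnosis = np.where(affected, "AD", "control")
    return diagnosis, age


def _simulate_family(
    config: SimConfig, bg_afs: np.ndarray, rng: np.random.Generator
) -> tuple[Haplotypes, np.ndarray, np.ndarray, np.ndarray]:
    """One nuclear family, with optional >=k-affected ascertainment."""
    for _ in range(1000):
        founders = sample_founders(config, rng, n=2, bg_afs=bg_afs)
        lo, hi = config.offspring_per_family
        n_off = int(rng.integers(lo, hi + 1))
        kids = transmit_alleles(founders, n_off, rng)
        haps = Haplotypes(
            apoe=np.concatenate([founders.apoe, kids.apoe]),
            prot=np.concatenate([founders.prot, kids.prot]),
            bg=np.concatenate([founders.bg, kids.bg]),
        )
        diagnosis, age = assign_phenotype(haps.e4_dosage, haps.prot_dosage, config, rng)
        if (diagnosis == "AD").sum() >= config.min_affected_per_family:
            sex = np.where(rng.random(haps.n) < 0.5, "F", "M")
            return haps, diagnosis, age, sex
    raise RuntimeError("ascertainment filter rejected 1000 consecutive families")


def _apoe_string(pair: np.ndarray) -> str:
    a, b = sorted(int(x) for x in pair)
    return f"e{a}/e{b}"


def _variant_table(config: SimConfig, bg_afs: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Planted + background variant records, sorted by genome coordinate."""
    n_bg = len(bg_afs)
    chroms = rng.integers(1, 23, size=n_bg).astype(str)
    pos = rng.integers(1_000_000, 240_000_000, size=n_bg)
    ref_i = rng.integers(0, 4, size=n_bg)
    alt_i = (ref_i + rng.integers(1, 4, size=n_bg)) % 4
    consequence = rng.choice(
        ["missense", "synonymous", "LOF"], size=n_bg, p=[0.7, 0.2, 0.1]
    )
    rows = pd.DataFrame(
        {
            "chrom": np.concatenate([[_PLANTED_CHROM], chroms]),
            "pos": np.concatenate([[_PLANTED_POS], pos]).astype(np.int64),
            "ref": np.concatenate([[_PLANTED_REF], _BASES[ref_i]]),
            "alt": np.concatenate([[_PLANTED_ALT], _BASES[alt_i]]),
            "gene": [_PLANTED_GENE] + [f"GENE{i:04d}" for i in range(n_bg)],
            "consequence": np.concatenate([["missense"], consequence]),
            "ref_af": np.concatenate([[_PLANTED_REF_AF], bg_afs]),
            "planted": [True] + [False] * n_bg,
        }
    )
    rows["variant_id"] = (
        rows.chrom + ":" + rows.pos.astype(str) + ":" + rows.ref + ":" + rows.alt
    )
    order = np.lexsort((rows.pos.to_numpy(), rows.chrom.astype(int).to_numpy()))
    return rows.iloc[order].reset_index(drop=True)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Simulate a full cohort; deterministic given ``config`` (incl. seed).

    Returns the cohort (phenotype table, genotype matrix with GQ/DP, and a
    variant annotation table) together with the ground truth needed to
    evaluate downstream recovery.
    """
    config.validate()
    bg_afs = draw_background_afs(config, _rng_for(config.seed, 0))
    variants = _variant_table(config, bg_afs, _rng_for(config.seed, 3))

    fam_haps: list[Haplotypes] = []
    records: list[dict] = []
    for i in range(config.n_families):
        rng = _rng_for(config.seed, 1, i)
        haps, diagnosis, age, sex = _simulate_family(config, bg_afs, rng)
        fam_id = f"{config.cohort_name}_F{i + 1:04d}"
        for j in range(haps.n):
            records.append(
                {
                    "sample_id": f"{fam_id}_S{j + 1:02d}",
                    "family_id": fam_id,
                    "cohort": config.cohort_name,
                    "apoe": _apoe_string(haps.apoe[j]),
                    "diagnosis": diagnosis[j],
                    "age": float(age[j]),
                    "sex": sex[j],
                    "ancestry": config.ancestry,
                }
            )
        fam_haps.append(haps)

    pheno_columns = [
        "sample_id", "family_id", "cohort", "apoe", "diagnosis", "age", "sex", "ancestry",
    ]
    phenotypes = pd.DataFrame.from_records(records, columns=pheno_columns)
    samples = phenotypes.sample_id.tolist()

    if fam_haps:
        prot_dosage = np.concatenate([h.prot_dosage for h in fam_haps])
        bg_dosage = np.concatenate([h.bg.sum(axis=2) for h in fam_haps])  # (n, n_bg)
    else:
        prot_dosage = np.zeros(0, dtype=np.int8)
        bg_dosage = np.zeros((0, len(bg_afs)), dtype=np.int8)

    # variant x sample dosage matrix in annotation (coordinate) order
    n_var, n_samp = len(variants), len(samples)
    dosage = np.empty((n_var, n_samp), dtype=np.int8)
    planted_row = int(np.flatnonzero(variants.planted.to_numpy())[0])
    bg_rows = np.flatnonzero(~variants.planted.to_numpy())
    dosage[planted_row] = prot_dosage
    # background variants keep their generation order within the table
    bg_order = variants.loc[~variants.planted, "gene"].str.slice(4).astype(int).to_numpy()
    dosage[bg_rows] = bg_dosage[:, bg_order].T

    qc_rng = _rng_for(config.seed, 2)
    dp = qc_rng.poisson(config.mean_depth, size=(n_var, n_samp)).astype(np.int32)
    gq_mu, gq_sd = config.gq_distribution
    gq = np.clip(np.rint(qc_rng.normal(gq_mu, gq_sd, size=(n_var, n_samp))), 0, 99).astype(
        np.int16
    )
    if config.qc_fail_fraction > 0:
        fail = qc_rng.random((n_var, n_samp)) < config.qc_fail_fraction
        # degrade (never delete) the failing calls: half below the GQ
        # threshold, half below the DP threshold
        which = qc_rng.random((n_var, n_samp)) < 0.5
        gq_fail = fail & which
        dp_fail = fail & ~which
        gq[gq_fail] = qc_rng.integers(0, 20, size=int(gq_fail.sum()))
        dp[dp_fail] = qc_rng.integers(0, 10, size=int(dp_fail.sum()))

    genotypes = GenotypeData(
        variants=variants[["chrom", "pos", "ref", "alt", "variant_id"]].copy(),
        samples=samples,
        dosage=dosage,
        gq=gq,
        dp=dp,
    )
    annotation = variants[
        ["chrom", "pos", "ref", "alt", "gene", "consequence", "ref_af", "variant_id"]
    ].copy()

    planted_id = variants.loc[variants.planted, "variant_id"].iloc[0]
    truth = SimTruth(
        planted_variant_id=planted_id,
        planted_dosage=pd.Series(prot_dosage, index=samples, name="dosage"),
        protective_or=config.protective_or,
        aao_delay_per_allele=config.aao_delay_per_allele,
        background_variant_ids=tuple(
            variants.loc[~variants.planted, "variant_id"].tolist()
        ),
        background_afs=tuple(bg_afs[bg_order].tolist()) if len(bg_rows) else (),
    )
    cohort = Cohort(
        phenotypes=phenotypes,
        genotypes=genotypes,
        annotation=annotation,
        name=config.cohort_name,
    )
    return cohort, truth


def simulate_homozygote_panel(
    n: int,
    config: SimConfig | None = None,
    seed: int | None = None,
    carrier_hap_prob: float | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` unrelated APOE e4/4 individuals for effect-recovery checks.

    Protective dosage is Hardy-Weinberg at the per-haplotype carrier
    probability among e4 haplotypes; status and ages follow the same
    liability / onset model as the cohort generator.  Returns a data frame
    with columns ``dosage``, ``status`` (1 = AD), ``age``.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    c = config.e4_hap_carrier_prob if carrier_hap_prob is None else carrier_hap_prob
    k = (rng.random((n, 2)) < c).sum(axis=1)
    d = np.full(n, 2)
    diagnosis, age = assign_phenotype(d, k, config, rng)
    return pd.DataFrame(
        {"dosage": k, "status": (diagnosis == "AD").astype(int), "age": age}
    )


# ---------------------------------------------------------------------------
# output


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=e4screen
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (phred)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as VCF v4.2 + phenotype/annotation TSVs.

    The files round-trip losslessly through :mod:`e4screen.cohort_io`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "annotation": outdir / "annotation.tsv",
    }
    gd = cohort.genotypes
    with open(paths["vcf"], "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted(set(gd.variants.chrom), key=lambda c: (len(c), c)):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if gd.samples:
            cols += "\tFORMAT\t" + "\t".join(gd.samples)
        fh.write(cols + "\n")
        for i, row in enumerate(gd.variants.itertuples(index=False)):
            line = f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t."
            if gd.samples:
                calls = "\t".join(
                    f"{_GT_BY_DOSAGE[int(d)]}:{int(q)}:{int(p)}"
                    for d, q, p in zip(gd.dosage[i], gd.gq[i], gd.dp[i])
                )
                line += f"\tGT:GQ:DP\t{calls}"
            fh.write(line + "\n")
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    cohort.annotation.drop(columns=["variant_id"]).to_csv(
        paths["annotation"], sep="\t", index=False
    )
    return paths
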