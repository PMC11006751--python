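import numpy as np
import pandas as pd
import pytest

from e4screen.cohort_io import GenotypeData
from e4screen.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_families=80)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = simulate_cohort(small_config)
    return cohort, truth


def build_single_variant_cohort(strata_spec, cohort="TOY", variant_id="1:100:A:G"):
    """Construct a one-variant cohort from per-stratum (n, alt_alleles) counts.

    ``strata_spec`` maps a (apoe, diagnosis, age) template name to
    ``(n, alt_alleles)``; alt alleles are placed as heterozygous carriers.
    Returns (GenotypeData, phenotype DataFrame).
    """
    templates = {
        "elderly_healthy_hom": ("e4/e4", "control", 75.0),
        "young_healthy_hom": ("e4/e4", "control", 65.0),
        "hom_AD": ("e4/e4", "AD", 70.0),
        "elderly_healthy_het": ("e3/e4", "control", 85.0),
        "young_healthy_het": ("e3/e4", "control", 70.0),
        "het_AD": ("e3/e4", "AD", 72.0),
        "noncarrier": ("e3/e3", "control", 75.0),
        "noncarrier_AD": ("e3/e3", "AD", 75.0),
    }
    rows, dosages = [], []
    i = 0
    for name, (n, alt) in strata_spec.items():
        apoe, dx, age = templates[name]
        assert alt <= n, "heterozygous placement requires alt <= n"
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "family_id": f"F{i:04d}",
                    "cohort": cohort,
                    "apoe": apoe,
                    "diagnosis": dx,
                    "age": age,
                    "sex": "F",
                    "ancestry": "EUR",
                }
            )
            dosages.append(1 if j < alt else 0)
            i += 1
    pheno = pd.DataFrame(rows)
    chrom, pos, ref, alt_allele = variant_id.split(":")
    gd = GenotypeData(
        variants=pd.DataFrame(
            {
                "chrom": [chrom],
                "pos": [int(pos)],
                "ref": [ref],
                "alt": [alt_allele],
                "variant_id": [variant_id],
            }
        ),
        samples=pheno.sample_id.tolist(),
        dosage=np.array([dosages], dtype=np.int8),
        gq=np.full((1, len(rows)), 99, dtype=np.int16),
        dp=np.full((1, len(rows)), 30, dtype=np.int32),
    )
    return gd, pheno
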