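"""Segregation-cascade gates, ranking, soundness and null calibration."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_single_variant_cohort
from e4screen import cohort_io
from e4screen.discovery_filter import (
    CascadeConfig,
    StratumError,
    case_absence_flags,
    elderly_hom_carrier_fraction,
    noncarrier_absence,
    run_cascade,
)
from e4screen.stratification import assign_strata
from e4screen.synthetic_cohort import SimConfig, simulate_cohort


def prepared(cohort):
    """QC + variant-level filters, as the cascade contract expects."""
    gd = cohort_io.apply_genotype_qc(cohort.genotypes)
    ann = cohort_io.filter_by_reference_af(cohort.annotation)
    ann = cohort_io.filter_by_consequence(ann)
    return gd.subset_variants(ann.variant_id), ann


class TestGates:
    def test_noncarrier_carrier_fails_gate_one(self):
        gd, pheno = build_single_variant_cohort(
            {"elderly_healthy_hom": (20, 5), "elderly_healthy_het": (20, 2),
             "noncarrier": (30, 1)}
        )
        strata = assign_strata(pheno)
        assert not noncarrier_absence(gd.dosage[0], strata["noncarrier"])
        res = run_cascade(gd, pheno, config=CascadeConfig(case_absence_mode="rank_only"))
        assert res.candidates.empty

    def test_allele_only_in_carriers_passes_gate_one(self):
        gd, pheno = build_single_variant_cohort(
            {"elderly_healthy_hom": (20, 5), "elderly_healthy_het": (20, 2),
             "noncarrier": (30, 0)}
        )
        strata = assign_strata(pheno)
        assert noncarrier_absence(gd.dosage[0], strata["noncarrier"])

    @pytest.mark.parametrize(
        "n,carriers,expected", [(27, 1, 1 / 27), (27, 0, 0.0), (10, 10, 1.0)]
    )
    def test_elderly_hom_carrier_fraction(self, n, carriers, expected):
        gd, pheno = build_single_variant_cohort(
            {"elderly_healthy_hom": (n, carriers), "noncarrier": (5, 0)}
        )
        strata = assign_strata(pheno)
        frac = elderly_hom_carrier_fraction(gd.dosage[0], strata["elderly_healthy_hom"])
        assert frac == pytest.approx(expected)

    def test_empty_stratum_fraction_undefined(self):
        gd, pheno = build_single_variant_cohort({"noncarrier": (5, 0)})
        strata = assign_strata(pheno)
        assert elderly_hom_carrier_fraction(gd.dosage[0], strata["elderly_healthy_hom"]) is None

    @pytest.mark.parametrize(
        "hom_ad_carriers,het_ad_carriers,expected",
        [(0, 1, (True, False)), (1, 0, (False, False)), (0, 0, (True, True))],
    )
    def test_case_absence_flags(self, hom_ad_carriers, het_ad_carriers, expected):
        gd, pheno = build_single_variant_cohort(
            {"hom_AD": (10, hom_ad_carriers), "het_AD": (10, het_ad_carriers),
             "noncarrier": (5, 0)}
        )
        strata = assign_strata(pheno)
        assert case_absence_flags(gd.dosage[0], strata) == expected


class TestRunCascade:
    def test_recovers_planted_variant(self):
        cohort, truth = simulate_cohort(SimConfig(seed=1))
        gd, ann = prepared(cohort)
        res = run_cascade(gd, cohort.phenotypes, ann,
                          CascadeConfig(case_absence_mode="rank_only"))
        assert truth.planted_variant_id in set(res.candidates.variant_id)

    def test_candidates_sorted_by_tier_then_fraction(self, small_cohort):
        cohort, _ = small_cohort
        gd, ann = prepared(cohort)
        res = run_cascade(gd, cohort.phenotypes, ann,
                          CascadeConfig(case_absence_mode="rank_only"))
        df = res.candidates
        if len(df) > 1:
            assert df.tier.is_monotonic_increasing or (
                df.sort_values(["tier"], kind="mergesort").tier.tolist()
                == df.tier.tolist()
            )
            for _, sub in df.groupby("tier"):
                assert sub.elderly_hom_fraction.is_monotonic_decreasing

    def test_raising_threshold_never_adds_candidates(self, small_cohort):
        cohort, _ = small_cohort
        gd, ann = prepared(cohort)
        loose = run_cascade(gd, cohort.phenotypes, ann,
                            CascadeConfig(min_elderly_hom_carrier_fraction=0.01,
                                          case_absence_mode="rank_only"))
        tight = run_cascade(gd, cohort.phenotypes, ann,
                            CascadeConfig(min_elderly_hom_carrier_fraction=0.05,
                                          case_absence_mode="rank_only"))
        assert set(tight.candidates.variant_id) <= set(loose.candidates.variant_id)

    def test_hard_modes_are_nested_subsets_of_rank_only(self, small_cohort):
        cohort, _ = small_cohort
        gd, ann = prepared(cohort)
        by_mode = {
            mode: set(
                run_cascade(gd, cohort.phenotypes, ann,
                            CascadeConfig(case_absence_mode=mode)).candidates.variant_id
            )
            for mode in ("rank_only", "hard_hom_AD_only", "hard_all_e4_AD")
        }
        assert by_mode["hard_all_e4_AD"] <= by_mode["hard_hom_AD_only"] <= by_mode["rank_only"]

    def test_soundness_against_brute_force_scan(self, small_cohort):
        # every emitted candidate re-checked on the raw genotype matrix
        cohort, _ = small_cohort
        gd, ann = prepared(cohort)
        cfg = CascadeConfig(case_absence_mode="rank_only")
        res = run_cascade(gd, cohort.phenotypes, ann, cfg)
        strata = assign_strata(cohort.phenotypes)
        expected = set()
        for i, vid in enumerate(gd.variants.variant_id):
            d = gd.dosage[i]

            def count(mask, d=d):
                dd = d[mask]
                return dd[dd >= 0]

            if count(strata["noncarrier"]).sum() != 0:
                continue
            eh = count(strata["elderly_healthy_hom"])
            if eh.size == 0 or (eh >= 1).sum() / eh.size < cfg.min_elderly_hom_carrier_fraction:
                continue
            if (count(strata["elderly_healthy_het"]) >= 1).sum() < 1:
                continue
            expected.add(vid)
        assert set(res.candidates.variant_id) == expected

    def test_missing_required_stratum_aborts_with_diagnostic(self):
        gd, pheno = build_single_variant_cohort(
            {"elderly_healthy_het": (10, 1), "noncarrier": (10, 0)}
        )
        with pytest.raises(StratumError, match="elderly_healthy_hom"):
            run_cascade(gd, pheno)

    def test_two_cohort_intersection_contains_shared_planted_variant(self):
        cohorts = []
        phenos = []
        for name, seed in (("A", 21), ("B", 23)):
            c, t = simulate_cohort(SimConfig(seed=seed, cohort_name=name))
            cohorts.append(c)
            phenos.append(c.phenotypes)
        # both cohorts share the planted site by construction
        gd_a, ann = prepared(cohorts[0])
        gd_b, _ = prepared(cohorts[1])
        common = sorted(set(gd_a.variants.variant_id) & set(gd_b.variants.variant_id))
        gd_a = gd_a.subset_variants(common)
        gd_b = gd_b.subset_variants(common)
        from e4screen.cohort_io import GenotypeData

        merged = GenotypeData(
            variants=gd_a.variants,
            samples=gd_a.samples + gd_b.samples,
            dosage=np.hstack([gd_a.dosage, gd_b.dosage]),
            gq=np.hstack([gd_a.gq, gd_b.gq]),
            dp=np.hstack([gd_a.dp, gd_b.dp]),
        )
        pheno = pd.concat(phenos, ignore_index=True)
        res = run_cascade(merged, pheno, ann,
                          CascadeConfig(case_absence_mode="rank_only"))
        planted = "2:216225163:C:T"
        per_cohort_ids = [set(df.variant_id) for df in res.per_cohort.values()]
        # set logic: the intersection is exactly the common candidates
        assert set(res.intersection.variant_id) == set.intersection(*per_cohort_ids)
        for ids in per_cohort_ids:
            assert len(res.intersection) <= len(ids)
        # both cohorts plant the same variant, so it is found in both lists
        assert all(planted in ids for ids in per_cohort_ids)
        assert planted in set(res.intersection.variant_id)


class TestNullCalibration:
    def test_false_positive_count_matches_binomial_expectation(self):
        """Founders-only null cohorts: candidate counts vs analytic binomial.

        With unrelated individuals, no protective effect and no QC noise,
        each neutral variant passes the three gates independently with
        P = (1-p)^(2 n_nc) * P(>=1 carrier in EH hom) * P(>=1 in EH het).
        """
        n_rep = 100
        observed = 0
        expected = 0.0
        variance = 0.0
        cfg_proto = dict(
            n_families=200,
            offspring_per_family=(0, 0),
            protective_af=0.0,
            qc_fail_fraction=0.0,
            n_background=120,
        )
        for rep in range(n_rep):
            cohort, truth = simulate_cohort(SimConfig(seed=10_000 + rep, **cfg_proto))
            gd, ann = prepared(cohort)
            res = run_cascade(gd, cohort.phenotypes, ann,
                              CascadeConfig(case_absence_mode="rank_only"))
            observed += len(res.candidates)
            strata = assign_strata(cohort.phenotypes)
            n_nc = int(strata["noncarrier"].sum())
            n_eh = int(strata["elderly_healthy_hom"].sum())
            n_ehet = int(strata["elderly_healthy_het"].sum())
            afs = dict(zip(truth.background_variant_ids, truth.background_afs))
            for vid in gd.variants.variant_id:
                p = afs.get(vid)
                if p is None:  # the planted site: af 0 here, never a candidate
                    continue
                q = 1 - (1 - p) ** 2  # per-individual carrier probability
                prob = (
                    (1 - p) ** (2 * n_nc)
                    * (1 - (1 - q) ** n_eh)
                    * (1 - (1 - q) ** n_ehet)
                )
                expected += prob
                variance += prob * (1 - prob)
        assert abs(observed - expected) <= 3 * np.sqrt(variance) + 1e-9
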