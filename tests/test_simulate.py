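"""Synthetic-cohort generator: reproducibility, HWE, planted structure."""

import numpy as np
import pytest
from scipy import stats

from rarescreen.core import VariantRecord
from rarescreen.fixtures import (
    DEFB1_KEY,
    DEFB119_KEY,
    METTL7B_KEY,
    defb119_discovery_column,
    fixture_from_tables,
)
from rarescreen.simulate import (
    ConfigError,
    ModifierSpec,
    PlantedVariant,
    SimulationConfig,
    defb1_like_variant,
    simulate_cohort,
    truncated_normal,
    write_study,
)


def _planted(case_af, control_af, modifier_prob=None):
    record = VariantRecord("chr3", 500, "G", "T", gene="GENE1",
                           consequence="stop_gained", lof_confidence="HC")
    modifier = None
    if modifier_prob is not None:
        modifier = ModifierSpec(
            VariantRecord("chr3", 501, "C", "A", gene="GENE1",
                          consequence="missense"),
            modifier_prob,
        )
    return PlantedVariant(record, case_af, control_af,
                          pop_afs={"AFR": 0.01}, modifier=modifier)


class TestReproducibility:
    def test_same_seed_same_study(self, tmp_path):
        cfg = dict(planted=[defb1_like_variant(modifier=True)], n_background=15)
        a = simulate_cohort(SimulationConfig(seed=123, **cfg))
        b = simulate_cohort(SimulationConfig(seed=123, **cfg))
        for label in a.cohorts:
            assert np.array_equal(a.cohorts[label].genotypes,
                                  b.cohorts[label].genotypes)
            assert np.array_equal(a.aim_genotypes[label], b.aim_genotypes[label])
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        write_study(a, dir_a)
        write_study(b, dir_b)
        for path_a in sorted(dir_a.iterdir()):
            assert path_a.read_bytes() == (dir_b / path_a.name).read_bytes()

    def test_different_seed_differs(self):
        cfg = dict(planted=[_planted(0.3, 0.3)], n_background=0, aims=None)
        a = simulate_cohort(SimulationConfig(seed=1, **cfg))
        b = simulate_cohort(SimulationConfig(seed=2, **cfg))
        assert any(
            not np.array_equal(a.cohorts[l].genotypes, b.cohorts[l].genotypes)
            for l in a.cohorts
        )


class TestGenotypeSampling:
    def test_zero_frequency_gives_all_zero_matrices(self):
        study = simulate_cohort(
            SimulationConfig(seed=3, planted=[_planted(0.0, 0.0)],
                             n_background=0, aims=None)
        )
        for cohort in study.cohorts.values():
            assert not cohort.genotypes.any()

    def test_realized_frequency_converges_to_generating_value(self):
        af = 0.12
        study = simulate_cohort(SimulationConfig(
            seed=4, cohort_sizes={"big_cases": 20_000},
            planted=[_planted(af, af)], n_background=0, aims=None,
        ))
        count = study.cohorts["big_cases"].allele_count(("chr3", 500, "G", "T"))
        assert float(count.maf) == pytest.approx(af, abs=0.005)

    def test_planted_case_mac_matches_generating_frequency_on_average(self):
        # combined-size case cohort at the published generating frequency:
        # mean realized MAC across replicates ~ 0.0144 * 694 ~ 10
        macs = []
        for seed in range(300):
            study = simulate_cohort(SimulationConfig(
                seed=seed, cohort_sizes={"combined_cases": 347},
                planted=[_planted(0.0144, 0.0013)], n_background=0, aims=None,
            ))
            macs.append(study.cohorts["combined_cases"]
                        .allele_count(("chr3", 500, "G", "T")).mac)
        assert np.mean(macs) == pytest.approx(0.0144 * 694, abs=0.35)

    def test_modifier_rides_target_haplotypes_only(self):
        study = simulate_cohort(SimulationConfig(
            seed=6, cohort_sizes={"cases_cases": 4000},
            planted=[_planted(0.05, 0.05, modifier_prob=0.4)],
            n_background=0, aims=None,
        ))
        cohort = study.cohorts["cases_cases"]
        target = cohort.column(("chr3", 500, "G", "T"))
        modifier = cohort.column(("chr3", 501, "C", "A"))
        assert (modifier <= target).all()
        carried = target > 0
        rate = modifier[carried].sum() / target[carried].sum()
        assert rate == pytest.approx(0.4, abs=0.05)


class TestTruncatedNormal:
    def test_bounds_and_moments(self):
        rng = np.random.default_rng(8)
        draws = truncated_normal(rng, 0.695, 0.073, 20_000)
        assert draws.min() >= 0.0 and draws.max() <= 1.0
        assert draws.mean() == pytest.approx(0.695, abs=0.005)
        assert draws.std() == pytest.approx(0.073, abs=0.005)


class TestConfigValidation:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, cohort_sizes={"cases": 0})

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ConfigError):
            _planted(1.5, 0.0)
        with pytest.raises(ConfigError):
            _planted(0.1, 0.1, modifier_prob=2.0)


class TestPaperFixture:
    def test_index_discovery_columns(self, paper_fixture):
        cases = paper_fixture.cohorts["discovery_cases"]
        controls = paper_fixture.cohorts["discovery_controls"]
        defb1 = cases.allele_count(DEFB1_KEY)
        assert (defb1.hom, defb1.het) == (0, 1)
        assert controls.allele_count(DEFB1_KEY).mac == 0
        mettl7b = cases.allele_count(METTL7B_KEY)
        assert (mettl7b.hom, mettl7b.het) == (0, 7)
        assert controls.allele_count(METTL7B_KEY).mac == 0

    def test_every_column_recounts_to_its_printed_triple(self, paper_fixture):
        # round-trip by construction: each realized column reproduces the
        # (hom, het) pair it was built from
        from rarescreen.fixtures import _ROWS

        cases = paper_fixture.cohorts["discovery_cases"]
        controls = paper_fixture.cohorts["discovery_controls"]
        checked = 0
        for record, _f, _l, case_counts, control_counts in _ROWS:
            if case_counts is None:
                continue
            cc = cases.allele_count(record.key)
            assert (cc.hom, cc.het) == case_counts
            kc = controls.allele_count(record.key)
            assert (kc.hom, kc.het) == (control_counts or (0, 0))
            checked += 1
        assert checked >= 10

    def test_stop_loss_carrier_column(self):
        col = defb119_discovery_column()
        assert col.size == 76
        assert (col == 2).sum() == 1
        assert (col == 1).sum() == 18

    def test_combined_counts_match_their_printed_frequencies(self, paper_fixture):
        case, control = paper_fixture.combined_counts_raw[DEFB1_KEY]
        assert (case.mac, case.total_alleles) == (10, 694)
        assert (control.mac, control.total_alleles) == (1, 751)
        rec_case, _ = paper_fixture.combined_counts_recoded[METTL7B_KEY]
        assert rec_case.mac == 19
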