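"""REP arithmetic and concentration-addition BEQ accounting."""

import math

import numpy as np
import pytest

from ahrqsar.curation import ActivityCategory
from ahrqsar.mixture import (
    CATEGORY_BASIS_EC25_UM,
    TCDD_EC25_DEFAULT_UM,
    REPEntry,
    SiteSample,
    beq_chem,
    category_rep,
    ng_per_l_to_nM,
    rep_from_ec25,
    run_scenarios,
)
from ahrqsar.synthetic import GeneratorConfig, generate_compounds, generate_sites


class TestREP:
    def test_category_basis_values(self):
        assert category_rep(ActivityCategory.HIGH).basis_ec25_uM == 0.5
        assert category_rep(ActivityCategory.LOW).basis_ec25_uM == 32.0
        assert category_rep(ActivityCategory.MEDIUM).basis_ec25_uM == 5.0
        assert category_rep(ActivityCategory.MEDIUM_HIGH).basis_ec25_uM == 2.5

    def test_equal_ec25_gives_rep_one(self):
        assert rep_from_ec25(2.0, 2.0) == 1.0

    def test_rep_vanishes_for_impotent_compound(self):
        assert rep_from_ec25(1e12, 2e-6) == pytest.approx(0.0, abs=1e-15)

    def test_cross_row_consistency(self):
        """The TCDD EC25 implied by one measured EC25/REP pair predicts the
        REP printed for a second compound."""
        tcdd = 2.43e-3 * 8.39e-4  # benzo[j]fluoranthene row
        rep = rep_from_ec25(9.30e-3, tcdd)  # indeno[123-cd]pyrene EC25
        assert rep == pytest.approx(2.19e-4, rel=5e-3)

    def test_high_to_low_rep_ratio_is_64(self):
        for tcdd in (1e-6, 2.0388e-6, 5e-4):
            ratio = (
                category_rep(ActivityCategory.HIGH, tcdd).rep
                / category_rep(ActivityCategory.LOW, tcdd).rep
            )
            assert ratio == pytest.approx(64.0)

    def test_inactive_has_no_rep(self):
        with pytest.raises(ValueError, match="no REP"):
            category_rep(ActivityCategory.INACTIVE)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            rep_from_ec25(-1.0, 2e-6)
        with pytest.raises(ValueError):
            rep_from_ec25(1.0, 0.0)


def test_unit_conversion():
    # 100 ng/L of a 200 g/mol compound is 0.5 nM
    assert ng_per_l_to_nM(100.0, 200.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        ng_per_l_to_nM(1.0, 0.0)


def _sample(conc: dict, beq_bio: float | None = None) -> SiteSample:
    return SiteSample("s1", "HLB", concentrations_nM=conc, beq_bio_nM=beq_bio)


def _rep(cid: str, rep: float) -> REPEntry:
    return REPEntry(cid, rep, "experimental", basis_ec25_uM=1.0)


class TestBEQChem:
    def test_single_compound_linearity(self):
        result = beq_chem(_sample({"a": 10.0}), [_rep("a", 1e-3)])
        assert result.beq_chem_nM == pytest.approx(0.01)
        assert result.n_contributing == 1

    def test_zero_concentrations(self):
        result = beq_chem(_sample({"a": 0.0}, beq_bio=1.0), [_rep("a", 1e-3)])
        assert result.beq_chem_nM == 0.0 and result.explained_pct == 0.0

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(7)
        conc = {f"c{i}": float(rng.uniform(0, 50)) for i in range(5)}
        reps = [_rep(f"c{i}", float(rng.uniform(1e-6, 1e-2))) for i in range(5)]
        result = beq_chem(_sample(conc), reps)
        expected = sum(conc[e.compound_id] * e.rep for e in reps)
        assert result.beq_chem_nM == pytest.approx(expected, rel=1e-12)

    def test_scaling_concentrations_scales_beq(self):
        rng = np.random.default_rng(9)
        conc = {f"c{i}": float(rng.uniform(0, 50)) for i in range(6)}
        reps = [_rep(f"c{i}", float(rng.uniform(1e-6, 1e-2))) for i in range(6)]
        base = beq_chem(_sample(conc), reps).beq_chem_nM
        scaled = beq_chem(
            _sample({k: 3.0 * v for k, v in conc.items()}), reps
        ).beq_chem_nM
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        items = [(f"c{i}", float(rng.uniform(0, 50))) for i in range(8)]
        reps = [_rep(cid, float(rng.uniform(1e-6, 1e-2))) for cid, _ in items]
        forward = beq_chem(_sample(dict(items)), reps).beq_chem_nM
        backward = beq_chem(_sample(dict(reversed(items))), list(reversed(reps))).beq_chem_nM
        assert forward == pytest.approx(backward, rel=1e-12)

    def test_adding_contributor_never_decreases_explained(self):
        base = beq_chem(_sample({"a": 5.0}, beq_bio=10.0), [_rep("a", 1e-2)])
        more = beq_chem(
            _sample({"a": 5.0, "b": 2.0}, beq_bio=10.0),
            [_rep("a", 1e-2), _rep("b", 1e-3)],
        )
        assert more.explained_pct >= base.explained_pct

    def test_explained_above_100_not_clipped(self):
        result = beq_chem(_sample({"a": 100.0}, beq_bio=0.5), [_rep("a", 1e-2)])
        assert result.explained_pct == pytest.approx(200.0)

    def test_conflicting_duplicate_reps_error(self):
        with pytest.raises(ValueError, match="conflicting"):
            beq_chem(_sample({"a": 1.0}), [_rep("a", 1e-2), _rep("a", 2e-2)])

    def test_compound_without_rep_contributes_zero(self):
        result = beq_chem(_sample({"a": 5.0, "unknown": 50.0}), [_rep("a", 1e-2)])
        assert result.beq_chem_nM == pytest.approx(0.05)


class TestScenarios:
    def _setup(self):
        samples = [_sample({"pred_high": 10.0, "tested_cyto": 20.0, "known": 5.0},
                           beq_bio=1.0)]
        baseline = [_rep("known", 1e-3)]
        predicted = {
            "pred_high": ActivityCategory.HIGH,
            "tested_cyto": ActivityCategory.MEDIUM,
        }
        priorities = {"pred_high": "4", "tested_cyto": "3"}
        return samples, baseline, predicted, priorities

    def test_cytotoxic_compound_present_in_s1_absent_in_s2(self):
        samples, baseline, predicted, priorities = self._setup()
        results = run_scenarios(
            samples, baseline, predicted, priorities,
            experimental_overrides={"tested_cyto": "cytotoxic"},
        )
        s1 = next(r for r in results if r.scenario == "scenario1")
        s2 = next(r for r in results if r.scenario == "scenario2")
        medium_rep = category_rep(ActivityCategory.MEDIUM).rep
        assert s1.beq_chem_nM - s2.beq_chem_nM == pytest.approx(20.0 * medium_rep)
        assert "tested_cyto" in s2.exclusions

    def test_no_overrides_scenario2_equals_scenario1(self):
        samples, baseline, predicted, priorities = self._setup()
        results = run_scenarios(samples, baseline, predicted, priorities)
        s1 = next(r for r in results if r.scenario == "scenario1")
        s2 = next(r for r in results if r.scenario == "scenario2")
        assert s1.beq_chem_nM == pytest.approx(s2.beq_chem_nM, rel=1e-12)

    def test_nr_compound_never_gets_predicted_rep(self):
        samples = [_sample({"nr_compound": 10.0}, beq_bio=1.0)]
        results = run_scenarios(
            samples, [], {"nr_compound": ActivityCategory.HIGH},
            priorities={"nr_compound": "NR"},
        )
        for r in results:
            assert r.beq_chem_nM == 0.0

    def test_experimental_override_rescales_by_basis_ratio(self):
        """A predicted-High compound (basis 0.5 uM) measured at 19.1 uM
        contributes 38.2x less in scenario 2."""
        samples = [_sample({"cmpd": 10.0}, beq_bio=1.0)]
        results = run_scenarios(
            samples, [], {"cmpd": ActivityCategory.HIGH}, {"cmpd": "4"},
            experimental_overrides={"cmpd": 19.1},
        )
        s1 = next(r for r in results if r.scenario == "scenario1")
        s2 = next(r for r in results if r.scenario == "scenario2")
        assert s1.beq_chem_nM / s2.beq_chem_nM == pytest.approx(19.1 / 0.5, rel=1e-9)

    def test_baseline_uses_only_preexisting_reps(self):
        samples, baseline, predicted, priorities = self._setup()
        results = run_scenarios(samples, baseline, predicted, priorities)
        base = next(r for r in results if r.scenario == "baseline")
        assert base.beq_chem_nM == pytest.approx(5.0 * 1e-3)


class TestDoubleEntry:
    def test_generator_bookkeeping_agrees_with_beq_module(self):
        """Double-entry oracle: recomputing BEQ from the generator's site
        tables with the true REPs reproduces its bookkeeping exactly."""
        for seed in range(5):
            cfg = GeneratorConfig(
                n_compounds=120, seed=seed, site_count=2, beq_inflation=4.0
            )
            comp = generate_compounds(cfg)
            sites = generate_sites(cfg, comp)
            book = sites.bookkeeping.set_index(["site_id", "sampler"])
            for sample in sites.samples:
                result = beq_chem(sample, sites.true_reps)
                row = book.loc[(sample.site_id, sample.sampler)]
                assert result.beq_chem_nM == pytest.approx(
                    row["true_beq_chem_nM"], rel=1e-9
                )
                assert result.explained_pct == pytest.approx(
                    row["true_explained_pct"], rel=1e-9
                )

    @pytest.mark.parametrize("inflation,expected", [(1.0, 100.0), (4.0, 25.0)])
    def test_inflation_sets_explained_fraction_exactly(self, inflation, expected):
        cfg = GeneratorConfig(
            n_compounds=100, seed=3, site_count=2, beq_inflation=inflation
        )
        comp = generate_compounds(cfg)
        sites = generate_sites(cfg, comp)
        for sample in sites.samples:
            result = beq_chem(sample, sites.true_reps)
            assert result.explained_pct == pytest.approx(expected, rel=1e-9)


def test_default_tcdd_reference_is_consistent_with_category_reps():
    rep_high = category_rep(ActivityCategory.HIGH).rep
    assert rep_high == pytest.approx(TCDD_EC25_DEFAULT_UM / 0.5)
    assert math.isclose(TCDD_EC25_DEFAULT_UM, 2.0388e-6, rel_tol=1e-3)
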