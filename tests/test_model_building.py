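"""Scenario-table building, model selection, splitting, outlier filtering."""

import numpy as np
import pandas as pd
import pytest

from skinqspr import (
    GeneratorConfig,
    PreferenceCriteria,
    ScenarioKey,
    assign,
    build_scenario_table,
    enumerate_scenarios,
    generate,
    load_registry,
    outlier_filter_refit,
    run_pooled_workflow,
    select_best,
    select_one_per_compound,
    split_train_test,
    train_size,
)
from skinqspr.io import CompoundDescriptors, Dataset, PermeabilityRecord
from skinqspr.model_building import ScenarioModelTable
from skinqspr.stratification import ScenarioAssignment
from tests.conftest import make_rows, random_design

PLANTED = {
    ScenarioKey("abdomen", "epidermis", "diluted", "20-25"): (-6.0, 0.8, -0.01, -0.005),
    ScenarioKey("thigh", "epidermis+dermis", "diluted", "36-40"): (-7.0, 0.5, 0.0, -0.002),
    ScenarioKey("breast", "dermis", "concentrated", "31-35"): (-5.0, 0.3, -0.02, 0.001),
}


class TestBuildScenarioTable:
    def test_noiseless_recovery_of_planted_scenarios(self):
        cfg = GeneratorConfig(
            n_compounds=90, records_per_compound=(1, 1), noise_sd=0.0,
            scenario_coefficients=PLANTED, seed=3,
        )
        ds, _ = generate(cfg)
        table = build_scenario_table(assign(ds.records, ds.descriptors))
        assert len(table) == 3
        for model in table:
            truth = PLANTED[model.scenario]
            np.testing.assert_allclose(model.coefficients, truth, atol=1e-9)

    def test_empty_assignment(self):
        assert len(build_scenario_table(ScenarioAssignment())) == 0

    def test_ordering_follows_enumeration(self):
        cfg = GeneratorConfig(
            n_compounds=90, records_per_compound=(1, 1),
            scenario_coefficients=PLANTED, seed=4,
        )
        ds, _ = generate(cfg)
        table = build_scenario_table(assign(ds.records, ds.descriptors))
        order = {k: i for i, k in enumerate(enumerate_scenarios())}
        positions = [order[m.scenario] for m in table]
        assert positions == sorted(positions)

    def test_single_row_group_gives_placeholder(self):
        key = ScenarioKey("abdomen", "epidermis", "diluted", "20-25")
        rec = PermeabilityRecord("c1", -5.0, skin_source="abdomen",
                                 skin_layer="epidermis", donor_concentration="diluted",
                                 donor_temperature_c=22.0)
        desc = CompoundDescriptors("c1", 1.0, 30.0, 100.0)
        table = build_scenario_table(ScenarioAssignment(groups={key: [(rec, desc)]}))
        assert len(table) == 1
        assert table.rows[0].underdetermined
        assert np.isnan(table.rows[0].intercept)

    def test_parameter_recovery_with_noise(self):
        """Fitted coefficients land within 3 SE of truth for big scenarios."""
        key = ScenarioKey("abdomen", "epidermis", "diluted", "20-25")
        cfg = GeneratorConfig(
            n_compounds=120, records_per_compound=(1, 1), noise_sd=0.3,
            scenario_coefficients={key: PLANTED[key]}, seed=8,
        )
        ds, _ = generate(cfg)
        table = build_scenario_table(assign(ds.records, ds.descriptors))
        model = table.rows[0]
        # standard errors computed long-hand from the design
        df = pd.DataFrame(
            [
                {"log_p": d.log_p, "tpsa": d.tpsa, "mv": d.mv}
                for d in ds.descriptors.values()
            ]
        )
        A = np.column_stack([np.ones(len(df)), df.to_numpy()])
        resid_var = model.rmse**2 * model.n / (model.n - 4)
        se = np.sqrt(np.diag(resid_var * np.linalg.inv(A.T @ A)))
        np.testing.assert_array_less(
            np.abs(model.coefficients - PLANTED[key]), 3 * se
        )


class TestSelectBest:
    def test_published_table_best_model(self, registry):
        table = ScenarioModelTable(rows=list(registry.scenario_models.values()))
        best = select_best(table, min_n=16)
        assert best.scenario == ScenarioKey("abdomen", "epidermis", "diluted", "20-25")
        assert best.n == 36
        assert best.r_squared == pytest.approx(0.8545)

    def test_no_qualifying_row_raises_with_largest_n(self, registry):
        table = ScenarioModelTable(
            rows=[m for m in registry.scenario_models.values() if m.n < 16]
        )
        with pytest.raises(ValueError, match="14"):
            select_best(table, min_n=16)

    def test_tie_breaks_to_earlier_scenario(self):
        keys = enumerate_scenarios()
        a = _mk_model(keys[5], n=20, r2=0.7)
        b = _mk_model(keys[10], n=25, r2=0.7)
        assert select_best(ScenarioModelTable(rows=[a, b])) is a


def _mk_model(key, n, r2):
    from skinqspr import QsprModel

    return QsprModel(
        intercept=-6.0, coef_logp=0.5, coef_tpsa=0.0, coef_mv=0.0,
        n=n, r_squared=r2, scenario=key,
    )


class TestSplitTrainTest:
    @pytest.mark.parametrize("n,expected_train,expected_test", [(36, 29, 7), (214, 171, 43)])
    def test_split_sizes(self, rng, n, expected_train, expected_test):
        assert train_size(n) == expected_train
        rows = make_rows((-6, 0.8, -0.01, -0.005), random_design(rng, n),
                         noise=rng.normal(0, 0.3, n))
        split = split_train_test(rows, seed=1)
        assert len(split.train_rows) == expected_train
        assert len(split.test_rows) == expected_test

    def test_partition_disjoint_union(self, rng):
        rows = make_rows((-6, 0.8, -0.01, -0.005), random_design(rng, 40),
                         noise=rng.normal(0, 0.3, 40))
        split = split_train_test(rows, seed=2)
        train_ids = set(split.train_rows.index)
        test_ids = set(split.test_rows.index)
        assert train_ids.isdisjoint(test_ids)
        assert train_ids | test_ids == set(rows.index)

    def test_determinism(self, rng):
        rows = make_rows((-6, 0.8, -0.01, -0.005), random_design(rng, 36),
                         noise=rng.normal(0, 0.3, 36))
        s1 = split_train_test(rows, seed=7)
        s2 = split_train_test(rows, seed=7)
        pd.testing.assert_frame_equal(s1.train_rows, s2.train_rows)
        pd.testing.assert_frame_equal(s1.test_rows, s2.test_rows)

    def test_coverage_check_enforced(self, rng):
        """Accepted test sets span every descriptor's range adequately."""
        rows = make_rows((-6, 0.8, -0.01, -0.005), random_design(rng, 50),
                         noise=rng.normal(0, 0.3, 50))
        split = split_train_test(rows, seed=3)
        for c in ("log_p", "tpsa", "mv"):
            full = rows[c].max() - rows[c].min()
            got = split.test_rows[c].max() - split.test_rows[c].min()
            assert got >= 0.25 * full

    def test_too_few_rows_raise(self, rng):
        rows = make_rows((-6, 0.8, -0.01, -0.005), random_design(rng, 4))
        with pytest.raises(ValueError, match="at least 5"):
            split_train_test(rows, seed=0)


class TestSelectOnePerCompound:
    def _dataset(self):
        preferred = PermeabilityRecord(
            "c1", -5.0, skin_source="abdomen", skin_layer="epidermis+dermis",
            donor_concentration="concentrated", donor_temperature_c=32.0, donor_ph=7.2,
        )  # satisfies all five criteria
        poor = PermeabilityRecord(
            "c1", -6.0, skin_source="thigh", skin_layer="epidermis",
            donor_concentration="diluted", donor_temperature_c=22.0, donor_ph=5.0,
        )  # satisfies none
        single = PermeabilityRecord("c2", -4.0, skin_source="breast")
        records = [poor, preferred, single]
        descriptors = {
            "c1": CompoundDescriptors("c1", 1.0, 40.0, 120.0),
            "c2": CompoundDescriptors("c2", 2.0, 20.0, 200.0),
        }
        return Dataset(records=records, descriptors=descriptors)

    def test_highest_score_wins(self):
        rows = select_one_per_compound(self._dataset())
        assert len(rows) == 2
        assert rows.set_index("compound_id").loc["c1", "log_kp"] == -5.0

    def test_single_record_kept_regardless(self):
        rows = select_one_per_compound(self._dataset())
        assert rows.set_index("compound_id").loc["c2", "log_kp"] == -4.0

    def test_tie_keeps_first_in_input_order(self):
        r1 = PermeabilityRecord("c1", -5.0, skin_source="thigh")
        r2 = PermeabilityRecord("c1", -6.0, skin_source="breast")
        ds = Dataset(records=[r1, r2],
                     descriptors={"c1": CompoundDescriptors("c1", 1.0, 1.0, 100.0)})
        rows = select_one_per_compound(ds)
        assert rows["log_kp"].iloc[0] == -5.0

    def test_missing_descriptors_dropped(self):
        ds = self._dataset()
        del ds.descriptors["c2"]
        rows = select_one_per_compound(ds)
        assert list(rows["compound_id"]) == ["c1"]

    def test_planted_preferred_records_recovered(self):
        """With one all-criteria record planted per compound, selection
        recovers exactly the planted rows."""
        rng = np.random.default_rng(15)
        records, descriptors, planted_kp = [], {}, {}
        for i in range(50):
            cid = f"c{i}"
            descriptors[cid] = CompoundDescriptors(
                cid, float(rng.uniform(-2, 4)), float(rng.uniform(0, 120)),
                float(rng.uniform(60, 400)),
            )
            decoy = PermeabilityRecord(
                cid, float(rng.uniform(-8, -3)), skin_source="thigh",
                skin_layer="epidermis", donor_concentration="diluted",
                donor_temperature_c=22.0, donor_ph=5.5,
            )
            target = PermeabilityRecord(
                cid, float(rng.uniform(-8, -3)), skin_source="abdomen",
                skin_layer="epidermis+dermis", donor_concentration="concentrated",
                donor_temperature_c=31.0, donor_ph=7.25,
            )
            planted_kp[cid] = target.log_kp
            records.extend([decoy, target])
        rows = select_one_per_compound(Dataset(records=records, descriptors=descriptors))
        assert len(rows) == 50
        for cid, kp in planted_kp.items():
            assert rows.set_index("compound_id").loc[cid, "log_kp"] == kp


class TestOutlierFilterRefit:
    def test_threshold_rule(self, rng):
        beta = (-6.0, 0.8, -0.01, -0.005)
        rows = make_rows(beta, random_design(rng, 60))
        # plant clear offsets on three rows; the fit stays near truth
        rows.loc[5, "log_kp"] += 2.5
        rows.loc[17, "log_kp"] -= 2.5
        rows.loc[30, "log_kp"] += 0.5
        result = outlier_filter_refit(rows, threshold=1.5)
        assert set(result.removed_rows.index) == {5, 17}
        assert len(result.kept_rows) == 58
        # partition invariants against the pre-filter model
        from skinqspr.regression import predict_rows

        resid = rows["log_kp"].to_numpy() - predict_rows(result.model_before, rows)
        assert all(abs(resid[i]) > 1.5 for i in result.removed_rows.index)
        kept_resid = result.kept_rows["log_kp"].to_numpy() - predict_rows(
            result.model_before, result.kept_rows
        )
        assert np.all(np.abs(kept_resid) <= 1.5)

    def test_no_outliers_is_identity(self, rng):
        rows = make_rows((-6, 0.8, -0.01, -0.005), random_design(rng, 30),
                         noise=rng.normal(0, 0.2, 30))
        result = outlier_filter_refit(rows, threshold=1.5)
        assert len(result.removed_rows) == 0
        assert result.model_after is result.model_before

    def test_infinite_threshold_removes_nothing(self, rng):
        rows = make_rows((-6, 0.8, -0.01, -0.005), random_design(rng, 30),
                         noise=rng.normal(0, 3.0, 30))
        result = outlier_filter_refit(rows, threshold=np.inf)
        assert len(result.removed_rows) == 0

    def test_planted_gross_outliers_recovered(self):
        """>= 90% of +/-3 offsets removed; refit closer to truth."""
        key = ScenarioKey("abdomen", "epidermis", "diluted", "20-25")
        beta = np.array([-6.136, 0.818, -0.005, -0.007])
        cfg = GeneratorConfig(
            n_compounds=253, records_per_compound=(1, 1), noise_sd=0.5,
            outlier_fraction=40 / 253, outlier_offset=3.0,
            scenario_coefficients={key: tuple(beta)}, seed=21,
        )
        ds, truth = generate(cfg)
        assert len(truth.outlier_record_indices) == 40
        rows = select_one_per_compound(ds, PreferenceCriteria())
        result = outlier_filter_refit(rows, threshold=1.5)
        planted_ids = {
            ds.records[i].compound_id for i in truth.outlier_record_indices
        }
        removed_ids = set(result.removed_rows["compound_id"])
        recall = len(planted_ids & removed_ids) / len(planted_ids)
        assert recall >= 0.9
        err_before = np.linalg.norm(result.model_before.coefficients - beta)
        err_after = np.linalg.norm(result.model_after.coefficients - beta)
        assert err_after < err_before


class TestPooledWorkflow:
    def test_bookkeeping_and_determinism(self):
        cfg = GeneratorConfig(
            n_compounds=253, records_per_compound=(1, 2), noise_sd=0.5,
            outlier_fraction=0.1, seed=31,
        )
        ds, _ = generate(cfg)
        r1 = run_pooled_workflow(ds, seed=5)
        r2 = run_pooled_workflow(ds, seed=5)
        assert r1.counts == r2.counts
        assert r1.counts["n_compounds_pooled"] == 253
        assert (
            r1.counts["n_kept"]
            == 253 - r1.counts["n_removed_outliers"]
        )
        assert r1.counts["n_train"] == train_size(r1.counts["n_kept"])
        np.testing.assert_allclose(
            r1.split_result.model.coefficients, r2.split_result.model.coefficients
        )

    def test_infinite_threshold_keeps_everything(self):
        ds, _ = generate(GeneratorConfig(n_compounds=60, seed=32))
        result = run_pooled_workflow(ds, threshold=np.inf, seed=1)
        assert result.counts["n_removed_outliers"] == 0


class TestCoefficientRecoveryShrinksWithN:
    def test_median_error_monotone_in_n(self):
        """Coefficient error decreases with sample size (median over seeds)."""
        key = ScenarioKey("abdomen", "epidermis", "diluted", "20-25")
        beta = np.array([-6.0, 0.8, -0.01, -0.005])
        medians = []
        for n in (20, 100, 500):
            errs = []
            for seed in range(20):
                cfg = GeneratorConfig(
                    n_compounds=n, records_per_compound=(1, 1), noise_sd=0.3,
                    scenario_coefficients={key: tuple(beta)}, seed=1000 + seed,
                )
                ds, _ = generate(cfg)
                table = build_scenario_table(assign(ds.records, ds.descriptors))
                errs.append(np.linalg.norm(table.rows[0].coefficients - beta))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]
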