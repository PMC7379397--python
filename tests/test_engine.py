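import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ordimpute as oi
from ordimpute.engine import InsufficientDataError

from conftest import cheap_hyperparams


@pytest.fixture
def masked_tiny(small_registry, tiny_cohort):
    return oi.apply_missingness(
        tiny_cohort, small_registry,
        oi.MissingnessPattern(item_mcar_rate=0.15, seed=21),
    )


class TestIterativeImputation:
    def test_complete_cohort_is_identity(self, small_registry, tiny_cohort):
        res = oi.run_iterative_imputation(
            tiny_cohort, small_registry, cheap_hyperparams(max_epochs=30)
        )
        assert res.completed_cohort.equals(tiny_cohort)
        assert sorted(res.imputation_order) == sorted(tiny_cohort.item_ids)
        assert all(r.n_cells_imputed == 0 for r in res.records)

    def test_planted_noise_free_item_selected_first(self, small_registry):
        """An item that is a deterministic threshold of an attention index
        is (a) selected at iteration 1 and (b) imputed in agreement with
        the exact rule-lookup oracle, while all other items are pure noise."""
        base = oi.generate_cohort(
            small_registry, oi.CohortConfig(n_case=240, n_control=160, seed=12)
        )
        rng = np.random.default_rng(13)
        items = rng.integers(0, 4, base.item_matrix().shape).astype(float)
        rule = np.digitize(base.ccpt_matrix()[:, 0], [-0.6, 0.0, 0.6])
        items[:, 3] = rule
        cohort = base.with_items(items)
        masked = oi.apply_missingness(
            cohort, small_registry, oi.MissingnessPattern(item_mcar_rate=0.2, seed=14)
        )
        hp = oi.HyperParams(
            patience_epochs=5, dropout_rate=0.0,
            batch_mode=oi.BatchMode.MINI_BATCH_8, max_epochs=30,
            learning_rate=1e-3, n_init_attempts=1, seed=2,
        )
        res = oi.run_iterative_imputation(masked, small_registry, hp)
        planted_id = cohort.item_ids[3]
        assert res.imputation_order[0] == planted_id
        first = res.records[0]
        noise_best = max(
            v for k, v in first.candidate_accuracies.items() if k != planted_id
        )
        assert first.selected_accuracy >= 0.55  # far above the ~0.3 chance level
        assert first.selected_accuracy > noise_best + 0.1
        # oracle agreement on the cells that were actually imputed
        mask = masked.missing_mask()[:, 3]
        imputed = res.completed_cohort.item_matrix()[mask, 3]
        assert (imputed == rule[mask]).mean() > 0.6

    def test_greedy_contract_and_feature_growth(self, small_registry, masked_tiny):
        res = oi.run_iterative_imputation(
            masked_tiny, small_registry, cheap_hyperparams(max_epochs=30)
        )
        for k, record in enumerate(res.records):
            assert record.iteration == k + 1
            assert record.selected_accuracy == max(record.candidate_accuracies.values())
            # iteration k trains networks with 12 + (k - 1) inputs
            model = res.models[record.selected_item]
            assert model.spec.n_inputs == 12 + k
        assert res.completed_cohort.count_missing() == 0

    def test_observed_cells_preserved(self, small_registry, masked_tiny):
        res = oi.run_iterative_imputation(
            masked_tiny, small_registry, cheap_hyperparams(max_epochs=30)
        )
        before = masked_tiny.item_matrix()
        after = res.completed_cohort.item_matrix()
        obs = ~np.isnan(before)
        assert (after[obs] == before[obs]).all()

    def test_deterministic(self, small_registry, masked_tiny):
        hp = cheap_hyperparams(seed=4, max_epochs=30)
        a = oi.run_iterative_imputation(masked_tiny, small_registry, hp)
        b = oi.run_iterative_imputation(masked_tiny, small_registry, hp)
        assert a.imputation_order == b.imputation_order
        assert a.completed_cohort.equals(b.completed_cohort)

    def test_exclude_odd_items(self, registry):
        ids = [f"SNAP_P_{p:02d}" for p in [1, 2, 3, 19, 20]]
        sub = oi.subset_registry(registry, item_ids=ids)
        cohort = oi.generate_cohort(sub, oi.CohortConfig(n_case=30, n_control=30, seed=1))
        masked = oi.apply_missingness(cohort, sub, oi.MissingnessPattern(item_mcar_rate=0.2, seed=2))
        res = oi.run_iterative_imputation(
            masked, sub, cheap_hyperparams(max_epochs=20),
            oi.ImputeOptions(exclude_odd_items=True),
        )
        assert sorted(res.imputation_order) == ["SNAP_P_01", "SNAP_P_02", "SNAP_P_03"]
        assert res.completed_cohort.item_ids == ["SNAP_P_01", "SNAP_P_02", "SNAP_P_03"]
        assert res.completed_cohort.count_missing() == 0

    def test_sparse_item_policies(self, small_registry, tiny_cohort):
        items = tiny_cohort.item_matrix()
        items[:, 0] = np.nan
        items[:3, 0] = [0, 1, 1]  # only 3 observed responses
        cohort = tiny_cohort.with_items(items)
        with pytest.raises(InsufficientDataError):
            oi.run_iterative_imputation(
                cohort, small_registry, cheap_hyperparams(max_epochs=20),
                oi.ImputeOptions(sparse_policy="error"),
            )
        res = oi.run_iterative_imputation(
            cohort, small_registry, cheap_hyperparams(max_epochs=20)
        )
        assert res.imputation_order[-1] == cohort.item_ids[0]
        assert res.records[-1].deferred
        assert res.completed_cohort.count_missing() == 0


class TestAssignTiers:
    @pytest.mark.parametrize(
        "n,expected",
        [(107, (35, 37, 35)), (6, (2, 2, 2)), (7, (2, 3, 2))],
    )
    def test_tier_sizes(self, n, expected):
        order = [f"item_{i}" for i in range(n)]
        tiers = oi.assign_tiers(order)
        sizes = tuple(
            sum(1 for t in tiers.values() if t == tier)
            for tier in (oi.Tier.TOP, oi.Tier.INTERMEDIATE, oi.Tier.BOTTOM)
        )
        assert sizes == expected

    def test_empty_order_rejected(self):
        with pytest.raises(ValueError):
            oi.assign_tiers([])

    @given(st.integers(min_value=1, max_value=400))
    @settings(max_examples=50, deadline=None)
    def test_thirds_property(self, n):
        tiers = oi.assign_tiers([str(i) for i in range(n)])
        top = sum(1 for t in tiers.values() if t == oi.Tier.TOP)
        bottom = sum(1 for t in tiers.values() if t == oi.Tier.BOTTOM)
        assert top == bottom == n // 3
        assert len(tiers) == n


class TestMeanImpute:
    def test_rounding_examples(self, tiny_cohort):
        items = tiny_cohort.item_matrix()
        items[:, 0] = np.nan
        items[:3, 0] = [0, 1, 3]  # mean 4/3 -> 1
        items[:, 1] = np.nan
        items[:2, 1] = [3, 3]  # -> 3
        items[:, 2] = np.nan
        items[:2, 2] = [1, 2]  # mean 1.5, half rounds up -> 2
        out = oi.mean_impute(tiny_cohort.with_items(items))
        filled = out.item_matrix()
        assert (filled[3:, 0] == 1).all()
        assert (filled[2:, 1] == 3).all()
        assert (filled[2:, 2] == 2).all()

    def test_complete_cohort_identity(self, tiny_cohort):
        assert oi.mean_impute(tiny_cohort).equals(tiny_cohort)

    def test_all_missing_item_rejected(self, tiny_cohort):
        items = tiny_cohort.item_matrix()
        items[:, 0] = np.nan
        with pytest.raises(ValueError, match=tiny_cohort.item_ids[0]):
            oi.mean_impute(tiny_cohort.with_items(items))


class TestInterpolateImpute:
    def test_midpoint_and_end_extension(self, small_registry, tiny_cohort):
        items = tiny_cohort.item_matrix()
        items[0, :3] = [0, np.nan, 2]   # positions 1..3 -> midpoint 1
        items[1, 0] = np.nan            # leading gap -> nearest observed
        items[1, 1] = 2
        out = oi.interpolate_impute(tiny_cohort.with_items(items), small_registry)
        filled = out.item_matrix()
        assert filled[0, 1] == 1
        assert filled[1, 0] == 2

    def test_complete_identity(self, small_registry, tiny_cohort):
        assert oi.interpolate_impute(tiny_cohort, small_registry).equals(tiny_cohort)

    def test_fully_missing_scale_falls_back_to_mean(self, small_registry, tiny_cohort):
        items = tiny_cohort.item_matrix()
        items[0, :] = np.nan  # whole (single-scale) row missing
        out = oi.interpolate_impute(tiny_cohort.with_items(items), small_registry)
        expected = oi.mean_impute(tiny_cohort.with_items(items)).item_matrix()[0]
        assert (out.item_matrix()[0] == expected).all()


class TestMultipleImpute:
    def test_preserves_observed_in_every_table(self, small_registry, masked_tiny):
        tables = oi.multiple_impute(masked_tiny, m=3, seed=1)
        assert len(tables) == 3
        before = masked_tiny.item_matrix()
        obs = ~np.isnan(before)
        for t in tables:
            after = t.item_matrix()
            assert (after[obs] == before[obs]).all()
            assert t.count_missing() == 0

    def test_collinear_item_recovered(self, small_registry, tiny_cohort):
        """A noise-free copy of another item is recovered almost exactly:
        the chained linear regression has zero residual, so redraws match
        the deterministic value."""
        items = tiny_cohort.item_matrix()
        items[:, 1] = items[:, 0]
        rng = np.random.default_rng(3)
        miss = rng.random(len(items)) < 0.3
        truth = items[:, 1].copy()
        items[miss, 1] = np.nan
        tables = oi.multiple_impute(tiny_cohort.with_items(items), m=3, seed=2)
        for t in tables:
            agree = (t.item_matrix()[miss, 1] == truth[miss]).mean()
            assert agree >= 0.9

    def test_complete_cohort_all_tables_identical(self, tiny_cohort):
        tables = oi.multiple_impute(tiny_cohort, m=2, seed=0)
        for t in tables:
            assert t.equals(tiny_cohort)

    def test_m_below_two_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            oi.multiple_impute(tiny_cohort, m=1, seed=0)


class TestAllImputersContract:
    """Completeness + preservation for every imputer on one masked cohort."""

    def test_contract(self, small_registry, masked_tiny):
        before = masked_tiny.item_matrix()
        obs = ~np.isnan(before)
        completions = {
            "mean": oi.mean_impute(masked_tiny),
            "interpolate": oi.interpolate_impute(masked_tiny, small_registry),
            "mice": oi.multiple_impute(masked_tiny, m=2, seed=5)[0],
            "dnn": oi.run_iterative_imputation(
                masked_tiny, small_registry, cheap_hyperparams(max_epochs=15)
            ).completed_cohort,
        }
        for name, done in completions.items():
            after = done.item_matrix()
            assert done.count_missing() == 0, name
            assert (after[obs] == before[obs]).all(), name
            assert np.isin(after, [0, 1, 2, 3]).all(), name
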