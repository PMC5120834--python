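"""Thinning, pseudo-absence design, extraction and variable selection."""

import numpy as np
import pandas as pd
import pytest

from ensdm.grids import EnvStack, Grid
from ensdm.occurrences import PSEUDO_ABSENCE, OccurrenceSet
from ensdm.preprocess import (
    ModelTable,
    extract_env,
    generate_pseudo_absences,
    partition,
    screen_collinearity,
    stepwise_aic,
    thin_by_cell,
)


def occ_at(points, species="sp"):
    return OccurrenceSet(
        pd.DataFrame({"species": species, "x": [p[0] for p in points], "y": [p[1] for p in points]})
    )


@pytest.fixture()
def template():
    return Grid(np.zeros((10, 10)), cell_size=1.0)


class TestThinning:
    def test_five_records_one_cell(self, template):
        occ = occ_at([(2.1, 3.1), (2.5, 3.5), (2.9, 3.9), (2.2, 3.8), (2.7, 3.2)])
        assert len(thin_by_cell(occ, template, seed=0)) == 1

    def test_distinct_cells_untouched(self, template):
        occ = occ_at([(0.5, 0.5), (1.5, 1.5), (2.5, 2.5), (3.5, 3.5)])
        assert len(thin_by_cell(occ, template, seed=0)) == 4

    def test_idempotent(self, template):
        rng = np.random.default_rng(1)
        occ = occ_at(list(zip(rng.uniform(0, 10, 60), rng.uniform(0, 10, 60))))
        once = thin_by_cell(occ, template, seed=3)
        twice = thin_by_cell(once, template, seed=99)  # any seed: groups are singletons
        assert once.records.equals(twice.records)

    def test_empty_input(self, template):
        assert len(thin_by_cell(OccurrenceSet(), template, seed=0)) == 0

    def test_deterministic(self, template):
        occ = occ_at([(2.1, 3.1), (2.5, 3.5), (2.9, 3.9)])
        a = thin_by_cell(occ, template, seed=7).records
        b = thin_by_cell(occ, template, seed=7).records
        assert a.equals(b)


class TestPseudoAbsences:
    def test_ten_to_one_ratio(self):
        template = Grid(np.zeros((50, 50)), cell_size=1.0)
        pres = occ_at([(0.5, 0.5), (1.5, 1.5)] * 10)  # 20 presences
        out = generate_pseudo_absences(pres, template, ratio=10, seed=0)
        assert out.n_presence == 20
        assert out.n_pseudo_absence == 200

    def test_ratio_zero_presences_only(self, template):
        pres = occ_at([(0.5, 0.5)])
        out = generate_pseudo_absences(pres, template, ratio=0, seed=0)
        assert out.n_pseudo_absence == 0 and out.n_presence == 1

    def test_no_shared_cell_with_presence(self, template):
        pres = occ_at([(0.5, 0.5), (5.5, 5.5)])
        out = generate_pseudo_absences(pres, template, ratio=10, seed=1)
        row, col = template.cell_index(out.records["x"], out.records["y"])
        cells = list(zip(row, col))
        pres_cells = {cells[i] for i in range(2)}
        assert not pres_cells & set(cells[2:])

    def test_insufficient_land_errors(self):
        tiny = Grid(np.zeros((3, 3)))
        pres = occ_at([(0.5, 0.5)])
        with pytest.raises(ValueError, match="insufficient"):
            generate_pseudo_absences(pres, tiny, ratio=10, seed=0)

    def test_presences_unchanged(self, template):
        pres = occ_at([(0.5, 0.5), (3.5, 2.5)])
        out = generate_pseudo_absences(pres, template, ratio=5, seed=2)
        pd.testing.assert_frame_equal(
            out.records.iloc[:2].reset_index(drop=True), pres.records
        )


class TestExtract:
    def test_direct_lookup_and_sea_drop(self):
        vals = np.array([[9.4, np.nan], [1.0, 2.0]])
        env = EnvStack(layers={"BIO10": Grid(vals)})
        occ = occ_at([(0.5, 0.5), (1.5, 0.5), (1.5, 1.5)])
        table = extract_env(occ, env)
        assert table.n == 2  # sea row dropped
        assert table.covariates["BIO10"].iloc[0] == 9.4

    def test_missing_layer_named(self):
        env = EnvStack(layers={"BIO10": Grid(np.ones((2, 2)))})
        occ = occ_at([(0.5, 0.5)])
        with pytest.raises(KeyError, match="BIO11"):
            extract_env(occ, env, layers=["BIO11"])

    def test_weights_balance_classes(self, template):
        pres = occ_at([(0.5, 0.5), (1.5, 1.5)])
        aug = generate_pseudo_absences(pres, template, ratio=10, seed=0)
        env = EnvStack(layers={"z": template.copy_with(np.random.default_rng(0).random((10, 10)))})
        table = extract_env(aug, env)
        assert table.weight[table.label == 1].sum() == pytest.approx(
            table.weight[table.label == 0].sum()
        )


class TestScreenCollinearity:
    def _table(self, data):
        df = pd.DataFrame(data)
        y = np.zeros(len(df), dtype=int)
        y[: len(df) // 2] = 1
        return ModelTable(covariates=df, label=y)

    def test_duplicated_column_keeps_priority(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        t = self._table({"a": x, "b": x.copy()})
        assert screen_collinearity(t, priority=["b", "a"]) == ["b"]

    def test_independent_noise_retained(self):
        rng = np.random.default_rng(1)
        t = self._table({"a": rng.standard_normal(500), "b": rng.standard_normal(500)})
        assert set(screen_collinearity(t)) == {"a", "b"}

    def test_three_way_cluster_keeps_top_priority(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        t = self._table(
            {"a": x, "b": x + 0.1 * rng.standard_normal(200), "c": x + 0.1 * rng.standard_normal(200)}
        )
        assert screen_collinearity(t, priority=["c", "a", "b"]) == ["c"]

    def test_zero_variance_warned_and_dropped(self):
        rng = np.random.default_rng(3)
        t = self._table({"a": rng.standard_normal(30), "const": np.ones(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = screen_collinearity(t)
        assert out == ["a"]

    def test_retained_pairwise_r_below_cut(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((300, 3))
        df = {
            "a": base[:, 0],
            "b": 0.9 * base[:, 0] + 0.3 * rng.standard_normal(300),
            "c": base[:, 1],
            "d": 0.95 * base[:, 1] + 0.2 * rng.standard_normal(300),
            "e": base[:, 2],
        }
        t = self._table(df)
        kept = screen_collinearity(t, r_cut=0.7)
        corr = t.covariates[kept].corr().to_numpy()
        off = corr[~np.eye(len(kept), dtype=bool)]
        assert (np.abs(off) <= 0.7).all()


class TestStepwiseAic:
    def test_recovers_true_covariate(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(3 * x)))
        y = rng.random(n) < p
        df = pd.DataFrame(
            {"true": x, "n1": rng.standard_normal(n), "n2": rng.standard_normal(n)}
        )
        t = ModelTable(covariates=df, label=y.astype(int))
        selected = stepwise_aic(t, max_vars=2)
        assert "true" in selected

    def test_empty_candidates(self, separable_table):
        assert stepwise_aic(separable_table, candidates=[]) == []

    def test_max_vars_from_presence_count(self):
        # 20 presences -> floor(20/10) = 2 variables at most
        rng = np.random.default_rng(6)
        n1, n0 = 20, 200
        x = np.concatenate([rng.normal(2, 1, n1), rng.normal(0, 1, n0)])
        df = pd.DataFrame({f"v{j}": x + rng.standard_normal(n1 + n0) for j in range(5)})
        y = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
        t = ModelTable(covariates=df, label=y)
        assert len(stepwise_aic(t)) <= 2

    def test_separation_falls_back_with_warning(self, separable_table):
        with pytest.warns(UserWarning, match="penalised"):
            selected = stepwise_aic(separable_table)
        assert selected == ["x0"]


class TestPartition:
    def _table(self, n=100, n_pos=20):
        rng = np.random.default_rng(7)
        y = np.zeros(n, int)
        y[:n_pos] = 1
        return ModelTable(covariates=pd.DataFrame({"x": rng.standard_normal(n)}), label=y)

    def test_eighty_twenty_sizes(self):
        t = self._table()
        splits = partition(t, train_frac=0.8, n_rep=10, seed=0)
        assert len(splits) == 10
        for train, test in splits:
            assert len(train) == 80 and len(test) == 20

    def test_partition_covers_all_rows_disjointly(self):
        t = self._table()
        for train, test in partition(t, n_rep=3, seed=1):
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(range(t.n))

    def test_stratified_presences_in_test(self):
        t = self._table(n=110, n_pos=10)
        for _, test in partition(t, n_rep=10, seed=2):
            assert t.label[test].sum() >= 1

    def test_reproducible(self):
        t = self._table()
        a = partition(t, n_rep=2, seed=5)
        b = partition(t, n_rep=2, seed=5)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_small_class_rejected(self):
        t = self._table(n=30, n_pos=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            partition(t)
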