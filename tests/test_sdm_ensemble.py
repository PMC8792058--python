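import numpy as np
import pandas as pd
import pytest

from finerange.grid import RasterGrid
from finerange.sdm_ensemble import (
    FAMILIES,
    ModelRunSpec,
    auc,
    cross_validate,
    default_model_specs,
    fit_predict,
    sample_pseudo_absences,
    tss,
)


class TestAUC:
    def test_perfect_and_inverted_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_enumerated_four_point_case(self):
        # 3 concordant of 4 positive-negative pairs
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(4, 20)
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
            assert auc(scores, labels) == pytest.approx(np.mean(pairs), abs=1e-12)


class TestTSS:
    def test_perfect_classifier(self):
        assert tss(10, 0, 10, 0) == 1.0

    def test_arithmetic_from_definition(self):
        assert tss(40, 10, 30, 20) == pytest.approx(0.4)

    def test_chance_level_is_zero(self):
        assert tss(5, 5, 5, 5) == pytest.approx(0.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            tss(0, 0, 5, 5)


@pytest.fixture()
def domain():
    return RasterGrid(np.zeros((20, 20)), cell_m=50.0, x0=0.0, y0=1000.0)


class TestPseudoAbsences:
    spec = ModelRunSpec("RF", pa_count=100, pa_sets=2, seed=3)

    def test_exact_count(self, domain):
        pres = pd.DataFrame({"x": [25.0], "y": [975.0]})
        assert len(sample_pseudo_absences(domain, pres, self.spec)) == 100

    def test_never_shares_a_cell_with_a_presence(self, domain):
        pres = pd.DataFrame({"x": [25.0, 75.0], "y": [975.0, 925.0]})
        pas = sample_pseudo_absences(domain, pres, self.spec)
        pr, pc = domain.cell_index(pres["x"].to_numpy(), pres["y"].to_numpy())
        ar, ac = domain.cell_index(pas["x"].to_numpy(), pas["y"].to_numpy())
        assert set(zip(ar, ac)).isdisjoint(set(zip(pr, pc)))

    def test_seeded_and_distinct_per_set(self, domain):
        pres = pd.DataFrame({"x": [25.0], "y": [975.0]})
        a = sample_pseudo_absences(domain, pres, self.spec, pa_set=0)
        b = sample_pseudo_absences(domain, pres, self.spec, pa_set=0)
        c = sample_pseudo_absences(domain, pres, self.spec, pa_set=1)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_insufficient_cells_rejected(self, domain):
        spec = ModelRunSpec("RF", pa_count=500, seed=0)
        with pytest.raises(ValueError):
            sample_pseudo_absences(domain, pd.DataFrame({"x": [], "y": []}), spec)


def axes_pair(n=20):
    pc1 = RasterGrid(np.tile(np.linspace(-2, 2, n), (n, 1)), 50.0)
    pc2 = pc1.like(np.tile(np.linspace(-1, 1, n)[:, None], (1, n)))
    return pc1, pc2


class TestFitPredict:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_signal_recovered_by_every_family(self, family, rng):
        X = np.column_stack([rng.uniform(-2, 2, 300), rng.uniform(-1, 1, 300)])
        y = (X[:, 0] > 0).astype(int)
        pc1, pc2 = axes_pair()
        suit = fit_predict(family, X, y, (pc1, pc2), seed=0)
        assert np.nanmin(suit.data) >= 0 and np.nanmax(suit.data) <= 1
        hi = suit.data[pc1.data > 0].mean()
        lo = suit.data[pc1.data < 0].mean()
        assert hi > lo

    def test_constant_predictors_give_prevalence_for_glm(self, rng):
        X = np.zeros((200, 2))
        y = (rng.random(200) < 0.3).astype(int)
        pc1, pc2 = axes_pair(5)
        suit = fit_predict("GLM", X, y, (pc1.like(np.zeros((5, 5))), pc2.like(np.zeros((5, 5)))))
        assert suit.data[2, 2] == pytest.approx(y.mean(), abs=0.01)

    def test_single_class_rejected(self):
        pc1, pc2 = axes_pair(5)
        with pytest.raises(ValueError):
            fit_predict("GLM", np.zeros((10, 2)), np.ones(10), (pc1, pc2))

    def test_nodata_propagates(self, rng):
        X = np.column_stack([rng.uniform(-2, 2, 100), rng.uniform(-1, 1, 100)])
        y = (X[:, 0] > 0).astype(int)
        pc1, pc2 = axes_pair(6)
        pc1.data[0, 0] = np.nan
        suit = fit_predict("GLM", X, y, (pc1, pc2))
        assert np.isnan(suit.data[0, 0])


class TestCrossValidate:
    def _data(self, rng, n=120, noise=0.0):
        X = np.column_stack([rng.uniform(-2, 2, n), rng.uniform(-1, 1, n)])
        y = (X[:, 0] + rng.normal(0, noise, n) > 0).astype(int)
        return X, y

    def test_record_cardinality(self, rng):
        spec = ModelRunSpec("CTA", pa_sets=2, cv_repeats=10, seed=1)
        datasets = [self._data(rng), self._data(rng)]
        records = cross_validate("CTA", datasets, spec)
        assert len(records) == 20
        assert {(r.pa_set, r.repeat) for r in records} == {
            (s, r) for s in range(2) for r in range(10)
        }

    def test_deterministic_labels_give_high_auc(self, rng):
        spec = ModelRunSpec("GLM", cv_repeats=10, seed=1)
        records = cross_validate("GLM", [self._data(rng)], spec)
        assert np.mean([r.auc for r in records]) > 0.95

    def test_shuffled_labels_give_chance_auc(self, rng):
        X, y = self._data(rng, n=200)
        y = rng.permutation(y)
        spec = ModelRunSpec("GLM", cv_repeats=10, seed=1)
        records = cross_validate("GLM", [(X, y)], spec)
        assert 0.4 <= np.mean([r.auc for r in records]) <= 0.6

    def test_metrics_come_from_heldout_data(self, rng):
        """An overfitting learner still scores imperfectly on noisy held-out data."""
        X, y = self._data(rng, n=150, noise=1.0)
        spec = ModelRunSpec("RF", cv_repeats=5, seed=2)
        records = cross_validate("RF", [(X, y)], spec)
        assert all(r.auc < 1.0 for r in records)


def test_default_specs_follow_family_recommendations():
    specs = default_model_specs(seed=0)
    assert specs["GLM"].pa_count == 10_000 and specs["GLM"].pa_sets == 3
    assert specs["RF"].pa_count is None and specs["RF"].pa_sets == 10
    assert specs["RF"].resolved_pa_count(150) == 150
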