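"""Descriptor pools, stepwise selection, and the LDA discriminant fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcrpqsar import (
    DescriptorMatrix,
    DiscriminantModel,
    SelectionConfig,
    build_model,
    fit_lda,
    generate_pools,
    stepwise_select,
)


def _blocks(sizes: dict[str, int]) -> dict[str, list[str]]:
    return {b: [f"{b}_{i}" for i in range(n)] for b, n in sizes.items()}


class TestGeneratePools:
    def test_sizes_fall_in_band(self):
        blocks = _blocks({"a": 50, "b": 80, "c": 70, "d": 40})
        pools = generate_pools(blocks, n_pools=8, target_size=200, seed=0)
        assert len(pools) == 8
        for p in pools:
            assert 160 <= p.size <= 240

    def test_infeasible_target_raises_with_range(self):
        with pytest.raises(ValueError, match="feasible"):
            generate_pools(_blocks({"a": 30, "b": 5}), n_pools=3, target_size=200)

    def test_deterministic_for_seed(self):
        blocks = _blocks({"a": 60, "b": 70, "c": 80, "d": 90, "e": 100})
        a = generate_pools(blocks, 102, 200, seed=42)
        b = generate_pools(blocks, 102, 200, seed=42)
        assert [p.block_names for p in a] == [p.block_names for p in b]

    def test_duplicates_only_when_unavoidable(self):
        blocks = _blocks({"a": 100, "b": 100})
        pools = generate_pools(blocks, n_pools=5, target_size=200, seed=1)
        # only one feasible combination exists; it must be reused
        assert all(p.block_names == ("a", "b") for p in pools)


def _signal_frame(rng, n=164, n_noise=20, gap=2.0):
    labels = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)]).astype(int)
    strong = rng.standard_normal(n) + gap / 2 * labels
    data = {"strong": strong}
    for j in range(n_noise):
        data[f"noise{j:02d}"] = rng.standard_normal(n)
    return pd.DataFrame(data), labels


class TestStepwiseSelect:
    def test_strong_discriminator_enters_first(self, rng):
        x, y = _signal_frame(rng)
        selected = stepwise_select(x, y, SelectionConfig())
        assert selected[0] == "strong"
        # brute-force F-to-enter at step 1: strong must maximize it
        def f_enter(col):
            r = stats.pearsonr(x[col], y)[0]
            return r**2 / (1 - r**2) * (len(y) - 2)
        best = max(x.columns, key=f_enter)
        assert best == "strong"

    def test_perfectly_collinear_candidate_never_enters(self, rng):
        x, y = _signal_frame(rng, n_noise=3)
        x["copy_of_strong"] = x["strong"] * 2.0 + 1.0  # tolerance 0 on the twin
        selected = stepwise_select(x, y, SelectionConfig(max_steps=10))
        # whichever twin enters first, the perfectly collinear other never does
        assert ("strong" in selected) != ("copy_of_strong" in selected)

    def test_cases_per_predictor_caps_model_size(self, rng):
        n = 164
        y = np.where(rng.random(n) < 0.5, 1, -1)
        # many strong independent predictors of a continuous target built from y
        x = pd.DataFrame(
            {f"d{j:02d}": y * 1.0 + rng.standard_normal(n) * 0.1 for j in range(30)}
        )
        selected = stepwise_select(
            x, y, SelectionConfig(max_steps=30, min_cases_per_predictor=11,
                                  tolerance_min=0.01)
        )
        assert len(selected) <= 164 // 11  # = 14

    def test_selection_is_deterministic(self, rng):
        x, y = _signal_frame(rng, n_noise=10)
        assert stepwise_select(x, y, SelectionConfig()) == stepwise_select(
            x, y, SelectionConfig()
        )

    def test_zero_variance_descriptor_skipped(self, rng):
        x, y = _signal_frame(rng, n_noise=2)
        x["flat"] = 3.14
        selected = stepwise_select(x, y, SelectionConfig())
        assert "flat" not in selected


class TestFitLDA:
    def test_symmetric_1d_boundary_at_zero(self):
        rng = np.random.default_rng(0)
        n = 400
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)]).astype(int)
        x = pd.DataFrame({"d": y + rng.standard_normal(n) * 0.8})
        model = fit_lda(x, y)
        # boundary sits near the midpoint 0; calls follow the side of it
        boundary = -model.intercept / model.coefficients[0]
        assert boundary == pytest.approx(0.0, abs=0.15)
        calls = model.classify(x)
        d = x["d"].to_numpy()
        assert (calls[d > boundary] == 1).all()
        assert (calls[d < boundary] == -1).all()

    def test_separable_toy_set_is_perfectly_classified(self):
        x = pd.DataFrame(
            {"u": [2.0, 2.5, 3.0, -2.0, -2.5, -3.0],
             "v": [1.0, 0.5, 1.5, -1.0, -0.5, -1.2]}
        )
        y = np.array([1, 1, 1, -1, -1, -1])
        model = fit_lda(x, y)
        assert (model.classify(x) == y).all()

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(3)
        accs = []
        for rep in range(20):
            n = 400
            x = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
            y = np.where(rng.permutation(n) < n // 2, 1, -1)
            model = fit_lda(x, y)
            accs.append(np.mean(model.classify(x) == y))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_singular_covariance_names_collinear_descriptors(self):
        x = pd.DataFrame({"p": [1.0, 2.0, 3.0, 4.0], "q": [2.0, 4.0, 6.0, 8.0]})
        y = np.array([1, 1, -1, -1])
        with pytest.raises(ValueError, match="collinear|singular"):
            fit_lda(x, y)

    def test_agrees_with_sklearn_lda_boundary(self):
        """Pooled-covariance LDA matches the reference implementation's
        class boundary on two-Gaussian data (independent route)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(8)
        n = 300
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)]).astype(int)
        x = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        x.iloc[:, 0] += 0.8 * y
        model = fit_lda(x, y)
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(x, y)
        assert np.array_equal(model.classify(x), ref.predict(x))


class TestScore:
    def test_df_arithmetic(self):
        model = DiscriminantModel(descriptors=["d1", "d2"],
                                  coefficients=np.array([1.0, -2.0]),
                                  intercept=0.5, n_train=10)
        row = pd.DataFrame({"d1": [0.3], "d2": [0.1]})
        assert model.score(row)[0] == pytest.approx(0.6)
        assert model.classify(row)[0] == 1

    def test_df_zero_is_called_nonsubstrate(self):
        model = DiscriminantModel(descriptors=["d"], coefficients=np.array([1.0]),
                                  intercept=0.0, n_train=10)
        assert model.classify(pd.DataFrame({"d": [0.0]}))[0] == -1

    def test_all_zero_descriptors_give_intercept(self):
        model = DiscriminantModel(descriptors=["d"], coefficients=np.array([3.0]),
                                  intercept=-1.25, n_train=10)
        assert model.score(pd.DataFrame({"d": [0.0]}))[0] == pytest.approx(-1.25)

    def test_missing_descriptor_column_raises(self):
        model = DiscriminantModel(descriptors=["d"], coefficients=np.array([1.0]),
                                  intercept=0.0, n_train=10)
        with pytest.raises(ValueError, match="lacks"):
            model.score(pd.DataFrame({"other": [1.0]}))

    def test_round_trip_json_dict(self):
        model = DiscriminantModel(descriptors=["d1", "d2"],
                                  coefficients=np.array([1.5, -0.5]),
                                  intercept=0.25, pool_id=3, n_train=100)
        back = DiscriminantModel.from_dict(model.to_dict())
        assert back.descriptors == model.descriptors
        assert np.allclose(back.coefficients, model.coefficients)
        assert back.intercept == model.intercept


def test_built_models_respect_invariants(small_dataset):
    """Every emitted model keeps cases/predictor >= floor and tolerances
    >= the configured minimum."""
    ds = small_dataset
    cfg = SelectionConfig(tolerance_min=0.1, max_steps=10)
    pools = generate_pools(ds.matrix.blocks, n_pools=5, target_size=60, seed=0)
    built = [m for m in (build_model(ds.matrix, ds.labels, p, cfg) for p in pools) if m]
    assert built, "expected at least one model"
    for m in built:
        assert m.cases_per_predictor >= cfg.min_cases_per_predictor
        assert all(t >= cfg.tolerance_min - 1e-9 for t in m.tolerances.values())
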