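"""Scaled PCA, cos2/loading thresholds, kinetics and the full funnel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ptrvoc.selection import (
    DegenerateColumnError,
    FeatureMatrix,
    PcaModel,
    SelectionConfig,
    classify_kinetics,
    filter_cos2,
    filter_loading,
    fit_pca,
    orient_model,
    scale_matrix,
    select_from_matrix,
)
from ptrvoc.synthetic import default_scenario, generate_experiment, planted_decay_channels
from ptrvoc import run_selection


def _df(arr, prefix="c"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def test_scale_closed_form():
    scaled = scale_matrix(_df([[1.0], [2.0], [3.0]]))
    expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3.0 / 2.0)
    assert np.allclose(scaled["c0"], expected)


def test_scale_idempotent(rng):
    scaled = scale_matrix(_df(rng.normal(size=(10, 4))))
    again = scale_matrix(scaled)
    assert np.allclose(scaled.to_numpy(), again.to_numpy(), atol=1e-12)


def test_scale_moments(rng):
    scaled = scale_matrix(_df(rng.normal(2.0, 3.0, size=(50, 6))))
    arr = scaled.to_numpy()
    assert np.all(np.abs(arr.mean(axis=0)) < 1e-10)
    assert np.allclose(arr.var(axis=0), 1.0, atol=1e-10)


def test_scale_rejects_constant_column_by_name():
    df = _df([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
    with pytest.raises(DegenerateColumnError, match="c0"):
        scale_matrix(df)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_perfectly_correlated_columns(rng):
    x = rng.normal(size=12)
    model = fit_pca(scale_matrix(_df(np.column_stack([x, 2.0 * x + 1.0]))))
    assert model.explained_var["PC1"] == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(model.cos2["PC1"], 1.0, atol=1e-12)


def test_two_column_explained_variance_is_eigenvalue_formula(rng):
    # correlation-matrix eigenvalues for 2 variables are (1 +/- |r|)/2 of total
    a = rng.normal(size=30)
    b = 0.6 * a + rng.normal(size=30)
    df = _df(np.column_stack([a, b]))
    r = np.corrcoef(df["c0"], df["c1"])[0, 1]
    model = fit_pca(scale_matrix(df))
    assert model.explained_var["PC1"] == pytest.approx((1 + abs(r)) / 2, abs=1e-10)
    assert model.explained_var["PC2"] == pytest.approx((1 - abs(r)) / 2, abs=1e-10)


@pytest.mark.parametrize("shape", [(6, 4), (8, 8), (5, 8)])
def test_pca_matches_dense_eigendecomposition(rng, shape):
    scaled = scale_matrix(_df(rng.normal(size=shape)))
    model = fit_pca(scaled)
    n, p = shape
    corr = scaled.to_numpy().T @ scaled.to_numpy() / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    eigvals = eigvals[::-1][: len(model.dims)]
    eigvecs = eigvecs[:, ::-1][:, : len(model.dims)]
    assert np.allclose(model.explained_var.to_numpy() * p, eigvals, atol=1e-8)
    # eigenvector directions are only defined for non-degenerate components
    keep = eigvals > 1e-10
    expected_coords = np.abs(eigvecs[:, keep] * np.sqrt(eigvals[keep]))
    assert np.allclose(
        np.abs(model.var_coords.to_numpy()[:, keep]), expected_coords, atol=1e-8
    )


def test_pca_matches_sklearn(rng):
    from sklearn.decomposition import PCA

    scaled = scale_matrix(_df(rng.normal(size=(9, 5))))
    model = fit_pca(scaled)
    sk = PCA().fit(scaled.to_numpy())
    n = 9
    # sklearn reports sample (n-1) variances of the scores
    assert np.allclose(
        sk.explained_variance_ * (n - 1) / n,
        model.explained_var.to_numpy() * 5,
        atol=1e-10,
    )
    assert np.allclose(
        np.abs(sk.transform(scaled.to_numpy())), np.abs(model.scores.to_numpy()), atol=1e-8
    )


@pytest.mark.parametrize("shape", [(12, 5), (4, 9)])
def test_cos2_conservation(rng, shape):
    # across all components each compound's cos2 sums to 1 (trace of the
    # correlation matrix), including the rank-deficient samples < compounds case
    model = fit_pca(scale_matrix(_df(rng.normal(size=shape))))
    assert np.allclose(model.cos2.sum(axis=1), 1.0, atol=1e-8)


# ---------------------------------------------------------------------------
# orientation and thresholds
# ---------------------------------------------------------------------------


def _labelled_matrix(rng, n_per=2):
    fungal = rng.normal(5.0, 0.1, size=(n_per, 4))
    plant = rng.normal(0.0, 0.1, size=(n_per, 4))
    values = _df(np.vstack([fungal, plant]))
    values.index = [f"f{i}" for i in range(n_per)] + [f"p{i}" for i in range(n_per)]
    labels = pd.Series(["fungal"] * n_per + ["plant"] * n_per, index=values.index)
    return values, labels


def test_orientation_makes_fungal_scores_negative(rng):
    values, labels = _labelled_matrix(rng)
    model = orient_model(fit_pca(scale_matrix(values)), labels)
    assert model.scores.loc[labels == "fungal", "PC1"].mean() < 0
    again = orient_model(model, labels)
    assert again.scores.equals(model.scores)  # already oriented: unchanged


def test_orientation_flips_scores_and_coords_together(rng):
    values, labels = _labelled_matrix(rng)
    model = fit_pca(scale_matrix(values))
    flipped = PcaModel(
        scores=model.scores.assign(PC1=-model.scores["PC1"]),
        var_coords=model.var_coords.assign(PC1=-model.var_coords["PC1"]),
        eigvecs=model.eigvecs.assign(PC1=-model.eigvecs["PC1"]),
        explained_var=model.explained_var,
    )
    a = orient_model(model, labels)
    b = orient_model(flipped, labels)
    assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())
    assert np.allclose(a.var_coords.to_numpy(), b.var_coords.to_numpy())
    assert np.allclose(a.cos2.to_numpy(), model.cos2.to_numpy())


def test_orientation_requires_fungal_samples(rng):
    values, labels = _labelled_matrix(rng)
    with pytest.raises(ValueError, match="fungal"):
        orient_model(fit_pca(scale_matrix(values)), labels.replace("fungal", "plant"))


def _toy_model(coords_dim1, coords_dim2, oriented=True):
    ids = [f"c{i}" for i in range(len(coords_dim1))]
    coords = pd.DataFrame({"PC1": coords_dim1, "PC2": coords_dim2}, index=ids)
    scores = pd.DataFrame(np.zeros((3, 2)), columns=["PC1", "PC2"])
    ev = pd.Series([0.6, 0.4], index=["PC1", "PC2"])
    return PcaModel(scores=scores, var_coords=coords, eigvecs=coords, explained_var=ev, oriented=oriented)


def test_cos2_filter_boundary_kept():
    # cos2 sums 0.1, 0.25, 0.9 -> boundary value kept, 2 survive
    model = _toy_model(
        np.sqrt([0.05, 0.125, 0.45]), np.sqrt([0.05, 0.125, 0.45])
    )
    assert filter_cos2(model, 0.25) == ["c1", "c2"]
    perfect = _toy_model([1.0], [0.0])
    assert filter_cos2(perfect, 0.25) == ["c0"]
    with pytest.raises(ValueError):
        filter_cos2(model, 1.5)


def test_loading_filter_strict_inequality():
    model = _toy_model([-0.5, -0.2, -0.19, 0.4], [0.0, 0.0, 0.0, 0.0])
    kept = filter_loading(model, ["c0", "c1", "c2", "c3"], -0.20)
    assert kept == ["c0"]


def test_loading_filter_requires_orientation():
    model = _toy_model([-0.5], [0.0], oriented=False)
    with pytest.raises(ValueError, match="orient"):
        filter_loading(model, ["c0"])


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def test_classify_kinetics_shapes():
    cfg = SelectionConfig()
    n = 2700
    t = np.arange(n)
    assert classify_kinetics(np.full(n, 7.0), cfg) == "constant"
    halving = 10.0 * np.exp(-np.log(2) / n * t)
    assert classify_kinetics(halving, cfg) == "decay"
    assert classify_kinetics(1.0 + t / n, cfg) == "rise"  # doubles: rho ~ +1
    with pytest.raises(ValueError, match="short"):
        classify_kinetics(np.ones(100), cfg)


# ---------------------------------------------------------------------------
# full funnel
# ---------------------------------------------------------------------------


def test_default_scenario_recovers_planted_set():
    scenario = default_scenario(seed=11)
    runs = generate_experiment(scenario)
    result = run_selection(runs)
    assert set(result.retained_ids) == planted_decay_channels(scenario)
    assert result.n_final == 12
    assert result.n_input >= result.n_after_cos2 >= result.n_after_loading >= result.n_final


def test_selection_invariant_under_sample_permutation():
    scenario = default_scenario(seed=12)
    runs = generate_experiment(scenario)
    forward = run_selection(runs)
    backward = run_selection(list(reversed(runs)))
    assert forward.retained_ids == backward.retained_ids
    assert forward.n_after_cos2 == backward.n_after_cos2


def test_no_signal_matrix_selects_nothing(rng):
    values = _df(rng.normal(size=(9, 20)))
    labels = pd.Series(["plant"] * 3 + ["fungal"] * 3 + ["cocultivation"] * 3, index=values.index)
    result = select_from_matrix(FeatureMatrix(values=values, sample_labels=labels))
    # without decaying trace evidence nothing survives the kinetics stage
    assert result.n_final == 0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    arrays(
        float,
        st.tuples(st.integers(4, 8), st.integers(2, 6)),
        elements=st.floats(-50, 50, allow_nan=False, width=32),
    )
)
def test_funnel_counts_never_increase(arr):
    values = _df(np.asarray(arr, dtype=float) + np.linspace(0, 0.7, arr.shape[0])[:, None])
    if (values.std(axis=0, ddof=0) == 0).any():
        return  # degenerate column: scaling rejects it, nothing to check
    labels = pd.Series(
        ["fungal"] + ["plant"] * (len(values) - 1), index=values.index
    )
    result = select_from_matrix(FeatureMatrix(values=values, sample_labels=labels))
    assert result.n_input >= result.n_after_cos2 >= result.n_after_loading >= result.n_final
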