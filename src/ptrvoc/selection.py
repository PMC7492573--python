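"""Selection of fungal-associated volatiles from the sample x compound matrix.

The cascade reproduces a four-stage variable-reduction funnel on a matrix of
net headspace concentrations (rows: measurement runs; columns: compound
channels):

1. **Scaled PCA** — columns are mean-centered and scaled to unit (population)
   variance, then decomposed by SVD.  Variable coordinates are the
   correlation-scaled loadings (eigenvector x sqrt(eigenvalue)), i.e. the
   correlation of each compound with each component; cos2 is their square
   and measures how well the dim-1/2 plane represents a compound.
2. **cos2 filter** — compounds whose cos2 summed over dimensions 1 and 2
   falls below 0.25 are discarded (a per-dimension AND variant is available).
3. **Loading filter** — after orienting dimension 1 so fungal samples score
   negative, compounds with a dim-1 coordinate below -0.20 (strict) are the
   fungal-associated candidates.
4. **Kinetics filter** — only candidates whose mean trace across the
   fungal-treatment runs decays over the measurement survive.  The decay
   call compares the first averaging window (after the stabilization skip)
   with the last: with relative change rho = (m2 - m1)/max(|m1|, eps), a
   trace is a decay when rho <= -delta, a rise when rho >= +delta, constant
   otherwise (delta = 0.2 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "PcaModel",
    "SelectionConfig",
    "SelectionResult",
    "DegenerateColumnError",
    "scale_matrix",
    "fit_pca",
    "orient_model",
    "filter_cos2",
    "filter_loading",
    "classify_kinetics",
    "run_selection",
]

CATEGORIES = ("plant", "fungal", "cocultivation")


class DegenerateColumnError(ValueError):
    """A compound column has zero variance and cannot be unit-scaled."""


@dataclass
class FeatureMatrix:
    """Samples x compounds net-concentration grid with sample categories."""

    values: pd.DataFrame
    sample_labels: pd.Series  # sample_id -> category
    compound_mz: pd.Series | None = None  # channel_id -> m/z, optional

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("feature matrix must have no missing cells")
        if len(self.values) < 3:
            raise ValueError("need at least 3 samples")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 compounds")
        self.sample_labels = self.sample_labels.loc[self.values.index]


@dataclass
class SelectionConfig:
    cos2_min: float = 0.25
    cos2_mode: str = "sum"  # "sum" of dims 1-2 (default) or "each"
    dim1_max: float = -0.20
    loading_kind: str = "coords"  # variable coordinates, or raw "eigvec" entries
    kinetics_skip: int = 20
    kinetics_window: int = 60
    kinetics_delta: float = 0.2
    kinetics_eps: float = 1e-9
    scale_ddof: int = 0


@dataclass
class PcaModel:
    """Scores, variable coordinates, cos2 and explained variance of a scaled PCA."""

    scores: pd.DataFrame  # samples x dims
    var_coords: pd.DataFrame  # compounds x dims
    eigvecs: pd.DataFrame  # compounds x dims, unit eigenvectors
    explained_var: pd.Series  # fraction per dim
    oriented: bool = False

    @property
    def cos2(self) -> pd.DataFrame:
        return self.var_coords**2

    @property
    def dims(self) -> list[str]:
        return list(self.scores.columns)


def scale_matrix(values: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Mean-center and unit-variance scale each column (population estimator)."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [str(values.columns[j]) for j in zero[:5]]
        raise DegenerateColumnError(
            f"constant column(s) cannot be scaled: {', '.join(names)}"
        )
    return pd.DataFrame((arr - mean) / sd, index=values.index, columns=values.columns)


def fit_pca(scaled: pd.DataFrame) -> PcaModel:
    """PCA of a scaled matrix via SVD of the data.

    With population-scaled input the decomposition equals the eigendecomposition
    of the correlation matrix: eigenvalues are s_i^2 / n, variable coordinates
    are v_i * sqrt(lambda_i), and the explained-variance fractions are
    lambda_i / p (the trace of a correlation matrix is the number of compounds).
    """
    X = scaled.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if not np.any(S > 0):
        raise ValueError("rank-0 input: no variance to decompose")
    eigvals = S**2 / n
    dims = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=scaled.index, columns=dims)
    eigvecs = pd.DataFrame(Vt.T, index=scaled.columns, columns=dims)
    var_coords = pd.DataFrame(
        Vt.T * np.sqrt(eigvals), index=scaled.columns, columns=dims
    )
    explained = pd.Series(eigvals / p, index=dims)
    return PcaModel(
        scores=scores, var_coords=var_coords, eigvecs=eigvecs, explained_var=explained
    )


def orient_model(model: PcaModel, sample_labels: pd.Series) -> PcaModel:
    """Fix the sign of dimension 1 so fungal-labeled samples score negative.

    PCA axes are sign-ambiguous; the signed loading threshold is only
    meaningful once dim 1 points away from the fungal treatments.  cos2 and
    explained variance are unaffected.
    """
    labels = sample_labels.loc[model.scores.index]
    fungal = labels == "fungal"
    if not fungal.any():
        raise ValueError("orientation requires at least one fungal-labeled sample")
    flip = model.scores.loc[fungal.to_numpy(), "PC1"].mean() > 0
    scores = model.scores.copy()
    coords = model.var_coords.copy()
    eigvecs = model.eigvecs.copy()
    if flip:
        scores["PC1"] *= -1
        coords["PC1"] *= -1
        eigvecs["PC1"] *= -1
    return PcaModel(
        scores=scores,
        var_coords=coords,
        eigvecs=eigvecs,
        explained_var=model.explained_var,
        oriented=True,
    )


def _plane_cos2(model: PcaModel) -> pd.Series:
    dims = model.dims[:2]
    return model.cos2[dims].sum(axis=1)


def filter_cos2(
    model: PcaModel, threshold: float = 0.25, mode: str = "sum"
) -> list[str]:
    """Keep compounds represented well enough in the dim-1/2 plane.

    ``sum`` mode (default) keeps cos2(dim1) + cos2(dim2) >= threshold; the
    boundary value itself is kept ("below ... discarded").  ``each`` mode
    requires both dimensions to reach the threshold individually.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("cos2 threshold must lie in [0, 1]")
    dims = model.dims[:2]
    cos2 = model.cos2[dims]
    if mode == "sum":
        keep = cos2.sum(axis=1) >= threshold
    elif mode == "each":
        keep = (cos2 >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown cos2 mode {mode!r}")
    return list(cos2.index[keep])


def filter_loading(
    model: PcaModel,
    subset: Sequence[str],
    threshold: float = -0.20,
    kind: str = "coords",
) -> list[str]:
    """Keep fungal-side compounds: dim-1 coordinate strictly below ``threshold``.

    Requires an oriented model.  ``kind`` selects the variable coordinate
    (correlation with the component; default) or the raw unit eigenvector
    entry as the "loading".
    """
    if not model.oriented:
        raise ValueError("model must be oriented (see orient_model) before thresholding")
    source = model.var_coords if kind == "coords" else model.eigvecs
    if kind not in ("coords", "eigvec"):
        raise ValueError(f"unknown loading kind {kind!r}")
    coords = source["PC1"]
    return [cid for cid in subset if coords[cid] < threshold]


def classify_kinetics(
    trace: np.ndarray | pd.Series, config: SelectionConfig | None = None
) -> str:
    """Classify a sample-block trace as decay, constant, or rise.

    Compares the mean of the first averaging window (after the stabilization
    skip) with the mean of the last window of the trace.
    """
    config = config or SelectionConfig()
    values = np.asarray(trace, dtype=float)
    needed = config.kinetics_skip + 2 * config.kinetics_window
    if len(values) < needed:
        raise ValueError(f"trace of {len(values)} cycles too short; need >= {needed}")
    w = config.kinetics_window
    m1 = values[config.kinetics_skip : config.kinetics_skip + w].mean()
    m2 = values[-w:].mean()
    rho = (m2 - m1) / max(abs(m1), config.kinetics_eps)
    if rho <= -config.kinetics_delta:
        return "decay"
    if rho >= config.kinetics_delta:
        return "rise"
    return "constant"


@dataclass
class SelectionResult:
    """Stage counts and per-compound records of the selection funnel."""

    n_input: int
    n_after_cos2: int
    n_after_loading: int
    n_final: int
    retained_ids: list[str]
    records: pd.DataFrame  # per compound: cos2_sum12, coord_dim1, kinetics_class
    explained_var: pd.Series

    def __post_init__(self) -> None:
        if not self.n_input >= self.n_after_cos2 >= self.n_after_loading >= self.n_final:
            raise ValueError("funnel counts must be non-increasing")
        if len(self.retained_ids) != self.n_final:
            raise ValueError("retained_ids length must equal n_final")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_cos2": self.n_after_cos2,
            "n_after_loading": self.n_after_loading,
            "n_final": self.n_final,
            "retained_ids": list(self.retained_ids),
            "explained_var": {k: float(v) for k, v in self.explained_var.items()},
            "records": {
                cid: {
                    k: (None if pd.isna(v) else (float(v) if k != "kinetics_class" else v))
                    for k, v in row.items()
                }
                for cid, row in self.records.to_dict(orient="index").items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _mean_fungal_trace(runs, channel: str) -> np.ndarray | None:
    traces = [
        run.sample[channel].to_numpy(dtype=float)
        for run in runs
        if run.category == "fungal" and channel in run.sample.columns
    ]
    if not traces:
        return None
    return np.mean(traces, axis=0)


def run_selection(
    runs,
    config: SelectionConfig | None = None,
    reduction_config=None,
) -> SelectionResult:
    """Full cascade: reduce -> matrix -> scale -> PCA -> orient -> filters.

    ``runs`` is a sequence of SampleRun; a compound's kinetics is judged on
    its mean trace across the fungal-treatment replicates.
    """
    from .reduction import build_feature_matrix, reduce_run  # lazy: avoid cycle

    config = config or SelectionConfig()
    tables = [reduce_run(r, reduction_config) for r in runs]
    labels = {r.sample_id: r.category for r in runs}
    fm = build_feature_matrix(tables, sample_labels=labels)
    return select_from_matrix(fm, config, runs=runs)


def select_from_matrix(
    fm: FeatureMatrix,
    config: SelectionConfig | None = None,
    runs=None,
) -> SelectionResult:
    """Selection funnel on an existing feature matrix.

    Without ``runs`` (no traces available) the kinetics stage classifies every
    candidate as constant, so nothing survives it — kinetic evidence is part
    of the contract, not optional.
    """
    config = config or SelectionConfig()
    scaled = scale_matrix(fm.values, ddof=config.scale_ddof)
    model = orient_model(fit_pca(scaled), fm.sample_labels)

    after_cos2 = filter_cos2(model, config.cos2_min, config.cos2_mode)
    after_loading = filter_loading(model, after_cos2, config.dim1_max, config.loading_kind)

    kinetics: dict[str, str] = {}
    final: list[str] = []
    for cid in after_loading:
        trace = _mean_fungal_trace(runs or [], cid)
        cls = "constant" if trace is None else classify_kinetics(trace, config)
        kinetics[cid] = cls
        if cls == "decay":
            final.append(cid)

    mz = fm.compound_mz
    order_key = (lambda cid: (float(mz[cid]), cid)) if mz is not None else (lambda cid: cid)
    final.sort(key=order_key)

    records = pd.DataFrame(
        {
            "cos2_sum12": _plane_cos2(model),
            "coord_dim1": model.var_coords["PC1"],
            "kinetics_class": pd.Series(kinetics).reindex(model.var_coords.index),
        }
    )
    return SelectionResult(
        n_input=fm.values.shape[1],
        n_after_cos2=len(after_cos2),
        n_after_loading=len(after_loading),
        n_final=len(final),
        retained_ids=final,
        records=records,
        explained_var=model.explained_var,
    )
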