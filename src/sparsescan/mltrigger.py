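"""ML acquisition oracle: predict XRF-like maps from transmission data.

A small per-pixel regressor is trained on a scan where both the fast
transmitted-signal features (STXM intensity, differential phase
contrast) plus beam diagnostics (ring current, four BPM blade
currents) and the slow XRF targets are available at the training
pixels. On a subsequent scan of a similar sample it predicts an
"XRF-like" map from the fast features alone; thresholding that map
gives the acquisition mask for a compressive-sensing scan, i.e. the
model acts as an oracle deciding where real (costly) XRF dwell is
worth spending.

Targets are rates (counts / dwell second), not raw counts, so a model
trained on a coarse fast map transfers across dwell settings.

The estimator follows the scikit-learn protocol (``fit`` /
``predict`` / ``get_params``); record-level helpers wrap it for the
scan workflow.
"""

from __future__ import annotations

import h5py
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .easymask_io import ScanMask
from .engine import XRF_SENTINEL, ScanRecord

__all__ = [
    "XRFOracle",
    "extract_features",
    "extract_feature_matrix",
    "train_oracle",
    "predict_maps",
    "oracle_trigger_mask",
    "save_oracle",
    "load_oracle",
]

BASE_FEATURES = ("stxm", "dpc_x", "dpc_y", "ring_current", "blade_1", "blade_2", "blade_3", "blade_4")
MIN_TRAINING_PIXELS = 50


def _neighborhood_stack(grid: np.ndarray) -> np.ndarray:
    """All nine 3x3-neighbourhood values per pixel, edges replicated."""
    padded = np.pad(grid, 1, mode="edge")
    views = [padded[di:di + grid.shape[0], dj:dj + grid.shape[1]]
             for di in range(3) for dj in range(3)]
    return np.stack(views, axis=-1)


def extract_feature_matrix(record: ScanRecord, neighborhood: bool = False) -> np.ndarray:
    """(P, n_features) matrix over all pixels in row-major grid order."""
    rows, cols = record.shape
    P = rows * cols
    rc = np.empty((rows, cols))
    bpm = np.empty((rows, cols, 4))
    flat_i = record.order_index
    rc.ravel()[flat_i] = record.ring_current_log
    bpm.reshape(P, 4)[flat_i] = record.bpm_log
    cols_list = [
        record.stxm.ravel(),
        record.dpc_x.ravel(),
        record.dpc_y.ravel(),
        rc.ravel(),
        *(bpm.reshape(P, 4).T),
    ]
    X = np.column_stack(cols_list)
    if neighborhood:
        X = np.hstack([X, _neighborhood_stack(record.stxm).reshape(P, 9)])
    return X


def extract_features(record: ScanRecord, pixel_index: tuple[int, int], neighborhood: bool = False) -> np.ndarray:
    """Feature vector for one pixel (see :data:`BASE_FEATURES`; with
    ``neighborhood`` the nine 3x3 STXM values, edge-replicated, are
    appended)."""
    i, j = pixel_index
    if not record.acquired_stxm_mask[i, j]:
        raise ValueError(f"no STXM measurement at pixel {pixel_index}")
    X = extract_feature_matrix(record, neighborhood=neighborhood)
    return X[i * record.config.cols + j]


class XRFOracle(BaseEstimator, RegressorMixin):
    """Per-pixel regressor from transmission + diagnostics features to
    per-element XRF rates.

    A feed-forward network (default two hidden layers of 32 ReLU
    units) fitted on standardized features and standardized targets;
    the standardization statistics come from the training set only.
    Prediction runs through the package's own forward pass on the
    extracted weights, which makes a serialized oracle predict
    identically after reload.

    Parameters
    ----------
    elements : tuple of str
        Output element labels, fixed at fit time if None.
    hidden_layer_sizes : tuple of int
        Network architecture.
    neighborhood : bool
        Append the 3x3 STXM neighbourhood to the features.
    alpha : float
        L2 penalty of the network.
    max_iter : int
        Optimizer iteration cap (LBFGS).
    random_state : int
        Seed for weight initialization; fitting is deterministic.
    """

    def __init__(
        self,
        elements=None,
        hidden_layer_sizes=(32, 32),
        neighborhood: bool = False,
        alpha: float = 1e-4,
        max_iter: int = 400,
        random_state: int = 0,
    ):
        self.elements = elements
        self.hidden_layer_sizes = hidden_layer_sizes
        self.neighborhood = neighborhood
        self.alpha = alpha
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if X.shape[0] < MIN_TRAINING_PIXELS:
            raise ValueError(
                f"need at least {MIN_TRAINING_PIXELS} training pixels, got {X.shape[0]}"
            )
        self.n_features_in_ = X.shape[1]
        self.elements_ = tuple(self.elements) if self.elements else tuple(
            f"y{k}" for k in range(y.shape[1])
        )
        if len(self.elements_) != y.shape[1]:
            raise ValueError("element labels disagree with target columns")
        self.scaler_ = StandardScaler().fit(X)
        # features that are constant up to numerical jitter (e.g. the
        # diagnostics of a perfectly stable beam) must not be amplified
        # by standardization: floor their scale to 1
        near_const = self.scaler_.scale_ < 1e-8 * np.maximum(1.0, np.abs(self.scaler_.mean_))
        self.scaler_.scale_ = np.where(near_const, 1.0, self.scaler_.scale_)
        self.y_mean_ = y.mean(axis=0)
        self.y_scale_ = np.where(y.std(axis=0) > 0, y.std(axis=0), 1.0)
        ys = (y - self.y_mean_) / self.y_scale_
        mlp = MLPRegressor(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="relu",
            solver="lbfgs",
            alpha=self.alpha,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # hitting the LBFGS iteration cap is an accepted stopping rule
            warnings.simplefilter("ignore", ConvergenceWarning)
            mlp.fit(self.scaler_.transform(X), ys if ys.shape[1] > 1 else ys.ravel())
        self.coefs_ = [w.copy() for w in mlp.coefs_]
        self.intercepts_ = [b.copy() for b in mlp.intercepts_]
        pred = self.predict(X)
        resid = pred - y
        self.train_rmse_ = np.sqrt((resid**2).mean(axis=0))
        return self

    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        h = Xs
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.coefs_[-1] + self.intercepts_[-1]

    def predict(self, X):
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected feature matrix with {self.n_features_in_} columns"
            )
        out = self._forward(self.scaler_.transform(X))
        if out.ndim == 1:
            out = out[:, None]
        return out * self.y_scale_ + self.y_mean_


# ----------------------------------------------------------------------
# record-level workflow
# ----------------------------------------------------------------------

def _targets_from_record(record: ScanRecord, mask: np.ndarray, elements) -> np.ndarray:
    cols = []
    for el in elements:
        if el not in record.xrf:
            raise KeyError(f"element {el!r} absent from record")
        grid = record.xrf[el]
        dwell = record.dwell_long
        acquired = grid != XRF_SENTINEL
        if not np.all(acquired[mask]):
            raise ValueError("training mask includes pixels without XRF targets")
        rate = np.zeros_like(grid)
        np.divide(grid, dwell, out=rate, where=acquired & (dwell > 0))
        cols.append(rate[mask])
    return np.column_stack(cols)


def train_oracle(
    record: ScanRecord,
    training_mask: ScanMask | np.ndarray,
    elements,
    seed: int = 0,
    **hyperparams,
) -> XRFOracle:
    """Fit an :class:`XRFOracle` on the training pixels of a record."""
    mask = training_mask.grid if isinstance(training_mask, ScanMask) else np.asarray(training_mask, bool)
    if mask.shape != record.shape:
        raise ValueError("training mask shape does not match record")
    neighborhood = bool(hyperparams.pop("neighborhood", False))
    X = extract_feature_matrix(record, neighborhood=neighborhood)[mask.ravel()]
    y = _targets_from_record(record, mask, elements)
    oracle = XRFOracle(
        elements=tuple(elements), neighborhood=neighborhood,
        random_state=seed, **hyperparams,
    )
    oracle.fit(X, y)
    oracle.training_mask_ = mask.copy()
    return oracle


def predict_maps(oracle: XRFOracle, record: ScanRecord) -> dict[str, np.ndarray]:
    """Per-element XRF-like rate grids from fast data only; no XRF
    measurement of ``record`` is consumed."""
    X = extract_feature_matrix(record, neighborhood=oracle.neighborhood)
    pred = oracle.predict(X)
    rows, cols = record.shape
    return {el: pred[:, k].reshape(rows, cols) for k, el in enumerate(oracle.elements_)}


def oracle_trigger_mask(predicted: np.ndarray, threshold: float) -> ScanMask:
    """Acquisition mask: acquire where the predicted map strictly
    exceeds the threshold."""
    return ScanMask(np.asarray(predicted) > threshold, provenance="ml oracle threshold")


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def save_oracle(oracle: XRFOracle, path) -> None:
    check_is_fitted(oracle, "coefs_")
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "xrf_oracle"
        f.attrs["elements"] = ",".join(oracle.elements_)
        f.attrs["neighborhood"] = oracle.neighborhood
        f.attrs["hidden_layer_sizes"] = list(oracle.hidden_layer_sizes)
        f.attrs["alpha"] = oracle.alpha
        f.attrs["max_iter"] = oracle.max_iter
        f.attrs["random_state"] = oracle.random_state
        f.attrs["n_features_in"] = oracle.n_features_in_
        f.create_dataset("scaler/mean", data=oracle.scaler_.mean_)
        f.create_dataset("scaler/scale", data=oracle.scaler_.scale_)
        f.create_dataset("target/mean", data=oracle.y_mean_)
        f.create_dataset("target/scale", data=oracle.y_scale_)
        f.create_dataset("train_rmse", data=oracle.train_rmse_)
        for k, (W, b) in enumerate(zip(oracle.coefs_, oracle.intercepts_)):
            f.create_dataset(f"layers/{k}/weights", data=W)
            f.create_dataset(f"layers/{k}/bias", data=b)


def load_oracle(path) -> XRFOracle:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "xrf_oracle":
            raise ValueError("not an oracle archive")
        oracle = XRFOracle(
            elements=tuple(str(f.attrs["elements"]).split(",")),
            hidden_layer_sizes=tuple(int(v) for v in f.attrs["hidden_layer_sizes"]),
            neighborhood=bool(f.attrs["neighborhood"]),
            alpha=float(f.attrs["alpha"]),
            max_iter=int(f.attrs["max_iter"]),
            random_state=int(f.attrs["random_state"]),
        )
        oracle.elements_ = tuple(oracle.elements)
        oracle.n_features_in_ = int(f.attrs["n_features_in"])
        scaler = StandardScaler()
        scaler.mean_ = f["scaler/mean"][()]
        scaler.scale_ = f["scaler/scale"][()]
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = oracle.n_features_in_
        scaler.n_samples_seen_ = 1
        scaler.with_mean = scaler.with_std = True
        oracle.scaler_ = scaler
        oracle.y_mean_ = f["target/mean"][()]
        oracle.y_scale_ = f["target/scale"][()]
        oracle.train_rmse_ = f["train_rmse"][()]
        nlayers = len(f["layers"])
        oracle.coefs_ = [f[f"layers/{k}/weights"][()] for k in range(nlayers)]
        oracle.intercepts_ = [f[f"layers/{k}/bias"][()] for k in range(nlayers)]
    return oracle
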