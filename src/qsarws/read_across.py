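"""Similarity-based read-across prediction and RASAR feature construction.

Read-across predicts a query compound's activity as the similarity-weighted
mean of its closest training analogues, with similarity computed on the
autoscaled descriptors selected by the structural model.  Three similarity
kernels are supported on the scaled space:

* ``ED`` — inverse Euclidean distance, s = 1/(1+d);
* ``GK`` — Gaussian kernel, s = exp(-d^2 / (2 sigma^2));
* ``LK`` — Laplacian kernel on the L1 distance, s = exp(-gamma * d1).

The per-query read-across predictions and similarity summaries can then be
appended to the descriptor table as *RASAR features* and fed back into an
ordinary OLS fit, giving the hybrid q-RASAR model.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import DescriptorTable
from .errors import NoAnalogueError, QsarError, SchemaError
from .regression import MLRModel, fit_ols
from .validation import ValidationReport, validate_model

KERNELS = ("ED", "GK", "LK")


@dataclasses.dataclass
class RAConfig:
    """Hyperparameters of one read-across predictor."""

    similarity: str = "ED"
    sigma: float = 1.0
    gamma: float = 1.0
    n_neighbors: int = 6
    distance_threshold: float = 1.0
    similarity_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.similarity not in KERNELS:
            raise QsarError(f"similarity must be one of {KERNELS}")
        if self.n_neighbors < 1:
            raise QsarError("n_neighbors must be >= 1")
        if self.sigma <= 0 or self.gamma <= 0:
            raise QsarError("sigma and gamma must be positive")


def autoscale(train_X, query_X=None):
    """Z-score using the training mean/SD; apply the same scaling to queries.

    Zero-variance training columns carry no distance information and are
    dropped with a warning.  Returns ``(train_Z, query_Z, params)`` where
    params is a dict with ``mean``, ``sd`` and ``columns`` (kept indices).
    """
    Xt = np.asarray(
        train_X.descriptors if hasattr(train_X, "descriptors") else train_X, float
    )
    sd = Xt.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise QsarError("every descriptor column has zero variance")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance column(s) before scaling",
            stacklevel=2,
        )
    mean = Xt[:, keep].mean(axis=0)
    Zt = (Xt[:, keep] - mean) / sd[keep]
    params = {"mean": mean, "sd": sd[keep], "columns": np.flatnonzero(keep)}
    Zq = None
    if query_X is not None:
        Xq = np.asarray(
            query_X.descriptors if hasattr(query_X, "descriptors") else query_X, float
        )
        if Xq.ndim == 1:
            Xq = Xq.reshape(1, -1)
        if Xq.shape[1] != Xt.shape[1]:
            raise SchemaError("query descriptor count differs from training")
        Zq = (Xq[:, params["columns"]] - mean) / params["sd"]
    return Zt, Zq, params


def similarities(train_Z, query_z, config: RAConfig) -> np.ndarray:
    """Per-training-compound similarity of one scaled query vector."""
    train_Z = np.asarray(train_Z, float)
    query_z = np.asarray(query_z, float).ravel()
    if train_Z.shape[1] != query_z.shape[0]:
        raise SchemaError("dimension mismatch between training matrix and query")
    diff = train_Z - query_z
    if config.similarity == "LK":
        d1 = np.abs(diff).sum(axis=1)
        return np.exp(-config.gamma * d1)
    d = np.sqrt((diff**2).sum(axis=1))
    if config.similarity == "ED":
        return 1.0 / (1.0 + d)
    return np.exp(-(d**2) / (2.0 * config.sigma**2))


class ReadAcrossModel:
    """A fitted read-across predictor over one training table.

    Precomputes the scaling, the scaled training matrix, and the maximum
    training-training distance used by the (multiplicative) distance
    threshold.  The predictor is lazy everywhere else: each query is scored
    against all training compounds at call time.
    """

    def __init__(
        self,
        train: DescriptorTable,
        descriptor_names: Sequence[str] | None = None,
        config: RAConfig | None = None,
    ) -> None:
        self.config = config or RAConfig()
        self.descriptor_names = (
            list(descriptor_names)
            if descriptor_names is not None
            else train.descriptor_names
        )
        self.train_ids = train.ids
        self.y = train.y()
        X = train.X(self.descriptor_names)
        self.Z, _, self._params = autoscale(X)
        # reference scale for the distance threshold
        d2 = (
            (self.Z[:, None, :] - self.Z[None, :, :]) ** 2
        ).sum(axis=2)
        self.max_train_distance = float(np.sqrt(d2.max()))
        d1 = np.abs(self.Z[:, None, :] - self.Z[None, :, :]).sum(axis=2)
        self.max_train_distance_l1 = float(d1.max())

    def _scale(self, query_x) -> np.ndarray:
        q = np.asarray(query_x, float).ravel()
        if q.shape[0] != len(self.descriptor_names):
            raise SchemaError(
                f"query has {q.shape[0]} descriptors, expected "
                f"{len(self.descriptor_names)}"
            )
        q = q[self._params["columns"]]
        return (q - self._params["mean"]) / self._params["sd"]

    def predict_one(self, query_x, exclude_id: str | None = None) -> dict:
        """Read-across prediction and neighbour diagnostics for one query.

        ``exclude_id`` removes one training compound from the candidate
        pool — used when computing features for training compounds
        themselves, so a compound never borrows its own response.
        """
        cfg = self.config
        qz = self._scale(query_x)
        diff = self.Z - qz
        d = np.sqrt((diff**2).sum(axis=1))
        d1 = np.abs(diff).sum(axis=1)
        s = similarities(self.Z, qz, cfg)
        dist = d1 if cfg.similarity == "LK" else d
        max_d = (
            self.max_train_distance_l1
            if cfg.similarity == "LK"
            else self.max_train_distance
        )
        eligible = (dist <= cfg.distance_threshold * max_d) | (
            s >= cfg.similarity_threshold
        )
        if exclude_id is not None:
            eligible &= np.array([tid != exclude_id for tid in self.train_ids])
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            raise NoAnalogueError("no eligible training analogue for query")
        # most similar first; stable tie-break on training order
        order = idx[np.argsort(-s[idx], kind="stable")]
        nn = order[: cfg.n_neighbors]
        w = s[nn]
        yn = self.y[nn]
        pred = float(w @ yn / w.sum())
        return {
            "prediction": pred,
            "neighbor_ids": [self.train_ids[i] for i in nn],
            "neighbor_similarities": w,
            "neighbor_responses": yn,
            "mean_similarity": float(w.mean()),
            "sd_similarity": float(w.std(ddof=1)) if len(w) > 1 else 0.0,
            "sd_neighbor_response": float(yn.std(ddof=1)) if len(yn) > 1 else 0.0,
        }


def ra_predict(
    train: DescriptorTable,
    query_x,
    config: RAConfig | None = None,
    descriptor_names: Sequence[str] | None = None,
) -> tuple[float, dict]:
    """One-shot read-across prediction (see :class:`ReadAcrossModel`)."""
    model = ReadAcrossModel(train, descriptor_names, config)
    info = model.predict_one(query_x)
    return info["prediction"], info


def rasar_features(
    train: DescriptorTable,
    queries: DescriptorTable,
    descriptor_names: Sequence[str] | None = None,
    configs: dict[str, RAConfig] | None = None,
    leave_out_self: bool = False,
) -> pd.DataFrame:
    """RASAR feature table: per-query read-across predictions under each
    kernel plus similarity summaries.

    ``leave_out_self`` must be True when the queries *are* training
    compounds, so each one is predicted from its neighbours only.
    The similarity summaries (mean/sd of neighbour similarity, sd of
    neighbour response) come from the ED kernel's neighbourhood.
    """
    if configs is None:
        configs = {k: RAConfig(similarity=k) for k in KERNELS}
    predictors = {
        k: ReadAcrossModel(train, descriptor_names, cfg) for k, cfg in configs.items()
    }
    rows = []
    names = (
        list(descriptor_names) if descriptor_names is not None else train.descriptor_names
    )
    Q = queries.X(names)
    for qid, qx in zip(queries.ids, Q):
        exclude = qid if leave_out_self else None
        row: dict = {"id": qid}
        for k, predictor in predictors.items():
            info = predictor.predict_one(qx, exclude_id=exclude)
            row[f"RA_{k}"] = info["prediction"]
            if k == "ED":
                row["mean_similarity"] = info["mean_similarity"]
                row["sd_similarity"] = info["sd_similarity"]
                row["sd_neighbor_response"] = info["sd_neighbor_response"]
                row["neighbor_ids"] = ";".join(info["neighbor_ids"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def optimize_ra_hyperparameters(
    train: DescriptorTable,
    grid: Sequence[RAConfig],
    descriptor_names: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[RAConfig, pd.DataFrame]:
    """Pick the grid configuration minimising subtest RMSE.

    The training set is split 3:1 (seeded, uniform) into a subtraining and
    a subtest part; every candidate configuration predicts the subtest from
    the subtraining compounds and is scored by RMSE.  Ties keep the first
    grid entry, so the search is deterministic.
    """
    if not grid:
        raise QsarError("hyperparameter grid is empty")
    rng = np.random.default_rng(seed)
    ids = np.array(train.ids, dtype=object)
    n_test = max(1, len(ids) // 4)
    test_ids = set(rng.choice(ids, size=n_test, replace=False))
    sub_train = train.subset([i for i in ids if i not in test_ids])
    sub_test = train.subset([i for i in ids if i in test_ids])
    y_test = sub_test.y()
    records = []
    best, best_rmse = None, np.inf
    for cfg in grid:
        predictor = ReadAcrossModel(sub_train, descriptor_names, cfg)
        preds = np.array(
            [
                predictor.predict_one(qx)["prediction"]
                for qx in sub_test.X(
                    list(descriptor_names)
                    if descriptor_names is not None
                    else train.descriptor_names
                )
            ]
        )
        rmse = float(np.sqrt(np.mean((preds - y_test) ** 2)))
        records.append({**dataclasses.asdict(cfg), "subtest_rmse": rmse})
        if rmse < best_rmse:
            best, best_rmse = cfg, rmse
    return best, pd.DataFrame(records)


def default_hyperparameter_grid(similarity: str = "ED") -> list[RAConfig]:
    """A small default grid over kernel width and neighbourhood size."""
    grid = []
    widths = [0.5, 1.0, 2.0]
    for n_neighbors, w in itertools.product((2, 4, 6, 8), widths):
        grid.append(
            RAConfig(similarity=similarity, sigma=w, gamma=w, n_neighbors=n_neighbors)
        )
    return grid


@dataclasses.dataclass
class QRASARResult:
    """Everything produced by a q-RASAR fit."""

    model: MLRModel
    report: ValidationReport
    train_features: pd.DataFrame
    pred_features: pd.DataFrame | None


def fit_qrasar(
    train: DescriptorTable,
    pred: DescriptorTable | None = None,
    descriptor_names: Sequence[str] | None = None,
    feature_descriptors: Sequence[str] = (),
    ra_columns: Sequence[str] = ("RA_ED",),
    configs: dict[str, RAConfig] | None = None,
    lmo_iterations: int = 2000,
    yscr_iterations: int = 2000,
    seed: int = 0,
) -> QRASARResult:
    """Fit the hybrid q-RASAR model: RASAR features + selected 2D descriptors.

    The read-across features are computed in the descriptor space of the
    structural model (``descriptor_names``); training compounds are
    featurised leave-self-out.  The combined feature matrix then goes
    through the ordinary OLS fit and the full validation battery.
    """
    feats_tr = rasar_features(
        train, train, descriptor_names, configs, leave_out_self=True
    )
    Xtr = pd.concat(
        [feats_tr[list(ra_columns)], train.descriptors[list(feature_descriptors)]],
        axis=1,
    )
    model = fit_ols(
        Xtr,
        train.y(),
        descriptor_names=list(Xtr.columns),
        training_ids=train.ids,
    )
    feats_pr = None
    X_pred = y_pred = None
    if pred is not None:
        feats_pr = rasar_features(train, pred, descriptor_names, configs)
        X_pred = pd.concat(
            [feats_pr[list(ra_columns)], pred.descriptors[list(feature_descriptors)]],
            axis=1,
        )
        y_pred = pred.y()
    report = validate_model(
        model,
        X_pred=X_pred,
        y_pred=y_pred,
        lmo_iterations=lmo_iterations,
        yscr_iterations=yscr_iterations,
        seed=seed,
    )
    return QRASARResult(
        model=model, report=report, train_features=feats_tr, pred_features=feats_pr
    )
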