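"""Applicability-domain diagnostics: leverages, standardized residuals,
Williams plot and Insubria graph tables, and a PCA score-box domain.

A compound's leverage h measures how far its descriptor vector sits from
the training design; compounds with h above the warning value
h* = 3(p+1)/n are structural outliers whose predictions extrapolate.
Compounds with standardized residuals beyond +-3 are response outliers.
The Insubria graph applies the leverage criterion to query compounds that
have no experimental value at all.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import DegeneratePCAError, QsarError, SchemaError
from .regression import MLRModel, _as_matrix


def warning_leverage(p: int, n_train: int) -> float:
    """Warning leverage h* = 3(p+1)/n for a p-descriptor model trained on n compounds."""
    if p < 1 or n_train <= 0:
        raise QsarError("need p >= 1 and n_train > 0")
    return 3.0 * (p + 1) / n_train


def leverages(model: MLRModel, X) -> np.ndarray:
    """Hat values h = [1,x] (X'X)^-1 [1,x]' against the training design."""
    X = _as_matrix(X, model.descriptor_names)
    if X.shape[1] != model.p:
        raise SchemaError(
            f"expected {model.p} descriptor columns, got {X.shape[1]}"
        )
    design_tr = np.column_stack([np.ones(model.n_train), model.X_train])
    xtx_inv = np.linalg.inv(design_tr.T @ design_tr)
    design = np.column_stack([np.ones(len(X)), X])
    return np.einsum("ij,jk,ik->i", design, xtx_inv, design)


def standardized_residuals(
    model: MLRModel, X, y, threshold: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals scaled by the training-fit RMSE, with response-outlier flags.

    The scale is the RMSE of the training fit (1/n convention), so training
    and prediction compounds are judged on the same footing.  A zero RMSE
    (perfect fit) flags nothing.
    """
    y = np.asarray(y, dtype=float)
    resid = y - model.predict(X)
    rmse = float(np.sqrt(np.mean(model.residuals**2)))
    if rmse == 0.0:
        return np.zeros_like(resid), np.zeros(len(resid), dtype=bool)
    std = resid / rmse
    return std, np.abs(std) > threshold


def williams(
    model: MLRModel,
    train_table,
    pred_table=None,
    h_star: float | None = None,
) -> pd.DataFrame:
    """Williams-plot table: leverage vs standardized residual, set-tagged.

    Accepts DescriptorTable objects (or anything exposing ``descriptors``
    and ``pic50``); returns one row per compound with the structural- and
    response-outlier flags already evaluated.
    """
    if h_star is None:
        h_star = warning_leverage(model.p, model.n_train)
    frames = []
    for tag, table in (("training", train_table), ("prediction", pred_table)):
        if table is None:
            continue
        X = table.descriptors if hasattr(table, "descriptors") else table
        y = table.pic50.to_numpy() if hasattr(table, "pic50") else None
        h = leverages(model, X)
        std, resp_flag = standardized_residuals(model, X, y)
        frames.append(
            pd.DataFrame(
                {
                    "id": list(X.index) if isinstance(X, pd.DataFrame) else range(len(h)),
                    "set": tag,
                    "h": h,
                    "std_resid": std,
                    "structural_outlier": h > h_star,
                    "response_outlier": resp_flag,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["inside_ad"] = ~(out["structural_outlier"] | out["response_outlier"])
    out.attrs["h_star"] = h_star
    return out


def insubria(
    model: MLRModel, external_X, ids=None, h_star: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Insubria-graph table (leverage vs predicted value) and AD coverage.

    For query compounds without experimental values the only available
    reliability signal is the leverage: predictions at h > h* are flagged
    low-confidence.  Coverage is the fraction of queries inside the domain.
    """
    if h_star is None:
        h_star = warning_leverage(model.p, model.n_train)
    X = external_X.descriptors if hasattr(external_X, "descriptors") else external_X
    if ids is None:
        ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(X)))
    h = leverages(model, X)
    pred = model.predict(X)
    table = pd.DataFrame(
        {
            "id": ids,
            "h": h,
            "pred": pred,
            "low_confidence": h > h_star,
        }
    )
    coverage = float(np.mean(h <= h_star))
    table.attrs["h_star"] = h_star
    return table, coverage


@dataclasses.dataclass
class PCABox:
    """PC1/PC2 score ranges of the training set, with the projection."""

    mean: np.ndarray
    sd: np.ndarray
    components: np.ndarray  # rows: PC1, PC2 loadings
    pc1_range: tuple[float, float]
    pc2_range: tuple[float, float]

    def scores(self, X) -> np.ndarray:
        Z = (np.asarray(X, float) - self.mean) / self.sd
        return Z @ self.components.T


def pca_domain(train_X, query_X, descriptor_names=None) -> tuple[np.ndarray, PCABox]:
    """PCA score-box domain: a query is inside iff its PC1 and PC2 scores
    fall within the training score ranges.

    The PCA is fitted on the autoscaled (correlation) training descriptors;
    the rectangular PC1 x PC2 bounding box of the training scores is the
    declared domain boundary.
    """
    Xt = _as_matrix(train_X, descriptor_names)
    Xq = _as_matrix(query_X, descriptor_names)
    if Xt.shape[1] < 2:
        raise QsarError("PCA domain needs at least 2 descriptors")
    if Xq.shape[1] != Xt.shape[1]:
        raise SchemaError("query descriptor count differs from training")
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegeneratePCAError("zero-variance descriptor in PCA domain")
    Z = (Xt - mean) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    comps = vt[:2].copy()
    for i in range(2):
        if comps[i, np.argmax(np.abs(comps[i]))] < 0:
            comps[i] = -comps[i]
    scores_tr = Z @ comps.T
    box = PCABox(
        mean=mean,
        sd=sd,
        components=comps,
        pc1_range=(float(scores_tr[:, 0].min()), float(scores_tr[:, 0].max())),
        pc2_range=(float(scores_tr[:, 1].min()), float(scores_tr[:, 1].max())),
    )
    sq = box.scores(Xq)
    inside = (
        (sq[:, 0] >= box.pc1_range[0])
        & (sq[:, 0] <= box.pc1_range[1])
        & (sq[:, 1] >= box.pc2_range[0])
        & (sq[:, 1] <= box.pc2_range[1])
    )
    return inside, box
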