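"""Per-compound prediction-reliability scoring for untested query compounds.

Each query is scored 3 ("Good"), 2 ("Moderate") or 1 ("Bad or Unreliable")
from three rules that use only quantities the rest of the workflow already
computes:

a. *inside the leverage domain* — leverage at or below h* = 3(p+1)/n;
b. *well-predicted neighbourhood* — the similarity-weighted mean absolute
   leave-one-out error of the query's closest training neighbours is at
   most 1.5x the training MAE;
c. *interpolated response* — the predicted value lies within the training
   response range.

Score 3 requires all three rules to hold, score 1 means at most one holds,
anything else scores 2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ad import leverages, warning_leverage
from .dataset import DescriptorTable
from .errors import QsarError
from .read_across import RAConfig, ReadAcrossModel
from .regression import MLRModel, press_residuals

SCORE_LABELS = {3: "Good", 2: "Moderate", 1: "Bad or Unreliable"}


@dataclasses.dataclass
class ReliabilityVerdict:
    id: str
    prediction: float
    score: int
    inside_leverage_ad: bool
    neighbor_error_ok: bool
    within_response_range: bool

    @property
    def label(self) -> str:
        return SCORE_LABELS[self.score]


def _composite(rules: tuple[bool, bool, bool]) -> int:
    n_true = sum(rules)
    if n_true == 3:
        return 3
    if n_true <= 1:
        return 1
    return 2


def reliability_scores(
    model: MLRModel,
    train: DescriptorTable,
    queries: DescriptorTable,
    n_neighbors: int = 6,
    error_factor: float = 1.5,
) -> pd.DataFrame:
    """Score every query compound; returns a frame with per-rule outcomes.

    The neighbour rule compares the similarity-weighted mean |LOO error| of
    the ``n_neighbors`` most similar training compounds (inverse-Euclidean
    similarity on the autoscaled model descriptors) against
    ``error_factor`` times the training MAE.
    """
    names = model.descriptor_names
    missing = [c for c in names if c not in train.descriptor_names]
    if missing:
        raise QsarError(f"training table lacks model descriptor(s): {missing}")
    h_star = warning_leverage(model.p, model.n_train)
    h = leverages(model, queries.descriptors[names])
    preds = model.predict(queries.descriptors[names])
    y_tr = train.y()
    loo_err = np.abs(press_residuals(train.descriptors[names], y_tr))
    mae_tr = float(np.mean(np.abs(model.residuals)))
    lo, hi = float(y_tr.min()), float(y_tr.max())

    ra = ReadAcrossModel(
        train, names, RAConfig(similarity="ED", n_neighbors=n_neighbors)
    )
    id_pos = {tid: i for i, tid in enumerate(ra.train_ids)}

    rows = []
    for qid, qx, h_i, p_i in zip(
        queries.ids, queries.X(names), h, preds
    ):
        info = ra.predict_one(qx)
        w = info["neighbor_similarities"]
        errs = np.array([loo_err[id_pos[t]] for t in info["neighbor_ids"]])
        weighted_err = float(w @ errs / w.sum())
        rules = (
            bool(h_i <= h_star),
            bool(weighted_err <= error_factor * mae_tr),
            bool(lo <= p_i <= hi),
        )
        verdict = ReliabilityVerdict(
            id=qid,
            prediction=float(p_i),
            score=_composite(rules),
            inside_leverage_ad=rules[0],
            neighbor_error_ok=rules[1],
            within_response_range=rules[2],
        )
        rows.append(dataclasses.asdict(verdict))
    out = pd.DataFrame(rows).set_index("id")
    out["label"] = out["score"].map(SCORE_LABELS)
    out.attrs["h_star"] = h_star
    out.attrs["training_mae"] = mae_tr
    return out
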