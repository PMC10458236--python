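"""Training/prediction splitting by sorted response, sorted structure, or at random.

All three schemes target an approximately 3:1 training:prediction ratio and
guarantee that the compounds with the extreme responses (and, for the
structure-aware schemes, the extreme PC1 scores) end up in the training set,
so that the prediction set is interpolated rather than extrapolated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DescriptorTable
from .errors import DegeneratePCAError, QsarError

SCHEMES = ("ORes", "OStr", "Random")


@dataclasses.dataclass
class SplitAssignment:
    """A training/prediction partition of a modeling table."""

    scheme: str
    training_ids: list[str]
    prediction_ids: list[str]
    forced_ids: list[str]
    seed: int | None = None

    @property
    def n_train(self) -> int:
        return len(self.training_ids)

    @property
    def n_pred(self) -> int:
        return len(self.prediction_ids)

    def labels(self) -> dict[str, str]:
        out = {cid: "training" for cid in self.training_ids}
        out.update({cid: "prediction" for cid in self.prediction_ids})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, "training") for cid in self.training_ids] + [
            (cid, "prediction") for cid in self.prediction_ids
        ]
        df = pd.DataFrame(rows, columns=["id", "set"])
        df["scheme"] = self.scheme
        df["seed"] = self.seed if self.seed is not None else ""
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def pc1_scores(table: DescriptorTable) -> pd.Series:
    """First-principal-component scores of the autoscaled descriptor matrix.

    Correlation-matrix PCA: each column is centred and scaled to unit
    variance before the decomposition.  Zero-variance columns are ignored.
    The component sign is fixed so that the loading of largest magnitude is
    positive, making the ordering reproducible across runs.
    """
    X = table.X()
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise DegeneratePCAError("all descriptor columns have zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # SVD of the scaled matrix gives the principal axes directly
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v1 = vt[0]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    return pd.Series(Z @ v1, index=table.descriptors.index, name="PC1")


def _every_fourth_from_second(n: int) -> np.ndarray:
    """0-based positions of ranks 2, 6, 10, ... (1-based) among n items."""
    return np.arange(1, n, 4)


def _sort_descending_stable(values: np.ndarray) -> np.ndarray:
    # mergesort is stable, so ties keep input order
    return np.argsort(-values, kind="stable")


def split_sorted_response(table: DescriptorTable) -> SplitAssignment:
    """Ordered-response split: sort by pIC50, every fourth compound to prediction.

    Compounds are sorted by decreasing potency; starting from the second,
    every fourth compound goes to the prediction set.  Any selected compound
    that holds the global maximum or minimum pIC50 is moved back to training
    so the prediction set never extends the response range.
    """
    y = table.y()
    if len(y) < 8:
        raise QsarError("ordered-response split needs at least 8 compounds")
    ids = np.asarray(table.ids, dtype=object)
    order = _sort_descending_stable(y)
    selected = set(order[_every_fourth_from_second(len(y))])
    extremes = {int(np.argmax(y)), int(np.argmin(y))}
    moved = selected & extremes
    selected -= extremes
    pred_ids = [str(i) for i in ids[sorted(selected)]]
    train_ids = [str(i) for i in ids if i not in set(pred_ids)]
    return SplitAssignment(
        scheme="ORes",
        training_ids=train_ids,
        prediction_ids=pred_ids,
        forced_ids=[str(i) for i in ids[sorted(extremes | moved)]],
    )


def split_sorted_structure(table: DescriptorTable) -> SplitAssignment:
    """Ordered-structure split: sort by PC1 score, every fourth to prediction.

    The response extremes are set aside into training first, then the
    remaining compounds are sorted by their PC1 score and every fourth from
    the second goes to prediction; a selected compound holding an extreme
    PC1 score is moved back to training.
    """
    y = table.y()
    if len(y) < 8:
        raise QsarError("ordered-structure split needs at least 8 compounds")
    if len(table.descriptor_names) < 2:
        raise QsarError("ordered-structure split needs at least 2 descriptors")
    ids = np.asarray(table.ids, dtype=object)
    pc1 = pc1_scores(table).to_numpy()

    resp_extremes = {int(np.argmax(y)), int(np.argmin(y))}
    pc1_extremes = {int(np.argmax(pc1)), int(np.argmin(pc1))}

    rest = np.array([i for i in range(len(y)) if i not in resp_extremes])
    order = rest[_sort_descending_stable(pc1[rest])]
    selected = set(order[_every_fourth_from_second(len(order))])
    selected -= pc1_extremes
    pred_ids = [str(i) for i in ids[sorted(selected)]]
    train_ids = [str(i) for i in ids if i not in set(pred_ids)]
    return SplitAssignment(
        scheme="OStr",
        training_ids=train_ids,
        prediction_ids=pred_ids,
        forced_ids=[str(i) for i in ids[sorted(resp_extremes | pc1_extremes)]],
    )


def split_random(table: DescriptorTable, seed: int) -> SplitAssignment:
    """Random split: ~25% to prediction after forcing the four extreme compounds.

    The compounds holding the maximum/minimum pIC50 and the maximum/minimum
    PC1 score are forced into training; a fixed-size prediction set of
    floor((n - n_forced)/4) compounds is then drawn uniformly without
    replacement from the remainder.  The same seed always reproduces the
    same assignment.
    """
    y = table.y()
    if len(y) < 8:
        raise QsarError("random split needs at least 8 compounds")
    ids = np.asarray(table.ids, dtype=object)
    pc1 = pc1_scores(table).to_numpy()
    forced = {
        int(np.argmax(y)),
        int(np.argmin(y)),
        int(np.argmax(pc1)),
        int(np.argmin(pc1)),
    }
    eligible = np.array([i for i in range(len(y)) if i not in forced])
    n_pred = (len(y) - len(forced)) // 4
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_pred, replace=False)
    pred_ids = [str(i) for i in ids[np.sort(chosen)]]
    train_ids = [str(i) for i in ids if i not in set(pred_ids)]
    return SplitAssignment(
        scheme="Random",
        training_ids=train_ids,
        prediction_ids=pred_ids,
        forced_ids=[str(i) for i in ids[sorted(forced)]],
        seed=seed,
    )


def split(table: DescriptorTable, scheme: str, seed: int | None = None) -> SplitAssignment:
    """Dispatch on scheme name (``ORes``, ``OStr`` or ``Random``)."""
    if scheme == "ORes":
        return split_sorted_response(table)
    if scheme == "OStr":
        return split_sorted_structure(table)
    if scheme == "Random":
        if seed is None:
            raise QsarError("random split requires a seed")
        return split_random(table, seed)
    raise QsarError(f"unknown splitting scheme {scheme!r}; expected one of {SCHEMES}")
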