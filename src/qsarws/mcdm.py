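"""Multiple-criteria decision making scores for ranking candidate models.

Each criterion is mapped to a linear desirability in [0, 1], anchored at
the best and worst values observed across the candidate set, and the
per-model score is the geometric mean of its desirabilities: 1 means best
on every criterion, 0 means worst on at least one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import QsarError
from .validation import ValidationReport

#: (criterion extractor, maximize?) for the fitting score
_FIT_CRITERIA = {
    "R2": (lambda r: r.R2, True),
    "R2_adj": (lambda r: r.R2_adj, True),
    "CCC_tr": (lambda r: r.CCC_tr, True),
    "R2_minus_R2_adj": (lambda r: r.R2 - r.R2_adj, False),
}

_EXT_CRITERIA = {
    "Q2_F1": (lambda r: r.external["Q2_F1"], True),
    "Q2_F2": (lambda r: r.external["Q2_F2"], True),
    "Q2_F3": (lambda r: r.external["Q2_F3"], True),
    "CCC_pr": (lambda r: r.external["CCC_pr"], True),
}


def _desirabilities(values: np.ndarray, maximize: bool) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)
    d = (values - lo) / (hi - lo)
    return d if maximize else 1.0 - d


def _score(reports, criteria) -> pd.DataFrame:
    if not reports:
        raise QsarError("need at least one model report")
    rows = {}
    for name, (getter, maximize) in criteria.items():
        vals = np.array([getter(r) for r in reports], dtype=float)
        if np.isnan(vals).any():
            raise QsarError(f"criterion {name} missing for some model")
        rows[name] = _desirabilities(vals, maximize)
    table = pd.DataFrame(rows)
    table["score"] = table[list(criteria)].prod(axis=1) ** (1.0 / len(criteria))
    return table


def mcdm_fit(reports: list[ValidationReport]) -> pd.DataFrame:
    """Fitting score: maximize R2, R2_adj and CCC_tr, minimize R2 - R2_adj.

    Returns one row per model with per-criterion desirabilities and the
    geometric-mean ``score``.  With a single candidate every desirability
    is 1 by convention.
    """
    return _score(reports, _FIT_CRITERIA)


def mcdm_ext(reports: list[ValidationReport]) -> pd.DataFrame:
    """External score: maximize Q2_F1, Q2_F2, Q2_F3 and CCC_pr."""
    for r in reports:
        if r.external is None:
            raise QsarError("every report needs an external block for mcdm_ext")
    return _score(reports, _EXT_CRITERIA)


def rank_models(
    reports: list[ValidationReport], model_ids: list[str] | None = None
) -> pd.DataFrame:
    """Convenience table ``model_id, mcdm_fit, mcdm_ext`` sorted by mcdm_ext."""
    fit = mcdm_fit(reports)["score"]
    ext = mcdm_ext(reports)["score"]
    if model_ids is None:
        model_ids = [f"model_{i}" for i in range(len(reports))]
    out = pd.DataFrame(
        {"model_id": model_ids, "mcdm_fit": fit, "mcdm_ext": ext}
    )
    return out.sort_values("mcdm_ext", ascending=False).reset_index(drop=True)
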