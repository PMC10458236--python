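"""The validation battery: fitting, robustness, chance-correlation and
external-predictivity statistics, plus the Golbraikh-Tropsha checks.

Internal statistics describe how well the model fits and how stable it is
under row deletion (Q2_LOO, Q2_LMO).  Y-scrambling estimates how much of
the apparent fit could arise by chance.  The external family (R2_pr,
Q2_F1/F2/F3, CCC_pr) measures genuine predictivity on compounds the fit
never saw; the three Q2_F variants differ only in the reference variance
used in the denominator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import (
    QsarError,
    SingularDesignError,
    UndefinedStatisticError,
)
from .regression import MLRModel, _as_matrix, fit_ols, q2_loo


@dataclasses.dataclass
class GTReport:
    """Golbraikh-Tropsha acceptability checks for an externally validated model."""

    k: float
    k_prime: float
    R2_0: float
    R2_0_prime: float
    passes: dict[str, bool]

    @property
    def overall(self) -> bool:
        return all(self.passes.values())


@dataclasses.dataclass
class ValidationReport:
    """All statistics for one model; external block is None when no
    prediction set was supplied."""

    R2: float
    R2_adj: float
    RMSE_tr: float
    MAE_tr: float
    Q2_LOO: float
    Q2_LMO: float | None = None
    Q2_Yscr: float | None = None
    R2_Yscr: float | None = None
    CCC_tr: float | None = None
    external: dict[str, float] | None = None
    gt: GTReport | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def internal_stats(model: MLRModel) -> tuple[float, float, float, float]:
    """Return (R2, R2_adj, RMSE_tr, MAE_tr) of the training fit.

    R2 = 1 - RSS/TSS; R2_adj = 1 - (1-R2)(n-1)/(n-p-1); RMSE uses the
    biased 1/n convention so a perfect fit is exactly zero.
    """
    y = model.y_train
    resid = model.residuals
    n, p = model.n_train, model.p
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedStatisticError("training response has zero variance")
    rss = float(np.sum(resid**2))
    r2 = 1.0 - rss / tss
    if n <= p + 1:
        raise UndefinedStatisticError("adjusted R2 undefined for n <= p + 1")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    rmse = float(np.sqrt(rss / n))
    mae = float(np.mean(np.abs(resid)))
    return r2, r2_adj, rmse, mae


def q2_lmo(
    X,
    y,
    frac_out: float = 0.30,
    iterations: int = 2000,
    seed: int = 0,
) -> float:
    """Leave-many-out Q2: hold out ``frac_out`` of the compounds, refit on
    the rest, score the held-out predictions against the *retained*-set
    mean; average over iterations.  Degenerate subsamples are skipped."""
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    n_out = max(1, int(round(frac_out * n)))
    if n - n_out <= p + 2:
        raise QsarError("too few retained compounds for leave-many-out")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(iterations):
        out_idx = rng.choice(n, size=n_out, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[out_idx] = True
        try:
            model = fit_ols(X[~mask], y[~mask])
        except (SingularDesignError, QsarError):
            continue
        y_hat = model.predict(X[mask])
        denom = float(np.sum((y[mask] - y[~mask].mean()) ** 2))
        if denom == 0.0:
            continue
        scores.append(1.0 - float(np.sum((y_hat - y[mask]) ** 2)) / denom)
    if not scores:
        raise UndefinedStatisticError("every leave-many-out iteration degenerated")
    return float(np.mean(scores))


def y_scramble(
    X, y, iterations: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Chance-correlation test: permute the response, refit, record R2 and
    Q2_LOO; return the means ``(Q2_Yscr, R2_Yscr)`` over iterations.

    For a model whose fit reflects real structure, both means sit near zero
    (Q2 typically slightly negative)."""
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r2s, q2s = [], []
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedStatisticError("response has zero variance")
    for _ in range(iterations):
        y_perm = rng.permutation(y)
        model = fit_ols(X, y_perm)
        r2s.append(1.0 - float(np.sum(model.residuals**2)) / tss)
        q2s.append(q2_loo(X, y_perm))
    return float(np.mean(q2s)), float(np.mean(r2s))


def ccc(x, y) -> float:
    """Concordance correlation coefficient of two paired vectors.

    2*S_xy / (S_xx + S_yy + n*(mean_x - mean_y)^2) with S the sums of
    (cross-)deviations; penalises both scatter and systematic offset.
    Conventions at the degenerate edges: two identical constant vectors
    agree perfectly (1); a constant vector cannot concord with a varying
    one (0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise QsarError("ccc expects two equal-length 1-D vectors, n >= 2")
    dx, dy = x - x.mean(), y - y.mean()
    num = 2.0 * float(dx @ dy)
    den = float(dx @ dx) + float(dy @ dy) + len(x) * (x.mean() - y.mean()) ** 2
    if den == 0.0:
        return 1.0  # both constant and equal
    return num / den


def external_stats(
    model: MLRModel, X_pred, y_pred, y_train=None
) -> dict[str, float]:
    """External-predictivity metrics of a fitted model on a prediction set.

    Q2_F1 scales the prediction error by the external deviance about the
    *training* mean, Q2_F2 about the *external* mean, and Q2_F3 compares
    per-compound error variances between the two sets.
    """
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_pred) == 0:
        raise QsarError("prediction set is empty")
    y_train = np.asarray(
        y_train if y_train is not None else model.y_train, dtype=float
    )
    y_hat = model.predict(X_pred)
    rss = float(np.sum((y_hat - y_pred) ** 2))
    n_ext, n_tr = len(y_pred), len(y_train)
    ybar_tr = y_train.mean()
    d_tr = float(np.sum((y_pred - ybar_tr) ** 2))
    d_ext = float(np.sum((y_pred - y_pred.mean()) ** 2))
    tss_tr = float(np.sum((y_train - ybar_tr) ** 2))
    if d_ext == 0.0:
        raise UndefinedStatisticError("constant external response; R2_pr undefined")
    r = np.corrcoef(y_hat, y_pred)[0, 1]
    return {
        "R2_pr": float(r**2),
        "Q2_F1": 1.0 - rss / d_tr,
        "Q2_F2": 1.0 - rss / d_ext,
        "Q2_F3": 1.0 - (rss / n_ext) / (tss_tr / n_tr),
        "CCC_pr": ccc(y_hat, y_pred),
        "RMSE_pr": float(np.sqrt(rss / n_ext)),
        "MAE_pr": float(np.mean(np.abs(y_hat - y_pred))),
    }


def golbraikh_tropsha(
    y_exp, y_pred, Q2_LOO: float, R2: float, R2_pr: float
) -> GTReport:
    """Evaluate the Golbraikh-Tropsha acceptability thresholds.

    k and k' are the slopes of the through-origin regressions of observed
    on predicted and predicted on observed; R2_0 and R2_0' are the
    corresponding through-origin determination coefficients.  A model is
    acceptable when Q2_LOO > 0.5, R2 and R2_pr > 0.6, at least one slope
    lies in [0.85, 1.15], and |R2_0 - R2_0'| < 0.3.
    """
    y = np.asarray(y_exp, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    s_yy, s_hh = float(yh @ yh), float(y @ y)
    if s_yy == 0.0 or s_hh == 0.0:
        raise UndefinedStatisticError("through-origin slope undefined (zero norm)")
    cross = float(y @ yh)
    k = cross / s_yy
    k_prime = cross / s_hh
    tss_y = float(np.sum((y - y.mean()) ** 2))
    tss_h = float(np.sum((yh - yh.mean()) ** 2))
    if tss_y == 0.0 or tss_h == 0.0:
        raise UndefinedStatisticError("constant vector; R2_0 undefined")
    r2_0 = 1.0 - float(np.sum((y - k * yh) ** 2)) / tss_y
    r2_0p = 1.0 - float(np.sum((yh - k_prime * y) ** 2)) / tss_h
    passes = {
        "q2_loo_gt_0.5": Q2_LOO > 0.5,
        "r2_gt_0.6": R2 > 0.6,
        "r2_pr_gt_0.6": R2_pr > 0.6,
        "slope_in_band": (0.85 <= k <= 1.15) or (0.85 <= k_prime <= 1.15),
        "r2_0_diff_lt_0.3": abs(r2_0 - r2_0p) < 0.3,
    }
    return GTReport(k=k, k_prime=k_prime, R2_0=r2_0, R2_0_prime=r2_0p, passes=passes)


def validate_model(
    model: MLRModel,
    X_pred=None,
    y_pred=None,
    lmo_iterations: int = 2000,
    yscr_iterations: int = 2000,
    lmo_frac_out: float = 0.30,
    seed: int = 0,
) -> ValidationReport:
    """Run the whole battery on a fitted model; the external block and the
    Golbraikh-Tropsha report are included when a prediction set is given."""
    r2, r2_adj, rmse, mae = internal_stats(model)
    q2 = q2_loo(model.X_train, model.y_train)
    q2lmo = q2_lmo(
        model.X_train,
        model.y_train,
        frac_out=lmo_frac_out,
        iterations=lmo_iterations,
        seed=seed,
    )
    q2_yscr, r2_yscr = y_scramble(
        model.X_train, model.y_train, iterations=yscr_iterations, seed=seed + 1
    )
    report = ValidationReport(
        R2=r2,
        R2_adj=r2_adj,
        RMSE_tr=rmse,
        MAE_tr=mae,
        Q2_LOO=q2,
        Q2_LMO=q2lmo,
        Q2_Yscr=q2_yscr,
        R2_Yscr=r2_yscr,
        CCC_tr=ccc(model.y_train, model.fitted_values),
    )
    if X_pred is not None and y_pred is not None:
        report.external = external_stats(model, X_pred, y_pred)
        report.gt = golbraikh_tropsha(
            np.asarray(y_pred, float),
            model.predict(X_pred),
            Q2_LOO=q2,
            R2=r2,
            R2_pr=report.external["R2_pr"],
        )
    return report
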