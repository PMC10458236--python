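"""Registry of the six published MGMT-inactivation model equations.

Each entry stores the printed regression equation verbatim (coefficients as
printed strings, parsed to floats on demand) together with the training-set
size, the warning leverage of the corresponding applicability domain, and
the headline validation statistics, so the equations are usable as
standalone pIC50 predictors on user-supplied descriptor vectors.

Equation 4 (the full nine-descriptor model refit on all 370 compounds)
additionally carries the observed descriptor ranges; evaluating it outside
those ranges triggers an out-of-domain warning rather than an error.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np

from .errors import NamedColumnError, QsarError


@dataclasses.dataclass(frozen=True)
class PublishedEquation:
    """One printed model equation: ordered (descriptor, coefficient) terms."""

    eq_id: int
    name: str
    intercept_str: str
    terms: tuple[tuple[str, str], ...]  # (descriptor name, printed coefficient)
    n_train: int
    statistics: Mapping[str, float]
    descriptor_ranges: Mapping[str, tuple[float, float]] | None = None

    @property
    def intercept(self) -> float:
        return float(self.intercept_str)

    @property
    def coefficients(self) -> dict[str, float]:
        return {name: float(c) for name, c in self.terms}

    @property
    def descriptor_names(self) -> list[str]:
        return [name for name, _ in self.terms]

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def h_star(self) -> float:
        return 3.0 * (self.p + 1) / self.n_train

    def predict(self, descriptor_vector: Mapping[str, float]) -> float:
        """Evaluate intercept + sum(coefficient * value).

        Missing descriptors raise; extra keys are ignored with a warning;
        values outside the recorded training ranges trigger an
        applicability-domain warning.
        """
        missing = [n for n in self.descriptor_names if n not in descriptor_vector]
        if missing:
            raise NamedColumnError(
                f"equation {self.eq_id} needs descriptor(s) {missing}"
            )
        extra = set(descriptor_vector) - set(self.descriptor_names)
        if extra:
            warnings.warn(
                f"ignoring descriptor(s) not in equation {self.eq_id}: {sorted(extra)}",
                stacklevel=2,
            )
        if self.descriptor_ranges:
            for name, (lo, hi) in self.descriptor_ranges.items():
                v = float(descriptor_vector[name])
                if not (lo <= v <= hi):
                    warnings.warn(
                        f"{name}={v} outside the training range [{lo}, {hi}] "
                        f"of equation {self.eq_id}; prediction extrapolates",
                        stacklevel=2,
                    )
        return self.intercept + float(
            np.sum(
                [
                    float(c) * float(descriptor_vector[name])
                    for name, c in self.terms
                ]
            )
        )


#: descriptor ranges observed over the full modeling set (min, max)
FULL_MODEL_RANGES = {
    "MATS6i": (-0.212, 0.371),
    "nCp": (0.0, 6.0),
    "O-060": (0.0, 4.0),
    "B03[O-S]": (0.0, 1.0),
    "SsNH2": (0.0, 11.662),
    "maxHBd": (0.0, 0.764),
    "hmin": (-0.447, 0.425),
    "MDEN-12": (0.0, 2.515),
    "minaaCH": (1.075, 2.329),
}

EQUATIONS: dict[int, PublishedEquation] = {
    1: PublishedEquation(
        eq_id=1,
        name="ORes",
        intercept_str="3.9243",
        terms=(
            ("F09[O-S]", "0.6729"),
            ("SaaN", "0.121"),
            ("MDEN-12", "1.005"),
        ),
        n_train=278,
        statistics={
            "R2": 0.5098,
            "Q2_LOO": 0.4968,
            "Q2_LMO": 0.4952,
            "R2_pr": 0.5319,
            "Q2_F1": 0.5271,
            "Q2_F2": 0.5266,
            "Q2_F3": 0.5658,
            "CCC_pr": 0.6891,
            "RMSE_tr": 0.8669,
            "RMSE_pr": 0.8151,
        },
    ),
    2: PublishedEquation(
        eq_id=2,
        name="OStr",
        intercept_str="7.1639",
        terms=(
            ("VE2sign_B(m)", "-47.2151"),
            ("MATS6i", "2.8662"),
            ("GATS7p", "-1.5036"),
            ("H-048", "-0.1826"),
            ("O-060", "0.5367"),
            ("B08[N-O]", "-0.3698"),
            ("F06[C-S]", "0.3948"),
            ("SsNH2", "-0.1856"),
            ("minHBint6", "0.0537"),
            ("MDEN-12", "1.8451"),
            ("MDEN-22", "0.1755"),
            ("minaaCH", "-0.8906"),
        ),
        n_train=278,
        statistics={
            "R2": 0.6826,
            "Q2_LOO": 0.6496,
            "Q2_LMO": 0.6451,
            "R2_pr": 0.5882,
            "Q2_F1": 0.5721,
            "Q2_F2": 0.5712,
            "Q2_F3": 0.5814,
            "CCC_pr": 0.7617,
            "RMSE_tr": 0.6917,
            "RMSE_pr": 0.7943,
        },
    ),
    3: PublishedEquation(
        eq_id=3,
        name="2D-QSAR",
        intercept_str="4.5562",
        terms=(
            ("MATS6i", "2.5829"),
            ("nCp", "-0.191"),
            ("O-060", "0.3196"),
            ("B03[O-S]", "0.6746"),
            ("SsNH2", "-0.2499"),
            ("maxHBd", "2.4853"),
            ("hmin", "-2.3712"),
            ("MDEN-12", "1.1784"),
            ("minaaCH", "-0.6509"),
        ),
        n_train=279,
        statistics={
            "R2": 0.6086,
            "Q2_LOO": 0.5743,
            "Q2_LMO": 0.5648,
            "Q2_Yscr": -0.0424,
            "R2_Yscr": 0.0324,
            "R2_pr": 0.7474,
            "Q2_F1": 0.7377,
            "Q2_F2": 0.7375,
            "Q2_F3": 0.7437,
            "CCC_pr": 0.8530,
            "RMSE_tr": 0.7682,
            "RMSE_pr": 0.6215,
        },
    ),
    4: PublishedEquation(
        eq_id=4,
        name="2D-QSAR-Full",
        intercept_str="4.7334",
        terms=(
            ("MATS6i", "2.3826"),
            ("nCp", "-0.2387"),
            ("O-060", "0.3401"),
            ("B03[O-S]", "0.6301"),
            ("SsNH2", "-0.248"),
            ("maxHBd", "2.1364"),
            ("hmin", "-2.3442"),
            ("MDEN-12", "1.8332"),
            ("minaaCH", "-0.6324"),
        ),
        n_train=370,
        statistics={
            "R2": 0.6426,
            "Q2_LOO": 0.6202,
            "Q2_LMO": 0.6127,
            "Q2_Yscr": -0.0309,
            "R2_Yscr": 0.0248,
            "RMSE_tr": 0.7320,
        },
        descriptor_ranges=FULL_MODEL_RANGES,
    ),
    5: PublishedEquation(
        eq_id=5,
        name="q-RASAR",
        intercept_str="-1.1683",
        terms=(
            ("RA function (ED)", "0.9192"),
            ("CATS2D_07_AL", "0.0718"),
            ("LLS_02", "1.2875"),
        ),
        n_train=279,
        statistics={
            "R2": 0.6059,
            "Q2_LOO": 0.5957,
            "Q2_LMO": 0.5926,
            "R2_pr": 0.7528,
            "Q2_F1": 0.7389,
            "Q2_F2": 0.7387,
            "Q2_F3": 0.7449,
            "CCC_pr": 0.8560,
            "RMSE_tr": 0.7708,
            "RMSE_pr": 0.6201,
        },
    ),
    6: PublishedEquation(
        eq_id=6,
        name="q-RASAR-Full",
        intercept_str="-1.1089",
        terms=(
            ("RA function (ED)", "0.9149"),
            ("CATS2D_07_AL", "0.0667"),
            ("LLS_02", "1.3166"),
        ),
        n_train=370,
        statistics={
            "R2": 0.6392,
            "Q2_LOO": 0.6322,
            "Q2_LMO": 0.6305,
            "Q2_Yscr": -0.0136,
            "R2_Yscr": 0.0083,
            "RMSE_tr": 0.7354,
        },
    ),
}


def predict_equation(eq_id: int, descriptor_vector: Mapping[str, float]) -> float:
    """Evaluate one registered equation on a descriptor vector."""
    if eq_id not in EQUATIONS:
        raise QsarError(f"no equation {eq_id}; known ids: {sorted(EQUATIONS)}")
    return EQUATIONS[eq_id].predict(descriptor_vector)


def list_equations() -> list[dict]:
    """Registry metadata for display: one row per equation."""
    return [
        {
            "eq_id": eq.eq_id,
            "name": eq.name,
            "n_descriptors": eq.p,
            "descriptors": eq.descriptor_names,
            "n_train": eq.n_train,
            "h_star": eq.h_star,
            "statistics": dict(eq.statistics),
        }
        for eq in EQUATIONS.values()
    ]
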