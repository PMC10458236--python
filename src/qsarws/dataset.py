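"""Compound/descriptor tables, the potency endpoint, and descriptor pruning.

The central container is :class:`DescriptorTable`: one row per compound, a
block of named numeric 2D descriptors, and the inactivation endpoint
expressed as pIC50 = -log10(IC50 in mol/L).  Compounds that failed to
inactivate the target at the highest tested concentration carry no IC50 and
are flagged *censored*; they keep their descriptors and can serve as
query-only (true external) compounds.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Iterable, Iterator, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CensoredEndpointError,
    EmptyPoolError,
    InvalidEndpointError,
    NamedColumnError,
    QsarError,
)

#: column names reserved for compound metadata in the CSV dialect
META_COLUMNS = ("id", "name", "smiles", "ic50_uM", "censored", "pic50")


def to_pic50(ic50_uM: float) -> float:
    """Convert an IC50 in micromolar to pIC50 (-log10 of the molar value).

    Higher pIC50 means a more potent inactivator: 1 uM -> 6.0, 0.01 uM -> 8.0.

    Raises
    ------
    InvalidEndpointError
        If the IC50 is missing, NaN, or non-positive.
    """
    if ic50_uM is None:
        raise InvalidEndpointError("IC50 value is missing")
    ic50_uM = float(ic50_uM)
    if math.isnan(ic50_uM) or ic50_uM <= 0:
        raise InvalidEndpointError(f"IC50 must be a positive number, got {ic50_uM!r}")
    return -math.log10(ic50_uM * 1e-6)


@dataclasses.dataclass
class CompoundRecord:
    """A single compound: identifier, optional structure, endpoint, descriptors."""

    id: str
    name: str = ""
    smiles: str | None = None
    ic50_uM: float | None = None
    censored: bool = False
    descriptors: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        has_ic50 = self.ic50_uM is not None and not (
            isinstance(self.ic50_uM, float) and math.isnan(self.ic50_uM)
        )
        if has_ic50 == self.censored:
            raise QsarError(
                f"compound {self.id!r}: exactly one of ic50_uM / censored must be set"
            )

    @property
    def pic50(self) -> float:
        if self.censored:
            raise CensoredEndpointError(f"compound {self.id!r} is censored; no pIC50")
        return to_pic50(self.ic50_uM)


class DescriptorTable:
    """Ordered compounds x named numeric descriptors, with the pIC50 endpoint.

    Parameters
    ----------
    descriptors
        Numeric frame indexed by unique compound id.  No missing cells.
    pic50
        Endpoint per compound; NaN exactly where ``censored`` is True.
    censored
        Boolean flag per compound.
    meta
        Optional frame with ``name`` / ``smiles`` / ``ic50_uM`` columns.
    """

    def __init__(
        self,
        descriptors: pd.DataFrame,
        pic50: pd.Series,
        censored: pd.Series | None = None,
        meta: pd.DataFrame | None = None,
    ) -> None:
        if descriptors.index.has_duplicates:
            dupes = descriptors.index[descriptors.index.duplicated()].tolist()
            raise QsarError(f"duplicate compound ids: {dupes}")
        if descriptors.isna().any().any():
            bad = descriptors.columns[descriptors.isna().any()].tolist()
            raise QsarError(f"missing descriptor values in columns {bad}")
        if censored is None:
            censored = pd.Series(False, index=descriptors.index)
        pic50 = pic50.reindex(descriptors.index).astype(float)
        censored = censored.reindex(descriptors.index).astype(bool)
        mismatch = pic50.isna() != censored
        if mismatch.any():
            raise QsarError(
                "pic50 must be defined exactly for non-censored compounds; "
                f"offending ids: {descriptors.index[mismatch].tolist()[:5]}"
            )
        self.descriptors = descriptors.astype(float)
        self.pic50 = pic50
        self.censored = censored
        self.meta = meta if meta is not None else pd.DataFrame(index=descriptors.index)

    # -- basic introspection -------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.descriptors.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    @property
    def n_compounds(self) -> int:
        return len(self.descriptors)

    def __len__(self) -> int:
        return self.n_compounds

    def X(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Descriptor sub-matrix as float ndarray (all columns by default)."""
        if columns is None:
            return self.descriptors.to_numpy(float)
        missing = [c for c in columns if c not in self.descriptors.columns]
        if missing:
            raise NamedColumnError(f"unknown descriptor column(s): {missing}")
        return self.descriptors.loc[:, list(columns)].to_numpy(float)

    def y(self) -> np.ndarray:
        """pIC50 vector; raises if any compound is censored."""
        if self.censored.any():
            raise CensoredEndpointError(
                "table contains censored compounds with no endpoint"
            )
        return self.pic50.to_numpy(float)

    def subset(self, ids: Iterable[str]) -> "DescriptorTable":
        ids = list(ids)
        missing = [i for i in ids if i not in self.descriptors.index]
        if missing:
            raise QsarError(f"unknown compound ids: {missing[:5]}")
        return DescriptorTable(
            self.descriptors.loc[ids],
            self.pic50.loc[ids],
            self.censored.loc[ids],
            self.meta.loc[ids] if len(self.meta.columns) else None,
        )

    def records(self) -> Iterator[CompoundRecord]:
        for cid in self.ids:
            censored = bool(self.censored.loc[cid])
            ic50 = None
            if "ic50_uM" in self.meta.columns and not censored:
                ic50 = float(self.meta.loc[cid, "ic50_uM"])
            elif not censored:
                ic50 = 10.0 ** (-self.pic50.loc[cid]) * 1e6
            yield CompoundRecord(
                id=str(cid),
                name=str(self.meta.loc[cid].get("name", "") or ""),
                smiles=self.meta.loc[cid].get("smiles") if "smiles" in self.meta.columns else None,
                ic50_uM=ic50,
                censored=censored,
                descriptors=self.descriptors.loc[cid].to_dict(),
            )

    # -- construction and I/O ------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[CompoundRecord]) -> "DescriptorTable":
        records = list(records)
        if not records:
            raise QsarError("no records")
        names = list(records[0].descriptors)
        for r in records:
            if list(r.descriptors) != names:
                raise QsarError(
                    f"compound {r.id!r} has a different descriptor set"
                )
        idx = pd.Index([r.id for r in records], name="id")
        desc = pd.DataFrame([r.descriptors for r in records], index=idx)
        pic50 = pd.Series(
            [math.nan if r.censored else r.pic50 for r in records], index=idx
        )
        cens = pd.Series([r.censored for r in records], index=idx)
        meta = pd.DataFrame(
            {
                "name": [r.name for r in records],
                "smiles": [r.smiles for r in records],
                "ic50_uM": [r.ic50_uM for r in records],
            },
            index=idx,
        )
        return cls(desc, pic50, cens, meta)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorTable":
        """Load the CSV dialect ``id,name,smiles,ic50_uM,censored,<descriptors...>``.

        An optional precomputed ``pic50`` column overrides the IC50 transform.
        """
        df = pd.read_csv(path, dtype={"id": str})
        if "id" not in df.columns:
            raise QsarError("input CSV lacks an 'id' column")
        df = df.set_index("id")
        if df.index.has_duplicates:
            raise QsarError("duplicate compound ids in input CSV")
        desc_cols = [c for c in df.columns if c not in META_COLUMNS]
        if not desc_cols:
            raise QsarError("input CSV has no descriptor columns")
        censored = (
            df["censored"].astype(str).str.lower().isin(("true", "1", "yes"))
            if "censored" in df.columns
            else pd.Series(False, index=df.index)
        )
        if "pic50" in df.columns:
            pic50 = df["pic50"].astype(float)
        elif "ic50_uM" in df.columns:
            pic50 = pd.Series(
                [
                    math.nan if c else to_pic50(v)
                    for v, c in zip(df["ic50_uM"], censored)
                ],
                index=df.index,
            )
        else:
            raise QsarError("input CSV needs an 'ic50_uM' or 'pic50' column")
        meta = df[[c for c in ("name", "smiles", "ic50_uM") if c in df.columns]]
        return cls(df[desc_cols], pic50, censored, meta)

    def write_csv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.descriptors.index)
        for col in ("name", "smiles", "ic50_uM"):
            if col in self.meta.columns:
                out[col] = self.meta[col]
        out["censored"] = self.censored
        out["pic50"] = self.pic50
        out = pd.concat([out, self.descriptors], axis=1)
        out.index.name = "id"
        out.to_csv(path)


# -- descriptor pruning ------------------------------------------------------


def prune_descriptors(
    table: DescriptorTable,
    near_constant_frac: float = 0.80,
    corr_cut: float = 0.95,
) -> tuple[DescriptorTable, list[dict]]:
    """Drop redundant descriptor columns; return the pruned table and a log.

    Two filters, applied in order:

    1. *near-constant*: a column whose modal value occurs in more than
       ``near_constant_frac`` of compounds carries almost no information and
       is dropped;
    2. *inter-correlation*: scanning column pairs in input order, whenever
       |Pearson r| exceeds ``corr_cut`` the later column of the pair is
       dropped, until no surviving pair exceeds the cut.

    The removal log records every dropped column with its reason, so the
    reduction is auditable and reproducible.
    """
    if table.n_compounds < 2:
        raise QsarError("need at least two compounds to prune descriptors")
    if not (0 < near_constant_frac < 1 and 0 < corr_cut < 1):
        raise QsarError("pruning thresholds must lie in (0, 1)")

    log: list[dict] = []
    desc = table.descriptors
    n = len(desc)

    keep: list[str] = []
    for col in desc.columns:
        modal_frac = desc[col].value_counts().iloc[0] / n
        if modal_frac > near_constant_frac:
            log.append(
                {
                    "column": col,
                    "reason": "near_constant",
                    "modal_fraction": float(modal_frac),
                }
            )
        else:
            keep.append(col)

    if keep:
        corr = desc[keep].corr().abs().to_numpy()
        dropped = np.zeros(len(keep), dtype=bool)
        for i in range(len(keep)):
            if dropped[i]:
                continue
            for j in range(i + 1, len(keep)):
                if dropped[j]:
                    continue
                if corr[i, j] > corr_cut:
                    dropped[j] = True
                    log.append(
                        {
                            "column": keep[j],
                            "reason": "correlated",
                            "with": keep[i],
                            "abs_r": float(corr[i, j]),
                        }
                    )
        keep = [c for c, d in zip(keep, dropped) if not d]

    if not keep:
        raise EmptyPoolError("descriptor pruning removed every column")

    pruned = DescriptorTable(
        desc[keep],
        table.pic50,
        table.censored,
        table.meta if len(table.meta.columns) else None,
    )
    return pruned, log


def write_removal_log(log: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2))


# -- modeling / true-external triage ----------------------------------------


def assemble_modeling_sets(
    table: DescriptorTable, outlier_ids: Sequence[str] = ()
) -> tuple[DescriptorTable, DescriptorTable]:
    """Partition into a modeling set and a true external set.

    The true external set collects (a) censored compounds, which have no
    numeric endpoint and can only ever be queries, and (b) the listed
    activity-cliff response outliers whose endpoints are suspect.  Everything
    else is available for training/prediction splitting.
    """
    outliers = set(map(str, outlier_ids))
    unknown = outliers - set(table.ids)
    if unknown:
        raise QsarError(f"outlier ids not in table: {sorted(unknown)[:5]}")
    external_ids = [
        cid for cid in table.ids if table.censored.loc[cid] or cid in outliers
    ]
    modeling_ids = [cid for cid in table.ids if cid not in set(external_ids)]
    return table.subset(modeling_ids), table.subset(external_ids)


def chemical_space_coords(
    table: DescriptorTable,
    x_col: str,
    y_col: str,
    membership: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Plot-ready chemical-space coordinates (e.g. MW vs ALogP).

    Returns one row per compound with ``x``, ``y`` and an optional ``set``
    tag, preserving table order.
    """
    for col in (x_col, y_col):
        if col not in table.descriptors.columns:
            raise NamedColumnError(f"column {col!r} not in table")
    out = pd.DataFrame(
        {
            "x": table.descriptors[x_col],
            "y": table.descriptors[y_col],
        },
        index=table.descriptors.index,
    )
    if membership is not None:
        out["set"] = [membership.get(cid, "unassigned") for cid in table.ids]
    return out
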