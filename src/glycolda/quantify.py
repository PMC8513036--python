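"""Relative-abundance feature construction from isomer peak-area tables.

Raw extracted-ion-chromatogram peak areas are converted, per sample, to
percentages of the summed area (closing the data to 100), which removes
injection/response differences between runs.  Three feature families are
built on that scale: individual isomer percentages, per-glycan sums over
all isomers of one composition, and within-glycan isomer ratios.  Because
the data are compositional, closure induces mild negative correlation
between features; the synthetic generator reproduces this so downstream
statistics are exercised under realistic dependence.

Feature descriptors are strings: ``"N5H6S2|iso4"`` (isomer percentage),
``"N5H6S2|sum"`` (glycan sum), ``"N5H6S2|r4:5"`` (isomer 4 / isomer 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .masses import parse_composition

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "CLASS_LABELS",
    "PeakTable",
    "FeatureMatrix",
    "relative_areas",
    "glycan_sums",
    "isomer_ratios",
    "group_summary",
    "all_isomer_pairs",
    "iso_feature",
    "sum_feature",
    "ratio_feature",
]

PEAK_TABLE_COLUMNS = ["sample_id", "class", "composition", "isomer_index", "rt_min", "area"]
CLASS_LABELS = ("melanoma", "control", "unknown")


def iso_feature(composition: str, isomer: int) -> str:
    return f"{composition}|iso{isomer}"

def sum_feature(composition: str) -> str:
    return f"{composition}|sum"

def ratio_feature(composition: str, i: int, j: int) -> str:
    return f"{composition}|r{i}:{j}"


@dataclass
class PeakTable:
    """Long-format sample x isomer peak-area table."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if (self.data["area"] < 0).any():
            bad = self.data.loc[self.data["area"] < 0].index[0]
            raise ValueError(f"negative peak area at row {bad}")
        dup = self.data.duplicated(["sample_id", "composition", "isomer_index"])
        if dup.any():
            raise ValueError(
                f"duplicate (sample, composition, isomer) rows at index "
                f"{list(self.data.index[dup])}"
            )
        bad_cls = ~self.data["class"].isin(CLASS_LABELS)
        if bad_cls.any():
            raise ValueError(
                f"unknown class label(s) {sorted(self.data.loc[bad_cls, 'class'].unique())}"
            )
        for comp in self.data["composition"].unique():
            parse_composition(comp)  # raises on malformed compositions

    @property
    def samples(self) -> list[str]:
        return list(self.data["sample_id"].unique())

    def class_of(self) -> pd.Series:
        return self.data.groupby("sample_id", sort=False)["class"].first()


@dataclass
class FeatureMatrix:
    """Samples x features with class labels.

    ``values`` is indexed by sample_id with feature-descriptor columns;
    ``labels`` maps sample_id to class.  ``flagged`` records (sample,
    feature) cells produced by the zero-denominator epsilon policy.
    """

    values: pd.DataFrame
    labels: pd.Series
    flagged: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise ValueError("every sample needs a class label")

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.labels.copy(), set(self.flagged))

    @property
    def isomer_columns(self) -> list[str]:
        return [c for c in self.values.columns if "|iso" in c]

    def compositions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.isomer_columns:
            seen.setdefault(c.split("|")[0])
        return list(seen)

    def isomers_of(self, composition: str) -> list[int]:
        prefix = f"{composition}|iso"
        return sorted(
            int(c[len(prefix):]) for c in self.values.columns if c.startswith(prefix)
        )


def relative_areas(table: PeakTable) -> FeatureMatrix:
    """Express each isomer area as a percentage of its sample's summed area."""
    wide = table.data.pivot_table(
        index="sample_id",
        columns=["composition", "isomer_index"],
        values="area",
        aggfunc="sum",
        fill_value=0.0,
        sort=False,
    )
    totals = wide.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total area: {list(zero.index)}")
    pct = wide.div(totals, axis=0) * 100.0
    pct.columns = [iso_feature(comp, iso) for comp, iso in pct.columns]
    labels = table.class_of().reindex(pct.index)
    return FeatureMatrix(pct, labels)


def glycan_sums(features: FeatureMatrix) -> FeatureMatrix:
    """Append one ``comp|sum`` feature per composition (sum over its isomers)."""
    out = features.copy()
    sums = {
        sum_feature(comp): out.values[
            [iso_feature(comp, i) for i in out.isomers_of(comp)]
        ].sum(axis=1)
        for comp in out.compositions()
    }
    out.values = pd.concat([out.values, pd.DataFrame(sums, index=out.values.index)], axis=1)
    return out


def all_isomer_pairs(features: FeatureMatrix) -> list[tuple[str, int, int]]:
    """All ordered within-glycan isomer pairs (i < j, elution order)."""
    pairs = []
    for comp in features.compositions():
        isos = features.isomers_of(comp)
        pairs.extend((comp, i, j) for k, i in enumerate(isos) for j in isos[k + 1:])
    return pairs


def isomer_ratios(
    features: FeatureMatrix,
    pairs: Optional[Iterable[tuple[str, int, int]]] = None,
) -> FeatureMatrix:
    """Append within-glycan isomer-ratio features ``comp|r{i}:{j}``.

    Zero denominators are floored at half the smallest nonzero isomer
    percentage in the matrix, and the affected cells are flagged (the study
    data contain no absent isomers, so this is a documented policy rather
    than an observed case).
    """
    out = features.copy()
    if pairs is None:
        pairs = all_isomer_pairs(out)
    iso_vals = out.values[out.isomer_columns]
    nonzero = iso_vals.values[iso_vals.values > 0]
    floor = 0.5 * nonzero.min() if len(nonzero) else np.nan
    new_cols = {}
    for comp, i, j in pairs:
        for idx in (i, j):
            if iso_feature(comp, idx) not in out.values.columns:
                raise ValueError(f"no isomer {idx} for glycan {comp}")
        num = out.values[iso_feature(comp, i)]
        den = out.values[iso_feature(comp, j)]
        name = ratio_feature(comp, i, j)
        zero_den = den <= 0
        safe_den = den.where(~zero_den, floor)
        new_cols[name] = num / safe_den
        for sample in out.values.index[zero_den]:
            out.flagged.add((sample, name))
    out.values = pd.concat(
        [out.values, pd.DataFrame(new_cols, index=out.values.index)], axis=1
    )
    return out


def group_summary(features: FeatureMatrix) -> pd.DataFrame:
    """Per-feature class means, melanoma/control fold change and per-class RSD%.

    RSD uses the sample standard deviation (n−1 denominator).
    """
    labels = features.labels
    groups = {}
    for cls in ("control", "melanoma"):
        members = features.values.loc[labels == cls]
        if len(members) < 2:
            raise ValueError(f"need >= 2 samples of class {cls!r}")
        groups[cls] = members
    out = pd.DataFrame(index=features.values.columns)
    for cls, members in groups.items():
        mean = members.mean(axis=0)
        sd = members.std(axis=0, ddof=1)
        out[f"{cls}_mean"] = mean
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{cls}_rsd_pct"] = np.where(mean != 0, 100.0 * sd / mean.abs(), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_change"] = out["melanoma_mean"] / out["control_mean"]
    out.index.name = "feature"
    return out
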