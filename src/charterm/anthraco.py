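"""Charcoal assemblage quantification.

Fragment counts per taxon and stratigraphic unit (SU) are summarised as
relative frequencies (%), ubiquity-corrected frequencies (%U -- the mean of a
taxon's per-SU percentages, weighting presence across contexts over raw
abundance), combined shares of the dominant taxa, minimum-taxa counts, and
prevalences of anatomical alteration features (vitrification, radial cracks).
Percentages are kept unrounded internally and rounded half-away-from-zero to
one decimal only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rounding import round_half_away

__all__ = [
    "TaxonCountTable",
    "relative_frequencies",
    "ubiquity_correction",
    "main_taxa_share",
    "minimum_taxa_number",
    "feature_prevalence",
    "table_report",
]

SIZE_CLASSES = ("0.3-0.99 cm", "1-1.99 cm", "2-2.99 cm")


@dataclass
class TaxonCountTable:
    """Fragment counts by taxon x stratigraphic unit, with optional extras.

    ``counts`` is a taxon-indexed DataFrame with one column per SU.
    ``indeterminate_labels`` are excluded from minimum-taxa counts (fragments
    identifiable only to a high rank, e.g. "Angiosperm").  ``size_classes``
    is an optional taxon x size-class count table and ``feature_counts`` maps
    (taxon, feature) to the number of fragments showing that feature.
    """

    counts: pd.DataFrame
    indeterminate_labels: set = field(default_factory=set)
    size_classes: pd.DataFrame | None = None
    feature_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")
        totals = self.counts.sum(axis=1)
        if self.size_classes is not None:
            for taxon in self.size_classes.index:
                if self.size_classes.loc[taxon].sum() > totals.get(taxon, 0):
                    raise ValidationError(f"size-class total exceeds count for {taxon}")
        for (taxon, _), c in self.feature_counts.items():
            if c > totals.get(taxon, 0):
                raise ValidationError(f"feature count exceeds fragment count for {taxon}")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, **kwargs) -> "TaxonCountTable":
        """Build from a tidy (taxon, su, count) frame, e.g. read from CSV."""
        wide = df.pivot_table(index="taxon", columns="su", values="count",
                              aggfunc="sum", fill_value=0, sort=False)
        return cls(wide, **kwargs)

    @property
    def sus(self) -> list:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list:
        return list(self.counts.index)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def relative_frequencies(t: TaxonCountTable) -> pd.DataFrame:
    """Per-SU and overall relative frequencies (%), unrounded.

    Columns: one per SU plus ``overall`` (from summed counts).
    """
    if t.grand_total == 0:
        raise ValidationError("all-zero count table")
    su_totals = t.counts.sum(axis=0)
    if (su_totals == 0).any():
        raise ValidationError("every SU needs at least one fragment")
    out = 100.0 * t.counts / su_totals
    out["overall"] = 100.0 * t.counts.sum(axis=1) / t.grand_total
    return out


def ubiquity_correction(t: TaxonCountTable) -> pd.Series:
    """%U per taxon: the mean of its unrounded per-SU percentages.

    An SU where the taxon is absent contributes 0, so %U down-weights taxa
    concentrated in a single context.  Summing %U over all taxa gives 100.
    """
    freq = relative_frequencies(t)[t.sus]
    return freq.mean(axis=1)


def main_taxa_share(t: TaxonCountTable, k: int):
    """Combined (%, %U) of the k most abundant taxa by overall count."""
    if k > len(t.taxa):
        raise ValidationError(f"k={k} exceeds the {len(t.taxa)} taxa present")
    top = t.counts.sum(axis=1).sort_values(ascending=False, kind="stable").index[:k]
    freq = relative_frequencies(t)
    return float(freq.loc[top, "overall"].sum()), float(ubiquity_correction(t).loc[top].sum())


def minimum_taxa_number(t: TaxonCountTable, su) -> int:
    """Number of determinate taxa present (count > 0) in one SU."""
    if su not in t.counts.columns:
        raise ValidationError(f"unknown SU {su!r}")
    col = t.counts[su]
    return int(((col > 0) & ~col.index.isin(list(t.indeterminate_labels))).sum())


def feature_prevalence(t: TaxonCountTable, taxon: str, feature: str) -> float:
    """Percentage of a taxon's fragments showing an anatomical feature (unrounded)."""
    if (taxon, feature) not in t.feature_counts:
        raise ValidationError(f"no record of feature {feature!r} for {taxon!r}")
    total = int(t.counts.loc[taxon].sum())
    if total == 0:
        raise ValidationError(f"no fragments counted for {taxon!r}")
    return 100.0 * t.feature_counts[(taxon, feature)] / total


def table_report(t: TaxonCountTable) -> pd.DataFrame:
    """Assemblage summary in the shape of a printed abundance table.

    One row per taxon with per-SU N and %, overall N, % and %U (one-decimal,
    half-away-from-zero), plus a Total row.
    """
    freq = relative_frequencies(t)
    pu = ubiquity_correction(t)
    rows = {}
    for taxon in t.taxa:
        row = {}
        for su in t.sus:
            row[f"N {su}"] = int(t.counts.loc[taxon, su])
            row[f"% {su}"] = round_half_away(freq.loc[taxon, su], 1)
        row["N total"] = int(t.counts.loc[taxon].sum())
        row["% total"] = round_half_away(freq.loc[taxon, "overall"], 1)
        row["%U"] = round_half_away(pu.loc[taxon], 1)
        rows[taxon] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    total = {f"N {su}": int(t.counts[su].sum()) for su in t.sus}
    total.update({f"% {su}": 100.0 for su in t.sus})
    total.update({"N total": t.grand_total, "% total": 100.0, "%U": 100.0})
    report.loc["Total"] = total
    for su in t.sus:
        report[f"N {su}"] = report[f"N {su}"].astype(int)
    report["N total"] = report["N total"].astype(int)
    return report
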