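"""Catalog of the 10 morphological wave-pattern features and the
relative-frequency histogram computed from binary score tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "MorphologicalFeature",
    "FEATURES",
    "FeatureScoreTable",
    "feature_histogram",
    "group_sizes",
]


@dataclass(frozen=True)
class MorphologicalFeature:
    id: int
    name: str
    definition: str


FEATURES: Tuple[MorphologicalFeature, ...] = (
    MorphologicalFeature(1, "rho_flickers",
                         "spatially disorganized local flashes of activity "
                         "with no evidence of spatial propagation"),
    MorphologicalFeature(2, "pulse_mediated_turbulence",
                         "individual activity maxima randomly emerge and "
                         "erratically move a short distance before "
                         "disappearing; propagation evident in kymographs"),
    MorphologicalFeature(3, "spiral_turbulence",
                         "well-formed wave fragments densely populate the "
                         "field of view; temporal but not spatial "
                         "correlation"),
    MorphologicalFeature(4, "localized_spiral_turbulence",
                         "turbulent dynamics confined to limited areas "
                         "surrounded by organized wave trains and spirals"),
    MorphologicalFeature(5, "lamellar_wave_trains",
                         "persistent domains of flat or slightly curved "
                         "waves with robust propagation"),
    MorphologicalFeature(6, "wave_front_dislocations",
                         "dislocations of wave fronts"),
    MorphologicalFeature(7, "grain_boundaries",
                         "interface pattern of two wave trains with near "
                         "orthogonal wave vectors"),
    MorphologicalFeature(8, "single_armed_spirals",
                         "well-formed spiral waves with >=2-3 full turns"),
    MorphologicalFeature(9, "two_armed_spirals",
                         "stable two-armed spiral waves with >=2-3 full "
                         "turns"),
    MorphologicalFeature(10, "line_defects",
                         "boundaries between wave trains with nearly "
                         "antiparallel wave vectors"),
)

FEATURE_COLUMNS = [f"f{i}" for i in range(1, 11)]


class FeatureScoreTable:
    """Binary presence/absence scores: one row per experiment.

    Columns are a ``group`` label plus ``f1`` ... ``f10`` 0/1 entries.
    """

    def __init__(self, df: pd.DataFrame):
        missing = {"group", *FEATURE_COLUMNS} - set(df.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        scores = df[FEATURE_COLUMNS].to_numpy()
        if not np.isin(scores, (0, 1)).all():
            raise ValueError("feature scores must be binary 0/1")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "FeatureScoreTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_counts(cls, group_feature_rows: Dict[str, list]) -> "FeatureScoreTable":
        """Build from {group: [list of 10-element 0/1 rows]}."""
        rows = []
        for group, experiments in group_feature_rows.items():
            for scores in experiments:
                rows.append({"group": group,
                             **dict(zip(FEATURE_COLUMNS, scores))})
        return cls(pd.DataFrame(rows))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, index=False)


def feature_histogram(table: FeatureScoreTable,
                      normalize: str = "grand") -> pd.DataFrame:
    """Per-(group, feature) relative occurrence frequencies.

    ``normalize='grand'`` divides each (group, feature) occurrence sum by
    the grand total of occurrences over the whole table (entries then sum
    to 1 over the matrix); ``normalize='group'`` divides by each group's
    own occurrence total instead.
    """
    sums = table.df.groupby("group", sort=False)[FEATURE_COLUMNS].sum()
    grand = float(sums.to_numpy().sum())
    if grand == 0:
        raise ValueError("all-zero score table: no occurrences to normalize")
    if normalize == "grand":
        return sums / grand
    if normalize == "group":
        totals = sums.sum(axis=1)
        return sums.div(totals.replace(0, np.nan), axis=0)
    raise ValueError("normalize must be 'grand' or 'group'")


def group_sizes(table: FeatureScoreTable) -> Tuple[pd.Series, int]:
    """Row counts per group and their total."""
    counts = table.df.groupby("group", sort=False).size()
    return counts, int(counts.sum())
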