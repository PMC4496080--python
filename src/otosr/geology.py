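"""Watershed geology and the candidate covariates of the Sr isoscape.

River-water ⁸⁷Sr/⁸⁶Sr tracks the age and composition of the rock a watershed
drains: old cratonic shield terrain (high Rb/Sr, long in-growth of
radiogenic ⁸⁷Sr) produces high ratios, while young Andean sediment produces
low ones.  This module turns a tabular description of a watershed's geologic
units — one row per mapped unit with its age range, a broad rock class and
its outcrop area — into the covariates the isoscape regression consumes:

* the fraction of watershed area in each geologic age class,
* the fraction in each broad rock class (intrusive / extrusive / other),
* the area-weighted mean age of the watershed (Ma).

Age-class bounds are read from a small editable table bundled with the
package (``data/age_class_bounds.csv``) so that chart revisions do not
require code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ROCK_CLASSES = ("intrusive", "extrusive", "other")

#: Rock-class fractions offered to the regression.  "other" is the complement
#: of the two informative classes and would be collinear with them.
CANDIDATE_ROCK_CLASSES = ("intrusive", "extrusive")

MEAN_AGE_NAME = "mean_age"

GEOLOGY_COLUMNS = (
    "watershed_id",
    "age_class",
    "age_min_ma",
    "age_max_ma",
    "rock_class",
    "area_km2",
)


@dataclass(frozen=True)
class GeologyUnit:
    """One mapped geologic unit inside a watershed."""

    watershed_id: str
    age_class: str
    age_min: float  # Ma
    age_max: float  # Ma
    rock_class: str
    area: float  # km^2

    def __post_init__(self):
        if self.age_min < 0 or self.age_max < 0:
            raise ValidationError(
                f"unit in {self.watershed_id!r}: negative age bounds "
                f"({self.age_min}, {self.age_max})"
            )
        if self.age_min > self.age_max:
            raise ValidationError(
                f"unit in {self.watershed_id!r}: age_min {self.age_min} "
                f"> age_max {self.age_max}"
            )
        if self.area <= 0:
            raise ValidationError(
                f"unit in {self.watershed_id!r}: area must be positive"
            )
        if self.rock_class not in ROCK_CLASSES:
            raise ValidationError(
                f"unknown rock class {self.rock_class!r}; "
                f"expected one of {ROCK_CLASSES}"
            )


@dataclass(frozen=True)
class WatershedCovariates:
    """Area-fraction summary of a watershed's geology.

    Fractions are stored in [0, 1]; ``mean_age`` is in Ma and is weighted by
    unit area.
    """

    fractions_by_age_class: Mapping[str, float]
    fractions_by_rock_class: Mapping[str, float] = field(default_factory=dict)
    mean_age: float = 0.0

    def as_dict(self) -> dict[str, float]:
        """Flatten to candidate-variable name -> value."""
        out = dict(self.fractions_by_age_class)
        for rc in CANDIDATE_ROCK_CLASSES:
            if rc in self.fractions_by_rock_class:
                out[rc] = self.fractions_by_rock_class[rc]
        out[MEAN_AGE_NAME] = self.mean_age
        return out


def unit_mean_age(unit: GeologyUnit) -> float:
    """Midpoint of a unit's age range (Ma).

    Geologic map codes give an age *range*; the continuous age variable used
    by the regression is the midpoint of that range.
    """
    return 0.5 * (unit.age_min + unit.age_max)


def compute_covariates(
    units: Sequence[GeologyUnit], watershed_id: str
) -> WatershedCovariates:
    """Summarise one watershed's units into area fractions and weighted age.

    ``fractions_by_age_class[c]`` is the summed area of units in class ``c``
    divided by the watershed's total area; likewise for rock classes.  The
    mean age is sum(area_i * midpoint_i) / sum(area_i).
    """
    mine = [u for u in units if u.watershed_id == watershed_id]
    if not mine:
        raise ValidationError(f"no geology units for watershed {watershed_id!r}")
    total = sum(u.area for u in mine)
    if total <= 0:
        raise ValidationError(f"watershed {watershed_id!r} has zero total area")
    by_age: dict[str, float] = {}
    by_rock: dict[str, float] = {}
    wage = 0.0
    for u in mine:
        by_age[u.age_class] = by_age.get(u.age_class, 0.0) + u.area
        by_rock[u.rock_class] = by_rock.get(u.rock_class, 0.0) + u.area
        wage += u.area * unit_mean_age(u)
    return WatershedCovariates(
        fractions_by_age_class={k: v / total for k, v in sorted(by_age.items())},
        fractions_by_rock_class={k: v / total for k, v in sorted(by_rock.items())},
        mean_age=wage / total,
    )


@dataclass(frozen=True)
class CandidateMatrix:
    """A named design-matrix description: one row per site, one column per
    candidate explanatory variable (age-class fractions, informative
    rock-class fractions, then area-weighted mean age, in that order)."""

    variables: tuple[str, ...]
    frame: pd.DataFrame  # index = site_name, columns = variables

    def __len__(self) -> int:
        return len(self.frame)


def build_candidate_matrix(sites: Iterable) -> CandidateMatrix:
    """Assemble the candidate explanatory variables for a set of water sites.

    ``sites`` is an iterable of :class:`otosr.io.WaterSite` (anything with
    ``site_name`` and ``covariates`` works).  The candidate set is the union
    of every age class present across sites, the intrusive/extrusive rock
    fractions when any site carries them, and the area-weighted mean age.
    A site missing an age class that others have simply drains no area of
    that class, so the entry is 0.
    """
    sites = list(sites)
    if not sites:
        raise ValidationError("no sites supplied")
    age_classes: set[str] = set()
    rock_classes: set[str] = set()
    for s in sites:
        if s.covariates is None:
            raise ValidationError(f"site {s.site_name!r} has no covariates")
        age_classes.update(s.covariates.fractions_by_age_class)
        rock_classes.update(
            rc
            for rc in s.covariates.fractions_by_rock_class
            if rc in CANDIDATE_ROCK_CLASSES
        )
    variables = tuple(
        sorted(age_classes) + sorted(rock_classes) + [MEAN_AGE_NAME]
    )
    rows = []
    for s in sites:
        d = s.covariates.as_dict()
        rows.append([d.get(v, 0.0) for v in variables])
    frame = pd.DataFrame(
        rows, index=[s.site_name for s in sites], columns=list(variables)
    )
    return CandidateMatrix(variables=variables, frame=frame)


def load_age_class_bounds() -> pd.DataFrame:
    """Bundled chronostratigraphic age-class bounds (Ma), one row per class."""
    with resources.files("otosr.data").joinpath("age_class_bounds.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("age_class")


def read_geology_table(path: str | Path) -> list[GeologyUnit]:
    """Read a geology unit table (CSV or TSV) into :class:`GeologyUnit` rows."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in GEOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"geology table missing required column(s): {missing}")
    return [
        GeologyUnit(
            watershed_id=str(r.watershed_id),
            age_class=str(r.age_class),
            age_min=float(r.age_min_ma),
            age_max=float(r.age_max_ma),
            rock_class=str(r.rock_class),
            area=float(r.area_km2),
        )
        for r in df.itertuples(index=False)
    ]


def write_geology_table(units: Sequence[GeologyUnit], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "watershed_id": [u.watershed_id for u in units],
            "age_class": [u.age_class for u in units],
            "age_min_ma": [repr(float(u.age_min)) for u in units],
            "age_max_ma": [repr(float(u.age_max)) for u in units],
            "rock_class": [u.rock_class for u in units],
            "area_km2": [repr(float(u.area)) for u in units],
        }
    )
    df.to_csv(path, index=False)


def covariates_for_watersheds(
    units: Sequence[GeologyUnit],
) -> dict[str, WatershedCovariates]:
    """Covariates for every watershed id present in ``units``."""
    ids = sorted({u.watershed_id for u in units})
    return {wid: compute_covariates(units, wid) for wid in ids}
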