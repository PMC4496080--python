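"""Tabular input/output and the bundled in-study baselines.

All tables are plain delimited text (comma by default, tab accepted) with
required named headers, so fixtures stay diff-able and round-trip
bit-exactly.  Percent-valued covariate cells may be written either as
fractions ("0.21") or with a percent sign ("21%"); internally everything is
a fraction in [0, 1].  Missing values are empty cells, never sentinel
numbers.

Two reference tables ship with the package:

* ``load_water_baseline()`` — the literature water-chemistry baseline for the
  Amazon basin (site, river, river group, ⁸⁷Sr/⁸⁶Sr, sampling SD/n, geologic
  covariates, predicted/outlier markers);
* ``load_fish_records()`` — the market-sampled *Brachyplatystoma* specimens
  (dourada, piramutaba, piraíba) whose otoliths the pipeline analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RowError, ValidationError
from .geology import MEAN_AGE_NAME, WatershedCovariates
from .movement import MovementSummaryRow, Transect  # noqa: F401  (re-export)

SPECIES = ("dourada", "piramutaba", "piraiba")
PORTS = ("Belem", "Manaus")

WATER_REQUIRED = ("site_name", "source", "river", "sr_ratio")
FISH_REQUIRED = ("sample_id", "species", "port")
TRANSECT_COLUMNS = ("distance_um", "sr87_sr86")

_AGE_PREFIX = "pct_"
_ROCK_PREFIX = "rockpct_"


@dataclass(frozen=True)
class FishRecord:
    """One market-sampled fish."""

    sample_id: str
    species: str
    port: str
    total_length: float | None = None  # cm
    weight: float | None = None  # kg
    weight_estimated: bool = False
    otolith_excluded: bool = False

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValidationError(
                f"{self.sample_id}: unknown species {self.species!r}"
            )
        if self.total_length is not None and not self.total_length > 0:
            raise ValidationError(f"{self.sample_id}: total_length must be > 0")
        if self.weight is not None and not self.weight > 0:
            raise ValidationError(f"{self.sample_id}: weight must be > 0")


@dataclass(frozen=True)
class WaterSite:
    """One baseline river site: measured or regression-predicted ⁸⁷Sr/⁸⁶Sr
    plus the geologic covariates of its upstream watershed."""

    site_name: str
    source: str
    river: str
    sr_ratio: float
    group_label: str | None = None
    sr_sd: float | None = None
    n_samples: int | None = None
    covariates: WatershedCovariates | None = None
    predicted: bool = False
    pred_interval_halfwidth: float | None = None
    outlier: bool = False

    def __post_init__(self):
        if not 0.70 < self.sr_ratio < 0.80:
            raise ValidationError(
                f"{self.site_name}: sr_ratio {self.sr_ratio} outside (0.70, 0.80)"
            )
        if self.sr_sd is not None and self.sr_sd < 0:
            raise ValidationError(f"{self.site_name}: sr_sd must be >= 0")
        if self.predicted and (self.sr_sd is not None or self.n_samples is not None):
            raise ValidationError(
                f"{self.site_name}: predicted sites carry no sampling sd/n"
            )


def _parse_fraction(cell, *, site: str, column: str) -> float:
    """'21%' -> 0.21; bare numbers are taken as fractions already."""
    if isinstance(cell, str):
        cell = cell.strip()
        if cell.endswith("%"):
            v = float(cell[:-1]) / 100.0
        else:
            v = float(cell)
    else:
        v = float(cell)
    if not 0.0 <= v <= 1.0:
        raise ValidationError(
            f"{site}: {column} = {v} is not a fraction in [0, 1]"
        )
    return v


def _parse_bool(cell) -> bool:
    if isinstance(cell, (bool, np.bool_)):
        return bool(cell)
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    s = str(cell).strip().lower()
    if s in ("true", "t", "yes", "1"):
        return True
    if s in ("false", "f", "no", "0", ""):
        return False
    raise ValidationError(f"cannot interpret {cell!r} as a boolean")


def _is_missing(cell) -> bool:
    return cell is None or (isinstance(cell, float) and math.isnan(cell)) or (
        isinstance(cell, str) and not cell.strip()
    )


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_water_table(path: str | Path) -> list[WaterSite]:
    """Read a water-baseline table into :class:`WaterSite` rows (order kept).

    Age-class covariates live in ``pct_<age_class>`` columns, rock-class
    covariates in ``rockpct_<rock_class>`` columns, the area-weighted mean
    age in ``mean_age_ma``.
    """
    df = _read_delimited(path)
    missing = [c for c in WATER_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"water table missing required column(s): {missing}")
    age_cols = [c for c in df.columns if c.startswith(_AGE_PREFIX)]
    rock_cols = [c for c in df.columns if c.startswith(_ROCK_PREFIX)]
    sites: list[WaterSite] = []
    for idx, row in enumerate(df.to_dict("records")):
        name = str(row["site_name"])
        try:
            sr = float(row["sr_ratio"])
        except (TypeError, ValueError):
            raise RowError(idx, f"unparseable sr_ratio {row['sr_ratio']!r}") from None
        by_age = {
            c[len(_AGE_PREFIX):]: _parse_fraction(row[c], site=name, column=c)
            for c in age_cols
            if not _is_missing(row[c])
        }
        by_rock = {
            c[len(_ROCK_PREFIX):]: _parse_fraction(row[c], site=name, column=c)
            for c in rock_cols
            if not _is_missing(row[c])
        }
        cov = None
        if by_age or by_rock or not _is_missing(row.get("mean_age_ma")):
            cov = WatershedCovariates(
                fractions_by_age_class=by_age,
                fractions_by_rock_class=by_rock,
                mean_age=(
                    0.0
                    if _is_missing(row.get("mean_age_ma"))
                    else float(row["mean_age_ma"])
                ),
            )
        sites.append(
            WaterSite(
                site_name=name,
                source=str(row.get("source", "")),
                river=str(row.get("river", "")),
                group_label=(
                    None
                    if _is_missing(row.get("group_label"))
                    else str(row["group_label"])
                ),
                sr_ratio=sr,
                sr_sd=(
                    None if _is_missing(row.get("sr_sd")) else float(row["sr_sd"])
                ),
                n_samples=(
                    None if _is_missing(row.get("n")) else int(float(row["n"]))
                ),
                covariates=cov,
                predicted=_parse_bool(row.get("predicted")),
                pred_interval_halfwidth=(
                    None
                    if _is_missing(row.get("pred_interval"))
                    else float(row["pred_interval"])
                ),
                outlier=_parse_bool(row.get("outlier")),
            )
        )
    return sites


def write_water_table(sites: Sequence[WaterSite], path: str | Path) -> None:
    """Write sites in the same dialect :func:`read_water_table` consumes."""
    age_classes = sorted(
        {
            ac
            for s in sites
            if s.covariates is not None
            for ac in s.covariates.fractions_by_age_class
        }
    )
    rock_classes = sorted(
        {
            rc
            for s in sites
            if s.covariates is not None
            for rc in s.covariates.fractions_by_rock_class
        }
    )
    rows = []
    for s in sites:
        row: dict[str, object] = {
            "site_name": s.site_name,
            "source": s.source,
            "river": s.river,
            "group_label": s.group_label or "",
            "sr_ratio": repr(s.sr_ratio),
            "sr_sd": "" if s.sr_sd is None else repr(s.sr_sd),
            "n": "" if s.n_samples is None else s.n_samples,
        }
        for ac in age_classes:
            row[_AGE_PREFIX + ac] = (
                ""
                if s.covariates is None
                else repr(s.covariates.fractions_by_age_class.get(ac, 0.0))
            )
        for rc in rock_classes:
            row[_ROCK_PREFIX + rc] = (
                ""
                if s.covariates is None
                else repr(s.covariates.fractions_by_rock_class.get(rc, 0.0))
            )
        row["mean_age_ma"] = (
            "" if s.covariates is None else repr(s.covariates.mean_age)
        )
        row["predicted"] = "true" if s.predicted else "false"
        row["outlier"] = "true" if s.outlier else "false"
        row["pred_interval"] = (
            ""
            if s.pred_interval_halfwidth is None
            else repr(s.pred_interval_halfwidth)
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fish_table(path: str | Path) -> list[FishRecord]:
    """Read a fish metadata table; duplicate sample ids are rejected."""
    df = _read_delimited(path)
    missing = [c for c in FISH_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"fish table missing required column(s): {missing}")
    records: list[FishRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.to_dict("records")):
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        records.append(
            FishRecord(
                sample_id=sid,
                species=str(row["species"]),
                port=str(row["port"]),
                total_length=(
                    None
                    if _is_missing(row.get("total_length_cm"))
                    else float(row["total_length_cm"])
                ),
                weight=(
                    None
                    if _is_missing(row.get("weight_kg"))
                    else float(row["weight_kg"])
                ),
                weight_estimated=_parse_bool(row.get("weight_estimated")),
                otolith_excluded=_parse_bool(row.get("otolith_excluded")),
            )
        )
    return records


def write_fish_table(records: Sequence[FishRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "species": r.species,
            "port": r.port,
            "total_length_cm": "" if r.total_length is None else repr(r.total_length),
            "weight_kg": "" if r.weight is None else repr(r.weight),
            "weight_estimated": "true" if r.weight_estimated else "false",
            "otolith_excluded": "true" if r.otolith_excluded else "false",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transect(
    path: str | Path, sample_id: str | None = None, species: str | None = None
) -> Transect:
    """Read one otolith transect (columns ``distance_um``, ``sr87_sr86``)."""
    df = _read_delimited(path)
    missing = [c for c in TRANSECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"transect file missing required column(s): {missing}")
    sid = sample_id or Path(path).stem
    return Transect(
        sample_id=sid,
        species=species,
        distances=df["distance_um"].astype(float).to_numpy(),
        ratios=df["sr87_sr86"].astype(float).to_numpy(),
    )


def write_transect(transect: Transect, path: str | Path) -> None:
    pd.DataFrame(
        {
            "distance_um": [repr(float(v)) for v in transect.distances],
            "sr87_sr86": [repr(float(v)) for v in transect.ratios],
        }
    ).to_csv(path, index=False)


def transects_from_xlsx(path: str | Path) -> list[Transect]:
    """Best-effort conversion of a spreadsheet of otolith transects.

    Each worksheet is taken to hold one sample (the sheet name is the sample
    id) with the first two numeric columns interpreted as distance from the
    core (um) and ⁸⁷Sr/⁸⁶Sr; header rows and trailing blanks are skipped.
    This keeps the rest of the package format-agnostic: convert once, then
    work with the plain-text transect CSVs.
    """
    from openpyxl import load_workbook

    wb = load_workbook(filename=str(path), read_only=True, data_only=True)
    out: list[Transect] = []
    for ws in wb.worksheets:
        dist: list[float] = []
        ratio: list[float] = []
        for row in ws.iter_rows(values_only=True):
            vals = [c for c in (row or ()) if c is not None]
            nums = []
            for c in vals:
                try:
                    nums.append(float(c))
                except (TypeError, ValueError):
                    break
            if len(nums) >= 2:
                dist.append(nums[0])
                ratio.append(nums[1])
        if len(dist) >= 10:
            out.append(
                Transect(
                    sample_id=str(ws.title),
                    distances=np.asarray(dist),
                    ratios=np.asarray(ratio),
                )
            )
    wb.close()
    return out


def load_water_baseline() -> list[WaterSite]:
    """The bundled literature water baseline (29 sites: 24 sampled of which
    one is flagged as a regression outlier, plus 5 regression-predicted)."""
    with resources.as_file(
        resources.files("otosr.data").joinpath("water_baseline.csv")
    ) as p:
        return read_water_table(p)


def load_fish_records() -> list[FishRecord]:
    """The bundled specimen table (16 dourada, 5 piramutaba, 3 piraíba)."""
    with resources.as_file(
        resources.files("otosr.data").joinpath("fish_records.csv")
    ) as p:
        return read_fish_table(p)


def movement_summary_table(rows: Iterable[MovementSummaryRow]) -> pd.DataFrame:
    """Per-fish movement summary as a tidy frame (one row per fish)."""
    rows = list(rows)
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "species": [r.species for r in rows],
            "n_segments": [r.n_segments for r in rows],
            "n_signature_moves": [r.n_signature_moves for r in rows],
            "n_group_moves": [r.n_group_moves for r in rows],
            "group_sequence": [" -> ".join(r.group_sequence) for r in rows],
        }
    )
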