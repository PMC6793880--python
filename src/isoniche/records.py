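"""Shared record types, CSV I/O, run configuration and logging.

All tabular exchange uses UTF-8 CSV with a header row and "." decimal.
Arbitrary input headers are bound to canonical field names through a
column map, so files produced by other groups can be read unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("isoniche")

FISHED = "fished"
PROTECTED = "protected"
#: ordered protection levels: fished < protected
STATUS_LEVELS = (FISHED, PROTECTED)

#: minimum group size for ellipse estimation; the small-sample correction
#: divides by n - 2 and a 2-point covariance is degenerate
MIN_ELLIPSE_N = 3


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler with level and module tags (idempotent)."""
    root = logging.getLogger("isoniche")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class ConfigurationError(ValueError):
    """Invalid run configuration or malformed input structure (e.g. missing column)."""


class DataError(ValueError):
    """A data row violates a record invariant; message carries row context."""


class StructureError(ValueError):
    """The site/area hierarchy is inconsistent (e.g. one site in two areas)."""


class NonEstimableGroupError(ValueError):
    """A species x area group is too small for ellipse estimation (n < 3)."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class IsotopeRecord:
    """One fish: grouping labels, size, and bulk tissue isotope values.

    ``d13c`` and ``d15n`` are per-mil (permille) deviations from the
    international standards (V-PDB, atmospheric air).  ``weight_g`` may be
    missing (None): it is never used by the isotope analysis.
    """

    fish_id: str
    species: str
    site: str
    area: str
    status: str
    length_cm: float
    d13c: float
    d15n: float
    weight_g: float | None = None

    def __post_init__(self):
        if self.status not in STATUS_LEVELS:
            raise DataError(
                f"fish {self.fish_id}: status {self.status!r} not in {STATUS_LEVELS}")
        for name in ("d13c", "d15n"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DataError(f"fish {self.fish_id}: non-finite {name}={v!r}")
        if self.length_cm is not None and not (self.length_cm > 0):
            raise DataError(f"fish {self.fish_id}: length must be > 0, got {self.length_cm}")
        if self.weight_g is not None and not (self.weight_g > 0):
            raise DataError(f"fish {self.fish_id}: weight must be > 0 or missing")


@dataclass(frozen=True, slots=True)
class SurveyRecord:
    """One belt-transect observation cell (transect x species).

    ``benthic_habitat`` is an ordinal substrate-complexity code 1..6
    (gravel -> bedrock); ``kelp`` is 0..2 (zero / fragmented / full canopy);
    ``depth_stratum`` is 'shallow' (5-8 m) or 'deep' (10-13 m).
    A zero count records sampled effort with no fish seen (length is NaN).
    """

    site: str
    transect_id: str
    depth_stratum: str
    benthic_habitat: int
    kelp: int
    species: str
    count: int
    length_cm: float

    def __post_init__(self):
        if self.count < 0:
            raise DataError(f"transect {self.transect_id}: negative count")
        if not 1 <= self.benthic_habitat <= 6:
            raise DataError(f"transect {self.transect_id}: benthic habitat code "
                            f"{self.benthic_habitat} outside 1..6")
        if not 0 <= self.kelp <= 2:
            raise DataError(f"transect {self.transect_id}: kelp code {self.kelp} outside 0..2")
        if self.depth_stratum not in ("shallow", "deep"):
            raise DataError(f"transect {self.transect_id}: depth stratum "
                            f"{self.depth_stratum!r} not shallow/deep")


@dataclass(frozen=True, slots=True)
class DietRecord:
    """One prey taxon inside one (non-empty) predator stomach."""

    predator_id: str
    predator_species: str
    area: str
    prey_taxon: str
    prey_count: int
    prey_mass_g: float

    def __post_init__(self):
        if self.prey_count < 1:
            raise DataError(f"stomach {self.predator_id}: prey count must be >= 1")
        if self.prey_mass_g < 0:
            raise DataError(f"stomach {self.predator_id}: negative prey mass")


@dataclass(slots=True)
class RunConfig:
    """Analysis configuration shared by the pipeline stages.

    Defaults follow the study conventions: 10^4 posterior draws per group,
    a vague normal-inverse-Wishart prior, a rock-scallop d15N baseline of
    10.32 permil (SD 0.4), and AICc support / averaging cut-offs of 2 and 4.
    """

    seed: int = 0
    n_draws: int = 10_000
    prior_mean: tuple[float, float] | None = None  # None -> group sample mean
    prior_kappa: float = 1e-3
    prior_df: float = 3.0
    prior_scale: Sequence[Sequence[float]] = ((1.0, 0.0), (0.0, 1.0))
    baseline_d15n: float = 10.32
    baseline_sd: float = 0.4
    delta_aicc_support: float = 2.0
    delta_aicc_average: float = 4.0

    def __post_init__(self):
        if self.n_draws < 100:
            raise ConfigurationError("n_draws must be >= 100")
        if self.prior_kappa <= 0 or self.prior_df < 3:
            raise ConfigurationError("prior_kappa must be > 0 and prior_df >= 3")
        if self.delta_aicc_support <= 0 or self.delta_aicc_average <= 0:
            raise ConfigurationError("AICc cut-offs must be positive")
        if self.baseline_sd <= 0:
            raise ConfigurationError("baseline_sd must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping")
        known = set(cls.__dataclass_fields__)
        extra = set(data) - known
        if extra:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(extra)}")
        if "prior_mean" in data and data["prior_mean"] is not None:
            data["prior_mean"] = tuple(data["prior_mean"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior_scale"] = [list(r) for r in np.asarray(self.prior_scale, dtype=float)]
        return d

    def config_hash(self) -> str:
        """Stable hash of the canonicalised configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

ISOTOPE_COLUMNS = ("fish_id", "species", "site", "area", "status",
                   "length_cm", "d13c", "d15n")
DIET_COLUMNS = ("predator_id", "predator_species", "area",
                "prey_taxon", "prey_count", "prey_mass_g")
SURVEY_COLUMNS = ("site", "transect_id", "depth_stratum", "benthic_habitat",
                  "kelp", "species", "count", "length_cm")


def _load_mapped(path: str | Path, required: Sequence[str],
                 column_map: Mapping[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")
    return df


def _float_field(raw: str, row: int, label: str, *, allow_missing: bool = False):
    raw = raw.strip()
    if raw == "" or raw.upper() in ("NA", "NAN"):
        if allow_missing:
            return None
        raise DataError(f"row {row} ({label}): missing or non-numeric value {raw!r}")
    try:
        return float(raw)
    except ValueError:
        raise DataError(f"row {row} ({label}): non-numeric value {raw!r}") from None


def read_isotope_csv(path: str | Path,
                     column_map: Mapping[str, str] | None = None) -> list[IsotopeRecord]:
    """Read per-fish isotope records, validating every row.

    Rows violating record invariants raise :class:`DataError` naming the
    1-based data row and the fish id; a missing column raises
    :class:`ConfigurationError`.
    """
    df = _load_mapped(path, ISOTOPE_COLUMNS, column_map)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        fish = getattr(row, "fish_id")
        weight = None
        if "weight_g" in df.columns:
            weight = _float_field(getattr(row, "weight_g"), i, fish, allow_missing=True)
        try:
            records.append(IsotopeRecord(
                fish_id=fish,
                species=getattr(row, "species"),
                site=getattr(row, "site"),
                area=getattr(row, "area"),
                status=getattr(row, "status"),
                length_cm=_float_field(getattr(row, "length_cm"), i, fish),
                d13c=_float_field(getattr(row, "d13c"), i, fish),
                d15n=_float_field(getattr(row, "d15n"), i, fish),
                weight_g=weight,
            ))
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") from None
    logger.info("read %d isotope records from %s", len(records), path)
    return records


def write_isotope_csv(records: Iterable[IsotopeRecord], path: str | Path) -> None:
    df = isotope_frame(records)
    df.to_csv(path, index=False, float_format="%.10g")


def isotope_frame(records: Iterable[IsotopeRecord]) -> pd.DataFrame:
    """Records as a DataFrame (the in-memory table the analysis layers use)."""
    rows = [{
        "fish_id": r.fish_id, "species": r.species, "site": r.site,
        "area": r.area, "status": r.status, "length_cm": r.length_cm,
        "weight_g": np.nan if r.weight_g is None else r.weight_g,
        "d13c": r.d13c, "d15n": r.d15n,
    } for r in records]
    return pd.DataFrame(rows, columns=ISOTOPE_COLUMNS[:5] + ("length_cm", "weight_g", "d13c", "d15n"))


def read_diet_csv(path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> list[DietRecord]:
    df = _load_mapped(path, DIET_COLUMNS, column_map)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = getattr(row, "predator_id")
        try:
            records.append(DietRecord(
                predator_id=pid,
                predator_species=getattr(row, "predator_species"),
                area=getattr(row, "area"),
                prey_taxon=getattr(row, "prey_taxon"),
                prey_count=int(_float_field(getattr(row, "prey_count"), i, pid)),
                prey_mass_g=_float_field(getattr(row, "prey_mass_g"), i, pid),
            ))
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") from None
    return records


def write_diet_csv(records: Iterable[DietRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False, float_format="%.10g")


def read_survey_csv(path: str | Path,
                    column_map: Mapping[str, str] | None = None) -> list[SurveyRecord]:
    df = _load_mapped(path, SURVEY_COLUMNS, column_map)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        tid = getattr(row, "transect_id")
        try:
            length = _float_field(getattr(row, "length_cm"), i, tid, allow_missing=True)
            records.append(SurveyRecord(
                site=getattr(row, "site"),
                transect_id=tid,
                depth_stratum=getattr(row, "depth_stratum"),
                benthic_habitat=int(_float_field(getattr(row, "benthic_habitat"), i, tid)),
                kelp=int(_float_field(getattr(row, "kelp"), i, tid)),
                species=getattr(row, "species"),
                count=int(_float_field(getattr(row, "count"), i, tid)),
                length_cm=math.nan if length is None else length,
            ))
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") from None
    return records


def write_survey_csv(records: Iterable[SurveyRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# hierarchy validation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class HierarchySummary:
    """Nested design summary: areas -> sites, per species x area sample sizes,
    and the species x area cells too small for ellipse fitting (n < 3)."""

    areas: dict[str, list[str]]
    status_by_area: dict[str, str]
    n_by_species_area: dict[tuple[str, str], int]
    non_estimable: set[tuple[str, str]] = field(default_factory=set)

    @property
    def n_sites(self) -> int:
        return sum(len(s) for s in self.areas.values())


def validate_hierarchy(records: Sequence[IsotopeRecord]) -> HierarchySummary:
    """Check the nested site-within-area design and count samples per cell.

    Deterministic and order-independent: the summary is identical for any
    permutation of the input.  Raises :class:`StructureError` if a site is
    assigned to two areas or an area carries two protection statuses.
    """
    if not records:
        raise StructureError("no records")
    site_area: dict[str, str] = {}
    area_status: dict[str, str] = {}
    counts: dict[tuple[str, str], int] = {}
    areas: dict[str, set[str]] = {}
    for r in records:
        prev = site_area.setdefault(r.site, r.area)
        if prev != r.area:
            raise StructureError(f"site {r.site!r} assigned to areas {prev!r} and {r.area!r}")
        prev_s = area_status.setdefault(r.area, r.status)
        if prev_s != r.status:
            raise StructureError(f"area {r.area!r} carries statuses {prev_s!r} and {r.status!r}")
        areas.setdefault(r.area, set()).add(r.site)
        key = (r.species, r.area)
        counts[key] = counts.get(key, 0) + 1
    non_estimable = {k for k, n in counts.items() if n < MIN_ELLIPSE_N}
    for sp, ar in sorted(non_estimable):
        logger.warning("species %r in area %r has n=%d < %d: not estimable for ellipses",
                       sp, ar, counts[(sp, ar)], MIN_ELLIPSE_N)
    return HierarchySummary(
        areas={a: sorted(s) for a, s in sorted(areas.items())},
        status_by_area=dict(sorted(area_status.items())),
        n_by_species_area=dict(sorted(counts.items())),
        non_estimable=non_estimable,
    )


# ---------------------------------------------------------------------------
# length-weight helper (survey summarisation)
# ---------------------------------------------------------------------------

def length_weight(length_cm, a: float, b: float):
    """Species-specific length-weight power law W = a * L^b (grams from cm)."""
    length_cm = np.asarray(length_cm, dtype=float)
    if np.any(length_cm < 0):
        raise DataError("negative length in length-weight conversion")
    return a * length_cm ** b


def survey_biomass(records: Sequence[SurveyRecord],
                   coefficients: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """Per site x species biomass (g) from transect counts and lengths.

    ``coefficients`` maps species -> (a, b) of the length-weight power law.
    Records with zero count contribute zero biomass.
    """
    rows = []
    for r in records:
        if r.count == 0:
            rows.append({"site": r.site, "species": r.species, "biomass_g": 0.0,
                         "count": 0})
            continue
        if r.species not in coefficients:
            raise ConfigurationError(f"no length-weight coefficients for {r.species!r}")
        a, b = coefficients[r.species]
        rows.append({"site": r.site, "species": r.species,
                     "biomass_g": float(r.count * length_weight(r.length_cm, a, b)),
                     "count": r.count})
    df = pd.DataFrame(rows)
    return (df.groupby(["site", "species"], as_index=False)
              .agg(biomass_g=("biomass_g", "sum"), count=("count", "sum")))
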