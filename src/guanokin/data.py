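"""Domain types and plain-text I/O for mite gut histology score tables.

The raw observations are ordinal guanine scores (0 = contracted / no
guanine, 1 = some, 2 = expanded with lots) taken on the Malpighian
tubules associated with each of 15 gut regions, plus a parallel score
for guanine inside the gut lumen, for each destructively-sampled mite.
Times are minutes since the start of feeding; the canonical internal
time unit is minutes (all design times are exact integers in minutes),
while kinetic rate constants elsewhere in the package are per hour.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SCHEMA_VERSION = 1

SCORE_COLUMNS = [
    "mite_id",
    "sex",
    "time_min",
    "region",
    "malpighian_score",
    "lumen_score",
]


class RegionGroup(str, enum.Enum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"
    RECTAL_VESICLE = "rectal_vesicle"


class GutRegion(str, enum.Enum):
    """The 15 scored gut regions, anterior to posterior.

    Codes follow the standard abbreviations for the pergamasid gut
    (anterodorsal caeca, ventriculus, mesenteron, posterior caeca,
    hind gut, rectal vesicle).
    """

    ANTDCLH = "ANTDCLH"    # anterodorsal caecum, left
    ANTDCRH = "ANTDCRH"    # anterodorsal caecum, right
    VENTRIC = "VENTRIC"    # ventriculus
    MESANT = "MESANT"      # mesenteron, anterior
    MESPOST = "MESPOST"    # mesenteron, posterior
    POSDCLHA = "POSDCLHA"  # posterodorsal caecum, left, anterior part
    POSDCRHA = "POSDCRHA"
    POSVCLHA = "POSVCLHA"  # posteroventral caecum, left, anterior part
    POSVCRHA = "POSVCRHA"
    POSDCLHP = "POSDCLHP"  # posterodorsal caecum, left, posterior part
    POSDCRHP = "POSDCRHP"
    POSVCLHP = "POSVCLHP"
    POSVCRHP = "POSVCRHP"
    HINDG = "HINDG"        # hind gut
    RECTALV = "RECTALV"    # rectal vesicle

    @property
    def anatomical_order(self) -> int:
        """1-based anterior-to-posterior rank."""
        return _ORDER[self]

    @property
    def group(self) -> RegionGroup:
        if self is GutRegion.RECTALV:
            return RegionGroup.RECTAL_VESICLE
        if _ORDER[self] <= 5:
            return RegionGroup.ANTERIOR
        return RegionGroup.POSTERIOR


_ORDER = {r: i + 1 for i, r in enumerate(GutRegion)}

#: Regions whose associated tubules count as "anterior" in the
#: anterior-vs-posterior odds-ratio contrast (configurable downstream).
ANTERIOR_REGIONS = frozenset(
    r for r in GutRegion if r.group is RegionGroup.ANTERIOR
)
#: The remaining non-rectal regions (posterior caeca + hind gut).
POSTERIOR_REGIONS = frozenset(
    r for r in GutRegion if r.group is RegionGroup.POSTERIOR
)

VALID_SCORES = (0, 1, 2)
VALID_SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class ScoreRecord:
    """A single (mite, gut region) histology observation."""

    mite_id: str
    sex: str
    time_min: float
    region: GutRegion
    malpighian_score: int
    lumen_score: int

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if self.time_min < 0:
            raise ValueError(f"time_min must be >= 0, got {self.time_min}")
        if not isinstance(self.region, GutRegion):
            raise ValueError(f"unknown gut region {self.region!r}")
        for name in ("malpighian_score", "lumen_score"):
            v = getattr(self, name)
            if v not in VALID_SCORES:
                raise ValueError(f"{name} must be in {VALID_SCORES}, got {v!r}")


@dataclass
class ScoreTable:
    """Long-format collection of ScoreRecords (the raw-data surrogate).

    Invariants: each (mite_id, region) pair appears at most once and
    every mite carries all 15 regions.
    """

    records: list[ScoreRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("ScoreTable must contain at least one record")
        seen: set[tuple[str, GutRegion]] = set()
        per_mite: dict[str, set[GutRegion]] = {}
        for rec in self.records:
            key = (rec.mite_id, rec.region)
            if key in seen:
                raise ValueError(f"duplicate record for {key}")
            seen.add(key)
            per_mite.setdefault(rec.mite_id, set()).add(rec.region)
        for mite, regions in per_mite.items():
            if len(regions) != len(GutRegion):
                missing = sorted(r.value for r in set(GutRegion) - regions)
                raise ValueError(f"mite {mite!r} missing regions {missing}")

    @property
    def design_times_min(self) -> list[float]:
        """Distinct sampling times present, sorted ascending."""
        return sorted({rec.time_min for rec in self.records})

    @property
    def n_mites(self) -> int:
        return len({rec.mite_id for rec in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mite_id": [r.mite_id for r in self.records],
                "sex": [r.sex for r in self.records],
                "time_min": [r.time_min for r in self.records],
                "region": [r.region.value for r in self.records],
                "malpighian_score": [r.malpighian_score for r in self.records],
                "lumen_score": [r.lumen_score for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScoreTable":
        records = []
        for i, row in enumerate(frame.itertuples(index=False)):
            try:
                region = GutRegion(str(row.region))
            except ValueError as exc:
                raise ValueError(f"row {i + 1}: unknown region {row.region!r}") from exc
            try:
                records.append(
                    ScoreRecord(
                        mite_id=str(row.mite_id),
                        sex=str(row.sex),
                        time_min=float(row.time_min),
                        region=region,
                        malpighian_score=int(row.malpighian_score),
                        lumen_score=int(row.lumen_score),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"row {i + 1}: {exc}") from exc
        return cls(records)


@dataclass(frozen=True)
class PhaseLandmarks:
    """Physiological phase boundaries (minutes since start of feeding).

    Defaults: 120 min ingestion/digestion knot, 12.5 h onset of net gut
    emptying, 52.5 h gut void (worst-case total feeding cycle), 48 h to
    10 d Malpighian guanine window, starvation onset at 10 d.
    """

    knot_min: float = 120.0
    emptying_onset_min: float = 750.0
    gut_void_min: float = 3150.0
    guanine_window_min: tuple[float, float] = (2880.0, 14400.0)
    starvation_onset_min: float = 14400.0

    def __post_init__(self) -> None:
        for name in ("knot_min", "emptying_onset_min", "gut_void_min", "starvation_onset_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.guanine_window_min
        if not (0 < lo < hi):
            raise ValueError("guanine_window_min must be an increasing positive pair")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path, dialect: dict | None = None) -> ScoreTable:
    """Read a long-format scores table (header row, the six score columns).

    ``dialect`` passes format options straight to the CSV reader (e.g.
    ``{"sep": "\\t"}``).  Raises ValueError naming the offending row for
    malformed rows, unknown region codes, or scores outside {0, 1, 2}.
    """
    path = Path(path)
    frame = pd.read_csv(path, **(dialect or {}))
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return ScoreTable.from_frame(frame[SCORE_COLUMNS])


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


# Result serialization: every result dataclass round-trips through a tagged
# JSON envelope {"schema_version": ..., "type": ..., "payload": {...}}.
# The registry is populated by register_result() calls in the modules that
# define each result type.

_RESULT_REGISTRY: dict[str, type] = {}


def register_result(cls: type) -> type:
    """Class decorator registering a dataclass for write/read round-trips."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


def _to_payload(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            **{
                f.name: _to_payload(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (list, tuple)):
        return [_to_payload(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_payload(v) for k, v in obj.items()}
    return obj


def _from_payload(obj):
    if isinstance(obj, dict) and "__type__" in obj:
        name = obj["__type__"]
        cls = _RESULT_REGISTRY.get(name)
        if cls is None:
            raise ValueError(f"unknown result type {name!r}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in obj:
                kwargs[f.name] = _coerce_field(f, _from_payload(obj[f.name]))
        return cls(**kwargs)
    if isinstance(obj, list):
        return [_from_payload(v) for v in obj]
    return obj


def _coerce_field(f: dataclasses.Field, value):
    # JSON has no tuples; restore tuple-typed fields.
    if isinstance(value, list) and str(f.type).startswith("tuple"):
        return tuple(value)
    return value


def write_results(obj, path: str | Path) -> None:
    """Serialize a registered result object (or list of them) to JSON."""
    payload = _to_payload(obj)
    doc = {"schema_version": SCHEMA_VERSION, "payload": payload}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_results(path: str | Path):
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {doc.get('schema_version')!r}")
    return _from_payload(doc["payload"])
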