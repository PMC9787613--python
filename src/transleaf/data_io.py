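"""Reading, validating and joining tree-record and species-trait tables.

The canonical on-disk form of a tree table is a UTF-8 CSV with a header
row and the default column names::

    tree_id, species, dbh_cm, lcr, crown_class, sg_obs, leaf_mass_kg,
    mat_c, map_mm, study_id

Column names can be remapped via a ``column_map`` (field name -> column
name).  Crown class may be given either as one of the five canonical
labels (``open_grown``, ``dominant``, ``codominant``, ``intermediate``,
``overtopped``; ``suppressed`` is accepted as an alias of ``overtopped``)
or as an ordinal integer code 1-5 (1 = overtopped ... 5 = open grown).

A packaged species-trait table (61 species: 25 softwoods, 36 hardwoods)
provides published leaf longevity (months), shade tolerance score and
published wood specific gravity, keyed by scientific name or numeric
species code.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

__all__ = [
    "CrownClass",
    "CROWN_CLASS_ORDER",
    "TreeRecord",
    "SpeciesTraits",
    "TraitTable",
    "SchemaError",
    "RowError",
    "TraitLookupError",
    "ReadResult",
    "RowIssue",
    "DEFAULT_COLUMNS",
    "parse_crown_class",
    "read_tree_table",
    "write_tree_table",
    "attach_traits",
    "count_sigfigs",
    "filter_min_sigfigs",
    "packaged_traits",
    "packaged_species_stats",
]


class SchemaError(ValueError):
    """A required column is missing or the header is unusable."""


class RowError(ValueError):
    """One or more rows failed validation (carries per-row diagnostics)."""

    def __init__(self, issues: Sequence["RowIssue"]):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues[:20])
        extra = "" if len(self.issues) <= 20 else f" (+{len(self.issues) - 20} more)"
        super().__init__(f"{len(self.issues)} invalid row(s): {lines}{extra}")


class TraitLookupError(KeyError):
    """Species missing from a trait table."""

    def __init__(self, missing: Sequence[str]):
        self.missing = sorted(missing)
        super().__init__(
            "species not found in trait table: "
            + ", ".join(self.missing)
            + " -- supply leaf longevity, shade tolerance and published "
            "specific gravity for these species to proceed"
        )


class CrownClass(str, Enum):
    """Canopy-position class used as the variable intercept."""

    OPEN_GROWN = "open_grown"
    DOMINANT = "dominant"
    CODOMINANT = "codominant"
    INTERMEDIATE = "intermediate"
    OVERTOPPED = "overtopped"


#: Fixed level order used everywhere (intercept block, encodings, reports).
CROWN_CLASS_ORDER: tuple[CrownClass, ...] = (
    CrownClass.OPEN_GROWN,
    CrownClass.DOMINANT,
    CrownClass.CODOMINANT,
    CrownClass.INTERMEDIATE,
    CrownClass.OVERTOPPED,
)

#: Ordinal integer codes: 1 = overtopped ... 5 = open grown.
CROWN_CLASS_CODES: dict[int, CrownClass] = {
    1: CrownClass.OVERTOPPED,
    2: CrownClass.INTERMEDIATE,
    3: CrownClass.CODOMINANT,
    4: CrownClass.DOMINANT,
    5: CrownClass.OPEN_GROWN,
}
CODE_OF_CROWN_CLASS = {v: k for k, v in CROWN_CLASS_CODES.items()}

_CC_ALIASES = {
    "suppressed": CrownClass.OVERTOPPED,
    "open grown": CrownClass.OPEN_GROWN,
    "open-grown": CrownClass.OPEN_GROWN,
}


def parse_crown_class(value: Union[str, int, CrownClass]) -> CrownClass:
    """Parse a crown-class label, alias or 1-5 integer code."""
    if isinstance(value, CrownClass):
        return value
    if isinstance(value, int):
        try:
            return CROWN_CLASS_CODES[value]
        except KeyError:
            raise ValueError(f"unknown crown-class code {value!r} (expected 1-5)")
    token = str(value).strip().lower()
    if token.isdigit():
        return parse_crown_class(int(token))
    token_norm = token.replace("-", "_").replace(" ", "_")
    for cc in CrownClass:
        if token_norm == cc.value:
            return cc
    if token in _CC_ALIASES:
        return _CC_ALIASES[token]
    raise ValueError(f"unknown crown-class label {value!r}")


@dataclass
class TreeRecord:
    """One sampled (or to-be-predicted) tree.

    ``leaf_mass`` is required for fitting/validation and absent for pure
    prediction; ``sg_obs`` is only needed by models with an observed
    specific-gravity term.
    """

    tree_id: str
    species: str
    dbh: float  # stem diameter at breast height, cm
    lcr: float  # live crown ratio, (0, 1]
    cc: CrownClass
    mat: float  # mean annual temperature, degC
    map_mm: float  # mean annual precipitation, mm
    sg_obs: float | None = None
    leaf_mass: float | None = None  # dry leaf mass, kg
    study_id: str | None = None
    #: Original text tokens by field name, kept when read from a file so
    #: that recording precision (significant figures) can be assessed.
    raw_text: dict[str, str] | None = field(default=None, repr=False, compare=False)

    def violations(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        out: list[str] = []
        if not (isinstance(self.dbh, (int, float)) and math.isfinite(self.dbh) and self.dbh > 0):
            out.append(f"dbh must be > 0, got {self.dbh!r}")
        if not (isinstance(self.lcr, (int, float)) and math.isfinite(self.lcr) and 0 < self.lcr <= 1):
            out.append(f"lcr must be in (0, 1], got {self.lcr!r}")
        if not (isinstance(self.map_mm, (int, float)) and math.isfinite(self.map_mm) and self.map_mm > 0):
            out.append(f"map_mm must be > 0, got {self.map_mm!r}")
        if not (isinstance(self.mat, (int, float)) and math.isfinite(self.mat) and self.mat > -30):
            out.append(f"mat must be > -30 degC, got {self.mat!r}")
        if self.leaf_mass is not None and not (math.isfinite(self.leaf_mass) and self.leaf_mass > 0):
            out.append(f"leaf_mass must be > 0 when present, got {self.leaf_mass!r}")
        if self.sg_obs is not None and not (math.isfinite(self.sg_obs) and self.sg_obs > 0):
            out.append(f"sg_obs must be > 0 when present, got {self.sg_obs!r}")
        if not isinstance(self.cc, CrownClass):
            out.append(f"cc must be a CrownClass, got {self.cc!r}")
        return out


@dataclass(frozen=True)
class SpeciesTraits:
    """Species-level published trait values."""

    species: str
    ll: float  # leaf longevity, months
    st: float  # shade tolerance score
    sg_pub: float  # published wood specific gravity
    species_code: str | None = None
    group: str | None = None  # softwood / hardwood

    def __post_init__(self):
        for name in ("ll", "st", "sg_pub"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be > 0, got {v!r}")


def _normalize_key(s: str) -> str:
    return " ".join(str(s).strip().lower().replace("_", " ").split())


@dataclass
class TraitTable:
    """Mapping species -> :class:`SpeciesTraits`, keyed by name or code."""

    traits: dict[str, SpeciesTraits]
    provenance: str = ""

    def __post_init__(self):
        self._index: dict[str, str] = {}
        for name, tr in self.traits.items():
            key = _normalize_key(name)
            if key in self._index:
                raise ValueError(f"duplicate species key {name!r}")
            self._index[key] = name
            if tr.species_code:
                code_key = _normalize_key(tr.species_code)
                if code_key in self._index and self._index[code_key] != name:
                    raise ValueError(f"duplicate species code {tr.species_code!r}")
                self._index[code_key] = name

    def __contains__(self, species: str) -> bool:
        return _normalize_key(species) in self._index

    def __len__(self) -> int:
        return len(self.traits)

    @property
    def species(self) -> list[str]:
        return sorted(self.traits)

    def lookup(self, species: str) -> SpeciesTraits:
        try:
            return self.traits[self._index[_normalize_key(species)]]
        except KeyError:
            raise TraitLookupError([str(species)])

    @classmethod
    def from_csv(cls, source: Union[str, Path, TextIO], provenance: str = "") -> "TraitTable":
        """Read a trait table CSV (``#`` comment lines are skipped)."""
        close = False
        if isinstance(source, (str, Path)):
            fh: TextIO = open(source, "r", encoding="utf-8", newline="")
            close = True
        else:
            fh = source
        try:
            lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
        finally:
            if close:
                fh.close()
        reader = csv.DictReader(lines)
        required = {"species", "leaf_longevity_months", "shade_tolerance", "sg_published"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise SchemaError(f"trait table missing column(s): {', '.join(missing)}")
        traits: dict[str, SpeciesTraits] = {}
        for row in reader:
            name = row["species"].strip()
            traits[name] = SpeciesTraits(
                species=name,
                ll=float(row["leaf_longevity_months"]),
                st=float(row["shade_tolerance"]),
                sg_pub=float(row["sg_published"]),
                species_code=(row.get("species_code") or "").strip() or None,
                group=(row.get("group") or "").strip() or None,
            )
        return cls(traits=traits, provenance=provenance)


@lru_cache(maxsize=1)
def packaged_traits() -> TraitTable:
    """The packaged 61-species published-trait table."""
    ref = resources.files("transleaf.data") / "species_traits.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return TraitTable.from_csv(fh, provenance="packaged species trait reference table")


@dataclass(frozen=True)
class SpeciesStats:
    """Per-species sample sizes and DBH / LCR summary moments."""

    species: str
    species_code: str
    n_attr: int
    n_cv: int
    dbh_mean: float
    dbh_sd: float | None
    lcr_mean: float
    lcr_sd: float | None


@lru_cache(maxsize=1)
def packaged_species_stats() -> dict[str, SpeciesStats]:
    """Packaged per-species sample sizes and measurement summaries."""
    ref = resources.files("transleaf.data") / "species_stats.csv"
    with ref.open("r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
    out: dict[str, SpeciesStats] = {}
    for row in csv.DictReader(lines):
        name = row["species"].strip()
        out[name] = SpeciesStats(
            species=name,
            species_code=row["species_code"].strip(),
            n_attr=int(row["n_attr"]),
            n_cv=int(row["n_cv"]),
            dbh_mean=float(row["dbh_mean_cm"]),
            dbh_sd=float(row["dbh_sd_cm"]) if row["dbh_sd_cm"] else None,
            lcr_mean=float(row["lcr_mean"]),
            lcr_sd=float(row["lcr_sd"]) if row["lcr_sd"] else None,
        )
    return out


# ---------------------------------------------------------------------------
# tree-table reading / writing

DEFAULT_COLUMNS: dict[str, str] = {
    "tree_id": "tree_id",
    "species": "species",
    "dbh": "dbh_cm",
    "lcr": "lcr",
    "cc": "crown_class",
    "sg_obs": "sg_obs",
    "leaf_mass": "leaf_mass_kg",
    "mat": "mat_c",
    "map_mm": "map_mm",
    "study_id": "study_id",
}

_REQUIRED_FIELDS = ("species", "dbh", "lcr", "cc", "mat", "map_mm")
_NUMERIC_FIELDS = ("dbh", "lcr", "sg_obs", "leaf_mass", "mat", "map_mm")


@dataclass(frozen=True)
class RowIssue:
    row: int  # 1-based data-row number (header excluded)
    field: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}: [{self.field}] {self.message}"


@dataclass
class ReadResult:
    """Records plus row-indexed diagnostics for rejected rows."""

    records: list[TreeRecord]
    rejected: list[RowIssue]

    def __iter__(self) -> Iterator[TreeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_tree_table(
    source: Union[str, Path, TextIO],
    column_map: Mapping[str, str] | None = None,
    on_invalid: str = "drop",
) -> ReadResult:
    """Read a delimited tree table into validated :class:`TreeRecord` s.

    Parameters
    ----------
    source
        Path or open text stream of a header-bearing CSV.
    column_map
        Optional overrides of :data:`DEFAULT_COLUMNS` (field -> column).
    on_invalid
        ``"drop"`` rejects invalid rows and records diagnostics in
        :attr:`ReadResult.rejected`; ``"raise"`` raises :class:`RowError`.

    Raises
    ------
    SchemaError
        If a required column is absent from the header.
    RowError
        With ``on_invalid="raise"`` when any row fails to parse/validate.
    """
    if on_invalid not in ("drop", "raise"):
        raise ValueError("on_invalid must be 'drop' or 'raise'")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise SchemaError(f"column_map has unknown field(s): {sorted(unknown)}")
        cols.update(column_map)

    close = False
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source, "r", encoding="utf-8", newline="")
        close = True
    else:
        fh = source
    try:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [cols[f] for f in _REQUIRED_FIELDS if cols[f] not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records: list[TreeRecord] = []
        issues: list[RowIssue] = []
        for i, row in enumerate(reader, start=1):
            rec, row_issues = _parse_row(i, row, cols, header)
            if row_issues:
                issues.extend(row_issues)
            else:
                assert rec is not None
                records.append(rec)
    finally:
        if close:
            fh.close()

    if issues:
        if on_invalid == "raise":
            raise RowError(issues)
        for iss in issues:
            logger.warning("rejected %s", iss)
    return ReadResult(records=records, rejected=issues)


def _parse_row(
    rownum: int, row: Mapping[str, str], cols: Mapping[str, str], header: Sequence[str]
) -> tuple[TreeRecord | None, list[RowIssue]]:
    issues: list[RowIssue] = []
    raw: dict[str, str] = {}

    def get(fieldname: str) -> str | None:
        colname = cols[fieldname]
        if colname not in header:
            return None
        v = (row.get(colname) or "").strip()
        return v or None

    def num(fieldname: str, required: bool) -> float | None:
        tok = get(fieldname)
        if tok is None:
            if required:
                issues.append(RowIssue(rownum, fieldname, "missing value"))
            return None
        raw[fieldname] = tok
        try:
            return float(tok)
        except ValueError:
            issues.append(RowIssue(rownum, fieldname, f"unparseable numeric {tok!r}"))
            return None

    species = get("species")
    if species is None:
        issues.append(RowIssue(rownum, "species", "missing value"))
    dbh = num("dbh", required=True)
    lcr = num("lcr", required=True)
    mat = num("mat", required=True)
    map_mm = num("map_mm", required=True)
    sg_obs = num("sg_obs", required=False)
    leaf_mass = num("leaf_mass", required=False)

    cc: CrownClass | None = None
    cc_tok = get("cc")
    if cc_tok is None:
        issues.append(RowIssue(rownum, "cc", "missing value"))
    else:
        try:
            cc = parse_crown_class(cc_tok)
        except ValueError as e:
            issues.append(RowIssue(rownum, "cc", str(e)))

    if issues:
        return None, issues

    rec = TreeRecord(
        tree_id=get("tree_id") or f"row{rownum}",
        species=str(species),
        dbh=float(dbh),  # type: ignore[arg-type]
        lcr=float(lcr),  # type: ignore[arg-type]
        cc=cc,  # type: ignore[arg-type]
        mat=float(mat),  # type: ignore[arg-type]
        map_mm=float(map_mm),  # type: ignore[arg-type]
        sg_obs=sg_obs,
        leaf_mass=leaf_mass,
        study_id=get("study_id"),
        raw_text=raw,
    )
    for msg in rec.violations():
        fieldname = msg.split(" ", 1)[0]
        issues.append(RowIssue(rownum, fieldname, msg))
    if issues:
        return None, issues
    return rec, []


def write_tree_table(
    records: Iterable[TreeRecord],
    dest: Union[str, Path, TextIO],
    column_map: Mapping[str, str] | None = None,
    crown_class_as: str = "label",
) -> None:
    """Write records as CSV (full round-trip float precision via ``repr``)."""
    if crown_class_as not in ("label", "code"):
        raise ValueError("crown_class_as must be 'label' or 'code'")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    close = False
    if isinstance(dest, (str, Path)):
        fh: TextIO = open(dest, "w", encoding="utf-8", newline="")
        close = True
    else:
        fh = dest
    try:
        writer = csv.writer(fh)
        order = ["tree_id", "species", "dbh", "lcr", "cc", "sg_obs",
                 "leaf_mass", "mat", "map_mm", "study_id"]
        writer.writerow([cols[f] for f in order])

        def fmt(v) -> str:
            if v is None:
                return ""
            if isinstance(v, float):
                return repr(v)
            return str(v)

        for r in records:
            cc_out = str(CODE_OF_CROWN_CLASS[r.cc]) if crown_class_as == "code" else r.cc.value
            writer.writerow([
                fmt(r.tree_id), fmt(r.species), fmt(float(r.dbh)), fmt(float(r.lcr)),
                cc_out, fmt(r.sg_obs), fmt(r.leaf_mass), fmt(float(r.mat)),
                fmt(float(r.map_mm)), fmt(r.study_id),
            ])
    finally:
        if close:
            fh.close()


def attach_traits(
    trees: Sequence[TreeRecord], traits: TraitTable
) -> list[tuple[TreeRecord, SpeciesTraits]]:
    """Pair each tree with its species' published traits (pure join).

    Raises :class:`TraitLookupError` listing *all* missing species, so a
    user applying the model to new species knows exactly what to supply.
    """
    missing = sorted({t.species for t in trees if t.species not in traits})
    if missing:
        raise TraitLookupError(missing)
    return [(t, traits.lookup(t.species)) for t in trees]


# ---------------------------------------------------------------------------
# recording-precision (significant figures) filter

def count_sigfigs(token: str) -> int:
    """Count significant digits in a numeric text token.

    Leading zeros never count; every digit from the first nonzero digit to
    the last written digit counts (so ``"20"`` has 2, ``"0.1"`` has 1 and
    ``"0.010"`` has 2).  Exponents are ignored.
    """
    t = str(token).strip().lstrip("+-")
    for sep in ("e", "E"):
        t = t.split(sep)[0]
    digits = t.replace(".", "").lstrip("0")
    return len(digits)


def filter_min_sigfigs(
    trees: Sequence[TreeRecord], min_sigfigs: int
) -> tuple[list[TreeRecord], list[TreeRecord]]:
    """Split records into (kept, dropped) by recorded numeric precision.

    A record is kept iff every numeric field present carries at least
    ``min_sigfigs`` significant digits in its as-read text token.  Records
    constructed in memory (no ``raw_text``) cannot be assessed -- they are
    kept with a logged warning, since the rule is about *recording*
    precision, which only text preserves.
    """
    if min_sigfigs < 1:
        raise ValueError("min_sigfigs must be >= 1")
    kept: list[TreeRecord] = []
    dropped: list[TreeRecord] = []
    warned = False
    for rec in trees:
        if rec.raw_text is None:
            if not warned:
                logger.warning(
                    "filter_min_sigfigs: record(s) without raw text tokens; "
                    "precision filter is a no-op for them"
                )
                warned = True
            kept.append(rec)
            continue
        ok = all(
            count_sigfigs(rec.raw_text[f]) >= min_sigfigs
            for f in _NUMERIC_FIELDS
            if f in rec.raw_text
        )
        (kept if ok else dropped).append(rec)
    return kept, dropped
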