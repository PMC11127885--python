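"""Species-level functional trait database and the four-three species-code scheme.

A species code is a compact lowercase token built from the genus and specific
epithet (``agrogit`` for *Agrostemma githago*).  Codes key every table in the
package: the trait database, raw count matrices, flowering-period tables and
composite-taxon specs.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MANDATORY_TRAITS",
    "NUMERIC_TRAITS",
    "ALL_TRAITS",
    "LIFE_HISTORIES",
    "TraitRecord",
    "TraitDatabase",
    "UnknownCodeWarning",
    "make_species_code",
    "validate_code",
    "lookup",
    "read_trait_csv",
    "write_trait_csv",
]

#: Numeric traits that every database record must carry.
MANDATORY_TRAITS = ("SLA", "ARNODE", "LOGCANH", "LOGCAND")

#: Numeric traits a record may carry (VEGPROP and FLOWPER may be missing).
NUMERIC_TRAITS = ("SLA", "ARNODE", "LOGCANH", "LOGCAND", "VEGPROP", "FLOWPER")

#: All trait columns exposed by :func:`lookup`, in canonical order.
ALL_TRAITS = ("SLA", "ARNODE", "LOGCANH", "LOGCAND", "VEGPROP", "FLOWPER", "LIFEHIST")

LIFE_HISTORIES = ("annual", "perennial", "other")

_CODE_RE = re.compile(r"^[a-z_]+$")
_ALPHA_RE = re.compile(r"^[A-Za-z]+$")


class UnknownCodeWarning(UserWarning):
    """Raised when requested species codes are absent from the database."""


def validate_code(code: str) -> str:
    """Normalise ``code`` to lowercase and check the allowed alphabet.

    Raises :class:`ValueError` for empty codes or codes containing anything
    other than letters and underscores.
    """
    if not isinstance(code, str) or not code:
        raise ValueError(f"species code must be a non-empty string, got {code!r}")
    norm = code.strip().lower()
    if not _CODE_RE.match(norm):
        raise ValueError(
            f"invalid species code {code!r}: only letters and underscore allowed"
        )
    return norm


def make_species_code(
    genus: str, epithet: str, existing: Iterable[str] = ()
) -> str:
    """Build a four-three species code from a binomial.

    The default form is the first four letters of the genus plus the first
    three of the epithet.  Genera shorter than four letters keep the full
    genus followed by an underscore (``poa_ann`` for *Poa annua*).  If the
    candidate collides with a code in ``existing``, the epithet part is
    extended one letter at a time, then the genus part, until a unique code
    is found.

    Parameters
    ----------
    genus, epithet:
        Alphabetic name parts; case is ignored.
    existing:
        Codes already taken (compared case-insensitively).

    Raises
    ------
    ValueError
        If either name part is empty/non-alphabetic, or every candidate
        derived from the two names is already taken.
    """
    for label, part in (("genus", genus), ("epithet", epithet)):
        if not isinstance(part, str) or not _ALPHA_RE.match(part or ""):
            raise ValueError(f"{label} must be non-empty and alphabetic, got {part!r}")
    g = genus.lower()
    e = epithet.lower()
    taken = {validate_code(c) for c in existing}

    def candidate(gn: int, en: int) -> str:
        gpart = g[:gn]
        sep = "_" if len(g) < 4 else ""
        return gpart + sep + e[:en]

    g0 = min(len(g), 4)
    # Epithet extension first, then genus extension (with the 3-letter epithet
    # re-tried at each genus length before longer epithet cuts).
    for en in range(3, len(e) + 1):
        cand = candidate(g0, en)
        if cand not in taken:
            return cand
    for gn in range(g0 + 1, len(g) + 1):
        for en in range(3, len(e) + 1):
            cand = candidate(gn, en)
            if cand not in taken:
                return cand
    raise ValueError(
        f"cannot derive a unique species code for {genus!r} {epithet!r}: "
        "all candidates collide with existing codes"
    )


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass
class TraitRecord:
    """One species' functional trait values.

    ``VEGPROP`` distinguishes 0 (does not propagate vegetatively) from
    missing (``NaN``/``None``): a missing value is excluded from any
    average, a 0 contributes to the denominator.
    """

    code: str
    genus: str = ""
    epithet: str = ""
    SLA: float = math.nan
    ARNODE: float = math.nan
    LOGCANH: float = math.nan
    LOGCAND: float = math.nan
    VEGPROP: float | None = None
    LIFEHIST: str | None = None
    FLOWPER: float | None = None

    def __post_init__(self) -> None:
        self.code = validate_code(self.code)
        if self.VEGPROP is not None and math.isnan(self.VEGPROP):
            self.VEGPROP = None
        if self.FLOWPER is not None and math.isnan(self.FLOWPER):
            self.FLOWPER = None
        self.validate()

    def validate(self) -> None:
        for name in ("SLA", "ARNODE"):
            v = getattr(self, name)
            if not _is_missing(v) and v <= 0:
                raise ValueError(f"{self.code}: {name} must be > 0, got {v}")
        # species records are 0/1; composite records may carry an averaged
        # fraction, so the invariant is the closed unit interval
        if self.VEGPROP is not None and not (0.0 <= self.VEGPROP <= 1.0):
            raise ValueError(
                f"{self.code}: VEGPROP must lie in [0, 1] or be missing, "
                f"got {self.VEGPROP}"
            )
        if self.FLOWPER is not None and not (1 <= self.FLOWPER <= 12):
            raise ValueError(
                f"{self.code}: FLOWPER must lie in [1, 12] months, got {self.FLOWPER}"
            )

    def get(self, trait: str):
        """Return a trait value with missing normalised to ``NaN``."""
        v = getattr(self, trait)
        if _is_missing(v):
            return math.nan
        return v

    def replace(self, **changes) -> "TraitRecord":
        return replace(self, **changes)


class TraitDatabase:
    """Collection of :class:`TraitRecord` keyed by species code.

    Every record must carry the four always-provided numeric traits
    (SLA, ARNODE, LOGCANH, LOGCAND); duplicate codes are rejected.
    """

    def __init__(self, records: Iterable[TraitRecord] = (), version: str = "unversioned"):
        self.version = str(version)
        self._records: dict[str, TraitRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: TraitRecord) -> None:
        if record.code in self._records:
            raise ValueError(f"duplicate species code {record.code!r}")
        for trait in MANDATORY_TRAITS:
            if _is_missing(getattr(record, trait)):
                raise ValueError(
                    f"record {record.code!r} is missing mandatory trait {trait}"
                )
        self._records[record.code] = record

    @property
    def codes(self) -> list[str]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, code: str) -> bool:
        return validate_code(code) in self._records

    def __getitem__(self, code: str) -> TraitRecord:
        return self._records[validate_code(code)]

    def __iter__(self):
        return iter(self._records.values())

    def merged_with(self, extra: Iterable[TraitRecord]) -> "TraitDatabase":
        """Return a copy with additional records (e.g. composite taxa)."""
        out = TraitDatabase(self._records.values(), version=self.version)
        for rec in extra:
            out.add(rec)
        return out

    def with_vegprop_overrides(
        self, overrides: Mapping[str, float | None]
    ) -> "TraitDatabase":
        """Return a copy with per-species VEGPROP replacements.

        An override of ``None``/``NaN`` blanks the trait so the species is
        excluded from VEGPROP averaging; 0 or 1 replaces the stored value.
        """
        out = TraitDatabase(version=self.version)
        todo = {validate_code(c): v for c, v in overrides.items()}
        missing = [c for c in todo if c not in self._records]
        if missing:
            raise KeyError(
                f"VEGPROP overrides name unknown species codes: {sorted(missing)}"
            )
        for code, rec in self._records.items():
            if code in todo:
                v = todo[code]
                if v is not None and isinstance(v, float) and math.isnan(v):
                    v = None
                rec = rec.replace(VEGPROP=v)
            out.add(rec)
        return out


def lookup(
    db: TraitDatabase,
    codes: Sequence[str],
    traits: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Extract a trait table for the requested species codes.

    Rows follow the input code order; unknown codes are excluded and listed
    in ``result.attrs["unknown_codes"]`` (with a :class:`UnknownCodeWarning`).

    Raises :class:`KeyError` if *no* requested code is present, and
    :class:`ValueError` for an empty request or unknown trait names.
    """
    if len(codes) == 0:
        raise ValueError("lookup requires at least one species code")
    if traits is None:
        traits = list(ALL_TRAITS)
    else:
        traits = list(traits)
        bad = [t for t in traits if t not in ALL_TRAITS]
        if bad:
            raise ValueError(f"unknown trait name(s): {bad}; choose from {ALL_TRAITS}")

    norm = [validate_code(c) for c in codes]
    known = [c for c in norm if c in db]
    unknown = [c for c in norm if c not in db]
    if not known:
        raise KeyError(f"none of the requested codes are in the database: {norm}")
    if unknown:
        warnings.warn(
            f"codes not in trait database (excluded): {unknown}", UnknownCodeWarning,
            stacklevel=2,
        )
    rows = {c: [db[c].get(t) if t != "LIFEHIST" else db[c].LIFEHIST for t in traits]
            for c in known}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=traits)
    table.index.name = "code"
    table.attrs["unknown_codes"] = unknown
    return table


_CSV_COLUMNS = ["code", "genus", "epithet", *MANDATORY_TRAITS, "VEGPROP", "LIFEHIST"]
_VERSION_PREFIX = "# trait_db_version="


def write_trait_csv(db: TraitDatabase, path: str | Path) -> None:
    """Write the database to CSV with a version line as the first row."""
    frame = pd.DataFrame(
        [
            {
                "code": r.code,
                "genus": r.genus,
                "epithet": r.epithet,
                **{t: r.get(t) for t in MANDATORY_TRAITS},
                "VEGPROP": ""
                if r.VEGPROP is None
                else (int(r.VEGPROP) if float(r.VEGPROP).is_integer() else r.VEGPROP),
                "LIFEHIST": r.LIFEHIST or "",
            }
            for r in db
        ],
        columns=_CSV_COLUMNS,
    )
    buf = io.StringIO()
    buf.write(f"{_VERSION_PREFIX}{db.version}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_trait_csv(path: str | Path, version: str | None = None) -> TraitDatabase:
    """Read a trait database CSV (schema ``code,genus,epithet,SLA,...,LIFEHIST``).

    A leading ``# trait_db_version=`` line sets the database version; pass
    ``version`` to override.  Duplicate codes and missing mandatory columns
    raise :class:`ValueError` naming the offender.  Extra columns (e.g. flora
    reference numbers in published datasets) are ignored.
    """
    text = Path(path).read_text()
    file_version = "unversioned"
    if text.startswith("#"):
        first, _, rest = text.partition("\n")
        if first.startswith(_VERSION_PREFIX):
            file_version = first[len(_VERSION_PREFIX):].strip()
        text = rest
    frame = pd.read_csv(io.StringIO(text), dtype={"code": str})
    missing_cols = [c for c in ("code", *MANDATORY_TRAITS) if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"trait CSV {path} is missing required column(s): {missing_cols}")
    codes = [validate_code(c) for c in frame["code"]]
    dupes = sorted({c for c in codes if codes.count(c) > 1})
    if dupes:
        raise ValueError(f"trait CSV {path} contains duplicate code(s): {dupes}")

    db = TraitDatabase(version=version or file_version)
    for _, row in frame.iterrows():
        lh = row.get("LIFEHIST")
        db.add(
            TraitRecord(
                code=row["code"],
                genus=str(row.get("genus", "") or ""),
                epithet=str(row.get("epithet", "") or ""),
                SLA=float(row["SLA"]),
                ARNODE=float(row["ARNODE"]),
                LOGCANH=float(row["LOGCANH"]),
                LOGCAND=float(row["LOGCAND"]),
                VEGPROP=None if pd.isna(row.get("VEGPROP")) else float(row["VEGPROP"]),
                LIFEHIST=None if pd.isna(lh) or lh == "" else str(lh),
            )
        )
    return db
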