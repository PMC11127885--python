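"""Turn a raw taxa-by-samples count matrix into per-sample averaged trait profiles.

The pipeline stage implemented here converts raw seed counts to
presence/absence, merges composite-taxon trait records and a per-region
flowering-period table into the trait database, applies optional per-species
VEGPROP overrides, and averages each model-relevant trait over the taxa
present in each sample.  Each trait mean divides by the number of present
taxa with a *non-missing* value for that trait, so a missing VEGPROP shrinks
the denominator rather than counting as zero.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traitdb import (
    MANDATORY_TRAITS,
    NUMERIC_TRAITS,
    TraitDatabase,
    TraitRecord,
    UnknownCodeWarning,
    validate_code,
)

__all__ = [
    "MODEL_OUTPUT_TRAITS",
    "MODEL_PREDICTORS",
    "DEFAULT_MIN_SEEDS",
    "SampleCounts",
    "CompositeSpec",
    "SampleTraitProfile",
    "CleanReport",
    "to_presence_absence",
    "average_composite",
    "clean_samples",
    "organise",
    "profiles_to_frame",
    "read_counts_csv",
    "write_counts_csv",
    "read_flowper_csv",
    "read_composites_csv",
    "read_profiles_csv",
]

#: Canonical output column order (fixed across the package).
TRAIT_ORDER = ("SLA", "ARNODE", "LOGCANH", "LOGCAND", "VEGPROP", "FLOWPER")

#: Trait columns carried in the organised output, per model.
MODEL_OUTPUT_TRAITS = {
    1: ("SLA", "ARNODE", "LOGCANH", "LOGCAND", "FLOWPER"),
    2: ("SLA", "ARNODE", "LOGCANH", "LOGCAND"),
    3: ("SLA", "ARNODE", "LOGCANH", "LOGCAND", "VEGPROP", "FLOWPER"),
}

#: Predictors actually entering the discriminant, per model.
MODEL_PREDICTORS = {
    1: ("SLA", "ARNODE", "LOGCANH", "LOGCAND", "FLOWPER"),
    2: ("SLA", "ARNODE", "LOGCANH", "LOGCAND"),
    3: ("VEGPROP", "FLOWPER"),
}

#: Recommended minimum weed seeds per sample.
DEFAULT_MIN_SEEDS = 10

#: Samples with fewer species than this are flagged (never dropped).
LOW_DIVERSITY_THRESHOLD = 3


class SampleCounts:
    """Taxa-by-samples seed-count matrix.

    Wraps a :class:`pandas.DataFrame` whose index holds species codes and
    whose columns are sample identifiers.  Counts are non-negative; blanks
    in the input CSV are read as zero.
    """

    def __init__(self, matrix: pd.DataFrame):
        if matrix.shape[0] < 1 or matrix.shape[1] < 1:
            raise ValueError("count matrix needs at least one taxon and one sample")
        matrix = matrix.copy()
        matrix.index = [validate_code(c) for c in matrix.index]
        if matrix.index.has_duplicates:
            dupes = sorted(matrix.index[matrix.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon code(s) in count matrix: {dupes}")
        values = matrix.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("count matrix contains non-numeric or NaN cells")
        if (values < 0).any():
            raise ValueError("count matrix contains negative counts")
        matrix = matrix.astype(float)
        matrix.index.name = "species.codes"
        self.matrix = matrix

    @property
    def taxa(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.matrix.columns]

    def sample_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def taxa_per_sample(self) -> pd.Series:
        return (self.matrix > 0).sum(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleCounts) and self.matrix.equals(other.matrix)


@dataclass
class CompositeSpec:
    """A composite taxon averaged from a small set of candidate species.

    ``overrides`` maps trait name to a replacement value applied after
    averaging; an override of ``None``/``NaN`` blanks the trait (used to
    exclude uncertain composites from VEGPROP averaging).
    """

    composite_code: str
    members: Sequence[str]
    overrides: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.composite_code = validate_code(self.composite_code)
        self.members = [validate_code(m) for m in self.members]
        if len(self.members) < 2:
            raise ValueError(
                f"composite {self.composite_code!r} needs at least 2 member species"
            )
        bad = [t for t in self.overrides if t not in NUMERIC_TRAITS]
        if bad:
            raise ValueError(
                f"composite {self.composite_code!r}: unknown override trait(s) {bad}"
            )


def to_presence_absence(counts: SampleCounts) -> SampleCounts:
    """Convert counts to 0/1 presence/absence.  Idempotent."""
    return SampleCounts((counts.matrix > 0).astype(float))


def average_composite(db: TraitDatabase, spec: CompositeSpec) -> TraitRecord:
    """Average member species' trait values into a composite trait record.

    Per trait, the arithmetic mean over members with non-missing values;
    traits missing in every member stay missing.  Overrides are applied
    last.  Averaging more than four species triggers a caution warning.
    """
    missing = [m for m in spec.members if m not in db]
    if missing:
        raise KeyError(
            f"composite {spec.composite_code!r}: member(s) not in trait database: {missing}"
        )
    if spec.composite_code in db:
        raise ValueError(
            f"composite code {spec.composite_code!r} collides with an existing species code"
        )
    if len(spec.members) > 4:
        warnings.warn(
            f"composite {spec.composite_code!r} averages {len(spec.members)} species; "
            "averaging more than three or four species is discouraged",
            UserWarning,
            stacklevel=2,
        )
    values: dict[str, float | None] = {}
    for trait in NUMERIC_TRAITS:
        contrib = [db[m].get(trait) for m in spec.members]
        contrib = [v for v in contrib if not math.isnan(v)]
        values[trait] = float(np.mean(contrib)) if contrib else math.nan
    for trait, override in spec.overrides.items():
        if override is None or (isinstance(override, float) and math.isnan(override)):
            values[trait] = math.nan
        else:
            values[trait] = float(override)
    vp = values["VEGPROP"]
    fp = values["FLOWPER"]
    return TraitRecord(
        code=spec.composite_code,
        genus="",
        epithet="",
        SLA=values["SLA"],
        ARNODE=values["ARNODE"],
        LOGCANH=values["LOGCANH"],
        LOGCAND=values["LOGCAND"],
        VEGPROP=None if math.isnan(vp) else vp,
        FLOWPER=None if math.isnan(fp) else fp,
    )


def composite_divergence(db: TraitDatabase, spec: CompositeSpec) -> pd.DataFrame:
    """Advisory per-trait min/max/range over a composite's members.

    Never blocks — how divergent is too divergent is an analyst judgement.
    """
    rows = {}
    for trait in NUMERIC_TRAITS:
        vals = [db[m].get(trait) for m in spec.members if m in db]
        vals = [v for v in vals if not math.isnan(v)]
        if vals:
            rows[trait] = {"min": min(vals), "max": max(vals),
                           "range": max(vals) - min(vals)}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class CleanReport:
    """Outcome of :func:`clean_samples`."""

    dropped: list[str]
    low_diversity: list[str]
    min_seeds: int


def clean_samples(
    counts: SampleCounts, min_seeds: int = DEFAULT_MIN_SEEDS
) -> tuple[SampleCounts, CleanReport]:
    """Drop samples with fewer than ``min_seeds`` total seeds (inclusive keep).

    Retained samples with fewer than three taxa are flagged in the report
    but kept, so runs with and without low-diversity samples are both
    possible.  Raises :class:`ValueError` if every sample would be dropped.
    """
    totals = counts.sample_totals()
    keep = totals >= min_seeds
    dropped = [str(s) for s in totals.index[~keep]]
    if not keep.any():
        raise ValueError(
            f"all {len(dropped)} samples fall below the minimum of {min_seeds} seeds"
        )
    kept = SampleCounts(counts.matrix.loc[:, keep])
    ntaxa = kept.taxa_per_sample()
    low = [str(s) for s in ntaxa.index[ntaxa < LOW_DIVERSITY_THRESHOLD]]
    return kept, CleanReport(dropped=dropped, low_diversity=low, min_seeds=min_seeds)


@dataclass
class SampleTraitProfile:
    """Per-sample averaged trait vector plus bookkeeping."""

    sample_id: str
    traits: dict[str, float]
    n_species: int
    n_seeds: float
    low_diversity_flag: bool

    def get(self, trait: str) -> float:
        return self.traits.get(trait, math.nan)


def organise(
    counts: SampleCounts,
    db: TraitDatabase,
    model: int,
    flowper: Mapping[str, float] | None = None,
    composites: Sequence[CompositeSpec] | None = None,
    vegprop_overrides: Mapping[str, float | None] | None = None,
) -> list[SampleTraitProfile]:
    """Organise raw counts into per-sample averaged trait profiles.

    Composite trait records are merged into a working copy of the database,
    VEGPROP overrides applied, presence/absence taken, and each
    model-relevant trait averaged over the present taxa with non-missing
    values.  Taxa absent from the database are excluded with a warning.

    Parameters
    ----------
    counts:
        Raw (pre presence/absence) seed counts; totals feed ``n_seeds``.
    model:
        1, 2 or 3; selects the output trait columns.  A flowering-period
        table covering every known taxon in ``counts`` is required for
        models 1 and 3.
    flowper:
        Mapping species code -> flowering period in months.
    vegprop_overrides:
        Mapping species code -> 0/1/None applied after composites are merged.
    """
    if model not in MODEL_OUTPUT_TRAITS:
        raise ValueError(f"model must be 1, 2 or 3, got {model!r}")
    work = db
    if composites:
        seen: set[str] = set()
        for spec in composites:
            if spec.composite_code in seen:
                raise ValueError(f"duplicate composite code {spec.composite_code!r}")
            seen.add(spec.composite_code)
        work = db.merged_with(average_composite(db, s) for s in composites)
    if vegprop_overrides:
        work = work.with_vegprop_overrides(vegprop_overrides)

    known = [t for t in counts.taxa if t in work]
    unknown = [t for t in counts.taxa if t not in work]
    if not known:
        raise ValueError(
            "no taxon in the count matrix is present in the trait database"
        )
    if unknown:
        warnings.warn(
            f"taxa not in trait database (excluded from profiles): {unknown}",
            UnknownCodeWarning,
            stacklevel=2,
        )

    out_traits = MODEL_OUTPUT_TRAITS[model]
    needs_flowper = "FLOWPER" in out_traits
    flowtable: dict[str, float] = {}
    if needs_flowper:
        if flowper is None:
            raise ValueError(f"model {model} requires a FLOWPER table")
        flowtable = {validate_code(c): float(v) for c, v in flowper.items()}
        lacking = [t for t in known if t not in flowtable]
        if lacking:
            raise ValueError(
                f"FLOWPER table is missing taxa present in the counts: {lacking}"
            )

    def trait_value(code: str, trait: str) -> float:
        if trait == "FLOWPER" and code in flowtable:
            return flowtable[code]
        return work[code].get(trait)

    presence = to_presence_absence(counts).matrix.loc[known]
    totals = counts.sample_totals()
    profiles: list[SampleTraitProfile] = []
    for sample in counts.matrix.columns:
        present = [t for t in known if presence.at[t, sample] > 0]
        means: dict[str, float] = {}
        for trait in out_traits:
            vals = [trait_value(t, trait) for t in present]
            vals = [v for v in vals if not math.isnan(v)]
            means[trait] = float(np.mean(vals)) if vals else math.nan
        profiles.append(
            SampleTraitProfile(
                sample_id=str(sample),
                traits=means,
                n_species=len(present),
                n_seeds=float(totals[sample]),
                low_diversity_flag=len(present) < LOW_DIVERSITY_THRESHOLD,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[SampleTraitProfile]) -> pd.DataFrame:
    """Tabulate profiles with trait columns in canonical order."""
    traits = [t for t in TRAIT_ORDER if any(t in p.traits for p in profiles)]
    frame = pd.DataFrame(
        [
            {
                "sample": p.sample_id,
                **{t: p.traits.get(t, math.nan) for t in traits},
                "n_species": p.n_species,
                "n_seeds": p.n_seeds,
                "low_diversity": p.low_diversity_flag,
            }
            for p in profiles
        ]
    ).set_index("sample")
    return frame


# ---------------------------------------------------------------------------
# CSV plumbing


def read_counts_csv(path: str | Path) -> SampleCounts:
    """Read a count matrix CSV: first column ``species.codes``, blanks = 0."""
    frame = pd.read_csv(path, index_col=0)
    frame = frame.fillna(0.0)
    return SampleCounts(frame)


def write_counts_csv(counts: SampleCounts, path: str | Path) -> None:
    matrix = counts.matrix.copy()
    # Integral counts render without a trailing ".0".
    if (matrix.to_numpy() == matrix.to_numpy().round()).all():
        matrix = matrix.astype(int)
    matrix.to_csv(path)


def read_flowper_csv(path: str | Path) -> dict[str, float]:
    """Read a two-column flowering-period CSV (``species.codes,FLOWPER``)."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"FLOWPER CSV {path} needs code and FLOWPER columns")
    cols = {c.lower(): c for c in frame.columns}
    code_col = cols.get("species.codes") or cols.get("code") or frame.columns[0]
    flow_col = cols.get("flowper") or frame.columns[1]
    out: dict[str, float] = {}
    for _, row in frame.iterrows():
        code = validate_code(str(row[code_col]))
        if code in out:
            raise ValueError(f"FLOWPER CSV {path} has duplicate code {code!r}")
        fp = float(row[flow_col])
        if not (1 <= fp <= 12):
            raise ValueError(f"FLOWPER for {code!r} out of [1, 12]: {fp}")
        out[code] = fp
    return out


_NA_STRINGS = {"na", "nan", ""}


def read_composites_csv(path: str | Path) -> list[CompositeSpec]:
    """Read composite specs: ``composite_code,member1..member4`` plus optional
    ``override_<TRAIT>`` columns (cell ``NA`` blanks the trait; empty = no
    override)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "composite_code" not in frame.columns:
        raise ValueError(f"composite CSV {path} lacks a composite_code column")
    member_cols = [c for c in frame.columns if c.startswith("member")]
    override_cols = [c for c in frame.columns if c.startswith("override_")]
    specs = []
    for _, row in frame.iterrows():
        members = [row[c].strip() for c in member_cols if row[c].strip()]
        overrides: dict[str, float | None] = {}
        for col in override_cols:
            cell = row[col].strip()
            if not cell:
                continue
            trait = col[len("override_"):]
            overrides[trait] = None if cell.lower() in _NA_STRINGS else float(cell)
        specs.append(CompositeSpec(row["composite_code"], members, overrides))
    codes = [s.composite_code for s in specs]
    dupes = sorted({c for c in codes if codes.count(c) > 1})
    if dupes:
        raise ValueError(f"composite CSV {path} has duplicate composite code(s): {dupes}")
    return specs


def read_profiles_csv(path: str | Path) -> list[SampleTraitProfile]:
    """Read back a profiles CSV written from :func:`profiles_to_frame`."""
    frame = pd.read_csv(path, index_col=0)
    traits = [t for t in TRAIT_ORDER if t in frame.columns]
    return [
        SampleTraitProfile(
            sample_id=str(sample),
            traits={t: float(row[t]) for t in traits},
            n_species=int(row["n_species"]) if "n_species" in frame.columns else 0,
            n_seeds=float(row["n_seeds"]) if "n_seeds" in frame.columns else math.nan,
            low_diversity_flag=bool(row["low_diversity"])
            if "low_diversity" in frame.columns
            else False,
        )
        for sample, row in frame.iterrows()
    ]
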