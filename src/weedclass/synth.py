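"""Synthetic fixtures with known ground truth.

Generates trait databases, modern reference datasets and raw count matrices
that share the statistical structure the classifier assumes, so every stage
of the pipeline runs and is testable without any external download.

Species inclusion in a sample is tilted by an exponential weighting of the
species' standardised trait values along the configured group-separation
direction: samples assigned to group 1 preferentially contain species whose
traits sit on group 1's side, so trait-averaged profiles are separable by
construction.  All randomness flows through one :class:`numpy.random.Generator`
seeded from the config.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .organise import MODEL_PREDICTORS, SampleCounts
from .traitdb import LIFE_HISTORIES, TraitDatabase, TraitRecord, make_species_code

__all__ = ["SynthConfig", "make_trait_db", "make_model_data", "make_counts",
           "flowper_table", "group_assignment"]

#: Baseline (mean, within-group SD) per trait used by both the species
#: generator and the field-survey generator.
DEFAULT_TRAIT_PARAMS: dict[str, tuple[float, float]] = {
    "SLA": (25.0, 6.0),
    "ARNODE": (12.0, 4.0),
    "LOGCANH": (1.5, 0.30),
    "LOGCAND": (1.2, 0.30),
    "VEGPROP": (0.45, 0.12),
    "FLOWPER": (4.5, 1.5),  # species FLOWPER is uniform on 1..8 months (mean 4.5)
}

#: Default group-1-minus-group-2 mean separation per trait (group means sit
#: at baseline +/- shift/2).
DEFAULT_GROUP_SHIFT: dict[str, float] = {
    "SLA": 7.0,
    "ARNODE": 4.5,
    "LOGCANH": 0.35,
    "LOGCAND": 0.32,
    "VEGPROP": 0.28,
    "FLOWPER": 1.6,
}


@dataclass
class SynthConfig:
    """Knobs for the synthetic generators; defaults are desk-scale."""

    seed: int = 0
    n_species: int = 60
    n_fields_per_group: int = 20
    n_samples: int = 50
    group_mean_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SHIFT)
    )
    trait_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_PARAMS)
    )
    within_group_cov: np.ndarray | None = None  # over a model's predictors, canonical order
    species_per_sample: tuple[int, int] = (6, 12)
    seeds_per_species: float = 4.0  # mean of the 1 + Poisson count distribution
    missing_vegprop_rate: float = 0.10
    tilt_strength: float = 1.8

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be at least 2")
        if not (0.0 <= self.missing_vegprop_rate <= 1.0):
            raise ValueError("missing_vegprop_rate must lie in [0, 1]")
        lo, hi = self.species_per_sample
        if not (1 <= lo <= hi):
            raise ValueError("species_per_sample must be a (min, max) with 1 <= min <= max")
        if self.within_group_cov is not None:
            cov = np.asarray(self.within_group_cov, dtype=float)
            if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
                raise ValueError("within_group_cov must be square")
            if not np.allclose(cov, cov.T) or np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("within_group_cov must be symmetric positive-definite")
            self.within_group_cov = cov

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


def _fake_binomial(rng: np.random.Generator) -> tuple[str, str]:
    letters = string.ascii_lowercase
    glen = int(rng.integers(3, 9))
    elen = int(rng.integers(3, 9))
    genus = "".join(letters[i] for i in rng.integers(0, 26, glen)).capitalize()
    epithet = "".join(letters[i] for i in rng.integers(0, 26, elen))
    return genus, epithet


def make_trait_db(config: SynthConfig) -> TraitDatabase:
    """Generate a synthetic trait database with codes from fake binomials."""
    rng = config.rng(salt=1)
    existing: set[str] = set()
    records = []
    params = config.trait_params
    for _ in range(config.n_species):
        genus, epithet = _fake_binomial(rng)
        code = make_species_code(genus, epithet, existing)
        existing.add(code)
        sla = max(float(rng.normal(*params["SLA"])), 0.5)
        arnode = max(float(rng.normal(*params["ARNODE"])), 0.1)
        vp_base, _ = params["VEGPROP"]
        if rng.random() < config.missing_vegprop_rate:
            vegprop = None
        else:
            vegprop = float(rng.random() < vp_base)
        records.append(
            TraitRecord(
                code=code,
                genus=genus,
                epithet=epithet,
                SLA=sla,
                ARNODE=arnode,
                LOGCANH=float(rng.normal(*params["LOGCANH"])),
                LOGCAND=float(rng.normal(*params["LOGCAND"])),
                VEGPROP=vegprop,
                LIFEHIST=LIFE_HISTORIES[int(rng.integers(0, 3))],
                FLOWPER=float(rng.integers(1, 9)),
            )
        )
    return TraitDatabase(records, version=f"synthetic-seed{config.seed}")


def flowper_table(db: TraitDatabase) -> dict[str, float]:
    """Flowering-period table (code -> months) read off the database records."""
    return {r.code: float(r.FLOWPER) for r in db if r.FLOWPER is not None}


def make_model_data(config: SynthConfig, model_id: int):
    """Generate a modern reference dataset for the given model.

    Per-field predictor vectors are drawn from two Gaussians sharing the
    within-group covariance, with means at baseline +/- shift/2.  Models 2
    and 3 get two location labels per group.
    """
    from .lda import ModelDataset  # local import to avoid a cycle

    predictors = MODEL_PREDICTORS[model_id]
    p = len(predictors)
    rng = config.rng(salt=2 + model_id)
    base = np.array([config.trait_params[t][0] for t in predictors])
    shift = np.array([config.group_mean_shift.get(t, 0.0) for t in predictors])
    if config.within_group_cov is not None:
        cov = config.within_group_cov
        if cov.shape[0] != p:
            raise ValueError(
                f"within_group_cov is {cov.shape[0]}x{cov.shape[0]} but model "
                f"{model_id} has {p} predictors"
            )
    else:
        cov = np.diag([config.trait_params[t][1] ** 2 for t in predictors])
    n = config.n_fields_per_group
    n_locs = 2 if model_id in (2, 3) else 1
    rows = []
    for group, sign in ((1, +0.5), (2, -0.5)):
        X = rng.multivariate_normal(base + sign * shift, cov, size=n)
        for i in range(n):
            rows.append(
                {
                    "group": group,
                    "location": f"g{group}_loc{(i % n_locs) + 1}",
                    **{t: X[i, j] for j, t in enumerate(predictors)},
                }
            )
    return ModelDataset(model_id=model_id, frame=pd.DataFrame(rows))


def group_assignment(config: SynthConfig, group: int | Sequence[int] = 1) -> list[int]:
    """Expand a scalar group label to one label per sample."""
    if isinstance(group, int):
        return [group] * config.n_samples
    groups = list(group)
    if len(groups) != config.n_samples:
        raise ValueError("group assignment length must equal n_samples")
    return groups


def _species_scores(config: SynthConfig, db: TraitDatabase) -> np.ndarray:
    """Standardised projection of each species onto the group-shift direction."""
    traits = list(DEFAULT_TRAIT_PARAMS)
    shift = np.array([config.group_mean_shift.get(t, 0.0) for t in traits])
    sd = np.array([config.trait_params[t][1] for t in traits])
    u = shift / sd  # direction in standardised space
    norm = np.linalg.norm(u)
    if norm == 0:
        return np.zeros(len(db))
    u = u / norm
    scores = []
    for rec in db:
        z = 0.0
        for j, t in enumerate(traits):
            v = rec.get(t)
            if not math.isnan(v):
                z += u[j] * (v - config.trait_params[t][0]) / sd[j]
        scores.append(z)
    return np.asarray(scores)


def make_counts(
    config: SynthConfig,
    db: TraitDatabase,
    group_assignment: Sequence[int],
) -> SampleCounts:
    """Generate a raw count matrix whose samples lean toward their group.

    For a sample assigned to group ``g``, species are drawn without
    replacement with probabilities proportional to
    ``exp(sign(g) * tilt_strength * score)`` where ``score`` is the species'
    standardised position along the configured group-separation direction.
    Counts per present species are ``1 + Poisson(seeds_per_species - 1)``.
    Group 0 means untilted (null) sampling.
    """
    if len(db) == 0:
        raise ValueError("empty trait database")
    rng = config.rng(salt=9)
    codes = db.codes
    scores = _species_scores(config, db)
    lo, hi = config.species_per_sample
    lo = min(lo, len(codes))
    hi = min(hi, len(codes))
    lam = max(config.seeds_per_species - 1.0, 0.0)
    matrix = pd.DataFrame(
        0.0, index=codes, columns=[f"S{i + 1:03d}" for i in range(len(group_assignment))]
    )
    for j, group in enumerate(group_assignment):
        sign = {1: +1.0, 2: -1.0, 0: 0.0}.get(int(group))
        if sign is None:
            raise ValueError(f"group assignment must be 0, 1 or 2, got {group!r}")
        logits = sign * config.tilt_strength * scores
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(codes), size=k, replace=False, p=probs)
        for idx in chosen:
            matrix.iloc[idx, j] = 1.0 + float(rng.poisson(lam))
    return SampleCounts(matrix)
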