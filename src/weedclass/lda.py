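"""Two-group linear discriminant analysis, from first principles.

Fits Fisher's discriminant on a modern reference dataset (two farming
regimes) and classifies archaeobotanical sample profiles along the single
discriminant axis (LD1).

Conventions (documented because the axis scale and sign are arbitrary):

* pooled within-group covariance ``S = [(n1-1)S1 + (n2-1)S2] / (n1+n2-2)``;
* direction ``w = S^{-1}(m1 - m2)``, rescaled so the pooled within-group
  variance of LD1 equals 1;
* the constant maps the prior-weighted grand mean to LD1 = 0;
* the sign is flipped if needed so group 1 scores positive;
* standardised coefficients are unstandardised ones times the pooled
  within-group SD of each predictor, and standardised scores are computed
  on pooled-SD-scaled, grand-mean-centred predictors (hence classes from
  the two routes agree exactly).

Posteriors follow the two-group Gaussian rule with shared covariance, which
collapses to one dimension on LD1:
``log(p1/p2) = log(pi1/pi2) + LD1*(c1 - c2) - (c1^2 - c2^2)/2``
where ``c1``, ``c2`` are the group centroids on LD1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .organise import MODEL_PREDICTORS, SampleTraitProfile

__all__ = [
    "ModelDataset",
    "DiscriminantModel",
    "DiscriminantResult",
    "fit",
    "classify",
    "load_model_data",
    "builtin_model_ids",
]


@dataclass
class ModelDataset:
    """Modern survey fields with group labels, locations and averaged traits.

    ``frame`` has columns ``group`` (1/2), ``location`` and one column per
    predictor of the chosen model.
    """

    model_id: int
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PREDICTORS:
            raise ValueError(f"model_id must be 1, 2 or 3, got {self.model_id!r}")
        frame = self.frame.copy()
        required = ["group", "location", *self.predictors]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(
                f"model-{self.model_id} dataset is missing column(s): {missing}"
            )
        groups = set(frame["group"].astype(int))
        if groups != {1, 2}:
            raise ValueError(
                f"model dataset must contain groups 1 and 2, found {sorted(groups)}"
            )
        frame["group"] = frame["group"].astype(int)
        pred = frame[list(self.predictors)].astype(float)
        if pred.isna().any().any():
            bad = pred.columns[pred.isna().any()].tolist()
            raise ValueError(f"model dataset has missing predictor values in {bad}")
        p = len(self.predictors)
        for g in (1, 2):
            n_g = int((frame["group"] == g).sum())
            if n_g < p + 2:
                raise ValueError(
                    f"group {g} has {n_g} fields; need at least p+2 = {p + 2}"
                )
        frame[list(self.predictors)] = pred
        self.frame = frame.reset_index(drop=True)

    @property
    def predictors(self) -> tuple[str, ...]:
        return MODEL_PREDICTORS[self.model_id]

    def group_matrix(self, group: int) -> np.ndarray:
        sub = self.frame[self.frame["group"] == group]
        return sub[list(self.predictors)].to_numpy(dtype=float)


@dataclass
class DiscriminantModel:
    """A fitted two-group discriminant."""

    model_id: int
    predictors: tuple[str, ...]
    coef_unstd: np.ndarray
    coef_std: np.ndarray
    constant: float
    centroid_1: float
    centroid_2: float
    priors: tuple[float, float]
    pooled_cov: np.ndarray
    group_means: tuple[np.ndarray, np.ndarray]
    n1: int
    n2: int

    @property
    def pooled_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.pooled_cov))

    @property
    def grand_mean(self) -> np.ndarray:
        pi1, pi2 = self.priors
        return pi1 * self.group_means[0] + pi2 * self.group_means[1]

    def score(self, x: np.ndarray) -> np.ndarray:
        """Unstandardised LD1 for rows of ``x`` (shape (n, p) or (p,))."""
        return np.atleast_2d(x) @ self.coef_unstd + self.constant

    def score_standardised(self, x: np.ndarray) -> np.ndarray:
        """LD1 recomputed from pooled-SD-scaled, grand-mean-centred predictors."""
        z = (np.atleast_2d(x) - self.grand_mean) / self.pooled_sd
        return z @ self.coef_std


def fit(model_data: ModelDataset, equal_priors: bool = False) -> DiscriminantModel:
    """Fit the two-group discriminant on a modern reference dataset.

    Priors default to the group proportions; pass ``equal_priors=True`` for
    (0.5, 0.5).  Raises :class:`numpy.linalg.LinAlgError`-derived
    :class:`ValueError` when the pooled covariance is singular.
    """
    X1 = model_data.group_matrix(1)
    X2 = model_data.group_matrix(2)
    n1, n2 = X1.shape[0], X2.shape[0]
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    S1 = np.cov(X1, rowvar=False)
    S2 = np.cov(X2, rowvar=False)
    S = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    S = np.atleast_2d(S)
    try:
        w = np.linalg.solve(S, m1 - m2)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-group covariance is singular; remove collinear or "
            "constant predictors"
        ) from exc
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "pooled within-group covariance is numerically singular "
            f"(condition number {cond:.3g}); remove collinear predictors"
        )
    # Unit pooled within-group variance along LD1.
    scale = float(w @ S @ w)
    if scale <= 0:
        raise ValueError("degenerate discriminant direction (zero within-group variance)")
    w = w / math.sqrt(scale)

    if equal_priors:
        pi1 = pi2 = 0.5
    else:
        pi1 = n1 / (n1 + n2)
        pi2 = n2 / (n1 + n2)
    grand = pi1 * m1 + pi2 * m2
    constant = -float(w @ grand)
    c1 = float(w @ m1) + constant
    c2 = float(w @ m2) + constant
    if c1 < 0:  # group 1 scores positive, by convention
        w, constant, c1, c2 = -w, -constant, -c1, -c2
    coef_std = w * np.sqrt(np.diag(S))
    return DiscriminantModel(
        model_id=model_data.model_id,
        predictors=model_data.predictors,
        coef_unstd=w,
        coef_std=coef_std,
        constant=constant,
        centroid_1=c1,
        centroid_2=c2,
        priors=(pi1, pi2),
        pooled_cov=S,
        group_means=(m1, m2),
        n1=n1,
        n2=n2,
    )


@dataclass
class DiscriminantResult:
    """Per-sample discriminant scores, classes and posteriors."""

    model: DiscriminantModel
    table: pd.DataFrame  # index: sample; columns LD1_unstd, LD1_std, class, prob1, prob2

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample"
        out.to_csv(path)


def _posteriors(model: DiscriminantModel, ld1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pi1, pi2 = model.priors
    c1, c2 = model.centroid_1, model.centroid_2
    log_ratio = math.log(pi1 / pi2) + ld1 * (c1 - c2) - (c1**2 - c2**2) / 2.0
    # Numerically stable sigmoid.
    prob1 = np.where(
        log_ratio >= 0,
        1.0 / (1.0 + np.exp(-log_ratio)),
        np.exp(log_ratio) / (1.0 + np.exp(log_ratio)),
    )
    return prob1, 1.0 - prob1


def _profile_matrix(
    model: DiscriminantModel, profiles: Sequence[SampleTraitProfile]
) -> tuple[np.ndarray, list[str]]:
    rows, ids = [], []
    for p in profiles:
        vec = []
        for trait in model.predictors:
            v = p.get(trait)
            if math.isnan(v):
                raise ValueError(
                    f"sample {p.sample_id!r} is missing predictor {trait} "
                    f"required by model {model.model_id}"
                )
            vec.append(v)
        rows.append(vec)
        ids.append(p.sample_id)
    return np.asarray(rows, dtype=float), ids


def classify(
    model: DiscriminantModel, profiles: Sequence[SampleTraitProfile]
) -> DiscriminantResult:
    """Score and classify sample trait profiles against a fitted model.

    A posterior of exactly 0.5 is assigned to group 2 (the documented tie
    rule).  Raises :class:`ValueError` naming the sample and trait when a
    required predictor is missing.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to classify")
    X, ids = _profile_matrix(model, profiles)
    ld1 = model.score(X).ravel()
    ld1_std = model.score_standardised(X).ravel()
    prob1, prob2 = _posteriors(model, ld1)
    classes = np.where(prob1 > 0.5, 1, 2)
    table = pd.DataFrame(
        {
            "LD1_unstd": ld1,
            "LD1_std": ld1_std,
            "class": classes,
            "prob1": prob1,
            "prob2": prob2,
        },
        index=pd.Index(ids, name="sample"),
    )
    return DiscriminantResult(model=model, table=table)


# ---------------------------------------------------------------------------
# Model reference data IO

_BUILTIN_NOTE = "synthetic stand-in"


def builtin_model_ids() -> list[str]:
    return ["model1", "model2", "model3"]


def _builtin_path(name: str) -> Path:
    return Path(__file__).parent / "data" / f"{name}_reference.csv"


def load_model_data(source: str | Path, model_id: int | None = None) -> ModelDataset:
    """Load a model reference dataset from CSV or a builtin id.

    ``source`` is either a CSV path with columns ``group,location,<predictors>``
    or one of ``model1``/``model2``/``model3``, which resolve to packaged
    *synthetic stand-ins* for the published survey datasets (same schema; a
    real released file loads through the identical path).  ``model_id`` is
    inferred from a builtin id and otherwise required.
    """
    if isinstance(source, str) and source in builtin_model_ids():
        inferred = int(source[-1])
        if model_id is not None and model_id != inferred:
            raise ValueError(f"builtin {source!r} conflicts with model_id={model_id}")
        model_id = inferred
        path = _builtin_path(source)
    else:
        path = Path(source)
        if model_id is None:
            raise ValueError("model_id is required when loading from a CSV path")
    frame = pd.read_csv(path, comment="#")
    return ModelDataset(model_id=model_id, frame=frame)
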