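import math

import numpy as np
import pandas as pd
import pytest

from weedclass.lda import ModelDataset
from weedclass.organise import SampleCounts, SampleTraitProfile
from weedclass.traitdb import TraitDatabase, TraitRecord


@pytest.fixture
def toy_db() -> TraitDatabase:
    """Six species with hand-picked trait values (one missing VEGPROP)."""
    return TraitDatabase(
        [
            TraitRecord("agrogit", "Agrostemma", "githago",
                        SLA=20.0, ARNODE=10.0, LOGCANH=1.0, LOGCAND=1.0,
                        VEGPROP=0.0, LIFEHIST="annual"),
            TraitRecord("anthcot", "Anthemis", "cotula",
                        SLA=30.0, ARNODE=14.0, LOGCANH=2.0, LOGCAND=1.2,
                        VEGPROP=1.0, LIFEHIST="annual"),
            TraitRecord("chenalb", "Chenopodium", "album",
                        SLA=25.0, ARNODE=6.0, LOGCANH=3.0, LOGCAND=1.4,
                        VEGPROP=None, LIFEHIST="annual"),
            TraitRecord("avenste", "Avena", "sterilis",
                        SLA=18.0, ARNODE=8.0, LOGCANH=1.8, LOGCAND=1.1,
                        VEGPROP=0.0, LIFEHIST="annual"),
            TraitRecord("avenfat", "Avena", "fatua",
                        SLA=22.0, ARNODE=12.0, LOGCANH=2.2, LOGCAND=1.3,
                        VEGPROP=1.0, LIFEHIST="annual"),
            TraitRecord("poa_ann", "Poa", "annua",
                        SLA=28.0, ARNODE=9.0, LOGCANH=0.8, LOGCAND=0.9,
                        VEGPROP=1.0, LIFEHIST="annual"),
        ],
        version="test-1",
    )


@pytest.fixture
def toy_counts() -> SampleCounts:
    matrix = pd.DataFrame(
        {
            "s1": [66.0, 0.0, 2.0, 0.0],
            "s2": [0.0, 4.0, 8.0, 1.0],
            "s3": [5.0, 3.0, 0.0, 2.0],
        },
        index=["agrogit", "anthcot", "chenalb", "poa_ann"],
    )
    return SampleCounts(matrix)


@pytest.fixture
def toy_flowper() -> dict:
    return {"agrogit": 2.0, "anthcot": 5.0, "chenalb": 4.0, "poa_ann": 8.0,
            "avenste": 3.0, "avenfat": 3.0}


def make_profiles(traits_rows, ids=None) -> list[SampleTraitProfile]:
    """Build profiles straight from dicts of trait values."""
    profiles = []
    for i, row in enumerate(traits_rows):
        profiles.append(
            SampleTraitProfile(
                sample_id=(ids[i] if ids else f"u{i + 1}"),
                traits=dict(row),
                n_species=3,
                n_seeds=30.0,
                low_diversity_flag=False,
            )
        )
    return profiles


def exact_identity_cov_dataset(model_id=2, delta=(1.0, 0.0, 0.0, 0.0)):
    """Two groups of 2p points whose sample pooled covariance is exactly I.

    Each group holds points mu +/- a*e_j for every axis j with
    a = sqrt((2p-1)/2), giving a per-group sample covariance of the identity.
    """
    from weedclass.organise import MODEL_PREDICTORS

    predictors = MODEL_PREDICTORS[model_id]
    p = len(predictors)
    a = math.sqrt((2 * p - 1) / 2.0)
    base = np.zeros(p)
    rows = []
    for group, mu in ((1, base + np.asarray(delta[:p])), (2, base)):
        for j in range(p):
            for sign in (+1, -1):
                x = mu.copy()
                x[j] += sign * a
                rows.append({"group": group, "location": f"g{group}",
                             **{t: x[k] for k, t in enumerate(predictors)}})
    return ModelDataset(model_id=model_id, frame=pd.DataFrame(rows))
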