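import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from weedclass.organise import (
    DEFAULT_MIN_SEEDS,
    CompositeSpec,
    SampleCounts,
    average_composite,
    clean_samples,
    composite_divergence,
    organise,
    profiles_to_frame,
    read_composites_csv,
    read_counts_csv,
    read_flowper_csv,
    to_presence_absence,
    write_counts_csv,
)
from weedclass.traitdb import UnknownCodeWarning


def counts_from(matrix: dict, index: list) -> SampleCounts:
    return SampleCounts(pd.DataFrame(matrix, index=index))


class TestPresenceAbsence:
    def test_basic(self, toy_counts):
        pa = to_presence_absence(toy_counts)
        assert pa.matrix.at["agrogit", "s1"] == 1.0  # count 66
        assert pa.matrix.at["agrogit", "s2"] == 0.0  # blank
        assert set(np.unique(pa.matrix.to_numpy())) <= {0.0, 1.0}

    def test_idempotent(self, toy_counts):
        once = to_presence_absence(toy_counts)
        twice = to_presence_absence(once)
        assert once == twice

    def test_all_zero_column_stays_zero(self):
        c = counts_from({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, ["agrogit", "poa_ann"])
        pa = to_presence_absence(c)
        assert (pa.matrix["s2"] == 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            counts_from({"s1": [-1.0]}, ["agrogit"])

    @given(arrays(float, (4, 3), elements=st.floats(0, 500)))
    @settings(max_examples=50, deadline=None)
    def test_scaling_invariance(self, values):
        idx = ["aaa", "bbb", "ccc", "ddd"]
        base = SampleCounts(pd.DataFrame(values, index=idx, columns=["x", "y", "z"]))
        scaled = SampleCounts(base.matrix * 7)
        assert to_presence_absence(base) == to_presence_absence(scaled)


class TestAverageComposite:
    def test_self_average_is_identity(self, toy_db):
        rec = average_composite(toy_db, CompositeSpec("selfav", ["agrogit", "agrogit"]))
        for trait in ("SLA", "ARNODE", "LOGCANH", "LOGCAND"):
            assert rec.get(trait) == toy_db["agrogit"].get(trait)

    def test_arithmetic_mean(self, toy_db):
        rec = average_composite(toy_db, CompositeSpec("avgab", ["agrogit", "anthcot"]))
        assert rec.SLA == 25.0  # (20 + 30) / 2

    def test_avenstfa_hand_average_with_vegprop_blank(self, toy_db):
        # hand-average of the two fixture members; VEGPROP override -> missing
        spec = CompositeSpec("avenstfa", ["avenste", "avenfat"],
                             overrides={"VEGPROP": None})
        rec = average_composite(toy_db, spec)
        assert rec.SLA == pytest.approx((18.0 + 22.0) / 2)
        assert rec.ARNODE == pytest.approx((8.0 + 12.0) / 2)
        assert rec.LOGCANH == pytest.approx((1.8 + 2.2) / 2)
        assert rec.LOGCAND == pytest.approx((1.1 + 1.3) / 2)
        assert rec.VEGPROP is None

    def test_missing_values_shrink_denominator(self, toy_db):
        # chenalb VEGPROP missing: mean over the other member only
        rec = average_composite(toy_db, CompositeSpec("chanth", ["chenalb", "anthcot"]))
        assert rec.VEGPROP == 1.0

    def test_trait_missing_in_all_members_stays_missing(self, toy_db):
        rec = average_composite(toy_db, CompositeSpec("chch", ["chenalb", "chenalb"]))
        assert rec.VEGPROP is None

    def test_absent_member_raises(self, toy_db):
        with pytest.raises(KeyError, match="nosuchsp"):
            average_composite(toy_db, CompositeSpec("xx", ["agrogit", "nosuchsp"]))

    def test_collision_with_db_code_raises(self, toy_db):
        with pytest.raises(ValueError, match="poa_ann"):
            average_composite(toy_db, CompositeSpec("poa_ann", ["agrogit", "anthcot"]))

    def test_more_than_four_members_warns(self, toy_db):
        members = ["agrogit", "anthcot", "chenalb", "avenste", "avenfat"]
        with pytest.warns(UserWarning, match="more than three or four"):
            average_composite(toy_db, CompositeSpec("big", members))

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CompositeSpec("solo", ["agrogit"])

    def test_divergence_report_is_advisory(self, toy_db):
        report = composite_divergence(toy_db, CompositeSpec("ab", ["agrogit", "anthcot"]))
        assert report.loc["SLA", "range"] == 10.0


class TestCleanSamples:
    def test_nine_seed_sample_dropped(self):
        c = counts_from({"s1": [4.0, 5.0], "s2": [10.0, 5.0]}, ["aaa", "bbb"])
        kept, report = clean_samples(c)
        assert report.dropped == ["s1"]
        assert kept.samples == ["s2"]

    def test_exactly_ten_kept(self):
        c = counts_from({"s1": [4.0, 6.0], "s2": [1.0, 1.0]}, ["aaa", "bbb"])
        kept, report = clean_samples(c)
        assert "s1" in kept.samples  # inclusive boundary

    def test_low_diversity_flagged_not_dropped(self):
        c = counts_from({"s1": [25.0, 25.0, 0.0]}, ["aaa", "bbb", "ccc"])
        kept, report = clean_samples(c)
        assert kept.samples == ["s1"]
        assert report.low_diversity == ["s1"]

    def test_all_dropped_raises(self):
        c = counts_from({"s1": [1.0], "s2": [2.0]}, ["aaa"])
        with pytest.raises(ValueError, match="minimum of 10"):
            clean_samples(c)

    def test_custom_threshold(self):
        c = counts_from({"s1": [4.0, 5.0]}, ["aaa", "bbb"])
        kept, report = clean_samples(c, min_seeds=5)
        assert kept.samples == ["s1"]
        assert report.min_seeds == 5

    def test_default_is_ten(self):
        assert DEFAULT_MIN_SEEDS == 10


class TestOrganise:
    def test_single_species_sample_equals_record(self, toy_db, toy_flowper):
        c = counts_from({"s1": [12.0]}, ["agrogit"])
        (profile,) = organise(c, toy_db, model=1, flowper=toy_flowper)
        rec = toy_db["agrogit"]
        for trait in ("SLA", "ARNODE", "LOGCANH", "LOGCAND"):
            assert profile.get(trait) == rec.get(trait)
        assert profile.get("FLOWPER") == toy_flowper["agrogit"]
        assert profile.n_species == 1
        assert profile.low_diversity_flag

    def test_three_species_mean(self, toy_db, toy_flowper):
        c = counts_from({"s1": [1.0, 2.0, 9.0]}, ["agrogit", "anthcot", "chenalb"])
        (profile,) = organise(c, toy_db, model=1, flowper=toy_flowper)
        assert profile.get("LOGCANH") == pytest.approx(2.0)  # (1+2+3)/3

    def test_vegprop_missing_denominator(self, toy_db):
        # VEGPROP values {0, 1, missing} -> mean 0.5 over the two non-missing
        c = counts_from({"s1": [1.0, 1.0, 1.0]}, ["agrogit", "anthcot", "chenalb"])
        (profile,) = organise(c, toy_db, model=3, flowper={"agrogit": 2, "anthcot": 5,
                                                           "chenalb": 4})
        assert profile.get("VEGPROP") == pytest.approx(0.5)

    def test_counts_do_not_weight_means(self, toy_db, toy_flowper):
        c1 = counts_from({"s1": [1.0, 1.0]}, ["agrogit", "anthcot"])
        c2 = counts_from({"s1": [99.0, 1.0]}, ["agrogit", "anthcot"])
        p1 = organise(c1, toy_db, 2)[0]
        p2 = organise(c2, toy_db, 2)[0]
        assert p1.traits == p2.traits
        assert p2.n_seeds == 100.0

    def test_unknown_taxon_excluded_with_warning(self, toy_db, toy_flowper):
        c = counts_from({"s1": [1.0, 5.0]}, ["agrogit", "zzz"])
        with pytest.warns(UnknownCodeWarning, match="zzz"):
            (profile,) = organise(c, toy_db, model=2)
        known_only = organise(
            counts_from({"s1": [1.0]}, ["agrogit"]), toy_db, model=2)[0]
        assert profile.traits == known_only.traits

    def test_empty_intersection_raises(self, toy_db):
        c = counts_from({"s1": [1.0]}, ["zzz"])
        with pytest.raises(ValueError, match="no taxon"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                organise(c, toy_db, model=2)

    def test_flowper_required_for_models_1_and_3(self, toy_db):
        c = counts_from({"s1": [1.0]}, ["agrogit"])
        for model in (1, 3):
            with pytest.raises(ValueError, match="FLOWPER"):
                organise(c, toy_db, model=model)
        organise(c, toy_db, model=2)  # fine without

    def test_flowper_missing_taxon_named(self, toy_db):
        c = counts_from({"s1": [1.0, 1.0]}, ["agrogit", "anthcot"])
        with pytest.raises(ValueError, match="anthcot"):
            organise(c, toy_db, model=1, flowper={"agrogit": 2.0})

    def test_model_output_columns(self, toy_db, toy_flowper):
        c = counts_from({"s1": [1.0, 1.0, 1.0]}, ["agrogit", "anthcot", "poa_ann"])
        frames = {
            m: profiles_to_frame(organise(c, toy_db, m, flowper=toy_flowper))
            for m in (1, 2, 3)
        }
        trait_cols = lambda f: [c for c in f.columns
                                if c not in ("n_species", "n_seeds", "low_diversity")]
        assert trait_cols(frames[2]) == ["SLA", "ARNODE", "LOGCANH", "LOGCAND"]
        assert trait_cols(frames[1]) == ["SLA", "ARNODE", "LOGCANH", "LOGCAND", "FLOWPER"]
        assert trait_cols(frames[3]) == ["SLA", "ARNODE", "LOGCANH", "LOGCAND",
                                         "VEGPROP", "FLOWPER"]

    def test_composites_merged(self, toy_db, toy_flowper):
        spec = CompositeSpec("avenstfa", ["avenste", "avenfat"])
        c = counts_from({"s1": [3.0, 9.0]}, ["agrogit", "avenstfa"])
        flow = dict(toy_flowper, avenstfa=3.0)
        (profile,) = organise(c, toy_db, 1, flowper=flow, composites=[spec])
        assert profile.get("SLA") == pytest.approx((20.0 + 20.0) / 2)  # agrogit 20, comp 20
        assert profile.n_species == 2

    def test_vegprop_override_changes_denominator(self, toy_db):
        c = counts_from({"s1": [1.0, 1.0]}, ["agrogit", "anthcot"])
        flow = {"agrogit": 2.0, "anthcot": 5.0}
        base = organise(c, toy_db, 3, flowper=flow)[0]
        assert base.get("VEGPROP") == pytest.approx(0.5)
        over = organise(c, toy_db, 3, flowper=flow,
                        vegprop_overrides={"anthcot": None})[0]
        assert over.get("VEGPROP") == pytest.approx(0.0)  # only agrogit's 0 left

    def test_invalid_model(self, toy_db, toy_counts):
        with pytest.raises(ValueError, match="model"):
            organise(toy_counts, toy_db, model=4)

    @given(st.integers(1, 50))
    @settings(max_examples=25, deadline=None)
    def test_count_magnitude_invariance(self, factor, ):
        idx = ["agrogit", "anthcot", "chenalb"]
        base = counts_from({"s1": [1.0, 0.0, 2.0], "s2": [3.0, 4.0, 0.0]}, idx)
        scaled = SampleCounts(base.matrix * factor)
        db = _db()
        p_base = organise(base, db, 2)
        p_scaled = organise(scaled, db, 2)
        for a, b in zip(p_base, p_scaled):
            assert a.traits == b.traits

    def test_mean_times_denominator_equals_sum(self, toy_db, toy_flowper):
        c = counts_from({"s1": [1.0, 1.0, 1.0, 1.0]},
                        ["agrogit", "anthcot", "chenalb", "poa_ann"])
        (profile,) = organise(c, toy_db, 3, flowper=toy_flowper)
        vals = [toy_db[t].get("VEGPROP") for t in c.taxa]
        vals = [v for v in vals if not math.isnan(v)]
        assert profile.get("VEGPROP") * len(vals) == pytest.approx(sum(vals), abs=1e-12)


def _db():
    from weedclass.traitdb import TraitDatabase, TraitRecord

    return TraitDatabase(
        [
            TraitRecord("agrogit", SLA=20, ARNODE=10, LOGCANH=1, LOGCAND=1),
            TraitRecord("anthcot", SLA=30, ARNODE=14, LOGCANH=2, LOGCAND=1.2),
            TraitRecord("chenalb", SLA=25, ARNODE=6, LOGCANH=3, LOGCAND=1.4),
        ]
    )


class TestCsvIO:
    def test_counts_round_trip(self, toy_counts, tmp_path):
        path = tmp_path / "counts.csv"
        write_counts_csv(toy_counts, path)
        back = read_counts_csv(path)
        assert back == toy_counts

    def test_blank_cells_read_as_zero(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("species.codes,s1,s2\nagrogit,66,\nanthcot,,18\n")
        counts = read_counts_csv(path)
        assert counts.matrix.at["agrogit", "s2"] == 0.0
        assert counts.matrix.at["anthcot", "s2"] == 18.0

    def test_flowper_csv(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("species.codes,FLOWPER\nagrogit,2\nanthcot,5\n")
        assert read_flowper_csv(path) == {"agrogit": 2.0, "anthcot": 5.0}

    def test_flowper_out_of_range(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("species.codes,FLOWPER\nagrogit,14\n")
        with pytest.raises(ValueError, match="agrogit"):
            read_flowper_csv(path)

    def test_composites_csv(self, tmp_path):
        path = tmp_path / "comp.csv"
        path.write_text(
            "composite_code,member1,member2,member3,override_VEGPROP\n"
            "avenstfa,avenste,avenfat,,NA\n"
            "ranuabr,ranuacr,ranubul,ranurep,\n"
        )
        specs = read_composites_csv(path)
        assert [s.composite_code for s in specs] == ["avenstfa", "ranuabr"]
        assert specs[0].members == ["avenste", "avenfat"]
        assert specs[0].overrides == {"VEGPROP": None}
        assert specs[1].members == ["ranuacr", "ranubul", "ranurep"]
        assert specs[1].overrides == {}

    def test_duplicate_composite_codes_rejected(self, tmp_path):
        path = tmp_path / "comp.csv"
        path.write_text(
            "composite_code,member1,member2\nxx,aaa,bbb\nxx,ccc,ddd\n")
        with pytest.raises(ValueError, match="xx"):
            read_composites_csv(path)
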