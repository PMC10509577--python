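from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tidegam.detections import (
    Deployment,
    SequenceRecord,
    TriggerRecord,
    assemble_sequences,
    build_model_table,
    descriptive_summary,
    filter_service_days,
    fit_standardizer,
    season_of,
)
from tidegam.errors import (
    ArgumentError,
    DegenerateScaleError,
    OrphanRecordError,
)
from tidegam.tide_clock import synth_tide_schedule

T0 = datetime(2023, 3, 10, 9, 0, 0)


def trig(offset_s, count=1, cam="c1"):
    return TriggerRecord(cam, T0 + timedelta(seconds=offset_s), "capuchin", count)


class TestAssembleSequences:
    def test_gap_rule_splits(self):
        seqs = assemble_sequences([trig(0), trig(10), trig(45)])
        assert [s.start_ts for s in seqs] == [T0, T0 + timedelta(seconds=45)]

    def test_transitive_chaining(self):
        # each consecutive gap is 29 s < 30 s, so one sequence despite a
        # 58 s total span
        seqs = assemble_sequences([trig(0), trig(29), trig(58)])
        assert len(seqs) == 1 and seqs[0].start_ts == T0

    def test_count_is_chain_max(self):
        seqs = assemble_sequences([trig(0, 1), trig(5, 3), trig(10, 2)])
        assert seqs[0].count == 3

    def test_zero_count_sequences_dropped(self):
        seqs = assemble_sequences([trig(0, 0), trig(100, 2)])
        assert len(seqs) == 1 and seqs[0].count == 2

    def test_cameras_never_merge(self):
        seqs = assemble_sequences([trig(0, cam="a"), trig(5, cam="b")])
        assert len(seqs) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ArgumentError):
            assemble_sequences([trig(0)], gap_s=-1)

    def test_idempotent_on_own_output(self):
        triggers = [trig(0, 2), trig(20, 1), trig(60, 3), trig(95, 1)]
        seqs = assemble_sequences(triggers)
        again = assemble_sequences(
            [TriggerRecord(s.camera_id, s.start_ts, "capuchin", s.count)
             for s in seqs]
        )
        assert [(s.camera_id, s.start_ts, s.count) for s in seqs] == [
            (s.camera_id, s.start_ts, s.count) for s in again
        ]

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=600),
                st.integers(min_value=0, max_value=3),
                st.sampled_from(["a", "b"]),
            ),
            min_size=1,
            max_size=15,
        )
    )
    def test_brute_force_chaining_oracle(self, raw):
        triggers = [trig(o, c, cam) for o, c, cam in raw]
        got = assemble_sequences(triggers)

        # O(n^2) oracle: union triggers into chains whenever some pair at the
        # same camera is < 30 s apart (transitive closure), then apply the
        # max-count and zero-drop rules
        n = len(triggers)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(n):
                if (
                    triggers[i].camera_id == triggers[j].camera_id
                    and abs(
                        (triggers[i].timestamp - triggers[j].timestamp)
                        .total_seconds()
                    )
                    < 30
                ):
                    parent[find(i)] = find(j)
        chains = {}
        for i in range(n):
            chains.setdefault(find(i), []).append(triggers[i])
        expected = sorted(
            (
                (min(t.timestamp for t in ch), max(t.count for t in ch), ch[0].camera_id)
                for ch in chains.values()
                if max(t.count for t in ch) >= 1
            ),
        )
        assert sorted((s.start_ts, s.count, s.camera_id) for s in got) == expected


class TestServiceDays:
    dep = Deployment("c1", "s1", date(2023, 3, 9), date(2023, 3, 20), 50.0, "tool")

    def test_sequence_on_start_date_removed(self):
        seq = SequenceRecord("c1", datetime(2023, 3, 9, 12), 1)
        assert filter_service_days([seq], [self.dep]) == []

    def test_sequence_on_end_date_removed(self):
        seq = SequenceRecord("c1", datetime(2023, 3, 20, 6), 1)
        assert filter_service_days([seq], [self.dep]) == []

    def test_day_after_start_retained(self):
        seq = SequenceRecord("c1", datetime(2023, 3, 10, 12), 1)
        assert filter_service_days([seq], [self.dep]) == [seq]

    def test_empty_input(self):
        assert filter_service_days([], [self.dep]) == []

    def test_orphan_sequence_lists_ids(self):
        seq = SequenceRecord("ghost", datetime(2023, 3, 10, 12), 1)
        with pytest.raises(OrphanRecordError, match="ghost"):
            filter_service_days([seq], [self.dep])


class TestSeasonOf:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (date(2023, 1, 15), "dry"),
            (date(2023, 7, 15), "wet"),
            (date(2023, 4, 30), "dry"),
            (date(2023, 5, 1), "wet"),
            (date(2023, 12, 1), "dry"),
            (date(2023, 11, 30), "wet"),
        ],
    )
    def test_month_split(self, d, expected):
        assert season_of(d) == expected


class TestStandardizer:
    def test_two_point_case(self):
        s = fit_standardizer([-1.0, 1.0])
        assert s.mean == 0.0
        assert s.sd == pytest.approx(np.sqrt(2))
        assert s.transform(1.0) == pytest.approx(1 / np.sqrt(2))

    def test_transform_of_mean_is_zero(self):
        s = fit_standardizer([3.0, 9.0, 4.5, 7.7])
        assert s.transform(s.mean) == pytest.approx(0.0)

    def test_round_trip(self):
        s = fit_standardizer([0.0, 5.0, 11.0])
        x = np.array([0.3, 4.4, 10.9])
        assert np.allclose(s.inverse(s.transform(x)), x, atol=1e-12)

    def test_unit_sample_sd(self):
        vals = [1.0, 4.0, 2.0, 8.0, 5.0]
        z = fit_standardizer(vals).transform(vals)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateScaleError):
            fit_standardizer([2.0, 2.0, 2.0])


class TestBuildModelTable:
    def test_row_conservation_and_columns(self, small_study, small_table):
        triggers, deployments, tides, _ = small_study
        sequences = filter_service_days(assemble_sequences(triggers), deployments)
        assert len(small_table) == len(sequences)
        assert set(small_table.data["season"]) <= {"dry", "wet"}
        assert (small_table.data["count"] >= 1).all()
        assert small_table.data["t_z"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_both_seasons_present(self, small_table):
        # the campaign spans March–May, crossing the April/May season break
        assert set(small_table.data["season"]) == {"dry", "wet"}

    def test_order_invariance(self, small_study):
        triggers, deployments, tides, _ = small_study
        fwd = build_model_table(
            filter_service_days(assemble_sequences(triggers), deployments),
            deployments, tides,
        )
        rev = build_model_table(
            filter_service_days(
                assemble_sequences(list(reversed(triggers))), deployments
            ),
            deployments, tides,
        )
        assert len(fwd) == len(rev)
        assert fwd.data.equals(rev.data)

    def test_orphan_propagates(self, tiny_tides):
        seq = SequenceRecord("nocam", datetime(2023, 3, 2, 10), 2)
        with pytest.raises(OrphanRecordError):
            build_model_table([seq], [], tiny_tides)


class TestDescriptiveSummary:
    def test_known_campaign(self):
        deployments = [
            Deployment("c1", "s1", date(2023, 3, 1), date(2023, 3, 11), 5.0, "tool"),
            Deployment("c2", "s2", date(2023, 3, 1), date(2023, 3, 21), 9.0, "nontool"),
        ]
        seqs = [
            SequenceRecord("c1", datetime(2023, 3, 5, 8), 1),
            SequenceRecord("c1", datetime(2023, 3, 6, 9), 3),
            SequenceRecord("c2", datetime(2023, 3, 7, 10), 2),
        ]
        s = descriptive_summary(seqs, deployments)
        assert s["n_sequences"] == 3
        assert s["count_mean"] == pytest.approx(2.0)
        # nights exclude set-up and collection days
        assert s["sampling_nights"] == {"tool": 9, "nontool": 19}
        assert s["mean_nights_per_camera"] == pytest.approx(14.0)
        assert s["count_min"] == 1 and s["count_max"] == 3
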