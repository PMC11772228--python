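import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nicugaze as ng
from nicugaze import exposure as expo
from helpers_oracles import (
    exposure_oracle,
    presence_hours_oracle,
    word_frequency_oracle,
)


def _iv(start, end, infant="inf000", role="mother"):
    return pd.DataFrame(
        {
            "infant_id": [infant],
            "parent_role": [role],
            "start": [pd.Timestamp(start)],
            "end": [pd.Timestamp(end)],
        }
    )


class TestClipToWindow:
    def test_clips_early_morning_boundary(self):
        out = ng.clip_to_window(_iv("2024-03-04 06:30", "2024-03-04 08:00"))
        assert len(out) == 1
        assert out.at[0, "start"] == pd.Timestamp("2024-03-04 07:00")
        assert (out.at[0, "end"] - out.at[0, "start"]) == pd.Timedelta("1h")

    def test_clips_late_evening_boundary(self):
        out = ng.clip_to_window(_iv("2024-03-04 21:00", "2024-03-04 23:00"))
        assert out.at[0, "end"] == pd.Timestamp("2024-03-04 22:00")

    def test_midnight_spanning_interval_split_before_clipping(self):
        out = ng.clip_to_window(_iv("2024-03-04 20:00", "2024-03-05 09:00"))
        assert len(out) == 2
        assert out.at[0, "end"] == pd.Timestamp("2024-03-04 22:00")
        assert out.at[1, "start"] == pd.Timestamp("2024-03-05 07:00")

    def test_malformed_interval_names_the_row(self):
        bad = _iv("2024-03-04 10:00", "2024-03-04 09:00")
        with pytest.raises(ValueError, match="rows"):
            ng.clip_to_window(bad)

    def test_random_intervals_match_minute_membership_oracle(self):
        from conftest import random_minute_intervals

        rng = np.random.default_rng(17)
        iv = random_minute_intervals(rng, 50)
        clipped = expo.normalize_intervals(ng.clip_to_window(iv))
        got = ng.presence_hours(clipped).sum()
        assert got == pytest.approx(presence_hours_oracle(iv), rel=1e-12)


class TestPresenceHours:
    def test_empty_is_zero(self):
        assert ng.presence_hours(pd.DataFrame(columns=["infant_id", "parent_role",
                                                       "start", "end"])).empty

    def test_fourteen_days_of_eight_hours(self):
        rows = []
        for d in range(14):
            t0 = pd.Timestamp("2024-03-04 08:00") + pd.Timedelta(days=d)
            rows.append(("inf000", "mother", t0, t0 + pd.Timedelta(hours=8)))
        iv = pd.DataFrame(rows, columns=["infant_id", "parent_role", "start", "end"])
        assert ng.presence_hours(iv).iloc[0] == pytest.approx(112.0)

    def test_overlapping_intervals_not_double_counted(self):
        iv = pd.concat(
            [_iv("2024-03-04 08:00", "2024-03-04 12:00"),
             _iv("2024-03-04 10:00", "2024-03-04 14:00")],
            ignore_index=True,
        )
        merged = expo.normalize_intervals(iv)
        assert ng.presence_hours(merged).iloc[0] == pytest.approx(6.0)


def _segments(rows, infant="inf000"):
    return pd.DataFrame(
        [
            {
                "infant_id": infant,
                "start": pd.Timestamp(s),
                "duration_s": dur,
                "female_words": f,
                "male_words": m,
            }
            for s, dur, f, m in rows
        ]
    )


class TestObservedWordFrequency:
    def test_zero_words_gives_zero_frequency(self):
        seg = _segments([("2024-03-04 08:00", 3600, 0, 0),
                         ("2024-03-04 09:00", 3600, 0, 0)])
        pres = _iv("2024-03-04 08:00", "2024-03-04 10:00")
        out = ng.observed_word_frequency(seg, pres)
        mother = out[out["parent_role"] == "mother"].iloc[0]
        assert mother["word_frequency"] == 0.0

    def test_absent_parent_goes_to_imputation_path(self):
        seg = _segments([("2024-03-04 08:00", 3600, 120, 30)])
        pres = _iv("2024-03-04 08:00", "2024-03-04 09:00", role="mother")
        out = ng.observed_word_frequency(seg, pres)
        father = out[out["parent_role"] == "father"].iloc[0]
        assert np.isnan(father["word_frequency"])

    def test_partial_overlap_apportioned_by_duration_fraction(self):
        # 60-min segment, presence covers the last 15 min -> 1/4 of the words
        seg = _segments([("2024-03-04 08:00", 3600, 200, 0)])
        pres = _iv("2024-03-04 08:45", "2024-03-04 10:00")
        out = ng.observed_word_frequency(seg, pres)
        mother = out[out["parent_role"] == "mother"].iloc[0]
        # numerator 50 words; denominator = presence within segment span
        assert mother["word_frequency"] == pytest.approx(50 / 0.25)

    def test_random_data_matches_per_minute_apportionment_oracle(self):
        rng = np.random.default_rng(23)
        segs = _segments(
            [
                (
                    pd.Timestamp("2024-03-04 07:00") + pd.Timedelta(minutes=10 * k),
                    600,
                    int(rng.integers(0, 50)),
                    int(rng.integers(0, 20)),
                )
                for k in range(60)
            ]
        )
        from conftest import random_minute_intervals

        pres = random_minute_intervals(rng, 6, days=1)
        out = ng.observed_word_frequency(segs, pres)
        mother = out[out["parent_role"] == "mother"].iloc[0]
        want = word_frequency_oracle(segs, pres, "female_words")
        if want is None:
            assert np.isnan(mother["word_frequency"])
        else:
            assert mother["word_frequency"] == pytest.approx(want, rel=1e-9)


class TestImputation:
    def _infants(self):
        return pd.DataFrame(
            {
                "infant_id": ["i0", "i1", "i2", "i3", "i4"],
                "site": ["A", "A", "A", "A", "A"],
                "twin_pair_id": ["", "tw0", "tw0", "", ""],
                "single_parent": [True, False, False, False, False],
            }
        )

    def _freq(self, rows):
        return pd.DataFrame(rows, columns=["infant_id", "parent_role",
                                           "word_frequency", "recording_presence_h"])

    def test_single_parent_father_is_zero(self):
        freq = self._freq([("i0", "father", np.nan, 0.0),
                           ("i3", "father", 100.0, 2.0),
                           ("i4", "father", 400.0, 2.0)])
        out = ng.impute_word_frequency(freq, self._infants())
        row = out[out["infant_id"] == "i0"].iloc[0]
        assert row["word_frequency"] == 0.0
        assert row["frequency_source"] == "single_parent_zero"

    def test_twin_cosample_takes_precedence_over_site_median(self):
        freq = self._freq([("i1", "father", np.nan, 0.0),
                           ("i2", "father", 320.0, 3.0),
                           ("i3", "father", 1000.0, 2.0)])
        out = ng.impute_word_frequency(freq, self._infants())
        row = out[out["infant_id"] == "i1"].iloc[0]
        assert row["word_frequency"] == 320.0
        assert row["frequency_source"] == "twin_cosample"

    def test_site_median_of_observed_frequencies(self):
        freq = self._freq([("i0", "mother", np.nan, 0.0),
                           ("i1", "mother", 100.0, 1.0),
                           ("i2", "mother", 250.0, 1.0),
                           ("i3", "mother", 400.0, 1.0)])
        out = ng.impute_word_frequency(freq, self._infants())
        row = out[out["infant_id"] == "i0"].iloc[0]
        assert row["word_frequency"] == 250.0
        assert row["frequency_source"] == "site_median"

    def test_no_observed_values_raises(self):
        freq = self._freq([("i3", "mother", np.nan, 0.0)])
        with pytest.raises(expo.ImputationError):
            ng.impute_word_frequency(freq, self._infants())


class TestComputeExposure:
    def test_arithmetic(self):
        assert ng.compute_exposure(0.0, 100.0) == 0.0
        assert ng.compute_exposure(100.0, 14.0) == 1400.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ng.compute_exposure(-1.0, 10.0)

    @settings(max_examples=30, derandomize=True)
    @given(wf=st.floats(0, 1e4), ph=st.floats(0, 300), k=st.floats(0, 10))
    def test_scale_equivariance(self, wf, ph, k):
        assert ng.compute_exposure(k * wf, ph) == pytest.approx(
            k * ng.compute_exposure(wf, ph)
        )


class TestEndToEnd:
    def test_cohort_exposure_matches_minute_oracle(self, small_cohort):
        c = small_cohort
        got = ng.exposure_table(c.infants, c.diary, c.segments)
        want = exposure_oracle(c.infants, c.diary, c.segments)
        merged = got[got["parent_role"] != "total"].merge(
            want, on=["infant_id", "parent_role"], suffixes=("", "_oracle")
        )
        assert len(merged) == 2 * len(c.infants)
        np.testing.assert_allclose(
            merged["presence_hours_14d"], merged["presence_hours_14d_oracle"],
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            merged["exposure_words"], merged["exposure_words_oracle"], rtol=1e-9
        )

    def test_adding_presence_never_decreases_presence_hours(self, small_cohort):
        diary = small_cohort.diary
        before = ng.presence_hours(
            expo.normalize_intervals(ng.clip_to_window(diary))
        ).sum()
        extra = _iv("2024-03-06 09:00", "2024-03-06 11:00",
                    infant=diary["infant_id"].iloc[0])
        extra["modality"] = "present"
        after = ng.presence_hours(
            expo.normalize_intervals(
                ng.clip_to_window(pd.concat([diary, extra], ignore_index=True))
            )
        ).sum()
        assert after >= before

    def test_segments_outside_window_never_affect_output(self, small_cohort):
        c = small_cohort
        base = ng.exposure_table(c.infants, c.diary, c.segments)
        night = _segments([("2024-03-11 03:00", 600, 500, 500)],
                          infant=c.infants["infant_id"].iloc[0])
        spiked = pd.concat([c.segments, night], ignore_index=True)
        again = ng.exposure_table(c.infants, c.diary, spiked)
        pd.testing.assert_frame_equal(base, again)

    def test_doubling_word_counts_doubles_observed_exposure(self, small_cohort):
        c = small_cohort
        base = ng.exposure_table(c.infants, c.diary, c.segments)
        doubled_segs = c.segments.assign(
            female_words=2 * c.segments["female_words"],
            male_words=2 * c.segments["male_words"],
        )
        doubled = ng.exposure_table(c.infants, c.diary, doubled_segs)
        obs = base["frequency_source"] == "observed"
        np.testing.assert_allclose(
            doubled.loc[obs, "exposure_words"],
            2 * base.loc[obs, "exposure_words"],
            rtol=1e-12,
        )
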