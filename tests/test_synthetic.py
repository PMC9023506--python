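import numpy as np
import pytest
from hypothesis import given, strategies as st

import larvascreen as ls
from larvascreen.metrics import MEASURES, OMR_MEASURES
from larvascreen.protocol import VISUAL_CLASSES
from larvascreen.synthetic import (Phenotype, PhenotypeError, dmso_phenotype,
                                   expected_vector, reference_profiles,
                                   simulate_screen, simulate_track,
                                   vectors_from_tracks)
from larvascreen import io as lio


def uniform_gain(g):
    return {c: g for c in VISUAL_CLASSES}


class TestSimulateTrack:
    def test_determinism(self, fast_schedule, geometry):
        ph = dmso_phenotype()
        a = simulate_track(ph, fast_schedule, geometry, seed=7)
        b = simulate_track(ph, fast_schedule, geometry, seed=7)
        assert np.array_equal(a.moved, b.moved)
        assert np.array_equal(a.x_mm, b.x_mm) and np.array_equal(a.y_mm, b.y_mm)
        c = simulate_track(ph, fast_schedule, geometry, seed=8)
        assert not np.array_equal(a.moved, c.moved)

    def test_zero_probability_never_moves(self, fast_schedule, geometry):
        track = simulate_track(Phenotype(p_move_base=0.0), fast_schedule, geometry, 1)
        assert not track.moved.any()
        assert np.ptp(track.x_mm) == 0 and np.ptp(track.y_mm) == 0

    def test_stationary_between_movements(self, fast_schedule, geometry):
        track = simulate_track(dmso_phenotype(), fast_schedule, geometry, 3)
        still = ~track.moved[1:]
        assert np.array_equal(track.x_mm[1:][still], track.x_mm[:-1][still])
        assert np.array_equal(track.y_mm[1:][still], track.y_mm[:-1][still])

    def test_moved_fraction_in_binomial_interval(self, schedule, geometry):
        # n=1800, p=0.2: the 99% binomial interval is well inside +-3 pp
        track = simulate_track(Phenotype(p_move_base=0.2), schedule, geometry, 11)
        assert abs(track.moved[1:].mean() - 0.2) < 0.03

    @given(st.integers(0, 50))
    def test_positions_stay_inside_the_well(self, seed):
        sched = ls.default_schedule(frame_interval_s=60.0)
        geometry = ls.WellGeometry()
        ph = Phenotype(p_move_base=0.6, omr_gain=uniform_gain(0.8),
                       step_min_mm=0.5, step_max_mm=1.5)
        track = simulate_track(ph, sched, geometry, seed)
        r = np.hypot(track.x_mm, track.y_mm)
        assert (r <= geometry.position_radius_mm + 1e-9).all()

    def test_invalid_phenotype_rejected(self):
        with pytest.raises(PhenotypeError):
            Phenotype(p_move_base=1.4)
        with pytest.raises(PhenotypeError):
            Phenotype(p_move_base=0.2, omr_gain=uniform_gain(1.5))

    def test_up_state_defined_after_first_movement(self, fast_schedule, geometry):
        track = simulate_track(Phenotype(p_move_base=0.05), fast_schedule, geometry, 2)
        up = track.up_state()
        first = np.argmax(track.moved)
        assert track.moved.any()
        assert np.isnan(up[:first]).all()
        assert np.isfinite(up[first:]).all()
        assert np.array_equal(up[first:], (track.y_mm[first:] < 0).astype(float))


class TestUnbiasedOptomotor:
    def test_zero_gain_gives_zero_mean_omr(self, schedule, geometry):
        # 200 replicate tracks: |mean| bound is ~2.6 sigma of the Monte-Carlo
        # mean (per-track OMR sd ~25 pp -> se ~1.8 pp)
        ph = Phenotype(p_move_base=0.2, startle_gain=0.1, excitability_gain=0.15)
        tracks = [simulate_track(ph, schedule, geometry, seed) for seed in range(200)]
        table = vectors_from_tracks(tracks, schedule)
        for col in OMR_MEASURES:
            assert abs(np.nanmean(table[col])) < 5.0


class TestExpectedVector:
    def test_all_zero_gains(self):
        vec = expected_vector(Phenotype(p_move_base=0.3))
        assert vec.startle == 0 and vec.excit == 0 and vec.hab == 0
        assert all(getattr(vec, m) == 0 for m in OMR_MEASURES)
        assert vec.act_1h == 30.0 and vec.act_p15 == 30.0

    def test_startle_gain_maps_to_pp(self):
        vec = expected_vector(Phenotype(p_move_base=0.2, startle_gain=0.08))
        assert vec.startle == pytest.approx(8.0)

    def test_excitability_and_habituation(self):
        # E averages over the habituating second half: E = e - hab/2
        vec = expected_vector(Phenotype(p_move_base=0.2, startle_gain=0.1,
                                        excitability_gain=0.15, habituation_drop=0.05))
        assert vec.hab == pytest.approx(5.0)
        assert vec.excit == pytest.approx(15.0 - 2.5)

    def test_omr_expectation_matches_independent_monte_carlo(self, schedule, geometry):
        ph = Phenotype(p_move_base=0.2, omr_gain={"red": 0.3, "green": 0.3,
                                                  "blue": 0.3, "fast_red": 0.3})
        vec = expected_vector(ph, schedule, n_mc=1500, seed=101)
        # independent draw: different seed stream, direct simulation
        tracks = [simulate_track(ph, schedule, geometry, seed=50_000 + i)
                  for i in range(1500)]
        table = vectors_from_tracks(tracks, schedule)
        assert vec.omr_red == pytest.approx(np.nanmean(table["omr_red"]), abs=2.5)
        assert vec.omr_rgb == pytest.approx(np.nanmean(table["omr_rgb"]), abs=1.5)


class TestSimulateScreen:
    def test_one_track_per_well_and_determinism(self, fast_schedule, geometry):
        layout = ls.screen_session_layout([f"d{i}" for i in range(80)])
        pmap = {lab: dmso_phenotype() for lab in layout.labels}
        tracks = simulate_screen(layout, pmap, fast_schedule, geometry, seed=9)
        assert len(tracks) == 384
        again = simulate_screen(layout, pmap, fast_schedule, geometry, seed=9)
        for a, b in zip(tracks, again):
            assert np.array_equal(a.moved, b.moved)
            assert np.array_equal(a.x_mm, b.x_mm)

    def test_missing_phenotype_label(self, fast_schedule, geometry):
        layout = ls.screen_session_layout(["drugA"])
        with pytest.raises(PhenotypeError, match="drugA"):
            simulate_screen(layout, {"DMSO": dmso_phenotype(),
                                     "untreated": dmso_phenotype()},
                            fast_schedule, geometry, seed=0)

    def test_cohort_counts_48_per_drug(self, fast_schedule, geometry):
        # 12 sessions x 4 duplicate wells per session = 48 larvae per drug
        layout = ls.screen_session_layout([f"d{i}" for i in range(3)])
        pmap = {lab: dmso_phenotype() for lab in layout.labels}
        counts = {f"d{i}": 0 for i in range(3)}
        for session in range(12):
            tracks = simulate_screen(layout, pmap, fast_schedule, geometry, seed=session)
            for t in tracks:
                label = layout.wells[t.address]
                if label in counts:
                    counts[label] += 1
        assert all(c == 48 for c in counts.values())

    def test_parameter_recovery_at_n160(self, schedule, geometry):
        # one fixed-seed validation-sized group recovers its expectation:
        # activity family within +-3 pp, optomotor family within +-5 pp
        gain = ls.calibrate_omr_gain(30.0, dmso_phenotype(), schedule,
                                     n_mc=600, seed=4)
        ph = Phenotype(p_move_base=0.4, startle_gain=0.1, excitability_gain=0.3,
                       habituation_drop=0.05, omr_gain=uniform_gain(gain),
                       label="drug")
        expected = expected_vector(ph, schedule, n_mc=2000, seed=5)
        layout = ls.validation_session_layout(["DMSO"] + ["drug"] * 11,
                                              plates=(1, 2))
        tracks = simulate_screen(layout, {"DMSO": ph, "drug": ph}, schedule,
                                 geometry, seed=12345)
        table = vectors_from_tracks(tracks, schedule, layout=layout)
        sub = table[table["label"] == "drug"].head(160)
        assert len(sub) == 160
        for m in MEASURES[:5]:
            assert np.nanmean(sub[m]) == pytest.approx(getattr(expected, m), abs=3.0)
        for m in OMR_MEASURES:
            assert np.nanmean(sub[m]) == pytest.approx(getattr(expected, m), abs=5.0)


class TestReferenceProfiles:
    SIGNS = {"act_1h": 1, "act_p15": 1, "hab": 0, "startle": 0, "excit": 1,
             "omr_red": -1, "omr_green": -1, "omr_blue": -1,
             "omr_fast_red": -1, "omr_rgb": -1}

    def test_sign_patterns_and_negation(self):
        table = reference_profiles(n_per_family=3, noise_sd=0.0, seed=0)
        csa = table.loc["CsA-like-01"]
        indy = table.loc["INDY-like-01"]
        for m, sign in self.SIGNS.items():
            if sign == 0:
                assert csa[m] == 0
            else:
                assert np.sign(csa[m]) == sign
        assert np.allclose(indy.to_numpy(), -csa.to_numpy())

    def test_zero_noise_is_deterministic(self):
        a = reference_profiles(n_per_family=2, noise_sd=0.0, seed=1)
        assert np.allclose(a.loc["CsA-like-01"], a.loc["CsA-like-02"])
        b = reference_profiles(n_per_family=2, noise_sd=0.0, seed=99)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_rgb_consistent_with_class_mean(self):
        table = reference_profiles(n_per_family=2, noise_sd=3.0, seed=2)
        four = table[["omr_red", "omr_green", "omr_blue", "omr_fast_red"]]
        assert np.allclose(table["omr_rgb"], four.mean(axis=1))


def test_tracks_tsv_round_trip(tmp_path, fast_schedule, geometry):
    tracks = [simulate_track(dmso_phenotype(), fast_schedule, geometry, seed,
                             well_id=f"P1-A{seed + 1:02d}") for seed in range(3)]
    path = tmp_path / "tracks.tsv"
    lio.write_tracks_tsv(tracks, path)
    back = lio.read_tracks_tsv(path)
    assert [t.well_id for t in back] == [t.well_id for t in tracks]
    for a, b in zip(tracks, back):
        assert np.array_equal(a.moved, b.moved)
        assert np.allclose(a.x_mm, b.x_mm) and np.allclose(a.y_mm, b.y_mm)
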