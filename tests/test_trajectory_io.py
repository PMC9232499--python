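"""Track I/O, per-step kinematics and zone assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncostream import (
    Track,
    TrackTable,
    TrajectorySimConfig,
    ZoneROI,
    assign_zones,
    compute_kinematics,
    read_tracks,
    simulate_trajectories,
    summarize_speeds,
    write_tracks,
    write_tracks_xml,
)
from oncostream.trajectory_io import (
    TrackParseError,
    TrackValidationError,
    UNZONED,
)


def small_table():
    return TrackTable(
        [
            Track("a", [0.0, 10.0, 20.0], [0.0, 1.0, 1.0], [0.0, 0.0, -2.0]),
            Track("b", [0.0, 10.0], [5.0, 5.0], [5.0, 5.0]),
        ],
        frame_interval=10.0,
    )


class TestReadWrite:
    def test_csv_roundtrip_exact(self, tmp_path):
        table = small_table()
        path = tmp_path / "tracks.csv"
        write_tracks(table, path)
        back = read_tracks(path)
        assert len(back) == 2
        assert back.frame_interval == pytest.approx(10.0)
        for orig, rt in zip(table.tracks, sorted(back.tracks, key=lambda t: t.track_id)):
            np.testing.assert_allclose(rt.x, orig.x, atol=1e-6)
            np.testing.assert_allclose(rt.y, orig.y, atol=1e-6)
            np.testing.assert_allclose(rt.t, orig.t, atol=1e-6)

    def test_csv_single_track_interval_inferred(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text(
            "track_id,frame,t_min,x_um,y_um\n"
            "c1,0,0.0,1.0,2.0\nc1,1,10.0,2.0,2.0\nc1,2,20.0,3.0,2.0\n"
        )
        table = read_tracks(path)
        assert len(table) == 1
        assert table.tracks[0].n_samples == 3
        assert table.frame_interval == pytest.approx(10.0)

    def test_empty_table_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_tracks(TrackTable([]), path)
        assert path.read_text().strip() == "track_id,frame,t_min,x_um,y_um"
        assert len(read_tracks(path)) == 0

    def test_byte_stable_output(self, tmp_path):
        table, _ = simulate_trajectories(
            TrajectorySimConfig(pattern="flock", n_cells=100, n_frames=5, seed=3)
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_tracks(table, p1)
        write_tracks(table, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_column_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("track_id,frame,x_um,y_um\na,0,1,2\n")
        with pytest.raises(TrackParseError, match="t_min"):
            read_tracks(path)

    def test_bad_record_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "track_id,frame,t_min,x_um,y_um\na,0,0,1,2\na,1,10,oops,2\n"
        )
        with pytest.raises(TrackParseError, match="line 3"):
            read_tracks(path)

    def test_xml_roundtrip(self, tmp_path):
        table = small_table()
        path = tmp_path / "tracks.xml"
        write_tracks_xml(table, path)
        back = read_tracks(path)
        assert len(back) == 2
        assert back.frame_interval == pytest.approx(10.0)
        ids = {t.track_id: t for t in back.tracks}
        np.testing.assert_allclose(ids["a"].x, [0.0, 1.0, 1.0], atol=1e-6)
        np.testing.assert_allclose(ids["b"].y, [5.0, 5.0], atol=1e-6)

    def test_xml_tracks_sharing_a_spot_stay_independent(self, tmp_path):
        xml = """<?xml version="1.0"?>
<TrackMate><Model timeinterval="10.0">
<AllSpots><SpotsInFrame frame="0">
  <Spot ID="1" FRAME="0" POSITION_X="0" POSITION_Y="0"/>
  <Spot ID="2" FRAME="0" POSITION_X="5" POSITION_Y="5"/>
</SpotsInFrame><SpotsInFrame frame="1">
  <Spot ID="3" FRAME="1" POSITION_X="1" POSITION_Y="0"/>
  <Spot ID="4" FRAME="1" POSITION_X="6" POSITION_Y="5"/>
</SpotsInFrame></AllSpots>
<AllTracks>
  <Track TRACK_ID="0"><Edge SPOT_SOURCE_ID="1" SPOT_TARGET_ID="3"/></Track>
  <Track TRACK_ID="1"><Edge SPOT_SOURCE_ID="2" SPOT_TARGET_ID="4"/>
                      <Edge SPOT_SOURCE_ID="1" SPOT_TARGET_ID="2"/></Track>
</AllTracks></Model></TrackMate>"""
        path = tmp_path / "shared.xml"
        path.write_text(xml)
        table = read_tracks(path)
        assert len(table) == 2
        # spot 1 participates in both tracks without merging them
        sizes = sorted(t.n_samples for t in table.tracks)
        assert sizes == [2, 3]

    def test_xml_frames_without_interval_is_config_error(self, tmp_path):
        xml = """<TrackMate><Model>
<AllSpots><SpotsInFrame frame="0">
  <Spot ID="1" FRAME="0" POSITION_X="0" POSITION_Y="0"/>
  <Spot ID="2" FRAME="1" POSITION_X="1" POSITION_Y="0"/>
</SpotsInFrame></AllSpots>
<AllTracks><Track TRACK_ID="0">
  <Edge SPOT_SOURCE_ID="1" SPOT_TARGET_ID="2"/></Track></AllTracks>
</Model></TrackMate>"""
        path = tmp_path / "frames.xml"
        path.write_text(xml)
        from oncostream.trajectory_io import ConfigurationError

        with pytest.raises(ConfigurationError):
            read_tracks(path)
        table = read_tracks(path, frame_interval=10.0)
        np.testing.assert_allclose(table.tracks[0].t, [0.0, 10.0])


class TestKinematics:
    @pytest.mark.parametrize(
        "dxdy,expect_speed,expect_theta",
        [
            ((1.0, 0.0), 6.0, 0.0),
            ((0.0, -2.0), 12.0, 3 * np.pi / 2),
            ((-3.0, 0.0), 18.0, np.pi),
        ],
    )
    def test_step_arithmetic(self, dxdy, expect_speed, expect_theta):
        dx, dy = dxdy
        table = TrackTable(
            [Track("t", [0.0, 10.0], [0.0, dx], [0.0, dy])], frame_interval=10.0
        )
        kin = compute_kinematics(table)
        assert kin.loc[0, "speed"] == pytest.approx(expect_speed)
        assert kin.loc[0, "theta"] == pytest.approx(expect_theta)
        assert bool(kin.loc[0, "valid"])

    def test_zero_displacement_invalid(self):
        kin = compute_kinematics(small_table())
        b = kin[kin["track_id"] == "b"]
        assert not b["valid"].item()
        assert b["speed"].item() == 0.0
        assert np.isnan(b["theta"].item())

    def test_row_count_is_samples_minus_one_per_track(self, rng):
        tracks = []
        for i in range(20):
            n = rng.integers(2, 30)
            t = np.arange(n) * 10.0
            tracks.append(Track(str(i), t, rng.normal(size=n), rng.normal(size=n)))
        kin = compute_kinematics(TrackTable(tracks))
        assert len(kin) == sum(tr.n_samples - 1 for tr in tracks)

    def test_gap_uses_actual_dt(self):
        table = TrackTable(
            [Track("g", [0.0, 10.0, 40.0], [0.0, 1.0, 4.0], [0.0, 0.0, 0.0])]
        )
        kin = compute_kinematics(table)
        # 3 µm over 30 min across the gap -> 6 µm/h
        assert kin.loc[1, "speed"] == pytest.approx(6.0)

    def test_non_increasing_time_raises(self):
        with pytest.raises(TrackValidationError, match="increasing"):
            compute_kinematics(
                TrackTable([Track("x", [0.0, 10.0, 10.0], [0, 1, 2], [0, 0, 0])])
            )

    @given(phi=st.floats(0, 2 * np.pi, allow_nan=False))
    def test_rotation_equivariance(self, phi):
        rng = np.random.default_rng(7)
        n = 12
        t = np.arange(n) * 10.0
        x, y = rng.normal(size=n).cumsum(), rng.normal(size=n).cumsum()
        kin0 = compute_kinematics(TrackTable([Track("r", t, x, y)]))
        c, s = np.cos(phi), np.sin(phi)
        kin1 = compute_kinematics(
            TrackTable([Track("r", t, c * x - s * y, s * x + c * y)])
        )
        np.testing.assert_allclose(kin1["speed"], kin0["speed"], atol=1e-9)
        dtheta = np.mod(kin1["theta"] - kin0["theta"] - phi, 2 * np.pi)
        dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
        np.testing.assert_allclose(dtheta, 0.0, atol=1e-9)

    def test_reflection_preserves_speed(self):
        table = small_table()
        kin0 = compute_kinematics(table)
        refl = TrackTable(
            [Track(tr.track_id, tr.t, -tr.x, tr.y) for tr in table.tracks],
            table.frame_interval,
        )
        kin1 = compute_kinematics(refl)
        np.testing.assert_allclose(kin1["speed"], kin0["speed"], atol=1e-12)


class TestZones:
    def kin(self):
        return pd.DataFrame(
            {
                "track_id": ["a", "b", "c"],
                "t_mid": [5.0, 5.0, 5.0],
                "x_mid": [1.0, 10.0, 25.0],
                "y_mid": [1.0, 1.0, 1.0],
                "theta": [0.0, 0.0, 0.0],
                "speed": [6.0, 6.0, 6.0],
                "valid": [True, True, True],
            }
        )

    def test_half_open_upper_edge_excluded(self):
        zoned = assign_zones(self.kin(), [ZoneROI("Z", 0.0, 10.0, 0.0, 10.0)])
        inz = zoned[zoned["zone"] == "Z"]
        assert list(inz["track_id"]) == ["a"]  # x=10 excluded

    def test_overlapping_zones_duplicate_rows(self):
        rois = [ZoneROI("A", 0, 20, 0, 10), ZoneROI("B", 0, 30, 0, 10)]
        zoned = assign_zones(self.kin(), rois)
        a_rows = zoned[zoned["track_id"] == "a"]
        assert sorted(a_rows["zone"]) == ["A", "B"]

    def test_empty_roi_list_all_unzoned(self):
        zoned = assign_zones(self.kin(), [])
        assert set(zoned["zone"]) == {UNZONED}

    def test_degenerate_roi_rejected(self):
        with pytest.raises(TrackValidationError):
            ZoneROI("bad", 5.0, 5.0, 0.0, 1.0)


class TestSpeedSummary:
    def test_mean_of_two_steps(self):
        kin = compute_kinematics(
            TrackTable(
                [Track("a", [0, 10, 20], [0.0, 1.0, 3.0], [0.0, 0.0, 0.0])]
            )
        ).assign(zone="Z")
        out = summarize_speeds(kin)
        assert out["Z"]["mean"] == pytest.approx(9.0)
        assert out["Z"]["n"] == 2

    def test_all_invalid_group_reports_null_mean(self):
        kin = compute_kinematics(small_table()).assign(zone="Z")
        only_b = kin[kin["track_id"] == "b"]
        out = summarize_speeds(only_b)
        assert out["Z"]["n"] == 0
        assert out["Z"]["mean"] is None

    def test_include_stationary_flag(self):
        kin = compute_kinematics(small_table()).assign(zone="Z")
        excl = summarize_speeds(kin)["Z"]
        incl = summarize_speeds(kin, include_stationary=True)["Z"]
        assert incl["n"] == excl["n"] + 1
        assert incl["mean"] < excl["mean"]

    def test_generated_swarm_mean_speed_matches_default(self):
        # default swarm speed is the reported core value 6.27 µm/h
        cfg = TrajectorySimConfig(pattern="swarm", n_cells=100, n_frames=101, seed=11)
        table, truth = simulate_trajectories(cfg)
        kin = compute_kinematics(table).assign(zone="all")
        out = summarize_speeds(kin)["all"]
        # a few steps are lost where tracks split at the window edge
        assert out["n"] >= 0.95 * 100 * 100
        assert out["mean"] == pytest.approx(truth["speed_mean_um_per_h"], rel=0.05)
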