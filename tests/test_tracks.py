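"""Track data model, table I/O round trips, and filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ivtrack as iv
from ivtrack.errors import FormatError, TrackValidationError
from ivtrack.tracks import infer_frame_interval


def _write(tmp_path, text, name="tracks.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestTrackValidation:
    def test_lengths_must_match(self):
        with pytest.raises(TrackValidationError):
            iv.Track("a", [0.0, 0.5], [[0.0, 0.0]])

    def test_times_strictly_increasing(self):
        with pytest.raises(TrackValidationError, match="strictly increasing"):
            iv.Track("a", [0.0, 0.5, 0.5], np.zeros((3, 2)))

    def test_nonfinite_coordinate_rejected(self):
        with pytest.raises(TrackValidationError, match="non-finite"):
            iv.Track("a", [0.0, 0.5], [[0.0, 0.0], [np.nan, 1.0]])

    def test_dimensionality_2_or_3(self):
        with pytest.raises(TrackValidationError):
            iv.Track("a", [0.0], np.zeros((1, 4)))

    def test_duplicate_ids_rejected(self):
        t = iv.Track("a", [0.0], np.zeros((1, 2)))
        with pytest.raises(TrackValidationError, match="duplicate"):
            iv.TrackSet((t, t))

    def test_mixed_dimensionality_rejected(self):
        t2 = iv.Track("a", [0.0], np.zeros((1, 2)))
        t3 = iv.Track("b", [0.0], np.zeros((1, 3)))
        with pytest.raises(TrackValidationError, match="dimensionality"):
            iv.TrackSet((t2, t3))

    def test_frame_interval_tolerance(self):
        t = iv.Track("a", [0.0, 0.5, 1.0 + 1e-3], np.zeros((3, 2)))
        with pytest.raises(TrackValidationError, match="frame interval"):
            iv.TrackSet((t,), frame_interval=0.5)

    def test_project_2d_drops_z(self):
        t = iv.Track("a", [0.0, 0.5], [[0, 0, 5], [1, 1, 9]])
        flat = t.project_2d()
        assert flat.ndim == 2
        np.testing.assert_array_equal(flat.positions, [[0, 0], [1, 1]])


class TestReadTracks:
    def test_canonical_round_numbers(self, tmp_path):
        path = _write(
            tmp_path,
            "track_id,t_min,x_um,y_um\n"
            "a,0.0,0.0,0.0\na,0.5,1.0,0.0\na,1.0,1.0,1.0\n"
            "b,0.0,5.0,5.0\nb,0.5,6.0,5.0\nb,1.0,7.0,5.0\n",
        )
        ts = iv.read_tracks(path)
        assert len(ts) == 2
        assert all(t.n_points == 3 for t in ts)
        assert ts.frame_interval == 0.5

    def test_missing_column_names_it(self, tmp_path):
        path = _write(tmp_path, "track_id,t_min,x_um\na,0,0\n")
        with pytest.raises(FormatError, match="y_um"):
            iv.read_tracks(path)

    def test_duplicate_track_time_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "track_id,t_min,x_um,y_um\na,0.0,0,0\na,0.0,1,1\n",
        )
        with pytest.raises(TrackValidationError, match="'a'"):
            iv.read_tracks(path)

    def test_mixed_dimensionality_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "track_id,t_min,x_um,y_um,z_um\na,0.0,0,0,1\na,0.5,1,1,\n",
        )
        with pytest.raises(TrackValidationError, match="mixed dimensionality"):
            iv.read_tracks(path)

    def test_inconsistent_label_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "track_id,t_min,x_um,y_um,region\na,0.0,0,0,periphery\na,0.5,1,1,parenchyma\n",
        )
        with pytest.raises(TrackValidationError, match="region"):
            iv.read_tracks(path)

    def test_imaris_dialect(self, tmp_path):
        path = _write(
            tmp_path,
            "TrackID,Time,Position X,Position Y\n7,0.0,1.5,2.5\n7,0.5,2.0,2.5\n",
        )
        ts = iv.read_tracks(path, iv.IMARIS)
        assert ts.get("7").positions[1, 0] == 2.0

    def test_rows_sorted_by_time(self, tmp_path):
        path = _write(
            tmp_path,
            "track_id,t_min,x_um,y_um\na,0.5,1,0\na,0.0,0,0\n",
        )
        ts = iv.read_tracks(path)
        np.testing.assert_array_equal(ts.get("a").times, [0.0, 0.5])


class TestWriteTracks:
    def test_empty_set_header_only(self, tmp_path):
        path = iv.write_tracks(iv.TrackSet(()), tmp_path / "empty.csv")
        assert path.read_text().strip() == "track_id,t_min,x_um,y_um"

    def test_single_point_single_row(self, tmp_path):
        ts = iv.TrackSet((iv.Track("a", [0.0], [[1.0, 2.0]]),))
        path = iv.write_tracks(ts, tmp_path / "one.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2

    @given(
        data=st.lists(
            st.tuples(
                st.integers(2, 6),  # n_points
                st.floats(-1e3, 1e3, allow_nan=False).map(float),
            ),
            min_size=1,
            max_size=5,
        ),
        seed=st.integers(0, 2**20),
    )
    def test_round_trip_identity(self, tmp_path, data, seed):
        """write_tracks then read_tracks reproduces coordinates bit-exactly."""
        rng = np.random.default_rng(seed)
        tracks = []
        for i, (n, offset) in enumerate(data):
            tracks.append(
                iv.Track(
                    f"t{i}",
                    np.arange(n) * 0.5,
                    rng.normal(scale=100.0, size=(n, 2)) + offset,
                    labels={"group": f"g{i % 2}", "day": "1"},
                )
            )
        ts = iv.TrackSet(tuple(tracks), frame_interval=0.5)
        path = iv.write_tracks(ts, tmp_path / "rt.csv")
        back = iv.read_tracks(path)
        assert len(back) == len(ts)
        for t in ts:
            b = back.get(t.track_id)
            np.testing.assert_array_equal(b.times, t.times)
            np.testing.assert_array_equal(b.positions, t.positions)
            assert b.labels == t.labels
        assert back.frame_interval == ts.frame_interval


class TestFilterTracks:
    def _set(self):
        return iv.TrackSet(
            (
                iv.Track("short", [0.0], np.zeros((1, 2))),
                iv.Track(
                    "peri", [0.0, 0.5], np.ones((2, 2)),
                    labels={"region": "periphery"},
                ),
                iv.Track(
                    "para", [0.0, 0.5], np.ones((2, 2)) * 2,
                    labels={"region": "parenchyma"},
                ),
            )
        )

    def test_min_points_removes_singletons(self):
        res = iv.filter_tracks(self._set(), min_points=2)
        assert {t.track_id for t in res.trackset} == {"peri", "para"}
        assert res.n_removed == 1

    def test_label_query_mapping(self):
        res = iv.filter_tracks(self._set(), label_query={"region": "periphery"})
        assert [t.track_id for t in res.trackset] == ["peri"]

    def test_label_query_predicate(self):
        res = iv.filter_tracks(
            self._set(), label_query=lambda lab: lab.get("region") == "parenchyma"
        )
        assert [t.track_id for t in res.trackset] == ["para"]

    def test_counts_conserved_and_input_unchanged(self):
        ts = self._set()
        res = iv.filter_tracks(ts, min_points=2, label_query={"region": "periphery"})
        assert len(res.trackset) + res.n_removed == len(ts)
        assert len(ts) == 3  # original untouched


def test_infer_frame_interval():
    a = iv.Track("a", [0.0, 0.5, 1.0], np.zeros((3, 2)))
    b = iv.Track("b", [0.0, 0.7], np.zeros((2, 2)))
    assert infer_frame_interval((a,)) == 0.5
    assert infer_frame_interval((a, b)) is None
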