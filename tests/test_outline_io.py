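"""Outline reading, validation, reorientation, resampling and tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphodisp import (
    Dataset,
    Outline,
    read_chaincode,
    read_coeff_table,
    read_tps,
    resample_outline,
    write_coeff_table,
    write_tps,
)
from morphodisp.outline_io import (
    LabelError,
    ParseError,
    ValidationError,
    perimeter,
    signed_area,
    write_labels,
)
from .conftest import circle_points, random_smooth_outline

SQUARE_CCW = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
SQUARE_CW = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])


class TestOutlineType:
    def test_clockwise_input_is_reoriented_and_flagged(self):
        # shoelace oracle: SQUARE_CW has signed area -1
        assert signed_area(SQUARE_CW) == -1.0
        o = Outline("cw", SQUARE_CW)
        assert signed_area(o.points) > 0
        assert "reoriented-ccw" in o.provenance

    def test_reorientation_is_idempotent(self):
        o = Outline("ccw", SQUARE_CCW)
        o2 = Outline("again", o.points)
        assert np.array_equal(o.points, o2.points)
        assert "reoriented" not in o2.provenance

    def test_consecutive_duplicates_rejected(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        with pytest.raises(ValidationError, match="duplicate"):
            Outline("dup", pts)

    def test_self_intersection_is_an_error_not_a_repair(self):
        bowtie = np.array(
            [[0, 0], [1, 1], [1, 0], [0, 1], [-0.5, 0.8], [-0.5, 0.2], [-0.2, 0.1], [-0.1, 0.05]],
            dtype=float,
        )
        with pytest.raises(ValidationError, match="self-intersect"):
            Outline("bow", bowtie).validate()

    def test_validate_enforces_minimum_distinct_points(self, unit_square):
        with pytest.raises(ValidationError, match="distinct points"):
            unit_square.validate(min_points=8)

    def test_dataset_rejects_duplicate_ids(self, unit_square):
        with pytest.raises(ValidationError, match="duplicate specimen ids"):
            Dataset([unit_square, Outline("square", SQUARE_CCW)])


class TestTps:
    def _write(self, tmp_path, text):
        p = tmp_path / "f.tps"
        p.write_text(text)
        return p

    def test_minimal_record(self, tmp_path):
        p = self._write(
            tmp_path, "LM=0\nCURVES=1\nPOINTS=4\n0 0\n1 0\n1 1\n0 1\nID=sp1\n"
        )
        ds = read_tps(p)
        assert len(ds) == 1
        o = ds.outlines[0]
        assert o.specimen_id == "sp1" and o.n_points == 4

    def test_declared_point_count_mismatch(self, tmp_path):
        p = self._write(tmp_path, "LM=0\nCURVES=1\nPOINTS=100\n0 0\n1 0\n1 1\nID=sp1\n")
        with pytest.raises(ParseError, match="POINTS=100"):
            read_tps(p)

    def test_clockwise_record_reoriented_with_provenance(self, tmp_path):
        body = "\n".join(f"{x} {y}" for x, y in SQUARE_CW)
        p = self._write(tmp_path, f"LM=0\nCURVES=1\nPOINTS=4\n{body}\nID=cw\n")
        o = read_tps(p).outlines[0]
        assert signed_area(o.points) > 0
        assert "reoriented-ccw" in o.provenance

    def test_image_and_scale_lines_tolerated(self, tmp_path):
        p = self._write(
            tmp_path,
            "LM=0\nIMAGE=x.jpg\nCURVES=1\nPOINTS=4\n0 0\n1 0\n1 1\n0 1\nSCALE=0.1\nID=sp1\n",
        )
        assert len(read_tps(p)) == 1

    def test_label_join_and_missing_label(self, tmp_path):
        p = self._write(tmp_path, "LM=0\nCURVES=1\nPOINTS=4\n0 0\n1 0\n1 1\n0 1\nID=sp1\n")
        labels = pd.DataFrame(
            {"specimen_id": ["sp1"], "group": ["owllions"], "time_slice": ["extant"]}
        )
        o = read_tps(p, labels=labels).outlines[0]
        assert (o.group, o.time_slice) == ("owllions", "extant")
        with pytest.raises(LabelError, match="sp1"):
            read_tps(p, labels=labels.iloc[:0], require_labels=True)

    def test_roundtrip_preserves_coordinates_and_labels(self, tmp_path, rng):
        outlines = []
        for i in range(3):
            o = random_smooth_outline(rng, n=40)
            outlines.append(
                Outline(f"sp{i}", o.points, group="g", time_slice="cretaceous")
            )
        ds = Dataset(outlines)
        write_tps(ds, tmp_path / "o.tps")
        write_labels(ds, tmp_path / "l.csv")
        back = read_tps(tmp_path / "o.tps", labels=tmp_path / "l.csv")
        for a, b in zip(ds, back):
            assert a.specimen_id == b.specimen_id
            assert (a.group, a.time_slice) == (b.group, b.time_slice)
            np.testing.assert_allclose(a.points, b.points, atol=5e-7)


class TestChainCode:
    def test_unit_square_decodes(self, tmp_path):
        # Freeman directions hand-decoded: 0=+x, 2=+y, 4=-x, 6=-y
        p = tmp_path / "c.chc"
        p.write_text("sq 0 0 0 2 4 6 -1\n")
        o = read_chaincode(p).outlines[0]
        np.testing.assert_array_equal(o.points, SQUARE_CCW)

    def test_digit_out_of_range(self, tmp_path):
        p = tmp_path / "c.chc"
        p.write_text("bad 0 0 0 2 9 6 -1\n")
        with pytest.raises(ParseError, match=r"\[9\]"):
            read_chaincode(p)

    def test_open_chain_rejected(self, tmp_path):
        p = tmp_path / "c.chc"
        p.write_text("open 0 0 0 2 4 -1\n")
        with pytest.raises(ValidationError, match="open chain"):
            read_chaincode(p)


class TestResample:
    def test_square_quarters_hit_corners(self, unit_square):
        out = resample_outline(unit_square, 4)
        np.testing.assert_allclose(out.points, SQUARE_CCW, atol=1e-12)

    def test_circle_radii_preserved(self):
        o = Outline("c", circle_points(1000))
        out = resample_outline(o, 100)
        radii = np.hypot(*out.points.T)
        np.testing.assert_allclose(radii, 1.0, atol=1e-3)

    def test_perimeter_preserved_within_one_percent(self, rng):
        for _ in range(5):
            o = random_smooth_outline(rng)
            out = resample_outline(o, 200)
            assert abs(perimeter(out.points) - perimeter(o.points)) < 0.01 * perimeter(o.points)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        o = random_smooth_outline(np.random.default_rng(5), n=150)
        base = resample_outline(o, 64).points
        scaled = resample_outline(Outline("s", o.points * scale), 64).points
        np.testing.assert_allclose(scaled, base * scale, atol=1e-9 * scale)

    def test_zero_perimeter_impossible_but_small_k_rejected(self, unit_square):
        with pytest.raises(ValueError):
            resample_outline(unit_square, 2)


class TestCoeffTable:
    def _matrix(self, n_spec=2, n_harm=20):
        rng = np.random.default_rng(1)
        cols = ["d1"] + [f"{c}{h}" for h in range(2, n_harm + 1) for c in "abcd"]
        df = pd.DataFrame(rng.normal(size=(n_spec, len(cols))), columns=cols)
        meta = pd.DataFrame(
            {
                "specimen_id": [f"sp{i}" for i in range(n_spec)],
                "group": ["g"] * n_spec,
                "time_slice": ["extant"] * n_spec,
            }
        )
        return pd.concat([meta, df], axis=1)

    def test_shape_two_specimens_twenty_harmonics(self, tmp_path):
        m = self._matrix()
        write_coeff_table(m, tmp_path / "c.csv")
        back = read_coeff_table(tmp_path / "c.csv")
        assert back.shape == (2, 3 + 77)

    def test_roundtrip_to_twelve_significant_digits(self, tmp_path):
        m = self._matrix()
        write_coeff_table(m, tmp_path / "c.csv")
        back = read_coeff_table(tmp_path / "c.csv")
        num = m.columns[3:]
        np.testing.assert_allclose(
            back[num].to_numpy(), m[num].to_numpy(), rtol=1e-11
        )

    def test_empty_dataset_gives_header_only(self, tmp_path):
        m = self._matrix(n_spec=0)
        write_coeff_table(m, tmp_path / "c.csv")
        text = (tmp_path / "c.csv").read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("specimen_id,group,time_slice,d1")

    def test_duplicate_ids_rejected(self, tmp_path):
        m = self._matrix()
        m.loc[1, "specimen_id"] = "sp0"
        with pytest.raises(ValidationError, match="duplicate"):
            write_coeff_table(m, tmp_path / "c.csv")
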