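"""Format readers/writers: round-trip identity plus independent
struct-level oracles written against the published layouts (not the package
implementation)."""

import struct

import numpy as np
import pytest

from nmrdesk.core import (AcquisitionMeta, AxisCalibration, NUSSchedule,
                          Peak, PeakList, Spectrum)
from nmrdesk.formats import (NotBrukerError, NotFt2Error, NotUcsfError,
                             PeakListFormatError, TotxtDialectError,
                             read_bruker, read_ft2, read_nuslist,
                             read_peaklist, read_topspin_txt, read_ucsf,
                             write_bruker, write_ft2, write_nuslist,
                             write_peaklist, write_topspin_txt, write_ucsf)
from nmrdesk.formats.bruker import TruncatedDataError
from nmrdesk.synthetic import GroundTruth, TruthPeak, generate_fid


def _f32(spec: Spectrum) -> Spectrum:
    """Cast a spectrum's matrices to float32 values (the on-disk precision)
    so binary round trips are bit-exact."""
    cast = lambda m: None if m is None else m.astype(np.float32).astype(float)
    return Spectrum(data_real=cast(spec.data_real),
                    axis_direct=spec.axis_direct,
                    axis_indirect=spec.axis_indirect,
                    data_imag_direct=cast(spec.data_imag_direct),
                    data_imag_indirect=cast(spec.data_imag_indirect),
                    data_imag_both=cast(spec.data_imag_both))


@pytest.fixture
def spectrum_f32(random_spectrum):
    return _f32(random_spectrum)


# ------------------------------------------------------------------ Bruker

class TestBruker:
    @pytest.mark.parametrize("data_type,byte_order", [
        ("float64", "little"), ("float64", "big"),
        ("int32", "little"), ("int32", "big")])
    def test_roundtrip_identity(self, tmp_path, hsqc_meta, data_type,
                                byte_order):
        meta = AcquisitionMeta(**{**hsqc_meta.__dict__,
                                  "data_type": data_type,
                                  "byte_order": byte_order})
        truth = GroundTruth(peaks=[TruthPeak(8.0, 115.0, 1e5, 30, 15)],
                            acquisition=meta)
        td = generate_fid(truth)
        if data_type == "int32":
            td.data = np.round(td.data.real) + 1j * np.round(td.data.imag)
        write_bruker(td, meta, str(tmp_path / "fx"))
        td2, meta2 = read_bruker(str(tmp_path / "fx"))
        assert np.array_equal(td.data, td2.data)
        assert meta2.sw_direct_hz == meta.sw_direct_hz
        assert meta2.data_type == data_type
        assert meta2.byte_order == byte_order

    def test_byteswapped_int32_against_struct_oracle(self, tmp_path,
                                                     hsqc_meta):
        """Oracle: decode the big-endian ser with the struct module."""
        meta = AcquisitionMeta(**{**hsqc_meta.__dict__, "data_type": "int32",
                                  "byte_order": "big",
                                  "n_complex_direct": 8,
                                  "n_complex_indirect": 2})
        truth = GroundTruth(peaks=[TruthPeak(8.0, 115.0, 1e6, 100, 50)],
                            acquisition=meta)
        td = generate_fid(truth)
        td.data = np.round(td.data.real) + 1j * np.round(td.data.imag)
        write_bruker(td, meta, str(tmp_path / "fx"))
        raw = (tmp_path / "fx" / "ser").read_bytes()
        n = len(raw) // 4
        values = struct.unpack(f">{n}i", raw)
        oracle = np.asarray(values, dtype=float)
        oracle = oracle.reshape(-1, 2)[:, 0] + 1j * oracle.reshape(-1, 2)[:, 1]
        td2, _ = read_bruker(str(tmp_path / "fx"))
        assert np.array_equal(td2.data.ravel(), oracle)

    def test_trailing_bytes_error(self, tmp_path, three_peak_td, hsqc_meta):
        write_bruker(three_peak_td, hsqc_meta, str(tmp_path / "fx"))
        with open(tmp_path / "fx" / "ser", "ab") as fh:
            fh.write(b"\x00" * 7)
        with pytest.raises(TruncatedDataError,
                           match="truncated or inconsistent"):
            read_bruker(str(tmp_path / "fx"))

    def test_missing_files(self, tmp_path):
        with pytest.raises(NotBrukerError, match="not a Bruker dataset"):
            read_bruker(str(tmp_path))

    def test_group_delay_recorded_not_corrected(self, tmp_path, hsqc_meta):
        meta = AcquisitionMeta(**{**hsqc_meta.__dict__, "group_delay": 67.98})
        truth = GroundTruth(peaks=[TruthPeak(8.0, 115.0, 1.0, 30, 15)],
                            acquisition=meta)
        td = generate_fid(truth)
        write_bruker(td, meta, str(tmp_path / "fx"))
        _, meta2 = read_bruker(str(tmp_path / "fx"))
        assert meta2.group_delay == pytest.approx(67.98)

    def test_pseudo3d_plane_count_inferred(self, tmp_path, hsqc_meta):
        meta = AcquisitionMeta(**{**hsqc_meta.__dict__, "n_planes": 3})
        truth = GroundTruth(peaks=[TruthPeak(8.0, 115.0, 1.0, 30, 15)],
                            acquisition=meta)
        td = generate_fid(truth)
        write_bruker(td, meta, str(tmp_path / "fx"))
        td2, meta2 = read_bruker(str(tmp_path / "fx"))
        assert meta2.n_planes == 3
        assert td2.n_planes == 3


# --------------------------------------------------------------------- ft2

# word indices per the published fdata layout — kept independent of the
# package's own table on purpose
_ORACLE_WORDS = {"FDSIZE": 99, "FDSPECNUM": 219, "FDF2SW": 100,
                 "FDF2ORIG": 101, "FDF2OBS": 119, "FDF1SW": 229,
                 "FDF1ORIG": 249, "FDF1OBS": 218, "FDFLTORDER": 2,
                 "FDDIMCOUNT": 9, "FDF2QUADFLAG": 56, "FDF1QUADFLAG": 55}


def _oracle_read_header(path):
    with open(path, "rb") as fh:
        raw = fh.read(2048)
    vals = struct.unpack("<512f", raw)
    return {k: vals[i] for k, i in _ORACLE_WORDS.items()}


class TestFt2:
    def test_roundtrip_real(self, tmp_path, spectrum_f32):
        path = str(tmp_path / "a.ft2")
        write_ft2(spectrum_f32, path)
        back = read_ft2(path)
        assert np.array_equal(back.data_real, spectrum_f32.data_real)
        for ax_a, ax_b in [(back.axis_direct, spectrum_f32.axis_direct),
                           (back.axis_indirect, spectrum_f32.axis_indirect)]:
            assert ax_a.n_points == ax_b.n_points
            assert ax_a.sw_hz == pytest.approx(ax_b.sw_hz, rel=1e-6)
            assert ax_a.origin_hz == pytest.approx(ax_b.origin_hz, rel=1e-6)

    def test_roundtrip_hypercomplex(self, tmp_path, small_axes):
        ax_d, ax_i = small_axes
        rng = np.random.default_rng(7)
        mats = [rng.normal(size=(1, ax_i.n_points, ax_d.n_points))
                .astype(np.float32).astype(float) for _ in range(4)]
        spec = Spectrum(data_real=mats[0], axis_direct=ax_d,
                        axis_indirect=ax_i, data_imag_direct=mats[1],
                        data_imag_indirect=mats[2], data_imag_both=mats[3])
        path = str(tmp_path / "b.ft2")
        write_ft2(spec, path)
        back = read_ft2(path)
        assert np.array_equal(back.data_real, mats[0])
        assert np.array_equal(back.data_imag_direct, mats[1])
        assert np.array_equal(back.data_imag_indirect, mats[2])
        assert np.array_equal(back.data_imag_both, mats[3])

    def test_header_against_struct_oracle(self, tmp_path, spectrum_f32):
        path = str(tmp_path / "c.ft2")
        write_ft2(spectrum_f32, path)
        h = _oracle_read_header(path)
        assert h["FDFLTORDER"] == pytest.approx(2.345)
        assert h["FDDIMCOUNT"] == 2.0
        assert int(h["FDSIZE"]) == spectrum_f32.axis_direct.n_points
        assert int(h["FDSPECNUM"]) == spectrum_f32.axis_indirect.n_points
        assert h["FDF2SW"] == pytest.approx(
            spectrum_f32.axis_direct.sw_hz, rel=1e-6)
        assert h["FDF2OBS"] == pytest.approx(
            spectrum_f32.axis_direct.obs_mhz, rel=1e-6)
        assert h["FDF2ORIG"] == pytest.approx(
            spectrum_f32.axis_direct.origin_hz, rel=1e-6)
        assert h["FDF1SW"] == pytest.approx(
            spectrum_f32.axis_indirect.sw_hz, rel=1e-6)
        assert int(h["FDF2QUADFLAG"]) == 1  # real-only
        assert int(h["FDF1QUADFLAG"]) == 1

    def test_short_file_error(self, tmp_path):
        path = tmp_path / "short.ft2"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(NotFt2Error, match="not an ft2 file"):
            read_ft2(str(path))

    def test_bad_order_word(self, tmp_path):
        path = tmp_path / "bad.ft2"
        path.write_bytes(b"\x01\x02\x03\x04" * 600)
        with pytest.raises(NotFt2Error):
            read_ft2(str(path))

    def test_multiplane_roundtrip(self, tmp_path, small_axes):
        ax_d, ax_i = small_axes
        rng = np.random.default_rng(3)
        data = rng.normal(size=(4, ax_i.n_points, ax_d.n_points))
        data = data.astype(np.float32).astype(float)
        spec = Spectrum(data_real=data, axis_direct=ax_d, axis_indirect=ax_i)
        path = str(tmp_path / "p.ft2")
        write_ft2(spec, path)
        back = read_ft2(path)
        assert back.n_planes == 4
        assert np.array_equal(back.data_real, data)


# -------------------------------------------------------------------- ucsf

def _oracle_read_ucsf(path):
    """Independent tile reassembly from the published ucsf layout."""
    with open(path, "rb") as fh:
        raw = fh.read()
    assert raw[:8] == b"UCSF NMR"
    ndim = raw[10]
    axes = []
    for d in range(ndim):
        off = 180 + d * 128
        npts = struct.unpack(">i", raw[off + 8: off + 12])[0]
        tile = struct.unpack(">i", raw[off + 16: off + 20])[0]
        axes.append((npts, tile))
    (n1, t1), (n2, t2) = axes
    data = np.frombuffer(raw[180 + ndim * 128:], dtype=">f4")
    ntr, ntc = -(-n1 // t1), -(-n2 // t2)
    out = np.zeros((ntr * t1, ntc * t2))
    pos = 0
    for br in range(ntr):
        for bc in range(ntc):
            block = data[pos: pos + t1 * t2].reshape(t1, t2)
            out[br * t1:(br + 1) * t1, bc * t2:(bc + 1) * t2] = block
            pos += t1 * t2
    return out[:n1, :n2]


class TestUcsf:
    def test_roundtrip_non_tile_multiple(self, tmp_path, small_axes):
        ax_d, ax_i = small_axes  # 96 x 64: not multiples of 128
        rng = np.random.default_rng(11)
        data = rng.normal(size=(ax_i.n_points, ax_d.n_points))
        data = data.astype(np.float32).astype(float)
        spec = Spectrum(data_real=data[None], axis_direct=ax_d,
                        axis_indirect=ax_i)
        path = str(tmp_path / "a.ucsf")
        write_ucsf(spec, path, tile=40)  # forces padding on both axes
        back = read_ucsf(path)
        assert np.array_equal(back.data_real[0], data)

    def test_against_independent_reader(self, tmp_path, small_axes):
        ax_d, ax_i = small_axes
        rng = np.random.default_rng(12)
        data = rng.normal(size=(ax_i.n_points, ax_d.n_points))
        data = data.astype(np.float32).astype(float)
        spec = Spectrum(data_real=data[None], axis_direct=ax_d,
                        axis_indirect=ax_i)
        path = str(tmp_path / "b.ucsf")
        write_ucsf(spec, path, tile=33)
        oracle = _oracle_read_ucsf(path)
        assert np.array_equal(oracle, data)

    def test_3d_rejected(self, tmp_path):
        head = bytearray(180 + 3 * 128 + 8)
        head[0:10] = b"UCSF NMR\x00\x00"
        head[10] = 3
        path = tmp_path / "c.ucsf"
        path.write_bytes(bytes(head))
        with pytest.raises(NotUcsfError, match="only 2D supported"):
            read_ucsf(str(path))

    def test_bad_magic(self, tmp_path):
        path = tmp_path / "d.ucsf"
        path.write_bytes(b"NOT A UCSF FILE" + b"\x00" * 400)
        with pytest.raises(NotUcsfError, match="not a ucsf"):
            read_ucsf(str(path))

    def test_imag_dropped_with_warning(self, tmp_path, small_axes, caplog):
        ax_d, ax_i = small_axes
        z = np.zeros((1, ax_i.n_points, ax_d.n_points))
        spec = Spectrum(data_real=z, axis_direct=ax_d, axis_indirect=ax_i,
                        data_imag_direct=z.copy())
        import logging
        with caplog.at_level(logging.WARNING, logger="nmrdesk.formats.sparky"):
            write_ucsf(spec, str(tmp_path / "e.ucsf"))
        assert any("dropping imaginary" in r.message for r in caplog.records)

    def test_ppm_map_agrees_with_ft2(self, tmp_path, spectrum_f32):
        """One spectrum written to both formats: ppm scales agree."""
        ft2_path = str(tmp_path / "x.ft2")
        ucsf_path = str(tmp_path / "x.ucsf")
        write_ft2(spectrum_f32, ft2_path)
        write_ucsf(spectrum_f32, ucsf_path)
        a = read_ft2(ft2_path)
        b = read_ucsf(ucsf_path)
        for ax_a, ax_b in [(a.axis_direct, b.axis_direct),
                           (a.axis_indirect, b.axis_indirect)]:
            assert np.allclose(ax_a.ppm_scale, ax_b.ppm_scale, atol=1e-6)


# ------------------------------------------------------------------- totxt

class TestTotxt:
    def test_handwritten_fixture(self, tmp_path):
        text = ("# F1LEFT = 10.0 ppm. F1RIGHT = 8.0 ppm.\n"
                "# F2LEFT = 5.0 ppm. F2RIGHT = 3.0 ppm.\n"
                "# NROWS = 2 ( = number of points along the F1 axis)\n"
                "# NCOLS = 3 ( = number of points along the F2 axis)\n"
                "# row = 0\n1.5\n2.5\n3.5\n# row = 1\n-1.0\n0.0\n4.25\n")
        path = tmp_path / "a.txt"
        path.write_text(text)
        spec = read_topspin_txt(str(path))
        assert np.array_equal(spec.data_real[0],
                              [[1.5, 2.5, 3.5], [-1.0, 0.0, 4.25]])
        assert spec.axis_indirect.ppm_of_point(0) == pytest.approx(10.0)
        assert spec.axis_indirect.ppm_of_point(1) == pytest.approx(8.0)
        assert spec.axis_direct.ppm_of_point(2) == pytest.approx(3.0)

    def test_cross_format_consistency(self, tmp_path, spectrum_f32):
        """Same source written as ft2 and totxt agrees to 6 significant
        digits in values and ppm."""
        write_ft2(spectrum_f32, str(tmp_path / "s.ft2"))
        write_topspin_txt(spectrum_f32, str(tmp_path / "s.txt"))
        a = read_ft2(str(tmp_path / "s.ft2"))
        b = read_topspin_txt(str(tmp_path / "s.txt"))
        assert np.allclose(a.data_real, b.data_real, rtol=1e-6, atol=0)
        assert np.allclose(a.axis_direct.ppm_scale, b.axis_direct.ppm_scale,
                           rtol=1e-6, atol=2e-5)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(TotxtDialectError, match="unrecognized totxt"):
            read_topspin_txt(str(path))

    def test_missing_range_header(self, tmp_path):
        path = tmp_path / "norange.txt"
        path.write_text("# NROWS = 2\n# NCOLS = 2\n1\n2\n3\n4\n")
        with pytest.raises(TotxtDialectError):
            read_topspin_txt(str(path))


# -------------------------------------------------------------- peak lists

class TestPeakLists:
    def _peaks(self, n_z=4):
        return PeakList([
            Peak(x_ppm=8.1234, y_ppm=120.4567, height=1.5e5, sigma_x=1.2,
                 sigma_y=1.1, gamma_x=0.4, gamma_y=0.3, label="A1",
                 plane_heights=[1.0, 0.51, 0.26, 0.13][:n_z]),
            Peak(x_ppm=7.0001, y_ppm=110.9999, height=-2.0e4,
                 sigma_x=2.0, sigma_y=1.0, gamma_x=0.0, gamma_y=0.0,
                 plane_heights=[1.0, 0.4, 0.2, 0.1][:n_z]),
            Peak(x_ppm=6.5, y_ppm=105.25, height=3.33e3, sigma_x=1.0,
                 sigma_y=1.0, gamma_x=1.0, gamma_y=1.0, label="G45",
                 plane_heights=[1.0, 0.9, 0.8, 0.7][:n_z]),
        ])

    def test_tab_roundtrip_with_planes(self, tmp_path):
        peaks = self._peaks()
        path = str(tmp_path / "p.tab")
        write_peaklist(peaks, path)
        text = open(path).read()
        for col in ("Z_A0", "Z_A1", "Z_A2", "Z_A3"):
            assert col in text
        back = read_peaklist(path)
        assert len(back) == 3
        for a, b in zip(peaks, back):
            assert b.x_ppm == pytest.approx(a.x_ppm, abs=1e-4)
            assert b.y_ppm == pytest.approx(a.y_ppm, abs=1e-4)
            assert b.label == a.label
            assert b.plane_heights == pytest.approx(a.plane_heights,
                                                    rel=1e-4)

    def test_sparky_drops_plane_heights(self, tmp_path, caplog):
        import logging
        path = str(tmp_path / "p.list")
        with caplog.at_level(logging.WARNING,
                             logger="nmrdesk.formats.peaklist"):
            write_peaklist(self._peaks(), path, dialect="sparky_list")
        assert any("dropping Z_A" in r.message for r in caplog.records)
        back = read_peaklist(path, dialect="sparky_list")
        assert len(back) == 3
        assert back[0].plane_heights == []
        assert back[0].y_ppm == pytest.approx(120.4567, abs=1e-4)
        assert back[0].x_ppm == pytest.approx(8.1234, abs=1e-4)

    def test_reordered_vars_parse_by_name(self, tmp_path):
        """Oracle: hand-built expected records."""
        text = ("VARS Y_PPM HEIGHT X_PPM ASS\n"
                "FORMAT %9.4f %+e %9.4f %s\n"
                " 120.5000 +1.0e+05 8.2000 Q7\n"
                " 110.0000 -3.0e+04 7.1000 -\n")
        path = tmp_path / "r.tab"
        path.write_text(text)
        back = read_peaklist(str(path))
        assert back[0].x_ppm == pytest.approx(8.2)
        assert back[0].y_ppm == pytest.approx(120.5)
        assert back[0].height == pytest.approx(1.0e5)
        assert back[0].label == "Q7"
        assert back[1].label == ""
        assert back[1].height == pytest.approx(-3.0e4)

    def test_unknown_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text("VARS FOO BAR\nFORMAT %s %s\n1 2\n")
        with pytest.raises(PeakListFormatError, match="unrecognized peak"):
            read_peaklist(str(path))

    def test_heights_scientific_6_digits(self, tmp_path):
        path = str(tmp_path / "h.tab")
        write_peaklist(self._peaks(), path)
        line = [ln for ln in open(path) if "A1" in ln.split()][0]
        assert "+1.50000e+05" in line


# --------------------------------------------------------------- nuslists

class TestNuslist:
    def test_parse_dedupe(self, tmp_path):
        path = tmp_path / "n.lst"
        path.write_text("0\n3\n1\n3\n")
        sched = read_nuslist(str(path), full_size=8)
        assert sched.sampled_increments == (0, 1, 3)

    def test_complete(self, tmp_path):
        path = tmp_path / "n.lst"
        path.write_text("\n".join(str(i) for i in range(8)))
        assert read_nuslist(str(path), full_size=8).is_complete

    def test_out_of_grid(self, tmp_path):
        path = tmp_path / "n.lst"
        path.write_text("0\n12\n")
        with pytest.raises(ValueError, match="exceeds declared grid"):
            read_nuslist(str(path), full_size=8)

    def test_second_column_ignored(self, tmp_path):
        path = tmp_path / "n.lst"
        path.write_text("0 0\n2 1\n5 2\n")
        sched = read_nuslist(str(path), full_size=8)
        assert sched.sampled_increments == (0, 2, 5)

    def test_roundtrip(self, tmp_path):
        sched = NUSSchedule(sampled_increments=(0, 2, 5), full_size=8)
        path = str(tmp_path / "n.lst")
        write_nuslist(sched, path)
        assert read_nuslist(path, 8) == sched
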