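"""mzML round trip, RT-window averaging, peak matching, tables and cache."""

import numpy as np
import pytest

from n15quant import spectra_io as sio
from n15quant.simulate import SimConfig, generate_experiment


def make_scan(rt, peaks):
    mz, inten = zip(*peaks)
    return sio.Scan(rt=rt, mz=np.array(mz), intensity=np.array(inten))


class TestMzml:
    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        scans = [
            sio.Scan(rt=float(i), mz=np.sort(rng.uniform(300, 1500, 40)),
                     intensity=rng.uniform(1, 1e6, 40))
            for i in range(100)
        ]
        path = tmp_path / "run.mzML"
        sio.write_ms1(path, scans)
        back = sio.read_ms1(path)
        assert len(back) == 100
        for a, b in zip(scans, back):
            assert a.rt == b.rt
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_minutes_converted_to_seconds(self, tmp_path):
        path = tmp_path / "run.mzML"
        sio.write_ms1(path, [make_scan(30.0, [(500.0, 10.0)])])
        text = path.read_text().replace('unitName="second"', 'unitName="minute"')
        path.write_text(text)
        assert sio.read_ms1(path)[0].rt == pytest.approx(1800.0)

    def test_ms2_only_file_rejected(self, tmp_path):
        path = tmp_path / "run.mzML"
        sio.write_ms1(path, [make_scan(1.0, [(500.0, 10.0)])])
        text = path.read_text().replace(
            'name="ms level" value="1"', 'name="ms level" value="2"'
        )
        path.write_text(text)
        with pytest.raises(ValueError, match="MS1"):
            sio.read_ms1(path)

    def test_profile_mode_rejected_with_guidance(self, tmp_path):
        path = tmp_path / "run.mzML"
        sio.write_ms1(path, [make_scan(1.0, [(500.0, 10.0)])])
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"', 1)
        # the first replacement hits fileContent; patch the spectrum-level one
        text = text.replace('accession="MS:1000127" name="centroid spectrum"',
                            'accession="MS:1000128" name="profile spectrum"')
        path.write_text(text)
        with pytest.raises(ValueError, match="centroid"):
            sio.read_ms1(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sio.read_ms1(tmp_path / "nope.mzML")


class TestAveraging:
    def test_identical_scans_average_to_single_scan(self):
        peaks = [(400.0, 100.0), (401.0, 50.0)]
        scans = [make_scan(float(t), peaks) for t in range(10)]
        sl = sio.average_scans(scans, rt_center=5.0, window=(-5, 5))
        assert sl.n_scans_averaged == 10
        assert sl.peaks[:, 0] == pytest.approx([400.0, 401.0])
        assert sl.peaks[:, 1] == pytest.approx([100.0, 50.0])

    def test_peak_in_half_the_scans_averages_to_half(self):
        scans = [make_scan(float(t), [(400.0, 100.0)] if t % 2 == 0 else [(600.0, 1.0)])
                 for t in range(10)]
        sl = sio.average_scans(scans, rt_center=4.5, window=(-4.5, 5.0))
        idx = np.argmin(np.abs(sl.peaks[:, 0] - 400.0))
        assert sl.peaks[idx, 1] == pytest.approx(50.0)

    def test_empty_window_names_the_range(self):
        scans = [make_scan(100.0, [(400.0, 1.0)])]
        with pytest.raises(ValueError, match=r"\[195\.00, 215\.00\]"):
            sio.average_scans(scans, rt_center=200.0)

    def test_result_independent_of_scan_order(self, rng):
        scans = [make_scan(float(t), [(400.0 + 0.000001 * t, rng.uniform(1, 100))])
                 for t in range(8)]
        sl1 = sio.average_scans(scans, 4.0, (-4, 4))
        sl2 = sio.average_scans(list(reversed(scans)), 4.0, (-4, 4))
        assert np.allclose(sl1.peaks, sl2.peaks)

    def test_window_mean_matches_gaussian_ground_truth(self):
        """Averaged intensity equals the window mean of the elution profile."""
        apex, sigma, height = 100.0, 12.7, 1e6
        rts = np.arange(80.0, 120.0, 1.0)
        scans = [make_scan(t, [(500.0, height * np.exp(-0.5 * ((t - apex) / sigma) ** 2))])
                 for t in rts]
        sl = sio.average_scans(scans, apex, (-5, 15))
        inside = rts[(rts >= 95.0) & (rts <= 115.0)]
        expected = height * np.exp(-0.5 * ((inside - apex) / sigma) ** 2).mean()
        assert sl.peaks[0, 1] == pytest.approx(expected, rel=0.05)


class TestMatchPeak:
    def slice_of(self, peaks):
        return sio.average_scans([make_scan(0.0, peaks)], 0.0, (-1, 1))

    def test_exact_match_zero_ppm(self):
        m = sio.match_peak(self.slice_of([(500.0, 10.0)]), 500.0)
        assert m.found and m.ppm_error == pytest.approx(0.0, abs=1e-9)
        assert m.intensity == 10.0

    def test_peak_outside_tolerance_zeroed(self):
        tol = 500.0 / (2 * 240000.0)
        m = sio.match_peak(self.slice_of([(500.0 + 2.5 * tol, 10.0)]), 500.0)
        assert not m.found
        assert m.intensity == 0.0 and m.area == 0.0

    def test_nearer_peak_wins_tie_to_higher_intensity(self):
        # doublet separations > FWHM/2 so the peaks stay distinct clusters,
        # both still inside the matching tolerance of the target
        tol = 500.0 / (2 * 240000.0)
        sl = self.slice_of([(500.0 - 0.3 * tol, 5.0), (500.0 + 0.9 * tol, 50.0)])
        assert sio.match_peak(sl, 500.0).intensity == 5.0
        sl_tie = self.slice_of([(500.0 - 0.7 * tol, 5.0), (500.0 + 0.7 * tol, 50.0)])
        assert sio.match_peak(sl_tie, 500.0).intensity == 50.0

    def test_zero_noise_contract(self):
        """Absent peaks contribute exactly zero, never an imputed floor."""
        sl = self.slice_of([(900.0, 1e6)])
        m = sio.match_peak(sl, 500.0)
        assert m.intensity == 0.0 and m.area == 0.0 and m.matched_mz is None


class TestIdTable:
    def test_round_trip(self, tmp_path):
        exp = generate_experiment(SimConfig(n_proteins=3, peptides_per_protein=2, seed=5))
        path = tmp_path / "ids.tsv"
        sio.write_id_table(path, exp.id_records)
        back = sio.read_id_table(path)
        assert len(back) == len(exp.id_records)
        for a, b in zip(exp.id_records, back):
            assert (a.sequence, a.modifications, a.charge, a.protein, a.channel,
                    a.decoy, a.source_file) == (
                b.sequence, b.modifications, b.charge, b.protein, b.channel,
                b.decoy, b.source_file)
            assert a.rt_seconds == pytest.approx(b.rt_seconds, abs=1e-3)

    def test_14n_15n_channel_names_accepted(self, tmp_path):
        path = tmp_path / "ids.tsv"
        header = "\t".join(sio._ID_COLUMNS)
        path.write_text(header + "\nPEPTIDER\t\t2\t100.0\tP1\t15N\t30\t0\ta.mzML\n")
        assert sio.read_id_table(path)[0].channel == "heavy"

    def test_unknown_channel_names_row(self, tmp_path):
        path = tmp_path / "ids.tsv"
        header = "\t".join(sio._ID_COLUMNS)
        path.write_text(header + "\nPEPTIDER\t\t2\t100.0\tP1\tmedium\t30\t0\ta.mzML\n")
        with pytest.raises(ValueError, match="row 2"):
            sio.read_id_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text("sequence\tcharge\nPEPTIDER\t2\n")
        with pytest.raises(ValueError, match="missing columns"):
            sio.read_id_table(path)


class TestCache:
    def test_version_mismatch_is_explicit(self, tmp_path):
        path = tmp_path / "cache.json"
        path.write_text('{"schema_version": 99, "config": {}, "peptides": []}')
        with pytest.raises(ValueError, match="schema_version"):
            sio.read_cache(path)
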