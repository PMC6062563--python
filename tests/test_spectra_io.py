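"""Spectrum reading, trace consolidation and total-signal normalization."""

import numpy as np
import pytest

from conftest import brute_force_greedy_peaksets, make_sample
from inkms.errors import ParseError, ValidationError
from inkms.spectra_io import (
    SampleMeta,
    SamplePeakList,
    ScanSpectrum,
    TraceParams,
    consolidate_traces,
    normalize_tus,
    read_mzml,
    read_peaklist_tsv,
    write_mzml,
    write_peaklist_tsv,
)


def scan(idx, mzs, intensities=None):
    if intensities is None:
        intensities = [1.0] * len(mzs)
    return ScanSpectrum(scan_index=idx, mz=np.array(mzs), intensity=np.array(intensities))


class TestMzml:
    def test_write_read_round_trip(self, tmp_path):
        scans = [scan(0, [100.0, 200.5], [3.0, 7.0]), scan(1, [150.25], [2.0])]
        path = tmp_path / "s.mzML"
        write_mzml(path, scans)
        back = read_mzml(path)
        assert len(back) == 2
        for orig, rt in zip(scans, back):
            np.testing.assert_array_equal(orig.mz, rt.mz)
            np.testing.assert_array_equal(orig.intensity, rt.intensity)

    def test_ms2_scans_skipped(self, tmp_path):
        path = tmp_path / "mixed.mzML"
        write_mzml(path, [scan(0, [100.0]), scan(1, [200.0])])
        text = path.read_text().replace(
            'id="scan=2" defaultArrayLength="1">\n        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
            'id="scan=2" defaultArrayLength="1">\n        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>',
        )
        path.write_text(text)
        back = read_mzml(path)
        assert len(back) == 1 and back[0].mz[0] == 100.0

    def test_profile_mode_rejected(self, tmp_path):
        path = tmp_path / "profile.mzML"
        write_mzml(path, [scan(0, [100.0])])
        path.write_text(path.read_text().replace("MS:1000127", "MS:1000128"))
        with pytest.raises(ValidationError, match="centroided input required"):
            read_mzml(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mzml(tmp_path / "absent.mzML")

    def test_no_ms1_scans_is_error(self, tmp_path):
        path = tmp_path / "ms2only.mzML"
        write_mzml(path, [scan(0, [100.0])])
        path.write_text(path.read_text().replace('name="ms level" value="1"', 'name="ms level" value="2"'))
        with pytest.raises(ValidationError, match="no MS1"):
            read_mzml(path)


class TestPeaklistTsv:
    def test_basic(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("mz\tintensity\n100.0\t5.0\n200.0\t15.0\n")
        pl = read_peaklist_tsv(p)
        np.testing.assert_array_equal(pl.mz, [100.0, 200.0])
        np.testing.assert_array_equal(pl.intensity, [5.0, 15.0])
        assert not pl.normalized

    def test_dialect_tolerance(self, tmp_path):
        variants = [
            "mz\tintensity\n100.0\t5.0\n200.0\t15.0",          # no trailing newline
            "mz\tintensity\r\n100.0\t5.0\r\n200.0\t15.0\r\n",  # CRLF
            "# comment\nmz\tintensity\n100.0\t5.0\n\n200.0\t15.0\n",
        ]
        results = []
        for i, text in enumerate(variants):
            p = tmp_path / f"v{i}.tsv"
            p.write_text(text)
            pl = read_peaklist_tsv(p)
            results.append((tuple(pl.mz), tuple(pl.intensity)))
        assert len(set(results)) == 1

    def test_empty_body_warns(self, tmp_path, caplog):
        p = tmp_path / "empty.tsv"
        p.write_text("mz\tintensity\n")
        with caplog.at_level("WARNING"):
            pl = read_peaklist_tsv(p)
        assert len(pl) == 0 and "empty" in caplog.text

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("mz\tintensity\n100.0\t5.0\nnot_a_number\t3\n")
        with pytest.raises(ParseError, match=":3"):
            read_peaklist_tsv(p)

    def test_negative_intensity_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("mz\tintensity\n100.0\t-5.0\n")
        with pytest.raises(ValidationError, match="negative"):
            read_peaklist_tsv(p)

    def test_write_read_is_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(70, 700, 50))
        inten = rng.lognormal(4, 1, 50)
        p = tmp_path / "rt.tsv"
        write_peaklist_tsv(p, mz, inten)
        pl = read_peaklist_tsv(p)
        np.testing.assert_array_equal(pl.mz, mz)
        np.testing.assert_array_equal(pl.intensity, inten)


class TestConsolidateTraces:
    def test_consistent_peak_kept(self):
        rng = np.random.default_rng(1)
        scans = [
            scan(i, [100.0 * (1 + rng.uniform(-0.5e-6, 0.5e-6))]) for i in range(10)
        ]
        mz, inten = consolidate_traces(scans)
        assert len(mz) == 1
        assert abs(mz[0] - 100.0) / 100.0 * 1e6 < 1.0

    def test_rare_peak_dropped(self):
        scans = [scan(i, [100.0] + ([400.0] if i < 2 else [])) for i in range(10)]
        mz, _ = consolidate_traces(scans, TraceParams(min_scan_fraction=0.5))
        assert list(mz) == [pytest.approx(100.0)]

    def test_outlier_starts_new_trace_then_dropped(self):
        # third scan's peak sits ~18 ppm above the running mean of the
        # first two, so it opens its own trace with fraction 1/3 < 0.5
        scans = [scan(0, [100.0000]), scan(1, [100.0003]), scan(2, [100.0020])]
        mz, _ = consolidate_traces(scans)
        assert len(mz) == 1
        assert mz[0] == pytest.approx(100.00015, abs=1e-9)

    def test_intensity_summaries(self):
        scans = [scan(0, [100.0], [2.0]), scan(1, [100.0], [6.0])]
        for summary, expected in [("mean", 4.0), ("sum", 8.0), ("max", 6.0)]:
            _, inten = consolidate_traces(scans, TraceParams(intensity_summary=summary))
            assert inten[0] == expected

    def test_empty_scan_list_is_error(self):
        with pytest.raises(ValidationError):
            consolidate_traces([])

    def test_trace_count_monotone_in_scan_fraction(self):
        rng = np.random.default_rng(7)
        scans = []
        grid = rng.uniform(100, 500, 20)
        for i in range(10):
            present = grid[rng.uniform(size=20) > 0.4]
            scans.append(scan(i, np.sort(present)))
        counts = [
            len(consolidate_traces(scans, TraceParams(min_scan_fraction=f))[0])
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_oracle(self):
        # scans play the role of files; same clustering core, so the naive
        # pooled greedy oracle (sans retention threshold) must agree
        for seed in range(50):
            rng = np.random.default_rng(seed)
            scans = []
            n_scans = rng.integers(2, 5)
            peaks = []
            for i in range(n_scans):
                k = int(rng.integers(1, 8))
                mzs = np.sort(rng.uniform(100, 110, k))
                ints = rng.lognormal(1, 1, k)
                scans.append(scan(i, mzs, ints))
                peaks += [(f"{i:05d}", float(m), float(x)) for m, x in zip(mzs, ints)]
            expected = brute_force_greedy_peaksets(peaks, 5.0)
            # keep most intense per scan, then drop clusters below fraction 1/2
            surviving = []
            for members in expected:
                best = {}
                for sid, m, x in members:
                    if sid not in best or x > best[sid][2] or (x == best[sid][2] and m < best[sid][1]):
                        best[sid] = (sid, m, x)
                if len(best) / n_scans >= 0.5:
                    vals = sorted(best.values())
                    surviving.append(
                        (
                            np.mean([v[1] for v in vals]),
                            np.mean([v[2] for v in vals]),
                        )
                    )
            surviving.sort()
            mz, inten = consolidate_traces(scans, TraceParams())
            assert len(mz) == len(surviving)
            np.testing.assert_allclose(mz, [s[0] for s in surviving], rtol=1e-12)
            np.testing.assert_allclose(inten, [s[1] for s in surviving], rtol=1e-12)


class TestNormalize:
    def test_worked_example(self):
        pl = make_sample("s", [100, 200], [2, 3], normalized=False)
        out = normalize_tus(pl)
        np.testing.assert_allclose(out.intensity, [400.0, 600.0])
        assert out.normalized

    def test_single_peak_gets_full_scale(self):
        out = normalize_tus(make_sample("s", [150], [7], normalized=False))
        assert out.intensity[0] == pytest.approx(1000.0)

    def test_sum_is_1000(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(1, 40))
            pl = make_sample("s", np.sort(rng.uniform(70, 700, k)), rng.lognormal(2, 2, k), normalized=False)
            out = normalize_tus(pl)
            assert out.intensity.sum() == pytest.approx(1000.0, rel=1e-9)

    def test_double_normalization_rejected(self):
        out = normalize_tus(make_sample("s", [100], [1], normalized=False))
        with pytest.raises(ValidationError, match="already normalized"):
            normalize_tus(out)

    def test_zero_total_is_error(self):
        with pytest.raises(ValidationError, match="zero"):
            normalize_tus(make_sample("s", [100.0], [0.0], normalized=False))

    def test_empty_list_passes_with_warning(self, caplog):
        pl = make_sample("s", [], [], normalized=False)
        with caplog.at_level("WARNING"):
            out = normalize_tus(pl)
        assert out.normalized and len(out) == 0


def test_sample_meta_blank_consistency():
    with pytest.raises(ValidationError):
        SampleMeta("x", "d", "A", "ink", 1, is_blank=True)
    with pytest.raises(ValidationError):
        SampleMeta("x", "d", "blank", "blank", 1, is_blank=False)
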