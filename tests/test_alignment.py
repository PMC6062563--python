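"""Greedy peakset alignment, within-file dedup and matrix construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_greedy_peaksets, make_sample
from inkms.alignment import (
    AlignParams,
    PeakSet,
    align_and_build,
    align_greedy,
    build_matrix,
    dedupe_within_file,
)
from inkms.errors import ValidationError


class TestAlignGreedy:
    def test_two_files_within_tolerance_merge(self):
        a = make_sample("A", [100.0000], [1000.0])
        b = make_sample("B", [100.0003], [1000.0])
        sets = align_greedy([a, b])
        assert len(sets) == 1
        assert sets[0].mean_mz == pytest.approx(100.00015, abs=1e-9)

    def test_two_files_beyond_tolerance_split(self):
        a = make_sample("A", [100.0000], [1000.0])
        b = make_sample("B", [100.0010], [1000.0])
        assert len(align_greedy([a, b])) == 2

    def test_running_mean_rule(self):
        # 100.0008 is ~6 ppm from the mean of the first two -> new peakset
        s = [
            make_sample("A", [100.0000], [1000.0]),
            make_sample("B", [100.0004], [1000.0]),
            make_sample("C", [100.0008], [1000.0]),
        ]
        sets = align_greedy(s)
        assert [len(ps) for ps in sets] == [2, 1]

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValidationError, match="not normalized"):
            align_greedy([make_sample("A", [100.0], [5.0], normalized=False)])

    def test_single_file_distant_peaks_one_set_each(self):
        mzs = [100.0, 100.002, 100.004]  # 20 ppm apart
        sets = align_greedy([make_sample("A", mzs, [1.0] * 3)])
        assert len(sets) == 3

    def test_partition_property(self):
        rng = np.random.default_rng(11)
        samples = []
        total = 0
        for i in range(4):
            k = int(rng.integers(1, 15))
            samples.append(
                make_sample(f"S{i}", np.sort(rng.uniform(100, 120, k)), rng.lognormal(1, 1, k))
            )
            total += k
        sets = align_greedy(samples)
        assert sum(len(ps) for ps in sets) == total

    def test_deduped_ppm_spread_bounded(self):
        # with well-separated features and ~1 ppm within-feature jitter
        # (no chaining), running-mean admission bounds pairwise spread by
        # twice the tolerance
        for seed in range(30):
            rng = np.random.default_rng(seed)
            centers = 100.0 * (1 + np.arange(6) * 50e-6)  # 50 ppm apart
            samples = [
                make_sample(
                    f"S{i}",
                    np.sort(centers * (1 + rng.normal(0, 1e-6, 6))),
                    rng.lognormal(1, 1, 6),
                )
                for i in range(3)
            ]
            for ps in align_greedy(samples, AlignParams(ppm_tol=5)):
                deduped = dedupe_within_file(ps)
                mzs = [m[1] for m in deduped.members]
                spread = (max(mzs) - min(mzs)) / min(mzs) * 1e6
                assert spread <= 2 * 5 + 1e-9

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n_files = int(rng.integers(1, 6))
            samples = []
            pool = []
            for i in range(n_files):
                k = int(rng.integers(0, 11))
                mzs = np.sort(rng.uniform(100, 100.01, k))
                ints = np.round(rng.lognormal(1, 1, k), 3)
                samples.append(make_sample(f"S{i}", mzs, ints))
                pool += [(f"S{i}", float(m), float(x)) for m, x in zip(mzs, ints)]
            if not pool:
                continue
            expected = brute_force_greedy_peaksets(pool, 5.0)
            got = align_greedy(samples, AlignParams(ppm_tol=5.0))
            expected.sort(key=lambda ms: np.mean([m[1] for m in ms]))
            assert len(got) == len(expected)
            for ps, exp in zip(got, expected):
                assert sorted(ps.members) == sorted(exp)


class TestDedupe:
    def test_most_intense_retained(self):
        ps = PeakSet.from_members(
            [("S1", 100.0000, 5.0), ("S1", 100.0003, 9.0), ("S2", 100.0001, 4.0)]
        )
        out = dedupe_within_file(ps)
        assert sorted(out.members) == [("S1", 100.0003, 9.0), ("S2", 100.0001, 4.0)]
        assert out.mean_mz == pytest.approx(np.mean([100.0003, 100.0001]))

    def test_no_duplicates_unchanged(self):
        ps = PeakSet.from_members([("S1", 100.0, 5.0), ("S2", 100.0001, 4.0)])
        assert sorted(dedupe_within_file(ps).members) == sorted(ps.members)

    def test_tie_breaks_to_lower_mz(self):
        ps = PeakSet.from_members([("S1", 100.0000, 5.0), ("S1", 100.0004, 5.0)])
        assert dedupe_within_file(ps).members == [("S1", 100.0000, 5.0)]


class TestBuildMatrix:
    def _manifest(self, n=3):
        return [make_sample(f"S{i}", [], []).meta for i in range(n)]

    def test_shape_and_missing_cells(self):
        sets = [
            PeakSet.from_members([("S0", 100.0, 1.0), ("S1", 100.0001, 2.0)]),
            PeakSet.from_members([("S1", 200.0, 3.0), ("S2", 200.0001, 4.0)]),
        ]
        m = build_matrix(sets, self._manifest())
        assert m.values.shape == (2, 3)
        assert int(m.values.isna().sum().sum()) == 2
        assert list(m.values.columns) == ["S0", "S1", "S2"]

    def test_rows_sorted_by_mz(self):
        sets = [
            PeakSet.from_members([("S0", 300.0, 1.0)]),
            PeakSet.from_members([("S0", 100.0, 1.0)]),
        ]
        m = build_matrix(sets, self._manifest(1))
        assert list(m.feature_mz) == [100.0, 300.0]

    def test_empty_peaksets_valid(self):
        m = build_matrix([], self._manifest())
        assert m.n_features == 0

    def test_unknown_sample_rejected(self):
        sets = [PeakSet.from_members([("ghost", 100.0, 1.0)])]
        with pytest.raises(ValidationError, match="not in manifest"):
            build_matrix(sets, self._manifest())

    def test_nonblank_projection_equals_rebuild(self, small_corpus):
        from inkms.spectra_io import manifest_metas, normalize_tus

        samples = [
            normalize_tus(small_corpus.peak_lists[m.sample_id])
            for m in manifest_metas(small_corpus.manifest)
        ]
        full = align_and_build(samples)
        nonblank = full.nonblank_ids()
        projected = full.subset_samples(nonblank)

        from inkms.alignment import align_greedy, dedupe_within_file as dd

        sets = [dd(ps) for ps in align_greedy(samples)]
        keep = set(nonblank)
        restricted = [
            PeakSet.from_members([m for m in ps.members if m[0] in keep])
            for ps in sets
            if any(m[0] in keep for m in ps.members)
        ]
        rebuilt = build_matrix(
            restricted, [s.meta for s in samples if not s.meta.is_blank]
        )
        assert rebuilt.values.shape[1] == projected.values.shape[1]
        # per sample, the measured values are identical multisets
        for sid in nonblank:
            np.testing.assert_allclose(
                np.sort(rebuilt.values[sid].dropna().to_numpy()),
                np.sort(projected.values[sid].dropna().to_numpy()),
            )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 3),
            st.floats(100.0, 100.005),
            st.floats(0.1, 10.0),
        ),
        min_size=1,
        max_size=25,
    )
)
def test_partition_property_hypothesis(raw):
    """Every pooled peak lands in exactly one peakset, none duplicated."""
    by_file: dict[int, list[tuple[float, float]]] = {}
    for fid, mz, inten in raw:
        by_file.setdefault(fid, []).append((mz, inten))
    samples = [
        make_sample(f"S{fid}", [p[0] for p in peaks], [p[1] for p in peaks])
        for fid, peaks in sorted(by_file.items())
    ]
    sets = align_greedy(samples)
    pooled = sorted((sid, mz) for ps in sets for sid, mz, _ in ps.members)
    original = sorted(
        (s.meta.sample_id, float(mz)) for s in samples for mz in s.mz
    )
    assert pooled == original
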