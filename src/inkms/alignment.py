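"""Cross-file peakset alignment and feature-matrix construction.

Peaks from all files are pooled, sorted by m/z and collected greedily into
*peaksets*: a peak joins the open peakset while it is within ``ppm_tol`` of
the running mean m/z of peaks already admitted, otherwise the peakset is
closed and a new one opened.  A file contributing several peaks to one
peakset keeps only its most intense.  Peaksets become the rows of a
features x samples intensity matrix, absent peaks marked missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._greedy import greedy_clusters
from .errors import ValidationError
from .spectra_io import SampleMeta, SamplePeakList


@dataclass(frozen=True)
class AlignParams:
    """Alignment tolerance in parts per million (default 5)."""

    ppm_tol: float = 5.0

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValidationError("ppm_tol must be > 0")


@dataclass
class PeakSet:
    """One aligned cross-file feature.

    members : list of (sample_id, mz, intensity)
    mean_mz : arithmetic mean of the member m/z values
    """

    members: list[tuple[str, float, float]]
    mean_mz: float

    @classmethod
    def from_members(cls, members: list[tuple[str, float, float]]) -> "PeakSet":
        mean = float(np.mean([m[1] for m in members]))
        return cls(members=members, mean_mz=mean)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PeakMatrix:
    """Features x samples intensity matrix with sample metadata.

    ``values`` rows correspond to ``feature_mz`` entries (ascending); its
    columns are sample ids in manifest order.  Missing measurements are
    NaN, never zero, until imputation at the statistics stage.
    """

    feature_mz: np.ndarray
    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        if len(self.feature_mz) != len(self.values):
            raise ValidationError("feature_mz length must match matrix rows")
        if [s.sample_id for s in self.samples] != list(self.values.columns):
            raise ValidationError("sample metadata must match matrix columns")

    @property
    def n_features(self) -> int:
        return len(self.feature_mz)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta_of(self, sample_id: str) -> SampleMeta:
        return self._meta_map[sample_id]

    @property
    def _meta_map(self) -> dict[str, SampleMeta]:
        return {s.sample_id: s for s in self.samples}

    def blank_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.is_blank]

    def nonblank_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if not s.is_blank]

    def presence(self) -> pd.DataFrame:
        """Boolean presence mask (True where a peak was measured)."""
        return self.values.notna()

    def subset_features(self, mask: np.ndarray) -> "PeakMatrix":
        mask = np.asarray(mask)
        return PeakMatrix(
            feature_mz=self.feature_mz[mask],
            values=self.values.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakMatrix":
        metas = self._meta_map
        return PeakMatrix(
            feature_mz=self.feature_mz.copy(),
            values=self.values[list(sample_ids)].copy(),
            samples=[metas[sid] for sid in sample_ids],
        )

    def to_csv(self, path: str | Path) -> None:
        """Export: first column feature m/z (6 dp), empty cell = missing."""
        out = self.values.copy()
        out.insert(0, "feature_mz", [f"{m:.6f}" for m in self.feature_mz])
        out.to_csv(path, index=False)


def align_greedy(
    samples: Sequence[SamplePeakList], params: AlignParams = AlignParams()
) -> list[PeakSet]:
    """Align normalized per-file peak lists into peaksets.

    Pooled peaks are sorted ascending by m/z (ties: sample_id lexicographic,
    then intensity descending) and scanned left to right with the greedy
    running-mean rule at ``params.ppm_tol``.  Output is sorted by mean m/z.
    Every input peak lands in exactly one peakset; within-file deduplication
    is a separate, later step (:func:`dedupe_within_file`).
    """
    if not samples:
        raise ValidationError("align_greedy requires at least one sample")
    for s in samples:
        if not s.normalized:
            raise ValidationError(
                f"sample {s.meta.sample_id!r} is not normalized; "
                "run normalize_tus first"
            )
    mz = np.concatenate([s.mz for s in samples]) if samples else np.array([])
    if len(mz) == 0:
        return []
    intensity = np.concatenate([s.intensity for s in samples])
    sample_ids = np.concatenate(
        [np.full(len(s.mz), s.meta.sample_id, dtype=object) for s in samples]
    )
    order = np.lexsort((-intensity, sample_ids, mz))
    mz, intensity, sample_ids = mz[order], intensity[order], sample_ids[order]

    peaksets = [
        PeakSet.from_members(
            [
                (str(sample_ids[j]), float(mz[j]), float(intensity[j]))
                for j in range(start, stop)
            ]
        )
        for start, stop in greedy_clusters(mz, params.ppm_tol)
    ]
    peaksets.sort(key=lambda ps: ps.mean_mz)
    return peaksets


def dedupe_within_file(peakset: PeakSet) -> PeakSet:
    """Keep one peak per file: the most intense (ties: lower m/z).

    The mean m/z is recomputed from the survivors.
    """
    best: dict[str, tuple[str, float, float]] = {}
    for member in peakset.members:
        sid, mz, intensity = member
        if sid not in best:
            best[sid] = member
        else:
            _, bmz, bint = best[sid]
            if intensity > bint or (intensity == bint and mz < bmz):
                best[sid] = member
    survivors = [best[sid] for sid in sorted(best)]
    return PeakSet.from_members(survivors)


def build_matrix(
    peaksets: Sequence[PeakSet], manifest: Sequence[SampleMeta]
) -> PeakMatrix:
    """Assemble deduped peaksets into a features x samples matrix.

    One row per peakset (ascending mean m/z), one column per manifest
    sample; (sample, feature) pairs without a peak are NaN.
    """
    sample_ids = [s.sample_id for s in manifest]
    known = set(sample_ids)
    ordered = sorted(peaksets, key=lambda ps: ps.mean_mz)
    values = np.full((len(ordered), len(sample_ids)), np.nan)
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    for i, ps in enumerate(ordered):
        for sid, _mz, intensity in ps.members:
            if sid not in known:
                raise ValidationError(f"peakset member sample {sid!r} not in manifest")
            values[i, col_of[sid]] = intensity
    return PeakMatrix(
        feature_mz=np.array([ps.mean_mz for ps in ordered]),
        values=pd.DataFrame(values, columns=sample_ids),
        samples=list(manifest),
    )


def align_and_build(
    samples: Sequence[SamplePeakList], params: AlignParams = AlignParams()
) -> PeakMatrix:
    """Convenience: align, dedupe every peakset, and build the matrix."""
    peaksets = [dedupe_within_file(ps) for ps in align_greedy(samples, params)]
    return build_matrix(peaksets, [s.meta for s in samples])
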