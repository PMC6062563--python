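"""Shared fixtures and independent oracle implementations.

The oracles deliberately re-derive results by the most naive route
(explicit loops, rank statistics, step-up by hand) so they stay
independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from inkms.spectra_io import SampleMeta, SamplePeakList
from inkms.synthetic import CorpusConfig, generate_corpus


# ---------------------------------------------------------------------------
# Oracles


def brute_force_greedy_peaksets(
    peaks: list[tuple[str, float, float]], ppm_tol: float
) -> list[list[tuple[str, float, float]]]:
    """Naive reimplementation of greedy peakset collection.

    Sorts pooled (sample_id, mz, intensity) peaks by (mz, sample_id,
    -intensity) and walks left to right, recomputing the open set's mean
    from scratch at every step.
    """
    pool = sorted(peaks, key=lambda p: (p[1], p[0], -p[2]))
    sets: list[list[tuple[str, float, float]]] = []
    current: list[tuple[str, float, float]] = []
    for peak in pool:
        if not current:
            current = [peak]
            continue
        mean = sum(p[1] for p in current) / len(current)
        if abs(peak[1] - mean) / mean * 1e6 <= ppm_tol:
            current.append(peak)
        else:
            sets.append(current)
            current = [peak]
    if current:
        sets.append(current)
    return sets


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH by direct application of the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return np.clip(q, 0, 1)


def mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-statistic AUC with tie correction: P(S+ > S-) + 0.5 P(=)."""
    pos = np.asarray(scores)[np.asarray(positive, dtype=bool)]
    neg = np.asarray(scores)[~np.asarray(positive, dtype=bool)]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Fixtures


def make_sample(
    sample_id: str,
    mz,
    intensity,
    author: str = "A",
    document: str | None = None,
    normalized: bool = True,
    is_blank: bool = False,
) -> SamplePeakList:
    meta = SampleMeta(
        sample_id=sample_id,
        document_id=document or sample_id,
        author="blank" if is_blank else author,
        substrate="blank" if is_blank else "ink",
        replicate=1,
        is_blank=is_blank,
    )
    return SamplePeakList(
        meta=meta,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        normalized=normalized,
    )


SMALL_CONFIG = dict(
    n_documents_per_author=3,
    replicates=2,
    n_background_features=60,
    n_blank_contaminants=8,
    n_blanks=3,
)


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory):
    """One default-sized signal corpus shared across tests (seed 1)."""
    out = tmp_path_factory.mktemp("corpus_default")
    return generate_corpus(CorpusConfig(seed=1), out)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A reduced corpus for faster structural tests (seed 5)."""
    out = tmp_path_factory.mktemp("corpus_small")
    return generate_corpus(CorpusConfig(seed=5, **SMALL_CONFIG), out)
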