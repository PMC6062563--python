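"""Synthetic direct-infusion corpora with known ground truth.

Emulates the structure of a two-author manuscript study: several documents
per author, each sampled on two substrates (ink stroke and bare paper) in
technical triplicate, plus solvent blanks.  Features come in four classes:

* background ions shared by all real samples (a thinned subset also shows
  up in blanks, so a realistic number of background features survives the
  blank filter);
* author-diagnostic ions present only in one author's samples, at a
  fold-change above the background intensity scale (by default their m/z
  values are the study-style curated diagnostic ions, so annotation runs
  on synthetic output unchanged);
* blank contaminants present in every blank, half of which also bleed
  into a random subset of real samples — the blank filter has real work;
* everything is jittered: Gaussian ppm noise on m/z, lognormal
  multiplicative noise on intensity, and random missingness.

Generation is deterministic given the seed; each sample draws from its own
substream (derived from the corpus seed and a CRC of the sample id), so
adding a sample does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotate
from .errors import ValidationError
from .spectra_io import (
    BLANK_AUTHOR,
    MANIFEST_COLUMNS,
    SampleMeta,
    SamplePeakList,
    ScanSpectrum,
    write_mzml,
    write_peaklist_tsv,
)

CLASS_BACKGROUND = "background"
CLASS_CONTAMINANT = "contaminant"


def diagnostic_class(author: str) -> str:
    return f"diagnostic_{author}"


@dataclass(frozen=True)
class CorpusConfig:
    """Study-design and noise parameters of a synthetic corpus.

    Defaults reproduce the assumed study geometry: 2 authors x 5 documents
    x 2 substrates x 3 replicates + 4 solvent blanks = 64 infusions, with
    the curated 8-per-author diagnostic ions planted at an 8-fold
    intensity effect, 1 ppm mass jitter (well inside the 5 ppm alignment
    tolerance) and 10% missingness.
    """

    n_documents_per_author: int = 5
    replicates: int = 3
    substrates: tuple[str, ...] = ("ink", "paper")
    n_blanks: int = 4
    n_background_features: int = 300
    n_diagnostic_per_author: int = 8
    n_blank_contaminants: int = 20
    mz_jitter_ppm_sd: float = 1.0
    intensity_lognormal_sd: float = 0.5
    diagnostic_fold_change: float = 8.0
    missing_rate: float = 0.1
    n_scans_per_file: int = 10
    seed: int = 0
    authors: tuple[str, str] = ("A", "B")
    mz_range: tuple[float, float] = (70.0, 700.0)
    blank_background_rate: float = 0.15
    contaminant_overlap_fraction: float = 0.5
    contaminant_sample_rate: float = 0.3

    def __post_init__(self) -> None:
        counts = {
            "n_documents_per_author": self.n_documents_per_author,
            "replicates": self.replicates,
            "n_blanks": self.n_blanks,
            "n_background_features": self.n_background_features,
            "n_diagnostic_per_author": self.n_diagnostic_per_author,
            "n_blank_contaminants": self.n_blank_contaminants,
            "n_scans_per_file": self.n_scans_per_file,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.mz_jitter_ppm_sd <= 0 or self.intensity_lognormal_sd < 0:
            raise ValidationError("noise scales must be positive")
        if self.diagnostic_fold_change <= 0:
            raise ValidationError("diagnostic_fold_change must be > 0")
        if len(set(self.authors)) != 2:
            raise ValidationError("exactly two distinct author labels required")
        if self.mz_range[0] <= 0 or self.mz_range[1] <= self.mz_range[0]:
            raise ValidationError("invalid mz_range")


@dataclass
class TruthTable:
    """Ground truth of a generated corpus.

    One row per feature: true mean m/z, class (``background``,
    ``diagnostic_<author>`` or ``contaminant``), base intensity, and the
    sample ids it was planted in.
    """

    table: pd.DataFrame  # columns: feature_mz, class, base_intensity, planted_in

    def diagnostic_mz(self, author: str | None = None) -> np.ndarray:
        t = self.table
        mask = t["class"].str.startswith("diagnostic")
        if author is not None:
            mask = t["class"] == diagnostic_class(author)
        return t.loc[mask, "feature_mz"].to_numpy()

    def mz_of_class(self, klass: str) -> np.ndarray:
        return self.table.loc[self.table["class"] == klass, "feature_mz"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["planted_in"] = out["planted_in"].map(";".join)
        out.to_csv(path, index=False, float_format="%.6f")


@dataclass
class SyntheticCorpus:
    """A generated corpus on disk plus its in-memory ground truth."""

    out_dir: Path
    manifest_path: Path
    truth_path: Path
    manifest: pd.DataFrame
    truth: TruthTable
    peak_lists: dict[str, SamplePeakList]
    config: CorpusConfig


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # stable per-sample substream: corpus seed + CRC32 of the sample id
    return np.random.default_rng([seed % (2**31), zlib.crc32(sample_id.encode())])


def _build_manifest(config: CorpusConfig, fmt: str) -> pd.DataFrame:
    rows = []
    ext = "mzML" if fmt == "mzml" else "tsv"
    for author in config.authors:
        for d in range(1, config.n_documents_per_author + 1):
            doc = f"{author}_doc{d:02d}"
            for substrate in config.substrates:
                for r in range(1, config.replicates + 1):
                    sid = f"{doc}_{substrate}_r{r}"
                    rows.append(
                        dict(
                            sample_id=sid,
                            file=f"{sid}.{ext}",
                            document_id=doc,
                            author=author,
                            substrate=substrate,
                            replicate=r,
                            is_blank=0,
                        )
                    )
    for b in range(1, config.n_blanks + 1):
        sid = f"blank_r{b}"
        rows.append(
            dict(
                sample_id=sid,
                file=f"{sid}.{ext}",
                document_id="blank",
                author=BLANK_AUTHOR,
                substrate="blank",
                replicate=b,
                is_blank=1,
            )
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def _build_features(config: CorpusConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Feature grid: m/z, class, base intensity (raw arbitrary counts)."""
    lo, hi = config.mz_range
    rows = []
    bg_mz = np.sort(rng.uniform(lo, hi, config.n_background_features))
    bg_base = rng.lognormal(mean=4.0, sigma=1.0, size=config.n_background_features)
    for mz, base in zip(bg_mz, bg_base):
        rows.append((float(mz), CLASS_BACKGROUND, float(base)))
    curated = {a: annotate.diagnostic_peaks(a) for a in ("A", "B")}
    for author, pool_key in zip(config.authors, ("A", "B")):
        pool = curated[pool_key]
        k = config.n_diagnostic_per_author
        mzs = list(pool[:k])
        if k > len(pool):
            mzs += list(rng.uniform(lo, hi, k - len(pool)))
        base = rng.lognormal(mean=4.0, sigma=1.0, size=k)
        for mz, b in zip(mzs, base):
            rows.append(
                (float(mz), diagnostic_class(author), float(b * config.diagnostic_fold_change))
            )
    cont_mz = rng.uniform(lo, hi, config.n_blank_contaminants)
    cont_base = rng.lognormal(mean=4.0, sigma=1.0, size=config.n_blank_contaminants)
    for mz, b in zip(cont_mz, cont_base):
        rows.append((float(mz), CLASS_CONTAMINANT, float(b)))
    return pd.DataFrame(rows, columns=["feature_mz", "class", "base_intensity"])


def _feature_present(
    klass: str,
    meta: SampleMeta,
    u: float,
    config: CorpusConfig,
    overlap: bool,
    null: bool,
) -> bool:
    if klass == CLASS_CONTAMINANT:
        if meta.is_blank:
            return True
        return overlap and u < config.contaminant_sample_rate
    if klass == CLASS_BACKGROUND or null:
        if meta.is_blank:
            return u < config.blank_background_rate
        return u >= config.missing_rate
    # class-diagnostic feature, signal corpus
    if meta.is_blank or not klass.endswith(meta.author):
        return False
    return u >= config.missing_rate


def _generate(
    config: CorpusConfig, out_dir: str | Path, fmt: str, null: bool
) -> SyntheticCorpus:
    if fmt not in ("tsv", "mzml"):
        raise ValidationError("fmt must be 'tsv' or 'mzml'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng([config.seed % (2**31), 0])
    features = _build_features(config, root)
    if null:
        # remove the planted effect but keep the identical m/z grid
        features = features.copy()
        diag = features["class"].str.startswith("diagnostic")
        features.loc[diag, "base_intensity"] /= config.diagnostic_fold_change
    n_feat = len(features)
    overlap_flags = np.zeros(n_feat, dtype=bool)
    cont_idx = np.flatnonzero((features["class"] == CLASS_CONTAMINANT).to_numpy())
    n_overlap = int(round(len(cont_idx) * config.contaminant_overlap_fraction))
    overlap_flags[cont_idx[:n_overlap]] = True

    manifest = _build_manifest(config, fmt)
    metas = [
        SampleMeta(
            sample_id=r.sample_id,
            document_id=r.document_id,
            author=r.author,
            substrate=r.substrate,
            replicate=int(r.replicate),
            is_blank=bool(r.is_blank),
        )
        for r in manifest.itertuples()
    ]

    f_mz = features["feature_mz"].to_numpy()
    f_base = features["base_intensity"].to_numpy()
    f_class = features["class"].tolist()

    planted: list[list[str]] = [[] for _ in range(n_feat)]
    presence: dict[str, np.ndarray] = {}
    peak_lists: dict[str, SamplePeakList] = {}

    for meta in metas:
        rng = _sample_rng(config.seed, meta.sample_id)
        u = rng.uniform(size=n_feat)
        eps_int = rng.standard_normal(n_feat)
        eps_mz = rng.standard_normal(n_feat)
        mask = np.array(
            [
                _feature_present(f_class[i], meta, float(u[i]), config, overlap_flags[i], null)
                for i in range(n_feat)
            ]
        )
        presence[meta.sample_id] = mask
        intensity = f_base * np.exp(eps_int * config.intensity_lognormal_sd)
        mz = f_mz * (1.0 + eps_mz * config.mz_jitter_ppm_sd * 1e-6)
        peak_lists[meta.sample_id] = SamplePeakList(
            meta=meta, mz=mz[mask], intensity=intensity[mask]
        )

    if not null:
        _ensure_min_presence(config, metas, presence, planted_min=3)

    # rebuild peak lists after any forced presence, then record planted_in
    for meta in metas:
        mask = presence[meta.sample_id]
        pl = peak_lists[meta.sample_id]
        if mask.sum() != len(pl):
            rng = _sample_rng(config.seed, meta.sample_id)
            rng.uniform(size=n_feat)  # consume; keeps the substream aligned
            eps_int = rng.standard_normal(n_feat)
            eps_mz = rng.standard_normal(n_feat)
            intensity = f_base * np.exp(eps_int * config.intensity_lognormal_sd)
            mz = f_mz * (1.0 + eps_mz * config.mz_jitter_ppm_sd * 1e-6)
            peak_lists[meta.sample_id] = SamplePeakList(
                meta=meta, mz=mz[mask], intensity=intensity[mask]
            )
        for i in np.flatnonzero(mask):
            planted[i].append(meta.sample_id)

    # write files
    for meta in metas:
        pl = peak_lists[meta.sample_id]
        fname = manifest.loc[manifest.sample_id == meta.sample_id, "file"].iloc[0]
        path = out_dir / fname
        if fmt == "tsv":
            write_peaklist_tsv(path, pl.mz, pl.intensity)
        else:
            _write_scans(path, pl, config)

    features = features.copy()
    features["planted_in"] = planted
    truth = TruthTable(table=features[["feature_mz", "class", "base_intensity", "planted_in"]])
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path)
    return SyntheticCorpus(
        out_dir=out_dir,
        manifest_path=manifest_path,
        truth_path=truth_path,
        manifest=manifest,
        truth=truth,
        peak_lists=peak_lists,
        config=config,
    )


def _ensure_min_presence(
    config: CorpusConfig,
    metas: list[SampleMeta],
    presence: dict[str, np.ndarray],
    planted_min: int,
) -> None:
    """Force each diagnostic feature into >= planted_min samples of its author.

    Dropout makes this vanishingly rare at default sizes; tiny test corpora
    are repaired deterministically (first samples of the author, in
    manifest order) when possible.
    """
    by_author: dict[str, list[SampleMeta]] = {}
    for m in metas:
        if not m.is_blank:
            by_author.setdefault(m.author, []).append(m)
    n_feat = len(next(iter(presence.values())))
    # a repairable feature is one planted in this author only (diagnostics);
    # background features are present everywhere and never qualify
    for author, samples in by_author.items():
        counts = np.zeros(n_feat, dtype=int)
        for m in samples:
            counts += presence[m.sample_id]
        # features that can only belong to this author: planted nowhere else
        other = [m for m in metas if m.is_blank or m.author != author]
        elsewhere = np.zeros(n_feat, dtype=bool)
        for m in other:
            elsewhere |= presence[m.sample_id]
        fixable = (counts > 0) & (counts < planted_min) & ~elsewhere
        for i in np.flatnonzero(fixable):
            need = planted_min - counts[i]
            for m in samples:
                if need == 0:
                    break
                if not presence[m.sample_id][i]:
                    presence[m.sample_id][i] = True
                    need -= 1


def _write_scans(path: Path, pl: SamplePeakList, config: CorpusConfig) -> None:
    """Expand a file-level peak list into per-scan spectra and write mzML.

    Each scan re-jitters the file-level m/z (same ppm scale) and applies a
    modest per-scan intensity wobble; all file-level peaks appear in every
    scan, so trace consolidation recovers the file-level list.
    """
    rng = _sample_rng(config.seed, pl.meta.sample_id + "/scans")
    scans = []
    for k in range(config.n_scans_per_file):
        eps_mz = rng.standard_normal(len(pl.mz))
        eps_int = rng.standard_normal(len(pl.mz))
        scans.append(
            ScanSpectrum(
                scan_index=k,
                mz=pl.mz * (1.0 + eps_mz * config.mz_jitter_ppm_sd * 1e-6),
                intensity=pl.intensity * np.exp(0.2 * eps_int),
            )
        )
    write_mzml(path, scans)


def generate_corpus(
    config: CorpusConfig, out_dir: str | Path, fmt: str = "tsv"
) -> SyntheticCorpus:
    """Generate a two-author corpus with planted diagnostic ions.

    ``fmt="tsv"`` writes consolidated per-file peak lists; ``fmt="mzml"``
    writes multi-scan centroided mzML so the trace-consolidation stage is
    exercised too.  Deterministic given ``config.seed``.
    """
    return _generate(config, out_dir, fmt, null=False)


def generate_null_corpus(
    config: CorpusConfig, out_dir: str | Path, fmt: str = "tsv"
) -> SyntheticCorpus:
    """Generate a label-free corpus: same m/z grid, no author signal.

    Diagnostic features lose both their fold-change and their
    author-specific presence (they behave like background), so author
    labels carry no information.
    """
    return _generate(config, out_dir, fmt, null=True)


def truth_report(
    truth: TruthTable, selected: Sequence[float], ppm_tol: float = 5.0
) -> tuple[float, float]:
    """Score a selected feature list against the planted diagnostics.

    Returns ``(recall, false_discovery_fraction)``: the fraction of
    planted diagnostic ions recovered within ``ppm_tol``, and the fraction
    of selections matching no planted diagnostic.
    """
    diag = truth.diagnostic_mz()
    selected = np.asarray(list(selected), dtype=float)
    if len(diag) == 0:
        raise ValidationError("truth table contains no diagnostic features")
    if len(selected) == 0:
        return 0.0, 0.0
    hit = np.zeros(len(diag), dtype=bool)
    matched_sel = np.zeros(len(selected), dtype=bool)
    for j, mz in enumerate(selected):
        err = np.abs(mz - diag) / diag * 1e6
        close = err <= ppm_tol
        if close.any():
            hit |= close
            matched_sel[j] = True
    recall = float(hit.mean())
    fdf = float(1.0 - matched_sel.mean())
    return recall, fdf
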