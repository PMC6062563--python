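"""Reading, consolidating and normalizing direct-infusion spectra.

A direct-infusion acquisition yields a short series of MS1 scans of the
same analyte mixture.  This module turns each sample's scans into a single
per-file peak list:

1. :func:`read_mzml` / :func:`read_peaklist_tsv` load centroided peaks;
2. :func:`consolidate_traces` merges per-scan centroids into mass traces —
   m/z values consistently present across the infusion period;
3. :func:`normalize_tus` rescales intensities so each file sums to 1000
   ("total usable signal" normalization), making files comparable.

Only MS1 centroid data are handled; profile-mode input is rejected and
MS2 scans are skipped.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.sax.saxutils as _sax
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._greedy import greedy_clusters
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

NORMALIZATION_SCALE = 1000.0

BLANK_AUTHOR = "blank"

MANIFEST_COLUMNS = [
    "sample_id",
    "file",
    "document_id",
    "author",
    "substrate",
    "replicate",
    "is_blank",
]


class CentroidPeak(NamedTuple):
    """A single centroided ion signal: (m/z in Th, intensity in counts)."""

    mz: float
    intensity: float


@dataclass
class ScanSpectrum:
    """One MS1 scan: parallel m/z / intensity arrays sorted by m/z."""

    scan_index: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("m/z and intensity arrays differ in length")
        if len(self.mz) and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(m, i) for m, i in zip(self.mz, self.intensity)]


@dataclass(frozen=True)
class SampleMeta:
    """Manifest metadata for one analysed sample (one infusion)."""

    sample_id: str
    document_id: str
    author: str
    substrate: str
    replicate: int = 1
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.is_blank != (self.author == BLANK_AUTHOR):
            raise ValidationError(
                f"sample {self.sample_id!r}: is_blank must coincide with "
                f"author == {BLANK_AUTHOR!r} (got author={self.author!r})"
            )


@dataclass
class SamplePeakList:
    """A sample's consolidated peak list plus its manifest metadata."""

    meta: SampleMeta
    mz: np.ndarray
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("m/z and intensity arrays differ in length")
        if len(self.mz):
            if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
                raise ValidationError("non-finite peak values")
            if np.any(self.mz <= 0):
                raise ValidationError("m/z values must be positive")
            if np.any(self.intensity < 0):
                raise ValidationError("intensities must be non-negative")
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class TraceParams:
    """Mass-trace consolidation parameters.

    ppm_tol
        Clustering tolerance against the running-mean m/z (ppm).
    min_scan_fraction
        Minimum fraction of scans a trace must appear in to be retained.
    intensity_summary
        How member intensities are summarised: ``mean``, ``sum`` or ``max``.
        Scans missing the trace contribute nothing to the summary.
    """

    ppm_tol: float = 5.0
    min_scan_fraction: float = 0.5
    intensity_summary: str = "mean"

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValidationError("ppm_tol must be > 0")
        if not 0 < self.min_scan_fraction <= 1:
            raise ValidationError("min_scan_fraction must be in (0, 1]")
        if self.intensity_summary not in ("mean", "sum", "max"):
            raise ValidationError("intensity_summary must be mean, sum or max")


# ---------------------------------------------------------------------------
# mzML reading / minimal writing


# mzML controlled-vocabulary accessions used by the reader/writer
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem) -> tuple[str | None, np.ndarray]:
    """Decode one ``binaryDataArray``: returns (array accession, values)."""
    import zlib as _zlib

    dtype = "<f8"
    compressed = False
    kind = None
    payload = b""
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _CV_FLOAT32:
                dtype = "<f4"
            elif acc == _CV_ZLIB:
                compressed = True
            elif acc in (_CV_MZ_ARRAY, _CV_INTENSITY_ARRAY):
                kind = acc
        elif name == "binary" and child.text:
            payload = base64.b64decode(child.text.strip())
    if compressed:
        payload = _zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[ScanSpectrum]:
    """Read the MS1 scans of a centroided mzML file.

    Scans are returned in acquisition order with peaks sorted by m/z.
    MS2 (and higher-level) scans are skipped.  Profile-mode spectra raise
    a :class:`ValidationError` — centroided input is required.

    The parser is a compact, namespace-agnostic reader of the mzML
    spectrum list (64/32-bit float arrays, zlib or no compression).
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: list[ScanSpectrum] = []
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if _localname(elem.tag) != "spectrum":
            continue
        ms_level = 1
        centroid = False
        profile = False
        arrays: dict[str, np.ndarray] = {}
        for child in elem.iter():
            name = _localname(child.tag)
            if name == "cvParam":
                acc = child.get("accession", "")
                if acc == _CV_MS_LEVEL:
                    ms_level = int(child.get("value", "1"))
                elif acc == _CV_CENTROID:
                    centroid = True
                elif acc == _CV_PROFILE:
                    profile = True
            elif name == "binaryDataArray":
                kind, values = _decode_binary_array(child)
                if kind is not None:
                    arrays[kind] = values
        if ms_level == 1:
            if profile:
                raise ValidationError(
                    f"{path.name}: profile-mode spectrum found; "
                    "centroided input required"
                )
            if not centroid:
                logger.warning(
                    "%s: spectrum not flagged centroided; assuming centroid data",
                    path.name,
                )
            scans.append(
                ScanSpectrum(
                    scan_index=len(scans),
                    mz=arrays.get(_CV_MZ_ARRAY, np.array([])),
                    intensity=arrays.get(_CV_INTENSITY_ARRAY, np.array([])),
                )
            )
        elem.clear()
    if not scans:
        raise ValidationError(f"{path.name}: no MS1 scans found")
    return scans


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(path: str | Path, scans: Sequence[ScanSpectrum]) -> None:
    """Write a minimal centroided MS1 mzML file (64-bit, uncompressed).

    Deliberately small: enough of the standard for round-tripping the
    synthetic corpus through :func:`read_mzml`.
    """
    path = Path(path)
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id={_sax.quoteattr(path.stem)}>\n'
        f'    <spectrumList count="{len(scans)}">\n'
    ]
    for i, scan in enumerate(scans):
        n = len(scan.mz)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '        <binaryDataArrayList count="2">\n'
        )
        for accession, name, values in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            enc = _b64(values)
            parts.append(
                f'          <binaryDataArray encodedLength="{len(enc)}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
                f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n'
                f'            <binary>{enc}</binary>\n'
                '          </binaryDataArray>\n'
            )
        parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts), encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV peak lists and manifests


def read_peaklist_tsv(path: str | Path, meta: SampleMeta | None = None) -> SamplePeakList:
    """Read a two-column ``mz<TAB>intensity`` peak list.

    Lines starting with ``#`` are ignored; CRLF and trailing newlines are
    tolerated.  The returned list is unnormalized; ``meta`` defaults to a
    placeholder built from the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mzs: list[float] = []
    intens: list[float] = []
    header_seen = False
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != ["mz", "intensity"]:
                    raise ParseError(
                        f"{path.name}:{lineno}: expected header 'mz\\tintensity'"
                    )
                header_seen = True
                continue
            if len(fields) != 2:
                raise ParseError(f"{path.name}:{lineno}: expected 2 columns")
            try:
                mz = float(fields[0])
                intensity = float(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric value") from exc
            if intensity < 0:
                raise ValidationError(
                    f"{path.name}:{lineno}: negative intensity {intensity}"
                )
            mzs.append(mz)
            intens.append(intensity)
    if not header_seen:
        raise ParseError(f"{path.name}: missing 'mz\\tintensity' header")
    if not mzs:
        logger.warning("%s: empty peak list", path.name)
    if meta is None:
        meta = SampleMeta(path.stem, path.stem, "A", "unknown")
    return SamplePeakList(meta=meta, mz=np.array(mzs), intensity=np.array(intens))


def write_peaklist_tsv(path: str | Path, mz: np.ndarray, intensity: np.ndarray) -> None:
    """Write a peak list in the TSV dialect read by :func:`read_peaklist_tsv`.

    Values are written with ``repr`` so the round trip is float-exact.
    """
    lines = ["mz\tintensity"]
    for m, i in zip(mz, intensity):
        lines.append(f"{float(m)!r}\t{float(i)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV.

    Required columns: sample_id, file, document_id, author, substrate,
    replicate, is_blank (0/1).  sample_id must be unique.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "document_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in manifest: {dupes}")
    df["is_blank"] = df["is_blank"].astype(int).astype(bool)
    return df


def manifest_metas(df: pd.DataFrame) -> list[SampleMeta]:
    """Convert a manifest frame to :class:`SampleMeta` records."""
    return [
        SampleMeta(
            sample_id=row.sample_id,
            document_id=row.document_id,
            author=row.author,
            substrate=row.substrate,
            replicate=int(row.replicate),
            is_blank=bool(row.is_blank),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Trace consolidation and normalization


def consolidate_traces(
    scans: Sequence[ScanSpectrum], params: TraceParams = TraceParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Consolidate per-scan centroids into per-file mass traces.

    All peaks from all scans are pooled and clustered with the same greedy
    running-mean ppm rule used for cross-file alignment, the scan index
    playing the role of the file id.  If a scan contributes several peaks
    to a trace only its most intense one is kept.  Traces present in at
    least ``min_scan_fraction`` of scans survive; each emits one peak with
    m/z = mean member m/z and intensity = ``intensity_summary`` over member
    intensities.

    Returns ``(mz, intensity)`` arrays sorted by m/z.
    """
    if len(scans) == 0:
        raise ValidationError("consolidate_traces requires at least one scan")
    n_scans = len(scans)
    mz = np.concatenate([s.mz for s in scans]) if any(len(s.mz) for s in scans) else np.array([])
    if len(mz) == 0:
        return np.array([]), np.array([])
    intensity = np.concatenate([s.intensity for s in scans])
    scan_of = np.concatenate(
        [np.full(len(s.mz), s.scan_index, dtype=int) for s in scans]
    )
    # pooled sort: m/z ascending, ties by scan index then intensity descending
    order = np.lexsort((-intensity, scan_of, mz))
    mz, intensity, scan_of = mz[order], intensity[order], scan_of[order]

    summarise = {"mean": np.mean, "sum": np.sum, "max": np.max}[params.intensity_summary]
    out_mz: list[float] = []
    out_int: list[float] = []
    for start, stop in greedy_clusters(mz, params.ppm_tol):
        # within-scan dedup: keep the most intense member per scan
        best: dict[int, int] = {}
        for j in range(start, stop):
            s = int(scan_of[j])
            if s not in best or intensity[j] > intensity[best[s]] or (
                intensity[j] == intensity[best[s]] and mz[j] < mz[best[s]]
            ):
                best[s] = j
        idx = np.array(sorted(best.values()))
        if len(idx) / n_scans < params.min_scan_fraction:
            continue
        out_mz.append(float(np.mean(mz[idx])))
        out_int.append(float(summarise(intensity[idx])))
    order = np.argsort(out_mz, kind="stable")
    return np.asarray(out_mz)[order], np.asarray(out_int)[order]


def normalize_tus(sample: SamplePeakList) -> SamplePeakList:
    """Normalize a peak list to total usable signal, scaled to 1000.

    Each intensity is divided by the file's total intensity and multiplied
    by 1000, so every normalized file carries the same total signal and
    intensities are relative abundances (per-mille of total signal).
    """
    if sample.normalized:
        raise ValidationError(
            f"sample {sample.meta.sample_id!r} is already normalized"
        )
    if len(sample) == 0:
        logger.warning(
            "sample %s: empty peak list; normalization is a no-op",
            sample.meta.sample_id,
        )
        return replace(sample, normalized=True)
    total = float(sample.intensity.sum())
    if total <= 0:
        raise ValidationError(
            f"sample {sample.meta.sample_id!r}: total intensity is zero"
        )
    return SamplePeakList(
        meta=sample.meta,
        mz=sample.mz.copy(),
        intensity=sample.intensity / total * NORMALIZATION_SCALE,
        normalized=True,
    )


def load_sample(
    path: str | Path, meta: SampleMeta, trace_params: TraceParams = TraceParams()
) -> SamplePeakList:
    """Load one sample file (mzML or TSV) into an unnormalized peak list.

    mzML input is consolidated into mass traces; TSV input is taken as an
    already-consolidated per-file list.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        scans = read_mzml(path)
        mz, intensity = consolidate_traces(scans, trace_params)
        return SamplePeakList(meta=meta, mz=mz, intensity=intensity)
    if path.suffix.lower() in (".tsv", ".txt"):
        pl = read_peaklist_tsv(path, meta=meta)
        return pl
    raise ValidationError(f"unrecognised sample file type: {path.name}")
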