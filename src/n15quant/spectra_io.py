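"""mzML MS¹ access, retention-time-window averaging, peak matching, and the
TSV/JSON interchange formats (ID table, reports, quantification cache).

The mzML reader/writer here covers the subset this workflow touches:
centroided MS¹ spectra with 64- or 32-bit float arrays, uncompressed or
zlib-compressed. Profile-mode data is rejected — centroid during conversion.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "Scan",
    "SpectrumSlice",
    "PeakMeasurement",
    "IdRecord",
    "read_ms1",
    "write_ms1",
    "average_scans",
    "match_peak",
    "read_id_table",
    "write_id_table",
    "write_cache",
    "read_cache",
    "write_peptide_report",
    "write_protein_report",
]

_NS = "http://psi.hupo.org/ms/mzml"
CACHE_SCHEMA_VERSION = 1

# PSI-MS controlled-vocabulary accessions used in reading/writing
_CV_MS1 = "MS:1000579"
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_SCAN_START = "MS:1000016"
_CV_64BIT = "MS:1000523"
_CV_32BIT = "MS:1000521"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"


@dataclass(frozen=True)
class Scan:
    """One centroided MS¹ scan: retention time (seconds) and its peak list."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    scan_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")


@dataclass
class SpectrumSlice:
    """MS¹ peaks averaged over an RT window.

    ``peaks`` holds (m/z, mean intensity) with intensity averaged over all
    scans in the window (a peak present in half the scans contributes half
    its height). Per-cluster per-scan heights are retained so peak areas can
    be integrated over the window.
    """

    peaks: np.ndarray  # (n, 2): centroid m/z, mean intensity
    rt_window: tuple[float, float]
    n_scans_averaged: int
    scan_rts: np.ndarray = field(repr=False, default=None)
    cluster_heights: np.ndarray = field(repr=False, default=None)  # (n, n_scans)


@dataclass(frozen=True)
class PeakMeasurement:
    """A matched (or absent) peak. Absence is a valid zeroed result: the
    zero-noise contract — no imputation from local noise levels."""

    target_mz: float
    matched_mz: float | None
    intensity: float
    area: float
    ppm_error: float

    @property
    def found(self) -> bool:
        return self.matched_mz is not None


@dataclass(frozen=True)
class IdRecord:
    """One peptide-spectrum match from the ¹⁴N or ¹⁵N search export."""

    sequence: str
    modifications: str
    charge: int
    rt_seconds: float
    protein: str
    channel: str  # 'light' | 'heavy'
    score: float
    decoy: bool
    source_file: str

    def __post_init__(self):
        if self.channel not in ("light", "heavy"):
            raise ValueError(f"channel must be light/heavy, got {self.channel!r}")
        if self.rt_seconds < 0:
            raise ValueError("rt_seconds must be >= 0")


# ---------------------------------------------------------------------------
# mzML


def _decode_array(bda) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.findall(f"{{{_NS}}}cvParam")}
    raw = base64.b64decode(bda.findtext(f"{{{_NS}}}binary") or "")
    if _CV_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f8" if _CV_64BIT in accs else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_ms1(path) -> list[Scan]:
    """Read all MS¹ scans from an mzML file, RT normalized to seconds."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mzML file not found: {path}")
    scans: list[Scan] = []
    saw_spectrum = False
    for _event, elem in etree.iterparse(str(path), events=("end",), tag=f"{{{_NS}}}spectrum"):
        saw_spectrum = True
        accs = {cv.get("accession"): cv for cv in elem.findall(f"{{{_NS}}}cvParam")}
        level = accs.get(_CV_MS_LEVEL)
        if level is not None and level.get("value") != "1":
            elem.clear()
            continue
        if level is None and _CV_MS1 not in accs:
            elem.clear()
            continue
        if _CV_PROFILE in accs:
            raise ValueError(
                f"{path.name}: spectrum {elem.get('id')!r} is profile mode; "
                "centroid the data during mzML conversion"
            )
        rt = 0.0
        for scan in elem.iter(f"{{{_NS}}}scan"):
            for cv in scan.findall(f"{{{_NS}}}cvParam"):
                if cv.get("accession") == _CV_SCAN_START:
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "minute":
                        rt *= 60.0
        mz = intensity = None
        for bda in elem.iter(f"{{{_NS}}}binaryDataArray"):
            accs_b = {cv.get("accession") for cv in bda.findall(f"{{{_NS}}}cvParam")}
            if _CV_MZ_ARRAY in accs_b:
                mz = _decode_array(bda)
            elif _CV_INTENSITY_ARRAY in accs_b:
                intensity = _decode_array(bda)
        if mz is None or intensity is None:
            raise ValueError(f"{path.name}: spectrum {elem.get('id')!r} lacks m/z or intensity array")
        scans.append(Scan(rt=rt, mz=mz, intensity=intensity, scan_id=elem.get("id") or ""))
        elem.clear()
    if not scans:
        msg = "no spectra" if not saw_spectrum else "no MS1 scans (MS2-only file?)"
        raise ValueError(f"{path.name}: {msg}")
    scans.sort(key=lambda s: s.rt)
    return scans


def _encode_array(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def write_ms1(path, scans: Sequence[Scan]) -> None:
    """Write centroided MS¹ scans as a minimal valid mzML document."""
    out = []
    out.append('<?xml version="1.0" encoding="utf-8"?>')
    out.append(f'<mzML xmlns="{_NS}" version="1.1.0">')
    out.append(
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
    )
    out.append(
        "<fileDescription><fileContent>"
        f'<cvParam cvRef="MS" accession="{_CV_MS1}" name="MS1 spectrum" value=""/>'
        f'<cvParam cvRef="MS" accession="{_CV_CENTROID}" name="centroid spectrum" value=""/>'
        "</fileContent></fileDescription>"
    )
    out.append(
        '<softwareList count="1"><software id="n15quant" version="0.1">'
        '<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="n15quant"/>'
        "</software></softwareList>"
    )
    out.append(
        '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">'
        '<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>'
        "</instrumentConfiguration></instrumentConfigurationList>"
    )
    out.append(
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="0" softwareRef="n15quant">'
        '<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>'
        "</processingMethod></dataProcessing></dataProcessingList>"
    )
    out.append('<run id="run" defaultInstrumentConfigurationRef="IC1">')
    out.append(f'<spectrumList count="{len(scans)}" defaultDataProcessingRef="DP1">')
    for i, scan in enumerate(scans):
        mz_b64 = _encode_array(scan.mz)
        int_b64 = _encode_array(scan.intensity)
        sid = scan.scan_id or f"scan={i + 1}"
        out.append(
            f'<spectrum index="{i}" id="{sid}" defaultArrayLength="{scan.mz.size}">'
            f'<cvParam cvRef="MS" accession="{_CV_MS1}" name="MS1 spectrum" value=""/>'
            f'<cvParam cvRef="MS" accession="{_CV_MS_LEVEL}" name="ms level" value="1"/>'
            f'<cvParam cvRef="MS" accession="{_CV_CENTROID}" name="centroid spectrum" value=""/>'
            '<scanList count="1"><cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>'
            f'<scan><cvParam cvRef="MS" accession="{_CV_SCAN_START}" name="scan start time" value="{scan.rt!r}" '
            'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/></scan></scanList>'
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">'
            f'<cvParam cvRef="MS" accession="{_CV_64BIT}" name="64-bit float" value=""/>'
            f'<cvParam cvRef="MS" accession="{_CV_NO_COMPRESSION}" name="no compression" value=""/>'
            f'<cvParam cvRef="MS" accession="{_CV_MZ_ARRAY}" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f"<binary>{mz_b64}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(int_b64)}">'
            f'<cvParam cvRef="MS" accession="{_CV_64BIT}" name="64-bit float" value=""/>'
            f'<cvParam cvRef="MS" accession="{_CV_NO_COMPRESSION}" name="no compression" value=""/>'
            f'<cvParam cvRef="MS" accession="{_CV_INTENSITY_ARRAY}" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            f"<binary>{int_b64}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    out.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# averaging and matching


def average_scans(
    scans: Sequence[Scan],
    rt_center: float,
    window: tuple[float, float] = (-5.0, 15.0),
    resolution: float = 240000.0,
) -> SpectrumSlice:
    """Average MS¹ scans over ``[rt_center+window[0], rt_center+window[1]]``.

    Peaks pooled from all scans in the window are clustered on the m/z axis
    with the same FWHM/2 tolerance used for matching (FWHM = m/z /
    resolution); each cluster's intensity is its summed signal divided by the
    number of scans in the window, i.e. the mean height including scans where
    the peak is absent.
    """
    lo, hi = rt_center + window[0], rt_center + window[1]
    selected = sorted((s for s in scans if lo <= s.rt <= hi), key=lambda s: s.rt)
    if not selected:
        raise ValueError(f"no MS1 scans in RT window [{lo:.2f}, {hi:.2f}] s")
    n = len(selected)
    mz_all = np.concatenate([s.mz for s in selected])
    int_all = np.concatenate([s.intensity for s in selected])
    scan_idx = np.concatenate([np.full(s.mz.size, i) for i, s in enumerate(selected)])
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all, scan_idx = mz_all[order], int_all[order], scan_idx[order]

    peaks = []
    heights = []
    start = 0
    for i in range(1, mz_all.size + 1):
        if i == mz_all.size or (mz_all[i] - mz_all[i - 1]) > mz_all[i - 1] / (2.0 * resolution):
            seg = slice(start, i)
            tot = int_all[seg].sum()
            if tot > 0:
                centroid = float(np.average(mz_all[seg], weights=int_all[seg]))
            else:
                centroid = float(mz_all[seg].mean())
            per_scan = np.zeros(n)
            np.add.at(per_scan, scan_idx[seg], int_all[seg])
            peaks.append((centroid, tot / n))
            heights.append(per_scan)
            start = i
    return SpectrumSlice(
        peaks=np.array(peaks) if peaks else np.empty((0, 2)),
        rt_window=(lo, hi),
        n_scans_averaged=n,
        scan_rts=np.array([s.rt for s in selected]),
        cluster_heights=np.array(heights) if heights else np.empty((0, n)),
    )


def match_peak(
    slice_: SpectrumSlice, target_mz: float, resolution: float = 240000.0
) -> PeakMeasurement:
    """Nearest averaged peak within FWHM/2 of the target; ties toward the
    more intense peak. No peak in tolerance → zeroed measurement."""
    tol = target_mz / (2.0 * resolution)
    absent = PeakMeasurement(target_mz, None, 0.0, 0.0, float("nan"))
    if slice_.peaks.size == 0:
        return absent
    d = np.abs(slice_.peaks[:, 0] - target_mz)
    inside = np.nonzero(d <= tol)[0]
    if inside.size == 0:
        return absent
    dmin = d[inside].min()
    best = inside[d[inside] <= dmin + 1e-12]
    idx = int(best[np.argmax(slice_.peaks[best, 1])])
    mzv, inten = slice_.peaks[idx]
    area = float(np.trapezoid(slice_.cluster_heights[idx], slice_.scan_rts)) if slice_.scan_rts is not None and slice_.scan_rts.size > 1 else inten
    return PeakMeasurement(
        target_mz=target_mz,
        matched_mz=float(mzv),
        intensity=float(inten),
        area=area,
        ppm_error=float((mzv - target_mz) / target_mz * 1e6),
    )


# ---------------------------------------------------------------------------
# ID table

_ID_COLUMNS = [
    "sequence",
    "modifications",
    "charge",
    "rt_seconds",
    "protein",
    "channel",
    "score",
    "decoy",
    "source_file",
]

_CHANNEL_MAP = {"light": "light", "heavy": "heavy", "14n": "light", "15n": "heavy"}


def read_id_table(path) -> list[IdRecord]:
    """Read the peptide-identification TSV (one header line, documented schema)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty ID table")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _ID_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: ID table missing columns {missing}")
    idx = {c: header.index(c) for c in _ID_COLUMNS}
    records = []
    for row_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            channel_raw = parts[idx["channel"]].strip().lower()
            if channel_raw not in _CHANNEL_MAP:
                raise ValueError(f"unknown channel {parts[idx['channel']]!r} (use 14N/15N or light/heavy)")
            records.append(
                IdRecord(
                    sequence=parts[idx["sequence"]].strip(),
                    modifications=parts[idx["modifications"]].strip(),
                    charge=int(parts[idx["charge"]]),
                    rt_seconds=float(parts[idx["rt_seconds"]]),
                    protein=parts[idx["protein"]].strip(),
                    channel=_CHANNEL_MAP[channel_raw],
                    score=float(parts[idx["score"]]),
                    decoy=parts[idx["decoy"]].strip().lower() in ("1", "true", "yes"),
                    source_file=parts[idx["source_file"]].strip(),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
    return records


def write_id_table(path, records: Iterable[IdRecord]) -> None:
    lines = ["\t".join(_ID_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.sequence,
                    r.modifications,
                    str(r.charge),
                    f"{r.rt_seconds:.3f}",
                    r.protein,
                    r.channel,
                    f"{r.score:.4f}",
                    "1" if r.decoy else "0",
                    r.source_file,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cache and reports


def write_cache(path, quants: Sequence, config: dict) -> None:
    """Persist quantification results + run config as a versioned JSON cache,
    sufficient to regenerate every report without re-opening the mzML."""
    doc = {
        "schema_version": CACHE_SCHEMA_VERSION,
        "config": config,
        "peptides": [q.to_dict() for q in quants],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_cache(path) -> tuple[list, dict]:
    from .quant import PeptideQuant

    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != CACHE_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: cache schema_version {version!r} != supported {CACHE_SCHEMA_VERSION}"
        )
    return [PeptideQuant.from_dict(d) for d in doc["peptides"]], doc["config"]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        if np.isnan(x):
            return "NaN"
        if np.isinf(x):
            return "Inf" if x > 0 else "-Inf"
        return f"{x:.6g}"
    return str(x)


def write_peptide_report(path, quants: Sequence) -> None:
    cols = [
        "sequence", "modifications", "charge", "rt_seconds", "protein",
        "id_channel", "source_file", "light_corrected", "heavy_corrected",
        "ratio_LH", "status", "cs_light", "cs_heavy", "total_intensity", "flags",
    ]
    lines = ["\t".join(cols)]
    for q in quants:
        r = q.id_record
        lines.append(
            "\t".join(
                [
                    r.sequence, r.modifications, str(r.charge), _fmt(r.rt_seconds),
                    r.protein, r.channel, r.source_file,
                    _fmt(q.light_corrected), _fmt(q.heavy_corrected),
                    _fmt(q.ratio_LH), q.status, _fmt(q.cs_light), _fmt(q.cs_heavy),
                    _fmt(q.total_intensity), ",".join(q.flags),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_protein_report(path, proteins: Sequence) -> None:
    cols = [
        "accession", "n_peptides", "q1", "median", "q3",
        "normalized_median", "total_intensity", "flags",
    ]
    lines = ["\t".join(cols)]
    for p in proteins:
        lines.append(
            "\t".join(
                [
                    p.accession, str(p.n_peptide_quants), _fmt(p.q1), _fmt(p.median),
                    _fmt(p.q3), _fmt(p.normalized_median), _fmt(p.total_intensity),
                    ",".join(p.flags),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_boxplot_table(path, quants: Sequence) -> None:
    """Long-format (accession, ratio) table of finite peptide ratios, ready
    for box-plot tooling."""
    lines = ["accession\tratio_LH"]
    for q in quants:
        if q.ratio_LH is not None and np.isfinite(q.ratio_LH) and q.ratio_LH > 0:
            lines.append(f"{q.id_record.protein}\t{_fmt(q.ratio_LH)}")
    Path(path).write_text("\n".join(lines) + "\n")
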