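"""Spectrum containers, mzML input/output, averaging, EICs, and AUC.

Reading is a direct lxml parser of the mzML CV vocabulary (32/64-bit
arrays, zlib or no compression, minute/second scan times).  Writing uses a
small, deterministic mzML 1.1 serializer (64-bit little-endian, base64, no
compression, no timestamps) so that identical runs produce byte-identical
files — a property the synthetic-data contract relies on.  The writer is
cross-validated against Bioconductor's mzR reader in the test suite.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Scan",
    "SpectrumRun",
    "ChromatogramTrace",
    "read_mzml",
    "write_mzml",
    "average_spectra",
    "extract_eic",
    "total_ion_chromatogram",
    "base_peak_chromatogram",
    "auc",
]

CENTROID = "centroid"
PROFILE = "profile"


@dataclass
class Scan:
    """One mass spectrum: retention time (minutes) plus peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    mode: str = CENTROID

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            raise ValueError("mz array must be ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.mode not in (CENTROID, PROFILE):
            raise ValueError(f"unknown scan mode {self.mode!r}")


@dataclass
class SpectrumRun:
    """A time-ordered LC-MS run of MS1 scans plus acquisition metadata."""

    scans: list[Scan]
    instrument: str = "synthetic-qtof"
    mz_range: tuple[float, float] = (300.0, 3000.0)
    scan_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    @property
    def rt_span(self) -> tuple[float, float]:
        if not self.scans:
            return (0.0, 0.0)
        return (self.scans[0].rt, self.scans[-1].rt)

    def scans_in_window(self, rt_lo: float, rt_hi: float) -> list[Scan]:
        return [s for s in self.scans if rt_lo <= s.rt <= rt_hi]


@dataclass
class ChromatogramTrace:
    """Summed intensity of a set of m/z windows against retention time."""

    rt: np.ndarray
    intensity: np.ndarray
    windows: list[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("trace intensities must be non-negative")

    @property
    def apex_rt(self) -> float:
        return float(self.rt[int(np.argmax(self.intensity))])


# ---------------------------------------------------------------------------
# mzML writing (deterministic, uncompressed 64-bit)

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="fiberform" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000189" name="quadrupole time-of-flight" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="fiberform">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{n_scans}" defaultDataProcessingRef="DP1">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""

_MODE_CV = {
    CENTROID: '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
    PROFILE: '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>',
}


def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


def write_mzml(run: SpectrumRun, path, run_id: str = "run") -> None:
    """Serialize a run as uncompressed 64-bit mzML 1.1."""
    parts = [_MZML_HEADER.format(run_id=run_id, n_scans=len(run.scans))]
    for i, scan in enumerate(run.scans):
        mz_b64 = _encode_array(scan.mz)
        int_b64 = _encode_array(scan.intensity)
        parts.append(f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        {_MODE_CV[scan.mode]}
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    parts.append(_MZML_FOOTER)
    with open(path, "wb") as fh:
        fh.write("".join(parts).encode("utf-8"))


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(elem) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, float64 values)."""
    dtype = "<f8"
    compressed = False
    kind: str | None = None
    for cv in elem.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
    binary = elem.find(f"{_NS}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_mzml(path) -> SpectrumRun:
    """Parse an mzML file into a :class:`SpectrumRun` (MS1 scans only).

    Understands 32/64-bit float arrays with zlib or no compression, scan
    start times in minutes or seconds, and the centroid/profile mode CV
    params; a spectrum without a mode param gets the mode inferred from its
    sampling density (with a warning).
    """
    from lxml import etree

    scans: list[Scan] = []
    index = -1
    for _event, elem in etree.iterparse(str(path), tag=f"{_NS}spectrum"):
        index += 1
        ms_level = 1
        mode: str | None = None
        rt = float(index)
        for cv in elem.findall(f"{_NS}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000511":
                ms_level = int(cv.get("value"))
            elif acc == "MS:1000127":
                mode = CENTROID
            elif acc == "MS:1000128":
                mode = PROFILE
        for cv in elem.iter(f"{_NS}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        if ms_level != 1:
            elem.clear()
            continue
        mz = np.empty(0)
        inten = np.empty(0)
        for arr in elem.iter(f"{_NS}binaryDataArray"):
            kind, values = _decode_binary_array(arr)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mode is None:
            mode = _infer_mode(mz)
            warnings.warn(
                f"spectrum index {index} lacks a mode CV param; "
                f"inferred {mode} from peak density")
        scans.append(Scan(rt=rt, mz=mz, intensity=inten, mode=mode))
        elem.clear()
    return SpectrumRun(scans=scans, instrument="mzml")


def _infer_mode(mz: np.ndarray) -> str:
    """Dense, nearly uniform sampling suggests profile data."""
    if mz.size < 10:
        return CENTROID
    d = np.diff(mz)
    return PROFILE if np.median(d) < 0.005 else CENTROID


# ---------------------------------------------------------------------------
# averaging, EICs, AUC


def average_spectra(
    run: SpectrumRun,
    rt_window: tuple[float, float],
    cluster_tol: float = 0.01,
) -> Scan:
    """Average scans across a retention-time window into one spectrum.

    Centroid mode: peaks from all window scans are clustered along m/z with
    gap threshold ``cluster_tol``; each cluster reports the intensity-weighted
    mean m/z and the mean intensity over the window's scans (a scan without
    the peak contributes zero).  Profile mode: scans are resampled onto the
    first scan's grid and averaged.
    """
    lo, hi = rt_window
    scans = run.scans_in_window(lo, hi)
    if not scans:
        raise ValueError(
            f"rt window [{lo}, {hi}] contains no scans; run spans {run.rt_span}")
    n = len(scans)
    if scans[0].mode == PROFILE:
        grid = scans[0].mz
        acc = np.zeros_like(grid)
        for s in scans:
            acc += np.interp(grid, s.mz, s.intensity, left=0.0, right=0.0)
        return Scan(rt=0.5 * (lo + hi), mz=grid, intensity=acc / n, mode=PROFILE)

    mz_all = np.concatenate([s.mz for s in scans])
    int_all = np.concatenate([s.intensity for s in scans])
    if mz_all.size == 0:
        return Scan(rt=0.5 * (lo + hi), mz=mz_all, intensity=int_all)
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all = mz_all[order], int_all[order]
    breaks = np.nonzero(np.diff(mz_all) > cluster_tol)[0] + 1
    groups = np.concatenate([[0], breaks, [mz_all.size]])
    out_mz = np.empty(groups.size - 1)
    out_int = np.empty(groups.size - 1)
    for k in range(groups.size - 1):
        sl = slice(groups[k], groups[k + 1])
        w = int_all[sl]
        tot = w.sum()
        out_mz[k] = np.average(mz_all[sl], weights=w) if tot > 0 else mz_all[sl].mean()
        out_int[k] = tot / n
    keep = out_int > 0
    return Scan(rt=0.5 * (lo + hi), mz=out_mz[keep], intensity=out_int[keep])


def _merge_windows(
    windows: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    ws = sorted(windows)
    merged = [list(ws[0])]
    overlapped = False
    for lo, hi in ws[1:]:
        if lo < merged[-1][1]:
            overlapped = True
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    if overlapped:
        warnings.warn("overlapping m/z windows merged to avoid double counting")
    return [(lo, hi) for lo, hi in merged]


def extract_eic(
    run: SpectrumRun,
    windows: list[tuple[float, float]],
    label: str = "",
) -> ChromatogramTrace:
    """Extracted ion chromatogram over half-open m/z windows ``[lo, hi)``."""
    if not windows:
        raise ValueError("at least one m/z window is required")
    for lo, hi in windows:
        if not lo < hi:
            raise ValueError(f"invalid window ({lo}, {hi}): need lo < hi")
    merged = _merge_windows(list(windows))
    rts = np.array([s.rt for s in run.scans])
    intensity = np.zeros(len(run.scans))
    for i, scan in enumerate(run.scans):
        total = 0.0
        for lo, hi in merged:
            a = np.searchsorted(scan.mz, lo, side="left")
            b = np.searchsorted(scan.mz, hi, side="left")
            total += scan.intensity[a:b].sum()
        intensity[i] = total
    return ChromatogramTrace(rt=rts, intensity=intensity,
                             windows=merged, label=label)


def total_ion_chromatogram(run: SpectrumRun) -> ChromatogramTrace:
    rts = np.array([s.rt for s in run.scans])
    tic = np.array([s.intensity.sum() for s in run.scans])
    return ChromatogramTrace(rt=rts, intensity=tic, windows=[], label="TIC")


def base_peak_chromatogram(run: SpectrumRun) -> ChromatogramTrace:
    rts = np.array([s.rt for s in run.scans])
    bpc = np.array([s.intensity.max() if s.intensity.size else 0.0
                    for s in run.scans])
    return ChromatogramTrace(rt=rts, intensity=bpc, windows=[], label="BPC")


def auc(
    trace: ChromatogramTrace,
    rt_bounds: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal area under a chromatogram, optionally within rt bounds."""
    rt, y = trace.rt, trace.intensity
    if rt_bounds is not None:
        lo, hi = rt_bounds
        mask = (rt >= lo) & (rt <= hi)
        rt, y = rt[mask], y[mask]
    if rt.size < 2:
        raise ValueError("AUC needs at least two chromatogram points in bounds")
    return float(np.trapezoid(y, rt))
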