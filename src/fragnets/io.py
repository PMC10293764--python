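"""File interfaces: mzML, centroided peak lists, parameter tables, results.

mzML reading goes through pyteomics; writing synthetic spectra uses a
minimal mzML emitter (one MS1 + MS2 scans with precursor metadata and
uncompressed 64-bit float arrays) that pyteomics round-trips bit-exactly.
Parameter files are simple two-column CSVs: ``MaxAtomicSubscripts.csv``
maps element symbols to maximum subscripts, ``ParametersTable.csv`` maps
run-parameter names (``NoiseTresInt`` etc.) to values.
"""

from __future__ import annotations

import base64
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd

from .model import RESULT_COLUMNS, AnnotationResult, ResultRow
from .params import UNANNOTATED, RunParameters
from .space import SubscriptBounds

__all__ = [
    "Scan",
    "read_mzml",
    "select_ms2",
    "read_peaklist",
    "read_bounds",
    "read_params",
    "write_results",
    "write_mzml",
]


@dataclass(frozen=True)
class Scan:
    """One spectrum from an mzML file."""

    index: int
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    is_profile: bool = True

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions used when decoding spectra
_CV_MS_LEVEL = "MS:1000511"
_CV_PROFILE = "MS:1000128"
_CV_CENTROID = "MS:1000127"
_CV_SELECTED_MZ = "MS:1000744"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"


def _cv_accessions(element) -> dict[str, str]:
    return {cv.get("accession"): cv.get("value", "")
            for cv in element.iter(f"{_MZML_NS}cvParam")}


def _decode_binary_array(bda) -> np.ndarray:
    accs = _cv_accessions(bda)
    binary = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _CV_ZLIB in accs:
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_FLOAT32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(idx: int, spectrum) -> Scan:
    accs = _cv_accessions(spectrum)
    level = int(accs.get(_CV_MS_LEVEL, "1"))
    # unlabeled data is assumed raw/profile
    profile = _CV_CENTROID not in accs
    prec = None
    for ion in spectrum.iter(f"{_MZML_NS}selectedIon"):
        value = _cv_accessions(ion).get(_CV_SELECTED_MZ)
        if value:
            prec = float(value)
            break
    mz = intensity = np.array([])
    for bda in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
        arr_accs = _cv_accessions(bda)
        if _CV_MZ_ARRAY in arr_accs:
            mz = _decode_binary_array(bda)
        elif _CV_INTENSITY_ARRAY in arr_accs:
            intensity = _decode_binary_array(bda)
    return Scan(index=idx, ms_level=level, mz=mz, intensity=intensity,
                precursor_mz=prec, is_profile=profile)


def read_mzml(path) -> list[Scan]:
    """All scans of an mzML file, with MS level, precursor m/z for MS2, and
    the raw point arrays.

    Decodes the standard encodings (base64, 32/64-bit little-endian floats,
    optional zlib compression) directly from the XML; indexed wrappers are
    handled since the spectrum elements are read wherever they occur.
    Centroided-only MS2 data triggers a warning: per-peak
    confidence-interval estimation degrades to the fixed default tolerance.
    """
    from lxml import etree

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mzML file not found: {path}")
    scans: list[Scan] = []
    try:
        tree = etree.parse(str(path))
        for idx, spectrum in enumerate(tree.iter(f"{_MZML_NS}spectrum")):
            scans.append(_parse_spectrum(idx, spectrum))
    except FileNotFoundError:
        raise
    except etree.XMLSyntaxError as exc:  # malformed / truncated XML
        raise ValueError(f"failed to parse mzML file {path}: {exc}") from exc
    if not any(s.ms_level == 2 for s in scans):
        warnings.warn(f"{path.name}: no MS2 scans found", stacklevel=2)
    if any(s.ms_level == 2 and not s.is_profile for s in scans):
        warnings.warn(
            "centroided MS2 data: per-peak confidence intervals cannot be "
            "estimated, falling back to the default ppm tolerance",
            stacklevel=2,
        )
    return scans


def select_ms2(scans: Iterable[Scan], target_mz: float,
               precursor_tol: float = 0.5) -> Scan:
    """The MS2 scan whose recorded precursor m/z is nearest the target;
    among equals, the one with the highest total intensity (deterministic)."""
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    ms2 = [s for s in scans if s.ms_level == 2 and s.precursor_mz is not None]
    if not ms2:
        raise ValueError("no MS2 scans with precursor metadata")
    within = [s for s in ms2 if abs(s.precursor_mz - target_mz) <= precursor_tol]
    if not within:
        nearest = min(ms2, key=lambda s: abs(s.precursor_mz - target_mz))
        raise ValueError(
            f"no MS2 scan with precursor within {precursor_tol} Da of "
            f"{target_mz:.4f}; nearest recorded precursor is "
            f"{nearest.precursor_mz:.4f}")
    best_d = min(abs(s.precursor_mz - target_mz) for s in within)
    nearest = [s for s in within if abs(s.precursor_mz - target_mz) == best_d]
    return max(nearest, key=lambda s: s.total_intensity)


# ---------------------------------------------------------------------------
# mzML writing (minimal, for synthetic spectra)
# ---------------------------------------------------------------------------

def _b64(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _binary_array(xml: list[str], values, accession: str, name: str) -> None:
    encoded = _b64(list(values))
    xml.append(f'<binaryDataArray encodedLength="{len(encoded)}">')
    xml.append('<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>')
    xml.append('<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>')
    xml.append(f'<cvParam cvRef="MS" accession="{accession}" name={quoteattr(name)} value=""/>')
    xml.append(f"<binary>{encoded}</binary>")
    xml.append("</binaryDataArray>")


def _spectrum_xml(xml: list[str], index: int, scan: Scan) -> None:
    mode = ("MS:1000128", "profile spectrum") if scan.is_profile else \
        ("MS:1000127", "centroid spectrum")
    kind = ("MS:1000579", "MS1 spectrum") if scan.ms_level == 1 else \
        ("MS:1000580", "MSn spectrum")
    xml.append(f'<spectrum index="{index}" id="scan={index + 1}" '
               f'defaultArrayLength="{len(scan.mz)}">')
    xml.append(f'<cvParam cvRef="MS" accession="{kind[0]}" name="{kind[1]}" value=""/>')
    xml.append(f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
               f'value="{scan.ms_level}"/>')
    xml.append(f'<cvParam cvRef="MS" accession="{mode[0]}" name="{mode[1]}" value=""/>')
    if scan.ms_level == 2 and scan.precursor_mz is not None:
        xml.append("<precursorList count=\"1\"><precursor>"
                   "<selectedIonList count=\"1\"><selectedIon>")
        xml.append(f'<cvParam cvRef="MS" accession="MS:1000744" '
                   f'name="selected ion m/z" value="{scan.precursor_mz!r}" '
                   f'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>')
        xml.append("</selectedIon></selectedIonList></precursor></precursorList>")
    xml.append('<binaryDataArrayList count="2">')
    _binary_array(xml, scan.mz, "MS:1000514", "m/z array")
    _binary_array(xml, scan.intensity, "MS:1000515", "intensity array")
    xml.append("</binaryDataArrayList>")
    xml.append("</spectrum>")


def write_mzml(scans: Sequence[Scan], path) -> None:
    """Write scans as a minimal valid mzML file (uncompressed 64-bit float
    arrays, base64-encoded, little-endian) readable by pyteomics."""
    xml = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="1">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry '
        'Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "</cvList>",
        '<run id="synthetic">',
        f'<spectrumList count="{len(scans)}" defaultDataProcessingRef="dp1">',
    ]
    for i, scan in enumerate(scans):
        _spectrum_xml(xml, i, scan)
    xml.extend(["</spectrumList>", "</run>", "</mzML>"])
    text = "\n".join(xml)
    # sanity: well-formed XML before touching the target path
    ET.fromstring(text)
    Path(path).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# peak lists and parameter tables
# ---------------------------------------------------------------------------

def read_peaklist(path) -> list[tuple[float, float]]:
    """Two-column delimited text (m/z, intensity), header optional, any of
    comma/semicolon/tab/space separated; returns pairs sorted by m/z."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peak list not found: {path}")
    pairs: list[tuple[float, float]] = []
    lines = path.read_text().splitlines()
    non_empty = [(no, ln) for no, ln in enumerate(lines, 1) if ln.strip()]
    if not non_empty:
        raise ValueError(f"peak list {path} is empty")
    for pos, (no, line) in enumerate(non_empty):
        fields = [f for f in line.replace(";", ",").replace("\t", ",")
                  .replace(" ", ",").split(",") if f]
        if len(fields) < 2:
            raise ValueError(f"{path}:{no}: expected two columns, got {line!r}")
        try:
            pairs.append((float(fields[0]), float(fields[1])))
        except ValueError:
            if pos == 0:  # header row
                continue
            raise ValueError(f"{path}:{no}: non-numeric value in {line!r}") from None
    if not pairs:
        raise ValueError(f"peak list {path} contains no numeric rows")
    pairs.sort()
    return pairs


def read_bounds(path) -> SubscriptBounds:
    """``MaxAtomicSubscripts.csv`` dialect: one ``element,max`` row per
    element; isotopes may be written ``13C`` or ``[13C]``.  Unknown symbols
    and negative bounds raise."""
    path = Path(path)
    table: dict[str, int] = {}
    for no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) < 2:
            raise ValueError(f"{path}:{no}: expected 'element,max', got {line!r}")
        label, value = fields[0], fields[1]
        if no == 1 and not _is_int(value):
            continue  # header row
        if not _is_int(value):
            raise ValueError(f"{path}:{no}: non-integer bound {value!r}")
        table[label] = int(value)
    return SubscriptBounds.from_dict(table)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


_PARAM_ALIASES = {
    "noisetresint": "noise_threshold",
    "noise_threshold": "noise_threshold",
    "ionization": "ionization",
    "default_tol_ppm": "default_tol_ppm",
    "tolerance_ppm": "default_tol_ppm",
    "gap_ppm": "gap_ppm",
    "confidence_level": "confidence_level",
    "intensity_floor_pct": "intensity_floor_pct",
    "network_mode": "network_mode",
    "network_cap": "network_cap",
    "min_cluster_points": "min_cluster_points",
    "tol_floor_ppm": "tol_floor_ppm",
    "precursor_match_da": "precursor_match_da",
    "require_precursor_consistency": "require_precursor_consistency",
    "weighted_centroid": "weighted_centroid",
}

_BOOL_PARAMS = {"require_precursor_consistency", "weighted_centroid"}
_INT_PARAMS = {"network_cap", "min_cluster_points"}
_STR_PARAMS = {"ionization", "network_mode"}


def read_params(path) -> RunParameters:
    """``ParametersTable.csv`` dialect: ``name,value`` rows.  Unknown
    parameter names warn and are ignored; missing parameters take the
    documented defaults."""
    path = Path(path)
    changes = {}
    for no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) < 2:
            raise ValueError(f"{path}:{no}: expected 'parameter,value', got {line!r}")
        raw_name, raw_value = fields[0], fields[1]
        if no == 1 and raw_name.lower() in ("parameter", "name"):
            continue
        key = _PARAM_ALIASES.get(raw_name.strip().lower())
        if key is None:
            warnings.warn(f"{path}:{no}: unknown parameter {raw_name!r} ignored",
                          stacklevel=2)
            continue
        if key in _STR_PARAMS:
            value = raw_value.replace("−", "-")
        elif key in _BOOL_PARAMS:
            value = raw_value.strip().lower() in ("1", "true", "yes", "y")
        elif key in _INT_PARAMS:
            value = int(raw_value)
        else:
            value = float(raw_value)
        changes[key] = value
    return RunParameters(**changes)


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def _formatted_frame(rows: Sequence[ResultRow]) -> pd.DataFrame:
    """Rows rendered with the report precision: m/z 7 decimals, ppm and
    intensity 1 decimal; blanks for the unannotated placeholder."""
    def fmt(value, spec):
        return "" if value is None else format(value, spec)

    records = []
    for r in rows:
        records.append({
            "Molecular formula": r.molecular_formula,
            "Mass error (ppm)": fmt(r.mass_error_ppm, ".1f"),
            "Predicted m/z (Da)": fmt(r.predicted_mz, ".7f"),
            "Measured m/z (Da)": format(r.measured_mz, ".7f"),
            "Confidence interval (ppm)": fmt(r.ci_ppm, ".1f"),
            "Relative intensity (%)": format(r.relative_intensity_pct, ".1f"),
            "#Data points": r.n_points,
        })
    return pd.DataFrame(records, columns=list(RESULT_COLUMNS))


def write_results(result: AnnotationResult | Sequence[ResultRow], path,
                  format: str = "csv") -> None:
    """Write the results table as csv or xlsx with the canonical header."""
    rows = result.rows if isinstance(result, AnnotationResult) else list(result)
    if not rows:
        raise ValueError("no rows to write")
    frame = _formatted_frame(rows)
    path = Path(path)
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "xlsx":
        frame.to_excel(path, index=False)
    else:
        raise ValueError("format must be 'csv' or 'xlsx'")
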