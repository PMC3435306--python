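"""File formats: two-column text spectra, sample sheets, CSV tables, mzML.

The primary interchange format is plain text: '#'-prefixed ``key=value``
header lines followed by two whitespace-separated columns (m/z, intensity)
in ascending m/z order.  Cohort membership lives in a sample sheet CSV with
columns ``spectrum_id,sample_id,replicate,label``.

mzML support is intentionally minimal and self-contained: the writer emits
valid mzML 1.1 (MS1 profile spectra, 64-bit float, zlib-compressed binary
arrays) and the reader handles the common encodings (zlib or none, 32- or
64-bit floats).  Both directions are round-trip tested.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .preprocess import LabeledCohort, Spectrum

SAMPLE_SHEET_COLUMNS = ["spectrum_id", "sample_id", "replicate", "label"]


def write_spectrum_text(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# spectrum_id={spectrum.spectrum_id}",
        f"# sample_id={spectrum.sample_id}",
        f"# replicate={spectrum.replicate}",
    ]
    if spectrum.label is not None:
        lines.append(f"# label={spectrum.label}")
    for mz, it in zip(spectrum.mz, spectrum.intensity):
        lines.append(f"{mz:.10g} {it:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_text(path: str | Path) -> Spectrum:
    path = Path(path)
    meta: dict[str, str] = {}
    mz: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}: expected two columns, got {line!r}")
            mz.append(float(fields[0]))
            intensity.append(float(fields[1]))
    return Spectrum(
        mz=np.array(mz),
        intensity=np.array(intensity),
        spectrum_id=meta.get("spectrum_id", path.stem),
        sample_id=meta.get("sample_id", meta.get("spectrum_id", path.stem)),
        replicate=int(meta.get("replicate", 1)),
        label=meta.get("label") or None,
    )


def write_sample_sheet(cohort: LabeledCohort, path: str | Path) -> None:
    rows = [
        (s.spectrum_id, s.sample_id, s.replicate, cohort.labels[s.sample_id])
        for s in cohort.spectra
    ]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"spectrum_id": str, "sample_id": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {sorted(missing)}")
    return table


# --- mzML ---------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _binary_element(parent: ET.Element, values: np.ndarray, array_name: str, accession: str) -> None:
    raw = np.asarray(values, dtype="<f8").tobytes()
    encoded = base64.b64encode(zlib.compress(raw)).decode("ascii")
    bda = ET.SubElement(parent, "binaryDataArray", encodedLength=str(len(encoded)))
    ET.SubElement(
        bda, "cvParam", cvRef="MS", accession="MS:1000523", name="64-bit float", value=""
    )
    ET.SubElement(
        bda, "cvParam", cvRef="MS", accession="MS:1000574", name="zlib compression", value=""
    )
    ET.SubElement(bda, "cvParam", cvRef="MS", accession=accession, name=array_name, value="")
    ET.SubElement(bda, "binary").text = encoded


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write MS1 profile spectra as minimal mzML 1.1."""
    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    cv_list = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(
        cv_list,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, "run", id="run1")
    spectrum_list = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
    for index, spec in enumerate(spectra):
        el = ET.SubElement(
            spectrum_list,
            "spectrum",
            index=str(index),
            id=f"scan={index} spectrum_id={spec.spectrum_id}",
            defaultArrayLength=str(spec.mz.size),
        )
        ET.SubElement(el, "cvParam", cvRef="MS", accession="MS:1000511", name="ms level", value="1")
        ET.SubElement(el, "cvParam", cvRef="MS", accession="MS:1000128", name="profile spectrum", value="")
        arrays = ET.SubElement(el, "binaryDataArrayList", count="2")
        _binary_element(arrays, spec.mz, "m/z array", "MS:1000514")
        _binary_element(arrays, spec.intensity, "intensity array", "MS:1000515")
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _mzml_spectrum_id(raw_id: str) -> str:
    for token in str(raw_id).split():
        if token.startswith("spectrum_id="):
            return token.partition("=")[2]
    return str(raw_id)


def _decode_binary_array(bda: ET.Element, ns: str) -> tuple[str, np.ndarray]:
    accessions = {
        p.get("accession"): p.get("name", "")
        for p in bda.findall(f"{ns}cvParam")
    }
    raw = base64.b64decode((bda.find(f"{ns}binary").text or "").encode("ascii"))
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"  # 32- vs 64-bit float
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if "MS:1000514" in accessions:
        kind = "mz"
    elif "MS:1000515" in accessions:
        kind = "intensity"
    else:
        kind = "other"
    return kind, values


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read MS1 spectra from an mzML file.

    Uses a small built-in parser (zlib/no compression, 32/64-bit floats);
    round-trips with :func:`write_mzml` and matches Bioconductor's mzR on
    the files this package writes.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    ns = f"{{{_MZML_NS}}}" if root.tag.startswith("{") else ""
    spectra: list[Spectrum] = []
    for el in root.iter(f"{ns}spectrum"):
        sid = _mzml_spectrum_id(el.get("id", f"scan={len(spectra)}"))
        arrays: dict[str, np.ndarray] = {}
        for bda in el.iter(f"{ns}binaryDataArray"):
            kind, values = _decode_binary_array(bda, ns)
            arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum {sid!r} lacks m/z or intensity array")
        spectra.append(
            Spectrum(
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                spectrum_id=sid,
                sample_id=sid,
            )
        )
    return spectra


def read_spectra(paths: Iterable[str | Path]) -> list[Spectrum]:
    """Read a mixture of text and mzML spectrum files."""
    spectra: list[Spectrum] = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".mzml":
            spectra.extend(read_mzml(p))
        else:
            spectra.append(read_spectrum_text(p))
    return spectra
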