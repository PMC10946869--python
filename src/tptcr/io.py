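"""Standard-format I/O: delimited peak lists and tables, mzML, imzML, TIFF/PNG.

imzML goes through pyimzml. mzML uses a minimal self-contained
writer/reader pair (unindexed mzML 1.1, uncompressed 64-bit float arrays,
zlib accepted on read) — enough for single-spectrum exchange with standard
tools.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .msms import LigandRecord
from .simulate import LineScanDataset, Spectrum
from .targeting import MatchReport, TargetEntry, TargetTable

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_target_table",
    "write_target_table",
    "read_ligand_library",
    "write_ligand_library",
    "write_mzml",
    "read_mzml",
    "write_imzml",
    "read_imzml",
    "write_image_tiff",
    "write_image_png",
    "write_pixel_table",
    "write_match_report",
]


# ---------------------------------------------------------------- peak lists

def read_peaklist(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column delimited text (m/z, intensity); '#' comments allowed.
    A single m/z column is accepted with unit intensities."""
    df = pd.read_csv(path, sep=r"[\s,;]+", engine="python", comment="#",
                     header=None)
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy(float), np.ones(len(df))
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_peaklist(path: str | Path, mz: Sequence[float],
                   intensity: Sequence[float], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for m, i in zip(mz, intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")


# -------------------------------------------------------------- target table

_TT_COLUMNS = ["species", "precursor_mz", "precursor_charge", "product_charges",
               "isolation_width", "match_tolerance"]


def write_target_table(path: str | Path, table: TargetTable,
                       header: str | None = None) -> None:
    rows = [
        {
            "species": e.species_name,
            "precursor_mz": e.precursor_mz,
            "precursor_charge": e.precursor_charge,
            "product_charges": ";".join(str(z) for z in e.product_charges),
            "isolation_width": e.isolation_width,
            "match_tolerance": e.match_tolerance,
        }
        for e in table.entries
    ]
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# max_isolation_mz: {table.max_isolation_mz}\n")
        pd.DataFrame(rows, columns=_TT_COLUMNS).to_csv(fh, index=False)


def read_target_table(path: str | Path) -> TargetTable:
    max_iso = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln, line in enumerate(lines, 1):
        if line.startswith("#"):
            if "max_isolation_mz:" in line:
                max_iso = float(line.split(":", 1)[1])
            continue
        body.append((ln, line))
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("".join(l for _, l in body)))
        missing = [c for c in _TT_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        entries = []
        for i, row in df.iterrows():
            entries.append(
                TargetEntry(
                    species_name=str(row["species"]),
                    precursor_mz=float(row["precursor_mz"]),
                    precursor_charge=int(row["precursor_charge"]),
                    product_charges=tuple(
                        int(z) for z in str(row["product_charges"]).split(";")
                    ),
                    isolation_width=float(row.get("isolation_width", 4.0)),
                    match_tolerance=float(row.get("match_tolerance", 0.5)),
                )
            )
    except (ValueError, KeyError, TypeError) as exc:
        raise ValueError(f"malformed target table {path}: {exc}") from exc
    kwargs = {} if max_iso is None else {"max_isolation_mz": max_iso}
    return TargetTable(entries=tuple(entries), **kwargs)


# ------------------------------------------------------------ ligand library

def write_ligand_library(path: str | Path, library: Sequence[LigandRecord]) -> None:
    pd.DataFrame(
        [
            {"name": l.name, "formula": l.formula,
             "monoisotopic_mass": l.monoisotopic_mass,
             "average_mass": l.average_mass}
            for l in library
        ]
    ).to_csv(path, index=False)


def read_ligand_library(path: str | Path) -> list[LigandRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        LigandRecord(
            name=str(r["name"]), formula=str(r["formula"]),
            monoisotopic_mass=float(r["monoisotopic_mass"]),
            average_mass=float(r["average_mass"]),
        )
        for _, r in df.iterrows()
    ]


# --------------------------------------------------------------------- mzML

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _binary_array(parent: etree._Element, data: np.ndarray, accession: str,
                  name: str) -> None:
    packed = struct.pack(f"<{len(data)}d", *map(float, data))
    b64 = base64.b64encode(packed).decode()
    arr = etree.SubElement(parent, "binaryDataArray",
                           encodedLength=str(len(b64)))
    etree.SubElement(arr, "cvParam", cvRef="MS", accession="MS:1000523",
                     name="64-bit float", value="")
    etree.SubElement(arr, "cvParam", cvRef="MS", accession="MS:1000576",
                     name="no compression", value="")
    unit = dict(unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z") \
        if accession == "MS:1000514" else {}
    etree.SubElement(arr, "cvParam", cvRef="MS", accession=accession,
                     name=name, value="", **unit)
    etree.SubElement(arr, "binary").text = b64


def write_mzml(path: str | Path, spectra: Iterable[Spectrum]) -> None:
    """Write spectra as minimal (unindexed) mzML 1.1, uncompressed float64."""
    spectra = list(spectra)
    root = etree.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative "
        "Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = etree.SubElement(root, "run", id="run1")
    slist = etree.SubElement(run, "spectrumList", count=str(len(spectra)),
                             defaultDataProcessingRef="dp1")
    for i, spec in enumerate(spectra):
        s = etree.SubElement(slist, "spectrum", index=str(i),
                             id=f"scan={i + 1}",
                             defaultArrayLength=str(len(spec.mz)))
        etree.SubElement(s, "cvParam", cvRef="MS", accession="MS:1000511",
                         name="ms level", value="1")
        if spec.mode == "centroid":
            etree.SubElement(s, "cvParam", cvRef="MS", accession="MS:1000127",
                             name="centroid spectrum", value="")
        else:
            etree.SubElement(s, "cvParam", cvRef="MS", accession="MS:1000128",
                             name="profile spectrum", value="")
        bl = etree.SubElement(s, "binaryDataArrayList", count="2")
        _binary_array(bl, np.asarray(spec.mz), "MS:1000514", "m/z array")
        _binary_array(bl, np.asarray(spec.intensity), "MS:1000515",
                      "intensity array")
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def _decode_binary_array(arr: etree._Element) -> np.ndarray:
    ns = f"{{{_MZML_NS}}}"
    accessions = {cv.get("accession") for cv in arr.findall(f"{ns}cvParam")}
    raw = base64.b64decode(arr.findtext(f"{ns}binary") or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Spectrum]:
    ns = f"{{{_MZML_NS}}}"
    tree = etree.parse(str(path))
    out = []
    for s in tree.iter(f"{ns}spectrum"):
        accessions = {cv.get("accession")
                      for cv in s.findall(f"{ns}cvParam")}
        mode = "centroid" if "MS:1000127" in accessions else "profile"
        mz = inten = None
        for arr in s.iter(f"{ns}binaryDataArray"):
            arr_acc = {cv.get("accession") for cv in arr.findall(f"{ns}cvParam")}
            data = _decode_binary_array(arr)
            if "MS:1000514" in arr_acc:
                mz = data
            elif "MS:1000515" in arr_acc:
                inten = data
        if mz is None or inten is None:
            raise ValueError(f"spectrum {s.get('id')!r} lacks m/z or intensity array")
        out.append(Spectrum(mz, inten, mode=mode, metadata={"id": s.get("id")}))
    return out


# -------------------------------------------------------------------- imzML

def write_imzml(path: str | Path, dataset: LineScanDataset) -> None:
    """Write a line-scan dataset as processed-mode imzML (.imzML + .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="processed") as writer:
        for spec, (x, y) in zip(dataset.spectra, dataset.coordinates):
            writer.addSpectrum(np.asarray(spec.mz, float),
                               np.asarray(spec.intensity, float),
                               (x + 1, y + 1, 1))  # imzML coords are 1-based


def read_imzml(path: str | Path, mode: str = "profile") -> LineScanDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    spectra, coords = [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        spectra.append(Spectrum(np.asarray(mz, float),
                                np.asarray(inten, float), mode=mode))
        coords.append((int(x) - 1, int(y) - 1))
    h = max(c[1] for c in coords) + 1
    w = max(c[0] for c in coords) + 1
    order = sorted(range(len(coords)), key=lambda i: (coords[i][1], coords[i][0]))
    return LineScanDataset(
        tuple(spectra[i] for i in order),
        tuple(coords[i] for i in order),
        (h, w),
    )


# ------------------------------------------------------------------- images

def write_image_tiff(path: str | Path, values: np.ndarray) -> None:
    """16-bit grayscale TIFF, max-scaled to the full dynamic range."""
    import tifffile

    m = float(values.max())
    scaled = (values / m * 65535).astype(np.uint16) if m > 0 \
        else np.zeros_like(values, dtype=np.uint16)
    tifffile.imwrite(str(path), scaled)


def write_image_png(path: str | Path, rgb: np.ndarray) -> None:
    """RGB composite in [0, 1] written as 8-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


def write_pixel_table(path: str | Path, values: np.ndarray,
                      header: str | None = None) -> None:
    h, w = values.shape
    ys, xs = np.mgrid[0:h, 0:w]
    df = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel(),
                       "intensity": values.ravel()})
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_match_report(path: str | Path, reports: Sequence[MatchReport],
                       header: str | None = None) -> None:
    rows = []
    for rep in reports:
        for m in rep.matches:
            rows.append({
                "species": rep.entry.species_name,
                "product_charge": m.product_charge,
                "predicted_mz": round(m.predicted_mz, 4),
                "observed_mz": "" if m.observed_mz is None
                else round(m.observed_mz, 4),
                "intensity": m.intensity,
                "n_matched": rep.n_matched,
                "confirmed": rep.confirmed,
            })
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
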