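"""Readers and writers for the formats the pipeline touches.

MS2 spectra are read from mzML or from a plain-text peak-list dialect used
for fixtures; MS1 features arrive as CSV tables (the output of
any peak picker), and annotation / quantification tables are written as
deterministic TSV so results are diffable.  Retention times are minutes
everywhere.

Peak-list dialect (one file, many spectra)::

    # gipctools peak list v1
    BEGIN SPECTRUM
    ID=scan_0001
    PRECURSOR_MZ=1260.723700
    POLARITY=-
    RT=15.920000
    259.022442 1532.10
    ...
    END SPECTRUM

m/z values carry 6 decimals and intensities 2, and writers emit stable
ordering, so read(write(x)) round-trips exactly at that precision.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .annotate import Annotation, Feature
from .quantify import SampleMeta
from .rules import Spectrum

__all__ = [
    "read_ms2",
    "read_peaklist",
    "write_peaklist",
    "write_mzml",
    "read_features",
    "write_features",
    "read_sample_meta",
    "write_annotations",
    "read_annotations",
]

_POLARITY_ALIASES = {
    "+": "+", "-": "-", "pos": "+", "neg": "-", "positive": "+", "negative": "-",
}


def _norm_polarity(value: str, context: str) -> str:
    try:
        return _POLARITY_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"{context}: unrecognized polarity {value!r}") from None


# ---------------------------------------------------------------------------
# Peak-list dialect
# ---------------------------------------------------------------------------


def write_peaklist(spectra: Sequence[Spectrum], path: str | Path) -> None:
    lines = ["# gipctools peak list v1"]
    for s in spectra:
        lines.append("BEGIN SPECTRUM")
        lines.append(f"ID={s.scan_id}")
        lines.append(f"PRECURSOR_MZ={s.precursor_mz:.6f}")
        lines.append(f"POLARITY={s.polarity}")
        lines.append(f"RT={s.rt:.6f}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.6f} {inten:.2f}")
        lines.append("END SPECTRUM")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaklist(path: str | Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    header: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    in_spectrum = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN SPECTRUM":
            in_spectrum, header, peaks = True, {}, []
        elif line == "END SPECTRUM":
            if "POLARITY" not in header:
                raise ValueError(
                    f"{path}: spectrum {header.get('ID', '?')!r} is missing polarity metadata"
                )
            mz, inten = (
                np.array([p[0] for p in peaks]),
                np.array([p[1] for p in peaks]),
            )
            spectra.append(
                Spectrum(
                    precursor_mz=float(header["PRECURSOR_MZ"]),
                    polarity=_norm_polarity(header["POLARITY"], f"{path}:{lineno}"),
                    rt=float(header["RT"]),
                    mz=mz,
                    intensity=inten,
                    scan_id=header.get("ID", ""),
                )
            )
            in_spectrum = False
        elif in_spectrum and "=" in line:
            key, _, value = line.partition("=")
            header[key] = value
        elif in_spectrum:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'mz intensity', got {line!r}")
            peaks.append((float(parts[0]), float(parts[1])))
        else:
            raise ValueError(f"{path}:{lineno}: unexpected content outside spectrum: {line!r}")
    return spectra


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


_MZML_SPECTRUM = """\
   <spectrum index="{index}" id="{sid}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
    <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
     </scan>
    </scanList>
    <precursorList count="1">
     <precursor>
      <selectedIonList count="1">
       <selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{prec:.6f}"/>
       </selectedIon>
      </selectedIonList>
     </precursor>
    </precursorList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{mz_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{mz_b64}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{int_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{int_b64}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Minimal mzML 1.1 writer (64-bit float arrays, no compression)."""
    body = []
    for i, s in enumerate(spectra):
        mz_b64 = _encode_array(np.round(s.mz, 6))
        int_b64 = _encode_array(np.round(s.intensity, 2))
        body.append(
            _MZML_SPECTRUM.format(
                index=i,
                sid=escape(s.scan_id or f"scan={i}"),
                n=len(s),
                pol_acc="MS:1000130" if s.polarity == "+" else "MS:1000129",
                pol_name="positive scan" if s.polarity == "+" else "negative scan",
                rt=s.rt,
                prec=s.precursor_mz,
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <cvList count="2">\n'
        '  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        '  <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>\n'
        " </cvList>\n"
        ' <run id="run0">\n'
        f'  <spectrumList count="{len(spectra)}">\n'
        + "".join(body)
        + "  </spectrumList>\n </run>\n</mzML>\n"
    )
    Path(path).write_text(doc)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, str]:
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("name", "")] = child.get("value", "")
    return out


def _decode_binary_array(bda) -> np.ndarray:
    params: dict[str, str] = {}
    b64 = ""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            params[child.get("name", "")] = child.get("value", "")
        elif tag == "binary":
            b64 = child.text or ""
    raw = base64.b64decode(b64)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), params


def _read_mzml(path: str | Path) -> list[Spectrum]:
    """Read MS2 spectra from mzML (64/32-bit float arrays, optional zlib)."""
    import xml.etree.ElementTree as ET

    spectra = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        params = _cv_params(elem)
        if params.get("ms level", "") != "2":
            elem.clear()
            continue
        sid = elem.get("id", "")
        if "positive scan" in params:
            polarity = "+"
        elif "negative scan" in params:
            polarity = "-"
        else:
            raise ValueError(f"{path}: scan {sid!r} is missing polarity metadata")
        rt = 0.0
        precursor = None
        mz = intensity = None
        for sub in elem.iter():
            tag = _local(sub.tag)
            if tag == "scan":
                for name, value in _cv_params(sub).items():
                    if name == "scan start time":
                        rt = float(value)
                        # normalize seconds to minutes if the unit says so
                        for cv in sub:
                            if (
                                _local(cv.tag) == "cvParam"
                                and cv.get("name") == "scan start time"
                                and cv.get("unitName") == "second"
                            ):
                                rt /= 60.0
            elif tag == "selectedIon":
                sel = _cv_params(sub)
                if "selected ion m/z" in sel:
                    precursor = float(sel["selected ion m/z"])
            elif tag == "binaryDataArray":
                arr, aparams = _decode_binary_array(sub)
                if "m/z array" in aparams:
                    mz = arr
                elif "intensity array" in aparams:
                    intensity = arr
        if precursor is None or mz is None or intensity is None:
            raise ValueError(f"{path}: scan {sid!r} lacks precursor or peak arrays")
        spectra.append(
            Spectrum(
                precursor_mz=precursor, polarity=polarity, rt=rt,
                mz=mz, intensity=intensity, scan_id=sid,
            )
        )
        elem.clear()
    return spectra


def read_ms2(path: str | Path) -> list[Spectrum]:
    """Read MS2 spectra from mzML or the peak-list dialect (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return _read_mzml(path)
    return read_peaklist(path)


# ---------------------------------------------------------------------------
# Feature tables and sample metadata (CSV)
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ("mz", "rt", "area", "polarity", "sample")


def read_features(path: str | Path) -> list[Feature]:
    df = pd.read_csv(path)
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing column(s) {missing}")
    features = []
    for idx, row in df.iterrows():
        try:
            mz, rt, area = float(row["mz"]), float(row["rt"]), float(row["area"])
            m1 = float(row["m1_area"]) if "m1_area" in df.columns and pd.notna(row["m1_area"]) else None
        except (TypeError, ValueError):
            raise ValueError(f"{path}: non-numeric field in row {idx + 2}") from None
        features.append(
            Feature(
                mz=mz,
                rt=rt,
                area=area,
                polarity=_norm_polarity(row["polarity"], f"{path} row {idx + 2}"),
                sample=str(row["sample"]),
                m1_area=m1,
            )
        )
    return features


def write_features(features: Sequence[Feature], path: str | Path) -> None:
    rows = [
        {
            "mz": f"{f.mz:.6f}",
            "rt": f"{f.rt:.4f}",
            "area": f"{f.area:.2f}",
            "polarity": f.polarity,
            "sample": f.sample,
            "m1_area": "" if f.m1_area is None else f"{f.m1_area:.2f}",
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=list(_FEATURE_COLUMNS) + ["m1_area"]).to_csv(path, index=False)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    required = ["sample", "group", "dry_weight", "is_area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample metadata missing column(s) {missing}")
    metas = []
    for idx, row in df.iterrows():
        spiked = bool(row["is_spiked"]) if "is_spiked" in df.columns else True
        try:
            metas.append(
                SampleMeta(
                    sample=str(row["sample"]),
                    group=str(row["group"]),
                    dry_weight=float(row["dry_weight"]),
                    is_area=float(row["is_area"]),
                    is_spiked=spiked,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid metadata in row {idx + 2}: {exc}") from None
    return metas


# ---------------------------------------------------------------------------
# Annotation tables (TSV)
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "name",
    "sum_name",
    "level",
    "adduct_pos",
    "mz_pos",
    "ppm_pos",
    "mz_neg",
    "ppm_neg",
    "rt",
    "matched_neg",
    "matched_pos",
    "flags",
]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "name": a.name,
                "sum_name": a.sum_name,
                "level": a.level,
                "adduct_pos": a.pair.pos_adduct if a.pair else "",
                "mz_pos": f"{a.pair.positive.mz:.6f}" if a.pair else "",
                "ppm_pos": f"{a.pair.pos_ppm:.2f}" if a.pair else "",
                "mz_neg": f"{a.pair.negative.mz:.6f}" if a.pair else "",
                "ppm_neg": f"{a.pair.neg_ppm:.2f}" if a.pair else "",
                "rt": f"{a.rt:.4f}" if a.rt is not None else "",
                "matched_neg": ";".join(a.matched_fragments("-")),
                "matched_pos": ";".join(a.matched_fragments("+")),
                "flags": ";".join(sorted(a.flags)),
            }
        )
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
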