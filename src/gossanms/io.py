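"""Peak-list and cube file I/O plus run configuration.

Delimited-text dialect: comma-separated, UTF-8, "." decimal, mandatory
header.  Peak lists are ``mz,intensity`` tables; image cubes travel as a
long-format ``x,y,mz,intensity`` table next to a small manifest.  Single
centroided spectra can also be read from mzML.
"""

from __future__ import annotations

import base64
import logging
import zlib
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .imaging import IonImageCube
from .peaklist import PeakList

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_cube",
    "write_cube",
    "write_resolved_config",
]

log = logging.getLogger("gossanms")


def _read_csv_peaklist(path: Path, polarity: Optional[str]) -> PeakList:
    df = pd.read_csv(path)
    missing = {"mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)} "
            f"(found {list(df.columns)})"
        )
    for col in ("mz", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path}: empty cell in column {col!r} at line {line}")
        df[col] = coerced
    pl = PeakList.from_pairs(df[["mz", "intensity"]].to_numpy(), polarity)
    merged = pl.merged_duplicates()
    if len(merged) < len(pl):
        log.warning(
            "%s: merged %d duplicate m/z rows by intensity sum",
            path, len(pl) - len(merged),
        )
        return merged
    return pl


def _decode_binary_array(elem, ns: str) -> Optional[np.ndarray]:
    """Decode one <binaryDataArray>: returns the values, or None for arrays
    other than m/z / intensity."""
    accessions = {
        cv.get("accession") for cv in elem.findall(f"{ns}cvParam")
    }
    if "MS:1000514" in accessions:
        kind = "mz"
    elif "MS:1000515" in accessions:
        kind = "intensity"
    else:
        return None
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    return kind, arr


def _read_mzml_peaklist(path: Path, polarity: Optional[str]) -> PeakList:
    """Minimal reader for single centroided spectra in mzML documents.

    Supports 32/64-bit float arrays with optional zlib compression and reads
    scan polarity from the spectrum's controlled-vocabulary terms.
    """
    import xml.etree.ElementTree as ET

    tree = ET.parse(path)
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    spectrum = root.find(f".//{ns}spectrum")
    if spectrum is None:
        raise ValueError(f"{path}: no spectra found")
    if polarity is None:
        accessions = {cv.get("accession") for cv in spectrum.findall(f"{ns}cvParam")}
        if "MS:1000129" in accessions:
            polarity = "negative"
        elif "MS:1000130" in accessions:
            polarity = "positive"
    arrays = {}
    for elem in spectrum.iter(f"{ns}binaryDataArray"):
        decoded = _decode_binary_array(elem, ns)
        if decoded is not None:
            arrays[decoded[0]] = decoded[1]
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError(f"{path}: spectrum lacks m/z or intensity arrays")
    return PeakList.from_pairs(
        np.column_stack([arrays["mz"], arrays["intensity"]]),
        polarity,
        {"source": str(path), "id": spectrum.get("id")},
    )


def read_peaklist(
    path, dialect: Optional[str] = None, polarity: Optional[str] = None
) -> PeakList:
    """Read a peak list from CSV (``mz,intensity`` header) or mzML.

    The dialect is inferred from the file suffix unless given.  Duplicate
    m/z rows are merged by intensity sum with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "mzml" if path.suffix.lower() == ".mzml" else "csv"
    if dialect == "csv":
        return _read_csv_peaklist(path, polarity)
    if dialect == "mzml":
        return _read_mzml_peaklist(path, polarity)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_peaklist(peaks: PeakList, path) -> None:
    pd.DataFrame({"mz": peaks.mz, "intensity": peaks.intensity}).to_csv(
        path, index=False
    )


def write_cube(cube: IonImageCube, path) -> None:
    """Write a cube as long-format CSV plus a YAML manifest alongside."""
    path = Path(path)
    cube.to_long_frame().to_csv(path, index=False)
    manifest = {
        "width": cube.width,
        "height": cube.height,
        "polarity": cube.polarity,
        "pixel_size_um": cube.pixel_size_um,
    }
    with open(path.with_suffix(".manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_cube(path) -> IonImageCube:
    path = Path(path)
    manifest_path = path.with_suffix(".manifest.yaml")
    manifest: Dict = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh) or {}
    df = pd.read_csv(path)
    missing = {"x", "y", "mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return IonImageCube.from_long_frame(
        df,
        width=manifest.get("width"),
        height=manifest.get("height"),
        polarity=manifest.get("polarity"),
        pixel_size_um=manifest.get("pixel_size_um"),
    )


def write_resolved_config(config: Dict, outdir) -> Path:
    """Persist the fully resolved run configuration next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path
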