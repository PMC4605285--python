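"""Readers and writers: FASTA sequences, PTM-map TSV, feature-table TSV,
BED export, flat config files, and targeted mzML extraction.

All tabular formats are tab-separated with dot decimals.  PTM-map columns:
parent_id, position (1-based), mod_code, fraction, sd, n_obs, evidence.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .assembly import PtmMap, PtmSite
from .chemistry import MODIFICATIONS
from .digestion import AnnotatedSequence
from .matching import Feature, TheoreticalIndex

__all__ = [
    "read_fasta",
    "read_ptm_map",
    "write_ptm_map",
    "read_features",
    "write_features",
    "features_from_table",
    "write_bed",
    "read_config",
    "extract_features_mzml",
]

PathLike = Union[str, Path]

PTM_MAP_COLUMNS = [
    "parent_id",
    "position",
    "mod_code",
    "fraction",
    "sd",
    "n_obs",
    "evidence",
]

FEATURE_TSV_COLUMNS = ["run_id", "replicate", "mz", "charge", "rt_sec", "intensity", "msms"]


def read_fasta(path: PathLike, five_prime: str = "OH", three_prime: str = "OH") -> List[AnnotatedSequence]:
    """Read RNA (or DNA-alphabet) sequences; T is normalized to U with a warning."""
    sequences = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if "T" in seq:
            warnings.warn(
                f"{record.id}: T residues normalized to U", stacklevel=2
            )
        sequences.append(
            AnnotatedSequence(
                id=record.id,
                residues=seq.replace("T", "U"),
                five_prime=five_prime,
                three_prime=three_prime,
            )
        )
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    return sequences


def write_ptm_map(ptm_map: PtmMap, path: PathLike) -> None:
    rows = []
    for site in ptm_map.sites:
        rows.append(
            {
                "parent_id": site.parent_id,
                "position": site.position,
                "mod_code": site.mod_code,
                "fraction": f"{site.f:.6g}",
                "sd": f"{site.sd:.6g}",
                "n_obs": site.n_observations,
                "evidence": ";".join(site.evidence),
            }
        )
    pd.DataFrame(rows, columns=PTM_MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ptm_map(path: PathLike) -> PtmMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(PTM_MAP_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        code = row["mod_code"]
        if code not in MODIFICATIONS:
            raise ValueError(f"{path}:{line}: unknown mod code {code!r}")
        try:
            position = int(row["position"])
            fraction = float(row["fraction"])
            sd = float(row.get("sd", 0) or 0)
            n_obs = int(row.get("n_obs", 1) or 1)
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: malformed numeric field ({exc})")
        sites.append(
            PtmSite(
                parent_id=row["parent_id"],
                position=position,
                mod_code=code,
                f=fraction,
                sd=sd,
                n_observations=n_obs,
                evidence=tuple(e for e in row.get("evidence", "").split(";") if e),
            )
        )
    return PtmMap(sites=sites)


def write_features(table: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in table.columns]
    table.to_csv(path, sep="\t", index=False, columns=cols)


def read_features(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"mz", "charge", "rt_sec", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        line = i + 2
        if int(row["charge"]) < 1:
            raise ValueError(f"{path}:{line}: charge must be a positive integer")
        if float(row["intensity"]) <= 0:
            raise ValueError(f"{path}:{line}: intensity must be > 0")
    if "run_id" not in df.columns:
        df["run_id"] = "run"
    if "replicate" not in df.columns:
        df["replicate"] = 0
    if "msms" not in df.columns:
        df["msms"] = None
    return df


def features_from_table(table: pd.DataFrame) -> List[Feature]:
    """Convert a feature DataFrame into matching-layer Feature objects."""
    features = []
    for i, row in table.iterrows():
        msms = row.get("msms")
        peaks = None
        if isinstance(msms, str) and msms:
            peaks = tuple((float(m), float(h)) for m, h in json.loads(msms))
        features.append(
            Feature(
                mz=float(row["mz"]),
                charge=int(row["charge"]),
                rt=float(row["rt_sec"]),
                intensity=float(row["intensity"]),
                msms=peaks,
                run_id=str(row.get("run_id", "run")),
                replicate=int(row.get("replicate", 0)),
                feature_id=int(i),
            )
        )
    return features


def write_bed(ptm_map: PtmMap, path: PathLike) -> None:
    """0-based half-open BED export of a 1-based PTM map."""
    with open(path, "w") as fh:
        for site in ptm_map.sites:
            fh.write(
                f"{site.parent_id}\t{site.position - 1}\t{site.position}\t"
                f"{site.mod_code}\t{site.f:.4f}\t+\n"
            )


def read_config(path: PathLike) -> Dict[str, str]:
    """Flat ``key = value`` configuration mirroring the CLI flags."""
    out: Dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _iter_mzml_ms1(path: PathLike):
    """Yield (rt_seconds, mz_array, intensity_array) for MS1 spectra.

    Minimal targeted mzML reader over lxml: handles 32/64-bit float binary
    arrays with optional zlib compression, which covers instrument-exported
    centroid data.
    """
    import base64
    import struct
    import zlib as _zlib

    from lxml import etree

    import numpy as np

    ns = "{http://psi.hupo.org/ms/mzml}"
    for _event, spectrum in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        ms_level = None
        rt = None
        arrays: Dict[str, "np.ndarray"] = {}
        for cv in spectrum.iter(f"{ns}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000511":
                ms_level = int(cv.get("value"))
            elif acc == "MS:1000016":
                rt = float(cv.get("value"))
                unit = (cv.get("unitName") or "minute").lower()
                if unit.startswith("minute"):
                    rt *= 60.0
        for array in spectrum.iter(f"{ns}binaryDataArray"):
            dtype = "<d"
            compressed = False
            kind = None
            for cv in array.iter(f"{ns}cvParam"):
                acc = cv.get("accession")
                if acc == "MS:1000521":
                    dtype = "<f"
                elif acc == "MS:1000523":
                    dtype = "<d"
                elif acc == "MS:1000574":
                    compressed = True
                elif acc == "MS:1000514":
                    kind = "mz"
                elif acc == "MS:1000515":
                    kind = "intensity"
            binary = array.find(f"{ns}binary")
            if kind is None or binary is None or not binary.text:
                continue
            raw = base64.b64decode(binary.text)
            if compressed:
                raw = _zlib.decompress(raw)
            width = struct.calcsize(dtype)
            values = struct.unpack(f"<{len(raw) // width}{dtype[-1]}", raw)
            arrays[kind] = np.asarray(values, dtype=float)
        spectrum.clear(keep_tail=True)
        if ms_level == 1 and rt is not None and "mz" in arrays and "intensity" in arrays:
            yield rt, arrays["mz"], arrays["intensity"]


def extract_features_mzml(
    path: PathLike,
    index: TheoreticalIndex,
    tol_ppm: float = 20.0,
    min_intensity: float = 0.0,
    run_id: Optional[str] = None,
) -> pd.DataFrame:
    """Targeted extracted-ion-chromatogram feature extraction from mzML.

    For every theoretical species in ``index``, the MS1 signal within the
    ppm window is traced over retention time and reported at its apex —
    the extracted-ion-monitoring strategy used for oligonucleotide
    quantification.  Charge is taken from the index entry.
    """
    targets = [(e.mz, e.charge) for e in index.entries]
    traces: Dict[int, List[tuple]] = {i: [] for i in range(len(targets))}
    for rt, mz_arr, int_arr in _iter_mzml_ms1(path):
        order = mz_arr.argsort()
        mz_arr = mz_arr[order]
        int_arr = int_arr[order]
        for i, (target_mz, _z) in enumerate(targets):
            tol = target_mz * tol_ppm * 1e-6
            lo = mz_arr.searchsorted(target_mz - tol)
            hi = mz_arr.searchsorted(target_mz + tol)
            if hi > lo:
                window = int_arr[lo:hi]
                peak = int(window.argmax())
                traces[i].append(
                    (rt, float(window[peak]), float(mz_arr[lo + peak]))
                )
    rows = []
    for i, points in traces.items():
        if not points:
            continue
        rt, intensity, mz_obs = max(points, key=lambda p: p[1])
        if intensity < min_intensity:
            continue
        rows.append(
            {
                "run_id": run_id or Path(str(path)).stem,
                "replicate": 0,
                "mz": mz_obs,
                "charge": targets[i][1],
                "rt_sec": rt,
                "intensity": intensity,
                "msms": None,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_TSV_COLUMNS)
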