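"""File formats: topographs (TIFF/CSV + JSON sidecar), skeletons, records, params.

Topographs are stored as 32-bit float TIFF height maps in nm with a JSON
sidecar ``{"pixel_size_nm": ..., "zero_level_nm": ...}``; a plain CSV grid
is accepted as a fallback.  Skeletons round-trip through JSON
(vertices/edges/faces in nm), fitted-pit records through CSV, and model
parameter sets through a flat ``key = value`` config file in which
``R_memb`` may be ``inf``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .energy import ModelParams
from .morphometry import CCPRecord, LatticeSkeleton, Topograph

__all__ = [
    "write_topograph",
    "read_topograph",
    "skeleton_to_json",
    "skeleton_from_json",
    "write_skeleton",
    "read_skeleton",
    "records_to_dataframe",
    "write_records",
    "write_params",
    "read_params",
]

PathLike = Union[str, Path]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_topograph(t: Topograph, path: PathLike) -> Path:
    """Write heights as float32 TIFF (or CSV if the suffix is .csv) + sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, t.heights, delimiter=",")
    else:
        tifffile.imwrite(path, t.heights.astype(np.float32))
    _sidecar(path).write_text(json.dumps(
        {"pixel_size_nm": t.pixel_size, "zero_level_nm": t.zero_level,
         "image_id": t.image_id}))
    return path


def read_topograph(path: PathLike) -> Topograph:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        heights = np.loadtxt(path, delimiter=",")
    else:
        heights = tifffile.imread(path).astype(float)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return Topograph(
        heights=heights,
        pixel_size=float(meta.get("pixel_size_nm", 1.0)),
        zero_level=float(meta.get("zero_level_nm", 0.0)),
        image_id=str(meta.get("image_id", path.stem)),
    )


def skeleton_to_json(s: LatticeSkeleton) -> str:
    return json.dumps({
        "vertices": np.asarray(s.vertices).tolist(),
        "edges": [list(e) for e in s.edges],
        "faces": [list(f) for f in s.faces],
        "pentagon_count": s.pentagon_count,
    })


def skeleton_from_json(text: str) -> LatticeSkeleton:
    d = json.loads(text)
    return LatticeSkeleton(
        vertices=np.array(d["vertices"], dtype=float).reshape(-1, 3),
        edges=[tuple(e) for e in d["edges"]],
        faces=[list(f) for f in d["faces"]],
        pentagon_count=d.get("pentagon_count"),
    )


def write_skeleton(s: LatticeSkeleton, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(skeleton_to_json(s))
    return path


def read_skeleton(path: PathLike) -> LatticeSkeleton:
    return skeleton_from_json(Path(path).read_text())


def records_to_dataframe(records: Sequence[CCPRecord]) -> pd.DataFrame:
    """Fitted-pit table: id, R_nm, h_nm, A_nm2, theta_deg, residual_nm, E_total_kBT."""
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "id": r.image_id or f"ccp-{i}",
            "R_nm": r.cap.R,
            "h_nm": r.cap.h,
            "A_nm2": r.cap.A,
            "theta_deg": r.cap.theta,
            "residual_nm": r.residual,
            "E_total_kBT": r.energies.E_total if r.energies is not None else math.nan,
        })
    return pd.DataFrame(rows, columns=["id", "R_nm", "h_nm", "A_nm2", "theta_deg",
                                       "residual_nm", "E_total_kBT"])


def write_records(records: Sequence[CCPRecord], path: PathLike) -> Path:
    path = Path(path)
    records_to_dataframe(records).to_csv(path, index=False)
    return path


_PARAM_FIELDS = ("kappa_memb", "R_memb", "gamma", "kappa_clath", "R_clath", "a", "A_clath")


def write_params(p: ModelParams, path: PathLike) -> Path:
    """Flat ``key = value`` parameter file; ``inf`` is written for a flat membrane."""
    path = Path(path)
    lines = [f"{k} = {getattr(p, k)}" for k in _PARAM_FIELDS]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_params(path: PathLike) -> ModelParams:
    kw = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _PARAM_FIELDS:
            raise ValueError(f"unknown model parameter {key!r}")
        kw[key] = float(val.strip())
    return ModelParams(**kw)
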