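"""Tidy CSV and mask-image interchange.

Formats
-------
contour CSV   : cell_id, frame, vertex_index, x_um, y_um
mesh CSV      : cell_id, station, x, y, width_um, arclength_um, is_pole
trace CSV     : id, t, value, channel            (channel in {periplasm, cytoplasm})
triplet CSV   : cell_id, l1_um, l2_um, l3_um     (l3_um may be empty; optional strain)
OD CSV        : time_h, od, replicate            (optional strain, condition)
masks         : single-channel 8-bit images, background 0 / cell 255,
                TIFF (written here) or PNG, with the pixel size stated by the caller.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import tifffile
from skimage import io as skio

from .contours import CellContour, CenterlineMesh
from .synthetic import FluorTrace, ODCurve, PlasmolysisTriplet

PathLike = Union[str, Path]


# ---------------------------------------------------------------- contours

def write_contours_csv(path: PathLike,
                       contours: dict[tuple[str, int], CellContour]) -> None:
    """Write contours keyed by (cell_id, frame)."""
    rows = []
    for (cell_id, frame), c in contours.items():
        for k, (x, y) in enumerate(c.vertices):
            rows.append((cell_id, frame, k, x, y))
    pd.DataFrame(rows, columns=["cell_id", "frame", "vertex_index",
                                "x_um", "y_um"]).to_csv(path, index=False)


def read_contours_csv(path: PathLike) -> dict[tuple[str, int], CellContour]:
    df = pd.read_csv(path)
    out = {}
    for (cell_id, frame), g in df.groupby(["cell_id", "frame"], sort=False):
        g = g.sort_values("vertex_index")
        out[(str(cell_id), int(frame))] = CellContour(
            g[["x_um", "y_um"]].to_numpy(float))
    return out


# ---------------------------------------------------------------- meshes

def write_mesh_csv(path: PathLike, meshes: dict[str, CenterlineMesh]) -> None:
    rows = []
    for cell_id, m in meshes.items():
        for i in range(len(m.widths)):
            rows.append((cell_id, i, m.points[i, 0], m.points[i, 1],
                         m.widths[i], m.arclength[i], bool(m.is_pole[i])))
    pd.DataFrame(rows, columns=["cell_id", "station", "x", "y", "width_um",
                                "arclength_um", "is_pole"]).to_csv(path, index=False)


def read_mesh_csv(path: PathLike) -> dict[str, CenterlineMesh]:
    df = pd.read_csv(path)
    out = {}
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("station")
        widths = g["width_um"].to_numpy(float)
        arclength = g["arclength_um"].to_numpy(float)
        is_pole = g["is_pole"].to_numpy(bool)
        nonpole = widths[~is_pole]
        mean_w = float(nonpole.mean()) if nonpole.size else float(np.median(widths))
        length = float(arclength[-1])
        out[str(cell_id)] = CenterlineMesh(
            points=g[["x", "y"]].to_numpy(float), widths=widths,
            arclength=arclength, is_pole=is_pole, cell_length=length,
            mean_width=mean_w, is_round=length / max(mean_w, 1e-12) < 1.5)
    return out


# ---------------------------------------------------------------- traces

def write_traces_csv(path: PathLike, traces: Iterable[FluorTrace]) -> None:
    frames = []
    for tr in traces:
        for channel, values in (("periplasm", tr.periplasm),
                                ("cytoplasm", tr.cytoplasm)):
            frames.append(pd.DataFrame({"id": tr.cell_id, "t": tr.times,
                                        "value": values, "channel": channel}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: PathLike) -> list[FluorTrace]:
    df = pd.read_csv(path)
    out = []
    for cell_id, g in df.groupby("id", sort=False):
        peri = g[g.channel == "periplasm"].sort_values("t")
        cyto = g[g.channel == "cytoplasm"].sort_values("t")
        out.append(FluorTrace(cell_id=str(cell_id),
                              times=peri["t"].to_numpy(float),
                              periplasm=peri["value"].to_numpy(float),
                              cytoplasm=cyto["value"].to_numpy(float)))
    return out


# ---------------------------------------------------------------- triplets

def write_triplets_csv(path: PathLike, triplets: Iterable[PlasmolysisTriplet],
                       strain: Optional[str] = None) -> None:
    rows = [{"cell_id": t.cell_id, "l1_um": t.l1, "l2_um": t.l2,
             "l3_um": t.l3} for t in triplets]
    df = pd.DataFrame(rows)
    if strain is not None:
        df["strain"] = strain
    df.to_csv(path, index=False)


def read_triplets_csv(path: PathLike) -> pd.DataFrame:
    """Triplet table; use :func:`triplets_from_frame` to get objects."""
    return pd.read_csv(path)


def triplets_from_frame(df: pd.DataFrame) -> list[PlasmolysisTriplet]:
    out = []
    for _, row in df.iterrows():
        l3 = row.get("l3_um")
        out.append(PlasmolysisTriplet(
            l1=float(row["l1_um"]), l2=float(row["l2_um"]),
            l3=None if pd.isna(l3) else float(l3),
            cell_id=str(row.get("cell_id", ""))))
    return out


# ---------------------------------------------------------------- OD curves

def write_od_csv(path: PathLike, curves: Iterable[ODCurve],
                 strain: Optional[str] = None,
                 condition: Optional[str] = None) -> None:
    frames = []
    for c in curves:
        df = pd.DataFrame({"time_h": c.times, "od": c.od,
                           "replicate": c.replicate_id})
        if strain is not None:
            df["strain"] = strain
        if condition is not None:
            df["condition"] = condition
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_od_csv(path: PathLike) -> list[ODCurve]:
    df = pd.read_csv(path)
    return [ODCurve(times=g["time_h"].to_numpy(float),
                    od=g["od"].to_numpy(float), replicate_id=str(rep))
            for rep, g in df.groupby("replicate", sort=False)]


# ---------------------------------------------------------------- masks

def write_mask(path: PathLike, mask: np.ndarray) -> None:
    """8-bit single-channel TIFF, background 0, cell 255."""
    tifffile.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path: PathLike) -> np.ndarray:
    """Read a TIFF or PNG mask back to a 0/1 array."""
    img = skio.imread(str(path))
    if img.ndim == 3:
        img = img[..., 0]
    return (img > 0).astype(np.uint8)
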