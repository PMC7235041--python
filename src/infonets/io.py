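"""Reading and writing surface maps, DMs and tables (GIFTI / CSV)."""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .convergence import RegionClass
from .repgeom import ItemDM

__all__ = [
    "save_mesh_gifti",
    "save_scalar_map_gifti",
    "save_label_map_gifti",
    "scalar_map_to_csv",
    "scalar_map_from_csv",
    "itemdm_to_csv",
    "itemdm_from_csv",
    "itemdm_to_square_csv",
]

LABEL_PALETTE = {
    int(RegionClass.NONE): ("none", (0.5, 0.5, 0.5, 0.0)),
    int(RegionClass.A_ONLY): ("A_only", (0.0, 0.8, 0.0, 1.0)),
    int(RegionClass.B_ONLY): ("B_only", (0.0, 0.2, 0.9, 1.0)),
    int(RegionClass.OVERLAP): ("overlap", (0.9, 0.1, 0.1, 1.0)),
}


def save_mesh_gifti(mesh, path) -> Path:
    """Write mesh geometry as a .surf.gii (pointset + triangles)."""
    path = Path(path)
    coords = nib.gifti.GiftiDataArray(
        mesh.node_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    faces = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, faces]), str(path))
    return path


def save_scalar_map_gifti(values: np.ndarray, path) -> Path:
    """Write a per-node scalar map as a .func.gii."""
    path = Path(path)
    arr = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))
    return path


def save_label_map_gifti(labels: np.ndarray, path) -> Path:
    """Write a per-node label map as a .label.gii with the fixed palette."""
    path = Path(path)
    table = nib.gifti.GiftiLabelTable()
    for value, (name, rgba) in LABEL_PALETTE.items():
        lab = nib.gifti.GiftiLabel(key=value, red=rgba[0], green=rgba[1], blue=rgba[2], alpha=rgba[3])
        lab.label = name
        table.labels.append(lab)
    arr = nib.gifti.GiftiDataArray(
        np.asarray(labels, dtype=np.int32), intent="NIFTI_INTENT_LABEL"
    )
    img = nib.gifti.GiftiImage(darrays=[arr], labeltable=table)
    nib.save(img, str(path))
    return path


def scalar_map_to_csv(values: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"node_index": np.arange(len(values)), "value": np.asarray(values)}
    ).to_csv(path, index=False)
    return path


def scalar_map_from_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    out = np.full(int(df["node_index"].max()) + 1, np.nan)
    out[df["node_index"].to_numpy()] = df["value"].to_numpy()
    return out


def itemdm_to_csv(dm: ItemDM, path) -> Path:
    """Condensed DM with pair labels; exact round trip via repr precision."""
    path = Path(path)
    pairs = list(combinations(dm.item_ids, 2))
    pd.DataFrame(
        {
            "item_a": [a for a, _ in pairs],
            "item_b": [b for _, b in pairs],
            "dissimilarity": dm.condensed,
        }
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def itemdm_from_csv(path) -> ItemDM:
    df = pd.read_csv(path, float_precision='round_trip')
    ids: list = []
    for a in df["item_a"]:
        if a not in ids:
            ids.append(a)
    last = df["item_b"].iloc[-1]
    if last not in ids:
        ids.append(last)
    return ItemDM(condensed=df["dissimilarity"].to_numpy(dtype=np.float64), item_ids=tuple(ids))


def itemdm_to_square_csv(dm: ItemDM, path) -> Path:
    path = Path(path)
    pd.DataFrame(dm.to_square(), index=list(dm.item_ids), columns=list(dm.item_ids)).to_csv(
        path, float_format="%.17g"
    )
    return path
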