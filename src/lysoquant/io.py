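"""Reading and writing the pipeline's on-disk formats.

Images travel as OME-TIFF with channel names recording biological roles;
cell segmentations as labeled-image TIFF/PNG pairs (0 = background, k =
cell k) for cytoplasm and nucleus; ground truth as a JSON sidecar; all
measurement tables as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthgen import GroundTruth
from .types import BinaryMask, CellROI, MultiChannelImage, ValidationError

__all__ = [
    "write_ome_tiff",
    "read_ome_tiff",
    "write_label_masks",
    "read_label_masks",
    "write_ground_truth",
    "read_ground_truth",
]


def write_ome_tiff(image: MultiChannelImage, path: str | Path) -> Path:
    """Write all channels to one OME-TIFF, roles stored as channel names."""
    path = Path(path)
    stack = np.stack([image.planes[c] for c in image.channels]).astype(np.float32)
    ps = image.pixel_size_um
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": image.channels},
            "PhysicalSizeX": ps,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": ps,
            "PhysicalSizeYUnit": "µm",
        },
    )
    return path


def read_ome_tiff(
    path: str | Path, channel_names: Optional[Sequence[str]] = None
) -> MultiChannelImage:
    """Read a multichannel TIFF; channel names from OME metadata or override."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        names = None
        pixel_size = 0.08
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            chans = root.findall(".//ome:Channel", ns)
            got = [c.get("Name") for c in chans]
            if got and all(got):
                names = got
            px = root.find(".//ome:Pixels", ns)
            if px is not None and px.get("PhysicalSizeX"):
                pixel_size = float(px.get("PhysicalSizeX"))
    if arr.ndim == 2:
        arr = arr[None]
    if channel_names is not None:
        names = list(channel_names)
    if names is None or len(names) != arr.shape[0]:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    planes = {n: np.clip(arr[i].astype(float), 0, None) for i, n in enumerate(names)}
    return MultiChannelImage(planes=planes, pixel_size_um=pixel_size, metadata={"source": str(path)})


def write_label_masks(rois: Sequence[CellROI], cyto_path: str | Path, nuc_path: str | Path) -> None:
    """Write cytoplasm and nucleus labeled images (cell k has label k+1)."""
    if not rois:
        raise ValidationError("no ROIs to write")
    shape = rois[0].cytoplasm_mask.shape
    cyto = np.zeros(shape, dtype=np.uint16)
    nuc = np.zeros(shape, dtype=np.uint16)
    for k, roi in enumerate(rois, start=1):
        cyto[roi.cytoplasm_mask.pixels] = k
        nuc[roi.nucleus_mask.pixels] = k
    tifffile.imwrite(Path(cyto_path), cyto)
    tifffile.imwrite(Path(nuc_path), nuc)


def read_label_masks(
    cyto_path: str | Path, nuc_path: str | Path, animal_id: str = "", group_id: str = ""
) -> list[CellROI]:
    """Rebuild CellROIs from labeled cytoplasm/nucleus images."""
    cyto = np.asarray(tifffile.imread(Path(cyto_path)))
    nuc = np.asarray(tifffile.imread(Path(nuc_path)))
    if cyto.shape != nuc.shape:
        raise ValidationError("cytoplasm and nucleus label images differ in shape")
    labels = sorted(set(np.unique(cyto)) | set(np.unique(nuc)))
    rois = []
    for k in labels:
        if k == 0:
            continue
        rois.append(
            CellROI(
                cell_id=f"cell{int(k) - 1:02d}",
                cytoplasm_mask=BinaryMask(cyto == k),
                nucleus_mask=BinaryMask(nuc == k),
                animal_id=animal_id,
                group_id=group_id,
            )
        )
    return rois


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(truth), indent=1))
    return path


def read_ground_truth(path: str | Path) -> dict:
    """Ground truth round-trips as a plain dict (arrays become lists)."""
    return json.loads(Path(path).read_text())


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
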