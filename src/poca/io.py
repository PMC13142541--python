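"""Readers and writers for the on-disk interchange formats.

Images travel as one multi-page TIFF per channel (ZYX, 16-bit unsigned)
with the pixel size in the TIFF resolution tags and in a sidecar JSON;
networks as 2-column TSV edge lists plus an optional node-role TSV; LFQ
matrices as TSV with a sample-name header and a separate group-label TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from poca.frc import ImagePair
from poca.network import InteractionNetwork

__all__ = [
    "write_image_pair", "read_image_pair",
    "write_network", "read_network",
    "write_quant_matrix", "read_quant_matrix",
    "write_curve_tsv",
]


def _to_uint16(a: np.ndarray) -> np.ndarray:
    return np.clip(np.round(a), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def write_image_pair(pair: ImagePair, out_dir, prefix: str = "fov") -> dict:
    """Write target/deposition TIFFs and a sidecar JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    res = 1e7 / pair.pixel_size  # pixels per cm, from nm/pixel
    for name, stack in (("target", pair.target), ("deposition", pair.deposition)):
        path = out_dir / f"{prefix}_{name}.tif"
        tifffile.imwrite(path, _to_uint16(stack), resolution=(res, res),
                         resolutionunit="CENTIMETER")
        paths[name] = str(path)
    sidecar = out_dir / f"{prefix}_meta.json"
    sidecar.write_text(json.dumps({
        "pixel_size_nm": pair.pixel_size,
        "fov_id": pair.fov_id,
        "shape_zyx": list(pair.target.shape),
    }, indent=2))
    paths["meta"] = str(sidecar)
    return paths


def read_image_pair(target_path, deposition_path,
                    pixel_size: float | None = None,
                    fov_id: str | None = None) -> ImagePair:
    """Load a channel pair; pixel size from the sidecar unless overridden."""
    target = tifffile.imread(target_path).astype(float)
    deposition = tifffile.imread(deposition_path).astype(float)
    if pixel_size is None:
        sidecar = Path(str(target_path).replace("_target.tif", "_meta.json"))
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size = meta["pixel_size_nm"]
            fov_id = fov_id or meta.get("fov_id")
        else:
            raise ValueError("pixel_size not given and no sidecar JSON found")
    return ImagePair(target=target, deposition=deposition,
                     pixel_size=float(pixel_size), fov_id=fov_id or "fov")


def write_network(net: InteractionNetwork, edges_path, roles_path=None) -> None:
    pd.DataFrame(net.edges, columns=["bait", "prey"]).to_csv(
        edges_path, sep="\t", index=False)
    if roles_path is not None:
        pd.DataFrame(sorted(net.roles.items()),
                     columns=["node", "role"]).to_csv(
            roles_path, sep="\t", index=False)


def read_network(edges_path, roles_path=None) -> InteractionNetwork:
    edges_df = pd.read_csv(edges_path, sep="\t")
    edges = list(edges_df.itertuples(index=False, name=None))
    roles = None
    if roles_path is not None:
        roles_df = pd.read_csv(roles_path, sep="\t")
        roles = dict(zip(roles_df.iloc[:, 0], roles_df.iloc[:, 1]))
    return InteractionNetwork.from_edges(edges, roles=roles)


def write_quant_matrix(matrix: pd.DataFrame, groups: pd.Series,
                       matrix_path, groups_path) -> None:
    matrix.to_csv(matrix_path, sep="\t", index_label="protein_id")
    groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def read_quant_matrix(matrix_path, groups_path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a TSV quant matrix; blank, NA, and 0 entries become missing."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix = matrix.apply(pd.to_numeric, errors="coerce")
    matrix = matrix.where(matrix != 0)
    groups_df = pd.read_csv(groups_path, sep="\t", index_col=0)
    return matrix, groups_df.iloc[:, 0]


def write_curve_tsv(curve, path) -> None:
    """FRC curve as TSV: ring index, frequency, feature size, raw, smoothed."""
    pd.DataFrame({
        "ring_index": np.arange(len(curve.frequencies)),
        "frequency_per_nm": curve.frequencies,
        "feature_size_nm": curve.feature_sizes,
        "raw_frc": curve.raw_frc,
        "smoothed_frc": curve.smoothed_frc,
        "n_pixels": curve.n_pixels_per_ring,
    }).to_csv(path, sep="\t", index=False)
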