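"""Reading and writing of image stacks, masks, channel tables and results.

Arrays are indexed (row, column) = (y, x) internally; centroids are reported
in 0-based pixel units. Stacks on disk may be multi-page TIFF/OME-TIFF
(channel-first pages) or ``.npy`` arrays; masks likewise. The channel table
is always a CSV with columns ``channel_index, protein_name,
is_dna_intercalator, is_background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PixelStack",
    "SegmentationMask",
    "ChannelMap",
    "ShapeMismatchError",
    "load_sample",
    "load_clinical",
    "write_table",
    "save_cellviews",
    "load_cellviews",
]


class ShapeMismatchError(ValueError):
    """Raised when a stack and mask (or stack and channel table) disagree."""


@dataclass
class PixelStack:
    """Pixel-level expression counts, shape (y, x, channel), values >= 0."""

    pixels: np.ndarray
    sample_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(f"stack must be 3-D (y, x, channel); got ndim={self.pixels.ndim}")
        if np.any(self.pixels < 0):
            raise ValueError(f"negative pixel values in stack for sample {self.sample_id!r}")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def spatial_shape(self) -> tuple:
        return self.pixels.shape[:2]


@dataclass
class SegmentationMask:
    """Integer cell-ID assignment per pixel; 0 is background."""

    labels: np.ndarray
    sample_id: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2-D; got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValueError("mask contains non-integer labels")
            self.labels = self.labels.astype(np.int64)
        if np.any(self.labels < 0):
            raise ValueError("mask contains negative labels")

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class ChannelMap:
    """Channel-index to protein association, with DNA/background flags."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("channel_index", "protein_name", "is_dna_intercalator", "is_background")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"channel table missing columns: {missing}")
        t = self.table.copy()
        t["channel_index"] = t["channel_index"].astype(int)
        for c in ("is_dna_intercalator", "is_background"):
            t[c] = t[c].astype(bool)
        t = t.sort_values("channel_index").reset_index(drop=True)
        if not np.array_equal(t["channel_index"].to_numpy(), np.arange(len(t))):
            raise ValueError("channel_index must cover 0..C-1 bijectively")
        if t["protein_name"].duplicated().any():
            dups = t.loc[t["protein_name"].duplicated(), "protein_name"].tolist()
            raise ValueError(f"duplicate protein names: {dups}")
        n_dna = int(t["is_dna_intercalator"].sum())
        if n_dna != 2:
            raise ValueError(f"expected exactly 2 DNA-intercalator channels, found {n_dna}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def dna_indices(self) -> np.ndarray:
        return self.table.loc[self.table["is_dna_intercalator"], "channel_index"].to_numpy()

    @property
    def background_indices(self) -> np.ndarray:
        return self.table.loc[
            self.table["is_background"] & ~self.table["is_dna_intercalator"], "channel_index"
        ].to_numpy()

    @property
    def protein_indices(self) -> np.ndarray:
        keep = ~self.table["is_dna_intercalator"] & ~self.table["is_background"]
        return self.table.loc[keep, "channel_index"].to_numpy()

    @property
    def protein_names(self) -> list:
        keep = ~self.table["is_dna_intercalator"] & ~self.table["is_background"]
        return self.table.loc[keep, "protein_name"].tolist()


def _read_array(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(str(path))
    if path.suffix.lower() == ".npy":
        return np.load(str(path))
    raise ValueError(f"unsupported array container: {path} (expected .tif/.tiff/.npy)")


def load_sample(stack_path, mask_path, channel_table_path, sample_id=None):
    """Load and validate one (stack, mask, channel map) triplet.

    TIFF stacks are stored channel-first (pages) and transposed to the
    internal (y, x, channel) layout; ``.npy`` stacks are taken as
    (y, x, channel) already.
    """
    stack_path = Path(stack_path)
    if sample_id is None:
        sample_id = stack_path.stem
    arr = _read_array(stack_path)
    if arr.ndim != 3:
        raise ValueError(f"stack at {stack_path} is not 3-D")
    if stack_path.suffix.lower() in {".tif", ".tiff"}:
        arr = np.moveaxis(arr, 0, -1)  # pages are channels
    mask_arr = _read_array(mask_path)
    chmap = ChannelMap(pd.read_csv(channel_table_path))
    stack = PixelStack(arr, sample_id=sample_id)
    mask = SegmentationMask(mask_arr, sample_id=sample_id)
    if stack.spatial_shape != mask.labels.shape:
        raise ShapeMismatchError(
            f"stack spatial shape {stack.spatial_shape} != mask shape {mask.labels.shape} "
            f"for sample {sample_id!r}"
        )
    if stack.n_channels != len(chmap):
        raise ShapeMismatchError(
            f"stack has {stack.n_channels} channels but channel table has {len(chmap)} rows"
        )
    return stack, mask, chmap


def save_sample(stack: PixelStack, mask: SegmentationMask, chmap: ChannelMap, out_dir):
    """Write a triplet in the directory-of-arrays layout load_sample reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / f"{stack.sample_id}_stack.npy", stack.pixels)
    np.save(out_dir / f"{stack.sample_id}_mask.npy", mask.labels)
    chmap.table.to_csv(out_dir / "channels.csv", index=False)
    return (
        out_dir / f"{stack.sample_id}_stack.npy",
        out_dir / f"{stack.sample_id}_mask.npy",
        out_dir / "channels.csv",
    )


def load_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("clinical table must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in clinical table")
    if "event_indicator" in df.columns:
        ev = df["event_indicator"].dropna()
        if not set(np.unique(ev)).issubset({0, 1}):
            raise ValueError("event_indicator must be 0/1")
    if "survival_time" in df.columns and "event_indicator" in df.columns:
        has_event_data = df["survival_time"].notna()
        if np.any(df.loc[has_event_data, "survival_time"] <= 0):
            raise ValueError("survival_time must be > 0")
    return df


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV with header; floats round-trip exactly."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly
    table.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# CellViews / latent bundle serialization (AnnData container)
# ---------------------------------------------------------------------------


def save_cellviews(views, path) -> None:
    """Serialize a CellViews bundle (and optional latents) to .h5ad."""
    import anndata as ad

    obs = pd.DataFrame(
        {
            "cell_id": views.cell_ids,
            "sample_id": pd.Categorical(views.sample_ids),
        }
    )
    obs.index = [f"{s}_{c}" for s, c in zip(views.sample_ids, views.cell_ids)]
    var = pd.DataFrame(index=pd.Index(views.protein_names, name="protein"))
    adata = ad.AnnData(X=views.Y.copy(), obs=obs, var=var)
    adata.obsm["S"] = views.S
    adata.obsm["M"] = views.M
    adata.obsm["C"] = views.C
    adata.obsm["b"] = views.b
    adata.obsm["centroids"] = views.centroids
    adata.uns["covariate_names"] = list(views.covariate_names)
    adata.uns["sample_dims"] = {
        str(k): [int(v[0]), int(v[1])] for k, v in views.sample_dims.items()
    }
    adata.write_h5ad(str(path))


def load_cellviews(path):
    import anndata as ad

    from .views import CellViews

    adata = ad.read_h5ad(str(path))
    return CellViews(
        Y=np.asarray(adata.X, dtype=np.float64),
        S=np.asarray(adata.obsm["S"], dtype=np.float64),
        M=np.asarray(adata.obsm["M"], dtype=np.float64),
        C=np.asarray(adata.obsm["C"], dtype=np.float64),
        b=np.asarray(adata.obsm["b"], dtype=np.float64),
        cell_ids=adata.obs["cell_id"].to_numpy(),
        sample_ids=adata.obs["sample_id"].astype(str).to_numpy(),
        centroids=np.asarray(adata.obsm["centroids"], dtype=np.float64),
        protein_names=list(adata.var_names),
        covariate_names=list(adata.uns["covariate_names"]),
        sample_dims={k: tuple(v) for k, v in adata.uns["sample_dims"].items()},
    )
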