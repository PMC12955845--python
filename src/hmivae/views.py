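"""Derivation of the four per-cell views and conditioning covariates.

Views per cell: mean protein expression (Y), protein nuclear co-localization
score (S, per-cell Pearson r against the mean DNA-intercalator stain),
morphology (M, five features), and spatial context (C, the mean of the
spatial neighbours' standardized [Y|S|M] rows). Covariates b hold
technical background features plus a one-hot sample encoding.

DNA-intercalator and background channels are excluded from the protein
columns of Y and S: the intercalators define the nuclear stain and the
background channels define technical covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .io_ingest import ChannelMap, PixelStack, SegmentationMask

logger = logging.getLogger(__name__)

__all__ = [
    "CellViews",
    "mean_expression",
    "nuclear_localization",
    "morphology",
    "centroids",
    "spatial_neighbours",
    "spatial_context",
    "background_covariates",
    "one_hot",
    "extract_views",
    "N_MORPHOLOGY_FEATURES",
    "MORPHOLOGY_FEATURE_NAMES",
]

N_MORPHOLOGY_FEATURES = 5
MORPHOLOGY_FEATURE_NAMES = ["area", "perimeter", "eccentricity", "concavity", "asymmetry"]

DEFAULT_K_NEIGHBOURS = 10


@dataclass
class CellViews:
    """Per-cell feature views for N cells, P proteins, R samples."""

    Y: np.ndarray  # N x P mean expression
    S: np.ndarray  # N x P nuclear co-localization scores in [-1, 1]
    M: np.ndarray  # N x 5 morphology
    C: np.ndarray  # N x (2P+5) spatial context
    b: np.ndarray  # N x (B+R) covariates (background + one-hot)
    cell_ids: np.ndarray
    sample_ids: np.ndarray
    centroids: np.ndarray  # N x 2, (row, col) pixel units
    protein_names: list
    covariate_names: list
    sample_dims: dict  # sample_id -> (height, width) in pixels

    def __post_init__(self):
        n = self.Y.shape[0]
        for name in ("S", "M", "C", "b", "cell_ids", "sample_ids", "centroids"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} row count != Y row count")
        if self.M.shape[1] != N_MORPHOLOGY_FEATURES:
            raise ValueError("M must have exactly 5 columns")
        p = self.Y.shape[1]
        if self.C.shape[1] != 2 * p + N_MORPHOLOGY_FEATURES:
            raise ValueError("C width must be 2P+5")
        for name in ("Y", "S", "M", "C", "b"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in view {name}")

    @property
    def n_cells(self) -> int:
        return self.Y.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.Y.shape[1]

    @property
    def view_arrays(self) -> dict:
        return {"E": self.Y, "NC": self.S, "M": self.M, "SC": self.C}


def _cell_pixel_index(mask: SegmentationMask):
    """Return (cell_ids, list of flat pixel-index arrays, one per cell)."""
    labels = mask.labels.ravel()
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    ids, starts = np.unique(sorted_labels, return_index=True)
    bounds = np.append(starts, labels.size)
    out_ids, out_idx = [], []
    for i, cid in enumerate(ids):
        if cid == 0:
            continue
        out_ids.append(cid)
        out_idx.append(order[bounds[i] : bounds[i + 1]])
    return np.asarray(out_ids), out_idx


def mean_expression(stack: PixelStack, mask: SegmentationMask, chmap: ChannelMap) -> np.ndarray:
    """Per-cell mean of each protein channel over the cell's pixels."""
    cell_ids = mask.cell_ids()
    if cell_ids.size == 0:
        raise ValueError(f"mask for sample {mask.sample_id!r} has no cells")
    prot = chmap.protein_indices
    out = np.empty((cell_ids.size, prot.size))
    for j, ch in enumerate(prot):
        out[:, j] = ndimage.mean(stack.pixels[:, :, ch], labels=mask.labels, index=cell_ids)
    return out


def _pearson_columns(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r between vector x and each column of M; degenerate -> 0."""
    n = x.size
    if n < 3:
        return np.zeros(M.shape[1])
    xc = x - x.mean()
    Mc = M - M.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sm = np.sqrt((Mc**2).sum(axis=0))
    denom = sx * sm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Mc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def nuclear_localization(
    stack: PixelStack, mask: SegmentationMask, chmap: ChannelMap
) -> np.ndarray:
    """Per-cell Pearson correlation of each protein with the mean DNA stain.

    The mean nuclear stain is the per-pixel average of the two
    DNA-intercalator channels. Cells with <3 pixels or constant vectors on
    either side score 0.
    """
    dna = chmap.dna_indices
    if dna.size != 2:
        raise ValueError(f"expected 2 DNA-intercalator channels, found {dna.size}")
    nuclear = stack.pixels[:, :, dna].mean(axis=2).ravel()
    prot = chmap.protein_indices
    flat = stack.pixels.reshape(-1, stack.n_channels)[:, prot]
    cell_ids, pixel_idx = _cell_pixel_index(mask)
    out = np.zeros((cell_ids.size, prot.size))
    for i, idx in enumerate(pixel_idx):
        out[i] = _pearson_columns(nuclear[idx], flat[idx])
    return out


def morphology(mask: SegmentationMask) -> np.ndarray:
    """Five morphology features per cell: area, perimeter, eccentricity,
    concavity = 1 - area/convex_area, asymmetry = (major-minor)/(major+minor)."""
    from skimage.measure import regionprops

    if mask.cell_ids().size == 0:
        raise ValueError(f"mask for sample {mask.sample_id!r} has no cells")
    regions = regionprops(mask.labels)
    out = np.zeros((len(regions), N_MORPHOLOGY_FEATURES))
    for i, r in enumerate(regions):
        area = float(r.area)
        convex = float(r.area_convex)
        major, minor = float(r.axis_major_length), float(r.axis_minor_length)
        out[i, 0] = area
        out[i, 1] = float(r.perimeter)
        out[i, 2] = float(r.eccentricity)
        out[i, 3] = 1.0 - area / convex if convex > 0 else 0.0
        out[i, 4] = (major - minor) / (major + minor) if (major + minor) > 0 else 0.0
    return out


def centroids(mask: SegmentationMask) -> np.ndarray:
    """Mean (row, col) pixel coordinate of each cell's mask pixels."""
    cell_ids = mask.cell_ids()
    com = ndimage.center_of_mass(np.ones_like(mask.labels), labels=mask.labels, index=cell_ids)
    return np.asarray(com, dtype=np.float64)


def spatial_neighbours(
    cell_centroids: np.ndarray,
    sample_ids: np.ndarray,
    k: int = DEFAULT_K_NEIGHBOURS,
    cell_ids: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Binary k-nearest-neighbour indicator D (row i = neighbours of cell i).

    Neighbours are restricted to the same sample, exclude the cell itself,
    and distance ties are broken by lower cell ID. Samples with <= k cells
    use all available cells; a single-cell sample yields a zero row.
    """
    n = cell_centroids.shape[0]
    sample_ids = np.asarray(sample_ids)
    if cell_ids is None:
        cell_ids = np.arange(n)
    rows, cols = [], []
    for s in np.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == s)
        if idx.size == 1:
            logger.warning("sample %s has a single cell; zero neighbour row", s)
            continue
        pts = cell_centroids[idx]
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        kk = min(k, idx.size - 1)
        ids_local = np.asarray(cell_ids)[idx]
        for i in range(idx.size):
            order = np.lexsort((ids_local, d[i]))[:kk]
            rows.extend([idx[i]] * kk)
            cols.extend(idx[order])
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X, dtype=np.float64)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


def spatial_context(
    Y: np.ndarray, S: np.ndarray, M: np.ndarray, D: sp.spmatrix
) -> np.ndarray:
    """Neighbour-averaged standardized features: C = rownorm(D) @ z([Y|S|M])."""
    scaled = np.hstack([_zscore_columns(Y), _zscore_columns(S), _zscore_columns(M)])
    deg = np.asarray(D.sum(axis=1)).ravel()
    if np.any(deg == 0):
        logger.warning("%d cells have no neighbours; zero context rows", int((deg == 0).sum()))
    inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=np.float64), where=deg > 0)
    return sp.diags(inv) @ D @ scaled


def background_covariates(
    stack: PixelStack, mask: SegmentationMask, chmap: ChannelMap
) -> tuple:
    """Per-sample technical covariates, returned as (values, names).

    With flagged background channels: (i) per-protein correlation, across the
    sample's cells, of mean background staining per cell with mean protein
    expression per cell; (ii) mean sample intensity over all channels;
    (iii) mean intensity over the background channels. Without background
    channels: mean sample intensity and the per-protein mean over 0-labelled
    (background) pixels.
    """
    names: list = []
    vals: list = []
    prot_names = chmap.protein_names
    bg = chmap.background_indices
    if bg.size > 0:
        cell_ids = mask.cell_ids()
        if cell_ids.size < 3:
            logger.warning(
                "sample %s has <3 cells; background correlations set to 0", stack.sample_id
            )
            corr = np.zeros(len(prot_names))
        else:
            bg_img = stack.pixels[:, :, bg].mean(axis=2)
            bg_per_cell = ndimage.mean(bg_img, labels=mask.labels, index=cell_ids)
            Y = mean_expression(stack, mask, chmap)
            corr = _pearson_columns(bg_per_cell, Y)
        vals.extend(corr.tolist())
        names.extend([f"bg_corr_{p}" for p in prot_names])
        vals.append(float(stack.pixels.mean()))
        names.append("mean_sample_intensity")
        vals.append(float(stack.pixels[:, :, bg].mean()))
        names.append("mean_background_intensity")
    else:
        vals.append(float(stack.pixels.mean()))
        names.append("mean_sample_intensity")
        bg_pixels = mask.labels == 0
        for j, p in zip(chmap.protein_indices, prot_names):
            ch = stack.pixels[:, :, j]
            vals.append(float(ch[bg_pixels].mean()) if bg_pixels.any() else 0.0)
            names.append(f"bg_mean_{p}")
    return np.asarray(vals), names


def one_hot(sample_ids: np.ndarray) -> tuple:
    """N x R one-hot sample encoding; columns in lexicographic sample order."""
    sample_ids = np.asarray(sample_ids)
    samples = sorted(set(sample_ids.tolist()))
    out = np.zeros((sample_ids.size, len(samples)))
    for j, s in enumerate(samples):
        out[sample_ids == s, j] = 1.0
    return out, samples


def extract_views(samples, k: int = DEFAULT_K_NEIGHBOURS) -> CellViews:
    """Derive all views for a list of (PixelStack, SegmentationMask, ChannelMap).

    All samples must share the channel map. Z-scoring for the spatial
    context is pooled over the full dataset.
    """
    Ys, Ss, Ms, cents, cids, sids = [], [], [], [], [], []
    bg_vals, bg_names = [], None
    sample_dims = {}
    chmap = samples[0][2]
    for stack, mask, cm in samples:
        if cm.protein_names != chmap.protein_names:
            raise ValueError("all samples must share one channel map")
        Ys.append(mean_expression(stack, mask, cm))
        Ss.append(nuclear_localization(stack, mask, cm))
        Ms.append(morphology(mask))
        cents.append(centroids(mask))
        ids = mask.cell_ids()
        cids.append(ids)
        sids.append(np.repeat(stack.sample_id, ids.size))
        v, bg_names = background_covariates(stack, mask, cm)
        bg_vals.append(np.repeat(v[None, :], ids.size, axis=0))
        sample_dims[stack.sample_id] = mask.labels.shape
    Y = np.vstack(Ys)
    S = np.vstack(Ss)
    M = np.vstack(Ms)
    cent = np.vstack(cents)
    cell_ids = np.concatenate(cids)
    sample_ids = np.concatenate(sids)
    D = spatial_neighbours(cent, sample_ids, k=k)
    C = spatial_context(Y, S, M, D)
    onehot, sample_order = one_hot(sample_ids)
    b = np.hstack([np.vstack(bg_vals), onehot])
    covariate_names = list(bg_names) + [f"sample_{s}" for s in sample_order]
    return CellViews(
        Y=Y,
        S=S,
        M=M,
        C=C,
        b=b,
        cell_ids=cell_ids,
        sample_ids=sample_ids,
        centroids=cent,
        protein_names=chmap.protein_names,
        covariate_names=covariate_names,
        sample_dims=sample_dims,
    )
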