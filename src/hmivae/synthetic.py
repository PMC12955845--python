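"""Synthetic multiplexed-imaging fixtures with known ground truth.

Generates per-sample pixel stacks, segmentation masks, a channel map and
clinical tables. Cells are axis-aligned ellipses with an inner nuclear
disc; protein signal is split between nuclear and cytoplasmic pixels by a
per-protein nuclear fraction, two DNA-intercalator channels light up the
nuclear disc, one background channel carries uniform technical signal, and
a per-sample multiplier emulates staining batch effects. Cell phenotypes
are spatially correlated through a type-transition mixing matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_ingest import ChannelMap, PixelStack, SegmentationMask

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "generate_survival"]


def _default_type_means(n_types: int, n_proteins: int) -> np.ndarray:
    """Each type gets two strong marker proteins on a low shared baseline."""
    means = np.full((n_types, n_proteins), 1.0)
    for t in range(n_types):
        means[t, (2 * t) % n_proteins] = 25.0
        means[t, (2 * t + 1) % n_proteins] = 15.0
    return means


@dataclass
class SyntheticSpec:
    n_samples: int = 3
    shape: tuple = (128, 128)
    n_cell_types: int = 4
    n_proteins: int = 8
    cells_per_sample: int = 200
    type_means: np.ndarray | None = None  # (n_cell_types, n_proteins)
    nuclear_fraction: np.ndarray | None = None  # per protein, in [0, 1]
    mixing: np.ndarray | None = None  # spatial type-transition matrix
    batch_multipliers: np.ndarray | None = None  # per sample
    dna_rate: float = 40.0
    cyto_dna_rate: float = 1.0
    background_channel_rate: float = 0.5
    background_pixel_rate: float = 0.05
    clinical_log_odds: float = 3.0
    survival_log_hr: float = 0.5
    censoring_rate: float = 0.2
    noise: str = "poisson"  # "poisson" | "gaussian" | "none"
    seed: int = 0

    def __post_init__(self):
        if self.type_means is None:
            self.type_means = _default_type_means(self.n_cell_types, self.n_proteins)
        self.type_means = np.asarray(self.type_means, dtype=np.float64)
        if self.type_means.shape != (self.n_cell_types, self.n_proteins):
            raise ValueError("type_means must be (n_cell_types, n_proteins)")
        if np.any(self.type_means < 0):
            raise ValueError("expression rates must be >= 0")
        if self.nuclear_fraction is None:
            self.nuclear_fraction = np.tile([0.9, 0.1], self.n_proteins)[: self.n_proteins]
        self.nuclear_fraction = np.asarray(self.nuclear_fraction, dtype=np.float64)
        if np.any((self.nuclear_fraction < 0) | (self.nuclear_fraction > 1)):
            raise ValueError("nuclear_fraction must lie in [0, 1]")
        if self.mixing is None:
            t = self.n_cell_types
            self.mixing = np.full((t, t), 0.3 / max(t - 1, 1))
            np.fill_diagonal(self.mixing, 0.7)
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if not np.allclose(self.mixing.sum(axis=1), 1.0):
            raise ValueError("mixing matrix rows must sum to 1")
        if self.batch_multipliers is None:
            base = np.array([0.8, 1.0, 1.25])
            self.batch_multipliers = np.resize(base, self.n_samples)
        self.batch_multipliers = np.asarray(self.batch_multipliers, dtype=np.float64)
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class SyntheticDataset:
    samples: list  # [(PixelStack, SegmentationMask, ChannelMap), ...]
    channel_map: ChannelMap
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame = field(repr=False)
    spec: SyntheticSpec = field(repr=False, default=None)


def _channel_map(n_proteins: int) -> ChannelMap:
    rows = []
    for i in range(n_proteins):
        rows.append((i, f"protein_{i}", False, False))
    rows.append((n_proteins, "DNA1", True, False))
    rows.append((n_proteins + 1, "DNA2", True, False))
    rows.append((n_proteins + 2, "ArAr80", False, True))
    return ChannelMap(
        pd.DataFrame(
            rows,
            columns=["channel_index", "protein_name", "is_dna_intercalator", "is_background"],
        )
    )


def _place_cells(spec: SyntheticSpec, rng: np.random.Generator):
    """Jittered-grid ellipse placement; returns per-cell geometry arrays."""
    h, w = spec.shape
    spacing = 8
    margin = 5
    ys = np.arange(margin, h - margin, spacing)
    xs = np.arange(margin, w - margin, spacing)
    positions = [(y, x) for y in ys for x in xs]
    if spec.cells_per_sample > len(positions):
        raise ValueError(
            f"cannot pack {spec.cells_per_sample} cells into {h}x{w}; "
            "use a larger grid or smaller cell count"
        )
    chosen = sorted(rng.choice(len(positions), size=spec.cells_per_sample, replace=False))
    cells = []
    for pos_i in chosen:
        cy, cx = positions[pos_i]
        cy = cy + rng.uniform(-1, 1)
        cx = cx + rng.uniform(-1, 1)
        ry = rng.uniform(2.2, 3.4)
        rx = rng.uniform(2.2, 3.4)
        rn = rng.uniform(1.2, 1.7)
        cells.append((cy, cx, ry, rx, rn))
    return cells


def _assign_types(cells, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated types: each cell transitions from its nearest
    already-typed cell via the mixing matrix."""
    n = len(cells)
    types = np.full(n, -1, dtype=np.int64)
    coords = np.array([(c[0], c[1]) for c in cells])
    for i in range(n):
        if i == 0:
            types[i] = rng.integers(spec.n_cell_types)
            continue
        d = ((coords[:i] - coords[i]) ** 2).sum(axis=1)
        nearest = int(np.argmin(d))
        types[i] = rng.choice(spec.n_cell_types, p=spec.mixing[types[nearest]])
    return types


def _render_sample(spec, sample_idx, rng):
    h, w = spec.shape
    p = spec.n_proteins
    n_channels = p + 3
    mult = spec.batch_multipliers[sample_idx]
    cells = _place_cells(spec, rng)
    types = _assign_types(cells, spec, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int64)
    rates = np.zeros((h, w, n_channels))
    # background (outside cells)
    rates[:, :, :p] = spec.background_pixel_rate
    rates[:, :, p] = 0.2  # residual DNA signal off-cell
    rates[:, :, p + 1] = 0.2
    rates[:, :, p + 2] = spec.background_channel_rate
    gt_rows = []
    for i, ((cy, cx, ry, rx, rn), t) in enumerate(zip(cells, types)):
        cell_id = i + 1
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        nucleus = (yy - cy) ** 2 + (xx - cx) ** 2 <= rn**2
        nucleus &= inside
        mask[inside] = cell_id
        npix = int(inside.sum())
        nnuc = int(nucleus.sum())
        fn = nnuc / npix if npix else 0.0
        cyto = inside & ~nucleus
        for j in range(p):
            base = spec.type_means[t, j]
            nf = spec.nuclear_fraction[j]
            if 0 < fn < 1:
                rates[nucleus, j] = base * nf / fn
                rates[cyto, j] = base * (1 - nf) / (1 - fn)
            else:
                rates[inside, j] = base
        rates[nucleus, p] = spec.dna_rate
        rates[nucleus, p + 1] = spec.dna_rate
        rates[cyto, p] = spec.cyto_dna_rate
        rates[cyto, p + 1] = spec.cyto_dna_rate
        gt_rows.append(
            {
                "sample_id": f"sample_{sample_idx}",
                "cell_id": cell_id,
                "cell_type": int(t),
                "centroid_y": cy,
                "centroid_x": cx,
                "n_pixels": npix,
                "nuclear_pixel_fraction": fn,
            }
        )
    rates *= mult
    if spec.noise == "poisson":
        pixels = rng.poisson(rates).astype(np.float64)
    elif spec.noise == "gaussian":
        pixels = np.maximum(rates + rng.normal(0, np.sqrt(rates + 1e-9)), 0.0)
    else:
        pixels = rates
    sid = f"sample_{sample_idx}"
    return (
        PixelStack(pixels, sample_id=sid),
        SegmentationMask(mask, sample_id=sid),
        pd.DataFrame(gt_rows),
    )


def generate_survival(
    prevalence_values: np.ndarray,
    log_hr: float,
    seed: int = 0,
    baseline_hazard: float = 0.1,
    censoring_rate: float = 0.2,
) -> pd.DataFrame:
    """Exponential survival times with hazard proportional to exp(log_hr * prev).

    Censoring is independent exponential, tuned so roughly `censoring_rate`
    of subjects are censored at log_hr = 0; censoring_rate >= 1 censors all.
    """
    prevalence_values = np.asarray(prevalence_values, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rate = baseline_hazard * np.exp(log_hr * prevalence_values)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate >= 1.0:
        times = t_event
        events = np.zeros(times.size, dtype=int)
    elif censoring_rate > 0:
        c_rate = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=t_event.size)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
    else:
        times = t_event
        events = np.ones(times.size, dtype=int)
    return pd.DataFrame(
        {
            "sample_id": [f"sample_{i}" for i in range(times.size)],
            "survival_time": times,
            "event_indicator": events,
        }
    )


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Render all samples of a synthetic dataset plus clinical ground truth."""
    rng = np.random.default_rng(spec.seed)
    chmap = _channel_map(spec.n_proteins)
    samples, gt_parts = [], []
    for s in range(spec.n_samples):
        stack, mask, gt = _render_sample(spec, s, rng)
        samples.append((stack, mask, chmap))
        gt_parts.append(gt)
    ground_truth = pd.concat(gt_parts, ignore_index=True)
    # clinical category tied to the prevalence of cell type 0 per sample
    prev0 = (
        ground_truth.assign(is0=ground_truth["cell_type"] == 0)
        .groupby("sample_id")["is0"]
        .mean()
        .sort_index()
    )
    centered = prev0.to_numpy() - prev0.to_numpy().mean()
    p_cat = 1.0 / (1.0 + np.exp(-spec.clinical_log_odds * centered * 10.0))
    group = np.where(rng.uniform(size=spec.n_samples) < p_cat, "A", "B")
    surv = generate_survival(
        prev0.to_numpy(),
        spec.survival_log_hr,
        seed=spec.seed + 1,
        censoring_rate=spec.censoring_rate,
    )
    clinical = pd.DataFrame(
        {
            "sample_id": prev0.index.to_numpy(),
            "group": group,
            "grade": rng.integers(1, 4, size=spec.n_samples),
            "stage": rng.integers(1, 5, size=spec.n_samples),
        }
    ).merge(surv, on="sample_id")
    return SyntheticDataset(
        samples=samples,
        channel_map=chmap,
        clinical=clinical,
        ground_truth=ground_truth,
        spec=spec,
    )
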