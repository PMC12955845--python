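"""Reference-to-query latent projection and partition comparison.

A query dataset is embedded with a model trained on a reference dataset
after conforming its covariates to the reference schema; cluster labels are
then transferred with a k-nearest-neighbour vote and compared against
query-side clustering using the adjusted Rand index and its
class-balanced variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProjectionResult",
    "harmonize_covariates",
    "transfer_labels",
    "adjusted_rand_index",
    "balanced_adjusted_rand_index",
    "compare_partitions",
    "project",
]

DEFAULT_TRANSFER_K = 15


@dataclass
class ProjectionResult:
    space: str
    metric: str
    labels: np.ndarray
    ari: float | None = None
    balanced_ari: float | None = None


def harmonize_covariates(
    reference_covariate_names,
    reference_protein_names,
    query_views,
    seed: int = 0,
) -> np.ndarray:
    """Conform a query CellViews' covariates to the reference schema.

    Protein panels must match exactly. Background covariates present in both
    schemas are carried over; reference covariates missing from the query are
    zero-filled; extra query covariates are dropped. The sample one-hot block
    is replaced by a random valid one-hot of the reference width.
    """
    ref_cov = list(reference_covariate_names)
    ref_prot = list(reference_protein_names)
    if sorted(ref_prot) != sorted(query_views.protein_names):
        missing = sorted(set(ref_prot) ^ set(query_views.protein_names))
        raise ValueError(f"protein panels differ; unmatched proteins: {missing}")
    q_cov = list(query_views.covariate_names)
    q_bg = [c for c in q_cov if not c.startswith("sample_")]
    ref_bg = [c for c in ref_cov if not c.startswith("sample_")]
    ref_onehot = [c for c in ref_cov if c.startswith("sample_")]
    n = query_views.n_cells
    out = np.zeros((n, len(ref_cov)))
    for j, name in enumerate(ref_bg):
        if name in q_bg:
            out[:, j] = query_views.b[:, q_cov.index(name)]
        # missing stains stay zero-filled
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(ref_onehot), size=n)
    for i in range(n):
        out[i, len(ref_bg) + pick[i]] = 1.0
    return out


def project(model, query_views, covariate_seed: int = 0):
    """Embed a query dataset with a reference-trained model.

    Query views are standardized with the reference scaler (projection must
    not peek at query statistics) and covariates are harmonized first.
    Returns a LatentSpaces bundle for the query cells.
    """
    from ._autograd import Tensor
    from .model import VIEW_NAMES, LatentSpaces

    ref_cov_names = getattr(model, "covariate_names", None)
    ref_prot_names = getattr(model, "protein_names", None)
    if ref_cov_names is None or ref_prot_names is None:
        raise ValueError("model lacks schema metadata (covariate/protein names)")
    b = harmonize_covariates(ref_cov_names, ref_prot_names, query_views, covariate_seed)
    raw = [query_views.Y, query_views.S, query_views.M, query_views.C]
    scaled = model.scale(raw)
    embeds, mu, _ = model.encode([Tensor(a) for a in scaled], Tensor(b))
    return LatentSpaces(
        z=mu.data.copy(),
        view_embeddings={n: e.data.copy() for n, e in zip(VIEW_NAMES, embeds)},
    )


def transfer_labels(
    reference_embedding: np.ndarray,
    reference_labels: np.ndarray,
    query_embedding: np.ndarray,
    k: int = DEFAULT_TRANSFER_K,
    metric: str = "euclidean",
) -> np.ndarray:
    """Majority label of the k nearest reference cells; ties -> smallest label."""
    from sklearn.neighbors import NearestNeighbors

    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")
    reference_labels = np.asarray(reference_labels)
    k = min(k, reference_embedding.shape[0])
    nn = NearestNeighbors(n_neighbors=k, metric=metric).fit(reference_embedding)
    _, idx = nn.kneighbors(query_embedding)
    neigh = reference_labels[idx]
    n_labels = int(reference_labels.max()) + 1
    out = np.empty(query_embedding.shape[0], dtype=np.int64)
    for i in range(out.size):
        counts = np.bincount(neigh[i], minlength=n_labels)
        out[i] = int(np.argmax(counts))  # argmax returns the smallest on ties
    return out


def _contingency(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    a_vals, a_inv = np.unique(labels_a, return_inverse=True)
    b_vals, b_inv = np.unique(labels_b, return_inverse=True)
    table = np.zeros((a_vals.size, b_vals.size))
    np.add.at(table, (a_inv, b_inv), 1.0)
    return table


def _ari_from_contingency(table: np.ndarray) -> float:
    """Pair-counting adjusted Rand index; accepts fractional cell counts."""

    def comb2(x):
        return x * (x - 1.0) / 2.0

    n = table.sum()
    sum_ij = comb2(table).sum()
    a = comb2(table.sum(axis=1)).sum()
    b = comb2(table.sum(axis=0)).sum()
    expected = a * b / comb2(n) if comb2(n) > 0 else 0.0
    max_index = (a + b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions trivial/identical structure
    # clamp fp overshoot on fractional (balanced) tables; ARI <= 1 always
    return float(np.clip((sum_ij - expected) / (max_index - expected), -1.0, 1.0))


def adjusted_rand_index(labels_a, labels_b) -> float:
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must label the same cells")
    return _ari_from_contingency(_contingency(labels_a, labels_b))


def balanced_adjusted_rand_index(labels_true, labels_pred) -> float:
    """ARI after reweighting the true classes to equal mass.

    Each row of the contingency table (one true class) is rescaled so all
    classes contribute N/K points, then the standard adjusted formula is
    applied to the fractional table. Equal-sized classes reduce to the
    plain ARI.
    """
    labels_true, labels_pred = np.asarray(labels_true), np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("partitions must label the same cells")
    table = _contingency(labels_true, labels_pred)
    n = table.sum()
    k = table.shape[0]
    row_sums = table.sum(axis=1, keepdims=True)
    scaled = table * (n / k) / row_sums
    return _ari_from_contingency(scaled)


def compare_partitions(labels_a, labels_b) -> tuple:
    """(ARI, balanced ARI) with labels_a treated as the reference classes."""
    return (
        adjusted_rand_index(labels_a, labels_b),
        balanced_adjusted_rand_index(labels_a, labels_b),
    )
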