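"""Clustering and clinical/survival analyses over latent or original features.

Cluster labels come from Leiden community detection on a Euclidean kNN
graph. Cluster prevalence per sample is summarized two ways: as the
within-sample proportion and as instances per mm^2 of tissue (pixel area at
1 um/pixel, scaled by 1e6). Associations with categorical clinical
variables use maximum-likelihood logistic regression (Wald z reported as
the t-value); survival uses Cox proportional hazards with
Benjamini-Hochberg correction across clusters.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "cluster",
    "rank_features",
    "prevalence",
    "bh_adjust",
    "associate_latent",
    "associate_proportion",
    "survival",
    "segmentation_qc",
    "DEFAULT_RESOLUTIONS",
    "DEFAULT_CLUSTER_NEIGHBOURS",
    "DEFAULT_QC_PAIRS",
    "MM2_SCALE",
]

# Leiden resolution per embedding space: integrated, expression,
# nuclear co-localization, morphology, spatial context.
DEFAULT_RESOLUTIONS = {"integrated": 1.0, "E": 0.5, "NC": 1.0, "M": 0.1, "SC": 0.5}
DEFAULT_CLUSTER_NEIGHBOURS = 100
MM2_SCALE = 1e6  # pixel area -> per-mm^2 at 1 um/pixel (1000x1000 px = 1 mm^2)

DEFAULT_QC_PAIRS = [
    ("CD3", "CD20"),
    ("CK8/18", "CK5"),
    ("CD45", "CK8/18"),
    ("SMA", "PanCK"),
    ("GATA3", "CK14"),
]


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster IDs contiguously from 0 in first-appearance order."""
    mapping: dict = {}
    out = np.empty(labels.size, dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster(
    embedding: np.ndarray,
    n_neighbours: int = DEFAULT_CLUSTER_NEIGHBOURS,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden clustering on a Euclidean kNN graph of the embedding."""
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    embedding = np.asarray(embedding, dtype=np.float64)
    n = embedding.shape[0]
    if embedding.ndim != 2 or embedding.shape[1] < 2:
        raise ValueError("embedding must be N x d with d >= 2")
    if n <= n_neighbours:
        raise ValueError(f"need more cells ({n}) than neighbours ({n_neighbours})")
    nn = NearestNeighbors(n_neighbors=n_neighbours + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    src = np.repeat(np.arange(n), n_neighbours)
    dst = idx[:, 1:].ravel()
    edges = {(int(a), int(b)) if a < b else (int(b), int(a)) for a, b in zip(src, dst)}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return _relabel_first_appearance(np.asarray(part.membership))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(p, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def rank_features(
    X: np.ndarray,
    labels: np.ndarray,
    feature_names,
    alpha: float = 0.05,
    top: int = 3,
) -> pd.DataFrame:
    """Per-cluster Welch t-test of each feature (cluster vs rest).

    For each cluster the top `top` features with positive t and BH-adjusted
    p < alpha are selected; the union of selections is reported with t-values
    for every cluster (significance relaxed outside the selecting cluster).
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    feature_names = list(feature_names)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters to rank features")
    rows = []
    for c in clusters:
        in_c = labels == c
        if in_c.sum() < 2:
            logger.warning("cluster %s has <2 cells; skipped in ranking", c)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(X[in_c], X[~in_c], axis=0, equal_var=False)
        p_adj = bh_adjust(p)
        for j, name in enumerate(feature_names):
            rows.append(
                {
                    "cluster_id": c,
                    "feature": name,
                    "t_value": t[j],
                    "p_value": p[j],
                    "p_adj": p_adj[j],
                }
            )
    table = pd.DataFrame(rows)
    selected: set = set()
    for c, sub in table.groupby("cluster_id"):
        ok = sub[(sub["t_value"] > 0) & (sub["p_adj"] < alpha)].dropna(subset=["t_value"])
        top_feats = ok.sort_values("t_value", ascending=False)["feature"].head(top)
        selected.update(top_feats)
    table["selected"] = table["feature"].isin(selected)
    return table[table["selected"]].drop(columns="selected").reset_index(drop=True)


def prevalence(
    labels: np.ndarray, sample_ids: np.ndarray, sample_dims: dict
) -> pd.DataFrame:
    """Cluster prevalence per sample: proportion and instances per mm^2."""
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    clusters = np.unique(labels)
    rows = []
    for s in sorted(set(sample_ids.tolist())):
        in_s = sample_ids == s
        n_s = int(in_s.sum())
        h, w = sample_dims[s]
        area_px = float(h) * float(w)
        for c in clusters:
            n_cs = int((labels[in_s] == c).sum())
            rows.append(
                {
                    "sample_id": s,
                    "cluster_id": int(c),
                    "proportion": n_cs / n_s,
                    "per_mm2": n_cs / area_px * MM2_SCALE,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic association
# ---------------------------------------------------------------------------


def _fit_logistic(y: np.ndarray, X: np.ndarray, col_names):
    """MLE logistic fit with intercept; drops collinear columns and refits.

    Returns a DataFrame (predictor, t_value, p) or None if the fit fails.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=np.float64)
    col_names = list(col_names)
    # drop degenerate / collinear columns via pivoted QR on centered design
    keep = [j for j in range(X.shape[1]) if np.std(X[:, j]) > 0]
    if not keep:
        return None
    Xk = X[:, keep]
    centered = Xk - Xk.mean(axis=0)
    rank = int(np.linalg.matrix_rank(centered))
    if rank < Xk.shape[1]:
        # greedy forward selection of independent columns
        chosen: list = []
        for j in range(Xk.shape[1]):
            trial = chosen + [j]
            if np.linalg.matrix_rank(centered[:, trial]) == len(trial):
                chosen.append(j)
        keep = [keep[j] for j in chosen]
        Xk = X[:, keep]
    design = sm.add_constant(Xk, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200, method="lbfgs")
        except Exception:
            return None
    params = fit.params[1:]
    bse = fit.bse[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = params / bse
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    return pd.DataFrame(
        {"predictor": [col_names[j] for j in keep], "t_value": tvals, "p": pvals}
    )


def _category_targets(clinical: pd.DataFrame, variables, min_samples: int):
    """Yield (variable, category, binary y aligned to clinical rows) or NA flag."""
    for var in variables:
        vals = clinical[var]
        for cat in sorted(vals.dropna().unique().tolist(), key=str):
            y = (vals == cat).astype(float).to_numpy()
            ok = vals.notna().to_numpy()
            n_pos = int(y[ok].sum())
            n_neg = int(ok.sum() - n_pos)
            enough = n_pos >= min_samples and n_neg >= min_samples
            yield var, cat, y, ok, enough


def associate_latent(
    z: np.ndarray,
    sample_ids: np.ndarray,
    clinical: pd.DataFrame,
    variables,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Logistic association of per-sample median latent dims with categories.

    One fit per (variable, category): category membership regressed on all
    per-sample median latent dimensions jointly; collinear dimensions are
    dropped and the model refit. Categories with too few samples yield NA
    rows. BH adjustment within each fit family.
    """
    z = np.asarray(z)
    sample_ids = np.asarray(sample_ids)
    med = (
        pd.DataFrame(z, index=sample_ids)
        .groupby(level=0)
        .median()
        .rename(columns=lambda j: f"latent_{j}")
    )
    clin = clinical.set_index("sample_id").loc[med.index]
    rows = []
    for var, cat, y, ok, enough in _category_targets(clin.reset_index(), variables, min_samples):
        if not enough:
            rows.append(
                {
                    "clinical_variable": var,
                    "category": cat,
                    "predictor": pd.NA,
                    "t_value": np.nan,
                    "p": np.nan,
                    "p_adj": np.nan,
                }
            )
            continue
        res = _fit_logistic(y[ok], med.to_numpy()[ok], med.columns)
        if res is None:
            continue
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
        for _, r in res.iterrows():
            rows.append(
                {
                    "clinical_variable": var,
                    "category": cat,
                    "predictor": r["predictor"],
                    "t_value": r["t_value"],
                    "p": r["p"],
                    "p_adj": r["p_adj"],
                }
            )
    return pd.DataFrame(rows)


def associate_proportion(
    prevalence_table: pd.DataFrame,
    clinical: pd.DataFrame,
    variables,
    metric: str = "proportion",
    min_samples: int = 5,
) -> pd.DataFrame:
    """Logistic association of cluster prevalence with clinical categories.

    With metric='proportion' each cluster is fit one at a time (1 vs rest,
    univariate; avoids the degenerate simplex design); with metric='per_mm2'
    all clusters enter one joint fit. BH across the cluster family.
    """
    if metric not in ("proportion", "per_mm2"):
        raise ValueError(f"unknown prevalence metric {metric!r}")
    wide = prevalence_table.pivot(index="sample_id", columns="cluster_id", values=metric)
    wide = wide.fillna(0.0)
    clin = clinical.set_index("sample_id").loc[wide.index]
    cluster_cols = [f"cluster_{c}" for c in wide.columns]
    rows = []
    for var, cat, y, ok, enough in _category_targets(
        clin.reset_index(), variables, min_samples
    ):
        if not enough:
            for c in cluster_cols:
                rows.append(
                    {
                        "clinical_variable": var,
                        "category": cat,
                        "predictor": c,
                        "t_value": np.nan,
                        "p": np.nan,
                        "p_adj": np.nan,
                    }
                )
            continue
        if metric == "proportion":
            parts = []
            for j, cname in enumerate(cluster_cols):
                res = _fit_logistic(y[ok], wide.to_numpy()[ok][:, [j]], [cname])
                if res is not None:
                    parts.append(res)
            res = pd.concat(parts, ignore_index=True) if parts else None
        else:
            res = _fit_logistic(y[ok], wide.to_numpy()[ok], cluster_cols)
        if res is None:
            continue
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
        for _, r in res.iterrows():
            rows.append(
                {
                    "clinical_variable": var,
                    "category": cat,
                    "predictor": r["predictor"],
                    "t_value": r["t_value"],
                    "p": r["p"],
                    "p_adj": r["p_adj"],
                }
            )
    return pd.DataFrame(rows)


def survival(
    prevalence_table: pd.DataFrame,
    clinical: pd.DataFrame,
    metric: str = "proportion",
    covariates=("stage", "grade"),
) -> pd.DataFrame:
    """Cox proportional hazards per cluster, adjusting for stage/grade.

    Returns one row per cluster with the hazard ratio for the prevalence
    metric, BH-adjusted p across clusters, and the model concordance index.
    """
    from lifelines import CoxPHFitter

    if "survival_time" not in clinical.columns or "event_indicator" not in clinical.columns:
        raise ValueError("clinical table lacks survival_time/event_indicator")
    clin = clinical.dropna(subset=["survival_time", "event_indicator"]).copy()
    if np.any(clin["survival_time"] <= 0):
        raise ValueError("non-positive survival times")
    if clin["event_indicator"].sum() == 0:
        raise ValueError("no events observed; cannot fit Cox model")
    covs = [c for c in covariates if c in clin.columns]
    wide = prevalence_table.pivot(index="sample_id", columns="cluster_id", values=metric)
    wide = wide.fillna(0.0)
    rows = []
    for c in wide.columns:
        df = clin.set_index("sample_id").join(wide[[c]], how="inner").reset_index()
        df = df.rename(columns={c: "prev"})
        cols = ["survival_time", "event_indicator", "prev"] + covs
        df = df[cols].dropna()
        if df["prev"].std() == 0:
            rows.append(
                {
                    "cluster_id": int(c),
                    "metric": metric,
                    "hazard_ratio": np.nan,
                    "p": np.nan,
                    "concordance_index": np.nan,
                }
            )
            continue
        cph = CoxPHFitter(penalizer=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="survival_time", event_col="event_indicator")
        rows.append(
            {
                "cluster_id": int(c),
                "metric": metric,
                "hazard_ratio": float(np.exp(cph.params_["prev"])),
                "log_hr": float(cph.params_["prev"]),
                "p": float(cph.summary.loc["prev", "p"]),
                "concordance_index": float(cph.concordance_index_),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def segmentation_qc(
    Y: np.ndarray, protein_names, pairs=None
) -> pd.DataFrame:
    """Percentage of cells co-expressing each non-co-expressed protein pair.

    A cell counts if its mean expression exceeds the dataset-wide median for
    both proteins of the pair (strict inequality).
    """
    protein_names = list(protein_names)
    if pairs is None:
        available = set(protein_names)
        pairs = [p for p in DEFAULT_QC_PAIRS if p[0] in available and p[1] in available]
        if not pairs:
            raise ValueError(
                "no default QC pairs match the panel; pass pairs explicitly"
            )
    Y = np.asarray(Y)
    medians = np.median(Y, axis=0)
    rows = []
    for a, b in pairs:
        ia, ib = protein_names.index(a), protein_names.index(b)
        both = (Y[:, ia] > medians[ia]) & (Y[:, ib] > medians[ib])
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "percent_double_positive": 100.0 * both.mean(),
            }
        )
    return pd.DataFrame(rows)
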