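"""Multi-view conditional variational autoencoder.

Each of the four views (E = mean expression, NC = nuclear co-localization,
M = morphology, SC = spatial context) is encoded by its own branch —
consuming the view concatenated with the covariates b — into a
view-specific embedding. The embeddings are concatenated, passed through a
merge hidden layer, and mapped to the latent Gaussian (mu, log sigma^2).
The decoder is symmetric: z concatenated with b passes through a merge
layer, then view-specific branches reconstruct each view.

The objective is the ELBO

    sum_j lambda_j * E_q[log p(x_j | z)] - beta * KL(q(z|X) || N(0, I))

with a unit-variance Gaussian likelihood per feature on standardized
inputs, per-view weights lambda_j, and a beta warm-up schedule (0.1 per
epoch, capped at 1.0) or constant beta = 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._autograd import Adam, Parameter, Tensor, concat
from .views import CellViews

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "HmiVAEModel",
    "LatentSpaces",
    "beta_at",
    "kl_divergence",
    "elbo_terms",
    "train",
    "grid_search",
    "embed_all",
    "ablate",
    "default_grid",
    "VIEW_NAMES",
]

VIEW_NAMES = ("E", "NC", "M", "SC")

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelConfig:
    n_hidden_layers: int = 1
    hidden_size: int = 32
    latent_dim: int = 10
    view_weights: tuple = (1.0, 1.0, 1.0, 1.0)
    beta_scheme: str = "warmup"  # "warmup" | "constant"
    beta_increment: float = 0.1
    batch_size: int = 128
    seed: int = 0
    view_embed_dim: int | None = None  # defaults to hidden_size
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    min_delta: float = 1e-4

    def __post_init__(self):
        if any(w < 0 for w in self.view_weights):
            raise ValueError("view weights must be non-negative")
        if len(self.view_weights) != 4:
            raise ValueError("need exactly 4 view weights (E, NC, M, SC)")
        if self.beta_scheme not in ("warmup", "constant"):
            raise ValueError(f"unknown beta scheme {self.beta_scheme!r}")
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")

    @property
    def embed_dim(self) -> int:
        return self.view_embed_dim if self.view_embed_dim is not None else self.hidden_size


# Hyperparameter lattice searched in the original tuning protocol.
def default_grid(**overrides) -> list:
    seeds = overrides.pop("seeds", (0, 1, 42, 123, 1234))
    layers = overrides.pop("n_hidden_layers", (1, 2))
    hidden = overrides.pop("hidden_size", (8, 32, 64))
    latent = overrides.pop("latent_dim", (10, 20))
    betas = overrides.pop("beta_scheme", ("warmup", "constant"))
    batches = overrides.pop("batch_size", (40000, 16000, 8000, 5333, 4000))
    grid = []
    for s in seeds:
        for nl in layers:
            for h in hidden:
                for ld in latent:
                    for bs in betas:
                        for b in batches:
                            grid.append(
                                ModelConfig(
                                    n_hidden_layers=nl,
                                    hidden_size=h,
                                    latent_dim=ld,
                                    beta_scheme=bs,
                                    batch_size=b,
                                    seed=s,
                                    **overrides,
                                )
                            )
    return grid


def beta_at(epoch: int, scheme: str = "warmup", increment: float = 0.1) -> float:
    """KL weight at a given epoch: warm-up from 0 capped at 1, or constant 1."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if scheme == "constant":
        return 1.0
    if scheme == "warmup":
        return min(1.0, increment * epoch)
    raise ValueError(f"unknown beta scheme {scheme!r}")


def ablate(cfg: ModelConfig, view: str) -> ModelConfig:
    """Zero one view's reconstruction weight (others set to 1), or keep only
    expression with ``view='expression_only'``."""
    if view == "expression_only":
        return replace(cfg, view_weights=(1.0, 0.0, 0.0, 0.0))
    if view not in VIEW_NAMES:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEW_NAMES}")
    w = [1.0, 1.0, 1.0, 1.0]
    w[VIEW_NAMES.index(view)] = 0.0
    return replace(cfg, view_weights=tuple(w))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class _MLP:
    """Dense stack with ELU on all layers (last layer optionally linear)."""

    def __init__(self, sizes, rng, final_activation=True):
        self.final_activation = final_activation
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(Parameter(rng.normal(0.0, scale, size=(fan_in, fan_out))))
            self.biases.append(Parameter(np.zeros(fan_out)))

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ W + b
            if i < n - 1 or self.final_activation:
                x = x.elu()
        return x

    def parameters(self):
        return self.weights + self.biases


class HmiVAEModel:
    """Conditional multi-view VAE with NumPy parameters.

    Stores per-view standardization statistics so that embeddings for a
    query dataset can be computed under the reference scaling.
    """

    def __init__(self, view_dims, n_covariates: int, cfg: ModelConfig):
        self.view_dims = tuple(int(d) for d in view_dims)
        self.n_covariates = int(n_covariates)
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h, e, z = cfg.hidden_size, cfg.embed_dim, cfg.latent_dim
        nb = self.n_covariates
        # encoder: per-view branch (view + b) -> hidden^n -> embed
        self.encoders = [
            _MLP([d + nb] + [h] * cfg.n_hidden_layers + [e], rng) for d in self.view_dims
        ]
        self.enc_merge = _MLP([4 * e, h], rng)
        self.mu_head = _MLP([h, z], rng, final_activation=False)
        self.logvar_head = _MLP([h, z], rng, final_activation=False)
        # decoder: (z + b) -> merge hidden -> per-view hidden^n -> view output
        self.dec_merge = _MLP([z + nb, h], rng)
        self.decoders = [
            _MLP([h] + [h] * cfg.n_hidden_layers + [d], rng, final_activation=False)
            for d in self.view_dims
        ]
        # standardization stats (set by fit_scaler)
        self.scaler_mean = None
        self.scaler_std = None

    # -- scaling ----------------------------------------------------------
    def fit_scaler(self, views_list) -> None:
        self.scaler_mean, self.scaler_std = [], []
        for X in views_list:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            self.scaler_mean.append(mu)
            self.scaler_std.append(sd)

    def scale(self, views_list) -> list:
        if self.scaler_mean is None:
            raise RuntimeError("scaler not fitted")
        return [
            (X - mu) / sd for X, mu, sd in zip(views_list, self.scaler_mean, self.scaler_std)
        ]

    # -- forward ----------------------------------------------------------
    def encode(self, views_list, b):
        """Return (view embeddings, mu, logvar) for standardized view arrays."""
        for name, X in zip(VIEW_NAMES, views_list):
            if not np.all(np.isfinite(np.asarray(X if not isinstance(X, Tensor) else X.data))):
                raise ValueError(f"non-finite input in view {name}")
        b_t = b if isinstance(b, Tensor) else Tensor(b)
        embeds = []
        for enc, X in zip(self.encoders, views_list):
            x_t = X if isinstance(X, Tensor) else Tensor(X)
            embeds.append(enc(concat([x_t, b_t])))
        merged = self.enc_merge(concat(embeds))
        return embeds, self.mu_head(merged), self.logvar_head(merged)

    def decode(self, z, b):
        """Reconstruction means for all four views from latent z and covariates."""
        z_t = z if isinstance(z, Tensor) else Tensor(z)
        b_t = b if isinstance(b, Tensor) else Tensor(b)
        if z_t.shape[1] != self.cfg.latent_dim:
            raise ValueError(
                f"latent width {z_t.shape[1]} != configured {self.cfg.latent_dim}"
            )
        h = self.dec_merge(concat([z_t, b_t]))
        return [dec(h) for dec in self.decoders]

    def parameters(self):
        ps = []
        for enc in self.encoders:
            ps += enc.parameters()
        ps += self.enc_merge.parameters()
        ps += self.mu_head.parameters() + self.logvar_head.parameters()
        ps += self.dec_merge.parameters()
        for dec in self.decoders:
            ps += dec.parameters()
        return ps

    def get_state(self):
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def kl_divergence(mu, logvar):
    """Closed-form KL(N(mu, diag exp(logvar)) || N(0, I)), mean per cell."""
    mu_t = mu if isinstance(mu, Tensor) else Tensor(mu)
    lv_t = logvar if isinstance(logvar, Tensor) else Tensor(logvar)
    n = mu_t.shape[0]
    per = (mu_t.square() + lv_t.exp() - 1.0 - lv_t).sum() * 0.5
    return per * (1.0 / n)


def _gaussian_ll(x, mean):
    """Unit-variance Gaussian log-likelihood summed over features, mean per cell."""
    x_t = x if isinstance(x, Tensor) else Tensor(x)
    n, f = x_t.shape
    sq = (x_t - mean).square().sum()
    return (sq * -0.5 + (-0.5 * f * LOG2PI * n)) * (1.0 / n)


def elbo_terms(batch_views, reconstructions, mu, logvar, view_weights, beta):
    """ELBO (per-cell mean) and its components.

    Returns (total, {view: log-likelihood}, kl). total = sum_j lambda_j LL_j
    - beta * KL.
    """
    if beta < 0 or any(w < 0 for w in view_weights):
        raise ValueError("beta and view weights must be non-negative")
    lls = {}
    total = None
    for name, w, x, rec in zip(VIEW_NAMES, view_weights, batch_views, reconstructions):
        ll = _gaussian_ll(x, rec)
        lls[name] = ll
        term = ll * float(w)
        total = term if total is None else total + term
    kl = kl_divergence(mu, logvar)
    total = total + kl * (-float(beta))
    return total, lls, kl


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class LatentSpaces:
    """Posterior-mean latent z plus the four view-specific embeddings."""

    z: np.ndarray
    view_embeddings: dict = field(repr=False)
    reconstruction_ll: dict | None = None  # per-view per-cell mean LL
    kl: float | None = None

    def embedding(self, space: str) -> np.ndarray:
        if space == "integrated":
            return self.z
        return self.view_embeddings[space]


def _split_indices(n, sample_ids, fractions, rng):
    """Stratified-by-sample train/val/test index split."""
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("split fractions must sum to 1")
    tr, va, te = [], [], []
    sample_ids = np.asarray(sample_ids)
    for s in np.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == s)
        idx = rng.permutation(idx)
        n_tr = int(round(f_train * idx.size))
        n_va = int(round(f_val * idx.size))
        tr.append(idx[:n_tr])
        va.append(idx[n_tr : n_tr + n_va])
        te.append(idx[n_tr + n_va :])
    return (np.concatenate(tr), np.concatenate(va), np.concatenate(te))


def _dataset_loss(model, views_list, b, beta, rng=None):
    """-ELBO on a full array set; posterior mean if rng is None."""
    _, mu, logvar = model.encode(views_list, b)
    if rng is None:
        z = mu
    else:
        eps = rng.standard_normal(mu.shape)
        z = mu + Tensor(eps) * (logvar * 0.5).exp()
    recs = model.decode(z, b)
    total, lls, kl = elbo_terms(
        views_list, recs, mu, logvar, model.cfg.view_weights, beta
    )
    return -float(total.data), {k: float(v.data) for k, v in lls.items()}, float(kl.data)


def train(
    views: CellViews,
    cfg: ModelConfig,
    split=(0.70, 0.15, 0.15),
    verbose: bool = False,
):
    """Fit the VAE by minibatch Adam on -ELBO with early stopping.

    Returns (model, log) where log is a list of per-epoch dicts. Early
    stopping monitors the validation loss at full KL weight (beta = 1) so
    that the warm-up ramp does not masquerade as improvement.
    """
    rng = np.random.default_rng(cfg.seed)
    raw = [views.Y, views.S, views.M, views.C]
    model = HmiVAEModel([a.shape[1] for a in raw], views.b.shape[1], cfg)
    model.covariate_names = list(views.covariate_names)
    model.protein_names = list(views.protein_names)
    model.fit_scaler(raw)
    scaled = model.scale(raw)
    b = views.b
    tr_idx, va_idx, te_idx = _split_indices(views.n_cells, views.sample_ids, split, rng)
    model._test_idx = te_idx  # kept for grid_search scoring
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_val = np.inf
    best_state = model.get_state()
    best_epoch = -1
    log = []
    n_train = tr_idx.size
    bs = min(cfg.batch_size, n_train)
    for epoch in range(cfg.max_epochs):
        beta = beta_at(epoch, cfg.beta_scheme, cfg.beta_increment)
        order = rng.permutation(tr_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_train, bs):
            sel = order[start : start + bs]
            batch = [Tensor(a[sel]) for a in scaled]
            bt = Tensor(b[sel])
            _, mu, logvar = model.encode(batch, bt)
            eps = rng.standard_normal(mu.shape)
            z = mu + Tensor(eps) * (logvar * 0.5).exp()
            recs = model.decode(z, bt)
            total, _, _ = elbo_terms(batch, recs, mu, logvar, cfg.view_weights, beta)
            loss = -total
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training loss diverged (NaN/inf) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_loss, _, _ = _dataset_loss(
            model, [a[va_idx] for a in scaled], b[va_idx], beta=1.0
        )
        log.append(
            {
                "epoch": epoch,
                "beta": beta,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
            }
        )
        if verbose:
            logger.info("epoch %d beta %.2f train %.4f val %.4f", epoch, beta, *[
                log[-1]["train_loss"], val_loss])
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_state = model.get_state()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.set_state(best_state)
    return model, log


def heldout_likelihood(model, views: CellViews, idx=None) -> float:
    """Per-cell mean reconstruction log-likelihood (all views, posterior mean)."""
    raw = [views.Y, views.S, views.M, views.C]
    scaled = model.scale(raw)
    if idx is None:
        idx = getattr(model, "_test_idx", np.arange(views.n_cells))
    _, lls, _ = _dataset_loss(
        model, [a[idx] for a in scaled], views.b[idx], beta=0.0
    )
    return float(sum(lls.values()))


def _n_params(model) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def grid_search(views: CellViews, grid, split=(0.70, 0.15, 0.15)):
    """Exhaustively train every config; pick the best held-out likelihood.

    Ties are broken by smaller parameter count, then lower seed. Returns
    (best config, results table as list of dicts).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    results = []
    for cfg in grid:
        model, log = train(views, cfg, split=split)
        ll = heldout_likelihood(model, views)
        results.append(
            {
                "config": cfg,
                "test_likelihood": ll,
                "n_params": _n_params(model),
                "epochs": len(log),
            }
        )
    results_sorted = sorted(
        results, key=lambda r: (-r["test_likelihood"], r["n_params"], r["config"].seed)
    )
    return results_sorted[0]["config"], results


def embed_all(model, views: CellViews) -> LatentSpaces:
    """Deterministic embeddings for every cell (posterior mean, no sampling)."""
    raw = [views.Y, views.S, views.M, views.C]
    scaled = model.scale(raw)
    embeds, mu, logvar = model.encode([Tensor(a) for a in scaled], Tensor(views.b))
    recs = model.decode(mu, Tensor(views.b))
    _, lls, kl = elbo_terms(
        scaled, recs, mu, logvar, model.cfg.view_weights, beta=1.0
    )
    return LatentSpaces(
        z=mu.data.copy(),
        view_embeddings={n: e.data.copy() for n, e in zip(VIEW_NAMES, embeds)},
        reconstruction_ll={k: float(v.data) for k, v in lls.items()},
        kl=float(kl.data),
    )


def reconstruction_error(model, views: CellViews) -> dict:
    """Per-view mean squared reconstruction error on standardized features."""
    raw = [views.Y, views.S, views.M, views.C]
    scaled = model.scale(raw)
    _, mu, _ = model.encode([Tensor(a) for a in scaled], Tensor(views.b))
    recs = model.decode(mu, Tensor(views.b))
    return {
        name: float(np.mean((x - r.data) ** 2))
        for name, x, r in zip(VIEW_NAMES, scaled, recs)
    }


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model, path) -> None:
    import pickle

    payload = {
        "view_dims": model.view_dims,
        "n_covariates": model.n_covariates,
        "cfg": model.cfg,
        "state": model.get_state(),
        "scaler_mean": model.scaler_mean,
        "scaler_std": model.scaler_std,
        "covariate_names": getattr(model, "covariate_names", None),
        "protein_names": getattr(model, "protein_names", None),
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> HmiVAEModel:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    model = HmiVAEModel(payload["view_dims"], payload["n_covariates"], payload["cfg"])
    model.set_state(payload["state"])
    model.scaler_mean = payload["scaler_mean"]
    model.scaler_std = payload["scaler_std"]
    model.covariate_names = payload.get("covariate_names")
    model.protein_names = payload.get("protein_names")
    return model
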