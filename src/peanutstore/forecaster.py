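"""Multivariate storage-quality forecasting.

The main model combines three ideas on top of a Transformer encoder:

* **Dimension-segment-wise (DSW) embedding** - each variable's 16-day window
  is cut into contiguous segments of ``L_seg`` days; every segment becomes
  one token via a shared linear projection plus a distinct
  (segment, variable) position embedding, giving the encoder a
  (time-segment x variable) token grid that exposes cross-variable
  structure.
* **Statistical feature space** - per-day, per-variable median and standard
  deviation matrices computed across the training span's condition records;
  each window carries its days' median/std rows as two auxiliary channels
  that stabilise the raw signal against observation noise.
* **Median-centred reversible instance normalization (RevIN)** - each channel
  is normalised per window and per variable around its median with learnable
  affine parameters; the cached statistics make the output exactly
  denormalisable, which counters distribution shift along the storage
  timeline.

The three channels are compressed back to one plane by a learned 1x1
convolution before embedding.  A single-layer LSTM regressor is provided as
the classical baseline, and :func:`ablation_suite` trains the four structural
variants (backbone, +DSW, +statistics, full) under one budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .preprocess import FEATURES, ScalerParams
from .reference import INDICATORS


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSWConfig:
    """Architecture hyperparameters."""

    L_seg: int = 4
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol."""

    epochs: int = 150
    patience: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 2021


# ---------------------------------------------------------------------------
# statistical feature space
# ---------------------------------------------------------------------------

@dataclass
class StatFeatureSpace:
    """Per-day, per-variable median and std across condition records."""

    median: np.ndarray  # (n_days, D), raw units
    std: np.ndarray     # (n_days, D), raw units, >= 0
    days: np.ndarray    # (n_days,) 1-based day index

    def rows_for(self, end_days: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
        """Median/std channel blocks for windows ending at ``end_days``.

        Day indices outside the fitted span are clamped to its edges so the
        training-span statistics are reused frozen at inference.
        """
        lo, hi = int(self.days[0]), int(self.days[-1])
        idx = np.clip(np.asarray(end_days)[:, None]
                      - np.arange(L - 1, -1, -1)[None, :], lo, hi) - lo
        return self.median[idx], self.std[idx]


def build_stat_space(train_table: pd.DataFrame,
                     features: list[str] | None = None) -> StatFeatureSpace:
    """Median/std of each day's records (the condition replicates).

    A day observed under a single condition gets std 0 for that day.
    """
    features = features or [f for f in FEATURES if f in train_table.columns]
    grouped = train_table.groupby("day", sort=True)[features]
    median = grouped.median().to_numpy(dtype=float)
    std = grouped.std(ddof=0).fillna(0.0).to_numpy(dtype=float)
    days = np.asarray(sorted(train_table["day"].unique()), dtype=int)
    return StatFeatureSpace(median=median, std=std, days=days)


# ---------------------------------------------------------------------------
# reversible instance normalization (median-centred)
# ---------------------------------------------------------------------------

class RevIN(nn.Module):
    """Per-instance, per-variable median/variance normalization.

    normalize:    x_hat = lam * (x - median(x)) / sqrt(Var(x) + eps) + beta
    denormalize:  x = (x_hat - beta) / (lam + eps) * sqrt(Var(x) + eps) + median(x)

    The denominator ``lam + eps`` mirrors the published inverse form; with
    the default ``eps = 1e-8`` the round trip is exact to well below 1e-6.
    Instance statistics are taken over the window's time axis and treated as
    constants in the backward pass; only ``lam`` and ``beta`` are trained.
    """

    def __init__(self, n_vars: int, eps: float = 1e-8):
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.lam = Tensor(np.ones(n_vars), requires_grad=True)
        self.beta = Tensor(np.zeros(n_vars), requires_grad=True)
        self.eps = eps
        self._median: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    def normalize(self, x: Tensor | np.ndarray) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.data.shape[-2] == 0:
            raise ValueError("cannot normalize an empty series")
        med = np.median(x.data, axis=-2, keepdims=True)
        var = x.data.var(axis=-2, keepdims=True)
        self._median = med
        self._scale = np.sqrt(var + self.eps)
        xhat = (x - Tensor(med)) / Tensor(self._scale)
        return xhat * self.lam + self.beta

    def denormalize(self, xhat: Tensor | np.ndarray,
                    dims: slice | None = None) -> Tensor:
        if self._median is None:
            raise RuntimeError("denormalize requires cached statistics from "
                               "a prior normalize call")
        xhat = Tensor.as_tensor(xhat)
        dims = dims if dims is not None else slice(None)
        med = Tensor(self._median[..., dims])
        scale = Tensor(self._scale[..., dims])
        lam = self.lam[dims]
        beta = self.beta[dims]
        return (xhat - beta) / (lam + self.eps) * scale + med

    forward = normalize


# ---------------------------------------------------------------------------
# channel fusion and DSW embedding
# ---------------------------------------------------------------------------

class ChannelFusion(nn.Module):
    """1x1 convolution collapsing C channels of (L, D) planes into one."""

    def __init__(self, n_channels: int = 3):
        self.n_channels = n_channels
        self.weight = Tensor(np.full(n_channels, 1.0 / n_channels),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(1), requires_grad=True)

    def forward(self, channels: list[Tensor]) -> Tensor:
        if len(channels) != self.n_channels:
            raise ValueError(
                f"expected {self.n_channels} channels, got {len(channels)}")
        out = channels[0] * self.weight[0]
        for c in range(1, self.n_channels):
            out = out + channels[c] * self.weight[c]
        return out + self.bias


class DSWEmbedding(nn.Module):
    """Dimension-segment-wise token embedding.

    Cuts every variable's L-step window into ``L/L_seg`` contiguous
    segments (segment ``i`` covers steps ``(i-1)*L_seg < t <= i*L_seg``),
    projects each segment with a shared linear map and adds a distinct
    (segment, variable) position embedding.
    """

    def __init__(self, L: int, D: int, cfg: DSWConfig, rng: np.random.Generator):
        if L % cfg.L_seg:
            raise ValueError(f"window length {L} not divisible by "
                             f"L_seg={cfg.L_seg}")
        self.L, self.D, self.cfg = L, D, cfg
        self.n_seg = L // cfg.L_seg
        self.proj = nn.Linear(cfg.L_seg, cfg.d_model, rng, bias=False)
        self.pos = Tensor(rng.normal(0.0, 0.02,
                                     (self.n_seg, D, cfg.d_model)),
                          requires_grad=True)

    def grid(self, x: Tensor | np.ndarray) -> Tensor:
        """Embedded segment grid of shape (..., n_seg, D, d_model)."""
        x = Tensor.as_tensor(x)
        batched = x.ndim == 3
        shape = ((-1,) if batched else ()) + (self.n_seg, self.cfg.L_seg, self.D)
        segs = x.reshape(*shape)
        axes = (0, 1, 3, 2) if batched else (0, 2, 1)
        segs = segs.transpose(*axes)  # (..., n_seg, D, L_seg)
        return self.proj(segs) + self.pos

    def forward(self, x: Tensor) -> Tensor:
        """Token sequence (B, n_seg*D, d_model) for the encoder."""
        g = self.grid(x)
        return g.reshape(-1, self.n_seg * self.D, self.cfg.d_model)


def dsw_embed(X: np.ndarray, cfg: DSWConfig,
              seed: int = 0) -> np.ndarray:
    """Embed one (L, D) window into its (L/L_seg, D, d_model) segment grid."""
    X = np.asarray(X, dtype=float)
    L, D = X.shape
    emb = DSWEmbedding(L, D, cfg, np.random.default_rng(seed))
    return emb.grid(X).numpy()


def segment_membership(L: int, L_seg: int) -> np.ndarray:
    """Segment index of each raw time step (the partition is exact)."""
    if L % L_seg:
        raise ValueError("L not divisible by L_seg")
    return np.repeat(np.arange(L // L_seg), L_seg)


def fuse_channels(stack: np.ndarray,
                  weights: np.ndarray | None = None,
                  bias: float = 0.0) -> np.ndarray:
    """Functional channel compression of a (C, L, D) stack to (L, D)."""
    stack = np.asarray(stack, dtype=float)
    fusion = ChannelFusion(stack.shape[0])
    if weights is not None:
        fusion.weight.data = np.asarray(weights, dtype=float)
    fusion.bias.data = np.asarray([bias], dtype=float)
    return fusion([Tensor(c) for c in stack]).numpy()


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class DSCSformer(nn.Module):
    """Transformer forecaster with optional DSW embedding and stat fusion.

    ``use_dsw=False`` embeds each time step as one token instead of the
    segment grid; ``use_stat=False`` drops the median/std channels.  The
    four on/off combinations are the ablation variants.
    """

    def __init__(self, L: int = 16, D_in: int = 8, D_out: int = 6,
                 horizon: int = 8, cfg: DSWConfig = DSWConfig(),
                 use_dsw: bool = True, use_stat: bool = True,
                 seed: int = 2021):
        rng = np.random.default_rng(seed)
        self.L, self.D_in, self.D_out = L, D_in, D_out
        self.horizon, self.cfg = horizon, cfg
        self.use_dsw, self.use_stat = use_dsw, use_stat
        self.revin_raw = RevIN(D_in)
        if use_stat:
            self.revin_med = RevIN(D_in)
            self.revin_std = RevIN(D_in)
            self.fusion = ChannelFusion(3)
        if use_dsw:
            self.embed = DSWEmbedding(L, D_in, cfg, rng)
            n_tokens = self.embed.n_seg * D_in
        else:
            self.step_embed = nn.Linear(D_in, cfg.d_model, rng)
            self.step_pos = Tensor(rng.normal(0.0, 0.02, (L, cfg.d_model)),
                                   requires_grad=True)
            n_tokens = L
        self.encoder = nn.TransformerEncoder(
            cfg.n_layers, cfg.d_model, cfg.n_heads, cfg.d_ff, cfg.dropout, rng)
        self.head = nn.Linear(n_tokens * cfg.d_model, horizon * D_out, rng)

    def set_training(self, flag: bool) -> None:
        self.encoder.set_training(flag)

    def forward(self, x: np.ndarray, med: np.ndarray | None = None,
                std: np.ndarray | None = None) -> Tensor:
        """Standardized-scale forecast (B, horizon, D_out)."""
        if x.shape[-2] != self.L or x.shape[-1] != self.D_in:
            raise ValueError(f"expected window shape (*, {self.L}, "
                             f"{self.D_in}), got {x.shape}")
        raw = self.revin_raw.normalize(x)
        if self.use_stat:
            if med is None or std is None:
                raise ValueError("statistical channels required when "
                                 "use_stat=True")
            plane = self.fusion([raw,
                                 self.revin_med.normalize(med),
                                 self.revin_std.normalize(std)])
        else:
            plane = raw
        if self.use_dsw:
            tokens = self.embed(plane)
        else:
            tokens = self.step_embed(plane) + self.step_pos
        enc = self.encoder(tokens)
        b = enc.shape[0]
        out = self.head(enc.reshape(b, -1)).reshape(b, self.horizon, self.D_out)
        return self.revin_raw.denormalize(out, dims=slice(0, self.D_out))


class LSTMForecaster(nn.Module):
    """Plain recurrent baseline: LSTM encoder, linear multi-step head."""

    def __init__(self, L: int = 16, D_in: int = 8, D_out: int = 6,
                 horizon: int = 8, hidden: int = 64, seed: int = 2021):
        rng = np.random.default_rng(seed)
        self.L, self.D_in, self.D_out, self.horizon = L, D_in, D_out, horizon
        self.lstm = nn.LSTM(D_in, hidden, rng)
        self.head = nn.Linear(hidden, horizon * D_out, rng)

    def set_training(self, flag: bool) -> None:  # no dropout
        pass

    def forward(self, x: np.ndarray, med=None, std=None) -> Tensor:
        h = self.lstm(Tensor.as_tensor(x))
        return self.head(h).reshape(-1, self.horizon, self.D_out)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _evaluate_loss(model, X, y, med, std, batch_size: int = 256) -> float:
    model.set_training(False)
    total, n = 0.0, 0
    for i in range(0, len(X), batch_size):
        sl = slice(i, i + batch_size)
        pred = model.forward(X[sl],
                             None if med is None else med[sl],
                             None if std is None else std[sl])
        total += float(((pred.numpy() - y[sl]) ** 2).sum())
        n += y[sl].size
    return total / n


def train_forecaster(model, train_set: dict, val_set: dict | None,
                     stat_space: StatFeatureSpace | None = None,
                     train_cfg: TrainConfig = TrainConfig()) -> dict:
    """Minimise MSE on standardized targets with early stopping.

    Early stopping watches validation MSE with the configured patience and
    restores the best-validation parameters.  Fully reproducible given
    ``train_cfg.seed``.
    """
    rng = np.random.default_rng(train_cfg.seed)
    use_stat = getattr(model, "use_stat", False)

    def channels(dataset):
        if not use_stat:
            return None, None
        if stat_space is None:
            raise ValueError("stat_space required for a model with "
                             "statistical channels")
        return stat_space.rows_for(dataset["t"], model.L)

    Xtr, ytr = train_set["X"], train_set["y"]
    if len(Xtr) == 0:
        raise ValueError("empty training window set")
    med_tr, std_tr = channels(train_set)
    if val_set is not None and len(val_set["X"]):
        Xva, yva = val_set["X"], val_set["y"]
        med_va, std_va = channels(val_set)
    else:
        warnings.warn("empty validation set: early stopping disabled")
        Xva = None

    opt = nn.Adam(model.parameters(), lr=train_cfg.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, since_best = np.inf, None, 0
    stopped_epoch = train_cfg.epochs
    for epoch in range(1, train_cfg.epochs + 1):
        model.set_training(True)
        order = rng.permutation(len(Xtr))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            pred = model.forward(Xtr[idx],
                                 None if med_tr is None else med_tr[idx],
                                 None if std_tr is None else std_tr[idx])
            loss = nn.mse_loss(pred, ytr[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch {i // train_cfg.batch_size}); check learning "
                    "rate and input scaling")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
            seen += len(idx)
        history["train_loss"].append(epoch_loss / seen)
        if Xva is not None:
            val_loss = _evaluate_loss(model, Xva, yva, med_va, std_va)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val, since_best = val_loss, 0
                best_state = model.state_dict()
            else:
                since_best += 1
                if since_best >= train_cfg.patience:
                    stopped_epoch = epoch
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_val"] = best_val if Xva is not None else None
    history["stopped_epoch"] = stopped_epoch
    return history


def forecast(model, window: np.ndarray, scaler: ScalerParams,
             med: np.ndarray | None = None,
             std: np.ndarray | None = None) -> np.ndarray:
    """Forecast the next ``model.horizon`` days in original indicator units."""
    window = np.asarray(window, dtype=float)
    if window.shape != (model.L, model.D_in):
        raise ValueError(f"window shape {window.shape} does not match the "
                         f"trained configuration ({model.L}, {model.D_in})")
    model.set_training(False)
    pred = model.forward(window[None],
                         None if med is None else med[None],
                         None if std is None else std[None]).numpy()[0]
    mean = scaler.mean[:model.D_out]
    sd = scaler.std[:model.D_out]
    return pred * sd + mean


def predict_standardized(model, dataset: dict,
                         stat_space: StatFeatureSpace | None = None,
                         batch_size: int = 256) -> np.ndarray:
    """Standardized-scale predictions for a whole window set."""
    model.set_training(False)
    med = std = None
    if getattr(model, "use_stat", False):
        med, std = stat_space.rows_for(dataset["t"], model.L)
    outs = []
    for i in range(0, len(dataset["X"]), batch_size):
        sl = slice(i, i + batch_size)
        outs.append(model.forward(dataset["X"][sl],
                                  None if med is None else med[sl],
                                  None if std is None else std[sl]).numpy())
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = {
    "backbone_only": dict(use_dsw=False, use_stat=False),
    "+DSW": dict(use_dsw=True, use_stat=False),       # Model 1
    "+stat_fusion": dict(use_dsw=False, use_stat=True),  # Model 2
    "full": dict(use_dsw=True, use_stat=True),
}


def ablation_suite(datasets: dict, stat_space: StatFeatureSpace,
                   horizon: int, cfg: DSWConfig = DSWConfig(),
                   train_cfg: TrainConfig = TrainConfig(),
                   variants: dict | None = None,
                   L: int = 16, D_in: int = 8, D_out: int = 6) -> pd.DataFrame:
    """Train every structural variant under one shared data/seed/budget.

    Returns a table with per-variant test MSE/MAE (standardized scale) plus
    the MSE/MAE gap of the full model against each variant, following the
    convention ``variant - full`` (positive = full model is better).
    """
    variants = variants or ABLATION_VARIANTS
    rows = []
    for name, flags in variants.items():
        model = DSCSformer(L=L, D_in=D_in, D_out=D_out, horizon=horizon,
                           cfg=cfg, seed=train_cfg.seed, **flags)
        train_forecaster(model, datasets["train"], datasets["val"],
                         stat_space, train_cfg)
        pred = predict_standardized(model, datasets["test"], stat_space)
        err = pred - datasets["test"]["y"]
        rows.append({"variant": name,
                     "MSE": float((err ** 2).mean()),
                     "MAE": float(np.abs(err).mean())})
    table = pd.DataFrame(rows).set_index("variant")
    if "full" in table.index:
        table["MSE_gap_vs_full"] = table["MSE"] - table.loc["full", "MSE"]
        table["MAE_gap_vs_full"] = table["MAE"] - table.loc["full", "MAE"]
    return table


def clone_train_config(cfg: TrainConfig, **kwargs) -> TrainConfig:
    return replace(cfg, **kwargs)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Save parameters plus reconstruction metadata (bit-exact round trip)."""
    import json

    if isinstance(model, DSCSformer):
        meta = {"kind": "dscsformer", "L": model.L, "D_in": model.D_in,
                "D_out": model.D_out, "horizon": model.horizon,
                "use_dsw": model.use_dsw, "use_stat": model.use_stat,
                "cfg": vars(model.cfg) if not hasattr(model.cfg, "__dict__")
                else {f: getattr(model.cfg, f) for f in
                      ("L_seg", "d_model", "n_heads", "n_layers", "d_ff",
                       "dropout")}}
    elif isinstance(model, LSTMForecaster):
        meta = {"kind": "lstm", "L": model.L, "D_in": model.D_in,
                "D_out": model.D_out, "horizon": model.horizon,
                "hidden": model.lstm.d_hidden}
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    state = {f"p{i}": p for i, p in enumerate(model.state_dict())}
    np.savez(path, meta=json.dumps(meta), **state)


def load_model(path):
    """Restore a checkpointed forecaster."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    if meta["kind"] == "dscsformer":
        model = DSCSformer(L=meta["L"], D_in=meta["D_in"], D_out=meta["D_out"],
                           horizon=meta["horizon"], cfg=DSWConfig(**meta["cfg"]),
                           use_dsw=meta["use_dsw"], use_stat=meta["use_stat"])
    else:
        model = LSTMForecaster(L=meta["L"], D_in=meta["D_in"],
                               D_out=meta["D_out"], horizon=meta["horizon"],
                               hidden=meta["hidden"])
    model.load_state_dict(state)
    return model
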