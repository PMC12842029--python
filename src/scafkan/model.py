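"""The dual-path SCAF risk model and its statsmodels-style wrapper.

Architecture: two pathways read the same preprocessed feature vector —

* a ResKAN pathway (stacked residual Kolmogorov–Arnold blocks), built to
  capture smooth nonlinear per-feature effects, and
* an MLP pathway (residual dense blocks) for conventional feature mixing.

Each pathway's final hidden vector becomes one (or several pseudo-) token
per patient; the pathways are fused by cross-attention (bidirectionally by
default: each pathway attends to the other), the fused representations are
pooled, concatenated, and mapped by a dense head to a single logit, so the
model outputs a SCAF probability in (0, 1) per patient.

Usage follows the Model / Results convention::

    model = ResKANAttentionModel(X, y, config=FusionConfig(d=32))
    res = model.fit(TrainConfig(max_epochs=100, seed=0))
    p = res.predict(X_new)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .attention import MultiheadCrossAttention
from .kan import ResKANBlock, SplineGrid
from .nn import AdamW, Dropout, Linear, MLPBlock, Module, Sequential, Tensor, no_grad
from .metrics import roc_auc

__all__ = ["FusionConfig", "TrainConfig", "FusionModel", "train_network",
           "ResKANAttentionModel", "ResKANAttentionResults"]


@dataclass(frozen=True)
class FusionConfig:
    """Hyperparameters of the dual-path fusion architecture."""

    n_features: int = 27
    d: int = 64                      # token dimension
    n_heads: int = 4
    kan_depth: int = 2
    mlp_depth: int = 2
    mlp_hidden: int = 64
    dropout: float = 0.1
    fusion: str = "bidirectional"    # kan-queries-mlp | mlp-queries-kan | bidirectional
    n_tokens: int = 1                # pseudo-tokens per pathway
    grid: SplineGrid = field(default_factory=SplineGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d % self.n_heads != 0:
            raise ValueError("token dimension must be divisible by head count")
        if self.kan_depth < 1 or self.mlp_depth < 1:
            raise ValueError("pathway depths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.fusion not in ("kan-queries-mlp", "mlp-queries-kan", "bidirectional"):
            raise ValueError(f"unknown fusion direction {self.fusion!r}")
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = asdict(self.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        d = dict(d)
        d["grid"] = SplineGrid(**d["grid"])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: AdamW with early stopping on validation AUC."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("sizes must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class FusionModel(Module):
    """The trainable network (see module docstring for the wiring)."""

    def __init__(self, cfg: FusionConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d

        kan_blocks = [ResKANBlock(cfg.n_features, d, cfg.grid, rng)]
        kan_blocks += [ResKANBlock(d, d, cfg.grid, rng) for _ in range(cfg.kan_depth - 1)]
        self.kan_path = Sequential(*kan_blocks)

        self.mlp_in = Linear(cfg.n_features, d, rng)
        self.mlp_path = Sequential(*[MLPBlock(d, cfg.mlp_hidden, rng, cfg.dropout)
                                     for _ in range(cfg.mlp_depth)])

        if cfg.n_tokens > 1:  # expand each pathway vector into pseudo-tokens
            self.kan_tokens = Linear(d, cfg.n_tokens * d, rng)
            self.mlp_tokens = Linear(d, cfg.n_tokens * d, rng)
        else:
            self.kan_tokens = self.mlp_tokens = None

        self.attn_k2m = MultiheadCrossAttention(d, cfg.n_heads, rng)
        self.attn_m2k = MultiheadCrossAttention(d, cfg.n_heads, rng)
        self.drop = Dropout(cfg.dropout, rng)
        head_in = 2 * d if cfg.fusion == "bidirectional" else d
        self.head = Linear(head_in, 1, rng)
        # pathway gates: setting one to 0 ablates that pathway
        self.kan_gate = 1.0
        self.mlp_gate = 1.0

    def _tokens(self, vec: Tensor, expander: Optional[Linear]) -> Tensor:
        n, d = vec.shape
        if expander is None:
            return vec.reshape(n, 1, d)
        return expander(vec).reshape(n, self.cfg.n_tokens, d)

    def forward_logits(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.cfg.n_features:
            raise ValueError(f"expected {self.cfg.n_features} features, "
                             f"got {x.shape[-1]}")
        h_kan = self.kan_path(x) * self.kan_gate
        h_mlp = self.mlp_path(self.mlp_in(x)) * self.mlp_gate
        tok_k = self._tokens(h_kan, self.kan_tokens)
        tok_m = self._tokens(h_mlp, self.mlp_tokens)
        parts = []
        if self.cfg.fusion in ("kan-queries-mlp", "bidirectional"):
            parts.append(self.attn_k2m(tok_k, tok_m).mean(axis=1))
        if self.cfg.fusion in ("mlp-queries-kan", "bidirectional"):
            parts.append(self.attn_m2k(tok_m, tok_k).mean(axis=1))
        fused = parts[0] if len(parts) == 1 else Tensor.concat(parts, axis=-1)
        return self.head(self.drop(fused)).reshape(-1)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode risk for each row of X."""
        was_training = self.training
        self.eval()
        with no_grad():
            p = self.forward(Tensor(np.asarray(X, float))).data
        if was_training:
            self.train()
        return p


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    p = logits.sigmoid()
    eps = 1e-12
    yv = Tensor(np.asarray(y, float))
    loss = -(yv * (p + eps).log() + (1.0 - yv) * (1.0 - p + eps).log())
    return loss.mean()


class ResKANAttentionModel:
    """Model-object entry point: data in, :class:`ResKANAttentionResults` out.

    ``X`` must already be preprocessed (no missing values, continuous
    features standardised); ``y`` is the binary SCAF label.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 config: FusionConfig | None = None,
                 feature_names: Optional[list[str]] = None):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, int)
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; preprocess first")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y length mismatch")
        self.config = config or FusionConfig(n_features=self.X.shape[1])
        if self.config.n_features != self.X.shape[1]:
            raise ValueError("config.n_features does not match X")
        self.feature_names = feature_names

    @classmethod
    def from_dataframe(cls, df, label: str = "scaf",
                       config: FusionConfig | None = None) -> "ResKANAttentionModel":
        y = df[label].to_numpy()
        X = df.drop(columns=[label])
        cfg = config or FusionConfig(n_features=X.shape[1])
        return cls(X.to_numpy(float), y, cfg, feature_names=list(X.columns))

    def fit(self, train_config: TrainConfig = TrainConfig(),
            X_val: Optional[np.ndarray] = None,
            y_val: Optional[np.ndarray] = None,
            val_fraction: float = 0.2) -> "ResKANAttentionResults":
        """Train with AdamW and early stopping on validation AUC.

        If no validation split is given, a stratified ``val_fraction`` of the
        training rows is held out internally to drive the stopping rule.
        """
        X, y = self.X, self.y
        if X_val is None:
            rng = np.random.default_rng(train_config.seed)
            idx_val = []
            for c in (0, 1):
                rows = np.flatnonzero(y == c)
                rng.shuffle(rows)
                idx_val.extend(rows[:max(1, int(round(val_fraction * len(rows))))])
            mask = np.zeros(len(y), bool)
            mask[idx_val] = True
            X, X_val = X[~mask], X[mask]
            y, y_val = y[~mask], y[mask]

        net = FusionModel(self.config)
        history = train_network(net, X, y, X_val, y_val, train_config)
        return ResKANAttentionResults(self, net, history)


def train_network(net: Module, X: np.ndarray, y: np.ndarray,
                  X_val: np.ndarray, y_val: np.ndarray,
                  cfg: TrainConfig) -> dict:
    """Mini-batch AdamW with patience-based early stopping on validation AUC."""
    opt = AdamW(net.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    best_auc, best_state, best_epoch = -np.inf, net.state_dict(), 0
    since_improve = 0
    history = {"train_loss": [], "val_auc": []}
    n = len(y)
    for epoch in range(1, cfg.max_epochs + 1):
        net.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = net.forward_logits(Tensor(X[sel]))
            loss = _bce_with_logits(logits, y[sel])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sel)
        history["train_loss"].append(epoch_loss / n)
        val_auc = roc_auc(y_val, net.predict_proba(X_val))
        history["val_auc"].append(val_auc)
        if val_auc > best_auc:
            best_auc, best_state, best_epoch = val_auc, net.state_dict(), epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    net.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_auc"] = best_auc
    return history


class ResKANAttentionResults:
    """Fitted model: predictions, training diagnostics, serialisation."""

    def __init__(self, model: ResKANAttentionModel, net: FusionModel,
                 history: dict):
        self.model = model
        self.net = net
        self.history = history

    def predict(self, X: np.ndarray) -> np.ndarray:
        """SCAF probability per patient (evaluation mode, deterministic)."""
        return self.net.predict_proba(X)

    def predict_class(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict(X) > threshold).astype(int)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.net.parameters()))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "ResKAN-Attention fit summary",
            "=" * 44,
            f"patients (train input)     {len(self.model.y):>10d}",
            f"features                   {cfg.n_features:>10d}",
            f"token dim / heads          {cfg.d:>6d} / {cfg.n_heads}",
            f"pathway depths (KAN/MLP)   {cfg.kan_depth:>6d} / {cfg.mlp_depth}",
            f"fusion                     {cfg.fusion:>10s}",
            f"trainable parameters       {self.n_parameters:>10d}",
            f"epochs run                 {len(self.history['train_loss']):>10d}",
            f"best epoch                 {self.history['best_epoch']:>10d}",
            f"best validation AUC        {self.history['best_val_auc']:>10.4f}",
        ]
        return "\n".join(lines)

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "config": self.model.config.to_dict(),
            "history": {k: v for k, v in self.history.items()},
            "params": [p.data.tolist() for p in self.net.parameters()],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ResKANAttentionResults":
        payload = json.loads(Path(path).read_text())
        cfg = FusionConfig.from_dict(payload["config"])
        net = FusionModel(cfg)
        net.load_state_dict([np.array(p, float) for p in payload["params"]])
        net.eval()
        dummy = ResKANAttentionModel(np.zeros((2, cfg.n_features)),
                                     np.array([0, 1]), cfg)
        return cls(dummy, net, payload["history"])
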