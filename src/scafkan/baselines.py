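"""Reference classifier roster for model comparison.

Classical learners come straight from scikit-learn (plus the gradient
boosters where installed); the deep references (residual MLP,
feature-tokenizing transformer, plain KAN) are small networks built from
the package's own blocks and trained with the same AdamW / early-stopping
loop as the main model.  Every entry is a ``ModelFn`` so the harness runs
all of them through the identical leakage-safe fold pipeline.
"""

from __future__ import annotations

import numpy as np

from .kan import KANLayer, SplineGrid
from .model import TrainConfig, train_network
from .nn import LayerNorm, Linear, MLPBlock, Module, Sequential, Tensor, no_grad

__all__ = ["default_roster", "reskan_fn", "logistic_fn"]


class _LogitNet(Module):
    """Mixin-style base: logit network with probability prediction."""

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        with no_grad():
            p = self.forward(Tensor(np.asarray(X, float))).data
        if was_training:
            self.train()
        return p


class ResNetClassifier(_LogitNet):
    """Residual dense network over tabular features."""

    def __init__(self, n_features: int, d: int = 64, depth: int = 2,
                 dropout: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = Linear(n_features, d, rng)
        self.blocks = Sequential(*[MLPBlock(d, d, rng, dropout)
                                   for _ in range(depth)])
        self.norm = LayerNorm(d)
        self.head = Linear(d, 1, rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        return self.head(self.norm(self.blocks(self.stem(x)))).reshape(-1)


class KANClassifier(_LogitNet):
    """Plain two-layer KAN (no residual fusion)."""

    def __init__(self, n_features: int, hidden: int = 16,
                 grid: SplineGrid = SplineGrid(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.l1 = KANLayer(n_features, hidden, grid, rng)
        self.norm = LayerNorm(hidden)
        self.l2 = KANLayer(hidden, 1, grid, rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        return self.l2(self.norm(self.l1(x))).reshape(-1)


class FTTransformerClassifier(_LogitNet):
    """Feature-tokenizing transformer: one learned token per scalar feature,
    self-attention blocks, mean-pooled head."""

    def __init__(self, n_features: int, d: int = 32, n_heads: int = 4,
                 depth: int = 2, dropout: float = 0.1, seed: int = 0):
        from .attention import MultiheadCrossAttention
        from .nn import Parameter
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.tok_w = Parameter(rng.normal(0, 1 / np.sqrt(d), (n_features, d)))
        self.tok_b = Parameter(np.zeros((n_features, d)))
        self.attn = [MultiheadCrossAttention(d, n_heads, rng)
                     for _ in range(depth)]
        self.ffn = [MLPBlock(d, 2 * d, rng, dropout) for _ in range(depth)]
        self.norm = LayerNorm(d)
        self.head = Linear(d, 1, rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        n, p = x.shape
        tokens = x.reshape(n, p, 1) * self.tok_w + self.tok_b   # (n, p, d)
        for attn, ffn in zip(self.attn, self.ffn):
            tokens = ffn(attn(tokens, tokens))
        pooled = self.norm(tokens.mean(axis=1))
        return self.head(pooled).reshape(-1)


def _net_fn(builder, train_cfg: TrainConfig | None = None):
    cfg = train_cfg or TrainConfig(max_epochs=150, patience=15)
    def fn(X_tr, y_tr, X_va, y_va, seed):
        net = builder(X_tr.shape[1], seed)
        train_network(net, X_tr, y_tr, X_va, y_va,
                      TrainConfig(learning_rate=cfg.learning_rate,
                                  weight_decay=cfg.weight_decay,
                                  batch_size=cfg.batch_size,
                                  max_epochs=cfg.max_epochs,
                                  patience=cfg.patience, seed=seed))
        return net.predict_proba(X_va)
    return fn


def _sklearn_fn(factory):
    def fn(X_tr, y_tr, X_va, y_va, seed):
        est = factory(seed)
        est.fit(X_tr, y_tr)
        return est.predict_proba(X_va)[:, 1]
    return fn


def logistic_fn(C: float = 1.0):
    from sklearn.linear_model import LogisticRegression
    return _sklearn_fn(lambda seed: LogisticRegression(
        C=C, max_iter=2000, random_state=seed))


def reskan_fn(fusion_config=None, train_config: TrainConfig | None = None):
    """ModelFn for the dual-path fusion model itself."""
    from .model import FusionConfig, ResKANAttentionModel

    def fn(X_tr, y_tr, X_va, y_va, seed):
        cfg = fusion_config or FusionConfig(n_features=X_tr.shape[1], seed=seed)
        if cfg.n_features != X_tr.shape[1]:
            raise ValueError("fusion config feature count mismatch")
        tc = train_config or TrainConfig(seed=seed)
        res = ResKANAttentionModel(X_tr, y_tr, cfg).fit(tc, X_val=X_va, y_val=y_va)
        return res.predict(X_va)
    return fn


def default_roster(train_cfg: TrainConfig | None = None):
    """Name -> ModelFn map; entries whose dependency is missing map to None."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    roster = {
        "logistic_regression": logistic_fn(),
        "random_forest": _sklearn_fn(lambda s: RandomForestClassifier(
            n_estimators=200, random_state=s)),
        "knn": _sklearn_fn(lambda s: KNeighborsClassifier(n_neighbors=7)),
        "gaussian_nb": _sklearn_fn(lambda s: GaussianNB()),
        "svm": _sklearn_fn(lambda s: SVC(probability=True, random_state=s)),
        "mlp": _sklearn_fn(lambda s: MLPClassifier(
            hidden_layer_sizes=(64, 64), max_iter=800, random_state=s)),
        "resnet": _net_fn(lambda p, s: ResNetClassifier(p, seed=s), train_cfg),
        "ft_transformer": _net_fn(lambda p, s: FTTransformerClassifier(p, seed=s),
                                  train_cfg),
        "kan": _net_fn(lambda p, s: KANClassifier(p, seed=s), train_cfg),
    }
    try:
        from xgboost import XGBClassifier
        roster["xgboost"] = _sklearn_fn(lambda s: XGBClassifier(
            n_estimators=200, max_depth=3, random_state=s,
            eval_metric="logloss"))
    except ImportError:            # pragma: no cover
        roster["xgboost"] = None
    try:
        from lightgbm import LGBMClassifier
        roster["lightgbm"] = _sklearn_fn(lambda s: LGBMClassifier(
            n_estimators=200, random_state=s, verbose=-1))
    except ImportError:            # pragma: no cover
        roster["lightgbm"] = None
    try:                           # pragma: no cover - not in this image
        from catboost import CatBoostClassifier
        roster["catboost"] = _sklearn_fn(lambda s: CatBoostClassifier(
            iterations=200, random_seed=s, verbose=False))
    except ImportError:
        roster["catboost"] = None
    return roster
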