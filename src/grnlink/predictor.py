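"""Transformer-based regulatory link prediction over fused gene features.

Per-gene prior-knowledge embeddings (F columns) and temporal features from
the trajectory autoencoder (F' columns) are concatenated (h0), weighted by a
learned per-gene attention score (a linear layer followed by a softmax over
the gene axis), projected to a hidden dimension H (h1), passed through a
Transformer encoder block (multi-head self-attention over the unordered gene
set, residual + LayerNorm, position-wise feed-forward, residual + LayerNorm
-> h5), and decoded per candidate edge: the regulator and target rows of h5
are concatenated in that order (direction matters) and mapped by a linear
layer to a logit; a sigmoid yields the link probability.  Training minimises
binary cross-entropy over labeled edges, with sampled negatives balancing
the positives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor
from ._nn import Dropout, FeedForward, LayerNorm, Linear, Module, MultiheadSelfAttention
from .errors import ConfigError, StructuralError, TrainingError, UsageError
from .io import AlignedDataset, EdgeSet, EmbeddingTable
from .tcn import LatentTemporalFeatures, TCNAutoencoderResults

__all__ = [
    "PredictorConfig",
    "FusedGeneFeatures",
    "EncodedGeneFeatures",
    "EdgeScoreTable",
    "fuse",
    "encode_genes",
    "score_edges",
    "bce_loss",
    "sample_negatives",
    "LinkPredictionModel",
    "LinkPredictionResults",
    "train_predictor",
    "predict",
]


@dataclass
class PredictorConfig:
    hidden_dim: int = 128
    n_heads: int = 4
    ff_dim: int = 256
    dropout_p: float = 0.1
    n_blocks: int = 1
    epochs: int = 100
    learning_rate: float = 1e-3
    negative_ratio: float = 1.0
    batch_size: int | None = None  # None = full batch
    clip_eps: float = 1e-7
    finetune_tcn: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ConfigError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.negative_ratio <= 0:
            raise ConfigError("negative_ratio must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError("dropout_p must be in [0, 1)")


@dataclass
class FusedGeneFeatures:
    """Concatenated and attention-weighted gene features.

    ``alpha`` are the per-gene attention weights (non-negative, summing to 1
    over the gene axis); ``h0_att = alpha * h0``; ``h1`` is the projection of
    ``h0_att`` to the hidden dimension.
    """

    gene_names: list[str]
    h0: np.ndarray
    alpha: np.ndarray
    h0_att: np.ndarray
    h1: np.ndarray


@dataclass
class EncodedGeneFeatures:
    gene_names: list[str]
    h5: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.h5)):
            raise UsageError("encoded gene features contain non-finite values")


@dataclass
class EdgeScoreTable:
    """Predicted link probability per candidate (regulator, target) pair."""

    regulators: list[str]
    targets: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not (len(self.regulators) == len(self.targets) == len(self.scores)):
            raise UsageError("score table columns have unequal lengths")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise UsageError("scores must lie in [0, 1]")

    def __len__(self):
        return len(self.scores)

    def to_dataframe(self, sort: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {"regulator": self.regulators, "target": self.targets, "score": self.scores}
        )
        if sort:
            df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
        return df

    def write_tsv(self, path, sort: bool = True):
        self.to_dataframe(sort=sort).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class _Fusion(Module):
    """h0 -> per-gene attention weights -> weighted features -> hidden h1."""

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.attn = Linear(in_dim, 1, rng)
        self.embed = Linear(in_dim, hidden_dim, rng)

    def __call__(self, h0: Tensor):
        a = self.attn(h0)                    # (C, 1)
        alpha = a.softmax(axis=0)            # softmax over the gene axis
        h0_att = alpha * h0                  # per-gene scalar broadcast over columns
        h1 = self.embed(h0_att)
        return alpha, h0_att, h1


class _EncoderBlock(Module):
    """Post-norm Transformer block: self-attention and feed-forward sublayers."""

    def __init__(self, cfg: PredictorConfig, rng: np.random.Generator):
        super().__init__()
        self.mha = MultiheadSelfAttention(cfg.hidden_dim, cfg.n_heads, rng)
        self.drop1 = Dropout(cfg.dropout_p, rng)
        self.ln1 = LayerNorm(cfg.hidden_dim)
        self.ff = FeedForward(cfg.hidden_dim, cfg.ff_dim, rng)
        self.drop2 = Dropout(cfg.dropout_p, rng)
        self.ln2 = LayerNorm(cfg.hidden_dim)

    def __call__(self, h1: Tensor) -> Tensor:
        h2 = self.mha(h1)
        h3 = self.ln1(h1 + self.drop1(h2))
        h4 = self.ff(h3)
        return self.ln2(h3 + self.drop2(h4))


class _LinkDecoder(Module):
    """Linear layer on [h_regulator, h_target] concatenation -> logit."""

    def __init__(self, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(2 * hidden_dim, 1, rng)

    def __call__(self, h5: Tensor, reg_idx, tgt_idx) -> Tensor:
        pair = Tensor.concat([h5.gather_rows(reg_idx), h5.gather_rows(tgt_idx)], axis=1)
        return self.fc(pair).reshape(-1)  # logits


class _PredictorNet(Module):
    def __init__(self, in_dim: int, cfg: PredictorConfig, rng: np.random.Generator):
        super().__init__()
        self.fusion = _Fusion(in_dim, cfg.hidden_dim, rng)
        self.blocks = [_EncoderBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.decoder = _LinkDecoder(cfg.hidden_dim, rng)

    def encode(self, h0: Tensor) -> Tensor:
        _, _, h1 = self.fusion(h0)
        for b in self.blocks:
            h1 = b(h1)
        return h1

    def logits(self, h0: Tensor, reg_idx, tgt_idx) -> Tensor:
        return self.decoder(self.encode(h0), reg_idx, tgt_idx)


# ---------------------------------------------------------------------------
# operation-level API
# ---------------------------------------------------------------------------

def fuse(embeddings: EmbeddingTable, temporal: LatentTemporalFeatures,
         fusion: _Fusion | None = None, hidden_dim: int = 128,
         seed: int = 0) -> FusedGeneFeatures:
    """Concatenate embedding and temporal features and apply attention fusion.

    A fresh seeded fusion layer is built unless one is supplied (e.g. a
    trained layer, or one with hand-set weights for verification).
    """
    if embeddings.gene_names != temporal.gene_names:
        raise UsageError("embedding and temporal feature gene orders differ")
    h0 = np.concatenate([embeddings.vectors, temporal.features], axis=1)
    if fusion is None:
        fusion = _Fusion(h0.shape[1], hidden_dim, np.random.default_rng(seed))
    fusion.eval()
    alpha, h0_att, h1 = fusion(Tensor(h0))
    return FusedGeneFeatures(list(embeddings.gene_names), h0, alpha.data,
                             h0_att.data, h1.data)


def encode_genes(h1: np.ndarray, cfg: PredictorConfig, mode: str = "eval",
                 block: _EncoderBlock | None = None, gene_names=None,
                 seed: int = 0) -> EncodedGeneFeatures:
    """Run the Transformer encoder block(s) on hidden gene features h1."""
    h1 = np.asarray(h1, dtype=np.float64)
    if h1.shape[1] != cfg.hidden_dim:
        raise UsageError(f"h1 has {h1.shape[1]} columns, config expects {cfg.hidden_dim}")
    if block is None:
        block = _EncoderBlock(cfg, np.random.default_rng(seed))
    block.eval() if mode == "eval" else block.train()
    h5 = block(Tensor(h1)).data
    names = list(gene_names) if gene_names is not None else [str(i) for i in range(len(h1))]
    return EncodedGeneFeatures(names, h5)


def score_edges(h5: EncodedGeneFeatures | np.ndarray, pairs,
                gene_names=None, decoder: _LinkDecoder | None = None,
                seed: int = 0) -> EdgeScoreTable:
    """Score candidate directed pairs from encoded gene features."""
    if isinstance(h5, EncodedGeneFeatures):
        gene_names = h5.gene_names
        h5 = h5.h5
    h5 = np.asarray(h5, dtype=np.float64)
    if gene_names is None:
        raise UsageError("gene_names required when h5 is a bare matrix")
    index = {g: i for i, g in enumerate(gene_names)}
    unknown = sorted({g for p in pairs for g in p if g not in index})
    if unknown:
        raise UsageError(f"unknown genes in candidate pairs: {unknown}")
    if decoder is None:
        decoder = _LinkDecoder(h5.shape[1], np.random.default_rng(seed))
    reg_idx = np.array([index[r] for r, _ in pairs], dtype=np.intp)
    tgt_idx = np.array([index[t] for _, t in pairs], dtype=np.intp)
    logits = decoder(Tensor(h5), reg_idx, tgt_idx)
    scores = logits.sigmoid().data
    return EdgeScoreTable([r for r, _ in pairs], [t for _, t in pairs], scores)


def bce_loss(scores, labels, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; scores are clipped to (eps, 1-eps)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise UsageError("scores and labels must have equal length")
    if scores.size == 0:
        raise UsageError("bce_loss of empty input is undefined")
    p = np.clip(scores, eps, 1 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def sample_negatives(positives: EdgeSet, universe, ratio: float = 1.0,
                     seed: int = 0, constrain_sources: bool = True,
                     extra_exclude=()) -> EdgeSet:
    """Draw label-0 pairs uniformly without replacement.

    Candidates are ``{(r, t): r in sources, t in universe, r != t}`` minus the
    pairs already present in ``positives`` (and any ``extra_exclude`` pairs);
    ``sources`` is the positives' regulator universe unless
    ``constrain_sources=False`` (then any gene can be a source).  Exactly
    ``ceil(ratio * n_positives)`` pairs are returned.
    """
    universe = sorted(set(universe))
    sources = sorted(positives.regulator_universe) if constrain_sources else universe
    taken = set(positives.pairs) | set(extra_exclude)
    candidates = [
        (r, t) for r in sources for t in universe if r != t and (r, t) not in taken
    ]
    n_pos = sum(1 for _, _, lab in positives.edges if lab == 1)
    n_draw = math.ceil(ratio * n_pos)
    if n_draw > len(candidates):
        raise StructuralError(
            f"cannot sample {n_draw} negatives: only {len(candidates)} candidate "
            f"pairs available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_draw, replace=False)
    return EdgeSet(
        [(candidates[i][0], candidates[i][1], 0) for i in idx],
        regulator_universe=positives.regulator_universe,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class LinkPredictionModel:
    """Link prediction model over an aligned gene universe.

    Built from the embedding table and the temporal features (same genes in
    the same order); ``fit(train_edges)`` optimises the fusion, encoder and
    decoder parameters end to end against BCE on the labeled edges and
    returns a :class:`LinkPredictionResults`.

    With ``config.finetune_tcn=True`` and a fitted autoencoder passed as
    ``tcn_results``, the temporal branch is differentiated through and the
    autoencoder's encoder weights are updated jointly; by default the
    autoencoder is frozen and its pooled features are constants.
    """

    def __init__(self, embeddings: EmbeddingTable, temporal: LatentTemporalFeatures,
                 config: PredictorConfig | None = None,
                 tcn_results: TCNAutoencoderResults | None = None):
        if embeddings.gene_names != temporal.gene_names:
            raise UsageError("embedding and temporal gene orders differ")
        self.embeddings = embeddings
        self.temporal = temporal
        self.config = config or PredictorConfig()
        self.tcn_results = tcn_results
        if self.config.finetune_tcn and tcn_results is None:
            raise UsageError("finetune_tcn=True requires tcn_results")

    @classmethod
    def from_dataset(cls, dataset: AlignedDataset, temporal: LatentTemporalFeatures,
                     config: PredictorConfig | None = None, **kw):
        return cls(dataset.embeddings, temporal, config, **kw)

    def fit(self, train_edges: EdgeSet) -> "LinkPredictionResults":
        cfg = self.config
        labels = train_edges.labels
        if len(train_edges) == 0 or len(set(labels.tolist())) < 2:
            raise UsageError(
                "training edges must contain both positive and negative labels "
                "(run sample_negatives first)"
            )
        gene_names = self.embeddings.gene_names
        index = {g: i for i, g in enumerate(gene_names)}
        unknown = sorted(train_edges.genes() - set(gene_names))
        if unknown:
            raise UsageError(f"training edges reference unknown genes: {unknown}")
        reg_idx = np.array([index[r] for r, _, _ in train_edges.edges], dtype=np.intp)
        tgt_idx = np.array([index[t] for _, t, _ in train_edges.edges], dtype=np.intp)
        y = labels.astype(np.float64)

        rng = np.random.default_rng(cfg.seed)
        in_dim = self.embeddings.dim + self.temporal.dim
        net = _PredictorNet(in_dim, cfg, rng)
        params = net.parameters()
        emb_t = Tensor(self.embeddings.vectors)
        if cfg.finetune_tcn:
            tcn_enc = self.tcn_results.encoder
            tcn_enc.train()
            params = params + tcn_enc.parameters()
            X = self.tcn_results.trajectory.ordered_values()[:, None, :]
        else:
            temporal_const = Tensor(self.temporal.features)
        opt = Adam(params, lr=cfg.learning_rate)
        curve: list[float] = []
        n = len(y)
        eps = cfg.clip_eps
        net.train()
        for epoch in range(cfg.epochs):
            if cfg.batch_size is None or cfg.batch_size >= n:
                batches = [np.arange(n)]
            else:
                order = rng.permutation(n)
                batches = [order[i:i + cfg.batch_size]
                           for i in range(0, n, cfg.batch_size)]
            epoch_loss = 0.0
            for batch in batches:
                opt.zero_grad()
                if cfg.finetune_tcn:
                    z = tcn_enc(Tensor(X))             # (C, C', L)
                    temporal_feats = z.mean(axis=2)
                else:
                    temporal_feats = temporal_const
                h0 = Tensor.concat([emb_t, temporal_feats], axis=1)
                logits = net.logits(h0, reg_idx[batch], tgt_idx[batch])
                p = logits.sigmoid().clip(eps, 1 - eps)
                yb = Tensor(y[batch])
                loss = -(yb * p.log() + (1.0 - yb) * (1.0 - p).log()).mean()
                value = float(loss.data)
                if not np.isfinite(value):
                    raise TrainingError(f"non-finite BCE loss at epoch {epoch}")
                loss.backward()
                opt.step()
                epoch_loss += value * len(batch)
            curve.append(epoch_loss / n)
        net.eval()
        temporal_final = self.temporal
        if cfg.finetune_tcn:
            self.tcn_results.encoder.eval()
            temporal_final = self.tcn_results.encode()
        return LinkPredictionResults(
            net=net, config=cfg, gene_names=list(gene_names),
            embeddings=self.embeddings, temporal=temporal_final,
            loss_curve=np.array(curve), train_edges=train_edges,
        )


class LinkPredictionResults:
    """Trained link predictor: weights, configuration, loss curve, and the
    inference surface (per-pair probabilities)."""

    def __init__(self, net: _PredictorNet, config: PredictorConfig,
                 gene_names: list[str], embeddings: EmbeddingTable,
                 temporal: LatentTemporalFeatures, loss_curve: np.ndarray,
                 train_edges: EdgeSet | None = None):
        self.net = net
        self.config = config
        self.gene_names = gene_names
        self.embeddings = embeddings
        self.temporal = temporal
        self.loss_curve = loss_curve
        self.train_edges = train_edges
        self._index = {g: i for i, g in enumerate(gene_names)}

    # -- inference -------------------------------------------------------------
    def _h0(self, zero_temporal: bool = False) -> np.ndarray:
        feats = np.zeros_like(self.temporal.features) if zero_temporal \
            else self.temporal.features
        return np.concatenate([self.embeddings.vectors, feats], axis=1)

    def fused(self) -> FusedGeneFeatures:
        self.net.eval()
        h0 = self._h0()
        alpha, h0_att, h1 = self.net.fusion(Tensor(h0))
        return FusedGeneFeatures(self.gene_names, h0, alpha.data, h0_att.data, h1.data)

    def encoded(self, zero_temporal: bool = False) -> EncodedGeneFeatures:
        self.net.eval()
        h5 = self.net.encode(Tensor(self._h0(zero_temporal)))
        return EncodedGeneFeatures(self.gene_names, h5.data)

    def predict(self, pairs, zero_temporal: bool = False) -> EdgeScoreTable:
        """Score candidate (regulator, target) pairs, in input order.

        Works for regulators never seen as training-edge sources: every gene
        with an embedding and a temporal profile is encoded, so unseen-TF
        queries are first-class.
        """
        pairs = list(pairs)
        unknown = sorted({g for p in pairs for g in p if g not in self._index})
        if unknown:
            raise UsageError(f"unknown genes in candidate pairs: {unknown}")
        self.net.eval()
        reg_idx = np.array([self._index[r] for r, _ in pairs], dtype=np.intp)
        tgt_idx = np.array([self._index[t] for _, t in pairs], dtype=np.intp)
        logits = self.net.logits(Tensor(self._h0(zero_temporal)), reg_idx, tgt_idx)
        return EdgeScoreTable([r for r, _ in pairs], [t for _, t in pairs],
                              logits.sigmoid().data)

    def predict_all_pairs(self, regulators=None) -> EdgeScoreTable:
        """Score every directed (regulator, target) pair, self-pairs excluded."""
        if regulators is None:
            if self.train_edges is None:
                raise UsageError("no regulator set available; pass regulators=")
            regulators = sorted(self.train_edges.regulator_universe)
        pairs = [(r, t) for r in regulators for t in self.gene_names if r != t]
        return self.predict(pairs)

    def training_loss(self, edges: EdgeSet | None = None,
                      zero_temporal: bool = False) -> float:
        edges = edges if edges is not None else self.train_edges
        table = self.predict(edges.pairs, zero_temporal=zero_temporal)
        return bce_loss(table.scores, edges.labels, eps=self.config.clip_eps)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Link prediction results",
            "=" * 40,
            f"genes:             {len(self.gene_names)}",
            f"input feature dim: {self.embeddings.dim} (prior) + {self.temporal.dim} (temporal)",
            f"hidden dim H:      {cfg.hidden_dim} ({cfg.n_heads} heads, "
            f"{cfg.n_blocks} encoder block(s))",
            f"epochs trained:    {len(self.loss_curve)}",
        ]
        if len(self.loss_curve):
            lines.append(f"initial BCE loss:  {self.loss_curve[0]:.6g}")
            lines.append(f"final BCE loss:    {self.loss_curve[-1]:.6g}")
        if self.train_edges is not None:
            labs = self.train_edges.labels
            lines.append(f"training edges:    {len(labs)} "
                         f"({int(labs.sum())} positive / {int((1 - labs).sum())} negative)")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------
    def save(self, path):
        meta = {
            "config": asdict(self.config),
            "gene_names": self.gene_names,
            "regulators": sorted(self.train_edges.regulator_universe)
            if self.train_edges else [],
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            __loss_curve__=self.loss_curve,
            __emb__=self.embeddings.vectors,
            __temporal__=self.temporal.features,
            **self.net.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "LinkPredictionResults":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = PredictorConfig(**meta["config"])
        genes = meta["gene_names"]
        emb = EmbeddingTable(genes, data["__emb__"])
        temporal = LatentTemporalFeatures(genes, data["__temporal__"])
        net = _PredictorNet(emb.dim + temporal.dim, cfg, np.random.default_rng(cfg.seed))
        net.load_state_dict(
            {k: data[k] for k in data.files if not k.startswith("__")})
        net.eval()
        train_edges = None
        if meta["regulators"]:
            train_edges = EdgeSet([], regulator_universe=set(meta["regulators"]))
        return cls(net, cfg, genes, emb, temporal, data["__loss_curve__"], train_edges)


# -- functional wrappers -------------------------------------------------------

def train_predictor(dataset: AlignedDataset, temporal: LatentTemporalFeatures,
                    train_edges: EdgeSet,
                    cfg: PredictorConfig | None = None, **kw) -> LinkPredictionResults:
    return LinkPredictionModel(dataset.embeddings, temporal, cfg, **kw).fit(train_edges)


def predict(results: LinkPredictionResults, candidate_pairs) -> EdgeScoreTable:
    return results.predict(candidate_pairs)
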