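"""Validation protocols: inverted k-fold, unseen-regulator holdout, and
cross-dataset transfer filtering.

The inverted k-fold is deliberately strict: each fold *trains* on a single
1/k shard of the labeled edges and tests on the remaining (k-1)/k, probing
performance under scarce supervision.  The TF-holdout scheme partitions the
regulator universe so that no regulator contributes edges to both train and
test, probing generalization to unseen regulators.  Cross-dataset transfer
removes any (regulator, target) pair shared with the training corpus from
the test edges before scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import StructuralError
from .io import AlignedDataset, EdgeSet
from .metrics import MetricReport, metric_report
from .predictor import (
    EdgeScoreTable,
    LinkPredictionModel,
    PredictorConfig,
    sample_negatives,
)
from .tcn import LatentTemporalFeatures, TCNAutoencoder, TCNConfig

__all__ = [
    "SplitPlan",
    "make_split",
    "cross_dataset_filter",
    "permute_labels",
    "run_protocol",
    "ProtocolResults",
]


@dataclass
class SplitPlan:
    """Per-fold (train edge ids, test edge ids) into an EdgeSet's edge list."""

    folds: list[tuple[list[int], list[int]]]
    scheme: str
    seed: int

    def __post_init__(self):
        for train, test in self.folds:
            if set(train) & set(test):
                raise StructuralError("a fold has overlapping train and test edges")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"scheme": self.scheme, "seed": self.seed,
             "folds": [[list(map(int, tr)), list(map(int, te))] for tr, te in self.folds]}
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "SplitPlan":
        if not (isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{")):
            with open(source) as fh:
                source = fh.read()
        d = json.loads(source)
        return cls(folds=[(tr, te) for tr, te in d["folds"]],
                   scheme=d["scheme"], seed=d["seed"])


def make_split(edges: EdgeSet, scheme: str = "edge_kfold_inverted",
               k: int = 10, seed: int = 0) -> SplitPlan:
    """Build a deterministic split plan over an edge set.

    ``edge_kfold_inverted``: shuffle edges into k shards; fold i trains on
    shard i (1/k of the edges) and tests on the rest.  ``tf_holdout``:
    shuffle regulators into k groups and assign edges by regulator; fold i
    trains on group i's edges, so no regulator spans train and test.
    """
    rng = np.random.default_rng(seed)
    n = len(edges)
    labels = edges.labels
    has_both = len(set(labels.tolist())) == 2

    if scheme == "edge_kfold_inverted":
        if n < k:
            raise StructuralError(f"cannot split {n} edges into {k} folds")
        order = rng.permutation(n)
        shards = np.array_split(order, k)
        folds = []
        for i, shard in enumerate(shards):
            train = sorted(int(j) for j in shard)
            test = sorted(int(j) for j in order if j not in set(shard.tolist()))
            folds.append((train, test))
    elif scheme == "tf_holdout":
        regs = sorted({r for r, _, _ in edges.edges})
        if len(regs) < k:
            raise StructuralError(
                f"cannot hold out regulators: {len(regs)} regulators < {k} folds")
        reg_order = [regs[i] for i in rng.permutation(len(regs))]
        groups = [set(g) for g in np.array_split(np.array(reg_order, dtype=object), k)]
        folds = []
        for grp in groups:
            train = [i for i, (r, _, _) in enumerate(edges.edges) if r in grp]
            test = [i for i, (r, _, _) in enumerate(edges.edges) if r not in grp]
            if not train or not test:
                raise StructuralError(
                    "a TF-holdout fold has an empty train or test side; "
                    "use fewer folds or more edges")
            folds.append((train, test))
    else:
        raise StructuralError(f"unknown split scheme {scheme!r}")

    if has_both:
        for i, (train, _) in enumerate(folds):
            if len({int(labels[j]) for j in train}) < 2:
                raise StructuralError(
                    f"fold {i} training shard is single-class; re-seed the split "
                    f"or change the fold count")
    return SplitPlan(folds=folds, scheme=scheme, seed=seed)


def cross_dataset_filter(train_edges: EdgeSet, test_edges: EdgeSet) -> EdgeSet:
    """Drop from the test edges every (regulator, target) pair that occurs in
    the training edge set, regardless of label, to prevent memorised pairs
    from inflating transfer performance."""
    train_pairs = set(train_edges.pairs)
    kept = [e for e in test_edges.edges if (e[0], e[1]) not in train_pairs]
    if not kept:
        raise StructuralError("cross-dataset filter removed every test edge")
    return EdgeSet(kept, regulator_universe=test_edges.regulator_universe)


def permute_labels(edges: EdgeSet, seed: int = 0) -> EdgeSet:
    """Shuffle labels across edges (negative-control arm)."""
    rng = np.random.default_rng(seed)
    labels = edges.labels
    permuted = labels[rng.permutation(len(labels))]
    regs_with_pos = {r for (r, _, _), lab in zip(edges.edges, permuted) if lab == 1}
    return EdgeSet(
        [(r, t, int(lab)) for (r, t, _), lab in zip(edges.edges, permuted)],
        regulator_universe=edges.regulator_universe | regs_with_pos,
    )


def _fold_seed(base: int, fold: int, arm: int) -> int:
    return int(np.random.SeedSequence([base, fold, arm]).generate_state(1)[0] % (2**31))


class ProtocolResults:
    """Per-fold metric table, aggregate mean/sd, and audit score tables."""

    def __init__(self, per_fold: list[MetricReport], scheme: str,
                 score_tables: list[tuple[EdgeScoreTable, np.ndarray]]):
        self.scheme = scheme
        self.reports = per_fold
        self.per_fold = pd.DataFrame([r.to_dict() for r in per_fold])
        self.per_fold.insert(0, "fold", range(len(per_fold)))
        self.score_tables = score_tables

    @property
    def aggregate(self) -> pd.DataFrame:
        metrics = self.per_fold.drop(columns=["fold"])
        return pd.DataFrame({"mean": metrics.mean(), "sd": metrics.std(ddof=1)})

    def summary(self) -> str:
        agg = self.aggregate
        lines = [f"Protocol: {self.scheme} ({len(self.reports)} fold(s))", "=" * 40]
        for name in ("auroc", "auprc", "acc", "mcc"):
            lines.append(f"{name:>6}: {agg.loc[name, 'mean']:.4f} "
                         f"(sd {agg.loc[name, 'sd']:.4f})")
        return "\n".join(lines)


def run_protocol(dataset: AlignedDataset, plan: SplitPlan,
                 tcn_cfg: TCNConfig | None = None,
                 predictor_cfg: PredictorConfig | None = None,
                 temporal: LatentTemporalFeatures | None = None,
                 test_negative_ratio: float | None = None,
                 threshold: float = 0.5,
                 permute_train_labels: bool = False) -> ProtocolResults:
    """Train and evaluate the link predictor on every fold of ``plan``.

    The autoencoder is fitted once on the full trajectory (it is unsupervised,
    so sharing it across folds leaks no label information); pass ``temporal``
    to reuse a precomputed encoding.  Per fold: negatives are freshly sampled
    (seeded from the plan seed and fold index) for the training shard, the
    predictor is trained, and the held-out positives plus independently
    sampled test negatives are scored.  Known positive pairs anywhere in the
    dataset are never sampled as negatives; test negatives also avoid the
    fold's training pairs so train and test stay disjoint.

    ``permute_train_labels=True`` runs the label-permuted negative-control
    arm: training labels are shuffled after negative sampling, leaving the
    pipeline otherwise identical.
    """
    predictor_cfg = predictor_cfg or PredictorConfig()
    if temporal is None:
        temporal = TCNAutoencoder(dataset.trajectory, tcn_cfg or TCNConfig()).fit().encode()
    genes = dataset.gene_names
    all_positive_pairs = [(r, t) for r, t, lab in dataset.edges.edges if lab == 1]
    ratio = predictor_cfg.negative_ratio
    test_ratio = test_negative_ratio if test_negative_ratio is not None else ratio

    reports: list[MetricReport] = []
    tables: list[tuple[EdgeScoreTable, np.ndarray]] = []
    for fold_id, (train_ids, test_ids) in enumerate(plan.folds):
        # the training world knows only its own regulators: rebuild the fold
        # edge sets with observed-regulator universes so negative sampling
        # never names a held-out TF as a source (essential under TF holdout)
        train_pos = EdgeSet(
            [dataset.edges.edges[i] for i in train_ids]).positives()
        train_neg = sample_negatives(
            train_pos, genes, ratio=ratio,
            seed=_fold_seed(plan.seed, fold_id, 1),
            extra_exclude=all_positive_pairs,
        )
        train_edges = EdgeSet(train_pos.edges + train_neg.edges,
                              regulator_universe=train_pos.regulator_universe)
        if permute_train_labels:
            train_edges = permute_labels(train_edges,
                                         seed=_fold_seed(plan.seed, fold_id, 3))
        cfg = replace(predictor_cfg, seed=_fold_seed(plan.seed, fold_id, 4))
        results = LinkPredictionModel(dataset.embeddings, temporal, cfg).fit(train_edges)

        test_pos = EdgeSet(
            [dataset.edges.edges[i] for i in test_ids]).positives()
        test_neg = sample_negatives(
            test_pos, genes, ratio=test_ratio,
            seed=_fold_seed(plan.seed, fold_id, 2),
            extra_exclude=all_positive_pairs + train_edges.pairs,
        )
        test_edges = EdgeSet(test_pos.edges + test_neg.edges,
                             regulator_universe=test_pos.regulator_universe)
        table = results.predict(test_edges.pairs)
        labels = test_edges.labels
        reports.append(metric_report(table.scores, labels, threshold))
        tables.append((table, labels))
    return ProtocolResults(reports, plan.scheme, tables)
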