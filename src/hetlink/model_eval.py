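"""RBF-SVM classification of pair features and the full evaluation suite.

The classifier is a support-vector machine with a radial-basis-function
kernel, fed standardized 256-dimensional pair vectors (standardization
statistics come from the training partition only). Evaluation reports the
confusion counts and the six derived metrics

    PRE = TP/(TP+FP)            REC = TP/(TP+FN)
    SPE = TN/(FP+TN)            ACC = (TP+TN)/(TP+TN+FP+FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1  = 2*PRE*REC/(PRE+REC)

plus the ROC curve over continuous decision scores and its trapezoidal AUC
(equal to the normalized Mann-Whitney U statistic). Metrics with a zero
denominator are reported as undefined rather than silently zeroed; MCC with
a zero denominator is 0 by convention, flagged.

``cross_repeat_evaluate`` runs the whole method once per train/test repeat —
similarity graphs from training interactions, network assembly, metapath
walks, skip-gram embeddings, pair features, classifier — and reports
per-repeat and mean metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline as SkPipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig
from .heteronet import HeteroNetwork, InteractionDataset, Pair, RepeatSplit, assemble_network
from .io_formats import AlignmentHit, ValidationError, write_embeddings
from .negatives import NegativeSpec, sample_negatives
from .similarity import (
    NODE_LNC,
    NODE_PROT,
    AssociationSets,
    build_alignment_graph,
    build_jaccard_graph,
)
from .walks_embedding import (
    MetaPathScheme,
    PairFeatureSet,
    WalkCorpus,
    generate_walks,
    pair_features,
    splice_node_features,
    train_embeddings,
)

METRIC_NAMES = ("PRE", "REC", "SPE", "ACC", "MCC", "F1")


def _derive_seed(base: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31 from a base seed and a stage key."""
    ss = np.random.SeedSequence(base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RepeatMetrics:
    """Confusion counts and derived metrics for one evaluated repeat."""

    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, float | None]
    undefined: tuple[str, ...] = ()
    roc_points: list[tuple[float, float]] | None = None
    auc: float | None = None
    embed_dim: int | None = None
    node_dim: int | None = None
    pair_dim: int | None = None

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        out = {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            **{k: (None if v is None else float(v)) for k, v in self.metrics.items()},
            "undefined": list(self.undefined),
        }
        if self.auc is not None:
            out["AUC"] = float(self.auc)
        return out

    def to_tsv_row(self) -> str:
        vals = [self.metrics.get(m) for m in METRIC_NAMES] + [self.auc]
        return "\t".join(
            [str(self.tp), str(self.fp), str(self.tn), str(self.fn)]
            + ["NA" if v is None else f"{v:.6g}" for v in vals]
        )


@dataclass
class EvaluationReport:
    """Per-repeat metrics and their mean across repeats."""

    per_repeat: list[RepeatMetrics]
    mean: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean and self.per_repeat:
            self.mean = self._compute_mean()

    def _compute_mean(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name in METRIC_NAMES:
            vals = [r.metrics[name] for r in self.per_repeat if r.metrics.get(name) is not None]
            out[name] = float(np.mean(vals)) if vals else None
        aucs = [r.auc for r in self.per_repeat if r.auc is not None]
        out["AUC"] = float(np.mean(aucs)) if aucs else None
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "repeats": [r.to_dict() for r in self.per_repeat],
            "mean": {k: (None if v is None else float(v)) for k, v in self.mean.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path) -> None:
        header = "repeat\tTP\tFP\tTN\tFN\t" + "\t".join(METRIC_NAMES) + "\tAUC\n"
        with Path(path).open("w") as fh:
            fh.write(header)
            for i, rep in enumerate(self.per_repeat):
                fh.write(f"{i}\t{rep.to_tsv_row()}\n")


def train_classifier(
    train: PairFeatureSet,
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> SkPipeline:
    """Fit a standardized RBF-kernel SVM on a labelled pair-feature set."""
    if train.labels is None:
        raise ValidationError("training set has no labels")
    classes = set(np.unique(train.labels).tolist())
    if classes != {0, 1}:
        raise ValidationError(f"training set must contain both classes, got labels {sorted(classes)}")
    clf = SkPipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)),
    ])
    clf.fit(train.features, train.labels)
    return clf


def grid_search_classifier(
    train: PairFeatureSet,
    C_grid: Sequence[float] = (0.1, 1.0, 10.0),
    gamma_grid: Sequence[float | str] = ("scale", 0.01, 0.1),
    cv: int = 3,
    seed: int = 0,
) -> SkPipeline:
    """Optional hyperparameter search; off by default in the pipeline."""
    if train.labels is None:
        raise ValidationError("training set has no labels")
    base = SkPipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", random_state=seed)),
    ])
    search = GridSearchCV(base, {"svm__C": list(C_grid), "svm__gamma": list(gamma_grid)}, cv=cv)
    search.fit(train.features, train.labels)
    return search.best_estimator_


def decision_scores(clf: SkPipeline, features: np.ndarray) -> np.ndarray:
    """Continuous decision values (signed margin) for ROC ranking."""
    return np.asarray(clf.decision_function(features), dtype=float)


def compute_metrics(labels: Sequence[int], predictions: Sequence[int]) -> RepeatMetrics:
    """Confusion counts and the six derived metrics for hard predictions."""
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValidationError(f"label/prediction shape mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValidationError("empty label vector")
    for vec, name in ((y, "labels"), (yhat, "predictions")):
        if not np.isin(vec, (0, 1)).all():
            raise ValidationError(f"{name} must be binary 0/1")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fn = int(np.sum((y == 1) & (yhat == 0)))

    undefined: list[str] = []
    metrics: dict[str, float | None] = {}

    def ratio(name: str, num: float, den: float) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    metrics["PRE"] = ratio("PRE", tp, tp + fp)
    metrics["REC"] = ratio("REC", tp, tp + fn)
    metrics["SPE"] = ratio("SPE", tn, fp + tn)
    metrics["ACC"] = ratio("ACC", tp + tn, tp + tn + fp + fn)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        metrics["MCC"] = 0.0  # convention for a degenerate confusion matrix
        undefined.append("MCC")
    else:
        metrics["MCC"] = (tp * tn - fp * fn) / mcc_den
    pre, rec = metrics["PRE"], metrics["REC"]
    if pre is None or rec is None or (pre + rec) == 0:
        metrics["F1"] = None
        undefined.append("F1")
    else:
        metrics["F1"] = 2 * pre * rec / (pre + rec)
    return RepeatMetrics(tp=tp, fp=fp, tn=tn, fn=fn, metrics=metrics, undefined=tuple(undefined))


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[list[tuple[float, float]], float]:
    """ROC curve over all score thresholds (ties grouped) and trapezoidal AUC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1 or y.size == 0:
        raise ValidationError("labels and scores must be equal-length non-empty vectors")
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# --- end-to-end pipeline ---------------------------------------------------


@dataclass
class PipelineResources:
    """External inputs shared by all repeats of one run."""

    lncRNAs: tuple[str, ...]
    proteins: tuple[str, ...]
    lnc_hits: list[AlignmentHit] = field(default_factory=list)
    prot_hits: list[AlignmentHit] = field(default_factory=list)
    localization: Mapping[str, set[str]] | None = None


def _build_networks(
    train_pos: Sequence[Pair],
    assoc_source: Sequence[Pair],
    config: PipelineConfig,
    resources: PipelineResources,
) -> list[HeteroNetwork]:
    sim = config.similarity
    extra = dict(extra_lnc=resources.lncRNAs, extra_prot=resources.proteins)
    nets: list[HeteroNetwork] = []
    if config.variant == "KNet":
        nets.append(assemble_network(train_pos, **extra))
    if config.variant in ("KJNet", "full"):
        assoc = AssociationSets.from_interactions(assoc_source)
        lnc_j = build_jaccard_graph(assoc, NODE_LNC, sim.lnc_jaccard_threshold)
        prot_j = build_jaccard_graph(assoc, NODE_PROT, sim.prot_jaccard_threshold)
        nets.append(assemble_network(train_pos, lnc_j, prot_j, **extra))
    if config.variant in ("KBNet", "full"):
        known = set(resources.lncRNAs)
        lnc_b = build_alignment_graph(
            resources.lnc_hits, NODE_LNC, sim.lnc_evalue_cutoff, sim.orientation, known_ids=known
        )
        prot_b = build_alignment_graph(
            resources.prot_hits, NODE_PROT, sim.prot_evalue_cutoff, sim.orientation,
            known_ids=set(resources.proteins),
        )
        nets.append(assemble_network(train_pos, lnc_b, prot_b, **extra))
    return nets


def _negative_spec_for(config: PipelineConfig, count: int, seed: int) -> NegativeSpec:
    neg = config.negatives
    if neg.strategy == "distance":
        return NegativeSpec(
            "distance", count, seed,
            distance_min=neg.distance_min if neg.distance_min is not None else 2,
            distance_max=neg.distance_max if neg.distance_max is not None else 7,
        )
    return NegativeSpec(neg.strategy, count, seed)


def embed_networks(
    nets: Sequence[HeteroNetwork],
    test_pos: Sequence[Pair],
    config: PipelineConfig,
    repeat: int,
) -> dict[str, np.ndarray]:
    """Walks + skip-gram per network, spliced when two networks are given.

    Both metapath schemes run on every network and their corpora are
    concatenated before training. The leak check (no walk bigram equals a
    held-out test pair) is asserted on every corpus.
    """
    schemes = [MetaPathScheme.from_string(s) for s in config.walk.schemes]
    embeddings: list[dict[str, np.ndarray]] = []
    for net_idx, net in enumerate(nets):
        corpora = []
        for scheme in schemes:
            corpora.append(
                generate_walks(
                    net, scheme,
                    walks_per_node=config.walk.num_walks,
                    walk_length=config.walk.length,
                    seed=_derive_seed(config.embed.seed, repeat, net_idx),
                )
            )
        corpus = WalkCorpus.merge(corpora)
        corpus.assert_excludes(test_pos)
        emb = train_embeddings(
            corpus,
            dim=config.embed.dim,
            window=config.embed.window,
            epochs=config.embed.epochs,
            seed=_derive_seed(config.embed.seed, repeat, net_idx, 1),
            negative=config.embed.negative,
            alpha=config.embed.alpha,
            min_alpha=config.embed.min_alpha,
            all_nodes=sorted(net.graph.nodes),
        )
        embeddings.append(emb)
    if len(embeddings) == 2:
        return splice_node_features(embeddings[0], embeddings[1])
    return embeddings[0]


def evaluate_repeat(
    split: RepeatSplit,
    config: PipelineConfig,
    resources: PipelineResources,
    repeat: int = 0,
    all_positives: Sequence[Pair] | None = None,
    artifacts_dir: str | Path | None = None,
) -> RepeatMetrics:
    """Run the full method on one repeat's train partition; evaluate on its test partition."""
    train_pos, test_pos = split.train_pos, split.test_pos
    train_neg, test_neg = split.train_neg, split.test_neg
    if not train_neg and not test_neg:
        raise ValidationError(f"repeat {repeat}: no negatives attached to the split")
    assoc_source = train_pos if config.similarity.training_only else tuple(all_positives or train_pos)
    nets = _build_networks(train_pos, assoc_source, config, resources)
    node_feats = embed_networks(nets, test_pos, config, repeat)

    train_set = pair_features(
        node_feats,
        list(train_pos) + list(train_neg),
        labels=[1] * len(train_pos) + [0] * len(train_neg),
        partition="train",
    )
    test_set = pair_features(
        node_feats,
        list(test_pos) + list(test_neg),
        labels=[1] * len(test_pos) + [0] * len(test_neg),
        partition="test",
    )
    clf = train_classifier(
        train_set, C=config.classifier.C, gamma=config.classifier.gamma,
        seed=_derive_seed(config.classifier.seed, repeat, 2),
    )
    predictions = np.asarray(clf.predict(test_set.features))
    scores = decision_scores(clf, test_set.features)
    result = compute_metrics(test_set.labels, predictions)
    result.roc_points, result.auc = roc_auc(test_set.labels, scores)
    result.embed_dim = config.embed.dim
    result.node_dim = len(next(iter(node_feats.values())))
    result.pair_dim = train_set.dim

    if artifacts_dir is not None:
        artifacts_dir = Path(artifacts_dir)
        artifacts_dir.mkdir(parents=True, exist_ok=True)
        feats = {f"{l}~{p}": vec for (l, p), vec in zip(test_set.pairs, test_set.features)}
        write_embeddings(feats, artifacts_dir / f"repeat{repeat}_test_features.tsv")
        write_embeddings(node_feats, artifacts_dir / f"repeat{repeat}_node_features.tsv")
    return result


def attach_negatives(
    dataset: InteractionDataset,
    config: PipelineConfig,
    resources: PipelineResources,
) -> InteractionDataset:
    """Sample and split per-repeat negatives for a positives-only dataset.

    Negative count equals the positive count (balanced classes). With
    ``resample_per_repeat`` (default) each repeat draws an independent set;
    otherwise one set is drawn and re-split per repeat. Distance strategies
    measure distance on that repeat's training positives only.
    """
    new_splits: list[RepeatSplit] = []
    fixed: set[Pair] | None = None
    for r, split in enumerate(dataset.splits):
        if split.train_neg or split.test_neg:
            new_splits.append(split)
            continue
        seed = _derive_seed(config.negatives.seed, r, 3)
        if config.negatives.resample_per_repeat or fixed is None:
            spec = _negative_spec_for(config, len(dataset.positives), seed)
            sampled = sample_negatives(
                spec,
                resources.lncRNAs,
                resources.proteins,
                dataset.positives,
                localization=resources.localization,
                train_positives=split.train_pos,
            )
            if not config.negatives.resample_per_repeat:
                fixed = sampled
        else:
            sampled = fixed
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
        ordered = sorted(sampled)
        order = rng.permutation(len(ordered))
        n_train = int(round(len(ordered) * dataset.ratio))
        train_neg = tuple(ordered[i] for i in sorted(order[:n_train]))
        test_neg = tuple(ordered[i] for i in sorted(order[n_train:]))
        new_splits.append(RepeatSplit(split.train_pos, split.test_pos, train_neg, test_neg))
    negatives = tuple(sorted({p for s in new_splits for p in s.train_neg + s.test_neg}))
    return InteractionDataset(
        positives=dataset.positives,
        negatives=(),  # per-repeat sets may differ; union kept on the splits only
        splits=new_splits,
        ratio=dataset.ratio,
        seed=dataset.seed,
    ) if config.negatives.resample_per_repeat else InteractionDataset(
        positives=dataset.positives,
        negatives=negatives,
        splits=new_splits,
        ratio=dataset.ratio,
        seed=dataset.seed,
    )


def cross_repeat_evaluate(
    dataset: InteractionDataset,
    config: PipelineConfig,
    resources: PipelineResources,
    artifacts_dir: str | Path | None = None,
) -> EvaluationReport:
    """Full pipeline per repeat (network -> walks -> embeddings -> features ->
    classifier), evaluated on each repeat's held-out partition."""
    if dataset.repeats < 1:
        raise ValidationError("dataset has no repeats")
    needs_negatives = any(not (s.train_neg or s.test_neg) for s in dataset.splits)
    if needs_negatives:
        dataset = attach_negatives(dataset, config, resources)
    per_repeat = []
    for r, split in enumerate(dataset.splits):
        per_repeat.append(
            evaluate_repeat(
                split, config, resources,
                repeat=r,
                all_positives=dataset.positives,
                artifacts_dir=artifacts_dir,
            )
        )
    report = EvaluationReport(per_repeat=per_repeat)
    if artifacts_dir is not None:
        report.to_json(Path(artifacts_dir) / "report.json")
        report.to_tsv(Path(artifacts_dir) / "report.tsv")
    return report
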