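"""Classifier head, loss, optimization loop and evaluation metrics."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .corpus_io import Corpus
from .data_model import DependencyTree, EmbeddingTable, LabelSet, PASGraph
from .pas_encoder import PasEncoderParams, encode_pas, fuse
from .tree_encoders import TreeEncoderParams, encode_tree

__all__ = [
    "TrainConfig",
    "AblationConfig",
    "Metrics",
    "TriggerModel",
    "Adam",
    "classify",
    "loss",
    "train",
    "f1_score",
    "evaluate",
    "merge_token_labels",
    "predict_spans",
    "evaluate_model",
]


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the published configuration."""

    batch_size: int = 32
    dropout: float = 0.2
    learning_rate: float = 0.001
    epochs: int = 50
    l2: float = 0.003
    beta1: float = 0.88
    beta2: float = 0.90
    hidden: int = 256
    embedding_dim: int = 720
    n_layers: int = 2
    seed: int = 0
    patience: int | None = None
    init_scale: float = 0.1

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("batch_size", "epochs", "hidden", "embedding_dim", "n_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate < 0 or self.l2 < 0:
            raise ValueError("learning_rate and l2 must be nonnegative")

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AblationConfig:
    """Component switches: each branch can be disabled entirely or have
    its attention replaced by the plain/uniform aggregate."""

    use_dep: bool = True
    use_pas: bool = True
    attn_dep: bool = True
    attn_pas: bool = True

    def __post_init__(self):
        if not (self.use_dep or self.use_pas):
            raise ValueError("at least one of use_dep/use_pas must be enabled")

    @property
    def tag(self) -> str:
        def mark(flag, letter):
            return letter if flag else letter + "~"

        return (
            mark(self.attn_pas, "A")
            + mark(self.use_pas, "P")
            + mark(self.attn_dep, "A")
            + mark(self.use_dep, "D")
        )


# The eight component combinations of the ablation grid: full model,
# attention dropped on either side, either branch dropped, and the
# attention-free degenerate variants.
ABLATION_GRID: list[AblationConfig] = [
    AblationConfig(use_dep=True, use_pas=True, attn_dep=True, attn_pas=True),
    AblationConfig(use_dep=True, use_pas=True, attn_dep=True, attn_pas=False),
    AblationConfig(use_dep=True, use_pas=False, attn_dep=True, attn_pas=False),
    AblationConfig(use_dep=True, use_pas=True, attn_dep=False, attn_pas=False),
    AblationConfig(use_dep=True, use_pas=False, attn_dep=False, attn_pas=False),
    AblationConfig(use_dep=True, use_pas=True, attn_dep=False, attn_pas=True),
    AblationConfig(use_dep=False, use_pas=True, attn_dep=False, attn_pas=True),
    AblationConfig(use_dep=False, use_pas=True, attn_dep=False, attn_pas=False),
]


@dataclass
class Metrics:
    """Precision/recall/F1 on the percent scale, plus confusion counts."""

    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]
    tp: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------
# classifier + loss
# ---------------------------------------------------------------------

def classify(fused, W, b) -> Tensor:
    """Affine map followed by softmax: per-token class probabilities."""
    logits = ad.add(ad.matmul(ad.as_tensor(W), ad.as_tensor(fused)), ad.as_tensor(b))
    return ad.softmax(logits)


def loss(
    predictions: Sequence[Tensor],
    labels: Sequence[int],
    params: Sequence[Tensor] = (),
    l2: float = 0.0,
) -> Tensor:
    """Mean negative log-likelihood plus (l2/2) * ||theta||^2."""
    k = len(predictions)
    if k == 0:
        raise ValueError("loss needs at least one labeled node")
    if len(labels) != k:
        raise ValueError("prediction/label length mismatch")
    nll = ad.sum_tensors(
        [ad.mul(ad.log(ad.pick(p, y)), -1.0) for p, y in zip(predictions, labels)]
    )
    total = ad.mul(nll, 1.0 / k)
    if l2 > 0 and params:
        reg = ad.sum_tensors([ad.vsum(ad.mul(t, t)) for t in params])
        total = ad.add(total, ad.mul(reg, l2 / 2.0))
    return total


# ---------------------------------------------------------------------
# model
# ---------------------------------------------------------------------

class TriggerModel:
    """Dependency-tree branch + PAS-graph branch + softmax head.

    Every token is classified from the concatenation of its two branch
    hidden states (a disabled branch contributes zeros).
    """

    def __init__(
        self,
        d_x: int,
        d_h: int,
        label_set: LabelSet,
        ablation: AblationConfig | None = None,
        n_layers: int = 2,
        rng: np.random.Generator | None = None,
        init_scale: float = 0.1,
        learn_rho: bool = False,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d_x, self.d_h = d_x, d_h
        self.label_set = label_set
        self.ablation = ablation or AblationConfig()
        self.n_layers = n_layers
        self.tree_params = TreeEncoderParams.init(
            d_x, d_h, rng, attentive=True, scale=init_scale
        )
        self.pas_params = PasEncoderParams.init(
            d_x, d_h, rng, attentive=True, n_layers=n_layers,
            scale=init_scale, learn_rho=learn_rho,
        )
        n_labels = len(label_set)
        self.W_cls = Tensor(rng.normal(0, init_scale, (n_labels, 2 * d_h)), requires_grad=True)
        self.b_cls = Tensor(np.zeros(n_labels), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.ablation.use_dep:
            out += self.tree_params.cell.tensors()
            if self.ablation.attn_dep:
                if self.tree_params.attn is not None:
                    out += self.tree_params.attn.tensors()
                if self.tree_params.query_proj is not None:
                    out.append(self.tree_params.query_proj)
        if self.ablation.use_pas:
            out += self.pas_params.cell.tensors()
            if self.ablation.attn_pas and self.pas_params.attn is not None:
                out += self.pas_params.attn.tensors()
            if self.pas_params.rho is not None:
                out.append(self.pas_params.rho)
        out += [self.W_cls, self.b_cls]
        return out

    def forward(
        self,
        tree: DependencyTree,
        pas_graph: PASGraph | None,
        X: np.ndarray,
    ) -> tuple[dict[int, Tensor], list, list]:
        """Per-token probability tensors plus the two attention-map lists."""
        dep_states = pas_states = None
        dep_maps: list = []
        pas_maps: list = []
        if self.ablation.use_dep:
            mode = "attentive" if self.ablation.attn_dep else "plain"
            dep_states, dep_maps = encode_tree(tree, X, self.tree_params, mode=mode)
        if self.ablation.use_pas:
            graph = pas_graph if pas_graph is not None else PASGraph(tree.sentence_id, [])
            mode = "attentive" if self.ablation.attn_pas else "uniform"
            pas_states, pas_maps = encode_pas(
                graph, X, self.pas_params, mode=mode, n_tokens=len(tree)
            )
        fused = fuse(dep_states, pas_states, self.d_h, rho=self.pas_params.rho)
        probs = {j: classify(fused[j], self.W_cls, self.b_cls) for j in sorted(fused)}
        return probs, dep_maps, pas_maps

    def predict_labels(self, tree: DependencyTree, pas_graph: PASGraph | None,
                       X: np.ndarray) -> list[int]:
        probs, _, _ = self.forward(tree, pas_graph, X)
        return [int(np.argmax(probs[j].data)) for j in range(1, len(tree) + 1)]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def dump(t: Tensor):
            return np.asarray(t).tolist()

        state = {
            "d_x": self.d_x,
            "d_h": self.d_h,
            "n_layers": self.n_layers,
            "labels": self.label_set.names[1:],
            "ablation": asdict(self.ablation),
            "tree": {
                "W": {g: dump(self.tree_params.cell.W[g]) for g in "fiou"},
                "U": {g: dump(self.tree_params.cell.U[g]) for g in "fiou"},
                "b": {g: dump(self.tree_params.cell.b[g]) for g in "fiou"},
                "attn_W": dump(self.tree_params.attn.W),
                "attn_a": dump(self.tree_params.attn.a),
                "query_proj": dump(self.tree_params.query_proj),
            },
            "pas": {
                "W": {g: dump(self.pas_params.cell.W[g]) for g in "fiou"},
                "U": {g: dump(self.pas_params.cell.U[g]) for g in "fiou"},
                "b": {g: dump(self.pas_params.cell.b[g]) for g in "fiou"},
                "attn_W": dump(self.pas_params.attn.W),
                "attn_a": dump(self.pas_params.attn.a),
                "rho": dump(self.pas_params.rho) if self.pas_params.rho is not None else None,
            },
            "W_cls": dump(self.W_cls),
            "b_cls": dump(self.b_cls),
        }
        return state

    @classmethod
    def from_dict(cls, state: dict) -> "TriggerModel":
        label_set = LabelSet(state["labels"])
        model = cls(
            d_x=state["d_x"],
            d_h=state["d_h"],
            label_set=label_set,
            ablation=AblationConfig(**state["ablation"]),
            n_layers=state["n_layers"],
            rng=np.random.default_rng(0),
        )

        def load(t: Tensor, data):
            t.data = np.asarray(data, dtype=np.float64)

        for g in "fiou":
            load(model.tree_params.cell.W[g], state["tree"]["W"][g])
            load(model.tree_params.cell.U[g], state["tree"]["U"][g])
            load(model.tree_params.cell.b[g], state["tree"]["b"][g])
            load(model.pas_params.cell.W[g], state["pas"]["W"][g])
            load(model.pas_params.cell.U[g], state["pas"]["U"][g])
            load(model.pas_params.cell.b[g], state["pas"]["b"][g])
        load(model.tree_params.attn.W, state["tree"]["attn_W"])
        load(model.tree_params.attn.a, state["tree"]["attn_a"])
        load(model.tree_params.query_proj, state["tree"]["query_proj"])
        load(model.pas_params.attn.W, state["pas"]["attn_W"])
        load(model.pas_params.attn.a, state["pas"]["attn_a"])
        if state["pas"].get("rho") is not None:
            model.pas_params.rho = Tensor(state["pas"]["rho"], requires_grad=True)
        load(model.W_cls, state["W_cls"])
        load(model.b_cls, state["b_cls"])
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TriggerModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


class Adam:
    """Adam over a parameter list (first/second moment estimates)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.001,
                 beta1: float = 0.88, beta2: float = 0.90, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

class DivergenceError(RuntimeError):
    pass


def _sentence_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(
    corpus: Corpus,
    config: TrainConfig,
    ablation: AblationConfig | None = None,
    embeddings: EmbeddingTable | None = None,
    model: TriggerModel | None = None,
) -> tuple[TriggerModel, list[float]]:
    """Fit a :class:`TriggerModel` on ``corpus`` by Adam on the
    regularized cross-entropy; returns the model and per-epoch mean loss.

    All randomness (init, shuffling, dropout masks) flows from
    ``config.seed``.  Mini-batches are whole sentences.
    """
    rng = np.random.default_rng(config.seed)
    if embeddings is None:
        embeddings = EmbeddingTable(config.embedding_dim, seed=config.seed)
    if model is None:
        model = TriggerModel(
            d_x=embeddings.dimension,
            d_h=config.hidden,
            label_set=corpus.label_set,
            ablation=ablation,
            n_layers=config.n_layers,
            rng=rng,
            init_scale=config.init_scale,
        )

    sentences = []
    for doc in corpus.documents:
        labels_by_sid = doc.token_labels(corpus.label_set)
        for tree in doc.trees:
            X = embeddings.embed_tokens(tree.tokens)
            pas = doc.pas_graphs.get(tree.sentence_id)
            sentences.append((tree, pas, X, labels_by_sid[tree.sentence_id]))
    if not sentences:
        raise ValueError("empty corpus")

    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    trace: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        epoch_losses = []
        for batch in _sentence_batches(len(sentences), config.batch_size, rng):
            preds: list[Tensor] = []
            labels: list[int] = []
            for idx in batch:
                tree, pas, X, y = sentences[idx]
                if config.dropout > 0:
                    mask = (rng.random(X.shape) >= config.dropout) / (1 - config.dropout)
                    X = X * mask
                probs, _, _ = model.forward(tree, pas, X)
                for j in range(1, len(tree) + 1):
                    preds.append(probs[j])
                    labels.append(y[j - 1])
            batch_loss = loss(preds, labels, params, config.l2)
            if not np.isfinite(batch_loss.item()):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            epoch_losses.append(batch_loss.item())
        trace.append(float(np.mean(epoch_losses)))
        if config.patience is not None:
            if trace[-1] < best - 1e-6:
                best, stale = trace[-1], 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    return model, trace


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of percent-scale precision and recall, 2 decimals."""
    if not (0 <= precision_pct <= 100 and 0 <= recall_pct <= 100):
        raise ValueError("precision/recall must be on the percent scale [0, 100]")
    if precision_pct == 0 and recall_pct == 0:
        warnings.warn("P = R = 0; F1 defined as 0", stacklevel=2)
        return 0.0
    return round(2 * precision_pct * recall_pct / (precision_pct + recall_pct), 2)


def merge_token_labels(
    tree: DependencyTree, labels: Sequence[int], label_set: LabelSet
) -> list[tuple[str, int, int]]:
    """Merge runs of adjacent same-label tokens into (label, start, end)
    character spans; NONE tokens produce nothing."""
    spans = []
    i = 0
    n = len(tree)
    while i < n:
        y = labels[i]
        if y == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == y:
            j += 1
        spans.append(
            (label_set.name(y), tree.tokens[i].char_start, tree.tokens[j].char_end)
        )
        i = j + 1
    return spans


def predict_spans(
    model: TriggerModel, corpus: Corpus, embeddings: EmbeddingTable
) -> dict[str, list[tuple[str, str, int, int]]]:
    """Per-document predicted (sentence_id, label, start, end) spans."""
    out: dict[str, list[tuple[str, str, int, int]]] = {}
    for doc in corpus.documents:
        spans = []
        for tree in doc.trees:
            X = embeddings.embed_tokens(tree.tokens)
            labels = model.predict_labels(tree, doc.pas_graphs.get(tree.sentence_id), X)
            for label, start, end in merge_token_labels(tree, labels, corpus.label_set):
                spans.append((tree.sentence_id, label, start, end))
        out[doc.doc_id] = spans
    return out


def evaluate(
    predictions: Sequence[tuple],
    gold: Sequence[tuple],
    label_set: LabelSet,
) -> Metrics:
    """Exact-span, exact-type matching of (..., label, start, end) tuples.

    Tuples may carry any leading context fields (e.g. document/sentence
    ids) as long as predictions and gold agree; the label is always the
    third-from-last field.  NONE never counts as a positive.
    """
    def norm(items):
        out = set()
        for it in items:
            label = it[-3]
            if label not in label_set:
                raise KeyError(f"label {label!r} outside the label set")
            if label == LabelSet.NONE:
                continue
            out.add(tuple(it))
        return out

    pred_set, gold_set = norm(predictions), norm(gold)
    tp = len(pred_set & gold_set)
    fp = len(pred_set - gold_set)
    fn = len(gold_set - pred_set)
    if not pred_set:
        warnings.warn("no predictions; precision defined as 0", stacklevel=2)
    micro_p = 100.0 * tp / len(pred_set) if pred_set else 0.0
    micro_r = 100.0 * tp / len(gold_set) if gold_set else 0.0
    micro_f = (
        2 * micro_p * micro_r / (micro_p + micro_r) if (micro_p + micro_r) > 0 else 0.0
    )
    per_class: dict[str, dict[str, float]] = {}
    macro = []
    for name in label_set.trigger_names:
        p_c = {t for t in pred_set if t[-3] == name}
        g_c = {t for t in gold_set if t[-3] == name}
        tp_c = len(p_c & g_c)
        prec = 100.0 * tp_c / len(p_c) if p_c else 0.0
        rec = 100.0 * tp_c / len(g_c) if g_c else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[name] = {
            "precision": round(prec, 2),
            "recall": round(rec, 2),
            "f1": round(f1, 2),
            "tp": tp_c,
            "fp": len(p_c) - tp_c,
            "fn": len(g_c) - tp_c,
        }
        if g_c or p_c:
            macro.append(f1)
    return Metrics(
        micro_precision=round(micro_p, 2),
        micro_recall=round(micro_r, 2),
        micro_f1=round(micro_f, 2),
        macro_f1=round(float(np.mean(macro)) if macro else 0.0, 2),
        per_class=per_class,
        tp=tp,
        fp=fp,
        fn=fn,
    )


def evaluate_model(
    model: TriggerModel, corpus: Corpus, embeddings: EmbeddingTable
) -> Metrics:
    """Span-level metrics of ``model`` against the corpus annotations."""
    all_preds = predict_spans(model, corpus, embeddings)
    preds = []
    gold = []
    for doc in corpus.documents:
        doc.token_labels(corpus.label_set)  # resolves annotation alignment
        for sid, label, start, end in all_preds[doc.doc_id]:
            preds.append((doc.doc_id, label, start, end))
        for ann in doc.triggers:
            gold.append((doc.doc_id, ann.label, ann.char_start, ann.char_end))
    return evaluate(preds, gold, corpus.label_set)
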