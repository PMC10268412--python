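"""Seeded generator of synthetic corpora with the structure the model
assumes: random dependency trees, correlated PAS graphs, and trigger
labels planted by a rule the encoders can recover.

The planted rule: a token is a trigger of type tau(word) iff its word
belongs to the trigger vocabulary AND either (a) one of its dependency
children is an entity word, or (b) — for the configured PAS-only
fraction — one of its PAS neighbors is an entity word while no
dependency child is.  Trigger-vocabulary words also occur with neither
condition, as planted negatives, so word identity alone cannot solve
the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Corpus, Document
from .data_model import (
    DependencyTree,
    EmbeddingTable,
    LabelSet,
    PASGraph,
    Token,
    TriggerAnnotation,
)
from .corpus_io import EntityAnnotation

__all__ = ["SynthConfig", "generate", "generate_train_test", "synthetic_embeddings",
           "rule_labels", "ENTITY_TYPE"]

ENTITY_TYPE = "Protein"
DEFAULT_LABELS = ("Binding", "Regulation", "Phosphorylation")


@dataclass
class SynthConfig:
    n_sentences: int = 200
    min_len: int = 5
    max_len: int = 15
    branching: float = 0.5  # geometric pull toward recent heads
    trigger_vocab_size: int = 6
    entity_vocab_size: int = 8
    filler_vocab_size: int = 30
    labels: tuple[str, ...] = DEFAULT_LABELS
    trigger_position_rate: float = 0.25
    entity_rate: float = 0.35
    positive_rate: float = 0.65
    pas_only_fraction: float = 0.25
    pas_arc_rate: float = 0.5
    noise: float = 0.0
    sentences_per_doc: int = 10
    embedding_dim: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.min_len < 2 or self.max_len < self.min_len:
            raise ValueError("need max_len >= min_len >= 2")
        for name in ("pas_only_fraction", "noise", "positive_rate",
                     "trigger_position_rate", "entity_rate", "pas_arc_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trigger_vocab_size < 1 and self.trigger_position_rate > 0:
            raise ValueError("trigger vocabulary empty but trigger rate nonzero")
        if self.entity_vocab_size < 1 or self.filler_vocab_size < 1:
            raise ValueError("entity and filler vocabularies must be nonempty")
        if not self.labels:
            raise ValueError("need at least one trigger label")

    @property
    def label_set(self) -> LabelSet:
        return LabelSet(list(self.labels))

    def trigger_word(self, i: int) -> str:
        return f"trigv{i}"

    def entity_word(self, i: int) -> str:
        return f"entw{i}"

    def filler_word(self, i: int) -> str:
        return f"fill{i}"

    def tau(self, word: str) -> str:
        """Deterministic trigger word -> class map."""
        i = int(word.removeprefix("trigv"))
        return self.labels[i % len(self.labels)]


@dataclass
class _Sentence:
    words: list[str]
    head: dict[int, int]
    pas_edges: set = field(default_factory=set)
    labels: list[int] = field(default_factory=list)


def _random_tree(n: int, branching: float, rng: np.random.Generator) -> dict[int, int]:
    """Sequential random attachment; token 1 is the root."""
    head = {1: 0}
    for i in range(2, n + 1):
        if rng.random() < branching:
            head[i] = int(rng.integers(1, i))  # uniform over earlier tokens
        else:
            head[i] = i - 1  # chain step: keeps some depth in every tree
    return head


def rule_labels(
    words: list[str],
    head: dict[int, int],
    pas_edges: set,
    config: SynthConfig,
    use_pas: bool = True,
) -> list[int]:
    """Apply the planted rule to a sentence; the test-side oracle uses
    ``use_pas=False`` to read only the tree."""
    n = len(words)
    children: dict[int, list[int]] = {i: [] for i in range(1, n + 1)}
    for child, parent in head.items():
        if parent != 0:
            children[parent].append(child)
    neigh: dict[int, set[int]] = {i: set() for i in range(1, n + 1)}
    for pred, arg, _ in pas_edges:
        neigh[pred].add(arg)
        neigh[arg].add(pred)
    label_set = config.label_set
    out = []
    for i in range(1, n + 1):
        word = words[i - 1]
        label = 0
        if word.startswith("trigv"):
            dep_hit = any(words[c - 1].startswith("entw") for c in children[i])
            pas_hit = use_pas and any(words[k - 1].startswith("entw") for k in neigh[i])
            if dep_hit or pas_hit:
                label = label_set.index(config.tau(word))
        out.append(label)
    return out


def _generate_sentence(config: SynthConfig, rng: np.random.Generator) -> _Sentence:
    n = int(rng.integers(config.min_len, config.max_len + 1))
    head = _random_tree(n, config.branching, rng)
    children: dict[int, list[int]] = {i: [] for i in range(1, n + 1)}
    for child, parent in head.items():
        if parent != 0:
            children[parent].append(child)

    # phase 1: raw word assignment; triggers prefer internal nodes so the
    # tree-detectable route is usually feasible (a leaf has no child to
    # carry the entity)
    draw = rng.random(n)
    is_trigger_pos = np.array([
        draw[i] < config.trigger_position_rate * (1.6 if children[i + 1] else 0.4)
        for i in range(n)
    ])
    words = []
    for i in range(n):
        if is_trigger_pos[i]:
            words.append(config.trigger_word(int(rng.integers(config.trigger_vocab_size))))
        elif rng.random() < config.entity_rate:
            words.append(config.entity_word(int(rng.integers(config.entity_vocab_size))))
        else:
            words.append(config.filler_word(int(rng.integers(config.filler_vocab_size))))

    trigger_positions = [i + 1 for i in range(n) if is_trigger_pos[i]]

    def is_entity(i: int) -> bool:
        return words[i - 1].startswith("entw")

    def is_trig(i: int) -> bool:
        return words[i - 1].startswith("trigv")

    # phase 2: plant positives / PAS-dependent positives / negatives
    tree_pos: list[int] = []
    pas_pos: list[int] = []
    neg: list[int] = []
    for t in trigger_positions:
        positive = rng.random() < config.positive_rate
        wants_pas = positive and rng.random() < config.pas_only_fraction
        if positive and not wants_pas:
            candidates = [c for c in children[t] if not is_trig(c)]
            if any(is_entity(c) for c in candidates):
                tree_pos.append(t)
            elif candidates:
                pick = candidates[int(rng.integers(len(candidates)))]
                words[pick - 1] = config.entity_word(int(rng.integers(config.entity_vocab_size)))
                tree_pos.append(t)
            else:
                neg.append(t)  # leaf with no usable child: demote
        elif wants_pas:
            for c in children[t]:
                if is_entity(c):
                    words[c - 1] = config.filler_word(int(rng.integers(config.filler_vocab_size)))
            pas_pos.append(t)
        else:
            for c in children[t]:
                if is_entity(c):
                    words[c - 1] = config.filler_word(int(rng.integers(config.filler_vocab_size)))
            neg.append(t)

    # phase 3: PAS edges — a subset of dependency arcs plus long-range links
    roles = ("arg1", "arg2", "arg3", "arg4")
    pas_edges: set = set()
    for child, parent in head.items():
        if parent != 0 and rng.random() < config.pas_arc_rate:
            pas_edges.add((parent, child, roles[int(rng.integers(2))]))
    for _ in range(max(1, n // 3)):
        i, j = int(rng.integers(1, n + 1)), int(rng.integers(1, n + 1))
        if i != j:
            pas_edges.add((i, j, roles[int(rng.integers(4))]))

    # PAS-dependent triggers get a guaranteed entity neighbor
    for t in pas_pos:
        entity_nodes = [
            i for i in range(1, n + 1)
            if is_entity(i) and head[i] not in tree_pos + neg and i not in children[t]
        ]
        if not entity_nodes:
            fillers = [
                i for i in range(1, n + 1)
                if words[i - 1].startswith("fill") and head[i] not in trigger_positions
            ]
            if not fillers:
                neg.append(t)
                continue
            pick = fillers[int(rng.integers(len(fillers)))]
            words[pick - 1] = config.entity_word(int(rng.integers(config.entity_vocab_size)))
            entity_nodes = [pick]
        e = entity_nodes[int(rng.integers(len(entity_nodes)))]
        pas_edges.add((t, e, "arg2"))
    pas_pos = [t for t in pas_pos if t not in neg]

    # cleanup: planted negatives must satisfy neither condition
    for t in neg:
        for c in children[t]:
            if is_entity(c):
                words[c - 1] = config.filler_word(int(rng.integers(config.filler_vocab_size)))
        pas_edges = {
            (p, a, r) for (p, a, r) in pas_edges
            if not ((p == t and is_entity(a)) or (a == t and is_entity(p)))
        }
    # tree-planted positives must keep their entity child after cleanup;
    # cleanup only touches children of negatives, which are disjoint.

    labels = rule_labels(words, head, pas_edges, config, use_pas=True)
    if config.noise > 0:
        n_labels = len(config.label_set)
        for i in range(n):
            if rng.random() < config.noise:
                labels[i] = int(rng.integers(n_labels))
    return _Sentence(words=words, head=head, pas_edges=pas_edges, labels=labels)


def generate(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    doc_prefix: str = "d",
) -> Corpus:
    """Build an in-memory corpus; write it out with corpus_io.save_corpus."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    label_set = config.label_set
    documents = []
    sents = [_generate_sentence(config, rng) for _ in range(config.n_sentences)]
    for d0 in range(0, len(sents), config.sentences_per_doc):
        doc_sents = sents[d0 : d0 + config.sentences_per_doc]
        doc_id = f"{doc_prefix}{d0 // config.sentences_per_doc:04d}"
        lines = []
        trees = []
        pas_graphs = {}
        triggers: list[TriggerAnnotation] = []
        entities: list[EntityAnnotation] = []
        offset = 0
        t_counter = 0
        for s_idx, sent in enumerate(doc_sents):
            sid = f"{doc_id}-s{s_idx + 1}"
            tokens = []
            starts = []
            pos = offset
            for i, word in enumerate(sent.words):
                tokens.append(
                    Token(i + 1, word, word, "NN", pos, pos + len(word))
                )
                starts.append(pos)
                pos += len(word) + 1
            line = " ".join(sent.words)
            lines.append(line)
            trees.append(DependencyTree(sid, tokens, sent.head))
            if sent.pas_edges:
                pas_graphs[sid] = PASGraph(sid, sent.pas_edges, n_tokens=len(tokens))
            # adjacent same-label trigger tokens form one multi-word span,
            # matching how prediction spans are recovered downstream
            i = 0
            while i < len(sent.labels):
                label = sent.labels[i]
                if label == 0:
                    i += 1
                    continue
                j = i
                while j + 1 < len(sent.labels) and sent.labels[j + 1] == label:
                    j += 1
                t_counter += 1
                triggers.append(
                    TriggerAnnotation(
                        f"T{t_counter}",
                        label_set.name(label),
                        tokens[i].char_start,
                        tokens[j].char_end,
                        surface=" ".join(t.form for t in tokens[i : j + 1]),
                        sentence_id=sid,
                        token_indices=list(range(i + 1, j + 2)),
                    )
                )
                i = j + 1
            for i, label in enumerate(sent.labels):
                tok = tokens[i]
                if label == 0 and tok.form.startswith("entw"):
                    t_counter += 1
                    entities.append(
                        EntityAnnotation(f"T{t_counter}", ENTITY_TYPE,
                                         tok.char_start, tok.char_end, tok.form)
                    )
            offset = pos
        text = "\n".join(lines) + "\n"
        # token offsets were laid out on the same grid as the joined text
        documents.append(
            Document(doc_id, text, trees, pas_graphs, triggers, entities)
        )
    return Corpus(documents, label_set)


def generate_train_test(config: SynthConfig, n_test: int = 50) -> tuple[Corpus, Corpus]:
    """Two disjoint corpora drawn from independent child streams of the
    config seed: (n_sentences train, n_test test)."""
    ss = np.random.SeedSequence(config.seed)
    rng_train, rng_test = (np.random.default_rng(s) for s in ss.spawn(2))
    train = generate(config, rng_train, doc_prefix="d")
    test_cfg = SynthConfig(**{**config.__dict__, "n_sentences": n_test})
    test = generate(test_cfg, rng_test, doc_prefix="td")
    return train, test


def synthetic_embeddings(config: SynthConfig) -> EmbeddingTable:
    """Deterministic embeddings with class-informative components.

    The hashed fallback supplies a random base; vocabulary words get
    extra indicator components (entity flag, trigger flag, trigger-class
    one-hot) so the planted rule is learnable at small dimension.
    """
    d = config.embedding_dim
    n_labels = len(config.labels)
    if d < 2 + n_labels:
        raise ValueError(f"embedding_dim must be >= {2 + n_labels}")
    table = EmbeddingTable(d, seed=config.seed)

    def informative(word: str) -> np.ndarray:
        vec = table._fallback(word).copy()
        vec[: 2 + n_labels] *= 0.1
        if word.startswith("entw"):
            vec[0] += 1.0
        if word.startswith("trigv"):
            vec[1] += 1.0
            vec[2 + config.labels.index(config.tau(word))] += 1.0
        return vec

    for i in range(config.trigger_vocab_size):
        w = config.trigger_word(i)
        table[w] = informative(w)
    for i in range(config.entity_vocab_size):
        w = config.entity_word(i)
        table[w] = informative(w)
    for i in range(config.filler_vocab_size):
        w = config.filler_word(i)
        table[w] = informative(w)
    return table
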