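"""Core domain types: tokens, dependency trees, PAS graphs, labels, embeddings."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Token",
    "DependencyTree",
    "PASGraph",
    "LabelSet",
    "TriggerAnnotation",
    "EmbeddingTable",
    "StructureError",
    "AlignmentError",
    "PAS_ROLES",
    "children",
    "align_span",
]

PAS_ROLES = ("arg1", "arg2", "arg3", "arg4", "other")


class StructureError(ValueError):
    """Raised when a head map or edge list violates a structural invariant."""


class AlignmentError(ValueError):
    """Raised when a character span cannot be aligned to any token."""


@dataclass(frozen=True)
class Token:
    """A single token of a parsed sentence.

    ``index`` is the 1-based position within the sentence; character
    offsets are 0-based and end-exclusive, and may be absent (-1) when
    the source format does not carry them.
    """

    index: int
    form: str
    lemma: str = "_"
    pos: str = "_"
    char_start: int = -1
    char_end: int = -1

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")
        if self.char_start >= 0 or self.char_end >= 0:
            if not (0 <= self.char_start < self.char_end):
                raise ValueError(
                    f"bad offsets [{self.char_start}, {self.char_end}) for {self.form!r}"
                )

    @property
    def has_offsets(self) -> bool:
        return self.char_start >= 0


class DependencyTree:
    """Single-rooted dependency parse over an ordered token list.

    ``head`` maps each child index to its parent index, with 0 denoting
    the root.  Construction validates single-rootedness, acyclicity and
    connectivity; malformed multi-root input (as produced by some
    parsers) is repaired by attaching every root candidate to the first
    one, with a warning.
    """

    def __init__(
        self,
        sentence_id: str,
        tokens: Sequence[Token],
        head: Mapping[int, int],
        deprel: Mapping[int, str] | None = None,
    ):
        self.sentence_id = sentence_id
        self.tokens = list(tokens)
        indices = [t.index for t in self.tokens]
        if indices != list(range(1, len(self.tokens) + 1)):
            raise StructureError(f"{sentence_id}: token indices must be 1..n in order")
        self.head = dict(head)
        self.deprel = dict(deprel or {})
        self._repair_roots()
        self._validate()
        self._children: dict[int, list[int]] = {i: [] for i in indices}
        for child, parent in sorted(self.head.items()):
            if parent != 0:
                self._children[parent].append(child)

    def _repair_roots(self) -> None:
        roots = sorted(i for i, h in self.head.items() if h == 0)
        if len(roots) > 1:
            warnings.warn(
                f"{self.sentence_id}: {len(roots)} HEAD=0 tokens; "
                "attaching extras under the first root",
                stacklevel=3,
            )
            for extra in roots[1:]:
                self.head[extra] = roots[0]

    def _validate(self) -> None:
        n = len(self.tokens)
        if set(self.head) != set(range(1, n + 1)):
            raise StructureError(f"{self.sentence_id}: head map must cover tokens 1..{n}")
        roots = [i for i, h in self.head.items() if h == 0]
        if len(roots) != 1:
            raise StructureError(f"{self.sentence_id}: expected exactly one root")
        for child, parent in self.head.items():
            if parent != 0 and not (1 <= parent <= n):
                raise StructureError(
                    f"{self.sentence_id}: HEAD {parent} of token {child} out of range"
                )
        # Walk every token to the root; revisiting a node means a cycle.
        for start in range(1, n + 1):
            seen = set()
            node = start
            while node != 0:
                if node in seen:
                    raise StructureError(f"{self.sentence_id}: cycle through token {node}")
                seen.add(node)
                node = self.head[node]

    @property
    def root(self) -> int:
        return next(i for i, h in self.head.items() if h == 0)

    def __len__(self) -> int:
        return len(self.tokens)

    def children(self, j: int) -> list[int]:
        if j not in self._children:
            raise IndexError(f"{self.sentence_id}: no token with index {j}")
        return list(self._children[j])

    def postorder(self) -> list[int]:
        """Iterative post-order over token indices (root last)."""
        order: list[int] = []
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            stack.append((node, True))
            for c in reversed(self._children[node]):
                stack.append((c, False))
        return order


def children(tree: DependencyTree, j: int) -> list[int]:
    """Return C(j): the dependents of token ``j``, in surface order."""
    return tree.children(j)


class PASGraph:
    """Directed role-labelled predicate-argument edges with an undirected
    neighborhood view used by the graph encoder."""

    def __init__(
        self,
        sentence_id: str,
        edges: Iterable[tuple[int, int, str]],
        n_tokens: int | None = None,
    ):
        self.sentence_id = sentence_id
        self.edges: set[tuple[int, int, str]] = set()
        for pred, arg, role in edges:
            if role not in PAS_ROLES:
                warnings.warn(
                    f"{sentence_id}: unknown PAS role {role!r}, mapped to 'other'",
                    stacklevel=3,
                )
                role = "other"
            if pred < 1 or arg < 1:
                raise StructureError(f"{sentence_id}: PAS edge index < 1")
            if n_tokens is not None and (pred > n_tokens or arg > n_tokens):
                raise StructureError(
                    f"{sentence_id}: PAS edge ({pred}, {arg}) outside sentence of "
                    f"{n_tokens} tokens"
                )
            self.edges.add((pred, arg, role))
        self.neighborhood: dict[int, set[int]] = {}
        for pred, arg, _ in self.edges:
            self.neighborhood.setdefault(pred, set()).add(arg)
            self.neighborhood.setdefault(arg, set()).add(pred)

    def neighbors(self, j: int) -> set[int]:
        return set(self.neighborhood.get(j, set()))

    def __len__(self) -> int:
        return len(self.edges)


class LabelSet:
    """Ordered trigger class names with the reserved NONE class first."""

    NONE = "NONE"

    def __init__(self, names: Sequence[str]):
        names = list(names)
        if self.NONE in names:
            names.remove(self.NONE)
        if len(set(names)) != len(names):
            raise ValueError("duplicate label names")
        self.names: list[str] = [self.NONE] + names
        self._index = {name: i for i, name in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown label {name!r}") from None

    def name(self, idx: int) -> str:
        return self.names[idx]

    @property
    def trigger_names(self) -> list[str]:
        return self.names[1:]


@dataclass
class TriggerAnnotation:
    """A typed trigger span in document-level character coordinates."""

    annotation_id: str
    label: str
    char_start: int
    char_end: int
    surface: str = ""
    token_indices: list[int] = field(default_factory=list)
    sentence_id: str = ""

    def __post_init__(self):
        if self.label == LabelSet.NONE:
            raise ValueError("trigger annotations cannot carry the NONE label")
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(
                f"{self.annotation_id}: bad span [{self.char_start}, {self.char_end})"
            )


class EmbeddingTable:
    """Fixed-dimension word vectors with a deterministic hashed fallback.

    Unseen keys get a vector that is a pure function of (key, seed), so
    lookups are reproducible without storing the full vocabulary.
    """

    def __init__(self, dimension: int = 720, seed: int = 0):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self.seed = seed
        self._vectors: dict[str, np.ndarray] = {}

    def __setitem__(self, key: str, vec) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (self.dimension,):
            raise ValueError(f"vector for {key!r} has shape {vec.shape}")
        self._vectors[key] = vec

    def __contains__(self, key: str) -> bool:
        return key in self._vectors

    def _fallback(self, key: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}:{key}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return rng.normal(0.0, 1.0 / np.sqrt(self.dimension), size=self.dimension)

    def lookup(self, key: str) -> np.ndarray:
        vec = self._vectors.get(key)
        return vec if vec is not None else self._fallback(key)

    def embed_tokens(self, tokens: Sequence[Token]) -> np.ndarray:
        """(n, d) matrix of embeddings for a token sequence."""
        return np.stack([self.lookup(t.form) for t in tokens])


def align_span(
    text: str,
    tokens: Sequence[Token],
    start: int,
    end: int,
    strict: bool = True,
) -> list[int]:
    """Token indices whose offset ranges intersect [start, end).

    In strict mode an empty intersection raises :class:`AlignmentError`;
    lenient mode returns an empty list.
    """
    if not (0 <= start < end <= len(text)):
        raise ValueError(f"span [{start}, {end}) outside text of length {len(text)}")
    hits = [
        t.index
        for t in tokens
        if t.has_offsets and t.char_start < end and start < t.char_end
    ]
    if not hits and strict:
        raise AlignmentError(f"span [{start}, {end}) overlaps no token")
    return hits
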