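"""Readers and writers for the three on-disk formats.

* CoNLL-X tabular dependencies (8 or 10 columns, blank-line separated);
* a 4-column PAS TSV (``sentence_id  predicate  argument  role``), the
  ingestion contract for deep-parser predicate-argument output;
* BioNLP standoff annotations (.txt plus T/E lines).

A corpus on disk is a directory of documents sharing a basename:
``<doc>.txt``, ``<doc>.conll``, ``<doc>.pas.tsv``, ``<doc>.ann``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .data_model import (
    AlignmentError,
    DependencyTree,
    LabelSet,
    PASGraph,
    StructureError,
    Token,
    TriggerAnnotation,
    align_span,
)

__all__ = [
    "Document",
    "Corpus",
    "ParseError",
    "read_conll",
    "write_conll",
    "read_pas",
    "write_pas",
    "read_standoff",
    "write_standoff",
    "infer_token_offsets",
    "load_corpus",
    "save_corpus",
]


class ParseError(ValueError):
    """Malformed line in an input file; message carries the line number."""


# ---------------------------------------------------------------------
# CoNLL
# ---------------------------------------------------------------------

_SENT_ID_RE = re.compile(r"#\s*sent_id\s*=\s*(\S+)")


def read_conll(stream: IO[str] | Iterable[str]) -> list[DependencyTree]:
    """Parse blank-line-separated CoNLL-X blocks into dependency trees.

    Columns: ID FORM LEMMA CPOSTAG POSTAG FEATS HEAD DEPREL; anything
    after DEPREL is ignored, so 10-column CoNLL-X/2007 files work too.
    ``# sent_id = X`` comments name the sentence; otherwise sentences
    are numbered s1, s2, ...
    """
    trees: list[DependencyTree] = []
    tokens: list[Token] = []
    head: dict[int, int] = {}
    deprel: dict[int, str] = {}
    sent_id: str | None = None

    def flush():
        nonlocal tokens, head, deprel, sent_id
        if tokens:
            sid = sent_id if sent_id is not None else f"s{len(trees) + 1}"
            trees.append(DependencyTree(sid, tokens, head, deprel))
        tokens, head, deprel, sent_id = [], {}, {}, None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            m = _SENT_ID_RE.match(line)
            if m:
                sent_id = m.group(1)
            continue
        cols = line.split("\t")
        if len(cols) == 1:  # tolerate space-separated test snippets
            cols = line.split()
        if len(cols) < 8:
            raise ParseError(f"line {lineno}: expected >= 8 columns, got {len(cols)}")
        try:
            idx = int(cols[0])
            hd = int(cols[6])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer ID/HEAD ({exc})") from None
        tokens.append(Token(index=idx, form=cols[1], lemma=cols[2], pos=cols[4]))
        head[idx] = hd
        deprel[idx] = cols[7]
    flush()
    return trees


def write_conll(trees: Sequence[DependencyTree], stream: IO[str]) -> None:
    for tree in trees:
        stream.write(f"# sent_id = {tree.sentence_id}\n")
        for tok in tree.tokens:
            stream.write(
                "\t".join(
                    [
                        str(tok.index),
                        tok.form,
                        tok.lemma,
                        tok.pos,
                        tok.pos,
                        "_",
                        str(tree.head[tok.index]),
                        tree.deprel.get(tok.index, "_"),
                    ]
                )
                + "\n"
            )
        stream.write("\n")


# ---------------------------------------------------------------------
# PAS TSV
# ---------------------------------------------------------------------

def read_pas(
    stream: IO[str] | Iterable[str],
    sentence_lengths: dict[str, int] | None = None,
) -> list[PASGraph]:
    """Parse 4-column PAS TSV lines into per-sentence graphs.

    Duplicate edges are collapsed; output order follows first appearance
    of each sentence id, and the per-sentence edge set is independent of
    line order.  ``sentence_lengths`` enables index range checking.
    """
    grouped: dict[str, set[tuple[int, int, str]]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ParseError(f"line {lineno}: expected 4 columns, got {len(cols)}")
        sid, pred_s, arg_s, role = cols
        try:
            pred, arg = int(pred_s), int(arg_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer index") from None
        grouped.setdefault(sid, set()).add((pred, arg, role))
    graphs = []
    for sid, edges in grouped.items():
        n = sentence_lengths.get(sid) if sentence_lengths else None
        graphs.append(PASGraph(sid, edges, n_tokens=n))
    return graphs


def write_pas(graphs: Sequence[PASGraph], stream: IO[str]) -> None:
    for graph in graphs:
        for pred, arg, role in sorted(graph.edges):
            stream.write(f"{graph.sentence_id}\t{pred}\t{arg}\t{role}\n")


# ---------------------------------------------------------------------
# BioNLP standoff
# ---------------------------------------------------------------------

_T_LINE_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_E_LINE_RE = re.compile(r"^(E\d+)\t(.*)$")


@dataclass
class EntityAnnotation:
    annotation_id: str
    entity_type: str
    char_start: int
    char_end: int
    surface: str


def read_standoff(
    text_stream: IO[str],
    ann_stream: IO[str] | Iterable[str],
    label_set: LabelSet,
    strict: bool = True,
) -> tuple[str, list[TriggerAnnotation], list[EntityAnnotation]]:
    """Split T-lines into triggers (type in ``label_set``) and entities.

    E-lines are validated for dangling T references and kept only as
    metadata.  Surface strings are cross-checked against offsets; a
    mismatch is an error in strict mode, a warning otherwise.
    """
    text = text_stream.read()
    triggers: list[TriggerAnnotation] = []
    entities: list[EntityAnnotation] = []
    t_ids: set[str] = set()
    e_lines: list[tuple[str, str]] = []
    for lineno, raw in enumerate(ann_stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        m = _T_LINE_RE.match(line)
        if m:
            tid, ttype, start_s, end_s, surface = m.groups()
            start, end = int(start_s), int(end_s)
            expected = text[start:end]
            if expected != surface:
                msg = (
                    f"line {lineno}: surface {surface!r} does not match "
                    f"text[{start}:{end}] = {expected!r}"
                )
                if strict:
                    raise ParseError(msg)
                warnings.warn(msg, stacklevel=2)
            t_ids.add(tid)
            if ttype in label_set and ttype != LabelSet.NONE:
                triggers.append(
                    TriggerAnnotation(tid, ttype, start, end, surface=surface)
                )
            else:
                entities.append(EntityAnnotation(tid, ttype, start, end, surface))
            continue
        m = _E_LINE_RE.match(line)
        if m:
            e_lines.append((m.group(1), m.group(2)))
            continue
        if line.startswith(("A", "M", "R", "*", "N")):  # other standoff line kinds
            continue
        raise ParseError(f"line {lineno}: unrecognized annotation line {line!r}")
    for eid, body in e_lines:
        for part in body.split():
            _, _, ref = part.partition(":")
            if ref.startswith("T") and ref not in t_ids:
                raise ParseError(f"{eid}: reference to undefined annotation {ref}")
    return text, triggers, entities


def write_standoff(
    predictions: Sequence[tuple[str, int, int]],
    text: str,
    stream: IO[str],
) -> None:
    """Emit (label, start, end) predictions as sequentially numbered T-lines."""
    seen: set[tuple[str, int, int]] = set()
    counter = 0
    for label, start, end in predictions:
        if label == LabelSet.NONE:
            raise ValueError("cannot write a NONE prediction")
        triple = (label, start, end)
        if triple in seen:
            warnings.warn(f"duplicate prediction {triple} dropped", stacklevel=2)
            continue
        seen.add(triple)
        counter += 1
        stream.write(f"T{counter}\t{label} {start} {end}\t{text[start:end]}\n")


# ---------------------------------------------------------------------
# corpus container
# ---------------------------------------------------------------------

@dataclass
class Document:
    doc_id: str
    text: str
    trees: list[DependencyTree]
    pas_graphs: dict[str, PASGraph] = field(default_factory=dict)
    triggers: list[TriggerAnnotation] = field(default_factory=list)
    entities: list = field(default_factory=list)

    def pas_for(self, sentence_id: str) -> PASGraph:
        graph = self.pas_graphs.get(sentence_id)
        return graph if graph is not None else PASGraph(sentence_id, [])

    def token_labels(self, label_set: LabelSet) -> dict[str, list[int]]:
        """Per-sentence integer label per token (NONE = 0) from annotations."""
        labels = {t.sentence_id: [0] * len(t) for t in self.trees}
        for ann in self.triggers:
            for sid, idx_list in self._locate(ann):
                for i in idx_list:
                    labels[sid][i - 1] = label_set.index(ann.label)
        return labels

    def _locate(self, ann: TriggerAnnotation):
        for tree in self.trees:
            hits = align_span(self.text, tree.tokens, ann.char_start, ann.char_end, strict=False)
            if hits:
                ann.sentence_id = tree.sentence_id
                ann.token_indices = hits
                yield tree.sentence_id, hits
                return
        raise AlignmentError(
            f"{self.doc_id}: annotation {ann.annotation_id} aligns to no sentence"
        )


@dataclass
class Corpus:
    documents: list[Document]
    label_set: LabelSet

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def sentences(self):
        for doc in self.documents:
            for tree in doc.trees:
                yield doc, tree


def infer_token_offsets(text: str, trees: Sequence[DependencyTree]) -> list[DependencyTree]:
    """Attach character offsets by scanning token forms through ``text``.

    Tokens are assumed to occur in order; the scan is whitespace-robust.
    """
    cursor = 0
    out = []
    for tree in trees:
        tokens = []
        for tok in tree.tokens:
            pos = text.find(tok.form, cursor)
            if pos < 0:
                raise AlignmentError(
                    f"{tree.sentence_id}: token {tok.form!r} not found in text"
                )
            tokens.append(
                Token(tok.index, tok.form, tok.lemma, tok.pos, pos, pos + len(tok.form))
            )
            cursor = pos + len(tok.form)
        out.append(DependencyTree(tree.sentence_id, tokens, tree.head, tree.deprel))
    return out


def load_corpus(directory: str | Path, label_set: LabelSet, strict: bool = True) -> Corpus:
    directory = Path(directory)
    documents = []
    for txt_path in sorted(directory.glob("*.txt")):
        doc_id = txt_path.stem
        text = txt_path.read_text()
        with open(directory / f"{doc_id}.conll") as fh:
            trees = read_conll(fh)
        trees = infer_token_offsets(text, trees)
        lengths = {t.sentence_id: len(t) for t in trees}
        pas_path = directory / f"{doc_id}.pas.tsv"
        pas_graphs: dict[str, PASGraph] = {}
        if pas_path.exists():
            with open(pas_path) as fh:
                pas_graphs = {g.sentence_id: g for g in read_pas(fh, lengths)}
        triggers: list[TriggerAnnotation] = []
        entities: list = []
        ann_path = directory / f"{doc_id}.ann"
        if ann_path.exists():
            with open(txt_path) as t_fh, open(ann_path) as a_fh:
                _, triggers, entities = read_standoff(t_fh, a_fh, label_set, strict=strict)
        doc = Document(doc_id, text, trees, pas_graphs, triggers, entities)
        for ann in doc.triggers:  # resolve sentence / token alignment eagerly
            list(doc._locate(ann))
        documents.append(doc)
    return Corpus(documents, label_set)


def save_corpus(corpus: Corpus, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text)
        with open(directory / f"{doc.doc_id}.conll", "w") as fh:
            write_conll(doc.trees, fh)
        with open(directory / f"{doc.doc_id}.pas.tsv", "w") as fh:
            write_pas(
                [doc.pas_graphs[sid] for sid in sorted(doc.pas_graphs)], fh
            )
        with open(directory / f"{doc.doc_id}.ann", "w") as fh:
            counter = 0
            for ann in doc.triggers:
                counter += 1
                fh.write(
                    f"T{counter}\t{ann.label} {ann.char_start} {ann.char_end}"
                    f"\t{doc.text[ann.char_start:ann.char_end]}\n"
                )
            for ent in doc.entities:
                counter += 1
                fh.write(
                    f"T{counter}\t{ent.entity_type} {ent.char_start} {ent.char_end}"
                    f"\t{ent.surface}\n"
                )
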