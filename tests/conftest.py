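import numpy as np
import pytest

from treetrigger import (
    AttentionParams,
    CellParams,
    DependencyTree,
    LabelSet,
    PASGraph,
    SynthConfig,
    Token,
    TreeEncoderParams,
)
from treetrigger.autodiff import Tensor


def make_tokens(forms, text=None):
    tokens = []
    pos = 0
    for i, form in enumerate(forms):
        tokens.append(Token(i + 1, form, form, "NN", pos, pos + len(form)))
        pos += len(form) + 1
    return tokens


def chain_tree(n, sentence_id="chain"):
    """Path tree token i's head is i+1; the last token is the root, so
    post-order visits 1, 2, ..., n like a left-to-right sequence."""
    tokens = make_tokens([f"w{i}" for i in range(1, n + 1)])
    head = {i: i + 1 for i in range(1, n)}
    head[n] = 0
    return DependencyTree(sentence_id, tokens, head)


def star_tree(n_leaves, sentence_id="star"):
    tokens = make_tokens([f"w{i}" for i in range(1, n_leaves + 2)])
    head = {1: 0}
    head.update({i: 1 for i in range(2, n_leaves + 2)})
    return DependencyTree(sentence_id, tokens, head)


def scalar_cell(w=1.0, u=1.0, b=0.0):
    """d_x = d_h = 1 cell with every gate sharing the same scalars."""
    return CellParams(
        W={g: Tensor(np.array([[w]])) for g in "fiou"},
        U={g: Tensor(np.array([[u]])) for g in "fiou"},
        b={g: Tensor(np.array([b])) for g in "fiou"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def label_set():
    return LabelSet(["Binding", "Regulation", "Phosphorylation"])


@pytest.fixture
def tiny_config():
    return SynthConfig(n_sentences=12, seed=7, embedding_dim=8, sentences_per_doc=4)


@pytest.fixture
def small_tree():
    #       3(root)
    #      /  \
    #     1    4
    #          |
    #          5 ... plus 2 under 1
    tokens = make_tokens(["a", "b", "c", "d", "e"])
    head = {1: 3, 2: 1, 3: 0, 4: 3, 5: 4}
    return DependencyTree("s1", tokens, head)


@pytest.fixture
def small_pas():
    return PASGraph("s1", [(3, 1, "arg1"), (3, 4, "arg2"), (4, 5, "arg1")], n_tokens=5)
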