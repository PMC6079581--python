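"""Tokenisation, stopword filtering and serial numbering.

Every scorer in the package consumes the same canonical :class:`TermSequence`:
an ordered list of terms, each carrying the 1-based *serial number* of its
position in the original sentence.  Serial numbers are assigned at
tokenisation time and are never renumbered — stopword filtering removes
tokens but survivors keep their original serials, so downstream tie-breaking
on serial distance reflects true sentence distance.

Tokenisers are pluggable: the bundled default splits on whitespace and
punctuation, which suffices for pre-segmented Chinese text and for Western
languages.  External segmenters can be registered at run time via
:func:`register_tokenizer`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional

from .errors import ConfigError, ParseError
from .syntactic import DependencyTree, DepNode

__all__ = [
    "Token",
    "TermSequence",
    "tokenize",
    "preprocess",
    "register_tokenizer",
    "read_conllu",
    "load_stopwords",
]


@dataclass(frozen=True)
class Token:
    """One term with its 1-based position in the original sentence."""

    surface: str
    serial: int
    pos_tag: Optional[str] = None
    is_content: bool = True

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("Token surface must be non-empty")
        if self.serial < 1:
            raise ValueError("Token serial must be >= 1")


@dataclass(frozen=True)
class TermSequence:
    """Ordered, serial-numbered terms of one text."""

    tokens: tuple[Token, ...] = ()
    source_id: str = ""

    def __post_init__(self) -> None:
        serials = [t.serial for t in self.tokens]
        if any(b <= a for a, b in zip(serials, serials[1:])):
            raise ValueError("serials must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    @property
    def serials(self) -> list[int]:
        return [t.serial for t in self.tokens]


# --------------------------------------------------------------------------
# tokenisers

_WORD_RE = re.compile(r"\w+", re.UNICODE)


def _whitespace_tokenizer(raw_text: str) -> list[str]:
    # \w covers CJK ideographs, so pre-segmented Chinese survives intact
    return _WORD_RE.findall(raw_text)


_TOKENIZERS: dict[str, Callable[[str], list[str]]] = {
    "whitespace": _whitespace_tokenizer,
}


def register_tokenizer(tokenizer_id: str, fn: Callable[[str], list[str]]) -> None:
    """Register an external segmenter under ``tokenizer_id``."""
    _TOKENIZERS[tokenizer_id] = fn


def tokenize(raw_text: str, tokenizer_id: str = "whitespace",
             source_id: str = "") -> TermSequence:
    """Segment ``raw_text`` and assign serial numbers 1..n in reading order."""
    try:
        fn = _TOKENIZERS[tokenizer_id]
    except KeyError:
        raise ConfigError(
            f"unknown tokenizer {tokenizer_id!r}; known: {sorted(_TOKENIZERS)}"
        ) from None
    surfaces = fn(raw_text)
    tokens = tuple(Token(s, i + 1) for i, s in enumerate(surfaces))
    return TermSequence(tokens, source_id=source_id)


def preprocess(seq: TermSequence, stopwords: Iterable[str] = (),
               content_pos: Optional[set[str]] = None) -> TermSequence:
    """Drop stopword tokens; survivors keep their original serials.

    ``content_pos``, when given, additionally keeps only tokens whose POS tag
    is in the set (content-word filtering; off by default because tags are
    usually absent for raw text).
    """
    stop = set(stopwords)
    kept = []
    for t in seq.tokens:
        if t.surface in stop:
            continue
        if content_pos is not None and t.pos_tag not in content_pos:
            continue
        kept.append(replace(t, is_content=True))
    return TermSequence(tuple(kept), source_id=seq.source_id)


def load_stopwords(path) -> set[str]:
    """One term per line, UTF-8; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


# --------------------------------------------------------------------------
# CoNLL-U

def read_conllu(path) -> list[DependencyTree]:
    """Read dependency trees from a CoNLL-U file (standard 10-column dialect).

    Multiword-token ranges (``1-2``) and empty nodes (``1.1``) are skipped;
    comment lines start with ``#``; sentences are blank-line separated.
    Malformed head indices (out of range, self-loop, cycle) raise
    :class:`ParseError` naming the offending line.
    """
    sentences: list[DependencyTree] = []
    rows: list[tuple[int, list[str]]] = []  # (line_no, columns)

    def flush() -> None:
        if not rows:
            return
        nodes = []
        serials = set()
        for line_no, cols in rows:
            try:
                serial = int(cols[0])
                head = int(cols[6])
            except ValueError:
                raise ParseError(f"line {line_no}: non-integer ID or HEAD") from None
            nodes.append(DepNode(serial=serial, surface=cols[1],
                                 pos_tag=cols[3] if cols[3] != "_" else None,
                                 head_serial=head, relation_label=cols[7]))
            serials.add(serial)
        for (line_no, _), n in zip(rows, nodes):
            if n.head_serial != 0 and n.head_serial not in serials:
                raise ParseError(f"line {line_no}: head {n.head_serial} out of range")
            if n.head_serial == n.serial:
                raise ParseError(f"line {line_no}: token is its own head")
        try:
            tree = DependencyTree(nodes)
        except ValueError as exc:
            raise ParseError(f"sentence ending at line {rows[-1][0]}: {exc}") from None
        sentences.append(tree)
        rows.clear()

    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ParseError(f"line {line_no}: expected 10 columns, got {len(cols)}")
            if "-" in cols[0] or "." in cols[0]:
                continue
            rows.append((line_no, cols))
    flush()
    return sentences
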