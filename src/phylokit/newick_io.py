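"""Newick format: tokenizer, recursive-descent parser and serializer.

A Newick file holds one or more semicolon-terminated statements.  Nested
parentheses become child clades; a ``label:length`` suffix after a group
names the internal clade or — when the label is numeric and the dialect says
so — records its confidence (bootstrap supports are conventionally written in
the internal-label slot).  Quoted labels use single quotes with a doubled
quote as escape; bracketed comments are skipped (one level of nesting is
supported); whitespace outside quotes is insignificant.

Underscores in unquoted labels are preserved verbatim by default: round-trip
fidelity trumps the older underscore-means-space convention, which is offered
as a dialect flag instead.
"""

from __future__ import annotations

import dataclasses
import warnings

from .treemodel import Clade, NegativeBranchLengthWarning, Tree


class NewickError(ValueError):
    """Malformed Newick data; the message reports the offending position."""


@dataclasses.dataclass
class NewickDialect:
    """Parsing/serialization conventions.

    A dialect fully determines the parse of any valid statement — there is no
    data-dependent switching.
    """

    #: Interpret a purely numeric, unquoted internal label as a confidence
    #: value (e.g. bootstrap support) rather than a name.
    internal_labels_as_confidence: bool = True
    #: Convert underscores in unquoted labels to spaces on read (older
    #: convention; off by default for round-trip fidelity).
    underscore_to_space: bool = False


DEFAULT_DIALECT = NewickDialect()

_STRUCTURAL = set("()[],;:'")


def tokenize(text):
    """Yield (kind, value, position) tokens.

    Kinds: one of the punctuation characters ``( ) , ; :``, ``"label"``
    (unquoted run) or ``"quoted"`` (quote marks stripped, escapes resolved).
    Comments in square brackets (one nesting level or more) are skipped.
    """
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[":
            depth, j = 1, i + 1
            while j < n and depth:
                if text[j] == "[":
                    depth += 1
                elif text[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise NewickError(f"unterminated comment starting at position {i}")
            i = j
            continue
        if ch in "(),;:":
            yield (ch, ch, i)
            i += 1
            continue
        if ch == "'":
            j = i + 1
            buf = []
            while True:
                if j >= n:
                    raise NewickError(f"unterminated quote starting at position {i}")
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        buf.append("'")
                        j += 2
                        continue
                    j += 1
                    break
                buf.append(text[j])
                j += 1
            yield ("quoted", "".join(buf), i)
            i = j
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in _STRUCTURAL:
            j += 1
        yield ("label", text[i:j], i)
        i = j


def _is_number(text):
    try:
        float(text)
        return True
    except ValueError:
        return False


class _Parser:
    """Recursive-descent parser over a token list (iterative recursion on
    the parenthesis structure, so deeply nested trees cannot overflow the
    interpreter stack)."""

    def __init__(self, tokens, text_length, dialect, clade_factory=Clade):
        self.tokens = tokens
        self.pos = 0
        self.end = text_length
        self.dialect = dialect
        self.clade_factory = clade_factory

    def peek(self):
        if self.pos < len(self.tokens):
            return self.tokens[self.pos]
        return ("end", "", self.end)

    def take(self):
        token = self.peek()
        self.pos += 1
        return token

    def at_end(self):
        return self.pos >= len(self.tokens)

    def parse_statement(self):
        clade = self.parse_clade()
        kind, _, pos = self.take()
        if kind != ";":
            raise NewickError(f"missing ';' at end of statement (position {pos})")
        return Tree(root=clade, rooted=False)

    def parse_clade(self):
        # explicit stack instead of recursion: each frame is the list of
        # children collected so far for one open parenthesis
        stack = []
        while True:
            kind, _, _ = self.peek()
            if kind == "(":
                self.take()
                stack.append([])
                continue
            clade = self.parse_leaf_or_close(stack)
            while stack:
                kind, _, pos = self.peek()
                if kind == ",":
                    self.take()
                    stack[-1].append(clade)
                    break  # back to parsing the next sibling
                if kind == ")":
                    self.take()
                    stack[-1].append(clade)
                    children = stack.pop()
                    clade = self.finish_clade(children)
                    continue
                raise NewickError(
                    f"expected ',' or ')' at position {pos} (unbalanced parentheses?)"
                )
            else:
                return clade

    def parse_leaf_or_close(self, stack):
        kind, _, pos = self.peek()
        if kind == ")":
            # empty subtree before the ')': a bare unnamed clade
            if not stack:
                raise NewickError(f"unbalanced ')' at position {pos}")
            return self.finish_clade(None)
        return self.finish_clade(None)

    def finish_clade(self, children):
        """Read the optional label and branch length following a subtree."""
        clade = self.clade_factory()
        if children is not None:
            clade.clades = children
        label = None
        quoted = False
        kind, value, _ = self.peek()
        if kind in ("label", "quoted"):
            self.take()
            label = value
            quoted = kind == "quoted"
        kind, _, _ = self.peek()
        if kind == ":":
            self.take()
            kind, value, pos = self.take()
            if kind not in ("label",) or not _is_number(value):
                raise NewickError(f"invalid branch length {value!r} at position {pos}")
            clade.branch_length = float(value)
            if clade.branch_length < 0:
                warnings.warn(
                    f"negative branch length {value} at position {pos}",
                    NegativeBranchLengthWarning,
                    stacklevel=4,
                )
        if label is not None:
            if (
                children is not None
                and not quoted
                and self.dialect.internal_labels_as_confidence
                and _is_number(label)
            ):
                clade.confidence = float(label)
            else:
                if not quoted and self.dialect.underscore_to_space:
                    label = label.replace("_", " ")
                clade.name = label
        return clade


def parse_newick(text, dialect=None, clade_factory=Clade):
    """Parse a single semicolon-terminated Newick statement into a Tree."""
    dialect = dialect or DEFAULT_DIALECT
    tokens = list(tokenize(text))
    if not tokens:
        raise NewickError("no Newick statement found (empty input)")
    parser = _Parser(tokens, len(text), dialect, clade_factory)
    tree = parser.parse_statement()
    if not parser.at_end():
        _, value, pos = parser.peek()
        raise NewickError(f"unexpected trailing data {value!r} at position {pos}")
    return tree


def parse(handle, dialect=None, clade_factory=Clade):
    """Iteratively parse an open handle; yield one Tree per statement.

    Lazy: nothing is read until the first tree is requested, and parse
    errors are reported with the 1-based statement index.
    """
    dialect = dialect or DEFAULT_DIALECT
    text = handle.read()
    tokens = list(tokenize(text))
    parser = _Parser(tokens, len(text), dialect, clade_factory)
    statement = 0
    while not parser.at_end():
        statement += 1
        try:
            yield parser.parse_statement()
        except NewickError as err:
            raise NewickError(f"statement {statement}: {err}") from None


# ---------------------------------------------------------------------------
# Serialization

def format_number(value):
    """Shortest decimal that round-trips; integral values print as integers."""
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(float(value))


def quote_label(name):
    """Quote a label only when it contains structural characters, brackets,
    quotes or whitespace (minimal quoting)."""
    if name == "":
        return ""
    if any(ch in _STRUCTURAL or ch in "[]{}\"" or ch.isspace() for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def serialize_newick(tree, dialect=None, length_format=None):
    """Serialize one tree as a Newick statement (with trailing ';').

    ``length_format`` is an optional printf-style format for branch lengths
    (e.g. ``"%1.5f"``); the default emits the shortest round-tripping
    decimal.  When the dialect maps internal labels to confidences, an
    unnamed internal clade with a confidence writes it in the label slot.
    """
    dialect = dialect or DEFAULT_DIALECT
    fmt_len = (lambda x: length_format % x) if length_format else format_number

    def render(clade):
        # iterative post-order rendering to avoid recursion limits
        parts = {}
        for node in _postorder_clades(clade):
            if node.clades:
                inner = "(" + ",".join(parts.pop(id(c)) for c in node.clades) + ")"
            else:
                inner = ""
            label = ""
            if node.name is not None:
                label = quote_label(node.name)
                # a numeric internal name must be quoted, or it would be
                # re-read as a confidence value under the default dialect
                if (
                    node.clades
                    and dialect.internal_labels_as_confidence
                    and label == node.name
                    and _is_number(node.name)
                ):
                    label = "'" + node.name + "'"
            elif (
                node.clades
                and node.confidence is not None
                and dialect.internal_labels_as_confidence
            ):
                label = format_number(node.confidence)
            text = inner + label
            if node.branch_length is not None:
                text += ":" + fmt_len(node.branch_length)
            parts[id(node)] = text
        return parts[id(clade)]

    return render(tree.root) + ";"


def _postorder_clades(root):
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            stack.extend((c, False) for c in reversed(node.clades))


def write(trees, handle, dialect=None, length_format=None):
    """Write trees one statement per line; return the number written."""
    count = 0
    for tree in trees:
        handle.write(serialize_newick(tree, dialect, length_format) + "\n")
        count += 1
    return count
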