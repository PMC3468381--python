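"""Unified tree I/O: read, parse, write, convert and per-tree formatting.

All parsers return the common :class:`~phylokit.treemodel.Tree` type and all
writers accept it, so any two registered formats can be converted with a
single call.  Format names ("newick", "nexus", "phyloxml") are explicit and
case-insensitive — file extensions are never used for detection.  The
registry is pluggable: :func:`register_format` adds (or atomically replaces)
a format without disturbing the existing ones.

Sources and sinks may be file paths or already-open stream-like objects.
Streams are consumed exactly once and never seeked; writing to a path
truncates an existing file.
"""

from __future__ import annotations

import contextlib
import io
import logging

from . import newick_io, nexus_io, phyloxml_io
from .treemodel import Tree

logger = logging.getLogger(__name__)

_registry = {}


def register_format(name, parser, writer):
    """Register (or replace) a format.

    ``parser(handle)`` must yield Tree objects; ``writer(trees, handle)``
    must write them and return the count.
    """
    _registry[name.lower()] = (parser, writer)


def registered_formats():
    return sorted(_registry)


def _lookup(name):
    if not isinstance(name, str):
        raise TypeError("format name must be a string")
    try:
        return _registry[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown format {name!r}; registered formats: "
            f"{', '.join(registered_formats())}"
        ) from None


@contextlib.contextmanager
def _as_handle(source, mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source
    else:
        with open(source, mode, encoding="utf-8") as handle:
            yield handle


def parse(source, fmt):
    """Iteratively parse a file or handle; yield each tree it contains."""
    parser, _ = _lookup(fmt)

    def generate():
        with _as_handle(source) as handle:
            yield from parser(handle)

    return generate()


def read(source, fmt):
    """Parse a file containing exactly one tree and return it.

    A source with no trees or with several trees is an error (use
    :func:`parse` to iterate over a multi-tree file).
    """
    trees = parse(source, fmt)
    first = next(trees, None)
    if first is None:
        raise ValueError(f"no trees found in {fmt} input")
    if next(trees, None) is not None:
        raise ValueError(
            f"multiple trees found in {fmt} input; use parse() to iterate over them"
        )
    return first


def write(trees, sink, fmt, **kwargs):
    """Write a tree or sequence of trees; return the number written.

    Input trees are never mutated.
    """
    if isinstance(trees, Tree):
        trees = [trees]
    _, writer = _lookup(fmt)
    with _as_handle(sink, "w") as handle:
        count = writer(trees, handle, **kwargs)
    logger.info("wrote %d tree(s) in %s format", count, fmt)
    return count


def convert(source, in_fmt, sink, out_fmt, **kwargs):
    """Convert between two tree file formats with a single call.

    Equivalent to ``write(parse(source, in_fmt), sink, out_fmt)``; returns
    the number of trees converted.  Annotations with no representation in
    the output format are narrowed away silently (the common core — topology,
    names, branch lengths, one confidence per clade — always survives).
    """
    return write(parse(source, in_fmt), sink, out_fmt, **kwargs)


def format_tree(tree, fmt, **kwargs):
    """Serialize one tree as a string — identical bytes to :func:`write` on
    an in-memory sink."""
    buffer = io.StringIO()
    write(tree, buffer, fmt, **kwargs)
    return buffer.getvalue()


# built-in formats --------------------------------------------------------

register_format("newick", newick_io.parse, newick_io.write)
register_format("nexus", nexus_io.parse, nexus_io.write)
register_format("phyloxml", phyloxml_io.parse, phyloxml_io.write)
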