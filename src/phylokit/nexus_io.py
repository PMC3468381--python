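"""NEXUS format: reader and writer for the TREES block.

Only the TREES block is interpreted; every other block (DATA, CHARACTERS,
TAXA, ...) is skipped verbatim, since this toolkit is scoped to trees.  A
TRANSLATE table, when present, is applied to terminal labels only.  A leading
``[&R]`` / ``[&U]`` comment on a tree statement records rootedness.  Keywords
are case-insensitive.  Quoted labels follow the single-quote conventions
shared with the Newick tokenizer (one tokenizer, two grammars).  Comments in
square brackets support one level of nesting.
"""

from __future__ import annotations

import re

from . import newick_io


class NexusError(ValueError):
    """Malformed NEXUS data."""


def _split_commands(text):
    """Split NEXUS text into ';'-terminated commands, honoring quotes and
    bracketed comments; yields each command's raw text (comments kept, so
    rootedness annotations like [&R] survive)."""
    buf = []
    i, n = 0, len(text)
    depth = 0
    in_quote = False
    while i < n:
        ch = text[i]
        buf.append(ch)
        if in_quote:
            if ch == "'":
                if i + 1 < n and text[i + 1] == "'":
                    buf.append("'")
                    i += 1
                else:
                    in_quote = False
        elif ch == "'":
            in_quote = True
        elif ch == "[":
            depth += 1
        elif ch == "]":
            if depth > 0:
                depth -= 1
        elif ch == ";" and depth == 0:
            command = "".join(buf[:-1]).strip()
            if command:
                yield command
            buf = []
        i += 1
    tail = "".join(buf).strip()
    if tail:
        yield tail


def _first_word(command):
    match = re.match(r"\s*([A-Za-z#][A-Za-z0-9_.#]*)", _strip_comments(command))
    return match.group(1).lower() if match else ""


def _strip_comments(text):
    out = []
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if in_quote:
            out.append(ch)
            if ch == "'":
                in_quote = False  # doubled quotes re-enter immediately below
        elif ch == "'" and depth == 0:
            out.append(ch)
            in_quote = True
        elif ch == "[":
            depth += 1
        elif ch == "]":
            if depth > 0:
                depth -= 1
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def _parse_translate(body):
    """Parse the entries of a TRANSLATE command into a token->name mapping."""
    table = {}
    tokens = [
        (kind, value)
        for kind, value, _ in newick_io.tokenize(body)
        if kind in ("label", "quoted", ",")
    ]
    entry = []
    for kind, value in tokens + [(",", ",")]:
        if kind == ",":
            if entry:
                if len(entry) != 2:
                    raise NexusError(f"malformed translate entry: {entry!r}")
                token, name = entry
                if token in table:
                    raise NexusError(f"duplicate translate token {token!r}")
                table[token] = name
                entry = []
        else:
            entry.append(value)
    return table


_TREE_RE = re.compile(
    r"\s*tree\s+(?:\*\s*)?(?:'(?P<quoted>(?:[^']|'')*)'|(?P<plain>[^=\s\[\]';]+))"
    r"\s*(?:\[[^\]]*\]\s*)*=",
    re.IGNORECASE | re.DOTALL,
)
_ROOTED_RE = re.compile(r"\s*\[\s*&\s*([RU])\s*\]", re.IGNORECASE)


def _parse_tree_command(command, translate, dialect=None):
    match = _TREE_RE.match(command)
    if not match:
        raise NexusError(f"malformed tree statement: {command[:60]!r}")
    if match.group("quoted") is not None:
        name = match.group("quoted").replace("''", "'")
    else:
        name = match.group("plain")
    newick_part = command[match.end():]
    rooted = False
    while True:
        match = _ROOTED_RE.match(newick_part)
        if not match:
            break
        rooted = match.group(1).upper() == "R"
        newick_part = newick_part[match.end():]
    try:
        tree = newick_io.parse_newick(newick_part.strip() + ";", dialect=dialect)
    except newick_io.NewickError as err:
        raise NexusError(f"malformed tree statement {name!r}: {err}") from None
    tree.name = name
    tree.rooted = rooted
    if translate:
        for leaf in tree.get_terminals():
            if leaf.name in translate:
                leaf.name = translate[leaf.name]
    return tree


def parse(handle, dialect=None):
    """Yield one Tree per ``tree NAME = ...;`` statement in the TREES block.

    Raises on a missing ``#NEXUS`` header; a file without a TREES block
    yields nothing (that is not an error).
    """
    text = handle.read()
    head = text.lstrip("﻿ \t\r\n")
    if not head.lower().startswith("#nexus"):
        raise NexusError("not a NEXUS file: missing #NEXUS header")
    body = head[len("#nexus"):]
    in_trees = False
    translate = {}
    for command in _split_commands(body):
        word = _first_word(command)
        if word == "begin":
            block = _strip_comments(command).split()
            in_trees = len(block) > 1 and block[1].lower() == "trees"
        elif word in ("end", "endblock"):
            in_trees = False
        elif in_trees and word == "translate":
            stripped = _strip_comments(command)
            body_part = re.sub(r"^\s*translate\s*", "", stripped, flags=re.IGNORECASE)
            translate = _parse_translate(body_part)
        elif in_trees and word == "tree":
            yield _parse_tree_command(command, translate, dialect)


def write(trees, handle, dialect=None):
    """Write a #NEXUS document with a single TREES block; returns the count.

    Trees are named ``tree1..treeN`` unless they carry a name.  Rootedness is
    recorded as a [&R]/[&U] comment.  No translate table is emitted (valid
    per the standard, and simpler to round-trip).
    """
    handle.write("#NEXUS\n")
    handle.write("begin trees;\n")
    count = 0
    for i, tree in enumerate(trees, start=1):
        name = tree.name or f"tree{i}"
        flag = "[&R]" if tree.rooted else "[&U]"
        statement = newick_io.serialize_newick(tree, dialect)
        handle.write(f"  tree {newick_io.quote_label(name)} = {flag} {statement}\n")
        count += 1
    handle.write("end;\n")
    return count
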