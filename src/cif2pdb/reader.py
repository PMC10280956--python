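"""mmCIF (PDBx/mmCIF) tokenizer and category extractor.

This module reads CIF 1.1 syntax and materializes only the categories the
converter needs.  Every value is kept as its original string — numbers are
never parsed here — so the downstream fixed-width formatter can reproduce
the input text verbatim.

Gzip-compressed input is detected by magic bytes and decompressed
transparently.  Only the first ``data_`` block of a file is read; files
distributed by the PDB contain exactly one.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import CifParseError, InputError

logger = logging.getLogger(__name__)

# token kinds
VALUE = "value"
TAG = "tag"
LOOP_MARKER = "loop_marker"
DATA_MARKER = "data_marker"
STOP_MARKER = "stop_marker"

_GZIP_MAGIC = b"\x1f\x8b"


class CifToken(NamedTuple):
    """One lexical token.  ``text`` never includes quote/semicolon delimiters.

    A NamedTuple rather than a dataclass: a large structure produces
    millions of tokens and construction cost dominates parsing time.
    """

    text: str
    kind: str
    line: int = 0


@dataclass
class CifTable:
    """One parsed category: ordered item names plus rows of raw strings.

    The placeholder values ``.`` (inapplicable) and ``?`` (unknown) are kept
    verbatim; interpreting them is the writer's job.
    """

    category: str
    columns: list[str]
    rows: list[tuple[str, ...]] = field(default_factory=list)

    def col_index(self, item: str) -> int | None:
        try:
            return self.columns.index(item)
        except ValueError:
            return None

    def column(self, item: str) -> list[str] | None:
        """All values of one item, or ``None`` if the item is absent."""
        idx = self.col_index(item)
        if idx is None:
            return None
        return [row[idx] for row in self.rows]

    def first(self, item: str, default: str = "") -> str:
        """Value of ``item`` in the first row (key-value categories have one row)."""
        idx = self.col_index(item)
        if idx is None or not self.rows:
            return default
        return self.rows[0][idx]


def open_input(path) -> io.TextIOBase:
    """Open a plain or gzip-compressed mmCIF file as a text stream.

    Compression is detected from the leading magic bytes, not the file name,
    so ``foo.cif`` containing gzip data still decompresses.
    """
    try:
        raw = open(path, "rb")
    except OSError as exc:
        raise InputError(f"cannot open input file {path}: {exc}") from exc
    magic = raw.read(2)
    raw.seek(0)
    if magic == _GZIP_MAGIC:
        stream: io.BufferedIOBase = gzip.GzipFile(fileobj=raw)  # type: ignore[assignment]
    else:
        stream = raw
    return io.TextIOWrapper(stream, encoding="utf-8", errors="strict")


def tokenize(stream) -> list[CifToken]:
    """Lex a CIF character stream into tokens.

    Handles ``#`` comments, single- and double-quoted values (a quote closes
    only when followed by whitespace or end of line), semicolon-delimited
    multiline values (``;`` in column 1 opens and closes), and the
    case-insensitive ``data_``/``loop_``/``stop_`` keywords.

    Accepts either an open text stream or a string (convenient in tests).
    """
    if isinstance(stream, str):
        text = stream
    else:
        try:
            text = stream.read()
        except UnicodeDecodeError as exc:
            raise CifParseError(
                f"input is not decodable text at byte offset {exc.start}: {exc.reason}"
            ) from exc
        except OSError as exc:  # e.g. corrupt gzip stream
            raise CifParseError(f"cannot read input: {exc}") from exc
    nul = text.find("\x00")
    if nul != -1:
        raise CifParseError(f"binary content in input (NUL byte at offset {nul})")

    tokens: list[CifToken] = []
    lines = text.split("\n")
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith(";"):
            opened = i
            block = [line[1:]]
            i += 1
            while i < n and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            if i >= n:
                raise CifParseError(
                    f"unterminated semicolon-delimited value opened at line {opened + 1}"
                )
            tokens.append(CifToken("\n".join(block), VALUE, opened + 1))
            _scan_line(lines[i][1:], i + 1, tokens)
            i += 1
        else:
            _scan_line(line, i + 1, tokens)
            i += 1
    return tokens


def _classify(word: str, lineno: int) -> CifToken:
    c = word[0]
    if c == "_":
        return CifToken(word, TAG, lineno)
    if c in "dDlLsS":  # only then pay for the case-insensitive keyword check
        lw = word.lower()
        if lw.startswith("data_"):
            return CifToken(word, DATA_MARKER, lineno)
        if lw == "loop_":
            return CifToken(word, LOOP_MARKER, lineno)
        if lw == "stop_":
            return CifToken(word, STOP_MARKER, lineno)
    return CifToken(word, VALUE, lineno)


def _scan_line(s: str, lineno: int, tokens: list[CifToken]) -> None:
    if not s:
        return
    # fast path: no quoting or comment characters on this line
    if "'" not in s and '"' not in s and "#" not in s:
        for word in s.split():
            tokens.append(_classify(word, lineno))
        return
    j = 0
    n = len(s)
    while j < n:
        c = s[j]
        if c in " \t":
            j += 1
            continue
        if c == "#":
            break
        if c in "'\"":
            k = j + 1
            while True:
                k = s.find(c, k)
                if k == -1:
                    raise CifParseError(f"unterminated quoted value at line {lineno}")
                # a quote terminates only when followed by whitespace or EOL
                if k + 1 >= n or s[k + 1] in " \t":
                    break
                k += 1
            tokens.append(CifToken(s[j + 1 : k], VALUE, lineno))
            j = k + 1
        else:
            k = j
            while k < n and s[k] not in " \t":
                k += 1
            tokens.append(_classify(s[j:k], lineno))
            j = k
    return


def _split_tag(text: str) -> tuple[str, str]:
    """``_atom_site.group_PDB`` -> (``_atom_site``, ``group_PDB``)."""
    cat, sep, item = text.partition(".")
    if not sep:
        return text, ""
    return cat, item


def parse_categories(tokens, wanted) -> dict[str, CifTable]:
    """Extract the ``wanted`` categories from a token stream.

    Both loop_ form and key-value form populate a :class:`CifTable`
    (key-value form yields a one-row table).  Categories not in ``wanted``
    are streamed past without storing their rows.  Only the first ``data_``
    block is read.  Returned keys are lower-cased category names including
    the leading underscore (e.g. ``"_atom_site"``).
    """
    wanted_lc = {w.lower() for w in wanted}
    tables: dict[str, CifTable] = {}
    # key-value accumulation: cat_lc -> (display name, item -> value, item order)
    kv: dict[str, tuple[str, dict[str, str], list[str]]] = {}
    i = 0
    n = len(tokens)
    in_data = False
    while i < n:
        tok = tokens[i]
        if tok.kind == DATA_MARKER:
            if in_data:
                logger.warning(
                    "multiple data_ blocks in input; only the first is read"
                )
                break
            in_data = True
            i += 1
        elif tok.kind == LOOP_MARKER:
            loop_line = tok.line
            i += 1
            tag_toks: list[CifToken] = []
            while i < n and tokens[i].kind == TAG:
                tag_toks.append(tokens[i])
                i += 1
            if not tag_toks:
                raise CifParseError(f"loop_ without item tags at line {loop_line}")
            cat, _ = _split_tag(tag_toks[0].text)
            items: list[str] = []
            for t in tag_toks:
                tcat, item = _split_tag(t.text)
                if tcat.lower() != cat.lower():
                    raise CifParseError(
                        f"loop_ at line {loop_line} mixes categories "
                        f"{cat} and {tcat}"
                    )
                if item in items:
                    raise CifParseError(
                        f"duplicate item {t.text} in loop_ header at line {t.line}"
                    )
                items.append(item)
            ncol = len(items)
            store = cat.lower() in wanted_lc
            values: list[str] = []
            count = 0
            while i < n and tokens[i].kind == VALUE:
                if store:
                    values.append(tokens[i].text)
                count += 1
                i += 1
            if count % ncol != 0:
                raise CifParseError(
                    f"loop_ for {cat} at line {loop_line}: {count} values "
                    f"not divisible by {ncol} columns"
                )
            if store:
                if cat.lower() in tables:
                    logger.warning(
                        "category %s appears more than once; keeping the first", cat
                    )
                else:
                    rows = [
                        tuple(values[r : r + ncol]) for r in range(0, len(values), ncol)
                    ]
                    tables[cat.lower()] = CifTable(cat, items, rows)
        elif tok.kind == TAG:
            if i + 1 >= n or tokens[i + 1].kind != VALUE:
                raise CifParseError(
                    f"item {tok.text} at line {tok.line} has no value"
                )
            cat, item = _split_tag(tok.text)
            if cat.lower() in wanted_lc:
                display, d, order = kv.setdefault(cat.lower(), (cat, {}, []))
                if item in d:
                    logger.warning(
                        "item %s.%s given twice; keeping the last value", cat, item
                    )
                else:
                    order.append(item)
                d[item] = tokens[i + 1].text
            i += 2
        else:
            # stray value or stop_ outside any loop: skip
            i += 1

    for cat_lc, (display, d, order) in kv.items():
        if cat_lc in tables:
            logger.warning(
                "category %s given in both loop_ and key-value form; "
                "keeping the loop_ form",
                display,
            )
            continue
        tables[cat_lc] = CifTable(display, list(order), [tuple(d[k] for k in order)])
    return tables
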