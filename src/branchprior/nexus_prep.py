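"""Post-process Nexus character matrices for ML phylogeny programs.

Matrices downloaded from TreeBASE routinely need three repairs before a
standard ML program will accept them:

* ambiguity sets written in brace notation (``{A,C}``) are replaced by the
  single IUPAC nucleotide code for exactly that base set (``M``);
* blocks not associated with the alignment (TREES, NOTES, ASSUMPTIONS,
  MRBAYES, ...) are stripped, keeping TAXA and CHARACTERS/DATA;
* a named gene can be excised from a concatenated matrix using the CHARSET
  partitions of a SETS/ASSUMPTIONS block.

The document model is deliberately textual: blocks are kept as raw text and
edits are minimal substitutions, so a file that needs no repair passes
through byte-identical.  Charset-name matching against gene synonyms is
fuzzy by necessity (gene naming in public repositories is inconsistent):
a charset matches when its name contains, or is contained in, any synonym,
case-insensitively.  Excision can therefore pick the wrong partition on
adversarial inputs — outputs carry a ``flags`` list and files that could
not be excised are flagged for manual review rather than guessed at.

Coordinates: charset ranges are 1-based inclusive (the Nexus convention,
with ``a-b\\3`` codon steps honored); all internal column indices are
0-based half-open.  :func:`ranges_to_indices` is the single conversion
point.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import re

__all__ = [
    "NexusDocument",
    "read_nexus",
    "write_nexus",
    "normalize_ambiguities",
    "strip_blocks",
    "excise_gene",
    "parse_charsets",
    "parse_matrix",
    "count_taxa",
    "IUPAC_CODES",
    "ranges_to_indices",
]

logger = logging.getLogger(__name__)


class NexusPrepError(ValueError):
    pass


# base set -> IUPAC code, all 11 multi-base nucleotide codes
IUPAC_CODES = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

ALIGNMENT_BLOCKS = frozenset({"taxa", "characters", "data"})


@dataclasses.dataclass(frozen=True)
class Block:
    name: str  # lower-cased block name
    text: str  # raw text, "BEGIN ...;" through "END;"


@dataclasses.dataclass(frozen=True)
class NexusDocument:
    """A Nexus file as an ordered list of raw blocks plus processing flags."""

    blocks: tuple[Block, ...]
    flags: tuple[str, ...] = ()

    def get(self, *names: str) -> Block | None:
        wanted = {n.lower() for n in names}
        for b in self.blocks:
            if b.name in wanted:
                return b
        return None

    @property
    def alignment_block(self) -> Block:
        b = self.get("characters", "data")
        if b is None:
            raise NexusPrepError("no alignment block (CHARACTERS or DATA) present")
        return b


_BLOCK_RE = re.compile(
    r"begin\s+(\w+)\s*;.*?\bend\s*;", re.IGNORECASE | re.DOTALL
)


def read_nexus(source: str | os.PathLike) -> NexusDocument:
    """Parse a Nexus file (or raw text) into its blocks."""
    src = os.fspath(source) if isinstance(source, os.PathLike) else source
    if isinstance(src, str) and "\n" not in src and os.path.exists(src):
        with open(src) as fh:
            text = fh.read()
    else:
        text = str(src)
    if not text.lstrip().lower().startswith("#nexus"):
        raise NexusPrepError("not a Nexus file: missing #NEXUS header")
    blocks = tuple(
        Block(m.group(1).lower(), m.group(0)) for m in _BLOCK_RE.finditer(text)
    )
    if not blocks:
        raise NexusPrepError("no Nexus blocks found")
    return NexusDocument(blocks)


def write_nexus(doc: NexusDocument, path: str | os.PathLike | None = None) -> str:
    text = "#NEXUS\n\n" + "\n\n".join(b.text for b in doc.blocks) + "\n"
    if path is not None:
        with open(os.fspath(path), "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------- matrix


@dataclasses.dataclass(frozen=True)
class Matrix:
    """Parsed character matrix: ordered taxa and per-taxon column tokens.

    A brace ambiguity set such as ``{A,C}`` is one column token; plain
    characters are single-character tokens.
    """

    ntax: int
    nchar: int
    taxa: tuple[str, ...]
    rows: dict[str, list[str]]
    format_line: str | None

    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


_DIM_RE = re.compile(
    r"dimensions\b([^;]*);", re.IGNORECASE | re.DOTALL
)
_MATRIX_RE = re.compile(r"\bmatrix\b(.*?);", re.IGNORECASE | re.DOTALL)
_FORMAT_RE = re.compile(r"\bformat\b([^;]*);", re.IGNORECASE | re.DOTALL)


def _tokenize_sequence(seq: str, taxon: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "{":
            j = seq.find("}", i)
            if j < 0:
                raise NexusPrepError(f"unclosed brace in sequence of taxon {taxon!r}")
            tokens.append(seq[i : j + 1])
            i = j + 1
        else:
            tokens.append(ch)
            i += 1
    return tokens


def _split_row(line: str) -> tuple[str, str] | None:
    line = line.strip()
    if not line:
        return None
    if line[0] in "'\"":
        quote = line[0]
        end = line.find(quote, 1)
        if end < 0:
            raise NexusPrepError(f"unterminated quoted taxon name: {line[:40]!r}")
        return line[1:end], line[end + 1 :]
    parts = line.split(None, 1)
    if len(parts) == 1:
        return parts[0], ""
    return parts[0], parts[1]


def parse_matrix(doc: NexusDocument) -> Matrix:
    """Parse the CHARACTERS/DATA block matrix, de-interleaving if needed."""
    block = doc.alignment_block
    dim = _DIM_RE.search(block.text)
    if dim is None:
        raise NexusPrepError("alignment block has no DIMENSIONS statement")
    dims = dict(
        (k.lower(), int(v))
        for k, v in re.findall(r"(ntax|nchar)\s*=\s*(\d+)", dim.group(1), re.IGNORECASE)
    )
    if "nchar" not in dims:
        raise NexusPrepError("DIMENSIONS lacks NCHAR")
    fmt = _FORMAT_RE.search(block.text)
    format_line = fmt.group(0) if fmt else None
    mat = _MATRIX_RE.search(block.text)
    if mat is None:
        raise NexusPrepError("alignment block has no MATRIX")
    taxa: list[str] = []
    rows: dict[str, list[str]] = {}
    for line in mat.group(1).splitlines():
        line = re.sub(r"\[[^\]]*\]", "", line)  # bracket comments
        parsed = _split_row(line)
        if parsed is None:
            continue
        taxon, seq = parsed
        if taxon not in rows:
            taxa.append(taxon)
            rows[taxon] = []
        rows[taxon].extend(_tokenize_sequence(seq, taxon))
    if not rows:
        raise NexusPrepError("empty MATRIX")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise NexusPrepError(f"ragged matrix: row lengths {sorted(lengths)}")
    ncols = lengths.pop()
    nchar = dims["nchar"]
    if ncols != nchar:
        raise NexusPrepError(f"matrix has {ncols} columns but NCHAR={nchar}")
    ntax = dims.get("ntax", len(taxa))
    if ntax != len(taxa):
        raise NexusPrepError(f"matrix has {len(taxa)} rows but NTAX={ntax}")
    return Matrix(ntax=ntax, nchar=nchar, taxa=tuple(taxa), rows=rows, format_line=format_line)


def count_taxa(source: str | os.PathLike) -> int:
    """Sequence count of a Nexus matrix: the matrix row count (NTAX checked)."""
    return parse_matrix(read_nexus(source)).ntax


# ------------------------------------------------- ambiguity normalization

_BRACE_RE = re.compile(r"\{([^{}]*)\}")


def _brace_to_iupac(content: str, context: str) -> str:
    letters = [ch for ch in content if ch not in ", \t"]
    upper = {ch.upper() for ch in letters}
    upper = {("T" if ch == "U" else ch) for ch in upper}
    if not upper or not upper <= set("ACGT"):
        raise NexusPrepError(
            f"ambiguity set {{{content}}} at {context} contains non-nucleotide symbols"
        )
    if len(upper) == 1:
        code = next(iter(upper))
    else:
        code = IUPAC_CODES[frozenset(upper)]
    return code.lower() if letters and all(ch.islower() for ch in letters if ch.isalpha()) else code


def normalize_ambiguities(doc: NexusDocument) -> NexusDocument:
    """Replace every brace ambiguity set with its single-letter IUPAC code.

    Purely textual: a document without brace sets is returned unchanged
    (byte-identical), so the operation is idempotent.  Raises
    :class:`NexusPrepError` naming taxon and column if a brace set contains
    a non-nucleotide symbol.
    """
    block = doc.alignment_block
    if "{" not in block.text:
        return doc
    # locate each brace set's taxon and column for error reporting
    matrix = parse_matrix(doc)
    for taxon in matrix.taxa:
        for col0, token in enumerate(matrix.rows[taxon]):
            if token.startswith("{"):
                _brace_to_iupac(token[1:-1], f"taxon {taxon!r}, column {col0 + 1}")
    new_text = _BRACE_RE.sub(lambda m: _brace_to_iupac(m.group(1), "matrix"), block.text)
    n = len(_BRACE_RE.findall(block.text))
    logger.info("normalized %d ambiguity sets to IUPAC codes", n)
    blocks = tuple(
        Block(b.name, new_text) if b is block else b for b in doc.blocks
    )
    return NexusDocument(blocks, doc.flags)


# ------------------------------------------------------------ block strip


def strip_blocks(doc: NexusDocument, keep_sets: bool = False) -> NexusDocument:
    """Drop every block not associated with the alignment.

    Retains TAXA and CHARACTERS/DATA (and SETS/ASSUMPTIONS when
    ``keep_sets`` is set, for later gene excision); TREES, NOTES, MRBAYES
    and the rest are removed.
    """
    keep = set(ALIGNMENT_BLOCKS)
    if keep_sets:
        keep |= {"sets", "assumptions"}
    kept = tuple(b for b in doc.blocks if b.name in keep)
    if not any(b.name in ("characters", "data") for b in kept):
        raise NexusPrepError("no alignment block (CHARACTERS or DATA) present")
    dropped = [b.name for b in doc.blocks if b.name not in keep]
    if dropped:
        logger.info("stripped non-alignment blocks: %s", ", ".join(dropped))
    return NexusDocument(kept, doc.flags)


# ------------------------------------------------------------- excision

_CHARSET_RE = re.compile(
    r"charset\s+('[^']+'|\S+)\s*=\s*([^;]+);", re.IGNORECASE | re.DOTALL
)


def parse_charsets(doc: NexusDocument) -> dict[str, list[tuple[int, int, int]]]:
    """Charset name -> list of (start, end, step), 1-based inclusive."""
    out: dict[str, list[tuple[int, int, int]]] = {}
    for block in doc.blocks:
        if block.name not in ("sets", "assumptions"):
            continue
        for m in _CHARSET_RE.finditer(block.text):
            name = m.group(1).strip("'")
            ranges = []
            for tok in m.group(2).split():
                rm = re.fullmatch(r"(\d+)(?:-(\d+|\.))?(?:\\(\d+))?", tok)
                if rm is None:
                    raise NexusPrepError(f"cannot parse charset range {tok!r} in {name!r}")
                start = int(rm.group(1))
                end = -1 if rm.group(2) == "." else int(rm.group(2) or start)
                step = int(rm.group(3) or 1)
                ranges.append((start, end, step))
            out[name] = ranges
    return out


def ranges_to_indices(
    ranges: list[tuple[int, int, int]], nchar: int
) -> list[int]:
    """Convert 1-based inclusive (start, end, step) ranges to sorted 0-based indices.

    ``end == -1`` means "to the last character".  The single audited
    coordinate conversion of this module.
    """
    cols: set[int] = set()
    for start, end, step in ranges:
        if end == -1:
            end = nchar
        if not (1 <= start <= end <= nchar):
            raise NexusPrepError(
                f"charset range {start}-{end} outside alignment of {nchar} characters"
            )
        cols.update(range(start - 1, end, step))
    return sorted(cols)


def _charset_matches(charset_name: str, names: list[str]) -> bool:
    cs = charset_name.lower()
    for name in names:
        n = name.lower()
        if n in cs or cs in n:
            return True
    return False


def excise_gene(
    doc: NexusDocument, gene_name: str, synonyms: tuple[str, ...] = ()
) -> NexusDocument:
    """Reduce a concatenated matrix to the columns of one gene's charset.

    The first charset whose name matches the gene name or a synonym
    (case-insensitive containment, either direction) is used.  When no
    charset matches, the document is returned whole with a ``cannot excise``
    flag appended — such files need manual review, not silent guessing.
    """
    names = [gene_name, *synonyms]
    charsets = parse_charsets(doc)
    match = next((cs for cs in charsets if _charset_matches(cs, names)), None)
    if match is None:
        reason = f"cannot excise {gene_name!r}: no matching charset"
        logger.warning("%s (available: %s)", reason, sorted(charsets) or "none")
        return dataclasses.replace(doc, flags=doc.flags + (reason,))
    matrix = parse_matrix(doc)
    cols = ranges_to_indices(charsets[match], matrix.nchar)
    if not cols:
        raise NexusPrepError(f"charset {match!r} selects no columns")
    logger.info(
        "excising gene %r via charset %r: %d of %d columns",
        gene_name, match, len(cols), matrix.nchar,
    )
    new_blocks: list[Block] = []
    for b in doc.blocks:
        if b.name in ("sets", "assumptions"):
            continue  # partitions are invalid after column excision
        if b is not doc.alignment_block:
            new_blocks.append(b)
            continue
        new_blocks.append(_rebuild_alignment(b.name, matrix, cols))
    return NexusDocument(tuple(new_blocks), doc.flags)


def _format_taxon(name: str) -> str:
    return f"'{name}'" if re.search(r"[\s(){}\[\]]", name) else name


def _rebuild_alignment(block_name: str, matrix: Matrix, cols: list[int]) -> Block:
    fmt = matrix.format_line or "FORMAT DATATYPE=DNA MISSING=? GAP=-;"
    fmt = re.sub(r"\binterleave(\s*=\s*\w+)?\b", "", fmt, flags=re.IGNORECASE)
    fmt = re.sub(r"\s+", " ", fmt).replace(" ;", ";").strip()
    width = max(len(_format_taxon(t)) for t in matrix.taxa) + 2
    lines = [
        f"BEGIN {block_name.upper()};",
        f"    DIMENSIONS NTAX={matrix.ntax} NCHAR={len(cols)};",
        f"    {fmt}",
        "    MATRIX",
    ]
    for taxon in matrix.taxa:
        seq = "".join(matrix.rows[taxon][c] for c in cols)
        lines.append(f"    {_format_taxon(taxon):<{width}}{seq}")
    lines += ["    ;", "END;"]
    return Block(block_name, "\n".join(lines))
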