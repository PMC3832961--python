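"""Readers/writers for FASTA/FASTQ/Newick/panel-TSV and canonical in-memory records.

Coordinates are 0-based, half-open throughout the package; strand is
encoded as ``"+"``/``"-"``. Lowercase input is normalized to uppercase and
``U`` is mapped to ``T`` (with a warning) on ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "DNA_CODES",
    "IUPAC_SETS",
    "PROTEIN_CODES",
    "Alignment",
    "PanelForgeError",
    "ParseError",
    "ValidationError",
    "PanelRow",
    "PanelTable",
    "PhyloTree",
    "SequenceRecord",
    "read_alignment",
    "read_panel",
    "read_sequences",
    "read_tree",
    "reverse_complement",
    "write_panel",
    "write_sequences",
]


class PanelForgeError(Exception):
    """Base class for package errors."""


class ParseError(PanelForgeError):
    """Raised when an input file cannot be parsed."""


class ValidationError(PanelForgeError):
    """Raised when parsed content violates a domain invariant."""


#: Expansion sets of the 15 IUPAC nucleotide codes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse of :data:`IUPAC_SETS`: expansion set -> single-letter code.
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

DNA_CODES = frozenset(IUPAC_SETS)
PROTEIN_CODES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_residues(
    residues: str, alphabet: str, *, allow_gap: bool, context: str
) -> None:
    if alphabet == "dna":
        allowed = DNA_CODES
    elif alphabet == "protein":
        allowed = PROTEIN_CODES
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    for pos, ch in enumerate(residues):
        if ch == "-":
            if allow_gap:
                continue
            raise ValidationError(
                f"{context}: gap character at position {pos} outside an alignment"
            )
        if ch not in allowed:
            raise ValidationError(
                f"{context}: illegal {alphabet} character {ch!r} at position {pos}"
            )


@dataclass
class SequenceRecord:
    """A named residue string over a declared alphabet.

    ``residues`` are stored uppercase; ``qualities`` (Phred+33 scores, as
    integers) are retained when the record came from FASTQ.
    """

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""
    qualities: list[int] | None = None
    allow_gap: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if self.alphabet == "dna" and "U" in self.residues:
            warnings.warn(
                f"record {self.id!r}: 'U' mapped to 'T'", stacklevel=2
            )
            self.residues = self.residues.replace("U", "T")
        _validate_residues(
            self.residues,
            self.alphabet,
            allow_gap=self.allow_gap,
            context=f"record {self.id!r}",
        )
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValidationError(
                f"record {self.id!r}: quality length != sequence length"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """Equal-length gapped rows; the gap character is ``-``."""

    rows: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("alignment needs >=2 rows")
        n = len(self.rows[0].residues)
        for row in self.rows:
            if len(row.residues) != n:
                raise ValidationError(
                    f"ragged alignment: record {row.id!r} has length "
                    f"{len(row.residues)}, expected {n}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate ids in alignment: {dup}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, rid: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def column(self, i: int) -> list[str]:
        return [r.residues[i] for r in self.rows]


class PhyloTree:
    """Thin wrapper around a rooted/unrooted dendropy tree with branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate leaf labels: {dup}")
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
            elif edge.length < 0:
                raise ValidationError("negative branch length")
        if n_missing:
            warnings.warn(
                f"{n_missing} branch length(s) missing; defaulted to 0",
                stacklevel=2,
            )

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class PanelRow:
    """One primer pair of a panel table."""

    group_id: str
    fwd_seq: str
    rev_seq: str
    tm_min_c: float
    tm_max_c: float
    expected_len_bp: int

    def __post_init__(self) -> None:
        for name in ("fwd_seq", "rev_seq"):
            seq = getattr(self, name).upper()
            setattr(self, name, seq)
            bad = [ch for ch in seq if ch not in DNA_CODES]
            if bad:
                raise ValidationError(
                    f"group {self.group_id}: invalid IUPAC character {bad[0]!r} "
                    f"in {name}"
                )
            if not seq:
                raise ValidationError(f"group {self.group_id}: empty {name}")
        if self.tm_min_c > self.tm_max_c:
            raise ValidationError(
                f"group {self.group_id}: tm_min_c > tm_max_c"
            )
        if self.expected_len_bp <= 0:
            raise ValidationError(
                f"group {self.group_id}: expected_len_bp must be > 0"
            )


PANEL_COLUMNS = (
    "group_id",
    "fwd_seq",
    "rev_seq",
    "tm_min_c",
    "tm_max_c",
    "expected_len_bp",
)


@dataclass
class PanelTable:
    """A primer panel: one row per pair, unique group ids."""

    rows: list[PanelRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        gids = [r.group_id for r in self.rows]
        if len(set(gids)) != len(gids):
            dup = sorted({g for g in gids if gids.count(g) > 1})
            raise ValidationError(f"duplicate group ids in panel: {dup}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, group_id: str) -> PanelRow:
        for r in self.rows:
            if r.group_id == group_id:
                return r
        raise KeyError(group_id)


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna", ".faa", ".mfa"}:
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    raise ParseError(f"{path}: empty file")


def read_sequences(
    path: str | Path, alphabet: str = "dna", *, allow_gap: bool = False
) -> list[SequenceRecord]:
    """Read FASTA or FASTQ into validated records, preserving file order.

    FASTQ (DNA only) retains Phred+33 qualities. Duplicate ids and illegal
    characters raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path)
    if fmt == "fastq" and alphabet != "dna":
        raise ValidationError("FASTQ input is only supported for DNA")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ValidationError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            quals = rec.letter_annotations.get("phred_quality")
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    alphabet=alphabet,
                    description=rec.description[len(rec.id) :].strip(),
                    qualities=list(quals) if quals is not None else None,
                    allow_gap=allow_gap,
                )
            )
    except ValueError as exc:  # malformed FASTQ etc.
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (or FASTQ when every record has qualities)."""
    records = list(records)
    path = Path(path)
    as_fastq = bool(records) and all(r.qualities is not None for r in records)
    with open(path, "w") as fh:
        for rec in records:
            header = f"{rec.id} {rec.description}".strip()
            if as_fastq:
                qual = "".join(chr(q + 33) for q in rec.qualities)
                fh.write(f"@{header}\n{rec.residues}\n+\n{qual}\n")
            else:
                fh.write(f">{header}\n{rec.residues}\n")


def read_alignment(path: str | Path, alphabet: str = "dna") -> Alignment:
    """Read a gapped FASTA alignment; enforces >=2 equal-length rows."""
    records = read_sequences(path, alphabet, allow_gap=True)
    if len(records) < 2:
        raise ValidationError("alignment needs >=2 rows")
    return Alignment(rows=records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_sequences(aln.rows, path)


def read_tree(path: str | Path) -> PhyloTree:
    """Read a Newick tree; missing branch lengths default to 0 with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"{path}: duplicate leaf labels") from exc
        raise ParseError(f"{path}: {exc}") from exc
    return PhyloTree(tree)


def tree_from_newick(newick: str) -> PhyloTree:
    """Parse a Newick string (convenience mirror of :func:`read_tree`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError("duplicate leaf labels") from exc
        raise ParseError(str(exc)) from exc
    return PhyloTree(tree)


def read_panel(path: str | Path) -> PanelTable:
    """Read a panel TSV with the fixed six-column header."""
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = tuple(header_line.split("\t"))
        if header != PANEL_COLUMNS:
            unknown = [c for c in header if c not in PANEL_COLUMNS]
            if unknown:
                raise ValidationError(f"{path}: unknown column(s) {unknown}")
            raise ValidationError(
                f"{path}: expected columns {list(PANEL_COLUMNS)}, got {list(header)}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PANEL_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected 6 fields")
            try:
                rows.append(
                    PanelRow(
                        group_id=fields[0],
                        fwd_seq=fields[1],
                        rev_seq=fields[2],
                        tm_min_c=float(fields[3]),
                        tm_max_c=float(fields[4]),
                        expected_len_bp=int(fields[5]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PanelTable(rows=rows)


def write_panel(panel: PanelTable, path: str | Path) -> None:
    """Write a panel TSV with canonical formatting (floats to 2 decimals)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for r in panel.rows:
            fh.write(
                f"{r.group_id}\t{r.fwd_seq}\t{r.rev_seq}\t"
                f"{r.tm_min_c:.2f}\t{r.tm_max_c:.2f}\t{r.expected_len_bp}\n"
            )
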