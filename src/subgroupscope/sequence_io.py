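"""Sequence, alignment, substitution-matrix and domain-span I/O.

The package analyses chimeric bacterial transcription regulators that fuse an
N-terminal winged helix-turn-helix (wHTH) DNA-binding domain to a C-terminal
aminotransferase-like (AAT, fold type-I PLP-dependent) effector domain.  This
module provides the containers and readers every later stage consumes:
protein sequences, multiple sequence alignments, NCBI-format substitution
matrices, and per-sequence domain coordinate tables used to split each
chimera into its two domains.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_ALLOWED = set(AMINO_ACIDS) | {GAP, UNKNOWN}
# rare codes (B/Z/J ambiguity, U/O non-standard, * stop) collapse to unknown
_TO_UNKNOWN = str.maketrans({c: UNKNOWN for c in "BZJUO*"})


class NotGenuineChimera(ValueError):
    """Rejection: sequence lacks the required HTH-before-AAT architecture.

    Distinct from I/O errors so callers can count rejected sequences
    instead of aborting.
    """


def _normalize_residues(residues: str) -> str:
    s = residues.upper().replace(".", GAP).translate(_TO_UNKNOWN)
    bad = set(s) - _ALLOWED
    if bad:
        raise ValueError(f"invalid residue characters: {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence (possibly gapped) with a unique identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        object.__setattr__(self, "residues", _normalize_residues(self.residues))

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows with unique ids."""

    rows: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise ValueError("alignment has no rows")
        n = len(rows[0].residues)
        for r in rows:
            if len(r.residues) != n:
                raise ValueError(
                    f"ragged alignment: row {r.id!r} has length "
                    f"{len(r.residues)}, expected {n}"
                )
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row ids: {dup}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Row subset in the given order; column space unchanged."""
        return Alignment(tuple(self.row(i) for i in ids))

    def to_array(self) -> np.ndarray:
        """(n_rows, n_cols) array of single characters."""
        return np.array([list(r.residues) for r in self.rows])


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue scoring table (NCBI convention)."""

    alphabet: str
    scores: np.ndarray  # square, aligned to `alphabet`

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        n = len(self.alphabet)
        if scores.shape != (n, n):
            raise ValueError("score table shape does not match alphabet")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix is not symmetric")
        std = [i for i, c in enumerate(self.alphabet) if c in AMINO_ACIDS]
        if std:
            sub = scores[np.ix_(std, std)]
            if np.any(np.diag(sub) < sub.max(axis=1)):
                warnings.warn(
                    "some diagonal entries are not row maxima; "
                    "unusual for a standard substitution matrix",
                    stacklevel=2,
                )

    def index(self, residue: str) -> int:
        i = self.alphabet.find(residue)
        if i < 0:
            raise KeyError(f"residue {residue!r} not in matrix alphabet")
        return i

    def score(self, a: str, b: str) -> float:
        """Score of a residue pair; unknown 'X' scores 0 if absent."""
        try:
            return float(self.scores[self.index(a), self.index(b)])
        except KeyError:
            if UNKNOWN in (a, b):
                return 0.0
            raise

    def encoder(self) -> np.ndarray:
        """128-entry lookup: ord(char) -> alphabet index, -1 if absent."""
        enc = np.full(128, -1, dtype=np.int64)
        for i, c in enumerate(self.alphabet):
            enc[ord(c)] = i
        return enc


@dataclass(frozen=True)
class DomainSpan:
    """Half-open [start, end) span of one domain within one sequence."""

    seq_id: str
    domain_label: Literal["HTH", "AAT"]
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.domain_label not in ("HTH", "AAT"):
            raise ValueError(f"unknown domain label {self.domain_label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for {self.seq_id!r}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned (or gapped) FASTA; order preserved, ids unique."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, str(rec.seq), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = r.description if r.description.startswith(r.id) else r.id
            fh.write(f">{header}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


_ALN_FORMATS = {"fasta": "fasta", "clustal": "clustal", "stockholm": "stockholm"}


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a multiple sequence alignment ('fasta', 'clustal' or 'stockholm').

    '.' gap characters are normalized to '-'; Stockholm annotation lines
    (#=GC etc.) are ignored by the parser.  Ragged input raises with the
    offending row id.
    """
    if format not in _ALN_FORMATS:
        raise ValueError(
            f"unknown alignment format {format!r}; expected one of "
            f"{sorted(_ALN_FORMATS)}"
        )
    if format == "fasta":
        # parse row-wise ourselves so ragged input names the offending id
        rows = tuple(read_fasta(path))
    else:
        msa = AlignIO.read(str(path), _ALN_FORMATS[format])
        rows = tuple(
            SequenceRecord(rec.id, str(rec.seq), description=rec.description)
            for rec in msa
        )
    return Alignment(rows)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    if format not in _ALN_FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    if format == "fasta":
        write_fasta(aln.rows, path)
        return
    msa = AlignIO.MultipleSeqAlignment(
        [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.rows]
    )
    AlignIO.write(msa, str(path), _ALN_FORMATS[format])


def read_substitution_matrix(path: str | Path) -> SubstitutionMatrix:
    """Parse an NCBI-format substitution matrix text file.

    Format: '#' comment lines, a header row of residue letters, then one
    labeled score row per residue.  The matrix must cover the 20 standard
    amino acids and be symmetric.
    """
    path = Path(path)
    header: list[str] | None = None
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if header is None:
            if not all(len(f) == 1 for f in fields):
                raise ValueError(f"malformed matrix header in {path}")
            header = fields
            continue
        labels.append(fields[0])
        rows.append([float(x) for x in fields[1 : len(header) + 1]])
    if header is None or not rows:
        raise ValueError(f"no matrix found in {path}")
    if labels != header:
        raise ValueError(f"row labels do not match header in {path}")
    missing = sorted(set(AMINO_ACIDS) - set(header))
    if missing:
        raise ValueError(f"matrix {path} lacks standard residues: {missing}")
    scores = np.array(rows, dtype=float)
    if not np.allclose(scores, scores.T):
        ij = np.argwhere(~np.isclose(scores, scores.T))[0]
        a, b = header[ij[0]], header[ij[1]]
        raise ValueError(f"asymmetric entries in {path}: {a}/{b}")
    return SubstitutionMatrix("".join(header), scores)


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a named matrix (e.g. 'BLOSUM30', 'BLOSUM62') shipped with biotite."""
    import biotite.sequence.align as _align

    path = Path(_align.__file__).parent / "matrix_data" / f"{name.upper()}.mat"
    if not path.exists():
        raise FileNotFoundError(f"no bundled substitution matrix named {name!r}")
    return read_substitution_matrix(path)


_SPAN_HEADER = "# domain spans: 0-based, half-open [start, end)\n"


def read_domain_spans(path: str | Path) -> list[DomainSpan]:
    """Read a TSV of columns seq_id, domain_label, start, end (0-based half-open)."""
    spans: list[DomainSpan] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "seq_id":  # optional column header
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed span line: {line!r}")
            spans.append(DomainSpan(parts[0], parts[1], int(parts[2]), int(parts[3])))
    return spans


def write_domain_spans(spans: Sequence[DomainSpan], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_SPAN_HEADER)
        fh.write("seq_id\tdomain_label\tstart\tend\n")
        for s in spans:
            fh.write(f"{s.seq_id}\t{s.domain_label}\t{s.start}\t{s.end}\n")


# ---------------------------------------------------------------------------
# operations


def split_domains(
    record: SequenceRecord, spans: Sequence[DomainSpan]
) -> tuple[SequenceRecord, SequenceRecord]:
    """Split a chimeric regulator into its (HTH, AAT) domain records.

    Only sequences with exactly one HTH span followed (N-terminal first) by
    one AAT span count as genuine chimeric regulators; anything else raises
    :class:`NotGenuineChimera`.
    """
    mine = [s for s in spans if s.seq_id == record.id]
    hth = [s for s in mine if s.domain_label == "HTH"]
    aat = [s for s in mine if s.domain_label == "AAT"]
    if len(hth) != 1 or len(aat) != 1:
        raise NotGenuineChimera(
            f"{record.id!r}: requires exactly one HTH and one AAT span "
            f"(found {len(hth)} HTH, {len(aat)} AAT)"
        )
    h, a = hth[0], aat[0]
    if h.end > len(record.residues) or a.end > len(record.residues):
        raise ValueError(f"{record.id!r}: span exceeds sequence length")
    if min(h.end, a.end) > max(h.start, a.start):
        raise ValueError(f"{record.id!r}: HTH and AAT spans overlap")
    if h.start >= a.start:
        raise NotGenuineChimera(
            f"{record.id!r}: AAT domain precedes HTH; not the N-terminal "
            "HTH architecture"
        )
    return (
        replace(record, residues=record.residues[h.start : h.end], description=""),
        replace(record, residues=record.residues[a.start : a.end], description=""),
    )


def percent_identity(
    row_a: str,
    row_b: str,
    denominator: Literal["co_ungapped", "shorter_seq"] = "co_ungapped",
) -> float:
    """Fractional identity between two aligned rows.

    Identities are counted over columns where both rows are non-gap, then
    divided by either the number of such columns (``co_ungapped``) or the
    ungapped length of the shorter sequence (``shorter_seq``).
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    a = np.frombuffer(row_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.upper().encode(), dtype=np.uint8)
    gap = ord(GAP)
    both = (a != gap) & (b != gap)
    ident = int(np.sum((a == b) & both))
    if denominator == "co_ungapped":
        denom = int(both.sum())
    elif denominator == "shorter_seq":
        denom = int(min((a != gap).sum(), (b != gap).sum()))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        warnings.warn("no comparable columns; identity defined as 0.0", stacklevel=2)
        return 0.0
    return ident / denom
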