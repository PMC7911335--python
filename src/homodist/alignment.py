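"""Aligned multi-FASTA input/output and the equal-length alignment contract.

Everything downstream (pairwise distances, parsimony site scoring)
assumes a rectangular character matrix: every row has the same number of
columns and every taxon label is unique.  This module enforces that
contract at the boundary so the numeric code never has to re-check it.

Characters are normalised on read: uppercased, RNA ``U`` mapped to ``T``.
Gaps (``-``) and ``?`` are both treated as missing data downstream; any
character outside the IUPAC DNA alphabet plus ``-``/``?`` is a hard
error rather than a silently miscounted state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes, gap and explicit-missing symbols accepted in rows.
VALID_CHARS = frozenset("ACGTRYSWKMBDHVN-?")

#: Symbols carrying no state information (full {A,C,G,T} set downstream).
MISSING_CHARS = frozenset("-?N")


class AlignmentError(ValueError):
    """Raised when an input violates the alignment contract."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular, labelled DNA character matrix.

    Parameters
    ----------
    labels :
        Ordered, unique, non-empty taxon identifiers.  Input order is
        preserved because it is the tie-break reference for taxon
        ordering downstream.
    rows :
        Uppercase DNA strings over the IUPAC alphabet plus ``-``/``?``,
        all of identical length.
    """

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise AlignmentError("labels and rows differ in count")
        if len(self.labels) == 0:
            raise AlignmentError("empty alignment")
        seen: set[str] = set()
        for lab in self.labels:
            if not lab:
                raise AlignmentError("empty taxon label")
            if lab in seen:
                raise AlignmentError(f"duplicate taxon label: {lab!r}")
            seen.add(lab)
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            detail = ", ".join(
                f"{lab}={len(row)}" for lab, row in zip(self.labels, self.rows)
            )
            raise AlignmentError(f"rows have unequal lengths ({detail})")
        for lab, row in zip(self.labels, self.rows):
            bad = set(row) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"record {lab!r} contains non-IUPAC characters: "
                    f"{''.join(sorted(bad))!r}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, label: str) -> str:
        try:
            return self.rows[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def column(self, j: int) -> dict[str, str]:
        """Site ``j`` as a label -> character mapping."""
        return {lab: row[j] for lab, row in zip(self.labels, self.rows)}

    def subset(self, labels: Iterable[str]) -> "Alignment":
        """Restrict to ``labels``, keeping the given order."""
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            rows = tuple(self.rows[index[lab]] for lab in labels)
        except KeyError as exc:
            raise KeyError(f"unknown taxon label: {exc.args[0]!r}") from None
        return Alignment(labels, rows)


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta_alignment(path: Union[str, Path]) -> Alignment:
    """Read an aligned multi-FASTA file into an :class:`Alignment`.

    Rows are uppercased and ``U`` is mapped to ``T``.  Record order is
    preserved.  Raises :class:`AlignmentError` for fewer than two
    records, duplicate labels, unequal row lengths or characters outside
    the accepted alphabet.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise AlignmentError(f"no FASTA records in {path}")
    if len(records) < 2:
        raise AlignmentError(f"alignment needs >= 2 records, got {len(records)}")
    labels = tuple(rec.id for rec in records)
    rows = tuple(_normalise(str(rec.seq)) for rec in records)
    return Alignment(labels, rows)


def write_fasta_alignment(aln: Alignment, path: Union[str, Path], width: int = 60) -> None:
    """Write ``aln`` as wrapped multi-FASTA (default 60-column lines)."""
    records = [
        SeqRecord(Seq(row), id=lab, description="")
        for lab, row in zip(aln.labels, aln.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def trim_flanking_columns(aln: Alignment) -> Alignment:
    """Drop leading/trailing columns in which any row has a gap.

    Mirrors the common pre-processing step of trimming the ragged ends
    of a multiple alignment so all sequences span the same region.
    Interior gap columns are untouched.  Idempotent.  Raises
    :class:`AlignmentError` if nothing remains.
    """
    n = aln.n_sites
    start = 0
    while start < n and any(row[start] == "-" for row in aln.rows):
        start += 1
    end = n
    while end > start and any(row[end - 1] == "-" for row in aln.rows):
        end -= 1
    if end <= start:
        raise AlignmentError("alignment fully trimmed: no gap-free flank remains")
    if start == 0 and end == n:
        return aln
    return Alignment(aln.labels, tuple(row[start:end] for row in aln.rows))
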