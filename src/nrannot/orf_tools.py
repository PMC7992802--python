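"""Six-frame ORF extraction from assembled transcripts.

An ORF here is a maximal stop-free stretch in one of the six frame
translations of a transcript, optionally truncated at the transcript edges
("partial"): it need not begin with ATG and need not end at a stop codon,
which matches how fragmented de novo transcript assemblies are handled when
preparing protein evidence for spliced alignment. The standard genetic code
(table 1) is used; codons containing N or another ambiguity symbol translate
to 'X' and do not terminate an ORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MIN_LEN = 40

_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
# IUPAC nucleotide alphabet (unambiguous + ambiguity codes)
IUPAC_NT = set("ACGTURYSWKMBDHVN")


class SequenceError(ValueError):
    """Raised for transcripts containing non-IUPAC characters."""


@dataclass(frozen=True)
class OrfRecord:
    """One extracted open reading frame.

    ``frame`` is the offset (0-2) into the strand sequence (the reverse
    complement for the reverse strand); ``aa_start``/``aa_end`` are 0-based
    half-open coordinates within that frame's translation. ``complete5p`` is
    set when the ORF starts with Met or runs to the transcript edge;
    ``complete3p`` when it ends at a stop codon or the transcript edge.
    """

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int
    aa_start: int
    aa_end: int
    sequence: str
    complete5p: bool
    complete3p: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != self.aa_end - self.aa_start:
            raise ValueError("sequence length disagrees with coordinates")
        if "*" in self.sequence:
            raise ValueError("ORF contains a stop symbol")

    @property
    def header(self) -> str:
        flags = (
            ("5'complete" if self.complete5p else "5'partial")
            + ","
            + ("3'complete" if self.complete3p else "3'partial")
        )
        return f"{self.transcript_id}|{self.strand}|{self.frame}|{self.aa_start}-{self.aa_end}|{flags}"


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame; ambiguous codons become 'X', stops '*'."""
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3].upper().replace("U", "T")
        if codon in _STOPS:
            out.append("*")
        else:
            out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def _orfs_in_frame(
    transcript_id: str, strand: str, frame: int, aa: str, min_len: int
) -> Iterator[OrfRecord]:
    n = len(aa)
    start = 0
    while start < n:
        if aa[start] == "*":
            start += 1
            continue
        end = start
        while end < n and aa[end] != "*":
            end += 1
        seq = aa[start:end]
        if len(seq) >= min_len:
            yield OrfRecord(
                transcript_id=transcript_id,
                strand=strand,
                frame=frame,
                aa_start=start,
                aa_end=end,
                sequence=seq,
                complete5p=seq.startswith("M") or start == 0,
                complete3p=end < n or end == n,
            )
        start = end + 1


def extract_orfs(
    transcripts: Iterable[SeqRecord], min_len: int = DEFAULT_MIN_LEN
) -> list[OrfRecord]:
    """Extract all partial and complete ORFs of >= ``min_len`` amino acids.

    All six reading frames of every transcript are scanned; an ORF is a
    maximal stop-free stretch in a frame translation. ``min_len`` counts
    amino acids excluding any stop.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    orfs: list[OrfRecord] = []
    for rec in transcripts:
        nt = str(rec.seq).upper()
        bad = set(nt) - IUPAC_NT
        if bad:
            raise SequenceError(
                f"record {rec.id}: non-IUPAC character(s) {''.join(sorted(bad))!r}"
            )
        for strand, seq in (("+", nt), ("-", str(Seq(nt).reverse_complement()))):
            for frame in range(3):
                aa = translate_frame(seq, frame)
                orfs.extend(_orfs_in_frame(rec.id, strand, frame, aa, min_len))
    return orfs


def write_orf_fasta(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    """Write ORFs as FASTA with self-describing headers."""
    lines = []
    for orf in orfs:
        lines.append(f">{orf.header}")
        for i in range(0, len(orf.sequence), 60):
            lines.append(orf.sequence[i : i + 60])
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
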