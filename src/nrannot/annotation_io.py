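"""Readers and writers for the formats the annotation pipeline touches.

Handles GFF3 (standard three-level gene/mRNA/CDS hierarchy), the GFF dump
dialect emitted by spliced protein-to-genome aligners (GFF2-style attributes
bracketed by ``# --- START/END OF GFF DUMP ---`` lines), FASTA proteomes
(longest-isoform reduction), BUSCO ``full_table`` files and 12-column BLAST
tabular output.

Coordinates in :class:`GeneModel` are 1-based inclusive, exactly as they
appear in GFF; the only place a half-open conversion happens is inside the
interval index of :class:`AnnotationSet`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

HOMOLOGY = "homology"
TRANSCRIPT = "transcript"
EVIDENCE_TYPES = (HOMOLOGY, TRANSCRIPT)

BUSCO_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")
_STATUS_CANON = {s.lower(): s for s in BUSCO_STATUSES}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class GeneIdError(ValueError):
    """Raised when protein records carry no derivable gene identifier."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One candidate gene structure: ordered exons on one strand.

    Parameters
    ----------
    model_id:
        Unique identifier within an :class:`AnnotationSet`.
    seq_id:
        Genomic sequence (contig/scaffold) the model lies on.
    strand:
        ``'+'`` or ``'-'``.
    exons:
        Tuple of ``(start, end)`` pairs, 1-based inclusive, sorted ascending
        and non-overlapping.
    evidence:
        ``'homology'`` (protein-to-genome alignment) or ``'transcript'``
        (ORF from an assembled transcript).
    orf_len_aa:
        Predicted protein length in amino acids, ``floor(total CDS bp / 3)``.
    source_protein_id:
        Query protein for homology models, if known.
    """

    model_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    evidence: str
    orf_len_aa: int = -1
    source_protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for model {self.model_id}")
        if self.evidence not in EVIDENCE_TYPES:
            raise ValueError(f"bad evidence {self.evidence!r} for model {self.model_id}")
        if not self.exons:
            raise ValueError(f"model {self.model_id} has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"model {self.model_id}: exon start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(f"model {self.model_id}: exons overlap or are unsorted")
            prev_end = end
        if self.orf_len_aa < 0:
            object.__setattr__(self, "orf_len_aa", self.cds_length // 3)

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Gene span (first exon start, last exon end), 1-based inclusive."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def overlaps(self, other: "GeneModel") -> bool:
        """Span intersection on the same sequence and strand."""
        if self.seq_id != other.seq_id or self.strand != other.strand:
            return False
        a0, a1 = self.span
        b0, b1 = other.span
        return a0 <= b1 and b0 <= a1


class AnnotationSet:
    """A queryable collection of :class:`GeneModel` over one genome.

    The interval index maps (seq_id, strand) to an exon-level
    :class:`~intervaltree.IntervalTree`; a query returns exactly the models
    with at least one exon intersecting the requested interval.
    """

    def __init__(self, genome_id: str = "", models: Iterable[GeneModel] = ()) -> None:
        self.genome_id = genome_id
        self._models: dict[str, GeneModel] = {}
        self._exon_trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self._span_trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for m in models:
            self.add(m)

    def add(self, model: GeneModel) -> None:
        if model.model_id in self._models:
            raise ValueError(f"duplicate model_id {model.model_id!r}")
        self._models[model.model_id] = model
        key = (model.seq_id, model.strand)
        for start, end in model.exons:
            self._exon_trees[key].addi(start - 1, end, model.model_id)
        s0, s1 = model.span
        self._span_trees[key].addi(s0 - 1, s1, model.model_id)

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._models.values())

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._models

    def __getitem__(self, model_id: str) -> GeneModel:
        return self._models[model_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return sorted(self, key=lambda m: m.model_id) == sorted(other, key=lambda m: m.model_id)

    @property
    def model_ids(self) -> list[str]:
        return list(self._models)

    def models_sorted(self) -> list[GeneModel]:
        """Models in deterministic (seq_id, span start, model_id) order."""
        return sorted(self._models.values(), key=lambda m: (m.seq_id, m.span[0], m.model_id))

    def query(self, seq_id: str, strand: str, start: int, end: int) -> list[GeneModel]:
        """Models with >= 1 exon intersecting [start, end] (1-based inclusive)."""
        tree = self._exon_trees.get((seq_id, strand))
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start - 1, end)}
        return sorted((self._models[i] for i in ids), key=lambda m: m.model_id)

    def query_span(self, seq_id: str, strand: str, start: int, end: int) -> list[GeneModel]:
        """Models whose gene span intersects [start, end] (1-based inclusive)."""
        tree = self._span_trees.get((seq_id, strand))
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start - 1, end)}
        return sorted((self._models[i] for i in ids), key=lambda m: m.model_id)

    def subset(self, model_ids: Iterable[str], genome_id: str | None = None) -> "AnnotationSet":
        gid = self.genome_id if genome_id is None else genome_id
        return AnnotationSet(gid, (self._models[i] for i in model_ids))


@dataclass(frozen=True)
class BuscoRecord:
    """One row of a BUSCO ``full_table``."""

    busco_id: str
    status: str
    sequence: str | None = None
    score: float | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.status not in BUSCO_STATUSES:
            raise ValueError(f"bad BUSCO status {self.status!r}")


@dataclass(frozen=True)
class BlastHit:
    """One 12-column BLAST tabular row (outfmt 6)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("percent identity must lie in [0, 100]")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-"}


def _validate_gff_lines(path: Path, n_columns: int = 9) -> None:
    """Coordinate/strand sanity pass so errors carry line numbers.

    gffutils reports structural problems but not always the offending line;
    this cheap scan catches the malformed-coordinate and unknown-strand
    classes up front.
    """
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(f"{path}:{lineno}: expected >= 8 tab-separated columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            if cols[6] not in _STRANDS and cols[6] != ".":
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {cols[6]!r}")


def read_gff3(path: str | Path, evidence: str) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet`.

    One :class:`GeneModel` is produced per mRNA (or per top-level feature
    with CDS children); ``orf_len_aa`` is ``floor(total CDS bp / 3)``.
    mRNAs without CDS or exon children are skipped with a warning.
    """
    path = Path(path)
    _validate_gff_lines(path)
    with open(path, newline="") as fh:
        has_features = any(l.strip() and not l.startswith("#") for l in fh)
    if not has_features:
        return AnnotationSet(genome_id=path.stem)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several internal types
        raise ParseError(f"{path}: not parseable as GFF3 ({exc})") from None

    models: list[GeneModel] = []
    skipped = 0

    def build(feature_id: str, feature, parent=None) -> GeneModel | None:
        spans = sorted(
            (c.start, c.end) for c in db.children(feature, featuretype="CDS")
        )
        if not spans:
            spans = sorted(
                (c.start, c.end) for c in db.children(feature, featuretype="exon")
            )
        if not spans:
            return None
        source_protein = feature.attributes.get("source_protein", [None])[0]
        if source_protein is None and parent is not None:
            source_protein = parent.attributes.get("source_protein", [None])[0]
        return GeneModel(
            model_id=feature_id,
            seq_id=feature.seqid,
            strand=feature.strand,
            exons=tuple(spans),
            evidence=evidence,
            orf_len_aa=sum(e - s + 1 for s, e in spans) // 3,
            source_protein_id=source_protein,
        )

    mrna_parents: set[str] = set()
    for mrna in db.features_of_type(("mRNA", "transcript")):
        parents = list(db.parents(mrna, level=1))
        mrna_parents.update(p.id for p in parents)
        parent = parents[0] if len(parents) == 1 else None
        # a single-isoform mRNA is identified by its gene, so write->read
        # round-trips preserve the model id; multi-isoform genes keep
        # per-mRNA ids
        if parent is not None and sum(
            1 for c in db.children(parent, level=1, featuretype=("mRNA", "transcript"))
        ) == 1:
            feature_id = parent.id
        else:
            feature_id = mrna.id
        model = build(feature_id, mrna, parent)
        if model is None:
            skipped += 1
            logger.warning("%s: feature %s has no CDS/exon children; skipped", path, mrna.id)
        else:
            models.append(model)
    # top-level features (e.g. bare genes) carrying CDS children directly
    for gene in db.features_of_type("gene"):
        if gene.id in mrna_parents:
            continue
        model = build(gene.id, gene)
        if model is not None:
            models.append(model)
        else:
            skipped += 1
            logger.warning("%s: feature %s has no CDS/exon children; skipped", path, gene.id)

    if skipped:
        logger.warning("%s: skipped %d feature(s) without gene structure", path, skipped)
    return AnnotationSet(genome_id=path.stem, models=models)


def _phases(exons: Sequence[tuple[int, int]], strand: str) -> list[int]:
    """GFF3 CDS phase column, computed in transcription order."""
    order = range(len(exons)) if strand == "+" else range(len(exons) - 1, -1, -1)
    phases = [0] * len(exons)
    acc = 0
    for i in order:
        phases[i] = (3 - acc % 3) % 3
        acc += exons[i][1] - exons[i][0] + 1
    return phases


def write_gff3(aset: AnnotationSet, path: str | Path, source: str = "nrannot") -> None:
    """Write an :class:`AnnotationSet` as deterministic GFF3.

    Features sorted by (seq_id, span start, model_id); gene -> mRNA -> CDS
    hierarchy; re-reading reproduces the set and two writes of the same set
    are byte-identical.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    for m in aset.models_sorted():
        s0, s1 = m.span
        attrs = [f"ID={m.model_id}", f"evidence={m.evidence}"]
        if m.source_protein_id:
            attrs.append(f"source_protein={m.source_protein_id}")
        lines.append(
            "\t".join(
                [m.seq_id, source, "gene", str(s0), str(s1), ".", m.strand, ".", ";".join(attrs)]
            )
        )
        mrna_id = f"{m.model_id}.t1"
        lines.append(
            "\t".join(
                [m.seq_id, source, "mRNA", str(s0), str(s1), ".", m.strand, ".",
                 f"ID={mrna_id};Parent={m.model_id}"]
            )
        )
        for (start, end), phase in zip(m.exons, _phases(m.exons, m.strand)):
            lines.append(
                "\t".join(
                    [m.seq_id, source, "CDS", str(start), str(end), ".", m.strand,
                     str(phase), f"ID={mrna_id}.cds;Parent={mrna_id}"]
                )
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# exonerate GFF dump dialect
# ---------------------------------------------------------------------------

_DUMP_START = "# --- START OF GFF DUMP ---"
_DUMP_END = "# --- END OF GFF DUMP ---"


def _gff2_attributes(text: str) -> dict[str, str]:
    """Parse `key value ; key value` GFF2-style attribute strings."""
    attrs: dict[str, str] = {}
    for chunk in text.split(";"):
        parts = chunk.strip().split(None, 1)
        if len(parts) == 2:
            attrs[parts[0]] = parts[1].strip().strip('"')
        elif len(parts) == 1 and parts[0]:
            attrs[parts[0]] = ""
    return attrs


def read_exonerate_gff(path: str | Path, evidence: str = HOMOLOGY) -> AnnotationSet:
    """Read the GFF dump dialect of exonerate ``protein2genome`` output.

    Only ``gene`` and ``exon`` rows inside GFF dump sections are consumed;
    ``similarity``/``splice``/intron rows and free-form alignment blocks
    outside dump sections are ignored. One model is produced per ``gene``
    row; the query identifier (``sequence`` attribute) becomes
    ``source_protein_id``. A file without any dump section yields an empty
    set with a warning.
    """
    path = Path(path)
    models: list[GeneModel] = []
    seen_ids: dict[str, int] = {}
    in_dump = False
    saw_dump = False
    current: dict | None = None
    skipped = 0

    def finish() -> None:
        nonlocal current, skipped
        if current is None:
            return
        if not current["exons"]:
            skipped += 1
            logger.warning("%s: gene %s has no exon rows; skipped", path, current["model_id"])
        else:
            models.append(
                GeneModel(
                    model_id=current["model_id"],
                    seq_id=current["seq_id"],
                    strand=current["strand"],
                    exons=tuple(sorted(current["exons"])),
                    evidence=evidence,
                    orf_len_aa=sum(e - s + 1 for s, e in current["exons"]) // 3,
                    source_protein_id=current["source_protein"],
                )
            )
        current = None

    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line.startswith(_DUMP_START):
                in_dump = True
                saw_dump = True
                continue
            if line.startswith(_DUMP_END):
                finish()
                in_dump = False
                continue
            if not in_dump or not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                continue
            ftype = cols[2]
            if ftype not in ("gene", "exon"):
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            if cols[6] not in _STRANDS:
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {cols[6]!r}")
            if ftype == "gene":
                finish()
                attrs = _gff2_attributes(cols[8])
                query = attrs.get("sequence", "gene")
                base = f"{query}.g{attrs.get('gene_id', '0')}"
                n = seen_ids.get(base, 0)
                seen_ids[base] = n + 1
                model_id = base if n == 0 else f"{base}.{n + 1}"
                current = {
                    "model_id": model_id,
                    "seq_id": cols[0],
                    "strand": cols[6],
                    "source_protein": query or None,
                    "exons": [],
                }
            else:
                if current is not None:
                    current["exons"].append((start, end))
    finish()
    if not saw_dump:
        logger.warning("%s: no GFF dump section found; returning empty set", path)
    return AnnotationSet(genome_id=path.stem, models=models)


# ---------------------------------------------------------------------------
# proteome preparation
# ---------------------------------------------------------------------------


def _default_gene_of(record_id: str) -> str | None:
    """Gene id = everything before the last '.' (isoform suffix rule)."""
    head, sep, _ = record_id.rpartition(".")
    return head if sep else None


def longest_isoform_filter(
    records: Iterable[SeqRecord],
    gene_of: Callable[[str], str | None] | Mapping[str, str] | None = None,
) -> list[SeqRecord]:
    """Keep one representative record per gene: the longest isoform.

    ``gene_of`` maps a record id to its gene id; it may be a callable, a
    mapping, or None for the default isoform-suffix rule (strip the final
    dot-separated token). Ties on length are broken by the lexicographically
    smallest record id. Records with no derivable gene id raise
    :class:`GeneIdError` listing every offending id.
    """
    if gene_of is None:
        lookup: Callable[[str], str | None] = _default_gene_of
    elif callable(gene_of):
        lookup = gene_of
    else:
        mapping = gene_of
        lookup = lambda rid: mapping.get(rid)  # noqa: E731

    best: dict[str, SeqRecord] = {}
    order: list[str] = []
    orphans: list[str] = []
    for rec in records:
        gene = lookup(rec.id)
        if not gene:
            orphans.append(rec.id)
            continue
        cur = best.get(gene)
        if cur is None:
            best[gene] = rec
            order.append(gene)
        elif len(rec.seq) > len(cur.seq) or (
            len(rec.seq) == len(cur.seq) and rec.id < cur.id
        ):
            best[gene] = rec
    if orphans:
        raise GeneIdError(f"no gene id derivable for record(s): {', '.join(sorted(orphans))}")
    return [best[g] for g in order]


# ---------------------------------------------------------------------------
# BUSCO full_table
# ---------------------------------------------------------------------------


def read_busco_table(path: str | Path) -> list[BuscoRecord]:
    """Parse a BUSCO ``full_table`` TSV into :class:`BuscoRecord` rows.

    Comment lines start with '#'. Missing rows may carry only id + status;
    Duplicated genes appear on multiple rows (all are returned — presence
    queries collapse them downstream). CRLF line endings are tolerated.
    """
    path = Path(path)
    records: list[BuscoRecord] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            status = _STATUS_CANON.get(cols[1].strip().lower())
            if status is None:
                raise ParseError(f"{path}:{lineno}: unknown BUSCO status {cols[1]!r}")
            records.append(
                BuscoRecord(
                    busco_id=cols[0],
                    status=status,
                    sequence=cols[2] if len(cols) > 2 and cols[2] else None,
                    score=float(cols[3]) if len(cols) > 3 and cols[3] else None,
                    length=int(float(cols[4])) if len(cols) > 4 and cols[4] else None,
                )
            )
    return records


def write_busco_table(records: Iterable[BuscoRecord], path: str | Path) -> None:
    """Write records in BUSCO full_table layout (for fixtures and round-trips)."""
    path = Path(path)
    lines = ["# Busco id\tStatus\tSequence\tScore\tLength"]
    for r in records:
        cols = [r.busco_id, r.status]
        if r.sequence is not None:
            cols += [
                r.sequence,
                "" if r.score is None else f"{r.score:.1f}",
                "" if r.length is None else str(r.length),
            ]
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

#: outfmt-6 default column order
BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (outfmt 6) in file order."""
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        aln_len=int(cols[3]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_blast_tab(rows: Iterable[Sequence], path: str | Path) -> None:
    """Write pre-formed 12-column rows as BLAST tabular text."""
    path = Path(path)
    lines = ["\t".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")
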