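"""Seeded generators of test inputs with known ground truth.

Every other module is exercised against data built here: redundant gene-model
sets over toy genomes where the intended representative per locus is known by
construction, BUSCO full_table files realizing planted presence/absence
pattern frequencies, and bipartite BLAST tables with planted reciprocal-best
structure plus confounders (one-way bests, sub-threshold e-values, multiple
HSPs per pair).

Construction guarantees for the locus generator:

* loci are spaced at least twice the selection window size apart, so window
  coverage never mixes loci;
* every decoy's gene span is strictly nested inside the intended winner's
  span, so each window touched by the locus also touches the winner and the
  greedy selector must resolve the whole locus in the winner's favour;
* exactly one eligible model per locus attains the maximal ORF length,
  unless tie mode plants an exact tie to exercise the deterministic
  tie-breaks (the planted tie starts downstream of the winner, so the
  smaller-gene-start rule still identifies the winner).

Model coordinates, not genome sequence, drive the selector, so the toy
genomes carry no sequence; transcript fixtures for ORF extraction are
random A/C/G/T with planted composition. Regenerating with the same seed
reproduces byte-identical files.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation_io import (
    HOMOLOGY,
    TRANSCRIPT,
    AnnotationSet,
    BlastHit,
    BuscoRecord,
    GeneModel,
    write_busco_table,
    write_blast_tab,
    write_gff3,
)

DECOY_KINDS = ("short_isoform", "few_exons", "short_orf", "homology_duplicate")


# ---------------------------------------------------------------------------
# redundant locus sets
# ---------------------------------------------------------------------------


@dataclass
class LocusSpec:
    """Ground truth for one generated locus."""

    locus_id: str
    seq_id: str
    strand: str
    span: tuple[int, int]
    winner_id: str  # id after evidence prefixing (as the selector sees it)
    winner_evidence: str
    winner_orf_aa: int
    decoys: list[dict] = field(default_factory=list)


@dataclass
class FixtureManifest:
    """Bookkeeping for a generated fixture batch."""

    seed: int
    kind: str
    counts: dict = field(default_factory=dict)
    loci: list[LocusSpec] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def winner_ids(self) -> list[str]:
        return [l.winner_id for l in self.loci]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "kind": self.kind,
            "counts": self.counts,
            "loci": [asdict(l) for l in self.loci],
            "extra": self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _gene_structure(
    rng: np.random.Generator,
    start: int,
    n_exons: int,
    orf_aa: int,
    intron_lo: int,
    intron_hi: int,
) -> tuple[tuple[int, int], ...]:
    """Exons totalling exactly ``3 * orf_aa`` bp, separated by random introns."""
    total = 3 * orf_aa
    # split total into n_exons parts, each >= 3 bp
    cuts = np.sort(rng.choice(np.arange(1, total // 3), size=n_exons - 1, replace=False)) * 3
    sizes = np.diff(np.concatenate(([0], cuts, [total])))
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + int(size) - 1))
        if i < len(sizes) - 1:
            pos += int(size) + int(rng.integers(intron_lo, intron_hi + 1))
        else:
            pos += int(size)
    return tuple(exons)


def gen_locus_set(
    n_loci: int,
    seed: int,
    tie_mode: bool = False,
    window_size: int = 100,
    out_dir: str | Path | None = None,
) -> tuple[AnnotationSet, AnnotationSet, FixtureManifest]:
    """Generate redundant homology/transcript model sets with known winners.

    Returns the homology-evidence set, the transcript-evidence set and a
    manifest whose ``winner_ids`` are the ids the selector is expected to
    keep after the two sets are merged (evidence-prefixed namespace).
    With ``out_dir`` the two GFF3 files and a manifest JSON are also written.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    seq_ids = ("chr1", "chr2", "chr3")
    cursors = {s: 1000 for s in seq_ids}
    spacing = 2 * window_size + 300

    homology: list[GeneModel] = []
    transcript: list[GeneModel] = []
    manifest = FixtureManifest(seed=seed, kind="locus_set")

    def add(model: GeneModel) -> None:
        (homology if model.evidence == HOMOLOGY else transcript).append(model)

    for i in range(n_loci):
        seq_id = seq_ids[int(rng.integers(0, len(seq_ids)))]
        strand = "+" if rng.random() < 0.5 else "-"
        locus_start = cursors[seq_id]

        winner_orf = int(rng.integers(80, 201))
        winner_exons = _gene_structure(
            rng, locus_start, n_exons=int(rng.integers(3, 6)), orf_aa=winner_orf,
            intron_lo=120, intron_hi=300,
        )
        win_ev = HOMOLOGY if rng.random() < 0.5 else TRANSCRIPT
        winner = GeneModel(
            model_id=f"L{i:05d}_win",
            seq_id=seq_id,
            strand=strand,
            exons=winner_exons,
            evidence=win_ev,
            source_protein_id=f"PPA{i:05d}" if win_ev == HOMOLOGY else None,
        )
        add(winner)
        span0, span1 = winner.span
        cursors[seq_id] = span1 + spacing

        n_decoys = int(rng.integers(1, 6))
        decoys: list[dict] = []
        inner_lo, inner_hi = span0 + 3, span1 - 3

        def place(n_exons: int, orf_aa: int) -> tuple[tuple[int, int], ...] | None:
            # nested structure with tight introns; retry a few offsets
            for _ in range(8):
                ex = _gene_structure(rng, inner_lo, n_exons, orf_aa, 40, 80)
                length = ex[-1][1] - ex[0][0] + 1
                room = inner_hi - inner_lo + 1 - length
                if room < 0:
                    continue
                off = int(rng.integers(0, room + 1))
                return tuple((s + off, e + off) for s, e in ex)
            return None

        for j in range(n_decoys):
            kind = DECOY_KINDS[int(rng.integers(0, len(DECOY_KINDS)))]
            if kind == "short_isoform":
                orf = int(rng.integers(60, winner_orf)) if winner_orf > 60 else 0
                n_ex = 3
            elif kind == "few_exons":
                orf, n_ex = int(rng.integers(70, 120)), 2
            elif kind == "short_orf":
                orf, n_ex = int(rng.integers(20, 60)), 3
            else:  # homology_duplicate — eligible but shorter placement
                orf = int(rng.integers(60, winner_orf)) if winner_orf > 60 else 0
                n_ex = 3
            if orf == 0:
                continue
            exons = place(n_ex, orf)
            if exons is None:
                continue
            ev = HOMOLOGY if kind == "homology_duplicate" else (
                TRANSCRIPT if rng.random() < 0.6 else HOMOLOGY
            )
            decoy = GeneModel(
                model_id=f"L{i:05d}_d{j}_{kind}",
                seq_id=seq_id,
                strand=strand,
                exons=exons,
                evidence=ev,
                source_protein_id=(
                    winner.source_protein_id or f"PPA{i:05d}"
                ) if ev == HOMOLOGY else None,
            )
            add(decoy)
            decoys.append(
                {"model_id": f"{ev}:{decoy.model_id}", "kind": kind,
                 "orf_aa": decoy.orf_len_aa, "n_exons": n_ex}
            )

        if tie_mode:
            exons = place(3, winner_orf)
            if exons is not None:
                tie = GeneModel(
                    model_id=f"L{i:05d}_tie",
                    seq_id=seq_id,
                    strand=strand,
                    exons=exons,
                    evidence=TRANSCRIPT,
                )
                add(tie)
                decoys.append(
                    {"model_id": f"{TRANSCRIPT}:{tie.model_id}", "kind": "tie",
                     "orf_aa": tie.orf_len_aa, "n_exons": 3}
                )

        manifest.loci.append(
            LocusSpec(
                locus_id=f"L{i:05d}",
                seq_id=seq_id,
                strand=strand,
                span=(span0, span1),
                winner_id=f"{win_ev}:{winner.model_id}",
                winner_evidence=win_ev,
                winner_orf_aa=winner_orf,
                decoys=decoys,
            )
        )

    hom_set = AnnotationSet("toy", homology)
    txn_set = AnnotationSet("toy", transcript)
    manifest.counts = {
        "n_loci": n_loci,
        "n_homology": len(hom_set),
        "n_transcript": len(txn_set),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gff3(hom_set, out_dir / "homology.gff3")
        write_gff3(txn_set, out_dir / "transcript.gff3")
        manifest.to_json(out_dir / "manifest.json")
    return hom_set, txn_set, manifest


# ---------------------------------------------------------------------------
# exonerate-dialect emission (synthetic stand-in for real aligner output)
# ---------------------------------------------------------------------------

_EXO_ID = re.compile(r"^(?P<query>.+)\.g(?P<num>\w+)$")


def write_exonerate_gff(aset: AnnotationSet, path: str | Path) -> None:
    """Emit models in the GFF dump dialect of exonerate.

    Model ids must follow the ``<query>.g<n>`` convention the reader uses,
    so that read-back reproduces the ids. This is a synthetic emitter for
    fixtures; real aligner output additionally carries alignment blocks and
    similarity rows, which the reader ignores.
    """
    lines = ["Command line: [synthetic fixture]", "Hostname: [fixture]"]
    for m in aset.models_sorted():
        match = _EXO_ID.match(m.model_id)
        if not match:
            raise ValueError(
                f"model id {m.model_id!r} does not follow the <query>.g<n> convention"
            )
        query, num = match.group("query"), match.group("num")
        s0, s1 = m.span
        lines.append("# --- START OF GFF DUMP ---")
        lines.append("##gff-version 2")
        lines.append(f"##source-version exonerate:protein2genome:local 2.2.0")
        src = "exonerate:protein2genome:local"
        lines.append(
            "\t".join(
                [m.seq_id, src, "gene", str(s0), str(s1), "500", m.strand, ".",
                 f"gene_id {num} ; sequence {query} ; gene_orientation +"]
            )
        )
        for start, end in m.exons:
            lines.append(
                "\t".join(
                    [m.seq_id, src, "exon", str(start), str(end), ".", m.strand, ".",
                     "insertions 0 ; deletions 0"]
                )
            )
        lines.append(
            "\t".join(
                [m.seq_id, src, "similarity", str(s0), str(s1), "500", m.strand, ".",
                 f"alignment_id {num} ; Query {query}"]
            )
        )
        lines.append("# --- END OF GFF DUMP ---")
    Path(path).write_text("\n".join(lines) + "\n")


def gen_exonerate_models(n: int, seed: int) -> AnnotationSet:
    """Random homology models named per the ``<query>.g<n>`` convention."""
    rng = np.random.default_rng(seed)
    models = []
    pos = 500
    for i in range(n):
        query = f"PPA{i:05d}"
        exons = _gene_structure(
            rng, pos, n_exons=int(rng.integers(2, 7)), orf_aa=int(rng.integers(50, 300)),
            intron_lo=50, intron_hi=400,
        )
        models.append(
            GeneModel(
                model_id=f"{query}.g1",
                seq_id=f"chr{int(rng.integers(1, 4))}",
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
                evidence=HOMOLOGY,
                source_protein_id=query,
            )
        )
        pos = exons[-1][1] + int(rng.integers(200, 800))
    return AnnotationSet("exo_fixture", models)


# ---------------------------------------------------------------------------
# BUSCO tables with planted patterns
# ---------------------------------------------------------------------------


def gen_busco_tables(
    genomes: Sequence[str] | int,
    pattern_freqs: Mapping[str, int],
    seed: int,
    duplicated_fraction: float = 0.0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[BuscoRecord]], FixtureManifest]:
    """Per-genome full_table record lists realizing planted pattern counts.

    ``pattern_freqs`` maps presence bitstrings (one bit per genome, in
    genome order) to the number of genes that should show that pattern.
    A ``duplicated_fraction`` of present cells is emitted as two Duplicated
    rows instead of one Complete row — presence is unaffected.
    """
    if isinstance(genomes, int):
        genomes = [f"genome{i + 1:02d}" for i in range(genomes)]
    genomes = list(genomes)
    for pattern in pattern_freqs:
        if len(pattern) != len(genomes) or set(pattern) - {"0", "1"}:
            raise ValueError(f"pattern {pattern!r} does not match {len(genomes)} genomes")
    rng = np.random.default_rng(seed)
    tables: dict[str, list[BuscoRecord]] = {g: [] for g in genomes}
    gene_patterns: dict[str, str] = {}
    idx = 0
    for pattern, count in pattern_freqs.items():
        for _ in range(count):
            gene = f"BUSCOG{idx:05d}"
            gene_patterns[gene] = pattern
            idx += 1
            for bit, genome in zip(pattern, genomes):
                if bit == "0":
                    tables[genome].append(BuscoRecord(gene, "Missing"))
                    continue
                seq = f"ctg{int(rng.integers(1, 500)):04d}"
                score = float(np.round(rng.uniform(100, 1500), 1))
                length = int(rng.integers(100, 2000))
                if rng.random() < duplicated_fraction:
                    tables[genome].append(BuscoRecord(gene, "Duplicated", seq, score, length))
                    tables[genome].append(
                        BuscoRecord(gene, "Duplicated", seq + "b", score - 1.0, length)
                    )
                else:
                    tables[genome].append(BuscoRecord(gene, "Complete", seq, score, length))
    manifest = FixtureManifest(
        seed=seed,
        kind="busco_tables",
        counts={"n_genes": idx, "n_genomes": len(genomes)},
        extra={"genomes": genomes, "gene_patterns": gene_patterns,
               "pattern_freqs": dict(pattern_freqs)},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for genome in genomes:
            write_busco_table(tables[genome], out_dir / f"full_table_{genome}.tsv")
        manifest.to_json(out_dir / "manifest.json")
    return tables, manifest


# ---------------------------------------------------------------------------
# bipartite BLAST tables with planted RBH structure
# ---------------------------------------------------------------------------


def _row(
    rng: np.random.Generator, q: str, s: str, bitscore: float, evalue: float,
    aln_len: int | None = None, pident: float | None = None,
) -> tuple:
    aln_len = int(rng.integers(80, 400)) if aln_len is None else aln_len
    pident = float(np.round(rng.uniform(30, 95), 2)) if pident is None else pident
    mismatch = int(aln_len * (100 - pident) / 100)
    qstart = int(rng.integers(1, 20))
    return (
        q, s, f"{pident:.2f}", aln_len, mismatch, int(rng.integers(0, 5)),
        qstart, qstart + aln_len - 1, 1, aln_len,
        f"{evalue:.1e}", f"{np.round(bitscore, 1):.1f}",
    )


def rows_to_hits(rows: Sequence[tuple]) -> list[BlastHit]:
    """In-memory view of generated tabular rows."""
    return [
        BlastHit(
            query_id=r[0], subject_id=r[1], pct_identity=float(r[2]),
            aln_len=int(r[3]), evalue=float(r[10]), bitscore=float(r[11]),
        )
        for r in rows
    ]


def gen_blast_tables(
    n_ref: int,
    n_target: int,
    rbh_fraction: float,
    seed: int,
    n_one_way: int = 0,
    n_subthreshold: int = 0,
    multi_hsp: bool = False,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple], list[tuple], FixtureManifest]:
    """Forward/reverse BLAST tabular rows with planted mutual-best pairs.

    ``rbh_fraction`` of the reference proteins receive a planted reciprocal
    best partner whose bitscore is a strict maximum in both directions.
    Optional confounders: ``n_one_way`` queries whose best forward hit is
    not reciprocated, ``n_subthreshold`` mutual-best pairs with e-values
    above the conventional 1e-4 cutoff (so they must be filtered out), and
    one extra lower-scoring HSP row for the first planted pair.
    """
    if not 0.0 <= rbh_fraction <= 1.0:
        raise ValueError("rbh_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pairs = round(rbh_fraction * n_ref)
    if n_pairs + n_one_way + n_subthreshold > min(n_ref, n_target):
        raise ValueError("not enough proteins for the requested structure")

    refs = [f"REF{i:04d}" for i in range(n_ref)]
    tgts = [f"TGT{j:04d}" for j in range(n_target)]
    fwd: list[tuple] = []
    rev: list[tuple] = []
    planted: list[tuple[str, str]] = []
    one_way: list[tuple[str, str]] = []
    subthreshold: list[tuple[str, str]] = []

    def strong_evalue() -> float:
        return float(10.0 ** -rng.uniform(20, 80))

    for i in range(n_pairs):
        q, s = refs[i], tgts[i]
        b_fwd = float(rng.uniform(250, 500))
        b_rev = float(rng.uniform(250, 500))
        fwd.append(_row(rng, q, s, b_fwd, strong_evalue()))
        rev.append(_row(rng, s, q, b_rev, strong_evalue()))
        planted.append((q, s))
        for _ in range(int(rng.integers(0, 3))):  # weaker off-target decoys
            k = int(rng.integers(0, n_target))
            if tgts[k] != s:
                fwd.append(_row(rng, q, tgts[k], b_fwd - float(rng.uniform(10, 150)),
                                strong_evalue()))
            k = int(rng.integers(0, n_ref))
            if refs[k] != q:
                rev.append(_row(rng, s, refs[k], b_rev - float(rng.uniform(10, 150)),
                                strong_evalue()))
        if multi_hsp and i == 0:
            fwd.append(_row(rng, q, s, b_fwd - 30.0, strong_evalue(), aln_len=60))

    base = n_pairs
    for i in range(n_one_way):
        q, s = refs[base + i], tgts[base + i]
        fwd.append(_row(rng, q, s, float(rng.uniform(250, 400)), strong_evalue()))
        rev.append(_row(rng, s, q, 150.0, strong_evalue()))
        if n_pairs > 0:  # s prefers an already-paired ref: reciprocity broken
            rev.append(_row(rng, s, refs[0], 420.0, strong_evalue()))
        else:
            rev.append(_row(rng, s, refs[(base + i + 1) % n_ref], 420.0, strong_evalue()))
        one_way.append((q, s))

    base = n_pairs + n_one_way
    for i in range(n_subthreshold):
        q, s = refs[base + i], tgts[base + i]
        fwd.append(_row(rng, q, s, float(rng.uniform(40, 60)), 1e-3))
        rev.append(_row(rng, s, q, float(rng.uniform(40, 60)), 1e-3))
        subthreshold.append((q, s))

    manifest = FixtureManifest(
        seed=seed,
        kind="blast_tables",
        counts={"n_ref": n_ref, "n_target": n_target, "n_planted": n_pairs,
                "n_one_way": n_one_way, "n_subthreshold": n_subthreshold},
        extra={"planted_pairs": planted, "one_way": one_way, "subthreshold": subthreshold},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_blast_tab(fwd, out_dir / "fwd.blast.tsv")
        write_blast_tab(rev, out_dir / "rev.blast.tsv")
        manifest.to_json(out_dir / "manifest.json")
    return fwd, rev, manifest


# ---------------------------------------------------------------------------
# transcripts and rescue scenarios
# ---------------------------------------------------------------------------


def gen_transcripts(
    n: int, seed: int, min_len: int = 500, max_len: int = 2000, with_n: bool = False
) -> list[SeqRecord]:
    """Random nucleotide transcripts for ORF-extraction fixtures."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    records = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = alphabet[rng.integers(0, 4, size=length)]
        if with_n:
            pos = rng.integers(0, length, size=max(1, length // 200))
            seq[pos] = "N"
        records.append(SeqRecord(Seq("".join(seq)), id=f"tx{i:04d}", description=""))
    return records


def gen_rescue_fixture(
    n_genomes: int,
    n_missing_all: int,
    n_fully_supported: int,
    n_background: int,
    seed: int,
):
    """A planted rescue scenario.

    ``n_missing_all`` genes carry the all-zeros pattern; exactly
    ``n_fully_supported`` of them have a reciprocal-best partner in every
    genome, and the rest in only some genomes. ``n_background`` genes are
    present everywhere. Returns (tables, rbh_by_genome, busco_to_protein,
    manifest).
    """
    from .ortholog_eval import OrthologPair

    if n_fully_supported > n_missing_all:
        raise ValueError("n_fully_supported cannot exceed n_missing_all")
    rng = np.random.default_rng(seed)
    ones, zeros = "1" * n_genomes, "0" * n_genomes
    tables, manifest = gen_busco_tables(
        n_genomes, {ones: n_background, zeros: n_missing_all}, seed=seed
    )
    genomes = manifest.extra["genomes"]
    missing = [g for g, p in manifest.extra["gene_patterns"].items() if p == zeros]
    busco_to_protein = {g: f"CE_{g}" for g in manifest.extra["gene_patterns"]}

    def mkpair(gene: str, genome: str) -> "OrthologPair":
        prot = busco_to_protein[gene]
        bit = float(rng.uniform(100, 400))
        fh = BlastHit(prot, f"{genome}_p_{gene}", 55.0, 200, bit, 1e-30)
        rh = BlastHit(f"{genome}_p_{gene}", prot, 55.0, 200, bit, 1e-30)
        return OrthologPair(prot, fh.subject_id, fh, rh)

    rbh_by_genome: dict[str, list] = {g: [] for g in genomes}
    fully = missing[:n_fully_supported]
    for gene in fully:
        for genome in genomes:
            rbh_by_genome[genome].append(mkpair(gene, genome))
    for gene in missing[n_fully_supported:]:
        k = int(rng.integers(0, n_genomes))  # support in 0..n-1 genomes, never all
        for genome in genomes[:k]:
            rbh_by_genome[genome].append(mkpair(gene, genome))
    manifest.extra["fully_supported"] = fully
    manifest.counts["n_fully_supported"] = n_fully_supported
    return tables, rbh_by_genome, busco_to_protein, manifest
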