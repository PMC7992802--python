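"""Cross-genome audit of conserved single-copy orthologs.

A completeness pipeline such as BUSCO classifies each conserved ortholog per
genome as Complete, Duplicated, Fragmented or Missing. Summarising those
classifications across a clade as binary presence/absence patterns separates
random per-genome misannotation (many rare patterns) from systematic signals
(a few dominant patterns: a problematic assembly, a lineage-wide loss, or a
detection failure of the completeness pipeline itself).

Genes missing in *every* genome are then cross-examined with an independent
orthology proxy — best-reciprocal BLASTP hits against a reference proteome.
A gene "missing" everywhere yet with a reciprocal-best partner in every
genome points to a detection failure rather than a true loss. Alignment
metric matrices (bitscore, alignment length, percent identity, bitscore per
aligned column, aligned proportion of the query) quantify how sequence
divergence drives such failures, with matched downsampling so that gene-set
sizes are comparable.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import BlastHit, BuscoRecord

DEFAULT_PRESENT_STATUSES = frozenset({"Complete", "Duplicated"})
DEFAULT_MAX_EVALUE = 1e-4
DEFAULT_TOP_K = 20

METRICS = ("bitscore", "aln_len", "pct_identity", "normalized_bitscore", "aligned_proportion")


# ---------------------------------------------------------------------------
# presence/absence patterns
# ---------------------------------------------------------------------------


@dataclass
class PatternMatrix:
    """Binary presence matrix of orthologs across genomes, plus pattern tally.

    ``matrix`` is genes x genomes with values in {0, 1}; a row's pattern is
    its bitstring in genome order (e.g. ``"110"``).
    """

    genomes: list[str]
    matrix: pd.DataFrame  # index: busco_id; columns: genomes; int8 0/1
    pattern_tally: Counter = field(default_factory=Counter)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def top_patterns(self, k: int = DEFAULT_TOP_K) -> list[tuple[str, int]]:
        """The k most abundant patterns; ties broken by pattern string."""
        return sorted(self.pattern_tally.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def missing_in_all(self) -> list[str]:
        """Genes absent from every genome (all-zeros pattern)."""
        zeros = "0" * len(self.genomes)
        pat = self.matrix.apply(lambda row: "".join(map(str, row)), axis=1)
        return sorted(pat.index[pat == zeros])


def presence_matrix(
    tables: Mapping[str, Sequence[BuscoRecord]],
    present_statuses: Iterable[str] = DEFAULT_PRESENT_STATUSES,
) -> PatternMatrix:
    """Collapse per-genome BUSCO tables into one presence/absence matrix.

    The gene universe is the union of ids across all tables; a cell is 1 iff
    any record for that gene in that genome has a status in
    ``present_statuses`` (Complete + Duplicated by default; Fragmented
    counts as absent).
    """
    if not tables:
        raise ValueError("at least one genome table required")
    present = set(present_statuses)
    genomes = list(tables)
    universe: set[str] = set()
    present_per_genome: dict[str, set[str]] = {}
    for genome, records in tables.items():
        ids = set()
        for r in records:
            universe.add(r.busco_id)
            if r.status in present:
                ids.add(r.busco_id)
        present_per_genome[genome] = ids
    genes = sorted(universe)
    data = np.zeros((len(genes), len(genomes)), dtype=np.int8)
    for j, genome in enumerate(genomes):
        hits = present_per_genome[genome]
        for i, g in enumerate(genes):
            if g in hits:
                data[i, j] = 1
    matrix = pd.DataFrame(data, index=genes, columns=genomes)
    tally = Counter("".join(map(str, row)) for row in data)
    return PatternMatrix(genomes=genomes, matrix=matrix, pattern_tally=tally)


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrthologPair:
    """A best-reciprocal BLASTP pair between two proteomes."""

    query_id: str
    subject_id: str
    fwd_hit: BlastHit
    rev_hit: BlastHit


def best_hits(
    hits: Iterable[BlastHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> dict[str, BlastHit]:
    """Single best hit per query by bitscore, after a strict e-value cutoff.

    Hits with ``evalue >= max_evalue`` are removed first. Ties on bitscore
    are broken by lower e-value, then lexicographically smaller subject_id.
    """
    best: dict[str, BlastHit] = {}
    for h in hits:
        if h.evalue >= max_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore, cur.evalue, cur.subject_id
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    fwd: Iterable[BlastHit],
    rev: Iterable[BlastHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[OrthologPair]:
    """Mutual-best pairs between a reference and a target proteome.

    ``fwd`` holds reference->target hits, ``rev`` target->reference. A pair
    (q, s) is emitted iff s is q's best forward hit and q is s's best
    reverse hit, both by bitscore after the e-value cutoff. Output is sorted
    by query_id.
    """
    fwd_best = best_hits(fwd, max_evalue)
    rev_best = best_hits(rev, max_evalue)
    pairs = []
    for q, fh in fwd_best.items():
        rh = rev_best.get(fh.subject_id)
        if rh is not None and rh.subject_id == q:
            pairs.append(OrthologPair(q, fh.subject_id, fh, rh))
    return sorted(pairs, key=lambda p: p.query_id)


# ---------------------------------------------------------------------------
# rescue of apparently missing genes
# ---------------------------------------------------------------------------


@dataclass
class RescueReport:
    """Outcome of cross-examining missing-in-all genes with RBH support.

    ``fraction`` is n_rescued_all over the mapped missing-in-all genes.
    """

    n_missing_all: int
    n_mapped: int
    n_rescued_all: int
    fraction: float
    rescued_all: list[str]
    partial: dict[str, list[str]]  # gene -> genomes with RBH support (not all)
    unmapped: list[str]

    def to_dict(self) -> dict:
        return {
            "n_missing_all": self.n_missing_all,
            "n_mapped": self.n_mapped,
            "n_rescued_all": self.n_rescued_all,
            "fraction": self.fraction,
            "rescued_all": self.rescued_all,
            "partial": self.partial,
            "unmapped": self.unmapped,
        }


def rescue_missing(
    pattern: PatternMatrix,
    rbh_by_genome: Mapping[str, Sequence[OrthologPair]],
    busco_to_protein: Mapping[str, str],
) -> RescueReport:
    """Count missing-in-all genes that have an RBH partner in every genome.

    Genes whose id has no reference-protein mapping are listed as unmapped
    and excluded from the denominator. Genes with RBH support in only some
    genomes are reported separately as partial rescues.
    """
    import logging

    missing_all = pattern.missing_in_all()
    supported: dict[str, set[str]] = defaultdict(set)
    for genome, pairs in rbh_by_genome.items():
        queries = {p.query_id for p in pairs}
        for gene in missing_all:
            protein = busco_to_protein.get(gene)
            if protein is not None and protein in queries:
                supported[gene].add(genome)

    all_genomes = set(pattern.genomes)
    rescued, partial, unmapped = [], {}, []
    for gene in missing_all:
        if gene not in busco_to_protein:
            unmapped.append(gene)
            continue
        genomes = supported.get(gene, set())
        if genomes == all_genomes:
            rescued.append(gene)
        elif genomes:
            partial[gene] = sorted(genomes)
    if unmapped:
        logging.getLogger(__name__).warning(
            "%d missing-in-all gene(s) lack a protein mapping and are excluded", len(unmapped)
        )
    n_mapped = len(missing_all) - len(unmapped)
    return RescueReport(
        n_missing_all=len(missing_all),
        n_mapped=n_mapped,
        n_rescued_all=len(rescued),
        fraction=len(rescued) / n_mapped if n_mapped else 0.0,
        rescued_all=rescued,
        partial=partial,
        unmapped=unmapped,
    )


# ---------------------------------------------------------------------------
# alignment metric matrices
# ---------------------------------------------------------------------------


@dataclass
class MetricMatrix:
    """One gene x genome matrix of an alignment metric for one gene set.

    Cells without a hit are NaN, never zero-filled: an absent alignment is
    not a zero-score alignment.
    """

    gene_set: str
    metric: str
    values: pd.DataFrame


def metric_matrices(
    hits: Mapping[str, Sequence[BlastHit]],
    query_lengths: Mapping[str, int],
    gene_sets: Mapping[str, Sequence[str]],
) -> list[MetricMatrix]:
    """Build the five alignment-metric matrices for each named gene set.

    Per (gene, genome) the highest-bitscore hit represents the pair.
    ``normalized_bitscore`` is bitscore / alignment length;
    ``aligned_proportion`` is alignment length / reference query length.
    A gene with hits but no known query length is an error.
    """
    genomes = list(hits)
    designated: dict[str, dict[str, BlastHit]] = {}
    for genome, hit_list in hits.items():
        per_query: dict[str, BlastHit] = {}
        for h in hit_list:
            cur = per_query.get(h.query_id)
            if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
                -cur.bitscore, cur.evalue, cur.subject_id
            ):
                per_query[h.query_id] = h
        designated[genome] = per_query

    out: list[MetricMatrix] = []
    for set_name, genes in gene_sets.items():
        genes = list(genes)
        frames = {
            metric: pd.DataFrame(np.nan, index=genes, columns=genomes) for metric in METRICS
        }
        for genome in genomes:
            for gene in genes:
                h = designated[genome].get(gene)
                if h is None:
                    continue
                qlen = query_lengths.get(gene)
                if qlen is None:
                    raise KeyError(f"no query length for gene {gene!r} (has hits)")
                frames["bitscore"].loc[gene, genome] = h.bitscore
                frames["aln_len"].loc[gene, genome] = h.aln_len
                frames["pct_identity"].loc[gene, genome] = h.pct_identity
                frames["normalized_bitscore"].loc[gene, genome] = h.bitscore / h.aln_len
                frames["aligned_proportion"].loc[gene, genome] = h.aln_len / qlen
        out.extend(MetricMatrix(set_name, metric, frames[metric]) for metric in METRICS)
    return out


def subsample_matched(
    genes: Sequence[str], target_size: int, n_reps: int, seed: int
) -> list[list[str]]:
    """Repeated uniform without-replacement downsampling of a gene list.

    Used to compare metric distributions between gene sets of unequal size
    on matched sample sizes. Fully reproducible from ``seed``.
    """
    if target_size > len(genes):
        raise ValueError(f"target_size {target_size} exceeds gene list size {len(genes)}")
    rng = np.random.default_rng(seed)
    genes_arr = np.asarray(genes, dtype=object)
    return [
        [str(g) for g in genes_arr[rng.choice(len(genes_arr), size=target_size, replace=False)]]
        for _ in range(n_reps)
    ]
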