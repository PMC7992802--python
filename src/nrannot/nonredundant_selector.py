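"""Greedy window-coverage reduction of a redundant gene annotation.

Draft-genome annotation from mixed evidence (spliced protein-to-genome
alignments plus ORFs from assembled transcripts) produces several candidate
gene models per locus: alternative isoforms, duplicate homology placements,
transcript fragments. This module reduces such a joint annotation to one
representative model per locus:

1. Gene models from the two DNA strands are treated independently.
2. Every exon start and end coordinate is assigned to a fixed-size window
   (100 bp by default); window coverage is the number of boundary features
   assigned to it.
3. Starting with the most highly covered window, the intersecting gene model
   with the longest ORF is chosen and all other gene models overlapping the
   chosen model are discarded. Only models with an ORF of at least
   ``min_orf_aa`` amino acids (60) and at least ``min_exons`` exons (3) are
   eligible for selection. The step is repeated for every remaining window.

The exon-count and ORF-length floors suppress inflation of gene counts by
partially assembled transcript fragments and transcriptional noise; they are
tuned for gene-dense nematode genomes with many exons per gene and are
exposed as parameters.

Every input model ends up either selected or discarded with a reason, and
an audit log records each (window, chosen model) decision, so a run is
fully reconstructible.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .annotation_io import AnnotationSet, GeneModel

DEFAULT_WINDOW_SIZE = 100
DEFAULT_MIN_ORF_AA = 60
DEFAULT_MIN_EXONS = 3

#: discard reasons recorded in :class:`SelectionResult`
REASON_OVERLAP = "overlap_with_selected"
REASON_EXONS = "filter_exons"
REASON_ORF = "filter_orf_len"

_STRAND_ORDER = {"+": 0, "-": 1}

WindowKey = tuple[str, str, int]  # (seq_id, strand, window_index)


def window_index(coord: int, window_size: int) -> int:
    """Window index of a 1-based coordinate: floor((coord - 1) / size)."""
    return (coord - 1) // window_size


@dataclass
class WindowCoverageMap:
    """Per (seq_id, strand, window) counts of exon boundary features.

    Each exon contributes its start and its end coordinate, so the counts
    sum to twice the number of exons; a start and an end falling in the
    same window increment it twice.
    """

    window_size: int
    counts: dict[WindowKey, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def ordered_windows(self) -> list[WindowKey]:
        """Windows by descending count; ties by seq_id, strand (+ first), index."""
        return sorted(
            self.counts,
            key=lambda k: (-self.counts[k], k[0], _STRAND_ORDER[k[1]], k[2]),
        )


def build_windows(
    aset: AnnotationSet | Iterable[GeneModel], window_size: int = DEFAULT_WINDOW_SIZE
) -> WindowCoverageMap:
    """Tally exon boundary coordinates of every model into windows."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    counts: dict[WindowKey, int] = defaultdict(int)
    for m in aset:
        for start, end in m.exons:
            counts[(m.seq_id, m.strand, window_index(start, window_size))] += 1
            counts[(m.seq_id, m.strand, window_index(end, window_size))] += 1
    return WindowCoverageMap(window_size=window_size, counts=dict(counts))


@dataclass(frozen=True)
class WindowDecision:
    """One audit entry: which model a window selected, and the fallout."""

    seq_id: str
    strand: str
    window: int  # window index; -1 for the post-pass over leftover models
    coverage: int
    chosen: str
    n_discarded: int


@dataclass
class SelectionResult:
    """Outcome of :func:`select_nonredundant`.

    ``selected`` and the ids in ``discarded`` partition the input; every
    discarded model carries one reason. ``audit`` logs the window decisions
    in the order they were taken.
    """

    selected: AnnotationSet
    discarded: list[tuple[str, str]]
    audit: list[WindowDecision]

    @property
    def discarded_ids(self) -> list[str]:
        return [mid for mid, _ in self.discarded]

    def counts_by_evidence(self) -> dict[str, int]:
        tally: dict[str, int] = defaultdict(int)
        for m in self.selected:
            tally[m.evidence] += 1
        return dict(tally)


def _eligible(m: GeneModel, min_orf_aa: int, min_exons: int) -> bool:
    return m.n_exons >= min_exons and m.orf_len_aa >= min_orf_aa


def _filter_reason(m: GeneModel, min_orf_aa: int, min_exons: int) -> str:
    return REASON_EXONS if m.n_exons < min_exons else REASON_ORF


def select_nonredundant(
    aset: AnnotationSet,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_orf_aa: int = DEFAULT_MIN_ORF_AA,
    min_exons: int = DEFAULT_MIN_EXONS,
    discard_scope: Literal["model", "window"] = "model",
) -> SelectionResult:
    """Pick one representative gene model per locus by greedy window coverage.

    Window coverage is computed from ALL models, including ones failing the
    exon/ORF filters: the filters apply only when choosing a representative.
    Windows are visited by descending coverage (deterministic tie-breaks);
    at each window the eligible, still-live model whose gene span intersects
    the window and has the longest ORF wins (ties: smaller gene start, then
    smaller model_id), and every other live model overlapping the winner's
    gene span is discarded. With ``discard_scope='window'`` the discard
    radius is the window itself instead of the winner's span (a stricter
    variant; the default span scope never deletes non-competing neighbours).

    After all windows are processed a deterministic sweep resolves any
    leftover models: still-eligible ones that overlap no selected model are
    selected; everything else is discarded with its reason. A selected model
    is never revisited or displaced (greedy, no backtracking).
    """
    cov = build_windows(aset, window_size)
    selected: dict[str, GeneModel] = {}
    discarded: dict[str, str] = {}
    audit: list[WindowDecision] = []

    def live(m: GeneModel) -> bool:
        return m.model_id not in selected and m.model_id not in discarded

    for seq_id, strand, widx in cov.ordered_windows():
        wstart = widx * window_size + 1
        wend = (widx + 1) * window_size
        candidates = [
            m
            for m in aset.query_span(seq_id, strand, wstart, wend)
            if live(m) and _eligible(m, min_orf_aa, min_exons)
        ]
        if not candidates:
            continue
        winner = min(candidates, key=lambda m: (-m.orf_len_aa, m.span[0], m.model_id))
        selected[winner.model_id] = winner
        if discard_scope == "model":
            s0, s1 = winner.span
            losers = aset.query_span(seq_id, strand, s0, s1)
        else:
            losers = aset.query_span(seq_id, strand, wstart, wend)
        n_disc = 0
        for m in losers:
            if m.model_id != winner.model_id and live(m):
                discarded[m.model_id] = REASON_OVERLAP
                n_disc += 1
        audit.append(
            WindowDecision(seq_id, strand, widx, cov.counts[(seq_id, strand, widx)],
                           winner.model_id, n_disc)
        )

    # Post-pass: every model's own boundaries define windows, so eligible
    # models are normally consumed above; this sweep pins down the leftovers
    # (filter failures and, under 'window' scope, stranded neighbours)
    # deterministically.
    for m in aset.models_sorted():
        if not live(m):
            continue
        overlaps_selected = any(
            s.model_id in selected and s.model_id != m.model_id
            for s in aset.query_span(m.seq_id, m.strand, *m.span)
        )
        if overlaps_selected:
            discarded[m.model_id] = REASON_OVERLAP
        elif _eligible(m, min_orf_aa, min_exons):
            selected[m.model_id] = m
            audit.append(WindowDecision(m.seq_id, m.strand, -1, 0, m.model_id, 0))
        else:
            discarded[m.model_id] = _filter_reason(m, min_orf_aa, min_exons)

    result = SelectionResult(
        selected=aset.subset(sorted(selected)),
        discarded=sorted(discarded.items()),
        audit=audit,
    )
    assert len(result.selected) + len(result.discarded) == len(aset)
    return result


def merge_evidence(
    homology: AnnotationSet,
    transcript: AnnotationSet,
    prefix: bool = True,
) -> AnnotationSet:
    """Union of homology and transcript models into one joint annotation.

    Evidence labels are preserved so the final report can count how many
    selected models came from each track. With ``prefix`` (default) model
    ids are namespaced as ``<evidence>:<id>`` to guarantee disjointness;
    duplicate ids after prefixing raise ``ValueError``.
    """
    from dataclasses import replace

    merged = AnnotationSet(genome_id=homology.genome_id or transcript.genome_id)
    for source in (homology, transcript):
        for m in source:
            merged.add(replace(m, model_id=f"{m.evidence}:{m.model_id}") if prefix else m)
    return merged


def prefixed_id(model: GeneModel) -> str:
    """The id a model receives from :func:`merge_evidence` with prefixing on."""
    return f"{model.evidence}:{model.model_id}"
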