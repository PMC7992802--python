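"""Independent naive reference implementations used only by the tests.

Everything here recomputes results from scratch with plain loops and no
shared code paths with the package internals (no interval trees, no window
maps): brute-force window tallies, a literal re-implementation of the greedy
selection procedure, six-frame ORF enumeration via whole-frame translation
and stop-splitting, and a double-loop mutual-best-hit search.
"""

from __future__ import annotations

from collections import defaultdict

from Bio.Seq import Seq


def naive_window_counts(models, window_size):
    """Brute-force tally of exon boundary coordinates per window."""
    counts = defaultdict(int)
    for m in models:
        for start, end in m.exons:
            for coord in (start, end):
                counts[(m.seq_id, m.strand, (coord - 1) // window_size)] += 1
    return dict(counts)


def _span(m):
    return m.exons[0][0], m.exons[-1][1]


def _intersects(a0, a1, b0, b1):
    return a0 <= b1 and b0 <= a1


def naive_select(models, window_size=100, min_orf_aa=60, min_exons=3,
                 discard_scope="model"):
    """Literal greedy selection with linear scans at every step.

    Returns (selected ids, {discarded id: reason}, audit list of
    (seq, strand, window, chosen id)).
    """
    models = list(models)
    counts = naive_window_counts(models, window_size)
    strand_rank = {"+": 0, "-": 1}
    windows = sorted(counts, key=lambda k: (-counts[k], k[0], strand_rank[k[1]], k[2]))

    def eligible(m):
        return len(m.exons) >= min_exons and m.orf_len_aa >= min_orf_aa

    selected, discarded, audit = {}, {}, []
    for seq_id, strand, widx in windows:
        w0, w1 = widx * window_size + 1, (widx + 1) * window_size
        cands = [
            m for m in models
            if m.seq_id == seq_id and m.strand == strand
            and m.model_id not in selected and m.model_id not in discarded
            and eligible(m) and _intersects(*_span(m), w0, w1)
        ]
        if not cands:
            continue
        winner = min(cands, key=lambda m: (-m.orf_len_aa, _span(m)[0], m.model_id))
        selected[winner.model_id] = winner
        if discard_scope == "model":
            z0, z1 = _span(winner)
        else:
            z0, z1 = w0, w1
        for m in models:
            if (
                m.seq_id == seq_id and m.strand == strand
                and m.model_id not in selected and m.model_id not in discarded
                and _intersects(*_span(m), z0, z1)
            ):
                discarded[m.model_id] = "overlap_with_selected"
        audit.append((seq_id, strand, widx, winner.model_id))

    # deterministic sweep over leftovers, mirroring the documented contract
    for m in sorted(models, key=lambda m: (m.seq_id, _span(m)[0], m.model_id)):
        if m.model_id in selected or m.model_id in discarded:
            continue
        touches_selected = any(
            s.seq_id == m.seq_id and s.strand == m.strand
            and _intersects(*_span(m), *_span(s))
            for s in selected.values()
        )
        if touches_selected:
            discarded[m.model_id] = "overlap_with_selected"
        elif eligible(m):
            selected[m.model_id] = m
            audit.append((m.seq_id, m.strand, -1, m.model_id))
        elif len(m.exons) < min_exons:
            discarded[m.model_id] = "filter_exons"
        else:
            discarded[m.model_id] = "filter_orf_len"
    return set(selected), discarded, audit


def naive_orfs(seq_id, nt, min_len):
    """All six-frame ORFs >= min_len via full-frame translation + stop split.

    Returns a set of (seq_id, strand, frame, aa_start, aa_end, sequence).
    """
    out = set()
    nt = nt.upper()
    for strand, s in (("+", nt), ("-", str(Seq(nt).reverse_complement()))):
        for frame in range(3):
            trimmed = s[frame : frame + 3 * ((len(s) - frame) // 3)]
            aa = str(Seq(trimmed).translate())
            pos = 0
            for chunk in aa.split("*"):
                if len(chunk) >= min_len:
                    out.add((seq_id, strand, frame, pos, pos + len(chunk), chunk))
                pos += len(chunk) + 1
    return out


def naive_rbh(fwd, rev, max_evalue=1e-4):
    """Double-loop mutual best search over all hit pairs."""
    fwd = [h for h in fwd if h.evalue < max_evalue]
    rev = [h for h in rev if h.evalue < max_evalue]

    def best_of(hits, query):
        mine = [h for h in hits if h.query_id == query]
        return min(mine, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)) if mine else None

    pairs = set()
    for q in {h.query_id for h in fwd}:
        fbest = best_of(fwd, q)
        rbest = best_of(rev, fbest.subject_id)
        if rbest is not None and rbest.subject_id == q:
            pairs.add((q, fbest.subject_id))
    return pairs
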