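"""Term-seq 3'-end calling: CPM normalization, cross-replicate consensus,
primary/secondary/internal classification, 3'-UTR lengths, and long-read
transcriptional-unit calls.

The consensus rule follows the filtering used for enriched 3'-end
detection: peaks are gap-bridged runs of nonzero positions in the
replicate-summed CPM track; within each peak the per-replicate maximum
position is taken, and a consensus position is emitted only when the
identical position is the maximum in at least ``min_replicates``
replicates and its mean CPM over the supporting replicates is at least
``min_cpm`` (default 5).  Ends are then assigned to genes as primary
(highest end within 300 nt downstream), secondary (other downstream
ends), or internal (inside the coding range).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import EndTrack, GeneModel

__all__ = [
    "Peak",
    "EndCall",
    "cpm_normalize",
    "call_consensus_ends",
    "classify_ends",
    "utr3_lengths",
    "call_transcriptional_units",
    "evaluate_end_recovery",
]


@dataclass(frozen=True)
class Peak:
    contig: str
    strand: str
    start: int
    end: int
    rep_argmax: tuple[int, ...]      # per-replicate argmax position (-1 if empty)
    rep_height: tuple[float, ...]    # CPM at that position

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("empty peak interval")


@dataclass(frozen=True)
class EndCall:
    contig: str
    strand: str
    position: int
    height: float                    # mean CPM over supporting replicates
    n_supporting: int
    gene_id: str | None = None
    end_class: str = "orphan"        # primary | secondary | internal | orphan
    utr3_len: int | None = None


def cpm_normalize(track: EndTrack, library_total: float | None = None) -> EndTrack:
    """Counts-per-million scaling by the replicate's total end count."""
    if track.normalized == "cpm":
        raise ValueError("track is already CPM-normalized")
    total = track.library_total if library_total is None else library_total
    if total <= 0:
        raise ValueError("library_total must be positive")
    factor = 1e6 / total
    return replace(
        track,
        counts={p: c * factor for p, c in track.counts.items()},
        library_total=total,
        normalized="cpm",
    )


def _find_peaks(tracks: Sequence[EndTrack], merge_window: int) -> list[tuple[int, int]]:
    positions = sorted(set().union(*(t.counts.keys() for t in tracks)))
    peaks: list[tuple[int, int]] = []
    if not positions:
        return peaks
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev - 1 <= merge_window:
            prev = p
        else:
            peaks.append((start, prev))
            start = prev = p
    peaks.append((start, prev))
    return peaks


def _replicate_argmax(track: EndTrack, start: int, end: int, strand: str) -> tuple[int, float]:
    """Argmax position within [start, end]; ties broken toward the most
    gene-proximal position (lowest coordinate on +, highest on -)."""
    best_pos, best_val = -1, 0.0
    rng = range(start, end + 1) if strand == "+" else range(end, start - 1, -1)
    for p in rng:
        v = track.counts.get(p, 0.0)
        if v > best_val:
            best_pos, best_val = p, v
    return best_pos, best_val


def call_consensus_ends(
    tracks: Sequence[EndTrack],
    min_replicates: int = 3,
    min_cpm: float = 5.0,
    merge_window: int = 3,
) -> list[tuple[Peak, EndCall]]:
    """Cross-replicate consensus 3'-end positions for one contig+strand."""
    if len(tracks) < min_replicates:
        raise ValueError("fewer replicates than min_replicates")
    contigs = {t.contig for t in tracks}
    strands = {t.strand for t in tracks}
    if len(contigs) > 1 or len(strands) > 1:
        raise ValueError("tracks mix contigs or strands")
    if any(t.normalized != "cpm" for t in tracks):
        raise ValueError("tracks must be CPM-normalized")
    contig, strand = contigs.pop(), strands.pop()

    results: list[tuple[Peak, EndCall]] = []
    for start, end in _find_peaks(tracks, merge_window):
        argmaxes = [_replicate_argmax(t, start, end, strand) for t in tracks]
        peak = Peak(
            contig, strand, start, end,
            rep_argmax=tuple(a for a, _ in argmaxes),
            rep_height=tuple(h for _, h in argmaxes),
        )
        votes: dict[int, list[float]] = {}
        for pos, h in argmaxes:
            if pos >= 0:
                votes.setdefault(pos, []).append(h)
        for pos in sorted(votes):
            heights = votes[pos]
            if len(heights) >= min_replicates and float(np.mean(heights)) >= min_cpm:
                results.append(
                    (peak, EndCall(contig, strand, pos, float(np.mean(heights)),
                                   len(heights)))
                )
    return results


def _downstream_offset(gene: GeneModel, position: int) -> int:
    """Signed offset of a position past the gene 3' boundary (transcript
    orientation); 0 at the boundary itself."""
    if gene.strand == "+":
        return position - gene.three_prime
    return gene.three_prime - position


def classify_ends(
    ends: Iterable[EndCall],
    genes: Sequence[GeneModel],
    downstream_window: int = 300,
) -> list[EndCall]:
    """Assign consensus ends to genes as primary/secondary/internal/orphan.

    The downstream window is half-open: the 3' boundary itself belongs to
    the coding range (internal).  Ends falling in the downstream window of
    two genes are assigned to the nearer one; the highest end per gene
    becomes primary (ties toward the gene), the rest secondary.
    """
    genes_by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        genes_by_key.setdefault((g.contig, g.strand), []).append(g)

    assigned: dict[str, list[tuple[EndCall, int]]] = {}
    out_internal_orphan: list[EndCall] = []
    for call in ends:
        candidates = genes_by_key.get((call.contig, call.strand), [])
        body_gene = next(
            (g for g in candidates if g.start <= call.position <= g.end), None
        )
        if body_gene is not None:
            out_internal_orphan.append(
                replace(call, gene_id=body_gene.gene_id, end_class="internal")
            )
            continue
        best, best_off = None, None
        for g in candidates:
            off = _downstream_offset(g, call.position)
            if 0 < off <= downstream_window and (best_off is None or off < best_off):
                best, best_off = g, off
        if best is None:
            out_internal_orphan.append(replace(call, end_class="orphan"))
        else:
            assigned.setdefault(best.gene_id, []).append((call, best_off))

    gene_by_id = {g.gene_id: g for g in genes}
    out: list[EndCall] = []
    for gid, calls in assigned.items():
        # primary = highest CPM; ties broken toward the gene (smaller offset)
        calls.sort(key=lambda t: (-t[0].height, t[1]))
        (primary, off), rest = calls[0], calls[1:]
        out.append(replace(primary, gene_id=gid, end_class="primary", utr3_len=off))
        out.extend(replace(c, gene_id=gid, end_class="secondary") for c, _ in rest)
    out.extend(out_internal_orphan)
    out.sort(key=lambda c: (c.contig, c.position, c.strand))
    return out


def utr3_lengths(calls: Iterable[EndCall], genes: Sequence[GeneModel]) -> pd.Series:
    """Per-gene 3'-UTR length (gene 3' boundary to primary end), nt."""
    gene_by_id = {g.gene_id: g for g in genes}
    data = {}
    for c in calls:
        if c.end_class != "primary":
            continue
        g = gene_by_id[c.gene_id]
        off = _downstream_offset(g, c.position)
        data[c.gene_id] = max(off, 0)
    return pd.Series(data, name="utr3_len", dtype=int)


def call_transcriptional_units(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    min_span_fraction: float = 0.5,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Co-transcription calls for adjacent same-strand gene pairs.

    A pair is co-transcribed when at least ``min_reads`` reads each
    overlap at least ``min_span_fraction`` of both genes.  ``reads`` needs
    columns contig, start, end (1-based inclusive), strand.
    """
    rows = []
    for strand in "+-":
        sub = sorted(
            (g for g in genes if g.strand == strand),
            key=lambda g: g.start, reverse=(strand == "-"),
        )
        strand_reads = reads[reads["strand"] == strand]
        for a, b in zip(sub, sub[1:]):
            if a.contig != b.contig:
                continue
            n_support = 0
            for _, r in strand_reads[strand_reads["contig"] == a.contig].iterrows():
                ok = True
                for g in (a, b):
                    ov = min(r["end"], g.end) - max(r["start"], g.start) + 1
                    if ov < min_span_fraction * g.length:
                        ok = False
                        break
                if ok:
                    n_support += 1
            rows.append(
                {"gene_a": a.gene_id, "gene_b": b.gene_id, "strand": strand,
                 "n_spanning_reads": n_support,
                 "unit": "co-transcribed" if n_support >= min_reads else "separate"}
            )
    return pd.DataFrame(rows)


def evaluate_end_recovery(
    calls: Sequence[EndCall],
    truth_ends: pd.DataFrame,
    min_truth_cpm: float = 0.0,
    tolerance: int = 0,
) -> dict:
    """Precision/recall/F1 of called ends against a planted truth table.

    A truth end counts as recovered when a call of any class lies within
    ``tolerance`` nt on the same strand; class accuracy compares the
    matched call's class with the planted class.  Truth ends below
    ``min_truth_cpm`` expected height are ignored on both sides of the
    match (calls hitting them are not counted as false positives).
    """
    truth = truth_ends.copy()
    kept = truth[truth["cpm"] >= min_truth_cpm]
    low = truth[truth["cpm"] < min_truth_cpm]

    call_list = [(c.strand, c.position, c.end_class) for c in calls]
    matched_truth = set()
    matched_calls = set()
    n_class_correct = 0
    for ti, t in kept.reset_index(drop=True).iterrows():
        best_ci, best_d = None, None
        for ci, (strand, pos, _cls) in enumerate(call_list):
            if ci in matched_calls or strand != t["strand"]:
                continue
            d = abs(pos - t["position"])
            if d <= tolerance and (best_d is None or d < best_d):
                best_ci, best_d = ci, d
        if best_ci is not None:
            matched_truth.add(ti)
            matched_calls.add(best_ci)
            if call_list[best_ci][2] == t["end_class"]:
                n_class_correct += 1
    # calls matching low-height planted ends are neither TP nor FP
    excused = set()
    for ci, (strand, pos, _cls) in enumerate(call_list):
        if ci in matched_calls:
            continue
        for _, t in low.iterrows():
            if strand == t["strand"] and abs(pos - t["position"]) <= tolerance:
                excused.add(ci)
                break
    tp = len(matched_truth)
    fp = len(call_list) - len(matched_calls) - len(excused)
    fn = len(kept) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision, "recall": recall, "f1": f1,
        "class_accuracy": n_class_correct / tp if tp else float("nan"),
    }
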