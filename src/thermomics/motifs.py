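"""Promoter/terminator sequence features and related statistics.

Archaeal core promoters carry a BRE element (consensus G/C(A/T)AAA) and a
TATA box (TTT(A/T)(A/T)(A/T)) upstream of the TSS.  Genes are classified
by scanning a consensus-seeded position weight matrix over the -50..+10
window around the TSS; the exact site p-value (probability that a random
background sequence scores at least as high, computed by dynamic-
programming convolution of the per-position score distributions) doubles
as a promoter-strength estimate when restricted to -42..-19, smaller
meaning stronger.  Terminators are classified by a windowed U-count rule
in -35..+2 around the primary 3' end, capturing the ~16-nt poly(U)
stretch of archaeal intrinsic terminators.  Also here: position-specific
nucleotide enrichment against randomly sampled intergenic background,
leaderless-proportion chi-square tests, palindromic regulon scanning, and
codon adaptation index / GC content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable

from .io import Genome, GeneModel, extract_window, revcomp
from .ends import EndCall

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_from_consensus",
    "pwm_scan_pvalue",
    "classify_promoter",
    "classify_polyU",
    "nucleotide_enrichment",
    "leadered_test",
    "regulon_scan",
    "sequence_composition",
    "BASES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# classification window around the TSS, strength window, and terminator
# window around the primary 3' end (transcript-orientation offsets)
PROMOTER_WINDOW = (-50, 10)
STRENGTH_WINDOW = (-42, -19)
TERMINATOR_WINDOW = (-35, 2)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PWM:
    """Log2-odds position weight matrix over {A,C,G,T}.

    ``scores`` has shape (length, 4) in base order A,C,G,T; ``background``
    is the strictly positive background distribution the odds are taken
    against.
    """

    scores: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PWM scores must be finite")
        if np.any(self.background <= 0):
            raise ValueError("background must be strictly positive")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score(self, seq: str) -> float:
        if len(seq) != self.length:
            raise ValueError("sequence length does not match PWM length")
        return float(sum(self.scores[i, _BASE_INDEX[b]] for i, b in enumerate(seq)))

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    gene_id: str | None
    offset: int            # window start offset relative to the anchor
    score: float
    p_value: float
    strand: str = "+"
    found: bool = True


def pwm_from_consensus(
    consensus: str,
    match_prob: float = 0.9,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.0,
) -> PWM:
    """Build a PWM from a degenerate IUPAC consensus.

    At each position, probability mass ``match_prob`` is split uniformly
    over the allowed bases and the remainder over the disallowed ones;
    scores are log2 odds against ``background`` (with ``pseudocount``
    added to the per-base probabilities before taking odds).
    """
    if not 0.5 < match_prob < 1.0:
        raise ValueError("match_prob must lie in (0.5, 1)")
    bg = np.asarray(background, dtype=float)
    scores = np.zeros((len(consensus), 4))
    for i, code in enumerate(consensus.upper()):
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}")
        allowed = IUPAC[code]
        n_allowed = len(allowed)
        for b in BASES:
            if n_allowed == 4:
                p = 0.25
            elif b in allowed:
                p = match_prob / n_allowed
            else:
                p = (1.0 - match_prob) / (4 - n_allowed)
            scores[i, _BASE_INDEX[b]] = math.log2(
                (p + pseudocount) / (bg[_BASE_INDEX[b]] + pseudocount)
            )
    return PWM(scores=scores, background=bg, pseudocount=pseudocount)


def score_distribution(pwm: PWM, epsilon: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the PWM score under the background model.

    Scores are discretized to multiples of ``epsilon`` and the per-position
    distributions convolved by dynamic programming.  Returns (support
    offsets as integer multiples of epsilon relative to the minimum, and
    probabilities); use :func:`pwm_sf` for tail lookups.
    """
    int_scores = np.rint(pwm.scores / epsilon).astype(np.int64)
    mins = int_scores.min(axis=1)
    maxs = int_scores.max(axis=1)
    span = int((maxs - mins).sum()) + 1
    probs = np.zeros(span)
    probs[0] = 1.0
    width = 1
    for i in range(pwm.length):
        new_width = width + int(maxs[i] - mins[i])
        new = np.zeros(span)
        for b in range(4):
            shift = int(int_scores[i, b] - mins[i])
            new[shift : shift + width] += pwm.background[b] * probs[:width]
        probs = new
        width = new_width
    base = int(mins.sum())
    return np.arange(span) + base, probs


def pwm_sf(pwm: PWM, score: float, epsilon: float = 1e-3) -> float:
    """P(random background sequence scores >= ``score``), exact up to the
    epsilon discretization."""
    support, probs = score_distribution(pwm, epsilon)
    target = int(np.rint(score / epsilon))
    return float(probs[support >= target].sum())


def pwm_scan_pvalue(
    pwm: PWM,
    sequence: str,
    epsilon: float = 1e-3,
    _dist: tuple[np.ndarray, np.ndarray] | None = None,
) -> MotifHit:
    """Best-scoring window of ``sequence`` with its exact site p-value.

    Windows containing N are skipped; if every window contains an N the
    hit is returned with ``found=False``.
    """
    L = pwm.length
    if len(sequence) < L:
        raise ValueError("sequence shorter than the PWM")
    sequence = sequence.upper()
    best_score, best_offset = -math.inf, None
    for off in range(len(sequence) - L + 1):
        window = sequence[off : off + L]
        if "N" in window:
            continue
        s = pwm.score(window)
        if s > best_score:
            best_score, best_offset = s, off
    if best_offset is None:
        return MotifHit(None, 0, float("nan"), 1.0, found=False)
    if _dist is None:
        p = pwm_sf(pwm, best_score, epsilon)
    else:
        support, probs = _dist
        target = int(np.rint(best_score / epsilon))
        p = float(probs[support >= target].sum())
    return MotifHit(None, best_offset, best_score, max(p, 1e-300))


def classify_promoter(
    genes: Sequence[GeneModel],
    genome: Genome,
    bre_tata: PWM,
    window: tuple[int, int] = (-50, 10),
    strength_window: tuple[int, int] = (-42, -19),
    alpha: float = 1e-3,
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """BRE/TATA promoter classification and strength per gene.

    A gene is +promoter when the best PWM hit in the classification
    window around its TSS has p <= alpha; strength is the best-hit
    p-value within the narrower strength window (smaller = stronger).
    Genes lacking a TSS, or whose window runs off the contig, are
    reported with status ``no_tss`` / ``skipped``.
    """
    dist = score_distribution(bre_tata, epsilon)
    rows = []
    for g in genes:
        if g.tss is None:
            rows.append({"gene_id": g.gene_id, "status": "no_tss"})
            continue
        seq = extract_window(genome, g, g.tss, window[0], window[1])
        seq_strength = extract_window(genome, g, g.tss, strength_window[0], strength_window[1])
        if seq is None or seq_strength is None:
            rows.append({"gene_id": g.gene_id, "status": "skipped"})
            continue
        hit = pwm_scan_pvalue(bre_tata, seq, epsilon, _dist=dist)
        strength = pwm_scan_pvalue(bre_tata, seq_strength, epsilon, _dist=dist)
        rows.append(
            {
                "gene_id": g.gene_id,
                "status": "ok",
                "promoter": bool(hit.found and hit.p_value <= alpha),
                "score": hit.score,
                "p_value": hit.p_value,
                "offset": (hit.offset + window[0]) if hit.found else np.nan,
                "strength_p": strength.p_value if strength.found else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def classify_polyU(
    ends: Sequence[EndCall],
    genome: Genome,
    window: tuple[int, int] = (-35, 2),
    u_window: int = 8,
    min_u: int = 6,
) -> pd.DataFrame:
    """Poly(U) terminator classification of primary 3' ends.

    +polyU when some ``u_window``-nt subwindow of the sense-strand
    -35..+2 sequence contains at least ``min_u`` T; the maximum U count
    over subwindows is reported.
    """
    rows = []
    for c in ends:
        seq = extract_window(genome, c.contig, c.position, window[0], window[1],
                             strand=c.strand)
        if seq is None:
            rows.append({"gene_id": c.gene_id, "position": c.position,
                         "status": "skipped"})
            continue
        max_u = 0
        for off in range(len(seq) - u_window + 1):
            max_u = max(max_u, seq[off : off + u_window].count("T"))
        rows.append(
            {"gene_id": c.gene_id, "position": c.position, "status": "ok",
             "max_u": max_u, "polyU": max_u >= min_u}
        )
    return pd.DataFrame(rows)


def intergenic_intervals(genome: Genome, genes: Sequence[GeneModel]) -> list[tuple[str, int, int]]:
    """1-based inclusive intervals not covered by any gene body."""
    out = []
    for contig, clen in genome.lengths.items():
        spans = sorted(
            (g.start, g.end) for g in genes if g.contig == contig
        )
        cursor = 1
        for s, e in spans:
            if s > cursor:
                out.append((contig, cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= clen:
            out.append((contig, cursor, clen))
    return out


def nucleotide_enrichment(
    group_seqs: Sequence[str],
    genome: Genome,
    intergenic: Sequence[tuple[str, int, int]],
    n_background: int = 100_000,
    seed: int = 0,
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """Per-position per-base log2 enrichment of a sequence group versus a
    background of bases sampled from intergenic regions.

    ``enrichment(pos, b) = log2((f_group(pos, b) + pc) / (f_bg(b) + pc))``
    with the background from ``n_background`` positions drawn uniformly
    with replacement from the intergenic intervals.
    """
    if not group_seqs:
        raise ValueError("group_seqs is empty")
    if not intergenic:
        raise ValueError("intergenic interval set is empty")
    L = len(group_seqs[0])
    if any(len(s) != L for s in group_seqs):
        raise ValueError("group sequences must have equal length")

    rng = np.random.default_rng(seed)
    widths = np.array([e - s + 1 for _, s, e in intergenic], dtype=float)
    picks = rng.choice(len(intergenic), size=n_background, p=widths / widths.sum())
    bg_counts = np.zeros(4)
    for idx in picks:
        contig, s, e = intergenic[idx]
        p = int(rng.integers(s, e + 1))
        b = genome[contig][p - 1]
        if b in _BASE_INDEX:
            bg_counts[_BASE_INDEX[b]] += 1
    f_bg = bg_counts / bg_counts.sum()

    rows = []
    arr = np.array([[_BASE_INDEX.get(b, -1) for b in s] for s in group_seqs])
    for pos in range(L):
        col = arr[:, pos]
        col = col[col >= 0]
        counts = np.bincount(col, minlength=4)
        f_grp = counts / max(counts.sum(), 1)
        for bi, b in enumerate(BASES):
            rows.append(
                {"position": pos, "base": "U" if b == "T" else b,
                 "enrichment": math.log2((f_grp[bi] + pseudocount) / (f_bg[bi] + pseudocount))}
            )
    return pd.DataFrame(rows)


def leadered_test(
    groups: Mapping[str, Sequence[int]],
    control: Sequence[int],
) -> pd.DataFrame:
    """Leaderless-vs-leadered proportion tests against the control set.

    A transcript is leaderless when its 5' UTR length is 0.  Each group is
    compared to control via a 2x2 Pearson chi-square without continuity
    correction (df = 1); expected cells below 1 flag the row as low-count.
    """
    ctrl = np.asarray(control)
    c_leaderless = int((ctrl == 0).sum())
    c_leadered = int((ctrl > 0).sum())
    rows = []
    for name, utr5 in groups.items():
        u = np.asarray(utr5)
        if len(u) == 0:
            raise ValueError(f"group {name!r} is empty")
        g_leaderless = int((u == 0).sum())
        g_leadered = int((u > 0).sum())
        table = np.array([[g_leaderless, g_leadered], [c_leaderless, c_leadered]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            stat, p = 0.0, 1.0
            expected = np.full((2, 2), np.nan)
        else:
            stat, p, _df, expected = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "group": name,
                "n": len(u),
                "leaderless_proportion": g_leaderless / len(u),
                "chi2": float(stat),
                "p": float(p),
                "low_count": bool(np.nanmin(expected) < 1),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _revcomp_pwm(pwm: PWM) -> PWM:
    # complement = reverse base order (A<->T, C<->G) then reverse positions
    return PWM(scores=pwm.scores[::-1, ::-1].copy(), background=pwm.background,
               pseudocount=pwm.pseudocount)


def is_palindromic(pwm: PWM, tol: float = 1e-9) -> bool:
    return bool(np.allclose(pwm.scores, _revcomp_pwm(pwm).scores, atol=tol))


def regulon_scan(
    genes: Sequence[GeneModel],
    genome: Genome,
    motif: PWM,
    search: tuple[int, int] = (-100, -1),
    alpha: float = 1e-4,
    epsilon: float = 1e-3,
    warn: list | None = None,
) -> pd.DataFrame:
    """Scan upstream windows for a palindromic regulator binding box.

    Both strands of the -100..-1 window (relative to the TSS, or the start
    codon for genes without a TSS) are scanned; hits with p <= alpha are
    returned ranked by score.  A non-palindromic motif triggers a warning
    but both strands are still scanned.
    """
    if motif.length % 2 != 0 or not is_palindromic(motif, tol=1e-6):
        if warn is not None:
            warn.append("motif is not palindrome-symmetric")
    dist = score_distribution(motif, epsilon)
    rows = []
    for g in genes:
        anchor = g.tss if g.tss is not None else g.five_prime
        seq = extract_window(genome, g, anchor, search[0], search[1])
        if seq is None:
            continue
        best = None
        for strand_tag, s in (("sense", seq), ("antisense", revcomp(seq))):
            hit = pwm_scan_pvalue(motif, s, epsilon, _dist=dist)
            if hit.found and (best is None or hit.score > best[0].score):
                best = (hit, strand_tag)
        if best is None:
            continue
        hit, strand_tag = best
        if hit.p_value <= alpha:
            rows.append(
                {"gene_id": g.gene_id, "score": hit.score, "p_value": hit.p_value,
                 "offset": hit.offset + search[0], "scan_strand": strand_tag}
            )
    df = pd.DataFrame(rows, columns=["gene_id", "score", "p_value", "offset", "scan_strand"])
    return df.sort_values(["score", "gene_id"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# codon adaptation index / GC

_STANDARD = CodonTable.unambiguous_dna_by_id[11]
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
_STOP_CODONS = set(_STANDARD.stop_codons)
_SINGLE_CODON_AAS = {aa for aa, codons in _SYNONYMS.items() if len(codons) == 1}


def relative_adaptiveness(
    reference_seqs: Iterable[str], pseudocount: float = 0.5
) -> dict[str, float]:
    """Sharp-Li relative adaptiveness w(codon) from a reference gene set."""
    counts: dict[str, float] = {}
    for seq in reference_seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in _STOP_CODONS or "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0.0) + 1.0
    w: dict[str, float] = {}
    for aa, codons in _SYNONYMS.items():
        freqs = {c: counts.get(c, 0.0) + pseudocount for c in codons}
        fmax = max(freqs.values())
        for c in codons:
            w[c] = freqs[c] / fmax
    return w


def cai(seq: str, w: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of w over the coding codons,
    excluding stops and single-codon amino acids (Met, Trp)."""
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError("coding length not divisible by 3")
    log_sum, n = 0.0, 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS or codon not in _STANDARD.forward_table:
            continue
        if _STANDARD.forward_table[codon] in _SINGLE_CODON_AAS:
            continue
        log_sum += math.log(w[codon])
        n += 1
    if n == 0:
        return float("nan")
    return math.exp(log_sum / n)


def sequence_composition(
    genes: Sequence[GeneModel],
    genome: Genome,
    reference_set: Sequence[str],
) -> pd.DataFrame:
    """Per-gene CAI (vs the reference set, e.g. the top-5% most abundant
    proteins) and coding GC fraction."""
    if not reference_set:
        raise ValueError("reference_set is empty")
    by_id = {g.gene_id: g for g in genes}
    ref_seqs = []
    for gid in reference_set:
        g = by_id[gid]
        s = genome.fetch(g.contig, g.start, g.end, g.strand)
        if len(s) % 3 == 0:
            ref_seqs.append(s)
    w = relative_adaptiveness(ref_seqs)
    rows = []
    for g in genes:
        s = genome.fetch(g.contig, g.start, g.end, g.strand)
        if len(s) % 3 != 0:
            rows.append({"gene_id": g.gene_id, "status": "skipped_length"})
            continue
        gc = (s.count("G") + s.count("C")) / len(s)
        rows.append(
            {"gene_id": g.gene_id, "status": "ok", "cai": cai(s, w), "gc": gc}
        )
    return pd.DataFrame(rows).set_index("gene_id")
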