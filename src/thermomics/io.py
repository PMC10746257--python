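"""Readers and writers for the genomic file formats the pipeline touches.

All in-memory coordinates are 1-based and inclusive on both ends (GFF3
convention).  bedGraph's 0-based half-open intervals are converted at the
I/O boundary only: bedGraph position ``p`` maps to internal position
``p + 1``.  Signed offsets ("upstream", "downstream") are always taken in
transcript orientation, so for minus-strand genes downstream means
decreasing coordinates and extracted sequences are reverse-complemented.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "Genome",
    "GeneModel",
    "EndTrack",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bedgraph",
    "write_bedgraph",
    "revcomp",
    "extract_window",
]


class FormatError(ValueError):
    """A file violated the expected format."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Genome:
    """A set of contigs, uppercase, alphabet restricted to {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {cid!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {cid!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )

    def __getitem__(self, cid: str) -> str:
        return self.contigs[cid]

    def length(self, cid: str) -> int:
        return len(self.contigs[cid])

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive slice, reverse-complemented on the minus strand."""
        if start < 1 or end > self.length(contig) or start > end:
            raise ValueError(
                f"window {start}..{end} outside contig {contig} "
                f"(length {self.length(contig)})"
            )
        seq = self.contigs[contig][start - 1 : end]
        return revcomp(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval with optional TSS / 5'-UTR / category labels.

    ``start``/``end`` are the 1-based inclusive coding boundaries.  ``tss``
    is the primary transcription start site; ``utr5_len`` its distance to
    the first coding base (0 = leaderless).
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    tss: int | None = None
    utr5_len: int | None = None
    arcog: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.tss is not None:
            if self.strand == "+" and self.tss > self.start:
                raise FormatError(f"gene {self.gene_id}: TSS downstream of start")
            if self.strand == "-" and self.tss < self.end:
                raise FormatError(f"gene {self.gene_id}: TSS downstream of start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def three_prime(self) -> int:
        """Coordinate of the last coding base in transcript orientation."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def offset_position(self, offset: int, anchor: int | None = None) -> int:
        """Genomic coordinate at a signed transcript-orientation offset.

        ``offset`` 0 is the anchor itself (default: the TSS); positive
        offsets run downstream, negative upstream.
        """
        if anchor is None:
            if self.tss is None:
                raise ValueError(f"gene {self.gene_id} has no TSS")
            anchor = self.tss
        return anchor + offset if self.strand == "+" else anchor - offset


@dataclass
class EndTrack:
    """Strand-specific per-position read 3'-end counts for one replicate.

    ``counts`` maps 1-based positions to non-negative values.
    ``library_total`` is the total end count of the replicate across both
    strands (and all contigs), used for CPM normalization.
    """

    contig: str
    strand: str
    counts: dict[int, float]
    library_total: float
    normalized: str = "raw"  # "raw" | "cpm"
    contig_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.library_total <= 0 and self.counts:
            raise ValueError("library_total must be positive")
        if self.contig_length is not None:
            for p in self.counts:
                if p < 1 or p > self.contig_length:
                    raise FormatError(
                        f"position {p} outside contig {self.contig} "
                        f"(length {self.contig_length})"
                    )

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def positions(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=int)


# ---------------------------------------------------------------------------
# FASTA


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly gzipped) multi-record FASTA into a :class:`Genome`.

    Record ids are the first whitespace-delimited token of the header;
    sequences are uppercased and checked against {A,C,G,T,N}.
    """
    contigs: dict[str, str] = {}
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise FormatError(f"duplicate contig id {rec.id!r}")
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"record {rec.id!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
            contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for cid in genome.contigs:
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_genes(
    path: str | Path,
    feature: str = "gene",
    attr_filter: tuple[str, str] | None = None,
) -> list[GeneModel]:
    """Read gene records from a GFF3 file.

    Keeps rows whose type equals ``feature`` and, if ``attr_filter`` is
    given as ``(key, value)``, whose attribute column carries that
    key=value pair.  Gene ids come from the ``ID`` attribute; optional
    ``tss``, ``utr5_len`` and ``arcog`` attributes are picked up when
    present (they are emitted by this package's own writer).
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype != feature:
                continue
            attrs = _parse_attributes(attr_s)
            if attr_filter is not None:
                key, value = attr_filter
                if attrs.get(key) != value:
                    continue
            if "ID" not in attrs:
                raise FormatError(f"line {lineno}: record lacks an ID attribute")
            gid = attrs["ID"]
            if gid in seen:
                raise FormatError(f"line {lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            start, end = int(start_s), int(end_s)
            if start > end:
                raise FormatError(f"line {lineno}: start {start} > end {end}")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    tss=int(attrs["tss"]) if "tss" in attrs else None,
                    utr5_len=int(attrs["utr5_len"]) if "utr5_len" in attrs else None,
                    arcog=attrs.get("arcog"),
                )
            )
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}", "biotype=protein_coding"]
            if g.tss is not None:
                attrs.append(f"tss={g.tss}")
            if g.utr5_len is not None:
                attrs.append(f"utr5_len={g.utr5_len}")
            if g.arcog is not None:
                attrs.append(f"arcog={g.arcog}")
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "thermomics",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: str | Path,
    contig_lengths: Mapping[str, int],
    strand: str,
    library_total: float | None = None,
) -> EndTrack:
    """Read a single-contig, single-strand bedGraph file into an EndTrack.

    bedGraph intervals are 0-based half-open; each covered position
    contributes the interval's value to internal position ``p + 1``.
    ``library_total`` should be supplied by the caller when the replicate's
    counts are split across strand files; it defaults to the file's own
    total.
    """
    counts: dict[int, float] = {}
    contig = None
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"line {lineno}: expected 4 columns")
            cid, start_s, end_s, value_s = cols
            start, end, value = int(start_s), int(end_s), float(value_s)
            if cid not in contig_lengths:
                raise FormatError(f"line {lineno}: unknown contig {cid!r}")
            if value < 0:
                raise FormatError(f"line {lineno}: negative value {value}")
            if end > contig_lengths[cid]:
                raise FormatError(
                    f"line {lineno}: interval end {end} beyond contig length "
                    f"{contig_lengths[cid]}"
                )
            if contig is None:
                contig = cid
            elif cid != contig:
                raise FormatError("multi-contig bedGraph files are not supported")
            for p0 in range(start, end):
                counts[p0 + 1] = counts.get(p0 + 1, 0.0) + value
    if contig is None:
        contig = next(iter(contig_lengths))
    total = library_total if library_total is not None else sum(counts.values())
    return EndTrack(
        contig=contig,
        strand=strand,
        counts=counts,
        library_total=max(total, 1e-300) if not counts else total,
        contig_length=contig_lengths[contig],
    )


def write_bedgraph(track: EndTrack, path: str | Path) -> None:
    """Write an EndTrack as bedGraph (adjacent equal-value runs merged)."""
    with _open(path, "wt") as fh:
        run_start = None
        run_end = None
        run_value = None
        for p in sorted(track.counts):
            v = track.counts[p]
            if v == 0:
                continue
            if run_start is not None and p == run_end + 1 and v == run_value:
                run_end = p
                continue
            if run_start is not None:
                fh.write(f"{track.contig}\t{run_start - 1}\t{run_end}\t{run_value:g}\n")
            run_start = run_end = p
            run_value = v
        if run_start is not None:
            fh.write(f"{track.contig}\t{run_start - 1}\t{run_end}\t{run_value:g}\n")


def extract_window(
    genome: Genome,
    gene_or_contig: GeneModel | str,
    anchor: int,
    lo: int,
    hi: int,
    strand: str | None = None,
) -> str | None:
    """Sense-strand sequence at transcript-orientation offsets ``lo..hi``.

    Offset 0 is the anchor position itself.  Returns None when the window
    would run off the contig.
    """
    if isinstance(gene_or_contig, GeneModel):
        contig = gene_or_contig.contig
        strand = gene_or_contig.strand
    else:
        contig = gene_or_contig
        if strand is None:
            raise ValueError("strand required when contig given directly")
    if strand == "+":
        start, end = anchor + lo, anchor + hi
    else:
        start, end = anchor - hi, anchor - lo
    if start < 1 or end > genome.length(contig):
        return None
    return genome.fetch(contig, start, end, strand)
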