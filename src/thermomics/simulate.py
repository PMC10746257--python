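"""Synthetic thermal-stress multi-omics data with planted ground truth.

Emulates the statistical structure of a hyperthermophile stress study:
a small archaeal-like genome with non-overlapping protein-coding genes,
a leaderless fraction, planted BRE/TATA promoters and U-rich intrinsic
terminators; strand-specific Term-seq 3'-end tracks over four replicates;
negative-binomial RNA counts and lognormal protein intensities across a
control plus seven stress conditions, with planted fold changes driven by
condition-profile cluster templates; arCOG-like category labels with one
planted enriched category; and single-molecule long reads for
transcriptional-unit calling.  Everything is deterministic under
``(seed, config)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Genome, GeneModel, EndTrack, revcomp, write_fasta, write_gff3_genes, write_bedgraph

__all__ = [
    "SimConfig",
    "Truth",
    "make_genome_annotation",
    "simulate_termseq",
    "simulate_omics",
    "simulate_longreads",
    "simulate_foldchange_profiles",
    "write_dataset",
    "DEFAULT_CONDITIONS",
    "DEFAULT_TEMPLATES",
]

DEFAULT_CONDITIONS = ["Ctrl", "CS1", "CS2", "CS3", "CSR", "HS1", "HS2", "HSR"]

# Condition-profile templates over the seven stress contrasts (vs Ctrl),
# loosely shaped on heat-shock-transient / heat-persistent / cold-gradual /
# general-down responses.
DEFAULT_TEMPLATES = {
    1: {"CS1": 0.0, "CS2": 0.1, "CS3": 0.2, "CSR": 0.0, "HS1": 1.0, "HS2": 0.8, "HSR": 0.2},
    2: {"CS1": 0.8, "CS2": 1.0, "CS3": 1.0, "CSR": 0.3, "HS1": 0.0, "HS2": -0.1, "HSR": 0.0},
    3: {"CS1": -0.5, "CS2": -0.7, "CS3": -1.0, "CSR": -0.3, "HS1": -0.8, "HS2": -1.0, "HSR": -0.2},
    4: {"CS1": 0.1, "CS2": 0.0, "CS3": -0.2, "CSR": 0.0, "HS1": 1.0, "HS2": 0.1, "HSR": -0.4},
}

BRE_CONSENSUS = "SWAAA"        # G/C, A/T, A, A, A
TATA_CONSENSUS = "TTTWWW"      # T, T, T, A/T, A/T, A/T
PROMOTER_CONSENSUS = BRE_CONSENSUS + "NN" + TATA_CONSENSUS  # planted at -38..-26
REGULON_CONSENSUS = "TTTACANNTGTAAA"  # palindromic repressor box

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the emulated design: four biological replicates over a
    control and seven stress conditions, ~15% leaderless transcripts, a
    ~40% poly(U)-terminator fraction, lognormal expression baselines with
    negative-binomial count noise, and replicate size factors log-uniform
    in [0.5, 2] so that normalization genuinely matters.
    """

    seed: int = 0
    n_genes: int = 200
    contig_length: int | None = None  # auto-sized from n_genes when None
    gc: float = 0.41
    leaderless_fraction: float = 0.15
    promoter_fraction: float = 0.6
    polyU_fraction: float = 0.4
    secondary_fraction: float = 0.3
    internal_fraction: float = 0.2
    regulon_fraction: float = 0.05
    n_replicates: int = 4
    conditions: tuple[str, ...] = tuple(DEFAULT_CONDITIONS)
    # planted log2FC mixture: 0 with prob pi0, else amplitude ~ N(mu, sigma)
    pi0: float = 0.7
    de_mu: float = 2.0
    de_sigma: float = 0.5
    rna_protein_rho: float = 0.69
    k_true: int = 4
    templates: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEMPLATES.items()}
    )
    # noise
    rna_dispersion: float = 0.05
    termseq_dispersion: float = 0.1
    protein_sigma: float = 0.3
    protein_missing_rate: float = 0.05
    sigma_jitter: float = 1.0
    background_rate: float = 5e-4       # background end positions per nt per replicate
    termseq_depth: float = 2e6          # nominal end reads per replicate
    min_end_cpm: float = 20.0           # floor for planted end heights (CPM)
    # expression baselines
    baseline_log_mean: float = np.log(200.0)
    baseline_log_sd: float = 1.0
    # arCOG-like categories
    n_categories: int = 20
    enriched_category: str = "C01"
    enrichment_fold: float = 3.0
    # long reads
    n_reads_per_gene: int = 20
    readthrough_prob: float = 0.0
    read_jitter: int = 0

    def __post_init__(self) -> None:
        for name in ("leaderless_fraction", "promoter_fraction", "polyU_fraction", "pi0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3")
        if "Ctrl" not in self.conditions:
            raise ValueError("conditions must contain 'Ctrl'")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must lie in (0,1)")

    @property
    def contrasts(self) -> list[str]:
        return [c for c in self.conditions if c != "Ctrl"]


@dataclass
class Truth:
    """Planted ground truth, one row per gene plus a 3'-end table.

    ``genes`` columns: gene_id, tss, utr5_len, promoter, polyU, regulon,
    arcog, cluster (1..k_true or <NA> for null genes), de (0/1), plus
    log2FC columns ``rna_lfc_<cond>`` / ``prot_lfc_<cond>``.
    ``ends`` columns: gene_id, contig, strand, position, end_class
    (primary/secondary/internal), cpm (expected height in CPM).
    """

    genes: pd.DataFrame
    ends: pd.DataFrame


def _degenerate_instance(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_IUPAC[c])) for c in consensus)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _write_sense(seq: np.ndarray, contig_pos_hi: int, s: str, strand: str, anchor: int, lo: int) -> None:
    """Write ``s`` (sense orientation) at offsets lo..lo+len(s)-1 from anchor."""
    if strand == "+":
        start = anchor + lo
        seq[start - 1 : start - 1 + len(s)] = list(s)
    else:
        start = anchor - lo - len(s) + 1
        seq[start - 1 : start - 1 + len(s)] = list(revcomp(s))


def make_genome_annotation(cfg: SimConfig) -> tuple[Genome, list[GeneModel], Truth]:
    """Build the synthetic genome, gene models, and the truth tables."""
    rng = np.random.default_rng(cfg.seed)
    gene_lens = (rng.integers(100, 500, size=cfg.n_genes) * 3).astype(int)  # 300..1500, multiple of 3
    spacings = rng.integers(400, 800, size=cfg.n_genes + 1).astype(int)
    needed = int(gene_lens.sum() + spacings.sum())
    contig_length = cfg.contig_length if cfg.contig_length is not None else needed + 1000
    if needed > contig_length:
        raise ValueError(
            f"contig length {contig_length} too small for {cfg.n_genes} genes "
            f"(need >= {needed})"
        )
    seq = _random_seq(rng, contig_length, cfg.gc)
    contig = "synth1"

    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    leaderless = rng.random(cfg.n_genes) < cfg.leaderless_fraction
    utr5 = np.where(leaderless, 0, 1 + rng.geometric(1 / 30.0, size=cfg.n_genes))
    promoter = rng.random(cfg.n_genes) < cfg.promoter_fraction
    polyU = rng.random(cfg.n_genes) < cfg.polyU_fraction
    secondary = rng.random(cfg.n_genes) < cfg.secondary_fraction
    internal = rng.random(cfg.n_genes) < cfg.internal_fraction
    regulon = rng.random(cfg.n_genes) < cfg.regulon_fraction
    utr3 = rng.integers(20, 150, size=cfg.n_genes)

    genes: list[GeneModel] = []
    end_rows: list[dict] = []
    gene_rows: list[dict] = []
    pos = int(spacings[0])
    for i in range(cfg.n_genes):
        gid = f"g{i + 1:04d}"
        start = pos
        end = start + int(gene_lens[i]) - 1
        strand = str(strands[i])
        if strand == "+":
            tss = start - int(utr5[i])
            p3 = end + int(utr3[i])
        else:
            tss = end + int(utr5[i])
            p3 = start - int(utr3[i])
        g = GeneModel(gid, contig, start, end, strand, tss=tss, utr5_len=int(utr5[i]))
        genes.append(g)

        if promoter[i]:
            inst = _degenerate_instance(PROMOTER_CONSENSUS, rng)
            _write_sense(seq, contig_length, inst, strand, tss, -38)
        if regulon[i]:
            inst = _degenerate_instance(REGULON_CONSENSUS, rng)
            offset = int(rng.integers(-80, -20 - len(inst)))
            _write_sense(seq, contig_length, inst, strand, tss, offset)
        if polyU[i]:
            # U-rich stretch (>=13 T of 16 on the coding strand) immediately
            # upstream of the primary 3' end
            stretch = list("T" * 16)
            for j in sorted(rng.choice(16, size=3, replace=False)):
                stretch[j] = str(rng.choice(list("ACG")))
            _write_sense(seq, contig_length, "".join(stretch), strand, p3, -16)

        end_rows.append(
            {"gene_id": gid, "contig": contig, "strand": strand,
             "position": p3, "end_class": "primary"}
        )
        if secondary[i]:
            off2 = int(utr3[i]) + int(rng.integers(40, 120))
            if off2 <= 290:
                p2 = end + off2 if strand == "+" else start - off2
                end_rows.append(
                    {"gene_id": gid, "contig": contig, "strand": strand,
                     "position": p2, "end_class": "secondary"}
                )
        if internal[i]:
            off_in = int(rng.integers(30, max(31, int(gene_lens[i]) - 30)))
            p_in = start + off_in if strand == "+" else end - off_in
            end_rows.append(
                {"gene_id": gid, "contig": contig, "strand": strand,
                 "position": p_in, "end_class": "internal"}
            )
        gene_rows.append(
            {"gene_id": gid, "tss": tss, "utr5_len": int(utr5[i]),
             "promoter": bool(promoter[i]), "polyU": bool(polyU[i]),
             "regulon": bool(regulon[i]), "utr3_len": int(utr3[i])}
        )
        pos = end + int(spacings[i + 1])

    ends = pd.DataFrame(end_rows)
    # planted expected heights in CPM: lognormal, then scaled so that the
    # total planted + background mass is one million (CPM is a closed unit)
    primary_rel = pd.Series(
        rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes),
        index=[f"g{i + 1:04d}" for i in range(cfg.n_genes)],
    )
    rel = primary_rel.loc[ends["gene_id"]].to_numpy()
    rel[(ends["end_class"] == "secondary").to_numpy()] *= 0.3
    rel[(ends["end_class"] == "internal").to_numpy()] *= 0.2
    bg_positions = cfg.background_rate * contig_length * 2
    bg_mass_guess = bg_positions * 1.0 / cfg.termseq_depth * 1e6  # ~1 read each
    scale = (1e6 - bg_mass_guess) / rel.sum()
    cpm = np.maximum(rel * scale, cfg.min_end_cpm)
    ends["cpm"] = cpm

    truth_genes = pd.DataFrame(gene_rows).set_index("gene_id", drop=False)
    genome = Genome({contig: "".join(seq)})
    return genome, genes, Truth(genes=truth_genes, ends=ends)


def simulate_termseq(cfg: SimConfig, truth: Truth, genome: Genome) -> list[dict[str, EndTrack]]:
    """Per-replicate raw end tracks, one ``{"+": track, "-": track}`` pair each.

    Counts at each planted end are negative-binomial around the planted
    height (converted to reads at the replicate's depth), individual reads
    jittered by a rounded Gaussian; uniform single-read background
    positions are added at ``background_rate`` per nt per strand.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    contig = truth.ends["contig"].iloc[0]
    clen = genome.length(contig)
    size_factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=cfg.n_replicates))
    out: list[dict[str, EndTrack]] = []
    disp = cfg.termseq_dispersion
    for r in range(cfg.n_replicates):
        depth = cfg.termseq_depth * size_factors[r]
        counts = {"+": {}, "-": {}}
        for _, row in truth.ends.iterrows():
            mean_reads = row["cpm"] / 1e6 * depth
            if disp > 0:
                n_nb = 1.0 / disp
                p_nb = n_nb / (n_nb + mean_reads)
                n_reads = int(rng.negative_binomial(n_nb, p_nb))
            else:
                n_reads = int(rng.poisson(mean_reads))
            if n_reads == 0:
                continue
            strand_counts = counts[row["strand"]]
            if cfg.sigma_jitter > 0:
                offsets = np.rint(rng.normal(0.0, cfg.sigma_jitter, size=n_reads)).astype(int)
                pos_arr, cnt = np.unique(row["position"] + offsets, return_counts=True)
                for p, c in zip(pos_arr, cnt):
                    p = int(min(max(p, 1), clen))
                    strand_counts[p] = strand_counts.get(p, 0.0) + float(c)
            else:
                p = int(row["position"])
                strand_counts[p] = strand_counts.get(p, 0.0) + float(n_reads)
        for strand in "+-":
            n_bg = rng.poisson(cfg.background_rate * clen)
            bg_pos = rng.integers(1, clen + 1, size=n_bg)
            for p in bg_pos:
                counts[strand][int(p)] = counts[strand].get(int(p), 0.0) + 1.0
        library_total = sum(sum(c.values()) for c in counts.values())
        out.append(
            {
                strand: EndTrack(contig, strand, counts[strand], library_total,
                                 contig_length=clen)
                for strand in "+-"
            }
        )
    return out


def _plant_effects(cfg: SimConfig, truth: Truth, rng: np.random.Generator) -> None:
    """Fill truth.genes with DE flags, cluster labels and log2FC matrices."""
    n = len(truth.genes)
    contrasts = cfg.contrasts
    # genes in the planted enriched category are enrichment_fold times more
    # likely to be differentially expressed
    cats = [f"C{i + 1:02d}" for i in range(cfg.n_categories)]
    cat_labels = rng.choice(cats, size=n)
    truth.genes["arcog"] = cat_labels
    in_cat = cat_labels == cfg.enriched_category
    f_cat = in_cat.mean()
    base_p = (1 - cfg.pi0) / (1 + (cfg.enrichment_fold - 1) * f_cat)
    p_de = np.where(in_cat, np.minimum(cfg.enrichment_fold * base_p, 0.95), base_p)
    de = rng.random(n) < p_de
    clusters = np.where(de, rng.integers(1, cfg.k_true + 1, size=n), 0)
    amplitude = rng.normal(cfg.de_mu, cfg.de_sigma, size=n)

    rna = np.zeros((n, len(contrasts)))
    for k, tpl in cfg.templates.items():
        mask = clusters == k
        rna[mask] = amplitude[mask, None] * np.array([tpl[c] for c in contrasts])
    # protein effects: correlation rho with the RNA effects among DE genes;
    # genes without a planted RNA effect have none at the protein layer either
    sd_fx = rna[de].std() if de.any() and rna[de].std() > 0 else 1.0
    rho = cfg.rna_protein_rho
    prot = rho * rna + np.sqrt(max(1 - rho**2, 0.0)) * sd_fx * rng.normal(size=rna.shape)
    prot[~de] = 0.0

    truth.genes["de"] = de
    truth.genes["cluster"] = pd.array(
        np.where(de, clusters, np.nan), dtype="Int64"
    )
    for j, c in enumerate(contrasts):
        truth.genes[f"rna_lfc_{c}"] = rna[:, j]
        truth.genes[f"prot_lfc_{c}"] = prot[:, j]


def simulate_omics(
    cfg: SimConfig, truth: Truth, gene_lengths: pd.Series | None = None
):
    """RNA count and protein intensity matrices with an attached design.

    Returns two :class:`~thermomics.de.OmicsMatrix` objects.  RNA counts
    are negative binomial around ``baseline * 2**lfc * size_factor``;
    protein intensities are lognormal around a compressed power of the RNA
    baseline times ``2**lfc_protein``, with values missing at random at
    ``protein_missing_rate``.
    """
    from .de import OmicsMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    if "de" not in truth.genes.columns:
        _plant_effects(cfg, truth, rng)
    n = len(truth.genes)
    contrasts = cfg.contrasts
    baselines = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    samples = [(c, r + 1) for c in cfg.conditions for r in range(cfg.n_replicates)]
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))

    rna_lfc = np.zeros((n, len(cfg.conditions)))
    prot_lfc = np.zeros((n, len(cfg.conditions)))
    for j, c in enumerate(cfg.conditions):
        if c == "Ctrl":
            continue
        rna_lfc[:, j] = truth.genes[f"rna_lfc_{c}"].to_numpy()
        prot_lfc[:, j] = truth.genes[f"prot_lfc_{c}"].to_numpy()

    cond_index = {c: j for j, c in enumerate(cfg.conditions)}
    rna_vals = np.zeros((n, len(samples)))
    for s, (c, _r) in enumerate(samples):
        mu = baselines * 2.0 ** rna_lfc[:, cond_index[c]] * sf[s]
        if cfg.rna_dispersion > 0:
            n_nb = 1.0 / cfg.rna_dispersion
            rna_vals[:, s] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
        else:
            rna_vals[:, s] = rng.poisson(mu)

    prot_base = 100.0 * baselines**0.8
    prot_vals = np.zeros((n, len(samples)))
    for s, (c, _r) in enumerate(samples):
        mu = prot_base * 2.0 ** prot_lfc[:, cond_index[c]]
        prot_vals[:, s] = mu * rng.lognormal(0.0, cfg.protein_sigma, size=n)
    if cfg.protein_missing_rate > 0:
        miss = rng.random(prot_vals.shape) < cfg.protein_missing_rate
        prot_vals[miss] = np.nan

    gene_ids = truth.genes["gene_id"].tolist()
    sample_names = [f"{c}_{r}" for c, r in samples]
    design = pd.DataFrame(
        {"sample": sample_names, "condition": [c for c, _ in samples],
         "replicate": [r for _, r in samples]}
    ).set_index("sample")
    if gene_lengths is None:
        gene_lengths = pd.Series(
            rng.integers(300, 1501, size=n), index=gene_ids, name="length"
        )
    rna = OmicsMatrix(
        values=pd.DataFrame(rna_vals, index=gene_ids, columns=sample_names),
        design=design, kind="rna", lengths=gene_lengths,
    )
    protein = OmicsMatrix(
        values=pd.DataFrame(prot_vals, index=gene_ids, columns=sample_names),
        design=design.copy(), kind="protein",
    )
    return rna, protein


def simulate_longreads(
    cfg: SimConfig,
    truth: Truth,
    genes: list[GeneModel],
    readthrough_pairs: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Single-molecule read intervals spanning each gene TSS to 3' end.

    ``readthrough_pairs`` maps (upstream_gene, downstream_gene) to the
    probability that a read starting in the upstream gene continues
    through the downstream one (default: ``cfg.readthrough_prob`` for all
    adjacent same-strand pairs).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    by_id = {g.gene_id: g for g in genes}
    p3 = truth.ends.query("end_class == 'primary'").set_index("gene_id")["position"]
    # downstream neighbour on the same strand, by transcript order
    neighbour: dict[str, str] = {}
    for strand in "+-":
        sub = [g for g in genes if g.strand == strand]
        sub.sort(key=lambda g: g.start, reverse=(strand == "-"))
        for a, b in zip(sub, sub[1:]):
            neighbour[a.gene_id] = b.gene_id
    rows = []
    for g in genes:
        rt_prob = cfg.readthrough_prob
        nxt = neighbour.get(g.gene_id)
        if readthrough_pairs is not None:
            rt_prob = readthrough_pairs.get((g.gene_id, nxt), 0.0) if nxt else 0.0
        for _ in range(cfg.n_reads_per_gene):
            jit5 = int(rng.integers(-cfg.read_jitter, cfg.read_jitter + 1)) if cfg.read_jitter else 0
            jit3 = int(rng.integers(-cfg.read_jitter, cfg.read_jitter + 1)) if cfg.read_jitter else 0
            five = g.tss + jit5 if g.strand == "+" else g.tss - jit5
            three = int(p3[g.gene_id])
            if nxt is not None and rt_prob > 0 and rng.random() < rt_prob:
                three = int(p3[nxt])
            three = three + jit3 if g.strand == "+" else three - jit3
            start, end = (five, three) if g.strand == "+" else (three, five)
            rows.append(
                {"contig": g.contig, "start": min(start, end),
                 "end": max(start, end), "strand": g.strand, "origin": g.gene_id}
            )
    return pd.DataFrame(rows)


def simulate_foldchange_profiles(
    n_genes: int,
    k_true: int,
    separation: float,
    noise_sd: float = 1.0,
    n_conditions: int = 7,
    n_layers: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene-profile matrix from ``k_true`` templates at a given separation.

    Templates are the vertices of a regular simplex, randomly rotated,
    with every pairwise template distance equal to ``separation`` times
    the noise magnitude of one profile (``noise_sd * sqrt(n_features)``,
    the root-mean norm of a gene's iid noise vector); per-gene noise is
    iid normal with per-feature sd ``noise_sd``.  Returns the (genes x
    condition/layer) fold-change frame and the true labels.
    """
    rng = np.random.default_rng(seed)
    d = n_conditions * n_layers
    if k_true > d:
        raise ValueError("k_true may not exceed the number of features")
    # regular simplex: centered unit basis vectors have pairwise distance
    # sqrt(2); embed in d dims and rotate by a random orthogonal matrix
    simplex = np.eye(k_true, d)
    simplex -= simplex.mean(axis=0)
    q, _r = np.linalg.qr(rng.normal(size=(d, d)))
    templates = simplex @ q.T
    target = separation * noise_sd * math.sqrt(d)
    templates *= target / math.sqrt(2.0)
    labels = rng.integers(0, k_true, size=n_genes)
    data = templates[labels] + rng.normal(0.0, noise_sd, size=(n_genes, d))
    cols = pd.MultiIndex.from_tuples(
        [(f"cond{j + 1}", layer) for layer in ("rna", "protein")[:n_layers]
         for j in range(n_conditions)],
        names=["condition", "layer"],
    )
    frame = pd.DataFrame(data, index=[f"g{i + 1:04d}" for i in range(n_genes)], columns=cols)
    return frame, labels + 1


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full dataset and write every artifact to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = make_genome_annotation(cfg)
    tracks = simulate_termseq(cfg, truth, genome)
    rna, protein = simulate_omics(cfg, truth)
    reads = simulate_longreads(cfg, truth, genes)

    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["fasta"])
    paths["gff"] = outdir / "genes.gff3"
    write_gff3_genes(genes, paths["gff"])
    for r, pair in enumerate(tracks, start=1):
        for strand, tag in (("+", "plus"), ("-", "minus")):
            key = f"bedgraph_rep{r}_{tag}"
            paths[key] = outdir / f"termseq_rep{r}_{tag}.bedgraph"
            write_bedgraph(pair[strand], paths[key])
    paths["rna"] = outdir / "rna_counts.tsv"
    rna.values.to_csv(paths["rna"], sep="\t")
    paths["protein"] = outdir / "protein_ibaq.tsv"
    protein.values.to_csv(paths["protein"], sep="\t")
    paths["design"] = outdir / "design.tsv"
    rna.design.to_csv(paths["design"], sep="\t")
    paths["lengths"] = outdir / "gene_lengths.tsv"
    rna.lengths.to_frame().to_csv(paths["lengths"], sep="\t")
    paths["arcog"] = outdir / "arcog.tsv"
    truth.genes[["gene_id", "arcog"]].to_csv(paths["arcog"], sep="\t", index=False)
    paths["reads"] = outdir / "longreads.bed"
    bed = reads.copy()
    bed["bed_start"] = bed["start"] - 1
    bed[["contig", "bed_start", "end", "origin", "strand"]].assign(score=0)[
        ["contig", "bed_start", "end", "origin", "score", "strand"]
    ].to_csv(paths["reads"], sep="\t", index=False, header=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_ends"] = outdir / "truth_ends.tsv"
    truth.ends.to_csv(paths["truth_ends"], sep="\t", index=False)
    return paths
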