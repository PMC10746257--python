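import itertools
import math

import numpy as np
import pandas as pd
import pytest

from thermomics.io import Genome, GeneModel, revcomp
from thermomics.ends import EndCall
from thermomics.motifs import (
    PWM, pwm_from_consensus, pwm_sf, pwm_scan_pvalue, score_distribution,
    classify_promoter, classify_polyU, nucleotide_enrichment,
    intergenic_intervals, leadered_test, regulon_scan, is_palindromic,
    relative_adaptiveness, cai, sequence_composition, BASES,
)
from thermomics.simulate import (
    SimConfig, make_genome_annotation, PROMOTER_CONSENSUS, REGULON_CONSENSUS,
)


class TestPwmConstruction:
    def test_single_base_scores(self):
        pwm = pwm_from_consensus("A", match_prob=0.9)
        assert pwm.scores[0, 0] == pytest.approx(math.log2(0.9 / 0.25))
        assert pwm.scores[0, 1] == pytest.approx(math.log2((0.1 / 3) / 0.25))

    def test_degenerate_split(self):
        pwm = pwm_from_consensus("W", match_prob=0.9)
        # A and T share 0.45 each
        assert pwm.scores[0, 0] == pytest.approx(math.log2(0.45 / 0.25))
        assert pwm.scores[0, 3] == pytest.approx(pwm.scores[0, 0])

    def test_length_and_invalid_code(self):
        assert pwm_from_consensus("TTTWWW").length == 6
        with pytest.raises(ValueError):
            pwm_from_consensus("TTX")


class TestExactPvalue:
    def test_length_one_enumeration(self):
        pwm = PWM(scores=np.array([[1.0, -1.0, -1.0, -1.0]]),
                  background=np.full(4, 0.25))
        assert pwm_sf(pwm, 1.0) == pytest.approx(0.25)
        assert pwm_sf(pwm, -1.0) == pytest.approx(1.0)

    def test_dp_equals_enumeration_up_to_length_five(self):
        rng = np.random.default_rng(7)
        eps = 1e-3
        for _ in range(30):
            L = int(rng.integers(1, 6))
            scores = np.round(rng.normal(0, 2, size=(L, 4)), 3)
            bg = rng.dirichlet([5, 5, 5, 5])
            pwm = PWM(scores=scores, background=bg)
            seqs = list(itertools.product(range(4), repeat=L))
            all_scores = np.array(
                [sum(scores[i, b] for i, b in enumerate(s)) for s in seqs])
            all_probs = np.array(
                [np.prod([bg[b] for b in s]) for s in seqs])
            for thr in rng.choice(all_scores, size=min(5, len(all_scores)),
                                  replace=False):
                exact = all_probs[all_scores >= thr - eps / 2].sum()
                assert pwm_sf(pwm, float(thr), eps) == pytest.approx(
                    exact, abs=1e-9)

    def test_consensus_sequence_attains_minimal_pvalue(self):
        pwm = pwm_from_consensus("TTTWWW")
        hit = pwm_scan_pvalue(pwm, "TTTAAT")
        assert hit.score == pytest.approx(pwm.max_score)
        support, probs = score_distribution(pwm)
        assert hit.p_value == pytest.approx(probs[-1] + probs[support >= support[-1]].sum() - probs[-1])

    def test_pvalue_monotone_in_score(self):
        pwm = pwm_from_consensus("SWAAA")
        support, probs = score_distribution(pwm)
        sf = probs[::-1].cumsum()[::-1]
        assert (np.diff(sf) <= 1e-12).all()

    def test_n_windows_skipped(self):
        pwm = pwm_from_consensus("AAA")
        hit = pwm_scan_pvalue(pwm, "NNANN")
        assert not hit.found
        hit2 = pwm_scan_pvalue(pwm, "NAAAN")
        assert hit2.found and hit2.offset == 1


class TestPromoterClassification:
    def test_planted_promoters_detected(self, small_dataset):
        cfg, genome, genes, truth = small_dataset
        pwm = pwm_from_consensus(PROMOTER_CONSENSUS)
        res = classify_promoter(genes, genome, pwm)
        planted = truth.genes.index[truth.genes["promoter"]]
        assert res.loc[planted, "promoter"].all()
        # strength p-value available and smaller for planted genes
        unplanted = truth.genes.index[~truth.genes["promoter"]]
        assert (res.loc[planted, "strength_p"].median()
                < res.loc[unplanted, "strength_p"].median())

    def test_mismatches_score_lower_than_exact(self):
        pwm = pwm_from_consensus(PROMOTER_CONSENSUS)
        exact = "GAAAA" + "CC" + "TTTAAA"
        two_mm = "GACGA" + "CC" + "TTTAAA"
        assert pwm.score(two_mm) < pwm.score(exact)

    def test_gene_without_tss_reported(self, toy_genome):
        g = GeneModel("g1", "c1", 40, 60, "+")
        res = classify_promoter([g], toy_genome, pwm_from_consensus("SWAAA"))
        assert res.loc["g1", "status"] == "no_tss"

    def test_tss_near_edge_skipped(self, toy_genome):
        g = GeneModel("g1", "c1", 20, 40, "+", tss=10)
        res = classify_promoter([g], toy_genome, pwm_from_consensus("SWAAA"))
        assert res.loc["g1", "status"] == "skipped"


class TestPolyU:
    def _end(self, pos, strand="+"):
        return EndCall("c1", strand, pos, 50.0, 4, gene_id="g1",
                       end_class="primary")

    def test_u_run_detected(self):
        genome = Genome({"c1": "A" * 30 + "TTTTTTTT" + "A" * 30})
        res = classify_polyU([self._end(45)], genome)
        assert res.loc[0, "polyU"] and res.loc[0, "max_u"] == 8

    def test_all_a_window_negative(self):
        genome = Genome({"c1": "A" * 100})
        res = classify_polyU([self._end(50)], genome)
        assert not res.loc[0, "polyU"]

    def test_boundary_six_of_eight(self):
        genome = Genome({"c1": "A" * 30 + "TTTATTTA" + "A" * 30})
        res = classify_polyU([self._end(45)], genome)
        assert res.loc[0, "polyU"] and res.loc[0, "max_u"] == 6

    def test_minus_strand_reads_sense_sequence(self):
        # poly(U) on the minus-strand transcript = poly(A) on the + genome
        genome = Genome({"c1": "G" * 30 + "AAAAAAAA" + "G" * 30})
        res = classify_polyU([self._end(25, strand="-")], genome)
        assert res.loc[0, "polyU"]


class TestNucleotideEnrichment:
    def test_definition_on_known_frequencies(self):
        genome = Genome({"c1": "ACGT" * 2500})  # uniform background
        inter = [("c1", 1, 10000)]
        seqs = ["TA", "TC", "TG", "TT"]  # pos0: all T; pos1: uniform
        res = nucleotide_enrichment(seqs, genome, inter, n_background=20000,
                                    seed=1)
        u0 = res.query("position == 0 and base == 'U'")["enrichment"].iloc[0]
        assert u0 == pytest.approx(2.0, abs=0.05)  # log2(1.0/0.25)
        u1 = res.query("position == 1 and base == 'U'")["enrichment"].iloc[0]
        assert abs(u1) < 0.1

    def test_null_group_centered_at_zero(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        genome = Genome({"c1": seq})
        inter = [("c1", 1, 20000)]
        means = []
        for size in (200, 3000):
            starts = rng.integers(1, 19950, size=size)
            seqs = [genome["c1"][s - 1 : s + 9] for s in starts]
            res = nucleotide_enrichment(seqs, genome, inter,
                                        n_background=50000, seed=2)
            means.append(res["enrichment"].abs().mean())
        assert means[1] < means[0]
        assert means[1] < 0.1

    def test_empty_intergenic_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            nucleotide_enrichment(["AC"], toy_genome, [])


class TestLeaderedTest:
    def test_hand_computed_chi_square(self):
        # 2x2 table [[10,90],[30,70]]: expected 20/80 in each row -> 12.5
        groups = {"g": [0] * 10 + [5] * 90}
        control = [0] * 30 + [5] * 70
        res = leadered_test(groups, control)
        assert res.loc["g", "chi2"] == pytest.approx(12.5)
        assert res.loc["g", "leaderless_proportion"] == pytest.approx(0.1)

    def test_identical_distribution_gives_zero(self):
        groups = {"g": [0] * 20 + [9] * 80}
        res = leadered_test(groups, [0] * 20 + [9] * 80)
        assert res.loc["g", "chi2"] == pytest.approx(0.0)
        assert res.loc["g", "p"] == pytest.approx(1.0)

    def test_all_leadered_group(self):
        groups = {"up": [9, 12, 30, 44]}
        res = leadered_test(groups, [0] * 15 + [20] * 85)
        assert res.loc["up", "leaderless_proportion"] == 0.0

    def test_low_count_flagged(self):
        res = leadered_test({"g": [0, 1]}, [0, 1, 1])
        assert bool(res.loc["g", "low_count"])


class TestRegulonScan:
    def test_planted_regulon_hits_found(self):
        cfg = SimConfig(seed=13, n_genes=150, regulon_fraction=0.1)
        genome, genes, truth = make_genome_annotation(cfg)
        motif = pwm_from_consensus(REGULON_CONSENSUS)
        hits = regulon_scan(genes, genome, motif, alpha=1e-4)
        planted = set(truth.genes.index[truth.genes["regulon"]])
        assert planted and planted <= set(hits["gene_id"])

    def test_palindrome_reverse_complement_symmetry(self):
        motif = pwm_from_consensus(REGULON_CONSENSUS)
        assert is_palindromic(motif)
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            fwd = pwm_scan_pvalue(motif, seq)
            rev = pwm_scan_pvalue(motif, revcomp(seq))
            assert fwd.score == pytest.approx(rev.score, abs=1e-9)

    def test_alpha_zero_empty(self):
        cfg = SimConfig(seed=13, n_genes=20)
        genome, genes, _truth = make_genome_annotation(cfg)
        hits = regulon_scan(genes, genome, pwm_from_consensus(REGULON_CONSENSUS),
                            alpha=0.0)
        assert hits.empty

    def test_non_palindromic_motif_warns(self):
        cfg = SimConfig(seed=13, n_genes=5)
        genome, genes, _ = make_genome_annotation(cfg)
        warnings_list = []
        regulon_scan(genes, genome, pwm_from_consensus("AAAACC"),
                     warn=warnings_list)
        assert warnings_list


class TestCai:
    def test_preferred_codon_gene_scores_one(self):
        # reference uses GCT (Ala) and AAA (Lys) exclusively
        ref = ["GCTGCTAAA" * 4]
        w = relative_adaptiveness(ref)
        assert cai("GCTAAAGCT", w) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_reference_gives_cai_one(self):
        w = {c: 1.0 for aa, codons in
             [("*", [])] for c in []}
        # uniform synonymous usage -> all w == 1 (with zero counts,
        # pseudocounts make every codon equally frequent)
        w = relative_adaptiveness([])
        assert all(v == pytest.approx(1.0) for v in w.values())
        assert cai("GCTAAAGGG", w) == pytest.approx(1.0)

    def test_hand_computed_geometric_mean(self):
        w = {"GCT": 0.5, "AAA": 0.125}
        w.update({c: 1.0 for c in relative_adaptiveness([]) if c not in w})
        assert cai("GCTAAA", w) == pytest.approx(0.25)

    def test_single_codon_amino_acids_excluded(self):
        w = relative_adaptiveness(["GCTGCTGCT"])
        # ATG (Met) and TGG (Trp) contribute nothing
        assert cai("ATGTGGGCT", w) == pytest.approx(cai("GCT", w))

    def test_synonymous_permutation_invariance(self):
        w = relative_adaptiveness(["GCTGCAAAAAAGGAT"])
        a = cai("GCTAAAGAT", w)
        b = cai("GATGCTAAA", w)
        assert a == pytest.approx(b)
        assert 0 < a <= 1

    def test_sequence_composition_table(self, small_dataset):
        cfg, genome, genes, _truth = small_dataset
        ref = [g.gene_id for g in genes[:5]]
        res = sequence_composition(genes, genome, ref)
        ok = res[res["status"] == "ok"]
        assert ((ok["cai"] > 0) & (ok["cai"] <= 1)).all()
        assert ((ok["gc"] >= 0) & (ok["gc"] <= 1)).all()


class TestStrandMirror:
    def test_promoter_and_polyu_invariant_under_mirroring(self):
        cfg = SimConfig(seed=17, n_genes=40)
        genome, genes, truth = make_genome_annotation(cfg)
        L = genome.length("synth1")
        mirror_genome = Genome({"synth1": revcomp(genome["synth1"])})
        mirror_genes = [
            GeneModel(g.gene_id, g.contig, L - g.end + 1, L - g.start + 1,
                      "-" if g.strand == "+" else "+",
                      tss=L - g.tss + 1, utr5_len=g.utr5_len)
            for g in genes
        ]
        pwm = pwm_from_consensus(PROMOTER_CONSENSUS)
        fwd = classify_promoter(genes, genome, pwm)
        rev = classify_promoter(mirror_genes, mirror_genome, pwm)
        ok = fwd["status"] == "ok"
        assert fwd.loc[ok, "promoter"].equals(rev.loc[ok, "promoter"])
        np.testing.assert_allclose(fwd.loc[ok, "score"], rev.loc[ok, "score"])

        prim = truth.ends.query("end_class == 'primary'")
        ends_f = [EndCall("synth1", r["strand"], int(r["position"]), 50.0, 4,
                          gene_id=r["gene_id"], end_class="primary")
                  for _, r in prim.iterrows()]
        ends_r = [EndCall("synth1", "-" if r["strand"] == "+" else "+",
                          L - int(r["position"]) + 1, 50.0, 4,
                          gene_id=r["gene_id"], end_class="primary")
                  for _, r in prim.iterrows()]
        pf = classify_polyU(ends_f, genome)
        pr = classify_polyU(ends_r, mirror_genome)
        assert pf["polyU"].tolist() == pr["polyU"].tolist()
        assert pf["max_u"].tolist() == pr["max_u"].tolist()
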