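import numpy as np
import pandas as pd
import pytest

from conftest import make_track
from thermomics.io import EndTrack, GeneModel
from thermomics.ends import (
    cpm_normalize, call_consensus_ends, classify_ends, utr3_lengths,
    call_transcriptional_units, evaluate_end_recovery, EndCall,
)
from thermomics.simulate import SimConfig, make_genome_annotation, simulate_termseq


def brute_force_consensus(tracks, min_replicates, min_cpm, merge_window, length):
    """Literal re-statement of the consensus rule over every coordinate."""
    strand = tracks[0].strand
    covered = [any(t.counts.get(p, 0) > 0 for t in tracks)
               for p in range(length + 1)]  # index 0 unused
    # maximal nonzero runs, bridging gaps <= merge_window
    runs, p = [], 1
    while p <= length:
        if covered[p]:
            start = p
            end = p
            q = p + 1
            gap = 0
            while q <= length and gap <= merge_window:
                if covered[q]:
                    end = q
                    gap = 0
                else:
                    gap += 1
                q += 1
            runs.append((start, end))
            p = end + 1
        else:
            p += 1
    out = []
    for start, end in runs:
        votes = {}
        for t in tracks:
            best_pos, best_val = -1, 0.0
            positions = range(start, end + 1)
            if strand == "-":
                positions = reversed(list(positions))
            for q in positions:
                v = t.counts.get(q, 0.0)
                if v > best_val:
                    best_pos, best_val = q, v
            if best_pos >= 0:
                votes.setdefault(best_pos, []).append(best_val)
        for pos in sorted(votes):
            hs = votes[pos]
            if len(hs) >= min_replicates and np.mean(hs) >= min_cpm:
                out.append((pos, round(float(np.mean(hs)), 9), len(hs)))
    return sorted(out)


class TestCpmNormalize:
    def test_conservation(self):
        t = make_track({1: 10, 2: 30, 3: 60}, total=100)
        c = cpm_normalize(t)
        assert c.counts == {1: 1e5, 2: 3e5, 3: 6e5}
        assert sum(c.counts.values()) == pytest.approx(1e6)

    def test_single_position(self):
        c = cpm_normalize(make_track({5: 7}, total=7))
        assert c.counts[5] == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        t = make_track({1: 1}, total=1)
        with pytest.raises(ValueError):
            cpm_normalize(t, library_total=0)

    def test_double_normalization_rejected(self):
        c = cpm_normalize(make_track({1: 1}, total=1))
        with pytest.raises(ValueError):
            cpm_normalize(c)

    def test_split_strand_totals_sum_to_one_million(self):
        plus = make_track({1: 30}, strand="+", total=100)
        minus = make_track({9: 70}, strand="-", total=100)
        cp, cm = cpm_normalize(plus), cpm_normalize(minus)
        assert sum(cp.counts.values()) + sum(cm.counts.values()) == pytest.approx(1e6)


class TestConsensus:
    def _tracks(self, argmaxes, height=50.0):
        tracks = []
        for am in argmaxes:
            counts = {997: 1.0, am: height}
            tracks.append(make_track(counts, total=1e6, normalized="cpm"))
        return tracks

    def test_three_of_four_identical_argmax(self):
        calls = call_consensus_ends(self._tracks([1000, 1000, 1000, 998]))
        assert len(calls) == 1
        _pk, c = calls[0]
        assert (c.position, c.n_supporting) == (1000, 3)

    def test_two_two_split_gives_no_call(self):
        assert call_consensus_ends(self._tracks([1000, 1000, 998, 998])) == []

    def test_mean_cpm_just_below_five_excluded(self):
        calls = call_consensus_ends(
            [make_track({1000: 4.9}, total=1e6, normalized="cpm")] * 4
        )
        assert calls == []
        calls = call_consensus_ends(
            [make_track({1000: 5.0}, total=1e6, normalized="cpm")] * 4
        )
        assert len(calls) == 1

    def test_requires_cpm_tracks(self):
        with pytest.raises(ValueError):
            call_consensus_ends([make_track({1: 10})] * 4)

    def test_mixed_strands_rejected(self):
        t = [make_track({1: 10}, normalized="cpm", total=10, strand=s)
             for s in "++--"]
        with pytest.raises(ValueError):
            call_consensus_ends(t)

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(0)
        tracks = []
        for _ in range(4):
            pos = rng.choice(2000, size=60, replace=False) + 1
            vals = rng.integers(1, 40, size=60).astype(float)
            tracks.append(make_track(dict(zip(map(int, pos), vals)),
                                     total=1e6, normalized="cpm"))
        base = call_consensus_ends(tracks, min_replicates=3, min_cpm=5)
        stricter_cpm = call_consensus_ends(tracks, min_replicates=3, min_cpm=10)
        stricter_rep = call_consensus_ends(tracks, min_replicates=4, min_cpm=5)
        base_pos = {c.position for _p, c in base}
        assert {c.position for _p, c in stricter_cpm} <= base_pos
        assert {c.position for _p, c in stricter_rep} <= base_pos

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_on_random_tracks(self, strand):
        rng = np.random.default_rng(42 if strand == "+" else 43)
        for _trial in range(50):
            length = int(rng.integers(100, 2000))
            tracks = []
            for _ in range(4):
                n = int(rng.integers(5, 40))
                pos = rng.choice(length, size=n, replace=False) + 1
                vals = rng.integers(1, 30, size=n).astype(float)
                tracks.append(
                    EndTrack("c1", strand, dict(zip(map(int, pos), vals)),
                             1e6, normalized="cpm", contig_length=length)
                )
            got = sorted(
                (c.position, round(c.height, 9), c.n_supporting)
                for _p, c in call_consensus_ends(tracks, merge_window=3)
            )
            want = brute_force_consensus(tracks, 3, 5.0, 3, length)
            assert got == want


class TestClassification:
    GENES = [
        GeneModel("gA", "c1", 4000, 5000, "+"),
        GeneModel("gB", "c1", 6000, 7000, "+"),
        GeneModel("gC", "c1", 2000, 3000, "-"),
    ]

    def _call(self, pos, height, strand="+"):
        return EndCall("c1", strand, pos, height, 4)

    def test_primary_secondary_internal(self):
        calls = [self._call(5060, 80.0), self._call(5150, 20.0),
                 self._call(4500, 10.0)]
        out = {c.position: c for c in classify_ends(calls, self.GENES)}
        assert out[5060].end_class == "primary" and out[5060].gene_id == "gA"
        assert out[5150].end_class == "secondary"
        assert out[4500].end_class == "internal"
        assert out[5060].utr3_len == 60

    def test_boundary_position_is_internal(self):
        out = classify_ends([self._call(5000, 50.0)], self.GENES)
        assert out[0].end_class == "internal"

    def test_outside_window_is_orphan(self):
        out = classify_ends([self._call(5350, 50.0)], self.GENES)
        assert out[0].end_class == "orphan"

    def test_minus_strand_downstream(self):
        out = classify_ends([self._call(1940, 50.0, strand="-")], self.GENES)
        assert out[0].gene_id == "gC" and out[0].end_class == "primary"
        assert out[0].utr3_len == 60

    def test_shared_window_assigned_to_nearer_gene(self):
        # 5290 is downstream of gA (offset 290) and upstream-of-body of gB;
        # make both windows overlap by placing an end between two + genes
        genes = [GeneModel("g1", "c1", 1000, 2000, "+"),
                 GeneModel("g2", "c1", 2100, 2200, "+")]
        out = classify_ends([self._call(2250, 50.0)], genes)
        # offset from g1 = 250, from g2 = 50 -> nearer gene g2
        assert out[0].gene_id == "g2"

    def test_tie_height_broken_toward_gene(self):
        calls = [self._call(5100, 50.0), self._call(5040, 50.0)]
        out = {c.position: c for c in classify_ends(calls, self.GENES)}
        assert out[5040].end_class == "primary"
        assert out[5100].end_class == "secondary"


class TestUtr3:
    def test_lengths_and_omissions(self):
        genes = [GeneModel("gA", "c1", 4000, 5000, "+"),
                 GeneModel("gB", "c1", 6000, 7000, "+")]
        calls = classify_ends([EndCall("c1", "+", 5060, 80.0, 4)], genes)
        table = utr3_lengths(calls, genes)
        assert table.to_dict() == {"gA": 60}

    def test_primary_at_boundary_plus_one(self):
        genes = [GeneModel("gA", "c1", 4000, 5000, "+")]
        calls = classify_ends([EndCall("c1", "+", 5001, 80.0, 4)], genes)
        assert utr3_lengths(calls, genes).to_dict() == {"gA": 1}


class TestTranscriptionalUnits:
    GENES = [GeneModel("g1", "c1", 1000, 2000, "+"),
             GeneModel("g2", "c1", 2500, 3500, "+")]

    def _reads(self, n, start, end):
        return pd.DataFrame(
            {"contig": "c1", "start": start, "end": end, "strand": "+",
             "origin": "g1"}, index=range(n)
        )

    def test_spanning_reads_call_cotranscription(self):
        reads = self._reads(10, 1000, 3500)
        out = call_transcriptional_units(reads, self.GENES)
        assert out.loc[0, "unit"] == "co-transcribed"
        assert out.loc[0, "n_spanning_reads"] == 10

    def test_no_spanning_reads(self):
        reads = self._reads(10, 1000, 2000)
        out = call_transcriptional_units(reads, self.GENES)
        assert out.loc[0, "unit"] == "separate"

    def test_threshold_boundary(self):
        out4 = call_transcriptional_units(self._reads(4, 1000, 3500), self.GENES)
        out5 = call_transcriptional_units(self._reads(5, 1000, 3500), self.GENES)
        assert out4.loc[0, "unit"] == "separate"
        assert out5.loc[0, "unit"] == "co-transcribed"


class TestRecoveryOnSynthetic:
    def _run(self, cfg):
        genome, genes, truth = make_genome_annotation(cfg)
        tracks = simulate_termseq(cfg, truth, genome)
        calls = []
        for strand in "+-":
            cpm = [cpm_normalize(rep[strand]) for rep in tracks]
            calls.extend(c for _p, c in call_consensus_ends(cpm))
        return classify_ends(calls, genes), truth

    def test_noise_free_exact_recovery(self):
        cfg = SimConfig(seed=5, n_genes=100, sigma_jitter=0.0, background_rate=0.0)
        classified, truth = self._run(cfg)
        res = evaluate_end_recovery(classified, truth.ends,
                                    min_truth_cpm=5.0, tolerance=0)
        assert res["f1"] == 1.0
        assert res["class_accuracy"] == 1.0

    def test_strand_mirror_symmetry(self):
        cfg = SimConfig(seed=6, n_genes=60, sigma_jitter=0.0, background_rate=0.0)
        genome, genes, truth = make_genome_annotation(cfg)
        tracks = simulate_termseq(cfg, truth, genome)
        L = genome.length("synth1")

        def consensus_positions(track_pairs, flip):
            out = {}
            for strand in "+-":
                cpm = [cpm_normalize(rep[strand]) for rep in track_pairs]
                for _p, c in call_consensus_ends(cpm):
                    out[(strand, c.position)] = round(c.height, 6)
            return out

        fwd = consensus_positions(tracks, flip=False)
        mirrored = []
        for rep in tracks:
            flip = {}
            for strand, other in (("+", "-"), ("-", "+")):
                flip[other] = EndTrack(
                    "synth1", other,
                    {L - p + 1: v for p, v in rep[strand].counts.items()},
                    rep[strand].library_total, contig_length=L,
                )
            mirrored.append(flip)
        rev = consensus_positions(mirrored, flip=True)
        assert fwd == {
            ("+" if s == "-" else "-", L - p + 1): v for (s, p), v in rev.items()
        }
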