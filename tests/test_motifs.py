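"""PWM scanning vs brute force, conservation filtering, scores, enrichment."""

import math

import numpy as np
import pytest

from hcrtkit.motifs import (
    PositionWeightMatrix,
    bh_adjust,
    combined_gene_score,
    conserved_hits_by_gene,
    filter_conserved_hits,
    read_transfac,
    scan_sequence,
    tf_set_enrichment,
)
from hcrtkit.simulate import simulate_promoter_set

from conftest import consensus_pwm

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_scan(seq: str, pwm: PositionWeightMatrix):
    """Independent oracle: per-window log-odds summation in plain Python."""
    order = "ACGT"
    hits = []
    L = len(pwm)
    for o in range(len(seq) - L + 1):
        window = seq[o : o + L]
        if any(b not in order for b in window):
            continue
        for strand, w in (("+", window), ("-", revcomp(window))):
            score = sum(pwm.log_odds[i, order.index(b)] for i, b in enumerate(w))
            if score >= pwm.threshold:
                hits.append((o, strand, score))
    return hits


def hypergeom_tail_by_enumeration(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for hypergeometric X, by direct summation of the pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestPositionWeightMatrix:
    def test_threshold_defaults_to_fraction_of_max(self):
        pwm = consensus_pwm("ACGTAC")
        assert pwm.threshold == pytest.approx(0.85 * pwm.max_score)

    def test_threshold_above_max_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            consensus_pwm("ACGTAC", threshold=100.0)

    def test_too_short_matrix_rejected(self):
        with pytest.raises(ValueError, match="length"):
            consensus_pwm("ACG")


class TestScanSequence:
    def test_palindromic_consensus_hits_both_strands(self):
        # ACGT equals its own reverse complement, so the planted instance
        # at offset 2 is found on both strands with the same score
        pwm = consensus_pwm("ACGT", threshold_fraction=0.9)
        hits = scan_sequence("AAACGTAA", pwm)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+"), (2, "-")]
        assert hits[0].score == pytest.approx(hits[1].score)

    def test_non_palindromic_consensus_hits_plus_strand_only(self):
        pwm = consensus_pwm("ACGG", threshold_fraction=0.9)
        hits = scan_sequence("AAACGGAA", pwm)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]
        # the reverse-complemented promoter carries it on the minus strand
        rc_hits = scan_sequence(revcomp("AAACGGAA"), pwm)
        assert [(h.offset, h.strand) for h in rc_hits] == [(2, "-")]

    def test_sequence_shorter_than_motif_yields_nothing(self):
        assert scan_sequence("ACG", consensus_pwm("ACGTA")) == []

    def test_windows_with_n_are_skipped(self):
        pwm = consensus_pwm("ACGT", threshold_fraction=0.9)
        assert scan_sequence("AANCGTAA", pwm) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 300))
        matrix = rng.dirichlet(np.full(4, 0.5), size=8)
        pwm = PositionWeightMatrix("rand", matrix, threshold_fraction=0.7)
        got = [(h.offset, h.strand, h.score) for h in scan_sequence(seq, pwm)]
        want = brute_force_scan(seq, pwm)
        assert len(got) == len(want)
        for (o1, s1, v1), (o2, s2, v2) in zip(got, want):
            assert (o1, s1) == (o2, s2)
            assert v1 == pytest.approx(v2, abs=1e-9)

    def test_reverse_complement_maps_hits(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 200))
        pwm = PositionWeightMatrix("rand", rng.dirichlet(np.full(4, 0.5), size=6),
                                   threshold_fraction=0.6)
        fwd = {(h.offset, h.strand): h.score for h in scan_sequence(seq, pwm)}
        L = len(pwm)
        rc = {(len(seq) - L - o, "-" if s == "+" else "+"): v
              for (o, s), v in fwd.items()}
        got = {(h.offset, h.strand): h.score for h in scan_sequence(revcomp(seq), pwm)}
        assert set(got) == set(rc)
        for key in got:
            assert got[key] == pytest.approx(rc[key], abs=1e-9)


class TestConservationFilter:
    def _hit(self, offset, species, tf="M", gene="g"):
        from hcrtkit.motifs import MotifHit

        return MotifHit(gene, species, offset, "+", 5.0, tf)

    def test_single_species_passes_everything(self):
        hits = {"sp1": [self._hit(5, "sp1"), self._hit(80, "sp1")]}
        assert filter_conserved_hits(hits, "sp1") == hits["sp1"]

    def test_hit_absent_in_second_species_is_removed(self):
        hits = {"sp1": [self._hit(5, "sp1")], "sp2": []}
        assert filter_conserved_hits(hits, "sp1") == []

    def test_overlap_window_controls_support(self):
        hits = {"sp1": [self._hit(50, "sp1")], "sp2": [self._hit(58, "sp2")]}
        assert len(filter_conserved_hits(hits, "sp1", window=10)) == 1
        assert len(filter_conserved_hits(hits, "sp1", window=5)) == 0

    def test_conserved_set_shrinks_with_more_species(self):
        # same reference promoters; requiring support in more species can
        # only remove reference hits
        from hcrtkit.motifs import PromoterSet

        pwm = consensus_pwm("ACGTACGTGA", threshold_fraction=0.85)
        prom3, _ = simulate_promoter_set(60, 500, pwm, 0.5, 0.3, n_species=3,
                                         n_foreground=20, seed=5)
        counts = []
        for n_sp in (1, 2, 3):
            keep = {f"sp{i + 1}" for i in range(n_sp)}
            sub = PromoterSet(
                sequences={k: v for k, v in prom3.sequences.items() if k[1] in keep},
                species=[s for s in prom3.species if s in keep],
                genes=prom3.genes,
            )
            hits = conserved_hits_by_gene(sub, pwm)
            counts.append(sum(len(v) for v in hits.values()))
        assert counts[2] <= counts[1] <= counts[0]

    def test_planted_conserved_sites_are_retained(self):
        # a sharp matrix so sampled planted instances score above threshold
        pwm = consensus_pwm("ACGTACGTGA", p=0.997, threshold_fraction=0.8)
        prom, truth = simulate_promoter_set(
            100, 800, pwm, 0.6, 0.0, n_species=3, n_foreground=30, seed=13
        )
        conserved = conserved_hits_by_gene(prom, pwm)
        planted_offsets = {
            (g, o) for g, sp, o, s in truth.motif_placements if sp == "sp1"
        }
        found = 0
        for gene, offset in planted_offsets:
            if any(abs(h.offset - offset) <= 1 for h in conserved.get(gene, [])):
                found += 1
        assert found / len(planted_offsets) >= 0.9


class TestCombinedGeneScore:
    def test_empty_hit_list_scores_zero(self):
        assert combined_gene_score([], consensus_pwm("ACGTA")) == 0.0

    def test_sum_of_above_threshold_excess(self):
        from hcrtkit.motifs import MotifHit

        pwm = consensus_pwm("ACGTA")
        t = pwm.threshold
        hits = [MotifHit("g", "sp1", 0, "+", t + 1.0, pwm.tf_name),
                MotifHit("g", "sp1", 9, "-", t + 2.0, pwm.tf_name)]
        assert combined_gene_score(hits, pwm) == pytest.approx(3.0)
        assert combined_gene_score(hits, pwm, method="max") == pytest.approx(2.0)
        assert combined_gene_score(hits, pwm, method="count") == 2.0

    def test_adding_a_hit_never_decreases_the_score(self):
        from hcrtkit.motifs import MotifHit

        pwm = consensus_pwm("ACGTA")
        hits = [MotifHit("g", "sp1", 0, "+", pwm.threshold + 0.5, pwm.tf_name)]
        more = hits + [MotifHit("g", "sp1", 20, "+", pwm.threshold, pwm.tf_name)]
        assert combined_gene_score(more, pwm) >= combined_gene_score(hits, pwm)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_hand_applied_step_up(self):
        # m/i * p_(i) = (0.04, 0.04, 0.04, 0.04) after monotonicity
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04] * 4)

    def test_monotone_in_raw_ranks(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTfSetEnrichment:
    def test_tf_hitting_every_gene_is_unenriched(self):
        bg = [f"g{i}" for i in range(20)]
        res = tf_set_enrichment(bg[:5], bg, {"T": {g: 1.0 for g in bg}})
        assert res[0].p_raw == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # 25/48 foreground carriers vs 50/480 background carriers
        bg = [f"g{i:03d}" for i in range(480)]
        fg = bg[:48]
        carriers = set(fg[:25]) | set(bg[48 : 48 + 25])
        res = tf_set_enrichment(fg, bg, {"T": {g: 1.0 for g in carriers}})
        want = hypergeom_tail_by_enumeration(25, 480, 50, 48)
        assert res[0].p_raw == pytest.approx(want, rel=1e-9)

    def test_small_population_enumeration_grid(self):
        bg = [f"g{i}" for i in range(40)]
        fg = bg[:12]
        for k_fg, k_bg_extra in [(0, 5), (3, 2), (6, 10), (12, 0)]:
            carriers = set(fg[:k_fg]) | set(bg[12 : 12 + k_bg_extra])
            res = tf_set_enrichment(fg, bg, {"T": {g: 1.0 for g in carriers}})
            want = hypergeom_tail_by_enumeration(k_fg, 40, len(carriers), 12)
            assert res[0].p_raw == pytest.approx(want, rel=1e-9)

    def test_empty_foreground_is_an_error(self):
        with pytest.raises(ValueError, match="foreground"):
            tf_set_enrichment([], ["g1"], {"T": {}})

    def test_planted_tf_reaches_significance(self):
        pwm = consensus_pwm("ACGTACGTGA", threshold_fraction=0.85)
        prom, truth = simulate_promoter_set(
            480, 2000, pwm, 30 / 48, 0.05, n_species=3, n_foreground=48, seed=21
        )
        conserved = conserved_hits_by_gene(prom, pwm)
        hits = {pwm.tf_name: {g: combined_gene_score(h, pwm)
                              for g, h in conserved.items() if h}}
        res = tf_set_enrichment(truth.foreground_genes, prom.genes, hits)
        assert res[0].p_bh < 0.05


class TestTransfacReader:
    def test_round_trip_counts(self, tmp_path):
        text = (
            "VV  TRANSFAC-like matrix table\n"
            "//\n"
            "ID  M001\n"
            "P0      A      C      G      T\n"
            "01      8      1      1      0      A\n"
            "02      0      9      1      0      C\n"
            "03      1      0      9      0      G\n"
            "04      0      1      0      9      T\n"
            "05      9      0      1      0      A\n"
            "//\n"
        )
        path = tmp_path / "matrices.txt"
        path.write_text(text)
        pwms = read_transfac(path)
        assert len(pwms) == 1
        assert pwms[0].tf_name == "M001"
        assert len(pwms[0]) == 5
        hits = scan_sequence("TTACGTATT", pwms[0])
        assert any(h.offset == 2 and h.strand == "+" for h in hits)
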