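"""Exon-set derivation, domain overlap, splice-site profiles and positional
tests, polypyrimidine profiling and PWM motif enrichment."""

import numpy as np
import pytest

from cardiosplice.io import (DomainRecord, ExonRecord, GeneRecord, Genome,
                             PWM, TranscriptAnnotation, revcomp)
from cardiosplice.simulate import make_splice_profiles, simulate_splice_sets
from cardiosplice import splicing as sp


def _ann(genes):
    """{gene: {iso: [(eid, start, end, strand)]}} -> annotation on chr1."""
    g, t, e, tg = {}, {}, {}, {}
    for gid, isos in genes.items():
        strand = next(iter(isos.values()))[0][3]
        g[gid] = GeneRecord(gid, gid, strand, list(isos))
        for tid, exs in isos.items():
            for eid, s, en, st_ in exs:
                e[eid] = ExonRecord(eid, "chr1", s, en, st_)
            t[tid] = [x[0] for x in exs]
            tg[tid] = gid
    return TranscriptAnnotation(g, t, e, tg)


class TestDeriveSpecificExons:
    def test_set_difference(self):
        ann = _ann({"g": {
            "isoA": [("e1", 0, 10, "+"), ("e2", 20, 30, "+"), ("e3", 40, 50, "+")],
            "isoB": [("e1", 0, 10, "+"), ("e3", 40, 50, "+")],
        }})
        pair = sp.derive_specific_exons(["isoA"], ["isoB"], ann)
        assert pair.set1 == ["e2"] and pair.set2 == []

    def test_identical_exon_sets_give_empty_sides(self):
        ann = _ann({"g": {
            "isoA": [("e1", 0, 10, "+")], "isoB": [("e1", 0, 10, "+")]}})
        pair = sp.derive_specific_exons(["isoA"], ["isoB"], ann)
        assert pair.set1 == [] and pair.set2 == []

    def test_gene_without_both_sides_excluded(self):
        ann = _ann({
            "g1": {"a1": [("e1", 0, 10, "+"), ("e2", 20, 30, "+")],
                   "a2": [("e1", 0, 10, "+")]},
            "g2": {"b1": [("e9", 100, 110, "+")]},
        })
        # g2 contributes only a tissue1-specific isoform: dropped entirely
        pair = sp.derive_specific_exons(["a1", "b1"], ["a2"], ann)
        assert pair.set1 == ["e2"] and "e9" not in pair.set1


class TestDomainOverlap:
    def _pair(self, n=20):
        exons = {f"x{i}": ExonRecord(f"x{i}", "chr1", i * 100, i * 100 + 50, "+")
                 for i in range(2 * n)}
        pair = sp.ExonSetPair("t", [f"x{i}" for i in range(n)], "s1",
                              [f"x{i}" for i in range(n, 2 * n)], "s2")
        return pair, exons

    def test_equal_overlap_or_one(self):
        pair, exons = self._pair()
        doms = [DomainRecord("d", "chr1", i * 100, i * 100 + 10)
                for i in list(range(12)) + list(range(20, 32))]
        res = sp.domain_overlap_test(pair, exons, doms)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_single_bp_touch_counts(self):
        pair, exons = self._pair(1)
        # exon x0 = [0,50); domain [49,60) overlaps by 1 bp; [50,60) does not
        res = sp.domain_overlap_test(pair, exons, [DomainRecord("d", "chr1", 49, 60)])
        assert res["flags1"]["x0"] is True
        res2 = sp.domain_overlap_test(pair, exons, [DomainRecord("d", "chr1", 50, 60)])
        assert res2["flags1"]["x0"] is False

    def test_matches_enumeration_oracle(self):
        from cardiosplice.experiments import conditional_mle_enumeration
        pair, exons = self._pair(4)
        doms = [DomainRecord("d", "chr1", i * 100, i * 100 + 10)
                for i in [0, 1, 2, 4]]
        res = sp.domain_overlap_test(pair, exons, doms)
        or_ref, p_ref = conditional_mle_enumeration(res["table"])
        assert res["p"] == pytest.approx(p_ref, abs=1e-10)
        assert res["odds_ratio"] == pytest.approx(or_ref, rel=1e-4)

    def test_empty_set_skipped(self):
        pair = sp.ExonSetPair("t", [], "s1", ["x0"], "s2")
        exons = {"x0": ExonRecord("x0", "chr1", 0, 50, "+")}
        assert sp.domain_overlap_test(pair, exons, [])["skipped"]


class TestProfiles:
    def test_plus_strand_windows(self):
        g = Genome.from_dict({"chr1": "A" * 200 + "C" * 100 + "G" * 100})
        exons = {"e": ExonRecord("e", "chr1", 200, 300, "+")}
        pair = sp.ExonSetPair("t", ["e"], "s1", [], "s2")
        prof = sp.splice_profiles(pair, exons, g)["s1"]
        # acceptor window [100,200) = all A; donor window [300,400) = all G
        assert prof["acceptor"].counts[:, 0].sum() == 100
        assert prof["donor"].counts[:, 2].sum() == 100

    def test_minus_strand_windows_reverse_complement(self):
        g = Genome.from_dict({"chr1": "A" * 200 + "C" * 100 + "G" * 100})
        exons = {"e": ExonRecord("e", "chr1", 200, 300, "-")}
        pair = sp.ExonSetPair("t", ["e"], "s1", [], "s2")
        prof = sp.splice_profiles(pair, exons, g)["s1"]
        # acceptor = revcomp of [300,400) = all C; donor = revcomp [100,200) = T
        assert prof["acceptor"].counts[:, 1].sum() == 100
        assert prof["donor"].counts[:, 3].sum() == 100

    def test_counts_conserved_per_position(self):
        prof = make_splice_profiles()
        sim = simulate_splice_sets(30, prof, prof, seed=1)
        profiles = sp.splice_profiles(sim.pair, sim.exons, sim.genome)
        for side in ("acceptor", "donor"):
            p = profiles["set1"][side]
            assert (p.counts.sum(axis=1) == 30).all()

    def test_strand_flip_leaves_profiles_unchanged(self):
        prof = make_splice_profiles()
        sim = simulate_splice_sets(20, prof, prof, seed=2)
        profiles = sp.splice_profiles(sim.pair, sim.exons, sim.genome)
        L = sim.genome.chrom_length("chrS")
        flipped_genome = Genome.from_dict(
            {"chrS": revcomp(sim.genome.fetch("chrS", 0, L))})
        flipped_exons = {
            eid: ExonRecord(eid, "chrS", L - e.end, L - e.start,
                            "+" if e.strand == "-" else "-")
            for eid, e in sim.exons.items()}
        flipped = sp.splice_profiles(sim.pair, flipped_exons, flipped_genome)
        for label in ("set1", "set2"):
            for side in ("acceptor", "donor"):
                assert (flipped[label][side].counts
                        == profiles[label][side].counts).all()


class TestPositionalTests:
    def test_identical_composition_not_flagged(self):
        g = Genome.from_dict({"chr1": "ACGT" * 200})
        exons = {f"e{i}": ExonRecord(f"e{i}", "chr1", 200, 300, "+")
                 for i in range(10)}
        pair = sp.ExonSetPair("t", [f"e{i}" for i in range(5)], "s1",
                              [f"e{i}" for i in range(5, 10)], "s2")
        out = sp.positional_tests(sp.splice_profiles(pair, exons, g))
        assert (out["p"] == 1.0).all()
        assert np.allclose(out["odds_ratio"].dropna(), 1.0)

    def test_planted_difference_flagged(self):
        g1, g2 = 0.95, 0.70
        lo1 = [(1 - g1) / 3] * 4; lo1[2] = g1
        lo2 = [(1 - g2) / 3] * 4; lo2[2] = g2
        p1 = make_splice_profiles(overrides={("donor", 1): lo1})
        p2 = make_splice_profiles(overrides={("donor", 1): lo2})
        sim = simulate_splice_sets(400, p1, p2, seed=4)
        out = sp.positional_tests(
            sp.splice_profiles(sim.pair, sim.exons, sim.genome), ci=False)
        hit = out[(out["side"] == "donor") & (out["position"] == 1)
                  & (out["nucleotide"] == "G")]
        assert hit["p_adj"].iloc[0] < 0.05

    def test_fisher_matches_oracle_on_small_table(self):
        from cardiosplice.experiments import conditional_mle_enumeration
        from cardiosplice.stats import fisher_2x2_ci
        or_, ci, p = fisher_2x2_ci((380, 20, 280, 120))
        or_ref, p_ref = conditional_mle_enumeration((380, 20, 280, 120))
        assert p == pytest.approx(p_ref, rel=1e-6)
        assert or_ == pytest.approx(or_ref, rel=1e-4)
        assert ci[0] < or_ < ci[1]


class TestPolypyrimidine:
    def test_pyrimidine_fraction_additivity(self):
        prof = make_splice_profiles()
        sim = simulate_splice_sets(50, prof, prof, seed=5)
        res = sp.polypyrimidine_profile(
            sp.splice_profiles(sim.pair, sim.exons, sim.genome))
        f = res["fractions"]["set1"]
        assert np.allclose(f["pyrimidine_fraction"],
                           f["t_fraction"] + f["c_fraction"])

    def test_planted_thymine_excess_flagged(self):
        hiT = make_splice_profiles(ppt_t=0.60, ppt_c=0.20)
        loT = make_splice_profiles(ppt_t=0.40, ppt_c=0.20)
        sim = simulate_splice_sets(400, hiT, loT, seed=6)
        res = sp.polypyrimidine_profile(
            sp.splice_profiles(sim.pair, sim.exons, sim.genome))
        # tract spans -20..-5: most of those positions should flag for set1;
        # the other direction sees at most FDR-level noise
        assert res["summary"]["n_sig_set1"] >= 10
        assert res["summary"]["n_sig_set2"] <= 2


class TestMotifEnrichment:
    def _pwm(self):
        cols = np.full((7, 4), 0.02)
        cols[np.arange(7), [0, 1, 2, 3, 0, 1, 2]] = 0.94
        return PWM("M0", "RBP0", cols)

    def test_consensus_always_contained(self):
        pwm = self._pwm()
        seq = "T" * 40 + pwm.consensus() + "T" * 40
        assert sp.pwm_max_score(seq, pwm) == pytest.approx(
            float(np.log2(0.94 / 0.25)) * 7)

    def test_identical_sets_not_enriched(self):
        prof = make_splice_profiles()
        sim = simulate_splice_sets(40, prof, prof, seed=7)
        out = sp.motif_window_enrichment(sim.pair, sim.exons, sim.genome,
                                         [self._pwm()])
        assert out["q"].iloc[0] > 0.2

    def test_planted_motif_detected_with_direction(self):
        pwm = self._pwm()
        prof = make_splice_profiles()
        sim = simulate_splice_sets(150, prof, prof, seed=8)
        rng = np.random.default_rng(8)
        # plant consensus into 60% of set1 acceptor windows, 20% of set2
        seq = list(sim.genome.fetch("chrS", 0, sim.genome.chrom_length("chrS")))
        for ids, rate in ((sim.set1, 0.6), (sim.set2, 0.2)):
            for eid in ids:
                if rng.random() < rate:
                    ex = sim.exons[eid]
                    cons = pwm.consensus()
                    off = int(rng.integers(0, 90))
                    if ex.strand == "+":
                        start = ex.start - 100 + off
                        seq[start:start + 7] = list(cons)
                    else:
                        start = ex.end + 100 - off - 7
                        seq[start:start + 7] = list(revcomp(cons))
        genome = Genome.from_dict({"chrS": "".join(seq)})
        out = sp.motif_window_enrichment(sim.pair, sim.exons, genome, [pwm])
        assert out["favored"].iloc[0] == "set1"
        assert out["q"].iloc[0] < 0.05
        assert out["log2_ratio"].iloc[0] == pytest.approx(np.log2(3), abs=0.8)

    def test_overlong_pwm_skipped(self):
        prof = make_splice_profiles()
        sim = simulate_splice_sets(5, prof, prof, seed=9)
        cols = np.tile([[0.25, 0.25, 0.25, 0.25]], (150, 1))
        with pytest.warns(UserWarning, match="longer than window"):
            out = sp.motif_window_enrichment(sim.pair, sim.exons, sim.genome,
                                             [PWM("L", "L", cols)])
        assert len(out) == 0
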