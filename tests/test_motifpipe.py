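import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ldsplit.motifpipe import (
    OopsEm,
    PWM,
    SnpVariant,
    consensus_match,
    derive_seed,
    discover_motifs,
    find_motif_occurrences_with_snp,
    oops_em,
    plant_motifs,
    snp_flank_sequences,
)


def revcomp(s):
    return str(Seq(s).reverse_complement())


class TestFindOccurrences:
    def test_plus_strand_occurrence(self):
        #           0123456789...
        reference = {"chr1": "AACCTCCCTAA"}
        snp = SnpVariant("chr1", 4, ("T", "C"))
        occ = find_motif_occurrences_with_snp(reference, "CCTCCCT", [snp])
        assert len(occ) == 1
        o = occ[0]
        assert (o.start, o.strand) == (2, "+")
        assert o.preserving_allele == "T" and o.disrupting_allele == "C"
        assert o.snp_offset == 2
        assert o.disrupted_text == "CCCCCCT"
        assert not o.ref_mismatch

    def test_minus_strand_occurrence(self):
        planted = revcomp("CCTCCCT")  # AGGGAGG
        reference = {"chr2": "TT" + planted + "TT"}
        snp = SnpVariant("chr2", 4, ("G", "T"))  # inside the motif's rc
        occ = find_motif_occurrences_with_snp(reference, "CCTCCCT", [snp])
        assert len(occ) == 1
        assert occ[0].strand == "-"
        assert occ[0].preserving_allele == "G"

    def test_sequence_without_motif_is_empty(self):
        occ = find_motif_occurrences_with_snp(
            {"c": "AAAAAAAAAA"}, "CCTCCCT", [SnpVariant("c", 5, ("A", "C"))]
        )
        assert occ == []

    def test_window_with_two_snps_excluded(self):
        reference = {"c": "AACCTCCCTAA"}
        snps = [SnpVariant("c", 4, ("T", "C")), SnpVariant("c", 6, ("C", "G"))]
        occ = find_motif_occurrences_with_snp(reference, "CCTCCCT", snps)
        assert occ == []

    def test_reference_mismatch_flagged_not_fatal(self):
        reference = {"c": "AACCTCCCTAA"}
        snp = SnpVariant("c", 4, ("A", "T"))  # neither allele is the ref base? T is
        occ = find_motif_occurrences_with_snp(reference, "CCTCCCT", [snp])
        # T completes the motif; reference base is T so no mismatch flag
        assert occ and not occ[0].ref_mismatch
        snp2 = SnpVariant("c", 4, ("G", "A"))
        occ2 = find_motif_occurrences_with_snp(reference, "CCTCCCT", [snp2])
        assert occ2 == []  # neither allele completes the motif

    def test_strand_duality_under_reference_revcomp(self):
        reference = {"c": "GGAACCTCCCTAATT"}
        snp = SnpVariant("c", 7, ("C", "A"))
        fwd = find_motif_occurrences_with_snp(reference, "CCTCCCT", [snp])
        L = len(reference["c"])
        rc_ref = {"c": revcomp(reference["c"])}
        rc_snp = SnpVariant("c", L - 1 - 7, tuple(revcomp(a) for a in snp.alleles))
        rev = find_motif_occurrences_with_snp(rc_ref, "CCTCCCT", [rc_snp])
        assert len(fwd) == len(rev) == 1
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}
        assert rev[0].start == L - fwd[0].end


class TestSnpFlanks:
    REF = {"c": "".join("ACGT"[i % 4] for i in range(400))}

    def test_interior_window_is_101_bases_with_snp_centered(self):
        recs = snp_flank_sequences(self.REF, [SnpVariant("c", 200, ("A", "C"))])
        assert len(recs[0].seq) == 101
        assert str(recs[0].seq)[50] == self.REF["c"][200]
        assert not recs[0].annotations["truncated"]

    def test_edge_truncation_flagged(self):
        recs = snp_flank_sequences(self.REF, [SnpVariant("c", 10, ("A", "C"))])
        assert len(recs[0].seq) == 61
        assert recs[0].annotations["truncated"]

    def test_zero_flank_single_base(self):
        recs = snp_flank_sequences(self.REF, [SnpVariant("c", 7, ("A", "C"))], flank=0)
        assert str(recs[0].seq) == self.REF["c"][7]

    def test_off_contig_position_errors(self):
        with pytest.raises(IndexError):
            snp_flank_sequences(self.REF, [SnpVariant("c", 1000, ("A", "C"))])


class TestPlantMotifs:
    def windows(self, rng, n=10):
        recs = []
        for i in range(n):
            s = "".join(rng.choice(list("ACGT"), size=101))
            r = SeqRecord(Seq(s), id=f"w{i}")
            r.annotations = {"snp_offset": 50}
            recs.append(r)
        return recs

    def test_planted_record_keeps_length_and_spans_center(self, rng):
        motif = "ACTATCGATCTAG"
        recs = self.windows(rng)
        out = plant_motifs(recs, motif, {"w0", "w3"}, seed=5)
        for rec in out:
            assert len(rec.seq) == 101
            if rec.id in {"w0", "w3"}:
                start = str(rec.seq).index(motif)
                assert start <= 50 < start + len(motif)

    def test_empty_causal_set_is_identity(self, rng):
        recs = self.windows(rng)
        out = plant_motifs(recs, "ACTATCGATCTAG", set(), seed=1)
        assert [str(r.seq) for r in out] == [str(r.seq) for r in recs]

    def test_scan_recovers_planted_coordinates(self, rng):
        motif = "CCTCCCT"
        recs = self.windows(rng)
        out = plant_motifs(recs, motif, {"w2"}, seed=9)
        planted = next(r for r in out if r.id == "w2")
        start = planted.annotations["planted_at"]
        snp_pos = 50
        off = snp_pos - start
        base = motif[off]
        other = "A" if base != "A" else "G"
        occ = find_motif_occurrences_with_snp(
            {"w2": str(planted.seq)}, motif, [SnpVariant("w2", 50, (base, other))]
        )
        assert any(o.start == start and o.strand == "+" for o in occ)


class TestOopsEm:
    def test_identical_records_recover_consensus(self):
        recs = [SeqRecord(Seq("ACGTACGTACGTACGTACGT"), id=f"r{i}") for i in range(20)]
        pwm = oops_em(recs, width=8, n_restarts=2, seed=0)
        assert consensus_match(pwm, str(recs[0].seq)) >= 0.95

    def test_loglik_trace_monotone_nondecreasing(self, rng):
        recs = [
            SeqRecord(Seq("".join(rng.choice(list("ACGT"), size=60))), id=f"r{i}")
            for i in range(15)
        ]
        model = OopsEm(width=8, n_restarts=3, seed=1).fit(recs)
        trace = model.loglik_trace_
        assert np.all(np.diff(trace) >= -1e-7)

    def test_planted_motif_recovered(self, rng):
        motif = "ACTATCGATCTAG"
        recs = []
        for i in range(40):
            s = "".join(rng.choice(list("ACGT"), size=101))
            if i < 30:
                off = int(rng.integers(0, 101 - 13))
                s = s[:off] + motif + s[off + 13:]
            recs.append(SeqRecord(Seq(s), id=f"r{i}"))
        pwm = oops_em(recs, width=13, n_restarts=5, seed=2)
        assert consensus_match(pwm, motif) >= 0.8

    def test_width_larger_than_record_errors(self):
        recs = [SeqRecord(Seq("ACGTAC"), id="a"), SeqRecord(Seq("ACGTAC"), id="b")]
        with pytest.raises(ValueError):
            oops_em(recs, width=10, seed=0)


class TestDiscoverMotifs:
    def test_single_rank_matches_best_width(self, rng):
        motif = "ACTATCGATCTAG"
        recs = []
        for i in range(30):
            s = "".join(rng.choice(list("ACGT"), size=80))
            off = int(rng.integers(0, 80 - 13))
            recs.append(SeqRecord(Seq(s[:off] + motif + s[off + 13:]), id=f"r{i}"))
        found = discover_motifs(recs, n_motifs=1, width_min=12, width_max=14,
                                min_sites=10, n_restarts=3, seed=4)
        assert len(found) == 1
        # consistency: same candidates re-fit independently
        best = None
        for w in (12, 13, 14):
            m = OopsEm(width=w, n_restarts=3, seed=derive_seed(4, 0, w)).fit(recs)
            n_sites = max(len(m.strong_sites_), 1)
            score = (m.site_pwm_.score - 0.5 * 3 * w * np.log(n_sites)) / n_sites
            if best is None or score > best[0]:
                best = (score, m.site_pwm_)
        np.testing.assert_allclose(found[0].probs, best[1].probs)

    def test_pure_noise_yields_low_information_or_nothing(self, rng):
        recs = [
            SeqRecord(Seq("".join(rng.choice(list("ACGT"), size=101))), id=f"n{i}")
            for i in range(30)
        ]
        found = discover_motifs(recs, n_motifs=1, width_min=12, width_max=14,
                                min_sites=10, n_restarts=2, seed=5)
        planted_regime_ic_per_col = 1.5
        for pwm in found:
            assert pwm.information_content / pwm.width < planted_regime_ic_per_col


class TestConsensusMatch:
    def test_one_hot_scores_one(self):
        motif = "ACGTACGT"
        probs = np.full((8, 4), 0.0)
        for i, b in enumerate(motif):
            probs[i, "ACGT".index(b)] = 1.0
        assert consensus_match(PWM(probs=probs), motif) == pytest.approx(1.0)

    def test_uniform_scores_quarter(self):
        pwm = PWM(probs=np.full((6, 4), 0.25))
        assert consensus_match(pwm, "ACGTAC") == pytest.approx(0.25)

    def test_invariant_under_joint_reverse_complement(self, rng):
        probs = rng.dirichlet(np.ones(4), size=9)
        pwm = PWM(probs=probs)
        consensus = "ACGTTGCAA"
        assert consensus_match(pwm, consensus) == pytest.approx(
            consensus_match(pwm.reverse_complement(), revcomp(consensus))
        )
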