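import itertools
import math

import numpy as np
import pytest

from pollenselect import divergence as dvg
from pollenselect.codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from pollenselect.io_formats import HitRecord


def hit(q, s, pid=90.0, length=200, bits=300.0):
    return HitRecord(q, s, pid, length, bits)


class TestReciprocalBestHits:
    def test_mutual_best_retained(self):
        pairs = dvg.reciprocal_best_hits([hit("a", "b", 35.0)], [hit("b", "a", 35.0)])
        assert len(pairs) == 1
        assert (pairs[0].gene_id_a, pairs[0].gene_id_b) == ("a", "b")

    def test_identity_threshold(self):
        pairs = dvg.reciprocal_best_hits([hit("a", "b", 25.0)], [hit("b", "a", 25.0)])
        assert pairs == []

    def test_length_threshold(self):
        pairs = dvg.reciprocal_best_hits(
            [hit("a", "b", 90.0, length=100)], [hit("b", "a", 90.0, length=100)]
        )
        assert pairs == []

    def test_reciprocity_required(self):
        ab = [hit("a", "b", 90.0)]
        ba = [hit("b", "c", 90.0, bits=400.0), hit("b", "a", 90.0, bits=300.0)]
        assert dvg.reciprocal_best_hits(ab, ba) == []

    def test_tie_break_deterministic(self):
        # equal bit scores: higher identity wins, then smaller subject id
        ab = [hit("a", "c", 80.0, bits=300.0), hit("a", "b", 90.0, bits=300.0)]
        ba = [hit("b", "a", 90.0, bits=300.0), hit("c", "a", 80.0, bits=300.0)]
        (pair,) = dvg.reciprocal_best_hits(ab, ba)
        assert pair.gene_id_b == "b"
        ab2 = [hit("a", "c", 90.0, bits=300.0), hit("a", "b", 90.0, bits=300.0)]
        ba2 = [hit("b", "a", 90.0, bits=300.0), hit("c", "a", 90.0, bits=300.0)]
        (pair2,) = dvg.reciprocal_best_hits(ab2, ba2)
        assert pair2.gene_id_b == "b"  # lexicographic


class TestBacktranslate:
    def test_gap_insertion(self):
        a, b = dvg.backtranslate_alignment("M-K", "MQK", "ATGAAA", "ATGCAAAAG")
        assert a == "ATG---AAA"
        assert b == "ATGCAAAAG"

    def test_identical_proteins(self):
        a, b = dvg.backtranslate_alignment("MK", "MK", "ATGAAATGA", "ATGAAGTAA")
        assert (a, b) == ("ATGAAA", "ATGAAG")  # terminal stops trimmed

    def test_translation_mismatch_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            dvg.backtranslate_alignment("MK", "MK", "ATGCCC", "ATGAAG")


def oracle_path_counts(c1, c2):
    """Independent recursion over all orderings of the differing sites."""
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0
    results = []

    def walk(cur, remaining, syn, non):
        if not remaining:
            results.append((syn, non))
            return
        for p in remaining:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            step_syn = (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and CODON_TO_AA[cur] == CODON_TO_AA[nxt]
            )
            walk(nxt, [q for q in remaining if q != p], syn + step_syn, non + (not step_syn))

    walk(c1, diffs, 0, 0)
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


class TestPairwiseDnds:
    def test_identical_sequences(self):
        est = dvg.pairwise_dnds("ATGAAA", "ATGAAA")
        assert est.dN == 0.0 and est.dS == 0.0
        assert math.isnan(est.omega)
        assert est.excluded  # omega undefined

    def test_one_synonymous_difference(self):
        est = dvg.pairwise_dnds("TTT", "TTC")  # Phe -> Phe
        assert est.s_diffs == pytest.approx(1.0)
        assert est.n_diffs == pytest.approx(0.0)

    def test_site_count_conservation(self, rng):
        for _ in range(20):
            codons = rng.choice(SENSE_CODONS, size=30)
            a = "".join(codons)
            b = "".join(rng.choice(SENSE_CODONS, size=30))
            est = dvg.pairwise_dnds(a, b)
            assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(SENSE_CODONS, size=25))
            b = "".join(rng.choice(SENSE_CODONS, size=25))
            e1 = dvg.pairwise_dnds(a, b)
            e2 = dvg.pairwise_dnds(b, a)
            assert e1.s_diffs == pytest.approx(e2.s_diffs, abs=1e-12)
            assert e1.n_diffs == pytest.approx(e2.n_diffs, abs=1e-12)
            assert e1.s_sites == pytest.approx(e2.s_sites, abs=1e-12)

    def test_path_enumeration_spot_checks(self):
        for c1, c2 in (("TTT", "GGG"), ("ATG", "TGG"), ("AAA", "AGG"), ("CTT", "AGT")):
            assert dvg.codon_path_counts(c1, c2) == pytest.approx(oracle_path_counts(c1, c2))

    def test_jc_monotonic_increasing(self):
        ps = np.linspace(0, 0.74, 100)
        ds = [dvg.jukes_cantor(p) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))
        assert dvg.jukes_cantor(0.0) == 0.0
        with pytest.raises(ValueError):
            dvg.jukes_cantor(0.75)

    def test_ds_ceiling_excludes(self):
        # one synonymous difference in a short gene: dS well above a tiny ceiling
        est = dvg.pairwise_dnds("TTT" * 10, "TTC" + "TTT" * 9, ds_max=0.01)
        assert est.excluded and est.reason.startswith("ds_above")

    def test_saturated_pair_excluded(self, rng):
        from pollenselect.synthetic_data import evolve_cds
        cds = "".join(rng.choice(SENSE_CODONS, size=500))
        div = evolve_cds(cds, 6.0, 1.0, rng)
        est = dvg.pairwise_dnds(cds, div)
        assert est.excluded

    def test_gap_and_stop_columns_dropped(self):
        est = dvg.pairwise_dnds("ATG---TTT", "ATGAAATTC")
        assert est.n_codons == 2
        est2 = dvg.pairwise_dnds("ATGTAATTT", "ATGAAATTT")
        assert est2.n_codons == 2  # TAA column dropped


class TestOmegaRecovery:
    def test_counting_estimator_recovers_generator_rates(self, rng):
        """NG+JC estimates on a 3,000-codon pair evolved at dS=0.15,
        ω=0.2 land within 15% of the generating values."""
        from pollenselect.synthetic_data import evolve_cds

        cds = "".join(rng.choice(SENSE_CODONS, size=3000))
        div = evolve_cds(cds, 0.15, 0.2, rng)
        est = dvg.pairwise_dnds(cds, div)
        assert not est.excluded
        assert abs(est.dS - 0.15) / 0.15 < 0.15
        assert abs(est.omega - 0.2) / 0.2 < 0.15

    def test_omega_zero_keeps_protein(self, rng):
        from pollenselect.codons import translate
        from pollenselect.synthetic_data import evolve_cds

        cds = "".join(rng.choice(SENSE_CODONS, size=200))
        div = evolve_cds(cds, 0.3, 0.0, rng)
        assert translate(div) == translate(cds)
        assert dvg.pairwise_dnds(cds, div).dN == 0.0
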