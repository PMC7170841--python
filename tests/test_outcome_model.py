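import itertools
import math

import numpy as np
import pytest

from bescreen.outcome_model import (
    ActivityProfile,
    OutcomeError,
    classify_sgg,
    genotype_key,
    guide_features,
    model_coverage,
    predict_outcomes,
    random_combination_percentile,
    rank_agreement_test,
    rank_positions,
)

from helpers import make_site_reference


class TestRankPositions:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ({-19}, [-19]),
            ({-18, -14}, [-18, -14]),
            ({-19, -17}, [-17, -19]),
            ({-20, -15}, [-15, -20]),  # equal weight: tie toward the PAM
        ],
    )
    def test_ordering(self, positions, expected):
        assert rank_positions(positions) == expected

    def test_empty(self):
        assert rank_positions(set()) == []

    def test_profile_validation(self):
        with pytest.raises(OutcomeError):
            ActivityProfile(weight={-18: 1.0, -17: 0.9, -19: 0.1, -16: 0.3})


class TestPredictOutcomes:
    def test_glycine_codon_gives_arg_and_ser(self):
        """Template-strand C paired with the first G of GGC: the model's two
        rank-1 outcomes are Arg (C→G) and Ser (C→T)."""
        ref, guide, res = make_site_reference("GGC", 0, "-")
        outs = predict_outcomes(guide, ref.gene("focal"), ref)
        rank1 = [o for o in outs if o.edits[0][0] == -18]
        assert {o.aa_changes[0][2] for o in rank1} == {"R", "S"}
        assert all(o.aa_changes[0] == (res, "G", o.aa_changes[0][2]) for o in rank1)
        assert all(o.consequence == "missense" for o in rank1)

    def test_single_editable_c_gives_two_genotypes(self):
        ref, guide, _ = make_site_reference("CAT", 0, "+")
        outs = predict_outcomes(guide, ref.gene("focal"), ref)
        assert len(outs) == 2
        assert {o.edits[0][2] for o in outs} == {"G", "T"}

    def test_silent_third_position(self):
        # GCx codons all encode Ala, so editing the wobble C is silent
        ref, guide, _ = make_site_reference("GCC", 2, "+")
        outs = predict_outcomes(guide, ref.gene("focal"), ref)
        rank1 = [o for o in outs if o.edits[0][0] == -18]
        assert all(o.consequence == "silent" for o in rank1)

    def test_model_set_never_contains_c_to_a(self, random_reference,
                                             random_library):
        for guide in random_library[:12]:
            gene = random_reference.gene(guide.gene_id)
            for o in predict_outcomes(guide, gene, random_reference):
                assert len(o.edits) == 1
                assert o.edits[0][2] in {"G", "T"}

    def test_noncoding_edit_maps_to_complement_on_mrna(self, random_reference,
                                                       random_library):
        seen = 0
        for guide in random_library:
            if guide.strand_class != "noncoding":
                continue
            gene = random_reference.gene(guide.gene_id)
            for o in predict_outcomes(guide, gene, random_reference):
                (pos, _, alt), (cds_idx, ref_c, alt_c) = o.edits[0], o.coding_changes[0]
                assert ref_c == "G"
                assert alt_c == {"G": "C", "T": "A"}[alt]
                seen += 1
        assert seen > 0


def _codon_stop_oracle(codon, base_idx, strand):
    """Direct enumeration: can editing this base (C→G/T on the protospacer
    strand) turn the codon into a stop?"""
    stops = {"TAA", "TAG", "TGA"}
    if codon in stops:
        return set()  # stop-to-stop is silent, not a gained stop
    results = set()
    for alt in "GT":
        mutated = list(codon)
        if strand == "+":
            mutated[base_idx] = alt
        else:
            mutated[base_idx] = {"G": "C", "T": "A"}[alt]
        if "".join(mutated) in stops:
            results.add(f"C>{alt}")
    return results


class TestClassifySgg:
    def test_brute_force_over_all_codons(self):
        """classify_sgg agrees with direct stop enumeration for every codon
        and every editable-base placement at the top activity position."""
        n_checked = 0
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            for base_idx in range(3):
                base = codon[base_idx]
                strand = "+" if base == "C" else "-" if base == "G" else None
                if strand is None:
                    continue
                ref, guide, _ = make_site_reference(codon, base_idx, strand)
                gene = ref.gene("focal")
                sgg = classify_sgg(guide, gene, ref)
                # oracle over the guide's top-2 model positions
                expected = set()
                for pos in rank_positions(guide.pam_relative_c_positions)[:2]:
                    gpos = guide.genomic_position(pos)
                    off = gpos - gene.cds_intervals[0][0]
                    ci, cb = divmod(off, 3)
                    cod = gene.cds_sequence(ref.sequences["chr"])[ci * 3 : ci * 3 + 3]
                    expected |= _codon_stop_oracle(cod, cb, guide.protospacer_strand)
                if expected:
                    assert sgg is not None, (codon, base_idx)
                else:
                    assert sgg is None, (codon, base_idx)
                n_checked += 1
        assert n_checked > 80

    def test_stop_capable_codon_set(self):
        """Which coding codons admit a model-set stop at the focal base."""
        stop_codons = set()
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            for base_idx in range(3):
                if codon[base_idx] == "C" and _codon_stop_oracle(codon, base_idx, "+"):
                    stop_codons.add(codon)
                if codon[base_idx] == "G" and _codon_stop_oracle(codon, base_idx, "-"):
                    stop_codons.add(codon)
        assert stop_codons == {"TCA", "TAC", "CAA", "CAG", "CGA", "TGG"}

    def test_tgg_targeted_on_noncoding_strand(self):
        ref, guide, _ = make_site_reference("TGG", 1, "-")
        sgg = classify_sgg(guide, ref.gene("focal"), ref)
        assert sgg is not None and sgg.codon == "TGG"
        assert sgg.stop_via == "C>T"
        assert "non-coding" in sgg.strand_note

    def test_caa_stop_via_c_to_t_only(self):
        ref, guide, _ = make_site_reference("CAA", 0, "+")
        sgg = classify_sgg(guide, ref.gene("focal"), ref)
        assert sgg is not None and sgg.stop_via == "C>T"

    def test_gca_is_not_sgg(self):
        ref, guide, _ = make_site_reference("GCA", 1, "+")
        assert classify_sgg(guide, ref.gene("focal"), ref) is None


SUGIMOTO_DH_DS = {
    "AA": (-7.8, -21.9), "AC": (-5.9, -12.3), "AG": (-9.1, -23.5),
    "AT": (-8.3, -23.9), "CA": (-9.0, -26.1), "CC": (-9.3, -23.2),
    "CG": (-16.3, -47.1), "CT": (-7.0, -19.7), "GA": (-5.5, -13.5),
    "GC": (-8.0, -17.1), "GG": (-12.8, -31.9), "GT": (-7.8, -21.6),
    "TA": (-7.8, -23.2), "TC": (-8.6, -22.9), "TG": (-10.4, -28.4),
    "TT": (-11.5, -36.4),
}


class TestGuideFeatures:
    def test_nearest_neighbor_hand_sum(self):
        """Tm of a fixed 20-mer equals an independent hand summation of the
        published RNA/DNA nearest-neighbor enthalpies/entropies.

        Na = 1000 mM makes the salt-correction term ln(1 M) = 0.
        """
        seq = "ACGTACGTACGTACGTACGT"
        dh, ds = 1.9, -3.9  # duplex initiation
        for a, b in zip(seq, seq[1:]):
            h, s = SUGIMOTO_DH_DS[a + b]
            dh += h
            ds += s
        k = (25 - 25 / 2) * 1e-9
        tm = dh * 1000 / (ds + 1.987 * math.log(k)) - 273.15
        got = guide_features(seq, Na=1000)["duplex_tm"]
        assert got == pytest.approx(tm, abs=0.05)

    def test_gc_monotonicity(self):
        hi = guide_features("GC" * 10)["duplex_tm"]
        lo = guide_features("AT" * 10)["duplex_tm"]
        assert hi > lo

    def test_fractions(self):
        f = guide_features("GGGGGGGGGGCCCCCCCCCC")
        assert f["gc_fraction"] == 1.0
        assert f["g_fraction"] == 0.5
        assert f["c_fraction"] == 0.5

    def test_rejects_ambiguous(self):
        with pytest.raises(OutcomeError):
            guide_features("N" * 20)


class TestModelCoverage:
    def test_arithmetic(self):
        obs = {"a": 60, "b": 30, "c": 10}
        assert model_coverage(obs, {"a", "b"}) == pytest.approx(0.9)

    def test_full_coverage(self):
        assert model_coverage({"a": 5}, {"a", "b"}) == 1.0

    def test_zero_reads_error(self):
        with pytest.raises(OutcomeError):
            model_coverage({}, {"a"})


class TestRandomCombinationPercentile:
    def test_exhaustive_vs_sampled(self):
        positions = [-19, -18]  # universe of 6 single-edit genotypes
        obs = {genotype_key([(-19, "G")]): 50, genotype_key([(-18, "T")]): 30,
               genotype_key([(-19, "T")]): 20}
        exact = random_combination_percentile(obs, positions, k=3, q=90,
                                              exhaustive_cap=10000)
        sampled = random_combination_percentile(obs, positions, k=3, q=90,
                                                exhaustive_cap=1,
                                                n_samples=4000, seed=5)
        assert sampled == pytest.approx(exact, abs=0.1)

    def test_concentrated_lower_bound(self):
        obs = {genotype_key([(-18, "G")]): 100}
        thr = random_combination_percentile(obs, [-18, -17, -16, -15], k=4, q=50)
        assert thr in (0.0, 1.0)  # subsets either contain the genotype or not

    def test_determinism(self):
        obs = {genotype_key([(-18, "G")]): 3, genotype_key([(-17, "T")]): 9}
        args = dict(c_positions=[-18, -17, -16], k=2, q=99,
                    exhaustive_cap=1, n_samples=500, seed=11)
        assert random_combination_percentile(obs, **args) == \
            random_combination_percentile(obs, **args)

    def test_k_too_large(self):
        with pytest.raises(OutcomeError):
            random_combination_percentile({"x": 1}, [-18], k=4)


class TestRankAgreement:
    def test_perfect_agreement_floor(self):
        # 10 guides x 3 sites: 6^10 permutations, so perfect agreement
        # pins p at the resolution floor 1/(n_perm + 1)
        ranks = [[1, 2, 3]] * 10
        stat, p = rank_agreement_test(ranks, ranks, n_perm=10000, seed=0)
        assert stat == 30
        assert p == pytest.approx(1 / 10001, rel=0.5)

    def test_two_permutations(self):
        stat, p = rank_agreement_test([[1, 2]], [[1, 2]], n_perm=4000, seed=0)
        assert p == pytest.approx(0.5, abs=0.05)

    def test_null_calibration(self):
        """With observed ranks independent of predictions, p is not
        systematically small."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(60):
            pred = [[1, 2, 3]] * 6
            obs = [list(rng.permutation([1, 2, 3])) for _ in range(6)]
            ps.append(rank_agreement_test(pred, obs, n_perm=300,
                                          seed=int(rng.integers(1 << 30)))[1])
        assert 0.3 < np.mean(ps) < 0.7

    def test_length_mismatch(self):
        with pytest.raises(OutcomeError):
            rank_agreement_test([[1, 2]], [[1, 2], [1, 2]])
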