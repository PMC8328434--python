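"""IUPAC primer matching, in-silico PCR, GC clamp, pairwise divergence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemocomp.clonemarkers import (
    DGGE_PAIR,
    GC_CLAMP,
    PRIMER_2104R,
    PRIMER_3770F,
    PRIMER_3770F_GC,
    PrimerPair,
    attach_gc_clamp,
    find_primer_sites,
    in_silico_pcr,
    pairwise_divergence,
    read_fasta,
    reverse_complement,
    write_fasta,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestReverseComplement:
    def test_self_complementary(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_whitespace_stripped(self):
        assert reverse_complement("GATC CGGT") == "ACCGGATC"

    def test_iupac_codes(self):
        assert reverse_complement("RYSWKM") == "KMWSRY"
        assert reverse_complement("N") == "N"

    @given(DNA)
    @settings(max_examples=100, derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")


def brute_force_sites(template, primer, max_mismatches=0):
    """Independent oracle: naive scan with explicit IUPAC expansion."""
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
        "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }

    def matches(p, w):
        return sum(t not in iupac[c] for c, t in zip(p, w)) <= max_mismatches

    rc = reverse_complement(primer)
    hits = []
    for i in range(len(template) - len(primer) + 1):
        w = template[i : i + len(primer)]
        if matches(primer, w):
            hits.append((i, "+"))
        if matches(rc, w):
            hits.append((i, "-"))
    return hits


class TestFindPrimerSites:
    def test_single_forward_hit_at_known_offset(self):
        template = "T" * 50 + PRIMER_3770F + "T" * 50
        assert find_primer_sites(template, PRIMER_3770F) == [(50, "+")]

    def test_absent_primer_gives_empty(self):
        assert find_primer_sites("ACGT" * 100, PRIMER_3770F) == []

    def test_primer_longer_than_template(self):
        assert find_primer_sites("ACGT", PRIMER_3770F) == []

    def test_ambiguity_codes_match_expansions(self):
        assert find_primer_sites("AAGAGG", "RAG") == [(0, "+"), (2, "+")]

    @given(template=st.text(alphabet="ACGT", min_size=30, max_size=300), seed=st.integers(0, 10**6))
    @settings(max_examples=100, derandomize=True)
    def test_equals_brute_force_oracle(self, template, seed):
        rng = random.Random(seed)
        start = rng.randrange(0, len(template) - 8)
        primer = template[start : start + 8]
        assert find_primer_sites(template, primer) == brute_force_sites(template, primer)
        assert find_primer_sites(template, primer, 1) == brute_force_sites(template, primer, 1)


class TestInSilicoPcr:
    def test_constructed_template_gives_143bp_product(self):
        template = PRIMER_3770F + "N" * 100 + reverse_complement(PRIMER_2104R)
        products = in_silico_pcr(template, DGGE_PAIR)
        assert len(products) == 1
        amp = products[0]
        assert amp.length == 143
        assert (amp.start, amp.end) == (0, 143)

    def test_no_product_without_reverse_site(self):
        template = PRIMER_3770F + "A" * 200
        assert in_silico_pcr(template, DGGE_PAIR) == []

    def test_max_len_excludes_distant_products(self):
        template = PRIMER_3770F + "A" * 6000 + reverse_complement(PRIMER_2104R)
        assert in_silico_pcr(template, DGGE_PAIR, max_len=5000) == []
        assert len(in_silico_pcr(template, DGGE_PAIR, max_len=7000)) == 1

    def test_amplicon_coordinates_roundtrip(self):
        flank_l = "GT" * 37
        flank_r = "CA" * 23
        template = flank_l + PRIMER_3770F + "ACGT" * 60 + reverse_complement(PRIMER_2104R) + flank_r
        amp = in_silico_pcr(template, DGGE_PAIR)[0]
        product = template[amp.start : amp.end]
        assert find_primer_sites(product, DGGE_PAIR.forward)[0] == (0, "+")
        rev_sites = [s for s in find_primer_sites(product, DGGE_PAIR.reverse) if s[1] == "-"]
        assert rev_sites[-1][0] + len(DGGE_PAIR.reverse) == amp.length

    def test_synthetic_clone_templates_give_distinct_product_lengths(self):
        # synthetic stand-ins for the three clone rDNA fragments: identical
        # conserved primer sites, ITS spacers of different lengths
        rng = random.Random(7)
        products = []
        for spacer_len in (467, 484, 472):
            spacer = "".join(rng.choice("ACGT") for _ in range(spacer_len))
            template = (
                "AGCT" * 25
                + PRIMER_3770F
                + spacer
                + reverse_complement(PRIMER_2104R)
                + "TTGA" * 25
            )
            amps = in_silico_pcr(template, DGGE_PAIR)
            assert len(amps) == 1
            products.append(amps[0].length)
        assert products == [510, 527, 515]


class TestGcClamp:
    def test_clamp_length_and_composition(self):
        assert len(GC_CLAMP) == 40
        gc = sum(c in "GC" for c in GC_CLAMP) / len(GC_CLAMP)
        assert gc > 0.95  # GC-rich clamp (the printed sequence has a single T)

    def test_default_clamp_on_forward_primer(self):
        clamped = attach_gc_clamp(PRIMER_3770F)
        assert clamped == PRIMER_3770F_GC
        assert len(clamped) == 61
        assert clamped.startswith(GC_CLAMP) and clamped.endswith(PRIMER_3770F)

    def test_empty_clamp_is_identity(self):
        assert attach_gc_clamp(PRIMER_3770F, "") == PRIMER_3770F


class TestPairwiseDivergence:
    def test_identical_sequences_zero(self):
        assert pairwise_divergence("ACGTACGT" * 10, "ACGTACGT" * 10) == 0.0

    def test_single_mismatch_in_hundred(self):
        a = "ACGT" * 25
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        assert pairwise_divergence(a, b) == pytest.approx(0.01)

    def test_gap_columns_excluded(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACGTACGT"  # clean terminal deletion
        assert pairwise_divergence(a, b) == 0.0

    @given(a=st.text(alphabet="ACGT", min_size=20, max_size=100),
           b=st.text(alphabet="ACGT", min_size=20, max_size=100))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_symmetric(self, a, b):
        assert pairwise_divergence(a, b) == pytest.approx(pairwise_divergence(b, a))

    def test_its_scale_divergence_recovered(self):
        # mutate ~3.5% of sites of a synthetic ITS-like sequence
        rng = random.Random(3)
        a = "".join(rng.choice("ACGT") for _ in range(500))
        b = list(a)
        mutated = rng.sample(range(500), 18)
        for i in mutated:
            b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
        d = pairwise_divergence(a, "".join(b))
        assert d == pytest.approx(18 / 500, abs=0.005)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_divergence("", "ACGT")


def test_fasta_roundtrip_and_bundled_primers(tmp_path):
    from importlib import resources

    seqs = {"a": "ACGT" * 30, "b": "GGCC" * 10}
    path = tmp_path / "seqs.fasta"
    write_fasta(seqs, path)
    assert read_fasta(path) == seqs

    bundled = read_fasta(resources.files("chemocomp.data").joinpath("primers.fasta"))
    assert bundled["3770F"] == PRIMER_3770F
    assert bundled["2104R"] == PRIMER_2104R
    assert bundled["3770F_GC"] == PRIMER_3770F_GC


def test_primer_pair_validation():
    with pytest.raises(ValueError):
        PrimerPair("bad", "ACGT", "AC-GT")
    with pytest.raises(ValueError):
        PrimerPair("bad", "", "ACGT")
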