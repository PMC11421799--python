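"""Motif classes, position-frequency matrices, codon context, background sites."""

import itertools
import re

import numpy as np
import pytest

import psistop as ps
from psistop.motifs import amino_acid_fractions, scan_motif_sites, site_5mer


def brute_force_class(kmer: str) -> str:
    """Independent regex classifier over the published motif patterns."""
    if re.fullmatch("UU[AG]AA", kmer):
        return "UURAA"
    if re.fullmatch("UU[AG][CGU]A", kmer):
        return "UURBA"
    if re.fullmatch("UU[CU]AA", kmer):
        return "UUYAA"
    return "other"


class TestMotifClasses:
    @pytest.mark.parametrize("kmer,expected", [
        ("UUGAA", "UURAA"),
        ("UUAAA", "UURAA"),
        ("UUCAA", "UUYAA"),
        ("UUGCA", "UURBA"),
        ("AUGAA", "other"),
        ("UUGAG", "other"),
    ])
    def test_examples(self, kmer, expected):
        assert ps.classify_5mer(kmer) == expected

    def test_exhaustive_partition_over_all_1024_5mers(self):
        """Classification is exhaustive and exclusive, matching an
        independent regex classifier on every RNA 5-mer."""
        counts = {c: 0 for c in ("UURAA", "UURBA", "UUYAA", "other")}
        for kmer in map("".join, itertools.product("ACGU", repeat=5)):
            got = ps.classify_5mer(kmer)
            assert got == brute_force_class(kmer), kmer
            counts[got] += 1
        assert sum(counts.values()) == 1024
        # pattern cardinalities: UURAA 2, UURBA 2*3, UUYAA 2
        assert counts["UURAA"] == 2
        assert counts["UURBA"] == 6
        assert counts["UUYAA"] == 2

    def test_dna_input_accepted(self):
        assert ps.classify_5mer("TTGAA") == "UURAA"

    def test_strand_symmetry_under_reverse_complement(self):
        genome = ps.GenomeSequence("g", "CCCTTGAACCC")
        site = 3  # TTGAA on the plus strand
        assert ps.classify_motif(genome, site, "+") == "UURAA"
        rc = genome.reverse_complement()
        rc_site = len(genome) - 1 - site
        assert ps.classify_motif(rc, rc_site, "-") == "UURAA"


class TestPositionFrequency:
    def test_single_site_one_hot(self):
        genome = ps.GenomeSequence("g", "ACGTACGTACGT")
        pfm = ps.position_frequency([(5, "+")], genome, flank=2)
        # the site base at offset 0 is C; every column is one-hot
        assert list(pfm.loc[0]) == [1 if b == "C" else 0 for b in "ACGU"]
        assert (pfm.sum(axis=1) == 1).all()

    def test_column_sums_equal_site_count(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 300))
        genome = ps.GenomeSequence("g", seq)
        sites = [(int(p), "+") for p in rng.integers(10, 290, size=12)]
        pfm = ps.position_frequency(sites, genome, flank=5)
        assert (pfm.sum(axis=1) == 12).all()

    def test_planted_uuraa_sites_fix_offsets_one_and_four(self):
        """On synthetic UURAA-planted sites the +1 column is all U and the
        +4 column all A (offset 0 being the site U itself)."""
        cfg = ps.SimulationConfig(
            n_transcripts=8, transcript_length=400, depth=1000,
            planted_sites=[ps.PlantedSite(f"gene00{i}", 150 + 7 * i)
                           for i in range(8)],
            seed=4,
        )
        tr = ps.make_transcriptome(cfg)
        sites = [tr.genomic_site(s) for s in tr.sites]
        pfm = ps.position_frequency(sites, tr.genome, flank=5)
        n = len(sites)
        assert pfm.loc[0, "U"] == n
        assert pfm.loc[1, "U"] == n
        assert pfm.loc[4, "A"] == n


class TestCodonContext:
    def test_frame_arithmetic(self):
        genome = ps.GenomeSequence("g", "A" * 120)
        m = ps.TranscriptModel(gene_id="g", strand="+", start=90, end=120,
                               cds_start=100, cds_end=112)
        ctx = ps.codon_context(106, m, genome)
        assert ctx.codon_index == 3 and ctx.position_in_codon == 1

    def test_gtt_codon_is_valine(self):
        genome = ps.GenomeSequence("g", "AAAGTTAAA")
        m = ps.TranscriptModel(gene_id="g", strand="+", start=0, end=9,
                               cds_start=3, cds_end=9)
        ctx = ps.codon_context(4, m, genome)
        assert ctx.codon == "GUU" and ctx.amino_acid == "V"
        assert ctx.position_in_codon == 2

    def test_minus_strand_frame(self):
        # coding GUU on the minus strand: genomic AAC
        genome = ps.GenomeSequence("g", "TTTAACTTT")
        m = ps.TranscriptModel(gene_id="g", strand="-", start=0, end=9,
                               cds_start=3, cds_end=9)
        # minus-strand CDS reads AAA GUU from genomic position 8 leftward;
        # genomic position 5 is the G of the second codon
        ctx = ps.codon_context(5, m, genome)
        assert ctx.codon == "GUU" and ctx.amino_acid == "V"
        assert ctx.codon_index == 2 and ctx.position_in_codon == 1

    def test_utr_site_has_no_codon_context(self):
        genome = ps.GenomeSequence("g", "A" * 50)
        m = ps.TranscriptModel(gene_id="g", strand="+", start=0, end=50,
                               cds_start=12, cds_end=45)
        assert ps.codon_context(5, m, genome) is None

    def test_sites_planted_in_valine_codons_are_all_valine(self):
        """Sites constructed inside GUU codons report 100% valine."""
        seq = list("A" * 200)
        m = ps.TranscriptModel(gene_id="g", strand="+", start=0, end=200,
                               cds_start=30, cds_end=150)
        sites = []
        for codon_start in (30, 60, 90):
            seq[codon_start:codon_start + 3] = "GTT"
            sites.append((codon_start + 1, "+"))
        genome = ps.GenomeSequence("g", "".join(seq))
        frac = amino_acid_fractions(sites, [m], genome)
        assert frac.to_dict() == {"V": 1.0}


@pytest.fixture(scope="module")
def background_setting():
    rng = np.random.default_rng(10)
    seq = list(rng.choice(list("ACGT"), 3000))
    # plant UURAA (DNA TTRAA) instances at known spots in both genes
    for pos, r in [(200, "G"), (430, "A"), (700, "G"), (1210, "A"),
                   (1600, "G"), (2400, "A")]:
        seq[pos:pos + 5] = list("TT" + r + "AA")
    genome = ps.GenomeSequence("g", "".join(seq))
    models = [
            ps.TranscriptModel(gene_id="hi", strand="+", start=100, end=1400,
                               rpkm=500.0),
            ps.TranscriptModel(gene_id="lo", strand="+", start=1500, end=2800,
                               rpkm=104.9),
        ]
    return genome, models


class TestBackgroundSelection:
    def test_low_rpkm_gene_excluded(self, background_setting):
        genome, models = background_setting
        bg = ps.select_background(models, genome, psi_sites=[])
        lo = models[1]
        assert all(not lo.contains(p) for p, _ in bg)

    def test_exclusion_zone_around_psi(self, background_setting):
        genome, models = background_setting
        all_bg = ps.select_background(models, genome, psi_sites=[])
        assert all_bg, "fixture needs at least one motif instance"
        psi = [all_bg[0]]
        bg = ps.select_background(models, genome, psi_sites=psi)
        for p, strand in bg:
            assert abs(p - psi[0][0]) > 100

    def test_matches_brute_force_scan(self, background_setting):
        genome, models = background_setting
        psi = [(700, "+")]
        bg = ps.select_background(models, genome, psi_sites=psi)
        expected = []
        hi = models[0]
        for pos in range(hi.start, hi.end):
            if pos + 5 > len(genome):
                continue
            kmer = genome.subseq(pos, pos + 5).replace("T", "U")
            if re.fullmatch("UU[AG]AA", kmer) and abs(pos - 700) > 100:
                expected.append((pos, "+"))
        assert bg == expected

    def test_n_max_subsamples_deterministically(self, background_setting):
        genome, models = background_setting
        full = ps.select_background(models, genome, psi_sites=[])
        k = max(1, len(full) - 1)
        a = ps.select_background(models, genome, psi_sites=[], n_max=k, seed=3)
        b = ps.select_background(models, genome, psi_sites=[], n_max=k, seed=3)
        assert a == b and len(a) == k
        assert set(a) <= set(full)


def test_site_5mer_minus_strand():
    # plus-strand TTCAA at 2..6; its reverse complement TTGAA sits on minus
    genome = ps.GenomeSequence("g", "GGTTCAAGG")
    assert site_5mer(genome, 2, "+") == "UUCAA"
    assert site_5mer(genome, 6, "-") == "UUGAA"


def test_scan_motif_sites_finds_planted(small_sim):
    cfg, tr, _ = small_sim
    for s in tr.sites:
        m = tr.model(s.gene_id)
        g, _ = tr.genomic_site(s)
        assert g in scan_motif_sites(tr.genome, m, "UURAA")
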