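"""Amplicon constructs, read simulation, demultiplexing, alignment, calling."""

import numpy as np
import pytest

from sibtrace import amplicon
from sibtrace.amplicon import (
    I5_ADAPTER,
    I7_ADAPTER,
    INSERT_LENGTH,
    SNP_OFFSET,
    TAG_LENGTH,
    AlignmentHit,
    BarcodeScheme,
    PileupCounts,
    UngappedAligner,
    build_constructs,
    build_mini_reference,
    call_genotype,
    demultiplex,
    generate_reads,
    iter_demultiplex,
    revcomp,
    trim_pair,
)
from sibtrace.genotypes import HET, HOM_ALT, HOM_REF, GenotypeMatrix, VariantSite
from sibtrace.snp_select import Panel


class TestMiniReference:
    def test_ten_site_panel_gives_2000_bases(self, small_genome, planted_panel):
        ref = build_mini_reference(small_genome, planted_panel, window=200)
        assert len(ref.names) == 10
        assert ref.total_length == 2000
        assert all(len(ref.seqs[n]) == 200 for n in ref.names)

    def test_windows_equal_genome_slices(self, small_genome, planted_panel):
        ref = build_mini_reference(small_genome, planted_panel)
        for name in ref.names:
            chrom, start0 = ref.origins[name]
            assert ref.seqs[name] == small_genome[chrom][start0 : start0 + 200]
            # SNP column carries the ref base and lifts back to the site
            site = ref.sites[name]
            off = ref.snp_offsets[name]
            assert ref.seqs[name][off] == site.ref
            assert ref.lift_over(name, off) == (site.chrom, site.pos)

    def test_empty_panel_gives_empty_reference(self, small_genome):
        ref = build_mini_reference(small_genome, Panel([]))
        assert ref.names == [] and ref.total_length == 0

    def test_site_absent_from_genome_rejected(self, small_genome):
        bad = Panel([VariantSite("chrX", 500, "A", "G")])
        with pytest.raises(ValueError, match="absent"):
            build_mini_reference(small_genome, bad)

    def test_round_trip(self, tmp_path, small_genome, planted_panel):
        ref = build_mini_reference(small_genome, planted_panel)
        ref.write(tmp_path / "mr.fasta", tmp_path / "mr_map.tsv")
        back = amplicon.MiniReference.read(tmp_path / "mr.fasta", tmp_path / "mr_map.tsv")
        assert back.names == ref.names
        assert back.seqs == ref.seqs
        assert back.snp_offsets == ref.snp_offsets
        assert back.origins == ref.origins


class TestConstructs:
    def test_first_sample_prefix_matches_printed_tags(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme()
        c = build_constructs(small_genome, planted_panel, scheme, "sample_01", ["ref"])[0]
        assert c.sequence.startswith("AATAT" + "AGGTA" + I5_ADAPTER)

    def test_geometry(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme()
        constructs = build_constructs(small_genome, planted_panel, scheme, "sample_02")
        assert len(constructs) == 2 * len(planted_panel)
        for c in constructs:
            assert len(c.insert) == INSERT_LENGTH == 120
            allele_base = c.site.ref if c.allele == "ref" else c.site.alt
            assert c.insert[SNP_OFFSET - 1] == allele_base  # SNP at offset 60
            assert len(c.sequence) == 10 + 19 + 120 + 19 + 10 == 178

    def test_ref_and_alt_differ_at_exactly_one_base(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme()
        by_allele = {
            c.allele: c
            for c in build_constructs(small_genome, planted_panel, scheme, "sample_03")
            if c.site == planted_panel.sites[0]
        }
        diff = [
            i for i, (a, b) in enumerate(
                zip(by_allele["ref"].sequence, by_allele["alt"].sequence)
            ) if a != b
        ]
        assert len(diff) == 1
        assert diff[0] == TAG_LENGTH + len(I5_ADAPTER) + SNP_OFFSET - 1

    def test_mate2_starts_with_i7_tag_then_adapter(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme()
        c = build_constructs(small_genome, planted_panel, scheme, "sample_01", ["ref"])[0]
        r2 = revcomp(c.sequence)
        assert r2.startswith("CCTCT" + "GGAGA" + I7_ADAPTER)


class TestBarcodeScheme:
    def test_reference_scheme_holds_19_unique_pairs(self):
        scheme = BarcodeScheme.reference_scheme()
        assert len(scheme) == 19

    def test_combinatorial_capacity(self):
        names = [f"s{i}" for i in range(361)]
        scheme = BarcodeScheme.combinatorial(names)
        assert len(scheme) == 361
        with pytest.raises(ValueError, match="at most"):
            BarcodeScheme.combinatorial([f"s{i}" for i in range(362)])

    def test_duplicate_pairs_rejected(self):
        tag = amplicon.BarcodeTag("AATAT", "AGGTA", "CCTCT", "GGAGA")
        with pytest.raises(ValueError, match="unique"):
            BarcodeScheme({"a": tag, "b": tag})

    def test_tsv_round_trip(self, tmp_path):
        scheme = BarcodeScheme.combinatorial([f"s{i}" for i in range(25)])
        scheme.write_tsv(tmp_path / "scheme.tsv")
        back = BarcodeScheme.read_tsv(tmp_path / "scheme.tsv")
        assert back.entries == scheme.entries


@pytest.fixture(scope="module")
def read_setup(small_genome, planted_panel):
    """19 offspring-like samples with known genotypes at the panel sites."""
    rng = np.random.default_rng(71)
    scheme = BarcodeScheme.reference_scheme()
    samples = scheme.samples
    calls = rng.integers(0, 3, size=(len(samples), len(planted_panel))).astype(np.int8)
    genotypes = GenotypeMatrix(samples, list(planted_panel.sites), calls)
    return scheme, genotypes


class TestGenerateReads:
    def test_error_free_hom_ref_reads_carry_ref_allele(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme(["s1"])
        site = planted_panel.sites[0]
        genotypes = GenotypeMatrix(["s1"], [site], np.array([[HOM_REF]], dtype=np.int8))
        pairs = list(
            generate_reads(small_genome, Panel([site]), scheme, genotypes,
                           depth_mean=200, quality_q=None, seed=72)
        )
        snp_col = TAG_LENGTH + len(I5_ADAPTER) + SNP_OFFSET - 1
        assert pairs and all(p.seq1[snp_col] == site.ref for p in pairs)

    def test_mean_depth_within_5_percent(self, small_genome, planted_panel, read_setup):
        scheme, genotypes = read_setup
        one_sample = genotypes.restrict_to_samples(["sample_01"])
        pairs = list(
            generate_reads(small_genome, planted_panel, scheme, one_sample,
                           depth_mean=2300, quality_q=None, seed=73)
        )
        per_site = len(pairs) / len(planted_panel)
        assert abs(per_site - 2300) / 2300 < 0.05

    def test_het_allele_balance_binomial(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme(["s1"])
        site = planted_panel.sites[0]
        genotypes = GenotypeMatrix(["s1"], [site], np.array([[HET]], dtype=np.int8))
        n = 10_000
        pairs = list(
            generate_reads(small_genome, Panel([site]), scheme, genotypes,
                           depth_mean=n, quality_q=None, seed=74,
                           depth_distribution="fixed")
        )
        snp_col = TAG_LENGTH + len(I5_ADAPTER) + SNP_OFFSET - 1
        alt_frac = np.mean([p.seq1[snp_col] == site.alt for p in pairs])
        assert abs(alt_frac - 0.5) < 3 * np.sqrt(0.25 / len(pairs))

    def test_zero_depth_warns_and_yields_nothing(self, small_genome, planted_panel, read_setup):
        scheme, genotypes = read_setup
        with pytest.warns(UserWarning, match="depth"):
            pairs = list(
                generate_reads(small_genome, planted_panel, scheme, genotypes,
                               depth_mean=0, seed=75)
            )
        assert pairs == []

    def test_substitution_error_rate_tracks_quality(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme(["s1"])
        site = planted_panel.sites[0]
        genotypes = GenotypeMatrix(["s1"], [site], np.array([[HOM_REF]], dtype=np.int8))
        panel1 = Panel([site])
        template = build_constructs(
            small_genome, panel1, scheme, "s1", ["ref"]
        )[0].sequence[:150]
        pairs = list(
            generate_reads(small_genome, panel1, scheme, genotypes,
                           depth_mean=2000, quality_q=20, seed=76,
                           depth_distribution="fixed")
        )
        mism = sum(a != b for p in pairs for a, b in zip(p.seq1, template))
        n_bases = len(pairs) * 150
        rate = mism / n_bases
        assert abs(rate - 0.01) < 3 * np.sqrt(0.01 * 0.99 / n_bases)


class TestDemultiplex:
    def test_printed_row1_tags_map_to_first_sample(self, small_genome, planted_panel, read_setup):
        scheme, _ = read_setup
        site = planted_panel.sites[0]
        genotypes = GenotypeMatrix(
            ["sample_01"], [site], np.array([[HOM_REF]], dtype=np.int8)
        )
        pair = next(
            iter(generate_reads(small_genome, Panel([site]), scheme, genotypes,
                                depth_mean=10, quality_q=None, seed=81))
        )
        assert pair.seq1.startswith("AATATAGGTA")
        assert pair.seq2.startswith("CCTCTGGAGA")
        (sample, _), = iter_demultiplex([pair], scheme)
        assert sample == "sample_01"

    def test_unknown_tag_goes_unassigned(self, small_genome, planted_panel, read_setup):
        scheme, genotypes = read_setup
        pairs = list(
            generate_reads(small_genome, planted_panel, scheme,
                           genotypes.restrict_to_samples(["sample_01"]),
                           depth_mean=5, quality_q=None, seed=82)
        )
        mangled = [p._replace(seq1="GGGGGGGGGG" + p.seq1[10:]) for p in pairs]
        assigned, unassigned = demultiplex(mangled, scheme)
        assert sum(map(len, assigned.values())) == 0
        assert len(unassigned) == len(mangled)

    def test_error_free_reads_all_assigned_to_true_sample(
        self, small_genome, planted_panel, read_setup
    ):
        """19 samples, error-free reads: every pair lands on the sample its
        read name records, and assignment partitions the input."""
        scheme, genotypes = read_setup
        pairs = list(
            generate_reads(small_genome, planted_panel, scheme, genotypes,
                           depth_mean=20, quality_q=None, seed=83)
        )
        assert len(pairs) >= 200 * 19
        assigned, unassigned = demultiplex(pairs, scheme)
        assert not unassigned
        assert sum(map(len, assigned.values())) == len(pairs)
        for sample, sample_pairs in assigned.items():
            assert all(p.name.split("|")[0] == sample for p in sample_pairs)

    def test_one_mismatch_mode_recovers_mangled_tag(self, read_setup):
        scheme, _ = read_setup
        tag = scheme.tag_for("sample_02")
        seq1 = "C" + tag.i5_tag[1:] + "A" * 140
        seq2 = tag.i7_tag + "A" * 140
        pair = amplicon.ReadPair("r", seq1, "I" * 150, seq2, "I" * 150)
        assert next(iter_demultiplex([pair], scheme))[0] is None
        loose = BarcodeScheme(scheme.entries, max_mismatch=1)
        assert next(iter_demultiplex([pair], loose))[0] == "sample_02"


@pytest.fixture(scope="module")
def reference(small_genome, planted_panel):
    return build_mini_reference(small_genome, planted_panel)


class TestAlignment:
    @staticmethod
    def brute_force_best(reference, read):
        """Independent exhaustive scan over every window, strand and offset."""
        best = None
        for name in reference.names:
            for strand in "+-":
                seq = reference.seqs[name] if strand == "+" else revcomp(reference.seqs[name])
                for off in range(len(seq) - len(read) + 1):
                    d = sum(a != b for a, b in zip(read, seq[off : off + len(read)]))
                    if best is None or d < best[0]:
                        best = (d, name, strand, off)
        return best

    def test_exact_window_substring_aligns_at_distance_zero(self, reference):
        aligner = UngappedAligner(reference)
        name = reference.names[3]
        read = reference.seqs[name][40:160]
        hit = aligner.align(read)
        assert hit == AlignmentHit(name, 40, "+", 0)

    def test_single_substitution_still_unique_best(self, reference):
        aligner = UngappedAligner(reference)
        name = reference.names[5]
        read = list(reference.seqs[name][10:130])
        read[60] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[60]]
        hit = aligner.align("".join(read))
        assert (hit.name, hit.offset, hit.distance) == (name, 10, 1)

    def test_agreement_with_exhaustive_scan(self, reference):
        """100 random reads (mutated window slices and pure noise): the seeded
        aligner must reproduce the exhaustive scan's best distance and its
        keep/discard decision."""
        rng = np.random.default_rng(91)
        aligner = UngappedAligner(reference)
        bases = np.array(list("ACGT"))
        for k in range(100):
            if k % 2 == 0:
                name = reference.names[rng.integers(0, len(reference.names))]
                off = int(rng.integers(0, 80))
                read = list(reference.seqs[name][off : off + 120])
                for pos in rng.choice(120, size=rng.integers(0, 9), replace=False):
                    read[pos] = str(rng.choice(bases))
                read = "".join(read)
            else:
                read = "".join(rng.choice(bases, 120))
            d_best, *_ = self.brute_force_best(reference, read)
            hit = aligner.align(read)
            if d_best > int(0.10 * 120):
                assert hit is None
            else:
                assert hit is not None and hit.distance == d_best

    def test_reverse_strand_base_extraction(self, reference):
        aligner = UngappedAligner(reference)
        name = reference.names[0]
        col = reference.snp_offsets[name]
        read = revcomp(reference.seqs[name][col - 50 : col + 70])
        hit = aligner.align(read)
        assert hit.strand == "-" and hit.offset == col - 50
        assert aligner.base_at(read, hit, col) == reference.seqs[name][col]


class TestCallGenotype:
    site = VariantSite("chr2", 500, "A", "G")

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (1000, 0, HOM_REF),
            (520, 480, HET),       # alt fraction 0.48 inside [0.2, 0.8]
            (0, 1000, HOM_ALT),
            (30, 0, amplicon.NO_CALL),  # depth below min_depth
            (850, 150, HOM_REF),   # 0.15 < 0.2
            (150, 850, HOM_ALT),   # 0.85 > 0.8
            (800, 200, HET),       # boundary 0.2 inclusive
        ],
    )
    def test_threshold_caller(self, ref, alt, expected):
        counts = PileupCounts(ref=ref, alt=alt)
        call = call_genotype("s", self.site, counts, min_depth=100, het_band=(0.2, 0.8))
        assert call.call == expected

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            call_genotype("s", self.site, PileupCounts(), het_band=(0.9, 0.1))


class TestEndToEndGenotypeRecovery:
    def test_true_genotypes_recovered_at_depth_500_q30(
        self, small_genome, planted_panel, read_setup
    ):
        """simulate -> demultiplex -> align -> call reproduces the true panel
        genotypes (<= 1 discordance per 3,320 calls at 500x, Q30)."""
        scheme, genotypes = read_setup
        reference = build_mini_reference(small_genome, planted_panel)
        pairs = generate_reads(
            small_genome, planted_panel, scheme, genotypes,
            depth_mean=500, quality_q=30, seed=92,
        )
        pileups, discarded = amplicon.trim_and_align(
            iter_demultiplex(pairs, scheme), reference
        )
        calls = amplicon.call_all_genotypes(
            pileups, reference, genotypes.samples, min_depth=100
        )
        n_calls = len(calls)
        assert n_calls == 19 * 10
        discordant = 0
        for c in calls:
            true = genotypes.calls[
                genotypes.sample_index(c.sample), genotypes.site_index(c.site.key)
            ]
            discordant += int(c.call != true)
        assert discordant <= max(1, n_calls // 3320)

    def test_trim_recovers_insert_from_both_mates(self, small_genome, planted_panel):
        scheme = BarcodeScheme.reference_scheme(["s1"])
        c = build_constructs(small_genome, planted_panel, scheme, "s1", ["ref"])[0]
        pair = amplicon.ReadPair(
            "r", c.sequence[:150], "I" * 150, revcomp(c.sequence)[:150], "I" * 150
        )
        t1, t2 = trim_pair(pair)
        assert t1 == c.insert
        assert t2 == c.insert
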