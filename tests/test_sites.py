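"""Coordinate conventions, consensus derivation, strength, extraction."""

import numpy as np
import pytest

from splicesel.sites import (
    ACCEPTOR,
    DONOR,
    ConsensusTable,
    Role,
    SpliceSiteRecord,
    assign_strength_classes,
    derive_consensus,
    parse_splice_sites,
    position_role,
    read_site_table,
    site_offsets,
    ss_strength,
    write_site_table,
)

from conftest import CHR1, revcomp


class TestPositionRole:
    @pytest.mark.parametrize(
        "site_type, offset, role",
        [
            (DONOR, -1, Role.EXONIC),
            (DONOR, -3, Role.EXONIC),
            (DONOR, 1, Role.INVARIANT),
            (DONOR, 2, Role.INVARIANT),
            (DONOR, 3, Role.INTRONIC),
            (ACCEPTOR, -2, Role.INVARIANT),
            (ACCEPTOR, -1, Role.INVARIANT),
            (ACCEPTOR, -4, Role.NO_CONSENSUS),
            (ACCEPTOR, 1, Role.EXONIC),
            (ACCEPTOR, -24, Role.INTRONIC),
        ],
    )
    def test_role_table(self, site_type, offset, role):
        assert position_role(site_type, offset) is role

    @pytest.mark.parametrize(
        "site_type, offset", [(DONOR, 0), (DONOR, 7), (ACCEPTOR, -25), (ACCEPTOR, 2)]
    )
    def test_out_of_range_rejected(self, site_type, offset):
        with pytest.raises(ValueError):
            position_role(site_type, offset)

    def test_offset_ranges(self):
        assert site_offsets(DONOR) == tuple(range(-3, 0)) + tuple(range(1, 7))
        assert site_offsets(ACCEPTOR) == tuple(range(-24, 0)) + (1,)


class TestConsensusTable:
    def test_scored_offset_counts(self, consensus):
        # donor: -3..-1 and +3..+6; acceptor: -24..-3 minus -4, plus +1
        assert len(consensus.scored_offsets(DONOR)) == 7
        assert len(consensus.scored_offsets(ACCEPTOR)) == 22
        assert -4 not in consensus.scored_offsets(ACCEPTOR)

    def test_invariant_positions_carry_no_cn(self, consensus):
        assert consensus.cn(DONOR, 1) is None
        assert consensus.cn(ACCEPTOR, -1) is None
        assert consensus.cn(ACCEPTOR, -4) is None

    def test_cn_sets_have_size_one_or_two(self, consensus):
        for st in (DONOR, ACCEPTOR):
            for off in consensus.scored_offsets(st):
                assert 1 <= len(consensus.cn(st, off)) <= 2

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            ConsensusTable({(DONOR, 4): {"A", "C", "G"}})


class TestDeriveConsensus:
    def test_single_top_nucleotide(self):
        table = derive_consensus(
            {(DONOR, 4): {"A": 0.60, "C": 0.30, "G": 0.06, "T": 0.04}},
            secondary_threshold=0.35,
        )
        assert table.cn(DONOR, 4) == frozenset({"A"})

    def test_two_nucleotides_above_threshold(self):
        table = derive_consensus({(ACCEPTOR, -10): {"T": 0.5, "C": 0.4}})
        assert table.cn(ACCEPTOR, -10) == frozenset({"T", "C"})

    def test_forced_roles_ignore_frequencies(self):
        table = derive_consensus({(DONOR, 1): {"A": 0.9, "C": 0.1}})
        assert table.cn(DONOR, 1) is None
        assert position_role(DONOR, 1) is Role.INVARIANT

    def test_invariant_to_rescaling_and_idempotent(self):
        freqs = {(DONOR, 4): {"A": 6.0, "C": 3.0, "G": 0.6, "T": 0.4}}
        scaled = {(DONOR, 4): {k: 7.0 * v for k, v in freqs[(DONOR, 4)].items()}}
        assert derive_consensus(freqs) == derive_consensus(scaled)


class TestStrength:
    def _record(self, seq):
        return SpliceSiteRecord(
            site_id="x", site_type=DONOR, seq_by_species={"ref": seq}
        )

    def test_all_consensus_fraction_one(self, consensus):
        assert ss_strength(self._record("CAGGTAAGT"), consensus) == 1.0

    def test_partial_fraction(self, consensus):
        # offsets -3..-1, +3..+6 scored; flip -1 G->T, +5 G->C, +6 T->A
        assert ss_strength(self._record("CATGTAACA"), consensus) == pytest.approx(4 / 7)

    def test_tertiles_split_evenly(self):
        fractions = [0.2] * 100 + [0.5] * 100 + [0.9] * 100
        labels, bounds = assign_strength_classes(fractions)
        assert labels.count("weak") == labels.count("middle") == 100
        assert labels.count("strong") == 100
        assert labels[0] == "weak" and labels[150] == "middle" and labels[250] == "strong"
        assert bounds == [0.2, 0.5]


class TestExtraction:
    def test_plus_strand_donor_window(self, toy_gff, toy_fasta):
        records = parse_splice_sites(toy_gff, toy_fasta)
        donors = {r.boundary: r for r in records if r.site_type == DONOR and r.chrom == "chr1"}
        assert donors[30].seq_by_species["ref"] == "CAGGTAAGT"

    def test_minus_strand_is_reverse_complement(self, toy_gff, toy_fasta):
        records = parse_splice_sites(toy_gff, toy_fasta)
        chr2_donors = sorted(
            (r for r in records if r.site_type == DONOR and r.chrom == "chr2"),
            key=lambda r: r.boundary,
        )
        # the mirrored gene must yield the same transcribed-strand sequences
        assert any(
            r.seq_by_species["ref"] == "CAGGTAAGT" for r in chr2_donors
        )
        for r in chr2_donors:
            start, end = r.boundary - 6, r.boundary + 3
            assert r.seq_by_species["ref"] == revcomp(
                revcomp(CHR1)[start:end]
            )

    def test_noncanonical_site_excluded_by_any_species(
        self, toy_gff, toy_fasta, toy_genome
    ):
        # break the GT of the chr1 intron-1 donor in the sister species only
        sister = dict(toy_genome)
        sister["chr1"] = CHR1[:30] + "C" + CHR1[31:]
        with_sister = parse_splice_sites(
            toy_gff, toy_fasta, alignments={"sister": sister}
        )
        plain = parse_splice_sites(toy_gff, toy_fasta)
        lost = {(r.chrom, r.boundary, r.site_type) for r in plain} - {
            (r.chrom, r.boundary, r.site_type) for r in with_sister
        }
        assert lost == {("chr1", 30, DONOR)}

    def test_duplicates_collapsed_and_classes_assigned(self, toy_gff, toy_fasta):
        records = parse_splice_sites(toy_gff, toy_fasta)
        keys = [(r.chrom, r.strand, r.boundary, r.site_type) for r in records]
        assert len(keys) == len(set(keys))
        by_key = {k: r for k, r in zip(keys, records)}
        # exon2 is absent from transcript t2, so its flanking acceptor/donor
        # are cassette sites; exon1 and exon3 sites are constitutive
        assert by_key[("chr1", "+", 70, ACCEPTOR)].splicing_class == "cassette"
        assert by_key[("chr1", "+", 100, DONOR)].splicing_class == "cassette"
        assert by_key[("chr1", "+", 30, DONOR)].splicing_class == "constitutive"
        assert by_key[("chr1", "+", 30, DONOR)].coding_class == "coding"
        assert by_key[("chr2", "-", 140, DONOR)].coding_class == "noncoding"

    def test_exon_outside_genome_rejected(self, toy_gff, tmp_path):
        short = tmp_path / "short.fa"
        short.write_text(">chr1\n" + CHR1[:100] + "\n>chr2\nACGT\n")
        with pytest.raises(ValueError):
            parse_splice_sites(toy_gff, str(short))


class TestSiteTableRoundTrip:
    def test_records_survive_write_read(self, toy_gff, toy_fasta, tmp_path):
        records = parse_splice_sites(toy_gff, toy_fasta)
        path = tmp_path / "sites.tsv"
        write_site_table(records, path)
        back = read_site_table(path)
        assert back == records
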