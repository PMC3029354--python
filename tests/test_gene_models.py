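"""Gene-structure parsing, phase arithmetic and round-trip fidelity."""

from __future__ import annotations

import pytest
from Bio.Seq import reverse_complement

from intronmap.gene_models import (
    GeneModel, extract_all_introns, extract_introns, read_gene_models,
    read_introns_fasta, read_sequences, translate_cds, write_introns_fasta,
)

GFF_HEADER = "##gff-version 3\n"


def _write_inputs(tmp_path, gff_body: str, contigs: dict[str, str]):
    gff = tmp_path / "a.gff3"
    gff.write_text(GFF_HEADER + gff_body)
    fasta = tmp_path / "a.fasta"
    fasta.write_text("".join(f">{k}\n{v}\n" for k, v in contigs.items()))
    return gff, fasta


def _gene_lines(contig, gid, strand, cds_intervals, species="spX"):
    lo = min(s for s, _ in cds_intervals)
    hi = max(e for _, e in cds_intervals)
    lines = [
        f"{contig}\t.\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gid};species={species}",
        f"{contig}\t.\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\tID={gid}.t1;Parent={gid}",
    ]
    for i, (s, e) in enumerate(cds_intervals, 1):
        lines.append(f"{contig}\t.\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                     f"ID={gid}.c{i};Parent={gid}.t1")
    return "\n".join(lines) + "\n"


class TestTranslation:
    @pytest.mark.parametrize("cds,expected", [
        ("ATGGCTTAA", "MA"),          # terminal stop dropped
        ("ATGNNNTAA", "MX"),          # ambiguous codon
        ("ATGGCT", "MA"),             # no stop at all
    ])
    def test_examples(self, cds, expected):
        assert translate_cds(cds) == expected

    def test_internal_stop_is_hard_error(self):
        with pytest.raises(ValueError, match="codon 2"):
            translate_cds("ATGTAAGCTTAA")

    def test_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError):
            translate_cds("ATGG")


class TestReadGeneModels:
    def test_single_exon_plus_strand(self, tmp_path):
        cds = "ATG" + "GCT" * 99 + "TAA"  # 303 nt
        gff, fasta = _write_inputs(
            tmp_path, _gene_lines("c1", "g1_H2A_1", "+", [(1, 303)]),
            {"c1": cds + "ACGT"})
        (gene,) = read_gene_models(gff, fasta)
        assert gene.exons == ((0, 303),)
        assert len(gene.cds_seq) == 303
        assert gene.protein_length == 100 and gene.has_stop
        assert gene.family == "H2A" and gene.copy_label == "H2A_1"

    def test_two_exon_minus_strand_coding_orientation(self, tmp_path):
        cds = "ATG" + "GGT" * 32 + "TAA"  # 102 nt split 51 + 51
        contig = ["A"] * 200
        # coding-order exon 1 at genomic 100..150, exon 2 at 10..60 (1-based)
        contig[99:150] = reverse_complement(cds[:51])
        contig[9:60] = reverse_complement(cds[51:])
        gff, fasta = _write_inputs(
            tmp_path, _gene_lines("c1", "g1_H3_1", "-", [(10, 60), (100, 150)]),
            {"c1": "".join(contig)})
        (gene,) = read_gene_models(gff, fasta)
        assert gene.exons == ((99, 150), (9, 60))  # coding order, 0-based
        assert gene.cds_seq == cds

    def test_missing_sequence_region_is_hard_error(self, tmp_path):
        gff, fasta = _write_inputs(
            tmp_path, _gene_lines("nope", "g1_H4_1", "+", [(1, 6)]), {"c1": "ACGTAA"})
        with pytest.raises(ValueError, match="g1_H4_1"):
            read_gene_models(gff, fasta)

    def test_cds_not_multiple_of_three_excluded_not_crash(self, tmp_path, caplog):
        body = (_gene_lines("c1", "bad_H4_1", "+", [(1, 7)])
                + _gene_lines("c1", "ok_H4_1", "+", [(11, 16)]))
        gff, fasta = _write_inputs(tmp_path, body, {"c1": "ATGGCTA" + "AAA" + "ATGTAA"})
        genes = read_gene_models(gff, fasta)
        assert [g.gene_id for g in genes] == ["ok_H4_1"]

    def test_copy_labels_follow_genomic_position(self, tmp_path):
        body = (_gene_lines("c1", "gB_H4", "+", [(31, 36)])
                + _gene_lines("c1", "gA_H4", "+", [(1, 6)]))
        gff, fasta = _write_inputs(tmp_path, body,
                                   {"c1": "ATGTAA" + "C" * 24 + "ATGTAA"})
        labels = {g.gene_id: g.copy_label for g in read_gene_models(gff, fasta)}
        assert labels == {"gA_H4": "H4_1", "gB_H4": "H4_2"}


def _gene(exons, cds, strand="+"):
    from intronmap.gene_models import _translate
    protein, has_stop = _translate(cds)
    return GeneModel(gene_id="g", species="s", family="H4", copy_label="H4_1",
                     contig="c", strand=strand, exons=tuple(exons), cds_seq=cds,
                     protein_seq=protein, has_stop=has_stop)


class TestExtractIntrons:
    def test_two_exons_phase_arithmetic(self):
        # coding lengths 10 and 8 -> one intron, offset 10, phase 1, anchor 3
        cds = "ATGGCTGCTGCTGCTGCT"  # 18 nt, no stop
        contig = cds[:10] + "GTAAAAAAAG" + cds[10:]
        gene = _gene([(0, 10), (20, 28)], cds)
        (intron,) = extract_introns(gene, contig)
        assert (intron.cds_offset, intron.phase, intron.anchor_residue) == (10, 1, 3)
        assert intron.seq == "GTAAAAAAAG"
        assert intron.length_nt == 10

    def test_intronless_gene(self):
        cds = "ATGGCTGCT"
        gene = _gene([(0, 9)], cds)
        assert extract_introns(gene, cds) == []

    def test_three_exons_9_9_9(self):
        cds = "ATGGCTGCTGCTGCTGCTGCTGCTGCT"  # 27 nt
        contig = cds[:9] + "GTTTAG" + cds[9:18] + "GTCCAG" + cds[18:]
        gene = _gene([(0, 9), (15, 24), (30, 39)], cds)
        introns = extract_introns(gene, contig)
        assert [(i.cds_offset, i.phase, i.anchor_residue) for i in introns] == [
            (9, 0, 3), (18, 0, 6)]
        assert [i.ordinal for i in introns] == [1, 2]

    def test_overlapping_exons_hard_error(self):
        cds = "ATGGCTGCTGCTGCTGCT"
        gene = _gene([(0, 10), (5, 13)], cds)
        with pytest.raises(ValueError, match="overlap"):
            extract_introns(gene, cds * 3)


class TestRoundTrip:
    def test_generator_output_reparses_exactly(self, small_truth):
        truth, paths = small_truth
        genes = read_gene_models(paths["gff"], paths["fasta"])
        seqs = read_sequences(paths["fasta"])
        introns = extract_all_introns(genes, seqs)
        expected_genes = {g.gene_id: g for g in truth.genes}
        assert {g.gene_id for g in genes} == set(expected_genes)
        for g in genes:
            t = expected_genes[g.gene_id]
            assert (g.exons, g.cds_seq, g.protein_seq, g.strand, g.has_stop,
                    g.copy_label) == (t.exons, t.cds_seq, t.protein_seq,
                                      t.strand, t.has_stop, t.copy_label)
        expected = {i.intron_id: i for i in truth.introns}
        assert {i.intron_id for i in introns} == set(expected)
        for i in introns:
            t = expected[i.intron_id]
            assert (i.cds_offset, i.phase, i.anchor_residue, i.seq,
                    i.genomic_start, i.genomic_end) == (
                t.cds_offset, t.phase, t.anchor_residue, t.seq,
                t.genomic_start, t.genomic_end)

    def test_strand_symmetry_under_contig_reverse_complement(self, small_truth, tmp_path):
        truth, paths = small_truth
        seqs = read_sequences(paths["fasta"])
        lengths = {k: len(v) for k, v in seqs.items()}
        flipped_fasta = tmp_path / "flipped.fasta"
        flipped_fasta.write_text("".join(
            f">{k}\n{reverse_complement(v)}\n" for k, v in seqs.items()))
        out = []
        for line in paths["gff"].read_text().splitlines():
            if line.startswith("#"):
                out.append(line)
                continue
            f = line.split("\t")
            L = lengths[f[0]]
            s, e = int(f[3]), int(f[4])
            f[3], f[4] = str(L - e + 1), str(L - s + 1)
            f[6] = "-" if f[6] == "+" else "+"
            out.append("\t".join(f))
        flipped_gff = tmp_path / "flipped.gff3"
        flipped_gff.write_text("\n".join(out) + "\n")

        genes = read_gene_models(flipped_gff, flipped_fasta)
        introns = extract_all_introns(genes, read_sequences(flipped_fasta))
        expected = {i.intron_id: i for i in truth.introns}
        assert {i.intron_id for i in introns} == set(expected)
        for i in introns:
            t = expected[i.intron_id]
            assert (i.cds_offset, i.phase, i.anchor_residue, i.seq) == (
                t.cds_offset, t.phase, t.anchor_residue, t.seq)

    def test_resplicing_reproduces_protein(self, small_truth):
        truth, paths = small_truth
        seqs = read_sequences(paths["fasta"])
        for g in truth.genes:
            spliced = "".join(
                seqs[g.contig][s:e] for s, e in sorted(g.exons))
            if g.strand == "-":
                spliced = reverse_complement(spliced)
            assert translate_cds(spliced) == g.protein_seq

    def test_introns_fasta_round_trip(self, small_truth, tmp_path):
        truth, _ = small_truth
        path = tmp_path / "introns.fasta"
        write_introns_fasta(truth.introns, path)
        back = {i.intron_id: i for i in read_introns_fasta(path)}
        assert len(back) == len(truth.introns)
        for i in truth.introns:
            assert back[i.intron_id] == i
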