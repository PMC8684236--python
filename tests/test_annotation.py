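"""Region and coding-effect classification."""

from types import SimpleNamespace

import numpy as np
import pytest

from oracles import effect_oracle
from somacohort.annotation import GenomeAnnotator, annotation_table
from somacohort.genome import GeneModel, Transcript, revcomp


def _variant(chrom, pos, ref, alt, vt=None):
    if vt is None:
        vt = "SNV" if len(ref) == len(alt) == 1 else \
            ("INS" if len(alt) > len(ref) else "DEL")
    return SimpleNamespace(chromosome=chrom, position=pos, ref_allele=ref,
                           alt_allele=alt, variant_type=vt)


def _single_exon_genome(cds: str, strand="+", pad=50):
    """One transcript whose CDS occupies [pad+1, pad+len] on one chromosome."""
    rng = np.random.default_rng(4)
    flank = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    insert = cds if strand == "+" else revcomp(cds)
    seq = flank(pad) + insert + flank(pad)
    tx = Transcript("GENE1", "GENE1-001", "chrT", strand,
                    exons=[(pad + 1, pad + len(cds))],
                    cds=[(pad + 1, pad + len(cds))])
    return {"chrT": seq}, GeneModel([tx]), tx


def _cds_with(fixed: dict, n_codons=500) -> str:
    filler = "GCT"  # Ala
    codons = ["ATG"] + [filler] * (n_codons - 2) + ["TAA"]
    for idx, codon in fixed.items():
        codons[idx - 1] = codon
    return "".join(codons)


class TestEffectExamples:
    def test_tgg_middle_transition_is_nonsense_W425X(self):
        cds = _cds_with({425: "TGG"})
        seqs, model, tx = _single_exon_genome(cds)
        pos = tx.cds_to_genomic(424 * 3 + 1)  # cds position 1274, codon pos 2
        annotator = GenomeAnnotator(model, seqs)
        effect, change, gene = annotator.classify_effect(
            _variant("chrT", pos, "G", "A"))
        assert (effect, change) == ("nonsense", "p.W425X")

    def test_cgg_middle_transition_is_missense_R463Q(self):
        cds = _cds_with({463: "CGG"})
        seqs, model, tx = _single_exon_genome(cds)
        pos = tx.cds_to_genomic(462 * 3 + 1)  # cds position 1388
        annotator = GenomeAnnotator(model, seqs)
        effect, change, _ = annotator.classify_effect(
            _variant("chrT", pos, "G", "A"))
        assert (effect, change) == ("missense", "p.R463Q")

    def test_third_base_gct_to_gcc_is_silent(self):
        cds = _cds_with({})
        seqs, model, tx = _single_exon_genome(cds)
        pos = tx.cds_to_genomic(10 * 3 + 2)  # third base of codon 11 (GCT)
        annotator = GenomeAnnotator(model, seqs)
        effect, change, _ = annotator.classify_effect(
            _variant("chrT", pos, "T", "C"))
        assert (effect, change) == ("silent", "p.A11A")

    def test_39nt_deletion_is_in_frame_indel(self):
        cds = _cds_with({44: "CCT", 56: "GAT"})
        seqs, model, tx = _single_exon_genome(cds)
        anchor = tx.cds_to_genomic(43 * 3) - 1  # base before codon 44
        seq = seqs["chrT"]
        ref = seq[anchor - 1 : anchor - 1 + 40]  # anchor + 39 deleted bases
        annotator = GenomeAnnotator(model, seqs)
        effect, change, _ = annotator.classify_effect(
            _variant("chrT", anchor, ref, ref[0]))
        assert effect == "indel"
        assert change == "p.P44_D56del"  # 13 residues removed in frame

    def test_non_triplet_deletion_is_frameshift(self):
        cds = _cds_with({})
        seqs, model, tx = _single_exon_genome(cds)
        anchor = tx.cds_to_genomic(30)
        seq = seqs["chrT"]
        ref = seq[anchor - 1 : anchor + 4]  # 5 deleted bases
        annotator = GenomeAnnotator(model, seqs)
        effect, change, _ = annotator.classify_effect(
            _variant("chrT", anchor, ref, ref[0]))
        assert effect == "indel" and change.endswith("fs")

    def test_in_frame_insertion(self):
        cds = _cds_with({})
        seqs, model, tx = _single_exon_genome(cds)
        pos = tx.cds_to_genomic(60)
        base = seqs["chrT"][pos - 1]
        annotator = GenomeAnnotator(model, seqs)
        effect, change, _ = annotator.classify_effect(
            _variant("chrT", pos, base, base + "GATGAT"))
        assert effect == "indel" and change.endswith("ins2")


class TestRegions:
    def _two_gene_model(self):
        # tx1 exons [101..160],[301..360]; tx2 CDS overlapping tx1's intron
        tx1 = Transcript("AAA", "AAA-001", "chr1", "+",
                         exons=[(101, 160), (301, 360)],
                         cds=[(101, 160), (301, 360)])
        tx2 = Transcript("BBB", "BBB-001", "chr1", "-",
                         exons=[(181, 240)], cds=[(181, 240)])
        return GeneModel([tx1, tx2])

    def setup_method(self):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        self.seqs = {"chr1": seq}
        self.annotator = GenomeAnnotator(self._two_gene_model(), self.seqs)

    def _var_at(self, pos):
        ref = self.seqs["chr1"][pos - 1]
        alt = "A" if ref != "A" else "C"
        return _variant("chr1", pos, ref, alt)

    def test_cds_position_is_exonic(self):
        assert self.annotator.classify_region(self._var_at(130)) == "exonic"

    def test_between_genes_is_intergenic(self):
        assert self.annotator.classify_region(self._var_at(700)) == "intergenic"

    def test_intron_is_intronic(self):
        assert self.annotator.classify_region(self._var_at(260)) == "intronic"

    def test_intron_of_one_gene_overlapping_cds_of_another_is_exonic(self):
        # pos 200: intron of AAA, CDS of BBB -> exonic precedence
        assert self.annotator.classify_region(self._var_at(200)) == "exonic"

    def test_unknown_chromosome_warns_intergenic(self):
        with pytest.warns(UserWarning, match="absent"):
            region = self.annotator.classify_region(
                _variant("chrZ", 10, "A", "C"))
        assert region == "intergenic"


class TestAgainstTranslationOracle:
    def test_500_random_cds_snvs_match_full_protein_diff(self, small_genome):
        """Codon-level effect equals a translate-the-whole-protein oracle."""
        rng = np.random.default_rng(12)
        annotator = GenomeAnnotator(small_genome.gene_model,
                                    small_genome.chromosomes)
        txs = small_genome.gene_model.transcripts
        checked = 0
        while checked < 500:
            tx = txs[int(rng.integers(0, len(txs)))]
            cds = tx.cds_sequence(small_genome.chromosomes)
            off = int(rng.integers(3, tx.cds_length - 3))  # keep start/stop
            ref_tx = cds[off]
            alt_tx = "ACGT"[int(rng.integers(0, 4))]
            if alt_tx == ref_tx:
                continue
            pos = tx.cds_to_genomic(off)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            ref_g = ref_tx if tx.strand == "+" else comp[ref_tx]
            alt_g = alt_tx if tx.strand == "+" else comp[alt_tx]
            effect, change, _ = annotator.classify_effect(
                _variant(tx.chromosome, pos, ref_g, alt_g))
            expect_effect, expect_change = effect_oracle(cds, off, alt_tx)
            assert (effect, change) == (expect_effect, expect_change)
            assert effect in {"missense", "silent", "nonsense"}
            checked += 1

    def test_strand_symmetry(self):
        """The same CDS yields the same protein change on either strand."""
        cds = _cds_with({100: "TGG", 200: "CGG"})
        rng = np.random.default_rng(8)
        for codon, within, alt_tx, expected in [
            (100, 1, "A", ("nonsense", "p.W100X")),
            (200, 1, "A", ("missense", "p.R200Q")),
            (50, 0, "C", None),
        ]:
            results = []
            for strand in "+-":
                seqs, model, tx = _single_exon_genome(cds, strand=strand)
                annotator = GenomeAnnotator(model, seqs)
                off = (codon - 1) * 3 + within
                pos = tx.cds_to_genomic(off)
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                ref_g = cds[off] if strand == "+" else comp[cds[off]]
                alt_g = alt_tx if strand == "+" else comp[alt_tx]
                effect, change, _ = annotator.classify_effect(
                    _variant(tx.chromosome, pos, ref_g, alt_g))
                results.append((effect, change))
            assert results[0] == results[1]
            if expected is not None:
                assert results[0] == expected


def test_longest_cds_transcript_wins_ties_alphabetical():
    cds_long = _cds_with({}, n_codons=60)
    cds_short = _cds_with({10: "TGG"}, n_codons=40)
    seqs, _, tx_long = _single_exon_genome(cds_long)
    # a second, shorter transcript over the same region
    tx_short = Transcript("ZZZ", "ZZZ-001", "chrT", "+",
                          exons=[(51, 50 + len(cds_short))],
                          cds=[(51, 50 + len(cds_short))])
    model = GeneModel([tx_long, tx_short])
    annotator = GenomeAnnotator(model, seqs)
    pos = tx_long.cds_to_genomic(30)
    ref = seqs["chrT"][pos - 1]
    alt = "A" if ref != "A" else "G"
    _, _, gene = annotator.classify_effect(_variant("chrT", pos, ref, alt))
    assert gene == "GENE1"  # longest CDS preferred


def test_annotate_and_table(small_cohort):
    genome, truth = small_cohort["genome"], small_cohort["truth"]
    annotator = GenomeAnnotator(genome.gene_model, genome.chromosomes)
    anns = [annotator.annotate(v, sample_id=v.sample_id)
            for v in truth.variants[:500]]
    for a in anns:
        assert (a.effect_class != "none") == (a.region_class == "exonic")
        assert (a.protein_change is not None) == (a.effect_class != "none")
    df = annotation_table({"s": anns})
    assert len(df) == len(anns)
    assert set(df["region_class"]) <= {"exonic", "intronic", "intergenic"}
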