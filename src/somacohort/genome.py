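"""Genome and gene-model containers shared by the generator and annotator.

Coordinate conventions follow the file formats: FASTA sequences are plain
strings, BED intervals are 0-based half-open, GFF3 features are 1-based
closed. In-memory intervals on :class:`Transcript` are 1-based closed
(GFF3 convention); gap/mask intervals on :class:`SyntheticGenome` are
0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT_TABLE)[::-1]


@dataclass
class Transcript:
    """A protein-coding transcript: exons and CDS as 1-based closed intervals.

    ``cds`` intervals are stored in ascending genomic order regardless of
    strand; translation order is reversed for minus-strand transcripts.
    """

    gene_name: str
    transcript_id: str
    chromosome: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a "
                "multiple of 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_in_translation_order(self) -> list[tuple[int, int]]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def phases(self) -> list[int]:
        """GFF3 phase of each CDS segment, in genomic order."""
        out, cum = {}, 0
        for iv in self.cds_in_translation_order():
            out[iv] = (3 - cum % 3) % 3
            cum += iv[1] - iv[0] + 1
        return [out[iv] for iv in self.cds]

    def cds_sequence(self, sequences) -> str:
        """Coding sequence on the transcript strand (starts with the ATG)."""
        chunks = [str(sequences[self.chromosome][s - 1 : e]).upper() for s, e in self.cds]
        seq = "".join(chunks)
        return seq if self.strand == "+" else revcomp(seq)

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a 1-based genomic position to a 0-based CDS offset, or None."""
        cum = 0
        for s, e in self.cds_in_translation_order():
            if s <= pos <= e:
                return cum + (pos - s if self.strand == "+" else e - pos)
            cum += e - s + 1
        return None

    def cds_to_genomic(self, offset: int) -> int:
        """Map a 0-based CDS offset to its 1-based genomic position."""
        cum = 0
        for s, e in self.cds_in_translation_order():
            seg = e - s + 1
            if offset < cum + seg:
                k = offset - cum
                return s + k if self.strand == "+" else e - k
            cum += seg
        raise IndexError(f"CDS offset {offset} beyond CDS length {self.cds_length}")


@dataclass
class GeneModel:
    transcripts: list[Transcript] = field(default_factory=list)

    def by_chromosome(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            out.setdefault(t.chromosome, []).append(t)
        return out

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class SyntheticGenome:
    """A small self-contained reference: sequences, gaps, mask, gene model."""

    chromosomes: dict[str, str]
    gap_intervals: dict[str, list[tuple[int, int]]]  # 0-based half-open
    low_complexity_mask: dict[str, list[tuple[int, int]]]  # 0-based half-open
    gene_model: GeneModel

    def chromosome_length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def non_gap_extent(self, name: str) -> tuple[int, int]:
        """0-based half-open extent from first to last non-N base."""
        seq = self.chromosomes[name]
        first = len(seq) - len(seq.lstrip("N"))
        last = len(seq.rstrip("N"))
        return (first, last)

    def terminal_windows(self, fraction: float = 0.05) -> dict[str, list[tuple[int, int]]]:
        """Outermost ``fraction`` of each chromosome's non-gap span, both ends.

        Returns 0-based half-open windows. ``fraction`` must be < 0.5 so
        the two windows do not meet.
        """
        if not 0 < fraction < 0.5:
            raise ValueError("terminal fraction must be in (0, 0.5)")
        out = {}
        for name in self.chromosomes:
            s, e = self.non_gap_extent(name)
            w = int(round(fraction * (e - s)))
            out[name] = [(s, s + w), (e - w, e)]
        return out


# ---------------------------------------------------------------------------
# File I/O


def write_fasta(genome: SyntheticGenome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: dict[str, list[tuple[int, int]]], path, name: str = "") -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for s, e in sorted(intervals[chrom]):
                cols = [chrom, str(s), str(e)]
                if name:
                    cols.append(name)
                fh.write("\t".join(cols) + "\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(s), int(e)))
    return out


def write_gff3(model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in model.transcripts:
            s, e = t.span
            gid, tid = t.gene_name, t.transcript_id
            fh.write(
                f"{t.chromosome}\tsomacohort\tgene\t{s}\t{e}\t.\t{t.strand}\t.\t"
                f"ID=gene:{gid};Name={gid}\n"
            )
            fh.write(
                f"{t.chromosome}\tsomacohort\tmRNA\t{s}\t{e}\t.\t{t.strand}\t.\t"
                f"ID=tx:{tid};Parent=gene:{gid}\n"
            )
            for i, (xs, xe) in enumerate(t.exons, 1):
                fh.write(
                    f"{t.chromosome}\tsomacohort\texon\t{xs}\t{xe}\t.\t{t.strand}\t.\t"
                    f"ID=exon:{tid}.{i};Parent=tx:{tid}\n"
                )
            for (cs, ce), phase in zip(t.cds, t.phases()):
                fh.write(
                    f"{t.chromosome}\tsomacohort\tCDS\t{cs}\t{ce}\t.\t{t.strand}\t"
                    f"{phase}\tID=cds:{tid};Parent=tx:{tid}\n"
                )


def read_gff3(path) -> GeneModel:
    """Load a gene model from GFF3 (gene/mRNA/exon/CDS features)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        gene_name = mrna.attributes.get("Parent", ["gene:?"])[0].split(":", 1)[-1]
        tid = mrna.id.split(":", 1)[-1]
        transcripts.append(
            Transcript(
                gene_name=gene_name,
                transcript_id=tid,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    return GeneModel(transcripts=transcripts)
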