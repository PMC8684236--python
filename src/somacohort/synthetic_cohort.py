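"""Synthetic tumor-normal cohort generator.

Builds a small self-contained reference genome (FASTA + gap BED +
low-complexity BED + GFF3 gene model), plants per-sample somatic truth
mutations with signature-driven trinucleotide contexts, kataegis clusters,
chromosome-terminal enrichment and subtype-specific driver events, then
emulates three callers' VCF output with configurable false positives and
negatives plus a shared artifact background across matched normals.

The emulated cohort mirrors a 26-pair craniopharyngioma-like design: 16
adamantinomatous-like (ACP) and 10 papillary-like (PCP) samples, on the
order of 760 SNVs and 39 InDels per tumor, CTNNB1-exon-3-like drivers in
ACP and BRAF-V600E-like drivers in PCP, mutually exclusive. All mutation
counts are per genome, so the analysis downstream is independent of the
(desk-scale) genome size.

Randomness: every operation derives its generator from ``config.seed`` plus
a fixed stream offset, so each stage is individually deterministic and the
whole pipeline is byte-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome import GeneModel, SyntheticGenome, Transcript, revcomp, write_bed, write_fasta, write_gff3
from .samples import SampleMeta, write_sample_metadata
from .sigdata import bundled_signatures
from .spectrum import CHANNELS_96, collapse_to_context96
from .vcfio import CallRecord, write_vcf

CALLER_A = "A_mutect2like"  # SNVs, with PASS flags
CALLER_B = "B_strelka2like"  # SNVs + InDels
CALLER_C = "C_varscan2like"  # InDels, with p-values

DRIVER_ACP = "CTNNB1-exon3-like"
DRIVER_PCP = "BRAF-V600E-like"

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G

# 61 sense codons of the standard code (no TAA/TAG/TGA).
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class CallerError:
    """Per-caller error model: FP records per true call, and FN drop rate."""

    fp_rate: float = 0.05
    fn_rate: float = 0.02

    def __post_init__(self):
        for r in (self.fp_rate, self.fn_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"caller error rate {r} outside [0,1]")


@dataclass
class KataegisSpec:
    """A planted cluster: n_mutations placed within [start, start+span)."""

    chromosome: str
    start: int
    n_mutations: int
    span: int


@dataclass
class CohortConfig:
    n_acp: int = 16
    n_pcp: int = 10
    chromosome_lengths: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_200_000, "chr3": 800_000}
    )
    mean_snv: float = 760.0
    mean_indel: float = 39.0
    ages: list | None = None  # per-sample; drawn uniformly on [6, 70] if None
    age_slope: float = 0.6  # relative burden increase across the age range
    signature_mixture: dict = field(
        default_factory=lambda: {"S1": 0.18, "S2": 0.65, "S3": 0.10}
    )
    kataegis_spec: list = field(
        default_factory=lambda: [
            KataegisSpec("chr1", 1_000_000, 8, 3_000),
            KataegisSpec("chr2", 600_000, 9, 2_500),
        ]
    )
    terminal_bias: float = 0.30
    caller_error: dict = field(
        default_factory=lambda: {
            CALLER_A: CallerError(),
            CALLER_B: CallerError(),
            CALLER_C: CallerError(),
        }
    )
    artifact_site_rate: float = 2e-5  # shared-normal background sites per non-gap bp
    low_complexity_per_bp: float = 1 / 25_000
    gap_length: int = 3_000
    driver_fraction_acp: float = 11 / 16
    driver_fraction_pcp: float = 7 / 10
    terminal_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        mix = self.signature_mixture
        if any(w < 0 for w in mix.values()) or sum(mix.values()) > 1 + 1e-9:
            raise ConfigurationError("signature mixture weights must be >= 0, sum <= 1")
        for r in (self.terminal_bias, self.artifact_site_rate,
                  self.driver_fraction_acp, self.driver_fraction_pcp):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"rate {r} outside [0,1]")
        if len(self.chromosome_lengths) < 2:
            raise ConfigurationError("at least 2 chromosomes are required")
        for name, length in self.chromosome_lengths.items():
            if length < 200_000:
                raise ConfigurationError(f"{name}: chromosomes must be >= 200 kb")
            window = int(round(self.terminal_fraction * length))
            if length < 2 * window + 2 * self.gap_length:
                raise ConfigurationError(
                    f"{name} shorter than twice its terminal window plus gaps"
                )
        self.kataegis_spec = [
            k if isinstance(k, KataegisSpec)
            else (KataegisSpec(**k) if isinstance(k, dict) else KataegisSpec(*k))
            for k in self.kataegis_spec
        ]
        self.caller_error = {
            k: (v if isinstance(v, CallerError) else CallerError(**v))
            for k, v in self.caller_error.items()
        }

    @property
    def n_samples(self) -> int:
        return self.n_acp + self.n_pcp

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class TruthVariant:
    sample_id: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_type: str  # SNV / INS / DEL
    channel: str | None  # 96-context for SNVs, None for InDels
    kataegis: bool = False
    driver: str = "none"
    region_class: str | None = None
    effect_class: str | None = None

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chromosome, self.position,
                self.ref_allele, self.alt_allele)


@dataclass
class PlantedCluster:
    sample_id: str
    chromosome: str
    start: int
    end: int
    n_mutations: int


@dataclass
class TruthSet:
    samples: list  # list[SampleMeta]
    variants: list  # list[TruthVariant]
    clusters: list = field(default_factory=list)  # list[PlantedCluster]

    def by_sample(self) -> dict:
        out = {s.sample_id: [] for s in self.samples}
        for v in self.variants:
            out[v.sample_id].append(v)
        return out

    def keys_by_sample(self) -> dict:
        return {
            sid: {(v.chromosome, v.position, v.ref_allele, v.alt_allele) for v in vs}
            for sid, vs in self.by_sample().items()
        }

    def to_json(self, path) -> None:
        doc = {
            "samples": [dataclasses.asdict(s) for s in self.samples],
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "clusters": [dataclasses.asdict(c) for c in self.clusters],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Reference generation

# Gene layout: (gene, transcript, chrom index, strand, position as fraction
# of chromosome length, n_codons, exon CDS lengths in nt, fixed codons).
# CTNB1L exon 3 is the designated ACP driver locus and hosts hotspot codons
# (the real gene's S33/S37/T41/S45 orthologs) plus the composite
# A43G + 39-nt in-frame deletion event; BRAFL codon 600 (GTG) is the PCP
# driver; FBXW7L codon 425 (TGG) yields a stop on a middle-base transition;
# CHD8L codon 463 (CGG) yields R->Q.
_GENE_LAYOUT = [
    ("CTNB1L", "CTNB1L-001", 0, "+", 0.10, 300, [45, 39, 420, 210, 186],
     {32: "GAT", 33: "TCT", 37: "TCT", 41: "ACT", 43: "GCA", 44: "CCT",
      45: "TCT", 56: "GAT"}),
    ("BRAFL", "BRAFL-001", 0, "-", 0.45, 650, [510, 480, 510, 450],
     {600: "GTG"}),
    ("FBXW7L", "FBXW7L-001", 1, "-", 0.15, 500, [480, 540, 480], {425: "TGG"}),
    ("CHD8L", "CHD8L-001", 1, "+", 0.50, 500, [360, 420, 390, 330], {463: "CGG"}),
]

# CTNB1L exon-3 hotspot substitutions: (codon, 0-based base in codon, alt on
# transcript strand). All are missense by the standard code.
_ACP_HOTSPOTS = [(32, 1, "G"), (33, 0, "C"), (41, 0, "G"), (45, 0, "C")]
_ACP_COMPOSITE_SNV = (43, 1, "G")  # GCA -> GGA, Ala -> Gly
_ACP_COMPOSITE_DEL = (44, 56)  # codons deleted in frame (39 nt)
_PCP_DRIVER_SNV = (600, 1, "A")  # GTG -> GAG, Val -> Glu


def _build_cds(rng, n_codons: int, fixed: dict[int, str]) -> str:
    codons = [None] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for idx, codon in fixed.items():
        if codon in _STOPS:
            raise ConfigurationError(f"fixed codon {idx} is a stop codon")
        codons[idx - 1] = codon
    picks = rng.integers(0, len(_SENSE_CODONS), n_codons)
    for i in range(1, n_codons - 1):
        if codons[i] is None:
            codons[i] = _SENSE_CODONS[picks[i]]
    return "".join(codons)


def generate_reference(config: CohortConfig) -> SyntheticGenome:
    """Generate the synthetic reference genome, deterministic for a seed."""
    rng = np.random.default_rng([config.seed, 1])
    names = list(config.chromosome_lengths)
    arrays: dict[str, np.ndarray] = {}
    gaps: dict[str, list] = {}
    masks: dict[str, list] = {name: [] for name in names}

    for name in names:
        length = config.chromosome_lengths[name]
        arr = rng.integers(0, 4, length).astype(np.uint8)
        g = config.gap_length
        arr[:g] = 4
        arr[length - g:] = 4
        gaps[name] = [(0, g), (length - g, length)]
        arrays[name] = arr
    # one interior gap in the largest chromosome (assembly-gap stand-in)
    big = max(names, key=lambda n: config.chromosome_lengths[n])
    gl = config.chromosome_lengths[big]
    istart = int(0.62 * gl)
    arrays[big][istart : istart + 5_000] = 4
    gaps[big].append((istart, istart + 5_000))
    gaps[big].sort()

    # gene model
    transcripts = []
    gene_spans: dict[str, list] = {name: [] for name in names}
    for gene, tid, ci, strand, frac, n_codons, exon_lens, fixed in _GENE_LAYOUT:
        chrom = names[min(ci, len(names) - 1)]
        if sum(exon_lens) != n_codons * 3:
            raise ConfigurationError(f"{gene}: exon lengths do not sum to CDS")
        cds_seq = _build_cds(rng, n_codons, fixed)
        start = int(frac * config.chromosome_lengths[chrom])
        introns = rng.integers(400, 1_200, len(exon_lens) - 1)
        # genomic chunks laid left to right; translation order reverses on "-"
        chunks = []
        off = 0
        for ln in exon_lens:
            chunks.append(cds_seq[off : off + ln])
            off += ln
        if strand == "-":
            chunks = [revcomp(c) for c in reversed(chunks)]
        cds_intervals = []
        pos = start
        for i, chunk in enumerate(chunks):
            s1, e1 = pos + 1, pos + len(chunk)  # 1-based closed
            arrays[chrom][pos : pos + len(chunk)] = [_CODE[b] for b in chunk]
            cds_intervals.append((s1, e1))
            pos = e1 + (int(introns[i]) if i < len(introns) else 0)
        transcripts.append(
            Transcript(
                gene_name=gene,
                transcript_id=tid,
                chromosome=chrom,
                strand=strand,
                exons=list(cds_intervals),
                cds=cds_intervals,
            )
        )
        gene_spans[chrom].append((cds_intervals[0][0] - 1, cds_intervals[-1][1]))

    # low-complexity tracts, avoiding gaps and gene bodies
    repeat_units = ["A", "T", "AT", "CA", "AG", "AAT", "CAG"]
    for name in names:
        length = config.chromosome_lengths[name]
        n_tracts = int(round(length * config.low_complexity_per_bp))
        placed = []
        tries = 0
        while len(placed) < n_tracts and tries < n_tracts * 20:
            tries += 1
            tract_len = int(rng.integers(40, 200))
            pos = int(rng.integers(0, length - tract_len))
            iv = (pos, pos + tract_len)
            bad = any(iv[0] < e + 200 and s - 200 < iv[1] for s, e in gene_spans[name])
            bad = bad or any(iv[0] < e and s < iv[1] for s, e in gaps[name])
            bad = bad or any(iv[0] < e and s < iv[1] for s, e in placed)
            if bad:
                continue
            unit = repeat_units[int(rng.integers(0, len(repeat_units)))]
            rep = (unit * (tract_len // len(unit) + 1))[:tract_len]
            arrays[name][pos : pos + tract_len] = [_CODE[b] for b in rep]
            placed.append(iv)
        masks[name] = sorted(placed)

    chromosomes = {
        name: bytes(_BASES[arr]).decode("ascii") for name, arr in arrays.items()
    }
    return SyntheticGenome(
        chromosomes=chromosomes,
        gap_intervals=gaps,
        low_complexity_mask=masks,
        gene_model=GeneModel(transcripts=transcripts),
    )


def make_samples(config: CohortConfig) -> list[SampleMeta]:
    """Deterministic sample sheet: ids, ages, sex, subtype."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_samples
    if config.ages is not None:
        if len(config.ages) != n:
            raise ConfigurationError("ages must have one entry per sample")
        ages = list(config.ages)
    else:
        ages = [int(a) for a in rng.integers(6, 71, n)]
    sexes = ["M" if x < 0.5 else "F" for x in rng.random(n)]
    out = []
    for i in range(n):
        subtype = "ACP" if i < config.n_acp else "PCP"
        out.append(SampleMeta(f"CP{i + 1:02d}", ages[i], sexes[i], subtype))
    return out


# ---------------------------------------------------------------------------
# Context-indexed mutation planting


class _ContextIndex:
    """Eligible (unmasked, non-gap, N-free flank) positions per trinucleotide.

    Keys are pyrimidine-strand reference triplets, e.g. "ACG" for any
    position whose collapsed context is A.C.G. Values are (chrom index,
    1-based position) arrays. A parallel boolean marks terminal-window
    membership.
    """

    def __init__(self, genome: SyntheticGenome, terminal_fraction: float):
        self.chrom_names = list(genome.chromosomes)
        windows = genome.terminal_windows(terminal_fraction)
        chrom_idx_parts, pos_parts, ctx_parts, term_parts = [], [], [], []
        for ci, name in enumerate(self.chrom_names):
            seq = genome.chromosomes[name]
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            code = np.full(arr.shape, 4, dtype=np.uint8)
            for b, v in _CODE.items():
                code[arr == ord(b)] = v
            f5, c, f3 = code[:-2], code[1:-1], code[2:]
            valid = (f5 < 4) & (c < 4) & (f3 < 4)
            masked = np.zeros(len(seq), dtype=bool)
            for s, e in genome.low_complexity_mask.get(name, []):
                masked[s:e] = True
            valid &= ~masked[1:-1]
            is_pyr = (c == 1) | (c == 3)
            cf5 = np.where(is_pyr, f5, _COMP_CODE[f3])
            cc = np.where(is_pyr, c, _COMP_CODE[c])
            cf3 = np.where(is_pyr, f3, _COMP_CODE[f5])
            ctx_id = cf5.astype(np.int32) * 8 + (cc == 3) * 4 + cf3
            idx0 = np.nonzero(valid)[0]  # center at 0-based idx0+1
            pos1 = idx0 + 2  # 1-based position of the center base
            term = np.zeros(len(seq) + 1, dtype=bool)
            for s, e in windows[name]:
                term[s + 1 : e + 1] = True  # 1-based
            chrom_idx_parts.append(np.full(len(pos1), ci, dtype=np.int16))
            pos_parts.append(pos1.astype(np.int64))
            ctx_parts.append(ctx_id[idx0])
            term_parts.append(term[pos1])
        chrom_idx = np.concatenate(chrom_idx_parts)
        pos = np.concatenate(pos_parts)
        ctx = np.concatenate(ctx_parts)
        term = np.concatenate(term_parts)
        self.pools: dict[str, dict] = {}
        for key_id in range(32):
            f5 = "ACGT"[key_id // 8]
            center = "CT"[(key_id % 8) // 4]
            f3 = "ACGT"[key_id % 4]
            sel = ctx == (("ACGT".index(f5)) * 8 + ("CT".index(center)) * 4
                          + "ACGT".index(f3))
            self.pools[f5 + center + f3] = {
                "chrom": chrom_idx[sel],
                "pos": pos[sel],
                "term": term[sel],
            }
        self._by_chrom = {"chrom": chrom_idx, "pos": pos}

    def positions_in(self, chrom_name: str, start: int, end: int) -> np.ndarray:
        """Eligible 1-based positions within [start, end) on one chromosome."""
        ci = self.chrom_names.index(chrom_name)
        sel = (self._by_chrom["chrom"] == ci) & \
              (self._by_chrom["pos"] >= start) & (self._by_chrom["pos"] < end)
        return self._by_chrom["pos"][sel]


def _channel_triplet(channel: str) -> str:
    return channel[0] + channel[2] + channel[6]


def _draw_unique(rng, pool: np.ndarray, n: int, used: set, what: str) -> list[int]:
    """Draw n distinct values from pool avoiding ``used``; error when exhausted."""
    if n == 0:
        return []
    if n > len(pool):
        raise GenerationError(f"no genomic position available for {what}")
    out: list[int] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50:
            raise GenerationError(f"no genomic position available for {what}")
        draw = rng.choice(pool, size=min(len(pool), n - len(out) + 8), replace=False)
        for v in draw:
            v = int(v)
            if v not in used:
                used.add(v)
                out.append(v)
                if len(out) == n:
                    break
    return out


def _snv_alleles(genome_base: str, channel: str) -> tuple[str, str]:
    """Reference-strand ref/alt for a channel placed at a site whose collapsed
    context matches; the site may carry the purine on the reference strand."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    pyr_ref, pyr_alt = channel[2], channel[4]
    if genome_base == pyr_ref:
        return genome_base, pyr_alt
    if genome_base == comp[pyr_ref]:
        return genome_base, comp[pyr_alt]
    raise GenerationError(
        f"genome base {genome_base} incompatible with channel {channel}"
    )


def plant_somatic_mutations(genome: SyntheticGenome, config: CohortConfig) -> TruthSet:
    """Plant per-sample truth mutations into the synthetic genome."""
    rng = np.random.default_rng([config.seed, 2])
    samples = make_samples(config)
    sigs = bundled_signatures()
    for name in config.signature_mixture:
        if name not in sigs.columns:
            raise ConfigurationError(f"unknown signature {name} in mixture")

    index = _ContextIndex(genome, config.terminal_fraction)
    mix_w = np.array([config.signature_mixture.get(c, 0.0) for c in sigs.columns])
    profile = sigs.to_numpy() @ mix_w
    profile = profile + (1.0 - mix_w.sum()) / 96.0
    profile = profile / profile.sum()

    ages = np.array([s.age for s in samples], dtype=float)
    mean_age = ages.mean() if len(ages) else 0.0
    age_span = max(ages.max() - ages.min(), 1.0) if len(ages) else 1.0
    factors = 1.0 + config.age_slope * (ages - mean_age) / age_span

    # driver assignment: fixed counts, mutually exclusive by subtype
    n_acp_drv = int(round(config.driver_fraction_acp * config.n_acp))
    n_pcp_drv = int(round(config.driver_fraction_pcp * config.n_pcp))
    acp_ids = [s.sample_id for s in samples if s.subtype == "ACP"]
    pcp_ids = [s.sample_id for s in samples if s.subtype == "PCP"]
    acp_drv = set(rng.choice(acp_ids, n_acp_drv, replace=False)) if n_acp_drv else set()
    pcp_drv = set(rng.choice(pcp_ids, n_pcp_drv, replace=False)) if n_pcp_drv else set()
    composite_sample = sorted(acp_drv)[0] if acp_drv else None

    model = genome.gene_model
    variants: list[TruthVariant] = []
    clusters: list[PlantedCluster] = []

    def seq_of(chrom):
        return genome.chromosomes[chrom]

    def snv_truth(sid, chrom, pos, channel=None, kataegis=False,
                  driver="none", alt=None):
        seq = seq_of(chrom)
        base = seq[pos - 1]
        if channel is not None:
            ref, a = _snv_alleles(base, channel)
        else:
            ref = base
            a = alt
            channel = collapse_to_context96(ref, a, seq[pos - 2], seq[pos])
        return TruthVariant(sid, chrom, pos, ref, a, "SNV", channel,
                            kataegis=kataegis, driver=driver)

    for si, meta in enumerate(samples):
        sid = meta.sample_id
        used: set = set()  # encoded (chrom_idx, pos) to keep positions unique

        def enc(chrom, pos):
            return index.chrom_names.index(chrom) * (1 << 40) + pos

        # --- drivers -----------------------------------------------------
        if sid in acp_drv:
            tx = model.get("CTNB1L-001")
            if sid == composite_sample:
                codon, within, alt_tx = _ACP_COMPOSITE_SNV
                pos = tx.cds_to_genomic((codon - 1) * 3 + within)
                variants.append(snv_truth(sid, tx.chromosome, pos,
                                          alt=alt_tx if tx.strand == "+" else
                                          {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_tx],
                                          driver=DRIVER_ACP))
                used.add(enc(tx.chromosome, pos))
                c1, c2 = _ACP_COMPOSITE_DEL
                gstart = tx.cds_to_genomic((c1 - 1) * 3)
                gend = tx.cds_to_genomic(c2 * 3 - 1)
                lo, hi = min(gstart, gend), max(gstart, gend)
                seq = seq_of(tx.chromosome)
                anchor = lo - 1
                ref = seq[anchor - 1 : hi]
                variants.append(TruthVariant(sid, tx.chromosome, anchor, ref,
                                             ref[0], "DEL", None,
                                             driver=DRIVER_ACP))
                used.add(enc(tx.chromosome, anchor))
            else:
                codon, within, alt_tx = _ACP_HOTSPOTS[
                    int(rng.integers(0, len(_ACP_HOTSPOTS)))
                ]
                pos = tx.cds_to_genomic((codon - 1) * 3 + within)
                alt = alt_tx if tx.strand == "+" else \
                    {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_tx]
                variants.append(snv_truth(sid, tx.chromosome, pos, alt=alt,
                                          driver=DRIVER_ACP))
                used.add(enc(tx.chromosome, pos))
        if sid in pcp_drv:
            tx = model.get("BRAFL-001")
            codon, within, alt_tx = _PCP_DRIVER_SNV
            pos = tx.cds_to_genomic((codon - 1) * 3 + within)
            alt = alt_tx if tx.strand == "+" else \
                {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_tx]
            variants.append(snv_truth(sid, tx.chromosome, pos, alt=alt,
                                      driver=DRIVER_PCP))
            used.add(enc(tx.chromosome, pos))

        # --- kataegis clusters -------------------------------------------
        for spec in config.kataegis_spec:
            pool = index.positions_in(spec.chromosome, spec.start,
                                      spec.start + spec.span)
            if len(pool) < spec.n_mutations:
                raise GenerationError(
                    f"kataegis span {spec.chromosome}:{spec.start} has too few "
                    "eligible positions"
                )
            ci = index.chrom_names.index(spec.chromosome)
            local_used = {p - ci * (1 << 40) for p in used}
            chosen = sorted(
                _draw_unique(rng, pool, spec.n_mutations,
                             {p for p in local_used}, "kataegis cluster")
            )
            seq = seq_of(spec.chromosome)
            for pos in chosen:
                used.add(enc(spec.chromosome, pos))
                ref = seq[pos - 1]
                # kataegis is typically C>T/C>G at TpC; approximate by
                # mutating pyrimidine-strand C when available
                alts = [b for b in "ACGT" if b != ref]
                alt = alts[int(rng.integers(0, 3))]
                variants.append(snv_truth(sid, spec.chromosome, pos, alt=alt,
                                          kataegis=True))
            clusters.append(PlantedCluster(sid, spec.chromosome, chosen[0],
                                           chosen[-1], spec.n_mutations))

        # --- background SNVs ---------------------------------------------
        n_snv = int(rng.poisson(config.mean_snv * factors[si]))
        channel_counts = rng.multinomial(n_snv, profile)
        by_triplet: dict[str, list] = {}
        for chan, cnt in zip(CHANNELS_96, channel_counts):
            if cnt:
                by_triplet.setdefault(_channel_triplet(chan), []).append((chan, cnt))
        for triplet, chans in by_triplet.items():
            pool = index.pools[triplet]
            enc_pool = pool["chrom"].astype(np.int64) * (1 << 40) + pool["pos"]
            term_pool_idx = np.nonzero(pool["term"])[0]
            total = sum(c for _, c in chans)
            n_forced = int(rng.binomial(total, config.terminal_bias))

            def draw_from(idx_pool, n, what):
                """Uniform draws without replacement via rejection sampling."""
                if n == 0:
                    return []
                if len(idx_pool) < n:
                    raise GenerationError(
                        f"no genomic position available for {what}")
                picked: list[int] = []
                attempts = 0
                while len(picked) < n:
                    attempts += 1
                    if attempts > 200:
                        raise GenerationError(
                            f"no genomic position available for {what}")
                    cand = idx_pool[rng.integers(0, len(idx_pool),
                                                 n - len(picked) + 8)]
                    for i in cand:
                        e = int(enc_pool[i])
                        if e not in used:
                            used.add(e)
                            picked.append(int(i))
                            if len(picked) == n:
                                break
                return picked

            forced = draw_from(term_pool_idx, n_forced,
                               f"terminal channel context {triplet}")
            free = draw_from(np.arange(len(pool["pos"])), total - n_forced,
                             f"channel context {triplet}")
            chosen_idx = np.array(forced + free, dtype=np.int64)
            rng.shuffle(chosen_idx)
            k = 0
            for chan, cnt in chans:
                for i in chosen_idx[k : k + cnt]:
                    chrom = index.chrom_names[int(pool["chrom"][i])]
                    pos = int(pool["pos"][i])
                    variants.append(snv_truth(sid, chrom, pos, channel=chan))
                k += cnt

        # --- background InDels -------------------------------------------
        n_indel = int(rng.poisson(config.mean_indel))
        all_pool = index._by_chrom
        for _ in range(n_indel):
            for _try in range(50):
                j = int(rng.integers(0, len(all_pool["pos"])))
                chrom = index.chrom_names[int(all_pool["chrom"][j])]
                pos = int(all_pool["pos"][j])
                if enc(chrom, pos) in used:
                    continue
                seq = seq_of(chrom)
                if rng.random() < 0.7:  # deletion
                    dlen = int(rng.integers(1, 6))
                    chunk = seq[pos - 1 : pos + dlen]
                    if len(chunk) < dlen + 1 or any(b == "N" for b in chunk):
                        continue
                    footprint = range(pos, pos + dlen + 1)
                    if any(enc(chrom, p) in used for p in footprint):
                        continue
                    if _overlaps_mask(genome, chrom, pos, pos + dlen):
                        continue
                    variants.append(TruthVariant(sid, chrom, pos, chunk,
                                                 chunk[0], "DEL", None))
                else:  # insertion
                    ilen = int(rng.integers(1, 5))
                    ins = "".join("ACGT"[b] for b in rng.integers(0, 4, ilen))
                    base = seq[pos - 1]
                    variants.append(TruthVariant(sid, chrom, pos, base,
                                                 base + ins, "INS", None))
                used.add(enc(chrom, pos))
                break

    # truth region/effect via the annotator
    from .annotation import GenomeAnnotator

    annotator = GenomeAnnotator(model, genome.chromosomes)
    for v in variants:
        ann = annotator.annotate(v)
        v.region_class = ann.region_class
        v.effect_class = ann.effect_class

    variants.sort(key=lambda v: (v.sample_id, v.chromosome, v.position, v.alt_allele))
    return TruthSet(samples=samples, variants=variants, clusters=clusters)


def _overlaps_mask(genome: SyntheticGenome, chrom: str, start1: int, end1: int) -> bool:
    """1-based closed interval vs 0-based half-open mask intervals."""
    for s, e in genome.low_complexity_mask.get(chrom, []):
        if start1 <= e and s + 1 <= end1:
            return True
    return False


# ---------------------------------------------------------------------------
# Caller emulation


@dataclass
class CohortFiles:
    """Paths produced by the emulator."""

    tumor_vcfs: dict  # sample_id -> {caller -> path}
    normal_vcfs: dict  # sample_id -> path
    artifact_sites: list  # [(chrom, pos, ref, alt)]


def _true_evidence(rng, variant_type: str) -> dict:
    """Evidence for a genuine somatic call: drawn conditional on passing QC.

    The generator models well-covered clonal variants; marginal-evidence
    sites are represented by the injected false positives instead.
    """
    ndp = 15 + int(rng.poisson(14))
    tdp = (11 if variant_type != "SNV" else 9) + int(rng.poisson(18))
    vaf0 = float(rng.uniform(0.15, 0.55))
    tad = max(1, int(round(vaf0 * tdp)))
    mbq = float(np.clip(round(rng.normal(32, 4)), 20, 40))
    info = {"NDP": ndp, "TDP": tdp, "TAD": tad,
            "VAF": round(tad / tdp, 4), "MBQ": mbq}
    if variant_type != "SNV":
        info["VP"] = round(float(rng.uniform(1e-6, 5e-4)), 6)
    return info


def _fp_evidence(rng, kind: str) -> dict:
    mbq = float(np.clip(round(rng.normal(32, 4)), 2, 40))
    if kind == "lowvaf" or kind == "artifact":
        tdp = 25 + int(rng.poisson(15))
        vaf = float(rng.uniform(0.02, 0.08))
        tad = max(1, int(vaf * tdp))
    else:  # masked-region FP: healthy evidence, removed by the mask rule
        tdp = 9 + int(rng.poisson(18))
        vaf = float(rng.uniform(0.15, 0.55))
        tad = max(1, int(round(vaf * tdp)))
    return {"NDP": 15 + int(rng.poisson(14)), "TDP": tdp, "TAD": tad,
            "VAF": round(tad / tdp, 4), "MBQ": mbq}


def emulate_caller_outputs(truth: TruthSet, genome: SyntheticGenome,
                           config: CohortConfig, outdir) -> CohortFiles:
    """Write per-caller tumor VCFs and normal-panel VCFs for the cohort."""
    rng = np.random.default_rng([config.seed, 3])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = {n: len(s) for n, s in genome.chromosomes.items()}
    chrom_names = list(genome.chromosomes)

    # shared artifact background sites
    non_gap = sum(
        length - sum(e - s for s, e in genome.gap_intervals[name])
        for name, length in contigs.items()
    )
    n_art = int(round(config.artifact_site_rate * non_gap))
    truth_positions = {(v.chromosome, v.position) for v in truth.variants}
    artifact_sites = []
    index_pools = _ContextIndex(genome, config.terminal_fraction)._by_chrom
    while len(artifact_sites) < n_art:
        j = int(rng.integers(0, len(index_pools["pos"])))
        chrom = chrom_names[int(index_pools["chrom"][j])]
        pos = int(index_pools["pos"][j])
        if (chrom, pos) in truth_positions:
            continue
        ref = genome.chromosomes[chrom][pos - 1]
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
        artifact_sites.append((chrom, pos, ref, alt))
    artifact_sites.sort()

    # masked-region FP position pool
    masked_positions = []
    for name, ivs in genome.low_complexity_mask.items():
        seq = genome.chromosomes[name]
        for s, e in ivs:
            for p in range(s + 1, e + 1):
                if seq[p - 1] != "N":
                    masked_positions.append((name, p))

    sample_ids = [s.sample_id for s in truth.samples]
    by_sample = truth.by_sample()
    tumor_vcfs: dict = {}
    normal_vcfs: dict = {}

    # each artifact site recurs in >= 2 normals
    n_normals = len(sample_ids)
    site_normals: dict[int, list] = {}
    for i in range(len(artifact_sites)):
        k = int(rng.integers(2, max(3, n_normals // 3 + 1)))
        site_normals[i] = list(rng.choice(n_normals, min(k, n_normals),
                                          replace=False))

    for si, sid in enumerate(sample_ids):
        tvars = by_sample[sid]
        evidence = {v.key: _true_evidence(rng, v.variant_type) for v in tvars}
        caller_records: dict[str, list] = {CALLER_A: [], CALLER_B: [], CALLER_C: []}
        for v in tvars:
            info = evidence[v.key]
            emit_to = [CALLER_A, CALLER_B] if v.variant_type == "SNV" \
                else [CALLER_B, CALLER_C]
            for caller in emit_to:
                if rng.random() < config.caller_error[caller].fn_rate:
                    continue
                rec_info = dict(info)
                if caller != CALLER_C:
                    rec_info.pop("VP", None)
                caller_records[caller].append(
                    CallRecord(v.chromosome, v.position, v.ref_allele,
                               v.alt_allele, passed=True, info=rec_info)
                )
        # false positives
        n_snv_true = sum(1 for v in tvars if v.variant_type == "SNV")
        n_indel_true = len(tvars) - n_snv_true
        for caller in (CALLER_A, CALLER_B, CALLER_C):
            err = config.caller_error[caller]
            n_true = {CALLER_A: n_snv_true, CALLER_B: len(tvars),
                      CALLER_C: n_indel_true}[caller]
            n_fp = int(rng.poisson(err.fp_rate * max(n_true, 1))) if err.fp_rate else 0
            for _ in range(n_fp):
                kinds = ["mask", "lowvaf"]
                if caller != CALLER_C and artifact_sites:
                    kinds.append("artifact")
                kind = kinds[int(rng.integers(0, len(kinds)))]
                if kind == "artifact":
                    chrom, pos, ref, alt = artifact_sites[
                        int(rng.integers(0, len(artifact_sites)))
                    ]
                elif kind == "mask" and masked_positions:
                    chrom, pos = masked_positions[
                        int(rng.integers(0, len(masked_positions)))
                    ]
                    ref = genome.chromosomes[chrom][pos - 1]
                    alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                else:
                    j = int(rng.integers(0, len(index_pools["pos"])))
                    chrom = chrom_names[int(index_pools["chrom"][j])]
                    pos = int(index_pools["pos"][j])
                    ref = genome.chromosomes[chrom][pos - 1]
                    alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                info = _fp_evidence(rng, kind)
                if caller == CALLER_C:
                    # emulated as a 1-bp deletion call at the site
                    seq = genome.chromosomes[chrom]
                    if pos >= len(seq):
                        continue
                    ref = seq[pos - 1 : pos + 1]
                    alt = ref[0]
                    info["VP"] = round(float(rng.uniform(0, 0.05)), 6)
                passed = True
                if caller == CALLER_A and kind != "mask":
                    passed = bool(rng.random() < 0.5)
                caller_records[caller].append(
                    CallRecord(chrom, pos, ref, alt, passed=passed, info=info)
                )
        # dedupe per caller on key (FPs may collide with truth records)
        tumor_vcfs[sid] = {}
        for caller, recs in caller_records.items():
            seen, uniq = set(), []
            for r in recs:
                if r.key not in seen:
                    seen.add(r.key)
                    uniq.append(r)
            path = outdir / f"{sid}.{caller}.vcf"
            write_vcf(path, uniq, contigs)
            tumor_vcfs[sid][caller] = path
        # normal VCF: this normal's share of the artifact background
        normal_records = []
        for i, (chrom, pos, ref, alt) in enumerate(artifact_sites):
            if si in site_normals[i]:
                normal_records.append(
                    CallRecord(chrom, pos, ref, alt, passed=True,
                               info=_fp_evidence(rng, "artifact"))
                )
        npath = outdir / f"{sid}.normal.vcf"
        write_vcf(npath, normal_records, contigs)
        normal_vcfs[sid] = npath

    return CohortFiles(tumor_vcfs=tumor_vcfs, normal_vcfs=normal_vcfs,
                       artifact_sites=artifact_sites)


# ---------------------------------------------------------------------------
# Convenience: write all cohort inputs to a directory


def write_cohort_inputs(config: CohortConfig, outdir) -> dict:
    """Generate the full synthetic cohort and write every input file.

    Returns a dict of paths plus the in-memory genome/truth objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_reference(config)
    truth = plant_somatic_mutations(genome, config)
    files = emulate_caller_outputs(truth, genome, config, outdir / "calls")
    write_fasta(genome, outdir / "reference.fa")
    write_bed(genome.gap_intervals, outdir / "gaps.bed", name="gap")
    write_bed(genome.low_complexity_mask, outdir / "low_complexity.bed",
              name="low_complexity")
    write_gff3(genome.gene_model, outdir / "genes.gff3")
    write_sample_metadata(truth.samples, outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")
    config.to_yaml(outdir / "config.yaml")
    return {
        "genome": genome,
        "truth": truth,
        "files": files,
        "fasta": outdir / "reference.fa",
        "gaps_bed": outdir / "gaps.bed",
        "mask_bed": outdir / "low_complexity.bed",
        "gff3": outdir / "genes.gff3",
        "metadata": outdir / "samples.tsv",
    }
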