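"""Rainfall distances, kataegis detection, chromosome-terminal enrichment.

Rainfall points record each mutation's genomic distance to the previous
mutation on the same chromosome (SNVs and InDels together). Kataegis is
operationally defined as a run of at least ``min_n`` consecutive mutations
whose mean inter-mutation distance is at most ``max_mean_imd`` (defaults 6
and 1 kb, the common working definition); overlapping qualifying runs are
merged into maximal events.

The terminal-enrichment test asks whether mutations concentrate in the
outermost fraction of each chromosome's non-gap span (both ends), which in
a telomere-gapped reference is the region adjacent to the telomeres. The
null distribution is built by placing the same number of mutations
uniformly over the non-gap genome; the permutation p-value uses the
add-one estimator (1 + #{perm >= obs}) / (n_perm + 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import SyntheticGenome
from .spectrum import six_class


@dataclass
class RainfallPoint:
    chromosome: str
    position: int
    distance_to_previous: int | None  # None for the first point per chromosome
    label: str  # six-class label for SNVs, "indel" otherwise


@dataclass
class KataegisEvent:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    n_mutations: int
    mean_imd: float


@dataclass
class TerminalEnrichmentResult:
    observed_fraction: float
    expected_fraction: float
    permutation_p: float
    n_permutations: int
    n_mutations: int
    terminal_fraction: float
    window_definition: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def intermutation_distances(variants) -> list[RainfallPoint]:
    """Per-chromosome distances to the previous mutation; input order free.

    Mutations at the same position (different alleles) are kept with
    distance 0.
    """
    items = sorted(variants, key=lambda v: (v.chromosome, v.position))
    out = []
    prev_chrom, prev_pos = None, None
    for v in items:
        if len(v.ref_allele) == 1 and len(v.alt_allele) == 1:
            label = six_class(v.ref_allele, v.alt_allele)
        else:
            label = "indel"
        dist = None if v.chromosome != prev_chrom else v.position - prev_pos
        out.append(RainfallPoint(v.chromosome, v.position, dist, label))
        prev_chrom, prev_pos = v.chromosome, v.position
    return out


def rainfall_table(points: list[RainfallPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.chromosome, p.position,
          "" if p.distance_to_previous is None else p.distance_to_previous,
          p.label) for p in points],
        columns=["chromosome", "position", "imd", "class"],
    )


def detect_kataegis(points, min_n: int = 6,
                    max_mean_imd: float = 1000.0) -> list[KataegisEvent]:
    """Find maximal clustered-mutation events.

    ``points`` may be RainfallPoints or any objects with chromosome and
    position. A window of consecutive mutations [i..j] qualifies when it
    has >= min_n members and (pos_j - pos_i) / (j - i) <= max_mean_imd;
    qualifying windows sharing mutations are merged.
    """
    by_chrom: dict[str, list[int]] = {}
    for p in points:
        by_chrom.setdefault(p.chromosome, []).append(p.position)
    events = []
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        n = len(pos)
        qualifying = []  # index intervals [i, j]
        for i in range(n - min_n + 1):
            limit = max_mean_imd * (n - 1 - i)
            best_j = None
            for j in range(i + min_n - 1, n):
                span = pos[j] - pos[i]
                if span > limit:
                    break
                if span <= max_mean_imd * (j - i):
                    best_j = j
            if best_j is not None:
                qualifying.append((i, best_j))
        # merge overlapping index intervals into maximal events
        qualifying.sort()
        merged = []
        for i, j in qualifying:
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            events.append(
                KataegisEvent(
                    chromosome=chrom,
                    start=pos[i],
                    end=pos[j],
                    n_mutations=j - i + 1,
                    mean_imd=(pos[j] - pos[i]) / (j - i),
                )
            )
    return events


def kataegis_table(events: list[KataegisEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.chromosome, e.start, e.end, e.n_mutations, e.mean_imd)
         for e in events],
        columns=["chromosome", "start", "end", "n_mutations", "mean_imd"],
    )


def write_kataegis_bed(events: list[KataegisEvent], path) -> None:
    """0-based half-open BED of events."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{e.chromosome}\t{e.start - 1}\t{e.end}\t"
                     f"kataegis_n{e.n_mutations}\n")


# ---------------------------------------------------------------------------
# Terminal enrichment


def _non_gap_segments(genome: SyntheticGenome, chrom: str) -> list[tuple[int, int]]:
    """0-based half-open complement of the gap intervals."""
    length = genome.chromosome_length(chrom)
    gaps = sorted(genome.gap_intervals.get(chrom, []))
    segments, cursor = [], 0
    for s, e in gaps:
        if s > cursor:
            segments.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        segments.append((cursor, length))
    return segments


def terminal_enrichment(variants, genome: SyntheticGenome,
                        terminal_fraction: float = 0.05,
                        n_perm: int = 1000, seed: int = 0
                        ) -> TerminalEnrichmentResult:
    """Permutation test for mutation enrichment in chromosome-terminal windows.

    Observed: fraction of mutations inside the outermost
    ``terminal_fraction`` of each chromosome's non-gap span (both ends).
    Null: the same number of positions placed uniformly over the non-gap
    genome, ``n_perm`` times.
    """
    windows = genome.terminal_windows(terminal_fraction)  # validates fraction
    rng = np.random.default_rng(seed)

    # universe of non-gap positions, concatenated across chromosomes
    terminal_flags = []
    chrom_of_segment = []
    for chrom in genome.chromosomes:
        segs = _non_gap_segments(genome, chrom)
        wins = windows[chrom]
        for s, e in segs:
            flags = np.zeros(e - s, dtype=bool)
            for ws, we in wins:
                lo, hi = max(s, ws), min(e, we)
                if hi > lo:
                    flags[lo - s : hi - s] = True
            terminal_flags.append(flags)
            chrom_of_segment.append(chrom)
    universe = np.concatenate(terminal_flags)
    u_size = len(universe)
    expected = float(universe.sum() / u_size)

    variants = list(variants)
    n_mut = len(variants)
    observed = 0
    for v in variants:
        p0 = v.position - 1
        for ws, we in windows[v.chromosome]:
            if ws <= p0 < we:
                observed += 1
                break
    observed_fraction = observed / n_mut if n_mut else 0.0

    if n_mut == 0:
        perm_ge = n_perm
    else:
        draws = rng.integers(0, u_size, size=(n_perm, n_mut))
        perm_counts = universe[draws].sum(axis=1)
        perm_ge = int(np.sum(perm_counts >= observed))
    p = (1 + perm_ge) / (n_perm + 1)
    return TerminalEnrichmentResult(
        observed_fraction=observed_fraction,
        expected_fraction=expected,
        permutation_p=p,
        n_permutations=n_perm,
        n_mutations=n_mut,
        terminal_fraction=terminal_fraction,
        window_definition=(
            f"outermost {terminal_fraction:.0%} of each chromosome's non-gap "
            "span, both ends"
        ),
    )
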