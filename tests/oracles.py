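"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by the most literal method
available (enumeration, full-protein translation, dense grid search) and
never calls the implementation path it checks.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Filtering: literal rule-by-rule re-implementation


def filter_oracle_retained(call, panel_sites, mask_intervals, thresholds) -> bool:
    """Apply each published rule to one merged call, literally."""
    t = thresholds
    if call.vaf < t.min_vaf:
        return False
    if call.mean_base_quality < t.min_bq:
        return False
    if call.variant_type == "SNV":
        if not (call.normal_depth > t.min_normal_depth):
            return False
        if not (call.tumor_depth > t.min_tumor_depth):
            return False
        if not ("A_mutect2like" in call.callers and call.passed_primary):
            return False
    else:
        if not (call.tumor_depth > t.min_indel_depth):
            return False
        if "C_varscan2like" in call.callers and call.indel_pvalue is not None:
            if call.indel_pvalue > t.max_indel_p:
                return False
        if not ("B_strelka2like" in call.callers
                and "C_varscan2like" in call.callers):
            return False
    if (call.chromosome, call.position, call.alt_allele) in panel_sites:
        return False
    ref_span = max(len(call.ref_allele), 1)
    for s, e in mask_intervals.get(call.chromosome, []):
        if call.position - 1 < e and s < call.position - 1 + ref_span:
            return False
    return True


# ---------------------------------------------------------------------------
# Kataegis: exhaustive window scan


def kataegis_oracle(positions_by_chrom, min_n=6, max_mean_imd=1000.0):
    """Enumerate every qualifying window, merge the overlapping ones."""
    events = []
    for chrom in sorted(positions_by_chrom):
        pos = sorted(positions_by_chrom[chrom])
        n = len(pos)
        windows = []
        for i in range(n):
            for j in range(i + min_n - 1, n):
                if (pos[j] - pos[i]) / (j - i) <= max_mean_imd:
                    windows.append((i, j))
        windows.sort()
        merged = []
        for i, j in windows:
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            events.append((chrom, pos[i], pos[j], j - i + 1))
    return events


# ---------------------------------------------------------------------------
# Signature refitting: dense grid search (coarse-to-fine, 0.001 resolution)


def grid_search_exposures(spectrum, sigs, names, step=0.001, coarse=0.02):
    """Global SSE optimum over the K<=3 simplex {w >= 0, sum w <= 1}.

    Full grid at ``coarse``, then a local full grid at ``step`` around the
    coarse optimum.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    cols = [np.asarray(sigs[n], dtype=float) for n in names]

    def scan(lo, hi, s):
        axes = [np.arange(max(0.0, l), min(1.0, h) + s / 2, s)
                for l, h in zip(lo, hi)]
        best = (np.inf, None)
        if len(cols) == 1:
            for w0 in axes[0]:
                r = spectrum - w0 * cols[0]
                sse = float(r @ r)
                if sse < best[0]:
                    best = (sse, (w0,))
            return best
        if len(cols) == 2:
            for w0 in axes[0]:
                w1 = axes[1][axes[1] <= 1 - w0 + 1e-12]
                if len(w1) == 0:
                    continue
                R = spectrum[None, :] - w0 * cols[0][None, :] \
                    - w1[:, None] * cols[1][None, :]
                sse = (R * R).sum(axis=1)
                k = int(sse.argmin())
                if sse[k] < best[0]:
                    best = (float(sse[k]), (w0, float(w1[k])))
            return best
        for w0 in axes[0]:
            for w1 in axes[1]:
                if w0 + w1 > 1 + 1e-12:
                    continue
                w2 = axes[2][axes[2] <= 1 - w0 - w1 + 1e-12]
                if len(w2) == 0:
                    continue
                R = spectrum[None, :] - (w0 * cols[0] + w1 * cols[1])[None, :] \
                    - w2[:, None] * cols[2][None, :]
                sse = (R * R).sum(axis=1)
                k = int(sse.argmin())
                if sse[k] < best[0]:
                    best = (float(sse[k]), (w0, w1, float(w2[k])))
        return best

    k = len(cols)
    sse_c, w_c = scan([0.0] * k, [1.0] * k, coarse)
    lo = [w - coarse for w in w_c]
    hi = [w + coarse for w in w_c]
    return scan(lo, hi, step)


# ---------------------------------------------------------------------------
# Pearson correlation from closed forms


def pearson_oracle(x, y):
    """r from the sum formulas; two-sided p from the t transform."""
    from scipy.special import stdtr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stdtr(n - 2, -abs(t))
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Full-protein translation diff for effect classification

_CODON_TABLE = {}


def _codon_table():
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(seq: str) -> str:
    table = _codon_table()
    return "".join(table[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


def effect_oracle(cds_seq: str, offset: int, alt_tx: str):
    """(effect, protein_change) by translating the whole mutated protein."""
    mutated = cds_seq[:offset] + alt_tx + cds_seq[offset + 1 :]
    p0, p1 = translate(cds_seq), translate(mutated)
    diffs = [i for i, (a, b) in enumerate(zip(p0, p1)) if a != b]
    if not diffs:
        aa = p0[offset // 3]
        return "silent", f"p.{aa}{offset // 3 + 1}{aa}"
    i = diffs[0]
    ref_aa, alt_aa = p0[i], p1[i]
    if alt_aa == "*":
        return "nonsense", f"p.{ref_aa}{i + 1}X"
    return "missense", f"p.{ref_aa}{i + 1}{alt_aa}"
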