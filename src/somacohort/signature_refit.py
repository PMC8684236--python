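"""Non-negative refitting of reference signatures to observed 96-spectra.

The fit expresses an observed 96-channel mutation frequency vector as a
non-negative weighted sum of fixed reference signature columns, with the
weight sum bounded by 1. The solver is greedy forward selection with a
one-dimensional golden-section line search: at each round, every allowed
signature's weight is individually re-optimised (others held fixed) and
the single move giving the largest squared-error improvement is applied;
iteration stops when the best improvement falls below ``tol``. When the
weight-sum constraint is active, mass-transfer moves between signature
pairs are also searched, since single-weight moves cannot travel along the
simplex face. Weights below ``cutoff`` are then zeroed and the search is
re-run restricted to the surviving signatures. Because the objective is a
convex quadratic over a box-plus-simplex feasible set, this coordinate
search converges to the constrained global optimum up to the stopping
tolerance.

Exposures are reported un-normalised by default (their sum may be < 1,
the remainder being unexplained spectrum); ``renormalize=True`` rescales
the surviving weights to sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrum import SpectrumVector


class LowMutationCountError(ValueError):
    """Sample has too few mutations for a stable spectrum fit."""


class InputError(ValueError):
    pass


@dataclass
class ExposureVector:
    weights: dict  # signature name -> weight
    residual_sse: float

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))

    def as_array(self, names) -> np.ndarray:
        return np.array([self.weights.get(n, 0.0) for n in names])


def normalize_spectrum(counts96, min_mutations: int = 50) -> np.ndarray:
    """Counts -> frequency vector summing to 1; refuse low-count samples."""
    counts = np.asarray(counts96, dtype=float)
    if counts.shape != (96,):
        raise InputError("expected a 96-channel count vector")
    if (counts < 0).any() or not np.isfinite(counts).all():
        raise InputError("counts must be finite and non-negative")
    total = counts.sum()
    if total < min_mutations:
        raise LowMutationCountError(
            f"{int(total)} mutations < required minimum {min_mutations}"
        )
    return counts / total


_INVPHI = (math.sqrt(5) - 1) / 2  # 1/phi


def _golden_section(f, lo: float, hi: float, tol: float = 1e-4) -> float:
    """Minimise a unimodal f on [lo, hi] to within tol."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2


def reconstruct_and_score(sigs: pd.DataFrame, exposures: ExposureVector | dict,
                          spectrum) -> tuple[np.ndarray, float]:
    """Weighted signature sum and its squared error against the spectrum."""
    weights = exposures.weights if isinstance(exposures, ExposureVector) else exposures
    spectrum = np.asarray(spectrum, dtype=float)
    recon = np.zeros(sigs.shape[0])
    for name, w in weights.items():
        recon = recon + w * sigs[name].to_numpy()
    sse = float(np.sum((spectrum - recon) ** 2))
    return recon, sse


def refit_exposures(spectrum, sigs: pd.DataFrame, allowed=None,
                    cutoff: float = 0.06, tol: float = 1e-5,
                    search_tol: float = 1e-4,
                    renormalize: bool = False) -> ExposureVector:
    """Fit non-negative signature exposures to a 96-channel frequency vector.

    ``tol`` is the convergence threshold on the per-round decrease of the
    reconstruction error (root of the SSE); ``cutoff`` zeroes trace
    exposures after convergence; ``search_tol`` is the golden-section
    bracket width on each single weight.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if not np.isfinite(spectrum).all():
        raise InputError("spectrum contains non-finite entries")
    if allowed is None:
        allowed = list(sigs.columns)
    allowed = list(allowed)
    if not allowed:
        raise InputError("allowed signature set is empty")
    unknown = [a for a in allowed if a not in sigs.columns]
    if unknown:
        raise InputError(f"unknown signatures in allowed set: {unknown}")
    if not 0 <= cutoff < 1:
        raise InputError("cutoff must be in [0, 1)")

    cols = {name: sigs[name].to_numpy(dtype=float) for name in allowed}

    def solve(active: list) -> dict:
        # Gauss-Southwell coordinate search on a convex quadratic: each
        # round re-optimises the single most-improving weight within the
        # room left by the sum <= 1 constraint. Improvement is measured on
        # the root-SSE (Frobenius) scale, the scale refitting error is
        # conventionally reported on; an absolute SSE threshold would stop
        # the search long before the zigzag into an interior optimum ends.
        weights = {name: 0.0 for name in active}
        recon = np.zeros_like(spectrum)
        sse = float(np.sum(spectrum**2))
        for _ in range(10_000):
            best = None  # (new_sse, {name: new_weight})
            total = sum(weights.values())
            for name in active:
                col = cols[name]
                base = recon - weights[name] * col
                hi = 1.0 - (total - weights[name])
                if hi <= 0:
                    continue

                def f(w, col=col, base=base):
                    return float(np.sum((spectrum - base - w * col) ** 2))

                w = _golden_section(f, 0.0, hi, tol=search_tol)
                cand = f(w)
                if best is None or cand < best[0]:
                    best = (cand, {name: w})
            if 1.0 - total < 0.02 and len(active) > 1:
                # the sum <= 1 constraint is (nearly) active: single-weight
                # moves are blocked along the simplex face, so also consider
                # transferring mass between two signatures
                for src in active:
                    if weights[src] <= 0:
                        continue
                    for dst in active:
                        if dst == src:
                            continue
                        diff = cols[dst] - cols[src]

                        def g(t, diff=diff):
                            return float(np.sum((spectrum - recon - t * diff) ** 2))

                        t = _golden_section(g, 0.0, weights[src], tol=search_tol)
                        cand = g(t)
                        if best is None or cand < best[0]:
                            best = (cand, {src: weights[src] - t,
                                           dst: weights[dst] + t})
            if best is None or math.sqrt(sse) - math.sqrt(best[0]) <= tol \
                    or sse - best[0] <= 0:
                break
            sse = best[0]
            for name, w in best[1].items():
                recon = recon + (w - weights[name]) * cols[name]
                weights[name] = w
        return weights

    weights = solve(allowed)
    survivors = [n for n, w in weights.items() if w >= cutoff]
    if survivors and len(survivors) < len([n for n, w in weights.items() if w > 0]):
        weights = solve(survivors)
        weights = {n: (w if n in survivors else 0.0) for n, w in weights.items()}
    final = {n: weights.get(n, 0.0) for n in allowed}
    final = {n: (w if w >= cutoff else 0.0) for n, w in final.items()}
    total = sum(final.values())
    if total > 1.0:  # numerical guard; the search keeps the sum <= 1
        final = {n: w / total for n, w in final.items()}
    if renormalize and total > 0:
        final = {n: w / total for n, w in final.items()}
    _, sse = reconstruct_and_score(sigs, final, spectrum)
    return ExposureVector(weights=final, residual_sse=sse)


def cohort_contributions(spectra: list[SpectrumVector], sigs: pd.DataFrame,
                         allowed=None, min_mutations: int = 50,
                         cutoff: float = 0.06, tol: float = 1e-5,
                         renormalize: bool = False) -> pd.DataFrame:
    """Per-sample exposure table for a cohort.

    ``allowed`` may be one list applied to all samples, or a mapping of
    sample id -> list (e.g. different restricted sets for adult-like and
    pediatric-like samples). Low-count samples are flagged and skipped.
    """
    rows = []
    for sv in spectra:
        sample_allowed = allowed.get(sv.sample_id) if isinstance(allowed, dict) \
            else allowed
        row = {"sample_id": sv.sample_id, "n_mutations": sv.total,
               "low_count": False, "residual_sse": np.nan}
        for name in sigs.columns:
            row[name] = np.nan
        try:
            freq = normalize_spectrum(sv.counts96, min_mutations=min_mutations)
        except LowMutationCountError:
            row["low_count"] = True
            rows.append(row)
            continue
        fit = refit_exposures(freq, sigs, allowed=sample_allowed, cutoff=cutoff,
                              tol=tol, renormalize=renormalize)
        for name in sigs.columns:
            row[name] = fit.weights.get(name, 0.0)
        row["residual_sse"] = fit.residual_sse
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("sample_id")
    return df


def contribution_summary(table: pd.DataFrame, sigs: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of each signature's contribution over fitted samples."""
    rows = []
    for name in sigs.columns:
        if name not in table.columns:
            continue
        vals = table[name].dropna()
        if len(vals) == 0:
            rows.append((name, np.nan, np.nan, np.nan, 0))
            continue
        rows.append((name, vals.mean(), vals.min(), vals.max(), int(len(vals))))
    return pd.DataFrame(rows, columns=["signature", "mean", "min", "max", "n"]
                        ).set_index("signature")
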