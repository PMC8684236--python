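"""Bundled synthetic reference signatures.

The refitting machinery takes any user-supplied signature matrix (96 rows x
K columns, column-normalised). For tests and synthetic cohorts the package
bundles five synthetic signatures, built deterministically in code rather
than shipped as data. They are loosely modelled on processes relevant to a
low-burden benign tumor genome, with well-separated profiles so that
mixture recovery is identifiable:

S1  CpG-deamination-like: concentrated on N[C>T]G, peak A[C>T]G.
S2  flat clock-like background spread over C>T and T>C (the dominant
    process in the emulated cohort).
S3  T>C-heavy with peak A[T>C]A.
S4  C>A-heavy (oxidative-damage-like).
S5  T>G-heavy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectrum import CHANNELS_96, CHANNEL_INDEX

SIGNATURE_NAMES = ("S1", "S2", "S3", "S4", "S5")

# Fixed seed for the small Dirichlet jitter that keeps profiles generic;
# part of the package definition, not a tunable.
_SIG_SEED = 902_611


def _peaked(rng, group: str, peaks: dict[str, float], spread: float) -> np.ndarray:
    """Profile with named channel peaks plus jittered mass over one group."""
    v = np.zeros(96)
    for channel, w in peaks.items():
        v[CHANNEL_INDEX[channel]] = w
    idx = [i for i, c in enumerate(CHANNELS_96) if f"[{group}]" in c]
    v[idx] += spread * rng.dirichlet(np.full(len(idx), 5.0))
    return v / v.sum()


def bundled_signatures() -> pd.DataFrame:
    """Return the bundled 96 x 5 signature matrix (columns sum to 1)."""
    rng = np.random.default_rng(_SIG_SEED)
    s1 = _peaked(
        rng,
        "C>T",
        {"A[C>T]G": 0.28, "G[C>T]G": 0.22, "C[C>T]G": 0.14, "T[C>T]G": 0.11},
        spread=0.25,
    )
    # S2: broad, split across C>T and T>C with mild jitter.
    v = np.zeros(96)
    ct = [i for i, c in enumerate(CHANNELS_96) if "[C>T]" in c]
    tc = [i for i, c in enumerate(CHANNELS_96) if "[T>C]" in c]
    ta = [i for i, c in enumerate(CHANNELS_96) if "[T>A]" in c]
    v[ct] = 0.40 * rng.dirichlet(np.full(16, 20.0))
    v[tc] = 0.45 * rng.dirichlet(np.full(16, 20.0))
    v[ta] = 0.15 * rng.dirichlet(np.full(16, 20.0))
    s2 = v / v.sum()
    s3 = _peaked(rng, "T>C", {"A[T>C]A": 0.30, "A[T>C]G": 0.18, "T[T>C]A": 0.12}, 0.40)
    s4 = _peaked(rng, "C>A", {"C[C>A]A": 0.18, "T[C>A]T": 0.15, "A[C>A]A": 0.12}, 0.55)
    s5 = _peaked(rng, "T>G", {"T[T>G]T": 0.25, "G[T>G]T": 0.15, "C[T>G]C": 0.12}, 0.48)
    mat = pd.DataFrame(
        np.column_stack([s1, s2, s3, s4, s5]),
        index=list(CHANNELS_96),
        columns=list(SIGNATURE_NAMES),
    )
    return mat


def write_signature_tsv(path, matrix: pd.DataFrame | None = None) -> None:
    """Serialize a signature matrix (rows = channels, header = names)."""
    if matrix is None:
        matrix = bundled_signatures()
    matrix.to_csv(path, sep="\t", index_label="channel")


def read_signature_tsv(path) -> pd.DataFrame:
    """Load a signature matrix TSV and validate channels/column sums."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if list(mat.index) != list(CHANNELS_96):
        raise ValueError(
            "signature matrix rows must be the 96 canonical channels in order"
        )
    sums = mat.to_numpy().sum(axis=0)
    if (mat.to_numpy() < 0).any() or not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must be non-negative and sum to 1")
    return mat
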