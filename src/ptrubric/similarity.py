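"""Pairwise Spearman similarity between PT probability columns.

The similarity metric is the Spearman rank correlation ρ between the
per-article probability columns of two PTs: articles are ranked within each
column (average ranks on ties) and the Pearson correlation of the ranks is
taken. Because it is rank-based, the metric is invariant to any strictly
increasing transform of either column, so it measures how consistently two
PTs order the literature rather than how their raw scores are calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .vocab_io import MatrixValueError, ProbabilityMatrix, PTVocabulary, SimilarityMatrix

__all__ = [
    "SimilarityMatrix",
    "MatrixSummary",
    "ConstantColumnError",
    "compute_similarity",
    "enumerate_pairs",
    "summarize",
]

#: Default histogram binning for the pooled pairwise-correlation distribution:
#: 40 equal-width bins on [-1, 1], enough to resolve the two modes without
#: over-binning 2556 values.
DEFAULT_BINS = 40

#: Decimal places used when rounding summary statistics for reporting.
SUMMARY_DECIMALS = 3


class ConstantColumnError(MatrixValueError):
    """A PT column has zero rank variance, so Spearman ρ is undefined."""


@dataclass(frozen=True)
class MatrixSummary:
    """Summary of the strict upper triangle of a similarity matrix."""

    min_offdiag: float
    max_offdiag: float
    mean_offdiag: float
    n_pairs: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    def rounded(self) -> dict:
        return {
            "min": round(self.min_offdiag, SUMMARY_DECIMALS),
            "max": round(self.max_offdiag, SUMMARY_DECIMALS),
            "mean": round(self.mean_offdiag, SUMMARY_DECIMALS),
            "n_pairs": self.n_pairs,
        }


def compute_similarity(P: ProbabilityMatrix, allow_nan: bool = False) -> SimilarityMatrix:
    """Spearman ρ between every pair of PT probability columns.

    Requires at least 3 articles and 2 PT columns. A constant column makes ρ
    undefined; by default this raises :class:`ConstantColumnError` naming the
    offending PTs (pass ``allow_nan=True`` to propagate NaN instead, which
    will fail SimilarityMatrix validation unless handled by the caller).
    """
    arr = P.values.to_numpy(dtype=float)
    n, p = arr.shape
    if n < 3:
        raise ValueError(f"need at least 3 articles, got {n}")
    if p < 2:
        raise ValueError(f"need at least 2 PT columns, got {p}")
    constant = [P.vocab.terms[j] for j in range(p) if np.ptp(arr[:, j]) == 0.0]
    if constant and not allow_nan:
        raise ConstantColumnError(
            f"constant probability column(s), Spearman undefined: {constant}"
        )
    rho = stats.spearmanr(arr, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if p == 2:  # spearmanr returns a scalar for two columns
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    df = pd.DataFrame(rho, index=P.values.columns, columns=P.values.columns)
    return SimilarityMatrix(df, P.vocab)


def enumerate_pairs(vocab: PTVocabulary) -> list[tuple[str, str]]:
    """All n(n−1)/2 unordered PT pairs, each once, in lexicographic order."""
    if len(vocab) < 2:
        raise ValueError(f"need at least 2 terms to form pairs, got {len(vocab)}")
    return list(combinations(sorted(vocab.terms), 2))


def summarize(S: SimilarityMatrix, bins: int | np.ndarray = DEFAULT_BINS) -> MatrixSummary:
    """Min/max/mean and histogram over the strict upper triangle of ``S``.

    Each unordered pair is counted exactly once; the diagonal never enters.
    ``bins`` may be a count (equal-width bins on [-1, 1]) or explicit edges.
    """
    n = len(S)
    if n < 2:
        raise ValueError("summary undefined for a 1×1 matrix (no pairs)")
    iu = np.triu_indices(n, k=1)
    vals = S.rho[iu]
    if isinstance(bins, (int, np.integer)):
        edges = np.linspace(-1.0, 1.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(vals, bins=edges)
    return MatrixSummary(
        min_offdiag=float(vals.min()),
        max_offdiag=float(vals.max()),
        mean_offdiag=float(vals.mean()),
        n_pairs=int(vals.size),
        bin_edges=edges,
        bin_counts=counts,
    )
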