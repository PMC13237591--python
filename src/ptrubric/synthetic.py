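"""Synthetic probability matrices with planted rank-correlation structure.

The generator stands in for the transformer model's per-article PT
probabilities, so that every pipeline stage — similarity, clustering,
stability, thresholding — can be exercised against a known ground truth.

Articles are drawn from a Gaussian copula: a latent multivariate normal
with a *pre-warped* correlation matrix, pushed coordinate-wise through a
logistic squashing shifted to each PT's base rate. Because the squashing is
strictly monotone, the Spearman structure of the output is exactly the
copula's. The pre-warp inverts the classical Gaussian-vs-Spearman relation
ρ_S = (6/π)·arcsin(r/2), i.e. the latent Pearson target is r = 2·sin(π·ρ_S/6),
so the *Spearman* targets in the config are what the sample converges to —
the pipeline's metric is rank-based, so that is the scale that matters.

The planted structure is block-diagonal: high Spearman correlation within
named blocks, a configurable (default zero) background across blocks, and
optional negatively correlated block pairs (emulating functionally
unrelated PT pairs such as clinical studies vs. biographies). A target that
is not positive semidefinite is refused with the offending eigenvalue —
silent repair would change the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .vocab_io import (
    ProbabilityMatrix,
    PTVocabulary,
    SimilarityMatrix,
    load_default_rubric_table,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "NotPSDError",
    "generate",
    "fig2_like_scenario",
    "block_correlation_matrix",
    "synthetic_reference_matrix",
]

#: Eigenvalues below this are a genuine PSD violation, not round-off.
PSD_TOL = 1e-8


class NotPSDError(ValueError):
    """The implied correlation target is not positive semidefinite."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted block-correlation design for the generator.

    ``blocks`` lists (block name, member PT names, within-block Spearman
    target in [0, 1)); ``negative_pairs`` lists (block, block, Spearman
    target in (−1, 0]) overriding the cross-block background for those two
    blocks. ``base_rate`` is the approximate mean probability level (scalar
    or per-PT mapping); it shifts marginals without touching ranks.
    """

    n_articles: int
    blocks: tuple[tuple[str, tuple[str, ...], float], ...]
    cross_block_correlation: float = 0.0
    negative_pairs: tuple[tuple[str, str, float], ...] = ()
    base_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, members, within in self.blocks:
            if not 0.0 <= within < 1.0:
                raise ValueError(f"within-block target for {name!r} outside [0, 1): {within}")
        for a, b, r in self.negative_pairs:
            if not -1.0 < r <= 0.0:
                raise ValueError(f"negative target for ({a!r}, {b!r}) outside (-1, 0]: {r}")
        all_members = [m for _, members, _ in self.blocks for m in members]
        if len(set(all_members)) != len(all_members):
            raise ValueError("blocks are not a partition: a PT appears twice")

    @property
    def vocab(self) -> PTVocabulary:
        return PTVocabulary(tuple(m for _, members, _ in self.blocks for m in members))

    @property
    def membership(self) -> dict[str, str]:
        return {m: name for name, members, _ in self.blocks for m in members}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated matrix: block memberships and targets."""

    membership: dict[str, str]
    target: pd.DataFrame  # Spearman-scale target correlation matrix
    seed: int


def _target_matrix(cfg: SyntheticConfig) -> pd.DataFrame:
    terms = cfg.vocab.terms
    n = len(terms)
    block_of = cfg.membership
    neg = {frozenset((a, b)): r for a, b, r in cfg.negative_pairs}
    within = {name: w for name, _, w in cfg.blocks}
    T = np.full((n, n), cfg.cross_block_correlation)
    for i, ti in enumerate(terms):
        for j, tj in enumerate(terms):
            bi, bj = block_of[ti], block_of[tj]
            if i == j:
                T[i, j] = 1.0
            elif bi == bj:
                T[i, j] = within[bi]
            elif frozenset((bi, bj)) in neg:
                T[i, j] = neg[frozenset((bi, bj))]
    return pd.DataFrame(T, index=terms, columns=terms)


def _spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    np.fill_diagonal(r, 1.0)
    return r


def generate(cfg: SyntheticConfig) -> tuple[ProbabilityMatrix, SyntheticTruth]:
    """Draw a seeded article × PT probability matrix with the planted structure.

    Raises :class:`NotPSDError` (naming the offending eigenvalue) before any
    sampling if the pre-warped target is not a valid correlation matrix.
    Generated values lie strictly inside (0, 1).
    """
    target = _target_matrix(cfg)
    latent = _spearman_to_pearson(target.to_numpy())
    w, V = np.linalg.eigh(latent)
    if w.min() < -PSD_TOL:
        raise NotPSDError(
            f"implied correlation target is not PSD (smallest eigenvalue {w.min():.3e})"
        )
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(cfg.seed)
    Z = rng.standard_normal((cfg.n_articles, len(target))) @ L.T
    if isinstance(cfg.base_rate, dict):
        offsets = np.array([logit(cfg.base_rate[t]) for t in target.columns])
    else:
        offsets = np.full(len(target), logit(cfg.base_rate))
    probs = expit(Z + offsets)
    ids = [f"A{i + 1:06d}" for i in range(cfg.n_articles)]
    P = ProbabilityMatrix(pd.DataFrame(probs, index=ids, columns=target.columns))
    return P, SyntheticTruth(cfg.membership, target, cfg.seed)


def fig2_like_scenario(seed: int, n_articles: int = 5000) -> SyntheticConfig:
    """Canned design emulating the pooled-correlation regime of the real PTs.

    72 PTs in the 13 rubric blocks, within-block Spearman target 0.6 (a
    stand-in for the positive mode of the real pooled distribution, whose
    location the source data only fix loosely), near-zero background across
    blocks, and two negatively correlated category pairs standing in for
    functionally unrelated PTs (general clinical studies vs. biographical
    works, trial methodology vs. commentary). The pooled off-diagonal
    correlation histogram of the generated data is bimodal: one mode near 0,
    one near the within-block target.
    """
    rubric = load_default_rubric_table()
    blocks = tuple(
        (cat, tuple(sub["publication_type"]), 0.6)
        for cat, sub in rubric.groupby("low_level_category", sort=False)
    )
    return SyntheticConfig(
        n_articles=n_articles,
        blocks=blocks,
        cross_block_correlation=0.0,
        negative_pairs=(
            (
                "General Clinical & Observational Studies",
                "Biographical, Historical & Narrative Works",
                -0.45,
            ),
            (
                "Controlled & Randomized Trial Methodology",
                "Scientific Commentary & Professional Discourse",
                -0.3,
            ),
        ),
        base_rate=0.15,
        seed=seed,
    )


def block_correlation_matrix(
    blocks: tuple[tuple[str, tuple[str, ...], float], ...],
    cross: float = 0.0,
    negative_pairs: tuple[tuple[str, str, float], ...] = (),
) -> SimilarityMatrix:
    """The exact (noise-free) block correlation matrix as a SimilarityMatrix.

    Useful for protocols that operate on the matrix itself rather than on
    sampled articles (e.g. the perturbation stability runs).
    """
    cfg = SyntheticConfig(
        n_articles=1, blocks=blocks, cross_block_correlation=cross, negative_pairs=negative_pairs
    )
    return SimilarityMatrix(_target_matrix(cfg))


def synthetic_reference_matrix(
    seed: int, n_articles: int = 5000
) -> tuple[SimilarityMatrix, SyntheticTruth]:
    """SYNTHETIC stand-in for the published 72×72 PT Spearman matrix.

    The real reference matrix is distributed as supplementary material to
    the source study and is not bundled here; this stand-in is generated
    from :func:`fig2_like_scenario` and reproduces the structural features
    the pipeline relies on (72 labels, 2556 pairs, block structure matching
    the rubric, bimodal pooled correlations, Case Reports/Case Series as
    mutual nearest neighbours) — not the real data's exact values.
    """
    from .similarity import compute_similarity

    P, truth = generate(fig2_like_scenario(seed, n_articles))
    return compute_similarity(P), truth
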