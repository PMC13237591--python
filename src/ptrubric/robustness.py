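"""Perturbation and order-shuffle protocol for clustering stability.

The protocol asks whether the structure extracted from the similarity matrix
— above all, each PT's nearest neighbour — survives small multiplicative
noise on the correlations and reordering of the PT list. For a relative
magnitude x, every off-diagonal correlation is independently multiplied by a
factor drawn uniformly from {1−x, 1, 1+x} (so a zero correlation stays
zero), mirrored to keep the matrix symmetric, and clamped to [−1, 1]. The
x grid runs from 1% to 2.5% in 0.1% increments by default. Each of the
``n_reps`` perturbation repetitions is crossed with each of the
``n_shuffles`` label-order shuffles, giving n_reps × n_shuffles combined
runs per x value (2000 × 100 = 200 000 under the defaults); the x-grid loop
sits outside that product. Nearest neighbours (and, optionally, flat
cluster memberships) are extracted in the shuffled order and compared back
in the original label space.

All randomness flows from one master seed through per-(x, repetition,
shuffle) substreams, so the report is bit-reproducible and individual runs
are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import all_nearest_neighbours, cluster_labels
from .vocab_io import PTVocabulary, SimilarityMatrix

__all__ = [
    "PerturbationConfig",
    "StabilityReport",
    "perturb",
    "run_stability",
    "shuffle_invariance_check",
    "ShuffleInvarianceResult",
]


def default_x_grid() -> tuple[float, ...]:
    """Relative perturbation magnitudes 0.010 … 0.025 in steps of 0.001."""
    return tuple(np.round(np.arange(10, 26) * 0.001, 3))


@dataclass(frozen=True)
class PerturbationConfig:
    """Protocol parameters; ``seed`` fully determines all draws."""

    x_grid: tuple[float, ...] = field(default_factory=default_x_grid)
    n_reps: int = 2000
    n_shuffles: int = 100
    seed: int = 0
    cluster_k: int | None = None  # also track flat-cluster membership at this cut

    def __post_init__(self) -> None:
        if any(not (0.0 < x < 1.0) for x in self.x_grid):
            raise ValueError("all perturbation magnitudes must lie in (0, 1)")
        if self.n_reps < 1 or self.n_shuffles < 1:
            raise ValueError("n_reps and n_shuffles must be >= 1")

    @property
    def runs_per_x(self) -> int:
        return self.n_reps * self.n_shuffles

    @property
    def total_runs(self) -> int:
        return len(self.x_grid) * self.runs_per_x


@dataclass
class StabilityReport:
    """Per-(x, PT) nearest-neighbour retention under the protocol."""

    retention: pd.DataFrame  # long format: x, publication_type, nn_retention
    membership_retention: pd.DataFrame | None
    runs_per_x: int
    executed_runs: int
    baseline_nn: dict[str, str]

    def min_retention_per_x(self) -> pd.Series:
        return self.retention.groupby("x")["nn_retention"].min()

    def min_retention(self) -> float:
        return float(self.retention["nn_retention"].min())


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def perturb(S: SimilarityMatrix, x: float, rng: np.random.Generator) -> SimilarityMatrix:
    """Multiply each off-diagonal entry by a factor uniform on {1−x, 1, 1+x}.

    The draw is made once per unordered pair and mirrored, the diagonal is
    untouched, and results are clamped to [−1, 1].
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"perturbation magnitude {x} outside (0, 1)")
    rho = S.rho.copy()
    n = rho.shape[0]
    iu = np.triu_indices(n, k=1)
    factors = 1.0 + (rng.integers(0, 3, size=iu[0].size) - 1) * x
    vals = np.clip(rho[iu] * factors, -1.0, 1.0)
    rho[iu] = vals
    rho[(iu[1], iu[0])] = vals
    df = pd.DataFrame(rho, index=S.values.index, columns=S.values.columns)
    return SimilarityMatrix(df, S.vocab)


def _permute(S: SimilarityMatrix, perm: np.ndarray) -> SimilarityMatrix:
    names = [S.vocab.terms[i] for i in perm]
    df = S.values.iloc[perm, perm]
    df.index = names
    df.columns = names
    return SimilarityMatrix(df.copy(), PTVocabulary(tuple(names)))


def _partition_sets(labels: np.ndarray, names: tuple[str, ...]) -> dict[str, frozenset]:
    clusters: dict[int, set] = {}
    for name, lab in zip(names, labels):
        clusters.setdefault(int(lab), set()).add(name)
    frozen = {lab: frozenset(members) for lab, members in clusters.items()}
    return {name: frozen[int(lab)] for name, lab in zip(names, labels)}


def run_stability(S: SimilarityMatrix, cfg: PerturbationConfig) -> StabilityReport:
    """Execute the full perturbation × shuffle protocol on ``S``.

    For every x in the grid, every perturbation repetition is crossed with
    every label-order shuffle; nearest neighbours are extracted from the
    shuffled, perturbed matrix and compared against the unperturbed ones in
    the original label space. Retention for (x, PT) is the fraction of the
    runs in which the neighbour is unchanged.
    """
    names = S.vocab.terms
    n = len(names)
    baseline_nn = all_nearest_neighbours(S)
    baseline_membership = (
        _partition_sets(cluster_labels(S, cfg.cluster_k), names)
        if cfg.cluster_k is not None
        else None
    )
    nn_rows, mem_rows = [], []
    executed = 0
    for xi, x in enumerate(cfg.x_grid):
        nn_hits = dict.fromkeys(names, 0)
        mem_hits = dict.fromkeys(names, 0)
        for rep in range(cfg.n_reps):
            P = perturb(S, x, _substream(cfg.seed, 0, xi, rep))
            for sh in range(cfg.n_shuffles):
                perm = _substream(cfg.seed, 1, xi, rep, sh).permutation(n)
                Pp = _permute(P, perm)
                nn = all_nearest_neighbours(Pp)
                for pt in names:
                    if nn[pt] == baseline_nn[pt]:
                        nn_hits[pt] += 1
                if baseline_membership is not None:
                    membership = _partition_sets(
                        cluster_labels(Pp, cfg.cluster_k), Pp.vocab.terms
                    )
                    for pt in names:
                        if membership[pt] == baseline_membership[pt]:
                            mem_hits[pt] += 1
                executed += 1
        denom = cfg.runs_per_x
        nn_rows += [
            {"x": x, "publication_type": pt, "nn_retention": nn_hits[pt] / denom}
            for pt in names
        ]
        if baseline_membership is not None:
            mem_rows += [
                {"x": x, "publication_type": pt, "membership_retention": mem_hits[pt] / denom}
                for pt in names
            ]
    return StabilityReport(
        retention=pd.DataFrame(nn_rows),
        membership_retention=pd.DataFrame(mem_rows) if mem_rows else None,
        runs_per_x=cfg.runs_per_x,
        executed_runs=executed,
        baseline_nn=baseline_nn,
    )


@dataclass
class ShuffleInvarianceResult:
    passed: bool
    n_shuffles: int
    discordant: list[np.ndarray]  # permutations whose partition differed


def shuffle_invariance_check(
    S: SimilarityMatrix, k: int, n_shuffles: int, rng: np.random.Generator
) -> ShuffleInvarianceResult:
    """Cluster under random label orders and compare partitions in original space.

    Passes iff every shuffled run reproduces the baseline partition exactly.
    Exact criterion ties can legitimately fail this; the discordant
    permutations are returned for inspection.
    """
    names = S.vocab.terms
    baseline = _partition_sets(cluster_labels(S, k), names)
    discordant = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(names))
        Pp = _permute(S, perm)
        part = _partition_sets(cluster_labels(Pp, k), Pp.vocab.terms)
        if part != baseline:
            discordant.append(perm)
    return ShuffleInvarianceResult(
        passed=not discordant, n_shuffles=n_shuffles, discordant=discordant
    )
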