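"""From probability scores to hierarchy-consistent binary PT tags.

Three steps, always in this order:

1. per-PT thresholds chosen on a validation set to maximize F1;
2. thresholding — a PT is tagged iff its score strictly exceeds the
   threshold;
3. post-prediction normalization — each article additionally receives every
   pt-term ancestor of its tags, regardless of those ancestors' own scores.

Thresholds are fit on raw scores only; normalization never feeds back into
threshold selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import Hierarchy
from .vocab_io import MatrixValueError, ProbabilityMatrix, PTVocabulary, _validate_alignment

__all__ = [
    "LabelTable",
    "PredictionThresholds",
    "TagSet",
    "select_threshold",
    "select_thresholds",
    "apply_thresholds",
    "normalize_predictions",
    "save_thresholds",
    "load_thresholds",
]


@dataclass
class LabelTable:
    """Article × PT binary ground-truth labels (same layout as ProbabilityMatrix)."""

    values: pd.DataFrame
    vocab: PTVocabulary = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vocab = _validate_alignment(self.values, self.vocab)
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise MatrixValueError(
                f"label {arr[bad[0], bad[1]]!r} not in {{0, 1}} at article "
                f"{self.values.index[bad[0]]!r}, PT {self.values.columns[bad[1]]!r}"
            )
        self.values = self.values.astype(int)


@dataclass
class PredictionThresholds:
    """Per-PT decision thresholds with a provenance note (which validation set)."""

    thresholds: dict[str, float]
    provenance: str = ""

    def for_vocab(self, vocab: PTVocabulary) -> np.ndarray:
        missing = [t for t in vocab.terms if t not in self.thresholds]
        if missing:
            raise KeyError(f"missing threshold for PT(s): {missing}")
        return np.array([self.thresholds[t] for t in vocab.terms])


#: per-article tag assignment: article id → set of PT names
TagSet = dict[str, set]


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(scores, labels) -> float:
    """Threshold maximizing F1 for one PT (tag iff score > threshold).

    Candidates are the midpoints between adjacent distinct sorted scores
    plus sentinels below the minimum and above the maximum, which covers
    every achievable confusion table. F1 ties resolve to the largest
    qualifying threshold (favouring precision).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive labels: F1 undefined at every threshold")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([uniq[0] - 0.5], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 0.5])
    )
    best_t, best_f1 = None, -1.0
    for t in candidates:
        pred = scores > t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = n_pos - tp
        f1 = _f1(tp, fp, fn)
        if f1 > best_f1 or (f1 == best_f1 and t > best_t):
            best_t, best_f1 = float(t), f1
    return best_t


def select_thresholds(
    P: ProbabilityMatrix, labels: LabelTable, provenance: str = ""
) -> PredictionThresholds:
    """F1-optimal threshold for every PT column of a validation set."""
    if P.vocab.terms != labels.vocab.terms:
        raise ValueError("probability and label tables cover different vocabularies")
    th = {
        pt: select_threshold(P.values[pt].to_numpy(), labels.values[pt].to_numpy())
        for pt in P.vocab.terms
    }
    return PredictionThresholds(th, provenance)


def apply_thresholds(P: ProbabilityMatrix, th: PredictionThresholds) -> TagSet:
    """Tag each article with every PT whose score strictly exceeds its threshold."""
    tvec = th.for_vocab(P.vocab)
    arr = P.values.to_numpy(dtype=float)
    names = np.asarray(P.vocab.terms)
    out: TagSet = {}
    for i, aid in enumerate(P.article_ids):
        out[aid] = set(names[arr[i] > tvec])
    return out


def normalize_predictions(tags: TagSet, h: Hierarchy) -> TagSet:
    """Ancestor-close every article's tag set via the unified hierarchy.

    Never removes a tag; idempotent. Tags absent from the hierarchy raise a
    KeyError listing the offenders.
    """
    pts = h.pt_terms()
    offenders = sorted({t for ts in tags.values() for t in ts} - pts)
    if offenders:
        raise KeyError(f"tags are not pt-terms of the hierarchy: {offenders}")
    return {aid: h.normalize_tags(ts) for aid, ts in tags.items()}


def save_thresholds(th: PredictionThresholds, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"provenance": th.provenance, "thresholds": th.thresholds}, indent=1)
    )


def load_thresholds(path: str | Path) -> PredictionThresholds:
    raw = json.loads(Path(path).read_text())
    return PredictionThresholds(dict(raw["thresholds"]), raw.get("provenance", ""))
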