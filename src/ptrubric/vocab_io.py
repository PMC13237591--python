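"""Vocabulary, matrix containers, readers/writers, run configuration and logging.

Everything downstream operates on three containers defined here:

``PTVocabulary``
    The ordered roster of publication-type / study-design terms (PTs).
    Order is significant: it is the axis order of every matrix, and the
    order-shuffling robustness protocol permutes exactly this order.

``ProbabilityMatrix``
    One row per article, one column per PT, values in [0, 1] — the
    per-article probabilities emitted by a multi-label PT tagger.

``SimilarityMatrix``
    Square, symmetric matrix of pairwise Spearman correlations between PT
    probability columns, with unit diagonal.

Matrices are serialized as delimited text (comma by default, tab accepted)
with a header row of PT names and a leading label column, values written
with 6 significant digits.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PTVocabulary",
    "ProbabilityMatrix",
    "SimilarityMatrix",
    "RunConfig",
    "read_probability_matrix",
    "write_probability_matrix",
    "read_correlation_matrix",
    "write_correlation_matrix",
    "load_default_vocabulary",
    "load_default_rubric_table",
    "default_hierarchy_path",
    "file_digest",
    "get_logger",
]

#: Absolute asymmetry tolerated in a correlation table before it is an error
#: (anything below is treated as serialization round-off and symmetrized away).
ASYMMETRY_TOL = 1e-8

#: Significant digits used when writing matrices to delimited text.
WRITE_PRECISION = 6

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def get_logger(name: str = "ptrubric", logfile: str | Path | None = None) -> logging.Logger:
    """Package logger; optionally teed to ``logfile`` inside a run directory."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(fh)
    return logger


class PTVocabularyError(ValueError):
    """Invalid vocabulary (duplicates, empty names)."""


class MatrixFormatError(ValueError):
    """Malformed delimited matrix file."""


class MatrixValueError(ValueError):
    """Well-formed file with out-of-contract values."""


@dataclass(frozen=True)
class PTVocabulary:
    """Ordered, duplicate-free roster of PT names."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if any(not t for t in self.terms):
            raise PTVocabularyError("vocabulary contains an empty PT name")
        if len(set(self.terms)) != len(self.terms):
            dupes = sorted({t for t in self.terms if list(self.terms).count(t) > 1})
            raise PTVocabularyError(f"duplicate PT names: {dupes}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)

    def __contains__(self, term: object) -> bool:
        return term in self.terms

    def index(self, term: str) -> int:
        return self.terms.index(term)


def _validate_alignment(values: pd.DataFrame, vocab: PTVocabulary | None) -> PTVocabulary:
    cols = PTVocabulary(tuple(str(c) for c in values.columns))
    if vocab is not None and tuple(vocab.terms) != cols.terms:
        raise PTVocabularyError(
            "column labels do not match the vocabulary "
            f"(first mismatch at position "
            f"{next(i for i, (a, b) in enumerate(zip(vocab.terms, cols.terms)) if a != b) if len(vocab) == len(cols) else 'length'})"
        )
    return cols


@dataclass
class ProbabilityMatrix:
    """Article × PT probability table.

    ``values`` is a pandas DataFrame indexed by opaque article ids with one
    column per PT, every entry in the closed interval [0, 1] and no missing
    values. Column order is preserved through all operations.
    """

    values: pd.DataFrame
    vocab: PTVocabulary = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vocab = _validate_alignment(self.values, self.vocab)
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise MatrixValueError(
                f"missing value at article {self.values.index[i]!r}, PT {self.values.columns[j]!r}"
            )
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValueError(
                f"probability {arr[i, j]!r} outside [0, 1] at article "
                f"{self.values.index[i]!r}, PT {self.values.columns[j]!r}"
            )

    @property
    def article_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.values.index)

    @property
    def n_articles(self) -> int:
        return len(self.values)


@dataclass
class SimilarityMatrix:
    """Symmetric PT × PT Spearman correlation matrix with unit diagonal."""

    values: pd.DataFrame
    vocab: PTVocabulary = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vocab = _validate_alignment(self.values, self.vocab)
        if tuple(str(i) for i in self.values.index) != self.vocab.terms:
            raise MatrixFormatError("row labels differ from column labels")
        arr = self.values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise MatrixFormatError(f"matrix is {arr.shape[0]}×{arr.shape[1]}, not square")
        if np.isnan(arr).any():
            raise MatrixValueError("correlation matrix contains missing values")
        if (np.abs(arr) > 1 + 1e-9).any():
            i, j = np.argwhere(np.abs(arr) > 1 + 1e-9)[0]
            raise MatrixValueError(
                f"correlation {arr[i, j]!r} outside [-1, 1] at "
                f"({self.values.index[i]!r}, {self.values.columns[j]!r})"
            )
        asym = np.abs(arr - arr.T).max() if arr.size else 0.0
        if asym > ASYMMETRY_TOL:
            raise MatrixValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL}")
        # symmetrize round-off and pin the diagonal
        arr = np.clip((arr + arr.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(arr, 1.0)
        self.values = pd.DataFrame(arr, index=self.values.index, columns=self.values.columns)

    @property
    def rho(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.vocab)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    The single ``seed`` determines all stochastic behaviour (simulation,
    perturbation draws, order shuffles).
    """

    out_dir: str = "ptrubric-run"
    seed: int = 0
    probs_path: str | None = None
    corr_path: str | None = None
    scenario: str | None = None
    n_articles: int = 5000
    k_low: int = 13
    k_broad: int = 5
    excluded_pts: tuple[str, ...] = ("Scientific Integrity Review",)
    # a rare PT is excluded from clustering and joins the category of a
    # designated anchor PT ("with:<PT>"), mirroring its manual placement
    # alongside the retraction/erratum terms
    manual_placements: dict = field(
        default_factory=lambda: {"Scientific Integrity Review": "with:Retraction of Publication"}
    )
    x_min: float = 0.010
    x_max: float = 0.025
    x_step: float = 0.001
    n_reps: int = 2000
    n_shuffles: int = 100
    histogram_bins: int = 40

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.excluded_pts = tuple(cfg.excluded_pts)
        return cfg

    def to_json(self, path: str | Path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["excluded_pts"] = list(self.excluded_pts)
        Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# Delimited matrix I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t", ",": ",", "\t": "\t"}.get(dialect, dialect)
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _read_table(path: str | Path, dialect: str | None) -> pd.DataFrame:
    """Read a labelled delimited table, validating row lengths with line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path, dialect)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixFormatError(f"{path}: empty file") from None
        columns = [c for c in header[1:]]
        ids, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(columns) + 1:
                raise MatrixFormatError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {len(columns) + 1}"
                )
            ids.append(row[0])
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    return pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=columns)


def read_probability_matrix(
    path: str | Path, dialect: str | None = None, vocab: PTVocabulary | None = None
) -> ProbabilityMatrix:
    """Read an article × PT probability table.

    First row is the header of PT names, first column the article id.
    Column order in the file is preserved. Raises :class:`MatrixFormatError`
    for malformed rows (naming the line) and :class:`MatrixValueError` for
    values outside [0, 1] (naming the cell).
    """
    return ProbabilityMatrix(_read_table(path, dialect), vocab)


def write_probability_matrix(P: ProbabilityMatrix, path: str | Path, dialect: str | None = None) -> None:
    delim = _sniff_delimiter(Path(path), dialect)
    P.values.to_csv(path, sep=delim, float_format=f"%.{WRITE_PRECISION}g", index_label="article_id")


def read_correlation_matrix(path: str | Path, dialect: str | None = None) -> SimilarityMatrix:
    """Read a square PT × PT correlation table.

    Row and column labels must be identical and in the same order. Asymmetry
    below :data:`ASYMMETRY_TOL` is averaged away; larger asymmetry, a
    non-square table, or |entry| > 1 are errors.
    """
    df = _read_table(path, dialect)
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(f"{path}: table is {df.shape[0]}×{df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise MatrixFormatError(f"{path}: row labels differ from column labels")
    return SimilarityMatrix(df)


def write_correlation_matrix(S: SimilarityMatrix, path: str | Path, dialect: str | None = None) -> None:
    delim = _sniff_delimiter(Path(path), dialect)
    S.values.to_csv(path, sep=delim, float_format=f"%.{WRITE_PRECISION}g", index_label="publication_type")


# ---------------------------------------------------------------------------
# Shipped fixtures (assembled from the published rubric and hierarchy tables)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("ptrubric.data").joinpath(name)


def load_default_vocabulary() -> PTVocabulary:
    """The 72-term PT vocabulary."""
    text = _data_path("vocabulary.txt").read_text()
    return PTVocabulary(tuple(line for line in text.splitlines() if line.strip()))


def load_default_rubric_table() -> pd.DataFrame:
    """The shipped rubric: PT → (low-level category, broad category, manual flag)."""
    with resources.as_file(_data_path("rubric.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["manual"] = df["manual"].astype(bool)
    return df


def default_hierarchy_path() -> Path:
    """Path to the shipped unified-hierarchy JSON."""
    with resources.as_file(_data_path("hierarchy.json")) as p:
        return Path(p)


def file_digest(path: str | Path) -> str:
    """sha256 of a file, for run manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
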