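"""Immunohistochemical (IHC) staining-pattern encoding and Hamming distances.

Each lymphoma case carries the *set* of IHC stains a pathologist applied to
reach the definitive diagnosis (not their positive/negative results).  Over a
fixed stain vocabulary of size ``L`` the set becomes a binary vector ``S``,
and dissimilarity between two cases is the Hamming distance
``d(S_m, S_n) = ||S_m - S_n||_1`` — the number of stains used for exactly one
of the two cases.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "StainVocabulary",
    "CaseRecord",
    "StainPatternEncoder",
    "normalize_stain",
    "build_vocabulary",
    "encode_pattern",
    "hamming_distance",
    "distance_matrix",
    "read_cases_csv",
    "write_cases_csv",
]


def normalize_stain(name: str) -> str:
    """Canonical token for a stain name: trimmed, case-folded.

    No synonym resolution — e.g. ``CD3`` and ``CD3epsilon`` are distinct
    antibodies and stay distinct.
    """
    return name.strip().lower()


@dataclass(frozen=True)
class StainVocabulary:
    """Ordered stain vocabulary defining the coordinates of the binary pattern.

    Order is descending usage count with alphabetical tie-break, so encodings
    are reproducible across runs.  ``len(vocab)`` is ``L``.
    """

    names: tuple[str, ...]
    usage: dict[str, int] = field(default_factory=dict)
    min_usage: int = 1

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("vocabulary names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.names)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"names": list(self.names), "usage": self.usage, "min_usage": self.min_usage},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainVocabulary":
        d = json.loads(Path(path).read_text())
        return cls(names=tuple(d["names"]), usage=d["usage"], min_usage=d["min_usage"])


@dataclass
class CaseRecord:
    """One lymphoma case: id, subtype index in ``[0, K)``, applied stains.

    ``pattern`` is filled by encoding against a vocabulary; ``slide_ref``
    optionally points at the whole-slide image (or a raster stand-in).
    """

    case_id: str
    subtype: int
    stains: frozenset[str]
    pattern: np.ndarray | None = None
    slide_ref: str | None = None


def build_vocabulary(
    cases: Sequence[CaseRecord] | Sequence[Iterable[str]], min_usage: int = 10
) -> StainVocabulary:
    """Build the stain vocabulary from case stain sets.

    Keeps exactly the stains used by at least ``min_usage`` cases; rarely used
    stains are dropped because they act as noise in the typicality geometry.

    Parameters
    ----------
    cases : list of CaseRecord or list of stain-name iterables
    min_usage : int
        Minimum number of cases a stain must appear in (default 10).
    """
    if min_usage < 1:
        raise ValueError("min_usage must be >= 1")
    if len(cases) == 0:
        raise ValueError("cannot build a vocabulary from an empty case list")
    counts: Counter[str] = Counter()
    for c in cases:
        stains = c.stains if isinstance(c, CaseRecord) else c
        toks = {normalize_stain(s) for s in stains if normalize_stain(s)}
        if not toks:
            raise ValueError("every case must have at least one stain name")
        counts.update(toks)
    kept = {s: n for s, n in counts.items() if n >= min_usage}
    if not kept:
        raise ValueError(
            f"no stain is used by at least min_usage={min_usage} cases "
            f"(max observed usage {max(counts.values())})"
        )
    # descending usage, ties alphabetical
    names = tuple(sorted(kept, key=lambda s: (-kept[s], s)))
    dropped = len(counts) - len(kept)
    logger.info(
        "vocabulary: %d stains kept (min_usage=%d), %d dropped", len(names), min_usage, dropped
    )
    return StainVocabulary(names=names, usage=kept, min_usage=min_usage)


def encode_pattern(stains: Iterable[str], vocab: StainVocabulary) -> np.ndarray:
    """Binary pattern vector of length ``L`` for a stain set.

    Stains absent from the vocabulary are ignored (logged at debug level).
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    idx = vocab.index()
    v = np.zeros(len(vocab), dtype=np.int8)
    unknown = []
    for s in stains:
        tok = normalize_stain(s)
        if tok in idx:
            v[idx[tok]] = 1
        else:
            unknown.append(tok)
    if unknown:
        logger.debug("ignored %d stain(s) outside vocabulary: %s", len(unknown), unknown)
    return v


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance ``||a - b||_1`` between two binary patterns."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"pattern length mismatch: {a.shape} vs {b.shape}")
    return int(np.sum(a != b))


def distance_matrix(patterns: np.ndarray | Sequence[CaseRecord]) -> np.ndarray:
    """N×N Hamming distance matrix ``D`` with ``D[m, n] = d(S_m, S_n)``."""
    if len(patterns) and isinstance(patterns[0], CaseRecord):
        pats = [c.pattern for c in patterns]
        if any(p is None for p in pats):
            raise ValueError("all cases must carry an encoded pattern")
        X = np.asarray(pats)
    else:
        X = np.asarray(patterns)
    X = np.atleast_2d(X).astype(np.int16)
    # |a - b|_1 for binary vectors via matrix products
    ones = X @ X.T
    w = X.sum(axis=1)
    D = w[:, None] + w[None, :] - 2 * ones
    return D.astype(np.int64)


class StainPatternEncoder(BaseEstimator, TransformerMixin):
    """Encode stain sets as binary pattern vectors over a learned vocabulary.

    Parameters
    ----------
    min_usage : int, default=10
        Stains used by fewer cases than this are dropped from the vocabulary.

    Attributes
    ----------
    vocabulary_ : StainVocabulary
        Ordered stain vocabulary (descending usage, alphabetical ties).
    n_features_out_ : int
        Vocabulary size ``L``.
    """

    def __init__(self, min_usage: int = 10):
        self.min_usage = min_usage

    def fit(self, X: Sequence[Iterable[str]], y=None) -> "StainPatternEncoder":
        self.vocabulary_ = build_vocabulary(X, min_usage=self.min_usage)
        self.n_features_out_ = len(self.vocabulary_)
        return self

    def transform(self, X: Sequence[Iterable[str]]) -> np.ndarray:
        check_is_fitted(self, "vocabulary_")
        stain_sets = [c.stains if isinstance(c, CaseRecord) else c for c in X]
        return np.array([encode_pattern(s, self.vocabulary_) for s in stain_sets])


def read_cases_csv(path: str | Path, subtype_order: Sequence[str] | None = None) -> list[CaseRecord]:
    """Read a case table CSV with columns ``case_id,subtype,stains``.

    ``stains`` is a semicolon-separated list.  Subtype labels are mapped to
    integer indices either by ``subtype_order`` or by first appearance.
    An optional ``slide`` column gives the slide image path/id.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"case_id", "subtype", "stains"}
    if not required.issubset(df.columns):
        raise ValueError(f"case CSV must have columns {sorted(required)}; got {list(df.columns)}")
    if subtype_order is None:
        subtype_order = list(dict.fromkeys(df["subtype"]))
    sub_idx = {s: i for i, s in enumerate(subtype_order)}
    cases = []
    for _, row in df.iterrows():
        stains = frozenset(
            normalize_stain(s) for s in str(row["stains"]).split(";") if normalize_stain(s)
        )
        cases.append(
            CaseRecord(
                case_id=str(row["case_id"]),
                subtype=sub_idx[row["subtype"]],
                stains=stains,
                slide_ref=row["slide"] if "slide" in df.columns else None,
            )
        )
    return cases


def write_cases_csv(
    cases: Sequence[CaseRecord], path: str | Path, subtype_names: Sequence[str] | None = None
) -> None:
    """Write cases to the ``case_id,subtype,stains[,slide]`` CSV layout."""
    rows = []
    for c in cases:
        name = subtype_names[c.subtype] if subtype_names is not None else str(c.subtype)
        rows.append(
            {
                "case_id": c.case_id,
                "subtype": name,
                "stains": ";".join(sorted(c.stains)),
                "slide": c.slide_ref or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
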