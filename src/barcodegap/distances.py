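"""Pairwise Kimura two-parameter (K2P) distances over an aligned barcode set.

The K2P model corrects the observed divergence with separate transition
(P) and transversion (Q) proportions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Only columns where both sequences carry an unambiguous base are compared
(pairwise deletion by default; complete deletion available).  Saturated
pairs, for which either logarithm argument is non-positive, are recorded
as undefined rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .seqio import AlignedSet

__all__ = [
    "SitePatternCounts",
    "DistanceMatrix",
    "count_site_patterns",
    "k2p",
    "k2p_variance",
    "distance_matrix",
]

# Base codes: A=0, C=1, G=2, T=3; anything else (gap, N, ambiguity) = 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# Pair-class codes used by the vectorized paths.
SAME, TRANSITION, TRANSVERSION, INCOMPARABLE = 0, 1, 2, 3

#: Transition partner of each base code (A<->G, C<->T).
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)


@dataclass(frozen=True)
class SitePatternCounts:
    """Comparable-site count with transition/transversion proportions."""

    n: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one comparable site")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid proportions P={self.P}, Q={self.Q}")


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence string to base codes (non-ACGT -> 255)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def encode_alignment(aligned: AlignedSet) -> np.ndarray:
    """Encode an aligned set as an (n_records, n_sites) code matrix."""
    return np.vstack([encode(r.sequence) for r in aligned])


def pair_classes(codes: np.ndarray) -> np.ndarray:
    """Per-column pair classification for every unordered pair (i<j).

    Returns an (n_pairs, n_sites) uint8 matrix over {SAME, TRANSITION,
    TRANSVERSION, INCOMPARABLE}, pairs in row-major (i, j) order.  Computed
    once, it lets bootstrap replicates re-count patterns with plain slicing.
    """
    n = codes.shape[0]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            comparable = (a != 255) & (b != 255)
            cls = np.full(codes.shape[1], INCOMPARABLE, dtype=np.uint8)
            same = comparable & (a == b)
            ts = comparable & (b == _TS_PARTNER[np.minimum(a, 3)]) & (a != b)
            cls[comparable] = TRANSVERSION
            cls[ts] = TRANSITION
            cls[same] = SAME
            rows.append(cls)
    return np.vstack(rows) if rows else np.empty((0, codes.shape[1]), np.uint8)


def count_site_patterns(a: str, b: str) -> SitePatternCounts:
    """Count comparable sites and transition/transversion proportions.

    Columns where either symbol is outside {A,C,G,T} are skipped (pairwise
    deletion).  Raises if no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    ca, cb = encode(a), encode(b)
    comparable = (ca != 255) & (cb != 255)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("zero comparable sites")
    diff = comparable & (ca != cb)
    ts = diff & (cb == _TS_PARTNER[np.minimum(ca, 3)])
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return SitePatternCounts(n=n, P=n_ts / n, Q=n_tv / n)


def k2p(counts: SitePatternCounts) -> float:
    """K2P distance in substitutions/site; NaN when the pair is saturated.

    Saturation (1 - 2P - Q <= 0 or 1 - 2Q <= 0) is an "undefined distance"
    signal recorded by the caller, not an exception.
    """
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_variance(counts: SitePatternCounts) -> float:
    """Delta-method sampling variance of the K2P distance (Kimura 1980)."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    c1 = 1.0 / w1
    c3 = 0.5 * (1.0 / w1 + 1.0 / w2)
    P, Q = counts.P, counts.Q
    return (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / counts.n


@dataclass
class DistanceMatrix:
    """Symmetric K2P distances with per-pair comparable-site counts.

    ``undefined_pairs`` lists unordered label pairs with no defined distance
    (saturation or zero comparable sites); the corresponding matrix cells
    hold NaN.
    """

    labels: List[str]
    d: np.ndarray
    n_sites: np.ndarray
    undefined_pairs: Set[FrozenSet[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def is_defined(self, a: str, b: str) -> bool:
        return frozenset((a, b)) not in self.undefined_pairs

    def defined_pairs(self):
        """Yield ((label_a, label_b), distance) over defined unordered pairs."""
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                pair = (self.labels[i], self.labels[j])
                if frozenset(pair) not in self.undefined_pairs:
                    yield pair, float(self.d[i, j])

    def drop(self, labels_to_drop) -> "DistanceMatrix":
        drop = set(labels_to_drop)
        keep = [i for i, lab in enumerate(self.labels) if lab not in drop]
        idx = np.ix_(keep, keep)
        kept_labels = [self.labels[i] for i in keep]
        kept_set = set(kept_labels)
        return DistanceMatrix(
            labels=kept_labels,
            d=self.d[idx].copy(),
            n_sites=self.n_sites[idx].copy(),
            undefined_pairs={
                p for p in self.undefined_pairs if p <= kept_set
            },
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path, decimals: int = 3) -> None:
        """Write the square labeled matrix; reported at 3 decimals by default."""
        self.to_dataframe().round(decimals).to_csv(path, sep="\t")


def _matrix_from_classes(
    classes: np.ndarray, n_taxa: int, columns: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, int]]]:
    """K2P matrix from a precomputed pair-class matrix (optionally resampled).

    Returns (d, n_sites, undefined index pairs).
    """
    sub = classes if columns is None else classes[:, columns]
    n_comp = (sub != INCOMPARABLE).sum(axis=1).astype(float)
    n_ts = (sub == TRANSITION).sum(axis=1)
    n_tv = (sub == TRANSVERSION).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_comp > 0, n_ts / n_comp, np.nan)
        Q = np.where(n_comp > 0, n_tv / n_comp, np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        dist = np.where(
            (w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(w2)), np.nan
        )
    d = np.zeros((n_taxa, n_taxa))
    ns = np.zeros((n_taxa, n_taxa), dtype=int)
    undefined: List[Tuple[int, int]] = []
    k = 0
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = dist[k]
            ns[i, j] = ns[j, i] = int(n_comp[k])
            if not np.isfinite(dist[k]):
                undefined.append((i, j))
            k += 1
    np.fill_diagonal(ns, classes.shape[1] if columns is None else len(columns))
    return d, ns, undefined


def distance_matrix(
    aligned: AlignedSet, deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an aligned set.

    deletion="pairwise" skips, per pair, columns where either member has a
    gap/ambiguity; "complete" first drops every column with any non-ACGT
    symbol.  Undefined pairs (saturated, or zero comparable sites) land in
    ``undefined_pairs`` instead of aborting the run.
    """
    if len(aligned) < 2:
        raise ValueError("need at least two records")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    codes = encode_alignment(aligned)
    if deletion == "complete":
        codes = codes[:, (codes != 255).all(axis=0)]
    labels = [r.accession for r in aligned]
    classes = pair_classes(codes)
    d, ns, undef = _matrix_from_classes(classes, len(labels))
    return DistanceMatrix(
        labels=labels,
        d=d,
        n_sites=ns,
        undefined_pairs={
            frozenset((labels[i], labels[j])) for i, j in undef
        },
    )
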