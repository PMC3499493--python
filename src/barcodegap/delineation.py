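"""Barcoding-gap species delineation and anomaly flagging.

Pairwise K2P distances are partitioned by the label metadata into
conspecific (same species), congeneric (same genus, different species)
and cross-genus pairs.  The delineation thresholds are the maximum
conspecific and minimum congeneric divergence over species whose records
cluster cohesively, and the "barcoding gap" is their fold ratio
(min congeneric / max conspecific).  Distances violating the thresholds
are flagged:

* ``conspecific_merge`` — a congeneric pair at or below the conspecific
  maximum (mislabeled database record or synonymy candidate);
* ``deep_conspecific_divergence`` — a conspecific pair above the
  conspecific maximum (independent lineage / cryptic species candidate);
* ``subthreshold_congeneric`` — a congeneric pair strictly inside the gap.

Cross-genus pairs never enter thresholds or flags; the gap statistic is
defined within genera only.

Because a deep-divergent record that still attaches next to its own
species is topologically cohesive, thresholds additionally exclude
"dispersed" records: records whose nearest conspecific distance exceeds
half the congeneric floor and would therefore cap the barcoding gap
below the method's two-fold premise.  This is the record-level
counterpart of judging cohesive clustering on a tree plot, and it keeps
a single anomalous record from inflating the conspecific maximum and
thereby hiding its own flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .distances import DistanceMatrix
from .njtree import BarcodeTree, is_cohesive
from .seqio import BarcodeRecord

__all__ = [
    "PairPartition",
    "DelineationThresholds",
    "AnomalyFlag",
    "SpeciesStatus",
    "partition_pairs",
    "dispersed_records",
    "compute_thresholds",
    "flag_anomalies",
    "delineate",
]

Pair = Tuple[str, str]


@dataclass
class PairPartition:
    """Defined distance pairs split by species/genus relationship."""

    conspecific: List[Tuple[Pair, float]] = field(default_factory=list)
    congeneric: List[Tuple[Pair, float]] = field(default_factory=list)
    other: List[Tuple[Pair, float]] = field(default_factory=list)

    def total(self) -> int:
        return len(self.conspecific) + len(self.congeneric) + len(self.other)


@dataclass(frozen=True)
class DelineationThresholds:
    """Conspecific/congeneric extremes and the fold-ratio barcoding gap."""

    max_conspecific: float
    min_congeneric: float

    @property
    def gap_fold(self) -> float:
        return self.min_congeneric / self.max_conspecific

    @property
    def gap_fold_rounded(self) -> float:
        """Fold ratio at reporting precision (two decimals)."""
        return round(self.gap_fold, 2)


@dataclass(frozen=True)
class AnomalyFlag:
    """A threshold violation attached to one record pair."""

    kind: str  # conspecific_merge | deep_conspecific_divergence | subthreshold_congeneric
    pair: Pair
    distance: float

    def implicates(self, accession: str) -> bool:
        return accession in self.pair


@dataclass
class SpeciesStatus:
    species: str
    status: str  # delineated | ambiguous
    n_records: int
    flags: List[AnomalyFlag] = field(default_factory=list)


def _as_record_map(
    records: Mapping[str, BarcodeRecord] | Sequence[BarcodeRecord],
) -> Mapping[str, BarcodeRecord]:
    if isinstance(records, Mapping):
        return records
    return {r.accession: r for r in records}


def partition_pairs(
    matrix: DistanceMatrix,
    records: Mapping[str, BarcodeRecord] | Sequence[BarcodeRecord],
) -> PairPartition:
    """Partition every defined pair by the two records' species and genus."""
    recs = _as_record_map(records)
    part = PairPartition()
    for (a, b), dist in matrix.defined_pairs():
        try:
            ra, rb = recs[a], recs[b]
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} has no species metadata")
        if ra.species == rb.species:
            part.conspecific.append(((a, b), dist))
        elif ra.genus == rb.genus:
            part.congeneric.append(((a, b), dist))
        else:
            part.other.append(((a, b), dist))
    return part


def dispersed_records(
    partition: PairPartition,
    cohesion: Mapping[str, bool],
    records: Mapping[str, BarcodeRecord] | Sequence[BarcodeRecord],
    gap_premise: float = 2.0,
) -> Set[str]:
    """Records sitting too far from every conspecific to trust in thresholds.

    The delineation method presupposes a congeneric/conspecific gap of at
    least ``gap_premise``-fold.  A record whose *nearest* conspecific
    distance exceeds (congeneric floor / gap_premise) — the floor taken
    over cohesively clustering species — would by itself cap the gap below
    that premise, so it is treated as dispersed: kept in the analysis and
    flagged, but excluded from threshold estimation.  This is the
    record-level counterpart of reading cohesive clustering off a tree.

    Singleton species have no conspecific distance and are never
    dispersed; without any congeneric pair among cohesive species the
    screen stays inactive.
    """
    recs = _as_record_map(records)
    floor = np.inf
    for (a, b), dist in partition.congeneric:
        if cohesion.get(recs[a].species, False) and cohesion.get(
            recs[b].species, False
        ):
            floor = min(floor, dist)
    if not np.isfinite(floor):
        return set()
    cutoff = floor / gap_premise
    nearest: Dict[str, float] = {}
    for (a, b), dist in partition.conspecific:
        for acc in (a, b):
            if dist < nearest.get(acc, np.inf):
                nearest[acc] = dist
    return {acc for acc, v in nearest.items() if v > cutoff}


def compute_thresholds(
    partition: PairPartition,
    cohesion: Mapping[str, bool],
    records: Mapping[str, BarcodeRecord] | Sequence[BarcodeRecord] = None,
    exclude_records: Iterable[str] = (),
) -> DelineationThresholds:
    """Max conspecific / min congeneric divergence over well-behaved pairs.

    A conspecific pair is eligible when its species clusters cohesively; a
    congeneric pair when both species do.  Pairs touching ``exclude_records``
    (typically :func:`dispersed_records`) are ineligible on either side.
    ``records`` resolves accessions to species for the cohesion lookup.
    """
    if records is None:
        raise ValueError("records are required to resolve pair species")
    recs = _as_record_map(records)
    excluded = set(exclude_records)

    def ok(acc: str) -> bool:
        return acc not in excluded and cohesion.get(recs[acc].species, False)

    consp = [d for (a, b), d in partition.conspecific if ok(a) and ok(b)]
    congen = [d for (a, b), d in partition.congeneric if ok(a) and ok(b)]
    if not consp:
        raise ValueError(
            "thresholds undefined: no eligible conspecific pairs "
            "(all species singleton, non-cohesive, or dispersed)"
        )
    if not congen:
        raise ValueError("thresholds undefined: no eligible congeneric pairs")
    return DelineationThresholds(
        max_conspecific=max(consp), min_congeneric=min(congen)
    )


def flag_anomalies(
    partition: PairPartition, thresholds: DelineationThresholds
) -> List[AnomalyFlag]:
    """Flag every pair that violates the barcoding-gap thresholds.

    Boundary convention: equality with the conspecific maximum counts as a
    merge (conservative flagging); the subthreshold band is the open
    interval between the two thresholds.
    """
    flags: List[AnomalyFlag] = []
    for pair, d in partition.congeneric:
        if d <= thresholds.max_conspecific:
            flags.append(AnomalyFlag("conspecific_merge", pair, d))
        elif d < thresholds.min_congeneric:
            flags.append(AnomalyFlag("subthreshold_congeneric", pair, d))
    for pair, d in partition.conspecific:
        if d > thresholds.max_conspecific:
            flags.append(
                AnomalyFlag("deep_conspecific_divergence", pair, d)
            )
    return flags


def delineate(
    records: Mapping[str, BarcodeRecord] | Sequence[BarcodeRecord],
    matrix: DistanceMatrix,
    tree: BarcodeTree,
    thresholds: DelineationThresholds,
    flags: Optional[List[AnomalyFlag]] = None,
    cohesion: Optional[Mapping[str, bool]] = None,
    min_support: Optional[float] = None,
) -> List[SpeciesStatus]:
    """Per-species delineation verdicts.

    A species is delineated iff its records cluster cohesively in the tree
    and none of them appears in any anomaly flag; otherwise it is ambiguous
    and carries the flags that touch it.  ``flags`` and ``cohesion`` are
    recomputed from the other inputs when not supplied.
    """
    recs = _as_record_map(records)
    species_names = sorted({r.species for r in recs.values()})
    if cohesion is None:
        cohesion = {
            sp: is_cohesive(tree, sp, recs, min_support=min_support)
            for sp in species_names
        }
    if flags is None:
        flags = flag_anomalies(partition_pairs(matrix, recs), thresholds)
    out: List[SpeciesStatus] = []
    for sp in species_names:
        accs = {a for a, r in recs.items() if r.species == sp}
        touching = [f for f in flags if any(f.implicates(a) for a in accs)]
        ok = cohesion.get(sp, False) and not touching
        out.append(
            SpeciesStatus(
                species=sp,
                status="delineated" if ok else "ambiguous",
                n_records=len(accs),
                flags=touching,
            )
        )
    return out
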