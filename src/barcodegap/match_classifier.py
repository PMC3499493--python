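"""Classification of reference-database similarity matches.

Each query species carries the best-hit species name and percent
similarity per database (GenBank BLASTN and BOLD-IDS), consumed as an
already-filled table — no live queries.  Similarity is banded as
significant (>=97%), moderate (92-96%) or insignificant (<92%); a match
is "specific" when the hit bears the query's own name.  A species has a
definitive identity when every returned match is specific and
significant (databases returning no match are ignored); otherwise it
falls into one or more ambiguity categories:

* cat1 — significant matches to both the same and a different name;
* cat2 — same-named matches both significant and insignificant;
* cat3 — same-named match in the moderate band;
* cat4 — same-named match insignificant, with none significant;
* cat5 — only non-specific hits (missing reference data for the query).

Insignificant non-specific hits are background similarity to distant
relatives and are ignored whenever any same-named match exists —
a <=91% hit to another genus does not argue against an identity.

``resolve_with_flags`` reconciles the categories with the NJ/divergence
anomaly flags: conflicting evidence that traces to a mislabeled or
deviant database record is discounted, while moderate/insignificant
same-name evidence combined with deep conspecific divergence stays
inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

__all__ = [
    "MatchRow",
    "MatchCategory",
    "band",
    "classify_species",
    "summarize",
    "resolve_with_flags",
    "read_match_table",
    "read_anomaly_table",
    "load_survey_matches",
    "load_survey_anomalies",
]

SIGNIFICANT, MODERATE, INSIGNIFICANT = "significant", "moderate", "insignificant"
DATABASES = ("genbank", "bold")
NO_MATCH = "NO_MATCH"

CATEGORIES = ("cat1", "cat2", "cat3", "cat4", "cat5")


@dataclass(frozen=True)
class MatchRow:
    """One database best-hit for one query species (or an explicit no-match)."""

    query_species: str
    database: str
    match_species: Optional[str] = None
    similarity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.database not in DATABASES:
            raise ValueError(f"unknown database {self.database!r}")
        if (self.match_species is None) != (self.similarity is None):
            raise ValueError(
                f"{self.query_species}/{self.database}: similarity must be "
                "present exactly when a match is"
            )

    @property
    def has_match(self) -> bool:
        return self.match_species is not None

    @property
    def specific(self) -> bool:
        """A match bearing the query's own species name."""
        return self.has_match and _norm(self.match_species) == _norm(
            self.query_species
        )

    @property
    def band(self) -> Optional[str]:
        return band(self.similarity) if self.has_match else None


@dataclass(frozen=True)
class MatchCategory:
    """Per-species classification outcome."""

    species: str
    definitive: bool
    categories: frozenset

    def __post_init__(self) -> None:
        if self.definitive == bool(self.categories):
            raise ValueError(
                "a species is either definitive or carries >=1 category"
            )


def _norm(name: str) -> str:
    return " ".join(name.split()).lower()


def band(similarity: float) -> str:
    """Band a percent similarity: >=97 significant, [92,97) moderate, <92 insignificant."""
    if not 0 <= similarity <= 100:
        raise ValueError(f"similarity {similarity} outside [0, 100]")
    if similarity >= 97:
        return SIGNIFICANT
    if similarity >= 92:
        return MODERATE
    return INSIGNIFICANT


def classify_species(rows: Sequence[MatchRow]) -> MatchCategory:
    """Classify one query species from all of its database rows.

    Row order never matters.  Databases reporting no match are ignored; a
    species matched by a single database alone can still be definitive.
    """
    if not rows:
        raise ValueError("no rows for species")
    species = rows[0].query_species
    if any(r.query_species != species for r in rows):
        raise ValueError("classify_species expects rows of a single species")
    matches = [r for r in rows if r.has_match]
    if not matches:
        return MatchCategory(species, False, frozenset({"cat5"}))

    any_specific = any(r.specific for r in matches)
    if any_specific:
        # insignificant hits to other names are background, not conflict
        matches = [
            r for r in matches if r.specific or r.band != INSIGNIFICANT
        ]
    if all(r.specific and r.band == SIGNIFICANT for r in matches):
        return MatchCategory(species, True, frozenset())

    sig_spec = any(r.specific and r.band == SIGNIFICANT for r in matches)
    mod_spec = any(r.specific and r.band == MODERATE for r in matches)
    ins_spec = any(r.specific and r.band == INSIGNIFICANT for r in matches)
    sig_other = any(not r.specific and r.band == SIGNIFICANT for r in matches)

    cats: Set[str] = set()
    if sig_spec and sig_other:
        cats.add("cat1")
    if sig_spec and ins_spec:
        cats.add("cat2")
    if mod_spec:
        cats.add("cat3")
    if ins_spec and not sig_spec:
        cats.add("cat4")
    if not any_specific:
        cats.add("cat5")
    if not cats:
        # e.g. significant same-name plus a moderate different-name hit:
        # the foreign evidence is sub-significant, treat as cat1-type conflict
        cats.add("cat1" if sig_spec else "cat5")
    return MatchCategory(species, False, frozenset(cats))


def summarize(rows: Sequence[MatchRow]) -> Dict[str, int]:
    """Headline counts over a whole match table.

    ``definitive + ambiguous_total`` equals the number of query species;
    ``cat5_only`` counts species whose only category is missing reference
    data, and ``straightforward`` the species resolvable without anomaly
    reconciliation (definitive plus cat5-only).
    """
    by_species: Dict[str, List[MatchRow]] = {}
    for r in rows:
        by_species.setdefault(r.query_species, []).append(r)
    if not by_species:
        raise ValueError("empty match table")
    cats = {sp: classify_species(rs) for sp, rs in by_species.items()}
    definitive = sum(c.definitive for c in cats.values())
    cat5_only = sum(c.categories == {"cat5"} for c in cats.values())
    return {
        "n_species": len(cats),
        "definitive": definitive,
        "cat5_only": cat5_only,
        "ambiguous_total": len(cats) - definitive,
        "straightforward": definitive + cat5_only,
    }


def _flag_kinds(flags: Iterable) -> Set[str]:
    return {f if isinstance(f, str) else f.kind for f in flags}


def resolve_with_flags(
    categories: Mapping[str, MatchCategory],
    flags: Mapping[str, Iterable],
) -> Dict[str, str]:
    """Final per-species identification statuses.

    ``flags`` maps species to anomaly flags (AnomalyFlag objects or kind
    strings) from the divergence analysis.  Rules, in order:

    1. moderate/insignificant same-name evidence (cat3/cat4) combined with
       deep conspecific divergence -> ``inconclusive`` (possible cryptic or
       independently evolving lineage, unresolvable from distance alone);
    2. significant-conflict evidence (cat1/cat2) whose deviant record is
       flagged (merge, or a lone deviant same-named database record at deep
       divergence) -> ``identified_mislabel_note``;
    3. unflagged definitive or missing-reference (cat5) species ->
       ``identified`` (the latter delineated by tree and gap alone);
    4. anything else -> ``inconclusive``.
    """
    out: Dict[str, str] = {}
    for sp, cat in categories.items():
        kinds = _flag_kinds(flags.get(sp, ()))
        cats = cat.categories
        if cats & {"cat3", "cat4"} and "deep_conspecific_divergence" in kinds:
            out[sp] = "inconclusive"
        elif cats & {"cat1", "cat2"} and kinds:
            out[sp] = "identified_mislabel_note"
        elif not kinds and (cat.definitive or cats == {"cat5"}):
            out[sp] = "identified"
        elif cat.definitive and kinds <= {"subthreshold_congeneric"}:
            out[sp] = "identified"
        else:
            out[sp] = "inconclusive"
    return out


def read_match_table(path) -> List[MatchRow]:
    """Read a similarity table (TSV: query_species, database, match_species,
    similarity); the literal ``NO_MATCH`` marks databases without a hit."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"query_species", "database", "match_species", "similarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"match table missing columns {sorted(missing)}")
    rows: List[MatchRow] = []
    for rec in df.itertuples(index=False):
        no_match = (
            pd.isna(rec.match_species) or rec.match_species == NO_MATCH
        )
        rows.append(
            MatchRow(
                query_species=rec.query_species,
                database=rec.database,
                match_species=None if no_match else rec.match_species,
                similarity=None if no_match else float(rec.similarity),
            )
        )
    return rows


def read_anomaly_table(path) -> Dict[str, List[str]]:
    """Read per-species anomaly flag kinds (TSV: species, kind, accession)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, List[str]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(rec.species, []).append(rec.kind)
    return out


def _data_path(name: str) -> Path:
    return Path(resources.files("barcodegap").joinpath("data", name))


def load_survey_matches() -> List[MatchRow]:
    """Bundled consensus-barcode similarity table for the 25-species
    North-East Indian catfish COI survey (GenBank BLASTN and BOLD-IDS
    best hits)."""
    return read_match_table(_data_path("catfish_coi_similarity.tsv"))


def load_survey_anomalies() -> Dict[str, List[str]]:
    """Bundled NJ/divergence anomaly flags for the catfish COI survey:
    database records that merged into another species' conspecific range
    or sat at deep conspecific divergence."""
    return read_anomaly_table(_data_path("catfish_coi_tree_anomalies.tsv"))
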