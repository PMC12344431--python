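"""Drug-interaction catalogue: loading, validation, name annotation, filtering.

The catalogue describes drugs that interact with a single anchor drug
(citalopram by default) either pharmacokinetically -- as CYP2C19 substrates,
inhibitors or inducers -- or pharmacodynamically, with a four-level clinical
severity grade taken from regulator labelling ('contraindicated',
'not_recommended', 'use_with_caution', 'to_be_considered').  Entries of the
mildest grade are retained on load but excluded from analysis by default.

Raw dispensing records carry free-text names ("Omeprazole 20mg capsules",
trade names, combination products); :func:`annotate_names` resolves them to
canonical catalogue entries by case-insensitive whole-word synonym matching.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

PK_ROLES = frozenset({"substrate", "inhibitor", "inducer"})
SEVERITIES = ("contraindicated", "not_recommended", "use_with_caution",
              "to_be_considered", "none")
ROUTES = ("systemic", "topical")
FILTER_MODES = ("default", "exclude_topical", "contraindicated_only")

DEFAULT_ANCHOR = "citalopram"


class CatalogError(ValueError):
    """Raised for an unparseable or internally inconsistent catalogue file."""


@dataclass(frozen=True)
class DrugEntry:
    """One catalogue drug: canonical name, synonyms and interaction metadata."""

    canonical_name: str
    synonyms: frozenset[str]
    pk_roles: frozenset[str] = frozenset()
    is_pd: bool = False
    severity: str = "none"
    route: str = "systemic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical_name", self.canonical_name.lower())
        object.__setattr__(
            self, "synonyms",
            frozenset(s.lower() for s in self.synonyms) | {self.canonical_name})
        object.__setattr__(self, "pk_roles", frozenset(self.pk_roles))
        if not self.pk_roles <= PK_ROLES:
            raise CatalogError(
                f"{self.canonical_name}: unknown PK role(s) {sorted(self.pk_roles - PK_ROLES)}")
        if self.severity not in SEVERITIES:
            raise CatalogError(f"{self.canonical_name}: unknown severity {self.severity!r}")
        if self.route not in ROUTES:
            raise CatalogError(f"{self.canonical_name}: unknown route {self.route!r}")
        if self.is_pd and self.severity == "none":
            raise CatalogError(
                f"{self.canonical_name}: pharmacodynamic entries need a severity grade")

    @property
    def interacting(self) -> bool:
        return bool(self.pk_roles) or self.is_pd


@dataclass
class Catalog:
    """Validated interaction catalogue keyed by canonical drug name.

    ``entries`` holds the interacting drugs only; the anchor drug is kept
    separately so its synonyms can be matched in prescription text without
    ever being reported as an interaction with itself.
    """

    entries: dict[str, DrugEntry]
    anchor: DrugEntry
    index_drug: str = DEFAULT_ANCHOR
    synonym_index: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.index_drug in self.entries:
            raise CatalogError(
                f"anchor drug {self.index_drug!r} listed as an interacting entry")
        index: dict[str, str] = {}
        for entry in [self.anchor, *self.entries.values()]:
            if not entry.interacting and entry is not self.anchor:
                raise CatalogError(
                    f"{entry.canonical_name}: neither PK role nor PD flag set")
            for syn in entry.synonyms:
                if syn in index and index[syn] != entry.canonical_name:
                    raise CatalogError(
                        f"synonym {syn!r} maps to both {index[syn]!r} "
                        f"and {entry.canonical_name!r}")
                index[syn] = entry.canonical_name
        self.synonym_index = index

    def interacting_names(self, include_to_be_considered: bool = False) -> set[str]:
        """Canonical names of interacting drugs; the mildest severity grade is
        excluded unless explicitly requested."""
        return {
            name for name, e in self.entries.items()
            if include_to_be_considered or e.severity != "to_be_considered"
        }

    def _matcher(self) -> re.Pattern[str]:
        # Whole-word match: a synonym counts only when delimited by non-letters,
        # so "amitriptyline" does not fire inside "nortriptyline".
        alts = sorted(self.synonym_index, key=len, reverse=True)
        pattern = "|".join(re.escape(a) for a in alts)
        return re.compile(rf"(?<![a-z])(?:{pattern})(?![a-z])")


def _entry_from_record(rec: Mapping) -> DrugEntry:
    try:
        return DrugEntry(
            canonical_name=rec["name"],
            synonyms=frozenset(rec.get("synonyms", [])),
            pk_roles=frozenset(rec.get("pk_roles", [])),
            is_pd=bool(rec.get("pd", False)),
            severity=rec.get("severity", "none"),
            route=rec.get("route", "systemic"),
        )
    except KeyError as exc:
        raise CatalogError(f"catalogue record missing field {exc}") from exc


def load_catalog(path: str | Path, index_drug: str = DEFAULT_ANCHOR) -> Catalog:
    """Load and validate a JSON catalogue file.

    The file is a JSON array of objects with fields ``name``, ``synonyms``,
    ``pk_roles``, ``pd``, ``severity``, ``route``.  The anchor drug may appear
    as a record (to supply its synonyms); it must not carry interaction flags.

    Raises
    ------
    CatalogError
        On parse failure, duplicate synonyms across entries, entries with
        neither a PK role nor a PD flag, or a missing/interacting anchor.
    """
    try:
        records = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CatalogError(f"cannot parse catalogue {path}: {exc}") from exc
    if not isinstance(records, list):
        raise CatalogError("catalogue file must be a JSON array of drug records")
    return build_catalog([_entry_from_record(r) for r in records], index_drug)


def build_catalog(entries: Iterable[DrugEntry], index_drug: str = DEFAULT_ANCHOR) -> Catalog:
    """Assemble a Catalog from entry objects (anchor identified by name)."""
    index_drug = index_drug.lower()
    anchor = None
    interacting: dict[str, DrugEntry] = {}
    for entry in entries:
        if entry.canonical_name == index_drug:
            if entry.interacting:
                raise CatalogError(f"anchor {index_drug!r} must not carry interaction flags")
            anchor = entry
        else:
            if entry.canonical_name in interacting:
                raise CatalogError(f"duplicate entry {entry.canonical_name!r}")
            interacting[entry.canonical_name] = entry
    if anchor is None:
        anchor = DrugEntry(canonical_name=index_drug, synonyms=frozenset({index_drug}))
    return Catalog(entries=interacting, anchor=anchor, index_drug=index_drug)


def packaged_catalog_path() -> Path:
    """Path of the miniature catalogue shipped with the package."""
    return Path(str(resources.files("rxddi").joinpath("data/ddi_catalog.json")))


def load_packaged_catalog() -> Catalog:
    return load_catalog(packaged_catalog_path())


def annotate_names(raw_names: Iterable[str], catalog: Catalog) -> dict[str, tuple[str, ...]]:
    """Resolve free-text drug names to canonical catalogue entries.

    Matching is case-insensitive and whole-word (tokens delimited by
    non-letters), so dose strings and formulation suffixes around the name are
    ignored.  Combination products matching several synonyms report every
    matched canonical entry.  Unmatched names map to an empty tuple -- they are
    reported, never silently dropped.
    """
    matcher = catalog._matcher()
    out: dict[str, tuple[str, ...]] = {}
    for raw in raw_names:
        hits = matcher.findall(raw.lower())
        canon = sorted({catalog.synonym_index[h] for h in hits})
        out[raw] = tuple(canon)
    return out


def filter_catalog(catalog: Catalog, mode: str = "default") -> Catalog:
    """Apply an analysis-mode severity/route filter; result entries are always
    a subset of the input entries.

    default
        drop the 'to_be_considered' severity grade (the study's base rule);
    exclude_topical
        additionally drop topically administered drugs;
    contraindicated_only
        keep only entries graded 'contraindicated'.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; expected one of {FILTER_MODES}")
    kept: list[DrugEntry] = []
    for entry in catalog.entries.values():
        if entry.severity == "to_be_considered":
            continue
        if mode == "exclude_topical" and entry.route == "topical":
            continue
        if mode == "contraindicated_only" and entry.severity != "contraindicated":
            continue
        kept.append(entry)
    return build_catalog([catalog.anchor, *kept], catalog.index_drug)
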