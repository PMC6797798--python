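"""Free-text medication strings -> per-subject Boolean drug-class flags.

Baseline medication records arrive as free text ("Lipitor 10mg tab",
"ATORVASTATIN Calcium").  Each string is normalized (lowercased, dosage and
form tokens stripped), resolved against an offline brand/generic dictionary
to a standardized ingredient, and the ingredient's drug-class labels are
OR-aggregated per subject into Boolean flags — the representation that
makes medication confounding easy to adjust for downstream.

The bundled dictionary is a small, versioned offline stand-in for a live
terminology service (one ships with the package; any service can populate a
:class:`DrugDictionary` through :class:`TerminologyAdapter`).  Unmatched
strings are reported, never silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Protocol

import pandas as pd

__all__ = [
    "DrugDictionary",
    "DrugClassFlags",
    "TerminologyAdapter",
    "normalize_med_name",
    "map_medications",
    "load_dictionary",
    "load_default_dictionary",
]

# tokens that carry dosage/route/form information rather than identity
_NOISE_TOKEN = re.compile(
    r"""^(
        \d+(\.\d+)?(mg|mcg|ug|µg|g|ml|iu)? |        # 10, 0.5, 10mg, 100mcg
        mg|mcg|ug|µg|g|ml|iu |
        tab(s)?|tablet(s)?|cap(s)?|capsule(s)?|pill(s)? |
        po|oral(ly)?|qd|bid|tid|qhs|prn|daily|weekly
    )$""",
    re.VERBOSE,
)
_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)


def normalize_med_name(text: str) -> str:
    """Canonicalize one free-text medication string.

    Lowercases, replaces punctuation by spaces, drops dosage/unit/form
    tokens, and collapses whitespace.  Deterministic; may return "".

    >>> normalize_med_name("Lipitor 10mg tab")
    'lipitor'
    """
    text = _PUNCT.sub(" ", str(text).lower())
    kept = [t for t in text.split() if not _NOISE_TOKEN.match(t)]
    return " ".join(kept)


@dataclass
class DrugDictionary:
    """Normalized name -> ingredient -> drug classes, with a version tag."""

    name_to_ingredient: dict[str, str]
    ingredient_classes: dict[str, set[str]]
    version: str

    def __post_init__(self) -> None:
        for name in self.name_to_ingredient:
            if name != normalize_med_name(name):
                raise ValueError(f"dictionary key {name!r} is not normalized")
        for ing, classes in self.ingredient_classes.items():
            if not classes:
                raise ValueError(f"ingredient {ing!r} has no drug class")

    @property
    def classes(self) -> list[str]:
        out: set[str] = set()
        for c in self.ingredient_classes.values():
            out |= c
        return sorted(out)

    def lookup(self, normalized: str) -> str | None:
        """Exact lookup, then longest token-boundary prefix fallback.

        The fallback resolves salt/remnant suffixes ("atorvastatin calcium"
        matches the "atorvastatin" entry).
        """
        if normalized in self.name_to_ingredient:
            return self.name_to_ingredient[normalized]
        best = None
        for key in self.name_to_ingredient:
            if normalized.startswith(key) and (
                len(normalized) == len(key) or normalized[len(key)] == " "
            ):
                if best is None or len(key) > len(best):
                    best = key
        return self.name_to_ingredient[best] if best else None


class TerminologyAdapter(Protocol):
    """Interface a live terminology service implements to feed the mapper.

    ``fetch_entries`` yields (normalized_name, ingredient, classes) triples;
    :func:`dictionary_from_adapter` assembles them into a DrugDictionary.
    """

    def fetch_entries(self) -> Iterable[tuple[str, str, set[str]]]: ...

    @property
    def version(self) -> str: ...


def dictionary_from_adapter(adapter: TerminologyAdapter) -> DrugDictionary:
    name_to_ing: dict[str, str] = {}
    ing_classes: dict[str, set[str]] = {}
    for name, ing, classes in adapter.fetch_entries():
        name_to_ing[normalize_med_name(name)] = ing
        ing_classes.setdefault(ing, set()).update(classes)
    return DrugDictionary(name_to_ing, ing_classes, version=adapter.version)


def load_dictionary(path: str | Path) -> DrugDictionary:
    """Load a versioned dictionary CSV.

    First line ``# dictionary_version=<v>``, then columns
    ``normalized_name, ingredient, classes`` (classes ``;``-separated).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        m = re.match(r"#\s*dictionary_version=(\S+)", first)
        if not m:
            raise ValueError(f"{path}: missing '# dictionary_version=' header line")
        version = m.group(1)
        df = pd.read_csv(fh)
    required = {"normalized_name", "ingredient", "classes"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: dictionary needs columns {sorted(required)}")
    name_to_ing: dict[str, str] = {}
    ing_classes: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        name_to_ing[str(row["normalized_name"])] = str(row["ingredient"])
        ing_classes.setdefault(str(row["ingredient"]), set()).update(
            c.strip() for c in str(row["classes"]).split(";") if c.strip()
        )
    return DrugDictionary(name_to_ing, ing_classes, version=version)


def load_default_dictionary() -> DrugDictionary:
    """Load the dictionary bundled with the package."""
    with resources.as_file(
        resources.files("metabocurate") / "data" / "drug_dictionary.csv"
    ) as p:
        return load_dictionary(p)


@dataclass
class DrugClassFlags:
    """Per-subject Boolean class flags plus mapping accounting."""

    flags: pd.DataFrame                 # subjects x classes, bool
    has_any_record: pd.Series           # bool per subject
    unmapped: list = field(default_factory=list)  # (subject_id, raw text)
    n_records: int = 0
    n_matched: int = 0

    @property
    def n_unmatched(self) -> int:
        return len(self.unmapped)


def map_medications(
    med_table: pd.DataFrame,
    dictionary: DrugDictionary,
    subjects: Iterable[str] | None = None,
) -> DrugClassFlags:
    """Resolve a (subject_id, medication_text) table to class flags.

    Every record is either matched (all classes of the resolved ingredient
    set true for the subject, OR-aggregated) or reported in ``unmapped``;
    matched + unmatched always equals the record count.  ``subjects``
    optionally widens the output index to subjects without any record
    (all-false flags, ``has_any_record`` false).
    """
    required = {"subject_id", "medication_text"}
    if not required <= set(med_table.columns):
        raise ValueError(f"medication table needs columns {sorted(required)}")
    extra = set(subjects) if subjects is not None else set()
    subj_index = pd.Index(
        sorted(set(med_table["subject_id"]) | extra), name="subject_id"
    )
    flags = pd.DataFrame(False, index=subj_index, columns=dictionary.classes)
    has_record = pd.Series(False, index=subj_index, name="has_any_record")
    unmapped: list[tuple[str, str]] = []
    n_matched = 0
    for _, row in med_table.iterrows():
        sid, raw = row["subject_id"], row["medication_text"]
        has_record.at[sid] = True
        ing = dictionary.lookup(normalize_med_name(raw))
        if ing is None:
            unmapped.append((sid, str(raw)))
            continue
        n_matched += 1
        for c in dictionary.ingredient_classes[ing]:
            flags.at[sid, c] = True
    return DrugClassFlags(
        flags=flags,
        has_any_record=has_record,
        unmapped=unmapped,
        n_records=len(med_table),
        n_matched=n_matched,
    )
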