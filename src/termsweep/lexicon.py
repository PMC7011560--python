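"""Categorized risk-factor vocabulary and its matching semantics.

A :class:`TermGroup` names one risk factor (e.g. ``Pesticides``) and lists
the surface variants whose occurrences are summed into that factor's
mention count.  Groups carry one of three category labels:

* ``general_environmental`` — broad environmental language (pollution,
  contamination, the precautionary principle);
* ``specific_environmental`` — named chemicals or chemical classes
  (phthalates, flame retardants, PFAS, ...);
* ``other`` — lifestyle, genetic, anatomical and pharmaceutical factors
  (exercise, diet, family history, HRT, ...).

Four ambiguous terms are banned as standalone variants — "environment",
"toxic", "chemical" and "hormone therapy" — because on cancer-organization
websites they frequently occur in contexts unrelated to environmental
exposure (chemotherapy, treatment toxicity, endocrine treatment).  The ban
applies to a variant *equal to* one of these strings; multi-word variants
that merely contain the token "chemical" (e.g. "endocrine disrupting
chemicals") are legitimate and kept.

All-caps acronym variants (BPA, HRT, DES, ...) are flagged and matched
case-sensitively so that e.g. the city name "des moines" does not count as
a diethylstilbestrol mention.  All other variants match case-insensitively.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "CATEGORIES",
    "EXCLUDED_STANDALONE_TERMS",
    "LexiconError",
    "TermGroup",
    "Lexicon",
    "build_default_lexicon",
    "load_lexicon",
    "save_lexicon",
]

CATEGORIES = ("general_environmental", "specific_environmental", "other")

#: Ambiguous terms that must never appear as a standalone variant.
EXCLUDED_STANDALONE_TERMS = frozenset(
    {"environment", "toxic", "chemical", "hormone therapy"}
)


class LexiconError(ValueError):
    """Malformed or invalid lexicon configuration."""


def _normalize_variant(variant: str) -> str:
    """Casefolded, hyphen/whitespace-collapsed form used for identity checks."""
    return re.sub(r"[\s\-]+", " ", variant.strip().casefold())


@dataclass(frozen=True)
class TermGroup:
    """One named risk factor and its surface variants.

    ``acronym_flags[i]`` marks ``variants[i]`` as a case-sensitive acronym.
    ``printed_flags[i]`` distinguishes the variants printed in the source
    survey's published term table from supplementary spellings added for
    robustness (e.g. BRCA1/BRCA2 alongside the table's BRAC1/BRAC2).
    """

    factor_name: str
    category: str
    variants: tuple[str, ...]
    acronym_flags: tuple[bool, ...]
    printed_flags: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not self.factor_name:
            raise LexiconError("factor_name must be non-empty")
        if self.category not in CATEGORIES:
            raise LexiconError(
                f"group {self.factor_name!r}: category {self.category!r} "
                f"not one of {CATEGORIES}"
            )
        if not self.variants:
            raise LexiconError(f"group {self.factor_name!r}: variants is empty")
        if len(self.acronym_flags) != len(self.variants):
            raise LexiconError(
                f"group {self.factor_name!r}: acronym_flags length mismatch"
            )
        if not self.printed_flags:
            object.__setattr__(self, "printed_flags", (True,) * len(self.variants))
        elif len(self.printed_flags) != len(self.variants):
            raise LexiconError(
                f"group {self.factor_name!r}: printed_flags length mismatch"
            )
        seen: set[str] = set()
        for v in self.variants:
            if not v or not v.strip():
                raise LexiconError(
                    f"group {self.factor_name!r}: empty variant string"
                )
            norm = _normalize_variant(v)
            if norm in EXCLUDED_STANDALONE_TERMS:
                raise LexiconError(
                    f"group {self.factor_name!r}: variant {v!r} is an excluded "
                    "ambiguous term and may not stand alone"
                )
            if norm in seen:
                raise LexiconError(
                    f"group {self.factor_name!r}: duplicate variant {v!r}"
                )
            seen.add(norm)


@dataclass(frozen=True)
class Lexicon:
    """An ordered collection of term groups with unique factor names."""

    groups: tuple[TermGroup, ...]
    version_tag: str = ""
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_name: dict[str, TermGroup] = {}
        for g in self.groups:
            if g.factor_name in by_name:
                raise LexiconError(f"duplicate factor_name {g.factor_name!r}")
            by_name[g.factor_name] = g
        object.__setattr__(self, "_by_name", by_name)

    def __iter__(self) -> Iterator[TermGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, factor_name: str) -> bool:
        return factor_name in self._by_name

    def group(self, factor_name: str) -> TermGroup:
        try:
            return self._by_name[factor_name]
        except KeyError:
            raise KeyError(f"no factor named {factor_name!r}") from None

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(g.factor_name for g in self.groups)

    def summary(self) -> dict:
        """Counts of groups, variants and categories.

        ``n_printed_variants`` counts only the variants carried over from
        the published term table; ``n_variants`` includes supplementary
        spellings as well.
        """
        by_cat = {c: 0 for c in CATEGORIES}
        for g in self.groups:
            by_cat[g.category] += 1
        return {
            "n_groups": len(self.groups),
            "n_variants": sum(len(g.variants) for g in self.groups),
            "n_printed_variants": sum(
                sum(g.printed_flags) for g in self.groups
            ),
            "groups_by_category": by_cat,
        }


# --------------------------------------------------------------------------
# Default vocabulary: the 23 risk-factor groups of the 2018 survey of 81
# U.S. breast cancer organization websites.  "(s)" notation in the published
# table is expanded into explicit singular+plural variants (no stemming).
# Entries are (variant, acronym, printed); BRCA1/BRCA2 are supplementary
# standard spellings of the table's BRAC1/BRAC2, and "hormone replacement
# therapy" is the supplementary spelled-out form of HRT.
# --------------------------------------------------------------------------

_DEFAULT_TABLE: tuple[tuple[str, str, tuple[tuple[str, bool, bool], ...]], ...] = (
    ("Exercise", "other", (
        ("exercise", False, True),
        ("physical activity", False, True),
        ("physically active", False, True),
    )),
    ("Family history", "other", (
        ("family history", False, True),
    )),
    ("Diet", "other", (
        ("diet", False, True),
    )),
    ("Genetics", "other", (
        ("genetics", False, True),
        ("BRAC1", True, True),
        ("BRAC2", True, True),
        ("BRCA1", True, False),
        ("BRCA2", True, False),
    )),
    ("Alcohol", "other", (
        ("alcohol", False, True),
    )),
    ("Breast density", "other", (
        ("breast density", False, True),
        ("dense breasts", False, True),
    )),
    ("Body weight", "other", (
        ("overweight", False, True),
        ("obese", False, True),
    )),
    ("Hormone replacement therapy", "other", (
        ("HRT", True, True),
        ("hormone replacement therapy", False, False),
    )),
    ("Pesticides", "specific_environmental", (
        ("pesticide", False, True),
        ("pesticides", False, True),
    )),
    ("Bisphenols", "specific_environmental", (
        ("BPA", True, True),
        ("bisphenol", False, True),
        ("bisphenols", False, True),
    )),
    ("Contamination", "general_environmental", (
        ("contaminant", False, True),
        ("contaminants", False, True),
        ("contamination", False, True),
    )),
    ("Pollution", "general_environmental", (
        ("pollution", False, True),
        ("pollutant", False, True),
        ("pollutants", False, True),
    )),
    ("Birth control", "other", (
        ("birth control", False, True),
        ("oral contraceptives", False, True),
    )),
    ("Parabens", "specific_environmental", (
        ("paraben", False, True),
        ("parabens", False, True),
    )),
    ("Endocrine disrupting chemicals", "specific_environmental", (
        ("endocrine disruptor", False, True),
        ("endocrine disruptors", False, True),
        ("endocrine disrupting chemical", False, True),
        ("endocrine disrupting chemicals", False, True),
        ("hormone disrupting chemical", False, True),
        ("hormone disrupting chemicals", False, True),
    )),
    ("Phthalates", "specific_environmental", (
        ("phthalate", False, True),
        ("phthalates", False, True),
    )),
    ("Diethylstilbestrol", "other", (
        ("diethylstilbestrol", False, True),
        ("DES", True, True),
    )),
    ("The precautionary principle", "general_environmental", (
        ("precautionary principle", False, True),
    )),
    ("Flame retardants", "specific_environmental", (
        ("flame retardant", False, True),
        ("flame retardants", False, True),
    )),
    ("Air pollution", "specific_environmental", (
        ("air pollution", False, True),
    )),
    ("Polycyclic aromatic hydrocarbons", "specific_environmental", (
        ("PAH", True, True),
        ("PAHs", True, True),
    )),
    ("PFAS", "specific_environmental", (
        ("PFOA", True, True),
        ("PFOS", True, True),
        ("PFAS", True, True),
        ("PFC", True, True),
        ("PFCs", True, True),
        ("perfluorinated chemicals", False, True),
    )),
    ("Oxybenzone", "specific_environmental", (
        ("oxybenzone", False, True),
    )),
)


def build_default_lexicon() -> Lexicon:
    """The default 23-group risk-factor vocabulary (deterministic)."""
    groups = tuple(
        TermGroup(
            factor_name=name,
            category=category,
            variants=tuple(v for v, _a, _p in rows),
            acronym_flags=tuple(a for _v, a, _p in rows),
            printed_flags=tuple(p for _v, _a, p in rows),
        )
        for name, category, rows in _DEFAULT_TABLE
    )
    return Lexicon(groups=groups, version_tag="default-2018-survey")


# --------------------------------------------------------------------------
# CSV round-trip.  One variant per row: factor_name, category, variant,
# acronym_flag[, printed_flag].
# --------------------------------------------------------------------------

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_bool(value: str, where: str) -> bool:
    try:
        return _BOOL[value.strip().casefold()]
    except KeyError:
        raise LexiconError(f"{where}: not a boolean: {value!r}") from None


def load_lexicon(source: str | Path | io.TextIOBase, version_tag: str = "") -> Lexicon:
    """Load a lexicon from CSV (path, or an open text stream).

    Raises :class:`LexiconError` naming the offending row on malformed
    records, excluded standalone terms, or duplicate (factor, variant)
    pairs.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return load_lexicon(fh, version_tag=version_tag or str(source))
    reader = csv.DictReader(source)
    required = {"factor_name", "category", "variant", "acronym_flag"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise LexiconError(
            f"lexicon CSV must have columns {sorted(required)}; "
            f"got {reader.fieldnames}"
        )
    order: list[str] = []
    rows: dict[str, dict] = {}
    for i, rec in enumerate(reader, start=2):
        where = f"row {i}"
        factor = (rec.get("factor_name") or "").strip()
        category = (rec.get("category") or "").strip()
        variant = (rec.get("variant") or "").strip()
        if not factor or not category or not variant:
            raise LexiconError(
                f"{where}: record requires factor_name, category and variant "
                f"(got {rec!r})"
            )
        acronym = _parse_bool(rec.get("acronym_flag") or "false", where)
        printed_raw = rec.get("printed_flag")
        printed = (
            True if printed_raw in (None, "") else _parse_bool(printed_raw, where)
        )
        if factor not in rows:
            order.append(factor)
            rows[factor] = {"category": category, "variants": []}
        elif rows[factor]["category"] != category:
            raise LexiconError(
                f"{where}: factor {factor!r} declared with two categories"
            )
        if any(
            _normalize_variant(v) == _normalize_variant(variant)
            for v, _a, _p in rows[factor]["variants"]
        ):
            raise LexiconError(
                f"{where}: duplicate variant {variant!r} for factor {factor!r}"
            )
        rows[factor]["variants"].append((variant, acronym, printed))
    groups = tuple(
        TermGroup(
            factor_name=name,
            category=rows[name]["category"],
            variants=tuple(v for v, _a, _p in rows[name]["variants"]),
            acronym_flags=tuple(a for _v, a, _p in rows[name]["variants"]),
            printed_flags=tuple(p for _v, _a, p in rows[name]["variants"]),
        )
        for name in order
    )
    return Lexicon(groups=groups, version_tag=version_tag)


def save_lexicon(lexicon: Lexicon, dest: str | Path | io.TextIOBase) -> None:
    """Write a lexicon to CSV, one variant per row (UTF-8)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            save_lexicon(lexicon, fh)
        return
    writer = csv.writer(dest)
    writer.writerow(
        ["factor_name", "category", "variant", "acronym_flag", "printed_flag"]
    )
    for g in lexicon:
        for v, a, p in zip(g.variants, g.acronym_flags, g.printed_flags):
            writer.writerow(
                [g.factor_name, g.category, v, str(a).lower(), str(p).lower()]
            )
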