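"""ICD-based multimorbidity classification.

Discharge abstracts carry a list of ICD-9-CM / ICD-10-CA diagnosis codes,
one of which is flagged as the Most Responsible Diagnosis (MRDx).  This
module classifies the *secondary* codes (everything except the MRDx) into
13 admission-morbidity categories — Hypertension through Peptic Ulcer
Disease — and derives the multimorbidity count, i.e. the number of disease
categories present in addition to the index hemorrhage.

The category → code-pattern mapping ships as an editable plain-text file
(``data/morbidity_codes.txt``) so the classification rules can be audited
and amended without touching code.  Patterns come in three shapes:

* exact codes, e.g. ``416.8`` — match the code itself and any further
  sub-subdivision (``416.80``);
* wildcard stems, e.g. ``401.x`` — match any code with that stem;
* inclusive ranges, e.g. ``430.x–438.x`` or ``250.0–250.3`` — match any
  code whose stem (and, where the endpoints carry decimals, decimal
  prefix) lies between the endpoints.

A pattern whose stem starts with a letter is an ICD-10 pattern, otherwise
ICD-9; a pattern never matches a code of the other scheme.  (ICD-9-CM
V-codes share their leading letter with ICD-10 chapters; because codes are
assigned a scheme by the same rule, matching stays internally consistent —
see the package methods note.)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CatalogParseError",
    "ClassificationError",
    "CodePattern",
    "MorbidityCatalog",
    "MorbidityProfile",
    "normalize_code",
    "match_code",
    "classify",
    "load_default_catalog",
    "parse_catalog",
    "CATEGORIES",
]

#: Category order as used throughout the package (most to least prevalent).
CATEGORIES = (
    "Hypertension",
    "Secondary Cerebrovascular Disease",
    "Diabetes",
    "Cardiac Disorders",
    "Chronic Pulmonary Disease",
    "Malignancy or Tumour",
    "Dementia",
    "Mood Disorders",
    "Renal Disease",
    "Peripheral Vascular Disease",
    "Liver Disease",
    "Rheumatic Disease",
    "Peptic Ulcer Disease",
)

#: MRDx codes defining an index intracerebral hemorrhage admission.
ICH_MRDX_CODES = (
    "431",
    "I61.0", "I61.1", "I61.2", "I61.3", "I61.4", "I61.5", "I61.6",
    "I61.8", "I61.9",
)

_RANGE_SEPARATORS = ("–", "—", "-")  # en dash, em dash, hyphen
_ATOM_RE = re.compile(r"^([A-Z]?)(\d{1,3})(?:\.(\d+|X))?$")


class CatalogParseError(ValueError):
    """Raised when a catalog file or pattern cannot be parsed."""


class ClassificationError(ValueError):
    """Raised for invalid classification input (e.g. MRDx flag problems)."""


def normalize_code(code: str) -> str:
    """Normalize an ICD code as recorded in an administrative extract.

    Uppercases, strips whitespace, and restores the decimal point when a
    code is recorded without it ("I610" -> "I61.0", "2500" -> "250.0").
    Stems are one optional letter followed by up to three digits.
    """
    c = code.strip().upper().replace(" ", "")
    if not c:
        raise ClassificationError("empty ICD code")
    if "." not in c:
        m = re.match(r"^([A-Z]?)(\d+)$", c)
        if m:
            # stems are letter + 2 digits (ICD-10) or 3 digits (ICD-9)
            stem_len = 2 if m.group(1) else 3
            if len(m.group(2)) > stem_len:
                c = (
                    f"{m.group(1)}{m.group(2)[:stem_len]}"
                    f".{m.group(2)[stem_len:]}"
                )
    return c


def _split_code(code: str) -> tuple[str, int, str]:
    """Split a normalized code into (alpha prefix, numeric stem, suffix)."""
    stem, _, suffix = code.partition(".")
    m = re.match(r"^([A-Z]?)(\d{1,3})$", stem)
    if m is None:
        raise ClassificationError(f"malformed ICD code: {code!r}")
    return m.group(1), int(m.group(2)), suffix


@dataclass(frozen=True)
class _Atom:
    """One endpoint of a pattern: alpha prefix, numeric stem, suffix.

    ``suffix`` is ``None`` for wildcard atoms ("401.x") and for bare stems.
    """

    alpha: str
    stem: int
    suffix: str | None

    @classmethod
    def parse(cls, text: str, pattern: str) -> "_Atom":
        m = _ATOM_RE.match(text)
        if m is None:
            raise CatalogParseError(f"malformed pattern atom {text!r} in {pattern!r}")
        alpha, stem, suffix = m.group(1), int(m.group(2)), m.group(3)
        if suffix == "X":
            suffix = None
        return cls(alpha, stem, suffix)


@dataclass(frozen=True)
class CodePattern:
    """A single printed code pattern (exact code, wildcard stem, or range)."""

    raw: str
    lo: _Atom = field(repr=False)
    hi: _Atom = field(repr=False)
    is_range: bool = field(repr=False, default=False)

    @property
    def scheme(self) -> str:
        """"ICD10" if the stem starts with a letter, else "ICD9"."""
        return "ICD10" if self.lo.alpha else "ICD9"

    @classmethod
    def parse(cls, raw: str) -> "CodePattern":
        text = raw.strip().upper().replace(" ", "")
        if not text:
            raise CatalogParseError("empty pattern")
        for sep in _RANGE_SEPARATORS:
            if sep in text:
                parts = text.split(sep)
                if len(parts) != 2:
                    raise CatalogParseError(f"malformed range pattern {raw!r}")
                lo, hi = (_Atom.parse(p, raw) for p in parts)
                if lo.alpha != hi.alpha:
                    raise CatalogParseError(
                        f"range endpoints of {raw!r} are from different schemes"
                    )
                if (lo.stem, lo.suffix or "") > (hi.stem, hi.suffix or ""):
                    raise CatalogParseError(f"descending range {raw!r}")
                return cls(raw=raw.strip(), lo=lo, hi=hi, is_range=True)
        atom = _Atom.parse(text, raw)
        return cls(raw=raw.strip(), lo=atom, hi=atom, is_range=False)


def match_code(pattern: CodePattern, code: str) -> bool:
    """True iff a (normalized) ICD code falls under a catalog pattern.

    Scheme mismatch is always False.  Exact patterns match at their own
    decimal precision ("294.1" covers "294.10"); wildcard patterns match
    any suffix of their stem; ranges compare the code's stem — and decimal
    prefix, when the endpoints specify decimals — against both endpoints
    inclusively.
    """
    alpha, stem, suffix = _split_code(normalize_code(code))
    lo, hi = pattern.lo, pattern.hi
    if alpha != lo.alpha:
        return False  # scheme / chapter mismatch
    if not pattern.is_range:
        if stem != lo.stem:
            return False
        if lo.suffix is None:
            return True
        return suffix.startswith(lo.suffix)
    # Range: stem strictly inside is enough; at an endpoint with a stated
    # decimal, compare the code's decimal prefix truncated to the
    # endpoint's precision (so "250.0–250.3" covers 250.03 and 250.31).
    if stem < lo.stem or stem > hi.stem:
        return False
    if stem == lo.stem and lo.suffix is not None:
        if suffix[: len(lo.suffix)] < lo.suffix:
            return False
    if stem == hi.stem and hi.suffix is not None:
        if suffix[: len(hi.suffix)] > hi.suffix or not suffix:
            return False
    return True


@dataclass(frozen=True)
class MorbidityProfile:
    """Per-discharge classification outcome."""

    flags: Mapping[str, bool]
    count: int
    any: bool

    @classmethod
    def from_flags(cls, flags: Mapping[str, bool]) -> "MorbidityProfile":
        count = sum(bool(v) for v in flags.values())
        return cls(flags=dict(flags), count=count, any=count >= 1)


@dataclass(frozen=True)
class MorbidityCatalog:
    """Ordered mapping of the 13 morbidity categories to their patterns."""

    categories: Mapping[str, tuple[CodePattern, ...]]

    def __post_init__(self) -> None:
        names = tuple(self.categories)
        if names != CATEGORIES:
            raise CatalogParseError(
                f"catalog must contain exactly the 13 canonical categories in "
                f"order; got {names}"
            )

    def match_categories(self, code: str) -> list[str]:
        """All categories whose pattern list covers ``code`` (may be several)."""
        return [
            name
            for name, patterns in self.categories.items()
            if any(match_code(p, code) for p in patterns)
        ]


def parse_catalog(text: str) -> MorbidityCatalog:
    """Parse the stanza-format catalog file (see module docstring)."""
    categories: dict[str, list[CodePattern]] = {}
    current: list[CodePattern] | None = None
    seen: set[str] = set()  # per-category; a code may repeat across categories
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip()
            if name in categories:
                raise CatalogParseError(f"duplicate category {name!r} (line {lineno})")
            current = categories.setdefault(name, [])
            seen = set()
            continue
        if current is None:
            raise CatalogParseError(f"pattern outside any category at line {lineno}")
        for token in line.split(","):
            token = token.strip()
            if not token:
                continue
            pat = CodePattern.parse(token)
            key = pat.raw.replace("–", "-")
            if key in seen:
                raise CatalogParseError(f"pattern {token!r} appears twice in a category")
            seen.add(key)
            current.append(pat)
    return MorbidityCatalog(
        categories={k: tuple(v) for k, v in categories.items()}
    )


def load_default_catalog() -> MorbidityCatalog:
    """Load the catalog shipped with the package."""
    text = (
        resources.files("costlab").joinpath("data/morbidity_codes.txt").read_text("utf-8")
    )
    return parse_catalog(text)


def classify(
    codes: Sequence[tuple[str, bool]],
    catalog: MorbidityCatalog | None = None,
) -> MorbidityProfile:
    """Classify one discharge's diagnosis codes into a morbidity profile.

    Parameters
    ----------
    codes
        ``(icd_code, is_mrdx)`` pairs; exactly one pair must carry the
        MRDx flag.  The MRDx code itself is excluded from classification
        (it is the index hemorrhage); every other code is tested against
        every category, so a single code may raise several flags and a
        secondary hemorrhage/cerebrovascular code counts as Secondary
        Cerebrovascular Disease.
    catalog
        Defaults to the catalog shipped with the package.

    Returns
    -------
    MorbidityProfile
        Per-category booleans, the multimorbidity count (number of
        categories, not codes), and the any-morbidity indicator.
    """
    if catalog is None:
        catalog = load_default_catalog()
    n_mrdx = sum(bool(flag) for _, flag in codes)
    if n_mrdx != 1:
        raise ClassificationError(
            f"expected exactly one MRDx-flagged code, got {n_mrdx}"
        )
    flags = {name: False for name in catalog.categories}
    for code, is_mrdx in codes:
        if is_mrdx:
            continue
        for name in catalog.match_categories(code):
            flags[name] = True
    return MorbidityProfile.from_flags(flags)


def classify_many(
    code_lists: Iterable[Sequence[tuple[str, bool]]],
    catalog: MorbidityCatalog | None = None,
) -> list[MorbidityProfile]:
    """Vector convenience wrapper around :func:`classify`."""
    if catalog is None:
        catalog = load_default_catalog()
    return [classify(codes, catalog) for codes in code_lists]
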