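"""Drug-name standardization and PT→SOC mapping.

Spontaneous-report databases carry free-text drug names (trade names, research
codes, spelling variants) and MedDRA-coded reaction terms.  This module provides
two deterministic, table-driven vocabularies:

* :class:`DrugLexicon` — a synonym → canonical-name map used to standardize drug
  names before suspect-drug selection (a table-driven replacement for NLP-based
  name normalizers).
* :class:`MeddraDictionary` — a Preferred Term → System Organ Class map following
  the primary-SOC convention (each PT belongs to exactly one SOC).

Both ship with synthetic stand-in tables (``data/*_synthetic.tsv``) that mirror
the file structure of real exports, so real licensed exports can be swapped in
via the same two-column format.  MedDRA itself is licensed content and is not
distributed here; the bundled dictionary is an artificial vocabulary assembled
for testing and simulation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "Unmapped"

_FOLD_RE = re.compile(r"[^a-z0-9 ]+")


def fold(text: str) -> str:
    """Case-, whitespace- and punctuation-insensitive key for vocabulary lookup."""
    folded = _FOLD_RE.sub(" ", text.strip().lower())
    return " ".join(folded.split())


def _bundled(name: str) -> Path:
    return Path(str(resources.files("pvsignals").joinpath("data", name)))


@dataclass
class DrugLexicon:
    """Synonym → canonical drug-name map.

    Lookup is total: unknown names return the folded input with ``matched=False``
    rather than failing, so unrecognized drugs stay in the corpus under a
    normalized spelling.  Canonical names always map to themselves.
    """

    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # canonical names must resolve to themselves
        for canonical in list(self.synonyms.values()):
            self.synonyms.setdefault(fold(canonical), canonical)

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugLexicon":
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header:
                raise ValueError(f"empty lexicon file: {path}")
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                synonym, canonical = line.split("\t")
                mapping[fold(synonym)] = canonical
        return cls(mapping)

    @classmethod
    def default(cls) -> "DrugLexicon":
        return cls.from_file(_bundled("drug_lexicon_synthetic.tsv"))

    def normalize(self, raw: str) -> tuple[str, bool]:
        """Return ``(canonical_name, matched)`` for a raw drug-name string."""
        key = fold(raw)
        if key in self.synonyms:
            return self.synonyms[key], True
        return key, False

    @property
    def canonical_names(self) -> set[str]:
        return set(self.synonyms.values())


def normalize_drug_name(raw: str, lexicon: DrugLexicon) -> tuple[str, bool]:
    """Standardize one drug name; see :meth:`DrugLexicon.normalize`."""
    return lexicon.normalize(raw)


@dataclass
class MeddraDictionary:
    """PT → SOC map (primary SOC convention: exactly one SOC per PT).

    Unknown PTs map to the sentinel SOC ``"Unmapped"`` and are counted in
    :attr:`unmapped_count` so ingestion noise is visible rather than fatal.
    """

    pt_to_soc: dict[str, tuple[str, str]] = field(default_factory=dict)
    version: str = "unversioned"
    unmapped_count: int = 0

    @classmethod
    def from_file(cls, path: str | Path, version: str | None = None) -> "MeddraDictionary":
        mapping: dict[str, tuple[str, str]] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header:
                raise ValueError(f"empty dictionary file: {path}")
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                pt, soc = line.split("\t")
                key = fold(pt)
                if key in mapping and mapping[key][1] != soc:
                    raise ValueError(f"PT {pt!r} mapped to more than one SOC")
                mapping[key] = (pt, soc)
        return cls(mapping, version=version or Path(path).stem)

    @classmethod
    def default(cls) -> "MeddraDictionary":
        return cls.from_file(_bundled("pt_soc_synthetic.tsv"), version="SYNTHETIC-26.0")

    @classmethod
    def from_catalog(cls, catalog, version: str = "generator") -> "MeddraDictionary":
        """Build a dictionary from a generator PT catalogue of (pt, soc, prob) rows."""
        mapping = {fold(pt): (pt, soc) for pt, soc, _ in catalog}
        return cls(mapping, version=version)

    def map(self, pt: str) -> str:
        """Return the SOC for a PT, or the ``"Unmapped"`` sentinel."""
        entry = self.pt_to_soc.get(fold(pt))
        if entry is None:
            self.unmapped_count += 1
            logger.warning("PT %r not in dictionary %s; mapped to %s", pt, self.version, UNMAPPED_SOC)
            return UNMAPPED_SOC
        return entry[1]

    @property
    def pts(self) -> list[str]:
        return [display for display, _ in self.pt_to_soc.values()]

    @property
    def socs(self) -> set[str]:
        return {soc for _, soc in self.pt_to_soc.values()}

    def __len__(self) -> int:
        return len(self.pt_to_soc)


def map_pt_to_soc(pt: str, dictionary: MeddraDictionary) -> str:
    """Map one PT name to its (primary) SOC; see :meth:`MeddraDictionary.map`."""
    return dictionary.map(pt)
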