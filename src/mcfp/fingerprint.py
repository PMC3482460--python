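"""Monomer alphabets, peptide records and monomer-composition fingerprints.

A nonribosomal peptide (NRP) is described here by its *monomer composition*:
the ordered list of monomer codes (amino acids, their derivates, lipids,
chromophores...) that make up the peptide, e.g. ``NAc-Leu, Aib, Leu, Aib,
Pheol`` for peptaibolin.  The monomer composition fingerprint (MCFP) maps a
composition onto an integer occurrence vector over a fixed *monomer
alphabet*: element ``i`` holds the number of times alphabet code ``i``
appears in the composition, and is 0 for absent monomers.  The fingerprint
deliberately discards monomer order and bond structure.

Monomer codes are opaque, case-sensitive labels ("D-aThr" and "D-aIle" differ
only in case-sensitive detail); the only canonicalization applied is
trimming of surrounding whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "CompositionParseError",
    "UnknownMonomerError",
    "AlphabetMismatchError",
    "MonomerAlphabet",
    "PeptideRecord",
    "MCFP",
    "parse_composition",
    "build_alphabet",
    "compute_mcfp",
    "fingerprint_records",
]

# "," and ";" both act as separators: published composition strings mix them
# (a lipid moiety is often set off from the peptide part with ";").
_SEPARATORS = re.compile(r"[,;]")


class CompositionParseError(ValueError):
    """Raised when a monomer-composition string cannot be tokenized."""


class UnknownMonomerError(KeyError):
    """Raised when a composition contains a code absent from the alphabet."""


class AlphabetMismatchError(ValueError):
    """Raised when two fingerprints built on different alphabets are combined."""


def parse_composition(text: str) -> list[str]:
    """Tokenize a monomer-composition string into an ordered code list.

    Both ``,`` and ``;`` separate tokens; whitespace around each code is
    trimmed; codes are kept case-sensitively and in order of appearance.

    Raises
    ------
    CompositionParseError
        If *text* is empty or any token trims to the empty string; the
        message names the 1-based position of the offending token.
    """
    if text is None or not text.strip():
        raise CompositionParseError("empty monomer composition")
    codes = []
    for pos, token in enumerate(_SEPARATORS.split(text), start=1):
        code = token.strip()
        if not code:
            raise CompositionParseError(
                f"empty monomer code at position {pos} in {text!r}"
            )
        codes.append(code)
    return codes


@dataclass(frozen=True)
class MonomerAlphabet:
    """Ordered registry of unique monomer codes defining fingerprint positions.

    ``codes[i]`` is the monomer written at fingerprint position ``i``; the
    order is fixed at construction, so any two fingerprints built against the
    same alphabet are positionally comparable.
    """

    codes: tuple[str, ...]
    index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("alphabet must contain at least one monomer code")
        cleaned = tuple(c.strip() for c in self.codes)
        if any(not c for c in cleaned):
            raise ValueError("alphabet codes must be non-empty after trimming")
        if len(set(cleaned)) != len(cleaned):
            raise ValueError("alphabet codes must be unique")
        object.__setattr__(self, "codes", cleaned)
        object.__setattr__(
            self, "index", {c: i for i, c in enumerate(cleaned)}
        )

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code.strip() in self.index

    def position(self, code: str) -> int:
        code = code.strip()
        if code not in self.index:
            raise UnknownMonomerError(f"monomer code {code!r} not in alphabet")
        return self.index[code]

    def extended(self, new_codes: Iterable[str]) -> "MonomerAlphabet":
        """Return a new alphabet with unseen codes appended in given order."""
        extra = [c.strip() for c in new_codes if c.strip() not in self.index]
        # preserve first-occurrence order among the extras themselves
        seen: set[str] = set()
        extra = [c for c in extra if not (c in seen or seen.add(c))]
        if not extra:
            return self
        return MonomerAlphabet(self.codes + tuple(extra))

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "MonomerAlphabet":
        """Build from an explicit code list: order preserved, duplicates
        dropped (first occurrence wins)."""
        seen: set[str] = set()
        unique = []
        for c in codes:
            c = c.strip()
            if c and c not in seen:
                seen.add(c)
                unique.append(c)
        if not unique:
            raise ValueError("no monomer codes supplied")
        return cls(tuple(unique))

    @classmethod
    def from_records(cls, records: Iterable["PeptideRecord"]) -> "MonomerAlphabet":
        """Build from a dataset: the union of all composition codes, sorted
        lexicographically so the alphabet is reproducible across runs."""
        codes: set[str] = set()
        for rec in records:
            codes.update(rec.composition)
        if not codes:
            raise ValueError("no monomer codes found in records")
        return cls(tuple(sorted(codes)))

    @classmethod
    def from_file(cls, path: str | Path) -> "MonomerAlphabet":
        """Read an alphabet file: one code per line, '#' starts a comment."""
        codes = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                codes.append(line)
        return cls.from_codes(codes)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.codes) + "\n")


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: identifier, name, activity labels and monomer composition.

    ``activities`` may be empty (an unlabeled peptide); ``composition`` is
    ordered and non-empty.
    """

    id: str
    name: str
    activities: frozenset[str]
    composition: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValueError(f"peptide {self.id!r}: empty composition")
        object.__setattr__(
            self, "composition", tuple(c.strip() for c in self.composition)
        )
        if any(not c for c in self.composition):
            raise ValueError(f"peptide {self.id!r}: blank monomer code")
        acts = frozenset(a.strip() for a in self.activities)
        if "" in acts:
            raise ValueError(f"peptide {self.id!r}: blank activity label")
        object.__setattr__(self, "activities", acts)

    @property
    def monomer_set(self) -> frozenset[str]:
        """Distinct monomers: the positions 'on' in the fingerprint."""
        return frozenset(self.composition)

    def composition_string(self, sep: str = ", ") -> str:
        return sep.join(self.composition)


@dataclass(frozen=True)
class MCFP:
    """A monomer-composition fingerprint: sparse integer occurrence vector.

    Stored sparsely as ``{position: count}`` because real alphabets run to
    hundreds of codes while peptides contain ~3-18 monomers, so the dense
    vector is overwhelmingly zero.  ``dense()`` materializes the full vector.
    """

    counts: Mapping[int, int]
    alphabet: MonomerAlphabet

    def __post_init__(self) -> None:
        counts = {int(p): int(c) for p, c in self.counts.items() if c != 0}
        if any(c < 0 for c in counts.values()):
            raise ValueError("fingerprint counts must be non-negative")
        if counts and (min(counts) < 0 or max(counts) >= len(self.alphabet)):
            raise ValueError("fingerprint position outside alphabet")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.alphabet)

    @property
    def length(self) -> int:
        """Total monomer count = length of the underlying composition."""
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        """Number of nonzero positions (distinct monomers)."""
        return len(self.counts)

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.counts)

    def dense(self, dtype=np.int64) -> np.ndarray:
        vec = np.zeros(len(self.alphabet), dtype=dtype)
        for pos, cnt in self.counts.items():
            vec[pos] = cnt
        return vec

    def to_sparse_string(self) -> str:
        """``code:count`` pairs, comma-joined, in alphabet order."""
        items = sorted(self.counts.items())
        return ",".join(f"{self.alphabet.codes[p]}:{c}" for p, c in items)

    def same_alphabet(self, other: "MCFP") -> bool:
        return self.alphabet is other.alphabet or (
            self.alphabet.codes == other.alphabet.codes
        )


def build_alphabet(
    sources: Iterable[PeptideRecord] | Iterable[str],
) -> MonomerAlphabet:
    """Build a monomer alphabet from peptide records or an explicit code list.

    An explicit list of code strings keeps its order (duplicates dropped,
    first occurrence wins); a list of records yields the lexicographically
    sorted union of all composition codes.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("no alphabet sources supplied")
    if isinstance(sources[0], PeptideRecord):
        return MonomerAlphabet.from_records(sources)
    return MonomerAlphabet.from_codes(sources)


def compute_mcfp(
    record: PeptideRecord,
    alphabet: MonomerAlphabet,
    unknown_policy: Literal["error", "extend", "ignore"] = "error",
) -> MCFP:
    """Fingerprint a peptide over *alphabet*.

    ``unknown_policy`` governs composition codes missing from the alphabet:
    ``error`` (default) raises :class:`UnknownMonomerError`, ``extend``
    returns a fingerprint over an alphabet with the unseen codes appended
    (supporting incrementally growing databases), ``ignore`` drops them —
    under ``ignore`` the count-conservation invariant no longer holds.
    """
    if unknown_policy not in ("error", "extend", "ignore"):
        raise ValueError(f"unknown_policy {unknown_policy!r}")
    if unknown_policy == "extend":
        alphabet = alphabet.extended(record.composition)
    counts: dict[int, int] = {}
    for code in record.composition:
        if code not in alphabet:
            if unknown_policy == "ignore":
                continue
            raise UnknownMonomerError(
                f"peptide {record.id!r}: monomer code {code!r} not in alphabet"
            )
        pos = alphabet.position(code)
        counts[pos] = counts.get(pos, 0) + 1
    return MCFP(counts, alphabet)


def fingerprint_records(
    records: Sequence[PeptideRecord],
    alphabet: MonomerAlphabet | None = None,
    unknown_policy: Literal["error", "extend", "ignore"] = "error",
) -> tuple[list[MCFP], MonomerAlphabet]:
    """Fingerprint a whole dataset against one shared alphabet.

    When *alphabet* is None it is derived from the records (sorted union),
    so every composition code is covered by construction.
    """
    if alphabet is None:
        alphabet = MonomerAlphabet.from_records(records)
        unknown_policy = "error"  # cannot occur; keep strict
    elif unknown_policy == "extend":
        # extend once, up front, so every fingerprint shares one alphabet
        for rec in records:
            alphabet = alphabet.extended(rec.composition)
        unknown_policy = "error"
    fps = [compute_mcfp(r, alphabet, unknown_policy) for r in records]
    return fps, alphabet
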