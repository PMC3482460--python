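"""Synthetic labeled NRP datasets with controllable class structure.

Real nonribosomal-peptide collections have a few unbalanced activity
classes, monomer usage that is partly class-specific (iron-chelating
monomers in siderophores, Aib-rich peptaibols among antibiotics), a large
pool of monomers shared across classes, peptide lengths of roughly 3-18
monomers, and a sizeable minority of peptides carrying two activities
(antibiotic/toxin crossing above all).  The generator emulates exactly
those features so that fingerprinting, curation, similarity search and
prediction can all be exercised end to end without external data.

Each activity class is described by a :class:`ClassProfile`: a pool of
monomers the class tends to use, a pool *specific* to the class (disjoint
across classes by construction), a length range, and an ``enrichment``
knob.  Per monomer draw, the probability of sampling from the shared /
class / specific pool is controlled by enrichment ``e``:

    p_shared = 1 / (1 + e);  the rest splits again by e, so
    p_specific = (e / (1 + e))^2.

``e = 0`` makes every class draw from the shared pool only (labels carry no
signal); large ``e`` concentrates draws on class-specific monomers until
supports are disjoint in the limit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .fingerprint import PeptideRecord

__all__ = [
    "ClassProfile",
    "GeneratorConfig",
    "default_profiles",
    "default_config",
    "generate_dataset",
    "fixture_table5",
    "monomer_universe",
]

# Shared pool: common proteogenic-style monomers every class can use.
SHARED_POOL = (
    "Ala", "Gly", "Val", "Leu", "Ile", "Ser", "Thr", "Pro", "Asp", "Glu",
    "Gln", "Asn", "Lys", "Phe", "Trp", "Tyr", "Orn", "Dab", "D-Ala", "D-Ser",
)

# Activity classes mirror the five retained at full scale in curated NRP
# collections, with sizes (319, 157, 82, 25, 22); antibiotic and toxin class
# pools overlap heavily, reflecting how often those activities co-occur.
_DEFAULTS = [
    dict(
        label="antibiotic",
        n=319,
        specific=("Aib", "Iva", "Pheol", "Leuol", "Valol", "NAc-Leu"),
        pool=("D-Leu", "D-Phe", "D-Glu", "Hyp", "C10:0-OH(3)", "Dhb"),
        length=(3, 18),
    ),
    dict(
        label="toxin",
        n=157,
        specific=("Mdha", "MeAsp", "Adda", "N-MeAla", "D-Abu", "Mdhb"),
        pool=("D-Leu", "D-Phe", "D-Glu", "Dhb", "C10:0-OH(3)", "Me-Val"),
        length=(5, 12),
    ),
    dict(
        label="siderophore",
        n=82,
        specific=("OH-Orn", "Fo-OH-Orn", "ChrP", "OH-His", "OH-cOrn", "ChrA"),
        pool=("D-Ser", "Gly", "Ser", "Thr", "D-Ala", "Dab"),
        length=(6, 12),
    ),
    dict(
        label="antitumor",
        n=25,
        specific=("Sar", "Me-Gly", "Thz", "Me-Tyr", "D-Val", "Piz"),
        pool=("D-Leu", "Me-Val", "D-Phe", "Pro", "Val", "Thr"),
        length=(4, 10),
    ),
    dict(
        label="protease-inhibitor",
        n=22,
        specific=("Arg-al", "Phe-al", "Ahp", "Agm", "Leu-al", "Tyr-al"),
        pool=("Val", "Leu", "Pro", "Thr", "Ile", "Gln"),
        length=(3, 7),
    ),
]

# Which second activity a multi-activity peptide may pick up; classes absent
# here never cross.
DEFAULT_CROSSINGS: Mapping[str, tuple[str, ...]] = {
    "antibiotic": ("toxin", "antitumor"),
    "toxin": ("antibiotic", "antitumor"),
    "antitumor": ("antibiotic", "toxin"),
}


@dataclass(frozen=True)
class ClassProfile:
    """Sampling profile for one activity class."""

    label: str
    monomer_pool: tuple[str, ...]
    specific_pool: tuple[str, ...]
    length_range: tuple[int, int]
    enrichment: float = 4.0
    n_peptides: int = 50

    def __post_init__(self) -> None:
        if not self.monomer_pool or not self.specific_pool:
            raise ValueError(f"class {self.label!r}: empty monomer pool")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"class {self.label!r}: bad length range")
        if self.enrichment < 0:
            raise ValueError(f"class {self.label!r}: enrichment must be >= 0")
        if self.n_peptides < 1:
            raise ValueError(f"class {self.label!r}: n_peptides must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic dataset."""

    profiles: tuple[ClassProfile, ...]
    shared_pool: tuple[str, ...] = SHARED_POOL
    multi_activity_fraction: float = 0.25
    crossings: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CROSSINGS)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("at least one class profile required")
        if not 0 <= self.multi_activity_fraction <= 1:
            raise ValueError("multi_activity_fraction must be in [0, 1]")
        seen: set[str] = set()
        for p in self.profiles:
            overlap = seen & set(p.specific_pool)
            if overlap:
                raise ValueError(
                    f"specific pools overlap across classes: {sorted(overlap)}"
                )
            seen |= set(p.specific_pool)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        profiles = tuple(
            ClassProfile(
                label=p["label"],
                monomer_pool=tuple(p["monomer_pool"]),
                specific_pool=tuple(p["specific_pool"]),
                length_range=tuple(p["length_range"]),
                enrichment=float(p.get("enrichment", 4.0)),
                n_peptides=int(p.get("n_peptides", 50)),
            )
            for p in raw["profiles"]
        )
        return cls(
            profiles=profiles,
            shared_pool=tuple(raw.get("shared_pool", SHARED_POOL)),
            multi_activity_fraction=float(
                raw.get("multi_activity_fraction", 0.25)
            ),
            crossings={
                k: tuple(v)
                for k, v in raw.get("crossings", DEFAULT_CROSSINGS).items()
            },
            rng_seed=int(raw.get("rng_seed", 0)),
        )


def default_profiles(
    scale: float = 1.0, enrichment: float = 4.0
) -> tuple[ClassProfile, ...]:
    """The five stock class profiles, scaled.

    ``scale`` multiplies every class size (rounded, floor 2) so tests can
    run on small datasets with the same relative class imbalance.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return tuple(
        ClassProfile(
            label=d["label"],
            monomer_pool=d["pool"],
            specific_pool=d["specific"],
            length_range=d["length"],
            enrichment=enrichment,
            n_peptides=max(2, round(d["n"] * scale)),
        )
        for d in _DEFAULTS
    )


def default_config(
    scale: float = 1.0,
    enrichment: float = 4.0,
    multi_activity_fraction: float = 0.25,
    seed: int = 0,
) -> GeneratorConfig:
    return GeneratorConfig(
        profiles=default_profiles(scale, enrichment),
        multi_activity_fraction=multi_activity_fraction,
        rng_seed=seed,
    )


def _pool_probabilities(enrichment: float) -> tuple[float, float, float]:
    """(p_shared, p_class, p_specific) for a given enrichment."""
    if math.isinf(enrichment):
        return 0.0, 0.0, 1.0
    focus = enrichment / (1.0 + enrichment)
    p_shared = 1.0 - focus
    p_specific = focus * focus
    p_class = focus - p_specific
    return p_shared, p_class, p_specific


def generate_dataset(config: GeneratorConfig) -> list[PeptideRecord]:
    """Draw a labeled peptide dataset; fully reproducible from ``rng_seed``.

    For each class, ``n_peptides`` peptides are drawn: the composition
    length is uniform over the class length range and each monomer comes
    from the shared / class / specific pool with enrichment-controlled
    probabilities.  A ``multi_activity_fraction`` of peptides in classes
    listed in the crossing table receive a second activity label.
    Composition order is random — the fingerprint must not care.
    """
    rng = np.random.default_rng(config.rng_seed)
    records: list[PeptideRecord] = []
    counter = 1
    for profile in config.profiles:
        p_shared, p_class, p_specific = _pool_probabilities(profile.enrichment)
        pools = (
            list(config.shared_pool),
            list(profile.monomer_pool),
            list(profile.specific_pool),
        )
        probs = np.array([p_shared, p_class, p_specific])
        partners = config.crossings.get(profile.label, ())
        lo, hi = profile.length_range
        for _ in range(profile.n_peptides):
            length = int(rng.integers(lo, hi + 1))
            which = rng.choice(3, size=length, p=probs)
            composition = tuple(
                pools[w][int(rng.integers(len(pools[w])))] for w in which
            )
            activities = {profile.label}
            if partners and rng.random() < config.multi_activity_fraction:
                activities.add(partners[int(rng.integers(len(partners)))])
            records.append(
                PeptideRecord(
                    id=f"SYN{counter:05d}",
                    name=f"synthetic-{profile.label}-{counter}",
                    activities=frozenset(activities),
                    composition=composition,
                )
            )
            counter += 1
    return records


def monomer_universe(n: int, prefix: str = "M") -> list[str]:
    """Deterministic list of *n* placeholder monomer codes (``M0001``...).

    Used to pad an alphabet to a target size, e.g. a realistic
    526-code registry, without shipping any database content.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def fixture_table5() -> list[PeptideRecord]:
    """Five published NRPs (outside any database snapshot) as a fixture.

    Coelichelin, hypomurocin A1, orfamide A, pyoverdin PSEN and TVB I with
    their printed monomer compositions and literature activities.  The
    peptides carry no database accession, so the ids TAB5-01..TAB5-05 are
    synthetic.
    """
    rows = [
        ("TAB5-01", "coelichelin", {"siderophore"},
         ("D-Fo-OH-Orn", "D-aThr", "OH-Orn", "D-Fo-OH-Orn")),
        ("TAB5-02", "hypomurocin A1", {"antibiotic"},
         ("Ac-Aib", "Gln", "Val", "Val", "Aib", "Pro", "Leu", "Leu", "Aib",
          "Pro", "Leuol")),
        ("TAB5-03", "orfamide A", {"antibiotic"},
         ("C14:0-OH(3)", "Leu", "D-Glu", "D-aThr", "D-aIle", "Leu", "D-Ser",
          "Leu", "Leu", "D-Ser", "Val")),
        ("TAB5-04", "pyoverdin PSEN", {"siderophore"},
         ("ChrP", "D-Ala", "Asn", "Dab", "OH-His", "Gly", "Gly", "Ser",
          "Thr", "D-Ser", "OH-cOrn")),
        ("TAB5-05", "TVB I", {"antibiotic"},
         ("Ac-Aib", "Gly", "Ala", "Val", "Aib", "Gln", "Aib", "Ala", "Aib",
          "Ser", "Leu", "Aib", "Pro", "Leu", "Aib", "Aib", "Gln", "Valol")),
    ]
    return [
        PeptideRecord(id=i, name=n, activities=frozenset(a), composition=c)
        for i, n, a, c in rows
    ]
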