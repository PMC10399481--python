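"""Guner-Henry (GH) enrichment validation of a pharmacophore query.

Screening a labelled library yields the classical confusion counts —
database size D, actives A, total hits Ht, active hits Ha — from which the
GH family of statistics is derived:

    yield%  = 100 * Ha / Ht          (precision of the hit list)
    ratio%  = 100 * Ha / A           (recall of the actives)
    E       = Ha * D / (Ht * A)      (enrichment over random selection)
    GH      = [Ha (3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha) / (D - A)]

GH ranges from 0 (null model, no active retrieved) to 1 (ideal model:
every active retrieved with no false positive).  A model scoring in
0.7-1 is conventionally called excellent; that band is reported as a
label only, never enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .chem import Molecule3D
from .features import DEFAULT_RULES, PerceptionRules
from .pharmacophore import MatcherSettings, PharmacophoreQuery, screen_library

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass
class LabeledLibrary:
    """Molecules plus an activity label per compound id."""

    molecules: list[Molecule3D]
    labels: dict[str, str]
    jitter_warning: bool = False

    def __post_init__(self) -> None:
        for m in self.molecules:
            label = self.labels.get(m.id)
            if label not in (ACTIVE, INACTIVE):
                raise ValueError(f"compound {m.id!r} lacks a valid activity label")

    @property
    def n_actives(self) -> int:
        ids = {m.id for m in self.molecules}
        return sum(1 for cid, lab in self.labels.items() if cid in ids and lab == ACTIVE)


@dataclass(frozen=True)
class EnrichmentStats:
    """The full GH statistic family for one validation run."""

    D: int
    A: int
    Ht: int
    Ha: int
    yield_pct: float
    ratio_pct: float
    E: float
    FN: int
    FP: int
    GH: float

    def rounded(self) -> dict:
        """Presentation values: GH to 2 dp, E and percentages to integers."""
        return {
            "D": self.D,
            "A": self.A,
            "Ht": self.Ht,
            "Ha": self.Ha,
            "yield_pct": round(self.yield_pct),
            "ratio_pct": round(self.ratio_pct),
            "E": round(self.E),
            "FN": self.FN,
            "FP": self.FP,
            "GH": round(self.GH, 2),
        }

    @property
    def quality_label(self) -> str:
        return "excellent" if self.GH >= 0.7 else "not excellent"


def gh_statistics(D: int, A: int, Ht: int, Ha: int) -> EnrichmentStats:
    """Compute the GH statistic family from confusion counts.

    Preconditions: D > A > 0, Ht >= Ha >= 0, Ha <= A, Ht <= D, and
    Ht - Ha <= D - A (a screen cannot retrieve more inactives than the
    database holds; outside this domain the GH formula leaves [0, 1]).
    Ht must be positive (yield, E and GH are undefined for an empty hit
    list), and D > A is required (GH's second factor has denominator
    D - A).
    """
    for name, v in (("D", D), ("A", A), ("Ht", Ht), ("Ha", Ha)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if A <= 0:
        raise ValueError("A must be positive (no actives: validation undefined)")
    if D <= A:
        raise ValueError("D must exceed A (GH undefined when D == A)")
    if Ht > D:
        raise ValueError("Ht cannot exceed D")
    if Ha > min(Ht, A):
        raise ValueError("Ha cannot exceed min(Ht, A)")
    if Ht - Ha > D - A:
        raise ValueError(
            "inactive hits (Ht - Ha) cannot exceed the inactive count (D - A)"
        )
    if Ht == 0:
        raise ValueError("Ht is zero: yield, E and GH are undefined")

    yield_pct = 100.0 * Ha / Ht
    ratio_pct = 100.0 * Ha / A
    enrich = (Ha * D) / (Ht * A)
    gh = (Ha * (3 * A + Ht)) / (4.0 * Ht * A) * (1.0 - (Ht - Ha) / float(D - A))
    return EnrichmentStats(
        D=int(D),
        A=int(A),
        Ht=int(Ht),
        Ha=int(Ha),
        yield_pct=yield_pct,
        ratio_pct=ratio_pct,
        E=enrich,
        FN=int(A - Ha),
        FP=int(Ht - Ha),
        GH=gh,
    )


def validate_query(
    query: PharmacophoreQuery,
    lib: LabeledLibrary,
    rules: PerceptionRules = DEFAULT_RULES,
    settings: MatcherSettings = MatcherSettings(),
) -> EnrichmentStats:
    """Screen a labelled library and derive the GH statistics.

    Raises if the library is empty or contains no actives.
    """
    if not lib.molecules:
        raise ValueError("empty library")
    if lib.n_actives == 0:
        raise ValueError("library contains no actives; GH validation undefined")
    hits = screen_library(query, lib.molecules, rules, settings)
    hit_ids = {h.compound_id for h in hits}
    D = len(lib.molecules)
    A = lib.n_actives
    Ht = len(hit_ids)
    Ha = sum(1 for cid in hit_ids if lib.labels[cid] == ACTIVE)
    return gh_statistics(D, A, Ht, Ha)
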