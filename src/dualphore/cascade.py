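"""Dual-target docking-score screening funnel.

Pharmacophore hits are filtered per target by a binding-energy threshold
(kcal/mol, more negative = predicted stronger binding), the per-target
survivor lists are intersected, and the intersection is ranked — by
default ascending by summed binding energy across targets, so the
compound predicted to bind both targets most strongly comes first.

Thresholds are strict (<) by default; both the comparison and the cutoff
sign convention are explicit in :class:`ThresholdRule`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import ScoreRecord


@dataclass(frozen=True)
class ThresholdRule:
    """Pass a compound iff its energy for ``target_id`` beats ``cutoff``."""

    target_id: str
    cutoff: float  # kcal/mol
    strict: bool = True  # energy < cutoff when strict, <= otherwise

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def passes(self, energy: float) -> bool:
        return energy < self.cutoff if self.strict else energy <= self.cutoff

    @classmethod
    def parse(cls, text: str) -> "ThresholdRule":
        """Parse ``TARGET:cutoff[:strict|lenient]`` (CLI rule syntax)."""
        parts = text.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"bad rule {text!r}; expected TARGET:cutoff[:strict]")
        strict = True
        if len(parts) == 3:
            if parts[2] not in ("strict", "lenient"):
                raise ValueError(f"bad rule qualifier {parts[2]!r}")
            strict = parts[2] == "strict"
        return cls(parts[0], float(parts[1]), strict)


@dataclass
class CascadeResult:
    """Per-stage survivor lists and the final ranking of the funnel."""

    stage_survivors: dict[str, list[str]]
    final_ranked: list[tuple[str, float]]

    @property
    def stage_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.stage_survivors.items()}


def apply_threshold(
    scores: Sequence[ScoreRecord], rule: ThresholdRule
) -> list[str]:
    """Compound ids whose energy for the rule's target satisfies it, input order.

    Raises if the score table carries no records for the target at all.
    """
    target_rows = [r for r in scores if r.target_id == rule.target_id]
    if not target_rows:
        raise ValueError(f"no score records for target {rule.target_id!r}")
    return [r.compound_id for r in target_rows if rule.passes(r.binding_energy)]


def run_cascade(
    hits: Sequence[str] | None,
    scores: Sequence[ScoreRecord],
    rules: Sequence[ThresholdRule],
    rank_key: str = "sum_energy",
) -> CascadeResult:
    """Run the threshold funnel and rank the multi-target intersection.

    ``hits`` restricts the funnel to an upstream (pharmacophore) hit list;
    pass ``None`` to screen every compound in the score table.  Ranking is
    ascending by summed binding energy over the rule targets
    (``sum_energy``, default) or grouped per target (``per_target``: sorted
    by the first rule's target energy, then subsequent ones).  Ties break
    lexicographically by compound id.
    """
    if not rules:
        raise ValueError("at least one threshold rule required")
    if rank_key not in ("sum_energy", "per_target"):
        raise ValueError(f"unknown rank_key {rank_key!r}")

    energy = {(r.compound_id, r.target_id): r.binding_energy for r in scores}
    stages: dict[str, list[str]] = {}
    if hits is not None:
        stages["pharmacophore_hits"] = list(hits)

    survivor_sets = []
    for rule in rules:
        survivors = apply_threshold(scores, rule)
        if hits is not None:
            hit_set = set(hits)
            survivors = [c for c in survivors if c in hit_set]
        stages[f"{rule.target_id}_threshold"] = survivors
        survivor_sets.append(set(survivors))

    inter = set.intersection(*survivor_sets) if survivor_sets else set()
    # intersection listed in first-rule survivor order for reproducibility
    ordered_inter = [c for c in stages[f"{rules[0].target_id}_threshold"] if c in inter]
    stages["intersection"] = ordered_inter

    targets = [r.target_id for r in rules]

    def sum_energy(cid: str) -> float:
        return sum(energy[(cid, t)] for t in targets if (cid, t) in energy)

    if rank_key == "sum_energy":
        ranked = sorted(ordered_inter, key=lambda c: (sum_energy(c), c))
        final = [(c, sum_energy(c)) for c in ranked]
    else:
        key = lambda c: tuple(
            energy.get((c, t), float("inf")) for t in targets
        ) + (c,)
        ranked = sorted(ordered_inter, key=key)
        final = [(c, energy[(c, targets[0])]) for c in ranked]

    return CascadeResult(stage_survivors=stages, final_ranked=final)
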