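"""Pipeline orchestration: config model, report model, and the full screen.

``run_full_screen`` chains the pharmacophore screen and the dual-target
threshold cascade and emits a versioned JSON report (stage counts,
survivor ids, ranked finals, settings echo, seed) plus a human-readable
log.  Reports contain no timestamps, so identical config + seed gives
byte-identical report files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

from .cascade import ThresholdRule, run_cascade
from .chem import SDFParseError, ScoreTableError, read_score_table, read_sdf
from .features import PerceptionRules
from .pharmacophore import MatcherSettings, PharmacophoreQuery, screen_library

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


class ConfigError(Exception):
    """Invalid or unusable pipeline configuration (missing files, bad fields)."""


class DataError(Exception):
    """Input files exist but cannot be parsed or are inconsistent."""


class MatcherConfig(BaseModel):
    mode: str = "superpose"
    rmsd_cutoff: float = 1.0
    assignment_ceiling: int = 10**6


class RuleConfig(BaseModel):
    target_id: str
    cutoff: float
    strict: bool = True


class PerceptionConfig(BaseModel):
    min_cluster_size: int = 3
    planarity_tol: float = 0.10
    ring_size_min: int = 5
    ring_size_max: int = 7


class PipelineConfig(BaseModel):
    query: str
    library: str
    scores: str
    rules: list[RuleConfig] = Field(min_length=1)
    matcher: MatcherConfig = MatcherConfig()
    perception: PerceptionConfig = PerceptionConfig()
    output_dir: str = "dualphore_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            with open(path) as fh:
                payload = yaml.safe_load(fh) or {}
            return cls.model_validate(payload)
        except (ValidationError, yaml.YAMLError) as exc:
            raise ConfigError(str(exc)) from exc


class StageReport(BaseModel):
    name: str
    count: int
    compound_ids: list[str]


class RankedCompound(BaseModel):
    compound_id: str
    score: float


class ScreeningReport(BaseModel):
    schema_version: str = REPORT_SCHEMA_VERSION
    seed: int
    settings: dict
    stages: list[StageReport]
    final_ranked: list[RankedCompound]

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n"


def report_json_schema() -> dict:
    """The JSON schema the report validates against (shipped in the package)."""
    return ScreeningReport.model_json_schema()


def run_full_screen(config: PipelineConfig) -> ScreeningReport:
    """Pharmacophore screen -> threshold cascade -> report.

    Writes ``report.json`` and ``run.log`` under ``config.output_dir`` and
    returns the report.  Missing inputs raise :class:`ConfigError`; parse
    failures raise :class:`DataError`.  An empty final intersection is a
    successful run with an empty list.
    """
    t0 = time.perf_counter()
    for attr in ("query", "library", "scores"):
        if not Path(getattr(config, attr)).exists():
            raise ConfigError(f"{attr} file not found: {getattr(config, attr)}")

    try:
        query = PharmacophoreQuery.from_json(config.query)
        mols = read_sdf(config.library)
        scores = read_score_table(config.scores)
    except (SDFParseError, ScoreTableError, ValueError, KeyError) as exc:
        raise DataError(str(exc)) from exc

    settings = MatcherSettings(
        mode=config.matcher.mode,
        rmsd_cutoff=config.matcher.rmsd_cutoff,
        assignment_ceiling=config.matcher.assignment_ceiling,
    )
    rules_obj = PerceptionRules(
        min_cluster_size=config.perception.min_cluster_size,
        planarity_tol=config.perception.planarity_tol,
        ring_size_min=config.perception.ring_size_min,
        ring_size_max=config.perception.ring_size_max,
    )
    hits = screen_library(query, mols, rules_obj, settings)
    hit_ids = [h.compound_id for h in hits]
    logger.info("pharmacophore screen: %d / %d matched", len(hit_ids), len(mols))

    thresholds = [
        ThresholdRule(r.target_id, r.cutoff, r.strict) for r in config.rules
    ]
    try:
        cascade = run_cascade(hit_ids, scores, thresholds)
    except ValueError as exc:
        raise DataError(str(exc)) from exc

    stages = [StageReport(name="library", count=len(mols), compound_ids=[m.id for m in mols])]
    for name, ids in cascade.stage_survivors.items():
        stages.append(StageReport(name=name, count=len(ids), compound_ids=list(ids)))
        logger.info("stage %s: %d survivor(s)", name, len(ids))

    report = ScreeningReport(
        seed=config.seed,
        settings=config.model_dump(),
        stages=stages,
        final_ranked=[
            RankedCompound(compound_id=c, score=s) for c, s in cascade.final_ranked
        ],
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    elapsed = time.perf_counter() - t0
    log_lines = [
        f"dualphore full screen (seed {config.seed})",
        f"library: {len(mols)} molecule(s)",
        *(f"stage {s.name}: {s.count}" for s in stages),
        f"final ranked: {len(report.final_ranked)}",
        f"wall time: {elapsed:.3f} s",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("full screen finished in %.3f s", elapsed)
    return report
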