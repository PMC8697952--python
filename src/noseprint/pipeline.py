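"""End-to-end driver: simulate -> encode -> match -> evaluate.

Convenience layer used by the CLI and the reproduction script; every
stage is just the corresponding module function, so each can also be run
(and inspected) on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .encoding import GaborBankParams, Template, encode
from .evaluation import DecisionPolicy, EvaluationReport, evaluate
from .matching import MatchResult, match_all
from .roi import DEFAULT_GRID, extract_roi, load_manifest
from .synthetic import CohortSpec, generate_cohort


def encode_manifest(
    manifest_path: str | Path,
    bank: GaborBankParams | None = None,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> list[Template]:
    """Load every manifest image, normalize its ROI and encode it."""
    bank = bank or GaborBankParams()
    return [encode(extract_roi(img, grid), bank) for img in load_manifest(manifest_path)]


@dataclass(frozen=True)
class PipelineResult:
    manifest_path: Path
    templates: list[Template]
    matches: list[MatchResult]
    report: EvaluationReport


def run_pipeline(
    spec: CohortSpec,
    work_dir: str | Path,
    bank: GaborBankParams | None = None,
    grid: tuple[int, int] = DEFAULT_GRID,
    max_shift: int = 3,
    policy: DecisionPolicy | None = None,
) -> PipelineResult:
    """Generate a synthetic cohort under ``work_dir`` and evaluate it."""
    manifest = generate_cohort(spec, Path(work_dir) / "cohort")
    templates = encode_manifest(manifest, bank, grid)
    matches = match_all(templates, max_shift=max_shift)
    report = evaluate(matches, policy or DecisionPolicy())
    return PipelineResult(
        manifest_path=manifest, templates=templates, matches=matches, report=report
    )
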