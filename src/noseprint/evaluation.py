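"""Genuine/impostor verification statistics and the threshold decision.

Given all pairwise matching distances of a cohort, this module labels
every unordered image pair genuine (same subject) or impostor (different
subjects), summarises the two distance populations (min / max / mean /
sample std), builds normalized histograms, and executes the fixed-
threshold decision rule: declare *same dog* when the distance is
strictly below the threshold (0.4 by convention), *different dogs*
otherwise.  The decision is error-free exactly when the two populations
separate — max genuine < threshold <= min impostor — which is the
headline property the pipeline is designed to verify.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matching import MatchResult

DEFAULT_THRESHOLD = 0.4
DEFAULT_BIN_WIDTH = 0.01

SAME_DOG = "same_dog"
DIFFERENT_DOGS = "different_dogs"


@dataclass(frozen=True)
class PairInventory:
    """Comparison bookkeeping for a cohort of images."""

    n_subjects: int
    images_per_subject: tuple[int, ...]
    n_images: int
    n_pairs: int
    n_genuine: int
    n_impostor: int


@dataclass(frozen=True)
class DistanceStats:
    comparison_type: str  # "genuine" | "impostor"
    min: float
    max: float
    mean: float
    std: float  # sample (n-1) standard deviation; 0 for a single value


@dataclass(frozen=True)
class DecisionPolicy:
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ParameterError("threshold must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class EvaluationReport:
    inventory: PairInventory
    stats: dict[str, DistanceStats]
    histograms: dict[str, np.ndarray]
    bin_width: float
    threshold: float
    decisions: dict[str, int]  # genuine_accepted/_rejected, impostor_accepted/_rejected
    far: float
    frr: float
    separation_margin: float  # min impostor - max genuine
    zero_error: bool
    eer: float


def enumerate_pairs(
    groups: Mapping[str, Sequence]
) -> tuple[PairInventory, list[tuple[tuple[str, int], tuple[str, int], str]]]:
    """Label every unordered image pair genuine or impostor.

    ``groups`` maps subject_id to its captures (any sequence; only the
    per-subject counts and positions matter).  Returns the inventory and
    the pair list ((subject, capture_pos), (subject, capture_pos), type).
    """
    keys = [(sid, i) for sid, caps in groups.items() for i in range(len(caps))]
    if len(keys) < 2:
        raise ParameterError("need at least 2 images to enumerate pairs")
    pairs = []
    n_genuine = 0
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            kind = "genuine" if keys[i][0] == keys[j][0] else "impostor"
            n_genuine += kind == "genuine"
            pairs.append((keys[i], keys[j], kind))
    counts = tuple(len(caps) for caps in groups.values())
    n = len(keys)
    inventory = PairInventory(
        n_subjects=len(groups),
        images_per_subject=counts,
        n_images=n,
        n_pairs=n * (n - 1) // 2,
        n_genuine=n_genuine,
        n_impostor=n * (n - 1) // 2 - n_genuine,
    )
    return inventory, pairs


def compute_stats(distances: Sequence[float], comparison_type: str) -> DistanceStats:
    """Min / max / mean / sample std (n-1 denominator) of one population."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ParameterError("cannot compute statistics of an empty distance list")
    std = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return DistanceStats(
        comparison_type=comparison_type,
        min=float(d.min()),
        max=float(d.max()),
        mean=float(d.mean()),
        std=std,
    )


def normalized_histogram(
    distances: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH
) -> np.ndarray:
    """Probability-density histogram over [0, 1]: sum(density)*bin_width = 1."""
    if not 0.0 < bin_width < 1.0:
        raise ParameterError("bin_width must lie in (0, 1)")
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ParameterError("cannot histogram an empty distance list")
    n_bins = int(math.ceil(round(1.0 / bin_width, 9)))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max(edges[-1], 1.0)  # the top bin absorbs distance == 1
    counts, _ = np.histogram(d, bins=edges)
    return counts / (d.size * bin_width)


def decide(distance: float, policy: DecisionPolicy) -> str:
    """Same-dog iff distance is strictly below the threshold."""
    return SAME_DOG if distance < policy.threshold else DIFFERENT_DOGS


def _inventory_from_results(results: Sequence[MatchResult]) -> PairInventory:
    images: dict[str, set[int]] = {}
    for r in results:
        images.setdefault(r.subject_a, set()).add(r.capture_a)
        images.setdefault(r.subject_b, set()).add(r.capture_b)
    counts = tuple(len(v) for v in images.values())
    n = sum(counts)
    n_genuine = sum(c * (c - 1) // 2 for c in counts)
    return PairInventory(
        n_subjects=len(images),
        images_per_subject=counts,
        n_images=n,
        n_pairs=n * (n - 1) // 2,
        n_genuine=n_genuine,
        n_impostor=n * (n - 1) // 2 - n_genuine,
    )


def equal_error_rate(genuine: np.ndarray, impostor: np.ndarray) -> float:
    """EER by linear interpolation of the FAR/FRR crossing over thresholds."""
    thresholds = np.unique(np.concatenate([genuine, impostor, [0.0, 1.0]]))
    far = np.array([(impostor < t).mean() for t in thresholds])
    frr = np.array([(genuine >= t).mean() for t in thresholds])
    diff = far - frr
    idx = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if diff[0] == 0:
        return float(far[0])
    if len(idx) == 0:
        return float(min(np.maximum(far, frr)))
    i = idx[0]
    t0, t1 = thresholds[i], thresholds[i + 1]
    d0, d1 = diff[i], diff[i + 1]
    t_star = t0 if d1 == d0 else t0 - d0 * (t1 - t0) / (d1 - d0)
    f0, f1 = far[i], far[i + 1]
    g0, g1 = frr[i], frr[i + 1]
    w = 0.0 if t1 == t0 else (t_star - t0) / (t1 - t0)
    return float(((f0 + (f1 - f0) * w) + (g0 + (g1 - g0) * w)) / 2.0)


def evaluate(
    results: Sequence[MatchResult],
    policy: DecisionPolicy | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> EvaluationReport:
    """Full verification report for an all-pairs distance set."""
    policy = policy or DecisionPolicy()
    genuine = np.array([r.distance for r in results if r.pair_type == "genuine"])
    impostor = np.array([r.distance for r in results if r.pair_type == "impostor"])
    if genuine.size == 0 or impostor.size == 0:
        raise ParameterError("need both genuine and impostor comparisons to evaluate")
    th = policy.threshold
    decisions = {
        "genuine_accepted": int((genuine < th).sum()),
        "genuine_rejected": int((genuine >= th).sum()),
        "impostor_accepted": int((impostor < th).sum()),
        "impostor_rejected": int((impostor >= th).sum()),
    }
    margin = float(impostor.min() - genuine.max())
    return EvaluationReport(
        inventory=_inventory_from_results(results),
        stats={
            "genuine": compute_stats(genuine, "genuine"),
            "impostor": compute_stats(impostor, "impostor"),
        },
        histograms={
            "genuine": normalized_histogram(genuine, bin_width),
            "impostor": normalized_histogram(impostor, bin_width),
        },
        bin_width=bin_width,
        threshold=th,
        decisions=decisions,
        far=decisions["impostor_accepted"] / impostor.size,
        frr=decisions["genuine_rejected"] / genuine.size,
        separation_margin=margin,
        zero_error=bool(margin > 0 and genuine.max() < th <= impostor.min()),
        eer=equal_error_rate(genuine, impostor),
    )


# ---------------------------------------------------------------------------
# serialization


def write_report(report: EvaluationReport, out_dir: str | Path) -> None:
    """Emit stats.csv, histogram_{genuine,impostor}.csv and report.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stats_rows = [
        {
            "Comparison Type": s.comparison_type,
            "Min": f"{s.min:.4f}",
            "Max": f"{s.max:.4f}",
            "Mean": f"{s.mean:.4f}",
            "Std": f"{s.std:.4f}",
        }
        for s in (report.stats["genuine"], report.stats["impostor"])
    ]
    pd.DataFrame(stats_rows).to_csv(out_dir / "stats.csv", index=False)
    for kind in ("genuine", "impostor"):
        dens = report.histograms[kind]
        edges = np.arange(len(dens) + 1) * report.bin_width
        pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bin_right": edges[1:],
                "density": dens,
            }
        ).to_csv(out_dir / f"histogram_{kind}.csv", index=False)
    payload = {
        "inventory": {
            "n_subjects": report.inventory.n_subjects,
            "n_images": report.inventory.n_images,
            "n_pairs": report.inventory.n_pairs,
            "n_genuine": report.inventory.n_genuine,
            "n_impostor": report.inventory.n_impostor,
        },
        "stats": {
            k: {
                "min": round(s.min, 4),
                "max": round(s.max, 4),
                "mean": round(s.mean, 4),
                "std": round(s.std, 4),
            }
            for k, s in report.stats.items()
        },
        "threshold": report.threshold,
        "decisions": report.decisions,
        "far": report.far,
        "frr": report.frr,
        "separation_margin": report.separation_margin,
        "zero_error": report.zero_error,
        "eer": report.eer,
    }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
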