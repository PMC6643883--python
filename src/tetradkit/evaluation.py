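"""Scoring reconstructions against simulator ground truth and the small
simulated benchmark grid."""

from __future__ import annotations

import time
from dataclasses import dataclass

import pandas as pd

from .config import ReconstructionConfig
from .genotype_io import TetradAssignment, default_centromeres
from .sim_meiosis import SimConfig, SimTruth, simulate
from .tetrad_search import run_pipeline


@dataclass
class EvalReport:
    """Agreement between an assignment and simulator truth.

    A detected group is *correct* when all of its spores share one truth
    tetrad; otherwise it is *false*.  Percentages are over the number of
    true tetrads.
    """

    n_true_tetrads: int
    correct_tetrads: int = 0
    false_tetrads: int = 0
    correct_triplets: int = 0
    false_triplets: int = 0
    correct_pairs: int = 0
    false_pairs: int = 0
    n_singles: int = 0
    runtime_seconds: float | None = None

    @property
    def detected_tetrads_pct(self) -> float:
        return 100.0 * self.correct_tetrads / self.n_true_tetrads

    @property
    def missed_tetrads(self) -> int:
        return self.n_true_tetrads - self.correct_tetrads


def score_against_truth(
    assignment: TetradAssignment, truth: SimTruth
) -> EvalReport:
    """Count correct and false tetrads, triplets and pairs."""
    unknown = [s for s in assignment.spore_ids if s not in truth.spore_to_tetrad]
    if unknown:
        raise ValueError(f"spores absent from truth: {unknown[:5]}")
    report = EvalReport(n_true_tetrads=truth.n_tetrads)
    for group in assignment.groups:
        if group.kind == "single":
            report.n_singles += 1
            continue
        tids = {truth.spore_to_tetrad[s][0] for s in group.spore_ids}
        ok = len(tids) == 1
        name = {"tetrad": "tetrads", "triplet": "triplets", "pair": "pairs"}[group.kind]
        attr = ("correct_" if ok else "false_") + name
        setattr(report, attr, getattr(report, attr) + 1)
    return report


#: per-cell settings of the small benchmark grid: noisy cells need relaxed
#: segregation cutoffs and a slightly higher similarity threshold
SMALL_GRID: list[dict] = [
    {"noise": 0.0, "missing": 0.0, "similarity_coefficient": 0.21,
     "seg_cutoff_d4": 0.9, "seg_cutoff_d3": 0.95},
    {"noise": 0.0, "missing": 0.05, "similarity_coefficient": 0.19,
     "seg_cutoff_d4": 0.9, "seg_cutoff_d3": 0.95},
    {"noise": 0.0, "missing": 0.10, "similarity_coefficient": 0.2,
     "seg_cutoff_d4": 0.9, "seg_cutoff_d3": 0.95},
    {"noise": 0.05, "missing": 0.0, "similarity_coefficient": 0.2,
     "seg_cutoff_d4": 0.75, "seg_cutoff_d3": 0.88},
    {"noise": 0.10, "missing": 0.0, "similarity_coefficient": 0.24,
     "seg_cutoff_d4": 0.6, "seg_cutoff_d3": 0.83},
]


def benchmark_small(
    seed: int, n_tetrads: int = 100, n_markers: int = 500
) -> pd.DataFrame:
    """Run simulate + reconstruct over the small benchmark grid.

    Returns one row per grid cell with the settings used, the detection
    percentage, false-positive count and runtime.
    """
    cens = default_centromeres()
    rows = []
    for i, cell in enumerate(SMALL_GRID):
        sim = SimConfig(
            n_tetrads=n_tetrads,
            n_markers=n_markers,
            noise_rate=cell["noise"],
            missing_rate=cell["missing"],
            seed=seed + i,
        )
        matrix, truth = simulate(sim)
        config = ReconstructionConfig(
            similarity_coefficient=cell["similarity_coefficient"],
            seg_cutoff_d4=cell["seg_cutoff_d4"],
            seg_cutoff_d3=cell["seg_cutoff_d3"],
            seed=seed + i,
        )
        t0 = time.perf_counter()
        assignment, _ = run_pipeline(matrix, cens, config)
        runtime = time.perf_counter() - t0
        ev = score_against_truth(assignment, truth)
        rows.append(
            {
                "n_tetrads": n_tetrads,
                "n_markers": n_markers,
                "noise_pct": 100 * cell["noise"],
                "missing_pct": 100 * cell["missing"],
                "sim_coeff": cell["similarity_coefficient"],
                "cutoff_22": cell["seg_cutoff_d4"],
                "cutoff_21": cell["seg_cutoff_d3"],
                "runtime_s": round(runtime, 1),
                "detected_tetrads_pct": ev.detected_tetrads_pct,
                "false_tetrads": ev.false_tetrads,
            }
        )
    return pd.DataFrame(rows)
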