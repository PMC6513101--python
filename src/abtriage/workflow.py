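"""End-to-end pipeline helpers tying the stages together.

The canonical workflow mirrors the experimentally guided campaign: dock
(or load) a pose ensemble, alanine-scan a mutation panel in every pose,
filter poses against the experimental phenotypes, rank the survivors by
partial-knockout consistency, and carry the winning pose into saturation
mutagenesis and panel selection.
"""

from __future__ import annotations

import pandas as pd

from .fixtures import (FixtureSpec, default_fixture_spec, make_decoy_set,
                       make_toy_complex, simulate_phenotypes,
                       split_binder_target)
from .posegen import DockedPose, realise_pose
from .scoring import EnergyParams, alanine_scan
from .structures import Complex
from .triage import consistency_filter, rank_partial_knockout

__all__ = ["build_ddE_matrix", "run_recovery", "recovery_rate"]


def build_ddE_matrix(binder: Complex, target: Complex,
                     poses: list[DockedPose], positions,
                     params: EnergyParams | None = None) -> pd.DataFrame:
    """Rigid alanine-scan ddE_binding matrix (pose x mutation, AU)."""
    rows = {}
    for pose in poses:
        pose_cx = realise_pose(binder, target, pose.transform)
        results = alanine_scan(pose_cx, positions, params, pose_id=pose.pose_id)
        rows[pose.pose_id] = {str(r.mutation): r.ddE_binding for r in results}
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.index.name = "pose_id"
    return matrix


def run_recovery(seed: int, n_decoys: int = 200,
                 spec: FixtureSpec | None = None) -> dict:
    """One planted-pose recovery experiment on a seeded fixture.

    Builds the toy complex, simulates phenotypes from the planted
    hotspots, generates the decoy ensemble, scans, filters and ranks.
    Returns a summary dict with the filter outcome and whether the true
    pose ranked first.
    """
    spec = spec or default_fixture_spec(seed, decoys=n_decoys)
    cx, truth = make_toy_complex(spec)
    binder, target = split_binder_target(cx)
    poses = make_decoy_set(truth, binder, target, n_decoys, seed)
    phenotypes = simulate_phenotypes(truth)
    positions = [(chain, str(pos)) for chain, pos, _wt in truth.panel]
    matrix = build_ddE_matrix(binder, target, poses, positions)
    passing, violations = consistency_filter(matrix, phenotypes)
    ranked = rank_partial_knockout(passing, matrix,
                                   phenotypes.reduced, phenotypes.full_knockouts) \
        if passing else []
    return {
        "true_pose_id": truth.true_pose_id,
        "n_poses": len(poses),
        "n_passing": len(passing),
        "true_pose_passed": truth.true_pose_id in passing,
        "top_ranked": ranked[0] if ranked else None,
        "recovered": bool(ranked) and ranked[0] == truth.true_pose_id,
        "matrix": matrix,
        "violations": violations,
    }


def recovery_rate(seeds, n_decoys: int = 200) -> float:
    """Fraction of seeds in which the true pose ranks first."""
    seeds = list(seeds)
    hits = sum(run_recovery(s, n_decoys)["recovered"] for s in seeds)
    return hits / len(seeds)
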