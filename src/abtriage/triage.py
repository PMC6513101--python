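"""Experimentally constrained pose triage and validation-panel design.

This is the core of the workflow: docked poses are kept or discarded by
whether their per-pose mutational (ddE) profiles are consistent with
experimental mutant phenotypes:

* every non-binding or reduced-binding mutation must have
  ddE_binding >= ``deleterious_min`` (default 0.00 AU), and
* every binding-retained mutation must have
  ddE_binding <= ``neutral_max`` (default 0.50 AU).

Among passing poses, partial-knockout mutations (reduced but not abolished
binding) are expected to sit below the full knockouts; poses are ranked by
how well they reproduce that ordering, formalised as the margin

    margin = mean over reduced mutations of
             (ddE(reduced) - min over full-knockout ddE)

with poses whose every reduced ddE lies strictly below every full-knockout
ddE ranked ahead of all others.

The module also designs the alanine validation panel (unique-interaction
positions, pose-discriminating singles, greedy max-min triples, and
near-zero negative controls) and scores interaction-loss agreement between
a pose and the deleterious mutation set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interface import InteractionGeometry, detect_interactions
from .scoring import Mutation, apply_mutation, _pos_sort_key
from .structures import Complex

__all__ = [
    "PhenotypeTable",
    "TriageCriteria",
    "Violation",
    "PanelVariant",
    "VariantPanel",
    "consistency_filter",
    "rank_partial_knockout",
    "interaction_loss_score",
    "design_validation_panel",
]

PHENOTYPE_LABELS = ("non_binding", "reduced", "retained")


@dataclass
class PhenotypeTable:
    """Experimental phenotype label per mutation (labels are inputs)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mut, label in self.entries.items():
            if label not in PHENOTYPE_LABELS:
                raise ValueError(f"unknown phenotype label {label!r} for {mut}")

    @classmethod
    def from_csv(cls, text: str) -> "PhenotypeTable":
        entries = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("mutation"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ValueError(f"phenotype line {lineno}: expected mutation,label")
            entries[parts[0]] = parts[1]
        return cls(entries)

    def to_csv(self) -> str:
        lines = ["mutation,label"]
        lines += [f"{m},{l}" for m, l in self.entries.items()]
        return "\n".join(lines) + "\n"

    @property
    def deleterious(self) -> list[str]:
        """non_binding + reduced mutations (both must score >= deleterious_min)."""
        return [m for m, l in self.entries.items() if l in ("non_binding", "reduced")]

    @property
    def full_knockouts(self) -> list[str]:
        return [m for m, l in self.entries.items() if l == "non_binding"]

    @property
    def reduced(self) -> list[str]:
        return [m for m, l in self.entries.items() if l == "reduced"]

    @property
    def retained(self) -> list[str]:
        return [m for m, l in self.entries.items() if l == "retained"]


@dataclass
class TriageCriteria:
    deleterious_min: float = 0.00
    neutral_max: float = 0.50

    def __post_init__(self) -> None:
        if not (np.isfinite(self.deleterious_min) and np.isfinite(self.neutral_max)):
            raise ValueError("criteria must be finite")


@dataclass(frozen=True)
class Violation:
    mutation: str
    value: float
    rule: str  # "deleterious>=min" or "retained<=max"


@dataclass(frozen=True)
class PanelVariant:
    mutations: tuple
    category: str  # unique | single | triple | control | design

    def __str__(self) -> str:
        return "+".join(str(m) for m in self.mutations)


@dataclass
class VariantPanel:
    variants: list[PanelVariant] = field(default_factory=list)

    def by_category(self, category: str) -> list[PanelVariant]:
        return [v for v in self.variants if v.category == category]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"variant": str(v), "category": v.category,
              "n_mutations": len(v.mutations)} for v in self.variants]
        )


# ---------------------------------------------------------------------------
# consistency filtering and ranking
# ---------------------------------------------------------------------------

def _matrix_value(ddE_matrix: pd.DataFrame, pose, mutation: str) -> float:
    try:
        v = ddE_matrix.loc[pose, mutation]
    except KeyError as exc:
        raise KeyError(f"ddE matrix misses pose {pose!r}, mutation {mutation!r}") from exc
    if pd.isna(v):
        raise KeyError(f"ddE matrix has no value for pose {pose!r}, mutation {mutation!r}")
    return float(v)


def consistency_filter(ddE_matrix: pd.DataFrame, phenotypes: PhenotypeTable,
                       criteria: TriageCriteria | None = None
                       ) -> tuple[list, dict]:
    """Filter poses by agreement between ddE profiles and phenotypes.

    ``ddE_matrix`` has one row per pose (index = pose id) and one column
    per mutation string.  Returns the passing pose ids (input order) and a
    per-pose list of :class:`Violation` (exhaustive, not short-circuited).
    """
    criteria = criteria or TriageCriteria()
    if not phenotypes.deleterious:
        raise ValueError("phenotype table needs at least one non-retained entry")
    passing, violations = [], {}
    for pose in ddE_matrix.index:
        viol = []
        for mut in phenotypes.deleterious:
            v = _matrix_value(ddE_matrix, pose, mut)
            if v < criteria.deleterious_min:
                viol.append(Violation(mut, v, "deleterious>=min"))
        for mut in phenotypes.retained:
            v = _matrix_value(ddE_matrix, pose, mut)
            if v > criteria.neutral_max:
                viol.append(Violation(mut, v, "retained<=max"))
        violations[pose] = viol
        if not viol:
            passing.append(pose)
    return passing, violations


def rank_partial_knockout(passing, ddE_matrix: pd.DataFrame,
                          reduced_mutations, full_knockout_mutations) -> list:
    """Order passing poses by partial-knockout consistency.

    A pose where every reduced-binding ddE lies strictly below every
    full-knockout ddE ranks ahead of all other poses; within each group the
    order is ascending margin (see module docstring), then pose id.  With
    an empty reduced set the input order is returned unchanged.
    """
    passing = list(passing)
    reduced = sorted(set(reduced_mutations))
    knockouts = sorted(set(full_knockout_mutations))
    if not reduced:
        return passing
    if not knockouts:
        raise ValueError("full-knockout mutation set must be non-empty")

    def key(pose):
        ko = [_matrix_value(ddE_matrix, pose, m) for m in knockouts]
        red = [_matrix_value(ddE_matrix, pose, m) for m in reduced]
        min_ko = min(ko)
        margin = float(np.mean([r - min_ko for r in red]))
        all_below = max(red) < min_ko
        return (0 if all_below else 1, margin, pose)

    return sorted(passing, key=key)


def interaction_loss_score(cx: Complex, deleterious_positions,
                           geometry: InteractionGeometry | None = None
                           ) -> tuple[int, int]:
    """How many interface interactions the deleterious set explains.

    For each deleterious antibody position, counts the cross-interface
    interactions involving it that disappear under rigid alanine
    truncation.  Returns ``(explained, total_interactions_at_positions)``;
    poses are compared on the explained count.
    """
    positions = []
    for p in deleterious_positions:
        if isinstance(p, str):
            chain, pos = p.split(":")
        else:
            chain, pos = p
        if chain not in "HL":
            raise ValueError(f"position {chain}:{pos} is not on the antibody")
        positions.append((chain, str(pos)))

    def records_at(records, label):
        return {(r.kind, r.binder_residue, r.target_residue)
                for r in records if r.binder_label == label}

    wt_records = detect_interactions(cx, geometry)
    explained = total = 0
    for chain, pos in positions:
        from .scoring import _resolve_residue  # local import to avoid cycle
        res = _resolve_residue(cx, Mutation(chain, pos, "A", "A"))
        wt_here = records_at(wt_records, res.label)
        total += len(wt_here)
        if not wt_here or res.aa1 in ("A", "G"):
            continue
        mutant = apply_mutation(cx, Mutation(chain, pos, res.aa1, "A"))
        mut_here = records_at(detect_interactions(mutant, geometry), res.label)
        explained += len(wt_here - mut_here)
    return explained, total


# ---------------------------------------------------------------------------
# validation-panel design
# ---------------------------------------------------------------------------

def design_validation_panel(scan_matrix: pd.DataFrame, profiles,
                            annotations: dict,
                            discrimination_delta: float = 0.5,
                            min_discordant_poses: int = 2,
                            control_epsilon: float = 0.05,
                            n_triples: int = 5) -> VariantPanel:
    """Design the alanine validation panel from per-pose scan profiles.

    ``scan_matrix``: poses x positions ddE_binding values (columns are
    ``"H:55"``-style position labels).  ``profiles`` is one
    :class:`~abtriage.interface.InterfaceProfile` per pose, in matrix row
    order.  ``annotations`` maps position label to a dict with keys
    ``wt_aa`` and ``annotation`` (a set of CDR/Vernier/FR tags).

    Selection rules:

    * **unique** - CDR/Vernier positions whose interactions appear in
      exactly one pose's profile;
    * **single** - CDR/Vernier positions whose ddE in some pose differs by
      at least ``discrimination_delta`` from at least
      ``min_discordant_poses`` other poses;
    * **triple** - ``n_triples`` greedy combinations of three singles
      maximising the minimum pairwise Euclidean distance between the
      pose-wise ddE-sum vectors;
    * **control** - one position per antibody chain with
      max over poses |ddE| <= ``control_epsilon``.

    Categories are emitted disjointly (unique > single > control) with
    deterministic tie-breaks by chain then position.
    """
    if len(scan_matrix.index) < 2:
        raise ValueError("panel design needs at least 2 poses")
    profiles = list(profiles)
    if len(profiles) != len(scan_matrix.index):
        raise ValueError("need one interface profile per pose")

    def eligible(label: str) -> bool:
        ann = annotations.get(label, {}).get("annotation", set())
        return any(a.startswith("CDR") or a == "Vernier" for a in ann)

    def to_mutation(label: str) -> Mutation:
        chain, pos = label.split(":")
        wt = annotations[label]["wt_aa"]
        return Mutation(chain, pos, wt, "A")

    columns = sorted(scan_matrix.columns,
                     key=lambda c: _pos_sort_key(*c.split(":")))

    unique_positions = []
    for label in columns:
        if not eligible(label):
            continue
        n_with = sum(1 for pr in profiles if pr.count_at(label) > 0)
        if n_with == 1:
            unique_positions.append(label)

    singles = []
    for label in columns:
        if not eligible(label) or label in unique_positions:
            continue
        vals = scan_matrix[label].to_numpy(dtype=float)
        for i in range(len(vals)):
            n_discordant = int(np.sum(np.abs(np.delete(vals, i) - vals[i])
                                      >= discrimination_delta))
            if n_discordant >= min_discordant_poses:
                singles.append(label)
                break

    triples: list[tuple] = []
    if len(singles) >= 3 and n_triples > 0:
        combos = list(itertools.combinations(singles, 3))
        vectors = {c: scan_matrix[list(c)].to_numpy(dtype=float).sum(axis=1)
                   for c in combos}
        spread = {c: float(np.ptp(vectors[c])) for c in combos}
        order = sorted(combos, key=lambda c: (-spread[c], c))
        selected = [order[0]]
        remaining = list(order[1:])
        while remaining and len(selected) < n_triples:
            def min_sep(c):
                return min(float(np.linalg.norm(vectors[c] - vectors[s]))
                           for s in selected)
            best_score = max(min_sep(c) for c in remaining)
            # deterministic tie-break: lexicographically smallest combo among maxima
            best = sorted(c for c in remaining
                          if abs(min_sep(c) - best_score) < 1e-12)[0]
            selected.append(best)
            remaining.remove(best)
        triples = selected

    controls = []
    taken = set(unique_positions) | set(singles)
    for chain in ("H", "L"):
        candidates = []
        for label in columns:
            if not label.startswith(chain + ":") or label in taken:
                continue
            worst = float(np.max(np.abs(scan_matrix[label].to_numpy(dtype=float))))
            if worst <= control_epsilon:
                candidates.append((worst, label))
        if candidates:
            candidates.sort(key=lambda t: (t[0], _pos_sort_key(*t[1].split(":"))))
            controls.append(candidates[0][1])
        else:
            warnings.warn(f"no qualifying control position on chain {chain}",
                          stacklevel=2)

    panel = VariantPanel()
    for label in unique_positions:
        panel.variants.append(PanelVariant((to_mutation(label),), "unique"))
    for label in singles:
        panel.variants.append(PanelVariant((to_mutation(label),), "single"))
    for combo in triples:
        panel.variants.append(
            PanelVariant(tuple(to_mutation(l) for l in combo), "triple"))
    for label in controls:
        panel.variants.append(PanelVariant((to_mutation(label),), "control"))
    return panel
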