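"""Affinity-maturation candidate filtering, consensus, pooling and panel selection.

Candidate point mutations (typically from a saturation scan over the CDR
positions, or from several scoring methods run side by side) are filtered
on stabilising binding energy and non-destabilising stability, intersected
across the two clash-accommodation modes, pooled across methods with
per-extra-occurrence duplicate counting, and reduced to a laboratory panel
under diversity constraints (at most two substitutions per position,
round-robin across methods, plus one near-zero negative control).

The default binding filter keeps mutations stabilising by at least 1 AU
(ddE_binding <= -1.0); the sign is exposed because printed filter
conventions vary while accepted candidates are invariably stabilising.
"""

from __future__ import annotations

import pandas as pd

from .scoring import Mutation
from .triage import PanelVariant, VariantPanel

__all__ = [
    "validate_candidate_table",
    "filter_candidates",
    "dual_mode_consensus",
    "pool_dedupe",
    "select_panel",
]

CANDIDATE_COLUMNS = ["mutation", "method_tag", "mode", "ddE_binding_AU",
                     "ddE_stability_AU"]


def validate_candidate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the candidate-table contract: columns and row uniqueness."""
    missing = [c for c in CANDIDATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"candidate table misses columns {missing}")
    dup = table.duplicated(subset=["mutation", "method_tag", "mode"])
    if dup.any():
        bad = table.loc[dup, ["mutation", "method_tag", "mode"]].iloc[0].tolist()
        raise ValueError(f"duplicate candidate row {bad}")
    return table


def filter_candidates(table: pd.DataFrame, binding_max: float = -1.0,
                      stability_max: float = 0.5) -> pd.DataFrame:
    """Keep rows with ddE_binding <= binding_max and ddE_stability <= stability_max."""
    validate_candidate_table(table)
    if not (pd.notna(binding_max) and pd.notna(stability_max)):
        raise ValueError("thresholds must be finite")
    keep = (table["ddE_binding_AU"] <= binding_max) \
        & (table["ddE_stability_AU"] <= stability_max)
    return table.loc[keep].reset_index(drop=True)


def _identity_key(mutation) -> tuple:
    if isinstance(mutation, Mutation):
        return mutation.identity_key
    return Mutation.parse(str(mutation)).identity_key


def dual_mode_consensus(rigid_accepted, tolerant_accepted) -> set:
    """Mutations accepted by both clash modes (keyed by chain, position, mutant)."""
    rigid = {_identity_key(m): m for m in rigid_accepted}
    tolerant = {_identity_key(m) for m in tolerant_accepted}
    return {m for k, m in rigid.items() if k in tolerant}


def pool_dedupe(method_sets) -> tuple[int, int, list]:
    """Pool tagged mutation sets across methods and deduplicate.

    ``method_sets`` is a list of ``(method_tag, mutation set)`` pairs.
    Returns ``(pooled_count, duplicate_count, unique)`` where
    ``pooled_count`` is the summed set sizes, ``duplicate_count`` counts
    each extra occurrence beyond the first, and ``unique`` is a sorted list
    of ``(mutation, [contributing method tags])``.
    """
    method_sets = list(method_sets)
    if not method_sets:
        raise ValueError("need at least one method set")
    pooled_count = sum(len(s) for _tag, s in method_sets)
    by_key: dict[tuple, tuple] = {}
    tags_for: dict[tuple, list[str]] = {}
    for tag, mutations in method_sets:
        for m in mutations:
            k = _identity_key(m)
            by_key.setdefault(k, m)
            tags = tags_for.setdefault(k, [])
            if tag not in tags:
                tags.append(tag)
    duplicate_count = pooled_count - len(by_key)
    unique = sorted(((by_key[k], tags_for[k]) for k in by_key),
                    key=lambda t: str(t[0]))
    return pooled_count, duplicate_count, unique


def select_panel(candidates: pd.DataFrame, n: int = 20,
                 max_per_position: int = 2, include_control: bool = True,
                 spread_methods: bool = True, control_epsilon: float = 0.05,
                 control_source: pd.DataFrame | None = None) -> VariantPanel:
    """Greedy diversity-constrained selection of the maturation panel.

    Candidates are taken in ascending ddE_binding order (most stabilising
    first, ties by mutation string) subject to ``max_per_position`` per
    (chain, position) and, when ``spread_methods``, round-robin across
    method tags.  When ``include_control``, one mutation whose |ddE| is at
    most ``control_epsilon`` under every method in ``control_source`` is
    appended, so the returned panel holds up to n-1 designs + 1 control.
    """
    validate_candidate_table(candidates)
    if n < 1:
        raise ValueError("n must be >= 1")

    table = candidates.copy()
    table["_mut"] = table["mutation"].map(lambda m: Mutation.parse(str(m)))
    table["_site"] = table["_mut"].map(lambda m: m.site_key)
    table = table.sort_values(["ddE_binding_AU", "mutation"], kind="mergesort")

    n_designs = n - 1 if include_control else n
    per_site: dict[tuple, int] = {}
    chosen_keys: set = set()
    chosen: list = []

    def try_take(row) -> bool:
        key = row["_mut"].identity_key
        if key in chosen_keys:
            return False
        if per_site.get(row["_site"], 0) >= max_per_position:
            return False
        chosen_keys.add(key)
        per_site[row["_site"]] = per_site.get(row["_site"], 0) + 1
        chosen.append(row["_mut"])
        return True

    if spread_methods:
        tags = sorted(table["method_tag"].unique())
        queues = {t: list(table.loc[table["method_tag"] == t].itertuples(index=False))
                  for t in tags}
        queues = {t: [dict(zip(table.columns, row)) for row in q]
                  for t, q in queues.items()}
        progress = True
        while len(chosen) < n_designs and progress:
            progress = False
            for tag in tags:
                if len(chosen) >= n_designs:
                    break
                q = queues[tag]
                while q:
                    row = q.pop(0)
                    if try_take(row):
                        progress = True
                        break
    else:
        for row in table.to_dict("records"):
            if len(chosen) >= n_designs:
                break
            try_take(row)

    panel = VariantPanel([PanelVariant((m,), "design") for m in chosen])

    if include_control:
        source = control_source if control_source is not None else candidates
        validate_candidate_table(source)
        grouped = source.groupby("mutation")
        all_tags = set(source["method_tag"].unique())
        best = None
        for mut, grp in grouped:
            if set(grp["method_tag"]) != all_tags:
                continue
            worst = float(grp["ddE_binding_AU"].abs().max())
            if worst <= control_epsilon and _identity_key(mut) not in chosen_keys:
                cand = (worst, str(mut))
                if best is None or cand < best:
                    best = cand
        if best is None:
            raise ValueError(
                "infeasible constraints: no control mutation with "
                f"|ddE_binding| <= {control_epsilon} AU under every method"
            )
        panel.variants.append(
            PanelVariant((Mutation.parse(best[1]),), "control"))
    return panel
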