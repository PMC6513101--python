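"""Bundled worked-example data.

A published anti-chemokine antibody redocking study reported relative
ddE_binding values (AU, IMGT numbering, destabilising positive) for a
10-mutation alanine panel across five candidate docked poses, together
with the experimental phenotype of each mutation (capture-ELISA binding).
The panel is the canonical worked example for the consistency filter: none
of the five original poses satisfies the phenotype-consistency rules,
which is what motivated redocking in that workflow.
"""

from __future__ import annotations

import pandas as pd

from .triage import PhenotypeTable

__all__ = ["redock_panel_ddE", "redock_panel_phenotypes"]

_POSES = [1904, 1704, 1843, 1334, 1644]

_DDE = {
    "H:Y55A":  [2.93, 1.12, 0.39, 0.34, -0.07],
    "H:N107A": [0.32, 0.39, 0.23, 0.25, 0.73],
    "H:N113A": [0.14, 0.18, 0.56, 0.55, 0.39],
    "L:D34A":  [2.32, 1.54, 2.16, 1.68, 1.04],
    "L:K36A":  [-0.17, -0.29, -0.55, -0.25, -1.01],
    "L:Y38A":  [1.90, 1.92, 2.30, 2.13, 0.92],
    "H:R66A":  [0.67, 0.17, 0.18, 0.23, 0.31],
    "H:T110A": [0.97, 1.49, 1.39, 1.11, 0.38],
    "L:Y31A":  [3.55, 4.04, 1.06, 0.46, 0.08],
    "L:R116A": [0.43, 0.63, 0.68, 0.67, 1.48],
}

_PHENOTYPES = {
    "H:Y55A": "non_binding",
    "H:N107A": "non_binding",
    "H:N113A": "non_binding",
    "L:D34A": "non_binding",
    "L:K36A": "reduced",        # threefold weaker binding, not abolished
    "L:Y38A": "non_binding",
    "H:R66A": "retained",
    "H:T110A": "retained",
    "L:Y31A": "retained",
    "L:R116A": "retained",
}


def redock_panel_ddE() -> pd.DataFrame:
    """ddE_binding matrix (pose x mutation, AU) for the worked example."""
    return pd.DataFrame(_DDE, index=pd.Index(_POSES, name="pose_id"))


def redock_panel_phenotypes() -> PhenotypeTable:
    """Experimental phenotype labels for the 10-mutation panel."""
    return PhenotypeTable(dict(_PHENOTYPES))
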