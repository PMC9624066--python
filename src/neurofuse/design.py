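"""Experimental design: the 5 x 5 x 5 condition vocabulary.

The study design crosses 5 object categories with 5 exemplar identities and
5 viewing conditions (size/rotation variations), giving 125 conditions. Each
condition is shown repeatedly; fMRI-style acquisitions additionally split
repetitions over runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical category order (alphabetical; fixed everywhere).
CATEGORIES = ("animal", "chair", "face", "fruit", "vehicle")

#: Viewing conditions: v1 = 3deg size / 0deg rotation (the canonical view),
#: v2 = 3deg/45deg, v3 = 3deg/90deg (rotation variants),
#: v4 = 1.5deg/0deg, v5 = 6deg/0deg (scale variants).
VARIATIONS = ("v1", "v2", "v3", "v4", "v5")

VARIATION_DESCRIPTIONS = {
    "v1": "3deg visual angle, 0deg depth rotation",
    "v2": "3deg visual angle, 45deg depth rotation",
    "v3": "3deg visual angle, 90deg depth rotation",
    "v4": "1.5deg visual angle, 0deg depth rotation",
    "v5": "6deg visual angle, 0deg depth rotation",
}

#: Regions of interest shared by the ECoG electrode labelling and the fMRI
#: pattern sets: occipital-inferior, fusiform, lingual, parahippocampal,
#: inferior temporal and temporal pole.
ROIS = ("O-Inf", "T-LFus", "T-MLing", "T-MTPhip", "T-IT", "T-Pole")

LABEL_COLUMNS = ("condition_id", "category", "identity", "variation", "repetition", "run")


def condition_vocabulary(
    n_categories: int = 5, n_identities: int = 5, n_variations: int = 5
) -> pd.DataFrame:
    """Return the canonical condition table: one row per condition.

    Rows are ordered by (category, identity, variation) with categories in
    alphabetical order; ``condition_id`` runs 1..K in that order. This
    ordering is the contract every RDM in the package indexes by.
    """
    if not (1 <= n_categories <= len(CATEGORIES)):
        raise ValueError(f"n_categories must be in 1..{len(CATEGORIES)}")
    if not (1 <= n_variations <= len(VARIATIONS)):
        raise ValueError(f"n_variations must be in 1..{len(VARIATIONS)}")
    if n_identities < 1:
        raise ValueError("n_identities must be >= 1")
    rows = []
    cid = 1
    for cat in CATEGORIES[:n_categories]:
        for ident in range(1, n_identities + 1):
            for var in VARIATIONS[:n_variations]:
                rows.append((cid, cat, ident, var))
                cid += 1
    return pd.DataFrame(rows, columns=["condition_id", "category", "identity", "variation"])


def make_design(
    n_categories: int = 5,
    n_identities: int = 5,
    n_variations: int = 5,
    n_repetitions: int = 32,
    n_runs: int | None = None,
) -> pd.DataFrame:
    """Build the trial-level condition table.

    One row per (category, identity, variation, repetition). If ``n_runs``
    is given, repetitions are distributed evenly over runs (``n_repetitions``
    must then be divisible by ``n_runs``); otherwise the ``run`` column is
    left as NA.

    Under the full design (5, 5, 5, 32 repetitions) this yields 4000 rows,
    125 distinct conditions and 800 rows per category.
    """
    for name, val in (
        ("n_categories", n_categories),
        ("n_identities", n_identities),
        ("n_variations", n_variations),
        ("n_repetitions", n_repetitions),
    ):
        if int(val) != val or val < 1:
            raise ValueError(f"{name} must be a positive integer, got {val!r}")
    if n_runs is not None:
        if int(n_runs) != n_runs or n_runs < 1:
            raise ValueError(f"n_runs must be a positive integer, got {n_runs!r}")
        if n_repetitions % n_runs:
            raise ValueError(
                f"n_repetitions={n_repetitions} not divisible by n_runs={n_runs}"
            )
    vocab = condition_vocabulary(n_categories, n_identities, n_variations)
    reps = np.arange(1, n_repetitions + 1)
    table = vocab.loc[vocab.index.repeat(n_repetitions)].reset_index(drop=True)
    table["repetition"] = np.tile(reps, len(vocab))
    if n_runs is None:
        table["run"] = pd.array([pd.NA] * len(table), dtype="Int64")
    else:
        per_run = n_repetitions // n_runs
        table["run"] = ((table["repetition"] - 1) // per_run + 1).astype("Int64")
    return table[list(LABEL_COLUMNS)]


def validate_labels(labels: pd.DataFrame) -> None:
    """Check the trial-table invariants; raise ``ValueError`` on violation."""
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise ValueError(f"label table missing columns: {missing}")
    triples = labels[["category", "identity", "variation"]].drop_duplicates()
    ids = labels[["condition_id", "category", "identity", "variation"]].drop_duplicates()
    if len(ids) != len(triples) or labels["condition_id"].nunique() != len(triples):
        raise ValueError("condition_id does not biject onto (category, identity, variation)")
    counts = labels.groupby("condition_id").size()
    if counts.nunique() != 1:
        raise ValueError("unequal repetition counts across conditions")


def condition_order(labels: pd.DataFrame) -> np.ndarray:
    """Sorted unique condition ids — the canonical RDM row/column order."""
    return np.sort(labels["condition_id"].unique())
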