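"""3-state secondary-structure classes and per-class partitioning.

The eight DSSP-style states collapse to three classes under the usual
convention: H, G, I -> helix; E, B -> sheet; T, S, C -> coil.  Each class
trains and predicts with its own set of models; routing at inference uses the
*predicted* 8-state string, while evaluation may stratify by the actual one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import SS8_ALPHABET, FeatureMatrix
from .geometry import AngleTable

__all__ = [
    "SS3_CLASSES",
    "DEFAULT_SS3_MAP",
    "map_ss8_to_ss3",
    "partition_by_ss",
    "class_distribution",
]

SS3_CLASSES = ("helix", "sheet", "coil")

DEFAULT_SS3_MAP = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "sheet", "B": "sheet",
    "T": "coil", "S": "coil", "C": "coil",
}


def map_ss8_to_ss3(state: str, mapping: dict[str, str] | None = None) -> str:
    """Collapse one 8-state character to its 3-state class."""
    mapping = mapping or DEFAULT_SS3_MAP
    try:
        return mapping[state]
    except KeyError:
        raise ValueError(
            f"unknown SS8 state {state!r}; expected one of {SS8_ALPHABET!r}"
        ) from None


def partition_by_ss(
    matrix: FeatureMatrix, angles: AngleTable
) -> dict[str, tuple[FeatureMatrix, AngleTable]]:
    """Split aligned feature rows and angle rows into the three SS3 classes.

    The split is a bijection on rows: the three subsets are disjoint and their
    sizes sum to the input row count, with within-subset alignment preserved.
    """
    if len(matrix) != len(angles):
        raise ValueError(
            f"misaligned inputs: {len(matrix)} feature rows vs {len(angles)} angle rows"
        )
    out = {}
    for cls in SS3_CLASSES:
        idx = np.flatnonzero(matrix.ss3 == cls)
        out[cls] = (matrix.take(idx), angles.take(idx))
    return out


def class_distribution(labels_by_split: dict[str, np.ndarray]) -> pd.DataFrame:
    """Residue counts and percentages per SS3 class for each data split.

    ``labels_by_split`` maps a split name (e.g. "training") to a per-residue
    array of 3-state labels.  The layout mirrors a per-split distribution
    table: one row per class, count and percent columns per split.
    """
    data = {}
    for split, labels in labels_by_split.items():
        labels = np.asarray(labels)
        total = max(len(labels), 1)
        data[(split, "residues")] = [int((labels == c).sum()) for c in SS3_CLASSES]
        data[(split, "percent")] = [
            round(100.0 * (labels == c).sum() / total, 2) for c in SS3_CLASSES
        ]
    df = pd.DataFrame(data, index=list(SS3_CLASSES))
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df
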