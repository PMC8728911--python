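"""Accuracy metrics and report tables for predicted backbone angles.

All errors use the periodic absolute error AE = min(D, |360 - D|), D = |P - A|,
so that e.g. a prediction of 179 for an actual -179 counts 2 degrees, not 358.
Reports cover: overall and SS-stratified MAE, Spearman rank correlations,
relative improvement over competing methods, relative Delta% per method,
threshold-coverage curves (fraction of proteins with at least x% of angles
within 6 or 12 degrees), and MAE grouped by protein length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import ANGLE_NAMES, AngleTable

__all__ = [
    "absolute_error",
    "mae",
    "improvement",
    "delta_percent",
    "spearman_rho",
    "threshold_coverage",
    "length_group_report",
    "ss_stratified_report",
    "LENGTH_BINS",
]

#: protein-length bins for grouped reports (inclusive bounds)
LENGTH_BINS = ((1, 100), (101, 200), (201, 300), (301, 400), (401, 500), (501, 800))


def absolute_error(predicted, actual):
    """Periodic absolute error in degrees, in [0, 180]. Vectorized.

    The difference is reduced mod 360 first, so the error is well defined for
    arguments outside (-180, 180] as well.
    """
    d = np.mod(np.abs(np.asarray(predicted, float) - np.asarray(actual, float)), 360.0)
    ae = np.minimum(d, np.abs(360.0 - d))
    if ae.ndim == 0:
        return float(ae)
    return ae


def _paired_errors(pred: AngleTable, actual: AngleTable, angle: str, mask=None):
    if len(pred) != len(actual):
        raise ValueError("prediction and reference tables are not aligned")
    p = pred.angle(angle)
    a = actual.angle(angle)
    keep = np.isfinite(p) & np.isfinite(a)
    if mask is not None:
        keep &= np.asarray(mask, bool)
    return absolute_error(p[keep], a[keep])


def mae(
    pred: AngleTable, actual: AngleTable, angle: str, mask=None
) -> tuple[float, int]:
    """Mean periodic AE over residues defined in both tables (and in ``mask``).

    Returns (mae, count); an empty stratum yields (nan, 0) so callers can
    report it as absent rather than zero.
    """
    ae = _paired_errors(pred, actual, angle, mask)
    if len(ae) == 0:
        return float("nan"), 0
    return float(ae.mean()), int(len(ae))


def improvement(ours: float, others: list[float]) -> float:
    """Relative improvement (%) of our MAE over the best competing MAE.

    If ours is the best: (second_best - ours)/ours * 100 (positive).
    Otherwise: (best - ours)/ours * 100 (negative, a degradation).
    """
    if len(others) == 0:
        raise ValueError("need at least one competing MAE")
    if ours <= 0 or any(o <= 0 for o in others):
        raise ValueError("MAE values must be positive")
    best_other = min(others)
    return (best_other - ours) / ours * 100.0


def delta_percent(method: float, reference: float) -> float:
    """(method MAE - reference MAE) / reference MAE * 100."""
    if reference <= 0:
        raise ValueError("reference MAE must be positive")
    return (method - reference) / reference * 100.0


def spearman_rho(pred, actual) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if degenerate."""
    p = np.asarray(pred, float)
    a = np.asarray(actual, float)
    keep = np.isfinite(p) & np.isfinite(a)
    p, a = p[keep], a[keep]
    if len(p) < 2 or np.ptp(p) == 0 or np.ptp(a) == 0:
        return float("nan")
    return float(sps.spearmanr(p, a).statistic)


def threshold_coverage(
    per_protein_ae: list[np.ndarray],
    thresholds: tuple[float, ...] = (6.0, 12.0),
    step: int = 10,
) -> pd.DataFrame:
    """Percentage of proteins having at least x% of their angles within a threshold.

    ``per_protein_ae`` holds one array of periodic AEs (defined residues only)
    per protein.  For each threshold t and each x on the 0..100 grid, y is the
    percentage of proteins for which the fraction of angles with AE <= t is at
    least x%.  Curves are non-increasing in x.
    """
    if len(per_protein_ae) == 0:
        raise ValueError("empty protein set")
    grid = np.arange(0, 101, step)
    rows = []
    for t in thresholds:
        fracs = np.array(
            [100.0 * np.mean(ae <= t) if len(ae) else 0.0 for ae in per_protein_ae]
        )
        for x in grid:
            y = 100.0 * np.mean(fracs >= x)
            rows.append({"threshold": t, "pct_angles": int(x), "pct_proteins": y})
    return pd.DataFrame(rows)


def length_group_report(
    proteins: list[tuple[AngleTable, AngleTable]],
    bins: tuple[tuple[int, int], ...] = LENGTH_BINS,
    angles: tuple[str, ...] = ANGLE_NAMES,
) -> pd.DataFrame:
    """Per-length-bin protein counts and per-angle MAE.

    ``proteins`` pairs each protein's (predicted, actual) angle tables.
    Proteins longer than the last bin fall into an overflow bin.
    """
    labels = [f"{lo:03d}-{hi:03d}" for lo, hi in bins]
    rows = []
    edges = list(bins) + [(bins[-1][1] + 1, 10**9)]
    lab_all = labels + [f">{bins[-1][1]:03d}"]
    for (lo, hi), label in zip(edges, lab_all):
        members = [(p, a) for p, a in proteins if lo <= len(a) <= hi]
        row = {"length_group": label, "count": len(members)}
        for ang in angles:
            if members:
                ae = np.concatenate(
                    [_paired_errors(p, a, ang) for p, a in members]
                )
                row[f"mae_{ang}"] = float(ae.mean()) if len(ae) else float("nan")
            else:
                row[f"mae_{ang}"] = float("nan")
        if label.startswith(">") and len(members) == 0:
            continue  # omit an empty overflow bin
        rows.append(row)
    overall = {"length_group": "overall", "count": len(proteins)}
    for ang in angles:
        ae = np.concatenate([_paired_errors(p, a, ang) for p, a in proteins])
        overall[f"mae_{ang}"] = float(ae.mean()) if len(ae) else float("nan")
    rows.append(overall)
    return pd.DataFrame(rows)


def ss_stratified_report(
    pred: AngleTable,
    actual: AngleTable,
    ss3_actual: np.ndarray,
    angles: tuple[str, ...] = ANGLE_NAMES,
) -> pd.DataFrame:
    """MAE and counts per 3-state class of the *actual* secondary structure.

    Routing at inference uses predicted classes, but accuracy tables are
    stratified by the actual (DSSP-derived) class labels.
    """
    ss3_actual = np.asarray(ss3_actual)
    if len(ss3_actual) != len(pred):
        raise ValueError("SS3 label track not aligned with angle tables")
    rows = []
    for cls_name in ("helix", "sheet", "coil", "all"):
        mask = None if cls_name == "all" else (ss3_actual == cls_name)
        row = {"ss3": cls_name}
        for ang in angles:
            m, n = mae(pred, actual, ang, mask)
            row[f"mae_{ang}"] = m
            row[f"n_{ang}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
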