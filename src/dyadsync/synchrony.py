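"""Dyadic RSA synchrony: lag-0 cross-correlation of first-differenced RSA,
Fisher-transformed, with dyad-level outlier screening."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DiffSeries


@dataclass
class SynchronyEstimate:
    dyad_id: str
    r: Optional[float]
    z: Optional[float]
    n_pairs: int
    lag_s: int = 0
    missing: bool = False
    reason: Optional[str] = None


def fisher_z(r: float) -> float:
    """z = atanh(r) = 0.5 * ln((1+r)/(1-r)); requires |r| < 1."""
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def rsa_synchrony(
    parent_diff: DiffSeries,
    child_diff: DiffSeries,
    lag_s: int = 0,
    min_overlap: int = 30,
    dyad_id: str = "",
) -> SynchronyEstimate:
    """Pearson correlation over seconds where both (child t, parent t+lag)
    are valid, Fisher-transformed.

    Missing (never an exception) when overlap < ``min_overlap``, either series
    is constant on the overlap, or |r| = 1 exactly (infinite z cannot feed the
    downstream regression).
    """
    if parent_diff.task_length_s != child_diff.task_length_s:
        raise ValueError(
            f"task clock mismatch: parent {parent_diff.task_length_s} vs "
            f"child {child_diff.task_length_s}"
        )
    n = child_diff.task_length_s
    t = np.arange(n)
    tp = t + lag_s
    ok_t = (tp >= 0) & (tp < n)
    child_idx = t[ok_t]
    parent_idx = tp[ok_t]
    both = child_diff.valid[child_idx] & parent_diff.valid[parent_idx]
    x = child_diff.values[child_idx[both]]
    y = parent_diff.values[parent_idx[both]]
    n_pairs = len(x)

    if n_pairs < min_overlap:
        return SynchronyEstimate(dyad_id, None, None, n_pairs, lag_s, True,
                                 "insufficient overlap")
    if np.std(x) == 0 or np.std(y) == 0:
        return SynchronyEstimate(dyad_id, None, None, n_pairs, lag_s, True,
                                 "constant reactivity")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        return SynchronyEstimate(dyad_id, None, None, n_pairs, lag_s, True,
                                 "degenerate r=±1")
    return SynchronyEstimate(dyad_id, r, fisher_z(r), n_pairs, lag_s)


def flag_outlier_dyads(
    estimates: Sequence[SynchronyEstimate],
    threshold_sd: float = 3.92,
) -> tuple[list[SynchronyEstimate], list[SynchronyEstimate]]:
    """Split estimates into (retained, excluded) by the |z - mean| >
    threshold_sd * sd rule, computed over non-missing z values."""
    usable = [e for e in estimates if not e.missing]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 non-missing estimates, got {len(usable)}")
    if not np.isfinite(threshold_sd):
        return list(estimates), []
    zs = np.array([e.z for e in usable])
    mean = zs.mean()
    sd = zs.std(ddof=1)
    retained: list[SynchronyEstimate] = []
    excluded: list[SynchronyEstimate] = []
    for e in estimates:
        if not e.missing and sd > 0 and abs(e.z - mean) > threshold_sd * sd:
            excluded.append(e)
        else:
            retained.append(e)
    return retained, excluded


def synchrony_table(
    estimates: Sequence[SynchronyEstimate],
    excluded: Sequence[SynchronyEstimate] = (),
) -> pd.DataFrame:
    """Tidy dyad-level synchrony table (dyad_id, r, z, n_pairs,
    excluded_flag, reason)."""
    excluded_ids = {e.dyad_id for e in excluded}
    rows = []
    for e in estimates:
        rows.append({
            "dyad_id": e.dyad_id,
            "r": e.r if e.r is not None else np.nan,
            "z": e.z if e.z is not None else np.nan,
            "n_pairs": e.n_pairs,
            "lag_s": e.lag_s,
            "excluded_flag": int(e.dyad_id in excluded_ids),
            "reason": e.reason if e.reason else ("outlier" if e.dyad_id in excluded_ids else ""),
        })
    return pd.DataFrame(rows)
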