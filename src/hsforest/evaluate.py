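"""Evaluation criteria for decoy-selection methods against known natives.

Two standard summaries are provided.  Criterion-1: for each decoy set, the
percentage of decoys whose distance to the native is strictly greater than
the selected decoy's, averaged over sets — "how much of the set did the
pick outperform".  Criterion-2: across sets, how often a method's pick is
strictly closer to the native than the pick of the energy function alone.
Ties count for neither method in either criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import DecoySet
from .metrics import ca_rmsd_many


@dataclass
class EvalRecord:
    """Per-set outcome of one selection run."""

    set_id: str
    selected_id: str
    dist_to_native: float
    baseline_id: Optional[str] = None
    baseline_dist: Optional[float] = None

    def __post_init__(self):
        if self.dist_to_native < 0:
            raise ValueError("distances must be >= 0")


def distances_to_native(decoy_set: DecoySet) -> np.ndarray:
    """Cα RMSD of every decoy to the set's native (evaluation only; these
    evaluations are outside the selection's distance budget)."""
    if decoy_set.native is None:
        raise ValueError("decoy set has no native structure")
    return ca_rmsd_many(decoy_set.native.coords, decoy_set.coords_array())


def criterion1(records: Sequence[EvalRecord], sets: Mapping[str, DecoySet]) -> float:
    """Mean over sets of the percentage of decoys strictly farther from the
    native than the selected decoy (denominator = full set size N)."""
    if not records:
        raise ValueError("no records")
    scores = []
    for rec in records:
        dset = sets[rec.set_id]
        d = distances_to_native(dset)
        outperformed = int(np.sum(d > rec.dist_to_native))
        scores.append(100.0 * outperformed / dset.n)
    return float(np.mean(scores))


def criterion2(records: Sequence[EvalRecord]) -> int:
    """Number of sets where the selection is strictly closer to the native
    than the baseline's selection."""
    if not records:
        raise ValueError("no records")
    count = 0
    for rec in records:
        if rec.baseline_dist is None:
            raise ValueError(f"record {rec.set_id} has no baseline")
        if rec.dist_to_native < rec.baseline_dist:
            count += 1
    return count


def criterion2_over_runs(counts: Sequence[float]) -> tuple[float, float]:
    """Mean ± sample std of Criterion-2 counts across stochastic runs."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 1:
        raise ValueError("no runs")
    std = float(np.std(counts, ddof=1)) if counts.size > 1 else 0.0
    return float(np.mean(counts)), std


def run_std(dists: Sequence[float]) -> float:
    """Sample standard deviation of a method's distance-to-native across
    repeated runs on one decoy set."""
    dists = np.asarray(dists, dtype=float)
    if dists.size < 2:
        raise ValueError("need at least 2 runs")
    return float(np.std(dists, ddof=1))


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample (unpaired, equal-variance) t-test helper for comparing
    per-set scores of two methods; returns (statistic, p-value)."""
    from scipy import stats

    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def records_table(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Tidy per-set table (one row per set) for reporting."""
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in records],
            "selected": [r.selected_id for r in records],
            "rmsd_to_native": [r.dist_to_native for r in records],
            "baseline": [r.baseline_id for r in records],
            "baseline_rmsd": [r.baseline_dist for r in records],
        }
    )
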