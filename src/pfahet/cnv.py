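"""Arm-level copy-number calls from log2 ratios and dense/sparse enrichment testing.

Methylation-array copy-number profiles give one log2 ratio per chromosome arm
and sample.  An arm is called gained at log2 >= +0.25 and lost at <= -0.25
(boundaries inclusive, so the stated cutoff itself triggers a call).  For a
cohort with one cell-dense and one cell-sparse sample per case, the paired
2x2 table (area type x aberration present/absent) is tested for enrichment
with a two-sided Fisher exact test, implemented here by direct hypergeometric
enumeration in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ArmCall",
    "call_arm",
    "call_arms_table",
    "aggregate_segments",
    "paired_table",
    "fisher_exact_two_sided",
    "novel_at_relapse",
]

GAIN_CUTOFF = 0.25
LOSS_CUTOFF = -0.25

# relative tolerance when comparing point probabilities in the two-sided sum
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ArmCall:
    case_id: str
    area_label: str
    arm: str
    status: str  # "gain" | "loss" | "balanced"


def call_arm(
    log2_ratio: float,
    gain_cutoff: float = GAIN_CUTOFF,
    loss_cutoff: float = LOSS_CUTOFF,
) -> str:
    """Call one arm: gain iff log2 >= gain_cutoff, loss iff <= loss_cutoff."""
    if not loss_cutoff < gain_cutoff:
        raise ValueError("loss_cutoff must be below gain_cutoff")
    if not np.isfinite(log2_ratio):
        raise ValueError(f"non-finite log2 ratio: {log2_ratio}")
    if log2_ratio >= gain_cutoff:
        return "gain"
    if log2_ratio <= loss_cutoff:
        return "loss"
    return "balanced"


def aggregate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-segment log2 ratios to one value per (case, area, arm).

    ``segments`` columns: case_id, area_label, arm, start, end, log2_ratio
    (1-based inclusive coordinates).  The arm value is the length-weighted
    mean of its segments.
    """
    seg = segments.copy()
    seg["_len"] = seg["end"] - seg["start"] + 1
    if (seg["_len"] <= 0).any():
        raise ValueError("segment with non-positive length")

    def _wmean(g: pd.DataFrame) -> float:
        return float(np.average(g["log2_ratio"], weights=g["_len"]))

    out = (
        seg.groupby(["case_id", "area_label", "arm"], sort=True)
        .apply(_wmean, include_groups=False)
        .rename("log2_ratio")
        .reset_index()
    )
    return out


def call_arms_table(
    profiles: pd.DataFrame,
    gain_cutoff: float = GAIN_CUTOFF,
    loss_cutoff: float = LOSS_CUTOFF,
) -> pd.DataFrame:
    """Vectorized arm calls for a table with columns case_id, area_label, arm, log2_ratio."""
    out = profiles.copy()
    lr = out["log2_ratio"].to_numpy(dtype=float)
    if not np.all(np.isfinite(lr)):
        raise ValueError("non-finite log2 ratios in profile table")
    status = np.where(lr >= gain_cutoff, "gain", np.where(lr <= loss_cutoff, "loss", "balanced"))
    out["status"] = status
    return out


def paired_table(calls: pd.DataFrame, arm: str, aberration_status: str | None = None) -> np.ndarray:
    """Build the 2x2 dense/sparse x aberrant/not contingency table for one arm.

    Rows are (dense, sparse); columns are (aberrant, not aberrant).  Each case
    must contribute exactly one dense and one sparse call for the arm.  The
    relevant aberration defaults to "gain" for 1q and "loss" for 6q.
    """
    if aberration_status is None:
        aberration_status = {"1q": "gain", "6q": "loss"}.get(arm, "gain")
    sub = calls[calls["arm"] == arm]
    bad = []
    for case_id, grp in sub.groupby("case_id"):
        labels = sorted(grp["area_label"])
        if labels != ["dense", "sparse"]:
            bad.append(case_id)
    if bad:
        raise ValueError(f"cases without exactly one dense and one sparse call for {arm}: {bad}")
    if sub.empty:
        raise ValueError(f"no calls for arm {arm}")
    table = np.zeros((2, 2), dtype=int)
    for i, area in enumerate(("dense", "sparse")):
        grp = sub[sub["area_label"] == area]
        n_ab = int((grp["status"] == aberration_status).sum())
        table[i, 0] = n_ab
        table[i, 1] = len(grp) - n_ab
    return table


def _log_hypergeom_pmf(k: np.ndarray, n_row1: int, n_col1: int, n_total: int) -> np.ndarray:
    """log P(X = k) for the table [[k, r-k],[c-k, N-r-c+k]] with fixed margins."""
    r, c, n = n_row1, n_col1, n_total
    return (
        gammaln(r + 1)
        - gammaln(k + 1)
        - gammaln(r - k + 1)
        + gammaln(n - r + 1)
        - gammaln(c - k + 1)
        - gammaln(n - r - c + k + 1)
        - (gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1))
    )


def fisher_exact_two_sided(table: np.ndarray | list) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integer counts.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed that of the observed
    table (point-probability method, with relative tolerance 1e-7 on the
    comparison).  A table that is degenerate in both rows or both columns
    (a zero margin) has only one admissible configuration, so p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r = a + b
    col1 = a + c
    if n == 0 or r == 0 or r == n or col1 == 0 or col1 == n:
        return 1.0
    k_min = max(0, r + col1 - n)
    k_max = min(r, col1)
    ks = np.arange(k_min, k_max + 1)
    logp = _log_hypergeom_pmf(ks, r, col1, n)
    logp_obs = logp[a - k_min]
    # stabilize: normalize in log space, sum admissible tables
    keep = logp <= logp_obs + np.log1p(_REL_TOL)
    m = logp.max()
    p = float(np.exp(logp[keep] - m).sum() / np.exp(logp - m).sum())
    return min(p, 1.0)


def novel_at_relapse(primary: pd.DataFrame, relapse: pd.DataFrame) -> pd.DataFrame:
    """Flag cases whose relapse carries a 1q gain or 6q loss absent in the primary.

    ``primary`` and ``relapse`` are call tables (case_id, arm, status) with the
    1q and 6q rows per case.  Returns one row per case with a ``novel`` flag;
    the cohort count is ``out["novel"].sum()``.
    """

    def _aberrations(calls: pd.DataFrame, case_id: str) -> set[tuple[str, str]]:
        grp = calls[calls["case_id"] == case_id]
        ab = set()
        for _, row in grp.iterrows():
            if row["arm"] == "1q" and row["status"] == "gain":
                ab.add(("1q", "gain"))
            if row["arm"] == "6q" and row["status"] == "loss":
                ab.add(("6q", "loss"))
        return ab

    cases_p = set(primary["case_id"])
    cases_r = set(relapse["case_id"])
    if cases_p != cases_r:
        raise ValueError(
            f"unpaired cases: primary-only {sorted(cases_p - cases_r)}, "
            f"relapse-only {sorted(cases_r - cases_p)}"
        )
    rows = []
    for case_id in sorted(cases_p):
        novel = bool(_aberrations(relapse, case_id) - _aberrations(primary, case_id))
        rows.append({"case_id": case_id, "novel": novel})
    return pd.DataFrame(rows)
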