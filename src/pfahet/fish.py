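"""Per-nucleus FISH scoring for chromosome 1q gain and 6q loss, and area-level calls.

Dual-colour interphase FISH counts a test-locus probe (1q25.3 for the gain,
6q25.1 for the loss) against a control probe in each of typically 100
non-overlapping intact nuclei per tumor area.  A nucleus is scored aberrant
by the count of test signals or by the test/control ratio; the whole area is
called aberrant when at least ``min_fraction`` (default 10%) of scored nuclei
are aberrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FishNucleus",
    "FishAreaResult",
    "score_nucleus_1q",
    "score_nucleus_6q",
    "call_area",
    "call_areas_table",
]

ABERRATIONS = ("gain_1q", "loss_6q")


@dataclass(frozen=True)
class FishNucleus:
    """Signal counts for one nucleus: test-locus probe vs control probe."""

    test_count: int
    control_count: int

    def __post_init__(self) -> None:
        if self.test_count < 0 or self.control_count < 0:
            raise ValueError("FISH signal counts must be non-negative")
        if self.test_count != int(self.test_count) or self.control_count != int(
            self.control_count
        ):
            raise ValueError("FISH signal counts must be integers")


@dataclass(frozen=True)
class FishAreaResult:
    """Area-level call: fraction of aberrant nuclei and the 10%-rule verdict."""

    n_scored: int
    n_aberrant: int
    fraction: float
    area_call: str  # "aberrant" | "normal"


def score_nucleus_1q(n: FishNucleus) -> str:
    """Score one nucleus for 1q gain.

    Gain iff the nucleus shows three or more test signals, or the
    test/control ratio exceeds one (strictly).  A nucleus with zero control
    signals is a hybridization failure for the ratio branch: the branch is
    skipped (with a warning) and only the count branch applies.
    """
    if n.test_count >= 3:
        return "gain"
    if n.control_count == 0:
        warnings.warn(
            "nucleus with 0 control signals: ratio branch undefined, "
            "scored by test-count branch only",
            stacklevel=2,
        )
        return "no_gain"
    return "gain" if n.test_count / n.control_count > 1 else "no_gain"


def score_nucleus_6q(n: FishNucleus) -> str:
    """Score one nucleus for 6q loss.

    Loss iff the nucleus shows one or fewer test signals, or the
    test/control ratio is at most 0.5 (inclusive boundary).
    """
    if n.test_count <= 1:
        return "loss"
    if n.control_count > 0 and n.test_count / n.control_count <= 0.5:
        return "loss"
    return "no_loss"


def _is_aberrant(n: FishNucleus, aberration: str) -> bool:
    if aberration == "gain_1q":
        return score_nucleus_1q(n) == "gain"
    if aberration == "loss_6q":
        return score_nucleus_6q(n) == "loss"
    raise ValueError(f"unknown aberration {aberration!r}; expected one of {ABERRATIONS}")


def call_area(
    nuclei: Sequence[FishNucleus] | Iterable[FishNucleus],
    aberration: str,
    min_fraction: float = 0.10,
) -> FishAreaResult:
    """Call a whole tumor area aberrant when >= ``min_fraction`` of nuclei are.

    The boundary is inclusive: exactly 10 aberrant of 100 scored nuclei is an
    aberrant area at the default threshold.
    """
    nuclei = list(nuclei)
    if not nuclei:
        raise ValueError("call_area requires at least one scored nucleus")
    n_ab = sum(_is_aberrant(n, aberration) for n in nuclei)
    frac = n_ab / len(nuclei)
    call = "aberrant" if frac >= min_fraction else "normal"
    return FishAreaResult(n_scored=len(nuclei), n_aberrant=n_ab, fraction=frac, area_call=call)


def call_areas_table(
    table: pd.DataFrame, aberration: str, min_fraction: float = 0.10
) -> pd.DataFrame:
    """Area calls for a long-format table (area_id, nucleus_id, test_count, control_count).

    Returns one row per area with n_scored, n_aberrant, fraction and area_call.
    """
    required = {"area_id", "test_count", "control_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for area_id, grp in table.groupby("area_id", sort=True):
        nuclei = [
            FishNucleus(int(t), int(c))
            for t, c in zip(grp["test_count"], grp["control_count"])
        ]
        res = call_area(nuclei, aberration, min_fraction)
        rows.append(
            {
                "area_id": area_id,
                "n_scored": res.n_scored,
                "n_aberrant": res.n_aberrant,
                "fraction": res.fraction,
                "area_call": res.area_call,
            }
        )
    return pd.DataFrame(rows)
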