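"""QC and normalization of ROI-level digital-spatial-profiling count matrices.

The chain mirrors standard GeoMx DSP processing: ROIs failing read-alignment
or negative-probe QC are flagged; counts are scaled to nuclei number by the
geometric-mean method; each ROI is Q3-normalized (75th percentile of its
gene counts equalized across ROIs); background estimated from the negative
probes is subtracted (floored at zero), with per-gene signal-to-noise ratios
reported alongside so an SNR cutoff can be applied instead of subtraction.

Each step records itself in the set's metadata and is a no-op when applied
again, so every step (and the whole chain) is idempotent on its own output.
Negative-probe summaries use the zero-robust geometric mean
geomean(x + 1) - 1, which equals the plain geomean for large counts but
tolerates the occasional zero count a real probe panel produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RoiSet",
    "QcResult",
    "qc_filter",
    "scale_to_nuclei",
    "q3_normalize",
    "background_correct",
    "normalize_chain",
    "rank_genes",
]


@dataclass(frozen=True)
class RoiSet:
    """ROI x gene counts, ROI x probe negative counts, and ROI annotations.

    ``annot`` is indexed by roi_id with columns case_id, density_label
    (dense | sparse), nuclei_count, aligned_fraction.  All three frames share
    the same ROI index order.
    """

    counts: pd.DataFrame
    negatives: pd.DataFrame
    annot: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValueError("RoiSet with no ROIs")
        if not (self.counts.index.equals(self.negatives.index) and self.counts.index.equals(self.annot.index)):
            raise ValueError("counts, negatives and annot must share the same ROI index")
        if (self.annot["nuclei_count"] < 1).any():
            raise ValueError("nuclei_count must be >= 1 for every ROI")

    def subset(self, roi_ids) -> "RoiSet":
        return replace(
            self,
            counts=self.counts.loc[roi_ids],
            negatives=self.negatives.loc[roi_ids],
            annot=self.annot.loc[roi_ids],
        )


@dataclass(frozen=True)
class QcResult:
    flags: pd.DataFrame  # index roi_id; columns: pass_qc, reasons
    passed: RoiSet


def _geomean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("geometric mean of negative values")
    if np.any(x == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(x))))


def _neg_geomean(x: np.ndarray) -> float:
    """Zero-robust geometric mean for negative-probe counts:
    geomean(x + 1) - 1 (>= min(x), ~ geomean for large counts)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative-probe counts must be non-negative")
    return float(np.expm1(np.mean(np.log1p(x))))


def _already_applied(rois: RoiSet, step: str) -> bool:
    return any(s.split(":")[0] == step for s in rois.meta.get("steps", []))


def qc_filter(
    rois: RoiSet, min_aligned_fraction: float = 0.8, min_neg_geomean: float = 1.0
) -> QcResult:
    """Flag ROIs with too few aligned reads or too little negative-probe signal.

    An ROI fails iff aligned_fraction < min_aligned_fraction OR the
    (zero-robust) geometric mean of its negative-probe counts <
    min_neg_geomean; each failure carries machine-readable reasons.
    """
    if rois.negatives.shape[1] == 0:
        raise ValueError("QC requires negative probes")
    rows = []
    for roi_id in rois.counts.index:
        reasons = []
        if rois.annot.loc[roi_id, "aligned_fraction"] < min_aligned_fraction:
            reasons.append("low_aligned_fraction")
        if _neg_geomean(rois.negatives.loc[roi_id].to_numpy()) < min_neg_geomean:
            reasons.append("low_neg_geomean")
        rows.append({"roi_id": roi_id, "pass_qc": not reasons, "reasons": ";".join(reasons)})
    flags = pd.DataFrame(rows).set_index("roi_id")
    passed = rois.subset(flags.index[flags["pass_qc"]])
    return QcResult(flags=flags, passed=passed)


def scale_to_nuclei(rois: RoiSet) -> tuple[RoiSet, pd.Series]:
    """Scale counts to nuclei number by the geometric-mean method.

    factor_i = geomean(nuclei counts) / nuclei_i, so the geometric mean of
    the factors is 1.  Re-applying the step to its own output is a no-op
    (unit factors): the scaling is recorded in the set's metadata and the
    stored nuclei counts are set to their geometric mean.
    """
    if _already_applied(rois, "scale_to_nuclei"):
        return rois, pd.Series(1.0, index=rois.counts.index, name="nuclei_factor")
    nuclei = rois.annot["nuclei_count"].to_numpy(dtype=float)
    if np.any(nuclei <= 0):
        raise ValueError("nuclei counts must be positive")
    g = _geomean(nuclei)
    factors = pd.Series(g / nuclei, index=rois.counts.index, name="nuclei_factor")
    annot = rois.annot.copy()
    annot["nuclei_count"] = g
    out = replace(
        rois,
        counts=rois.counts.mul(factors, axis=0),
        negatives=rois.negatives.mul(factors, axis=0),
        annot=annot,
        meta={**rois.meta, "steps": rois.meta.get("steps", []) + ["scale_to_nuclei"]},
    )
    return out, factors


def q3_normalize(rois: RoiSet) -> tuple[RoiSet, pd.Series]:
    """Equalize each ROI's 75th percentile of gene counts (Q3 normalization).

    factor_i = geomean(Q3 over ROIs) / Q3_i; afterwards every ROI's Q3 equals
    the pre-normalization geometric mean of Q3s.  Q3 is the linear-
    interpolation 75th percentile over gene targets only (negative probes
    excluded).  ROIs with Q3 = 0 are excluded from the geomean and get a NaN
    factor (flagged, left unscaled).  Re-application is a no-op.
    """
    if _already_applied(rois, "q3_normalize"):
        return rois, pd.Series(1.0, index=rois.counts.index, name="q3_factor")
    q3 = rois.counts.quantile(0.75, axis=1)
    ok = q3 > 0
    if not ok.any():
        raise ValueError("no ROI with positive Q3")
    g = _geomean(q3[ok].to_numpy())
    factors = pd.Series(np.where(ok, g / q3, np.nan), index=rois.counts.index, name="q3_factor")
    out = replace(
        rois,
        counts=rois.counts.mul(factors.fillna(1.0), axis=0),
        meta={**rois.meta, "steps": rois.meta.get("steps", []) + ["q3_normalize"]},
    )
    return out, factors


def background_correct(
    rois: RoiSet, method: str = "subtract"
) -> tuple[RoiSet, pd.Series, pd.DataFrame]:
    """Background-correct against the negative-probe geometric mean.

    background_i = (zero-robust) geomean of the negative probes in ROI i;
    SNR(gene, ROI) = count / background_i.  With method="subtract" the
    corrected count is max(count - background_i, 0); with method="snr"
    counts become SNR values instead (background division).  Returns
    (corrected set, per-ROI background, SNR matrix).  Re-application is a
    no-op: it subtracts a zero background and reports SNR against the
    background recorded at the first application.
    """
    if method not in ("subtract", "snr"):
        raise ValueError("method must be 'subtract' or 'snr'")
    if rois.negatives.shape[1] < 2:
        raise ValueError("background correction requires >= 2 negative probes per ROI")
    if _already_applied(rois, "background_correct"):
        bg0 = pd.Series(rois.meta["background"], name="background").reindex(rois.counts.index)
        snr = rois.counts.div(bg0.replace(0.0, np.nan), axis=0)
        return rois, pd.Series(0.0, index=rois.counts.index, name="background"), snr
    bg = pd.Series(
        [_neg_geomean(rois.negatives.loc[r].to_numpy()) for r in rois.negatives.index],
        index=rois.negatives.index,
        name="background",
    )
    with np.errstate(divide="ignore"):
        snr = rois.counts.div(bg.replace(0.0, np.nan), axis=0)
    if method == "subtract":
        counts = rois.counts.sub(bg, axis=0).clip(lower=0.0)
    else:
        counts = snr.fillna(np.inf)
    out = replace(
        rois,
        counts=counts,
        meta={
            **rois.meta,
            "steps": rois.meta.get("steps", []) + [f"background_correct:{method}"],
            "background": bg.to_dict(),
        },
    )
    return out, bg, snr


def normalize_chain(
    rois: RoiSet,
    min_aligned_fraction: float = 0.8,
    min_neg_geomean: float = 1.0,
    background_method: str = "subtract",
) -> dict:
    """Full chain: QC -> nuclei scaling -> Q3 -> background correction.

    The order is fixed and recorded in the output metadata.  Returns a dict
    with the final RoiSet ("normalized"), QC flags, and all factor families.
    """
    qc = qc_filter(rois, min_aligned_fraction, min_neg_geomean)
    scaled, nuclei_factors = scale_to_nuclei(qc.passed)
    q3d, q3_factors = q3_normalize(scaled)
    corrected, background, snr = background_correct(q3d, method=background_method)
    return {
        "normalized": corrected,
        "qc_flags": qc.flags,
        "nuclei_factors": nuclei_factors,
        "q3_factors": q3_factors,
        "background": background,
        "snr": snr,
        "steps": corrected.meta["steps"],
    }


def rank_genes(rois: RoiSet, by: str = "density_label") -> pd.Series:
    """Rank genes by dense-vs-sparse separation (rank-biserial effect size).

    A nonparametric two-group comparison per gene (Mann-Whitney U on the
    normalized counts), returned as a Series of rank-biserial correlations
    sorted descending (positive = higher in dense ROIs).  Ranking only — no
    differential-expression model is fitted.
    """
    labels = rois.annot[by]
    dense = rois.counts[labels == "dense"].to_numpy()
    sparse = rois.counts[labels == "sparse"].to_numpy()
    if len(dense) == 0 or len(sparse) == 0:
        raise ValueError("both dense and sparse ROIs required")
    from scipy.stats import mannwhitneyu

    u, _ = mannwhitneyu(dense, sparse, axis=0, alternative="two-sided")
    rb = 2.0 * u / (len(dense) * len(sparse)) - 1.0
    return pd.Series(rb, index=rois.counts.columns, name="rank_biserial").sort_values(
        ascending=False
    )
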