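"""Synthetic-data generators with planted ground truth.

Every input the analysis consumes can be generated here: point-process
tissue images with demarcated high-density nodules (plus a Ki67 channel),
clonal-mixture FISH signal counts, subclone-diluted arm-level log2 ratios,
survival cohorts with a step hazard at a known density-fraction cutoff, and
ROI count matrices with a dense-area expression signature and negative-probe
background.  All generators are seed-deterministic and return the planted
truth alongside the data, so recovery by the downstream stages is testable.

Default tissue densities are 2 cells/1,000 µm² for the loose glial
background and 15 cells/1,000 µm² inside nodules, placing the operating
classification threshold of 8.5 cells/1,000 µm² at the mixture midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as _draw_disk

from .roinorm import RoiSet

__all__ = [
    "SynthTissueSpec",
    "SynthClonalSpec",
    "SynthCohortSpec",
    "SynthRoiSpec",
    "SynthTissue",
    "gen_tissue_image",
    "gen_fish_counts",
    "gen_arm_profiles",
    "gen_survival_cohort",
    "gen_roi_counts",
]


# ---------------------------------------------------------------- tissue ----


@dataclass(frozen=True)
class SynthTissueSpec:
    """Parameters of a synthetic tissue field.

    Densities are in cells per 1,000 µm²; the nodule process tops up the
    background so that total density inside nodules equals nodule_density.
    """

    field_width_um: float = 2000.0
    field_height_um: float = 2000.0
    background_density: float = 2.0
    nodule_density: float = 15.0
    nodule_fraction: float = 0.3
    nucleus_radius_um: float = 3.0
    ki67_rate_dense: float = 0.30
    ki67_rate_sparse: float = 0.05
    scale_um_per_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if self.background_density < 0 or self.nodule_density < 0:
            raise ValueError("densities must be non-negative")
        if self.nodule_fraction > 0 and not self.nodule_density > self.background_density:
            raise ValueError("nodule_density must exceed background_density")
        if not 0 <= self.nodule_fraction <= 1:
            raise ValueError("nodule_fraction must be in [0, 1]")
        if self.nucleus_radius_um <= 0 or self.scale_um_per_px <= 0:
            raise ValueError("nucleus radius and pixel scale must be positive")
        for r in (self.ki67_rate_dense, self.ki67_rate_sparse):
            if not 0 <= r <= 1:
                raise ValueError("Ki67 rates must be probabilities")


class SynthTissue(NamedTuple):
    """A rendered tissue field plus its planted truth."""

    image: np.ndarray  # primary channel, float, isolated-nucleus peak ~ 1
    ki67: np.ndarray  # Ki67 channel, same shape
    scale_um_per_px: float
    nodule_mask: np.ndarray  # bool, pixel grid; True inside nodules
    nuclei: pd.DataFrame  # x_um, y_um, ki67_positive, in_nodule
    nodule_fraction_realized: float


def _grow_nodule_mask(
    shape_px: tuple[int, int], target: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Union of random discs grown until the covered area fraction reaches
    the target (within about half a percentage point)."""
    mask = np.zeros(shape_px, dtype=bool)
    if target <= 0:
        return mask
    if target >= 1:
        return ~mask
    total = mask.size
    radius_um = (150.0, 300.0)
    for _ in range(10_000):
        frac = mask.sum() / total
        if frac >= target - 0.005:
            break
        r_px = rng.uniform(*radius_um) / scale
        # shrink the disc if it would overshoot the tolerance band
        for _ in range(20):
            cy = rng.uniform(0, shape_px[0])
            cx = rng.uniform(0, shape_px[1])
            rr, cc = _draw_disk((cy, cx), r_px, shape=shape_px)
            trial = mask.copy()
            trial[rr, cc] = True
            if trial.sum() / total <= target + 0.005:
                mask = trial
                break
            r_px *= 0.7
            if r_px < 20.0 / scale:
                break
    return mask


def gen_tissue_image(spec: SynthTissueSpec) -> SynthTissue:
    """Render a two-channel tissue field from two homogeneous point processes.

    Background nuclei fall uniformly over the field at ``background_density``;
    nodule nuclei top the density up to ``nodule_density`` inside a union of
    random discs covering ``nodule_fraction`` of the field (within about
    +/- 2 percentage points).  Each nucleus is a Gaussian blob of sigma
    ``nucleus_radius_um / 2`` and carries a Ki67 flag drawn with its
    compartment's rate.  Identical spec and seed give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.scale_um_per_px
    h_px = int(round(spec.field_height_um / scale))
    w_px = int(round(spec.field_width_um / scale))
    area_um2 = spec.field_width_um * spec.field_height_um

    mask = _grow_nodule_mask((h_px, w_px), spec.nodule_fraction, scale, rng)
    frac_real = mask.sum() / mask.size

    # background process over the full field
    n_bg = rng.poisson(spec.background_density / 1000.0 * area_um2)
    xy_bg = rng.uniform([0, 0], [spec.field_width_um, spec.field_height_um], size=(n_bg, 2))

    # nodule top-up process, rejection-sampled into the mask
    extra = (spec.nodule_density - spec.background_density) / 1000.0
    n_nod = rng.poisson(extra * frac_real * area_um2) if frac_real > 0 else 0
    pts = []
    while len(pts) < n_nod:
        cand = rng.uniform(
            [0, 0], [spec.field_width_um, spec.field_height_um], size=(max(64, n_nod), 2)
        )
        iy = np.minimum((cand[:, 1] / scale).astype(int), h_px - 1)
        ix = np.minimum((cand[:, 0] / scale).astype(int), w_px - 1)
        inside = mask[iy, ix]
        pts.extend(cand[inside].tolist())
    xy_nod = np.array(pts[:n_nod]).reshape(n_nod, 2)

    xy = np.vstack([xy_bg, xy_nod])
    iy = np.minimum((xy[:, 1] / scale).astype(int), h_px - 1)
    ix = np.minimum((xy[:, 0] / scale).astype(int), w_px - 1)
    in_nodule = mask[iy, ix] if mask.any() else np.zeros(len(xy), dtype=bool)
    rate = np.where(in_nodule, spec.ki67_rate_dense, spec.ki67_rate_sparse)
    ki67_pos = rng.uniform(size=len(xy)) < rate

    sigma_px = spec.nucleus_radius_um / 2.0 / scale
    img = np.zeros((h_px, w_px), dtype=float)
    kimg = np.zeros_like(img)
    np.add.at(img, (iy, ix), 1.0)
    np.add.at(kimg, (iy, ix), np.where(ki67_pos, 1.0, 0.0))
    peak = 2.0 * np.pi * sigma_px**2  # rescale so an isolated nucleus peaks at ~1
    img = gaussian_filter(img, sigma_px) * peak
    kimg = gaussian_filter(kimg, sigma_px) * peak

    nuclei = pd.DataFrame(
        {
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "ki67_positive": ki67_pos,
            "in_nodule": in_nodule,
        }
    )
    return SynthTissue(
        image=img,
        ki67=kimg,
        scale_um_per_px=scale,
        nodule_mask=mask,
        nuclei=nuclei,
        nodule_fraction_realized=float(frac_real),
    )


# ------------------------------------------------------------------ FISH ----


@dataclass(frozen=True)
class SynthClonalSpec:
    """Clonal mixture for FISH counts: a fraction of nuclei per area carry the
    aberrant signal pattern; each probe count may miscount by +/- 1."""

    clone_fraction_dense: float = 0.4
    clone_fraction_sparse: float = 0.05
    n_nuclei_per_area: int = 100
    probe_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.clone_fraction_dense, self.clone_fraction_sparse, self.probe_noise):
            if not 0 <= f <= 1:
                raise ValueError("fractions and probe_noise must be in [0, 1]")
        if self.n_nuclei_per_area < 1:
            raise ValueError("n_nuclei_per_area must be >= 1")


_FISH_PATTERNS = {"gain_1q": (3, 2), "loss_6q": (1, 2)}
_DIPLOID = (2, 2)


def gen_fish_counts(spec: SynthClonalSpec, aberration: str) -> pd.DataFrame:
    """Per-nucleus FISH counts for a dense and a sparse area.

    Clone nuclei emit the aberrant pattern (1q gain: test 3 / control 2;
    6q loss: test 1 / control 2), the rest are diploid (2/2).  Each count is
    independently perturbed by +/- 1 with probability ``probe_noise``,
    floored at 0.  Columns: area_id, nucleus_id, test_count, control_count,
    is_clone (truth).
    """
    if aberration not in _FISH_PATTERNS:
        raise ValueError(f"unknown aberration {aberration!r}")
    rng = np.random.default_rng(spec.seed)
    pattern = _FISH_PATTERNS[aberration]
    frames = []
    for area_id, frac in (
        ("dense", spec.clone_fraction_dense),
        ("sparse", spec.clone_fraction_sparse),
    ):
        n = spec.n_nuclei_per_area
        is_clone = rng.uniform(size=n) < frac
        counts = np.where(is_clone[:, None], pattern, _DIPLOID).astype(int)
        flip = rng.uniform(size=counts.shape) < spec.probe_noise
        sign = rng.choice([-1, 1], size=counts.shape)
        counts = np.maximum(counts + flip * sign, 0)
        frames.append(
            pd.DataFrame(
                {
                    "area_id": area_id,
                    "nucleus_id": np.arange(n),
                    "test_count": counts[:, 0],
                    "control_count": counts[:, 1],
                    "is_clone": is_clone,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------- arm log2s ----


def gen_arm_profiles(
    n_cases: int,
    clone_fraction_dense: float | np.ndarray,
    clone_fraction_sparse: float | np.ndarray,
    noise_sd: float = 0.02,
    seed: int = 0,
    arm: str = "1q",
    direction: str = "gain",
) -> pd.DataFrame:
    """Arm-level log2 ratios for paired dense/sparse samples.

    A one-copy gain diluted to clone fraction f gives log2(1 + f/2); a
    one-copy loss gives log2(1 - f/2) (linear mixing of clone and diploid
    copy number before the log).  Gaussian noise of ``noise_sd`` is added.
    Columns: case_id, area_label, arm, log2_ratio, clone_fraction (truth).
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    f_dense = np.broadcast_to(np.asarray(clone_fraction_dense, dtype=float), (n_cases,))
    f_sparse = np.broadcast_to(np.asarray(clone_fraction_sparse, dtype=float), (n_cases,))
    for f in (f_dense, f_sparse):
        if np.any((f < 0) | (f > 1)):
            raise ValueError("clone fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cases):
        for area, f in (("dense", f_dense[i]), ("sparse", f_sparse[i])):
            lr = np.log2(1 + f / 2) if direction == "gain" else np.log2(1 - f / 2)
            rows.append(
                {
                    "case_id": f"case{i:03d}",
                    "area_label": area,
                    "arm": arm,
                    "log2_ratio": lr + rng.normal(0, noise_sd),
                    "clone_fraction": f,
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- survival ----


@dataclass(frozen=True)
class SynthCohortSpec:
    """Survival cohort with a step hazard at a known density-fraction cutoff."""

    n_cases: int = 120
    density_cutoff_true: float = 0.7
    hazard_ratio: float = 4.0
    baseline_hazard: float = 0.02  # events per month below the cutoff
    censor_rate: float = 0.01  # per month
    follow_up_max: float = 120.0  # months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard_ratio and baseline_hazard must be positive")
        if self.censor_rate < 0 or self.follow_up_max <= 0:
            raise ValueError("censor_rate must be >= 0 and follow_up_max positive")
        if not 0 <= self.density_cutoff_true <= 1:
            raise ValueError("density_cutoff_true must be in [0, 1]")


def gen_survival_cohort(spec: SynthCohortSpec) -> tuple[pd.DataFrame, dict]:
    """Exponential proportional-hazards cohort with a step at the true cutoff.

    The covariate (dense-area fraction) is uniform on [0, 1]; the event
    hazard is baseline_hazard below the cutoff and baseline * hazard_ratio
    at or above it; censoring is exponential at censor_rate, truncated at
    follow_up_max.  Returns (records, truth); records columns: case_id,
    time_months, event, covariate.
    """
    rng = np.random.default_rng(spec.seed)
    cov = rng.uniform(size=spec.n_cases)
    above = cov >= spec.density_cutoff_true
    hazard = spec.baseline_hazard * np.where(above, spec.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n_cases)
    else:
        t_cens = np.full(spec.n_cases, np.inf)
    t_cens = np.minimum(t_cens, spec.follow_up_max)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    records = pd.DataFrame(
        {
            "case_id": [f"case{i:03d}" for i in range(spec.n_cases)],
            "time_months": time,
            "event": event,
            "covariate": cov,
        }
    )
    truth = {
        "density_cutoff_true": spec.density_cutoff_true,
        "hazard_ratio": spec.hazard_ratio,
        "n_above": int(above.sum()),
    }
    return records, truth


# ------------------------------------------------------------------ ROIs ----


@dataclass(frozen=True)
class SynthRoiSpec:
    """ROI count matrices for digital spatial profiling.

    Each case contributes ``rois_per_density`` dense and sparse ROIs.  Gene
    counts are negative-binomial with an ROI size factor proportional to its
    nuclei count; the first ``dense_signature_genes`` genes are multiplied by
    ``signature_fold`` in dense ROIs.  Negative probes follow the background
    distribution only.  ``n_fail_aligned`` / ``n_fail_neg`` ROIs are planted
    as QC failures (low aligned-read fraction / low negative-probe counts).
    """

    n_cases: int = 6
    rois_per_density: int = 3
    n_genes: int = 200
    n_neg_probes: int = 20
    dense_signature_genes: int = 10
    signature_fold: float = 4.0
    nuclei_mean_dense: float = 400.0
    nuclei_mean_sparse: float = 200.0
    nb_dispersion: float = 0.1  # var = mu + disp * mu^2
    neg_probe_mean: float = 5.0
    n_fail_aligned: int = 0
    n_fail_neg: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.rois_per_density < 1:
            raise ValueError("n_cases and rois_per_density must be >= 1")
        if self.dense_signature_genes > self.n_genes:
            raise ValueError("dense_signature_genes must be <= n_genes")
        if self.n_genes < 1 or self.n_neg_probes < 0:
            raise ValueError("need >= 1 gene and >= 0 negative probes")
        if self.signature_fold <= 0:
            raise ValueError("signature_fold must be positive")
        if self.nuclei_mean_dense <= 0 or self.nuclei_mean_sparse <= 0:
            raise ValueError("nuclei means must be positive")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    if disp <= 0:
        return rng.poisson(mu)
    r = 1.0 / disp
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def gen_roi_counts(spec: SynthRoiSpec) -> tuple[RoiSet, dict]:
    """Generate an RoiSet plus planted truth (signature genes, QC failures)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{g:04d}" for g in range(spec.n_genes)]
    probes = [f"neg{p:03d}" for p in range(spec.n_neg_probes)]
    signature = genes[: spec.dense_signature_genes]
    base_mu = rng.lognormal(mean=3.0, sigma=1.0, size=spec.n_genes)

    roi_ids, case_ids, labels, nuclei, aligned = [], [], [], [], []
    count_rows, neg_rows = [], []
    for i in range(spec.n_cases):
        for label, nmean in (("dense", spec.nuclei_mean_dense), ("sparse", spec.nuclei_mean_sparse)):
            for j in range(spec.rois_per_density):
                roi_ids.append(f"case{i:03d}_{label}_{j}")
                case_ids.append(f"case{i:03d}")
                labels.append(label)
                nuclei.append(max(1, int(rng.poisson(nmean))))
                aligned.append(float(rng.beta(70, 3)))  # healthy ROIs clear a 0.8 QC bar
    nuclei_arr = np.array(nuclei, dtype=float)
    size = nuclei_arr / nuclei_arr.mean()

    order = rng.permutation(len(roi_ids))
    fail_aligned = set(order[: spec.n_fail_aligned])
    fail_neg = set(order[spec.n_fail_aligned : spec.n_fail_aligned + spec.n_fail_neg])

    for k in range(len(roi_ids)):
        mu = base_mu * size[k]
        if labels[k] == "dense":
            mu = mu.copy()
            mu[: spec.dense_signature_genes] *= spec.signature_fold
        count_rows.append(_nb_draw(rng, mu, spec.nb_dispersion))
        neg_mean = 0.2 if k in fail_neg else spec.neg_probe_mean
        neg_rows.append(_nb_draw(rng, np.full(spec.n_neg_probes, neg_mean * size[k]), spec.nb_dispersion))
        if k in fail_aligned:
            aligned[k] = float(rng.beta(8, 8) * 0.7)  # well below a 0.8 QC bar

    counts = pd.DataFrame(count_rows, index=roi_ids, columns=genes)
    negatives = pd.DataFrame(neg_rows, index=roi_ids, columns=probes)
    annot = pd.DataFrame(
        {
            "case_id": case_ids,
            "density_label": labels,
            "nuclei_count": nuclei,
            "aligned_fraction": aligned,
        },
        index=pd.Index(roi_ids, name="roi_id"),
    )
    truth = {
        "signature_genes": signature,
        "fail_aligned": sorted(roi_ids[k] for k in fail_aligned),
        "fail_neg": sorted(roi_ids[k] for k in fail_neg),
    }
    return RoiSet(counts=counts, negatives=negatives, annot=annot), truth
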