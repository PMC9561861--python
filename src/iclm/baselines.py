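"""Comparison methods: lesion-overlap heterogeneity, VLSM, and overlay LNM.

These are the classical approaches the component-based pipeline is measured
against. Overlap analysis quantifies how little lesion territory patients
share; VLSM tests behavior voxel-by-voxel between lesioned and spared
groups; overlay LNM thresholds each patient's lesion-connectivity t-map and
keeps voxels connected in most patients — a procedure that collapses when
lesion locations are heterogeneous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import FCVector
from .volumes import LesionCohort, Mask, Volume, embed

__all__ = [
    "OverlapSummary",
    "VLSMResult",
    "LNMResult",
    "overlap_summary",
    "pairwise_overlap",
    "vlsm",
    "lnm_patient_map",
    "lnm_overlay",
]

log = logging.getLogger(__name__)


@dataclass
class OverlapSummary:
    overlap_map: Volume  # integer counts
    curve: np.ndarray  # proportion of ever-lesioned voxels shared by >= k, k = 1..n
    pairwise_mean: float
    pairwise_sd: float
    pairwise_values: np.ndarray


@dataclass
class VLSMResult:
    eligible_index: np.ndarray  # flat voxel positions tested
    t_map: Volume  # t of significant voxels projected into the volume
    p_map: Volume
    fdr_significant: Mask
    alpha: float
    t_values: np.ndarray
    p_values: np.ndarray


@dataclass
class LNMResult:
    t_maps: list[Volume]
    positive_masks: list[Mask]
    overlay: Volume
    common_maps: dict[float, Mask]


def pairwise_overlap(a: Mask, b: Mask, mode: str = "min") -> float:
    """Overlap of two lesions: |A∩B| over min(|A|,|B|) ('min', default),
    (|A|+|B|)/2 ('dice'), or |A∪B| ('union')."""
    inter = int((a.data & b.data).sum())
    if mode == "min":
        return inter / min(a.n_voxels, b.n_voxels)
    if mode == "dice":
        return 2.0 * inter / (a.n_voxels + b.n_voxels)
    if mode == "union":
        union = int((a.data | b.data).sum())
        return inter / union
    raise ValueError(f"unknown overlap mode {mode!r}")


def overlap_summary(cohort: LesionCohort, mode: str = "min") -> OverlapSummary:
    """Voxelwise lesion-count map, sharing curve, and pairwise overlap stats.

    curve[k-1] = fraction of ever-lesioned voxels lesioned in >= k patients.
    """
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 patients")
    counts = np.zeros(cohort.grid.dims)
    for _, lesion in cohort:
        counts += lesion.data
    ever = counts >= 1
    denom = int(ever.sum())
    curve = np.array([(counts >= k).sum() / denom for k in range(1, n + 1)])
    masks = [m for _, m in cohort]
    pair = np.array(
        [pairwise_overlap(masks[i], masks[j], mode) for i in range(n) for j in range(i + 1, n)]
    )
    return OverlapSummary(
        overlap_map=Volume(cohort.grid, counts),
        curve=curve,
        pairwise_mean=float(pair.mean()),
        pairwise_sd=float(pair.std(ddof=1)) if pair.size > 1 else 0.0,
        pairwise_values=pair,
    )


def vlsm(
    cohort: LesionCohort,
    behavior: np.ndarray,
    min_frac: float = 0.25,
    max_frac: float = 0.75,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> VLSMResult:
    """Voxel-based lesion-symptom mapping with Benjamini-Hochberg correction.

    Voxels lesioned in [min_frac, max_frac] of patients are eligible; at
    each, behavior is compared between lesioned and spared patients with a
    two-sample t-test (pooled variance by default, Welch via
    ``equal_var=False``); BH-FDR across eligible voxels at ``alpha``.
    """
    behavior = np.asarray(behavior, dtype=float)
    n = len(cohort)
    if behavior.size != n:
        raise ValueError("behavior length must match cohort size")
    if not 0 < min_frac < max_frac < 1:
        raise ValueError("need 0 < min_frac < max_frac < 1")
    stack = np.stack([m.flat() for _, m in cohort])  # n x n_total
    counts = stack.sum(axis=0)
    eligible = np.flatnonzero((counts >= min_frac * n) & (counts <= max_frac * n))
    t_vals, p_vals, keep = [], [], []
    for v in eligible:
        lesioned = stack[:, v].astype(bool)
        g1, g2 = behavior[lesioned], behavior[~lesioned]
        if g1.size < 2 or g2.size < 2:
            log.info("voxel %d dropped: group of size < 2", v)
            continue
        t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
        t_vals.append(float(t))
        p_vals.append(float(p))
        keep.append(v)
    eligible = np.array(keep, dtype=int)
    t_vals = np.array(t_vals)
    p_vals = np.array(p_vals)
    grid = cohort.grid
    sig = np.zeros(grid.n_total, dtype=bool)
    t_proj = np.zeros(grid.n_total)
    p_proj = np.ones(grid.n_total)
    if eligible.size:
        reject, _, _, _ = multipletests(p_vals, alpha=alpha, method="fdr_bh")
        sig[eligible[reject]] = True
        t_proj[eligible[reject]] = t_vals[reject]
        p_proj[eligible] = p_vals
    return VLSMResult(
        eligible_index=eligible,
        t_map=Volume(grid, t_proj.reshape(grid.dims, order="F")),
        p_map=Volume(grid, p_proj.reshape(grid.dims, order="F")),
        fdr_significant=Mask(grid, sig.reshape(grid.dims, order="F").astype(np.uint8)),
        alpha=alpha,
        t_values=t_vals,
        p_values=p_vals,
    )


def lnm_patient_map(
    per_subject_fc: list[FCVector],
    brain: Mask,
    alpha_corrected: float = 1e-6,
) -> tuple[Volume, Mask]:
    """One patient's lesion network map from unaveraged per-control FC vectors.

    Per voxel: one-sample t of the Fisher-Z values against 0 across
    controls; Bonferroni correction over tested voxels; the positive mask
    keeps voxels with corrected p below ``alpha_corrected`` and t > 0.
    """
    if len(per_subject_fc) < 3:
        raise ValueError("need at least 3 subjects")
    vals = np.stack([v.values for v in per_subject_fc])  # subjects x V
    lesion_cols = per_subject_fc[0].lesion_cols
    sd = vals.std(axis=0, ddof=1)
    testable = (~lesion_cols) & (sd > 0)
    n_dropped = int(((~lesion_cols) & (sd == 0)).sum())
    if n_dropped:
        log.info("%d zero-variance voxels excluded from one-sample t", n_dropped)
    n_tested = int(testable.sum())
    t = np.zeros(vals.shape[1])
    p_corr = np.ones(vals.shape[1])
    if n_tested:
        tt = stats.ttest_1samp(vals[:, testable], 0.0, axis=0)
        t[testable] = tt.statistic
        p_corr[testable] = np.minimum(tt.pvalue * n_tested, 1.0)  # Bonferroni
    pos = testable & (p_corr < alpha_corrected) & (t > 0)
    t_vol = embed(t, brain)
    pos_full = np.zeros(brain.grid.n_total, dtype=np.uint8)
    pos_full[brain.flat_index[pos]] = 1
    return t_vol, Mask(brain.grid, pos_full.reshape(brain.grid.dims, order="F"))


def lnm_overlay(masks: list[Mask], fractions: list[float]) -> LNMResult:
    """Overlay per-patient positive masks; common map at fraction f keeps
    voxels present in at least ceil(f * n) patients."""
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid.dims != grid.dims:
            raise ValueError("masks on different grids")
    counts = np.zeros(grid.dims)
    for m in masks:
        counts += m.data
    n = len(masks)
    common = {}
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fractions must be in (0, 1]")
        k = math.ceil(f * n)
        common[f] = Mask(grid, (counts >= k).astype(np.uint8))
    return LNMResult(
        t_maps=[],
        positive_masks=list(masks),
        overlay=Volume(grid, counts),
        common_maps=common,
    )
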