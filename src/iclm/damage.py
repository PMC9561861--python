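"""Network damage scores and brain-behavior correlation.

A patient's damage score is the maximum component Z-value inside the
intersection of the thresholded network map and the patient's lesion: where
the lesion strikes the network, how intense is the struck tissue's network
membership. Lesion size is regressed out of the scores before correlating
with behavior (WAB subtests and the AQ composite), and the Fisher r-to-z
test compares correlation strengths between maps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import Decomposition, NetworkMap, threshold_map
from .identify import ReferenceNetwork
from .volumes import LesionCohort, Mask

__all__ = [
    "wab_aq",
    "damage_score",
    "damage_scores",
    "damage_score_binary",
    "residualize",
    "behavior_correlation",
    "compare_correlations",
    "specificity_panel",
]

WAB_RANGES = {"naming": 100.0, "comprehension": 200.0, "fluency": 10.0, "repetition": 100.0}

BEHAVIOR_MEASURES = ("aq", "naming", "comprehension", "fluency", "repetition")


def wab_aq(naming: float, comprehension: float, fluency: float, repetition: float) -> float:
    """Aphasia Quotient from WAB subtests:
    (naming/10 + comprehension/20 + fluency + repetition/10) x 2."""
    for name, val in zip(WAB_RANGES, (naming, comprehension, fluency, repetition)):
        if not 0 <= val <= WAB_RANGES[name]:
            raise ValueError(f"{name}={val} outside WAB range [0, {WAB_RANGES[name]}]")
    return (naming / 10 + comprehension / 20 + fluency + repetition / 10) * 2


def damage_score(network: NetworkMap, lesion: Mask) -> tuple[float, int]:
    """(max Z inside positive-mask ∩ lesion, intersection size); 0 when disjoint."""
    inter = network.positive_mask.intersect(lesion)
    n = inter.n_voxels
    if n == 0:
        warnings.warn("lesion does not intersect the network; damage score set to 0")
        return 0.0, 0
    vals = network.zmap.flat()[inter.flat_index]
    return float(vals.max()), n


def damage_scores(network: NetworkMap, cohort: LesionCohort) -> pd.DataFrame:
    """Per-patient raw damage scores for a whole cohort."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, lesion in cohort:
            raw, n = damage_score(network, lesion)
            rows.append({"patient_id": pid, "raw_score": raw, "n_intersect": n,
                         "lesion_size": lesion.n_voxels})
    return pd.DataFrame(rows)


def damage_score_binary(ref: ReferenceNetwork, cohort: LesionCohort, brain: Mask) -> np.ndarray:
    """Binary-reference variant: intersection voxel counts, z-scored across
    the cohort (sample sd, n-1)."""
    ref_mask = ref.binary_mask(brain)
    counts = np.array(
        [float(ref_mask.intersect(lesion).n_voxels) for _, lesion in cohort], dtype=float
    )
    sd = counts.std(ddof=1)
    if sd == 0:
        raise ValueError("all patients have identical intersection counts")
    return (counts - counts.mean()) / sd


def residualize(scores: np.ndarray, lesion_sizes: np.ndarray) -> np.ndarray:
    """OLS residuals of scores on (intercept, lesion size)."""
    scores = np.asarray(scores, dtype=float)
    sizes = np.asarray(lesion_sizes, dtype=float)
    if scores.size != sizes.size or scores.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if sizes.std() == 0:
        raise ValueError("lesion sizes are constant; cannot residualize")
    X = np.column_stack([np.ones_like(sizes), sizes])
    beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
    return scores - X @ beta


def behavior_correlation(scores: np.ndarray, behavior: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df)."""
    scores = np.asarray(scores, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if scores.size != behavior.size or scores.size < 4:
        raise ValueError("need matched vectors of length >= 4")
    if scores.std() == 0 or behavior.std() == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(scores, behavior)
    return float(res.statistic), float(res.pvalue)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Independent-samples Fisher r-to-z comparison of two correlations."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n < 4:
            raise ValueError("need n >= 4")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _measure_columns(behavior: pd.DataFrame) -> list[str]:
    return [m for m in BEHAVIOR_MEASURES if m in behavior.columns]


def correlate_with_behavior(
    raw_scores: np.ndarray,
    lesion_sizes: np.ndarray,
    behavior: pd.DataFrame,
) -> pd.DataFrame:
    """Residualize scores for lesion size, then correlate with each measure."""
    resid = residualize(raw_scores, lesion_sizes)
    rows = []
    for measure in _measure_columns(behavior):
        vals = behavior[measure].to_numpy(dtype=float)
        r, p = behavior_correlation(resid, vals)
        rows.append({"measure": measure, "r": r, "p": p})
    return pd.DataFrame(rows)


def specificity_panel(
    decomp: Decomposition,
    refs: list[ReferenceNetwork],
    cohort: LesionCohort,
    behavior: pd.DataFrame,
    z: float = 1.0,
) -> pd.DataFrame:
    """Damage-behavior correlations for every IC and every reference network.

    ICs (and continuous references) use the max-Z damage score; binary
    references use z-scored intersection counts. One row per map and
    behavior measure, enabling the specificity contrast: the symptom-related
    IC should show the strongest negative behavior correlation.
    """
    behavior = behavior.set_index("patient_id").loc[cohort.patient_ids].reset_index()
    sizes = cohort.lesion_sizes.astype(float)
    panel = []

    def add_rows(map_type: str, name: str, raw: np.ndarray) -> None:
        corr = correlate_with_behavior(raw, sizes, behavior)
        for _, row in corr.iterrows():
            panel.append({"map_type": map_type, "map_name": name,
                          "measure": row["measure"], "r": row["r"], "p": row["p"]})

    for i, zmap in enumerate(decomp.ic_zmaps):
        net = threshold_map(zmap, z, brain=decomp.brain, label=f"IC{i + 1}")
        raw = damage_scores(net, cohort)["raw_score"].to_numpy()
        add_rows("ic", f"IC{i + 1}", raw)
    for ref in refs:
        if ref.kind == "binary":
            raw = damage_score_binary(ref, cohort, decomp.brain)
        else:
            vals = ref.values(decomp.brain)
            sd = vals.std()
            zvals = (vals - vals.mean()) / sd if sd > 0 else vals
            from .volumes import embed

            net = threshold_map(embed(zvals, decomp.brain), z, brain=decomp.brain,
                                label=ref.name)
            raw = damage_scores(net, cohort)["raw_score"].to_numpy()
        add_rows("reference", ref.name, raw)
    return pd.DataFrame(panel)
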