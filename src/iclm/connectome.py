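"""Resting-state cleaning, lesion-seeded connectivity and the union FC matrix.

For each patient the lesion mask is used as a seed region in every healthy
control's resting-state data: the mean seed time course is correlated with
every in-brain voxel, the correlations are Fisher-Z transformed, and the
per-control maps are averaged (within subject across sessions first, then
across subjects). Stacking the averaged vectors over patients — lesioned
entries filled with exact zeros — gives the union FC matrix that is
row-standardized and fed to the spatial ICA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .volumes import Fmri4D, Mask

__all__ = [
    "FCVector",
    "FCMatrix",
    "preprocess",
    "seed_fc",
    "average_fc",
    "assemble_fc_matrix",
]

R_CLAMP = 1.0 - 1e-7  # |r| clamp before arctanh; keeps duplicated series finite


@dataclass
class FCVector:
    """Fisher-Z connectivity of one patient's lesion seed over the in-brain index.

    ``values`` follows the canonical brain-mask flat index; entries at
    lesioned in-brain voxels are exactly zero and flagged in ``lesion_cols``.
    """

    patient_id: str
    values: np.ndarray
    lesion_cols: np.ndarray  # boolean over the brain index
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lesion_cols = np.asarray(self.lesion_cols, dtype=bool)
        if self.values.shape != self.lesion_cols.shape:
            raise ValueError("values and lesion_cols must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite connectivity values")
        if np.any(self.values[self.lesion_cols] != 0):
            raise ValueError("lesioned entries must be exactly zero")

    @property
    def n_valid(self) -> int:
        return int((~self.lesion_cols).sum())


@dataclass
class FCMatrix:
    """Patients x in-brain-voxels union connectivity matrix (ICA input)."""

    patient_ids: list[str]
    values: np.ndarray  # P x V
    lesion_cols: np.ndarray  # boolean P x V
    brain: Mask
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lesion_cols = np.asarray(self.lesion_cols, dtype=bool)
        if self.values.shape != self.lesion_cols.shape:
            raise ValueError("values/lesion_cols shape mismatch")
        if self.values.shape[0] != len(self.patient_ids):
            raise ValueError("row count does not match patient ids")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, ids: list[str]) -> "FCMatrix":
        pos = [self.patient_ids.index(i) for i in ids]
        return FCMatrix(list(ids), self.values[pos].copy(), self.lesion_cols[pos].copy(),
                        self.brain, self.standardized)


def preprocess(
    fmri: Fmri4D,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.08),
    brain: Mask | None = None,
    nuisance_masks: list[Mask] | None = None,
) -> Fmri4D:
    """Nuisance regression followed by a zero-phase band-pass.

    Regressors: an intercept, any supplied per-timepoint confound columns
    (e.g. motion parameters), the global mean series over ``brain`` when
    given, and the mean series over each nuisance mask (the usual stand-ins
    for ventricular / white-matter signals). Residuals are band-pass
    filtered with a 4th-order Butterworth applied forward and backward
    (zero phase); the output is mean-free.
    """
    t = fmri.n_timepoints
    nyq = 1.0 / (2.0 * fmri.tr)
    low, high = band
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:.3f} Hz)")
    flat = fmri.series.reshape(-1, t, order="F").T  # t x n_total
    regs = [np.ones(t)]
    names = ["intercept"]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != t:
            confounds = confounds.T
        if confounds.shape[0] != t:
            raise ValueError("confound rows must match timepoints")
        for i in range(confounds.shape[1]):
            regs.append(confounds[:, i])
            names.append(f"confound{i}")
    if brain is not None:
        regs.append(flat[:, brain.flat_index].mean(axis=1))
        names.append("global")
    for m, nmask in enumerate(nuisance_masks or []):
        regs.append(flat[:, nmask.flat_index].mean(axis=1))
        names.append(f"nuisance{m}")
    X = np.column_stack(regs)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a collinear column: first column whose removal restores full rank
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"confound matrix is rank-deficient (column {names[j]!r})")
        raise ValueError("confound matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    b, a = signal.butter(4, [low / nyq, high / nyq], btype="band")
    filtered = signal.filtfilt(b, a, resid, axis=0)
    filtered -= filtered.mean(axis=0)
    out = filtered.T.reshape(fmri.series.shape, order="F")
    return Fmri4D(fmri.grid, out, tr=fmri.tr,
                  subject_id=fmri.subject_id, session_id=fmri.session_id)


def seed_fc(fmri: Fmri4D, lesion: Mask, brain: Mask, patient_id: str = "") -> FCVector:
    """Fisher-Z correlation of the mean lesion-seed series with every brain voxel."""
    seed_mask = lesion.intersect(brain)
    if seed_mask.n_voxels < 1:
        raise ValueError("lesion does not intersect the brain mask")
    brain_idx = brain.flat_index
    series = fmri.voxel_series(brain_idx)  # t x V
    lesion_cols = lesion.flat()[brain_idx].astype(bool)
    seed = series[:, lesion_cols].mean(axis=1)
    if seed.std() == 0:
        raise ValueError("seed time series has zero variance")
    zs = seed - seed.mean()
    zs /= np.linalg.norm(zs)
    zv = series - series.mean(axis=0)
    norms = np.linalg.norm(zv, axis=0)
    norms[norms == 0] = np.inf  # zero-variance voxels get r = 0 (excluded upstream)
    r = (zs @ zv) / norms
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    values = np.arctanh(r)
    values[lesion_cols] = 0.0
    return FCVector(patient_id, values, lesion_cols, subject_id=fmri.subject_id)


def average_fc(per_subject: list[FCVector]) -> FCVector:
    """Two-stage mean: within subject across sessions, then across subjects.

    All vectors must share the patient, voxel index length and lesion
    zero-pattern. Equal subject weights regardless of session counts.
    """
    if not per_subject:
        raise ValueError("need at least one FC vector")
    first = per_subject[0]
    for v in per_subject[1:]:
        if v.values.shape != first.values.shape:
            raise ValueError("FC vectors have mismatched lengths")
        if not np.array_equal(v.lesion_cols, first.lesion_cols):
            raise ValueError("FC vectors have mismatched lesion zero-patterns")
    by_subject: dict[str, list[np.ndarray]] = {}
    for v in per_subject:
        by_subject.setdefault(v.subject_id, []).append(v.values)
    subject_means = [np.mean(vals, axis=0) for vals in by_subject.values()]
    mean = np.mean(subject_means, axis=0)
    mean[first.lesion_cols] = 0.0
    return FCVector(first.patient_id, mean, first.lesion_cols.copy())


def assemble_fc_matrix(
    vectors: list[FCVector],
    brain: Mask,
    standardize: bool = True,
    zscore_scope: str = "row",
) -> FCMatrix:
    """Stack per-patient averaged FC vectors into the union matrix.

    With ``standardize``, each row is centred and scaled to unit variance
    over its non-lesioned entries ("row" scope; "global" uses all
    non-lesioned cells of the matrix jointly), after which lesioned cells
    are reset to exact zero — the "empty elements filled with zeroes"
    convention.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 patients")
    n_brain = brain.flat_index.size
    for v in vectors:
        if v.values.size != n_brain:
            raise ValueError(f"patient {v.patient_id!r}: vector does not match brain index")
    values = np.stack([v.values for v in vectors])
    lesion_cols = np.stack([v.lesion_cols for v in vectors])
    ids = [v.patient_id for v in vectors]
    if standardize:
        if zscore_scope == "row":
            for i, v in enumerate(vectors):
                valid = ~lesion_cols[i]
                row = values[i, valid]
                sd = row.std()
                if sd == 0:
                    raise ValueError(f"patient {ids[i]!r}: zero-variance FC row")
                values[i, valid] = (row - row.mean()) / sd
        elif zscore_scope == "global":
            valid = ~lesion_cols
            sd = values[valid].std()
            if sd == 0:
                raise ValueError("zero-variance FC matrix")
            values[valid] = (values[valid] - values[valid].mean()) / sd
        else:
            raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
        values[lesion_cols] = 0.0
    return FCMatrix(ids, values, lesion_cols, brain, standardized=standardize)
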