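"""Matching independent components against reference networks.

Each component map is compared with each reference by (a) the Dice
coefficient between the component's positive |Z| > threshold mask and the
binarized reference, and (b) the Pearson correlation over brain voxels
between the positive part of the component z-map and the reference values.
The component with the best mean rank across all (reference, metric) pairs
is declared the symptom-related network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .decomposition import Decomposition, NetworkMap, threshold_map
from .volumes import Mask, Volume, binarize

__all__ = ["ReferenceNetwork", "SimilarityTable", "dice", "map_correlation", "rank_components"]


@dataclass
class ReferenceNetwork:
    """A reference map: binary (parcel) or continuous (e.g. meta-analytic z-map)."""

    name: str
    map: Volume | Mask
    kind: str = "continuous"  # or "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError("kind must be 'binary' or 'continuous'")
        if self.kind == "binary" and not isinstance(self.map, Mask):
            self.map = Mask(self.map.grid, (self.map.data > 0).astype(np.uint8))

    def binary_mask(self, brain: Mask, z: float = 1.0) -> Mask:
        """Binary form for Dice: binary refs as-is; continuous refs z-scored
        over brain voxels and thresholded at ``z`` (mirrors IC thresholding)."""
        if self.kind == "binary":
            return self.map.intersect(brain)
        vals = self.map.flat()[brain.flat_index]
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"reference {self.name!r} has zero variance over brain")
        zvals = (vals - vals.mean()) / sd
        full = np.zeros(brain.grid.n_total)
        full[brain.flat_index] = zvals
        zvol = Volume(brain.grid, full.reshape(brain.grid.dims, order="F"))
        return binarize(zvol, z).intersect(brain)

    def values(self, brain: Mask) -> np.ndarray:
        """Continuous vector over the brain index (binary refs as 0/1)."""
        return self.map.flat()[brain.flat_index].astype(float)


@dataclass
class SimilarityTable:
    table: pd.DataFrame  # columns: ic, reference, dice, pearson_r
    selected_ic: int
    selection_rule_trace: str


def dice(a: Mask, b: Mask) -> float:
    """2|A∩B| / (|A|+|B|); symmetric; undefined when both masks are empty."""
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("undefined Dice: both masks empty")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def map_correlation(ic_zmap: Volume, ref: ReferenceNetwork, brain: Mask) -> float:
    """Pearson r over brain voxels between the positive part of the IC map
    (negative z set to 0) and the reference values."""
    ic_vals = ic_zmap.flat()[brain.flat_index]
    ic_pos = np.where(ic_vals > 0, ic_vals, 0.0)
    ref_vals = ref.values(brain)
    if ic_pos.std() == 0 or ref_vals.std() == 0:
        raise ValueError("zero variance in one of the maps over the brain mask")
    return float(np.corrcoef(ic_pos, ref_vals)[0, 1])


def rank_components(
    decomp: Decomposition,
    refs: list[ReferenceNetwork],
    z: float = 1.0,
) -> SimilarityTable:
    """Score every IC against every reference; select by best mean rank.

    For each (reference, metric) pair ICs are ranked descending (rank 1 =
    best); the selected IC minimizes the mean rank, ties resolved to the
    smallest IC index. The trace records per-criterion winners and whether
    they were unanimous.
    """
    if not refs:
        raise ValueError("need at least one reference network")
    if z <= 0:
        raise ValueError("threshold must be positive")
    brain = decomp.brain
    rows = []
    nets: list[NetworkMap] = [
        threshold_map(zm, z, brain=brain, label=f"IC{i + 1}")
        for i, zm in enumerate(decomp.ic_zmaps)
    ]
    for i, net in enumerate(nets):
        for ref in refs:
            ref_mask = ref.binary_mask(brain, z=z)
            rows.append(
                {
                    "ic": i,
                    "reference": ref.name,
                    "dice": dice(net.positive_mask, ref_mask)
                    if net.positive_mask.n_voxels + ref_mask.n_voxels > 0
                    else 0.0,
                    "pearson_r": map_correlation(net.zmap, ref, brain),
                }
            )
    table = pd.DataFrame(rows)
    n_ic = len(nets)
    rank_sum = np.zeros(n_ic)
    winners = []
    for ref in refs:
        sub = table[table["reference"] == ref.name].sort_values("ic")
        for metric in ("dice", "pearson_r"):
            vals = sub[metric].to_numpy()
            ranks = rankdata(-vals, method="average")
            rank_sum += ranks
            winners.append((ref.name, metric, int(np.argmin(ranks))))
    mean_rank = rank_sum / (2 * len(refs))
    selected = int(np.argmin(mean_rank))
    winner_set = {w for _, _, w in winners}
    if len(winner_set) == 1:
        trace = f"IC{selected + 1} won every criterion (unanimous)."
    else:
        parts = ", ".join(f"{r}/{m}: IC{w + 1}" for r, m, w in winners)
        trace = (
            f"criteria disagree ({parts}); "
            f"IC{selected + 1} selected by best mean rank."
        )
    return SimilarityTable(table=table, selected_ic=selected, selection_rule_trace=trace)
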