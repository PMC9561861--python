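"""Full-pipeline orchestration, validation harnesses and provenance.

``run_iclm`` chains the stages over in-memory objects: brain mask →
preprocessing → lesion-seeded connectivity → union FC matrix → PCA/ICA →
component identification → damage scoring. ``run_full`` is the path-based
wrapper that reads NIfTI/CSV inputs and writes all artifacts plus a
provenance log. The harnesses (split-half, subgroups, robustness scan)
re-run the decomposition under perturbed designs and report Dice overlap
of the identified network against the reference run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import FCVector, assemble_fc_matrix, average_fc, preprocess, seed_fc
from .damage import correlate_with_behavior, damage_scores, wab_aq
from .decomposition import Decomposition, NetworkMap, decompose, threshold_map
from .identify import ReferenceNetwork, SimilarityTable, dice, rank_components
from .volumes import (
    Fmri4D,
    LesionCohort,
    Mask,
    binarize,
    compute_brain_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = [
    "RunConfig",
    "ConnectomeData",
    "ICLMResult",
    "ValidationReport",
    "prepare_connectome",
    "identify_network",
    "run_iclm",
    "run_full",
    "split_half",
    "subgroup_runs",
    "robustness_scan",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of a run; defaults are the study conditions."""

    n_runs: int = 30
    ic_threshold: float = 1.0  # alternates 0.5 / 1.5 for the robustness scan
    zscore_scope: str = "global"
    order: int | None = None  # None = knee point
    seed: int = 0
    band: tuple[float, float] = (0.01, 0.08)
    do_preprocess: bool = True
    overlay_fractions: tuple[float, ...] = (0.7, 0.8, 0.9)
    vlsm_min_frac: float = 0.25
    vlsm_max_frac: float = 0.75
    alpha: float = 0.05
    lnm_alpha_corrected: float = 1e-6

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "overlay_fractions" in raw:
            raw["overlay_fractions"] = tuple(raw["overlay_fractions"])
        return cls(**raw)


@dataclass
class ConnectomeData:
    """Connectivity stage output, kept subsettable for the harnesses."""

    brain: Mask
    per_subject_fc: dict[str, list[FCVector]]  # patient -> per-HC vectors
    averaged: list[FCVector]
    fc_matrix: "object"  # FCMatrix

    def matrix_for_hc_subset(self, n_hc: int, zscore_scope: str = "row"):
        """Re-average using only the first ``n_hc`` healthy controls."""
        subjects = sorted({v.subject_id for vecs in self.per_subject_fc.values() for v in vecs})
        keep = set(subjects[:n_hc])
        averaged = [
            average_fc([v for v in vecs if v.subject_id in keep])
            for vecs in self.per_subject_fc.values()
        ]
        return assemble_fc_matrix(averaged, self.brain, standardize=True,
                                  zscore_scope=zscore_scope)


@dataclass
class ICLMResult:
    connectome: ConnectomeData
    decomposition: Decomposition
    similarity: SimilarityTable
    network: NetworkMap
    damage: pd.DataFrame | None
    behavior_correlations: pd.DataFrame | None


@dataclass
class ValidationReport:
    splithalf: pd.DataFrame | None = None
    splithalf_mean: float | None = None
    subgroup: pd.DataFrame | None = None
    robustness: pd.DataFrame | None = None


def prepare_connectome(
    fmris: list[Fmri4D],
    cohort: LesionCohort,
    config: RunConfig | None = None,
) -> ConnectomeData:
    """Brain mask, optional cleaning, per-HC seed FC, averaging, matrix assembly."""
    cfg = config or RunConfig()
    brain = compute_brain_mask(fmris)
    if cfg.do_preprocess:
        fmris = [preprocess(f, band=cfg.band, brain=brain) for f in fmris]
    per_subject: dict[str, list[FCVector]] = {}
    for pid, lesion in cohort:
        per_subject[pid] = [seed_fc(f, lesion, brain, patient_id=pid) for f in fmris]
    averaged = [average_fc(per_subject[pid]) for pid in cohort.patient_ids]
    fc = assemble_fc_matrix(averaged, brain, standardize=True, zscore_scope=cfg.zscore_scope)
    return ConnectomeData(brain=brain, per_subject_fc=per_subject,
                          averaged=averaged, fc_matrix=fc)


def identify_network(
    decomp: Decomposition,
    refs: list[ReferenceNetwork],
    z: float = 1.0,
) -> tuple[SimilarityTable, NetworkMap]:
    """Rank components against the references; return the winner's map."""
    sim = rank_components(decomp, refs, z=z)
    zmap = decomp.ic_zmaps[sim.selected_ic]
    net = threshold_map(zmap, z, brain=decomp.brain, label=f"IC{sim.selected_ic + 1}")
    return sim, net


def run_iclm(
    fmris: list[Fmri4D],
    cohort: LesionCohort,
    refs: list[ReferenceNetwork],
    behavior: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> ICLMResult:
    """The full analysis on in-memory inputs."""
    cfg = config or RunConfig()
    conn = prepare_connectome(fmris, cohort, cfg)
    decomp = decompose(conn.fc_matrix, n_runs=cfg.n_runs, seed=cfg.seed, order=cfg.order)
    sim, net = identify_network(decomp, refs, z=cfg.ic_threshold)
    dmg = corr = None
    if behavior is not None:
        dmg = damage_scores(net, cohort)
        corr = correlate_with_behavior(
            dmg["raw_score"].to_numpy(), cohort.lesion_sizes.astype(float), _aligned(behavior, cohort)
        )
    return ICLMResult(conn, decomp, sim, net, dmg, corr)


def _aligned(behavior: pd.DataFrame, cohort: LesionCohort) -> pd.DataFrame:
    return behavior.set_index("patient_id").loc[cohort.patient_ids].reset_index()


# ---------------------------------------------------------------------------
# Validation harnesses


def split_half(
    fc_matrix,
    refs: list[ReferenceNetwork],
    n_repeats: int = 10,
    seed: int = 0,
    config: RunConfig | None = None,
) -> ValidationReport:
    """Reproducibility: split patients in halves, rerun the decomposition per
    half, and Dice the two identified network masks; repeated ``n_repeats``
    times (one random patient dropped first when the count is odd)."""
    cfg = config or RunConfig()
    ids = list(fc_matrix.patient_ids)
    if len(ids) < 6:
        raise ValueError("need at least 6 patients (3 per half)")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        pool = list(ids)
        if len(pool) % 2:
            pool.pop(int(rng.integers(len(pool))))
        perm = rng.permutation(len(pool))
        half = len(pool) // 2
        groups = ([pool[i] for i in perm[:half]], [pool[i] for i in perm[half:]])
        nets = []
        try:
            for g, members in enumerate(groups):
                sub = fc_matrix.subset(members)
                decomp = decompose(sub, n_runs=cfg.n_runs,
                                   seed=cfg.seed + 1000 * (rep + 1) + g, order=cfg.order)
                _, net = identify_network(decomp, refs, z=cfg.ic_threshold)
                nets.append(net)
            d = dice(nets[0].positive_mask, nets[1].positive_mask)
            rows.append({"repeat": rep, "dice": d, "failed": False})
        except Exception as exc:  # noqa: BLE001 - harness must survive a bad split
            log.warning("split-half repeat %d failed: %s", rep, exc)
            rows.append({"repeat": rep, "dice": np.nan, "failed": True})
    df = pd.DataFrame(rows, columns=["repeat", "dice", "failed"])
    ok = df.loc[~df["failed"], "dice"]
    return ValidationReport(splithalf=df,
                            splithalf_mean=float(ok.mean()) if len(ok) else None)


def subgroup_runs(
    fc_matrix,
    labels: dict[str, str],
    full_network: NetworkMap,
    refs: list[ReferenceNetwork],
    config: RunConfig | None = None,
) -> ValidationReport:
    """Stability across clinical subgroups: rerun per labelled subgroup and
    Dice each subgroup's identified map against the full-cohort map."""
    cfg = config or RunConfig()
    missing = [pid for pid in fc_matrix.patient_ids if pid not in labels]
    if missing:
        raise ValueError(f"labels missing for patients: {missing}")
    groups: dict[str, list[str]] = {}
    for pid in fc_matrix.patient_ids:
        groups.setdefault(labels[pid], []).append(pid)
    rows = []
    for name, members in groups.items():
        if len(members) < 3:
            log.warning("subgroup %r has %d patients; skipped", name, len(members))
            rows.append({"group": name, "n": len(members), "dice": np.nan, "skipped": True})
            continue
        sub = fc_matrix.subset(members)
        decomp = decompose(sub, n_runs=cfg.n_runs, seed=cfg.seed, order=cfg.order)
        _, net = identify_network(decomp, refs, z=cfg.ic_threshold)
        d = dice(net.positive_mask, full_network.positive_mask)
        rows.append({"group": name, "n": len(members), "dice": d, "skipped": False})
    return ValidationReport(subgroup=pd.DataFrame(rows))


def robustness_scan(
    conn: ConnectomeData,
    refs: list[ReferenceNetwork],
    cohort: LesionCohort,
    behavior: pd.DataFrame | None,
    hc_subsets: list[int] | None = None,
    thresholds: list[float] | None = None,
    config: RunConfig | None = None,
) -> ValidationReport:
    """Parameter-space stability: vary the number of healthy controls feeding
    the connectome and the component z-threshold; report Dice of each
    setting's identified map against the reference setting plus the
    damage-behavior correlations."""
    cfg = config or RunConfig()
    ref_decomp = decompose(conn.fc_matrix, n_runs=cfg.n_runs, seed=cfg.seed, order=cfg.order)
    _, ref_net = identify_network(ref_decomp, refs, z=cfg.ic_threshold)
    rows = []

    def behavior_r(net: NetworkMap) -> tuple[float, float]:
        if behavior is None:
            return np.nan, np.nan
        dmg = damage_scores(net, cohort)
        corr = correlate_with_behavior(
            dmg["raw_score"].to_numpy(), cohort.lesion_sizes.astype(float),
            _aligned(behavior, cohort),
        )
        row = corr[corr["measure"] == "aq"]
        if row.empty:
            return np.nan, np.nan
        return float(row["r"].iloc[0]), float(row["p"].iloc[0])

    for n_hc in hc_subsets or []:
        fc = conn.matrix_for_hc_subset(n_hc, zscore_scope=cfg.zscore_scope)
        decomp = decompose(fc, n_runs=cfg.n_runs, seed=cfg.seed, order=cfg.order)
        _, net = identify_network(decomp, refs, z=cfg.ic_threshold)
        r, p = behavior_r(net)
        rows.append({"setting": "n_hc", "value": n_hc,
                     "dice_vs_reference": dice(net.positive_mask, ref_net.positive_mask),
                     "aq_r": r, "aq_p": p})
    for thr in thresholds or []:
        net = threshold_map(ref_net.zmap, thr, brain=conn.brain, label=ref_net.label)
        r, p = behavior_r(net)
        rows.append({"setting": "threshold", "value": thr,
                     "dice_vs_reference": dice(net.positive_mask, ref_net.positive_mask),
                     "aq_r": r, "aq_p": p})
    return ValidationReport(robustness=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Path-based entry point


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_behavior(path: str | Path) -> pd.DataFrame:
    """Read the behavior CSV; the AQ composite is computed from the subtests
    when absent."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("behavior CSV needs a patient_id column")
    if "aq" not in df.columns:
        needed = ["naming", "comprehension", "fluency", "repetition"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"cannot compute AQ: missing columns {missing}")
        df["aq"] = [
            wab_aq(r.naming, r.comprehension, r.fluency, r.repetition)
            for r in df.itertuples()
        ]
    return df


def load_lesions(lesion_dir: str | Path) -> LesionCohort:
    paths = sorted(Path(lesion_dir).glob("*.nii*"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI lesions in {lesion_dir}")
    patients = []
    for p in paths:
        vol = read_volume(p)
        patients.append((p.name.split(".")[0], binarize(vol, 0.5)))
    return LesionCohort(patients)


def load_fmris(fmri_dir: str | Path) -> list[Fmri4D]:
    paths = sorted(Path(fmri_dir).glob("*.nii*"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI series in {fmri_dir}")
    return [read_volume(p) for p in paths]


def run_full(
    lesion_dir: str | Path,
    fmri_dir: str | Path,
    ref_paths: list[str | Path],
    out_dir: str | Path,
    behavior_path: str | Path | None = None,
    config: RunConfig | None = None,
) -> ICLMResult:
    """Load inputs from disk, run the full analysis, write all artifacts."""
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cohort = load_lesions(lesion_dir)
    fmris = load_fmris(fmri_dir)
    refs = []
    for rp in ref_paths:
        vol = read_volume(rp)
        uniq = np.unique(vol.data)
        kind = "binary" if np.all(np.isin(uniq, (0, 1))) else "continuous"
        refs.append(ReferenceNetwork(Path(rp).name.split(".")[0], vol, kind=kind))
    behavior = load_behavior(behavior_path) if behavior_path else None
    if behavior is not None:
        missing = set(cohort.patient_ids) - set(behavior["patient_id"])
        if missing:
            raise ValueError(f"behavior rows missing for patients: {sorted(missing)}")
    result = run_iclm(fmris, cohort, refs, behavior, cfg)

    for i, zmap in enumerate(result.decomposition.ic_zmaps):
        write_volume(zmap, out / f"ic{i + 1:02d}_zmap.nii.gz")
    write_mask(result.network.positive_mask, out / "identified_network_mask.nii.gz")
    write_mask(result.connectome.brain, out / "brain_mask.nii.gz")
    result.similarity.table.assign(
        selected=lambda d: d["ic"] == result.similarity.selected_ic
    ).to_csv(out / "similarity.csv", index=False)
    np.savetxt(out / "cross_isi.csv", result.decomposition.cross_isi, delimiter=",")
    pd.DataFrame(result.decomposition.patient_mixing,
                 index=result.connectome.fc_matrix.patient_ids).to_csv(out / "mixing.csv")
    if result.damage is not None:
        result.damage.to_csv(out / "damage.csv", index=False)
        result.behavior_correlations.to_csv(out / "behavior_correlations.csv", index=False)
    provenance = {
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
        "inputs": {
            "lesions": {p.name: _sha256(p) for p in sorted(Path(lesion_dir).glob("*.nii*"))},
            "fmri": {p.name: _sha256(p) for p in sorted(Path(fmri_dir).glob("*.nii*"))},
            "references": {str(p): _sha256(Path(p)) for p in ref_paths},
        },
        "selected_ic": int(result.similarity.selected_ic),
        "n_components": int(result.decomposition.n_components),
        "ica_runs": [
            {"seed": r.seed, "converged": bool(r.converged), "n_iter": r.n_iter}
            for r in result.decomposition.runs
        ],
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    report = [
        f"ICLM run ({len(cohort)} patients, {len(fmris)} HC runs)",
        f"brain mask: {result.connectome.brain.n_voxels} voxels",
        f"PCA order (knee point): {result.decomposition.n_components}",
        f"selected component: IC{result.similarity.selected_ic + 1}",
        result.similarity.selection_rule_trace,
    ]
    if result.behavior_correlations is not None:
        for _, row in result.behavior_correlations.iterrows():
            report.append(f"damage vs {row['measure']}: r={row['r']:+.3f} p={row['p']:.4f}")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return result
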