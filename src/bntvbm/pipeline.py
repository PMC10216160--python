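"""End-to-end orchestration: simulate/ingest -> clean -> score -> VBM -> ROI.

The pipeline analyses the control and MCI sub-cohorts separately (no fitted
quantity is shared between groups), emits descriptive and per-item summary
tables, cluster reports for the quantitative (model1), qualitative (model2)
and structural-covariance models, the post-hoc residualized ROI
correlations, and a run manifest whose participant accounting reconciles
exactly (ingested = analysed + dropped).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import item_scoring, roi_analysis, vbm_glm
from .item_scoring import load_default_norms
from .synthetic_cohort import (
    DifficultyLink,
    NeuroConfig,
    SimulationConfig,
    simulate_cohort,
)

log = logging.getLogger("bntvbm")

MEDIOTEMPORAL_ROIS = (
    "left_hippocampus",
    "right_hippocampus",
    "left_entorhinal",
    "right_entorhinal",
    "left_perirhinal",
    "right_perirhinal",
)


@dataclass
class PipelineConfig:
    """Analysis thresholds plus either a simulation section or input paths."""

    output_dir: str = "bntvbm_out"
    seed: int = 0
    n_perm: int = 200
    p_form: float = 0.01
    fwe_alpha: float = 0.05
    z_report_floor: float = 3.50
    models: tuple[str, ...] = ("model1", "model2", "structcov")
    norm_table: str | None = None  # packaged default when None
    responses: str | None = None  # real-data mode when set
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("p_form", "fwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        neuro_raw = sim_raw.pop("neuro", {})
        difficulty_raw = sim_raw.pop("difficulty", {})
        if "shape" in neuro_raw:
            neuro_raw["shape"] = tuple(neuro_raw["shape"])
        for key in (
            "ability_control", "ability_mci", "age_control", "age_mci",
            "education_control", "education_mci",
        ):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimulationConfig(
            difficulty=DifficultyLink(**difficulty_raw),
            neuro=NeuroConfig(**neuro_raw),
            **sim_raw,
        )
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(simulation=sim, **raw)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    counts: dict  # per group: ingested / dropped_* / analysed
    stages: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def reconciles(self) -> bool:
        for c in self.counts.values():
            if c["ingested"] != (
                c["analysed"] + c["dropped_missing_items"] + c["dropped_too_few_correct"]
            ):
                return False
        return True

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception, manifest: RunManifest):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def descriptives_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of demographics and scores.

    Continuous variables get a two-sample t test, pooled or Welch according
    to a Levene variance-equality check at 0.05 (the rule is recorded per
    row); the sex split gets a 2x2 chi-square.
    """
    groups = sorted(scores["group"].unique())
    if len(groups) != 2:
        raise ValueError("descriptives need exactly two groups")
    a = scores[scores["group"] == groups[0]]
    b = scores[scores["group"] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    rows = []
    for var in ("age", "education", "quantitative", "qualitative"):
        if var not in scores.columns:
            continue
        x = a[var].dropna().to_numpy(float)
        y = b[var].dropna().to_numpy(float)
        lev_p = stats.levene(x, y).pvalue
        equal_var = lev_p >= 0.05
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        rows.append(
            {
                "variable": var,
                f"mean_{groups[0]}": x.mean(),
                f"sd_{groups[0]}": x.std(ddof=1),
                f"mean_{groups[1]}": y.mean(),
                f"sd_{groups[1]}": y.std(ddof=1),
                "test": "t_pooled" if equal_var else "t_welch",
                "statistic": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
        )
    if "sex" in scores.columns:
        tab = pd.crosstab(scores["group"], scores["sex"])
        if tab.shape == (2, 2):
            if (tab.to_numpy() == 0).any():
                log.warning("zero cell in sex table; chi-square still computed")
            chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
            rows.append(
                {
                    "variable": "sex_F_M",
                    f"mean_{groups[0]}": float(tab.loc[groups[0]].get("F", 0)),
                    f"sd_{groups[0]}": float(tab.loc[groups[0]].get("M", 0)),
                    f"mean_{groups[1]}": float(tab.loc[groups[1]].get("F", 0)),
                    f"sd_{groups[1]}": float(tab.loc[groups[1]].get("M", 0)),
                    "test": "chi2",
                    "statistic": float(chi2),
                    "df": float(dof),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return aff


def _save_nifti(arr: np.ndarray, voxel_mm: float, path: Path) -> None:
    img = nib.Nifti1Image(np.nan_to_num(arr).astype(np.float32), _affine(voxel_mm))
    nib.save(img, str(path))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_config_dict(config), seed=config.seed, counts={}
    )

    def stage(name):
        manifest.stages.append(name)
        log.info("stage: %s", name)

    norms = (
        item_scoring.load_norm_table(config.norm_table)
        if config.norm_table
        else load_default_norms()
    )

    # --- ingest or simulate -------------------------------------------------
    stage("ingest")
    try:
        if config.responses:
            records = item_scoring.read_responses(config.responses)
            cohort = None
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim, norms, with_images=True)
            records = cohort.records
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("ingest", exc, manifest)

    # --- clean + score ------------------------------------------------------
    stage("clean_score")
    kept, dropped = item_scoring.clean_cohort(records, norms)
    reasons = {r.participant_id: why for r, why in dropped}
    scores = item_scoring.score_cohort(kept, norms)
    for g in sorted({r.group for r in records}):
        manifest.counts[g] = {
            "ingested": sum(1 for r in records if r.group == g),
            "dropped_missing_items": sum(
                1 for r, why in dropped if r.group == g and why == "missing_items"
            ),
            "dropped_too_few_correct": sum(
                1 for r, why in dropped if r.group == g and why == "too_few_correct"
            ),
            "analysed": sum(1 for r in kept if r.group == g),
        }
    all_pairs = [
        item_scoring.score_participant(r, norms) if r.n_missing() == 0 else None
        for r in records
    ]
    item_scoring.write_scores(records, all_pairs, reasons, out / "scores.tsv")
    manifest.outputs.append("scores.tsv")

    # --- descriptives + item summary ---------------------------------------
    stage("descriptives")
    try:
        desc = descriptives_table(scores)
        desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)
        manifest.outputs.append("descriptives.tsv")
        props = item_scoring.item_proportions(kept, norms)
        if {"prop_control", "prop_mci"}.issubset(props.columns):
            summary = item_scoring.item_summary_table(props, norms)
            for g in ("control", "mci"):
                summary.attrs[f"rho_{g}"] = item_scoring.smi_difficulty_correlation(
                    norms, props[f"prop_{g}"]
                )
            summary.to_csv(out / "item_summary.tsv", sep="\t")
            manifest.outputs.append("item_summary.tsv")
    except Exception as exc:
        raise StageError("descriptives", exc, manifest)

    if cohort is None or cohort.gm_maps is None:
        manifest.write(out / "manifest.json")
        return manifest

    # --- per-group VBM ------------------------------------------------------
    analysed = scores.merge(
        cohort.volumes.rename(columns={"bpr": "brain_parenchymal_ratio"}),
        on=["participant_id", "group"],
    )
    analysed["roi_volume"] = analysed["left_hippocampus_ml"]
    neuro = config.simulation.neuro
    mask = np.ones(neuro.shape, dtype=bool)
    idx_by_pid = {r.participant_id: i for i, r in enumerate(records)}

    for g in ("control", "mci"):
        sub = analysed[analysed["group"] == g].reset_index(drop=True)
        if sub.empty:
            continue
        rows_img = [idx_by_pid[p] for p in sub["participant_id"]]
        Y = cohort.gm_maps[rows_img].reshape(len(rows_img), -1)
        for model in config.models:
            stage(f"vbm_{model}_{g}")
            try:
                if config.n_perm < 1:
                    raise ValueError("n_perm must be >= 1")
                X, contrast = vbm_glm.build_design(sub, model)
                result = vbm_glm.cluster_fwe(
                    Y, X, contrast, mask,
                    p_form=config.p_form, n_perm=config.n_perm,
                    seed=np.random.default_rng(
                        np.random.SeedSequence(
                            [
                                config.seed,
                                100 + list(vbm_glm.MODEL_COLUMNS).index(model),
                                0 if g == "control" else 1,
                            ]
                        )
                    ),
                )
            except Exception as exc:
                raise StageError(f"vbm_{model}_{g}", exc, manifest)
            prefix = f"{model}_{g}"
            result.table.to_csv(out / f"{prefix}_clusters.tsv", sep="\t", index=False)
            report = vbm_glm.report_clusters(
                result, cohort.masks, z_floor=config.z_report_floor,
                fwe_alpha=config.fwe_alpha, voxel_mm=neuro.voxel_mm,
            )
            report.to_csv(out / f"{prefix}_peaks.tsv", sep="\t", index=False)
            _save_nifti(result.stat.t, neuro.voxel_mm, out / f"{prefix}_tmap.nii.gz")
            _save_nifti(
                result.labels.astype(float), neuro.voxel_mm,
                out / f"{prefix}_clusters.nii.gz",
            )
            manifest.outputs += [
                f"{prefix}_clusters.tsv", f"{prefix}_peaks.tsv",
                f"{prefix}_tmap.nii.gz", f"{prefix}_clusters.nii.gz",
            ]

    # --- post-hoc ROI correlations (MCI residual analysis) ------------------
    stage("roi_posthoc")
    try:
        roi_rows = []
        for g in ("control", "mci"):
            sub = analysed[analysed["group"] == g]
            if len(sub) < 10:
                continue
            resid = roi_analysis.residualize(
                sub["qualitative"], sub["quantitative"]
            )
            table = roi_analysis.roi_correlation_table(
                resid,
                {roi: sub[f"{roi}_ml"].to_numpy() for roi in MEDIOTEMPORAL_ROIS},
                tail="negative",
            )
            table.insert(0, "group", g)
            table["vif_quant_qual"] = roi_analysis.collinearity_vif(
                sub["quantitative"], sub["qualitative"]
            )
            roi_rows.append(table)
        if roi_rows:
            pd.concat(roi_rows).to_csv(
                out / "roi_correlations.tsv", sep="\t", index=False
            )
            manifest.outputs.append("roi_correlations.tsv")
    except Exception as exc:
        raise StageError("roi_posthoc", exc, manifest)

    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
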