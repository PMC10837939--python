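"""End-to-end analysis pipeline.

Stages: simulate -> score HADS -> score adherence -> impute -> fit
trajectories -> association analyses. Every stage reads and writes
delimited text under one output directory and appends an entry (inputs,
outputs, content hashes, seed) to a manifest, so a run with the same
configuration and seed reproduces every artifact byte-for-byte apart
from the manifest timestamps.

Trajectories are fitted on each imputed dataset; a subject's analysis
label is the modal group across imputations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .adherence import reconcile, score_adherence
from .association import (
    adherence_by_trajectory,
    chisq_test,
    contingency_from_labels,
    fit_ordered_logit,
    pool_ordered_logit,
    screen_univariate,
)
from .hads import CASENESS_THRESHOLD, add_caseness_columns
from .missing_data import ImputationConfig, impute
from .synthetic_cohort import CohortConfig, generate_dataset, write_dataset
from .trajectory import (
    GbtmConfig,
    GbtmFit,
    fit_gbtm_range,
    fit_to_dict,
    select_model,
    selection_table,
)

logger = logging.getLogger(__name__)

COVARIATE_COLS = (
    "age_band", "education", "income_band", "gender_identity",
    "marital_status", "sexual_role", "partner_band", "cai",
    "hiv_knowledge", "baseline_syphilis",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "preptraj_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    gbtm: GbtmConfig = field(default_factory=GbtmConfig)
    gbtm_groups: tuple[int, ...] = (1, 2, 3, 4, 5)
    caseness_threshold: int = CASENESS_THRESHOLD
    screening_threshold: float = 0.150
    significance: float = 0.050
    seed: int = 0
    with_truth: bool = False

    def validate(self) -> None:
        self.cohort.validate()
        self.imputation.validate()
        self.gbtm.validate()
        if not 0 < self.screening_threshold < 1:
            raise ValueError("screening_threshold must be in (0, 1)")
        if not 0 < self.significance < 1:
            raise ValueError("significance must be in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        imputation = ImputationConfig(**raw.pop("imputation", {}))
        gbtm = GbtmConfig(**raw.pop("gbtm", {}))
        if "gbtm_groups" in raw:
            raw["gbtm_groups"] = tuple(raw["gbtm_groups"])
        return cls(cohort=cohort, imputation=imputation, gbtm=gbtm, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.entries: list[dict] = []

    def record(self, stage: str, inputs: Sequence[Path],
               outputs: Sequence[Path], seed: int | None, **extra) -> None:
        self.entries.append({
            "stage": stage,
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seed": seed,
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **extra,
        })
        self.path.write_text(json.dumps(self.entries, indent=2))


def stage_simulate(config: PipelineConfig, out: Path,
                   manifest: _Manifest) -> dict[str, Path]:
    cohort_cfg = replace(config.cohort, seed=config.stage_seed("simulate"))
    tables = generate_dataset(cohort_cfg)
    written = write_dataset(tables, out, with_truth=config.with_truth)
    paths = {k: Path(v) for k, v in written.items()}
    manifest.record("simulate", [], list(paths.values()),
                    cohort_cfg.seed, n_subjects=len(tables["baseline"]))
    return paths


def stage_score_hads(config: PipelineConfig, out: Path,
                     manifest: _Manifest) -> Path:
    visits_path = out / "visits.csv"
    if not visits_path.exists():
        raise FileNotFoundError(f"visits table not found: {visits_path}")
    visits = pd.read_csv(visits_path)
    scored = add_caseness_columns(visits, threshold=config.caseness_threshold)
    target = out / "visits_scored.csv"
    scored.to_csv(target, index=False)
    manifest.record("score_hads", [visits_path], [target], None,
                    n_records=len(scored))
    return target


def stage_score_adherence(config: PipelineConfig, out: Path,
                          manifest: _Manifest) -> Path:
    diary_path = out / "diary.csv"
    disp_path = out / "dispensing.csv"
    for p in (diary_path, disp_path):
        if not p.exists():
            raise FileNotFoundError(f"required input not found: {p}")
    diary = pd.read_csv(diary_path)
    dispensing = pd.read_csv(disp_path)
    checked, audit = reconcile(diary, dispensing)
    scores = score_adherence(checked, dispensing)
    target = out / "adherence.csv"
    scores.to_csv(target, index=False)
    audit_path = out / "reconciliation_audit.csv"
    audit.to_csv(audit_path, index=False)
    manifest.record("score_adherence", [diary_path, disp_path],
                    [target, audit_path], None, n_records=len(scores))
    return target


def _wide_analysis_table(baseline: pd.DataFrame, visits: pd.DataFrame,
                         adherence: pd.DataFrame) -> pd.DataFrame:
    hads = visits.pivot_table(index="subject_id", columns="visit_month",
                              values=["hads_a", "hads_d"])
    hads.columns = [f"{v}_{int(m)}" for v, m in hads.columns]
    adh = adherence.pivot_table(index="subject_id", columns="visit_month",
                                values="score")
    adh.columns = [f"adh_{int(m)}" for m in adh.columns]
    wide = baseline.set_index("subject_id").join([hads, adh]).reset_index()
    return wide.drop(columns=["dropout_visit"], errors="ignore")


def stage_impute(config: PipelineConfig, out: Path,
                 manifest: _Manifest) -> list[Path]:
    inputs = [out / "baseline.csv", out / "visits_scored.csv",
              out / "adherence.csv"]
    for p in inputs:
        if not p.exists():
            raise FileNotFoundError(f"required input not found: {p}")
    baseline = pd.read_csv(inputs[0])
    visits = pd.read_csv(inputs[1])
    adherence = pd.read_csv(inputs[2])
    wide = _wide_analysis_table(baseline, visits, adherence)
    imp_cfg = replace(config.imputation, seed=config.stage_seed("impute"))
    completed = impute(wide, imp_cfg)
    targets = []
    for k, frame in enumerate(completed, start=1):
        t = out / f"imputed_{k}.csv"
        frame.to_csv(t, index=False)
        targets.append(t)
    manifest.record("impute", inputs, targets, imp_cfg.seed, m=imp_cfg.m)
    return targets


def _melt_outcome(wide: pd.DataFrame, prefix: str) -> pd.DataFrame:
    cols = [c for c in wide.columns if c.startswith(prefix)]
    long = wide.melt(id_vars="subject_id", value_vars=cols,
                     var_name="visit_month", value_name="value")
    long["visit_month"] = long["visit_month"].str.removeprefix(prefix).astype(int)
    return long.dropna(subset=["value"])


def _modal_assignments(fits: list[GbtmFit]) -> pd.DataFrame:
    """Modal group per subject across per-imputation fits; ties go to the
    smaller label. Reports the mean posterior of the modal group."""
    frames = []
    for j, fit in enumerate(fits):
        frames.append(pd.DataFrame({
            "subject_id": fit.subject_ids,
            "group": fit.assignments,
            "posterior": fit.posterior[np.arange(len(fit.assignments)),
                                       fit.assignments],
            "imputation": j,
        }))
    stacked = pd.concat(frames, ignore_index=True)
    modal = (stacked.groupby("subject_id")["group"]
             .agg(lambda g: int(np.bincount(g).argmax())).rename("group"))
    post = (stacked.merge(modal, on="subject_id",
                          suffixes=("", "_modal"))
            .query("group == group_modal")
            .groupby("subject_id")["posterior"].mean())
    return pd.DataFrame({"subject_id": modal.index, "group": modal.to_numpy(),
                         "max_posterior": post.reindex(modal.index).to_numpy()})


def stage_fit_trajectories(config: PipelineConfig, out: Path,
                           manifest: _Manifest) -> tuple[Path, Path]:
    imputed_paths = sorted(out.glob("imputed_*.csv"))
    if not imputed_paths:
        raise FileNotFoundError(f"no imputed datasets under {out}")
    imputed = [pd.read_csv(p) for p in imputed_paths]
    seed = config.stage_seed("fit_trajectories")

    report: dict = {}
    assignment_frames = []
    outcomes = {"anxiety": "hads_a_", "depression": "hads_d_",
                "adherence": "adh_"}
    for name, prefix in outcomes.items():
        per_imp_fits, per_imp_selected = [], []
        for j, wide in enumerate(imputed):
            long = _melt_outcome(wide, prefix)
            cfg = replace(config.gbtm, seed=seed + j)
            if name == "adherence":
                # Adherence ratios: noise scale varies by regimen design,
                # not by class, so classes share one residual variance.
                cfg = replace(cfg, variance="shared")
            fits = fit_gbtm_range(long, config.gbtm_groups, cfg,
                                  value_col="value")
            chosen = select_model(fits)
            per_imp_fits.append(fits)
            per_imp_selected.append(chosen)
        report[name] = {
            "selected_n_groups": [f.n_groups for f in per_imp_selected],
            "per_imputation": [
                selection_table(fits).to_dict(orient="records")
                for fits in per_imp_fits
            ],
            "selected_fit_first_imputation": fit_to_dict(per_imp_selected[0]),
        }
        modal = _modal_assignments(per_imp_selected)
        modal.insert(1, "outcome", name)
        assignment_frames.append(modal)

    traj_path = out / "trajectories.json"
    traj_path.write_text(json.dumps(report, indent=2, default=float))
    assign_path = out / "assignments.csv"
    pd.concat(assignment_frames, ignore_index=True).to_csv(assign_path,
                                                           index=False)
    manifest.record("fit_trajectories", imputed_paths,
                    [traj_path, assign_path], seed)
    return traj_path, assign_path


def stage_associate(config: PipelineConfig, out: Path,
                    manifest: _Manifest) -> list[Path]:
    inputs = [out / "baseline.csv", out / "assignments.csv",
              out / "adherence.csv"]
    for p in inputs:
        if not p.exists():
            raise FileNotFoundError(f"required input not found: {p}")
    baseline = pd.read_csv(inputs[0])
    assignments = pd.read_csv(inputs[1])
    adherence = pd.read_csv(inputs[2])
    imputed_paths = sorted(out.glob("imputed_*.csv"))
    imputed = [pd.read_csv(p) for p in imputed_paths]

    table2_rows, table3_frames, fig3_frames = [], [], []
    covariates = [c for c in COVARIATE_COLS if c in baseline.columns]
    for outcome in ("anxiety", "depression"):
        labels = assignments.query("outcome == @outcome")
        merged = baseline.merge(labels[["subject_id", "group"]],
                                on="subject_id")
        pvals = {}
        for cov in covariates:
            table = contingency_from_labels(merged[cov], merged["group"])
            try:
                res = chisq_test(table)
                pvals[cov] = res.pvalue
            except ValueError as err:
                logger.warning("%s x %s: %s", cov, outcome, err)
                continue
            table2_rows.append({"outcome": outcome, "covariate": cov,
                                "chi2": res.statistic, "df": res.df,
                                "pvalue": res.pvalue})
        selected = screen_univariate(pvals, config.screening_threshold)
        if not selected:
            logger.info("%s: no covariate passes screening", outcome)
            continue
        X_all = pd.get_dummies(merged.set_index("subject_id")[selected],
                               columns=[c for c in selected
                                        if merged[c].dtype == object],
                               drop_first=True, dtype=float)
        fits = []
        for wide in imputed or [merged]:
            y = merged.set_index("subject_id").loc[X_all.index, "group"]
            try:
                fits.append(fit_ordered_logit(y.to_numpy(), X_all))
            except ValueError as err:
                logger.warning("%s ordered logit: %s", outcome, err)
        if fits:
            pooled = pool_ordered_logit(fits, alpha=config.significance)
            pooled.insert(0, "outcome", outcome)
            table3_frames.append(pooled)

        summary, pairwise = adherence_by_trajectory(adherence, labels)
        summary.insert(0, "outcome", outcome)
        pairwise.insert(0, "outcome", outcome)
        fig3_frames.append((summary, pairwise))

    targets = []
    t2 = out / "table2.csv"
    pd.DataFrame(table2_rows).to_csv(t2, index=False)
    targets.append(t2)
    t3 = out / "table3.csv"
    (pd.concat(table3_frames, ignore_index=True)
     if table3_frames else pd.DataFrame()).to_csv(t3, index=False)
    targets.append(t3)
    f3 = out / "fig3_data.csv"
    pd.concat([s for s, _ in fig3_frames],
              ignore_index=True).to_csv(f3, index=False)
    targets.append(f3)
    f3p = out / "fig3_pairwise.csv"
    pd.concat([p for _, p in fig3_frames],
              ignore_index=True).to_csv(f3p, index=False)
    targets.append(f3p)
    manifest.record("associate", inputs + imputed_paths, targets, None)
    return targets


_STAGES = ("simulate", "score_hads", "score_adherence", "impute",
           "fit_trajectories", "associate")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; any stage error aborts with its stage name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    runners = {
        "simulate": stage_simulate,
        "score_hads": stage_score_hads,
        "score_adherence": stage_score_adherence,
        "impute": stage_impute,
        "fit_trajectories": stage_fit_trajectories,
        "associate": stage_associate,
    }
    report = {"out_dir": str(out), "seed": config.seed, "stages": []}
    for stage in _STAGES:
        logger.info("running stage %s", stage)
        try:
            runners[stage](config, out, manifest)
        except Exception as err:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(stage, str(err)) from err
        report["stages"].append(stage)
    report["manifest"] = str(manifest.path)
    return report
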