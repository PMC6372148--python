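"""End-to-end study orchestration.

Stages: ``control`` (replicate CLE ensembles at reference parameters) →
``sample`` (log-uniform random sets) / ``estimate`` (genetic local search) →
``classify`` (α-scaling + band test) → ``sensitivity`` (forward-difference
log-sensitivities) → ``analyze`` (PCA, z-scores, dominance, ratios,
correlations).  Each stage writes CSV artifacts plus a JSON manifest (config
snapshot, derived seed, input hashes) into ``outdir/<model>/``; a stage is
reproducible from its manifest alone.

Two budget profiles are built in: ``paper`` (1000 candidates, 10000 random
sets, 1000 replicates) and ``quick`` (100 / 1000 / 100), the latter sized for
desk-scale runs and the test suite.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .estimate import SearchConfig, estimate_parameters, random_sample_params
from .fit import FitnessReport, evaluate_parameter_set
from .models import MODEL_IDS, ModelSpec, build_model
from .paramsets import ParameterSet
from .sensitivity import build_sensitivity_table
from .signals import load_patterns
from .simulate import ControlData, generate_control_data
from .trend_stats import (integral_sensitivity_correlation, pairwise_dominance, pca,
                          sensitivity_matrix, zscore_across_reactions)

__all__ = ["RunConfig", "PrerequisiteError", "STAGES", "run_stage", "run_study",
           "StudyResult"]

log = logging.getLogger(__name__)

STAGES = ("control", "sample", "estimate", "classify", "sensitivity", "analyze")
_STAGE_CODE = {s: i + 1 for i, s in enumerate(STAGES)}


class PrerequisiteError(RuntimeError):
    """A required upstream artifact is missing; names the stage to run first."""


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int
    outdir: Path = Path("results")
    models: tuple[str, ...] = MODEL_IDS
    profile: str = "quick"
    n_replicates: int = 100
    dt: float = 0.01
    noise_scale: float = 1.0
    band: str = "sd"
    scaling: str = "per_pattern"
    rel_step: float = 0.001
    include_km: bool = False
    n_random: int = 1000
    n_candidates: int = 100
    sens_max_negative: int | None = 300
    search: dict = field(default_factory=dict)  # SearchConfig overrides
    log_level: str = "INFO"

    def __post_init__(self):
        self.outdir = Path(self.outdir)

    @classmethod
    def from_profile(cls, profile: str, seed: int, **kw) -> "RunConfig":
        presets = {
            "quick": dict(n_replicates=100, n_random=1000, n_candidates=100),
            "paper": dict(n_replicates=1000, n_random=10000, n_candidates=1000,
                          sens_max_negative=None),
        }
        if profile not in presets:
            raise ValueError(f"unknown profile {profile!r}")
        merged = {**presets[profile], **kw}
        return cls(seed=seed, profile=profile, **merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        raw["models"] = tuple(raw.get("models", MODEL_IDS))
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        d["models"] = list(self.models)
        return d

    def stage_seed(self, stage: str, model_id: str) -> int:
        """Deterministic derived seed: SeedSequence([root, stage code, model index])."""
        midx = list(MODEL_IDS).index(model_id) if model_id in MODEL_IDS else 99
        ss = np.random.SeedSequence([int(self.seed), _STAGE_CODE[stage], midx])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def search_config(self, model_id: str) -> SearchConfig:
        kw = dict(self.search)
        kw.setdefault("n_candidates", self.n_candidates)
        kw.setdefault("n_random", self.n_random)
        return SearchConfig(seed=self.stage_seed("estimate", model_id), **kw)

    def model_dir(self, model_id: str) -> Path:
        return self.outdir / model_id


# ---------------------------------------------------------------------------
# artifact I/O


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, model_id: str,
                    inputs: Sequence[Path], outputs: Sequence[Path]) -> None:
    man = {
        "stage": stage,
        "model": model_id,
        "seed": cfg.stage_seed(stage, model_id),
        "root_seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": [p.name for p in outputs],
        "package_version": _pkg_version,
    }
    path = cfg.model_dir(model_id) / f"{stage}.manifest.json"
    path.write_text(json.dumps(man, indent=2, sort_keys=True) + "\n")


def _require(cfg: RunConfig, model_id: str, filename: str, produced_by: str) -> Path:
    path = cfg.model_dir(model_id) / filename
    if not path.exists():
        raise PrerequisiteError(
            f"{filename} for {model_id} not found; run the '{produced_by}' stage first")
    return path


def _control_path(cfg, model_id):
    return cfg.model_dir(model_id) / "control.csv"


def save_control(control: ControlData, directory: Path) -> list[Path]:
    directory.mkdir(parents=True, exist_ok=True)
    csv = directory / "control.csv"
    control.to_frame().to_csv(csv, index=False)
    meta = directory / "control.json"
    meta.write_text(json.dumps({
        "model": control.model_id, "n_replicates": control.n_replicates,
        "dt": control.dt, "seed": control.rng_seed, "noise_scale": control.noise_scale,
        "sample_times": list(map(float, control.sample_times)),
        "patterns": list(control.pattern_ids),
    }, indent=2) + "\n")
    return [csv, meta]


def load_control(directory: Path) -> ControlData:
    meta = json.loads((directory / "control.json").read_text())
    df = pd.read_csv(directory / "control.csv")
    pats = meta["patterns"]
    st = np.array(meta["sample_times"], float)
    mean = np.empty((len(pats), st.size)); sd = np.empty_like(mean)
    for i, pid in enumerate(pats):
        sub = df[df["pattern"] == pid].sort_values("time")
        mean[i] = sub["mean"].to_numpy()
        sd[i] = sub["sd"].to_numpy()
    se = sd / np.sqrt(meta["n_replicates"])
    return ControlData(meta["model"], tuple(pats), st, mean, sd, se,
                       meta["n_replicates"], meta["dt"], meta["seed"],
                       meta["noise_scale"])


def sets_to_frame(model: ModelSpec, sets: Sequence[ParameterSet],
                  reports: Sequence[FitnessReport] | None = None) -> pd.DataFrame:
    rows = []
    for i, ps in enumerate(sets):
        row = {"id": ps.id, "provenance": ps.provenance,
               "fitness": ps.fitness, "label": ps.label}
        if reports is not None:
            rep = reports[i]
            row.update(fitness=rep.fitness, label=rep.label, excluded=rep.excluded)
            for pid, a in zip(load_patterns(), rep.alpha_per_pattern):
                row[f"alpha_{pid.id}"] = a
        for name, lv in zip(ps.param_names, ps.log_values):
            row[f"log_{name}"] = lv
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_sets(model: ModelSpec, df: pd.DataFrame) -> list[ParameterSet]:
    cols = [f"log_{name}" for name in model.param_names]
    out = []
    for _, row in df.iterrows():
        out.append(ParameterSet(
            id=row["id"], model_id=model.id, param_names=model.param_names,
            log_values=row[cols].to_numpy(float),
            provenance=row.get("provenance", "random"),
            fitness=None if pd.isna(row.get("fitness")) else float(row["fitness"]),
            label=row.get("label", "unclassified")))
    return out


# ---------------------------------------------------------------------------
# stages


def stage_control(cfg: RunConfig, model_id: str) -> list[Path]:
    model = build_model(model_id)
    control = generate_control_data(
        model, n_replicates=cfg.n_replicates, dt=cfg.dt,
        seed=cfg.stage_seed("control", model_id), noise_scale=cfg.noise_scale)
    outs = save_control(control, cfg.model_dir(model_id))
    _write_manifest(cfg, "control", model_id, [], outs)
    return outs


def stage_sample(cfg: RunConfig, model_id: str) -> list[Path]:
    model = build_model(model_id)
    sets = random_sample_params(model, cfg.n_random, cfg.stage_seed("sample", model_id))
    d = cfg.model_dir(model_id)
    d.mkdir(parents=True, exist_ok=True)
    path = d / "random.csv"
    sets_to_frame(model, sets).to_csv(path, index=False)
    _write_manifest(cfg, "sample", model_id, [], [path])
    return [path]


def stage_estimate(cfg: RunConfig, model_id: str) -> list[Path]:
    model = build_model(model_id)
    control = load_control(_require(cfg, model_id, "control.csv", "control").parent)
    sets = estimate_parameters(model, control, cfg.search_config(model_id))
    d = cfg.model_dir(model_id)
    path = d / "candidates.csv"
    sets_to_frame(model, sets).to_csv(path, index=False)
    _write_manifest(cfg, "estimate", model_id, [_control_path(cfg, model_id)], [path])
    return [path]


def stage_classify(cfg: RunConfig, model_id: str) -> list[Path]:
    model = build_model(model_id)
    control = load_control(_require(cfg, model_id, "control.csv", "control").parent)
    inputs = [_control_path(cfg, model_id)]
    sets: list[ParameterSet] = [ParameterSet.from_values(
        model, model.reference_params, id=f"{model_id}-orig", provenance="original")]
    for fname, stage in (("candidates.csv", "estimate"), ("random.csv", "sample")):
        path = cfg.model_dir(model_id) / fname
        if path.exists():
            sets.extend(frame_to_sets(model, pd.read_csv(path)))
            inputs.append(path)
    if len(sets) == 1:
        raise PrerequisiteError(
            f"no candidate or random sets for {model_id}; run 'estimate' or 'sample' first")
    cm = model.compile()
    reports, labeled = [], []
    for ps in sets:
        rep = evaluate_parameter_set(model, ps, control, band=cfg.band,
                                     scaling=cfg.scaling, compiled=cm)
        reports.append(rep)
        labeled.append(ps.with_label("excluded" if rep.excluded else rep.label,
                                     rep.fitness))
    path = cfg.model_dir(model_id) / "classified.csv"
    sets_to_frame(model, labeled, reports).to_csv(path, index=False)
    n_pos = sum(r.label == "positive" for r in reports)
    log.info("%s: %d positive / %d sets (%d excluded)", model_id, n_pos, len(sets),
             sum(r.excluded for r in reports))
    _write_manifest(cfg, "classify", model_id, inputs, [path])
    return [path]


def stage_sensitivity(cfg: RunConfig, model_id: str) -> list[Path]:
    model = build_model(model_id)
    cls_path = _require(cfg, model_id, "classified.csv", "classify")
    df = pd.read_csv(cls_path)
    keep = df[df["label"].isin(["positive", "negative"])]
    if cfg.sens_max_negative is not None:
        neg = keep[keep["label"] == "negative"].head(cfg.sens_max_negative)
        keep = pd.concat([keep[keep["label"] == "positive"], neg])
    sets = frame_to_sets(model, keep)
    table = build_sensitivity_table(model, sets, rel_step=cfg.rel_step,
                                    include_km=cfg.include_km)
    path = cfg.model_dir(model_id) / "sensitivity.csv"
    table.to_csv(path, index=False)
    _write_manifest(cfg, "sensitivity", model_id, [cls_path], [path])
    return [path]


def stage_analyze(cfg: RunConfig, model_id: str) -> list[Path]:
    model = build_model(model_id)
    sens_path = _require(cfg, model_id, "sensitivity.csv", "sensitivity")
    cls_path = _require(cfg, model_id, "classified.csv", "classify")
    table = pd.read_csv(sens_path)
    classified = pd.read_csv(cls_path)
    d = cfg.model_dir(model_id)
    outs = []

    # dominance + z-scores per pattern (signed, per the banding convention,
    # plus magnitude-based dominance for the strength reading)
    dom_rows, mag_rows, z_frames = [], [], []
    for pid in table["pattern"].unique():
        try:
            dom = pairwise_dominance(table, pid)
            dom.insert(0, "pattern", pid)
            dom_rows.append(dom)
            mag = pairwise_dominance(table, pid, use_magnitude=True)
            mag.insert(0, "pattern", pid)
            mag_rows.append(mag)
        except ValueError:
            continue
        z = zscore_across_reactions(table, pid)
        z = z.reset_index().melt(id_vars="set_id", var_name="reaction", value_name="z")
        z.insert(1, "pattern", pid)
        z_frames.append(z)
    if dom_rows:
        p = d / "dominance.csv"; pd.concat(dom_rows).to_csv(p, index=False); outs.append(p)
        p = d / "dominance_magnitude.csv"
        pd.concat(mag_rows).to_csv(p, index=False); outs.append(p)
        p = d / "zscores.csv"; pd.concat(z_frames).to_csv(p, index=False); outs.append(p)

    # PCA of sensitivity (positive sets, reactions x patterns as variables)
    wide = sensitivity_matrix(table, label_filter="positive")
    if wide.shape[0] >= 2 and wide.shape[1] >= 2:
        res = pca(wide)
        scores = pd.DataFrame(res.scores[:, :2], index=wide.index, columns=["PC1", "PC2"])
        p = d / "pca_sensitivity_scores.csv"; scores.to_csv(p); outs.append(p)
        load_df = pd.DataFrame(res.loadings[:, :2],
                               index=[f"{a}|{b}" for a, b in wide.columns],
                               columns=["PC1", "PC2"])
        load_df["explained_1"] = res.explained_variance_ratio[0]
        load_df["explained_2"] = res.explained_variance_ratio[1] \
            if res.explained_variance_ratio.size > 1 else 0.0
        p = d / "pca_sensitivity_loadings.csv"; load_df.to_csv(p); outs.append(p)

    # PCA of the positive log-parameter values
    pos = classified[classified["label"] == "positive"]
    log_cols = [f"log_{n}" for n in model.param_names]
    if len(pos) >= 2:
        res = pca(pos.set_index("id")[log_cols])
        scores = pd.DataFrame(res.scores[:, :2], index=pos["id"], columns=["PC1", "PC2"])
        p = d / "pca_params_scores.csv"; scores.to_csv(p); outs.append(p)

    corr = integral_sensitivity_correlation(table)
    p = d / "correlations.csv"; corr.to_csv(p, index=False); outs.append(p)

    summary = _summarize(model, classified, table, corr)
    p = d / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    outs.append(p)
    _write_manifest(cfg, "analyze", model_id, [sens_path, cls_path], outs)
    return outs


#: deactivation-type reactions whose sensitivities are expected negative
NEGATIVE_REACTIONS = ("D", "DS", "FBA", "FFA")


def _summarize(model: ModelSpec, classified: pd.DataFrame, table: pd.DataFrame,
               corr: pd.DataFrame) -> dict:
    pos_tab = table[table["label"] == "positive"]
    neg_mask = pos_tab["reaction"].isin(NEGATIVE_REACTIONS)
    frac_neg = float((pos_tab[neg_mask]["s_log"] < 0).mean()) if neg_mask.any() else None
    n_full, n_split = 0, 0
    for pid in table["pattern"].unique():
        try:
            dom = pairwise_dominance(table, pid)
        except ValueError:
            continue
        half = dom.iloc[::2]  # one row per unordered pair
        n_full += int(((half["pct_greater"] == 100.0) | (half["pct_less"] == 100.0)).sum())
        n_split += int(((half["pct_greater"] > 0) & (half["pct_less"] > 0)).sum())
    fitness = classified.loc[classified["provenance"] == "original", "fitness"]
    return {
        "model": model.id,
        "n_sets": int(len(classified)),
        "n_positive": int((classified["label"] == "positive").sum()),
        "n_negative": int((classified["label"] == "negative").sum()),
        "n_excluded": int((classified["label"] == "excluded").sum()),
        "best_fitness": float(classified["fitness"].min()),
        "original_fitness": float(fitness.iloc[0]) if len(fitness) else None,
        "original_label": str(classified.loc[classified["provenance"] == "original",
                                             "label"].iloc[0]) if len(fitness) else None,
        "frac_negative_reaction_sens_below_zero": frac_neg,
        "n_invariant_dominance_pairs": n_full,
        "n_split_dominance_pairs": n_split,
        "max_abs_pearson_r": float(corr["pearson_r"].abs().max())
        if corr["pearson_r"].notna().any() else None,
    }


def run_stage(stage: str, cfg: RunConfig, *, dry_run: bool = False) -> dict[str, list[Path]]:
    """Run one stage (or 'all') for every configured model."""
    if stage != "all" and stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    stages = STAGES if stage == "all" else (stage,)
    plan = {s: list(cfg.models) for s in stages}
    if dry_run:
        for s, models in plan.items():
            log.info("would run %s for %s into %s", s, models, cfg.outdir)
        return {}
    fns = {"control": stage_control, "sample": stage_sample, "estimate": stage_estimate,
           "classify": stage_classify, "sensitivity": stage_sensitivity,
           "analyze": stage_analyze}
    out: dict[str, list[Path]] = {}
    for s in stages:
        for m in cfg.models:
            out.setdefault(s, []).extend(fns[s](cfg, m))
    return out


# ---------------------------------------------------------------------------
# in-memory study (used by the acceptance checks)


@dataclass
class StudyResult:
    model: ModelSpec
    control: ControlData
    sets: list[ParameterSet]
    reports: list[FitnessReport]
    positives: list[ParameterSet]
    sensitivity: pd.DataFrame

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def best_fitness(self) -> float:
        return min(r.fitness for r in self.reports)


def run_study(model_id: str, seed: int, *, cfg: RunConfig | None = None,
              max_positive_sens: int | None = 60,
              include_negative_sens: int = 0) -> StudyResult:
    """Control data → estimation → classification → sensitivity, in memory.

    ``max_positive_sens`` caps how many positive sets enter the sensitivity
    table (best fitness first); negatives can be added for the ensemble-wide
    statistics.
    """
    cfg = cfg or RunConfig.from_profile("quick", seed)
    model = build_model(model_id)
    control = generate_control_data(model, n_replicates=cfg.n_replicates, dt=cfg.dt,
                                    seed=cfg.stage_seed("control", model_id),
                                    noise_scale=cfg.noise_scale)
    candidates = estimate_parameters(model, control, cfg.search_config(model_id))
    randoms = random_sample_params(model, cfg.n_random, cfg.stage_seed("sample", model_id))
    original = ParameterSet.from_values(model, model.reference_params,
                                        id=f"{model_id}-orig", provenance="original")
    sets = [original] + candidates + randoms
    cm = model.compile()
    reports, labeled = [], []
    for ps in sets:
        rep = evaluate_parameter_set(model, ps, control, band=cfg.band,
                                     scaling=cfg.scaling, compiled=cm)
        reports.append(rep)
        labeled.append(ps.with_label("excluded" if rep.excluded else rep.label,
                                     rep.fitness))
    positives = [ps for ps in labeled if ps.label == "positive"]
    sens_sets = sorted(positives, key=lambda p: np.inf if p.fitness is None else p.fitness)
    if max_positive_sens is not None:
        sens_sets = sens_sets[:max_positive_sens]
    if include_negative_sens:
        sens_sets = sens_sets + [ps for ps in labeled
                                 if ps.label == "negative"][:include_negative_sens]
    table = build_sensitivity_table(model, sens_sets, rel_step=cfg.rel_step,
                                    include_km=cfg.include_km)
    return StudyResult(model, control, labeled, reports, positives, table)
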