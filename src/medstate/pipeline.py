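"""End-to-end orchestration: simulate -> features -> decode -> clinical -> stats.

A single :class:`PipelineConfig` drives every stage; all randomness derives
from its top-level seed via stable per-stage streams, so a rerun with the
same config reproduces every artifact bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayesopt, clinical, decoder, spectral, stats, synthetic


@dataclass
class PipelineConfig:
    n_subjects: int = 20
    duration_s: float = 180.0
    sampling_rate_hz: float = 1000.0
    seed: int = 0
    effect_log_power_shift: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    clinical_coupling: float | tuple[float, ...] = 0.0
    k_folds: int = 10
    standardization: str = "global"
    balancing: str = "tail"
    optimize_c: bool = True
    fixed_c: float = 1.0
    opt_bounds: tuple[float, float] = (-6.0, 6.0)
    opt_max_evals: int = 30
    alpha: float = 0.05
    bh_q: float = 0.05
    spectral: spectral.FeatureConfig = field(default_factory=spectral.FeatureConfig)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["spectral"] = asdict(self.spectral)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        is_path = isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source)
        if is_path and Path(source).exists():
            d = yaml.safe_load(Path(source).read_text())
        else:
            d = yaml.safe_load(source)
        sp = d.pop("spectral", None)
        cfg = cls(**{k: _tuplify(v) for k, v in d.items()})
        if sp is not None:
            sp["bands"] = tuple(tuple(b) for b in sp.get(
                "bands", spectral.DEFAULT_BANDS))
            sp["rejection_band"] = tuple(sp.get("rejection_band", (50.0, 330.0)))
            cfg.spectral = spectral.FeatureConfig(**sp)
        return cfg


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def stage_seed(top_seed: int, stage: str, subject_id: str = "") -> int:
    """Stable per-stage seed derived from the top-level seed."""
    digest = hashlib.blake2s(f"{top_seed}|{stage}|{subject_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def cohort_from_config(config: PipelineConfig) -> synthetic.CohortSpec:
    if any(config.effect_log_power_shift) or np.any(
            np.atleast_1d(config.clinical_coupling)):
        return synthetic.effect_cohort(
            config.n_subjects, config.seed,
            effect=config.effect_log_power_shift,
            coupling=config.clinical_coupling,
            duration_s=config.duration_s, fs=config.sampling_rate_hz)
    return synthetic.null_cohort(config.n_subjects, config.seed,
                                 config.duration_s, config.sampling_rate_hz)


def decode_subject(table: pd.DataFrame, config: PipelineConfig,
                   subject_id: str) -> tuple[decoder.DecodeResult, dict | None]:
    """Hyperparameter search (optional) plus the final cross-validation."""
    if config.optimize_c:
        seed = stage_seed(config.seed, "bayesopt", subject_id)
        C, trace = bayesopt.select_box_constraint(
            table, k=config.k_folds, seed=seed, bounds=config.opt_bounds,
            max_evals=config.opt_max_evals,
            standardization=config.standardization)
        trace_dict = trace.to_dict()
    else:
        C, trace_dict = config.fixed_c, None
    result = decoder.cross_validate(table, C, config.k_folds,
                                    config.standardization)
    return result, trace_dict


def run_full_pipeline(config: PipelineConfig, outdir=None,
                      log=print) -> dict:
    """Run every stage; return (and optionally persist) the report bundle."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    log(f"[simulate] n_subjects={config.n_subjects} seed={config.seed}")
    cohort = synthetic.generate_cohort(cohort_from_config(config))

    feature_tables: dict[str, pd.DataFrame] = {}
    results: list[decoder.DecodeResult] = []
    traces: dict[str, dict] = {}
    for spec in cohort.spec.subject_specs:
        sid = spec.subject_id
        log(f"[features] subject={sid}")
        try:
            table = spectral.build_feature_table(
                cohort.subject_recordings(sid), config.spectral)
        except ValueError as exc:
            raise RuntimeError(f"stage=features subject={sid}: {exc}") from exc
        feature_tables[sid] = table
        log(f"[decode] subject={sid} n_samples={len(table)}")
        try:
            result, trace = decode_subject(table, config, sid)
        except ValueError as exc:
            raise RuntimeError(f"stage=decode subject={sid}: {exc}") from exc
        results.append(result)
        if trace is not None:
            traces[sid] = trace

    log("[clinical] factor scores")
    structure = clinical.default_factor_structure()
    all_scores = []
    off_mat, on_mat = [], []
    for spec in cohort.spec.subject_specs:
        per_cond = {}
        for cond in synthetic.CONDITIONS:
            ratings = clinical.ItemRatings(
                spec.subject_id, cond, cohort.ratings[(spec.subject_id, cond)])
            per_cond[cond] = clinical.factor_scores(ratings, structure)
            all_scores.append(per_cond[cond])
        off_mat.append(per_cond["OFF"].weighted_averages)
        on_mat.append(per_cond["ON"].weighted_averages)
    off_mat = np.array(off_mat)
    on_mat = np.array(on_mat)
    change = off_mat - on_mat

    log("[stats] clinical battery and accuracy regressions")
    battery = stats.clinical_battery(change, off_mat, on_mat, q=config.bh_q)
    rho, pmat = stats.spearman_matrix(change) if len(change) >= 4 else (None, None)
    accuracies = np.array([r.median_accuracy for r in results])
    regressions = None
    if len(accuracies) >= 3 and accuracies.std() > 0:
        regressions = stats.accuracy_change_regression(accuracies, change)

    bundle = {
        "config": config,
        "cohort": cohort,
        "feature_tables": feature_tables,
        "decode_results": results,
        "opt_traces": traces,
        "factor_scores": all_scores,
        "change_matrix": change,
        "battery": battery,
        "spearman": (rho, pmat),
        "regressions": regressions,
    }
    if out is not None:
        _persist(bundle, out)
    return bundle


def _persist(bundle: dict, out: Path) -> None:
    pd.concat(bundle["feature_tables"].values()).to_csv(
        out / "features.csv", index=False, float_format="%.10g")
    rejection = [entry for table in bundle["feature_tables"].values()
                 for entry in table.attrs.get("rejection_log", [])]
    if rejection:
        pd.DataFrame(rejection).to_csv(out / "rejection_log.csv", index=False)
    decoder.results_to_frame(bundle["decode_results"]).to_csv(
        out / "decoding.csv", index=False, float_format="%.10g")
    with open(out / "decode_results.json", "w") as f:
        json.dump([r.to_dict() for r in bundle["decode_results"]], f, indent=1)
    if bundle["opt_traces"]:
        with open(out / "opt_traces.json", "w") as f:
            json.dump(bundle["opt_traces"], f, indent=1)
    clinical.scores_to_frame(bundle["factor_scores"]).to_csv(
        out / "factor_scores.csv", index=False, float_format="%.10g")
    bundle["battery"].to_csv(out / "stats_battery.csv", index=False,
                             float_format="%.10g")
    if bundle["regressions"] is not None:
        with open(out / "regressions.json", "w") as f:
            json.dump({
                f"factor_{i + 1}": {
                    "slope": r.slope, "intercept": r.intercept,
                    "r_squared": r.r_squared, "p_value": r.p_value,
                } for i, r in enumerate(bundle["regressions"])}, f, indent=1)
    (out / "report.md").write_text(render_report(bundle))


def render_report(bundle: dict) -> str:
    results = bundle["decode_results"]
    accuracies = np.array([r.median_accuracy for r in results])
    lines = [
        "# Pipeline report",
        "",
        f"Subjects: {len(results)}",
        f"Grand median of per-subject median accuracies: "
        f"{np.median(accuracies):.3f}",
        "",
        "## Per-subject decoding",
        "",
        "| subject | median accuracy | box constraint |",
        "|---|---|---|",
    ]
    for r in results:
        lines.append(f"| {r.subject_id} | {r.median_accuracy:.3f} | "
                     f"{r.box_constraint:.3g} |")
    lines += ["", "## Clinical battery", ""]
    lines.append(bundle["battery"].to_string(index=False))
    if bundle["regressions"] is not None:
        lines += ["", "## Accuracy vs factor change regressions", ""]
        for i, r in enumerate(bundle["regressions"]):
            lines.append(f"- factor {i + 1}: R^2={r.r_squared:.3f}, "
                         f"unadjusted p={r.p_value:.4f}")
    return "\n".join(lines) + "\n"


def load_external_tables(accuracies_csv=None, changes_csv=None,
                         ratings_csv=None) -> dict:
    """Validate externally supplied tables for direct entry into the stats stage."""
    out: dict = {}
    if ratings_csv is not None:
        df = pd.read_csv(ratings_csv, dtype={"item_code": str})
        out["ratings"] = clinical.ratings_from_frame(df)
    if accuracies_csv is not None:
        df = pd.read_csv(accuracies_csv)
        missing = {"subject_id", "median_accuracy"} - set(df.columns)
        if missing:
            raise ValueError(f"accuracy table missing columns: {sorted(missing)}")
        out["accuracies"] = df
    if changes_csv is not None:
        df = pd.read_csv(changes_csv)
        required = {"subject_id"} | {f"factor_{i}" for i in range(1, 8)}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"change table missing columns: {sorted(missing)}")
        out["changes"] = df
    return out
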