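"""End-to-end study orchestration: runs -> measures -> reports.

The stage order mirrors the analysis sequence: preprocess each run,
stage vigilance from pupil loss, drop Discarded runs, extract the nine
measures, collapse runs per subject and state, screen outliers, then
compute reliability (ICC(2,k) and within-subject correlations), the
paired vigilant-vs-drowsy ANOVA, and twin heritability with the pair
table duplicated across vigilance states.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from biprkit import bipr, stats, twin, vigilance
from biprkit.bipr import MEASURE_NAMES
from biprkit.eyetrack import FilterSpec, PupilTrace, parse_asc_samples, preprocess
from biprkit.synthetic import (
    BIPRKernel,
    SimRunParams,
    TwinCohortSpec,
    simulate_pupil_run,
    simulate_twin_cohort,
)

log = logging.getLogger("biprkit.pipeline")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, run_id: str, message: str):
        super().__init__(f"stage {stage!r} failed for {run_id!r}: {message}")
        self.stage = stage
        self.run_id = run_id


@dataclass
class StudyConfig:
    """Every tunable of the pipeline; defaults follow the published values
    where one exists (thresholds, windows, the 0.05/9 correction)."""

    mode: str = "synthetic"  # or "asc_dir"
    seed: int = 0

    # synthetic cohort
    n_mz_pairs: int = 44
    n_dz_pairs: int = 36
    cohort_model: str = "AE"
    a2: float = 0.62
    c2_or_d2: float = 0.0
    e2: float = 0.38
    age_range: Tuple[float, float] = (22.0, 36.0)

    # synthetic runs
    runs_per_subject: int = 4
    run_duration_s: float = 160.0
    sampling_hz: int = 1000
    blink_rate_per_min: float = 12.0
    closure_targets: Tuple[float, ...] = (0.02, 0.02, 0.20, 0.20)
    noise_sd: float = 5.0
    kernel: BIPRKernel = field(default_factory=BIPRKernel)
    # heritable measure mapping: blink-duration centre = base + scale * latent
    heritable_measure: str = "blink_duration"
    blink_duration_center_au: float = 220.0
    blink_duration_scale_au: float = 30.0
    blink_duration_halfwidth_ms: float = 20.0

    # asc mode
    asc_dir: Optional[str] = None
    metadata_path: Optional[str] = None

    # analysis tunables
    vigilance_thresholds: Tuple[float, float, float] = (0.10, 0.40, 0.75)
    d_window_ms: Tuple[float, float] = (50.0, 900.0)
    c_window_ms: Tuple[float, float] = (300.0, 2500.0)
    min_epochs: int = 5
    outlier_multiplier: float = 2.0
    family_alpha: float = 0.05
    n_comparisons: int = 9
    filter_low_cutoff_hz: float = 0.02
    filter_high_cutoff_hz: float = 4.0
    filter_lp_order_factor: float = 3.0
    filter_hp_order_factor: float = 3.0
    heritability_covariates: bool = True
    heritability_ci: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "kernel" in raw and isinstance(raw["kernel"], dict):
            raw["kernel"] = BIPRKernel(**raw["kernel"])
        for key in ("closure_targets", "vigilance_thresholds", "d_window_ms",
                    "c_window_ms", "age_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.filter_low_cutoff_hz, self.filter_high_cutoff_hz,
                          self.filter_lp_order_factor, self.filter_hp_order_factor)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    measures: pd.DataFrame           # per run
    collapsed: pd.DataFrame          # per subject x state, outlier-screened
    classification: pd.DataFrame
    icc: pd.DataFrame
    anova: pd.DataFrame
    heritability: Optional[twin.HeritabilityResult]
    heritability_note: str
    manifest: Dict


def _run_measures(trace: PupilTrace, cfg: StudyConfig) -> Tuple[bipr.EyeMeasures, str, float]:
    """Preprocess one raw trace; returns (measures, merged state label, loss)."""
    from biprkit.eyetrack import detect_blinks, resample_to_1khz

    up = resample_to_1khz(trace)
    loss = vigilance.pupil_loss_fraction(up)
    state = vigilance.classify_run(loss, cfg.vigilance_thresholds)
    merged = vigilance.merge_label(state.label)
    if merged == vigilance.DISCARDED:
        return bipr.EyeMeasures(), merged, loss

    down, interp, blinks, closures = preprocess(trace, cfg.filter_spec())
    epochs = bipr.extract_epochs(down, blinks)
    profile = bipr.average_bipr(epochs, min_epochs=cfg.min_epochs)
    measures = bipr.compute_eye_measures(
        interp, blinks, closures, profile,
        d_window_ms=cfg.d_window_ms, c_window_ms=cfg.c_window_ms)
    return measures, merged, loss


def collapse_runs_per_state(measures: pd.DataFrame) -> pd.DataFrame:
    """Mean over available runs per (subject, state, measure), missing-aware."""
    meta_cols = [c for c in ("family_id", "zygosity", "twin_index", "age", "sex")
                 if c in measures.columns]
    agg = {c: "mean" for c in MEASURE_NAMES}
    agg.update({c: "first" for c in meta_cols})
    out = (measures.groupby(["subject_id", "state"], as_index=False)
           .agg(agg))
    return out


def screen_outliers(collapsed: pd.DataFrame, multiplier: float = 2.0) -> pd.DataFrame:
    """NaN-out values beyond 2 IQR of the quartiles, per state and measure."""
    out = collapsed.copy()
    for state, grp in collapsed.groupby("state"):
        for col in MEASURE_NAMES:
            keep = bipr.iqr_keep_mask(grp[col].to_numpy(dtype=float), multiplier)
            bad_idx = grp.index[~keep]
            out.loc[bad_idx, col] = np.nan
    return out


def build_pair_table(collapsed: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Twin-pair rows for one measure, one row per family per vigilance
    state (pairs duplicated across states, vig covariate 1/2)."""
    rows = []
    vig_code = {vigilance.VIGILANT: 1, vigilance.ALL_DROWSY: 2}
    for (fam, state), grp in collapsed.groupby(["family_id", "state"]):
        if state not in vig_code:
            continue
        twins = grp.sort_values("twin_index")
        if len(twins) != 2:
            continue
        t1, t2 = twins.iloc[0], twins.iloc[1]
        rows.append({
            "family_id": fam, "zygosity": t1["zygosity"],
            "y1": t1[measure], "y2": t2[measure],
            "age1": t1["age"], "age2": t2["age"],
            "sex1": t1["sex"], "sex2": t2["sex"],
            "vig1": vig_code[state], "vig2": vig_code[state],
        })
    return pd.DataFrame(rows)


def _synthetic_runs(cfg: StudyConfig):
    """Yield (subject row dict, [raw traces]) for the synthetic cohort."""
    spec = TwinCohortSpec(
        n_mz_pairs=cfg.n_mz_pairs, n_dz_pairs=cfg.n_dz_pairs,
        model=cfg.cohort_model, a2=cfg.a2, c2_or_d2=cfg.c2_or_d2, e2=cfg.e2,
        age_range=cfg.age_range, seed=cfg.seed,
    )
    cohort = simulate_twin_cohort(spec)
    subjects = []
    for _, pair in cohort.iterrows():
        for twin_index in (1, 2):
            subjects.append({
                "subject_id": f"fam{pair['family_id']:04d}_t{twin_index}",
                "family_id": int(pair["family_id"]),
                "zygosity": pair["zygosity"],
                "twin_index": twin_index,
                "age": float(pair[f"age{twin_index}"]),
                "sex": int(pair[f"sex{twin_index}"]),
                "latent": float(pair[f"u{twin_index}"]),
            })
    for si, subj in enumerate(subjects):
        center = np.clip(
            cfg.blink_duration_center_au
            + cfg.blink_duration_scale_au * subj["latent"],
            40.0 + cfg.blink_duration_halfwidth_ms,
            400.0 - cfg.blink_duration_halfwidth_ms,
        )
        traces = []
        for ri in range(cfg.runs_per_subject):
            closure = cfg.closure_targets[ri % len(cfg.closure_targets)]
            params = SimRunParams(
                duration_s=cfg.run_duration_s,
                sampling_hz=cfg.sampling_hz,
                blink_rate_per_min=cfg.blink_rate_per_min,
                blink_duration_range_ms=(
                    float(center - cfg.blink_duration_halfwidth_ms),
                    float(center + cfg.blink_duration_halfwidth_ms)),
                closure_target_fraction=float(closure),
                kernel=cfg.kernel,
                noise_sd=cfg.noise_sd,
                seed=cfg.seed * 1_000_003 + si * 101 + ri,
            )
            trace, _ = simulate_pupil_run(params)
            traces.append(trace)
        yield subj, traces


def _asc_runs(cfg: StudyConfig):
    meta = pd.read_csv(cfg.metadata_path)
    asc_dir = Path(cfg.asc_dir)
    for _, row in meta.iterrows():
        subj = {
            "subject_id": str(row["subject_id"]),
            "family_id": row.get("family_id"),
            "zygosity": row.get("zygosity"),
            "twin_index": row.get("twin_index", 1),
            "age": row.get("age", np.nan),
            "sex": row.get("sex", np.nan),
        }
        traces = []
        for path in sorted(asc_dir.glob(f"{subj['subject_id']}_*.asc")):
            with open(path) as fh:
                traces.append(parse_asc_samples(fh))
        yield subj, traces


def run_study(cfg: StudyConfig, out_dir: Optional[str] = None) -> StudyResult:
    """Execute a full study and (optionally) write the report bundle."""
    source = _synthetic_runs(cfg) if cfg.mode == "synthetic" else _asc_runs(cfg)

    rows, class_rows = [], []
    state_counts: Dict[str, int] = {}
    for subj, traces in source:
        for ri, trace in enumerate(traces):
            run_id = f"{subj['subject_id']}_run{ri + 1}"
            try:
                measures, state, loss = _run_measures(trace, cfg)
            except Exception as exc:  # noqa: BLE001 - stage errors abort with context
                raise PipelineError("preprocess", run_id, str(exc)) from exc
            state_counts[state] = state_counts.get(state, 0) + 1
            class_rows.append({"run_id": run_id, "loss_fraction": loss,
                               "state": state})
            if state == vigilance.DISCARDED:
                continue
            row = {"subject_id": subj["subject_id"],
                   "family_id": subj.get("family_id"),
                   "zygosity": subj.get("zygosity"),
                   "twin_index": subj.get("twin_index"),
                   "age": subj.get("age"), "sex": subj.get("sex"),
                   "run_id": run_id, "state": state,
                   "n_epochs": measures.n_epochs}
            row.update(measures.as_dict())
            rows.append(row)
    measures_df = pd.DataFrame(rows)
    classification = pd.DataFrame(class_rows)
    log.info("runs per state: %s", dict(sorted(state_counts.items())))

    alpha = stats.bonferroni_alpha(cfg.family_alpha, cfg.n_comparisons)
    icc_rows, anova_rows = [], []
    heritability = None
    note = ""
    collapsed = pd.DataFrame()

    if measures_df.empty:
        note = "no usable runs: heritability stage skipped"
        log.info(note)
    else:
        collapsed = collapse_runs_per_state(measures_df)
        collapsed = screen_outliers(collapsed, cfg.outlier_multiplier)

        # ICC(2,k) per state and measure on per-run values
        for state, grp in measures_df.groupby("state"):
            grp = grp.copy()
            grp["run_order"] = grp.groupby("subject_id").cumcount()
            for col in MEASURE_NAMES:
                wide = grp.pivot_table(index="subject_id", columns="run_order",
                                       values=col, aggfunc="first")
                try:
                    res = stats.icc2k(wide)
                    icc_rows.append({"state": state, "measure": col,
                                     "icc2k": res.icc,
                                     "k_effective": res.k_effective,
                                     "n_subjects": res.n_subjects})
                except stats.StatsError as exc:
                    log.info("ICC skipped for %s/%s: %s", state, col, exc)

        # paired vigilant vs all-drowsy ANOVA per measure
        pivot = collapsed.pivot_table(index="subject_id", columns="state",
                                      values=list(MEASURE_NAMES), aggfunc="first")
        for col in MEASURE_NAMES:
            try:
                vig = pivot[(col, vigilance.VIGILANT)]
                drw = pivot[(col, vigilance.ALL_DROWSY)]
            except KeyError:
                continue
            try:
                res = stats.paired_state_anova(vig.to_numpy(), drw.to_numpy(),
                                               alpha=alpha)
                anova_rows.append({
                    "measure": col, "F": res.F, "df1": res.df[0],
                    "df2": res.df[1], "p": res.p, "alpha": alpha,
                    "significant": res.significant_bonferroni})
            except stats.StatsError as exc:
                log.info("ANOVA skipped for %s: %s", col, exc)

        # heritability of the configured measure
        if {"family_id", "zygosity"}.issubset(collapsed.columns):
            pair_table = build_pair_table(collapsed, cfg.heritable_measure)
            if pair_table.empty:
                note = "no usable twin pairs: heritability stage skipped"
                log.info(note)
            else:
                try:
                    heritability = twin.heritability_analysis(
                        pair_table, covariates=cfg.heritability_covariates,
                        alpha=cfg.family_alpha, compute_ci=cfg.heritability_ci,
                        seed=cfg.seed)
                    log.info("best twin model for %s: %s (a2=%.3f)",
                             cfg.heritable_measure, heritability.best.model,
                             heritability.best.a2)
                except twin.TwinFitError as exc:
                    note = f"heritability stage skipped: {exc}"
                    log.info(note)
        else:
            note = "no twin metadata: heritability stage skipped"

    icc_df = pd.DataFrame(icc_rows)
    anova_df = pd.DataFrame(anova_rows)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "runs_total": int(sum(state_counts.values())),
        "state_counts": dict(sorted(state_counts.items())),
        "runs_used": int(len(measures_df)),
        "bonferroni_alpha": alpha,
        "heritability_note": note,
    }
    result = StudyResult(measures=measures_df, collapsed=collapsed,
                         classification=classification, icc=icc_df,
                         anova=anova_df, heritability=heritability,
                         heritability_note=note, manifest=manifest)
    if out_dir is not None:
        write_reports(result, cfg, out_dir)
    return result


def write_reports(result: StudyResult, cfg: StudyConfig, out_dir: str) -> None:
    """Write the deterministic TSV/JSON report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kw = dict(sep="\t", index=False, float_format="%.6g")
    result.measures.to_csv(out / "measures.tsv", **kw)
    result.collapsed.to_csv(out / "collapsed.tsv", **kw)
    result.classification.to_csv(out / "classification.tsv", **kw)
    result.icc.to_csv(out / "reliability_icc.tsv", **kw)
    result.anova.to_csv(out / "state_anova.tsv", **kw)

    herit: Dict = {"note": result.heritability_note}
    if result.heritability is not None:
        h = result.heritability
        herit = {
            "measure": cfg.heritable_measure,
            "r_mz": {"r": h.r_mz.r, "df": h.r_mz.df, "p": h.r_mz.p_one_sided},
            "r_dz": {"r": h.r_dz.r, "df": h.r_dz.df, "p": h.r_dz.p_one_sided},
            "family": h.family,
            "best_model": h.best.model,
            "best": _fit_payload(h.best),
            "models": {name: _fit_payload(f) for name, f in h.fits.items()},
            "comparisons": [dataclasses.asdict(c) for c in h.comparisons],
            "saturated_minus2LL": h.saturated_minus2LL,
        }
    with open(out / "heritability.json", "w") as fh:
        json.dump(herit, fh, indent=1, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)


def _fit_payload(fit: twin.VarianceComponents) -> Dict:
    return {
        "model": fit.model,
        "a2": fit.a2, "c2": fit.c2, "d2": fit.d2, "e2": fit.e2,
        "minus2LL": fit.minus2LL, "aic": fit.aic, "aic_chisq": fit.aic_chisq,
        "n_free": fit.n_free, "betas": fit.betas,
        "n_pairs_used": list(fit.n_pairs_used),
        "ci": {k: [v.lower, v.upper] for k, v in fit.ci.items()},
    }
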