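"""End-to-end pipeline: simulate -> clcr -> nca -> index -> egfr-fit -> compare.

Each stage reads/writes the CSV schemas in :mod:`pigletgfr.io`; a run
manifest (seed, config hash, package version, artifact list) makes runs
reproducible and auditable.  Stage failures abort with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    SimulationConfig,
    generate_cohort,
    apply_bw_exclusion,
    simulate_iohexol_profile,
    simulate_plasma_samples,
    simulate_urine_collections,
)
from .compare import anova_age_within_technique, paired_technique_within_age
from .creatinine import (
    PlasmaCreatinine,
    UrineCollection,
    correct_jaffe_pcr,
    creatinine_load_24h,
    flag_load_outliers,
    mean_plasma_creatinine,
    subject_clearance,
)
from .egfr import RegressionSpec, back_transform, build_design, evaluate_accuracy, stepwise_fit
from .errors import InsufficientDataError, PigletGfrError
from .io import read_table, write_table
from .nca import ConcentrationProfile, iohexol_clearance
from .normalize import index_clearance, summary_table

log = logging.getLogger("pigletgfr")


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    regression: RegressionSpec = field(default_factory=RegressionSpec)
    egfr_technique: str = "enzymatic"
    comparison_index: str = "per_bsa_ml_min_m2"
    bw_exclusion_kg: float | None = None  # group stats already post-exclusion

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.get("simulation", {})
        if "groups" in sim_kwargs:
            from .cohort import AgeGroupSpec

            sim_kwargs["groups"] = tuple(AgeGroupSpec(**g) for g in sim_kwargs["groups"])
        if "kinetics" in sim_kwargs:
            from .cohort import KineticsSpec

            sim_kwargs["kinetics"] = KineticsSpec(**sim_kwargs["kinetics"])
        reg_kwargs = raw.get("regression", {})
        if "candidate_terms" in reg_kwargs:
            reg_kwargs["candidate_terms"] = tuple(reg_kwargs["candidate_terms"])
        return cls(
            simulation=SimulationConfig(**sim_kwargs),
            regression=RegressionSpec(**reg_kwargs),
            egfr_technique=raw.get("egfr_technique", "enzymatic"),
            comparison_index=raw.get("comparison_index", "per_bsa_ml_min_m2"),
            bw_exclusion_kg=raw.get("bw_exclusion_kg"),
        )


def _config_hash(config: PipelineConfig) -> str:
    def default(o: Any):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_stage(config: SimulationConfig, out_dir: Path) -> dict[str, Path]:
    """Generate a cohort plus all its measurements and write the input CSVs."""
    cohort = generate_cohort(config)
    rng_offset = 10_000  # measurement streams separated from cohort streams
    subj_rows, urine_rows, plasma_rows, iohexol_rows = [], [], [], []
    for i, s in enumerate(cohort):
        rng = np.random.default_rng([config.seed, rng_offset + i])
        subj_rows.append(dataclasses.asdict(s))
        for sample in simulate_plasma_samples(s, config.assay_cv, rng):
            plasma_rows.append(dataclasses.asdict(sample))
        for coll in simulate_urine_collections(
            s, s.true_gfr_ml_min, s.pcr_mg_dl, config.urine_intervals, config.assay_cv, rng
        ):
            urine_rows.append(dataclasses.asdict(coll))
        profile = simulate_iohexol_profile(
            s,
            config.dose_mg_per_kg,
            s.true_gfr_ml_min,
            config.kinetics,
            config.sampling_schedule_min,
            config.assay_cv,
            rng,
            config.exo_fraction,
        )
        for t, c in zip(profile.times_min, profile.conc_ug_ml):
            iohexol_rows.append(
                {
                    "subject_id": s.subject_id,
                    "time_min": t,
                    "conc_ug_ml": c,
                    "dose_mg": profile.total_dose_mg,
                }
            )
    paths = {
        "subjects": write_table(pd.DataFrame(subj_rows), out_dir / "subjects.csv"),
        "plasma_creatinine": write_table(
            pd.DataFrame(plasma_rows), out_dir / "plasma_creatinine.csv"
        ),
        "urine": write_table(pd.DataFrame(urine_rows), out_dir / "urine.csv"),
        "iohexol": write_table(pd.DataFrame(iohexol_rows), out_dir / "iohexol.csv"),
    }
    return paths


def clcr_stage(
    plasma: pd.DataFrame, urine: pd.DataFrame, subjects: pd.DataFrame, assays=("jaffe", "enzymatic")
) -> pd.DataFrame:
    """Creatinine clearance per subject and assay, with the load screen."""
    tp_by_subject = subjects.set_index("subject_id")["total_protein_g_per_l"].to_dict()
    bw_by_subject = subjects.set_index("subject_id")["bw_kg"].to_dict()
    age_by_subject = subjects.set_index("subject_id")["age_days"].to_dict()
    rows = []
    for (subject_id, assay), grp in plasma.groupby(["subject_id", "assay"]):
        if assay not in assays:
            continue
        samples = []
        for _, r in grp.iterrows():
            p = r["p_cr_mg_dl"]
            if assay == "jaffe":
                p = correct_jaffe_pcr(p, tp_by_subject[subject_id])
            samples.append(
                PlasmaCreatinine(subject_id, str(r["clock_label"]), float(p), str(assay))
            )
        mean_pcr = mean_plasma_creatinine(samples)
        colls = [
            UrineCollection(
                subject_id,
                float(r["interval_start_min"]),
                float(r["interval_end_min"]),
                float(r["u_vol_ml"]),
                float(r["u_cr_mg_dl"]),
            )
            for _, r in urine[urine["subject_id"] == subject_id].iterrows()
        ]
        if not colls:
            log.warning("no urine collections for %s; skipped", subject_id)
            continue
        clearance = subject_clearance(colls, mean_pcr)
        load = float(
            np.mean([creatinine_load_24h(c.u_cr_mg_dl, c.u_vol_ml, c.t_min) for c in colls])
        )
        rows.append(
            {
                "subject_id": subject_id,
                "assay": assay,
                "age_days": age_by_subject[subject_id],
                "clearance_ml_min": clearance,
                "mean_pcr_mg_dl": mean_pcr,
                "load_mg_24h": load,
                "load_per_bw": load / bw_by_subject[subject_id],
            }
        )
    out = pd.DataFrame(rows)
    out["outlier_flag"] = False
    for (_, _), idx in out.groupby(["assay", "age_days"]).groups.items():
        loads = out.loc[idx, "load_per_bw"].tolist()
        if len(loads) >= 4:
            out.loc[idx, "outlier_flag"] = flag_load_outliers(loads)
    return out.drop(columns=["load_per_bw", "age_days"]).assign(
        outlier_flag=lambda d: d["outlier_flag"].astype(str)
    )


def nca_stage(iohexol: pd.DataFrame, exo_fraction: float) -> pd.DataFrame:
    """Run NCA per subject profile."""
    rows = []
    for subject_id, grp in iohexol.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_min")
        profile = ConcentrationProfile(
            subject_id=str(subject_id),
            times_min=tuple(grp["time_min"].astype(float)),
            conc_ug_ml=tuple(grp["conc_ug_ml"].astype(float)),
            total_dose_mg=float(grp["dose_mg"].iloc[0]),
            exo_fraction=exo_fraction,
        )
        res = iohexol_clearance(profile)
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def index_stage(
    clcr: pd.DataFrame, nca: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Merge clearances with subject metrics into the indexed GFR table."""
    from .cohort import SubjectRecord

    subj = {}
    for _, r in subjects.iterrows():
        subj[r["subject_id"]] = SubjectRecord(
            subject_id=str(r["subject_id"]),
            age_days=int(r["age_days"]),
            bw_kg=float(r["bw_kg"]),
            bsa_m2=float(r["bsa_m2"]),
            kw_g=float(r["kw_g"]),
            total_protein_g_per_l=float(r["total_protein_g_per_l"]),
            pcr_mg_dl=float(r.get("pcr_mg_dl", 1.0)),
            true_gfr_ml_min=float(r.get("true_gfr_ml_min", 1.0)),
        )
    rows = []
    for _, r in clcr.iterrows():
        s = subj[r["subject_id"]]
        res = index_clearance(float(r["clearance_ml_min"]), s, str(r["assay"]))
        rows.append({**dataclasses.asdict(res), "age_days": s.age_days})
    for _, r in nca.iterrows():
        s = subj[r["subject_id"]]
        res = index_clearance(float(r["clearance_ml_min"]), s, "exo_iohexol")
        rows.append({**dataclasses.asdict(res), "age_days": s.age_days})
    return pd.DataFrame(rows)


def egfr_stage(
    indexed: pd.DataFrame,
    subjects: pd.DataFrame,
    clcr: pd.DataFrame,
    spec: RegressionSpec,
    technique: str,
):
    """Stepwise fit of the power-law eGFR equation on one technique's GFR."""
    gfr = indexed[indexed["technique"] == technique][["subject_id", "clearance_ml_min"]]
    # Predictor Pcr: measured (protein-corrected) mean plasma creatinine from
    # the clearance stage when available; for exo_iohexol GFR the enzymatic
    # Pcr is used.  Falls back to the latent subjects column otherwise.
    pcr_assay = technique if technique in ("jaffe", "enzymatic") else "enzymatic"
    merged = gfr.merge(subjects[["subject_id", "bw_kg", "age_days"]], on="subject_id")
    if clcr is not None and "mean_pcr_mg_dl" in getattr(clcr, "columns", ()):
        pcr_tab = clcr[clcr["assay"] == pcr_assay][["subject_id", "mean_pcr_mg_dl"]]
        merged = merged.merge(pcr_tab.rename(columns={"mean_pcr_mg_dl": "pcr_mg_dl"}),
                              on="subject_id")
    else:
        merged = merged.merge(subjects[["subject_id", "pcr_mg_dl"]], on="subject_id")
    rows = pd.DataFrame(
        {
            "gfr": merged["clearance_ml_min"].to_numpy(float),
            "pcr": merged["pcr_mg_dl"].to_numpy(float),
            "bw": merged["bw_kg"].to_numpy(float),
            "age": merged["age_days"].to_numpy(float),
        }
    )
    if len(rows) <= len(spec.ordered_candidates()) + 1:
        raise InsufficientDataError(
            f"{len(rows)} subjects cannot support stepwise selection over "
            f"{len(spec.ordered_candidates())} candidate terms; enlarge the cohort"
        )
    design, response = build_design(rows, spec)
    fit = stepwise_fit(design, response, spec)
    model = back_transform(fit, spec)
    predictions = None
    if model is not None:
        model = evaluate_accuracy(model, rows["bw"], rows["pcr"], rows["gfr"])
        predictions = pd.DataFrame(
            {
                "subject_id": merged["subject_id"],
                "gfr_ml_min": rows["gfr"],
                "egfr_ml_min": model.predict(rows["bw"], rows["pcr"]),
            }
        )
    return fit, model, predictions, pcr_assay


def compare_stage(indexed: pd.DataFrame, value_col: str, log_base: float) -> pd.DataFrame:
    """Age-within-technique and technique-within-age comparison tables."""
    frames = []
    for technique in sorted(indexed["technique"].unique()):
        table = anova_age_within_technique(indexed, technique, value_col, log_base)
        if not table.degenerate:
            frames.append(table.to_frame())
    for age in sorted(indexed["age_days"].unique()):
        table = paired_technique_within_age(indexed, int(age), value_col, log_base)
        frames.append(table.to_frame())
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write all artifacts plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def _stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except PigletGfrError as exc:
            raise PigletGfrError(f"stage {name!r} failed: {exc}") from exc

    paths = _stage("simulate", lambda: simulate_stage(config.simulation, out))
    artifacts += [p.name for p in paths.values()]

    subjects = read_table(paths["subjects"], "subjects")
    if config.bw_exclusion_kg is not None:
        kept = subjects["bw_kg"] >= config.bw_exclusion_kg
        log.info("bodyweight exclusion: %d withdrawn", int((~kept).sum()))
        subjects = subjects[kept].reset_index(drop=True)
    plasma = read_table(paths["plasma_creatinine"], "plasma_creatinine")
    urine = read_table(paths["urine"], "urine")
    iohexol = read_table(paths["iohexol"], "iohexol")
    keep_ids = set(subjects["subject_id"])
    plasma = plasma[plasma["subject_id"].isin(keep_ids)]
    urine = urine[urine["subject_id"].isin(keep_ids)]
    iohexol = iohexol[iohexol["subject_id"].isin(keep_ids)]

    clcr = _stage("clcr", lambda: clcr_stage(plasma, urine, subjects))
    write_table(clcr, out / "clcr.csv")
    nca = _stage("nca", lambda: nca_stage(iohexol, config.simulation.exo_fraction))
    write_table(nca, out / "nca.csv")
    indexed = _stage("index", lambda: index_stage(clcr, nca, subjects))
    write_table(indexed, out / "gfr_indexed.csv")
    write_table(summary_table(indexed), out / "summary.csv")
    artifacts += ["clcr.csv", "nca.csv", "gfr_indexed.csv", "summary.csv"]

    fit, model, predictions, _ = _stage(
        "egfr-fit",
        lambda: egfr_stage(indexed, subjects, clcr, config.regression, config.egfr_technique),
    )
    if model is not None:
        (out / "model.json").write_text(model.to_json())
        write_table(predictions, out / "predictions.csv")
        artifacts += ["model.json", "predictions.csv"]

    comparisons = _stage(
        "compare",
        lambda: compare_stage(indexed, config.comparison_index, config.regression.log_base),
    )
    write_table(comparisons, out / "comparisons.csv")
    artifacts.append("comparisons.csv")

    manifest = {
        "seed": config.simulation.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "log_base": "e" if config.regression.log_base == math.e else config.regression.log_base,
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
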