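"""End-to-end orchestration of the clonal-population analysis stages.

Each stage reads/writes plain-text artifacts in an output directory and
contributes per-stage statistics (counts at each filter step, parameter
values, seeds) to a JSON run report, so every numerical output is
reproducible from the report alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import growth as growth_mod
from . import markrecapture as mr
from . import structure as structure_mod
from . import synthdata, vafloh, variants

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "variants", "structure", "vaf", "census", "growth")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: Path
    stages: tuple = STAGES
    seed: int = 0
    force: bool = False
    population: synthdata.PopulationSpec = field(default_factory=synthdata.PopulationSpec)
    read_model: synthdata.ReadModel = field(default_factory=synthdata.ReadModel)
    survey: synthdata.SurveySpec = field(default_factory=synthdata.SurveySpec)
    filters: variants.FilterConfig = field(default_factory=variants.FilterConfig)
    vaf: vafloh.VafConfig = field(default_factory=vafloh.VafConfig)
    growth: growth_mod.GrowthParams = field(default_factory=growth_mod.GrowthParams)
    variability: growth_mod.VariabilityParams = field(
        default_factory=lambda: growth_mod.VariabilityParams(
            snv_per_specimen=5865.0, current_n=192_000.0
        )
    )
    metric: str = "euclidean"
    kmeans_k: int = 200
    bootstrap_reps: int = 10_000


def _check_overwrite(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise PipelineError(f"{path} exists; pass force=True/--force to overwrite")


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages and write artifacts plus a run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "parameters": {}}
    report["parameters"]["population"] = asdict(config.population)
    report["parameters"]["read_model"] = asdict(config.read_model)
    report["parameters"]["filters"] = asdict(config.filters)

    state: dict = {}
    try:
        for stage in config.stages:
            report["stages"][stage] = _STAGE_FNS[stage](config, out, state)
    except Exception:
        (out / "run_report.failed").write_text(json.dumps(report, indent=2, default=str))
        raise
    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str, sort_keys=True))
    return report


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    ref = synthdata.generate_reference_profile(
        n_sites=config.population.n_sites,
        het_fraction=config.population.reference_het_fraction,
        seed=config.population.seed,
    )
    truth, lineage = synthdata.generate_clonal_genotypes(config.population, ref)
    vcf_path = out / "cohort.vcf"
    _check_overwrite(vcf_path, config.force)
    n_records = synthdata.emit_vcf(truth, ref, config.read_model, vcf_path, seed=config.seed)
    truth.to_tsv(out / "truth_dosage.tsv")
    lineage.to_csv(out / "truth_lineage.tsv", sep="\t", index=False)
    survey, hand = synthdata.generate_trap_survey(config.survey)
    survey.to_csv(out / "survey.csv")
    np.savetxt(out / "hand_densities.csv", hand.densities_per_m2,
               header="density_per_m2", comments="")
    np.savetxt(out / "hand_sizes.csv", hand.sizes_cm, header="size_cm", comments="")
    state.update(ref=ref, truth=truth, lineage=lineage, survey=survey, hand=hand,
                 vcf_path=vcf_path)
    return {
        "n_sites": int(ref.n_sites),
        "n_het_sites": int(ref.het_mask.sum()),
        "n_samples": truth.n_samples,
        "vcf_records": n_records,
        "survey_days": int(survey.data["day"].max()),
    }


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise PipelineError(f"stage '{stage}' requires the simulate stage (missing {key})")
    return state[key]


def _stage_variants(config: RunConfig, out: Path, state: dict) -> dict:
    vcf_path = state.get("vcf_path", Path(config.outdir) / "cohort.vcf")
    if not Path(vcf_path).exists():
        raise PipelineError(f"missing input VCF {vcf_path}")
    sites = variants.read_vcf(vcf_path)
    ref = _require(state, "ref", "variants")
    filtered = variants.apply_filters(sites, config.filters, ref=ref)
    groups = state["truth"].groups if "truth" in state else {}
    matrix = variants.recode_dosage(filtered, groups=groups)
    matrix.to_tsv(out / "dosage_matrix.tsv")
    summary = variants.polymorphic_partition(matrix)
    summary.to_json(out / "sharing_summary.json")
    state.update(sites=sites, matrix=matrix, sharing=summary)
    per_sample = summary.per_sample_snvs
    return {
        "sites_read": len(sites),
        "sites_after_filters": len(filtered),
        "per_sample_snvs": per_sample,
        "total_polymorphic": summary.total_polymorphic,
    }


def _stage_structure(config: RunConfig, out: Path, state: dict) -> dict:
    matrix = _require(state, "matrix", "structure")
    dm = structure_mod.pairwise_distance(matrix, metric=config.metric)
    tree = structure_mod.nj_tree(dm)
    (out / "nj_tree.nwk").write_text(tree.newick + "\n")
    pca_res = structure_mod.pca(matrix)
    np.savetxt(out / "pca_scores.tsv", pca_res.scores, delimiter="\t")
    k = min(config.kmeans_k, matrix.n_sites)
    centroids, _ = structure_mod.kmeans_row_aggregate(matrix, k=k, seed=config.seed)
    np.savetxt(out / "kmeans_centroids.tsv", centroids, delimiter="\t")
    return {
        "metric": config.metric,
        "n_clamped_branches": tree.n_clamped,
        "pc1_variance": float(pca_res.variance_explained[0]),
        "kmeans_k": k,
    }


def _stage_vaf(config: RunConfig, out: Path, state: dict) -> dict:
    ref = _require(state, "ref", "vaf")
    sites = state.get("sites")
    if sites is None:
        sites = variants.read_vcf(state.get("vcf_path", Path(config.outdir) / "cohort.vcf"))
    het_idx = vafloh.select_het_positions(ref, config.vaf)
    truth = _require(state, "truth", "vaf")
    frames = []
    n_flagged = 0
    for sid in truth.sample_ids:
        arrays = vafloh.sample_read_arrays(sites, sid, ref, het_idx)
        track = vafloh.windowed_vaf(sid, *arrays, config.vaf)
        if not track.windows:
            continue
        scan = vafloh.loh_scan(track, config.vaf)
        n_flagged += int(scan["flagged"].sum())
        frames.append(scan)
    if frames:
        import pandas as pd

        pd.concat(frames).to_csv(out / "vaf_track.tsv", sep="\t", index=False)
    return {"het_positions": int(het_idx.size), "flagged_windows": n_flagged}


def _stage_census(config: RunConfig, out: Path, state: dict) -> dict:
    survey = state.get("survey")
    if survey is None:
        survey_path = Path(config.outdir) / "survey.csv"
        if not survey_path.exists():
            raise PipelineError(f"missing survey table {survey_path}")
        survey = mr.TrapSurvey.from_csv(survey_path)
    hand = _require(state, "hand", "census")
    est = mr.schnabel(survey)
    daily = survey.daily()
    x = daily.index.to_numpy(dtype=float)
    y = daily["new_marks"].cumsum().to_numpy(dtype=float)
    try:
        sat = mr.fit_saturation(x, y)
    except mr.SaturationFitError:
        sat = None
    strata = mr.lake_reilingen_strata()
    total = mr.bootstrap_se(
        est, sat, strata, hand,
        trap_catches=survey.per_trap_catch(),
        n_reps=config.bootstrap_reps,
        seed=config.seed,
    )
    result = {
        "schnabel_n": est.n_hat,
        "schnabel_se": est.se,
        "saturation_a": sat.a if sat else None,
        "total_n": total.n_hat,
        "total_se": total.se,
        "components": total.components,
    }
    (out / "census.json").write_text(json.dumps(result, indent=2, default=str))
    return {"schnabel_n": est.n_hat, "total_n": total.n_hat, "total_se": total.se}


def _stage_growth(config: RunConfig, out: Path, state: dict) -> dict:
    vp = config.variability
    v_now, v_level = growth_mod.variability_current(vp)
    results = {"current_variability": v_now, "target_level": v_level, "models": {}}
    for model in ("exponential", "logistic", "allee"):
        traj = growth_mod.simulate(model, config.growth)
        values, meta = growth_mod.variability_trajectory(traj, vp)
        try:
            res = growth_mod.growth_intersection(
                config.growth, vp, target=v_level, model=model
            )
            results["models"][model] = {
                "t_star": res.t_star,
                "band": list(res.band),
                "strategy": res.strategy,
            }
        except growth_mod.NoIntersectionError:
            results["models"][model] = {"t_star": None, "strategy": meta["strategy"]}
    (out / "growth.json").write_text(json.dumps(results, indent=2))
    return results


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "variants": _stage_variants,
    "structure": _stage_structure,
    "vaf": _stage_vaf,
    "census": _stage_census,
    "growth": _stage_growth,
}
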