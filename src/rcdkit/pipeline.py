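"""End-to-end orchestration: synthetic inputs through every analysis stage.

A single global seed expands deterministically into per-stage seeds, so a
stage rerun in isolation reproduces its in-pipeline result exactly.  The
run report is a versioned JSON document in which every numeric result is
tagged with its stage and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

_STAGE_IDS = {
    "synth": 1,
    "mating": 2,
    "morphometrics": 3,
    "popgen": 4,
    "demography": 5,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    seed: int
    output_dir: str = "rcdkit_run"
    stages: tuple = ("synth", "mating", "morphometrics", "popgen", "demography")
    n_boot: int = 10_000
    n_perm: int = 499
    n_trials_per_cell: int = 60
    n_morph_per_group: int = 30
    n_indiv_per_pop: int = 10
    n_genotype_tags: int = 300
    abc_n_sims_per_model: int = 1000
    abc_tolerance: float = 0.1
    abc_n_tags: int = 100
    trials_csv: str | None = None     # existing inputs override synthesis
    features_csv: str | None = None
    input_files: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config requires a seed")
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        missing = [p for p in (cfg.trials_csv, cfg.features_csv, *cfg.input_files)
                   if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")
        return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write the report.

    Any stage failure aborts with the stage name; the partial report
    written so far is preserved in the output directory.
    """
    from . import datasets, mating, morphometrics, popgen, synth
    from .demography import DemographicModel, summarize
    from .abc import SecondaryContactABC, PriorSpec

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "global_seed": cfg.seed,
        "stages": {},
    }
    report_path = out / "report.json"

    def finish_stage(name, payload, t0):
        payload["seed"] = stage_seed(cfg.seed, name)
        payload["elapsed_s"] = round(time.time() - t0, 3)
        report["stages"][name] = payload
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, default=str)

    state: dict = {}
    for name in cfg.stages:
        t0 = time.time()
        try:
            if name == "synth":
                seed = stage_seed(cfg.seed, name)
                tcfg = synth.TrialSimConfig(n_trials_per_cell=cfg.n_trials_per_cell)
                state["trials"] = synth.gen_trials(tcfg, seed)
                state["morph"] = synth.gen_morph(
                    synth.MorphSimConfig(n_per_group=cfg.n_morph_per_group), seed + 1
                )
                nm = DemographicModel(
                    "NM", t_sp=5e5, t_reg_c=1.25e5, t_reg_f=2.5e5,
                    n_now=1e6, n_anc=1e5, m_intra=0.01,
                )
                state["gm"], state["tags"] = synth.gen_genotypes(
                    nm, n_indiv_per_pop=cfg.n_indiv_per_pop,
                    n_tags=cfg.n_genotype_tags, seed=seed + 2,
                )
                mating.write_trials_csv(state["trials"], out / "trials.csv")
                state["morph"].to_csv(out / "features.csv", index=False)
                state["gm"].write_vcf(out / "genotypes.vcf")
                finish_stage(name, {"n_trials": len(state["trials"]),
                                    "n_morph": len(state["morph"]),
                                    "n_loci": state["gm"].n_loci}, t0)
            elif name == "mating":
                if cfg.trials_csv:
                    state["trials"] = mating.read_trials_csv(cfg.trials_csv)
                seed = stage_seed(cfg.seed, name)
                payload = {}
                for loc in ("sympatric", "allopatric"):
                    table = mating.tabulate_trials(state["trials"], loc)
                    est = mating.IsolationIndexModel(table).fit(n_boot=cfg.n_boot, seed=seed)
                    payload[loc] = {
                        "i_psi": est.i_psi, "se_boot": est.se_boot,
                        "t": est.t_stat, "p_boot": est.p_value,
                        "n_matings": est.n_matings,
                    }
                for resp in ("mounting", "log_duration"):
                    try:
                        r = mating.three_way_interaction_test(state["trials"], resp)
                        payload[f"interaction_{resp}"] = {
                            "chi2": r.chi2, "df": r.df, "p": r.p_value,
                        }
                    except ValueError as exc:
                        payload[f"interaction_{resp}"] = {"error": str(exc)}
                b = mating.sperm_duration_test(state["trials"])
                payload["sperm_vs_duration"] = {"b": b.slope_logit, "se": b.se,
                                                "chi2": b.chi2, "p": b.p_value}
                finish_stage(name, payload, t0)
            elif name == "morphometrics":
                if cfg.features_csv:
                    state["morph"] = morphometrics.read_morph_csv(cfg.features_csv)
                seed = stage_seed(cfg.seed, name)
                adj = morphometrics.length_adjust(state["morph"])
                traj = morphometrics.TrajectoryModel(adj).fit(n_perm=cfg.n_perm, seed=seed)
                scores, frac = morphometrics.pca_scores(adj)
                per_trait = morphometrics.per_trait_tests(adj)
                state["pc_scores"] = scores
                finish_stage(name, {
                    "d_allopatry": traj.d_allopatry, "d_sympatry": traj.d_sympatry,
                    "p_magnitude": traj.p_magnitude, "angle_deg": traj.angle_deg,
                    "p_direction": traj.p_direction,
                    "pc1_variance_fraction": float(frac[0]),
                    "significant_traits": per_trait.loc[per_trait["significant"] == True, "feature"].tolist(),
                }, t0)
            elif name == "popgen":
                gm = state["gm"]
                filtered, rep = popgen.filter_loci(gm)
                scores, frac = popgen.genotype_pca(filtered)
                fst = popgen.nei_fst(filtered, grouping="site")
                fst.to_tsv(out / "fst.tsv")
                with open(out / "filter_report.json", "w") as fh:
                    fh.write(rep.to_json())
                finish_stage(name, {
                    "n_loci_in": rep.n_input_loci,
                    "n_loci_final": rep.n_after_callrate,
                    "pc1_variance_fraction": float(frac[0]) if len(frac) else 0.0,
                    "fst_between_species_sympatric": float(
                        fst.values.loc["C_symp", "F_symp"]
                    ),
                }, t0)
            elif name == "demography":
                seed = stage_seed(cfg.seed, name)
                observed = summarize(state["tags"])
                abc = SecondaryContactABC(
                    observed, priors=PriorSpec(), n_tags=cfg.abc_n_tags,
                )
                res = abc.fit(
                    n_sims_per_model=cfg.abc_n_sims_per_model,
                    tolerance=cfg.abc_tolerance, seed=seed,
                )
                finish_stage(name, {
                    "posteriors": res.posteriors, "best_model": res.best_model,
                }, t0)
            else:
                raise ValueError(f"unknown stage {name!r}")
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            report["failed_stage"] = name
            report["error"] = str(exc)
            with open(report_path, "w") as fh:
                json.dump(report, fh, indent=2, default=str)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return report
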