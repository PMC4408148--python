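"""End-to-end orchestration: simulate -> validate -> admix -> classify ->
diversity -> sgs -> glm, with a structured CSV/JSON report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genio import read_genepop, read_metadata, read_landscape, read_visitors, filter_missingness
from .synth import (
    SimulationConfig,
    DispersalConfig,
    sample_cluster_frequencies,
    sample_genotypes,
    attach_landscape_covariates,
    simulate_visitor_observations,
    write_dataset,
)
from .admixture import gibbs_admixture, model_evidence, evanno_delta_k, align_replicates, consensus_membership
from .introgression import (
    cumulative_wild_membership,
    classify_individuals,
    classification_table,
    introgression_rate,
    assign_wild_populations,
    infer_crop_clusters,
)
from .diversity import (
    heterozygosities,
    multilocus_means,
    wc_f_statistics,
    hwe_deficit_test,
    rarefied_allelic_richness,
    private_allelic_richness,
    site_filters,
)
from .spatial import sgs_analysis
from .landscape import run_model_1_2, run_model_3, visitor_summary


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    k_min: int = 4
    k_max: int = 7
    k_use: int | None = None  # default: true pool count of the simulation
    replicates: int = 2
    sweeps: int = 400
    burn_in: int = 100
    alpha: float = 1.0
    pure_threshold: float = 0.9
    crop_threshold: float = 0.1
    assign_threshold: float = 0.55
    g_richness: int = 2
    g_private: int = 10
    min_site_individuals: int = 4
    sgs_max_d: float = 10.0
    sgs_first_class: float = 1.0
    sgs_min_n: int = 15
    n_perm: int = 499
    glm_granularity: str = "taxa"
    visitor_effect: float = 1.0
    visitor_n_obs: int = 306
    seed: int = 0

    def validate(self):
        if not (0 <= self.crop_threshold < self.pure_threshold <= 1):
            raise ValueError("thresholds must satisfy 0 <= crop < pure <= 1")
        if self.k_max - self.k_min < 2:
            raise ValueError("K range must span >= 3 values for the delta-K table")
        self.simulation.validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        disp_raw = sim_raw.pop("dispersal", {})
        hybrids = [
            (tuple(h["ancestry"]), int(h["count"]), h.get("label", "hybrid"))
            for h in sim_raw.pop("hybrid_spec", [])
        ]
        sim = SimulationConfig(
            dispersal=DispersalConfig(**disp_raw), hybrid_spec=hybrids, **sim_raw
        )
        return cls(simulation=sim, **raw).validate()

    def stage_seed(self, counter: int) -> int:
        # counter-based fan-out so stages rerun identically in isolation
        return int(
            np.random.SeedSequence([self.seed, counter]).generate_state(1)[0]
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage on a synthetic dataset and write the report bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # -- stage 0: simulate ---------------------------------------------------
    try:
        sim = config.simulation
        freqs = sample_cluster_frequencies(sim, rng=np.random.default_rng(config.stage_seed(0)))
        G_true, truth = sample_genotypes(freqs, sim, rng=np.random.default_rng(config.stage_seed(1)))
        sites = sorted(set(truth["site_id"]) - {"orchard"})
        land_tab, probs = attach_landscape_covariates(
            sites, sim.landscape_effects, seed=config.stage_seed(2)
        )
        visitors = simulate_visitor_observations(
            management_effect=config.visitor_effect,
            n_obs=config.visitor_n_obs,
            seed=config.stage_seed(3),
        )
        data_dir = write_dataset(outdir / "data", G_true, truth, land_tab, visitors)
        log.append("simulate: ok")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    # -- stage 1: validate ---------------------------------------------------
    try:
        G = read_genepop(data_dir / "genotypes.gen")
        G = read_metadata(G, data_dir / "metadata.csv")
        land_tab = read_landscape(data_dir / "landscape.csv")
        visitors = read_visitors(data_dir / "visitors.csv")
        G, removed = filter_missingness(G, 0.20)
        log.append(f"validate: ok ({len(removed)} individuals removed for missingness)")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("validate", str(exc)) from exc

    # -- stage 2: admixture --------------------------------------------------
    try:
        evidence: dict[int, list[float]] = {}
        fits_by_k: dict[int, list] = {}
        counter = 10
        for K in range(config.k_min, config.k_max + 1):
            fits = []
            for _ in range(config.replicates):
                fit = gibbs_admixture(
                    G, K, n_sweeps=config.sweeps, burn_in=config.burn_in,
                    alpha=config.alpha, seed=config.stage_seed(counter),
                )
                counter += 1
                fits.append(fit)
            fits_by_k[K] = fits
            evidence[K] = [model_evidence(f) for f in fits]
        dk = evanno_delta_k(evidence)
        k_use = config.k_use or sim.n_pools
        if k_use not in fits_by_k:
            fits = [
                gibbs_admixture(
                    G, k_use, n_sweeps=config.sweeps, burn_in=config.burn_in,
                    alpha=config.alpha, seed=config.stage_seed(counter + r),
                )
                for r in range(config.replicates)
            ]
        else:
            fits = fits_by_k[k_use]
        aligned, perms, _ = align_replicates([f.Q for f in fits])
        Q = consensus_membership(aligned)
        # assignment-fraction consensus under the same label permutations;
        # used for thresholding (unshrunken by the Dirichlet prior)
        Zf = consensus_membership(
            [f.Z_fraction[:, p] for f, p in zip(fits, perms)]
        )
        occupied = int(((Q.max(axis=0)) > 0.5).sum())
        log.append(f"admix: ok (K={k_use}, occupied clusters={occupied})")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("admix", str(exc)) from exc

    # -- stage 3: classification ----------------------------------------------
    try:
        labels = G.metadata["species_label"].to_numpy()
        crop_clusters = infer_crop_clusters(Zf, labels)
        wild_clusters = [k for k in range(Zf.shape[1]) if k not in crop_clusters]
        wild_idx = np.nonzero(labels == "wild")[0]
        w = cumulative_wild_membership(Zf[wild_idx], wild_clusters)
        cats = classify_individuals(w, config.pure_threshold, config.crop_threshold)
        wild_ids = [G.individual_ids[i] for i in wild_idx]
        cls = classification_table(
            wild_ids, w, cats,
            groups=pd.DataFrame({"site_id": G.metadata["site_id"].to_numpy()[wild_idx]}),
        )
        rates_all = introgression_rate(cls)
        rates_site = introgression_rate(cls, group_by="site_id")
        pure_mask = cats == "pure_wild"
        Qw = Zf[wild_idx][:, wild_clusters]
        Qw = Qw / Qw.sum(axis=1, keepdims=True)
        assignment = assign_wild_populations(
            Qw[pure_mask], threshold=config.assign_threshold,
            cluster_names=[f"pop_{k + 1}" for k in range(len(wild_clusters))],
        )
        assignment.insert(0, "individual_id", [wild_ids[i] for i in np.nonzero(pure_mask)[0]])
        log.append(
            f"classify: ok ({int((cats == 'hybrid').sum())} hybrids, "
            f"{int((cats == 'misidentified_crop').sum())} misidentified)"
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classify", str(exc)) from exc

    # -- stage 4: diversity -----------------------------------------------------
    try:
        pure_ids = [wild_ids[i] for i in np.nonzero(pure_mask)[0]]
        Gp = G.subset_individuals(pure_ids)
        filt = site_filters(Gp, min_individuals=config.min_site_individuals)
        div_rows = []
        units = {}
        for site in filt["diversity_sites"]:
            idx = np.nonzero((Gp.sites() == site).to_numpy())[0]
            units[site] = idx
            het = multilocus_means(heterozygosities(Gp, idx))
            single = wc_f_statistics(Gp, {site: idx})
            ar = rarefied_allelic_richness(Gp, idx, g=config.g_richness)
            div_rows.append(
                {
                    "site_id": site,
                    "n": len(idx),
                    "H_O": het["H_O"],
                    "H_E": het["H_E"],
                    "F_IS": single["F_IS"],
                    "A_R": float(ar.loc[ar["included"], "A_R"].mean()),
                }
            )
        div_tab = pd.DataFrame(div_rows)
        if len(units) >= 2:
            ap = private_allelic_richness(Gp, units, g=config.g_private)
            div_tab = div_tab.merge(
                ap.rename(columns={"unit": "site_id"})[["site_id", "A_P"]],
                on="site_id", how="left",
            )
            fstats = wc_f_statistics(Gp, units)
        else:
            fstats = {"F_ST": np.nan, "F_IS": np.nan}
        hwe = hwe_deficit_test(Gp, n_perm=config.n_perm, seed=config.stage_seed(40))
        log.append("diversity: ok")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diversity", str(exc)) from exc

    # -- stage 5: spatial genetic structure --------------------------------------
    try:
        sgs_rows = []
        pops = assignment.groupby("population").size()
        for pop, n_pop in pops.items():
            if pop == "unassigned" or n_pop < config.sgs_min_n:
                continue
            ids = assignment.loc[assignment["population"] == pop, "individual_id"]
            res = sgs_analysis(
                G, list(ids), max_d=config.sgs_max_d,
                first_class_edge=config.sgs_first_class,
                n_perm=config.n_perm, seed=config.stage_seed(50),
            )
            sgs_rows.append(
                {"population": pop, "n": int(n_pop), "b": res["b"], "F_1": res["F_1"],
                 "r2": res["r2"], "p": res["p"], "Sp": res["Sp"]}
            )
        res_all = sgs_analysis(
            G, pure_ids, max_d=config.sgs_max_d,
            first_class_edge=config.sgs_first_class,
            n_perm=config.n_perm, seed=config.stage_seed(51),
        )
        sgs_rows.append(
            {"population": "all_pure_wild", "n": len(pure_ids), "b": res_all["b"],
             "F_1": res_all["F_1"], "r2": res_all["r2"], "p": res_all["p"],
             "Sp": res_all["Sp"]}
        )
        sgs_tab = pd.DataFrame(sgs_rows)
        log.append("sgs: ok")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("sgs", str(exc)) from exc

    # -- stage 6: landscape GLMs ---------------------------------------------------
    try:
        classified = cls.table.rename(columns={"w": "wild_membership"}).copy()
        classified["crop_ancestry"] = 1.0 - classified["wild_membership"]
        classified = classified[classified["category"] != "misidentified_crop"]
        glm12 = run_model_1_2(
            classified[["individual_id", "site_id", "crop_ancestry"]], land_tab
        )
        glm3 = run_model_3(visitors, granularity=config.glm_granularity)
        vis_sum = visitor_summary(visitors)
        log.append("glm: ok")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("glm", str(exc)) from exc

    # -- report ---------------------------------------------------------------------
    artifacts = {
        "delta_k.csv": dk,
        "q_consensus.csv": pd.DataFrame(
            Q, index=G.individual_ids,
            columns=[f"cluster_{k + 1}" for k in range(Q.shape[1])],
        ).rename_axis("individual_id").reset_index(),
        "classification.csv": cls.table,
        "introgression_rates_all.csv": rates_all,
        "introgression_rates_site.csv": rates_site,
        "population_assignment.csv": assignment,
        "diversity_sites.csv": div_tab,
        "sgs.csv": sgs_tab,
        "glm_model_1.csv": glm12["model_1"],
        "glm_model_2.csv": glm12["model_2"],
        "glm_model_3.csv": glm3,
        "visitor_summary.csv": vis_sum,
    }
    summary = {
        "seed": config.seed,
        "version": __version__,
        "k_used": k_use,
        "occupied_clusters": occupied,
        "hybrid_fraction_total": float(rates_all.loc[0, "hybrid_fraction_total"]),
        "mean_crop_ancestry": float(rates_all.loc[0, "mean_crop_ancestry"]),
        "species_F_ST": fstats["F_ST"],
        "species_F_IS": fstats["F_IS"],
        "hwe_deficit_p": hwe["p"],
        "sp_all_pure_wild": float(sgs_tab.iloc[-1]["Sp"]),
        "glm_model_1_interaction_p": float(glm12["model_1"].iloc[-1]["p"]),
        "glm_model_3_management_p": float(glm3.iloc[0]["p"]),
        "total_visitor_observations": int(vis_sum.attrs["total_observations"]),
        "stage_log": log,
    }
    write_report(artifacts, summary, outdir)
    return outdir


REPORT_SCHEMAS = {
    "delta_k.csv": ["K", "n_replicates", "mean_L", "sd_L", "delta_K"],
    "classification.csv": ["individual_id", "w", "category"],
    "introgression_rates_all.csv": ["group", "n_total", "n_hybrids"],
    "sgs.csv": ["population", "b", "F_1", "Sp"],
    "glm_model_1.csv": ["term", "F", "p"],
    "glm_model_3.csv": ["term", "F", "p"],
}


def write_report(artifacts: dict, summary: dict, outdir) -> Path:
    """Schema-validate artifact tables, write CSVs + JSON summary + manifest."""
    if not artifacts:
        raise PipelineError("report", "empty artifact set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, tab in artifacts.items():
        for col in REPORT_SCHEMAS.get(name, []):
            if col not in tab.columns:
                raise PipelineError("report", f"{name} missing column {col!r}")
        tab.to_csv(outdir / name, index=False, float_format="%.10g")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    manifest = {
        name: _sha256(outdir / name) for name in sorted(artifacts)
    }
    manifest["summary.json"] = _sha256(outdir / "summary.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
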