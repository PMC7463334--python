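"""End-to-end pipeline: simulate -> features -> GEA -> connectivity ->
PA -> indices.

One run is one immutable directory (named by a hash of the configuration
unless a path is given) containing every intermediate artifact as plain
CSV/JSON plus a line-oriented log recording the package version, seed and
the full configuration.  The stage topology follows the method's
workflow: the adaptive-potential index needs both the PA surface (from
the GEA stage) and the dFST matrix (from the connectivity stage); OCI and
ICI need only dFST.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from reefscape import __version__
from reefscape import connectivity as conn
from reefscape import env_features as envf
from reefscape import gea as gea_mod
from reefscape import indices as idx_mod
from reefscape import predict as predict_mod
from reefscape.genotypes import filter_snps, ld_prune, pairwise_fst, structure_covariate
from reefscape.synthetic import SeascapeConfig, generate_genotypes, generate_seascape

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables, with the method's reference values as
    defaults.  Unknown keys in a TOML file are rejected."""

    out_dir: str | None = None
    seed: int = 0
    # stage toggles
    run_gea: bool = True
    run_connectivity: bool = True
    run_indices: bool = True
    # simulation
    rows: int = 30
    cols: int = 30
    n_days: int = 1825
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 3
    # environmental descriptors
    baf_window_days: int = 14
    baf_threshold: float = 4.0
    # genotype filters
    maf: float = 0.05
    major_geno: float = 0.95
    miss: float = 0.1
    ld_r2: float = 0.3
    ld_window_snps: int = 50
    # GEA
    q_threshold: float = 0.01
    min_class_count: int = 10
    structure_axes: int = 1
    # connectivity
    min_site_n: int = 10
    pair_collapse: str = "min"
    # indices
    dfst_threshold: float = 0.02
    pa_tags: tuple = ("BAF",)

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pa_tags" in raw:
            raw["pa_tags"] = tuple(raw["pa_tags"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Run every enabled stage; returns the run directory."""
    out = Path(config.out_dir) if config.out_dir else Path(f"run_{config.digest()}")
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"

    def log(msg: str) -> None:
        line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}"
        logger.info(msg)
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    log(f"reefscape {__version__} seed={config.seed} config_digest={config.digest()}")
    log("config " + json.dumps(dataclasses.asdict(config), sort_keys=True, default=str))

    stage = "simulate"
    try:
        scfg = SeascapeConfig(
            rows=config.rows, cols=config.cols, n_days=config.n_days,
            seed=config.seed, n_neutral_loci=config.n_neutral_loci,
            n_adaptive_loci=config.n_adaptive_loci,
        )
        scape = generate_seascape(scfg)
        sites = scape["sites"]
        sites_out = sites.rename(columns={"site": "id"}).assign(site=sites["site"])
        sites_out[["id", "site", "lon", "lat"]].to_csv(out / "sites.csv", index=False)
        scape["reef_grid"].to_csv(out / "reefs.csv")
        log(f"simulate: {config.rows}x{config.cols} grid, {len(sites)} sites")

        stage = "connectivity-distances"
        acc = conn.accumulate_directional_speed(scape["u"], scape["v"])
        graph = conn.build_transition_graph(acc, scape["u"].mask)
        site_nodes = conn.map_points_to_nodes(
            graph, list(zip(sites["row"], sites["col"]))
        )
        site_dist = conn.least_cost(graph, site_nodes)
        pd.DataFrame(site_dist, index=sites["site"], columns=sites["site"]).to_csv(
            out / "distances.csv"
        )
        log(f"distances: {len(site_nodes)} sites, asymmetric least-cost")

        stage = "features"
        sst, aux = scape["sst"], scape["aux"]
        cur = envf.current_speed(scape["u"], scape["v"])
        at = envf.alkalinity(sst, aux["SSS"])
        baf = envf.bleaching_alert_frequency(
            sst, window_days=config.baf_window_days, threshold=config.baf_threshold
        )
        grid = scfg.grid
        rng_static = np.random.default_rng([config.seed, 11])
        depth = np.where(scape["u"].mask, rng_static.uniform(1, 40, scape["u"].mask.shape), np.nan)
        popdens = np.where(scape["u"].mask, rng_static.uniform(0, 500, scape["u"].mask.shape), np.nan)
        daily = {"SST": sst, "SSS": aux["SSS"], "CHL": aux["CHL"], "CUR": cur, "AT": at}
        monthly = {"SPM": aux["SPM"], "PAR": aux["PAR"]}
        static = {"BAF": baf, "DEPTH": depth, "POPDENS": popdens}
        pts = sites[["lon", "lat"]].assign(id=sites["site"])
        site_features = envf.build_feature_table(
            daily, monthly, static,
            assign=lambda m: envf.extract_at_points(m, grid, pts, mask=scape["u"].mask),
        )
        site_features.insert(0, "site", sites["site"].to_numpy())
        site_features.to_csv(out / "features.csv", index=False)
        reef_features = envf.build_feature_table(
            daily, monthly, static,
            assign=lambda m: envf.zonal_mean(m, scape["reef_grid"]),
        )
        reef_features.insert(0, "cell_id", scape["reef_grid"].ids)
        reef_features.to_csv(out / "reef_features.csv", index=False)
        log(f"features: {site_features.shape[1] - 1} descriptor columns")

        stage = "genotypes"
        env_site = site_features["BAF"].to_numpy(float)
        span = env_site.max() - env_site.min()
        env_norm = (env_site - env_site.min()) / (span if span > 0 else 1.0)
        matrix, truth = generate_genotypes(
            scfg, conn.collapse_directed(site_dist, config.pair_collapse), env_norm
        )
        truth.to_csv(out / "truth.csv", index=False)
        matrix.to_vcf(str(out / "genotypes.vcf"))
        filtered = filter_snps(matrix, config.maf, config.major_geno, config.miss)
        filtered = ld_prune(filtered, config.ld_r2, config.ld_window_snps)
        log(f"genotypes: {matrix.n_snps} simulated -> {filtered.n_snps} after filters")

        pa_table = None
        if config.run_gea:
            stage = "gea"
            covar = structure_covariate(filtered, k=config.structure_axes)
            env_ind = site_features.set_index("site").loc[
                filtered.individuals["site"]
            ].reset_index()
            env_cols = [c for c in site_features.columns if c != "site"]
            usable = [c for c in env_cols if np.nanstd(env_ind[c].to_numpy(float)) > 0]
            models = gea_mod.scan_associations(
                filtered, env_ind[usable], covariates=covar,
                min_class_count=config.min_class_count,
            )
            models = gea_mod.add_qvalues(models)
            models.to_csv(out / "models.csv", index=False)
            sgea = gea_mod.select_sgea(models, config.q_threshold)
            sgea.to_csv(out / "sgea.csv", index=False)
            log(f"gea: {len(models)} models tested, {len(sgea)} SGEAs")
            if len(sgea):
                pa = predict_mod.compute_pa(
                    sgea, reef_features, tags=[t for t in config.pa_tags
                                              if t in set(sgea["env_var"])] or None,
                )
                pa_table = pd.DataFrame({
                    "cell_id": scape["reef_grid"].ids, "PA": pa["PA"].to_numpy(),
                })
                pa_table.to_csv(out / "pa.csv", index=False)
                log(f"pa: mean={pa['PA'].mean():.3f}")

        model = None
        dfst = None
        if config.run_connectivity:
            stage = "connectivity-model"
            fst_tab = pairwise_fst(filtered, min_n=config.min_site_n)
            fst_tab.to_csv(out / "fst.csv", index=False)
            site_ix = {s: i for i, s in enumerate(sites["site"])}
            d_sym = conn.collapse_directed(site_dist, config.pair_collapse)
            d_pairs = np.array([d_sym[site_ix[a], site_ix[b]]
                                for a, b in zip(fst_tab["site1"], fst_tab["site2"])])
            model = conn.fit_connectivity_model(fst_tab["fst"].to_numpy(), d_pairs)
            eu = conn.euclidean_distances(sites["lon"].to_numpy(), sites["lat"].to_numpy())
            e_pairs = np.array([eu[site_ix[a], site_ix[b]]
                                for a, b in zip(fst_tab["site1"], fst_tab["site2"])])
            model_eu = conn.fit_connectivity_model(
                fst_tab["fst"].to_numpy(), e_pairs, kind="euclidean")
            with open(out / "connectivity_model.json", "w") as fh:
                json.dump({"least_cost": model.to_dict(),
                           "euclidean": model_eu.to_dict()}, fh, indent=2)
            log(f"connectivity: R2={model.r2:.3f} AIC={model.aic:.1f} "
                f"(euclidean R2={model_eu.r2:.3f} AIC={model_eu.aic:.1f})")

            stage = "dfst"
            reef_nodes = conn.map_points_to_nodes(
                graph, list(zip(scape["reef_grid"].cells["row"],
                                scape["reef_grid"].cells["col"]))
            )
            reef_dist = conn.least_cost(graph, reef_nodes)
            dfst = conn.predict_dfst(model, reef_dist)
            ids = scape["reef_grid"].ids
            pd.DataFrame(dfst, index=ids, columns=ids).to_csv(out / "dfst.csv")
            log(f"dfst: {dfst.shape[0]}x{dfst.shape[1]} directional matrix")

        if config.run_indices and dfst is not None:
            stage = "indices"
            areas = scape["reef_grid"].areas
            pa_vec = None
            if pa_table is not None:
                pa_vec = pa_table["PA"].to_numpy(float)
            table = idx_mod.index_table(
                scape["reef_grid"].ids, dfst, areas, pa_vec, T=config.dfst_threshold
            )
            table.to_csv(out / "indices.csv", index=False)
            log(f"indices: OCI mean={table['oci_km2'].mean():.1f} km2, "
                f"ICI mean={table['ici_km2'].mean():.1f} km2"
                + (f", API mean={table['api_km2'].mean():.1f} km2" if pa_vec is not None else ""))
    except Exception as exc:
        log(f"FAILED at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log("done")
    return out
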