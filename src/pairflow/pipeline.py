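"""End-to-end orchestration: inputs -> filter -> admixture -> divergence ->
pair table -> association, from a single declarative config.

Three entry modes:

* ``simulate`` -- generate genotypes, traits, climate and coordinates from
  a :class:`~pairflow.simulate.SimConfig`;
* ``files`` -- ingest a VCF, sample-metadata CSV, clade-level trait CSV,
  locality-level climate CSV and a pair-definition CSV;
* ``table`` -- start from a precomputed pair table (a path, or the
  packaged 21-pair comparison table) and run only the inferential stage.

All randomness flows from one master seed. Every stage failure aborts with
the stage name and cause; outputs already written are retained.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, datasets, divergence, io, pairs, simulate as sim
from .admixture import estimate_gene_flow, fit_admixture

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "closest_populations"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineConfig:
    mode: str = "table"  # simulate | files | table
    output_dir: str = "pairflow_out"
    seed: int = 0
    # simulate mode
    simulate: dict = field(default_factory=dict)
    # files mode
    vcf: str | None = None
    metadata: str | None = None
    traits: str | None = None
    climate: str | None = None
    pair_definitions: str | None = None
    # table mode ("sceloporus" loads the packaged fixture)
    table: str = "sceloporus"
    # stage settings
    filter: dict = field(default_factory=dict)  # max_missing_frac/min_quality/min_mac
    admixture: dict = field(default_factory=dict)  # n_restarts/max_iter/tol
    divergence: dict = field(default_factory=dict)  # scale/cum_threshold
    association: dict = field(default_factory=dict)  # iterations/burnin/thin/models/exclude
    species_map: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("simulate", "files", "table"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            for name in ("vcf", "metadata", "traits", "climate", "pair_definitions"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} input missing: {p}")
        if self.mode == "table" and self.table != "sceloporus":
            if not Path(self.table).exists():
                raise FileNotFoundError(f"pair table missing: {self.table}")


def closest_populations(meta: pd.DataFrame, clade_a, clade_b):
    """The geographically closest pair of populations across two clades,
    judged by great-circle distance between population mean coordinates."""
    best = None
    for pa in meta.loc[meta["clade"] == clade_a, "population"].unique():
        la, lo = pairs.mean_coordinates(meta, pa, unit_col="population")
        for pb in meta.loc[meta["clade"] == clade_b, "population"].unique():
            lb, lob = pairs.mean_coordinates(meta, pb, unit_col="population")
            d = pairs.haversine_km(la, lo, lb, lob)
            if best is None or d < best[0]:
                best = (d, pa, pb)
    if best is None:
        raise ValueError(f"no populations for clades {clade_a!r}/{clade_b!r}")
    return best[1], best[2]


def _geneflow_stage(g, meta, defs, seed: int, adm_opts: dict):
    """Per-pair K=2 admixture fits, clade- and population-based."""
    gf_clade, gf_pop, n_snps = {}, {}, {}
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(defs))
    meta_i = meta.set_index("sample", drop=False)
    for i, d in enumerate(defs):
        in_pair = meta_i.loc[meta_i["clade"].isin([d.clade_a, d.clade_b]), "sample"]
        sub = g.take_samples(list(in_pair))
        # drop sites monomorphic within the pair subset
        sub = sub.take_sites(io._minor_allele_count(sub.calls) >= 1)
        n_snps[d.pair_id] = sub.n_sites
        q = fit_admixture(sub, K=2, seed=int(seeds[2 * i]) % (2**31), **adm_opts)
        gf_clade[d.pair_id] = estimate_gene_flow(q, meta_i, pair_id=d.pair_id)

        pa, pb = d.population_a, d.population_b
        if pa is None or (isinstance(pa, float) and np.isnan(pa)):
            pa, pb = closest_populations(meta, d.clade_a, d.clade_b)
        in_pops = meta_i.loc[meta_i["population"].isin([pa, pb]), "sample"]
        subp = g.take_samples(list(in_pops))
        subp = subp.take_sites(io._minor_allele_count(subp.calls) >= 1)
        qp = fit_admixture(subp, K=2, seed=int(seeds[2 * i + 1]) % (2**31), **adm_opts)
        gf_pop[d.pair_id] = estimate_gene_flow(qp, meta_i, pair_id=d.pair_id)
    return gf_clade, gf_pop, n_snps


def _divergence_stage(traits, climate, defs, opts):
    scale = opts.get("scale", False)
    cum = opts.get("cum_threshold", 99.0)
    morph_model = divergence.run_pca(traits, scale=scale, cum_threshold=cum)
    clim_model = divergence.run_pca(climate, scale=scale, cum_threshold=cum)
    morph = {d.pair_id: divergence.pc_weighted_divergence(
        morph_model, d.clade_a, d.clade_b, pair_id=d.pair_id) for d in defs}
    clim = {d.pair_id: divergence.pc_weighted_divergence(
        clim_model, d.clade_a, d.clade_b, pair_id=d.pair_id) for d in defs}
    return morph, clim


def _association_stage(table, opts, seed, outdir):
    chain = {k: opts[k] for k in ("iterations", "burnin", "thin") if k in opts}
    exclude = opts.get("exclude", [])
    if exclude:
        table = association.exclude_comparisons(table, exclude)
    cols = {"clade mean vs clade prop":
            ("clade_admixture_mean_freq", "clade_admixture_prop_ind"),
            "pop mean vs pop prop":
            ("pop_admixture_mean_freq", "pop_admixture_prop_ind"),
            "clade vs pop mean":
            ("clade_admixture_mean_freq", "pop_admixture_mean_freq"),
            "clade vs pop prop":
            ("clade_admixture_prop_ind", "pop_admixture_prop_ind"),
            "morphology vs climate": ("morphology_pc", "climate_pc"),
            "distance vs morphology": ("distance_km", "morphology_pc"),
            "distance vs climate": ("distance_km", "climate_pc"),
            "time vs morphology": ("time_myr", "morphology_pc"),
            "time vs climate": ("time_myr", "climate_pc")}
    corr_rows = []
    for label, (a, b) in cols.items():
        r = association.spearman(table[a], table[b])
        corr_rows.append({"pair": label, "x": a, "y": b, "rho": r.rho, "p": r.p,
                          "degenerate": r.degenerate})
    pd.DataFrame(corr_rows).to_csv(outdir / "correlations.csv", index=False)

    glm_rows = []
    sub_seeds = np.random.SeedSequence(seed).generate_state(4)
    for s, pred in zip(sub_seeds, ("time", "space", "morphology", "climate")):
        try:
            res = association.fit_bayes_glm(
                table, association.ModelSpec((pred,), seed=int(s) % (2**31), **chain))
        except ValueError as exc:
            glm_rows.append({"model": f"gene_flow ~ {pred}", "coef": pred,
                             "error": str(exc)})
            continue
        row = res.summary.loc[pred]
        glm_rows.append({"model": res.spec.label, "coef": pred, "mean": row["mean"],
                         "ci_lower": row["ci_lower"], "ci_upper": row["ci_upper"],
                         "ess": row["ess"], "pmcmc": row["pmcmc"],
                         "dic": association.dic(res), "error": ""})
    pd.DataFrame(glm_rows).to_csv(outdir / "glm_summary.csv", index=False)

    model_set = association.default_model_set(opts.get("models") == "all15")
    ranking = association.rank_models(table, model_set, seed=seed + 1, **chain)
    rank_out = ranking.table.drop(columns=["predictors"])
    rank_out.to_csv(outdir / "model_ranking.csv", index=False)
    return table, ranking


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a dict of the main artifacts."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pairflow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    bundle = {}
    try:
        logger.info("config: %s", json.dumps(config.__dict__, default=str, sort_keys=True))
        species_map = config.species_map
        if config.mode == "table":
            with _stage("load pair table"):
                if config.table == "sceloporus":
                    table = datasets.load_sceloporus_pairs()
                    if species_map is None:
                        species_map = datasets.SPECIES_OF_CLADE
                else:
                    table = pd.read_csv(config.table)
        else:
            if config.mode == "simulate":
                with _stage("simulate"):
                    scfg = sim.SimConfig(seed=config.seed, **config.simulate)
                    g, truth = sim.simulate_genotypes(scfg)
                    traits, climate, meta = sim.simulate_traits_and_climate(scfg)
                    rng = np.random.default_rng(config.seed + 17)
                    labels = scfg.clade_labels()
                    defs = [pairs.PairDefinition(
                        pair_id=f"{a}|{b}", clade_a=a, clade_b=b,
                        divergence_time_myr=float(rng.uniform(2.5, 4.2)))
                        for i, a in enumerate(labels) for b in labels[i + 1:]]
                    bundle["truth"] = truth
            else:
                with _stage("ingest"):
                    g = io.read_vcf(config.vcf)
                    meta = io.read_sample_metadata(config.metadata)
                    defs = pairs.read_pair_definitions(config.pair_definitions)
                with _stage("divergence inputs"):
                    traits = divergence.TraitMatrix.from_dataframe(
                        pd.read_csv(config.traits, index_col=0))
                    clim_local = divergence.TraitMatrix.from_dataframe(
                        pd.read_csv(config.climate, index_col=0))
                    unit_of = meta.set_index("sample")["clade"]
                    climate = divergence.average_climate_by_unit(clim_local, unit_of)
            with _stage("filter"):
                g = io.filter_snps(g, **config.filter)
                logger.info("filter: %d sites retained", g.n_sites)
            with _stage("gene flow"):
                gf_clade, gf_pop, n_snps = _geneflow_stage(
                    g, meta, defs, config.seed + 29, dict(config.admixture))
            with _stage("divergence"):
                morph, clim = _divergence_stage(traits, climate, defs, config.divergence)
            with _stage("pair table"):
                table = pairs.build_pair_table(
                    defs, gf_clade, gf_pop, morph, clim, meta, n_snps=n_snps)
        table.to_csv(outdir / "pair_table.csv", index=False)
        bundle["pair_table"] = table

        with _stage("association"):
            used, ranking = _association_stage(
                table, dict(config.association), config.seed + 101, outdir)
            bundle["ranking"] = ranking
        if species_map is not None:
            with _stage("intra/inter summary"):
                summary = association.intra_inter_summary(table, species_map)
                summary.to_csv(outdir / "intra_inter.csv", index=False)
                bundle["intra_inter"] = summary
        logger.info("pipeline complete: %s", outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return bundle
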