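"""End-to-end orchestration: simulate/load -> rarefy -> filter -> SAD fits
-> diversity -> co-occurrence networks -> richness models.

A single master seed is split deterministically per stage; outputs are plain
TSV/JSON/SIF/GraphML files plus a manifest (config hash, seed, version, no
wallclock) so reruns with the same config are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity, network, richness, sad, synthetic
from .io_tables import (EnvTable, OTUTable, filter_rel_abundance, rarefy,
                        read_env_table, read_metadata, read_otu_table,
                        write_results)

logger = logging.getLogger(__name__)

DESK_DEPTHS = {"bacteria": 7000, "eukarya": 1200, "archaea": 3000}


class StageError(RuntimeError):
    def __init__(self, stage: str, fingerprint: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results"
    #: paths per domain; empty means simulate a fixture instead
    otu_tables: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    env: str | None = None
    fixture: dict = field(default_factory=dict)
    rarefy_depths: dict = field(default_factory=lambda: dict(DESK_DEPTHS))
    filter_threshold_pct: float = 0.001
    sad_scales: tuple = ("regional", "local")
    truncated: bool = True
    mic_alpha: float = 0.6
    mic_c: float = 15.0
    mic_threshold: float = 0.8
    p_threshold: float = 0.001
    n_perm: int = 199
    adjust_method: str = "benjamini_hochberg"
    run_null_test: bool = False
    model_families: dict = field(default_factory=lambda: {
        "bacteria": "negative_binomial", "eukarya": "gaussian",
        "archaea": "gaussian"})
    allow_splines: bool = False
    prune_r_threshold: float = 0.6

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for label, path in {**self.otu_tables, "env": self.env or ""}.items():
            if path and not Path(path).exists():
                raise FileNotFoundError(f"configured input {label!r} missing: {path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sad_scales"] = list(self.sad_scales)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage_seeds(master: int) -> dict[str, int]:
    names = ("simulate", "rarefy", "network", "null_test")
    state = np.random.SeedSequence(master).generate_state(len(names))
    return {name: int(s) for name, s in zip(names, state)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write per-stage outputs + manifest, return a report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {"stages": []}
    log_path = outdir / "run_log.jsonl"
    log_fh = log_path.open("w")

    def stage(name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            log_fh.write(json.dumps({"stage": name, "status": "failed",
                                     "error": str(exc)}) + "\n")
            log_fh.close()
            raise StageError(name, _fingerprint(args), exc) from exc
        dt = time.perf_counter() - t0
        logger.info("stage %-12s done in %.2fs", name, dt)
        log_fh.write(json.dumps({"stage": name, "status": "ok",
                                 "seconds": round(dt, 3)}) + "\n")
        report["stages"].append(name)
        return result

    # -- inputs ----------------------------------------------------------
    if config.otu_tables:
        tables = {}
        for domain, path in config.otu_tables.items():
            meta = read_metadata(config.metadata[domain])
            tables[domain] = stage(f"load[{domain}]", read_otu_table, path, meta)
        env = stage("load[env]", read_env_table, config.env) if config.env else None
        truth = None
    else:
        fix_cfg = synthetic.FixtureConfig(
            **{**config.fixture, "seed": seeds["simulate"]})
        bundle = stage("simulate", synthetic.make_fixture, fix_cfg)
        tables, env, truth = bundle.tables, bundle.env, bundle.truth
        synthetic.write_fixture(bundle, outdir / "fixture")

    # -- rarefy ----------------------------------------------------------
    rarefied = {}
    for i, (domain, table) in enumerate(sorted(tables.items())):
        depth = config.rarefy_depths.get(domain)
        rarefied[domain] = (stage(f"rarefy[{domain}]", rarefy, table, depth,
                                  seeds["rarefy"] + i)
                            if depth else table)

    # -- SAD fits --------------------------------------------------------
    comp_frames, curve_frames = [], []
    for domain, table in sorted(rarefied.items()):
        for scale in config.sad_scales:
            comp, curves = stage(f"sadfit[{domain},{scale}]", sad.fit_sad_suite,
                                 table, scale, config.truncated)
            comp.insert(0, "dataset", domain)
            curves.insert(0, "dataset", domain)
            comp_frames.append(comp)
            curve_frames.append(curves)
    comparisons = pd.concat(comp_frames, ignore_index=True)
    write_results(comparisons, outdir / "sad_model_comparison.tsv")
    write_results(pd.concat(curve_frames, ignore_index=True),
                  outdir / "sad_octave_curves.tsv")

    # -- diversity -------------------------------------------------------
    chao_tables = {d: diversity.chao1_by_sample(t) for d, t in sorted(rarefied.items())}
    chao_long = pd.concat(
        [pd.DataFrame({"dataset": d, "sample_id": s.index, "chao1": s.values})
         for d, s in chao_tables.items()], ignore_index=True)
    write_results(chao_long, outdir / "chao1_per_sample.tsv")
    if all(t.metadata is not None and "location" in t.metadata.columns
           for t in rarefied.values()):
        keys = {d: t.metadata["location"] for d, t in rarefied.items()}
        corr = stage("diversity[corr]", diversity.cross_domain_correlations,
                     chao_tables, keys)
        write_results(corr, outdir / "richness_correlations.tsv")
    curves = []
    for domain, table in sorted(rarefied.items()):
        pooled = table.counts.sum(axis=0).to_numpy()
        total = int(pooled.sum())
        depths = np.unique(np.linspace(1, total, 25, dtype=np.int64))
        rc = diversity.rarefaction_curve(pooled, depths)
        curves.append(pd.DataFrame({"dataset": domain, "depth": rc.depths,
                                    "expected_richness": rc.expected_richness}))
    write_results(pd.concat(curves, ignore_index=True),
                  outdir / "rarefaction_curves.tsv")

    # -- networks per region --------------------------------------------
    nets = {}
    null_ps = {}
    meta_any = next(iter(rarefied.values())).require_metadata()
    for r_i, region in enumerate(sorted(meta_any["region"].unique())):
        rel, domain_of = _combined_relative_frame(
            rarefied, region, config.filter_threshold_pct)
        if rel.shape[1] < 2:
            logger.warning("network[%s]: fewer than 2 OTUs after filtering", region)
            continue
        pairs = stage(f"network[{region}]", network.pairwise_mic_frame, rel,
                      config.mic_alpha, config.mic_c)
        pairs = network.permutation_pvalues_frame(
            rel, pairs, n_perm=config.n_perm, seed=seeds["network"] + r_i,
            alpha=config.mic_alpha, c=config.mic_c)
        net = network.build_network(pairs, config.mic_threshold,
                                    config.p_threshold, domain_of,
                                    config.adjust_method)
        nets[region] = net
        network.edge_table(net).to_csv(outdir / f"network_edges_{region}.tsv",
                                       sep="\t", index=False)
        network.write_sif(net, outdir / f"network_{region}.sif")
        network.write_graphml(net, outdir / f"network_{region}.graphml")
        if config.run_null_test:
            null_ps[region] = stage(
                f"null_test[{region}]", network.cooccurrence_null_test,
                _region_table(rarefied["bacteria"], region),
                config.n_perm, seeds["null_test"] + r_i,
                config.mic_threshold, config.p_threshold,
                config.filter_threshold_pct, config.mic_alpha, config.mic_c,
                config.adjust_method)
    if nets:
        write_results(network.topology_table(nets),
                      outdir / "network_topology.tsv")
    if null_ps:
        write_results(null_ps, outdir / "cooccurrence_null_test.json",
                      format="json")

    # -- richness models -------------------------------------------------
    model_results = {}
    if env is not None:
        pruned, removed = richness.prune_covariates(env, config.prune_r_threshold)
        write_results({"removed": removed}, outdir / "pruned_covariates.json",
                      format="json")
        for domain, table in sorted(rarefied.items()):
            shared = [s for s in table.sample_ids if s in pruned.data.index]
            if len(shared) < len(pruned.data.columns) + 4:
                logger.warning("model[%s]: too few samples with covariates", domain)
                continue
            sub = table.subset_samples(shared)
            response = diversity.chao1_by_sample(sub).to_numpy()
            family = config.model_families.get(domain, "gaussian")
            if family == "negative_binomial":
                logger.info("model[%s]: rounding Chao1 response to integers "
                            "for the NB family", domain)
                response = np.round(response)
            env_dom = EnvTable(pruned.data.loc[shared].copy(), pruned.units)
            env_dom, region_term = richness.add_factor(
                env_dom, "region", sub.require_metadata()["region"])
            model_results[domain] = stage(
                f"model[{domain}]", richness.stepwise_aic, response, env_dom,
                family, [region_term], "both", config.allow_splines)
        if model_results:
            write_results(richness.summarize_best_models(model_results),
                          outdir / "best_models.tsv")
            paths = {d: r.path for d, r in model_results.items()}
            write_results(paths, outdir / "stepwise_paths.json", format="json")

    # -- manifest --------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir")  # location of outputs must not affect their bytes
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "sadnet_version": __version__,
        "stages": report["stages"],
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log_fh.close()
    report.update({"outdir": str(outdir), "n_networks": len(nets),
                   "truth": truth, "comparisons": comparisons,
                   "models": model_results, "null_tests": null_ps})
    return report


def _region_table(table: OTUTable, region: str) -> OTUTable:
    meta = table.require_metadata()
    return table.subset_samples(list(meta.index[meta["region"] == region]))


def _combined_relative_frame(tables: dict[str, OTUTable], region: str,
                             threshold_pct: float):
    """Cross-domain relative-abundance frame for one region.

    Each domain is filtered (> threshold % within region x domain) and
    converted to within-domain relative abundances; domains are aligned on
    the shared ``location`` metadata key and OTU ids are domain-prefixed.
    """
    frames = []
    domain_of = {}
    shared = None
    for domain, table in sorted(tables.items()):
        sub = _region_table(table, region)
        if not sub.sample_ids:
            continue
        filt = filter_rel_abundance(sub, threshold_pct)
        rel = filt.counts.div(filt.counts.sum(axis=1).replace(0, 1), axis=0)
        meta = sub.require_metadata()
        key = meta["location"] if "location" in meta.columns else meta.index
        rel.index = key.loc[rel.index] if "location" in meta.columns else rel.index
        rel = rel[~rel.index.duplicated()]
        rel.columns = [f"{domain}:{o}" for o in rel.columns]
        for col in rel.columns:
            domain_of[col] = domain
        frames.append(rel)
        shared = rel.index if shared is None else shared.intersection(rel.index)
    if not frames or shared is None or len(shared) < 4:
        return pd.DataFrame(), {}
    combined = pd.concat([f.loc[shared] for f in frames], axis=1)
    return combined, domain_of


def _fingerprint(args) -> str:
    bits = []
    for a in args:
        if isinstance(a, OTUTable):
            bits.append(f"OTUTable{a.shape}")
        elif isinstance(a, pd.DataFrame):
            bits.append(f"frame{a.shape}")
        else:
            bits.append(type(a).__name__)
    return ",".join(bits) or "-"


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
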