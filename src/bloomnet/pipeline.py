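"""Config-driven end-to-end orchestration of the comparative analysis.

One run executes, in order: taxonomic cleanup -> rarefaction -> alpha
diversity + region tests -> Bray-Curtis PCoA + PERMANOVA -> constrained
ordination with forward selection -> per-region surface co-occurrence
networks with modules, keystones, and focal-taxon reports -> a
region-comparison report.  A single seed fans out deterministically to
every stochastic stage, so runs are pure functions of (inputs, config,
seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, network, ordination, preprocess
from .simulate import SimConfig, simulate_community

logger = logging.getLogger("bloomnet")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]

_THRESHOLD_RANGES = {
    "r_min": (0.0, 1.0), "p_max": (0.0, 1.0), "min_abund": (0.0, 1.0),
    "min_prev": (0.0, 1.0), "alpha": (0.0, 1.0),
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run parameters with field defaults matching the reference
    analysis (r_min 0.6, p_max 0.05, min_abund 0.01%, min_prev 20%,
    alpha 0.05, 999 permutations)."""

    seed: int = 0
    output_dir: str = "bloomnet_out"
    focal_genus: str = "Noctiluca"
    prok_counts: str | None = None
    euk_counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    simulate: SimConfig | None = None
    r_min: float = 0.6
    p_max: float = 0.05
    min_abund: float = 1e-4
    min_prev: float = 0.2
    alpha: float = 0.05
    n_perm: int = 999
    bh_correct: bool = False
    pcoa_correction: str | None = None
    genus_rda: bool = True
    bloom_density_cells_per_l: float | None = None

    def validate(self) -> None:
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"{key} must lie in [{lo}, {hi}], got {v!r}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm!r}")
        has_paths = all(getattr(self, k) is not None for k in
                        ("prok_counts", "euk_counts", "taxonomy", "metadata"))
        if self.simulate is None and not has_paths:
            raise ValueError("config must provide either a 'simulate' block or "
                             "all four input table paths")
        if self.simulate is not None:
            self.simulate.validate()


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    sim = raw.pop("simulate", None)
    if sim is not None:
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ValueError(f"{path}: unknown simulate keys: {sorted(sim_unknown)}")
        if "layers" in sim:
            sim["layers"] = tuple(sim["layers"])
        if "bloom_layer_decay" in sim:
            sim["bloom_layer_decay"] = tuple(sim["bloom_layer_decay"])
        sim = SimConfig(**sim)
    config = RunConfig(simulate=sim, **raw)
    config.validate()
    return config


def _child_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(names, children)}


_STAGE_SEEDS = ["simulate", "rarefy_prok", "rarefy_euk", "permanova_prok",
                "permanova_euk", "forward_select_prok", "forward_select_euk"]


def _load_inputs(config: RunConfig, seeds: dict[str, int]):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=seeds["simulate"])
        prok, euk, tax, meta, truth = simulate_community(sim)
        return prok, euk, tax, meta, truth
    prok = preprocess.read_count_table(config.prok_counts)
    euk = preprocess.read_count_table(config.euk_counts)
    tax = preprocess.read_taxonomy(config.taxonomy)
    meta = preprocess.read_metadata(config.metadata)
    preprocess.cross_check_samples(prok, meta)
    preprocess.cross_check_samples(euk, meta)
    return prok, euk, tax, meta, None


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / name, sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict of
    DataFrames/objects and writes TSV outputs plus ``summary.txt`` under
    ``config.output_dir``."""
    config.validate()
    seeds = _child_seeds(config.seed, _STAGE_SEEDS)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seeds": seeds}
    run_log: list[dict] = []

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                out = fn()
                run_log.append(dict(stage=name, status="ok"))
                return out
            except Exception as exc:
                run_log.append(dict(stage=name, status="FAILED", error=str(exc)))
                pd.DataFrame(run_log).to_csv(outdir / "run_log.tsv", sep="\t",
                                             index=False)
                (outdir / "FAILED").write_text(f"{name}: {exc}\n")
                raise PipelineError(name, str(exc)) from exc
        return deco

    prok_raw, euk_raw, tax, meta, truth = stage("load_inputs")(
        lambda: _load_inputs(config, seeds))
    report["truth"] = truth

    # --- cleanup + normalisation ---------------------------------------
    prok_f, euk_f = stage("filter_taxonomy")(lambda: (
        preprocess.filter_taxonomy(prok_raw, tax, "prokaryote"),
        preprocess.filter_taxonomy(euk_raw, tax, "eukaryote")))
    prok, euk = stage("rarefy")(lambda: (
        preprocess.rarefy_min_depth(prok_f, seeds["rarefy_prok"]),
        preprocess.rarefy_min_depth(euk_f, seeds["rarefy_euk"])))

    region = meta.loc[prok.index, "region"]

    # --- shared ASVs (presence after filtering, before rarefaction) ----
    def _shared(table):
        br = table.loc[region == "BR"]
        nr = table.loc[region == "NR"]
        return preprocess.shared_asv_summary(br, nr)

    shared = stage("shared_asvs")(lambda: pd.DataFrame(
        [("prokaryote", *_shared(prok_f)), ("eukaryote", *_shared(euk_f))],
        columns=["marker", "n_shared", "n_total", "percent_shared"]
    ).set_index("marker"))
    report["shared_asvs"] = shared

    # --- environment comparison (Table-1 style) ------------------------
    env_rows = []
    for layer in ("S", "M", "B"):
        if (meta["layer"] == layer).any():
            env_rows.append(diversity.group_compare_environment(meta, layer))
    env_cmp = stage("environment_comparison")(
        lambda: pd.concat(env_rows).reset_index().set_index(["layer", "variable"]))
    report["environment_comparison"] = env_cmp

    if config.bloom_density_cells_per_l is not None:
        report["bloom_call"] = preprocess.classify_bloom(
            config.bloom_density_cells_per_l)

    # --- alpha diversity + region tests --------------------------------
    def _alpha(table, marker):
        a = diversity.alpha_diversity(table)
        a["region"] = region
        a["marker"] = marker
        return a

    alpha = stage("alpha_diversity")(lambda: pd.concat(
        [_alpha(prok, "prokaryote"), _alpha(euk, "eukaryote")]))
    report["alpha_diversity"] = alpha

    def _alpha_tests():
        rows = []
        for marker in ("prokaryote", "eukaryote"):
            sub = alpha[alpha["marker"] == marker]
            for index in ("sobs", "shannon", "pielou"):
                x = sub.loc[sub["region"] == "BR", index].dropna()
                y = sub.loc[sub["region"] == "NR", index].dropna()
                res = diversity.wilcoxon_rank_sum(x, y)
                rows.append(dict(marker=marker, index=index,
                                 mean_br=float(x.mean()), mean_nr=float(y.mean()),
                                 br_lower=bool(x.mean() < y.mean()),
                                 p_value=res.p_value))
        return pd.DataFrame(rows).set_index(["marker", "index"])

    alpha_tests = stage("alpha_tests")(_alpha_tests)
    report["alpha_tests"] = alpha_tests

    # --- beta diversity -------------------------------------------------
    def _beta(table, marker):
        dm = diversity.bray_curtis(table)
        coords = diversity.pcoa(dm, n_axes=2, correction=config.pcoa_correction)
        perma = diversity.permanova(dm, region.loc[table.index],
                                    n_perm=config.n_perm,
                                    seed=seeds[f"permanova_{'prok' if marker == 'prokaryote' else 'euk'}"])
        return dm, coords, perma

    beta = stage("beta_diversity")(lambda: {
        "prokaryote": _beta(prok, "prokaryote"),
        "eukaryote": _beta(euk, "eukaryote")})
    report["permanova"] = pd.DataFrame(
        [dict(marker=m, pseudo_f=b[2].statistic, p_value=b[2].p_value)
         for m, b in beta.items()]).set_index("marker")
    report["pcoa"] = {m: b[1] for m, b in beta.items()}

    # --- constrained ordination -----------------------------------------
    env = stage("prepare_env")(lambda: ordination.prepare_env(meta.loc[prok.index]))
    retained = stage("vif_screen")(lambda: ordination.vif_screen(env))
    env_screened = env.data[retained]

    def _ordination(table, marker):
        y = ordination.aggregate_genus(table, tax) if config.genus_rda else table
        y = ordination.hellinger(y)
        trace, rda = ordination.forward_select(
            y, env_screened, alpha=config.alpha, n_perm=config.n_perm,
            seed=seeds[f"forward_select_{'prok' if marker == 'prokaryote' else 'euk'}"])
        return trace, rda

    ordn = stage("forward_selection")(lambda: {
        "prokaryote": _ordination(prok, "prokaryote"),
        "eukaryote": _ordination(euk, "eukaryote")})
    report["vif_retained"] = retained
    report["forward_selection"] = {m: t[0] for m, t in ordn.items()}
    report["rda"] = {m: t[1] for m, t in ordn.items()}

    # --- focal taxon vs environment -------------------------------------
    def _focal_env():
        focal_asvs = [a for a in euk.columns
                      if str(tax.loc[a, "genus"]).lower()
                      == config.focal_genus.lower()]
        if not focal_asvs:
            return None
        rel = preprocess.relative_abundance(euk)[focal_asvs].sum(axis=1)
        return ordination.taxon_env_spearman(rel, env_screened)

    report["focal_env_spearman"] = stage("focal_env_spearman")(_focal_env)

    # --- per-region surface networks ------------------------------------
    def _network(reg):
        surface = meta.index[(meta["region"] == reg) & (meta["layer"] == "S")]
        parts = []
        for table in (prok, euk):
            sub = table.loc[table.index.intersection(surface)]
            rel = preprocess.relative_abundance(sub)
            kept = network.network_filter(rel, config.min_abund, config.min_prev)
            parts.append(rel[kept])
        integrated = pd.concat(parts, axis=1)
        corr = network.spearman_matrix(integrated)
        meta_nodes = network.node_metadata(integrated, tax)
        net = network.build_network(corr, meta_nodes, r_min=config.r_min,
                                    p_max=config.p_max,
                                    bh_correct=config.bh_correct)
        modules = network.fast_greedy_modules(net)
        stats = network.network_stats(net, modules)
        keystones = network.keystone_rank(net)
        extracts = network.extract_modules(net, modules, config.focal_genus, tax)
        network.write_graphml(net, modules, outdir / f"network_{reg}.graphml")
        return dict(net=net, modules=modules, stats=stats,
                    keystones=keystones, extracts=extracts)

    nets = stage("networks")(lambda: {reg: _network(reg) for reg in ("BR", "NR")})
    report["networks"] = nets
    report["network_comparison"] = network.compare_regions(
        nets["BR"]["stats"], nets["NR"]["stats"])

    # --- outputs ---------------------------------------------------------
    def _write_outputs():
        _write(env_cmp, outdir, "environment_comparison.tsv")
        _write(alpha, outdir, "alpha_diversity.tsv")
        _write(alpha_tests, outdir, "alpha_tests.tsv")
        _write(shared, outdir, "shared_asvs.tsv")
        _write(report["permanova"], outdir, "permanova.tsv")
        for m, b in beta.items():
            _write(b[1].coordinates, outdir, f"pcoa_{m}.tsv")
        for m, (trace, _) in ordn.items():
            trace.to_csv(outdir / f"forward_selection_{m}.tsv", sep="\t",
                         index=False)
        _write(report["network_comparison"], outdir, "network_comparison.tsv")
        for reg in ("BR", "NR"):
            _write(nets[reg]["keystones"], outdir, f"keystones_{reg}.tsv")
        stats_df = pd.DataFrame({reg: dataclasses.asdict(nets[reg]["stats"])
                                 for reg in ("BR", "NR")})
        stats_df.to_csv(outdir / "network_stats.tsv", sep="\t")
        (outdir / "summary.txt").write_text(_summary_text(config, report))
        pd.DataFrame(run_log).to_csv(outdir / "run_log.tsv", sep="\t", index=False)

    stage("write_outputs")(_write_outputs)
    return report


def _summary_text(config: RunConfig, report: dict) -> str:
    lines = ["bloomnet pipeline summary", "=" * 40, ""]
    if "bloom_call" in report:
        lines += [f"Bloom classification at "
                  f"{config.bloom_density_cells_per_l:g} cells/L: "
                  f"{report['bloom_call']}", ""]
    lines += ["Shared ASVs between regions:",
              report["shared_asvs"].to_string(), ""]
    lines += ["Environmental comparison (BR vs NR per layer):",
              report["environment_comparison"].round(3).to_string(), ""]
    lines += ["Alpha-diversity region tests:",
              report["alpha_tests"].round(4).to_string(), ""]
    lines += ["PERMANOVA (region):", report["permanova"].round(4).to_string(), ""]
    for marker, trace in report["forward_selection"].items():
        sel = ", ".join(trace["variable"]) if len(trace) else "(none)"
        lines += [f"Forward-selected drivers ({marker}): {sel}"]
        rda = report["rda"][marker]
        if rda is not None:
            lines += [f"  explained variation: R2 = {rda.r_squared:.3f}, "
                      f"adjusted R2 = {rda.adj_r_squared:.3f}"]
    lines += ["", "Network comparison (surface, per region):",
              report["network_comparison"].to_string(), ""]
    for reg in ("BR", "NR"):
        ks = report["networks"][reg]["keystones"]
        lines += [f"Keystone ASVs ({reg}):",
                  ks.to_string() if len(ks) else "  (none: all betweenness zero)",
                  ""]
    return "\n".join(lines) + "\n"
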