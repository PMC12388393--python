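"""Synthetic amplicon-survey generator for bloom/non-bloom comparative studies.

Emulates a two-region, three-layer coastal sampling design: a bloom region
(BR) where a single dinoflagellate taxon overwhelmingly dominates surface
waters, and a non-bloom reference region (NR).  The generator plants every
structure the downstream analysis is meant to recover — a dominant bloom
taxon with depth-decaying relative abundance, correlated taxon modules,
environmental variables responding to bloom abundance, and a regional
richness deficit — and returns the planted parameters as a ground-truth
record so recovery can be scored.

Counts are drawn from a log-normal species-abundance model with
Dirichlet-multinomial sampling at a log-normally jittered library size,
which reproduces the long-tailed, overdispersed ASV tables typical of
marine 16S/18S surveys.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_community",
    "write_fixture",
    "read_ground_truth",
    "verify_manifest",
    "ENV_VARS",
    "NUTRIENT_VARS",
    "ENV_BASELINE",
]

ENV_VARS = ["T", "Sal", "Depth", "pH", "DO", "Chl_a", "NO3", "NO2", "NH4", "PO4", "SiO3"]
#: variables eligible for missing-at-random cells (field nutrient/pigment assays)
NUTRIENT_VARS = ["Chl_a", "NO3", "NO2", "NH4", "PO4", "SiO3"]

#: Per-(region, layer) environmental baselines (means of a coastal bloom
#: survey: T in degC, Sal PSU, Depth m, DO mg/L, Chl-a ug/L, nutrients mg/L).
ENV_BASELINE: dict[tuple[str, str], dict[str, float]] = {
    ("BR", "S"): dict(T=22.9, Sal=29.1, Depth=0.2, pH=7.7, DO=7.5, Chl_a=2.7,
                      NO3=184.4, NO2=29.7, NH4=851.8, PO4=72.8, SiO3=447.9),
    ("NR", "S"): dict(T=23.5, Sal=29.1, Depth=0.1, pH=7.6, DO=7.1, Chl_a=2.1,
                      NO3=240.8, NO2=28.9, NH4=130.2, PO4=27.2, SiO3=260.4),
    ("BR", "M"): dict(T=22.8, Sal=29.6, Depth=5.6, pH=7.7, DO=7.4, Chl_a=2.5,
                      NO3=96.5, NO2=24.5, NH4=291.5, PO4=13.7, SiO3=395.0),
    ("NR", "M"): dict(T=22.9, Sal=29.5, Depth=5.1, pH=7.6, DO=7.1, Chl_a=2.1,
                      NO3=97.3, NO2=21.0, NH4=316.1, PO4=10.8, SiO3=574.4),
    ("BR", "B"): dict(T=22.7, Sal=28.8, Depth=11.1, pH=7.7, DO=7.6, Chl_a=3.0,
                      NO3=147.3, NO2=37.3, NH4=222.0, PO4=51.6, SiO3=516.7),
    ("NR", "B"): dict(T=22.9, Sal=29.6, Depth=10.0, pH=7.6, DO=7.1, Chl_a=3.1,
                      NO3=90.9, NO2=21.4, NH4=311.1, PO4=12.4, SiO3=502.2),
}

# lineage pools: (phylum, class, order, family, genera)
_PROK_POOL = [
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae",
     ["Nautella", "Marivivens", "HIMB11", "Donghicola", "Unclassified"]),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae",
     ["Aurantivirga", "NS5_marine_group", "Unclassified"]),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Crocinitomicaceae",
     ["Fluviicola", "Unclassified"]),
    ("Bacteroidota", "Bacteroidia", "Chitinophagales", "Saprospiraceae",
     ["Lewinella", "Unclassified"]),
    ("Actinobacteriota", "Acidimicrobiia", "Microtrichales", "Microtrichaceae",
     ["Sva0996_marine_group"]),
    ("Actinobacteriota", "Acidimicrobiia", "Microtrichales", "Ilumatobacteraceae",
     ["Ilumatobacter", "Unclassified"]),
    ("Actinobacteriota", "Actinobacteria", "Actinomarinales", "Actinomarinaceae",
     ["Candidatus_Actinomarina"]),
    ("Proteobacteria", "Gammaproteobacteria", "Cellvibrionales", "Halieaceae",
     ["OM60_NOR5_clade", "Halioglobus"]),
    ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Burkholderiaceae",
     ["Limnobacter", "Unclassified"]),
    ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Halomonadaceae",
     ["Halomonas"]),
    ("Verrucomicrobiota", "Verrucomicrobiae", "Verrucomicrobiales", "Rubritaleaceae",
     ["Roseibacillus"]),
    ("Cyanobacteria", "Cyanobacteriia", "Synechococcales", "Cyanobiaceae",
     ["Synechococcus_CC9902"]),
]

_EUK_POOL = [
    ("Dinoflagellata", "Syndiniales", "Dino-Group-I", "Dino-Group-I-Clade-1",
     ["Dino-Group-I-Clade-1_X"]),
    ("Dinoflagellata", "Dinophyceae", "Gymnodiniales", "Gymnodiniaceae",
     ["Gymnodinium", "Lepidodinium", "Unclassified"]),
    ("Dinoflagellata", "Dinophyceae", "Peridiniales", "Peridiniaceae",
     ["Peridinium", "Unclassified"]),
    ("Cercozoa", "Thecofilosea", "Cryomonadida", "Protaspidae",
     ["Protaspa"]),
    ("Cercozoa", "Chlorarachniophyceae", "Chlorarachniales", "Chlorarachniaceae",
     ["Unclassified"]),
    ("Ochrophyta", "Bacillariophyceae", "Cymatosirales", "Cymatosiraceae",
     ["Minutocellus"]),
    ("Chlorophyta", "Mamiellophyceae", "Mamiellales", "Mamiellaceae",
     ["Micromonas"]),
    ("Cryptophyta", "Cryptophyceae", "Cryptomonadales", "Cryptomonadaceae",
     ["Cryptomonas", "Unclassified"]),
    ("Radiolaria", "Acantharea", "Arthracanthida", "Dorataspidae",
     ["Dorataspis_F3"]),
]

_BLOOM_LINEAGE = ("Eukaryota", "Dinoflagellata", "Dinophyceae", "Noctilucales",
                  "Noctilucaceae", "Noctiluca")

_PROK_CONTAMINANTS = [
    ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast", "Unclassified", "Unclassified"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales", "Mitochondria", "Unclassified"),
]
_EUK_CONTAMINANTS = [
    ("Eukaryota", "Metazoa", "Arthropoda", "Calanoida", "Paracalanidae", "Paracalanus"),
    ("Eukaryota", "Streptophyta", "Embryophyceae", "Unclassified", "Unclassified", "Unclassified"),
    ("Eukaryota", "Rhodophyta", "Florideophyceae", "Ceramiales", "Rhodomelaceae", "Unclassified"),
    ("Eukaryota", "Chlorophyta", "Trebouxiophyceae", "Chlorellales", "Chlorellaceae", "Chlorella"),
    ("Eukaryota", "Chlorophyta", "Ulvophyceae", "Ulvales", "Ulvaceae", "Ulva"),
]

RANKS = ["domain", "phylum", "class", "order", "family", "genus"]


@dataclass
class SimConfig:
    """Parameters of one synthetic survey.

    The defaults reproduce the reference design: 6 bloom-region (BR) and 9
    non-bloom-region (NR) sites, each sampled at surface/middle/bottom
    (45 samples), with the bloom taxon at ~96% relative abundance in BR
    surface waters and ammonium/phosphate tracking bloom abundance.
    """

    n_sites_br: int = 6
    n_sites_nr: int = 9
    layers: Sequence[str] = ("S", "M", "B")
    n_prok_taxa: int = 300
    n_euk_taxa: int = 150
    depth_per_sample: int = 50_000
    depth_jitter_sigma: float = 0.2
    bloom_taxon_fraction_surface: float = 0.96
    nr_bloom_fraction: float = 0.20
    #: multiplier on the BR surface fraction per layer (S, M, B); the
    #: defaults reproduce the observed 96% -> ~38% -> ~32% depth decay
    bloom_layer_decay: Sequence[float] = (1.0, 0.40, 0.34)
    bloom_logit_sigma: float = 0.25
    n_modules: int = 4
    module_size: int = 8
    module_rho: float = 0.9
    env_effect: Mapping[str, float] = field(
        default_factory=lambda: {"NH4": 1.0, "PO4": 0.6})
    richness_deficit_br: float = 0.3
    env_missing_frac: float = 0.05
    flat_env_baseline: bool = False
    sab_sigma: float = 1.2
    sample_noise_sigma: float = 0.6
    dispersion: float = 2000.0
    contaminant_frac: float = 0.04
    unclassified_frac: float = 0.03
    env_noise_frac: float = 0.08
    #: "cell": baselines are observational (bloom signature already in them);
    #: the driver response tracks within-cell bloom residuals only.
    #: "global": baselines are pre-bloom references; the response carries the
    #: full between-cell bloom signal.
    env_response_reference: str = "cell"
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_sites_br=self.n_sites_br, n_sites_nr=self.n_sites_nr,
                      n_prok_taxa=self.n_prok_taxa, n_euk_taxa=self.n_euk_taxa,
                      depth_per_sample=self.depth_per_sample,
                      n_modules=self.n_modules, module_size=self.module_size)
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("bloom_taxon_fraction_surface", "nr_bloom_fraction", "module_rho"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        for name in ("richness_deficit_br", "env_missing_frac",
                     "contaminant_frac", "unclassified_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")
        if len(self.layers) != len(self.bloom_layer_decay):
            raise ValueError("bloom_layer_decay must give one multiplier per layer")
        if self.n_modules * self.module_size > self.n_prok_taxa // 2:
            raise ValueError(
                f"module plan ({self.n_modules} x {self.module_size} taxa) exceeds "
                f"half the prokaryotic pool ({self.n_prok_taxa}); enlarge n_prok_taxa")
        unknown = set(self.env_effect) - set(ENV_VARS)
        if unknown:
            raise ValueError(f"env_effect names unknown variables: {sorted(unknown)}")
        if self.env_response_reference not in ("cell", "global"):
            raise ValueError("env_response_reference must be 'cell' or 'global', "
                             f"got {self.env_response_reference!r}")


@dataclass
class GroundTruth:
    """Planted parameters returned alongside a simulated survey."""

    module_assignment: dict[str, int]
    bloom_taxon_id: str
    true_env_drivers: list[str]
    expected_rel_abundance: dict[tuple[str, str], float]
    suppressed_taxa_br: list[str]

    def __post_init__(self) -> None:
        # each planted-module taxon carries exactly one module id by construction
        if self.bloom_taxon_id in self.module_assignment:
            raise ValueError("bloom taxon cannot belong to a planted module")


def _sample_ids(config: SimConfig) -> tuple[list[str], pd.DataFrame]:
    rows = []
    for region, n_sites in (("BR", config.n_sites_br), ("NR", config.n_sites_nr)):
        for s in range(1, n_sites + 1):
            for layer in config.layers:
                site = f"{region}{s}"
                rows.append((f"{site}_{layer}", region, layer, site))
    frame = pd.DataFrame(rows, columns=["sample_id", "region", "layer", "site"])
    return frame["sample_id"].tolist(), frame.set_index("sample_id")


def _lineages(rng: np.random.Generator, n: int, pool, domain: str,
              contaminants, contaminant_idx, unclassified_idx) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for i in range(n):
        if i in contaminant_idx:
            out.append(contaminants[rng.integers(len(contaminants))])
            continue
        phylum, cls, order, family, genera = pool[rng.integers(len(pool))]
        genus = genera[rng.integers(len(genera))]
        if i in unclassified_idx:
            out.append((domain, "Unclassified", "Unclassified", "Unclassified",
                        "Unclassified", "Unclassified"))
        else:
            out.append((domain, phylum, cls, order, family, genus))
    return out


#: idiosyncratic log-noise of module members; Spearman depends only on the
#: loading/noise ratio, so a small scale keeps module swings from dominating
#: the composition (which would anti-correlate modules through closure)
_MODULE_NOISE_SIGMA = 0.25
#: module taxa sit at these abundance ranks: high enough for counts to carry
#: the correlation signal, low enough not to distort the community
_MODULE_RANK_OFFSET = 10


def _module_loading(config: SimConfig) -> float:
    # bivariate-normal link: Spearman rho_s of a Gaussian pair with Pearson
    # rho_p satisfies rho_s = (6/pi) asin(rho_p/2); invert, then push the
    # latent correlation above target to absorb multinomial attenuation
    rho_p = 2.0 * np.sin(np.pi * config.module_rho / 6.0)
    rho_lat = rho_p + 0.94 * (1.0 - rho_p)
    return _MODULE_NOISE_SIGMA * np.sqrt(rho_lat / (1.0 - rho_lat))


def _draw_counts(rng: np.random.Generator, props: np.ndarray, depths: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """Dirichlet-multinomial rows; zero-expectation taxa stay exactly zero."""
    n, m = props.shape
    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        alpha = props[i] * dispersion
        g = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
        g[alpha <= 0] = 0.0
        p = g / g.sum()
        counts[i] = rng.multinomial(depths[i], p)
    return counts


def simulate_community(config: SimConfig):
    """Generate one synthetic survey.

    Returns
    -------
    (prok_counts, euk_counts, taxonomy, metadata, truth)
        Two sample x ASV count DataFrames, a taxonomy DataFrame (index
        ``asv_id``, columns domain..genus), a per-sample metadata DataFrame,
        and the :class:`GroundTruth` record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_ids, meta = _sample_ids(config)
    n_samples = len(sample_ids)
    region = meta["region"].to_numpy()
    layer = meta["layer"].to_numpy()
    layer_decay = dict(zip(config.layers, config.bloom_layer_decay))

    prok_ids = [f"ASV_P{i + 1:04d}" for i in range(config.n_prok_taxa)]
    euk_ids = [f"ASV_E{i + 1:04d}" for i in range(config.n_euk_taxa)]
    bloom_id = euk_ids[0]

    # ---- taxonomy ------------------------------------------------------
    def _pick_minor(n_taxa, frac, lo):
        k = int(round(frac * n_taxa))
        if k == 0:
            return set()
        return set(rng.choice(np.arange(lo, n_taxa), size=k, replace=False))

    prok_cont = _pick_minor(config.n_prok_taxa, config.contaminant_frac,
                            config.n_prok_taxa // 2)
    prok_uncl = _pick_minor(config.n_prok_taxa, config.unclassified_frac,
                            config.n_prok_taxa // 2) - prok_cont
    euk_cont = _pick_minor(config.n_euk_taxa, config.contaminant_frac,
                           max(1, config.n_euk_taxa // 2))
    euk_uncl = _pick_minor(config.n_euk_taxa, config.unclassified_frac,
                           max(1, config.n_euk_taxa // 2)) - euk_cont

    prok_lin = _lineages(rng, config.n_prok_taxa, _PROK_POOL, "Bacteria",
                         _PROK_CONTAMINANTS, prok_cont, prok_uncl)
    euk_lin = _lineages(rng, config.n_euk_taxa, _EUK_POOL, "Eukaryota",
                        _EUK_CONTAMINANTS, euk_cont, euk_uncl)
    euk_lin[0] = _BLOOM_LINEAGE
    taxonomy = pd.DataFrame(prok_lin + euk_lin, index=prok_ids + euk_ids,
                            columns=RANKS)
    taxonomy.index.name = "asv_id"

    # ---- planted modules (prokaryote table, most abundant ranks) -------
    module_assignment: dict[str, int] = {}
    module_of = np.full(config.n_prok_taxa, -1, dtype=int)
    k = 0
    for m in range(config.n_modules):
        for _ in range(config.module_size):
            module_of[k] = m
            module_assignment[prok_ids[k]] = m
            k += 1
    lam = _module_loading(config)

    is_br = region == "BR"

    def _log_abund(n_taxa, module_of_vec, protected):
        mu_sorted = np.sort(rng.normal(0.0, config.sab_sigma, size=n_taxa))[::-1]
        in_module = (module_of_vec >= 0) if module_of_vec is not None \
            else np.zeros(n_taxa, dtype=bool)
        # module members take moderate abundance ranks; everyone else fills
        # the remaining ranks in order
        mu = np.empty(n_taxa)
        k = int(in_module.sum())
        offset = min(_MODULE_RANK_OFFSET, n_taxa - k)
        module_ranks = np.arange(offset, offset + k)
        other_ranks = np.setdiff1d(np.arange(n_taxa), module_ranks)
        mu[in_module] = mu_sorted[module_ranks]
        mu[~in_module] = mu_sorted[other_ranks]
        # richness deficit: suppress a fraction of the shared pool in BR,
        # sampled with square-root abundance weighting — bloom regions lose
        # dominant shared taxa, not just rare ones, which is what shifts
        # the between-region community distance
        n_supp = int(round(config.richness_deficit_br * n_taxa))
        free = np.array([i for i in range(n_taxa) if i not in protected])
        n_supp = min(n_supp, len(free))
        if n_supp:
            w = np.exp(mu[free] / 2.0)
            supp = rng.choice(free, size=n_supp, replace=False, p=w / w.sum())
        else:
            supp = np.array([], dtype=int)
        eta = mu[None, :] + rng.normal(0.0, config.sample_noise_sigma,
                                       size=(n_samples, n_taxa))
        if k:
            n_mod = module_of_vec.max() + 1
            g = rng.normal(0.0, 1.0, size=(n_samples, n_mod))
            members = np.flatnonzero(in_module)
            # replace background noise by the shared factor + small
            # idiosyncratic noise; recenter so the lognormal mean matches
            # the taxon's assigned rank
            base = mu[members][None, :]
            noise = rng.normal(0.0, _MODULE_NOISE_SIGMA, size=(n_samples, k))
            # recenter partway between median- and mean-matching: full mean
            # compensation starves the median sample of counts (rank noise),
            # none lets surging modules distort the composition
            shift = 0.35 * (lam ** 2 + _MODULE_NOISE_SIGMA ** 2
                            - config.sample_noise_sigma ** 2) / 2.0
            eta[:, members] = (base - shift + noise
                               + lam * g[:, module_of_vec[members]])
        eta = np.exp(eta)
        if len(supp):
            eta[np.ix_(is_br, supp)] = 0.0
        return eta / eta.sum(axis=1, keepdims=True), supp

    prok_protected = set(range(config.n_modules * config.module_size))
    prok_props, prok_supp = _log_abund(config.n_prok_taxa, module_of,
                                       prok_protected)
    euk_props, euk_supp = _log_abund(config.n_euk_taxa, None, {0})
    suppressed_ids = [prok_ids[i] for i in prok_supp] \
        + [euk_ids[i] for i in euk_supp]

    # ---- bloom taxon: region/layer expected fraction, logit jitter -----
    expected = {}
    for reg in ("BR", "NR"):
        for lay in config.layers:
            if reg == "BR":
                expected[(reg, lay)] = (config.bloom_taxon_fraction_surface
                                        * layer_decay[lay])
            else:
                expected[(reg, lay)] = config.nr_bloom_fraction
    f_exp = np.array([expected[(r, l)] for r, l in zip(region, layer)])
    logit = np.log(f_exp / (1 - f_exp))
    f_s = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0.0, config.bloom_logit_sigma,
                                                   size=n_samples))))
    nonbloom = euk_props[:, 1:]
    nonbloom = nonbloom / nonbloom.sum(axis=1, keepdims=True)
    euk_props = np.column_stack([f_s, nonbloom * (1 - f_s)[:, None]])

    # ---- counts --------------------------------------------------------
    depths_p = np.maximum(1, np.round(rng.lognormal(
        np.log(config.depth_per_sample), config.depth_jitter_sigma,
        size=n_samples))).astype(np.int64)
    depths_e = np.maximum(1, np.round(rng.lognormal(
        np.log(config.depth_per_sample), config.depth_jitter_sigma,
        size=n_samples))).astype(np.int64)
    prok_counts = pd.DataFrame(
        _draw_counts(rng, prok_props, depths_p, config.dispersion),
        index=sample_ids, columns=prok_ids)
    euk_counts = pd.DataFrame(
        _draw_counts(rng, euk_props, depths_e, config.dispersion),
        index=sample_ids, columns=euk_ids)
    prok_counts.index.name = euk_counts.index.name = "sample_id"

    # realized bloom fraction feeds the environmental response
    bloom_rel = (euk_counts[bloom_id] / euk_counts.sum(axis=1)).to_numpy()

    # ---- environment ---------------------------------------------------
    env = {}
    grand = {v: np.mean([ENV_BASELINE[key][v] for key in ENV_BASELINE])
             for v in ENV_VARS}
    # survey baselines already carry the between-cell bloom signature, so the
    # driver response is centered on each cell's expected bloom fraction
    # (within-cell tracking only); flat baselines carry none, so the response
    # is centered globally and provides the full between-cell signal
    if config.flat_env_baseline or config.env_response_reference == "global":
        bloom_center = np.full(n_samples, float(np.mean(f_exp)))
    else:
        bloom_center = f_exp
    for v in ENV_VARS:
        if config.flat_env_baseline:
            base = np.full(n_samples, grand[v])
        else:
            base = np.array([ENV_BASELINE[(r, l)][v] for r, l in zip(region, layer)])
        # multiplicative (log-linear) response and noise: concentrations stay
        # positive and the driver is linear on the analysis's log scale
        beta = float(config.env_effect.get(v, 0.0))
        resp = np.exp(beta * (bloom_rel - bloom_center))
        noise = np.exp(rng.normal(0.0, config.env_noise_frac, size=n_samples))
        env[v] = base * resp * noise
    env_df = pd.DataFrame(env, index=sample_ids)
    if config.env_missing_frac > 0:
        mask = rng.random(size=(n_samples, len(NUTRIENT_VARS))) < config.env_missing_frac
        for j, v in enumerate(NUTRIENT_VARS):
            env_df.loc[mask[:, j], v] = np.nan
    metadata = pd.concat([meta, env_df], axis=1)

    truth = GroundTruth(
        module_assignment=module_assignment,
        bloom_taxon_id=bloom_id,
        true_env_drivers=sorted(v for v, b in config.env_effect.items() if b != 0),
        expected_rel_abundance=expected,
        suppressed_taxa_br=suppressed_ids,
    )
    return prok_counts, euk_counts, taxonomy, metadata, truth


# ---------------------------------------------------------------------------
# fixture persistence

_FIXTURE_FILES = ("prok_counts.tsv", "euk_counts.tsv", "taxonomy.tsv",
                  "metadata.tsv", "ground_truth.tsv")


def _lineage_string(row: pd.Series) -> str:
    prefixes = ("d__", "p__", "c__", "o__", "f__", "g__")
    return ";".join(p + str(row[r]) for p, r in zip(prefixes, RANKS))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(dir_path, prok_counts: pd.DataFrame, euk_counts: pd.DataFrame,
                  taxonomy: pd.DataFrame, metadata: pd.DataFrame,
                  truth: GroundTruth) -> pd.DataFrame:
    """Write the five survey tables as TSV plus a SHA-256 manifest.

    Returns the manifest (``file``, ``sha256``) as a DataFrame; the same
    table is written to ``MANIFEST.tsv`` inside ``dir_path``.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    try:
        prok_counts.to_csv(out / "prok_counts.tsv", sep="\t")
        euk_counts.to_csv(out / "euk_counts.tsv", sep="\t")
        tax = pd.DataFrame({"lineage": taxonomy.apply(_lineage_string, axis=1)})
        tax.index.name = "asv_id"
        tax.to_csv(out / "taxonomy.tsv", sep="\t")
        metadata.to_csv(out / "metadata.tsv", sep="\t")
        _write_ground_truth(out / "ground_truth.tsv", truth)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc
    manifest = pd.DataFrame(
        {"file": list(_FIXTURE_FILES),
         "sha256": [_sha256(out / f) for f in _FIXTURE_FILES]})
    manifest.to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    return manifest


def _write_ground_truth(path: Path, truth: GroundTruth) -> None:
    rows = [("bloom_taxon", "", truth.bloom_taxon_id)]
    rows += [("module", asv, str(m)) for asv, m in sorted(truth.module_assignment.items())]
    rows += [("env_driver", "", v) for v in truth.true_env_drivers]
    rows += [("expected_rel_abundance", f"{r}:{l}", repr(f))
             for (r, l), f in sorted(truth.expected_rel_abundance.items())]
    rows += [("suppressed_br", "", asv) for asv in truth.suppressed_taxa_br]
    pd.DataFrame(rows, columns=["field", "key", "value"]).to_csv(
        path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    modules = {r.key: int(r.value) for r in df.itertuples() if r.field == "module"}
    bloom = df.loc[df["field"] == "bloom_taxon", "value"].iloc[0]
    drivers = df.loc[df["field"] == "env_driver", "value"].tolist()
    expected = {}
    for r in df[df["field"] == "expected_rel_abundance"].itertuples():
        reg, lay = r.key.split(":")
        expected[(reg, lay)] = float(r.value)
    suppressed = df.loc[df["field"] == "suppressed_br", "value"].tolist()
    return GroundTruth(modules, bloom, drivers, expected, suppressed)


def verify_manifest(dir_path) -> None:
    """Raise ``ValueError`` if any fixture file fails its recorded checksum."""
    out = Path(dir_path)
    manifest = pd.read_csv(out / "MANIFEST.tsv", sep="\t")
    for row in manifest.itertuples():
        actual = _sha256(out / row.file)
        if actual != row.sha256:
            raise ValueError(
                f"checksum mismatch for {row.file}: manifest {row.sha256}, "
                f"file {actual}")

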