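"""Synthetic consortium-style datasets for the life-history trait pipeline.

The generator emulates the statistical structure of a multi-species
methylation-array study: a phylogeny with heterogeneous taxonomic orders,
log-scale life-history traits evolving by Brownian motion on that tree,
species-level methylation signatures at a planted subset of CpGs linearly
tied (through a logistic link) to log maximum life span, tissue offsets,
sex effects in a minority of species, age trends in selected
species-tissue strata, per-species probe dropout expressed through
detection p-values, and an optional "breed" structure in which one
species carries many low-divergence sub-populations whose trait variance
is invisible to methylation.

Every draw flows from a single integer seed, so a dataset is a pure
function of its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .containers import MethylationMatrix
from .errors import InvalidArgumentError
from .phylo import Phylogeny

__all__ = [
    "BreedCladeConfig",
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_traits",
    "simulate_methylation",
    "simulate_dataset",
]

#: default per-tissue additive offsets on the beta scale
DEFAULT_TISSUES = {"blood": 0.02, "liver": 0.0, "skin": -0.01, "muscle": -0.02}


@dataclass
class BreedCladeConfig:
    """Breed-like sub-structure attached to one host species.

    Breeds share the host's methylation signature (up to a small
    ``methylation_sd`` divergence) while their true life spans scatter
    around the host's with SD ``trait_sd`` on the log scale — i.e. real
    trait variance that methylation does not track. Within the clade,
    heavier breeds are shorter-lived (slope ``weight_slope`` of log
    weight on log life span), mirroring the inverse size-longevity
    relation seen among dog breeds.
    """

    n_breeds: int = 93
    trait_sd: float = 0.25
    methylation_sd: float = 0.01
    samples_per_breed: int = 8
    weight_slope: float = -3.0
    weight_sd: float = 0.4
    host_species: str | None = None  # default: species closest to median life span


@dataclass
class SimulationConfig:
    """Knobs of the synthetic data-generating process.

    Defaults describe the package's reference study: 120 species, 3,000
    CpGs of which 300 carry a life-span signal, 2-8 samples per species
    spread over 1-4 of four tissues, mild array noise, a 5% probe
    dropout rate and a handful of sex-dimorphic species and age-trend
    strata. Trait links are on the natural-log scale (gestation in days,
    maturity in years, weight in grams).
    """

    n_species: int = 120
    n_cpgs: int = 3000
    n_informative: int = 300
    effect_scale: float = 0.25  # logit-beta units per log-year of life span
    trait_residual_sd: float = 0.35  # log-years; species-level epigenetic residual
    phylo_cpg_sd: float = 0.3  # logit units per unit tree depth of CpG drift
    noise_sd_species: float = 0.03  # species-level beta noise
    noise_sd_sample: float = 0.04  # within-species sample beta noise
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    tissues_per_species: tuple = (1, 4)
    samples_per_species: tuple = (2, 8)
    n_sex_dimorphic_species: int = 10
    sex_effect: float = 0.05  # beta offset at informative CpGs
    n_age_trend_strata: int = 10
    age_slope: float = 0.005  # beta per year at informative CpGs
    dropout_rate: float = 0.05
    n_unreliable_cpgs: int = 150  # probes with elevated failure rates
    unreliable_dropout: float = 0.5
    brownian_sigma: float = 0.8  # log-years per unit tree depth (depth = 1)
    root_log_lifespan: float = float(np.log(15.0))
    # (intercept, slope on log max life span, residual SD) per linked trait
    trait_link: dict = field(
        default_factory=lambda: {
            "gestation": (1.5, 1.0, 0.30),
            "maturity": (-1.8, 1.0, 0.35),
        }
    )
    weight_link: tuple = (-1.0, 2.5, 1.2)
    breed_clade: BreedCladeConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_cpgs:
            raise InvalidArgumentError("n_informative exceeds n_cpgs")
        for name in ("noise_sd_species", "noise_sd_sample", "sex_effect",
                     "trait_residual_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise InvalidArgumentError("dropout_rate must be in [0, 1)")
        if self.brownian_sigma < 0:
            raise InvalidArgumentError("brownian_sigma must be >= 0")
        if not self.tissues:
            raise InvalidArgumentError("tissues must be non-empty")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery tests."""

    informative_cpgs: list
    cpg_slopes: dict  # cpg id -> logit-scale slope on log max life span
    dimorphic_species: dict  # species -> +1 (female-longer) or -1
    age_trend_strata: dict  # "species|tissue" -> beta-per-year slope sign
    true_log_traits: dict  # species -> {lifespan, gestation, maturity, weight}
    unreliable_cpgs: list = field(default_factory=list)
    breed_log_lifespan: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    """Everything one run of the generator produces."""

    phylo: Phylogeny
    traits: pd.DataFrame
    methylation: MethylationMatrix
    detection: pd.DataFrame  # species x CpG median detection p-values
    truth: PlantedTruth
    breeds: pd.DataFrame | None = None  # breed-level trait metadata
    config: SimulationConfig | None = None

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.phylo.write_newick(out / "tree.nwk")
        self.traits.to_csv(out / "traits.csv")
        self.methylation.beta.to_csv(out / "beta.csv")
        self.methylation.samples.to_csv(out / "samples.csv")
        self.detection.to_csv(out / "detection.csv")
        self.truth.to_json(out / "truth.json")
        if self.breeds is not None:
            self.breeds.to_csv(out / "breeds.csv")


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


def _yule_newick(n_species: int, rng: np.random.Generator) -> str:
    """Seeded pure-birth (Yule) tree, ultrametric with depth 1."""

    class _N:
        __slots__ = ("children", "length", "label", "birth")

        def __init__(self, birth):
            self.children = []
            self.length = 0.0
            self.label = None
            self.birth = birth

    t = 0.0
    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = list(active)
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        parent = active[i]
        kids = [_N(t), _N(t)]
        parent.children = kids
        active[i] = kids[0]
        active.append(kids[1])
        parent.length = t - parent.birth
    t += rng.exponential(1.0 / n_species)  # root-to-tip depth after last split
    for i, tip in enumerate(active):
        tip.length = t - tip.birth
    order = rng.permutation(n_species)
    width = len(str(n_species))
    for i, tip in enumerate(active):
        tip.label = f"Species{order[i] + 1:0{width}d}"

    def render(node) -> str:
        if not node.children:
            return f"{node.label}:{node.length / t:.10f}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length / t:.10f}"

    return f"({','.join(render(c) for c in root.children)});"


def _depth_cut_orders(tree: dendropy.Tree, depth: float) -> list[list[str]]:
    """Tip partition induced by cutting the tree at the given depth."""
    root = tree.seed_node
    node_depth = {root: 0.0}
    clades = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        d = node_depth[node.parent_node] + node.edge.length
        node_depth[node] = d
        if node_depth[node.parent_node] < depth <= d:
            clades.append([lf.taxon.label for lf in node.leaf_iter()])
    return clades


def simulate_tree(n_species: int, seed: int) -> Phylogeny:
    """Simulate a rooted ultrametric tree with taxonomic-order labels.

    Orders are obtained by cutting the tree at a depth chosen so the
    partition is as fine as possible while still containing one order of
    more than 20 species and at least one singleton order — the size
    heterogeneity the leave-one-clade-out scheme exercises. If no cut of
    a given tree qualifies, a fresh tree is drawn.
    """
    if n_species < 10:
        raise InvalidArgumentError("need at least 10 species")
    # an order "large" enough to trigger the LOCO extreme-pair rule needs
    # > 20 species; trees too small to contain one scale the target down
    big = 20 if n_species > 42 else max(2, n_species // 4)
    for attempt in range(50):
        rng = np.random.default_rng((seed, attempt))
        newick = _yule_newick(n_species, rng)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        best = None
        for depth in np.linspace(0.02, 0.98, 193):
            clades = _depth_cut_orders(tree, float(depth))
            sizes = [len(c) for c in clades]
            if max(sizes) > big and min(sizes) == 1:
                if best is None or len(clades) > len(best):
                    best = clades
        if best is not None:
            best = sorted(best, key=lambda c: (-len(c), c[0]))
            width = len(str(len(best)))
            orders = {}
            for i, clade in enumerate(best):
                for sp in clade:
                    orders[sp] = f"Order_{i + 1:0{width}d}"
            return Phylogeny(tree=tree, orders=orders)
    raise RuntimeError("no qualifying order cut found in 50 tree draws")


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------


def _brownian_tips(tree: dendropy.Tree, root_value: float, sigma: float,
                   rng: np.random.Generator) -> dict[str, float]:
    values = {tree.seed_node: root_value}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        step = rng.normal(0.0, sigma * np.sqrt(node.edge.length))
        values[node] = values[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = float(values[node])
    return out


def simulate_traits(phylo: Phylogeny, config: SimulationConfig) -> pd.DataFrame:
    """Evolve life-history traits on the tree.

    Log maximum life span follows Brownian motion with rate
    ``brownian_sigma``; log gestation (days), log age at sexual maturity
    (years) and log adult weight (grams) are linear in log life span
    plus independent Gaussian noise. Returned values are on the natural
    scale; the planted log values are recoverable via ``np.log``.
    """
    if config.brownian_sigma < 0:
        raise InvalidArgumentError("brownian_sigma must be >= 0")
    rng = np.random.default_rng((config.seed, 1))
    log_mls = _brownian_tips(
        phylo.tree, config.root_log_lifespan, config.brownian_sigma, rng
    )
    species = sorted(log_mls)
    mls = np.array([log_mls[s] for s in species])

    g0, g1, gsd = config.trait_link["gestation"]
    m0, m1, msd = config.trait_link["maturity"]
    w0, w1, wsd = config.weight_link
    gest = g0 + g1 * mls + rng.normal(0.0, gsd, len(species))
    matu = m0 + m1 * mls + rng.normal(0.0, msd, len(species))
    wght = w0 + w1 * mls + rng.normal(0.0, wsd, len(species))

    orders = phylo.orders or {}
    traits = pd.DataFrame(
        {
            "order": [orders.get(s, "unknown") for s in species],
            "max_lifespan_years": np.exp(mls),
            "gestation_days": np.exp(gest),
            "maturity_years": np.exp(matu),
            "weight_g": np.exp(wght),
            "lifespan_corrected": False,
            "lifespan_imputed": False,
            "lifespan_imputed_from": "",
        },
        index=pd.Index(species, name="species"),
    )
    return traits


# ---------------------------------------------------------------------------
# methylation simulation
# ---------------------------------------------------------------------------


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _sample_design(traits: pd.DataFrame, config: SimulationConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-species sample layout (tissue, sex, age)."""
    t_lo, t_hi = config.tissues_per_species
    s_lo, s_hi = config.samples_per_species
    tissue_names = list(config.tissues)
    rows = []
    for sp, row in traits.iterrows():
        n_samp = int(rng.integers(s_lo, s_hi + 1))
        n_tis = int(rng.integers(t_lo, min(t_hi, len(tissue_names)) + 1))
        n_tis = min(n_tis, n_samp)
        chosen = list(rng.choice(tissue_names, size=n_tis, replace=False))
        ages = rng.uniform(0.0, 0.8 * row["max_lifespan_years"], n_samp)
        for i in range(n_samp):
            # female/male pairs rotate through tissues so sex stays
            # balanced within every (species, tissue) stratum
            rows.append(
                {
                    "species": sp,
                    "tissue": chosen[(i // 2) % n_tis],
                    "sex": "female" if i % 2 == 0 else "male",
                    "age_years": float(ages[i]),
                    "breed": "",
                }
            )
    design = pd.DataFrame(rows)
    width = len(str(len(design)))
    design.index = pd.Index(
        [f"S{i + 1:0{width}d}" for i in range(len(design))], name="sample_id"
    )
    return design


def _brownian_matrix(
    tree: dendropy.Tree, species: list[str], n_cpg: int, sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-CpG Brownian drift on the tree: species x CpG logit offsets.

    This plants phylogenetic autocorrelation in the methylome itself
    (clade-marker CpGs), the structure that lets a predictor interpolate
    traits among close relatives under leave-one-species-out but not
    under leave-one-clade-out evaluation.
    """
    values = {tree.seed_node: np.zeros(n_cpg)}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        step = rng.normal(0.0, sigma * np.sqrt(node.edge.length), n_cpg)
        values[node] = values[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return np.vstack([out[s] for s in species])


def simulate_methylation(
    traits: pd.DataFrame,
    config: SimulationConfig,
    phylo: Phylogeny | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame, PlantedTruth, pd.DataFrame | None]:
    """Generate sample-level beta values, detection p-values and truth.

    Informative CpGs get a species mean of ``logistic(baseline + slope *
    log max life span)``; non-informative CpGs get trait-independent
    baselines. Tissue offsets, sex effects (dimorphic species only, at
    informative CpGs, aligned with each CpG's slope sign so the effect
    surfaces in predicted life span) and age slopes (designated strata
    only) are added before per-sample noise, and everything is clipped
    to [0, 1]. Dropped (species, CpG) pairs receive failing detection
    p-values from Uniform(0.1, 1); all others pass with Uniform(0, 1e-4).
    """
    if traits.empty:
        raise InvalidArgumentError("empty trait table")
    rng = np.random.default_rng((config.seed, 2))
    species = list(traits.index)
    n_sp, n_cpg, n_inf = len(species), config.n_cpgs, config.n_informative
    width = len(str(n_cpg))
    cpg_ids = [f"cpg{i + 1:0{width}d}" for i in range(n_cpg)]

    log_mls = np.log(traits["max_lifespan_years"].to_numpy(dtype=float))
    centred = log_mls - log_mls.mean()

    inf_idx = np.sort(rng.choice(n_cpg, size=n_inf, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_inf)
    slopes = np.zeros(n_cpg)
    slopes[inf_idx] = signs * config.effect_scale * rng.uniform(0.5, 1.5, n_inf)
    baselines = rng.normal(0.0, 1.0, n_cpg)

    # The methylation signature tracks a latent "epigenetic trait": the
    # true log life span plus a species-level residual. The residual is
    # shared by all informative CpGs, so it sets the ceiling on how well
    # any CpG ensemble can recover the recorded trait — emulating both
    # biological deviation and trait-record error.
    epi_trait = centred + rng.normal(0.0, config.trait_residual_sd, n_sp)
    logit_mean = baselines[None, :] + slopes[None, :] * epi_trait[:, None]
    if phylo is not None and config.phylo_cpg_sd > 0:
        logit_mean = logit_mean + _brownian_matrix(
            phylo.tree, species, n_cpg, config.phylo_cpg_sd, rng
        )
    # species-level mean beta (before tissue / sex / age structure)
    species_mean = _logistic(logit_mean)
    species_mean = species_mean + rng.normal(0.0, config.noise_sd_species,
                                             (n_sp, n_cpg))

    # planted confounders
    n_dim = min(config.n_sex_dimorphic_species, n_sp)
    dim_species = list(rng.choice(species, size=n_dim, replace=False))
    dim_dir = {s: int(d) for s, d in
               zip(dim_species, rng.choice([-1, 1], size=n_dim))}

    design = _sample_design(traits, config, rng)

    # breed structure: extra samples for one host species whose breeds
    # differ in true life span but (almost) not in methylation
    breeds_meta = None
    breed_truth: dict[str, float] = {}
    if config.breed_clade is not None:
        bc = config.breed_clade
        host = bc.host_species
        if host is None:
            host = traits["max_lifespan_years"].sub(
                traits["max_lifespan_years"].median()
            ).abs().idxmin()
        if host not in traits.index:
            raise InvalidArgumentError(f"breed host {host!r} not in trait table")
        host_i = species.index(host)
        host_log = float(np.log(traits.loc[host, "max_lifespan_years"]))
        bwidth = len(str(bc.n_breeds))
        tissue0 = next(iter(config.tissues))
        brows = []
        meta_rows = []
        for b in range(bc.n_breeds):
            name = f"Breed_{b + 1:0{bwidth}d}"
            blog = host_log + rng.normal(0.0, bc.trait_sd)
            breed_truth[name] = float(blog)
            bmax = float(np.exp(blog))
            bweight = float(
                np.exp(
                    float(np.log(traits.loc[host, "weight_g"]))
                    + bc.weight_slope * (blog - host_log)
                    + rng.normal(0.0, bc.weight_sd)
                )
            )
            meta_rows.append(
                {
                    "breed": name,
                    "median_lifespan_years": bmax / 1.33,
                    "avg_weight_g": bweight,
                }
            )
            for i in range(bc.samples_per_breed):
                brows.append(
                    {
                        "species": host,
                        "tissue": tissue0,
                        "sex": "female" if i % 2 == 0 else "male",
                        "age_years": float(rng.uniform(0.0, 0.8 * bmax)),
                        "breed": name,
                    }
                )
        bdesign = pd.DataFrame(brows)
        bdesign.index = pd.Index(
            [f"B{i + 1:05d}" for i in range(len(bdesign))], name="sample_id"
        )
        design = pd.concat([design, bdesign])
        breeds_meta = pd.DataFrame(meta_rows).set_index("breed")
        # per-breed methylation divergence from the host signature
        breed_dev = {
            name: rng.normal(0.0, bc.methylation_sd, n_cpg)
            for name in breed_truth
        }

    # Age-trend strata are drawn from realised (species, tissue) strata of
    # longer-lived species (life span above the panel median): at a fixed
    # beta-per-year drift, only species whose sampled age span covers
    # enough years accumulate an appreciable methylation change.
    med_mls = float(traits["max_lifespan_years"].median())
    long_lived = set(traits.index[traits["max_lifespan_years"] >= med_mls])
    strata = design.loc[design["breed"] == "", ["species", "tissue"]]
    uniq = sorted(
        {(sp, ti) for sp, ti in map(tuple, strata.to_numpy()) if sp in long_lived}
    )
    n_tr = min(config.n_age_trend_strata, len(uniq))
    tr_idx = rng.choice(len(uniq), size=n_tr, replace=False)
    age_strata = {f"{uniq[i][0]}|{uniq[i][1]}": 1 for i in tr_idx}

    sp_index = {s: i for i, s in enumerate(species)}
    inf_signs = np.sign(slopes)  # per-CpG direction, 0 for non-informative
    tissue_offsets = config.tissues

    beta = np.empty((len(design), n_cpg))
    for r, (sid, row) in enumerate(design.iterrows()):
        base = species_mean[sp_index[row["species"]]].copy()
        if row["breed"]:
            base = base + breed_dev[row["breed"]]
        base += tissue_offsets[row["tissue"]]
        if row["species"] in dim_dir and row["sex"] == "female":
            base += dim_dir[row["species"]] * config.sex_effect * inf_signs
        key = f"{row['species']}|{row['tissue']}"
        if key in age_strata and not row["breed"]:
            base += config.age_slope * row["age_years"] * inf_signs
        beta[r] = base
    beta += rng.normal(0.0, config.noise_sd_sample, beta.shape)
    np.clip(beta, 0.0, 1.0, out=beta)

    matrix = MethylationMatrix(
        beta=pd.DataFrame(beta, index=design.index, columns=cpg_ids),
        samples=design,
    )

    rate = np.full(n_cpg, config.dropout_rate)
    reliable = np.ones(n_cpg, dtype=bool)
    if config.n_unreliable_cpgs:
        # unreliable probes (drawn outside the informative set so planted
        # signal recovery stays interpretable) fail in about half the
        # species and are what the detection filter is meant to remove
        pool = np.setdiff1d(np.arange(n_cpg), inf_idx)
        unrel = rng.choice(
            pool, size=min(config.n_unreliable_cpgs, len(pool)), replace=False
        )
        rate[unrel] = config.unreliable_dropout
        reliable[unrel] = False
    drop = rng.random((n_sp, n_cpg)) < rate[None, :]
    det = np.where(
        drop,
        rng.uniform(0.1, 1.0, (n_sp, n_cpg)),
        rng.uniform(0.0, 1e-4, (n_sp, n_cpg)),
    )
    detection = pd.DataFrame(det, index=pd.Index(species, name="species"),
                             columns=cpg_ids)

    truth = PlantedTruth(
        informative_cpgs=[cpg_ids[i] for i in inf_idx],
        cpg_slopes={cpg_ids[i]: float(slopes[i]) for i in inf_idx},
        unreliable_cpgs=[cpg_ids[i] for i in np.flatnonzero(~reliable)],
        dimorphic_species=dim_dir,
        age_trend_strata=age_strata,
        true_log_traits={
            s: {
                "lifespan": float(np.log(traits.loc[s, "max_lifespan_years"])),
                "gestation": float(np.log(traits.loc[s, "gestation_days"])),
                "maturity": float(np.log(traits.loc[s, "maturity_years"])),
                "weight": float(np.log(traits.loc[s, "weight_g"])),
            }
            for s in species
        },
        breed_log_lifespan=breed_truth,
    )
    return matrix, detection, truth, breeds_meta


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run the full generator: tree -> traits -> methylation."""
    config = config or SimulationConfig()
    phylo = simulate_tree(config.n_species, config.seed)
    traits = simulate_traits(phylo, config)
    matrix, detection, truth, breeds = simulate_methylation(traits, config, phylo)
    return SimulatedDataset(
        phylo=phylo,
        traits=traits,
        methylation=matrix,
        detection=detection,
        truth=truth,
        breeds=breeds,
        config=config,
    )
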