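"""Synthetic two-cohort expression data with known ground truth.

The generator emulates the statistical structure of cross-sectional PBMC
aging cohorts: a factor model in which each planted module has a latent
eigengene profile (optionally driven by donor age, linearly or with a slope
change at a breakpoint age), each module gene loads on that eigengene with
independent noise, and background genes are i.i.d. standard normal.  A
two-cohort wrapper plants a module with identical gene membership in both
cohorts plus cohort-specific modules, and a PPI generator embeds designated
hub genes in dense cliques of their own module neighbourhood.

The factor model is chosen deliberately: the pipeline summarises a module by
its first principal component, so the planted eigengene and the estimand are
commensurable and recovery is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TraitTable

# Default noise levels for the standard simulated study conditions.
DEFAULT_EIGENGENE_NOISE_SD = 0.3
DEFAULT_GENE_NOISE_SD = 0.5
DEFAULT_LOADING_RANGE = (0.6, 0.95)
DEFAULT_AGE_RANGE = (21.0, 93.0)

BACKGROUND = "background"


# ---------------------------------------------------------------------------
# age-effect models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearEffect:
    """Eigengene mean changes linearly with age (slope per year)."""

    slope: float

    def __call__(self, ages: np.ndarray) -> np.ndarray:
        return self.slope * ages


@dataclass(frozen=True)
class BreakpointEffect:
    """Piecewise-linear age trend with a slope change at `change_age`."""

    change_age: float
    slope_before: float
    slope_after: float

    def __call__(self, ages: np.ndarray) -> np.ndarray:
        return self.slope_before * ages + (
            (self.slope_after - self.slope_before) * np.clip(ages - self.change_age, 0, None)
        )


AgeEffect = LinearEffect | BreakpointEffect | None


@dataclass(frozen=True)
class ModuleSpec:
    """Specification of one planted co-expression module.

    ``age_effect=None`` gives an eigengene drawn independently of age; the
    first ``n_hubs`` genes of the module are designated planted hubs for the
    PPI generator.
    """

    name: str
    n_genes: int
    age_effect: AgeEffect = None
    loading_range: tuple[float, float] = DEFAULT_LOADING_RANGE
    eigengene_noise_sd: float = DEFAULT_EIGENGENE_NOISE_SD
    gene_noise_sd: float = DEFAULT_GENE_NOISE_SD
    n_hubs: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must lie within (0, 1]")
        if self.eigengene_noise_sd < 0 or self.gene_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.n_hubs <= self.n_genes:
            raise ValueError("n_hubs must lie in [0, n_genes]")

    def gene_names(self) -> list[str]:
        return [f"{self.name}_{i:04d}" for i in range(self.n_genes)]


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    `gene_module` maps every gene to its planted module (background genes to
    ``"background"``); `eigengenes` holds the realised latent module
    profiles (modules x samples); `hubs` lists planted hub genes.
    """

    gene_module: dict[str, str]
    eigengenes: pd.DataFrame
    hubs: list[str]
    traits: TraitTable

    def module_genes(self, module: str) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module]

    def planted_genes(self) -> list[str]:
        return [g for g, m in self.gene_module.items() if m != BACKGROUND]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def default_modules(n_modules: int = 10, n_genes: int = 50) -> list[ModuleSpec]:
    """The standard planted-module set used throughout the test battery.

    One module carries a linear age trend, one a late-life slope change at
    70 years, and the rest are age-independent latent factors, so
    module-trait statistics see both signal and null modules.  (Only two
    modules carry age signal because age-driven eigengenes are mutually
    correlated by construction — in particular, linear trends of any slope
    standardize to the same profile — and heavily collinear planted modules
    are not separable by any correlation-network method.)
    """
    specs: list[ModuleSpec] = []
    for i in range(n_modules):
        if i == 0:
            eff: AgeEffect = LinearEffect(0.05)
        elif i == 1:
            eff = BreakpointEffect(70.0, 0.0, 0.1)
        else:
            eff = None
        specs.append(ModuleSpec(f"M{i + 1:02d}", n_genes, age_effect=eff, n_hubs=1))
    return specs


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    n_background: int,
    modules: list[ModuleSpec],
    n_samples: int,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    seed: int = 0,
    ages: np.ndarray | None = None,
    ethnicity: str = "synthetic",
    extra_background_genes: list[str] | None = None,
    background_prefix: str = "BG",
    sample_prefix: str = "S",
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Generate one cohort from the planted-module factor model.

    Every module gene g has profile ``loading_g * e + N(0, gene_noise_sd)``
    where ``e = standardize(age_effect(age)) + N(0, eigengene_noise_sd)``
    (an age-independent standard-normal draw when the effect is None);
    background genes are i.i.d. N(0, 1).  Pure function of its arguments
    and `seed`.
    """
    extra_background_genes = extra_background_genes or []
    if not modules and n_background + len(extra_background_genes) == 0:
        raise ValueError("nothing to generate: no modules and no background genes")
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    rng = np.random.default_rng(seed)

    if ages is None:
        lo, hi = age_range
        ages = rng.uniform(lo, hi, size=n_samples)
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.shape != (n_samples,):
            raise ValueError("explicit age list must have length n_samples")
    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)]

    # balanced sex labels, shuffled
    sex = np.array(["F"] * (n_samples // 2) + ["M"] * (n_samples - n_samples // 2))
    rng.shuffle(sex)
    group = np.where(ages <= 40, "young", np.where(ages < 65, "middle", "old"))
    traits = TraitTable(
        pd.DataFrame(
            {"age": ages, "sex": sex, "ethnicity": ethnicity, "group": group},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    gene_module: dict[str, str] = {}
    eigengenes: dict[str, np.ndarray] = {}
    hubs: list[str] = []

    for spec in modules:
        if spec.age_effect is None:
            base = _standardize(rng.standard_normal(n_samples))
        else:
            base = _standardize(spec.age_effect(ages))
        e = base + rng.normal(0.0, spec.eigengene_noise_sd, size=n_samples)
        eigengenes[spec.name] = e
        names = spec.gene_names()
        loadings = rng.uniform(*spec.loading_range, size=spec.n_genes)
        noise = rng.normal(0.0, spec.gene_noise_sd, size=(spec.n_genes, n_samples))
        block = loadings[:, None] * e[None, :] + noise
        rows.append(block)
        gene_ids.extend(names)
        for g in names:
            gene_module[g] = spec.name
        hubs.extend(names[: spec.n_hubs])

    bg_names = [f"{background_prefix}_{i:05d}" for i in range(n_background)]
    bg_names += extra_background_genes
    if bg_names:
        rows.append(rng.standard_normal((len(bg_names), n_samples)))
        gene_ids.extend(bg_names)
        for g in bg_names:
            gene_module[g] = BACKGROUND

    if len(set(gene_ids)) != len(gene_ids):
        seen, dups = set(), set()
        for g in gene_ids:
            (dups if g in seen else seen).add(g)
        raise ValueError(f"gene ID collision across modules/background: {sorted(dups)}")

    data = pd.DataFrame(
        np.vstack(rows), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )
    truth = CohortTruth(
        gene_module=gene_module,
        eigengenes=pd.DataFrame(eigengenes, index=sample_ids).T,
        hubs=hubs,
        traits=traits,
    )
    return ExpressionMatrix(data, scale_tag="normalized_intensity"), truth


def generate_two_cohorts(
    shared: list[ModuleSpec],
    only_a: list[ModuleSpec],
    only_b: list[ModuleSpec],
    n_samples_a: int,
    n_samples_b: int,
    seed: int = 0,
    n_background: int = 1600,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> tuple[tuple[ExpressionMatrix, CohortTruth], tuple[ExpressionMatrix, CohortTruth]]:
    """Generate two cohorts over one gene universe.

    Shared modules use the same gene membership in both cohorts (independent
    noise realisations); each cohort-specific module's genes appear as
    background noise in the other cohort, so both matrices cover the same
    universe and cross-cohort intersections are well defined.  The default
    background size keeps planted age-module gene sets at roughly a tenth
    of the universe, the geometry of the real cohorts this emulates, so
    overlap-significance tests are informative.
    """
    a_genes = {g for s in only_a for g in s.gene_names()}
    b_genes = {g for s in only_b for g in s.gene_names()}
    collision = a_genes & b_genes
    if collision:
        raise ValueError(f"gene ID collision between only_a and only_b: {sorted(collision)}")
    shared_genes = {g for s in shared for g in s.gene_names()}
    for side, pool in (("only_a", a_genes), ("only_b", b_genes)):
        overlap = pool & shared_genes
        if overlap:
            raise ValueError(f"{side} gene IDs collide with shared modules: {sorted(overlap)}")

    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    cohort_a = generate_cohort(
        n_background,
        shared + only_a,
        n_samples_a,
        age_range=age_range,
        seed=seed_a,
        ethnicity="cohortA",
        extra_background_genes=sorted(b_genes),
        sample_prefix="A",
    )
    cohort_b = generate_cohort(
        n_background,
        shared + only_b,
        n_samples_b,
        age_range=age_range,
        seed=seed_b,
        ethnicity="cohortB",
        extra_background_genes=sorted(a_genes),
        sample_prefix="B",
    )
    return cohort_a, cohort_b


def two_cohort_reference_specs() -> tuple[list[ModuleSpec], list[ModuleSpec], list[ModuleSpec]]:
    """The standard two-cohort design: a 95-gene shared age module with two
    planted hubs, plus one 150-gene age-related module specific to each
    cohort (slope changes of different shape, so cohort-specific modules do
    not mirror each other)."""
    shared = [ModuleSpec("SHARED", 95, age_effect=LinearEffect(0.05), n_hubs=2)]
    only_a = [ModuleSpec("ONLYA", 150, age_effect=BreakpointEffect(70.0, 0.0, 0.1), n_hubs=1)]
    only_b = [ModuleSpec("ONLYB", 150, age_effect=BreakpointEffect(45.0, 0.08, 0.0), n_hubs=1)]
    return shared, only_a, only_b


# ---------------------------------------------------------------------------
# PPI generation
# ---------------------------------------------------------------------------

def generate_ppi(
    truth: CohortTruth,
    hub_clique_size: int = 6,
    background_edge_prob: float = 0.02,
    seed: int = 0,
    genes: list[str] | None = None,
    cliques_per_hub: int = 2,
) -> nx.Graph:
    """Plant each hub at the centre of dense cliques of its own module.

    For each planted hub, `cliques_per_hub` cliques of `hub_clique_size`
    nodes are laid over the hub plus disjoint sets of sampled same-module
    genes (a windmill centred on the hub); every remaining node pair is
    connected independently with `background_edge_prob`.  With the default
    two cliques the hub's maximal-clique-centrality score is strictly above
    every clique mate's by construction, so planted hubs are recoverable as
    top-ranked nodes rather than score-tied with their neighbours.  The
    graph is simple and undirected, over `genes` (default: all genes in
    the truth).
    """
    if hub_clique_size < 3:
        raise ValueError("hub_clique_size must be >= 3")
    if cliques_per_hub < 1:
        raise ValueError("cliques_per_hub must be >= 1")
    if not 0 <= background_edge_prob <= 0.2:
        raise ValueError("background_edge_prob must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    nodes = list(genes) if genes is not None else list(truth.gene_module)
    node_set = set(nodes)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for hub in truth.hubs:
        if hub not in truth.gene_module:
            raise ValueError(f"planted hub {hub!r} not present in truth gene map")
        if hub not in node_set:
            continue
        mates = [
            m for m in truth.module_genes(truth.gene_module[hub]) if m != hub and m in node_set
        ]
        per_clique = hub_clique_size - 1
        want = per_clique * cliques_per_hub
        chosen = list(rng.choice(mates, size=min(want, len(mates)), replace=False))
        for c in range(cliques_per_hub):
            members = [hub] + chosen[c * per_clique : (c + 1) * per_clique]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    g.add_edge(members[i], members[j])

    if background_edge_prob > 0:
        n = len(nodes)
        iu, ju = np.triu_indices(n, k=1)
        hits = rng.random(iu.size) < background_edge_prob
        for i, j in zip(iu[hits], ju[hits]):
            g.add_edge(nodes[i], nodes[j])
    return g


def to_fpkm_like(m: ExpressionMatrix, scale: float = 4.0) -> ExpressionMatrix:
    """Map a log-like matrix onto a positive FPKM-like scale via 2**x.

    Exercises the linear-scale filter/log2 path; `scale` multiplies the
    exponentiated values so typical entries land above 1.
    """
    return ExpressionMatrix(scale * np.exp2(m.data), scale_tag="fpkm")
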