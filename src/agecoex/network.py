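"""Weighted co-expression network core.

Builds a soft-thresholded correlation network, computes the topological
overlap matrix (TOM), clusters genes into modules on 1 - TOM, summarises
each module by its eigengene (first principal component of the module's
standardized expression), merges near-duplicate modules by eigengene
correlation, and relates eigengenes to sample traits by Pearson
correlation with t-transform p-values.

The stage is exposed both as plain functions (one per operation) and as a
model/results pair: :class:`CoexpressionNetwork` holds the data and
configuration, ``fit()`` returns a :class:`CoexpressionResults` carrying
the chosen soft power, the module partition, eigengenes, module-trait
statistics and a ``summary()`` table.

Module labels are deterministic: clusters ordered by size descending are
named from a fixed color list (then numeric suffixes), so repeated runs on
identical input produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .containers import ExpressionMatrix, TraitTable, align_samples

log = logging.getLogger("agecoex")

UNASSIGNED = "unassigned"

# Fixed module color palette (size-rank order); overflows get numeric names.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
]

_P_MIN = float(np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# correlation, adjacency, soft-threshold selection
# ---------------------------------------------------------------------------

def pairwise_correlation(m: ExpressionMatrix) -> pd.DataFrame:
    """Genes x genes Pearson correlation matrix.

    Errors listing the offending genes if any gene has zero variance.
    """
    if m.n_samples < 3:
        raise ValueError("pairwise correlation needs >= 3 samples")
    vals = m.values
    sd = vals.std(axis=1)
    zero = [g for g, s in zip(m.gene_ids, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance genes: {zero[:20]}")
    cor = np.corrcoef(vals)
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=m.gene_ids, columns=m.gene_ids)


def soft_adjacency(cor: pd.DataFrame, beta: int, sign_mode: str = "unsigned") -> pd.DataFrame:
    """Raise correlations to the soft power beta.

    unsigned: ``a_ij = |r_ij| ** beta``; signed: ``((1 + r_ij) / 2) ** beta``.
    The diagonal is set to 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = cor.to_numpy()
    if sign_mode == "unsigned":
        a = np.abs(r) ** beta
    elif sign_mode == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of an adjacency's connectivity distribution.

    Connectivity ``k_i = sum_{j != i} a_ij`` is binned into `n_bins`
    equal-width bins; log10(mean bin frequency) is regressed on
    log10(bin-mean k) over non-empty bins.  Returns (R^2, slope).
    """
    a = adj.to_numpy()
    k = a.sum(axis=1) - np.diag(a)
    if np.allclose(k, k[0]):
        log.warning("scale_free_fit: all connectivities equal; no fit possible")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    n = len(k)
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.sum() / n
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 2:
        log.warning("scale_free_fit: fewer than 2 usable bins")
        return 0.0, 0.0
    res = stats.linregress(xs, ys)
    if not (np.isfinite(res.rvalue) and np.isfinite(res.slope)):
        return 0.0, 0.0
    return float(res.rvalue**2), float(res.slope)


def pick_soft_threshold(
    cor: pd.DataFrame,
    candidates: list[int],
    target: float = 0.8,
    sign_mode: str = "unsigned",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power: smallest beta with R^2 > target and slope < 0.

    Falls back (with a warning) to the beta maximizing R^2 — negative-slope
    candidates preferred — when no candidate reaches the target.  Returns
    the chosen beta and the per-candidate fit table.
    """
    if not candidates:
        raise ValueError("no beta candidates supplied")
    if list(candidates) != sorted(candidates):
        raise ValueError("beta candidates must be ascending")
    rows = []
    for beta in candidates:
        r2, slope = scale_free_fit(soft_adjacency(cor, beta, sign_mode), n_bins=n_bins)
        rows.append({"beta": beta, "r_squared": r2, "slope": slope})
    table = pd.DataFrame(rows)
    ok = table[(table.r_squared > target) & (table.slope < 0)]
    if len(ok):
        beta = int(ok.beta.iloc[0])
    else:
        neg = table[table.slope < 0]
        pool = neg if len(neg) else table
        beta = int(pool.loc[pool.r_squared.idxmax(), "beta"])
        log.warning(
            "pick_soft_threshold: no candidate reached R^2 > %.2f with negative "
            "slope; falling back to beta=%d (R^2=%.3f)",
            target, beta, float(pool.r_squared.max()),
        )
    return beta, table


# ---------------------------------------------------------------------------
# topological overlap and module detection
# ---------------------------------------------------------------------------

def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    ``TOM_ii = 1``.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModulePartition:
    """Gene -> module label assignment with a reserved 'unassigned' label."""

    labels: pd.Series
    min_module_size: int

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, dtype=object)
        sizes = self.sizes()
        small = [m for m, s in sizes.items() if s < self.min_module_size]
        if small:
            raise ValueError(f"modules below min size {self.min_module_size}: {small}")

    def sizes(self) -> dict[str, int]:
        counts = self.labels.value_counts()
        return {m: int(c) for m, c in counts.items() if m != UNASSIGNED}

    def modules(self) -> list[str]:
        """Module labels ordered by size descending, ties by name."""
        sizes = self.sizes()
        return sorted(sizes, key=lambda m: (-sizes[m], m))

    def module_genes(self, module: str) -> list[str]:
        if module != UNASSIGNED and module not in set(self.labels):
            raise KeyError(f"unknown module label {module!r}")
        return list(self.labels.index[self.labels == module])

    def as_dict(self) -> dict[str, str]:
        return dict(self.labels)


def _label_clusters(genes: list[str], raw: np.ndarray, min_module_size: int) -> ModulePartition:
    """Deterministically name raw integer clusters by size-rank colors."""
    ser = pd.Series(raw, index=genes)
    groups = {
        c: list(ser.index[ser == c]) for c in ser.unique() if c != -1
    }
    keep = {c: g for c, g in groups.items() if len(g) >= min_module_size}
    ordered = sorted(keep, key=lambda c: (-len(keep[c]), min(keep[c])))
    names = {}
    for rank, c in enumerate(ordered):
        names[c] = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
    labels = pd.Series(
        [names.get(c, UNASSIGNED) for c in raw], index=genes, dtype=object
    )
    return ModulePartition(labels=labels, min_module_size=min_module_size)


def _persistence_cut(merge: np.ndarray, n: int, min_module_size: int) -> np.ndarray:
    """Select dendrogram clusters by persistence instead of a single cut.

    Every internal node of the dendrogram is a candidate cluster, born at
    the merge height that creates it and dying at the height where it fuses
    into its parent (the root is taken to die at dissimilarity 1, the
    maximum possible).  A genuine module assembles at low height and then
    survives unchanged until the final coalescence, so its persistence
    (death - birth) is large; transient background agglomerates live only
    between consecutive merges.  Candidates of size >= min_module_size are
    selected greedily by persistence, skipping any candidate nested with an
    already selected one.  Returns raw integer labels (-1 = unassigned).
    """
    n_nodes = 2 * n - 1
    size = np.ones(n_nodes, dtype=int)
    birth = np.zeros(n_nodes)
    death = np.full(n_nodes, 1.0)
    parent = np.full(n_nodes, -1, dtype=int)
    children: dict[int, tuple[int, int]] = {}
    for i in range(n - 1):
        a, b, h = int(merge[i, 0]), int(merge[i, 1]), float(merge[i, 2])
        node = n + i
        size[node] = size[a] + size[b]
        birth[node] = h
        death[a] = death[b] = h
        parent[a] = parent[b] = node
        children[node] = (a, b)

    cands = [v for v in range(n, n_nodes) if size[v] >= min_module_size]
    cands.sort(key=lambda v: (-(death[v] - birth[v]), -size[v], v))
    chosen: list[int] = []
    chosen_set: set[int] = set()
    for v in cands:
        # nested with an already chosen cluster?
        u = v
        conflict = False
        while u != -1:
            if u in chosen_set:
                conflict = True
                break
            u = parent[u]
        if conflict:
            continue
        stack = list(children[v])
        while stack and not conflict:
            w = stack.pop()
            if w in chosen_set:
                conflict = True
            elif w >= n:
                stack.extend(children[w])
        if not conflict:
            chosen.append(v)
            chosen_set.add(v)

    labels = np.full(n, -1, dtype=int)
    for v in chosen:
        stack = [v]
        while stack:
            w = stack.pop()
            if w < n:
                labels[w] = v
            else:
                stack.extend(children[w])
    return labels


def cut_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_quantile: float = 0.99,
    method: str = "adaptive",
) -> ModulePartition:
    """Detect modules by average-linkage clustering on 1 - TOM.

    method='adaptive' (default) selects non-nested dendrogram clusters of
    maximal persistence (the height interval a cluster survives unchanged
    before fusing onward), which separates assembled modules from transient
    background agglomerates without a single global cut height.
    method='quantile' cuts statically at the `cut_quantile` quantile of
    merge heights.  In both cases clusters of size >= `min_module_size`
    become modules and everything else is 'unassigned'.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = list(tom.index)
    n = len(genes)
    if min_module_size > n:
        log.warning("cut_modules: min_module_size %d exceeds gene count %d", min_module_size, n)
        return ModulePartition(
            labels=pd.Series([UNASSIGNED] * n, index=genes, dtype=object),
            min_module_size=min_module_size,
        )
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    merge = linkage(squareform(diss, checks=False), method="average")
    if method == "adaptive":
        raw = _persistence_cut(merge, n, min_module_size)
    elif method == "quantile":
        cut = float(np.quantile(merge[:, 2], cut_quantile))
        raw = fcluster(merge, t=cut, criterion="distance")
    else:
        raise ValueError(f"unknown cut method {method!r}")
    part = _label_clusters(genes, raw, min_module_size)
    log.info(
        "cut_modules: %d modules, %d genes unassigned",
        len(part.modules()), int((part.labels == UNASSIGNED).sum()),
    )
    return part


# ---------------------------------------------------------------------------
# module eigengenes
# ---------------------------------------------------------------------------

@dataclass
class EigengeneMatrix:
    """Module eigengenes (modules x samples) and per-module variance explained."""

    eigengenes: pd.DataFrame
    variance_explained: pd.Series

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.index)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene in module; cannot standardize")
    return (x - mu) / sd


def module_eigengene(m: ExpressionMatrix, part: ModulePartition) -> EigengeneMatrix:
    """First-principal-component eigengene per module.

    Module rows are standardized; the eigengene is the first right-singular
    sample-score vector rescaled to unit sample variance, sign-flipped so it
    correlates non-negatively with the module's mean standardized profile.
    ``variance_explained`` is the first squared singular value over the
    total.
    """
    if m.n_samples < 3:
        raise ValueError("eigengene computation needs >= 3 samples")
    rows, ves = {}, {}
    for mod in part.modules():
        genes = part.module_genes(mod)
        x = _standardize_rows(m.subset_genes(genes).values)
        if x.shape[0] == 1:
            e = x[0]
            ve = 1.0
        else:
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            e = vt[0]
            ve = float(s[0] ** 2 / (s**2).sum())
        sd = e.std()
        e = e / sd if sd > 0 else e
        mean_profile = x.mean(axis=0)
        if mean_profile.std() > 0 and np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        rows[mod] = e
        ves[mod] = ve
    eg = pd.DataFrame(rows, index=m.sample_ids).T
    return EigengeneMatrix(eigengenes=eg, variance_explained=pd.Series(ves))


def merge_close_modules(
    m: ExpressionMatrix,
    part: ModulePartition,
    cut_height: float = 0.2,
    me: EigengeneMatrix | None = None,
) -> tuple[ModulePartition, EigengeneMatrix]:
    """Iteratively merge modules whose eigengenes are near-duplicates.

    Modules are clustered (average linkage) on eigengene dissimilarity
    ``1 - cor(ME_a, ME_b)``; groups joined below `cut_height` merge, their
    eigengenes are recomputed, and the step repeats until no pair is closer
    than `cut_height`.  'unassigned' never participates.
    """
    me = me or module_eigengene(m, part)
    labels = part.labels.copy()
    while True:
        mods = me.modules
        if len(mods) < 2:
            break
        eg = me.eigengenes.to_numpy()
        diss = 1.0 - np.corrcoef(eg)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, 2.0)
        if diss[np.triu_indices(len(mods), 1)].min() >= cut_height:
            break
        merge = linkage(squareform(diss, checks=False), method="average")
        raw = fcluster(merge, t=cut_height, criterion="distance")
        groups: dict[int, list[str]] = {}
        for mod, c in zip(mods, raw):
            groups.setdefault(int(c), []).append(mod)
        for members in groups.values():
            if len(members) < 2:
                continue
            sizes = {mm: (labels == mm).sum() for mm in members}
            target = sorted(members, key=lambda mm: (-sizes[mm], mm))[0]
            for mm in members:
                labels[labels == mm] = target
        part = ModulePartition(labels=labels, min_module_size=part.min_module_size)
        me = module_eigengene(m, part)
    return part, me


# ---------------------------------------------------------------------------
# module-trait statistics
# ---------------------------------------------------------------------------

def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n - 2 df."""
    r = np.asarray(r, dtype=float)
    denom = np.clip(1.0 - r**2, 0.0, None)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(denom)
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return np.clip(p, _P_MIN, 1.0)


def encode_traits(traits: TraitTable, columns: list[str] | None = None) -> pd.DataFrame:
    """Numeric encoding of trait columns for correlation analysis.

    age passes through as years; sex maps F=0 / M=1; a binary categorical
    maps to 0/1 (levels sorted, first level 0); a categorical with more
    levels expands to one-vs-rest indicator columns named ``col=level``.
    """
    df = traits.data
    columns = columns if columns is not None else list(df.columns)
    out = {}
    for col in columns:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            out[col] = series.astype(float).to_numpy()
            continue
        if col == "sex":
            out[col] = (series == "M").astype(float).to_numpy()
            continue
        levels = sorted(series.unique())
        if len(levels) <= 1:
            out[col] = np.zeros(len(series))
        elif len(levels) == 2:
            out[col] = (series == levels[1]).astype(float).to_numpy()
        else:
            for lv in levels:
                out[f"{col}={lv}"] = (series == lv).astype(float).to_numpy()
    return pd.DataFrame(out, index=df.index)


def module_trait_correlation(
    me: EigengeneMatrix, traits: TraitTable, columns: list[str] | None = None
) -> pd.DataFrame:
    """Pearson r and t-transform p between every eigengene and every trait.

    Returns a long-format frame with columns module, trait, r, p.  An
    explicitly requested constant trait is an error; when columns are
    auto-selected, constant encodings are skipped with a warning.
    """
    explicit = columns is not None
    enc = encode_traits(traits, columns)
    enc = enc.loc[me.eigengenes.columns]
    n = enc.shape[0]
    rows = []
    for trait in enc.columns:
        tvec = enc[trait].to_numpy()
        if tvec.std() == 0:
            if explicit:
                raise ValueError(f"trait {trait!r} is constant; correlation undefined")
            log.warning("module_trait_correlation: skipping constant trait %r", trait)
            continue
        tz = (tvec - tvec.mean()) / tvec.std()
        for mod in me.modules:
            e = me.eigengenes.loc[mod].to_numpy()
            ez = (e - e.mean()) / e.std()
            r = float(np.clip((ez * tz).mean(), -1.0, 1.0))
            rows.append(
                {"module": mod, "trait": trait, "r": r, "p": float(correlation_p(r, n))}
            )
    return pd.DataFrame(rows)


def gene_significance_and_membership(
    m: ExpressionMatrix, me: EigengeneMatrix, trait: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene trait significance (GS) and module membership (MM).

    ``GS_g = |cor(expression_g, trait)|``; ``MM_{g,M} = cor(expression_g,
    ME_M)``; both carry t-transform p-values.  Constant genes are excluded
    with a ``constant`` flag in the GS table.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.std() == 0:
        raise ValueError("constant trait; GS undefined")
    n = m.n_samples
    vals = m.values
    sd = vals.std(axis=1)
    const = sd == 0
    z = np.zeros_like(vals)
    z[~const] = (vals[~const] - vals[~const].mean(axis=1, keepdims=True)) / sd[~const, None]
    tz = (trait - trait.mean()) / trait.std()
    gs_r = z @ tz / n
    gs = pd.DataFrame(
        {
            "gs": np.abs(np.clip(gs_r, -1, 1)),
            "p": correlation_p(gs_r, n),
            "constant": const,
        },
        index=m.gene_ids,
    )
    gs.loc[const, ["gs", "p"]] = np.nan

    eg = me.eigengenes.to_numpy()
    egz = (eg - eg.mean(axis=1, keepdims=True)) / eg.std(axis=1, keepdims=True)
    mm_r = np.clip(z @ egz.T / n, -1, 1)
    mm = pd.DataFrame(mm_r, index=m.gene_ids, columns=me.modules)
    mm[const] = np.nan
    return gs, mm


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Weighted co-expression network model over one cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x samples matrix (any monotone scale; typically log2 or
        normalized intensities).
    traits : TraitTable, optional
        Per-sample traits; enables module-trait statistics and GS/MM.
    config : PipelineConfig, optional
        Thresholds and defaults; a fresh default config when omitted.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        traits: TraitTable | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.expression = expression
        self.traits = align_samples(expression, traits) if traits is not None else None
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        traits: pd.DataFrame | None = None,
        config: PipelineConfig | None = None,
        scale_tag: str = "normalized_intensity",
    ) -> "CoexpressionNetwork":
        return cls(
            ExpressionMatrix(expression, scale_tag=scale_tag),
            TraitTable(traits) if traits is not None else None,
            config,
        )

    def fit(self, beta: int | None = None) -> "CoexpressionResults":
        """Run the full network stage and return the fitted results."""
        cfg = self.config
        cor = pairwise_correlation(self.expression)
        if beta is None:
            beta, sft = pick_soft_threshold(
                cor, cfg.beta_candidates, cfg.scale_free_target, cfg.network_sign
            )
        else:
            r2, slope = scale_free_fit(soft_adjacency(cor, beta, cfg.network_sign))
            sft = pd.DataFrame([{"beta": beta, "r_squared": r2, "slope": slope}])
        adj = soft_adjacency(cor, beta, cfg.network_sign)
        tom = tom_similarity(adj)
        part = cut_modules(tom, cfg.min_module_size, cfg.cut_quantile, method=cfg.cut_method)
        if part.modules():
            part, me = merge_close_modules(self.expression, part, cfg.merge_cut_height)
        else:
            me = EigengeneMatrix(
                eigengenes=pd.DataFrame(columns=self.expression.sample_ids),
                variance_explained=pd.Series(dtype=float),
            )
        module_trait = gs = mm = None
        if self.traits is not None and part.modules():
            module_trait = module_trait_correlation(me, self.traits)
            gs, mm = gene_significance_and_membership(self.expression, me, self.traits.age)
        return CoexpressionResults(
            model=self,
            beta=beta,
            soft_threshold_table=sft,
            partition=part,
            eigengenes=me,
            module_trait=module_trait,
            gene_significance=gs,
            module_membership=mm,
        )


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: partition, eigengenes, diagnostics."""

    model: CoexpressionNetwork
    beta: int
    soft_threshold_table: pd.DataFrame
    partition: ModulePartition
    eigengenes: EigengeneMatrix
    module_trait: pd.DataFrame | None = None
    gene_significance: pd.DataFrame | None = None
    module_membership: pd.DataFrame | None = None

    def module_genes(self, module: str) -> list[str]:
        return self.partition.module_genes(module)

    def age_related_modules(self, min_abs_r: float = 0.0, max_p: float = 0.05) -> list[str]:
        """Modules whose eigengene correlates with age at the given cuts."""
        if self.module_trait is None:
            raise ValueError("no traits were supplied to the model")
        mt = self.module_trait
        hits = mt[(mt.trait == "age") & (mt.r.abs() >= min_abs_r) & (mt.p < max_p)]
        return list(hits.sort_values("r", key=lambda s: -s.abs()).module)

    def summary(self) -> pd.DataFrame:
        """Per-module summary: size, variance explained, age correlation."""
        sizes = self.partition.sizes()
        rows = []
        for mod in self.partition.modules():
            row = {
                "module": mod,
                "n_genes": sizes[mod],
                "variance_explained": float(self.eigengenes.variance_explained[mod]),
            }
            if self.module_trait is not None:
                mt = self.module_trait
                hit = mt[(mt.module == mod) & (mt.trait == "age")]
                if len(hit):
                    row["age_r"] = float(hit.r.iloc[0])
                    row["age_p"] = float(hit.p.iloc[0])
            rows.append(row)
        return pd.DataFrame(rows)
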