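"""Differential expression screening between young and old sample groups.

Per-gene log2 fold change (old - young) on log2-scale expression, a
two-sample test (Welch's t, or a moderated t that shrinks per-gene pooled
variances toward a common value estimated by method of moments from the
distribution of log sample variances), Benjamini-Hochberg step-up FDR, and
intersection of significant genes with co-expression modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix
from .network import ModulePartition

log = logging.getLogger("agecoex")

_P_MIN = float(np.nextafter(0, 1))


def _split_groups(
    m: ExpressionMatrix, groups, reference: str = "young", treatment: str = "old"
) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.Series(groups)
    missing = [s for s in m.sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    groups = groups.loc[m.sample_ids]
    ref_idx = np.where(groups.to_numpy() == reference)[0]
    trt_idx = np.where(groups.to_numpy() == treatment)[0]
    if len(ref_idx) == 0 or len(trt_idx) == 0:
        raise ValueError(
            f"both groups must be non-empty (got {len(ref_idx)} {reference!r}, "
            f"{len(trt_idx)} {treatment!r})"
        )
    vals = m.values
    return vals[:, ref_idx], vals[:, trt_idx]


def log_fold_change(
    m: ExpressionMatrix, groups, reference: str = "young", treatment: str = "old"
) -> pd.Series:
    """Per-gene mean(treatment) - mean(reference) on the log2 scale."""
    if m.scale_tag not in ("log2", "normalized_intensity"):
        raise ValueError("log fold change requires a log-scale matrix")
    young, old = _split_groups(m, groups, reference, treatment)
    return pd.Series(old.mean(axis=1) - young.mean(axis=1), index=m.gene_ids, name="logFC")


# ---------------------------------------------------------------------------
# variance moderation (method-of-moments fit of a scaled-F prior)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the variance prior from per-gene variances.

    Moments of ``z = log(s2)`` under the scaled-F model give
    ``Var(z) = trigamma(df/2) + trigamma(d0/2)``; the excess of the observed
    variance of z over ``trigamma(df/2)`` identifies d0, and the mean of z
    identifies s0^2.  Returns ``d0 = inf`` when there is no excess spread
    (all genes then share the common variance s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all per-gene variances are zero")
    z = np.log(s2[ok])
    e_adj = float(special.digamma(df / 2.0) - np.log(df / 2.0))
    evar = float(z.var(ddof=1) - special.polygamma(1, df / 2.0)) if len(z) > 1 else 0.0
    if evar <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(z.mean() - e_adj))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        adj0 = float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s0_2 = float(np.exp(z.mean() - e_adj + adj0))
    return d0, s0_2


def moderated_t_test(
    m: ExpressionMatrix,
    groups,
    method: str = "moderated",
    reference: str = "young",
    treatment: str = "old",
    d0_override: float | None = None,
) -> pd.Series:
    """Two-sided per-gene p-values for the young/old contrast.

    method='welch' uses the unequal-variance two-sample t with
    Welch-Satterthwaite degrees of freedom.  method='moderated' shrinks the
    pooled per-gene variance toward the common value fitted by
    :func:`fit_variance_prior` and tests with ``d0 + d_g`` df
    (`d0_override` forces a particular prior df; ``inf`` yields the common-
    variance z-like limit).

    A gene constant and equal in both groups gets p = 1; constant but
    different gets the representable minimum.
    """
    young, old = _split_groups(m, groups, reference, treatment)
    n1, n2 = young.shape[1], old.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    m1, m2 = young.mean(axis=1), old.mean(axis=1)
    v1 = young.var(axis=1, ddof=1)
    v2 = old.var(axis=1, ddof=1)
    delta = m2 - m1

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v1 / n1 + v2 / n2
            t = delta / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.where(np.isfinite(df), df, 1.0))
    elif method == "moderated":
        dg = n1 + n2 - 2.0
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg
        d0, s0_2 = fit_variance_prior(s2[s2 > 0], dg) if (s2 > 0).any() else (np.inf, 0.0)
        if d0_override is not None:
            d0 = d0_override
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_2 + dg * s2) / (d0 + dg)
            df_total = d0 + dg
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    else:
        raise ValueError(f"unknown method {method!r}")

    # degenerate genes: zero within-group variance
    degenerate = (v1 == 0) & (v2 == 0)
    p = np.where(degenerate & (delta == 0), 1.0, p)
    p = np.where(degenerate & (delta != 0), _P_MIN, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), _P_MIN, 1.0)
    return pd.Series(p, index=m.gene_ids, name="p")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


@dataclass
class DEGSummary:
    n_up: int
    n_down: int
    n_total: int


def select_degs(table: pd.DataFrame, lfc_threshold: float = 0.5, fdr: float = 0.05):
    """Flag significant genes: |logFC| >= threshold and adjusted p < fdr.

    `table` must have columns ``logFC`` and ``p``; returns the table with
    ``adj_p``, ``significant`` and ``direction`` columns plus up/down/total
    counts.
    """
    if lfc_threshold < 0 or fdr < 0:
        raise ValueError("thresholds must be non-negative")
    out = table.copy()
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["logFC"].abs() >= lfc_threshold) & (out["adj_p"] < fdr)
    out["direction"] = np.where(out["logFC"] >= 0, "up", "down")
    sig = out[out.significant]
    summary = DEGSummary(
        n_up=int((sig.direction == "up").sum()),
        n_down=int((sig.direction == "down").sum()),
        n_total=int(len(sig)),
    )
    log.info("select_degs: %d up, %d down of %d genes", summary.n_up, summary.n_down, len(out))
    return out, summary


def differential_expression(
    m: ExpressionMatrix,
    groups,
    lfc_threshold: float = 0.5,
    fdr: float = 0.05,
    method: str = "moderated",
    reference: str = "young",
    treatment: str = "old",
) -> tuple[pd.DataFrame, DEGSummary]:
    """One-call DEG screen: logFC + test + BH + significance flags."""
    lfc = log_fold_change(m, groups, reference, treatment)
    p = moderated_t_test(m, groups, method, reference, treatment)
    table = pd.DataFrame({"logFC": lfc, "p": p})
    return select_degs(table, lfc_threshold, fdr)


def intersect_with_module(
    deg_table: pd.DataFrame, part: ModulePartition, module: str
) -> tuple[list[str], tuple[int, int, int]]:
    """Significant-DEG ∩ module-member genes, with Venn region counts.

    Returns the sorted overlap gene list and counts
    (DEG-only, overlap, module-only).
    """
    module_genes = set(part.module_genes(module))
    degs = set(deg_table.index[deg_table["significant"]])
    overlap = degs & module_genes
    regions = (len(degs - module_genes), len(overlap), len(module_genes - degs))
    return sorted(overlap), regions
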