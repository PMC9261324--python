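"""Expression filtering, transformation, normalization, and outlier removal.

These steps precede network construction: drop lowly expressed genes on a
linear scale (e.g. FPKM > 1 in all samples), log2-transform, optionally
quantile-normalize across samples, and flag outlier samples by average-
linkage clustering of sample profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import LINEAR_SCALES, ExpressionMatrix

log = logging.getLogger("agecoex")


def filter_expressed(
    m: ExpressionMatrix, min_value: float = 1.0, min_fraction: float = 1.0
) -> ExpressionMatrix:
    """Keep genes with value > `min_value` in >= `min_fraction` of samples.

    Requires a linear-scale matrix (fpkm or raw_counts); gene order is
    preserved and values are never rescaled.
    """
    if m.scale_tag not in LINEAR_SCALES:
        raise ValueError(f"filter_expressed needs a linear scale, got {m.scale_tag!r}")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    frac = (m.values > min_value).mean(axis=1)
    keep = frac >= min_fraction
    out = ExpressionMatrix(m.data.loc[keep], m.scale_tag)
    log.info(
        "filter_expressed: %d/%d genes pass value > %g in >= %.0f%% of samples",
        out.n_genes, m.n_genes, min_value, 100 * min_fraction,
    )
    return out


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """value <- log2(value + pseudocount); output tagged log2."""
    if m.scale_tag not in LINEAR_SCALES:
        raise ValueError(f"log2_transform needs a linear scale, got {m.scale_tag!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (m.values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return ExpressionMatrix(np.log2(m.data + pseudocount), scale_tag="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's value distribution to the across-sample mean.

    After normalization each sample's sorted vector equals the mean of
    sorted vectors; ties within a sample receive the mean of the reference
    values at their rank positions.  Idempotent.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    vals = m.values
    order = np.sort(vals, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        # average reference values over tied ranks
        ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), m.scale_tag
    )


def detect_outlier_samples(
    m: ExpressionMatrix, cut_height: float | None = None
) -> tuple[list[str], list[str]]:
    """Flag outlier samples by average-linkage clustering.

    Samples are clustered on the Euclidean distance between standardized
    expression profiles; cutting the dendrogram at `cut_height` (default:
    mean merge height + 2.5 x SD of merge heights) flags every sample
    outside the largest cluster.  Returns (kept, flagged) sample ID lists.
    """
    if m.n_samples < 3:
        raise ValueError("outlier detection needs >= 3 samples")
    vals = m.values
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    d = pdist(z.T, metric="euclidean")
    merge = linkage(d, method="average")
    heights = merge[:, 2]
    if cut_height is None:
        cut_height = float(heights.mean() + 2.5 * heights.std())
    labels = fcluster(merge, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    main = sizes.idxmax()
    kept = [s for s, l in zip(m.sample_ids, labels) if l == main]
    flagged = [s for s, l in zip(m.sample_ids, labels) if l != main]
    if not kept:
        raise ValueError("degenerate cut: every sample flagged as outlier")
    if flagged:
        log.info("detect_outlier_samples: flagged %s at cut height %.3g", flagged, cut_height)
    return kept, flagged
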