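"""Expression screening: size-factor normalization, hierarchical clustering,
breadth categories, and relative qPCR quantification (2^-ddCt).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix, raw counts or normalized values."""

    values: pd.DataFrame
    normalized: bool = False
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")


def median_of_ratios(counts: pd.DataFrame) -> ExpressionMatrix:
    """Median-of-ratios size factors and the normalized matrix.

    The pseudo-reference is the per-gene geometric mean over samples; each
    sample's size factor is the median, over genes positive in every sample,
    of count / reference; normalized value = count / size factor.

    Note the estimator's exact invariance: scaling one sample by ``c``
    rescales the *whole* normalized matrix by the global factor ``c**(1/n)``
    (n = number of samples) and leaves all between-sample ratios unchanged.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "size factors need at least one gene with nonzero counts in all samples"
        )
    log_ref = np.log(values[all_positive]).mean(axis=1, keepdims=True)
    log_ratios = np.log(values[all_positive]) - log_ref
    factors = np.exp(np.median(log_ratios, axis=0))
    normalized = counts / factors
    return ExpressionMatrix(
        values=normalized,
        normalized=True,
        size_factors=pd.Series(factors, index=counts.columns, name="size_factor"),
    )


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene id -> cluster label in 1..k
    k: int
    profiles: pd.DataFrame  # cluster x sample mean expression ("model")
    merges: list[tuple[frozenset, frozenset, float]] = field(repr=False, default_factory=list)


def _zscore_log_rows(values: np.ndarray) -> np.ndarray:
    logged = np.log2(values + 1.0)
    mu = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # flat rows stay flat (all zeros) instead of NaN
    return (logged - mu) / sd


def hcluster(
    matrix: pd.DataFrame,
    k: int,
    *,
    row_scaling: str = "zscore",
) -> ClusterAssignment:
    """Agglomerative complete-linkage Euclidean clustering cut into k groups.

    Rows are optionally z-scored on log2(x + 1) first (``row_scaling="none"``
    disables this), so clusters reflect expression *shape* rather than
    magnitude.  Agglomeration is deterministic: among equal inter-cluster
    distances, the pair with the smallest (i, j) cluster indices — clusters
    ordered by creation — merges first.  Labels 1..k follow the first
    occurrence order of the input genes; per-cluster mean profiles are
    computed on the (scaled) matrix.
    """
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if row_scaling not in ("zscore", "none"):
        raise ValueError("row_scaling must be 'zscore' or 'none'")
    values = matrix.to_numpy(dtype=float)
    if row_scaling == "zscore":
        values = _zscore_log_rows(values)

    # complete-linkage agglomeration with explicit tie-breaks
    clusters: list[list[int] | None] = [[i] for i in range(n)]
    dist = np.sqrt(((values[:, None, :] - values[None, :, :]) ** 2).sum(axis=2))
    cdist = dist.copy()
    np.fill_diagonal(cdist, np.inf)
    active = set(range(n))
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(active) > k:
        # row-major argmin lands on the smallest (i, j), i < j, among ties
        flat = int(np.argmin(cdist))
        i, j = divmod(flat, n)
        d = float(cdist[i, j])
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        # complete linkage: distance to the union is the max of the parts
        row = np.maximum(cdist[i], cdist[j])
        cdist[i, :] = row
        cdist[:, i] = row
        cdist[i, i] = np.inf
        cdist[j, :] = np.inf
        cdist[:, j] = np.inf
        clusters[i] = clusters[i] + clusters[j]
        clusters[j] = None
        active.remove(j)

    membership = np.empty(n, dtype=int)
    ordered = sorted((min(clusters[i]), i) for i in active)
    for label, (_first, i) in enumerate(ordered, start=1):
        for g in clusters[i]:
            membership[g] = label
    labels = pd.Series(membership, index=matrix.index, name="cluster")
    profiles = (
        pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
        .groupby(labels)
        .mean()
    )
    return ClusterAssignment(labels=labels, k=k, profiles=profiles, merges=merges)


# ---------------------------------------------------------------------------
# expression breadth


def tau_specificity(profile: np.ndarray) -> float:
    """Tissue-specificity tau: mean(1 - x / max(x)) over the other samples;
    0 for a flat profile, 1 for a one-hot profile."""
    x = np.asarray(profile, dtype=float)
    peak = x.max()
    if peak <= 0:
        return 0.0
    return float((1.0 - x / peak).sum() / (x.size - 1))


def breadth_classify(
    matrix: pd.DataFrame,
    expressed_threshold: float = 1.0,
    ubiquitous_fraction: float = 1.0,
    tau_specific: float = 0.85,
) -> pd.Series:
    """Per-gene expression-breadth category.

    low: no sample reaches ``expressed_threshold``; ubiquitous: at least
    ``ubiquitous_fraction`` of samples reach it; tissue-specific: expressed
    somewhere with tau >= ``tau_specific``; everything else: intermediate.
    """
    cats = {}
    for gene, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        expressed = x >= expressed_threshold
        if not expressed.any():
            cats[gene] = "low"
        elif expressed.mean() >= ubiquitous_fraction and tau_specificity(x) < tau_specific:
            cats[gene] = "ubiquitous"
        elif tau_specificity(x) >= tau_specific:
            cats[gene] = "tissue-specific"
        else:
            cats[gene] = "intermediate"
    return pd.Series(cats, name="breadth")


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt


def ddct(
    ct: pd.DataFrame,
    calibrator: str,
    reference_gene: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` columns: gene, condition, replicate, Ct.  Replicate Ct values are
    averaged per (gene, condition); dCt = Ct_target - Ct_reference,
    ddCt = dCt_condition - dCt_calibrator, fold change = 2^-ddCt.
    Returns a frame indexed by (gene, condition) with dct, ddct and fold
    change columns.
    """
    required = {"gene", "condition", "replicate", "Ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    if not np.isfinite(ct["Ct"]).all() or (ct["Ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    means = ct.groupby(["gene", "condition"])["Ct"].mean()
    conditions = sorted(ct["condition"].unique())
    if calibrator not in conditions:
        raise ValueError(f"calibrator condition {calibrator!r} not present")
    targets = [g for g in means.index.get_level_values("gene").unique() if g != reference_gene]
    rows = []
    for cond in conditions:
        if (reference_gene, cond) not in means.index:
            raise ValueError(
                f"reference gene {reference_gene!r} has no Ct for condition {cond!r}"
            )
    for gene in targets:
        for cond in conditions:
            if (gene, cond) not in means.index:
                continue
            dct = means[(gene, cond)] - means[(reference_gene, cond)]
            dct_cal = means[(gene, calibrator)] - means[(reference_gene, calibrator)]
            ddct_val = dct - dct_cal
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "dct": dct,
                    "ddct": ddct_val,
                    "fold_change": 2.0 ** (-ddct_val),
                }
            )
    return pd.DataFrame(rows).set_index(["gene", "condition"])
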