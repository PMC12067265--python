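"""Cluster-blinded attribution of gene/BCR-diversity correlations.

Per-sample pseudobulk profiles (library-size-normalized, log1p, averaged
over cells) are correlated gene-by-gene with the sample's unique BCR
clonotype count (Pearson, Benjamini–Hochberg q-values). Each correlation
is then attributed to cell clusters by blinding one cluster at a time and
measuring the drop in correlation strength:

    delta(gene, cluster) = |R_full| - |R_blinded(cluster)|

A positive delta means the cluster carries the correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import InputError

TARGET_LIBRARY_SIZE = 1e4
MIN_SAMPLES = 4


@dataclass
class PseudobulkResult:
    """Per-sample mean normalized expression and the cells used."""

    profiles: pd.DataFrame  # samples x genes
    cells_used: pd.Series  # per sample
    dropped_samples: list = field(default_factory=list)


@dataclass
class AttributionMatrix:
    """Base correlations with q-values, per-cluster blinding deltas, and
    the cluster cell counts (to verify effects are not cluster-size
    artifacts)."""

    base: pd.DataFrame  # index gene: columns r, p, q
    delta: pd.DataFrame  # genes x clusters
    cluster_sizes: pd.Series
    skipped_clusters: list = field(default_factory=list)


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def normalize_counts(X) -> np.ndarray:
    """Scale each cell to a fixed library size then log1p."""
    X = _dense(X).astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * TARGET_LIBRARY_SIZE)


def pseudobulk(
    adata: ad.AnnData, blind_cluster: str | None = None
) -> PseudobulkResult:
    """Per-sample mean of normalized expression, optionally excluding the
    cells of one cluster. Samples emptied by blinding are dropped and
    reported."""
    obs = adata.obs
    for col in ("sample_id", "cluster"):
        if col not in obs.columns:
            raise InputError(f"cell metadata lacks column {col!r}")
    if blind_cluster is not None and blind_cluster not in set(obs["cluster"]):
        # a declared-but-empty cluster is a no-op blind; an unknown label is
        # an input error
        categories = getattr(obs["cluster"], "cat", None)
        known = set(categories.categories) if categories is not None else set()
        if blind_cluster not in known:
            raise InputError(f"unknown cluster label {blind_cluster!r}")
    keep = np.ones(adata.n_obs, dtype=bool)
    if blind_cluster is not None:
        keep = (obs["cluster"] != blind_cluster).to_numpy()
    norm_x = normalize_counts(adata.X)
    sample_ids = obs["sample_id"].to_numpy()
    samples = list(dict.fromkeys(sample_ids))
    rows, used, dropped = [], {}, []
    for s in samples:
        mask = (sample_ids == s) & keep
        n = int(mask.sum())
        if n == 0:
            dropped.append(s)
            continue
        rows.append(norm_x[mask].mean(axis=0))
        used[s] = n
    kept = [s for s in samples if s not in dropped]
    profiles = pd.DataFrame(rows, index=kept, columns=list(adata.var_names))
    return PseudobulkResult(profiles, pd.Series(used, dtype=int), dropped)


def gene_diversity_correlation(
    profiles: pd.DataFrame, bcr_counts: pd.Series
) -> pd.DataFrame:
    """Pearson R of each gene's pseudobulk values against per-sample
    unique-BCR counts, with BH q-values across tested genes. Genes with
    zero variance across samples are flagged and excluded from testing."""
    common = profiles.index.intersection(bcr_counts.index)
    if len(common) < MIN_SAMPLES:
        raise InputError(
            f"need >= {MIN_SAMPLES} overlapping samples, got {len(common)}"
        )
    X = profiles.loc[common].to_numpy(dtype=float)
    y = bcr_counts.loc[common].to_numpy(dtype=float)
    n = len(common)
    xs = X.std(axis=0)
    ystd = y.std()
    zero_var = (xs == 0) | (ystd == 0)
    r = np.full(X.shape[1], np.nan)
    ok = ~zero_var
    if ok.any() and ystd > 0:
        xc = X[:, ok] - X[:, ok].mean(axis=0)
        yc = y - y.mean()
        r[ok] = (xc * yc[:, None]).sum(axis=0) / (n * xs[ok] * ystd)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = np.full_like(r, np.nan)
    p[ok] = 2 * stats.t.sf(np.abs(tstat[ok]), df=n - 2)
    q = np.full_like(r, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"r": r, "p": p, "q": q, "zero_variance": zero_var},
        index=profiles.columns,
    )


def cluster_blinding_delta(
    adata: ad.AnnData,
    bcr_counts: pd.Series,
    genes: list[str] | None = None,
    clusters: list[str] | None = None,
) -> AttributionMatrix:
    """Change in correlation strength per gene when each cluster's cells
    are blinded. Clusters whose blinding empties more than half of the
    samples are skipped with a warning."""
    if clusters is None:
        clusters = sorted(set(adata.obs["cluster"]))
    if len(clusters) < 2:
        raise InputError("cluster attribution needs >= 2 clusters")
    base_pb = pseudobulk(adata)
    base = gene_diversity_correlation(base_pb.profiles, bcr_counts)
    if genes is None:
        genes = list(base.index[~base["zero_variance"]])
    missing = set(genes) - set(adata.var_names)
    if missing:
        raise InputError(f"genes not in the matrix: {sorted(missing)}")
    n_samples = len(base_pb.profiles)
    delta = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    skipped = []
    cluster_sizes = adata.obs["cluster"].value_counts().reindex(clusters, fill_value=0)
    for cl in clusters:
        if cluster_sizes[cl] == 0:
            delta[cl] = 0.0  # blinding an empty cluster is a no-op
            continue
        pb = pseudobulk(adata, blind_cluster=cl)
        if len(pb.profiles) < max(MIN_SAMPLES, n_samples // 2 + 1):
            warnings.warn(
                f"blinding cluster {cl!r} empties too many samples; skipped",
                stacklevel=2,
            )
            skipped.append(cl)
            delta[cl] = np.nan
            continue
        blinded = gene_diversity_correlation(pb.profiles, bcr_counts)
        # a gene whose blinded profile has zero variance lost all of its
        # expression with the blinded cluster: its remaining correlation
        # strength is 0 (the zero_variance flag is kept in `blinded`)
        blinded_strength = blinded.loc[genes, "r"].abs()
        blinded_strength[blinded.loc[genes, "zero_variance"]] = 0.0
        delta[cl] = base.loc[genes, "r"].abs() - blinded_strength
    return AttributionMatrix(
        base=base.loc[genes], delta=delta,
        cluster_sizes=cluster_sizes, skipped_clusters=skipped,
    )


def select_display_genes(
    base: pd.DataFrame, k: int, seed: int
) -> dict[str, list[str]]:
    """Top-k, bottom-k, and k seeded-random genes by correlation, disjoint.

    Ties in R are broken by lexicographic gene name for determinism.
    """
    eligible = base.loc[~base["zero_variance"] & base["r"].notna()]
    if len(eligible) < 3 * k:
        raise InputError(
            f"need >= {3 * k} eligible genes for k={k}, got {len(eligible)}"
        )
    ordered = eligible.sort_values(
        ["r"], ascending=False, kind="mergesort"
    )
    # stable secondary ordering: sort by name first, then by r (mergesort keeps
    # the lexicographic order within ties)
    ordered = (
        eligible.assign(_name=eligible.index)
        .sort_values("_name", kind="mergesort")
        .sort_values("r", ascending=False, kind="mergesort")
    )
    top = list(ordered.index[:k])
    bottom = list(ordered.index[-k:][::-1])
    remainder = [g for g in ordered.index if g not in set(top) | set(bottom)]
    rng = np.random.default_rng(seed)
    random = [remainder[i] for i in rng.choice(len(remainder), size=k, replace=False)]
    return {"top": top, "bottom": bottom, "random": random}
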