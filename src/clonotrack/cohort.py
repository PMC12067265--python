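"""Synthetic checkpoint-blockade cohort generator with planted ground truth.

Every input the analysis pipeline consumes is emulated here with known
planted structure, so downstream stages are testable without patient data:

* per-sample clonotype repertoires (AIRR-style records) with heavy-tailed
  clone sizes and Dirichlet sample-specific V-gene usage shared between
  the single-cell and spatial modality of the same patient-timepoint;
* clustered single-cell expression counts with cell-type markers and a
  gene/BCR-diversity correlation planted inside one cluster;
* spatial cell maps with planted T/B pseudoclone colocalization, planted
  three-type triads, and planted tumor/lymph-node clone sharing;
* exponential survival whose hazard depends on the induced-diversity label.

Randomness is organized as a hierarchical seed tree (cohort -> domain ->
patient -> sample) built on :class:`numpy.random.SeedSequence`, so
subsetting patients never changes the draws of the remaining patients and
identical configurations are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm, rankdata

from .config import (
    SPATIAL_MARKER_GENES,
    SPATIAL_TYPE_FREQS,
    CohortConfig,
    ConfigurationError,
    GenerationError,
)

# Seed-tree domain codes (first element of every spawn key).
_D_REPERTOIRE = 1
_D_EXPRESSION = 2
_D_SPATIAL = 3
_D_SURVIVAL = 4
_D_USAGE = 5
_D_PREDICTOR = 6

#: Spatial cell types that carry TR V-gene probes.
T_CELL_TYPES = ("Tfh", "CD8_activated", "CD8_exhausted", "CD4_T")

#: Concentration multiplier for T-locus V-gene usage. T repertoires on this
#: panel are modeled flatter than the clonally skewed IGH usage.
_T_USAGE_CONC_FACTOR = 8.0

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_TO_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Generator for one node of the hierarchical seed tree."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# clone sizes: truncated discrete power law
# ---------------------------------------------------------------------------

def sample_clone_sizes(
    n: int, alpha: float, size_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` clone sizes from a discrete power law on 1..size_max."""
    ks = np.arange(1, size_max + 1, dtype=float)
    pmf = ks ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, size_max + 1), size=n, p=pmf)


def fit_clone_size_exponent(sizes: np.ndarray, size_max: int | None = None) -> float:
    """Maximum-likelihood exponent of the truncated discrete power law."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("cannot fit an exponent to an empty sample")
    kmax = int(size_max if size_max is not None else sizes.max())
    log_ks = np.log(np.arange(1, kmax + 1, dtype=float))
    sum_log = np.log(sizes).sum()

    def nll(a: float) -> float:
        return a * sum_log + sizes.size * logsumexp(-a * log_ks)

    res = minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# repertoire arm
# ---------------------------------------------------------------------------

def _random_junctions(
    rng: np.random.Generator, n: int, used: set[str]
) -> tuple[list[str], list[str]]:
    """``n`` CDR3s as (nucleotide, amino-acid) lists, unique within ``used``."""
    lengths = rng.integers(12, 21, size=n)
    flat = rng.integers(0, 20, size=int(lengths.sum()))
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    nts: list[str] = []
    aas: list[str] = []
    for i in range(n):
        aa = "".join(_AA_ALPHABET[j] for j in flat[offsets[i]: offsets[i + 1]])
        while aa in used:  # vanishing collision probability
            aa = "".join(
                _AA_ALPHABET[j]
                for j in rng.integers(0, 20, size=int(rng.integers(12, 21)))
            )
        used.add(aa)
        aas.append(aa)
        nts.append("".join(_AA_TO_CODON[c] for c in aa))
    return nts, aas


def _sample_usage(config: CohortConfig, locus: str, rng: np.random.Generator) -> np.ndarray:
    conc = config.vgene_concentration
    if locus in ("TRA", "TRB"):
        conc *= _T_USAGE_CONC_FACTOR
    return rng.dirichlet(np.full(config.n_vgenes, conc))


def _sample_records(
    config: CohortConfig,
    sample_id: str,
    patient_id: str,
    timepoint: str,
    n_unique_bcr: int,
    n_unique_tcr: int,
    usage: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Cell-level chain records for one sample (one chain per cell)."""
    frames: list[pd.DataFrame] = []
    used_junctions: set[str] = set()
    specs = [
        ("BCR", n_unique_bcr, ("IGH", "IGK", "IGL"), (0.6, 0.2, 0.2)),
        ("TCR", n_unique_tcr, ("TRA", "TRB"), (0.55, 0.45)),
    ]
    for cls, n_unique, loci, locus_p in specs:
        if n_unique == 0:
            continue
        locus_choice = rng.choice(len(loci), size=n_unique, p=locus_p)
        sizes = sample_clone_sizes(
            n_unique, config.clone_size_alpha, config.clone_size_max, rng
        )
        locus_arr = np.array(loci, dtype=object)[locus_choice]
        v_arr = np.empty(n_unique, dtype=object)
        for li, locus in enumerate(loci):
            mask = locus_choice == li
            k = int(mask.sum())
            if k:
                universe = np.array(config.vgene_universe(locus), dtype=object)
                v_arr[mask] = universe[
                    rng.choice(config.n_vgenes, size=k, p=usage[locus])
                ]
        nt_arr, aa_arr = _random_junctions(rng, n_unique, used_junctions)
        rep = np.repeat(np.arange(n_unique), sizes)
        n_cells = rep.size
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{sample_id}_{cls}_c{i:06d}"
                                for i in range(n_cells)],
                    "sample_id": sample_id,
                    "patient_id": patient_id,
                    "timepoint": timepoint,
                    "locus": locus_arr[rep],
                    "v_call": v_arr[rep],
                    "junction": np.array(nt_arr, dtype=object)[rep],
                    "junction_aa": np.array(aa_arr, dtype=object)[rep],
                    "duplicate_count": rng.poisson(1.0, size=n_cells) + 1,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(
            ("cell_id", "sample_id", "patient_id", "timepoint", "locus",
             "v_call", "junction", "junction_aa", "duplicate_count")
        ))
    return pd.concat(frames, ignore_index=True)


def _draw_pre_post(
    rng: np.random.Generator, pre_rate: float, post_rate: float, increased: bool
) -> tuple[int, int]:
    """Poisson pre/post unique counts consistent with the planted arm.

    The induced-diversity label is *defined* by the observed phenotype
    (post > pre strictly), so each arm's pair is rejection-sampled until
    it realizes its defining phenotype; truth labels then coincide with
    what the trajectory classifier must recover.
    """
    while True:
        pre = int(rng.poisson(pre_rate))
        post = int(rng.poisson(post_rate))
        if (post > pre) == increased:
            return pre, post


# ---------------------------------------------------------------------------
# expression arm
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mu`` and dispersion ``theta``."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def _blom_scores(values: np.ndarray) -> np.ndarray:
    """Normal scores monotone in ``values`` (Blom's rank transform)."""
    r = rankdata(values)
    return norm.ppf((r - 0.375) / (len(values) + 0.25))


def generate_expression(
    config: CohortConfig,
    sample_meta: pd.DataFrame,
    bcr_counts: Mapping[str, int],
) -> tuple[ad.AnnData, dict]:
    """Cell-by-gene counts for all samples in ``sample_meta``.

    ``sample_meta`` has one row per sample with columns ``sample_id``,
    ``patient_id``, ``timepoint``. A monotone per-sample shift of the
    planted genes inside ``planted_corr_cluster`` plants a pseudobulk
    correlation with the sample's unique-BCR count of approximately
    ``planted_corr_strength``; the realized correlation is recomputed post
    hoc and returned in the truth record.
    """
    genes = np.array(config.gene_names)
    clusters = list(config.cluster_labels)
    n_genes, n_cells = config.n_genes, config.n_cells_per_sample
    planted_idx = np.array([list(genes).index(g) for g in config.planted_corr_genes])
    planted_mask = np.zeros(n_genes, dtype=bool)
    planted_mask[planted_idx] = True

    rng_global = rng_for(config.seed, _D_EXPRESSION)
    base_log_mu = np.log(config.nb_mean) + rng_global.normal(0.0, 0.3, size=n_genes)
    # cell-type marker structure: 5 marker genes per cluster, 4x up-shift
    # (marker block starts after the named panel head to stay clear of the
    # planted module)
    marker_shift = np.zeros((len(clusters), n_genes))
    start = 20
    for g in range(start, min(n_genes, start + 5 * len(clusters))):
        marker_shift[g % len(clusters), g] = np.log(4.0)

    sample_ids = list(sample_meta["sample_id"])
    counts = np.array([bcr_counts[s] for s in sample_ids], dtype=float)
    z = _blom_scores(counts)

    # Planted latent shift per (sample, planted gene): a monotone component
    # in the BCR score plus a latent component orthogonalized against it
    # in-sample, mixed so the latent correlation equals the planted strength
    # exactly (the realized pseudobulk correlation then differs only by
    # counting noise).
    strength = config.planted_corr_strength
    amp = 2.0  # large latent swing keeps NB counting noise from attenuating
    n_samples = len(sample_ids)
    rng_shift = rng_for(config.seed, _D_EXPRESSION, 999_999)
    z_hat = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    shifts = np.empty((n_samples, planted_idx.size))
    for k in range(planted_idx.size):
        eta = rng_shift.normal(size=n_samples)
        resid = eta - eta.mean() - (eta @ z_hat / n_samples) * z_hat
        resid_std = resid.std()
        eta_hat = resid / resid_std if resid_std > 0 else resid
        shifts[:, k] = amp * (
            strength * z_hat + np.sqrt(max(0.0, 1 - strength**2)) * eta_hat
        )

    exclusive = config.planted_corr_cluster != "all"
    X_parts: list[sparse.csr_matrix] = []
    obs_parts: list[pd.DataFrame] = []
    for si, row in enumerate(sample_meta.itertuples(index=False)):
        rng = rng_for(config.seed, _D_EXPRESSION, si)
        cl_idx = rng.integers(0, len(clusters), size=n_cells)
        log_mu = base_log_mu[None, :] + marker_shift[cl_idx, :]
        # generic inter-sample variability for non-planted genes
        sample_noise = rng.normal(0.0, 0.1, size=n_genes)
        sample_noise[planted_mask] = 0.0
        log_mu = log_mu + sample_noise[None, :]
        if exclusive:
            target_cells = cl_idx == clusters.index(config.planted_corr_cluster)
        else:
            target_cells = np.ones(n_cells, dtype=bool)
        for k, gi in enumerate(planted_idx):
            log_mu[target_cells, gi] += shifts[si, k]
            if exclusive:
                # planted genes are exclusive markers of the planted cluster
                log_mu[~target_cells, gi] = -np.inf
        mat = _nb_draw(rng, np.exp(log_mu), config.nb_dispersion).astype(np.int32)
        X_parts.append(sparse.csr_matrix(mat))
        obs_parts.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{row.sample_id}_x{j:05d}" for j in range(n_cells)],
                    "sample_id": row.sample_id,
                    "patient_id": row.patient_id,
                    "timepoint": row.timepoint,
                    "cluster": [clusters[c] for c in cl_idx],
                }
            )
        )

    X = sparse.vstack(X_parts, format="csr")
    obs = pd.concat(obs_parts, ignore_index=True).set_index("cell_id")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))

    realized = _realized_planted_correlation(adata, dict(zip(sample_ids, counts)),
                                             list(config.planted_corr_genes))
    truth = {
        "genes": list(config.planted_corr_genes),
        "cluster": config.planted_corr_cluster,
        "strength": strength,
        "realized": realized,
    }
    return adata, truth


def _realized_planted_correlation(
    adata: ad.AnnData, bcr_counts: Mapping[str, float], genes: list[str]
) -> dict[str, float]:
    """Post-hoc Pearson correlation of planted-gene pseudobulk vs BCR count."""
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    lib = X.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    norm_x = np.log1p(X / lib * 1e4)
    sample_ids = adata.obs["sample_id"].to_numpy()
    samples = list(dict.fromkeys(sample_ids))
    gidx = [adata.var_names.get_loc(g) for g in genes]
    pb = np.vstack(
        [norm_x[sample_ids == s][:, gidx].mean(axis=0) for s in samples]
    )
    y = np.array([bcr_counts[s] for s in samples], dtype=float)
    out = {}
    for k, g in enumerate(genes):
        v = pb[:, k]
        if v.std() == 0 or y.std() == 0:
            out[g] = float("nan")
        else:
            out[g] = float(np.corrcoef(v, y)[0, 1])
    return out


# ---------------------------------------------------------------------------
# spatial arm
# ---------------------------------------------------------------------------

@dataclass
class SpatialSample:
    """One segmented spatial map: cells with micron coordinates, types,
    compartment, treatment flag, per-cell V-gene probe counts and a small
    set of marker-gene probes; ``truth`` records the planted structure."""

    sample_id: str
    patient_id: str
    timepoint: str
    compartment: str
    treated: bool
    cells: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def vgene_columns(self) -> list[str]:
        return [c for c in self.cells.columns
                if c.startswith(("IGHV", "TRAV", "TRBV"))]


def _disk_point(rng: np.random.Generator, cx: float, cy: float,
                radius: float, lo: float, hi: float) -> tuple[float, float]:
    r = radius * np.sqrt(rng.random())
    th = rng.random() * 2 * np.pi
    # clipping into the field only shrinks each coordinate offset, so the
    # planted point stays within `radius` of the anchor
    return (float(np.clip(cx + r * np.cos(th), lo, hi)),
            float(np.clip(cy + r * np.sin(th), lo, hi)))


def _spatial_map(
    config: CohortConfig,
    sample_id: str,
    patient_id: str,
    timepoint: str,
    treated: bool,
    compartment: str,
    rng: np.random.Generator,
    usage_igh: np.ndarray,
    usage_tra: np.ndarray,
    allowed_igh: np.ndarray | None = None,
    allowed_tra: np.ndarray | None = None,
    force_igh: Iterable[int] = (),
    force_tra: Iterable[int] = (),
    plant_pairs: bool | None = None,
    plant_triads: bool | None = None,
    elevated_tra: Iterable[int] = (),
) -> SpatialSample:
    field_um = config.spatial_field_um
    radius = config.spatial_radius_um
    if radius > field_um:
        raise ConfigurationError("spatial_radius_um exceeds spatial_field_um")
    capacity = (field_um / 5.0) ** 2  # one cell per 25 um^2 at most
    if config.n_spatial_cells * 3 > capacity:
        raise GenerationError(
            f"requested {config.n_spatial_cells} cells exceeds the capacity of "
            f"a {field_um} um field"
        )
    if plant_pairs is None:
        plant_pairs = treated
    if plant_triads is None:
        plant_triads = treated and compartment == "lymph_node"
    n_v = config.n_vgenes
    coloc_idx = np.arange(config.n_pseudoclone_pairs)
    allowed_igh = np.ones(n_v, bool) if allowed_igh is None else np.asarray(allowed_igh)
    allowed_tra = np.ones(n_v, bool) if allowed_tra is None else np.asarray(allowed_tra)
    elevated_tra = set(int(i) for i in elevated_tra)

    def _restricted(usage: np.ndarray, mask: np.ndarray) -> np.ndarray:
        u = np.where(mask, usage, 0.0)
        s = u.sum()
        return u / s if s > 0 else u

    p_igh = _restricted(usage_igh, allowed_igh)
    p_tra = _restricted(usage_tra, allowed_tra)

    types = list(SPATIAL_TYPE_FREQS)
    freqs = np.array(list(SPATIAL_TYPE_FREQS.values()))
    n_bg = config.n_spatial_cells
    cell_type = [types[i] for i in rng.choice(len(types), size=n_bg, p=freqs)]
    xs = list(rng.uniform(0, field_um, size=n_bg))
    ys = list(rng.uniform(0, field_um, size=n_bg))
    dominant: list[int] = []  # V index, -1 for non-lymphocyte
    for t in cell_type:
        if t == "B" and p_igh.sum() > 0:
            dominant.append(int(rng.choice(n_v, p=p_igh)))
        elif t in T_CELL_TYPES and p_tra.sum() > 0:
            dominant.append(int(rng.choice(n_v, p=p_tra)))
        else:
            dominant.append(-1)

    pairs: list[tuple[int, int]] = []
    triads: list[tuple[int, int, int]] = []

    def _add_cell(t: str, x: float, y: float, dom: int) -> int:
        cell_type.append(t)
        xs.append(x)
        ys.append(y)
        dominant.append(dom)
        return len(cell_type) - 1

    for i in range(n_bg):
        if cell_type[i] != "B":
            continue
        if plant_pairs and dominant[i] in coloc_idx and allowed_tra[dominant[i]]:
            if rng.random() < config.colocalization_rate:
                x, y = _disk_point(rng, xs[i], ys[i], radius, 0.0, field_um)
                j = _add_cell("CD8_activated", x, y, dominant[i])
                pairs.append((i, j))
        if plant_triads and rng.random() < config.triad_rate:
            x1, y1 = _disk_point(rng, xs[i], ys[i], radius, 0.0, field_um)
            x2, y2 = _disk_point(rng, xs[i], ys[i], radius, 0.0, field_um)
            j = _add_cell("Tfh", x1, y1,
                          int(rng.choice(n_v, p=p_tra)) if p_tra.sum() else -1)
            k = _add_cell("CD8_activated", x2, y2,
                          int(rng.choice(n_v, p=p_tra)) if p_tra.sum() else -1)
            triads.append((i, j, k))

    present_b = {dominant[i] for i in range(len(cell_type)) if cell_type[i] == "B"}
    present_t = {dominant[i] for i in range(len(cell_type))
                 if cell_type[i] in T_CELL_TYPES}
    for gi in force_igh:
        if gi not in present_b:
            _add_cell("B", float(rng.uniform(0, field_um)),
                      float(rng.uniform(0, field_um)), int(gi))
    for gi in force_tra:
        if gi not in present_t:
            _add_cell("CD4_T", float(rng.uniform(0, field_um)),
                      float(rng.uniform(0, field_um)), int(gi))

    n_total = len(cell_type)
    igh_names = config.vgene_universe("IGH")
    tra_names = config.vgene_universe("TRA")
    igh_counts = np.zeros((n_total, n_v), dtype=np.int32)
    tra_counts = np.zeros((n_total, n_v), dtype=np.int32)
    marker_counts = np.zeros((n_total, len(SPATIAL_MARKER_GENES)), dtype=np.int32)
    dominant_names: dict[str, str] = {}
    cell_ids = [f"{sample_id}_s{i:05d}" for i in range(n_total)]
    for i in range(n_total):
        dom = dominant[i]
        t = cell_type[i]
        if t == "B" and dom >= 0:
            igh_counts[i, dom] = 1 + rng.poisson(3.0)
            if rng.random() < 0.1:  # probe noise on one other allowed gene
                others = np.flatnonzero(allowed_igh & (np.arange(n_v) != dom))
                if others.size:
                    igh_counts[i, rng.choice(others)] += 1
            dominant_names[cell_ids[i]] = igh_names[dom]
        elif t in T_CELL_TYPES and dom >= 0:
            tra_counts[i, dom] = 1 + rng.poisson(3.0)
            if rng.random() < 0.1:
                others = np.flatnonzero(allowed_tra & (np.arange(n_v) != dom))
                if others.size:
                    tra_counts[i, rng.choice(others)] += 1
            dominant_names[cell_ids[i]] = tra_names[dom]
        if t in T_CELL_TYPES:
            lam = 1.0 if (dom in elevated_tra) else 0.5
            marker_counts[i, :] = rng.poisson(lam, size=len(SPATIAL_MARKER_GENES))

    columns: dict = {
        "cell_id": cell_ids,
        "x_um": np.round(xs, 3),
        "y_um": np.round(ys, 3),
        "cell_type": cell_type,
        "compartment": compartment,
        "treated": bool(treated),
    }
    columns.update({name: igh_counts[:, k] for k, name in enumerate(igh_names)})
    columns.update({name: tra_counts[:, k] for k, name in enumerate(tra_names)})
    columns.update(
        {name: marker_counts[:, k] for k, name in enumerate(SPATIAL_MARKER_GENES)}
    )
    cells = pd.DataFrame(columns)

    truth = {
        "planted_pairs": [(cell_ids[a], cell_ids[b]) for a, b in pairs],
        "planted_triads": [(cell_ids[a], cell_ids[b], cell_ids[c])
                           for a, b, c in triads],
        "colocalized_gene_indices": [int(i) for i in coloc_idx],
        "dominant_gene": dominant_names,
    }
    return SpatialSample(sample_id, patient_id, timepoint, compartment,
                         bool(treated), cells, truth)


def generate_spatial_sample(
    config: CohortConfig,
    sample_id: str,
    treated: bool,
    compartment: str = "tumor",
    patient_id: str = "pt00",
    timepoint: str = "post",
    seed: int | None = None,
    usage_igh: np.ndarray | None = None,
    usage_tra: np.ndarray | None = None,
    **kwargs,
) -> SpatialSample:
    """One spatial map. Untreated maps carry no planted T/B association or
    triads regardless of the configured rates."""
    rng = rng_for(config.seed if seed is None else seed, _D_SPATIAL, 9999)
    if usage_igh is None:
        usage_igh = _sample_usage(config, "IGH", rng)
    if usage_tra is None:
        usage_tra = _sample_usage(config, "TRA", rng)
    return _spatial_map(config, sample_id, patient_id, timepoint, treated,
                        compartment, rng, usage_igh, usage_tra, **kwargs)


def generate_compartment_pair(
    config: CohortConfig, patient_id: str = "pt_share", seed: int | None = None
) -> tuple[SpatialSample, SpatialSample, dict]:
    """A lymph-node / tumor map pair with planted clone-pair sharing.

    All V-gene clone pairs are present in the lymph node; colocalized pairs
    (the first ``n_pseudoclone_pairs`` gene indices, whose members are
    seeded proximal) reappear in the tumor at ``sharing_rate_colocalized``,
    noncolocalized pairs at ``sharing_rate_flat``. Shared T clones carry a
    two-fold elevation of the marker probes.
    """
    rng = rng_for(config.seed if seed is None else seed, _D_SPATIAL, 7777)
    usage_igh = _sample_usage(config, "IGH", rng)
    usage_tra = _sample_usage(config, "TRA", rng)
    n_v = config.n_vgenes
    coloc = np.zeros(n_v, dtype=bool)
    coloc[: config.n_pseudoclone_pairs] = True
    shared = np.where(
        coloc,
        rng.random(n_v) < config.sharing_rate_colocalized,
        rng.random(n_v) < config.sharing_rate_flat,
    )
    elevated = np.flatnonzero(shared)
    ln = _spatial_map(
        config, f"{patient_id}_ln", patient_id, "post", True, "lymph_node",
        rng, usage_igh, usage_tra,
        force_igh=range(n_v), force_tra=range(n_v),
        plant_pairs=True, plant_triads=True, elevated_tra=elevated,
    )
    tumor = _spatial_map(
        config, f"{patient_id}_tumor", patient_id, "post", True, "tumor",
        rng, usage_igh, usage_tra,
        allowed_igh=shared, allowed_tra=shared,
        force_igh=np.flatnonzero(shared), force_tra=np.flatnonzero(shared),
        plant_pairs=True, plant_triads=False, elevated_tra=elevated,
    )
    truth = {
        "colocalized_gene_indices": [int(i) for i in np.flatnonzero(coloc)],
        "shared_gene_indices": [int(i) for i in elevated],
        "sharing_rate_colocalized": config.sharing_rate_colocalized,
        "sharing_rate_flat": config.sharing_rate_flat,
    }
    return ln, tumor, truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Bundle of generated tables plus the planted ground truth."""

    config: CohortConfig
    clonotypes: pd.DataFrame | None = None
    expression: ad.AnnData | None = None
    spatial_samples: list[SpatialSample] = field(default_factory=list)
    survival: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


ALL_ARMS = ("repertoire", "expression", "spatial", "survival")

#: Spatial maps are generated for this many patients (mirroring the study's
#: six treated patients with spatial profiling) plus lymph-node maps for two.
_N_SPATIAL_PATIENTS = 6
_N_LN_PATIENTS = 2


def generate_cohort(
    config: CohortConfig, include: Sequence[str] = ALL_ARMS
) -> SyntheticCohort:
    """Generate a full synthetic cohort with planted ground truth.

    ``include`` selects which arms to materialize ("repertoire",
    "expression", "spatial", "survival"); truth labels and planted
    per-sample clonotype counts are always produced.
    """
    unknown = set(include) - set(ALL_ARMS)
    if unknown:
        raise ConfigurationError(f"unknown cohort arms requested: {sorted(unknown)}")
    n = config.n_patients
    patient_ids = [f"pt{i:03d}" for i in range(n)]

    truth: dict = {
        "planted_hazard_ratio": config.hazard_ratio_increased,
        "patients": {},
        "vgene_usage": {},
        "spatial": {},
    }
    record_frames: list[pd.DataFrame] = []
    sample_meta_rows: list[dict] = []
    usages: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for i, pid in enumerate(patient_ids):
        rng = rng_for(config.seed, _D_REPERTOIRE, i)
        # per-patient arm draw from the patient's own seed-tree node, so
        # subsetting the cohort never changes another patient's draws
        increased = bool(rng.random() < config.fraction_increased)
        post_rate = (
            config.post_clonotype_rate_increased
            if increased
            else config.post_clonotype_rate_flat
        )
        bcr_pre, bcr_post = _draw_pre_post(
            rng, config.pre_clonotype_rate, post_rate, increased
        )
        tcr_pre = int(rng.poisson(config.tcr_clonotype_rate))
        tcr_post = int(rng.poisson(config.tcr_clonotype_rate))
        truth["patients"][pid] = {
            "increased": bool(increased),
            "bcr_pre": bcr_pre,
            "bcr_post": bcr_post,
            "tcr_pre": tcr_pre,
            "tcr_post": tcr_post,
        }
        for ti, (tp, nb, nt) in enumerate(
            [("pre", bcr_pre, tcr_pre), ("post", bcr_post, tcr_post)]
        ):
            sid = f"{pid}_{tp}"
            u_rng = rng_for(config.seed, _D_USAGE, i, ti)
            usage = {loc: _sample_usage(config, loc, u_rng)
                     for loc in ("IGH", "IGK", "IGL", "TRA", "TRB")}
            usages[(pid, tp)] = usage
            truth["vgene_usage"][sid] = {
                loc: [float(x) for x in usage[loc]] for loc in usage
            }
            sample_meta_rows.append(
                {"sample_id": sid, "patient_id": pid, "timepoint": tp,
                 "bcr_unique": nb, "tcr_unique": nt}
            )
            if "repertoire" in include:
                record_frames.append(
                    _sample_records(config, sid, pid, tp, nb, nt, usage, rng)
                )

    sample_meta = pd.DataFrame(sample_meta_rows)
    cohort = SyntheticCohort(config=config, truth=truth)
    if "repertoire" in include:
        cohort.clonotypes = pd.concat(record_frames, ignore_index=True)

    if "expression" in include:
        bcr_counts = dict(zip(sample_meta["sample_id"], sample_meta["bcr_unique"]))
        cohort.expression, truth["planted_corr"] = generate_expression(
            config, sample_meta[["sample_id", "patient_id", "timepoint"]], bcr_counts
        )

    if "spatial" in include:
        for i, pid in enumerate(patient_ids[: min(n, _N_SPATIAL_PATIENTS)]):
            for ti, tp in enumerate(("pre", "post")):
                sid = f"{pid}_{tp}_xen"
                rng = rng_for(config.seed, _D_SPATIAL, i, ti)
                usage = usages[(pid, tp)]
                smp = _spatial_map(
                    config, sid, pid, tp, treated=(tp == "post"),
                    compartment="tumor", rng=rng,
                    usage_igh=usage["IGH"], usage_tra=usage["TRA"],
                )
                cohort.spatial_samples.append(smp)
                truth["spatial"][sid] = smp.truth
            if i < _N_LN_PATIENTS:
                sid = f"{pid}_ln_xen"
                rng = rng_for(config.seed, _D_SPATIAL, i, 2)
                usage = usages[(pid, "post")]
                smp = _spatial_map(
                    config, sid, pid, "post", treated=True,
                    compartment="lymph_node", rng=rng,
                    usage_igh=usage["IGH"], usage_tra=usage["TRA"],
                )
                cohort.spatial_samples.append(smp)
                truth["spatial"][sid] = smp.truth

    if "survival" in include:
        surv_rows = []
        for i, pid in enumerate(patient_ids):
            rng = rng_for(config.seed, _D_SURVIVAL, i)
            increased = truth["patients"][pid]["increased"]
            hazard = config.baseline_hazard * (
                config.hazard_ratio_increased if increased else 1.0
            )
            t = float(rng.exponential(1.0 / hazard))
            event = 1
            if t > config.censor_time_days:
                t, event = config.censor_time_days, 0
            surv_rows.append(
                {"patient_id": pid, "time_days": round(t, 4), "event": event,
                 "group": "increased" if increased else "flat"}
            )
        cohort.survival = pd.DataFrame(surv_rows)

    return cohort


# ---------------------------------------------------------------------------
# predictor training/evaluation datasets (bulk-style pretreatment matrices)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorSimConfig:
    """Planted-signal pretreatment expression matrices for the trajectory
    predictor: ``n_de_genes`` genes shifted ``fold_change``-fold in patients
    whose BCR diversity will increase, log-normal sample noise, and external
    PD-1 / non-PD-1 arms whose survival benefit exists only under PD-1."""

    n_train: int = 60
    n_external: int = 120
    n_genes: int = 600
    n_de_genes: int = 117
    fold_change: float = 2.5
    noise_sd: float = 0.3
    external_noise_sd: float = 0.4
    fraction_increase: float = 0.5
    hazard_ratio_increase: float = 0.46
    baseline_hazard: float = 0.002
    censor_time_days: float = 1825.0
    seed: int = 0


def _expression_matrix(
    cfg: PredictorSimConfig,
    labels: np.ndarray,
    base_mean: np.ndarray,
    de_idx: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    prefix: str,
) -> pd.DataFrame:
    n = labels.size
    log_mu = np.log(base_mean)[None, :] + rng.normal(0, noise_sd, (n, cfg.n_genes))
    log_mu[:, de_idx] += np.log(cfg.fold_change) * labels[:, None]
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    return pd.DataFrame(
        np.exp(log_mu), columns=genes,
        index=[f"{prefix}{i:03d}" for i in range(n)],
    )


def generate_predictor_dataset(
    cfg: PredictorSimConfig, external_replicate: int = 0
) -> dict:
    """Training matrix + labels, external PD-1 and control arms with
    survival, and the planted truth.

    ``external_replicate`` redraws the external arms (patients, noise,
    survival) while keeping the planted gene structure and the training
    cohort fixed — the repeated-validation design of the specificity check.
    """
    rng = rng_for(cfg.seed, _D_PREDICTOR)
    base_mean = np.exp(rng.normal(3.0, 1.0, size=cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)

    def _labels(n: int, r: np.random.Generator) -> np.ndarray:
        k = int(round(cfg.fraction_increase * n))
        lab = np.zeros(n, dtype=int)
        lab[:k] = 1
        return lab[r.permutation(n)]

    train_labels = _labels(cfg.n_train, rng)
    train = _expression_matrix(cfg, train_labels, base_mean, de_idx,
                               cfg.noise_sd, rng, "tr")

    arms = {}
    for arm, benefit in (("pd1", True), ("control", False)):
        r = rng_for(cfg.seed, _D_PREDICTOR, 1 if arm == "pd1" else 2,
                    external_replicate)
        lab = _labels(cfg.n_external, r)
        mat = _expression_matrix(cfg, lab, base_mean, de_idx,
                                 cfg.external_noise_sd, r, f"{arm}_")
        hr = cfg.hazard_ratio_increase if benefit else 1.0
        surv = []
        for i, pid in enumerate(mat.index):
            h = cfg.baseline_hazard * (hr if lab[i] == 1 else 1.0)
            t = float(r.exponential(1.0 / h))
            event = 1
            if t > cfg.censor_time_days:
                t, event = cfg.censor_time_days, 0
            surv.append({"patient_id": pid, "time_days": round(t, 4),
                         "event": event, "arm": arm})
        arms[arm] = {
            "expression": mat,
            "labels": pd.Series(lab, index=mat.index),
            "survival": pd.DataFrame(surv),
        }

    return {
        "train": train,
        "train_labels": pd.Series(train_labels, index=train.index),
        "de_genes": [train.columns[i] for i in sorted(de_idx)],
        "external": arms,
        "config": cfg,
    }
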