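"""Spatial V-gene pseudoclones: colocalization, size coupling, sharing.

A pseudoclone groups spatial cells by their dominant V-gene probe — a
spatially measurable proxy for a clonotype when CDR3-level mapping is not
available. BCR pseudoclones use IGH V genes only (the light chains do not
reproduce the matched scRNA/in-situ usage pattern); T pseudoclones use the
TR V probes. Colocalization of a (T, B) pseudoclone pair is scored by a
permutation z of the number of proximal member links at a fixed radius
(default 20 µm, inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ranksums, spearmanr

from .config import InputError

DEFAULT_RADIUS_UM = 20.0
COLOCALIZATION_Z_THRESHOLD = 2.0

#: Spatial cell types eligible for TR pseudoclones.
T_TYPES = ("Tfh", "CD8_activated", "CD8_exhausted", "CD4_T")


@dataclass(frozen=True)
class Pseudoclone:
    sample_id: str
    locus_class: str  # "TCR" or "IGH"
    v_gene: str
    member_cells: tuple

    @property
    def size(self) -> int:
        return len(self.member_cells)


@dataclass
class ColocalizationResult:
    t_gene: str
    b_gene: str
    n_proximal_links: int
    enrichment_z: float
    colocalized: bool


@dataclass
class CompartmentSharing:
    patient_id: str
    n_pairs_colocalized: int
    n_pairs_noncolocalized: int
    fraction_shared_colocalized: float
    fraction_shared_noncolocalized: float
    ratio: float  # colocalized / noncolocalized sharing; nan if undefined
    undefined: bool = False


def _vgene_cols(cells: pd.DataFrame, locus_class: str) -> list[str]:
    if locus_class == "IGH":
        prefixes = ("IGHV",)
    elif locus_class == "TCR":
        prefixes = ("TRAV", "TRBV")
    else:
        raise InputError(f"unknown locus class {locus_class!r}")
    return [c for c in cells.columns if c.startswith(prefixes)]


def assign_pseudoclones(
    cells: pd.DataFrame, locus_class: str, sample_id: str = ""
) -> tuple[list[Pseudoclone], int]:
    """Assign each eligible cell to the pseudoclone of its maximal-count
    V gene (lexicographic tie-break). Cells with all-zero counts stay
    unassigned; cells of the wrong type for the locus class are skipped and
    counted. Returns (pseudoclones, n_skipped_wrong_type)."""
    cols = sorted(_vgene_cols(cells, locus_class))
    if not cols:
        raise InputError(f"no V-gene probe columns for class {locus_class!r}")
    eligible_types = ("B",) if locus_class == "IGH" else T_TYPES
    counts = cells[cols].to_numpy()
    has_signal = counts.sum(axis=1) > 0
    right_type = cells["cell_type"].isin(eligible_types).to_numpy()
    n_skipped = int((has_signal & ~right_type).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} cell(s) with {locus_class} probe counts but an "
            "inconsistent cell type were skipped",
            stacklevel=2,
        )
    use = has_signal & right_type
    best = np.argmax(counts[use], axis=1)  # first max = lexicographic winner
    members: dict[str, list[str]] = {}
    ids = cells.loc[use, "cell_id"].to_numpy()
    for cid, gi in zip(ids, best):
        members.setdefault(cols[gi], []).append(cid)
    clones = [
        Pseudoclone(sample_id, locus_class, g, tuple(m))
        for g, m in sorted(members.items())
    ]
    return clones, n_skipped


def proximity_graph(cells: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM) -> pd.DataFrame:
    """Undirected edges between cells at Euclidean distance <= radius."""
    if radius_um <= 0:
        raise InputError("radius must be positive")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius_um, output_type="ndarray")
    if pairs.size == 0:
        return pd.DataFrame(columns=["cell_a", "cell_b", "distance_um"])
    d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
    ids = cells["cell_id"].to_numpy()
    return pd.DataFrame(
        {"cell_a": ids[pairs[:, 0]], "cell_b": ids[pairs[:, 1]],
         "distance_um": d}
    )


def _edge_array(cells: pd.DataFrame, radius_um: float) -> np.ndarray:
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    return cKDTree(xy).query_pairs(radius_um, output_type="ndarray")


def neighborhood_enrichment(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    radius_um: float = DEFAULT_RADIUS_UM,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation z-score for excess spatial proximity of two cell types.

    The observed count of proximal a–b cell pairs is compared with its null
    under seeded shuffles of the type labels over the fixed positions.
    """
    if n_permutations < 100:
        raise InputError("need at least 100 permutations")
    labels = cells["cell_type"].to_numpy()
    for t in (type_a, type_b):
        if (labels == t).sum() == 0:
            return {"z": np.nan, "observed": 0, "null_mean": np.nan,
                    "null_sd": np.nan, "undefined": True}
    if type_a == type_b and (labels == type_a).sum() < 2:
        return {"z": np.nan, "observed": 0, "null_mean": np.nan,
                "null_sd": np.nan, "undefined": True}
    edges = _edge_array(cells, radius_um)

    def count(lab: np.ndarray) -> int:
        if edges.size == 0:
            return 0
        la, lb = lab[edges[:, 0]], lab[edges[:, 1]]
        if type_a == type_b:
            return int(((la == type_a) & (lb == type_a)).sum())
        return int(
            (((la == type_a) & (lb == type_b))
             | ((la == type_b) & (lb == type_a))).sum()
        )

    obs = count(labels)
    rng = np.random.default_rng(seed)
    null = np.array(
        [count(rng.permutation(labels)) for _ in range(n_permutations)],
        dtype=float,
    )
    mu, sd = null.mean(), null.std(ddof=1)
    z = (obs - mu) / sd if sd > 0 else 0.0
    return {"z": float(z), "observed": obs, "null_mean": float(mu),
            "null_sd": float(sd), "undefined": False}


def pseudoclone_colocalization(
    cells: pd.DataFrame,
    pairs: list[tuple[str, str]],
    radius_um: float = DEFAULT_RADIUS_UM,
    n_permutations: int = 1000,
    seed: int = 0,
    z_threshold: float = COLOCALIZATION_Z_THRESHOLD,
) -> list[ColocalizationResult]:
    """Colocalization of (T V-gene, B V-gene) pseudoclone pairs.

    For each pair the observed number of proximal T/B member links is
    compared with a null in which pseudoclone labels are permuted among
    cells of the same type class (positions fixed). A pair is called
    colocalized when its z reaches ``z_threshold``.
    """
    t_clones, _ = assign_pseudoclones(cells, "TCR")
    b_clones, _ = assign_pseudoclones(cells, "IGH")
    t_gene_of = {c: cl.v_gene for cl in t_clones for c in cl.member_cells}
    b_gene_of = {c: cl.v_gene for cl in b_clones for c in cl.member_cells}
    ids = cells["cell_id"].to_numpy()
    t_lab = np.array([t_gene_of.get(c, "") for c in ids])
    b_lab = np.array([b_gene_of.get(c, "") for c in ids])
    edges = _edge_array(cells, radius_um)
    if edges.size:
        u, v = edges[:, 0], edges[:, 1]
        # orient every T-B proximal link as (T index, B index)
        tb_mask = (t_lab[u] != "") & (b_lab[v] != "")
        bt_mask = (b_lab[u] != "") & (t_lab[v] != "")
        t_end = np.concatenate([u[tb_mask], v[bt_mask]])
        b_end = np.concatenate([v[tb_mask], u[bt_mask]])
    else:
        t_end = b_end = np.array([], dtype=int)

    def link_counts(tl: np.ndarray, bl: np.ndarray) -> dict:
        keys, cnts = np.unique(
            np.char.add(np.char.add(tl[t_end], "|"), bl[b_end]),
            return_counts=True,
        )
        return dict(zip(keys, cnts))

    obs_counts = link_counts(t_lab, b_lab)
    rng = np.random.default_rng(seed)
    t_members = np.flatnonzero(t_lab != "")
    b_members = np.flatnonzero(b_lab != "")
    null = {f"{tg}|{bg}": np.empty(n_permutations) for tg, bg in pairs}
    for it in range(n_permutations):
        tl = t_lab.copy()
        bl = b_lab.copy()
        tl[t_members] = tl[t_members[rng.permutation(t_members.size)]]
        bl[b_members] = bl[b_members[rng.permutation(b_members.size)]]
        c = link_counts(tl, bl)
        for key in null:
            null[key][it] = c.get(key, 0)

    out = []
    for tg, bg in pairs:
        key = f"{tg}|{bg}"
        obs = int(obs_counts.get(key, 0))
        mu, sd = null[key].mean(), null[key].std(ddof=1)
        z = (obs - mu) / sd if sd > 0 else 0.0
        out.append(
            ColocalizationResult(tg, bg, obs, float(z), bool(z >= z_threshold))
        )
    return out


def size_correlation_by_colocalization(pairs: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of paired T and B pseudoclone sizes per
    (treated, colocalized) stratum.

    ``pairs`` needs columns t_size, b_size, treated, colocalized. Strata
    with fewer than 4 pairs or zero variance are reported undefined.
    """
    for col in ("t_size", "b_size", "treated", "colocalized"):
        if col not in pairs.columns:
            raise InputError(f"pair table lacks column {col!r}")
    rows = []
    for (treated, coloc), sub in pairs.groupby(["treated", "colocalized"]):
        r, n = np.nan, len(sub)
        defined = n >= 4
        if defined and (sub["t_size"].nunique() < 2 or sub["b_size"].nunique() < 2):
            defined = False
        if defined:
            r = float(spearmanr(sub["t_size"], sub["b_size"]).statistic)
        rows.append(
            {"treated": treated, "colocalized": coloc, "n_pairs": n,
             "spearman_r": r, "defined": defined}
        )
    return pd.DataFrame(rows)


def _present_genes(cells: pd.DataFrame, locus_class: str) -> set[str]:
    clones, _ = assign_pseudoclones(cells, locus_class)
    return {c.v_gene for c in clones}


def shared_pair_fraction(
    ln_cells: pd.DataFrame,
    tumor_cells: pd.DataFrame,
    pair_flags: dict[tuple[str, str], bool],
    patient_id: str = "",
) -> CompartmentSharing:
    """Among lymph-node clone pairs, the fraction also detected in the
    tumor, separately for colocalized and noncolocalized pairs.

    ``pair_flags`` maps (T V-gene, B V-gene) pairs to their colocalization
    flag; a pair is "present" in a compartment when both member
    pseudoclones are detected there with at least one cell.
    """
    ln_t, ln_b = _present_genes(ln_cells, "TCR"), _present_genes(ln_cells, "IGH")
    tu_t, tu_b = _present_genes(tumor_cells, "TCR"), _present_genes(tumor_cells, "IGH")
    n = {True: 0, False: 0}
    shared = {True: 0, False: 0}
    for (tg, bg), flag in pair_flags.items():
        if tg in ln_t and bg in ln_b:
            n[flag] += 1
            if tg in tu_t and bg in tu_b:
                shared[flag] += 1
    if n[True] + n[False] == 0:
        return CompartmentSharing(patient_id, 0, 0, np.nan, np.nan, np.nan, True)
    f_col = shared[True] / n[True] if n[True] else np.nan
    f_non = shared[False] / n[False] if n[False] else np.nan
    ratio = f_col / f_non if (n[False] and f_non > 0) else np.nan
    return CompartmentSharing(
        patient_id, n[True], n[False], f_col, f_non, ratio, False
    )


def shared_vs_exclusive_expression(
    cells: pd.DataFrame,
    shared_genes: set[str],
    genes: tuple[str, ...] = ("MKI67", "CD69", "ENTPD1"),
) -> pd.DataFrame:
    """Marker expression of T cells from compartment-shared pseudoclones
    vs compartment-exclusive ones, per compartment: log1p mean difference
    (shared minus exclusive) with a Wilcoxon rank-sum p-value."""
    if not genes:
        raise InputError("gene list must be nonempty")
    clones, _ = assign_pseudoclones(cells, "TCR")
    gene_of = {c: cl.v_gene for cl in clones for c in cl.member_cells}
    rows = []
    for compartment, sub in cells.groupby("compartment"):
        member = sub["cell_id"].map(gene_of)
        is_member = member.notna()
        is_shared = member.isin(shared_genes) & is_member
        is_exclusive = is_member & ~is_shared
        for g in genes:
            if g not in sub.columns:
                rows.append({"compartment": compartment, "gene": g,
                             "effect": np.nan, "p": np.nan, "flag": "gene_absent"})
                continue
            a = np.log1p(sub.loc[is_shared, g].to_numpy(dtype=float))
            b = np.log1p(sub.loc[is_exclusive, g].to_numpy(dtype=float))
            if a.size == 0 or b.size == 0:
                rows.append({"compartment": compartment, "gene": g,
                             "effect": np.nan, "p": np.nan, "flag": "group_empty"})
                continue
            stat = ranksums(a, b)
            rows.append(
                {"compartment": compartment, "gene": g,
                 "effect": float(a.mean() - b.mean()),
                 "p": float(stat.pvalue), "flag": "ok"}
            )
    return pd.DataFrame(rows)
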