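"""Pseudoclone assignment, proximity statistics, and compartment sharing."""

import numpy as np
import pandas as pd
import pytest

import clonotrack as ct
from clonotrack.config import InputError
from clonotrack.spatial import _present_genes

from conftest import csr_map


def _cells(rows, vgenes=("IGHV01", "IGHV02", "TRAV01")):
    base = {"cell_id": "c0", "x_um": 0.0, "y_um": 0.0, "cell_type": "B",
            "compartment": "tumor", "treated": True}
    base.update({g: 0 for g in vgenes})
    return pd.DataFrame([{**base, **r} for r in rows])


class TestPseudocloneAssignment:
    def test_single_support_assigns_that_gene(self):
        cells = _cells([{"cell_id": "c1", "IGHV01": 3}])
        clones, skipped = ct.assign_pseudoclones(cells, "IGH")
        assert skipped == 0
        assert len(clones) == 1
        assert clones[0].v_gene == "IGHV01"
        assert clones[0].member_cells == ("c1",)

    def test_tie_breaks_lexicographically(self):
        cells = _cells([{"cell_id": "c1", "IGHV01": 0, "IGHV02": 2}])
        cells.loc[0, "IGHV01"] = 2  # tie between IGHV01 and IGHV02
        clones, _ = ct.assign_pseudoclones(cells, "IGH")
        assert clones[0].v_gene == "IGHV01"

    def test_all_zero_counts_stay_unassigned(self):
        cells = _cells([{"cell_id": "c1"}])
        clones, _ = ct.assign_pseudoclones(cells, "IGH")
        assert clones == []

    def test_wrong_cell_type_skipped_with_warning(self):
        cells = _cells([{"cell_id": "c1", "cell_type": "Tumor", "IGHV01": 5}])
        with pytest.warns(UserWarning, match="skipped"):
            clones, skipped = ct.assign_pseudoclones(cells, "IGH")
        assert skipped == 1
        assert clones == []

    def test_sizes_sum_to_assigned_cells(self, small_cohort):
        smp = small_cohort.spatial_samples[0]
        clones, _ = ct.assign_pseudoclones(smp.cells, "IGH")
        n_b = (
            (smp.cells["cell_type"] == "B")
            & (smp.cells[[c for c in smp.cells.columns
                          if c.startswith("IGHV")]].sum(axis=1) > 0)
        ).sum()
        assert sum(c.size for c in clones) == n_b

    def test_agreement_with_generator_truth(self, small_cohort):
        smp = small_cohort.spatial_samples[1]
        truth = smp.truth["dominant_gene"]
        clones_b, _ = ct.assign_pseudoclones(smp.cells, "IGH")
        clones_t, _ = ct.assign_pseudoclones(smp.cells, "TCR")
        agree = total = 0
        for cl in list(clones_b) + list(clones_t):
            for cid in cl.member_cells:
                total += 1
                agree += truth[cid] == cl.v_gene
        assert total > 100
        assert agree / total >= 0.95  # default probe-noise regime


class TestProximityGraph:
    def test_boundary_distance_is_inclusive(self):
        cells = _cells(
            [{"cell_id": "c1"}, {"cell_id": "c2", "x_um": 20.0}]
        )
        edges = ct.proximity_graph(cells, radius_um=20.0)
        assert len(edges) == 1
        assert edges["distance_um"].iloc[0] == pytest.approx(20.0)

    def test_single_cell_has_no_edges(self):
        edges = ct.proximity_graph(_cells([{"cell_id": "c1"}]), 20.0)
        assert len(edges) == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_all_pairs_scan(self, seed):
        cells = csr_map(500, seed, field=400.0)
        edges = ct.proximity_graph(cells, 20.0)
        xy = cells[["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        iu = np.triu_indices(len(cells), k=1)
        expected = int((d[iu] <= 20.0).sum())
        assert len(edges) == expected


class TestNeighborhoodEnrichment:
    def test_null_maps_are_calibrated(self):
        zs = [
            ct.neighborhood_enrichment(csr_map(350, s), "A", "B",
                                       n_permutations=150, seed=s)["z"]
            for s in range(12)
        ]
        assert abs(np.mean(zs)) < 0.5

    def test_planted_colocalization_detected(self, small_config):
        smp = ct.generate_spatial_sample(small_config, "t", treated=True, seed=6)
        res = ct.neighborhood_enrichment(
            smp.cells, "B", "CD8_activated", n_permutations=300, seed=0
        )
        assert res["z"] > 3

    def test_absent_type_is_undefined(self):
        res = ct.neighborhood_enrichment(csr_map(100, 0), "A", "Z",
                                         n_permutations=100, seed=0)
        assert res["undefined"]

    def test_invariant_under_rigid_motion(self):
        cells = csr_map(200, 3)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = cells.copy()
        xy = cells[["x_um", "y_um"]].to_numpy() @ rot.T + [500.0, -120.0]
        moved[["x_um", "y_um"]] = xy
        a = ct.neighborhood_enrichment(cells, "A", "B", n_permutations=150, seed=4)
        b = ct.neighborhood_enrichment(moved, "A", "B", n_permutations=150, seed=4)
        assert a["z"] == pytest.approx(b["z"], abs=1e-9)


class TestSizeCorrelation:
    def test_zero_variance_stratum_undefined(self):
        pairs = pd.DataFrame(
            {"t_size": [1, 2, 3, 4], "b_size": [5, 5, 5, 5],
             "treated": True, "colocalized": True}
        )
        res = ct.size_correlation_by_colocalization(pairs)
        assert not res["defined"].iloc[0]

    def test_small_stratum_undefined(self):
        pairs = pd.DataFrame(
            {"t_size": [1, 2, 3], "b_size": [2, 3, 4],
             "treated": False, "colocalized": False}
        )
        res = ct.size_correlation_by_colocalization(pairs)
        assert not res["defined"].iloc[0]

    def test_coupling_only_in_treated_colocalized_stratum(self, small_config):
        igh = small_config.vgene_universe("IGH")
        tra = small_config.vgene_universe("TRA")
        rows = []
        for treated in (True, False):
            for m in range(5):
                smp = ct.generate_spatial_sample(
                    small_config, f"m{treated}{m}", treated=treated,
                    seed=500 + m + 50 * treated,
                )
                t_size = {c.v_gene: c.size
                          for c in ct.assign_pseudoclones(smp.cells, "TCR")[0]}
                b_size = {c.v_gene: c.size
                          for c in ct.assign_pseudoclones(smp.cells, "IGH")[0]}
                coloc = set(smp.truth["colocalized_gene_indices"])
                for i in range(small_config.n_vgenes):
                    if tra[i] in t_size and igh[i] in b_size:
                        rows.append(
                            {"t_size": t_size[tra[i]], "b_size": b_size[igh[i]],
                             "treated": treated,
                             "colocalized": treated and i in coloc}
                        )
        res = ct.size_correlation_by_colocalization(pd.DataFrame(rows))
        res = res.set_index(["treated", "colocalized"])
        assert res.loc[(True, True), "spearman_r"] > 0
        assert abs(res.loc[(False, False), "spearman_r"]) < 0.3


class TestSharing:
    def _flags(self, cfg):
        igh, tra = cfg.vgene_universe("IGH"), cfg.vgene_universe("TRA")
        return {(tra[i], igh[i]): i < cfg.n_pseudoclone_pairs
                for i in range(cfg.n_vgenes)}

    def test_identical_compartments_share_everything(self, small_config):
        smp = ct.generate_spatial_sample(small_config, "a", treated=True, seed=8)
        flags = {
            (t, b): True
            for t in _present_genes(smp.cells, "TCR")
            for b in _present_genes(smp.cells, "IGH")
        }
        res = ct.shared_pair_fraction(smp.cells, smp.cells, flags)
        assert res.fraction_shared_colocalized == 1.0

    def test_disjoint_gene_sets_share_nothing(self):
        a = _cells([{"cell_id": "c1", "IGHV01": 2},
                    {"cell_id": "c2", "cell_type": "CD4_T", "TRAV01": 2}])
        b = _cells([{"cell_id": "c3", "IGHV02": 2}])
        res = ct.shared_pair_fraction(a, b, {("TRAV01", "IGHV01"): True})
        assert res.fraction_shared_colocalized == 0.0

    def test_no_lymph_node_pairs_is_undefined(self):
        a = _cells([{"cell_id": "c1"}])
        res = ct.shared_pair_fraction(a, a, {("TRAV01", "IGHV01"): True})
        assert res.undefined

    def test_planted_sharing_ratio_near_design(self):
        cfg = ct.CohortConfig(seed=31, n_vgenes=100, n_pseudoclone_pairs=50)
        shared = total = {True: 0, False: 0}
        n_col = n_non = s_col = s_non = 0
        for rep in range(3):
            ln, tumor, truth = ct.generate_compartment_pair(
                cfg, patient_id=f"p{rep}", seed=100 + rep
            )
            res = ct.shared_pair_fraction(ln.cells, tumor.cells,
                                          self._flags(cfg))
            n_col += res.n_pairs_colocalized
            n_non += res.n_pairs_noncolocalized
            s_col += res.fraction_shared_colocalized * res.n_pairs_colocalized
            s_non += res.fraction_shared_noncolocalized * res.n_pairs_noncolocalized
        ratio = (s_col / n_col) / (s_non / n_non)
        assert 2.0 <= ratio <= 10.0


class TestSharedVsExclusiveExpression:
    def test_planted_elevation_detected(self):
        cfg = ct.CohortConfig(seed=13, n_vgenes=60, n_pseudoclone_pairs=30)
        ln, tumor, truth = ct.generate_compartment_pair(cfg, seed=5)
        tra = cfg.vgene_universe("TRA")
        shared_genes = {tra[i] for i in truth["shared_gene_indices"]}
        res = ct.shared_vs_exclusive_expression(ln.cells, shared_genes)
        mki = res[(res["gene"] == "MKI67") & (res["flag"] == "ok")]
        assert len(mki) == 1
        assert mki["effect"].iloc[0] > 0
        assert mki["p"].iloc[0] < 0.01

    def test_absent_gene_flagged(self):
        cells = _cells([{"cell_id": "c1", "cell_type": "CD4_T", "TRAV01": 2},
                        {"cell_id": "c2", "cell_type": "CD4_T", "TRAV01": 2}])
        cells["MKI67"] = 1
        res = ct.shared_vs_exclusive_expression(
            cells, {"TRAV01"}, genes=("NOPE",)
        )
        assert (res["flag"] == "gene_absent").all()

    def test_empty_group_flagged(self):
        cells = _cells([{"cell_id": "c1", "cell_type": "CD4_T", "TRAV01": 2}])
        cells["MKI67"] = 1
        res = ct.shared_vs_exclusive_expression(cells, {"TRAV01"},
                                                genes=("MKI67",))
        assert (res["flag"] == "group_empty").all()

    def test_empty_gene_list_rejected(self):
        with pytest.raises(InputError):
            ct.shared_vs_exclusive_expression(_cells([{}]), set(), genes=())
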