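"""Distance maps, contact maps, weighted RINs and persistency classes.

The distance/contact machinery is pinned to an exhaustive O(atoms²)
double-loop oracle; persistency classification is pinned to ensembles with
planted contact frequencies, where edge weights are exact by construction.
"""

import numpy as np
import pytest

from idpensemble import (PAEMap, StructureEnsemble, accumulate_rin,
                         contact_map, ensemble_mean_distance_map,
                         pae_distance_concordance, persistency_histogram,
                         residue_distance_map, rin_summary)
from idpensemble.synthetic_ensembles import planted_persistency_ensemble

from conftest import build_model, random_model


def brute_force_distance_map(model):
    """Exhaustive double loop over atom pairs (independent oracle)."""
    n = model.n_residues
    d = np.zeros((n, n))
    coords = model.coords
    res = model.atom_residue
    for i in range(n):
        for j in range(i + 1, n):
            ai = coords[res == i]
            aj = coords[res == j]
            best = min(np.linalg.norm(a - b) for a in ai for b in aj)
            d[i, j] = d[j, i] = best
    return d


class TestDistanceMap:
    def test_three_four_five(self):
        model = build_model([[(0, 0, 0)], [(3, 4, 0)]])
        d = residue_distance_map(model)
        assert d.matrix[0, 1] == pytest.approx(5.0)
        assert d.matrix[0, 0] == 0.0 and d.matrix[1, 1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for k in range(5):
            model = random_model(rng, 15, atoms_per_residue=(1, 5), box=12.0)
            fast = residue_distance_map(model).matrix
            np.testing.assert_allclose(fast, brute_force_distance_map(model),
                                       atol=0)

    def test_mean_distance_map(self, ordered_fixture):
        mean = ensemble_mean_distance_map(ordered_fixture).matrix
        acc = sum(residue_distance_map(m).matrix for m in ordered_fixture)
        np.testing.assert_allclose(mean, acc / len(ordered_fixture))

    def test_two_member_average(self):
        a = build_model([[(0, 0, 0)], [(4, 0, 0)]], model_id="a")
        b = build_model([[(0, 0, 0)], [(6, 0, 0)]], model_id="b")
        mean = ensemble_mean_distance_map(StructureEnsemble([a, b]))
        assert mean.matrix[0, 1] == pytest.approx(5.0)


class TestContactMap:
    def test_strict_cutoff(self):
        just_under = build_model([[(0, 0, 0)], [(3.49, 0, 0)]])
        exactly_at = build_model([[(0, 0, 0)], [(3.50, 0, 0)]])
        assert contact_map(residue_distance_map(just_under)).matrix[0, 1] == 1
        assert contact_map(residue_distance_map(exactly_at)).matrix[0, 1] == 0

    def test_invalid_cutoff(self):
        model = build_model([[(0, 0, 0)], [(3, 0, 0)]])
        with pytest.raises(ValueError, match="positive"):
            contact_map(residue_distance_map(model), cutoff=0.0)

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(9)
        model = random_model(rng, 25, atoms_per_residue=(1, 3), box=8.0)
        cmap = contact_map(residue_distance_map(model))
        brute = brute_force_distance_map(model)
        expected = int(np.sum(np.triu(brute < 3.5, k=1) & (np.triu(brute, 1) > 0)))
        # diagonal-adjacent zero distances cannot occur in random clouds
        assert cmap.n_contacts == int(np.sum(np.triu(brute, k=1) < 3.5)
                                      - np.sum(np.triu(brute, k=1) == 0))
        assert cmap.n_contacts == expected

    def test_cutoff_monotonicity(self, disordered_fixture):
        lo = accumulate_rin(disordered_fixture, cutoff=3.0)
        hi = accumulate_rin(disordered_fixture, cutoff=4.5)
        assert np.all(hi.weights >= lo.weights)


class TestWeightedRIN:
    def test_planted_frequencies_exact(self):
        ens = planted_persistency_ensemble(
            [(0, 4, 0.8), (2, 8, 0.2), (6, 12, 0.5)], n_members=10, seed=3)
        rin = accumulate_rin(ens)
        weights = {tuple(sorted(e)): d["weight"]
                   for *e, d in rin.graph.edges(data=True)}
        classes = {tuple(sorted(e)): d["persistency_class"]
                   for *e, d in rin.graph.edges(data=True)}
        assert weights == {(0, 4): 8, (2, 8): 2, (6, 12): 5}
        assert classes == {(0, 4): "persistent", (2, 8): "transient",
                           (6, 12): "medium"}

    def test_weight_conservation(self, disordered_fixture):
        rin = accumulate_rin(disordered_fixture)
        per_member = [int(np.sum(np.triu(c, k=1)))
                      for c in rin.member_contacts]
        total_weight = sum(d["weight"]
                           for _, _, d in rin.graph.edges(data=True))
        assert total_weight == sum(per_member)

    def test_threshold_validation(self, ordered_fixture):
        with pytest.raises(ValueError, match="thresholds"):
            accumulate_rin(ordered_fixture, thresholds=(0.25, 0.75))

    def test_strict_threshold_boundaries(self):
        # weight 8/10 -> 0.8 > 0.75 persistent; 2/10 -> transient;
        # exactly 0.75 or 0.25 would be medium under the strict convention
        ens = planted_persistency_ensemble([(0, 4, 0.75), (2, 8, 0.25)],
                                           n_members=20, seed=6)
        rin = accumulate_rin(ens)
        classes = {d["persistency_class"]
                   for _, _, d in rin.graph.edges(data=True)}
        assert classes == {"medium"}

    def test_interchain_tagging(self):
        from idpensemble.synthetic_ensembles import synthetic_dimer_ensemble
        dim = synthetic_dimer_ensemble(24, 4, seed=8, noise_sigma=0.2,
                                       planted_interchain=[(0, 0, 1.0)])
        rin = accumulate_rin(dim)
        tags = {d["chain_pair"] for _, _, d in rin.graph.edges(data=True)}
        assert "A|B" in tags


class TestRINSummary:
    def test_planted_counts_survive_summary(self):
        planted = ([(k, k + 5, 0.9) for k in range(3)]
                   + [(14 + k, 19 + k, 0.5) for k in range(2)]
                   + [(26 + k, 31 + k, 0.1) for k in range(4)])
        ens = planted_persistency_ensemble(planted, n_members=10, seed=12,
                                           n_residues=40)
        summary = rin_summary(accumulate_rin(ens))
        assert summary.class_counts_no_backbone == {
            "persistent": 3, "medium": 2, "transient": 4}
        assert summary.total_edges == summary.total_edges_no_backbone == 9
        assert sum(summary.class_counts.values()) == summary.total_edges
        assert sum(summary.class_percent.values()) == pytest.approx(100.0)

    def test_backbone_only_chain(self):
        # residues 3.0 Å apart along a line: only peptide neighbors touch
        n = 8
        model = build_model([[(3.0 * k, 0, 0)] for k in range(n)])
        ens = StructureEnsemble([model.with_coords(model.coords,
                                                   model_id=f"m{k}")
                                 for k in range(3)])
        summary = rin_summary(accumulate_rin(ens))
        assert summary.total_edges == n - 1
        assert summary.total_edges_no_backbone == 0

    def test_residue_class_frequency_counts_endpoints(self):
        # one persistent contact between a GLY and a HIS residue
        ens = planted_persistency_ensemble([(0, 4, 1.0)], n_members=4,
                                           seed=1, n_residues=8)
        # rebuild with controlled names
        from idpensemble import Atom, StructureModel
        members = []
        for m in ens:
            atoms = [Atom(a.chain_id, a.residue_index, a.insertion_code,
                          "GLY" if a.residue_index == 1 else
                          ("HIS" if a.residue_index == 5 else "ALA"),
                          a.atom_name, a.element, a.position, a.confidence)
                     for a in m.atoms]
            members.append(StructureModel(m.model_id, atoms))
        summary = rin_summary(accumulate_rin(StructureEnsemble(members)))
        freq = summary.residue_class_frequencies
        assert freq["glycine"]["median"] == 1.0
        assert freq["aromatic"]["median"] == 1.0   # His is aromatic here
        assert freq["gly_his"]["median"] == 2.0    # both endpoints in class
        assert freq["charged"]["median"] == 0.0


class TestPAEConcordance:
    def test_proportional_maps_correlate_perfectly(self, ordered_fixture):
        dmap = ensemble_mean_distance_map(ordered_fixture)
        pae = PAEMap(matrix=0.5 * dmap.matrix, n_residues=dmap.n)
        assert pae_distance_concordance(pae, dmap) == pytest.approx(1.0)

    def test_constant_map_is_nan_with_warning(self, ordered_fixture):
        dmap = ensemble_mean_distance_map(ordered_fixture)
        pae = PAEMap(matrix=np.full_like(dmap.matrix, 7.0),
                     n_residues=dmap.n)
        with pytest.warns(RuntimeWarning, match="constant"):
            assert np.isnan(pae_distance_concordance(pae, dmap))

    def test_matches_textbook_pearson(self, ordered_fixture):
        rng = np.random.default_rng(4)
        dmap = ensemble_mean_distance_map(ordered_fixture)
        pae = PAEMap(matrix=rng.uniform(0, 30, size=dmap.matrix.shape),
                     n_residues=dmap.n)
        got = pae_distance_concordance(pae, dmap)
        sym = 0.5 * (pae.matrix + pae.matrix.T)
        ii, jj = np.triu_indices(dmap.n, k=2)
        x, y = sym[ii, jj], dmap.matrix[ii, jj]
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self, ordered_fixture):
        dmap = ensemble_mean_distance_map(ordered_fixture)
        with pytest.raises(ValueError, match="residues"):
            pae_distance_concordance(PAEMap(np.zeros((3, 3)), 3), dmap)


class TestPersistencyHistogram:
    def test_all_persistent_single_final_bin(self):
        ens = planted_persistency_ensemble([(0, 4, 1.0), (2, 8, 1.0)],
                                           n_members=6, seed=2)
        counts, edges = persistency_histogram(accumulate_rin(ens))
        assert counts[-1] == 2 and counts[:-1].sum() == 0

    def test_planted_bimodal(self):
        ens = planted_persistency_ensemble(
            [(0, 4, 0.1), (2, 8, 0.1), (6, 12, 0.9), (10, 16, 0.9)],
            n_members=10, seed=5, n_residues=20)
        counts, edges = persistency_histogram(accumulate_rin(ens), bins=10)
        occupied = np.flatnonzero(counts)
        assert list(occupied) == [1, 9]  # 0.1 -> [0.1, 0.2); 0.9 -> last bin
        assert counts.sum() == 4

    def test_counts_conserve_edges(self, disordered_fixture):
        rin = accumulate_rin(disordered_fixture)
        counts, _ = persistency_histogram(rin)
        assert counts.sum() == rin.n_edges


try:
    from hypothesis import given, settings, strategies as st

    @given(st.floats(min_value=0.5, max_value=8.0,
                     allow_nan=False, allow_infinity=False))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_contact_count_monotone_in_cutoff(cutoff):
        """Raising the cutoff never removes a contact."""
        model = build_model([[(1.7 * k, 0.3 * (k % 3), 0)]
                             for k in range(12)])
        dmap = residue_distance_map(model)
        small = contact_map(dmap, cutoff=cutoff)
        big = contact_map(dmap, cutoff=cutoff + 0.7)
        assert np.all(big.matrix >= small.matrix)
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_export_formats(tmp_path, disordered_fixture):
    import networkx as nx
    rin = accumulate_rin(disordered_fixture)
    rin.to_edge_tsv(tmp_path / "edges.tsv")
    rin.to_graphml(tmp_path / "rin.graphml")
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert len(lines) == rin.n_edges + 1
    g = nx.read_graphml(tmp_path / "rin.graphml")
    assert g.number_of_edges() == rin.n_edges
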