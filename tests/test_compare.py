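"""Cross-release analytics: growth accounting, profiles, cores, Venn counts."""

import warnings

import numpy as np
import pytest

from ppievo.compare import (
    core_overlap,
    growth_series,
    new_node_profile,
    proteome_coverage,
    source_overlap,
)
from ppievo.graph_model import (
    EdgeEvidence,
    ReferenceProteome,
    ReleaseSnapshot,
    snapshot_from_edges,
)
from ppievo.synthetic import EvolutionParams, simulate_series


def k4_snapshot(names, release_id):
    snap = ReleaseSnapshot(release_id=release_id)
    for i in range(4):
        for j in range(i + 1, 4):
            snap.add_edge(names[i], names[j], EdgeEvidence(pmids={"p"}))
    return snap


class TestGrowthSeries:
    def test_ppis_per_publication_is_exact_ratio(self):
        snap = ReleaseSnapshot(release_id="x")
        snap.add_edge("A", "B", EdgeEvidence(pmids={"1", "2"}))
        snap.add_edge("B", "C", EdgeEvidence(pmids={"2"}))
        snap.add_edge("C", "D", EdgeEvidence(pmids={"3"}))
        g = growth_series([snap])
        assert g.loc[0, "ppis_per_publication"] == 3 / 3
        assert g.loc[0, "single_publication_fraction"] == pytest.approx(2 / 3)

    def test_identical_releases_have_zero_percent_change(self):
        snap = k4_snapshot("ABCD", "r1")
        g = growth_series([snap, snap.copy()])
        for col in ("pct_n_nodes_prev", "pct_n_edges_prev", "pct_n_nodes_base"):
            assert g.loc[1, col] == 0.0

    def test_deltas_match_generator_truth_ledger(self):
        evo = EvolutionParams(n0=300, releases=4, blocks=2, seed=31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rels, truth = simulate_series(evo)
        g = growth_series(rels)
        for i in range(1, len(rels)):
            rel = rels[i].release_id
            assert g.loc[i, "n_nodes"] - g.loc[i - 1, "n_nodes"] == len(
                truth.added_nodes[rel]
            )
            assert g.loc[i, "n_edges"] - g.loc[i - 1, "n_edges"] == len(
                truth.added_edges[rel]
            )

    def test_no_evidence_yields_null_stats_with_warning(self):
        snap = snapshot_from_edges([("A", "B")], release_id="bare")
        with pytest.warns(UserWarning, match="publication"):
            g = growth_series([snap])
        assert g.loc[0, "n_publications"] is None

    def test_empty_release_list_errors(self):
        with pytest.raises(ValueError):
            growth_series([])


class TestNewNodeProfile:
    def test_identical_releases_empty_profile(self, triangle):
        prof = new_node_profile(triangle, triangle.copy())
        assert len(prof.nodes) == 0
        assert prof.n_new_hubs == 0

    def test_hand_counted_cumulative_fractions(self):
        older = snapshot_from_edges([("X", "Y")], release_id="old")
        newer = older.copy()
        newer.release_id = "new"
        degrees = {"A": 1, "B": 1, "C": 2, "D": 4, "E": 13}
        for node, d in degrees.items():
            for i in range(d):
                newer.add_edge(node, f"X{i:02d}" if node != "A" else "Y")
        # X0..X12 are also new; restrict to the 5 named arrivals via older set
        older_plus = older.copy()
        for i in range(13):
            older_plus.add_node(f"X{i:02d}")
        prof = new_node_profile(older_plus, newer)
        got = dict(zip(prof.nodes["node"], prof.nodes["degree"]))
        assert got == degrees
        assert prof.frac_le_4 == pytest.approx(0.8)
        assert prof.frac_le_12 == pytest.approx(0.8)
        assert prof.histogram["cum_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_matches_set_difference_oracle_on_synthetic_pair(self):
        evo = EvolutionParams(n0=250, releases=2, blocks=2, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (old, new), _ = simulate_series(evo)
        prof = new_node_profile(old, new)
        expect = sorted(new.nodes - old.nodes)
        deg = new.degrees()
        assert list(prof.nodes["node"]) == expect
        assert list(prof.nodes["degree"]) == [deg[n] for n in expect]

    def test_retracted_nodes_warn(self, triangle):
        smaller = snapshot_from_edges([("A", "B")], release_id="small")
        with pytest.warns(UserWarning, match="absent"):
            new_node_profile(triangle, smaller)


class TestCoreOverlap:
    def test_identical_releases_full_jaccard(self):
        a = k4_snapshot("ABCD", "r1")
        b = k4_snapshot("ABCD", "r2")
        rep = core_overlap([a, b])
        assert (rep.jaccard.to_numpy() == 1.0).all()
        assert rep.universal_intersection == {"A", "B", "C", "D"}

    def test_disjoint_cores(self):
        rep = core_overlap([k4_snapshot("ABCD", "r1"), k4_snapshot("EFGH", "r2")])
        assert rep.jaccard.loc["r1", "r2"] == 0.0
        assert rep.universal_intersection == set()

    def test_counts_match_set_intersection_oracle(self):
        from ppievo.metrics import core_decomposition

        evo = EvolutionParams(n0=200, releases=3, blocks=2, seed=19)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rels, _ = simulate_series(evo)
        rep = core_overlap(rels)
        cores = {r.release_id: core_decomposition(r).main_core for r in rels}
        for ri in cores:
            for rj in cores:
                assert rep.intersection_counts.loc[ri, rj] == len(
                    cores[ri] & cores[rj]
                )
                assert rep.intersection_counts.loc[ri, rj] <= min(
                    len(cores[ri]), len(cores[rj])
                )


class TestProteomeCoverage:
    def test_eight_of_ten_is_80_percent(self):
        snap = snapshot_from_edges(
            [(f"P{i}", f"P{i+1}") for i in range(0, 8, 2)], release_id="r"
        )
        prot = ReferenceProteome(
            entries={f"P{i}": "PE1" for i in range(8)} | {"Q1": "PE2", "Q2": "PE5"}
        )
        cov = proteome_coverage(snap, prot)
        assert cov.coverage_pct == pytest.approx(80.0)
        assert cov.n_with_ppi + cov.n_without_ppi == cov.proteome_size
        assert cov.without_ppi_by_pe == {
            "PE1": 0, "PE2": 1, "PE3": 0, "PE4": 0, "PE5": 1,
        }

    def test_all_network_nodes_pe5(self):
        snap = snapshot_from_edges([("A", "B")], release_id="r")
        prot = ReferenceProteome(entries={"A": "PE5", "B": "PE5", "C": "PE1"})
        cov = proteome_coverage(snap, prot)
        assert cov.network_pe_composition == {
            "PE1": 0, "PE2": 0, "PE3": 0, "PE4": 0, "PE5": 2,
        }

    def test_stray_network_nodes_warn(self):
        snap = snapshot_from_edges([("A", "Z")], release_id="r")
        prot = ReferenceProteome(entries={"A": "PE1"})
        with pytest.warns(UserWarning, match="absent"):
            cov = proteome_coverage(snap, prot)
        assert cov.network_nodes_not_in_proteome == 1

    def test_empty_proteome_errors(self, triangle):
        with pytest.raises(ValueError):
            proteome_coverage(triangle, ReferenceProteome())


class TestSourceOverlap:
    def test_single_source_single_region(self):
        snap = ReleaseSnapshot(release_id="r")
        for i in range(5):
            snap.add_edge(f"A{i}", f"B{i}", EdgeEvidence(pmids={"p"}, sources={"DB"}))
        venn = source_overlap(snap)
        assert venn[frozenset({"DB"})] == 5
        assert sum(venn.values()) == 5

    def test_three_sources_match_brute_force_enumeration(self, rng):
        snap = ReleaseSnapshot(release_id="r")
        labels = ["S1", "S2", "S3"]
        oracle: dict[frozenset, int] = {}
        for i in range(200):
            member = frozenset(
                lab for lab in labels if rng.random() < 0.5
            ) or frozenset({"S1"})
            snap.add_edge(
                f"A{i}", f"B{i}", EdgeEvidence(pmids={"p"}, sources=set(member))
            )
            oracle[member] = oracle.get(member, 0) + 1
        venn = source_overlap(snap)
        for region, count in oracle.items():
            assert venn[region] == count
        assert sum(venn.values()) == snap.n_edges

    def test_identical_source_sets_only_intersection_region(self):
        snap = ReleaseSnapshot(release_id="r")
        for i in range(4):
            snap.add_edge(
                f"A{i}", f"B{i}", EdgeEvidence(pmids={"p"}, sources={"X", "Y"})
            )
        venn = source_overlap(snap)
        assert venn[frozenset({"X", "Y"})] == 4
        assert venn[frozenset({"X"})] == 0
        assert venn[frozenset({"Y"})] == 0

    def test_unlabelled_edges_warn_and_conserve(self):
        snap = snapshot_from_edges([("A", "B"), ("C", "D")])
        with pytest.warns(UserWarning, match="unlabelled"):
            venn = source_overlap(snap)
        assert sum(venn.values()) == 2
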