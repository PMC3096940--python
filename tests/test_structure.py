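"""FST, AMOVA variance components, permutation tests, contiguity, SAMOVA."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from haplostat.seqio import HaplotypeTable, collapse_haplotypes
from haplostat.structure import (
    Partition,
    amova,
    amova_permutation_test,
    contiguity_graph,
    enumerate_contiguous_partitions,
    fst_matrix,
    hamming_matrix,
    hudson_fst,
    pairwise_differences,
    samova,
)
from haplostat.simulate import Deme, Locus, SimConfig, simulate_coalescent

from conftest import make_alignment, make_popmap


def table_from(seq_pop_pairs):
    """HaplotypeTable from [(sequence, population), ...]."""
    seqs = {f"s{i}": s for i, (s, _) in enumerate(seq_pop_pairs)}
    pm = make_popmap(
        {f"s{i}": (p, f"G_{p}") for i, (_, p) in enumerate(seq_pop_pairs)}
    )
    return collapse_haplotypes(make_alignment(seqs), pm), pm


class TestPairwiseDifferences:
    def test_manual_count(self):
        assert hamming_matrix(["AAAT", "AGTT"])[0, 1] == 2

    def test_symmetric_zero_diagonal_random(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(8)]
        d = hamming_matrix(seqs)
        assert (d == d.T).all() and (np.diag(d) == 0).all()

    def test_expanded_replicates_by_count(self):
        table, _ = table_from([("AAAA", "P1"), ("AAAA", "P1"), ("AAAT", "P2")])
        dm = pairwise_differences(table, expand=True)
        assert len(dm.labels) == 3
        assert dm.d.sum() == 4  # two 0-vs-1-difference pairs, both orders


class TestHudsonFst:
    def test_identical_populations_near_zero(self):
        # duplicate demes of n sequences give exactly -1/(n-1): the unbiased
        # within-pair mean slightly exceeds the cross mean, which includes
        # same-individual pairings
        rng = np.random.default_rng(1)
        a = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(10)]
        f = hudson_fst(a, list(a))
        assert f == pytest.approx(-1 / 9, abs=1e-12)
        assert abs(f) < 0.12

    def test_fixed_difference_no_within_variation(self):
        assert hudson_fst(["AAAA"] * 3, ["ATTT"] * 3) == pytest.approx(1.0)

    def test_identical_monomorphic_demes_undefined(self):
        assert np.isnan(hudson_fst(["AAAA"] * 3, ["AAAA"] * 3))

    def test_invariance_to_relabeling_and_duplication(self):
        rng = np.random.default_rng(3)
        a = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(4)]
        b = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(4)]
        f = hudson_fst(a, b)
        assert hudson_fst(b, a) == pytest.approx(f)
        # duplicating both demes rescales the within-pair mean by exactly
        # 2(n-1)/(2n-1) (duplicate pairs add zero distance), nothing else
        n = len(a)
        scale = 2 * (n - 1) / (2 * n - 1)
        assert hudson_fst(a * 2, b * 2) == pytest.approx(
            1 - scale * (1 - f), abs=1e-12
        )

    def test_group_matrix_modes(self, mimic):
        result, tables = mimic
        pooled = fst_matrix(tables["cp_like"], result.popmap, level="group")
        assert pooled.shape == (4, 4)
        iso = pooled.loc["Yushan"].drop("Yushan")
        rest = pooled.drop("Yushan").drop(columns="Yushan")
        assert iso.min() > np.nanmax(rest.values)


def independent_amova(seqs_by_pop, partition_of_pop):
    """First-principles AMOVA on expanded sequences (explicit loops)."""
    inds = [
        (seq, pop, partition_of_pop[pop])
        for pop, seqs in seqs_by_pop.items()
        for seq in seqs
    ]
    n_tot = len(inds)
    d2 = np.zeros((n_tot, n_tot))
    for i in range(n_tot):
        for j in range(n_tot):
            d2[i, j] = sum(a != b for a, b in zip(inds[i][0], inds[j][0]))
    pops = list(seqs_by_pop)
    groups = sorted(set(partition_of_pop.values()))

    def ssd(indices):
        if not indices:
            return 0.0
        return sum(d2[i, j] for i in indices for j in indices) / (2 * len(indices))

    everyone = range(n_tot)
    ssd_t = ssd(list(everyone))
    ssd_wp = sum(ssd([i for i in everyone if inds[i][1] == p]) for p in pops)
    ssd_wg = sum(ssd([i for i in everyone if inds[i][2] == g]) for g in groups)
    df_ag, df_ap, df_wp = len(groups) - 1, len(pops) - len(groups), n_tot - len(pops)
    n_p = {p: len(seqs_by_pop[p]) for p in pops}
    n_g = {g: sum(n_p[p] for p in pops if partition_of_pop[p] == g) for g in groups}
    sg_over = sum(
        sum(n_p[p] ** 2 for p in pops if partition_of_pop[p] == g) / n_g[g]
        for g in groups
    )
    n1 = (n_tot - sg_over) / df_ap
    n2 = (sg_over - sum(v**2 for v in n_p.values()) / n_tot) / df_ag
    n3 = (n_tot - sum(v**2 for v in n_g.values()) / n_tot) / df_ag
    sigma_c = (ssd_wp) / df_wp
    sigma_b = ((ssd_wg - ssd_wp) / df_ap - sigma_c) / n1
    sigma_a = ((ssd_t - ssd_wg) / df_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    def test_identical_populations_all_zero_among(self):
        table, pm = table_from([("AAAA", "P1")] * 3 + [("AAAA", "P2")] * 3)
        r = amova(table, pm, {"P1": 0, "P2": 1})
        assert r.sigma_a == 0 and r.sigma_b == 0 and r.sigma_c == 0

    def test_three_population_toy_matches_hand_oracle(self):
        seqs_by_pop = {
            "P1": ["AAAAAA", "AAAAAT", "AAAAAA"],
            "P2": ["AATTAA", "AATTAT"],
            "P3": ["TTTTTT", "TTTTTA", "TTTTTT", "TTTATT"],
        }
        part = {"P1": 0, "P2": 0, "P3": 1}
        table, pm = table_from(
            [(s, p) for p, seqs in seqs_by_pop.items() for s in seqs]
        )
        r = amova(table, pm, part)
        sa, sb, sc = independent_amova(seqs_by_pop, part)
        assert r.sigma_a == pytest.approx(sa, abs=1e-10)
        assert r.sigma_b == pytest.approx(sb, abs=1e-10)
        assert r.sigma_c == pytest.approx(sc, abs=1e-10)

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pairs = []
            for p in range(4):
                for _ in range(int(rng.integers(2, 6))):
                    pairs.append(("".join(rng.choice(list("ACGT"), 15)), f"P{p}"))
            table, pm = table_from(pairs)
            r = amova(table, pm, {"P0": 0, "P1": 0, "P2": 1, "P3": 1})
            assert sum(r.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_partition_must_cover_all_populations(self):
        table, pm = table_from([("AAAA", "P1")] * 2 + [("AAAT", "P2")] * 2)
        with pytest.raises(ValueError, match="cover"):
            amova(table, pm, {"P1": 0})


@pytest.fixture(scope="module")
def structured():
    # 4 demes in 2 isolated groups; strong structure
    mig = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j and (i < 2) == (j < 2):
                mig[i, j] = 5.0
    cfg = SimConfig(
        demes=[Deme(f"P{i}", "A" if i < 2 else "B", 6, lat=float(i), lon=0.0)
               for i in range(4)],
        loci=[Locus("l", 500)],
        theta_per_locus=5.0,
        migration=mig,
        split_time=2.0,
    )
    res = simulate_coalescent(cfg, seed=42)
    return collapse_haplotypes(res.alignments["l"], res.popmap), res.popmap


class TestPermutations:

    def test_strong_structure_small_p(self, structured):
        # individuals permuted among populations: Phi_ST strongly significant
        table, pm = structured
        r = amova_permutation_test(
            table, pm, {"P0": 0, "P1": 0, "P2": 1, "P3": 1}, n_perm=999, seed=0
        )
        assert r.p_values["phi_st"] <= 0.01

    def test_group_permutation_significant_with_many_populations(self, mimic):
        # 14 populations leave C(14,3) = 364 distinct 3-11 groupings, so the
        # isolated group can reach p << 0.05 under whole-population permutation
        result, tables = mimic
        truth = result.truth["true_partition"]
        r = amova_permutation_test(
            tables["cp_like"], result.popmap, dict(truth), n_perm=999, seed=2
        )
        assert r.p_values["phi_ct"] <= 0.05
        assert r.p_values["phi_st"] <= 0.01

    def test_degenerate_space_flagged(self):
        table, pm = table_from([("AAAA", "P1")] * 2 + [("AAAT", "P2")] * 2)
        r = amova_permutation_test(table, pm, {"P1": 0, "P2": 1}, n_perm=19, seed=1)
        assert r.p_values["degenerate"] == 1.0

    def test_p_values_bounded(self, structured):
        table, pm = structured
        r = amova_permutation_test(
            table, pm, {"P0": 0, "P1": 0, "P2": 1, "P3": 1}, n_perm=99, seed=5
        )
        for key in ("phi_ct", "phi_sc", "phi_st"):
            assert 1 / 100 <= r.p_values[key] <= 1.0


class TestContiguity:
    def test_three_points_complete(self):
        pm = make_popmap(
            {"a": ("P1", "G"), "b": ("P2", "G"), "c": ("P3", "G")},
            coords={"P1": (0, 0), "P2": (0, 1), "P3": (1, 0)},
        )
        g = contiguity_graph(pm)
        assert g.number_of_edges() == 3

    def test_four_convex_points_five_edges(self):
        pm = make_popmap(
            {f"s{i}": (f"P{i}", "G") for i in range(4)},
            coords={"P0": (0, 0), "P1": (0, 1), "P2": (1, 1), "P3": (1, 0)},
        )
        g = contiguity_graph(pm)
        assert g.number_of_edges() == 5  # 4 hull edges + 1 diagonal

    def test_collinear_fallback_chain(self):
        pm = make_popmap(
            {f"s{i}": (f"P{i}", "G") for i in range(4)},
            coords={f"P{i}": (0.0, float(i)) for i in range(4)},
        )
        g = contiguity_graph(pm)
        assert nx.is_connected(g)
        assert g.number_of_edges() == 3

    def test_duplicate_coordinates_jittered(self):
        pm = make_popmap(
            {"a": ("P1", "G"), "b": ("P2", "G"), "c": ("P3", "G")},
            coords={"P1": (0, 0), "P2": (0, 0), "P3": (1, 0)},
        )
        g = contiguity_graph(pm)
        assert nx.is_connected(g)

    def test_study_design_coordinates_connected(self, mimic):
        result, _ = mimic
        g = contiguity_graph(result.popmap)
        assert nx.is_connected(g)
        assert set(g.nodes) == set(result.popmap.populations)


class TestSamova:
    def test_two_populations_unique_partition(self):
        table, pm = table_from(
            [("AAAA", "P1"), ("AAAT", "P1"), ("TTTT", "P2"), ("TTTA", "P2")]
        )
        r = samova(table, pm, 2, n_runs=3, n_iter=50, seed=0)
        direct = amova(table, pm, r.partition)
        assert r.f_ct == pytest.approx(direct.phi_ct, abs=1e-12)
        assert r.partition.k == 2

    def test_k_out_of_range(self):
        table, pm = table_from([("AAAA", "P1")] * 2 + [("AAAT", "P2")] * 2)
        with pytest.raises(ValueError, match="outside"):
            samova(table, pm, 3)

    def test_disconnected_graph_rejected(self):
        table, pm = table_from(
            [("AAAA", "P1"), ("AAAT", "P1"), ("TTTT", "P2"), ("TTTA", "P2")]
        )
        g = nx.Graph()
        g.add_nodes_from(["P1", "P2"])
        with pytest.raises(ValueError, match="disconnected"):
            samova(table, pm, 2, graph=g)

    def test_reported_fct_equals_amova_recomputation(self, mimic):
        result, tables = mimic
        r = samova(tables["cp_like"], result.popmap, 2, n_runs=5, n_iter=500, seed=1)
        assert r.f_ct == pytest.approx(
            amova(tables["cp_like"], result.popmap, r.partition).phi_ct, abs=1e-12
        )

    def test_attains_exhaustive_optimum_small_problems(self):
        mig = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j and (i < 3) == (j < 3):
                    mig[i, j] = 5.0
        demes = [
            Deme(f"P{i + 1}", "A" if i < 3 else "B", 5,
                 lat=float(i < 3), lon=float(i % 3))
            for i in range(6)
        ]
        cfg = SimConfig(demes=demes, loci=[Locus("l", 600)], theta_per_locus=5.0,
                        migration=mig, split_time=1.0)
        for seed in range(5):
            res = simulate_coalescent(cfg, seed=seed)
            tab = collapse_haplotypes(res.alignments["l"], res.popmap)
            g = contiguity_graph(res.popmap)
            parts = enumerate_contiguous_partitions(g, list(tab.populations), 2)
            best = max(amova(tab, res.popmap, p).phi_ct for p in parts)
            r = samova(tab, res.popmap, 2, n_runs=50, n_iter=300, seed=seed, graph=g)
            assert r.f_ct == pytest.approx(best, abs=1e-9)

    def test_true_grouping_beats_random_on_isolated_fixture(self, mimic):
        result, tables = mimic
        table = tables["cp_like"]
        true = Partition(result.truth["true_partition"])
        f_true = amova(table, result.popmap, true).phi_ct
        rng = np.random.default_rng(0)
        pops = list(table.populations)
        worse = 0
        for _ in range(20):
            labels = np.zeros(len(pops), dtype=int)
            labels[rng.choice(len(pops), size=3, replace=False)] = 0
            labels = np.ones(len(pops), dtype=int)
            labels[rng.choice(len(pops), size=3, replace=False)] = 0
            rand = Partition(dict(zip(pops, (int(x) for x in labels))))
            worse += amova(table, result.popmap, rand).phi_ct < f_true
        assert worse >= 19
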