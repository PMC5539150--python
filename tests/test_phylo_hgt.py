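import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from luxcassette.io_formats import Alignment, TipMetadata
from luxcassette.phylo_hgt import (
    DistanceMatrix,
    PhyloError,
    bootstrap_support,
    classify_transfer_mode,
    detect_hgt,
    neighbor_joining,
    nj_builder,
    protein_distance,
)
from luxcassette.synthetic_data import HgtEvent, SyntheticScenario, evolve_on_tree
from luxcassette.tree import PhyloTree, robinson_foulds


def random_tree_newick(rng, n_tips, low=0.1, high=1.0):
    frags = [f"t{i:02d}:{rng.uniform(low, high):.6f}" for i in range(n_tips)]
    while len(frags) > 2:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        frags.append(f"({a},{b}):{rng.uniform(low, high):.6f}")
    return f"({frags[0]},{frags[1]});"


class TestProteinDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b", "c"], ["MKLV", "MKLV", "MKLV"])
        dm = protein_distance(aln)
        assert np.all(dm.d == 0)

    def test_closed_form_p_and_poisson(self):
        a = "AAAAAAAAAA"
        b = "CCCCCAAAAA"
        aln = Alignment(["a", "b", "c"], [a, b, a])
        p = protein_distance(aln, "p")
        assert p.d[0, 1] == pytest.approx(0.5)
        poisson = protein_distance(aln, "poisson")
        assert poisson.d[0, 1] == pytest.approx(-math.log(0.5))

    def test_gap_columns_excluded(self):
        aln = Alignment(["a", "b", "c"], ["MK-V", "MKL-", "MKLV"])
        dm = protein_distance(aln, "p")
        # a vs b compare columns 1,2 only -> 0 mismatches
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_names_pair(self):
        aln = Alignment(["a", "b", "c"], ["M-", "-K", "MK"])
        with pytest.raises(PhyloError, match="'a' and 'b'"):
            protein_distance(aln)

    def test_matches_column_scan_oracle(self, rng):
        letters = list("ARND-")
        for _ in range(5):
            n, L = 5, 40
            rows = ["".join(rng.choice(letters, size=L)) for _ in range(n)]
            rows = [r if set(r) != {"-"} else "A" * L for r in rows]
            aln = Alignment([f"s{i}" for i in range(n)], rows)
            try:
                dm = protein_distance(aln, "p")
            except PhyloError:
                continue
            for i in range(n):
                for j in range(i + 1, n):
                    comp = [
                        (x, y)
                        for x, y in zip(rows[i], rows[j])
                        if x != "-" and y != "-"
                    ]
                    expected = sum(x != y for x, y in comp) / len(comp)
                    assert dm.d[i, j] == pytest.approx(expected)

    def test_saturated_poisson_flagged(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "CCCC", "AACC"])
        dm = protein_distance(aln, "poisson")
        assert ("a", "b") in dm.saturated
        assert math.isinf(dm.d[0, 1])
        with pytest.raises(PhyloError, match="non-finite"):
            neighbor_joining(dm)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        _, pat = tree.tip_distance_matrix()
        ids = tree.tip_distance_matrix()[0]
        i = {name: k for k, name in enumerate(ids)}
        assert pat[i["A"], i["B"]] == pytest.approx(0.3)
        assert pat[i["A"], i["C"]] == pytest.approx(0.5)
        assert pat[i["B"], i["C"]] == pytest.approx(0.6)

    def test_additive_matrices_recover_topology(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 11))
            truth = PhyloTree.from_newick(random_tree_newick(rng, n))
            ids, d = truth.tip_distance_matrix()
            nj = neighbor_joining(DistanceMatrix(tuple(ids), d))
            assert robinson_foulds(nj, truth) == 0

    def test_agrees_with_skbio_on_additive_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj

        truth = PhyloTree.from_newick(random_tree_newick(rng, 8))
        ids, d = truth.tip_distance_matrix()
        mine = neighbor_joining(DistanceMatrix(tuple(ids), d))
        sk_tree = sk_nj(skbio.DistanceMatrix(d, ids))
        other = PhyloTree.from_newick(str(sk_tree))
        assert robinson_foulds(mine, other) == 0

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        assert neighbor_joining(dm).to_newick() == neighbor_joining(dm).to_newick()

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(PhyloError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), d)

    def test_negative_branches_clamped_and_flagged(self):
        # strongly non-additive matrix forces a negative NJ branch estimate
        d = np.array(
            [[0, 1.0, 1.0, 5.0],
             [1.0, 0, 1.0, 1.0],
             [1.0, 1.0, 0, 1.0],
             [5.0, 1.0, 1.0, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
        assert tree.clamped_negative_branches > 0


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert robinson_foulds(t, t.copy()) == 0

    def test_conflicting_quartets(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2

    def test_tip_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        t2 = PhyloTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="tip sets"):
            robinson_foulds(t1, t2)

    def test_matches_dendropy_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 10))
            nwk1 = random_tree_newick(rng, n)
            nwk2 = random_tree_newick(rng, n)
            mine = robinson_foulds(
                PhyloTree.from_newick(nwk1), PhyloTree.from_newick(nwk2)
            )
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=nwk1, schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=nwk2, schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert mine == treecompare.symmetric_difference(d1, d2)


class TestBootstrap:
    def test_strong_split_gets_high_support(self):
        sim = evolve_on_tree(SyntheticScenario(seed=2))
        tree = bootstrap_support(sim.alignments["16S"], nj_builder("p"),
                                 n_reps=100, seed=7)
        gp = frozenset(t for t in tree.tip_names if t.startswith("gp"))
        supports = tree.bipartition_supports()
        anchor = min(tree.tip_names)
        key = gp if anchor not in gp else frozenset(tree.tip_names) - gp
        assert key in supports
        assert supports[key] >= 95

    def test_single_replicate_supports_binary(self):
        sim = evolve_on_tree(SyntheticScenario(seed=2))
        tree = bootstrap_support(sim.alignments["16S"], nj_builder("p"),
                                 n_reps=1, seed=7)
        values = [s for _, s in tree.internal_clades() if s is not None]
        assert values and all(v in (0.0, 100.0) for v in values)

    def test_seed_reproducible_bit_for_bit(self):
        sim = evolve_on_tree(SyntheticScenario(seed=2))
        t1 = bootstrap_support(sim.alignments["luxI"], nj_builder("p"), 50, seed=9)
        t2 = bootstrap_support(sim.alignments["luxI"], nj_builder("p"), 50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_invalid_rep_count(self):
        sim = evolve_on_tree(SyntheticScenario(seed=2))
        with pytest.raises(PhyloError):
            bootstrap_support(sim.alignments["luxI"], n_reps=0)


def _trees_for(sim, genes=("luxI", "16S"), reps=100, seed=0):
    builder = nj_builder("poisson")
    return {
        g: bootstrap_support(sim.alignments[g], builder, reps, seed=seed + i)
        for i, g in enumerate(genes)
    }


class TestDetectHgt:
    def test_planted_transfer_recovered(self):
        sim = evolve_on_tree(
            SyntheticScenario(seed=5, hgt_events=(HgtEvent(genes="luxI"),))
        )
        trees = _trees_for(sim)
        calls = detect_hgt(trees["luxI"], trees["16S"], sim.metadata)
        planted = sim.truth["events"][0]["tip"]
        supported = [c for c in calls if c.verdict == "hgt_supported"]
        assert any(planted in c.clade_tips for c in supported)
        # the planted pair shares a niche by construction
        smallest = min(
            (c for c in supported if planted in c.clade_tips),
            key=lambda c: len(c.clade_tips),
        )
        assert smallest.niche_match

    def test_congruent_monophyletic_trees_give_no_supported_calls(self):
        sim = evolve_on_tree(SyntheticScenario(seed=6))
        trees = _trees_for(sim)
        calls = detect_hgt(trees["luxI"], trees["16S"], sim.metadata)
        assert not [c for c in calls if c.verdict == "hgt_supported"]

    def test_no_shared_tips_rejected(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        t2 = PhyloTree.from_newick("((x:1,y:1):1,z:1);")
        meta = {}
        with pytest.raises(PhyloError, match="share no tips"):
            detect_hgt(t1, t2, meta)

    def test_metadata_must_cover_shared_tips(self):
        t = PhyloTree.from_newick("((a:1,b:1)90:1,(c:1,d:1)90:1);")
        meta = {"a": TipMetadata("a", "positive")}
        with pytest.raises(PhyloError, match="metadata missing"):
            detect_hgt(t, t.copy(), meta)


class TestTransferMode:
    def test_both_gene_event_simultaneous(self):
        sim = evolve_on_tree(
            SyntheticScenario(seed=8, hgt_events=(HgtEvent(genes="both"),))
        )
        trees = _trees_for(sim, genes=("luxI", "luxR", "concat"))
        planted = sim.truth["events"][0]["tip"]
        donor = sim.truth["events"][0]["donor"]
        (mode,) = classify_transfer_mode(
            trees["luxI"], trees["luxR"], trees["concat"],
            {"cas1": planted}, sim.metadata,
        )
        assert mode.mode == "simultaneous"
        assert mode.partner_luxi == donor

    def test_single_gene_event_individual(self):
        sim = evolve_on_tree(
            SyntheticScenario(seed=9, hgt_events=(HgtEvent(genes="luxI"),))
        )
        trees = _trees_for(sim, genes=("luxI", "luxR", "concat"))
        planted = sim.truth["events"][0]["tip"]
        (mode,) = classify_transfer_mode(
            trees["luxI"], trees["luxR"], trees["concat"],
            {"cas1": planted}, sim.metadata,
        )
        assert mode.mode == "individual"
        assert mode.partner_luxi == sim.truth["events"][0]["donor"]
        assert mode.partner_luxi != mode.partner_luxr

    def test_absent_cassette_unclear_with_reason(self):
        sim = evolve_on_tree(SyntheticScenario(seed=8))
        trees = _trees_for(sim, genes=("luxI", "luxR", "concat"))
        (mode,) = classify_transfer_mode(
            trees["luxI"], trees["luxR"], trees["concat"],
            {"cas1": "not_a_tip"}, sim.metadata,
        )
        assert mode.mode == "unclear"
        assert "absent" in mode.reason
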