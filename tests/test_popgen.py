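"""Haplotype collapsing, networks, TN93, PhiST and Tajima's D."""
import numpy as np
import pandas as pd
import pytest

from chemotaxa import popgen, synthetic
from chemotaxa.synthetic import ScenarioConfig


def _aln(seqs: dict[str, str]) -> popgen.Alignment:
    return popgen.Alignment(list(seqs), list(seqs.values()))


class TestAlignment:
    def test_fasta_round_trip(self, tmp_path):
        aln = _aln({"a": "ACGT", "b": "ACGA"})
        path = tmp_path / "x.fasta"
        aln.to_fasta(path)
        back = popgen.Alignment.from_fasta(path)
        assert back.ids == aln.ids and back.seqs == aln.seqs

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            _aln({"a": "ACGT", "b": "ACG"})

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            _aln({"a": "ACXT"})


class TestCollapse:
    def test_all_identical_one_haplotype(self):
        aln = _aln({f"s{i}": "ACGTACGT" for i in range(5)})
        hs = popgen.collapse_haplotypes(aln)
        assert hs.n_haplotypes == 1
        assert hs.counts()["H1"] == 5

    def test_duplicate_changes_counts_not_list(self):
        base = {"a": "ACGT", "b": "ACGA", "c": "AGGA"}
        hs1 = popgen.collapse_haplotypes(_aln(base))
        hs2 = popgen.collapse_haplotypes(_aln({**base, "d": "ACGT"}))
        assert hs1.n_haplotypes == hs2.n_haplotypes == 3
        assert hs2.counts().sum() == 4

    def test_ambiguous_columns_excluded(self):
        # column with N is ignored, making a and b identical
        aln = _aln({"a": "ACGT", "b": "ACGN", "c": "TCGT"})
        hs = popgen.collapse_haplotypes(aln)
        assert hs.n_haplotypes == 2
        assert len(hs.sites) == 3

    def test_generator_fixed_snps_without_theta(self):
        cfg = ScenarioConfig(seed=3, theta=0.0, fixed_snps_between_species=16,
                             n_colonies_per_chemotype=10)
        aln, popmap = synthetic.gen_coi_alignment(cfg)
        hs = popgen.collapse_haplotypes(aln, popmap)
        assert hs.n_haplotypes == 2
        d = popgen.hamming_matrix(hs)
        assert d.loc["H1", "H2"] == 16

    def test_labels_by_decreasing_frequency(self):
        aln = _aln({"a": "AAAA", "b": "TTTT", "c": "TTTT", "d": "TTTT"})
        hs = popgen.collapse_haplotypes(aln)
        assert hs.members["H1"] == ["b", "c", "d"]


class TestHaplotypeNetwork:
    def test_two_haplotypes_one_edge(self):
        aln = _aln({"a": "AAAA", "b": "AATT"})
        hs = popgen.collapse_haplotypes(aln)
        net = popgen.haplotype_network(hs)
        assert net.mst_edges == [("H1", "H2", 2)]

    def test_star_topology(self):
        center = "AAAAAA"
        seqs = {"c1": center, "c2": center}
        for i, pos in enumerate(range(4)):
            s = list(center)
            s[pos] = "T"
            seqs[f"tip{i}"] = "".join(s)
        net = popgen.haplotype_network(popgen.collapse_haplotypes(_aln(seqs)))
        degrees = dict(net.graph.degree)
        assert degrees["H1"] == 4  # the shared central haplotype
        assert all(w == 1 for _, _, w in net.mst_edges)

    def test_max_link_disconnects_distant_clades(self):
        aln = _aln({"a": "AAAAAA", "b": "AAAAAT", "c": "TTTTTA", "d": "TTTTTT"})
        hs = popgen.collapse_haplotypes(aln)
        net = popgen.haplotype_network(hs, max_link=2)
        import networkx as nx

        assert nx.number_connected_components(net.graph) == 2


class TestTamuraNei:
    def test_identical_sequences_zero(self):
        d, und = popgen.tamura_nei_distance(_aln({"a": "ACGT" * 10, "b": "ACGT" * 10}))
        assert d.data[0, 1] == 0.0 and not und

    def test_reduces_to_jukes_cantor_in_symmetric_limit(self):
        # equal base composition, one transversion on a long sequence
        L = 100000
        core = "ACGT" * (L // 4)
        mutated = "T" + core[1:]  # A->T transversion at site 0
        d, _ = popgen.tamura_nei_distance(_aln({"a": core, "b": mutated}))
        p = 1.0 / L
        jc = -0.75 * np.log(1 - 4.0 * p / 3.0)
        assert d.data[0, 1] == pytest.approx(jc, abs=1e-6)

    def test_single_transition_matches_direct_formula(self):
        L = 100
        core = "ACGT" * 25
        mutated = "G" + core[1:]  # A->G transition at site 0
        d, _ = popgen.tamura_nei_distance(_aln({"a": core, "b": mutated}))
        # direct evaluation: pooled frequencies over both sequences
        gA, gC, gG, gT = 49 / 200, 50 / 200, 51 / 200, 50 / 200
        gR, gY = gA + gG, gC + gT
        P1, Q = 1 / 100, 0.0
        k1 = 2 * gA * gG / gR
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        expected = -k1 * np.log(1 - P1 / k1 - Q / (2 * gR))
        assert d.data[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_distance_at_least_p_distance(self):
        rng = np.random.default_rng(0)
        L = 400
        anc = rng.choice(list("ACGT"), size=L)
        seqs = {}
        for i in range(5):
            s = anc.copy()
            pos = rng.choice(L, size=10, replace=False)
            for q in pos:
                s[q] = rng.choice([b for b in "ACGT" if b != s[q]])
            seqs[f"s{i}"] = "".join(s)
        aln = _aln(seqs)
        d, _ = popgen.tamura_nei_distance(aln)
        arr = aln.char_array()
        for i in range(5):
            for j in range(i + 1, 5):
                p_dist = (arr[i] != arr[j]).mean()
                if np.isfinite(d.data[i, j]):
                    assert d.data[i, j] >= p_dist - 1e-12

    def test_saturated_pair_flagged(self):
        d, und = popgen.tamura_nei_distance(_aln({"a": "A" * 40, "b": "C" * 40}))
        assert np.isnan(d.data[0, 1])
        assert ("a", "b") in und


class TestPhiST:
    def test_fixed_difference_gives_one(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAA", "b1": "TTAA", "b2": "TTAA"})
        pm = pd.DataFrame({"population": ["p1", "p1", "p2", "p2"]}, index=aln.ids)
        fst, _ = popgen.pairwise_fst(aln, pm, n_perm=9, seed=0)
        assert fst.loc["p1", "p2"] == pytest.approx(1.0)

    def test_identical_composition_nonpositive(self):
        seqs = {"a1": "AAAT", "a2": "TTTT", "b1": "AAAT", "b2": "TTTT"}
        pm = pd.DataFrame({"population": ["p1", "p1", "p2", "p2"]}, index=list(seqs))
        fst, _ = popgen.pairwise_fst(_aln(seqs), pm, n_perm=9, seed=0)
        assert fst.loc["p1", "p2"] <= 0.0

    def test_null_split_centred_on_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for s in range(100):
            cfg = ScenarioConfig(seed=s, migration=1.0, n_colonies_per_chemotype=20)
            aln, popmap = synthetic.gen_coi_alignment(cfg)
            ids = [i for i in aln.ids if popmap.loc[i, "species"] == "A"]
            fst, _ = popgen.pairwise_fst(aln.subset(ids), popmap.loc[ids],
                                         n_perm=1, seed=s)
            off = fst.values[np.triu_indices(len(fst), 1)]
            if np.isfinite(off).any():
                vals.append(np.nanmean(off))
        assert abs(np.mean(vals)) < 0.05

    def test_small_population_gets_no_p(self):
        aln = _aln({"a1": "AAAA", "a2": "AATA", "b1": "TTAA"})
        pm = pd.DataFrame({"population": ["p1", "p1", "p2"]}, index=aln.ids)
        fst, pv = popgen.pairwise_fst(aln, pm, n_perm=9, seed=0)
        assert np.isfinite(fst.loc["p1", "p2"])
        assert np.isnan(pv.loc["p1", "p2"])

    def test_p_invariant_to_haplotype_relabeling(self):
        seqs = {"a1": "AAAA", "a2": "AAAT", "b1": "TTAA", "b2": "TTAT"}
        pm = pd.DataFrame({"population": ["p1", "p1", "p2", "p2"]}, index=list(seqs))
        f1, p1 = popgen.pairwise_fst(_aln(seqs), pm, n_perm=99, seed=5)
        swapped = {k: v.translate(str.maketrans("AT", "TA")) for k, v in seqs.items()}
        f2, p2 = popgen.pairwise_fst(_aln(swapped), pm, n_perm=99, seed=5)
        assert f1.loc["p1", "p2"] == pytest.approx(f2.loc["p1", "p2"])
        assert p1.loc["p1", "p2"] == p2.loc["p1", "p2"]


TOY_SEQS = {
    "s1": "AAAAAAAAAA",
    "s2": "AAAAAAAAAT",
    "s3": "AAAAAATTAT",
    "s4": "AAAATTTTAT",
    "s5": "AATTTTTTAT",
}


class TestTajimasD:
    def test_toy_alignment_matches_direct_formula(self):
        """Independent evaluation of the closed form on the toy alignment."""
        aln = _aln(TOY_SEQS)
        res = popgen.tajimas_d(aln)
        # direct formula, written out independently
        n, S = 5, 7
        pairs = [(a, b) for i, a in enumerate(aln.seqs) for b in aln.seqs[i + 1:]]
        pi = np.mean([sum(x != y for x, y in zip(a, b)) for a, b in pairs])
        a1 = 1 + 1 / 2 + 1 / 3 + 1 / 4
        a2 = 1 + 1 / 4 + 1 / 9 + 1 / 16
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert res["D"] == pytest.approx(expected, abs=1e-10)
        assert res["S"] == S and res["pi"] == pytest.approx(pi)

    def test_matches_dendropy(self):
        import dendropy
        from dendropy.calculate import popgenstat

        res = popgen.tajimas_d(_aln(TOY_SEQS))
        cm = dendropy.DnaCharacterMatrix.from_dict(TOY_SEQS)
        assert res["D"] == pytest.approx(popgenstat.tajimas_d(cm), abs=1e-10)

    def test_constructed_zero_numerator(self):
        # n=4: 8 singleton sites + 3 half-half sites -> pi = S/a1 exactly
        sites = []
        for k in range(8):
            col = ["A"] * 4
            col[k % 4] = "T"
            sites.append(col)
        for _ in range(3):
            sites.append(["T", "T", "A", "A"])
        seqs = {f"s{i}": "".join(site[i] for site in sites) for i in range(4)}
        res = popgen.tajimas_d(_aln(seqs))
        assert res["D"] == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites_is_explicit(self):
        with pytest.raises(ValueError, match="no segregating sites"):
            popgen.tajimas_d(_aln({f"s{i}": "ACGT" for i in range(5)}))

    def test_neutral_generator_mean_near_zero(self):
        ds = []
        for seed in range(60):
            cfg = ScenarioConfig(seed=seed, migration=1.0, theta=5.0,
                                 n_colonies_per_chemotype=30)
            aln, popmap = synthetic.gen_coi_alignment(cfg)
            ids = [i for i in aln.ids if popmap.loc[i, "species"] == "A"]
            try:
                ds.append(popgen.tajimas_d(aln.subset(ids))["D"])
            except ValueError:
                pass
        assert -0.3 <= np.mean(ds) <= 0.1

    def test_distance_matrices_symmetric_zero_diagonal(self):
        cfg = ScenarioConfig(seed=5, n_colonies_per_chemotype=8)
        aln, _ = synthetic.gen_coi_alignment(cfg)
        d, _ = popgen.tamura_nei_distance(aln)
        assert np.allclose(np.diag(d.data), 0.0)
        assert np.allclose(d.data, d.data.T, equal_nan=True)
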