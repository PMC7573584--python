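import itertools

import dendropy
import numpy as np
import pytest

import wingmorph as wm
from wingmorph.phylo import (SequenceAlignment, SubstitutionModel,
                             jc_distance_matrix, model_test, trim_alignment)
from wingmorph.trees import _bipartitions


def two_leaf_tree(t_a, t_b):
    ns = dendropy.TaxonNamespace(["a", "b"])
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    for label, t in (("a", t_a), ("b", t_b)):
        node = dendropy.Node(taxon=ns.get_taxon(label))
        node.edge.length = t
        tree.seed_node.add_child(node)
    return tree


def quartet_tree(lengths):
    """Unrooted 4-taxon tree AB|CD with named branch lengths."""
    tree = wm.parse_newick(
        "((A:{a},B:{b}):{i},C:{c},D:{d});".format(**lengths))
    return tree


def enumeration_log_likelihood(tree, aln, model):
    """Exhaustive oracle: sum over all internal-node state assignments."""
    rates = model.category_rates() if model.gamma else np.ones(1)
    pi = model.base_freqs
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    leaves = {nd.taxon.label: nd for nd in nodes if nd.is_leaf()}
    row = {lab: i for i, lab in enumerate(aln.labels)}
    total = 0.0
    for site in range(aln.length):
        site_lik = 0.0
        for rate in rates:
            P = {nd: model.transition_matrix(
                max(nd.edge.length or 0.0, 0.0) * rate)
                for nd in nodes if nd.parent_node is not None}
            lik = 0.0
            for states in itertools.product(range(4),
                                            repeat=len(internal)):
                assign = dict(zip(internal, states))
                prob = pi[assign[nodes[-1]]]
                for nd in nodes:
                    if nd.parent_node is None:
                        continue
                    parent_state = assign[nd.parent_node]
                    if nd.is_leaf():
                        code = aln.codes[row[nd.taxon.label], site]
                        if code == 4:
                            prob *= 1.0
                        else:
                            prob *= P[nd][parent_state, code]
                    else:
                        prob *= P[nd][parent_state, assign[nd]]
                lik += prob
            site_lik += lik / len(rates)
        total += np.log(site_lik)
    return total


class TestAlignment:
    def test_fasta_round_trip(self, tmp_path):
        aln = SequenceAlignment.from_pairs(
            [("x", "ACGT-N"), ("y", "TTGCAA")])
        path = tmp_path / "aln.fasta"
        aln.write_fasta(path)
        back = SequenceAlignment.read_fasta(path)
        assert back.labels == aln.labels
        # N and '-' both code as fully ambiguous and re-read as gaps
        np.testing.assert_array_equal(back.codes, aln.codes)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            SequenceAlignment.from_pairs([("x", "ACG"), ("y", "ACGT")])

    def test_base_frequencies_ignore_gaps(self):
        aln = SequenceAlignment.from_pairs([("x", "AAC-"), ("y", "GGNN")])
        np.testing.assert_allclose(aln.base_frequencies(),
                                   [2 / 5, 1 / 5, 2 / 5, 0])


class TestTrim:
    def test_trims_to_first_columns(self):
        aln = SequenceAlignment.from_pairs([("x", "ACGTACGT"),
                                            ("y", "TGCATGCA")])
        out = trim_alignment(aln, 5)
        assert out.length == 5
        np.testing.assert_array_equal(out.codes, aln.codes[:, :5])

    def test_idempotent_at_target_length(self):
        aln = SequenceAlignment.from_pairs([("x", "ACGTA"), ("y", "TGCAT")])
        out = trim_alignment(aln, 5)
        np.testing.assert_array_equal(out.codes, aln.codes)

    def test_short_alignment_rejected(self):
        aln = SequenceAlignment.from_pairs([("x", "ACG"), ("y", "TGC")])
        with pytest.raises(ValueError, match="shorter"):
            trim_alignment(aln, 550)


class TestModels:
    def test_base_frequency_validation(self):
        with pytest.raises(ValueError, match="unknown model"):
            SubstitutionModel(family="GTR")
        with pytest.raises(ValueError, match="positive"):
            SubstitutionModel(family="HKY85",
                              base_freqs=[0.5, 0.5, 0.0, 0.0])

    def test_rate_matrix_is_a_normalized_reversible_generator(self):
        m = SubstitutionModel(family="HKY85", kappa=4.0,
                              base_freqs=[0.3, 0.2, 0.3, 0.2])
        Q = m.rate_matrix()
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(-m.base_freqs @ np.diag(Q), 1.0)
        detail = m.base_freqs[:, None] * Q
        np.testing.assert_allclose(detail, detail.T, atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 7.0, 40.0])
    def test_gamma_category_rates_average_to_one(self, alpha):
        m = SubstitutionModel(family="JC69", gamma=True, alpha=alpha)
        rates = m.category_rates()
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(rates) > 0)

    def test_transition_matrix_rows_are_distributions(self):
        m = SubstitutionModel(family="HKY85", kappa=3.0,
                              base_freqs=[0.4, 0.1, 0.2, 0.3])
        for t in (0.0, 0.1, 5.0):
            P = m.transition_matrix(t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= 0)


class TestLikelihood:
    def test_identical_sequences_zero_branches(self):
        aln = SequenceAlignment.from_pairs([("a", "ACGT"), ("b", "ACGT")])
        lnl = wm.log_likelihood(two_leaf_tree(0.0, 0.0), aln,
                                SubstitutionModel(family="JC69"))
        assert lnl == pytest.approx(4 * np.log(0.25), abs=1e-10)

    def test_jc_pairwise_closed_form(self):
        aln = SequenceAlignment.from_pairs(
            [("a", "ACGTACGTAC"), ("b", "ACGTACGAAC")])
        t = 0.1
        lnl = wm.log_likelihood(two_leaf_tree(t / 2, t / 2), aln,
                                SubstitutionModel(family="JC69"))
        match = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3)))
        mismatch = np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3)))
        assert lnl == pytest.approx(9 * match + mismatch, abs=1e-10)

    def test_hky_with_unit_kappa_equals_jc(self, rng):
        tree = wm.random_binary_tree(list("ABCDE"), rng)
        aln = wm.simulate_sequences(tree, SubstitutionModel(family="JC69"),
                                    length=100, seed=1)
        jc = wm.log_likelihood(tree, aln, SubstitutionModel(family="JC69"))
        hky = wm.log_likelihood(tree, aln,
                                SubstitutionModel(family="HKY85", kappa=1.0))
        assert hky == pytest.approx(jc, abs=1e-10)

    @pytest.mark.parametrize("gamma", [False, True])
    def test_pruning_equals_exhaustive_enumeration(self, gamma):
        aln = SequenceAlignment.from_pairs(
            [("A", "ACGT"), ("B", "AAG-"), ("C", "CCGT"), ("D", "ACTT")])
        tree = quartet_tree(dict(a=0.1, b=0.25, c=0.4, d=0.05, i=0.15))
        model = SubstitutionModel(family="HKY85", kappa=2.5,
                                  base_freqs=[0.35, 0.15, 0.25, 0.25],
                                  gamma=gamma, alpha=0.6)
        assert wm.log_likelihood(tree, aln, model) == pytest.approx(
            enumeration_log_likelihood(tree, aln, model), abs=1e-10)

    def test_invariant_under_rerooting(self, rng):
        tree = wm.random_binary_tree(list("ABCDEF"), rng)
        model = SubstitutionModel(family="HKY85", kappa=3.0,
                                  base_freqs=[0.3, 0.2, 0.2, 0.3],
                                  gamma=True, alpha=0.8)
        aln = wm.simulate_sequences(tree, model, length=80, seed=5)
        lnl = wm.log_likelihood(tree, aln, model)
        other = tree.clone(depth=1)
        edge = [nd.edge for nd in other.preorder_node_iter()
                if nd.is_leaf()][2]
        other.reroot_at_edge(edge, length1=edge.length / 2,
                             length2=edge.length / 2)
        assert wm.log_likelihood(other, aln, model) == pytest.approx(
            lnl, abs=1e-8)

    def test_all_gap_columns_contribute_nothing(self, rng):
        tree = wm.random_binary_tree(list("ABCD"), rng)
        model = SubstitutionModel(family="JC69")
        aln = wm.simulate_sequences(tree, model, length=60, seed=2)
        padded = SequenceAlignment(
            list(aln.labels),
            np.hstack([aln.codes, np.full((4, 10), 4, dtype=np.uint8)]))
        assert wm.log_likelihood(tree, padded, model) == pytest.approx(
            wm.log_likelihood(tree, aln, model), abs=1e-9)

    def test_taxon_mismatch_rejected(self, rng):
        tree = wm.random_binary_tree(list("ABC"), rng)
        aln = SequenceAlignment.from_pairs([("A", "AC"), ("X", "GT"),
                                            ("C", "AA")])
        with pytest.raises(ValueError, match="differ"):
            wm.log_likelihood(tree, aln, SubstitutionModel(family="JC69"))


@pytest.fixture(scope="module")
def jc_alignment():
    tree = wm.random_binary_tree([f"t{i}" for i in range(8)],
                                 np.random.default_rng(3),
                                 edge_range=(0.05, 0.3))
    return wm.simulate_sequences(tree, SubstitutionModel(family="JC69"),
                                 length=400, seed=4)


class TestModelTest:
    def test_table_contract_and_aic_formula(self, jc_alignment):
        table, fits = model_test(jc_alignment, rounds=1)
        assert len(table) == 6
        assert list(table["aic"]) == sorted(table["aic"])
        for _, row in table.iterrows():
            assert row["aic"] == pytest.approx(
                2 * row["n_parameters"] - 2 * row["log_likelihood"],
                abs=1e-9)
        for name, fit in fits.items():
            assert fit.aic == pytest.approx(
                2 * fit.n_parameters - 2 * fit.log_likelihood, abs=1e-9)

    def test_jc_data_prefers_jc_over_hky_gamma(self, jc_alignment):
        table, _ = model_test(jc_alignment, rounds=1)
        aic = dict(zip(table["model"], table["aic"]))
        assert min(aic["JC69"], aic["JC69+G"]) < aic["HKY85+G"]


class TestMlSearch:
    def test_improves_on_nj_start_and_is_deterministic(self, rng):
        tree = wm.random_binary_tree([f"t{i}" for i in range(6)], rng,
                                     edge_range=(0.05, 0.3))
        model = SubstitutionModel(family="HKY85", kappa=3.0, gamma=False)
        aln = wm.simulate_sequences(tree, model, length=300, seed=6)
        nj_tree = wm.neighbor_joining(jc_distance_matrix(aln))
        nj_lnl = wm.log_likelihood(nj_tree, aln, model)
        fit1 = wm.ml_search(aln, model)
        fit2 = wm.ml_search(aln, model)
        assert fit1.log_likelihood >= nj_lnl - 1e-9
        assert fit1.log_likelihood == fit2.log_likelihood
        assert wm.write_newick(fit1.tree) == wm.write_newick(fit2.tree)

    def test_recovers_long_internal_branch_quartet(self):
        truth = quartet_tree(dict(a=0.05, b=0.05, c=0.05, d=0.05, i=0.3))
        model = SubstitutionModel(family="HKY85", kappa=3.0,
                                  gamma=True, alpha=0.5)
        aln = wm.simulate_sequences(truth, model, length=550, seed=7)
        fit = wm.ml_search(aln, model)
        assert set(_bipartitions(fit.tree)) == set(_bipartitions(truth))


class TestBootstrapMl:
    def test_identical_sequences_degenerate_but_defined(self):
        aln = SequenceAlignment.from_pairs(
            [(lab, "ACGTACGTAAGG") for lab in "ABCDE"])
        model = SubstitutionModel(family="JC69")
        tree = wm.bootstrap_ml(aln, model, n_reps=5, seed=1)
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == \
            set("ABCDE")

    def test_seed_determinism(self):
        truth = quartet_tree(dict(a=0.1, b=0.1, c=0.1, d=0.1, i=0.2))
        model = SubstitutionModel(family="JC69")
        aln = wm.simulate_sequences(truth, model, length=200, seed=9)
        t1 = wm.bootstrap_ml(aln, model, n_reps=10, seed=3)
        t2 = wm.bootstrap_ml(aln, model, n_reps=10, seed=3)
        assert wm.write_newick(t1) == wm.write_newick(t2)

    def test_strong_signal_supports_true_split(self):
        truth = quartet_tree(dict(a=0.15, b=0.15, c=0.15, d=0.15, i=0.3))
        model = SubstitutionModel(family="JC69")
        aln = wm.simulate_sequences(truth, model, length=550, seed=11)
        tree = wm.bootstrap_ml(aln, model, n_reps=30, seed=4)
        supports = {key: float(nd.label)
                    for key, nd in _bipartitions(tree).items()}
        assert supports[frozenset({"C", "D"})] >= 70.0
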