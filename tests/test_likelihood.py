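"""Pruning likelihood against exhaustive enumeration; BIC selection."""

import itertools

import numpy as np
import pytest

from aasubst import (
    Alignment,
    CandidateSpec,
    RateHeterogeneity,
    SimulationSpec,
    TreeSpec,
    apply_invariant,
    build_generator,
    discrete_gamma,
    fit_heterogeneity,
    log_likelihood,
    parse_newick,
    random_tree,
    select_model,
    simulate_alignment,
    site_pattern_compress,
    transition_probabilities,
)
from aasubst.likelihood import MISSING, _pattern_log_likelihoods

from conftest import rand_models


def brute_force_lnl(alignment, tree, model, het):
    """Sum over every assignment of states to internal nodes (tiny cases)."""
    gen = build_generator(model, scale=True)
    s = gen.n
    index = {sym: i for i, sym in enumerate(gen.alphabet)}
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf()]
    root = tree.tree.seed_node
    n_sites = alignment.n_sites

    lnl = 0.0
    for site in range(n_sites):
        leaf_state = {name: index.get(seq[site], MISSING)
                      for name, seq in alignment.sequences.items()}
        site_lik = 0.0
        for rate, prob in zip(het.category_rates, het.category_probs):
            Ps = {id(n): transition_probabilities(gen, rate * (n.edge.length or 0.0))
                  for n in nodes if n is not root}
            lik = 0.0
            for assignment in itertools.product(range(s), repeat=len(internals)):
                state = {id(n): a for n, a in zip(internals, assignment)}
                for n in nodes:
                    if n.is_leaf():
                        state[id(n)] = leaf_state[n.taxon.label]
                contrib = gen.pi[state[id(root)]]
                for n in nodes:
                    if n is root:
                        continue
                    child_state = state[id(n)]
                    parent_state = state[id(n.parent_node)]
                    if child_state == MISSING:
                        contrib *= 1.0  # missing data: marginalized at leaf
                    else:
                        contrib *= Ps[id(n)][parent_state, child_state]
                # Leaves with missing data contribute a factor 1 for every
                # parent state, which the line above already encodes.
                lik += contrib
            site_lik += prob * lik
        lnl += np.log(site_lik)
    return lnl


@pytest.fixture(scope="module")
def small_instance():
    model = rand_models(1, seed=3, n=4)[0]
    tree = random_tree(TreeSpec(n_taxa=4, seed=8, brlen_mean=0.3))
    spec = SimulationSpec(model=model, tree=tree, root_sequence="equilibrium",
                          length=30, replicates=1, seed=4)
    return model, tree, simulate_alignment(spec)[0]


class TestPatternCompression:
    def test_identical_columns_collapse(self):
        aln = Alignment({"a": "AAAA", "b": "RRRR"})
        patterns, counts, taxa = site_pattern_compress(aln, ("A", "R"))
        assert patterns.shape == (1, 2)
        assert counts.tolist() == [4]

    def test_matches_dictionary_grouping(self, small_instance):
        model, tree, aln = small_instance
        patterns, counts, taxa = site_pattern_compress(aln, model.alphabet)
        assert counts.sum() == aln.n_sites
        # Brute-force grouping oracle.
        cols = list(zip(*aln.sequences.values()))
        expected = {}
        for col in cols:
            expected[col] = expected.get(col, 0) + 1
        assert len(expected) == len(counts)
        # First-occurrence order.
        seen = list(dict.fromkeys(cols))
        got = ["".join(model.alphabet[s] for s in row) for row in patterns]
        assert got == ["".join(c) for c in seen]

    def test_compressed_equals_uncompressed_likelihood(self, small_instance):
        model, tree, aln = small_instance
        gen = build_generator(model)
        het = discrete_gamma(0.5, 4)
        patterns, counts, taxa = site_pattern_compress(aln, gen.alphabet)
        compressed = float(counts @ _pattern_log_likelihoods(
            patterns, taxa, tree, gen, het))
        coded = np.array([[gen.alphabet.index(c) for c in aln.sequences[t]]
                          for t in taxa])
        uncompressed = float(_pattern_log_likelihoods(
            coded.T.copy(), taxa, tree, gen, het).sum())
        assert compressed == pytest.approx(uncompressed, abs=1e-10)


class TestPruningCorrectness:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        """Pruning equals summation over all internal-state assignments on
        random instances with <= 5 taxa and <= 4 states."""
        n_taxa = 3 + seed % 3
        n_states = 3 + seed % 2
        model = rand_models(1, seed=seed, n=n_states)[0]
        tree = random_tree(TreeSpec(n_taxa=n_taxa, seed=seed + 50, brlen_mean=0.4))
        spec = SimulationSpec(model=model, tree=tree, root_sequence="equilibrium",
                              length=12, replicates=1, seed=seed)
        aln = simulate_alignment(spec)[0]
        het = discrete_gamma(0.6, 3) if seed % 2 else RateHeterogeneity.homogeneous()
        assert log_likelihood(aln, tree, model, het) == pytest.approx(
            brute_force_lnl(aln, tree, model, het), abs=1e-10
        )

    def test_enumeration_with_invariant_class(self, small_instance):
        model, tree, aln = small_instance
        het = apply_invariant(discrete_gamma(0.8, 2), 0.3)
        assert log_likelihood(aln, tree, model, het) == pytest.approx(
            brute_force_lnl(aln, tree, model, het), abs=1e-10
        )

    def test_single_leaf_no_evolution(self):
        """Degenerate one-leaf tree at t = 0: lnL = sum log f[x]."""
        model = rand_models(1, seed=2, n=4)[0]
        tree = parse_newick("(A:0);")
        seq = "".join(np.random.default_rng(0).choice(list(model.alphabet), 40))
        lnl = log_likelihood(Alignment({"A": seq}), tree, model)
        f = dict(zip(model.alphabet, model.f))
        assert lnl == pytest.approx(sum(np.log(f[c]) for c in seq), abs=1e-10)

    def test_reroot_invariance(self):
        """Reversibility pulley principle: the same unrooted tree rooted on
        two different edges gives identical likelihoods."""
        model = rand_models(1, seed=6, n=20)[0]
        t1 = parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);")
        t2 = parse_newick("(A:0.02,(B:0.2,(C:0.3,D:0.15):0.12):0.08);")
        spec = SimulationSpec(model=model, tree=t1, root_sequence="equilibrium",
                              length=100, replicates=1, seed=3)
        aln = simulate_alignment(spec)[0]
        for het in (RateHeterogeneity.homogeneous(), discrete_gamma(0.5, 4)):
            assert log_likelihood(aln, t1, model, het) == pytest.approx(
                log_likelihood(aln, t2, model, het), abs=1e-9
            )

    def test_gaps_treated_as_missing(self, small_instance):
        """All-gap columns contribute lnL 0 (partial likelihood 1)."""
        model, tree, aln = small_instance
        base = log_likelihood(aln, tree, model)
        padded = Alignment({k: v + "--" for k, v in aln.sequences.items()})
        assert log_likelihood(padded, tree, model) == pytest.approx(base, abs=1e-9)

    def test_taxa_mismatch_rejected(self, small_instance):
        model, tree, aln = small_instance
        renamed = Alignment({(k + "x"): v for k, v in aln.sequences.items()})
        with pytest.raises(ValueError, match="mismatch"):
            log_likelihood(renamed, tree, model)

    def test_no_underflow_large_problem(self):
        """200 taxa x 1000 sites with short branches stays finite."""
        model = rand_models(1, seed=1)[0]
        tree = random_tree(TreeSpec(n_taxa=200, seed=4, brlen_mean=0.02))
        spec = SimulationSpec(model=model, tree=tree, root_sequence="equilibrium",
                              length=1000, replicates=1, seed=2)
        aln = simulate_alignment(spec)[0]
        assert np.isfinite(log_likelihood(aln, tree, model))

    def test_generating_model_beats_distant_model(self):
        """Seeded regression: the data-generating matrix has higher lnL than
        an unrelated random matrix on the same data."""
        gen_model, other = rand_models(2, seed=40)
        tree = random_tree(TreeSpec(n_taxa=12, seed=12, brlen_mean=0.15))
        spec = SimulationSpec(model=gen_model, tree=tree,
                              root_sequence="equilibrium", length=500,
                              replicates=1, seed=8)
        aln = simulate_alignment(spec)[0]
        assert log_likelihood(aln, tree, gen_model) > log_likelihood(aln, tree, other)


@pytest.fixture(scope="module")
def sim16():
    model = rand_models(1, seed=21)[0]
    model.name = "A"
    tree = random_tree(TreeSpec(n_taxa=16, seed=16, brlen_mean=0.1))
    spec = SimulationSpec(model=model, tree=tree, het=discrete_gamma(0.5, 4),
                          root_sequence="equilibrium", length=1000,
                          replicates=1, seed=33)
    return model, tree, simulate_alignment(spec)[0]


class TestFitAndSelect:
    def test_plain_candidate_no_optimization(self, sim16):
        model, tree, aln = sim16
        fit = fit_heterogeneity(aln, tree, CandidateSpec(model=model))
        assert fit.alpha is None and fit.p_inv is None
        assert fit.lnL == pytest.approx(log_likelihood(aln, tree, model), abs=1e-9)

    def test_alpha_recovery(self, sim16):
        model, tree, aln = sim16
        fit = fit_heterogeneity(aln, tree, CandidateSpec(model=model, use_gamma=True))
        assert 0.35 <= fit.alpha <= 0.70
        assert fit.converged

    def test_homogeneous_data_pushes_alpha_to_boundary(self):
        model = rand_models(1, seed=22)[0]
        tree = random_tree(TreeSpec(n_taxa=16, seed=17, brlen_mean=0.1))
        spec = SimulationSpec(model=model, tree=tree, root_sequence="equilibrium",
                              length=1000, replicates=1, seed=34)
        aln = simulate_alignment(spec)[0]
        fit = fit_heterogeneity(aln, tree, CandidateSpec(model=model, use_gamma=True))
        assert fit.alpha >= 10.0

    def test_selection_ranks_generating_model_first(self, sim16):
        model, tree, aln = sim16
        other = rand_models(1, seed=55)[0]
        other.name = "B"
        candidates = [
            CandidateSpec(model=model),
            CandidateSpec(model=model, use_gamma=True),
            CandidateSpec(model=other),
            CandidateSpec(model=other, use_gamma=True),
        ]
        result = select_model(aln, tree, candidates)
        assert result.best.name == "A+G"
        # BIC formula identity for every candidate.
        for fit in result.fits:
            assert fit.bic == pytest.approx(
                -2 * fit.lnL + fit.kpar * np.log(aln.n_sites), abs=1e-9
            )
        df = result.to_dataframe()
        assert list(df["rank"]) == [1, 2, 3, 4]
        assert df["BIC"].is_monotonic_increasing

    def test_identical_candidates_tie_broken_deterministically(self, sim16):
        model, tree, aln = sim16
        twin = model.copy(name="A2")
        result = select_model(aln, tree, [CandidateSpec(model=model),
                                          CandidateSpec(model=twin)])
        assert result.fits[0].bic == pytest.approx(result.fits[1].bic, abs=1e-9)
        assert [f.name for f in result.fits] == ["A", "A2"]

    def test_too_few_candidates_rejected(self, sim16):
        model, tree, aln = sim16
        with pytest.raises(ValueError):
            select_model(aln, tree, [CandidateSpec(model=model)])
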