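"""phylo: trees, likelihoods (scipy-expm oracle), search, SH test."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import gammainc

from g2lhe import gtr, phylo
from g2lhe.phylo import (
    Alignment,
    LikelihoodModel,
    Tree,
    best_tree_under_constraint,
    is_monophyletic,
    jc_model,
    load_paml_matrix,
    neighbor_joining,
    optimize_branch_lengths,
    prune_hotspots,
    read_fasta_alignment,
    rf_distance,
    sh_test,
    site_loglik,
    total_loglik,
)
from g2lhe.synthetic import SimModel, simulate_alignment

from conftest import stable_seed

NT = {c: i for i, c in enumerate("ACGT")}


def aln_of(rows: dict) -> Alignment:
    taxa = list(rows)
    mat = np.array([[NT.get(c, -1) for c in rows[t]] for t in taxa], dtype=np.int8)
    return Alignment(taxa=taxa, matrix=mat)


# --- trees ------------------------------------------------------------------

def test_newick_round_trip():
    nwk = "((A:0.1,B:0.2):0.05,C:0.3,D:0.15);"
    t = Tree.from_newick(nwk)
    assert sorted(t.leaf_labels()) == ["A", "B", "C", "D"]
    t2 = Tree.from_newick(t.to_newick())
    assert rf_distance(t, t2) == 0


def test_bipartitions_known_tree():
    t = Tree.from_newick("((A,B),(C,D),(E,F));")
    bips = t.bipartitions()
    assert frozenset("AB") in bips and frozenset("EF") in bips
    assert len(bips) == 3


def test_is_monophyletic():
    nwk = "((A,B),(C,D),E);"
    assert is_monophyletic(nwk, {"A", "B"})
    assert is_monophyletic(nwk, {"C", "D", "E"})  # complement of {A,B}
    assert not is_monophyletic(nwk, {"A", "C"})
    with pytest.raises(ValueError):
        is_monophyletic(nwk, {"A", "Z"})
    with pytest.raises(ValueError):
        is_monophyletic(nwk, {"A"})


def test_rf_distance_examples_and_dendropy_oracle():
    assert rf_distance("((A,B),(C,D),E);", "((A,B),(C,D),E);") == 0
    assert rf_distance("((A,B),(C,D),E);", "((A,C),(B,D),E);") == 4
    with pytest.raises(ValueError):
        rf_distance("((A,B),C);", "((A,B),D);")
    # random-tree oracle against dendropy's symmetric difference
    import dendropy
    from dendropy.calculate import treecompare
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(8)])
    rng0 = np.random.default_rng(stable_seed("rf-oracle"))
    import random as _random
    for rep in range(5):
        r = _random.Random(int(rng0.integers(2**31)))
        t1 = treesim.birth_death_tree(1.0, 0.0, taxon_namespace=taxa, rng=r,
                                      num_extant_tips=8)
        t2 = treesim.birth_death_tree(1.0, 0.0, taxon_namespace=taxa, rng=r,
                                      num_extant_tips=8)
        for t in (t1, t2):
            t.is_rooted = False
            t.collapse_basal_bifurcation()
        want = treecompare.symmetric_difference(t1, t2)
        kw = dict(schema="newick", suppress_rooting=True)
        got = rf_distance(t1.as_string(**kw).strip(), t2.as_string(**kw).strip())
        assert got == want


def test_prune_hotspots():
    aln = aln_of({"A": "ACGTACGTAC", "B": "ACGTACGTAC"})
    core = prune_hotspots(aln, [("h1", (2, 4)), ("h2", (4, 5))])
    assert core.n_sites == 6
    assert core.taxa == aln.taxa
    assert core.matrix.tolist() == aln.matrix[:, [0, 5, 6, 7, 8, 9]].tolist()
    with pytest.raises(ValueError):
        prune_hotspots(aln, [("bad", (0, 3))])


# --- likelihood: closed-form and expm oracles --------------------------------

def test_jc_two_taxon_closed_form():
    aln = aln_of({"A": "AAAACCCCGG", "B": "AAAACCCCGT"})  # 9 match, 1 diff
    t1, t2 = 0.07, 0.05
    ll = total_loglik(aln, f"(A:{t1},B:{t2});", jc_model())
    d = t1 + t2
    p_same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
    p_diff = 0.25 - 0.25 * np.exp(-4.0 * d / 3.0)
    expect = 9 * np.log(0.25 * p_same) + 1 * np.log(0.25 * p_diff)
    assert ll == pytest.approx(expect, abs=1e-10)


def test_mixture_rates_against_scipy():
    # Yang's discrete-gamma category means, jointly normalized with the
    # invariant class, recomputed from the regularized incomplete gamma
    shape, p_inv, k = 0.7, 0.15, 4
    m = LikelihoodModel((1.0,) * 6, (0.25,) * 4, gamma_shape=shape,
                        p_invariant=p_inv, n_categories=k)
    _f, _s, rates, weights = m.machinery()
    from scipy.stats import gamma as gamma_dist

    bounds = gamma_dist.ppf(np.arange(k + 1) / k, shape, scale=1.0 / shape)
    means = k * (gammainc(shape + 1, shape * bounds[1:])
                 - gammainc(shape + 1, shape * bounds[:-1]))
    want_rates = np.concatenate([[0.0], means / (1.0 - p_inv)])
    want_weights = np.concatenate([[p_inv], np.full(k, (1 - p_inv) / k)])
    assert np.allclose(np.sort(rates), np.sort(want_rates), atol=1e-10)
    assert np.allclose(weights.sum(), 1.0)
    assert np.allclose(np.sort(weights), np.sort(want_weights), atol=1e-12)
    # mixture mean rate is exactly 1
    assert float(np.dot(rates, weights)) == pytest.approx(1.0, abs=1e-12)


def _oracle_Q(exch, freqs):
    """Independent GTR generator: Q_ij = s_ij pi_j, mean rate 1."""
    S = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for s, (i, j) in zip(exch, pairs):
        S[i, j] = S[j, i] = s
    Q = S * freqs[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(freqs, np.diag(Q)))
    return Q / mu


def test_site_loglik_against_expm_enumeration():
    # 4-taxon tree, non-uniform GTR + invariant + gamma; site likelihoods
    # recomputed by explicit summation over internal states with scipy expm
    exch = np.array([1.0, 2.5, 0.8, 1.3, 3.1, 1.0])
    freqs = np.array([0.33, 0.21, 0.27, 0.19])
    model = LikelihoodModel(tuple(exch), tuple(freqs), gamma_shape=0.9,
                            p_invariant=0.1, n_categories=4)
    _f, _spec, rates, weights = model.machinery()
    tA, tB, tU, tC, tD = 0.11, 0.23, 0.08, 0.31, 0.05
    tree = f"(A:{tA},B:{tB},(C:{tC},D:{tD}):{tU});"

    rng = np.random.default_rng(stable_seed("ll-oracle"))
    sites = rng.integers(0, 4, size=(4, 60)).astype(np.int8)
    sites[0, 5] = -1  # one gap cell
    aln = Alignment(taxa=["A", "B", "C", "D"], matrix=sites)

    Q = _oracle_Q(exch, freqs)
    # mixture mean rate is 1, but the invariant class rescales Q's clock:
    # category k uses P(t * rate_k)
    got = site_loglik(aln, tree, model)
    for s in range(60):
        a, b, c, d = sites[:, s]
        lik = 0.0
        for rate, w in zip(rates, weights):
            P = {t: expm(Q * t * rate) for t in (tA, tB, tU, tC, tD)}
            Lk = 0.0
            for r in range(4):
                pa = P[tA][r].sum() if a < 0 else P[tA][r, a]
                pb = P[tB][r, b]
                inner = 0.0
                for u in range(4):
                    inner += P[tU][r, u] * P[tC][u, c] * P[tD][u, d]
                Lk += freqs[r] * pa * pb * inner
            lik += w * Lk
        assert got[s] == pytest.approx(np.log(lik), abs=1e-9)


def test_rerooting_invariance():
    aln = aln_of({"A": "ACGTTGCAGT", "B": "ACGTTGCAAT",
                  "C": "ACGATGCAGT", "D": "TCGATGCAGT"})
    m = LikelihoodModel((1.0, 2.0, 1.0, 1.0, 2.0, 1.0), (0.3, 0.2, 0.3, 0.2))
    # same unrooted tree, internal edge attached on either side
    l1 = total_loglik(aln, "((A:0.1,B:0.2):0.25,C:0.3,D:0.15);", m)
    l2 = total_loglik(aln, "(A:0.1,B:0.2,(C:0.3,D:0.15):0.25);", m)
    assert l1 == pytest.approx(l2, abs=1e-10)


def test_negative_branch_rejected():
    aln = aln_of({"A": "ACGT", "B": "ACGT"})
    with pytest.raises(ValueError):
        total_loglik(aln, "(A:0.1,B:-0.2);", jc_model())


# --- optimization and search -------------------------------------------------

@pytest.fixture(scope="module")
def sim6():
    truth = ("((A:0.12,B:0.08):0.15,(C:0.1,(D:0.09,E:0.11):0.13):0.07,"
             "F:0.2);")
    fa = simulate_alignment(truth, SimModel(), 1200, seed=stable_seed("phylo-sim6"))
    return truth, read_fasta_alignment(fa)


def test_optimize_branch_lengths_improves(sim6):
    truth, aln = sim6
    m = jc_model()
    start = Tree.from_newick(truth)
    for e in start.edges():
        e.length = 0.5  # badly perturbed start
    ll0 = total_loglik(aln, start, m)
    opt, ll1 = optimize_branch_lengths(aln, start, m)
    assert ll1 > ll0
    # optimized lengths land near truth
    want = {frozenset(b): None for b in Tree.from_newick(truth).bipartitions()}
    assert total_loglik(aln, opt, m) == pytest.approx(ll1, abs=1e-6)
    truth_ll = total_loglik(aln, truth, m)
    assert ll1 >= truth_ll - 1e-6  # at least as good as the generator values


def test_exhaustive_search_recovers_quartet():
    fa = simulate_alignment("((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);",
                            SimModel(), 800, seed=stable_seed("quartet"))
    aln = read_fasta_alignment(fa)
    best, ll = best_tree_under_constraint(aln, jc_model(), search="exhaustive")
    assert rf_distance(best, "((A,B),(C,D));") == 0
    # constraining a false clade can only cost likelihood
    worse, ll_c = best_tree_under_constraint(aln, jc_model(),
                                             taxon_set={"A", "C"},
                                             search="exhaustive")
    assert is_monophyletic(worse, {"A", "C"})
    assert ll_c <= ll
    # a constraint the ML tree already satisfies changes nothing
    same, ll_s = best_tree_under_constraint(aln, jc_model(),
                                            taxon_set={"A", "B"},
                                            search="exhaustive")
    assert ll_s == pytest.approx(ll, abs=1e-9)


def test_nni_search_recovers_truth(sim6):
    truth, aln = sim6
    best, _ll = best_tree_under_constraint(aln, jc_model(), search="nni")
    assert rf_distance(best, truth) == 0


def test_neighbor_joining_additive_matrix():
    # additive distances on ((A,B),(C,D)) with internal edge 0.3
    names = ["A", "B", "C", "D"]
    D = np.array([
        [0.0, 0.2, 0.8, 0.9],
        [0.2, 0.0, 0.8, 0.9],
        [0.8, 0.8, 0.0, 0.3],
        [0.9, 0.9, 0.3, 0.0],
    ])
    t = neighbor_joining(names, D)
    assert rf_distance(t, "((A,B),(C,D));") == 0


# --- SH test ------------------------------------------------------------------

def test_sh_test_basics():
    rng = np.random.default_rng(stable_seed("sh"))
    M = rng.normal(-1.0, 0.3, size=(3, 400))
    M[0] += 0.5  # topology 0 clearly best
    res = sh_test(M, n_replicates=2000, seed=5)
    assert res.best_index() == 0
    assert res.deltas[0] == 0.0
    assert res.p_values[0] == 1.0  # the best tree is never rejected
    assert ((0.0 <= res.p_values) & (res.p_values <= 1.0)).all()
    assert res.p_values[1] < 0.05 and res.p_values[2] < 0.05
    # determinism
    res2 = sh_test(M, n_replicates=2000, seed=5)
    assert np.array_equal(res.p_values, res2.p_values)
    with pytest.raises(ValueError):
        sh_test(M[0][np.newaxis])


def test_sh_test_identical_rows_not_rejected():
    rng = np.random.default_rng(stable_seed("sh-null"))
    row = rng.normal(-1.0, 0.3, size=500)
    res = sh_test(np.vstack([row, row]), n_replicates=1000, seed=3)
    assert (res.p_values == 1.0).all()


# --- protein mode -------------------------------------------------------------

def test_load_paml_matrix_and_protein_loglik(tmp_path):
    rows = []
    for i in range(1, 20):
        rows.append(" ".join(["1.0"] * i))
    rows.append(" ".join(["0.05"] * 20))
    p = tmp_path / "flat.dat"
    p.write_text("\n".join(rows) + "\n")
    m = load_paml_matrix(p)
    assert m.alphabet == "aa"
    assert np.allclose(m.frequencies, 0.05)
    fa = tmp_path / "prot.fasta"
    fa.write_text(">A\nLAGLIDADGL\n>B\nLAGLIDADGI\n")
    aln = read_fasta_alignment(fa, alphabet="aa")
    assert aln.n_states == 20
    # single rate category so the 20-state JC closed form applies
    flat = LikelihoodModel(m.exchangeabilities, m.frequencies,
                           n_categories=1, alphabet="aa")
    ll = total_loglik(aln, "(A:0.05,B:0.05);", flat)
    d = 0.1
    p_same = 1 / 20 + (19 / 20) * np.exp(-20.0 / 19.0 * d)
    p_diff = 1 / 20 - (1 / 20) * np.exp(-20.0 / 19.0 * d)
    expect = 9 * np.log(p_same / 20) + np.log(p_diff / 20)
    assert ll == pytest.approx(expect, abs=1e-10)
    short = tmp_path / "short.dat"
    short.write_text("1 2 3")
    with pytest.raises(ValueError):
        load_paml_matrix(short)


def test_read_fasta_alignment_missing_codes(tmp_path):
    fa = tmp_path / "n.fasta"
    fa.write_text(">A\nACGTN-\n>B\nACGTAC\n")
    aln = read_fasta_alignment(fa)
    assert aln.matrix[0].tolist() == [0, 1, 2, 3, -1, -1]
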