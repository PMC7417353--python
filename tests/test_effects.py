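"""Per-actor effect statistics against independent brute-force enumeration."""

import itertools

import numpy as np
import pytest

from groomnet.effects import (
    Covariate,
    EffectSpec,
    ModelSpec,
    SpecError,
    effect_statistic,
    evaluation_fn,
    parameter_names,
    rate_fn,
    target_statistics,
)

STRUCTURAL = [
    "outdegree", "reciprocity", "transitive_triplets", "three_cycles",
    "transitive_recip_triplets", "indegree_popularity",
    "indegree_popularity_sqrt",
    "outdegree_popularity_sqrt", "outdegree_activity_sqrt",
    "out_out_assortativity",
]
COVARIATE = ["cov_ego", "cov_alter", "cov_same", "cov_similarity",
             "same_cov_x_reciprocity"]


# ---------------------------------------------------------------------------
# Brute-force oracle: definition-level loops over adjacency lists
# ---------------------------------------------------------------------------

def oracle(name, i, x, v=None):
    n = len(x)
    out_i = [j for j in range(n) if x[i][j]]
    if name == "outdegree":
        return len(out_i)
    if name == "reciprocity":
        return sum(1 for j in out_i if x[j][i])
    if name == "transitive_triplets":
        total = 0
        for h in out_i:
            for j in range(n):
                if x[h][j] and x[i][j]:
                    total += 1
        return total
    if name == "three_cycles":
        total = 0
        for j in out_i:
            for h in range(n):
                if x[j][h] and x[h][i]:
                    total += 1
        return total
    if name == "transitive_recip_triplets":
        total = 0
        for j in out_i:
            if not x[j][i]:
                continue
            for h in out_i:
                if x[h][j]:
                    total += 1
        return total
    if name == "indegree_popularity":
        return sum(sum(x[h][j] for h in range(n)) for j in out_i)
    if name == "indegree_popularity_sqrt":
        return sum(np.sqrt(sum(x[h][j] for h in range(n))) for j in out_i)
    if name == "outdegree_popularity_sqrt":
        return sum(np.sqrt(sum(x[j])) for j in out_i)
    if name == "outdegree_activity_sqrt":
        return len(out_i) ** 1.5
    if name == "out_out_assortativity":
        return sum(np.sqrt(len(out_i)) * np.sqrt(sum(x[j])) for j in out_i)
    if name == "cov_ego":
        return v[i] * len(out_i)
    if name == "cov_alter":
        return sum(v[j] for j in out_i)
    if name == "cov_same":
        return sum(1 for j in out_i if v[j] == v[i])
    if name == "cov_similarity":
        rng_v = max(v) - min(v) or 1.0
        sims = [1 - abs(v[a] - v[b]) / rng_v
                for a in range(n) for b in range(n) if a != b]
        mean_sim = sum(sims) / len(sims)
        return sum(1 - abs(v[i] - v[j]) / rng_v - mean_sim for j in out_i)
    if name == "same_cov_x_reciprocity":
        return sum(1 for j in out_i if x[j][i] and v[j] == v[i])
    raise ValueError(name)


def implementation(name, i, x, v=None):
    eff = EffectSpec(name, covariate="v" if name in COVARIATE else None)
    covs = {"v": np.asarray(v, dtype=float)} if v is not None else None
    return effect_statistic(eff, i, np.asarray(x, dtype=float), covs)


def all_digraphs(n):
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product([0, 1], repeat=len(slots)):
        x = [[0] * n for _ in range(n)]
        for (i, j), b in zip(slots, bits):
            x[i][j] = b
        yield x


def random_digraph(n, density, rng):
    x = (rng.random((n, n)) < density).astype(int)
    np.fill_diagonal(x, 0)
    return x.tolist()


@pytest.mark.parametrize("n", [2, 3])
def test_oracle_equivalence_exhaustive_small(n):
    v = list(range(n))
    for x in all_digraphs(n):
        for i in range(n):
            for name in STRUCTURAL + COVARIATE:
                got = implementation(name, i, x, v)
                want = oracle(name, i, x, v)
                assert got == pytest.approx(want, abs=1e-10), (name, i, x)


def test_oracle_equivalence_exhaustive_four_nodes():
    """Every statistic matches enumeration on all 4096 4-node digraphs."""
    v = [0.0, 1.0, 1.0, 2.5]
    for x in all_digraphs(4):
        for i in range(4):
            for name in STRUCTURAL + COVARIATE:
                got = implementation(name, i, x, v)
                want = oracle(name, i, x, v)
                assert got == pytest.approx(want, abs=1e-10), (name, i, x)


@pytest.mark.parametrize("n,count,density", [(5, 500, 0.4), (12, 200, 0.25)])
def test_oracle_equivalence_random_graphs(n, count, density, rng):
    v = rng.integers(0, 3, size=n).astype(float).tolist()
    for _ in range(count):
        x = random_digraph(n, density, rng)
        i = int(rng.integers(n))
        for name in STRUCTURAL + COVARIATE:
            got = implementation(name, i, x, v)
            want = oracle(name, i, x, v)
            assert got == pytest.approx(want, abs=1e-9), (name, i)


def test_worked_examples():
    # x = {A->B, B->A, A->C}
    x = np.zeros((3, 3))
    x[0, 1] = x[1, 0] = x[0, 2] = 1
    assert implementation("reciprocity", 0, x) == 1
    assert implementation("outdegree", 0, x) == 2
    # x = {A->B, B->C, A->C}: transitive triplet closed at A only
    y = np.zeros((3, 3))
    y[0, 1] = y[1, 2] = y[0, 2] = 1
    assert implementation("transitive_triplets", 0, y) == 1
    assert implementation("transitive_triplets", 1, y) == 0


def test_empty_network_all_statistics_zero():
    x = np.zeros((4, 4))
    v = [1.0, 2.0, 3.0, 4.0]
    for name in STRUCTURAL + COVARIATE:
        assert implementation(name, 2, x, v) == 0.0


def test_permutation_equivariance(rng):
    n = 8
    x = np.array(random_digraph(n, 0.3, rng), dtype=float)
    v = rng.normal(size=n)
    perm = rng.permutation(n)
    xp = x[np.ix_(perm, perm)]
    vp = v[perm]
    for name in STRUCTURAL + COVARIATE:
        stats = [implementation(name, i, x, v) for i in range(n)]
        stats_p = [implementation(name, i, xp, vp) for i in range(n)]
        assert np.allclose(np.asarray(stats)[perm], stats_p), name


def test_similarity_total_affine_invariant(rng):
    """cov_similarity totals are unchanged by affine covariate transforms."""
    n = 7
    x = np.array(random_digraph(n, 0.4, rng), dtype=float)
    v = rng.normal(size=n)
    tot = sum(implementation("cov_similarity", i, x, v.tolist())
              for i in range(n))
    tot2 = sum(implementation("cov_similarity", i, x, (3.0 * v - 1.0).tolist())
               for i in range(n))
    assert tot == pytest.approx(tot2, abs=1e-9)


# ---------------------------------------------------------------------------
# Evaluation and rate functions
# ---------------------------------------------------------------------------

def two_effect_spec(beta_out=-2.0, beta_rec=1.0, rates=(1.0,), alpha=None):
    effects = [EffectSpec("outdegree", parameter=beta_out),
               EffectSpec("reciprocity", parameter=beta_rec)]
    if alpha is not None:
        effects.append(EffectSpec("rate_outdegree", parameter=alpha))
    return ModelSpec(effects, list(rates), {})


def test_evaluation_fn_hand_computation():
    # outdegree -2, reciprocity 1; actor with outdeg 2, one reciprocated tie
    x = np.zeros((3, 3))
    x[0, 1] = x[0, 2] = x[1, 0] = 1
    spec = two_effect_spec(-2.0, 1.0)
    assert evaluation_fn(0, x, spec) == pytest.approx(-3.0)


def test_evaluation_fn_zero_betas():
    x = np.ones((4, 4)) - np.eye(4)
    spec = two_effect_spec(0.0, 0.0)
    assert evaluation_fn(2, x, spec) == 0.0


def test_rate_fn_closed_form():
    spec = two_effect_spec(alpha=0.1, rates=(2.0,))
    x5 = np.zeros((7, 7)); x5[0, 1:6] = 1
    x0 = np.zeros((7, 7))
    r5 = rate_fn(0, x5, 0, spec)
    r0 = rate_fn(0, x0, 0, spec)
    assert r5 / r0 == pytest.approx(np.exp(0.5))
    # alpha = 0: rate equals rho for every active actor
    spec0 = two_effect_spec(rates=(2.0,))
    assert rate_fn(3, x5, 0, spec0) == pytest.approx(2.0)


def test_rate_fn_inactive_actor_zero():
    spec = two_effect_spec(rates=(2.0,))
    x = np.zeros((3, 3))
    active = np.array([True, False, True])
    assert rate_fn(1, x, 0, spec, active=active) == 0.0


def test_rate_fn_nonpositive_rho_rejected():
    spec = two_effect_spec(rates=(0.0,))
    with pytest.raises(SpecError):
        rate_fn(0, np.zeros((3, 3)), 0, spec)


# ---------------------------------------------------------------------------
# Target statistics
# ---------------------------------------------------------------------------

def test_spec_validation():
    with pytest.raises(SpecError):
        ModelSpec([EffectSpec("reciprocity")], [1.0], {})  # no outdegree
    with pytest.raises(SpecError):
        ModelSpec([EffectSpec("outdegree"), EffectSpec("outdegree")], [1.0], {})
    with pytest.raises(SpecError):
        EffectSpec("cov_ego")  # covariate effect without covariate


def test_target_vector_shape_and_outdegree_total(paper_study):
    """The outdegree target is the total tie count over waves 2..W."""
    panel = paper_study.panel
    spec = ModelSpec([EffectSpec("outdegree")],
                     [1.0] * (panel.n_waves - 1), {})
    tv = target_statistics(panel, spec)
    assert len(tv) == (panel.n_waves - 1) + 1
    expect = sum(w.n_ties for w in panel.waves[1:])
    assert tv[-1] == pytest.approx(expect)
    assert parameter_names(spec)[-1] == "outdegree"


def test_printed_tie_counts_sum():
    """Tie counts printed for waves 2..6 sum to the outdegree target 1181."""
    assert sum((187, 180, 218, 252, 344)) == 1181


def test_identical_waves_zero_rate_targets(paper_study):
    import copy

    panel = copy.deepcopy(paper_study.panel)
    for w, wave in enumerate(panel.waves):
        wave.active = panel.waves[0].active.copy()
        wave.adj = panel.waves[0].adj.copy()
        # keep weeks strictly increasing
    spec = ModelSpec([EffectSpec("outdegree")],
                     [1.0] * (panel.n_waves - 1), {})
    tv = target_statistics(panel, spec)
    assert np.all(tv[: panel.n_waves - 1] == 0)
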