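"""Independent brute-force oracles used by the reproduction script.

Definition-level enumerations, deliberately written without reusing the
package's vectorized formulas.
"""

import numpy as np

from groomnet.effects import EffectSpec, effect_statistic

STRUCTURAL = [
    "outdegree", "reciprocity", "transitive_triplets", "three_cycles",
    "transitive_recip_triplets", "indegree_popularity",
    "indegree_popularity_sqrt",
    "outdegree_popularity_sqrt", "outdegree_activity_sqrt",
    "out_out_assortativity",
]
COVARIATE = ["cov_ego", "cov_alter", "cov_same", "cov_similarity",
             "same_cov_x_reciprocity"]


def implementation(name, i, x, v=None):
    eff = EffectSpec(name, covariate="v" if name in COVARIATE else None)
    covs = {"v": np.asarray(v, dtype=float)} if v is not None else None
    return effect_statistic(eff, i, np.asarray(x, dtype=float), covs)


def oracle(name, i, x, v=None):
    n = len(x)
    out_i = [j for j in range(n) if x[i][j]]
    if name == "outdegree":
        return len(out_i)
    if name == "reciprocity":
        return sum(1 for j in out_i if x[j][i])
    if name == "transitive_triplets":
        return sum(1 for h in out_i for j in range(n)
                   if x[h][j] and x[i][j])
    if name == "three_cycles":
        return sum(1 for j in out_i for h in range(n)
                   if x[j][h] and x[h][i])
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


def anova_icc_a_k(ratings):
    """Two-way ANOVA decomposition for ICC(A,k), written longhand."""
    ratings = np.asarray(ratings, dtype=float)
    n, k = ratings.shape
    grand = ratings.mean()
    ss_rows = k * ((ratings.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((ratings.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((ratings - grand) ** 2).sum() - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)
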