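"""Tests for the preranked enrichment implementation.

The independent oracle for the enrichment score is a literal
position-by-position running sum; on fixtures the pre-installed gseapy
package serves as an external cross-check of the same statistic.
"""

import numpy as np
import pandas as pd
import pytest

from canprot import gsea
from canprot.errors import DomainError


def brute_force_es(scores, hit_positions, weight=1.0):
    """Literal running-sum oracle, independent of the implementation."""
    n = len(scores)
    hits = set(int(h) for h in hit_positions)
    nr = sum(abs(scores[p]) ** weight for p in hits)
    vals = []
    run = 0.0
    for j in range(n):
        if j in hits:
            run += (abs(scores[j]) ** weight / nr) if nr > 0 else 1.0 / len(hits)
        else:
            run -= 1.0 / (n - len(hits))
        vals.append(run)
    return vals[int(np.argmax(np.abs(vals)))]


def _random_instance(rng):
    n = int(rng.integers(5, 51))
    k = int(rng.integers(1, min(11, n)))
    scores = np.sort(rng.normal(size=n))[::-1]
    hits = np.sort(rng.choice(n, size=k, replace=False))
    return scores, hits


# ---------------------------------------------------------------------------
# restriction
# ---------------------------------------------------------------------------

def test_restrict_sets_inclusive_minimum():
    genes = [f"g{i}" for i in range(30)]
    sets = {"s5": genes[:5], "s10": genes[:10], "s12": genes[:12]}
    out = gsea.restrict_sets(sets, genes, min_size=10)
    assert set(out) == {"s10", "s12"}


def test_restrict_sets_intersects_and_drops_disjoint():
    genes = ["a", "b", "c", "d"]
    sets = {"x": ["a", "b", "zz", "c"], "y": ["q", "r", "s"]}
    out = gsea.restrict_sets(sets, genes, min_size=2)
    assert out == {"x": ["a", "b", "c"]}


def test_restrict_sets_large_scale_counts():
    """5917 candidate sets of which 5052 fall below the size-10 floor."""
    rng = np.random.default_rng(13)
    genes = [f"g{i}" for i in range(600)]
    sets = {}
    for j in range(5917):
        size = int(rng.integers(3, 10)) if j < 5052 else int(rng.integers(10, 156))
        sets[f"s{j}"] = list(rng.choice(genes, size=size, replace=False))
    out = gsea.restrict_sets(sets, genes, min_size=10)
    assert len(out) == 5917 - 5052 == 865


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def test_singleton_first_and_last_extremes():
    scores = np.array([3.0, 2.0, 1.0, 0.5, -1.0])
    es, _, _ = gsea.enrichment_score(scores, [0])
    assert es == pytest.approx(1.0)
    es, _, _ = gsea.enrichment_score(scores, [4])
    assert es == pytest.approx(-1.0)


def test_degenerate_set_rejected():
    with pytest.raises(DomainError):
        gsea.enrichment_score(np.array([1.0, 0.5]), [0, 1])


def test_es_matches_brute_force_oracle():
    rng = np.random.default_rng(14)
    for _ in range(200):
        scores, hits = _random_instance(rng)
        es, _, _ = gsea.enrichment_score(scores, hits)
        assert es == pytest.approx(brute_force_es(scores, hits), abs=1e-12)


def test_vectorized_batch_matches_full_running_sum():
    rng = np.random.default_rng(15)
    for _ in range(200):
        scores, hits = _random_instance(rng)
        batch = gsea._es_batch(
            np.abs(scores), hits[None, :], len(scores)
        )
        es, _, _ = gsea.enrichment_score(scores, hits)
        assert batch[0] == pytest.approx(es, abs=1e-12)


def test_es_bounds_and_negation_antisymmetry():
    rng = np.random.default_rng(16)
    for _ in range(50):
        scores, hits = _random_instance(rng)
        es, _, _ = gsea.enrichment_score(scores, hits)
        assert -1.0 <= es <= 1.0
        # negate scores and reverse the list: hits mirror, ES negates
        n = len(scores)
        mirrored = np.sort(-scores)[::-1]
        es_neg, _, _ = gsea.enrichment_score(mirrored, n - 1 - hits)
        assert es_neg == pytest.approx(-es, abs=1e-12)


def test_leading_edge_sides():
    scores = np.array([4.0, 3.0, 2.0, 1.0, 0.5, -0.5, -1.0, -2.0])
    genes = [f"g{i}" for i in range(8)]
    rnk = pd.DataFrame({"gene_id": genes, "score": scores})
    es, _, led = gsea.score_set(rnk, ["g0", "g1", "g7"])
    assert es > 0 and led == ["g0", "g1"]
    es, _, led = gsea.score_set(rnk, ["g6", "g7"])
    assert es < 0 and set(led) == {"g6", "g7"}


def test_es_against_gseapy_oracle(random_rnk):
    """Cross-check the statistic against the reference implementation."""
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(17)
    genes = list(random_rnk["gene_id"])
    sets = {
        f"S{j}": list(rng.choice(genes, size=int(rng.integers(10, 40)),
                                 replace=False))
        for j in range(8)
    }
    pre = gseapy.prerank(
        rnk=random_rnk.rename(columns={"gene_id": 0, "score": 1}),
        gene_sets=sets, permutation_num=4, min_size=3, max_size=1000,
        seed=1, outdir=None, no_plot=True, weight=1,
    )
    ref = {row.Term: float(row.ES) for row in pre.res2d.itertuples()}
    for name, members in sets.items():
        es, _, _ = gsea.score_set(random_rnk, members)
        assert es == pytest.approx(ref[name], abs=1e-9)


# ---------------------------------------------------------------------------
# permutation null, NES, p, q
# ---------------------------------------------------------------------------

def test_null_reproducible_and_bounded(random_rnk):
    scores = random_rnk["score"].to_numpy()
    a = gsea.permutation_null(scores, 15, n_perm=100, rng=5)
    b = gsea.permutation_null(scores, 15, n_perm=100, rng=5)
    np.testing.assert_array_equal(a, b)
    assert np.all(a >= -1.0) and np.all(a <= 1.0)


def test_null_sign_balance_on_random_scores(random_rnk):
    scores = random_rnk["score"].to_numpy()
    null = gsea.permutation_null(scores, 20, n_perm=2000, rng=6)
    frac_pos = np.mean(null > 0)
    assert 0.4 <= frac_pos <= 0.6


def test_normalize_and_test_hand_cases():
    null = np.array([0.5, -0.5, 0.25, -0.25])
    nes, p = gsea.normalize_and_test(0.375, null)
    # same-signed nulls {0.5, 0.25}, mean 0.375 -> nes 1; one exceedance
    assert nes == pytest.approx(1.0)
    assert p == pytest.approx((1 + 1) / (2 + 1))
    nes, p = gsea.normalize_and_test(0.0, null)
    assert nes == 0.0 and p == 1.0
    nes, p = gsea.normalize_and_test(0.9, np.full(999, 0.1))
    assert p == pytest.approx(1 / 1000)


def test_normalize_no_same_signed_null_gives_absent_nes():
    nes, p = gsea.normalize_and_test(-0.5, np.array([0.2, 0.4]))
    assert nes is None and p == 1.0


def test_nominal_p_uniform_under_random_list():
    """Over 500 random sets on a random list, ~5% reach p<.05."""
    rng = np.random.default_rng(18)
    n = 200
    scores = np.sort(rng.normal(size=n))[::-1]
    genes = [f"g{i}" for i in range(n)]
    rnk = pd.DataFrame({"gene_id": genes, "score": scores})
    hits = 0
    for j in range(500):
        members = rng.choice(genes, size=15, replace=False)
        es, _, _ = gsea.score_set(rnk, members)
        null = gsea.permutation_null(scores, 15, n_perm=400, rng=1000 + j)
        _, p = gsea.normalize_and_test(es, null)
        hits += p < 0.05
    assert 0.03 <= hits / 500 <= 0.07


def test_fdr_q_extreme_and_monotone():
    obs = np.array([3.0, 2.0, 1.5, 1.0, -1.2, -2.5])
    null = np.concatenate([np.abs(np.random.default_rng(19).normal(1, 0.3, 500)),
                           -np.abs(np.random.default_rng(20).normal(1, 0.3, 500))])
    q = gsea.fdr_q(obs, null)
    assert np.all(q >= 0) and np.all(q <= 1)
    # most extreme positive with no null exceedance -> q == 0
    assert q[0] == 0.0
    # monotone non-increasing in |nes| within each sign
    assert q[0] <= q[1] <= q[2] <= q[3]
    assert q[5] <= q[4]


def test_fdr_q_null_equals_observed_is_near_one():
    """When observed NES are drawn from the null, median-set q is ~1."""
    rng = np.random.default_rng(21)
    pool = rng.normal(0, 1, 4000)
    obs = rng.choice(pool, size=200, replace=False)
    q = gsea.fdr_q(obs, pool)
    mid = np.abs(obs) < np.quantile(np.abs(obs), 0.5)
    assert np.nanmedian(q[mid]) == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------------------
# filtering and redundancy collapse
# ---------------------------------------------------------------------------

def _results(rows):
    return pd.DataFrame(
        rows, columns=["name", "size_used", "es", "nes", "nominal_p", "fdr_q",
                       "leading_edge"]
    )


def test_significant_sets_strict_thresholds():
    res = _results([
        ("a", 10, 0.5, 1.5, 0.01, 0.05, ["g1"]),     # p exactly .01 -> excluded
        ("b", 10, 0.5, 1.5, 0.005, 0.09, ["g1"]),    # retained
        ("c", 10, -0.5, -1.5, 0.005, 0.1, ["g1"]),   # q exactly .1 -> excluded
        ("d", 10, -0.6, -1.8, 0.001, 0.01, ["g2"]),  # retained, down
    ])
    sig = gsea.significant_sets(res)
    assert list(sig["name"]) == ["b", "d"]
    assert list(sig["direction"]) == ["up", "down"]


def test_collapse_identical_and_disjoint_edges():
    res = _results([
        ("a", 10, 0.5, 2.0, 0.001, 0.01, ["g1", "g2", "g3"]),
        ("b", 10, 0.5, 1.8, 0.001, 0.01, ["g1", "g2", "g3"]),
        ("c", 10, 0.5, 1.5, 0.001, 0.01, ["h1", "h2"]),
    ])
    out = gsea.collapse_redundant(res)
    assert list(out["name"]) == ["a", "c"]


def test_collapse_matches_independent_greedy():
    rng = np.random.default_rng(22)
    genes = [f"g{i}" for i in range(40)]
    rows = []
    for j in range(12):
        edge = list(rng.choice(genes, size=int(rng.integers(3, 12)),
                               replace=False))
        rows.append((f"s{j}", 10, 0.5, float(rng.normal(0, 2)), 0.001, 0.01, edge))
    res = _results(rows)
    out = gsea.collapse_redundant(res)

    # independent greedy re-run
    ordered = sorted(rows, key=lambda r: (-abs(r[3]), r[0]))
    kept = []
    for r in ordered:
        e = set(r[6])
        if all(len(e & set(k[6])) / len(e | set(k[6])) <= 0.5 for k in kept):
            kept.append(r)
    assert set(out["name"]) == {r[0] for r in kept}


# ---------------------------------------------------------------------------
# orchestration determinism
# ---------------------------------------------------------------------------

def test_prerank_identical_seeds_identical_results(random_rnk):
    rng = np.random.default_rng(23)
    genes = list(random_rnk["gene_id"])
    sets = {f"S{j}": list(rng.choice(genes, 15, replace=False)) for j in range(5)}
    a = gsea.prerank(random_rnk, sets, n_perm=200, seed=9)
    b = gsea.prerank(random_rnk, sets, n_perm=200, seed=9)
    pd.testing.assert_frame_equal(a, b)
    c = gsea.prerank(random_rnk, sets, n_perm=200, seed=10)
    assert not np.array_equal(a["nominal_p"].to_numpy(), c["nominal_p"].to_numpy())
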