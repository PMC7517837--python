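"""From-scratch preranked gene-set enrichment analysis.

Given a ranked gene list (scores non-increasing) and a gene-set collection,
the weighted Kolmogorov-Smirnov-like running sum walks down the list,
incrementing by ``|r_g|^weight / N_R`` at set members (hits, ``N_R`` the
sum of weighted scores over members) and decrementing by ``1/(N - N_H)``
at non-members. The enrichment score ES is the running-sum value furthest
from zero; the leading edge is the members at or before the extremum (at
or after it, for negative ES).

The null distribution comes from gene-tag permutation: size-matched random
gene sets drawn uniformly from the ranked list (phenotype permutation is
impossible for preranked input). NES divides ES by the mean magnitude of
same-signed null ES; the nominal p uses the add-one rule. The FDR q for a
set compares the pooled same-signed null NES exceedance fraction with the
observed exceedance fraction, clipped to [0, 1] and monotonized so q never
increases with |NES|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError

DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 1000
DEFAULT_MIN_SIZE = 10


# ---------------------------------------------------------------------------
# set restriction
# ---------------------------------------------------------------------------

def restrict_sets(
    gene_sets: dict, ranked_genes, min_size: int = DEFAULT_MIN_SIZE
) -> dict[str, list[str]]:
    """Intersect each set with the ranked list; drop sets below ``min_size``.

    ``gene_sets`` maps name -> members, or name -> (description, members)
    as returned by the GMT reader. The boundary is inclusive: a restricted
    size of exactly ``min_size`` is retained. Restricted members are
    returned in ranked-list order.
    """
    order = {g: i for i, g in enumerate(ranked_genes)}
    out: dict[str, list[str]] = {}
    for name, value in gene_sets.items():
        members = value[1] if isinstance(value, tuple) else value
        present = sorted((g for g in set(members) if g in order), key=order.get)
        if len(present) >= min_size:
            out[name] = present
    return out


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _hit_weights(abs_scores_w: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Normalized hit increments; equal weights when all hit scores are 0."""
    w = abs_scores_w[positions]
    total = w.sum()
    if total == 0.0:
        return np.full(len(positions), 1.0 / len(positions))
    return w / total


def enrichment_score(
    scores: np.ndarray,
    hit_positions: np.ndarray,
    weight: float = DEFAULT_WEIGHT,
) -> tuple[float, np.ndarray, int]:
    """ES, the full running sum, and the extremum index for one gene set.

    ``scores`` are the ranked-list scores (non-increasing); ``hit_positions``
    are the 0-based ranks of the set members. The ES is the running-sum
    element of largest magnitude (first such index on an exact tie).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    hits = np.asarray(sorted(hit_positions), dtype=int)
    n_h = len(hits)
    if n_h == 0:
        raise DomainError("enrichment_score requires >=1 hit in the ranked list")
    if n_h >= n:
        raise DomainError("degenerate set: every ranked gene is a member")
    running = np.full(n, -1.0 / (n - n_h))
    running[hits] = _hit_weights(np.abs(scores) ** weight, hits)
    running = np.cumsum(running)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, idx


def leading_edge(
    ranked_genes, hit_positions, es: float, extremum_index: int
) -> list[str]:
    """Members at/before the extremum (positive ES) or at/after (negative)."""
    hits = sorted(hit_positions)
    if es > 0:
        sel = [p for p in hits if p <= extremum_index]
    elif es < 0:
        sel = [p for p in hits if p >= extremum_index]
    else:
        sel = []
    return [ranked_genes[p] for p in sel]


def score_set(
    rnk: pd.DataFrame, members, weight: float = DEFAULT_WEIGHT
) -> tuple[float, np.ndarray, list[str]]:
    """Convenience wrapper: ES, running sum, leading edge from a ranked frame."""
    genes = list(rnk["gene_id"])
    order = {g: i for i, g in enumerate(genes)}
    positions = np.array(sorted(order[g] for g in members if g in order), dtype=int)
    es, running, idx = enrichment_score(rnk["score"].to_numpy(), positions, weight)
    return es, running, leading_edge(genes, positions, es, idx)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _es_batch(
    abs_scores_w: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many hit-position rows (each sorted ascending).

    Builds the full running sums row-wise with the same cumulative-sum
    accumulation order as :func:`enrichment_score`, so both paths pick the
    identical extremum even on near-exact ties.
    """
    n_perm, k = positions.shape
    w = abs_scores_w[positions]
    totals = w.sum(axis=1, keepdims=True)
    flat = totals[:, 0] == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(flat[:, None], 1.0 / k, w / np.where(totals == 0, 1.0, totals))
    steps = np.full((n_perm, n), -1.0 / (n - k))
    np.put_along_axis(steps, positions, w, axis=1)
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def permutation_null(
    scores: np.ndarray,
    set_size: int,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | int | None = None,
    weight: float = DEFAULT_WEIGHT,
) -> np.ndarray:
    """Null ES from ``n_perm`` uniformly drawn size-matched gene sets."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if set_size >= n:
        raise DomainError("degenerate: permutation set size must be < list length")
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    keys = rng.random((n_perm, n))
    positions = np.sort(np.argpartition(keys, set_size, axis=1)[:, :set_size], axis=1)
    return _es_batch(np.abs(scores) ** weight, positions, n)


def normalize_and_test(
    es: float, null_es: np.ndarray
) -> tuple[float | None, float]:
    """NES and nominal p against the same-signed half of the null.

    nes = es / mean(|null es of the same sign|); absent (None) when no null
    value shares the sign. p = (k+1)/(m+1) with k the count of same-signed
    null values at least as extreme — the add-one rule keeps p > 0.
    """
    null_es = np.asarray(null_es, dtype=float)
    if es == 0.0:
        return 0.0, 1.0
    same = null_es[null_es > 0] if es > 0 else null_es[null_es < 0]
    m = len(same)
    if m == 0:
        return None, 1.0
    nes = es / np.mean(np.abs(same))
    k = int(np.sum(np.abs(same) >= abs(es)))
    return float(nes), (k + 1) / (m + 1)


def normalize_null(null_es: np.ndarray) -> np.ndarray:
    """Scale a set's null ES by its same-sign means, for FDR pooling."""
    null_es = np.asarray(null_es, dtype=float)
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    out = np.zeros_like(null_es)
    if len(pos):
        out[null_es > 0] = null_es[null_es > 0] / pos.mean()
    if len(neg):
        out[null_es < 0] = null_es[null_es < 0] / np.abs(neg).mean()
    return out


def fdr_q(observed_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Permutation FDR q per observed NES against the pooled null NES.

    q(nes*) = [fraction of pooled same-signed null NES with |value| >=
    |nes*|] / [fraction of observed same-signed NES with |value| >=
    |nes*|], clipped to [0, 1], then monotonized within each sign so q is
    non-increasing in |NES| (reverse cumulative minimum, most extreme
    first). NaN observed values propagate as NaN.
    """
    obs = np.asarray(observed_nes, dtype=float)
    null = np.asarray(null_nes, dtype=float)
    q = np.full(len(obs), np.nan)
    for sign in (1, -1):
        sel = np.where(np.sign(obs) == sign)[0]
        if len(sel) == 0:
            continue
        obs_s = np.abs(obs[sel])
        null_s = np.abs(null[np.sign(null) == sign])
        raw = np.empty(len(sel))
        for j, v in enumerate(obs_s):
            num = np.mean(null_s >= v) if len(null_s) else 0.0
            den = np.mean(obs_s >= v)
            raw[j] = min(1.0, num / den) if den > 0 else 1.0
        order = np.argsort(-obs_s, kind="mergesort")
        mono = np.minimum.accumulate(raw[order][::-1])[::-1]
        q[sel[order]] = mono
    q[obs == 0] = 1.0
    return q


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def prerank(
    rnk: pd.DataFrame,
    gene_sets: dict,
    weight: float = DEFAULT_WEIGHT,
    n_perm: int = DEFAULT_N_PERM,
    min_size: int = DEFAULT_MIN_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Run preranked enrichment for a whole collection.

    Returns one row per retained set with columns ``name``, ``size_used``,
    ``es``, ``nes``, ``nominal_p``, ``fdr_q``, ``leading_edge`` (list).
    Each set's permutation stream derives from (seed, set index in sorted
    name order), so results are independent of dict ordering and identical
    for identical seeds.
    """
    genes = list(rnk["gene_id"])
    scores = rnk["score"].to_numpy(dtype=float)
    restricted = restrict_sets(gene_sets, genes, min_size=min_size)
    names = sorted(restricted)
    rows = []
    pooled_null: list[np.ndarray] = []
    for j, name in enumerate(names):
        members = restricted[name]
        if len(members) >= len(genes):
            # A set covering the entire ranked list carries no information.
            continue
        es, _running, led = score_set(rnk, members, weight=weight)
        rng = np.random.default_rng([int(seed), 4, j])
        null = permutation_null(scores, len(members), n_perm=n_perm, rng=rng,
                                weight=weight)
        nes, p = normalize_and_test(es, null)
        pooled_null.append(normalize_null(null))
        rows.append(
            {
                "name": name,
                "size_used": len(members),
                "es": es,
                "nes": np.nan if nes is None else nes,
                "nominal_p": p,
                "leading_edge": led,
            }
        )
    results = pd.DataFrame(
        rows, columns=["name", "size_used", "es", "nes", "nominal_p", "leading_edge"]
    )
    if len(results):
        results["fdr_q"] = fdr_q(
            results["nes"].to_numpy(), np.concatenate(pooled_null)
        )
    else:
        results["fdr_q"] = pd.Series(dtype=float)
    return results[
        ["name", "size_used", "es", "nes", "nominal_p", "fdr_q", "leading_edge"]
    ]


def summarize_directions(results: pd.DataFrame) -> str:
    """One-line count of up/down sets with percentages to 1 decimal."""
    n = len(results)
    n_up = int((results["es"] > 0).sum())
    n_down = int((results["es"] < 0).sum())
    if n == 0:
        return "0 gene sets"
    return (
        f"{n_up}/{n} gene sets ({100 * n_up / n:.1f}%) upregulated, "
        f"{n_down}/{n} ({100 * n_down / n:.1f}%) downregulated"
    )


def significant_sets(
    results: pd.DataFrame, p_thresh: float = 0.01, q_thresh: float = 0.1
) -> pd.DataFrame:
    """Sets passing both strict thresholds, tagged by direction."""
    mask = (results["nominal_p"] < p_thresh) & (results["fdr_q"] < q_thresh)
    out = results[mask].copy()
    out["direction"] = np.where(out["es"] > 0, "up", "down")
    return out.reset_index(drop=True)


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def collapse_redundant(
    significant: pd.DataFrame, max_jaccard: float = 0.5
) -> pd.DataFrame:
    """Greedy leading-edge redundancy collapse.

    Visits sets by |NES| descending (name ascending on ties) and retains a
    set only when the Jaccard similarity of its leading edge with every
    already-retained leading edge is <= ``max_jaccard``. The criterion is a
    package construction — the choice of redundancy rule is documented in
    the methods note.
    """
    if significant.empty:
        return significant.copy()
    ordered = significant.sort_values(
        "name", kind="mergesort"
    ).sort_values("nes", key=lambda s: -s.abs(), kind="mergesort")
    kept_edges: list[set] = []
    kept_idx = []
    for idx, row in ordered.iterrows():
        edge = set(row["leading_edge"])
        if all(_jaccard(edge, e) <= max_jaccard for e in kept_edges):
            kept_edges.append(edge)
            kept_idx.append(idx)
    return significant.loc[kept_idx].reset_index(drop=True)


def plot_running_sum(
    rnk: pd.DataFrame, members, name: str, path, weight: float = DEFAULT_WEIGHT
) -> None:
    """Export a static running-sum enrichment plot for one gene set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    es, running, _ = score_set(rnk, members, weight=weight)
    order = {g: i for i, g in enumerate(rnk["gene_id"])}
    hits = sorted(order[g] for g in members if g in order)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(running, lw=1.2, color="tab:green")
    ax.axhline(0.0, color="grey", lw=0.6)
    for h in hits:
        ax.axvline(h, ymin=0.0, ymax=0.05, color="black", lw=0.4)
    ax.set_xlabel("rank in gene list")
    ax.set_ylabel("running enrichment score")
    ax.set_title(f"{name} (ES = {es:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
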