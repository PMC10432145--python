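"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately written from first principles — exhaustive
configuration enumeration, naive greedy loops, direct density ratios —
independently of the code paths under test.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def wakefield_abf_density_ratio(beta: float, se: float, prior_sd: float) -> float:
    """ABF as a ratio of marginal normal densities at the observed beta."""
    return norm.pdf(beta, 0.0, np.sqrt(se**2 + prior_sd**2)) / norm.pdf(beta, 0.0, se)


def coloc_enumeration(labf1, labf2, p1=1e-4, p2=1e-4, p12=1e-5) -> np.ndarray:
    """PP0..PP4 by exhaustive enumeration of per-trait causal configurations.

    Each trait is either null or causal at one of the n SNPs; the joint prior
    follows the per-SNP association priors and the likelihood ratio of a
    configuration is the product of the involved ABFs.
    """
    n = len(labf1)
    bf1 = np.exp(np.asarray(labf1, dtype=float))
    bf2 = np.exp(np.asarray(labf2, dtype=float))
    ev = np.zeros(5)
    ev[0] = 1.0  # both null (baseline prior weight 1)
    for i in range(n):
        ev[1] += p1 * bf1[i]
        ev[2] += p2 * bf2[i]
        ev[4] += p12 * bf1[i] * bf2[i]
        for j in range(n):
            if i != j:
                ev[3] += p1 * p2 * bf1[i] * bf2[j]
    return ev / ev.sum()


def multicoloc_enumeration(labfs, prior1=1e-10, prior2=0.7):
    """Exact hypothesis posteriors for m traits by (n+1)^m enumeration.

    Each trait is null (assignment -1) or causal at one SNP. Traits sharing a
    SNP form a block with per-SNP prior prior1 * (1-prior2)^(k-1); distinct
    SNPs are handled exactly. Returns (partition-key -> posterior,
    full-colocalization posterior); partition keys are frozensets of
    frozensets of trait indices.
    """
    from itertools import product

    labfs = [np.asarray(l, dtype=float) for l in labfs]
    m = len(labfs)
    n = len(labfs[0])
    ev: dict = {}
    for assign in product(range(-1, n), repeat=m):
        blocks: dict = {}
        for t, s in enumerate(assign):
            if s >= 0:
                blocks.setdefault(s, []).append(t)
        log_prior = sum(
            np.log(prior1) + (len(b) - 1) * np.log1p(-prior2) for b in blocks.values()
        )
        log_lik = sum(labfs[t][s] for t, s in enumerate(assign) if s >= 0)
        key = frozenset(frozenset(b) for b in blocks.values())
        ev[key] = ev.get(key, 0.0) + np.exp(log_prior + log_lik)
    total = sum(ev.values())
    post = {k: v / total for k, v in ev.items()}
    full_key = frozenset([frozenset(range(m))])
    return post, post.get(full_key, 0.0)


def credible_set_sort_accumulate(posterior, mass=0.95):
    """Indices of the smallest prefix reaching the mass, naive version."""
    order = np.argsort(-np.asarray(posterior, dtype=float), kind="stable")
    out, cum = [], 0.0
    for i in order:
        out.append(int(i))
        cum += posterior[i]
        if cum >= mass:
            break
    return out


def bh_stepup(p):
    """Reference Benjamini-Hochberg step-up q values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def greedy_clump(positions, chroms, pvals, r2_matrix, r2_threshold, window_bp):
    """Naive greedy clumping returning kept indices."""
    order = sorted(range(len(pvals)), key=lambda i: (pvals[i], positions[i]))
    kept, removed = [], set()
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in order:
            if j == i or j in removed:
                continue
            if chroms[i] != chroms[j] or abs(positions[i] - positions[j]) > window_bp:
                continue
            if r2_matrix[i][j] >= r2_threshold:
                removed.add(j)
    return kept


def merge_components(edges, n):
    """Connected components via networkx, the locus-merge oracle."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return [sorted(c) for c in nx.connected_components(g)]


def classify_truth_table(flags: dict) -> tuple[int, int, int, int, str]:
    """Hand-derived restatement of the six-line scoring rules.

    Written as explicit branch logic (distinct from both the package scorer
    and the generator's oracle) so agreement is a three-way check.
    Returns (oa, t2d, missense, total, classification).
    """
    oa_lines = [flags["molqtl_coloc_oa"], flags["deg_oa"], flags["ko_mouse_oa"], flags["omim_oa"]]
    t2d_lines = [flags["molqtl_coloc_t2d"], flags["deg_t2d"], flags["ko_mouse_t2d"], flags["omim_t2d"]]
    oa = len([f for f in oa_lines if f])
    t2d = len([f for f in t2d_lines if f])
    if oa == 0 and flags["established_hc_oa"]:
        oa = 1
    if t2d == 0 and flags["established_hc_t2d"]:
        t2d = 1
    missense = 1 if flags["missense_in_credible_set"] else 0
    if oa + t2d == 0:
        total = 0
    else:
        total = oa + t2d + missense
    if oa > 0 and t2d > 0:
        cls = "high_confidence" if total >= 3 else "likely"
    elif oa + t2d > 0:
        cls = "potential"
    else:
        cls = "none"
    return oa, t2d, missense, total, cls
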