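"""Naive reference implementations used to validate the production code.

Each function here recomputes a pipeline primitive by the most direct route
available — exhaustive window checks, all-pairs overlap, transitive-closure
clustering, closed forms, direct probability formulas — deliberately sharing
no code with the optimized implementations they check.  They are quadratic
or worse and meant for small inputs inside the test and acceptance suites.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .integration import IndelCall


# ---------------------------------------------------------------------------
# TOH windows: examine every (start, end) pair
# ---------------------------------------------------------------------------

def brute_force_toh_windows(
    is_het: np.ndarray,
    is_missing: np.ndarray,
    max_het: int,
    max_missing: int,
    min_hom: int,
) -> list[tuple[int, int]]:
    """All maximal valid windows by checking every (start, end) pair.

    A window is valid when it starts and ends on a homozygous call and its
    het/missing/homozygous counts satisfy the limits; it is maximal when no
    valid window strictly contains it.  Vectorised over the (start, end)
    plane but still examines all O(n^2) windows.
    """
    het = np.asarray(is_het, dtype=bool)
    mis = np.asarray(is_missing, dtype=bool)
    n = het.size
    if n == 0:
        return []
    hom = ~het & ~mis
    hc = np.concatenate([[0], np.cumsum(het)])
    mc = np.concatenate([[0], np.cumsum(mis)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    het_in = hc[j + 1] - hc[i]
    mis_in = mc[j + 1] - mc[i]
    span = j - i + 1
    hom_in = span - het_in - mis_in
    valid = (
        (j >= i)
        & hom[:, None]
        & hom[None, :]
        & (het_in <= max_het)
        & (mis_in <= max_missing)
        & (hom_in >= min_hom)
    )
    # count of valid windows weakly containing each (i, j): cumulate valid
    # over i' <= i (prefix along starts) and j' >= j (suffix along ends)
    contain = np.cumsum(valid, axis=0)
    contain = np.flip(np.cumsum(np.flip(contain, axis=1), axis=1), axis=1)
    maximal = valid & (contain == 1)
    return [(int(a), int(b)) for a, b in zip(*np.nonzero(maximal))]


# ---------------------------------------------------------------------------
# coverage runs
# ---------------------------------------------------------------------------

def brute_force_coverage_runs(
    coverage: np.ndarray,
    chroms: np.ndarray,
    min_subjects: int,
    min_snps: int,
) -> list[tuple[int, int]]:
    """Maximal qualifying runs by direct left-to-right scanning."""
    out = []
    n = len(coverage)
    i = 0
    while i < n:
        if coverage[i] >= min_subjects:
            j = i
            while (
                j + 1 < n
                and coverage[j + 1] >= min_subjects
                and chroms[j + 1] == chroms[j]
            ):
                j += 1
            if j - i + 1 >= min_snps:
                out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def brute_force_position_coverage(tohs, n_markers: int) -> np.ndarray:
    """Per-position distinct-individual count by direct membership testing."""
    cov = np.zeros(n_markers, dtype=int)
    for pos in range(n_markers):
        cov[pos] = len(
            {t.sample_id for t in tohs if t.start <= pos <= t.end}
        )
    return cov


# ---------------------------------------------------------------------------
# interval overlap and clustering
# ---------------------------------------------------------------------------

def all_pairs_intersect(query, subject):
    """Every overlapping pair by the O(n*m) definition check."""
    pairs = []
    for q in query:
        for s in subject:
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                pairs.append((q, s))
    return pairs


def union_find_clusters(
    indels: list[IndelCall], merge_window: int
) -> list[frozenset]:
    """Transitive closure of the pairwise linkage relation via union-find."""
    parent = list(range(len(indels)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i, a in enumerate(indels):
        for j, b in enumerate(indels):
            if i < j and a.chrom == b.chrom:
                if (
                    a.start < b.start + b.length + merge_window
                    and b.start < a.start + a.length + merge_window
                ):
                    union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(len(indels)):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hwe_enumeration_pvalue(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact HWE p-value by direct evaluation of every configuration.

    Uses the closed-form conditional probability
    ``P(h) = n! na! nb! 2^h / (nAA! h! nBB! (2n)!)`` in log space for every
    admissible heterozygote count, then sums the probabilities no larger
    than the observed one.
    """
    a, b, c = int(n_hom_a), int(n_het), int(n_hom_b)
    n = a + b + c
    n_a, n_b = 2 * a + b, 2 * c + b
    na, nb = min(n_a, n_b), max(n_a, n_b)
    if na == 0:
        return 1.0
    hs = np.arange(na % 2, na + 1, 2)
    n_aa = (na - hs) // 2
    n_bb = (nb - hs) // 2
    logp = (
        hs * np.log(2.0)
        - gammaln(n_aa + 1)
        - gammaln(hs + 1)
        - gammaln(n_bb + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[np.searchsorted(hs, b)]
    return float(min(1.0, np.exp(logp[logp <= p_obs + 1e-12]).sum()))


def woolf_2x2(case_carrier: int, case_non: int, control_carrier: int, control_non: int):
    """Closed-form 2x2 log odds ratio and Woolf standard error."""
    a, b, c, d = case_carrier, case_non, control_carrier, control_non
    beta = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(beta), float(se)


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """BH q-values by the explicit min-over-tail definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        tail = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(tail))
    return q


def normal_tail_quadrature(z: float) -> float:
    """Two-sided normal tail probability by numerical integration."""
    from scipy.integrate import quad

    dens = lambda t: np.exp(-t * t / 2.0) / np.sqrt(2.0 * np.pi)
    upper, _err = quad(dens, abs(z), np.inf)
    return 2.0 * upper
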