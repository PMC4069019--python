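"""Independent brute-force oracles used to freeze expected values.

Every oracle here deliberately avoids the implementation path it checks:
exhaustive path/order enumeration for the copying-model forward recursion,
hypergeometric enumeration for the two-tailed exact test, dense grid search
for EM haplotype frequencies, and exhaustive assignment enumeration for the
allele-on-haplotype problem.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def enum_conditional_loglik(
    new_hap: np.ndarray,
    templates: np.ndarray,
    switch: np.ndarray,
    theta: float,
) -> float:
    """Sum over all k^S hidden-template paths of path x emission probability."""
    templates = np.atleast_2d(templates)
    k, S = templates.shape
    pm = (k + 0.5 * theta) / (k + theta)
    pe = 0.5 * theta / (k + theta)
    total = 0.0
    for path in itertools.product(range(k), repeat=S):
        p = 1.0 / k
        for s in range(1, S):
            sw = switch[s - 1]
            stay = (1.0 - sw) + sw / k if path[s] == path[s - 1] else sw / k
            p *= stay
        for s in range(S):
            p *= pm if templates[path[s], s] == new_hap[s] else pe
        total += p
    return math.log(total)


def enum_pac_loglik(
    alleles: np.ndarray, rho_len: np.ndarray, theta: float
) -> float:
    """Mean over ALL n! orders of the sequential-conditional log likelihood."""
    n, S = alleles.shape
    lls = []
    for order in itertools.permutations(range(n)):
        ll = -S * math.log(2.0)
        for k in range(1, n):
            switch = 1.0 - np.exp(-rho_len / k)
            ll += enum_conditional_loglik(
                alleles[order[k]], alleles[list(order[:k])], switch, theta
            )
        lls.append(ll)
    return float(np.mean(lls))


def fisher_two_tailed_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed exact p by hypergeometric enumeration: sum of the
    probabilities of all tables (fixed margins) no more probable than the
    observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return float(min(total, 1.0))


def genotype_loglik(freq: np.ndarray, haps: list[tuple[int, ...]], geno: np.ndarray) -> float:
    """Multinomial HWE log likelihood of unphased genotypes given haplotype
    frequencies (used by the grid-search oracle)."""
    idx = {h: i for i, h in enumerate(haps)}
    ll = 0.0
    for row in geno:
        tot = 0.0
        for h1 in haps:
            for h2 in haps:
                ok = True
                for s, g in enumerate(row):
                    if g == -1:
                        continue
                    if h1[s] + h2[s] != g:
                        ok = False
                        break
                if ok:
                    tot += freq[idx[h1]] * freq[idx[h2]]
        if tot <= 0:
            return -math.inf
        ll += math.log(tot)
    return ll


def em_grid_oracle(
    geno: np.ndarray, haps: list[tuple[int, ...]], coarse: float = 0.025
) -> np.ndarray:
    """Dense grid search over the frequency simplex maximising the HWE
    multinomial likelihood, with one local refinement pass."""
    m = len(haps)

    def simplex(step: float, centre: np.ndarray | None, width: float):
        if centre is None:
            axes = [np.arange(0.0, 1.0 + step / 2, step)] * (m - 1)
        else:
            axes = [
                np.arange(
                    max(0.0, centre[d] - width),
                    min(1.0, centre[d] + width) + step / 2,
                    step,
                )
                for d in range(m - 1)
            ]
        for combo in itertools.product(*axes):
            s = sum(combo)
            if s <= 1.0 + 1e-9:
                yield np.array(list(combo) + [max(1.0 - s, 0.0)])

    best, best_ll = None, -math.inf
    for f in simplex(coarse, None, 1.0):
        ll = genotype_loglik(f, haps, geno)
        if ll > best_ll:
            best, best_ll = f, ll
    for f in simplex(coarse / 25, best, coarse * 1.2):
        ll = genotype_loglik(f, haps, geno)
        if ll > best_ll:
            best, best_ll = f, ll
    return best


def assignment_enum_oracle(
    block_haps: dict[str, tuple[str, str]],
    typings: dict[str, tuple[str, str]],
) -> dict[tuple[str, str], float]:
    """Exhaustive maximum-likelihood assignment of alleles to haplotypes.

    Enumerates every combination of within-individual pairings; for each,
    the profile likelihood uses the closed-form ML carriage probabilities
    (normalised counts).  Returns the allele-share percentages of the best
    assignment.
    """
    inds = [i for i in typings if i in block_haps]
    ambiguous = [
        i
        for i in inds
        if block_haps[i][0] != block_haps[i][1] and typings[i][0] != typings[i][1]
    ]
    fixed = [i for i in inds if i not in ambiguous]
    best_ll, best_counts = -math.inf, None
    for flips in itertools.product((0, 1), repeat=len(ambiguous)):
        counts: dict[tuple[str, str], float] = {}

        def add(h, a):
            counts[(h, a)] = counts.get((h, a), 0.0) + 1.0

        for i in fixed:
            h1, h2 = block_haps[i]
            a1, a2 = typings[i]
            add(h1, a1)
            add(h2, a2)
        for i, f in zip(ambiguous, flips):
            h1, h2 = block_haps[i]
            a1, a2 = typings[i]
            if f:
                a1, a2 = a2, a1
            add(h1, a1)
            add(h2, a2)
        hap_tot: dict[str, float] = {}
        for (h, _), c in counts.items():
            hap_tot[h] = hap_tot.get(h, 0.0) + c
        ll = sum(c * math.log(c / hap_tot[h]) for (h, _), c in counts.items())
        if ll > best_ll:
            best_ll, best_counts = ll, counts
    allele_tot: dict[str, float] = {}
    for (_, a), c in best_counts.items():
        allele_tot[a] = allele_tot.get(a, 0.0) + c
    return {
        (h, a): 100.0 * c / allele_tot[a] for (h, a), c in best_counts.items()
    }


def tag_coverage_ok(
    alleles: np.ndarray,
    maf: np.ndarray,
    pos: np.ndarray,
    tag_idx: list[int],
    eligible_idx: list[int],
    r2_threshold: float,
) -> bool:
    """Brute-force check: every eligible SNP reaches r^2 >= threshold with a tag."""
    a = alleles.astype(float)
    for j in eligible_idx:
        covered = False
        for t in tag_idx:
            r = np.corrcoef(a[:, j], a[:, t])[0, 1]
            if not np.isnan(r) and r * r >= r2_threshold - 1e-12:
                covered = True
                break
        if not covered:
            return False
    return True
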