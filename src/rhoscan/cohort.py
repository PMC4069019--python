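"""Case-control statistics: block haplotype frequencies and comparisons,
per-haplotype exact tests with FDR, odds ratios, single-SNP trend scan, the
hotspot-intensity permutation test, and multi-allelic allele-on-haplotype
assignment.

All resampling tests share the :class:`~rhoscan.model.PermutationResult`
contract and the add-one empirical p estimator (1 + exceedances) /
(1 + permutations), two-sided on the absolute statistic.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .model import (
    MISSING,
    GenotypePanel,
    HaplotypeBlock,
    HaplotypeFreqTable,
    HaplotypePanel,
    PermutationResult,
)
from .pac import McmcConfig, PacConfig, estimate_rho_map

logger = logging.getLogger(__name__)

_EM_TOL = 1e-8
_EM_MAX_ITER = 5000


# --------------------------------------------------------------------------
# EM haplotype-frequency estimation (unphased genotypes, small blocks)
# --------------------------------------------------------------------------


def _compatible_pairs(geno_row: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All ordered haplotype pairs consistent with one individual's genotypes."""
    site_opts: list[list[tuple[int, int]]] = []
    for g in geno_row:
        if g == 0:
            site_opts.append([(0, 0)])
        elif g == 2:
            site_opts.append([(1, 1)])
        elif g == 1:
            site_opts.append([(0, 1), (1, 0)])
        elif g == MISSING:
            site_opts.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        else:  # pragma: no cover - guarded by GenotypePanel
            raise ValueError(f"bad genotype {g}")
    pairs = []
    for combo in itertools.product(*site_opts):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pairs.append((h1, h2))
    return pairs


def _em_frequencies(geno: np.ndarray) -> tuple[dict[tuple[int, ...], float], int]:
    """EM under Hardy-Weinberg random pairing; returns (freqs, n_individuals used)."""
    expansions = []
    dropped = 0
    for row in geno:
        if (row == MISSING).all():
            dropped += 1
            continue
        n_amb = int((row == 1).sum()) + 2 * int((row == MISSING).sum())
        if n_amb > 16:
            raise ValueError("individual with too many ambiguous sites for exact EM")
        expansions.append(_compatible_pairs(row))
    if dropped:
        logger.warning("em_haplotype_frequencies: dropped %d all-missing individuals", dropped)
    if not expansions:
        raise ValueError("no usable individuals")
    haps = sorted({h for pairs in expansions for pair in pairs for h in pair})
    index = {h: i for i, h in enumerate(haps)}
    pair_idx = [
        np.array([(index[h1], index[h2]) for h1, h2 in pairs], dtype=np.int64)
        for pairs in expansions
    ]
    freq = np.full(len(haps), 1.0 / len(haps))
    n_ind = len(expansions)
    for _ in range(_EM_MAX_ITER):
        counts = np.zeros(len(haps))
        for pi in pair_idx:
            w = freq[pi[:, 0]] * freq[pi[:, 1]]
            tot = w.sum()
            if tot == 0:
                w = np.full(len(pi), 1.0 / len(pi))
            else:
                w = w / tot
            np.add.at(counts, pi[:, 0], w)
            np.add.at(counts, pi[:, 1], w)
        new = counts / (2.0 * n_ind)
        if np.abs(new - freq).max() < _EM_TOL:
            freq = new
            break
        freq = new
    return {h: float(f) for h, f in zip(haps, freq)}, n_ind


def em_haplotype_frequencies(
    genotypes: GenotypePanel,
    block: HaplotypeBlock | None = None,
) -> HaplotypeFreqTable:
    """Maximum-likelihood block haplotype frequencies per cohort via EM.

    Intended for blocks of at most ~12 SNPs (the 2^S haplotype space must
    stay enumerable); missing genotypes are handled by summing over all
    consistent phase/imputation completions.
    """
    if block is not None:
        genotypes = genotypes.restrict_snps(block.snp_index_range)
    by_group = genotypes.split_by_group()
    freqs: dict[str, dict[tuple[int, ...], float]] = {}
    n_chrom: dict[str, int] = {}
    for g, panel in by_group.items():
        f, n_ind = _em_frequencies(panel.genotypes)
        freqs[g] = f
        n_chrom[g] = 2 * n_ind
    all_haps = sorted({h for f in freqs.values() for h in f})
    hap_strings = ["".join(map(str, h)) for h in all_haps]
    freq_by_group = {
        g: np.array([freqs[g].get(h, 0.0) for h in all_haps]) for g in freqs
    }
    # re-normalise away EM round-off
    for g in freq_by_group:
        freq_by_group[g] = freq_by_group[g] / freq_by_group[g].sum()
    return HaplotypeFreqTable(
        block=block,
        haplotypes=hap_strings,
        freq_by_group=freq_by_group,
        n_chromosomes_by_group=n_chrom,
    )


def freq_table_from_phased(
    panel: HaplotypePanel, block: HaplotypeBlock | None = None
) -> HaplotypeFreqTable:
    """Direct-counting frequency table from a phased panel."""
    if block is not None:
        panel = panel.restrict_snps(block.snp_index_range)
    groups = panel.groups()
    gh = np.array(panel.group_of_hap())
    haps = sorted(set(panel.hap_strings()))
    idx = {h: i for i, h in enumerate(haps)}
    strings = panel.hap_strings()
    freq_by_group = {}
    n_chrom = {}
    for g in groups:
        rows = np.flatnonzero(gh == g)
        c = np.zeros(len(haps))
        for r in rows:
            c[idx[strings[r]]] += 1
        n_chrom[g] = int(rows.size)
        freq_by_group[g] = c / c.sum()
    return HaplotypeFreqTable(block, haps, freq_by_group, n_chrom)


# --------------------------------------------------------------------------
# block-level distribution test (G statistic, label permutation)
# --------------------------------------------------------------------------


def _g_statistic(counts: np.ndarray, pool_below: float = 5.0) -> float:
    """Multinomial likelihood-ratio G between two count vectors (rows=groups).

    Haplotypes with total count below ``pool_below`` are pooled into one
    rare category.  Counts may be fractional (EM-expected).
    """
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum(axis=0)
    rare = tot < pool_below
    if rare.any():
        pooled = counts[:, ~rare]
        rare_col = counts[:, rare].sum(axis=1, keepdims=True)
        counts = np.hstack([pooled, rare_col]) if rare_col.sum() > 0 else pooled
    if counts.shape[1] < 2:
        return 0.0
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row * col / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(counts / expected), 0.0)
    return float(2.0 * terms.sum())


def _pairwise_similarity_statistic(alleles: np.ndarray, is_case: np.ndarray) -> float:
    """Similarity-weighted alternative: between-group minus within-group
    mean pairwise haplotype difference."""
    a = alleles.astype(np.float64)
    diff = a @ (1 - a).T + (1 - a) @ a.T  # pairwise hamming distances
    ca, co = np.flatnonzero(is_case), np.flatnonzero(~is_case)
    between = diff[np.ix_(ca, co)].mean()
    within = 0.5 * (
        _offdiag_mean(diff[np.ix_(ca, ca)]) + _offdiag_mean(diff[np.ix_(co, co)])
    )
    return float(between - within)


def _offdiag_mean(m: np.ndarray) -> float:
    n = m.shape[0]
    if n < 2:
        return 0.0
    return float((m.sum() - np.trace(m)) / (n * (n - 1)))


def block_distribution_test(
    case: HaplotypePanel | GenotypePanel,
    control: HaplotypePanel | GenotypePanel,
    block: HaplotypeBlock | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
    statistic: str = "g",
    pool_below: float = 5.0,
) -> PermutationResult:
    """Permutation test of the overall block haplotype distribution.

    Observed statistic: rare-pooled G between the two groups' haplotype
    counts (or the similarity-weighted variant with ``statistic='similarity'``
    on phased input).  The null is built by permuting individual cohort
    labels, keeping each individual's two chromosomes together.  The default
    1000 permutations follow the usual group-comparison setting.
    """
    rng = np.random.default_rng(seed)
    phased = isinstance(case, HaplotypePanel)
    if phased != isinstance(control, HaplotypePanel):
        raise TypeError("case and control must both be phased panels or both genotypes")
    if phased:
        return _block_test_phased(case, control, block, n_perm, rng, seed, statistic, pool_below)
    return _block_test_genotypes(case, control, block, n_perm, rng, seed, pool_below)


def _block_test_phased(case, control, block, n_perm, rng, seed, statistic, pool_below):
    if block is not None:
        case = case.restrict_snps(block.snp_index_range)
        control = control.restrict_snps(block.snp_index_range)
    if case.n_haplotypes == 0 or control.n_haplotypes == 0:
        raise ValueError("both groups must be non-empty")
    alleles = np.vstack([case.alleles, control.alleles])
    # individuals: consecutive row pairs within each source panel
    n_ind_case = case.n_haplotypes // 2
    n_ind = alleles.shape[0] // 2
    codes = np.unique(alleles, axis=0, return_inverse=True)[1].ravel()
    n_codes = codes.max() + 1
    ind_rows = np.arange(alleles.shape[0]).reshape(n_ind, 2)

    def stat(case_ind: np.ndarray) -> float:
        mask = np.zeros(n_ind, bool)
        mask[case_ind] = True
        rows_case = ind_rows[mask].ravel()
        rows_ctrl = ind_rows[~mask].ravel()
        if statistic == "g":
            c1 = np.bincount(codes[rows_case], minlength=n_codes)
            c2 = np.bincount(codes[rows_ctrl], minlength=n_codes)
            return _g_statistic(np.vstack([c1, c2]), pool_below)
        elif statistic == "similarity":
            is_case = np.zeros(alleles.shape[0], bool)
            is_case[rows_case] = True
            return _pairwise_similarity_statistic(alleles, is_case)
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(np.arange(n_ind_case))
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(n_ind)[:n_ind_case])
    return PermutationResult(observed, perms, seed=seed)


def _block_test_genotypes(case, control, block, n_perm, rng, seed, pool_below):
    if block is not None:
        case = case.restrict_snps(block.snp_index_range)
        control = control.restrict_snps(block.snp_index_range)
    geno = np.vstack([case.genotypes, control.genotypes])
    n_case = case.n_samples
    n_ind = geno.shape[0]
    if n_case == 0 or n_ind - n_case == 0:
        raise ValueError("both groups must be non-empty")

    def stat(case_ind: np.ndarray) -> float:
        mask = np.zeros(n_ind, bool)
        mask[case_ind] = True
        f1, n1 = _em_frequencies(geno[mask])
        f2, n2 = _em_frequencies(geno[~mask])
        haps = sorted(set(f1) | set(f2))
        c1 = np.array([f1.get(h, 0.0) for h in haps]) * 2 * n1
        c2 = np.array([f2.get(h, 0.0) for h in haps]) * 2 * n2
        return _g_statistic(np.vstack([c1, c2]), pool_below)

    observed = stat(np.arange(n_case))
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(n_ind)[:n_case])
    return PermutationResult(observed, perms, seed=seed)


# --------------------------------------------------------------------------
# per-haplotype Fisher scan with BH-FDR
# --------------------------------------------------------------------------


def bh_critical_values(m: int, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up critical values q*i/m for ranks i=1..m."""
    return q * np.arange(1, m + 1) / m


def haplotype_fisher_scan(
    table: HaplotypeFreqTable,
    group_pair: tuple[str, str] | None = None,
    min_freq: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed Fisher exact test per common haplotype, with BH-FDR flags.

    Haplotypes with frequency > ``min_freq`` in at least one of the two
    groups are tested (this haplotype vs all others, 2x2 by group) on
    chromosome counts reconstructed as round(freq x 2N).  BH step-up at
    ``q`` is applied across the tested haplotypes.
    """
    if group_pair is None:
        groups = list(table.freq_by_group)
        if len(groups) != 2:
            raise ValueError("group_pair required when table has != 2 groups")
        group_pair = (groups[0], groups[1])
    g1, g2 = group_pair
    f1, f2 = table.freq_by_group[g1], table.freq_by_group[g2]
    c1, c2 = table.counts(g1), table.counts(g2)
    n1, n2 = table.n_chromosomes_by_group[g1], table.n_chromosomes_by_group[g2]
    keep = (f1 > min_freq) | (f2 > min_freq)
    rows = []
    for i in np.flatnonzero(keep):
        a, b = int(c1[i]), n1 - int(c1[i])
        c, d = int(c2[i]), n2 - int(c2[i])
        if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
            p = 1.0
        else:
            p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append(
            {
                "haplotype": table.haplotypes[i],
                f"freq_{g1}": f1[i],
                f"freq_{g2}": f2[i],
                f"count_{g1}": a,
                f"count_{g2}": c,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        flags, _, _, _ = multipletests(df["p"].to_numpy(), alpha=q, method="fdr_bh")[:4]
        df["bh_significant"] = flags
    else:
        df["bh_significant"] = pd.Series(dtype=bool)
    return df


def odds_ratio_woolf(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    """Odds ratio ad/bc with Woolf 95% CI exp(ln OR +/- 1.96*sqrt(sum 1/cell)).

    Cells are 2x2 chromosome counts [[a, b], [c, d]] (exposed/unexposed by
    group).  Zero cells get the Haldane-Anscombe +0.5 correction (logged).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if (cells == 0).any():
        logger.warning("odds_ratio_woolf: zero cell, applying Haldane-Anscombe +0.5")
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    return float(or_), float(lo), float(hi)


# --------------------------------------------------------------------------
# single-SNP additive trend scan
# --------------------------------------------------------------------------


def trend_scan(case: GenotypePanel, control: GenotypePanel) -> pd.DataFrame:
    """Cochran-Armitage additive-trend test per SNP (uncorrected).

    Scores genotypes 0/1/2; missing genotypes are excluded per SNP.  No
    stratification correction is applied, so p-values are labelled
    uncorrected.  Monomorphic SNPs get p = 1 with a flag.
    """
    if [s.id for s in case.snps] != [s.id for s in control.snps]:
        raise ValueError("case and control must share the same SNP set")
    from scipy.stats import chi2

    rows = []
    for j, snp in enumerate(case.snps):
        gc = case.genotypes[:, j]
        gk = control.genotypes[:, j]
        gc, gk = gc[gc != MISSING], gk[gk != MISSING]
        r = np.array([(gc == x).sum() for x in (0, 1, 2)], dtype=float)  # cases
        s = np.array([(gk == x).sum() for x in (0, 1, 2)], dtype=float)
        n_i = r + s
        N, R = n_i.sum(), r.sum()
        x = np.array([0.0, 1.0, 2.0])
        mono = (n_i > 0).sum() < 2
        if mono or R == 0 or R == N:
            rows.append({"snp": snp.id, "pos": snp.pos, "stat": 0.0, "p": 1.0, "monomorphic": True})
            continue
        num = N * (N * (r @ x) - R * (n_i @ x)) ** 2
        den = R * (N - R) * (N * (n_i @ x**2) - (n_i @ x) ** 2)
        stat = num / den if den > 0 else 0.0
        p = 1.0 if den <= 0 else float(chi2.sf(stat, df=1))
        rows.append({"snp": snp.id, "pos": snp.pos, "stat": float(stat), "p": p, "monomorphic": bool(mono)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# hotspot-intensity difference permutation test
# --------------------------------------------------------------------------


def _check_same_snps(a: HaplotypePanel, b: HaplotypePanel) -> None:
    if [s.id for s in a.snps] != [s.id for s in b.snps] or not np.array_equal(
        a.positions, b.positions
    ):
        raise ValueError("panels must share an identical SNP list")


def hotspot_difference_test(
    case: HaplotypePanel,
    control: HaplotypePanel,
    interval_pair: tuple[str, str],
    n_perm: int = 250,
    mcmc: McmcConfig = McmcConfig(),
    cfg: PacConfig = PacConfig(),
    seed: int | None = 0,
    match_control_size: bool = False,
    relative: bool = False,
) -> PermutationResult:
    """Permutation test of the case-control recombination-rate difference
    across the interval flanked by ``interval_pair`` SNP ids.

    Observed statistic: (median posterior rate across the named span in
    cases) - (same in controls), each median taken over the pooled MCMC
    samples (4 runs x 1000 samples at the defaults); ``relative=True``
    compares intensities relative to each group's own background instead of
    per-bp rates.  The null re-assigns
    individuals to pseudo-case/pseudo-control groups of the original sizes
    ``n_perm`` times (default 250) and recomputes the same statistic;
    the empirical p is two-sided.  ``match_control_size`` first subsamples
    controls to the case count, mirroring matched-size sensitivity checks.
    """
    _check_same_snps(case, control)
    i_left = case.snp_index(interval_pair[0])
    i_right = case.snp_index(interval_pair[1])
    if i_right <= i_left:
        raise ValueError("interval_pair must be (left_snp, right_snp) in position order")
    span = (i_left, i_right - 1)  # interval i spans snp i -> snp i+1
    master = np.random.SeedSequence(0 if seed is None else seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    if match_control_size:
        samples = list(dict.fromkeys(control.sample_of_hap))
        n_case_ind = len(set(case.sample_of_hap))
        pick = rng.choice(len(samples), size=n_case_ind, replace=False)
        control = control.subset_samples([samples[i] for i in sorted(pick)])
    for panel, name in ((case, "case"), (control, "control")):
        if len(set(panel.sample_of_hap)) < 2:
            raise ValueError(f"{name} group has fewer than 2 individuals")

    alleles = np.vstack([case.alleles, control.alleles])
    sample_of_hap = list(case.sample_of_hap) + list(control.sample_of_hap)
    n_ind_case = len(set(case.sample_of_hap))
    ind_rows: dict[str, list[int]] = {}
    for i, s in enumerate(sample_of_hap):
        ind_rows.setdefault(s, []).append(i)
    individuals = list(ind_rows)

    # one seed pair for every evaluation (observed and permuted): the
    # statistic becomes a fixed deterministic function of the group split,
    # so permutation exactness holds while shared Monte-Carlo noise cancels
    # (identical groups give exactly 0) instead of inflating the null spread
    stat_seq = master.spawn(1)[0]
    s_est, s_ord = (int(x.generate_state(1)[0]) % (2**31) for x in stat_seq.spawn(2))

    def stat(case_ind_idx: np.ndarray) -> float:
        mask = np.zeros(len(individuals), bool)
        mask[case_ind_idx] = True
        med = []
        for m in (mask, ~mask):
            rows = np.concatenate([ind_rows[individuals[i]] for i in np.flatnonzero(m)])
            sub = HaplotypePanel(
                alleles[rows],
                case.snps,
                [sample_of_hap[r] for r in rows],
                paired=True,
                allow_monomorphic=True,
            )
            # pseudo-group subsets can lose polymorphism at single SNPs
            post = estimate_rho_map(
                sub,
                dataclasses.replace(mcmc, seed=s_est),
                dataclasses.replace(cfg, seed=s_ord),
                allow_monomorphic=True,
            )
            med.append(post.span_rate_median(span, relative=relative))
        return med[0] - med[1]

    observed = stat(np.arange(n_ind_case))
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(len(individuals))[:n_ind_case])
    return PermutationResult(observed, perms, seed=seed)


# --------------------------------------------------------------------------
# allele-on-haplotype EM assignment (HLA-like multi-allelic locus)
# --------------------------------------------------------------------------


@dataclass
class AlleleAssignment:
    """Result of assigning multi-allelic labels to block haplotypes.

    ``percent[(haplotype, allele)]`` is the percentage of that allele's
    chromosome copies predicted to ride on that haplotype; percentages for
    one allele sum to 100 across haplotypes.
    """

    percent: dict[tuple[str, str], float]
    expected_counts: pd.DataFrame  # haplotypes x alleles
    n_excluded: int

    def format_haplotype(self, haplotype: str, min_percent: float = 1.0) -> str:
        """Table-style rendering, e.g. ``"*06:01 (90%)"`` per haplotype row."""
        parts = [
            f"{a} ({self.percent[(h, a)]:.0f}%)"
            for (h, a) in sorted(self.percent, key=lambda ha: -self.percent[ha])
            if h == haplotype and self.percent[(h, a)] >= min_percent
        ]
        return " ".join(parts)


def allele_on_haplotype(
    block_haps: dict[str, tuple[str, str]],
    typings: dict[str, tuple[str, str]],
) -> AlleleAssignment:
    """EM assignment of which multi-allelic label rides which block haplotype.

    ``block_haps`` maps individuals to their two phased block haplotype
    strings; ``typings`` to their unordered pair of allele labels (e.g.
    HLA-type codes).  Within each doubly-heterozygous individual the pairing
    is latent; EM on the allele-given-haplotype carriage probabilities
    resolves it.  Typed individuals without phased block data are excluded
    and counted.
    """
    usable = []
    n_excluded = 0
    for ind, alleles in typings.items():
        if ind not in block_haps:
            n_excluded += 1
            continue
        usable.append((block_haps[ind], tuple(alleles)))
    if n_excluded:
        logger.warning("allele_on_haplotype: %d typed individuals lack phased data", n_excluded)
    if not usable:
        raise ValueError("no individuals with both typings and phased block haplotypes")
    haps = sorted({h for (h1, h2), _ in usable for h in (h1, h2)})
    alleles = sorted({a for _, (a1, a2) in usable for a in (a1, a2)})
    hi = {h: i for i, h in enumerate(haps)}
    ai = {a: i for i, a in enumerate(alleles)}
    theta = np.full((len(haps), len(alleles)), 1.0 / len(alleles))
    counts = np.zeros_like(theta)
    for _ in range(_EM_MAX_ITER):
        counts[:] = 0.0
        for (h1, h2), (a1, a2) in usable:
            i1, i2 = hi[h1], hi[h2]
            j1, j2 = ai[a1], ai[a2]
            w1 = theta[i1, j1] * theta[i2, j2]
            w2 = theta[i1, j2] * theta[i2, j1]
            tot = w1 + w2
            if tot == 0:
                w1 = w2 = 0.5
            else:
                w1, w2 = w1 / tot, w2 / tot
            counts[i1, j1] += w1
            counts[i2, j2] += w1
            counts[i1, j2] += w2
            counts[i2, j1] += w2
        row = counts.sum(axis=1, keepdims=True)
        new = np.where(row > 0, counts / np.where(row > 0, row, 1.0), theta)
        if np.abs(new - theta).max() < _EM_TOL:
            theta = new
            break
        theta = new
    col = counts.sum(axis=0)
    percent = {}
    for a, j in ai.items():
        for h, i in hi.items():
            percent[(h, a)] = float(100.0 * counts[i, j] / col[j]) if col[j] > 0 else 0.0
    df = pd.DataFrame(counts, index=haps, columns=alleles)
    return AlleleAssignment(percent=percent, expected_counts=df, n_excluded=n_excluded)
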