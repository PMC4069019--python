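"""Scan for cis-acting SNPs associated with recombination hotspot intensity.

The allele-split test partitions a phased panel into the two allelic
backgrounds at a flanking SNP and compares the posterior-median hotspot rate
estimated from each sub-panel; a permutation null (random partitions of the
same sizes) calibrates the difference.  The scan applies the test to a set
of tag SNPs (greedy pairwise tagging at r^2 >= 0.8, MAF > 0.07), repeats
each test on independently subsampled haplotype sets (MAF-dependent
subsample sizes), and flags a SNP only when every replicate p-value clears
the Bonferroni threshold alpha / n_tags.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import HaplotypePanel, PermutationResult
from .pac import McmcConfig, PacConfig, estimate_rho_map

logger = logging.getLogger(__name__)


@dataclass
class SplitScanConfig:
    """Replicate/subsampling rules for :func:`ldsplit_scan`.

    SNPs with MAF > ``maf_split`` (0.1) are tested on ``subsample_high_maf``
    (190) randomly drawn haplotypes per replicate; below it, every
    minor-allele haplotype is kept and major-allele haplotypes are drawn to a
    total of ``subsample_low_maf_total`` (160).  MAF exactly 0.1 follows the
    high-MAF rule.
    """

    n_replicates: int = 10
    subsample_high_maf: int = 190
    subsample_low_maf_total: int = 160
    maf_split: float = 0.1
    inner_n_perm: int = 200
    bonferroni_alpha: float = 0.05
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    pac: PacConfig = field(default_factory=PacConfig)
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SplitScanResult:
    """Per-tag-SNP replicate p-values and the all-replicates Bonferroni flag."""

    table: pd.DataFrame  # snp, pos, maf, p_1..p_R, min_p, max_p, passed
    threshold: float
    n_tags: int

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["passed"], "snp"].tolist()


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def r_squared_matrix(alleles: np.ndarray) -> np.ndarray:
    """Pairwise LD r^2 between SNP columns (squared allele correlation)."""
    a = alleles.astype(float)
    sd = a.std(axis=0)
    centred = a - a.mean(axis=0)
    cov = centred.T @ centred / a.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(sd, sd)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return r**2


def select_tag_snps(
    panel: HaplotypePanel,
    region: tuple[int, int] | None = None,
    r2_threshold: float = 0.8,
    maf_min: float = 0.07,
) -> list[str]:
    """Greedy pairwise tagging: every eligible non-tag SNP ends up at
    r^2 >= threshold with at least one tag.

    ``region`` is an optional (start_bp, end_bp) window, 1-based inclusive.
    SNPs with MAF <= ``maf_min`` are excluded first.  Ties on coverage are
    broken by higher MAF, then lower position.  Returned tag ids are sorted
    by position.
    """
    pos = panel.positions
    maf = panel.maf()
    eligible = maf > maf_min
    if region is not None:
        eligible &= (pos >= region[0]) & (pos <= region[1])
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError("no SNPs eligible for tagging in the requested region")
    r2 = r_squared_matrix(panel.alleles[:, idx])
    covers = r2 >= r2_threshold
    untagged = set(range(idx.size))
    tags: list[int] = []
    while untagged:
        best = min(
            untagged,
            key=lambda i: (-int(covers[i, sorted(untagged)].sum()), -maf[idx[i]], pos[idx[i]]),
        )
        tags.append(best)
        untagged -= set(np.flatnonzero(covers[best]).tolist())
    tag_ids = [panel.snps[idx[i]].id for i in tags]
    return sorted(tag_ids, key=lambda sid: pos[panel.snp_index(sid)])


def allele_split_test(
    panel: HaplotypePanel,
    split_snp: str,
    hotspot_interval: tuple[str, str],
    inner_n_perm: int = 200,
    mcmc: McmcConfig = McmcConfig(),
    cfg: PacConfig = PacConfig(),
    seed: int | None = 0,
    relative: bool = True,
) -> PermutationResult:
    """Two-sided permutation test of allele-conditioned hotspot intensity.

    Haplotype rows are partitioned by their allele at ``split_snp``; the
    statistic is the difference in posterior-median hotspot rate across the
    named span between the two allelic sub-panels — by default on the
    relative (x background) scale on which hotspot intensities are reported.
    The null redraws random partitions of the same sizes ``inner_n_perm``
    times.  The split SNP column itself is excluded from rate estimation:
    it is degenerate (fixed) within the allelic sub-panels but polymorphic
    within permuted ones, so keeping it would bias the observed statistic
    relative to its permutation null.
    """
    j = panel.snp_index(split_snp)
    carrier = panel.alleles[:, j] == 1
    n1, n0 = int(carrier.sum()), int((~carrier).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"split SNP {split_snp} is monomorphic in the panel")
    if min(n0, n1) < 4:
        raise ValueError("allelic sub-panel with < 4 haplotypes: cannot estimate rates")
    if hotspot_interval[0] == split_snp or hotspot_interval[1] == split_snp:
        raise ValueError("split SNP cannot flank the tested hotspot span")
    keep = [c for c in range(panel.n_snps) if c != j]
    panel = HaplotypePanel(
        panel.alleles[:, keep],
        [panel.snps[c] for c in keep],
        list(panel.sample_of_hap),
        dict(panel.group_of_sample),
        paired=panel.paired,
        allow_monomorphic=True,
    )
    i_left = panel.snp_index(hotspot_interval[0])
    i_right = panel.snp_index(hotspot_interval[1])
    if i_right <= i_left:
        raise ValueError("hotspot_interval must be (left_snp, right_snp) in position order")
    span = (i_left, i_right - 1)
    master = np.random.SeedSequence(0 if seed is None else seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    n = panel.n_haplotypes

    # one seed pair for every evaluation (observed and permuted): the
    # statistic is then a fixed deterministic function of the partition, so
    # permutation exactness holds while shared Monte-Carlo noise cancels
    # instead of inflating the null spread
    stat_seq = master.spawn(1)[0]
    s_est, s_ord = (int(x.generate_state(1)[0]) % (2**31) for x in stat_seq.spawn(2))

    def stat(rows_a: np.ndarray) -> float:
        med = []
        mask = np.zeros(n, bool)
        mask[rows_a] = True
        for m in (mask, ~mask):
            sub = panel.subset_haplotypes(np.flatnonzero(m), paired=False)
            post = estimate_rho_map(
                sub,
                dataclasses.replace(mcmc, seed=s_est),
                dataclasses.replace(cfg, seed=s_ord),
                allow_monomorphic=True,
            )
            med.append(post.span_rate_median(span, relative=relative))
        return med[0] - med[1]

    observed = stat(np.flatnonzero(carrier))
    perms = np.empty(inner_n_perm)
    for b in range(inner_n_perm):
        perms[b] = stat(rng.permutation(n)[:n1])
    return PermutationResult(observed, perms, seed=seed)


def _subsample_rows(
    panel: HaplotypePanel, j: int, cfg: SplitScanConfig, rng: np.random.Generator
) -> np.ndarray:
    """MAF-dependent replicate subsample of haplotype rows for one tag SNP."""
    n = panel.n_haplotypes
    col = panel.alleles[:, j]
    minor_is_one = col.mean() <= 0.5
    minor_rows = np.flatnonzero(col == (1 if minor_is_one else 0))
    major_rows = np.flatnonzero(col == (0 if minor_is_one else 1))
    maf = panel.maf()[j]
    if maf > cfg.maf_split or np.isclose(maf, cfg.maf_split):
        k = cfg.subsample_high_maf
        if k > n:
            logger.warning("subsample %d exceeds panel size %d; clipping", k, n)
            k = n
        return np.sort(rng.choice(n, size=k, replace=False))
    total = cfg.subsample_low_maf_total
    if total > n:
        logger.warning("subsample %d exceeds panel size %d; clipping", total, n)
        total = n
    n_major = max(total - minor_rows.size, 0)
    n_major = min(n_major, major_rows.size)
    pick = rng.choice(major_rows.size, size=n_major, replace=False)
    return np.sort(np.concatenate([minor_rows, major_rows[pick]]))


def ldsplit_scan(
    panel: HaplotypePanel,
    tag_snps: list[str],
    hotspot_interval: tuple[str, str],
    cfg: SplitScanConfig = SplitScanConfig(),
) -> SplitScanResult:
    """Replicated allele-split scan over tag SNPs with the all-replicates
    Bonferroni rule.

    Each tag SNP is tested ``cfg.n_replicates`` times on independent
    subsamples (per-replicate seeds derived from the master seed); the SNP
    passes only if every replicate p-value is below
    ``cfg.bonferroni_alpha / len(tag_snps)``.
    """
    thr = bonferroni_threshold(cfg.bonferroni_alpha, len(tag_snps))
    master = np.random.SeedSequence(0 if cfg.seed is None else cfg.seed)
    rows = []
    maf = panel.maf()
    for snp_id, snp_seq in zip(tag_snps, master.spawn(len(tag_snps))):
        j = panel.snp_index(snp_id)
        pvals = []
        for rep_seq in snp_seq.spawn(cfg.n_replicates):
            sub_seq, test_seq = rep_seq.spawn(2)
            rng = np.random.default_rng(sub_seq)
            rows_keep = _subsample_rows(panel, j, cfg, rng)
            sub = panel.subset_haplotypes(rows_keep, paired=False)
            try:
                res = allele_split_test(
                    sub,
                    snp_id,
                    hotspot_interval,
                    inner_n_perm=cfg.inner_n_perm,
                    mcmc=cfg.mcmc,
                    cfg=cfg.pac,
                    seed=int(test_seq.generate_state(1)[0]) % (2**31),
                )
                pvals.append(res.empirical_p)
            except ValueError as e:
                logger.warning("tag %s replicate skipped: %s", snp_id, e)
                pvals.append(1.0)
        row = {
            "snp": snp_id,
            "pos": int(panel.snps[j].pos),
            "maf": float(maf[j]),
        }
        row.update({f"p_{r + 1}": p for r, p in enumerate(pvals)})
        row["min_p"] = min(pvals)
        row["max_p"] = max(pvals)
        row["neg_log10_max_p"] = -np.log10(max(pvals))
        row["passed"] = all(p < thr for p in pvals)
        rows.append(row)
    return SplitScanResult(table=pd.DataFrame(rows), threshold=thr, n_tags=len(tag_snps))
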