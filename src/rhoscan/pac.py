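"""Li & Stephens copying-model (PAC) likelihood and MCMC rate estimation.

The sample likelihood of n phased haplotypes is approximated as a product of
approximate conditionals (PAC): haplotype k+1 is modelled as an imperfect
mosaic copy of the k haplotypes seen before it.  The hidden copied template
follows a Markov chain along the SNPs; in interval i (length L_i bp, per-bp
population-scaled rate rho_i) the chain leaves its template with probability
1 - exp(-rho_i * L_i / k) and then picks a template uniformly (including the
current one).  At each SNP the new haplotype copies its template correctly
with probability k/(k+theta) + theta/(2(k+theta)) and carries a "mutation"
(mismatch) with probability theta/(2(k+theta)), where theta is the per-site
mutation parameter (Watterson-style 1/sum_{i<n} 1/i by default).  The first
haplotype in an order is uniform over the 2^S possible strings, and the log
PAC likelihood is averaged over random haplotype orders.

Per-interval rates are estimated by Metropolis random-walk MCMC on the log
rates targeting posterior ∝ PAC likelihood × prior, with an independent
log-normal prior on each interval's rate relative to the regional background
plus a diffuse log-normal prior on the background level itself (which keeps
the posterior proper, since relative rates are invariant to overall scale).
Following the convention of running several independent chains and pooling,
the point estimate for each interval is the median of the pooled samples
(4 runs × 1000 samples = median of 4000 at the defaults).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import HaplotypePanel, RecombinationMap

logger = logging.getLogger(__name__)

_LOG2 = math.log(2.0)
_BG_PRIOR_SD = 3.0  # sd of the diffuse log-normal prior on the background level


def watterson_theta(n_haplotypes: int) -> float:
    """Watterson-style per-site mutation parameter 1 / sum_{i=1}^{n-1} 1/i."""
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    return 1.0 / sum(1.0 / i for i in range(1, n_haplotypes))


@dataclass
class PacConfig:
    """Copying-model nuisance parameters.

    theta_tilde: per-site mutation parameter; None = Watterson-style value
    for the panel at hand.  n_orders: number of random haplotype orders the
    log PAC likelihood is averaged over.
    """

    theta_tilde: float | None = None
    n_orders: int = 20
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.theta_tilde is not None and self.theta_tilde < 0:
            raise ValueError("theta_tilde must be >= 0")
        if self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")

    def resolve_theta(self, n_haplotypes: int) -> float:
        return self.theta_tilde if self.theta_tilde is not None else watterson_theta(n_haplotypes)


@dataclass
class McmcConfig:
    """Sampler settings for :func:`estimate_rho_map`."""

    n_runs: int = 4
    n_samples_per_run: int = 1000
    n_burnin: int = 500
    proposal_sd: float = 1.0
    prior_sd: float = 2.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_samples_per_run < 1:
            raise ValueError("n_runs and n_samples_per_run must be >= 1")
        if self.proposal_sd <= 0 or self.prior_sd <= 0:
            raise ValueError("proposal_sd and prior_sd must be > 0")


@dataclass
class RhoMapPosterior:
    """Pooled posterior samples of per-interval rates plus the median point map."""

    samples: np.ndarray  # (n_runs * n_samples_per_run, n_intervals)
    lengths: np.ndarray
    acceptance_rates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if (self.samples < 0).any():
            raise ValueError("rate samples must be >= 0")

    @property
    def point_map(self) -> RecombinationMap:
        return RecombinationMap(np.median(self.samples, axis=0), self.lengths)

    def span_rate_samples(self, span: tuple[int, int], relative: bool = False) -> np.ndarray:
        """Length-weighted mean per-bp rate over intervals [i0, i1] per sample.

        With ``relative=True`` each sample's span rate is divided by that
        sample's own length-weighted background, giving the relative
        (x background) scale on which hotspot intensities are reported;
        this also cancels the overall level, which the data identify far
        less sharply than the rate profile.
        """
        i0, i1 = span
        w = self.lengths[i0 : i1 + 1]
        vals = self.samples[:, i0 : i1 + 1] @ (w / w.sum())
        if relative:
            bg = self.samples @ (self.lengths / self.lengths.sum())
            vals = vals / bg
        return vals

    def span_rate_median(self, span: tuple[int, int], relative: bool = False) -> float:
        return float(np.median(self.span_rate_samples(span, relative=relative)))


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _forward_loglik(new_hap, templates, switch, pm, pe):  # pragma: no cover - jit
    k, S = templates.shape
    alpha = np.empty(k)
    tot = 0.0
    for j in range(k):
        e = pm if templates[j, 0] == new_hap[0] else pe
        alpha[j] = e / k
        tot += e / k
    ll = np.log(tot)
    for j in range(k):
        alpha[j] /= tot
    for s in range(1, S):
        sw = switch[s - 1]
        tot = 0.0
        for j in range(k):
            e = pm if templates[j, s] == new_hap[s] else pe
            a = e * ((1.0 - sw) * alpha[j] + sw / k)
            alpha[j] = a
            tot += a
        ll += np.log(tot)
        for j in range(k):
            alpha[j] /= tot
    return ll


@njit(cache=True, fastmath=True)
def _order_loglik(alleles, rho_len, theta):  # pragma: no cover - jit
    n, S = alleles.shape
    ll = -S * _LOG2
    alpha = np.empty(n)
    for k in range(1, n):
        pm = (k + 0.5 * theta) / (k + theta)
        pe = 0.5 * theta / (k + theta)
        tot = 0.0
        for j in range(k):
            e = pm if alleles[j, 0] == alleles[k, 0] else pe
            alpha[j] = e
            tot += e
        ll += np.log(tot / k)
        for j in range(k):
            alpha[j] /= tot
        for s in range(1, S):
            sw = 1.0 - np.exp(-rho_len[s - 1] / k)
            tot = 0.0
            for j in range(k):
                e = pm if alleles[j, s] == alleles[k, s] else pe
                a = e * ((1.0 - sw) * alpha[j] + sw / k)
                alpha[j] = a
                tot += a
            ll += np.log(tot)
            for j in range(k):
                alpha[j] /= tot
    return ll


@njit(cache=True, fastmath=True)
def _panel_loglik(ordered, rho_len, theta):  # pragma: no cover - jit
    tot = 0.0
    for o in range(ordered.shape[0]):
        tot += _order_loglik(ordered[o], rho_len, theta)
    return tot / ordered.shape[0]


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def conditional_haplotype_loglik(
    new_hap: np.ndarray,
    templates: np.ndarray,
    rho_map: RecombinationMap,
    cfg: PacConfig = PacConfig(),
) -> float:
    """Log copying-model probability of ``new_hap`` given ``templates``.

    Forward recursion over the hidden copied template; exponentials over all
    2^S candidate haplotypes sum to 1.
    """
    new_hap = np.ascontiguousarray(new_hap, dtype=np.int8)
    templates = np.ascontiguousarray(np.atleast_2d(templates), dtype=np.int8)
    k, S = templates.shape
    if k < 1:
        raise ValueError("need at least one template haplotype")
    if new_hap.shape != (S,):
        raise ValueError("new haplotype length mismatch with templates")
    if rho_map.n_intervals != S - 1:
        raise ValueError("rho map must have n_snps - 1 intervals")
    theta = cfg.resolve_theta(k + 1)
    switch = 1.0 - np.exp(-rho_map.rates * rho_map.lengths / k)
    pm = (k + 0.5 * theta) / (k + theta)
    pe = 0.5 * theta / (k + theta)
    return float(_forward_loglik(new_hap, templates, switch, pm, pe))


def pac_loglik(
    panel: HaplotypePanel,
    rho_map: RecombinationMap,
    cfg: PacConfig = PacConfig(),
    all_orders: bool = False,
) -> float:
    """Order-averaged log PAC likelihood of the panel under ``rho_map``.

    With ``all_orders=True`` the average runs over every n! haplotype order
    (small n only), making the value exactly invariant to row relabelling;
    otherwise ``cfg.n_orders`` random orders are drawn from ``cfg.seed``.
    """
    if panel.n_haplotypes < 2:
        raise ValueError("panel must contain at least 2 haplotypes")
    if rho_map.n_intervals != panel.n_snps - 1:
        raise ValueError("rho map / panel interval mismatch")
    if (panel.maf() == 0).any():
        logger.info("pac_loglik: panel has monomorphic columns")
    if all_orders:
        import itertools

        perms = list(itertools.permutations(range(panel.n_haplotypes)))
        ordered = np.ascontiguousarray(
            np.stack([panel.alleles[list(p)] for p in perms]), dtype=np.int8
        )
    else:
        ordered = _fixed_orders(panel.alleles, cfg.n_orders, np.random.default_rng(cfg.seed))
    theta = cfg.resolve_theta(panel.n_haplotypes)
    return float(_panel_loglik(ordered, rho_map.rates * rho_map.lengths, theta))


def _fixed_orders(alleles: np.ndarray, n_orders: int, rng: np.random.Generator) -> np.ndarray:
    n = alleles.shape[0]
    out = np.empty((n_orders, n, alleles.shape[1]), dtype=np.int8)
    for o in range(n_orders):
        out[o] = alleles[rng.permutation(n)]
    return np.ascontiguousarray(out)


def _ld_moment_init(panel: HaplotypePanel) -> np.ndarray:
    """Data-driven chain initialisation from adjacent-pair LD.

    Uses the moment approximation E[r^2] ~ 1/(1 + rho) + 1/n for the total
    scaled rate of an interval; clipped to a broad range.  Only the MCMC
    starting point — the posterior is unaffected.
    """
    a = panel.alleles.astype(float)
    n = a.shape[0]
    sd = a.std(axis=0)
    r2 = np.full(panel.n_snps - 1, np.nan)
    for i in range(panel.n_snps - 1):
        if sd[i] > 0 and sd[i + 1] > 0:
            c = np.corrcoef(a[:, i], a[:, i + 1])[0, 1]
            r2[i] = 0.0 if np.isnan(c) else c * c
    denom = np.clip(r2 - 1.0 / n, 0.01, None)
    rho_tot = np.clip(1.0 / denom - 1.0, 0.05, 100.0)
    log_init = np.log(rho_tot / panel.interval_lengths)
    # intervals touching a fixed column carry no LD signal: neutral start
    bad = np.isnan(r2)
    if (~bad).any():
        centre = float(np.median(log_init[~bad]))
    else:
        centre = 0.0
    if bad.any():
        log_init[bad] = centre
    # clip per-bp inits to a band around the panel median: climbing from a
    # modest start is fast (uphill moves accept readily) but descending
    # from a spuriously high start through a flat likelihood — short
    # intervals in particular barely constrain their per-bp rate — is slow
    return np.clip(log_init, centre - math.log(30.0), centre + math.log(30.0))


def _log_prior(log_rates: np.ndarray, lengths: np.ndarray, prior_sd: float, log_r0: float) -> float:
    bg = float(np.exp(log_rates) @ lengths) / lengths.sum()
    lb = math.log(bg)
    rel = log_rates - lb
    return float(-0.5 * (rel @ rel) / prior_sd**2 - 0.5 * ((lb - log_r0) / _BG_PRIOR_SD) ** 2)


def estimate_rho_map(
    panel: HaplotypePanel,
    mcmc: McmcConfig = McmcConfig(),
    cfg: PacConfig = PacConfig(),
    allow_monomorphic: bool = False,
) -> RhoMapPosterior:
    """Posterior samples of per-interval per-bp rates for ``panel``.

    Runs ``mcmc.n_runs`` independent Metropolis chains (seeds derived from
    the master seed); each post-burn-in iteration records one sample, and
    pooled samples define the median point map.  Non-convergence is not
    auto-detected; per-chain acceptance rates are logged and returned for
    inspection.
    """
    if panel.n_snps < 3:
        raise ValueError("need at least 3 SNPs to estimate an interval map")
    if panel.n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    if (panel.maf() == 0).any():
        # allele-conditioned sub-panels legitimately carry fixed columns
        # (e.g. the split SNP itself); rates around them lean on the prior
        if not allow_monomorphic:
            raise ValueError("panel must be polymorphic at every SNP")
        logger.info("estimate_rho_map: panel has monomorphic columns")
    lengths = panel.interval_lengths
    theta = cfg.resolve_theta(panel.n_haplotypes)
    log_init = _ld_moment_init(panel)
    # centre of the background-level prior: length-weighted mean of the init
    log_r0 = math.log(float(np.exp(log_init) @ lengths) / lengths.sum())
    master = np.random.SeedSequence(0 if mcmc.seed is None else mcmc.seed)
    run_seqs = master.spawn(mcmc.n_runs)
    all_samples = []
    acc_rates = []
    n_iv = panel.n_snps - 1
    for seq in run_seqs:
        rng = np.random.default_rng(seq)
        ordered = _fixed_orders(panel.alleles, cfg.n_orders, rng)
        log_rates = log_init.copy()
        cur_ll = _panel_loglik(ordered, np.exp(log_rates) * lengths, theta)
        cur_lp = _log_prior(log_rates, lengths, mcmc.prior_sd, log_r0)
        samples = np.empty((mcmc.n_samples_per_run, n_iv))
        n_acc = n_prop = 0
        for it in range(mcmc.n_burnin + mcmc.n_samples_per_run):
            # single-interval random-walk move
            i = int(rng.integers(n_iv))
            prop = log_rates.copy()
            prop[i] += rng.normal(0.0, mcmc.proposal_sd)
            ll = _panel_loglik(ordered, np.exp(prop) * lengths, theta)
            lp = _log_prior(prop, lengths, mcmc.prior_sd, log_r0)
            n_prop += 1
            if math.log(rng.random()) < (ll + lp) - (cur_ll + cur_lp):
                log_rates, cur_ll, cur_lp = prop, ll, lp
                n_acc += 1
            # global scale move (mixes the overall level)
            delta = rng.normal(0.0, mcmc.proposal_sd / max(1.0, math.sqrt(n_iv)))
            prop = log_rates + delta
            ll = _panel_loglik(ordered, np.exp(prop) * lengths, theta)
            lp = _log_prior(prop, lengths, mcmc.prior_sd, log_r0)
            n_prop += 1
            if math.log(rng.random()) < (ll + lp) - (cur_ll + cur_lp):
                log_rates, cur_ll, cur_lp = prop, ll, lp
                n_acc += 1
            if it >= mcmc.n_burnin:
                samples[it - mcmc.n_burnin] = np.exp(log_rates)
        all_samples.append(samples)
        acc_rates.append(n_acc / n_prop)
    logger.debug("estimate_rho_map acceptance rates: %s", acc_rates)
    return RhoMapPosterior(
        samples=np.concatenate(all_samples, axis=0),
        lengths=lengths,
        acceptance_rates=acc_rates,
    )


def background_and_relative(obj: RecombinationMap | RhoMapPosterior) -> RecombinationMap:
    """Return a RecombinationMap whose background and relative rates are defined.

    Accepts a map or a posterior (whose median point map is used).  Raises on
    an all-zero map, for which relative rates are undefined.
    """
    rmap = obj.point_map if isinstance(obj, RhoMapPosterior) else obj
    rmap.relative_rates  # raises if background is 0
    return rmap
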