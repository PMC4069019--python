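"""Core domain types: haplotype/genotype panels, recombination maps, called features.

The universal input is a :class:`HaplotypePanel` — a phased 0/1 allele matrix
(one row per haplotype, one column per SNP) with per-SNP metadata and a
sample → cohort-label mapping.  Recombination-rate estimates are carried as a
:class:`RecombinationMap`: per-bp population-scaled rates (rho = 4*Ne*c) for
each interval between adjacent SNPs, with the regional background defined as
the length-weighted mean rate and all hotspot/block thresholds expressed as
rates relative to that background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # missing genotype code in GenotypePanel


class PanelFormatError(ValueError):
    """A panel file or matrix violates the format contract."""


class UnphasedGenotypeError(PanelFormatError):
    """A phased-VCF record carries an unphased genotype."""


@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one biallelic SNP.

    pos is the 1-based physical position in bp; maf the minor-allele
    frequency in [0, 0.5]; major/minor the allele labels as coded (allele 0
    and allele 1 of the panel matrix respectively unless stated otherwise).
    """

    id: str
    chrom: str
    pos: int
    maf: float = 0.0
    major: str = "A"
    minor: str = "G"

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"MAF {self.maf} outside [0, 0.5] for SNP {self.id}")


def _check_positions(snps: list[SnpInfo]) -> None:
    pos = [s.pos for s in snps]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise PanelFormatError("SNP positions must be strictly increasing")


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with SNP metadata and cohort labels.

    ``alleles`` is (n_haplotypes, n_snps) of {0,1}; ``sample_of_hap`` maps each
    haplotype row to its individual; ``group_of_sample`` maps individuals to
    cohort labels (e.g. "case"/"control").  With ``paired=True`` (default)
    every individual must contribute exactly two rows; allele-conditioned
    sub-panels (one row per chromosome side) set ``paired=False``.
    """

    alleles: np.ndarray
    snps: list[SnpInfo]
    sample_of_hap: list[str]
    group_of_sample: dict[str, str] = field(default_factory=dict)
    paired: bool = True
    allow_monomorphic: bool = False

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise PanelFormatError("allele matrix must be 2-D")
        if self.alleles.shape[1] != len(self.snps):
            raise PanelFormatError(
                f"{self.alleles.shape[1]} allele columns but {len(self.snps)} SNPs"
            )
        if self.alleles.shape[0] != len(self.sample_of_hap):
            raise PanelFormatError("one sample label required per haplotype row")
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            raise PanelFormatError("allele codes outside {0,1}")
        _check_positions(self.snps)
        if self.paired:
            ids, counts = np.unique(self.sample_of_hap, return_counts=True)
            if (counts != 2).any():
                off = ids[counts != 2]
                raise PanelFormatError(
                    f"individuals must contribute exactly 2 haplotypes: {list(off[:5])}"
                )
        if not self.group_of_sample:
            self.group_of_sample = {s: "all" for s in set(self.sample_of_hap)}
        if not self.allow_monomorphic and self.n_haplotypes > 0:
            mono = np.flatnonzero(self.alleles.min(0) == self.alleles.max(0))
            if mono.size:
                raise PanelFormatError(
                    f"monomorphic columns {mono.tolist()[:5]} "
                    "(pass allow_monomorphic=True to permit)"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    @property
    def interval_lengths(self) -> np.ndarray:
        """bp length of each interval between adjacent SNPs (n_snps - 1)."""
        return np.diff(self.positions).astype(float)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def maf(self) -> np.ndarray:
        """Column minor-allele frequencies computed from the matrix."""
        f = self.alleles.mean(axis=0)
        return np.minimum(f, 1.0 - f)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_of_hap:
            seen.setdefault(self.group_of_sample[s], None)
        return list(seen)

    def group_of_hap(self) -> list[str]:
        return [self.group_of_sample[s] for s in self.sample_of_hap]

    # -- derived panels ----------------------------------------------------
    def with_snp_metadata_maf(self) -> "HaplotypePanel":
        """Return a copy whose SnpInfo.maf fields match the matrix."""
        maf = self.maf()
        snps = [dataclasses.replace(s, maf=round(float(m), 12)) for s, m in zip(self.snps, maf)]
        return dataclasses.replace(self, snps=snps)

    def subset_haplotypes(self, rows: np.ndarray, paired: bool | None = None) -> "HaplotypePanel":
        rows = np.asarray(rows)
        return HaplotypePanel(
            alleles=self.alleles[rows],
            snps=self.snps,
            sample_of_hap=[self.sample_of_hap[i] for i in rows],
            group_of_sample=dict(self.group_of_sample),
            paired=self.paired if paired is None else paired,
            allow_monomorphic=True,
        )

    def subset_samples(self, samples: list[str]) -> "HaplotypePanel":
        keep = set(samples)
        rows = np.array([i for i, s in enumerate(self.sample_of_hap) if s in keep])
        return self.subset_haplotypes(rows)

    def restrict_snps(self, index_range: tuple[int, int]) -> "HaplotypePanel":
        """Restrict to SNP columns [i0, i1] inclusive."""
        i0, i1 = index_range
        return HaplotypePanel(
            alleles=self.alleles[:, i0 : i1 + 1],
            snps=self.snps[i0 : i1 + 1],
            sample_of_hap=list(self.sample_of_hap),
            group_of_sample=dict(self.group_of_sample),
            paired=self.paired,
            allow_monomorphic=True,
        )

    def split_by_group(self) -> dict[str, "HaplotypePanel"]:
        out = {}
        gh = np.array(self.group_of_hap())
        for g in self.groups():
            out[g] = self.subset_haplotypes(np.flatnonzero(gh == g))
        return out

    def hap_strings(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.alleles]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            np.array_equal(self.alleles, other.alleles)
            and self.snps == other.snps
            and self.sample_of_hap == other.sample_of_hap
            and self.group_of_sample == other.group_of_sample
        )


@dataclass
class GenotypePanel:
    """Unphased genotype matrix (individuals × SNPs) with values {0,1,2,MISSING}."""

    genotypes: np.ndarray
    snps: list[SnpInfo]
    samples: list[str]
    group_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise PanelFormatError("genotype matrix shape mismatch")
        if not np.isin(self.genotypes, (0, 1, 2, MISSING)).all():
            raise PanelFormatError("genotype codes outside {0,1,2,missing}")
        _check_positions(self.snps)
        if not self.group_of_sample:
            self.group_of_sample = {s: "all" for s in self.samples}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def restrict_snps(self, index_range: tuple[int, int]) -> "GenotypePanel":
        i0, i1 = index_range
        return GenotypePanel(
            self.genotypes[:, i0 : i1 + 1],
            self.snps[i0 : i1 + 1],
            list(self.samples),
            dict(self.group_of_sample),
        )

    def split_by_group(self) -> dict[str, "GenotypePanel"]:
        out = {}
        labels = np.array([self.group_of_sample[s] for s in self.samples])
        for g in dict.fromkeys(labels.tolist()):
            idx = np.flatnonzero(labels == g)
            out[g] = GenotypePanel(
                self.genotypes[idx],
                self.snps,
                [self.samples[i] for i in idx],
                dict(self.group_of_sample),
            )
        return out


def genotypes_from_panel(panel: HaplotypePanel) -> GenotypePanel:
    """Collapse a phased panel to unphased genotypes (allele-1 dosage)."""
    order: dict[str, list[int]] = {}
    for i, s in enumerate(panel.sample_of_hap):
        order.setdefault(s, []).append(i)
    samples = list(order)
    geno = np.empty((len(samples), panel.n_snps), dtype=np.int8)
    for r, s in enumerate(samples):
        geno[r] = panel.alleles[order[s]].sum(axis=0)
    return GenotypePanel(geno, list(panel.snps), samples, dict(panel.group_of_sample))


@dataclass
class RecombinationMap:
    """Per-interval population-scaled recombination rates.

    ``rates`` are per-bp rho for each interval between adjacent SNPs and
    ``lengths`` the interval bp lengths.  ``background`` is the
    length-weighted mean rate over the region and ``relative_rates`` the
    per-interval rates divided by it — the scale on which hotspot (>10x) and
    block (<=5x) thresholds are defined.
    """

    rates: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.rates.shape != self.lengths.shape or self.rates.ndim != 1:
            raise ValueError("rates and lengths must be matching 1-D arrays")
        if (self.rates < 0).any():
            raise ValueError("recombination rates must be >= 0")
        if (self.lengths <= 0).any():
            raise ValueError("interval lengths must be > 0")

    @property
    def n_intervals(self) -> int:
        return self.rates.size

    @property
    def background(self) -> float:
        """Length-weighted mean per-bp rate across the region (rho-bar)."""
        return float(np.dot(self.rates, self.lengths) / self.lengths.sum())

    @property
    def relative_rates(self) -> np.ndarray:
        bg = self.background
        if bg == 0.0:
            raise ValueError("all-zero map: background rate is 0, relative rates undefined")
        return self.rates / bg

    def total_rho(self) -> float:
        return float(np.dot(self.rates, self.lengths))

    @staticmethod
    def uniform(rate: float, lengths: np.ndarray) -> "RecombinationMap":
        lengths = np.asarray(lengths, dtype=float)
        return RecombinationMap(np.full(lengths.shape, rate), lengths)


@dataclass(frozen=True)
class Hotspot:
    """Maximal run of adjacent-SNP intervals above the hotspot threshold.

    Named by its flanking SNPs, after the convention of reporting hotspots as
    the pair of SNPs that bracket the rate peak.
    """

    left_snp: str
    right_snp: str
    interval_span: tuple[int, ...]  # indices of spanned intervals (interval i = snp i..i+1)
    peak_relative_rate: float


@dataclass(frozen=True)
class HaplotypeBlock:
    """Maximal run of SNPs with all internal intervals at/below the block threshold."""

    snp_index_range: tuple[int, int]  # inclusive
    member_snps: tuple[str, ...]

    @property
    def n_snps(self) -> int:
        return self.snp_index_range[1] - self.snp_index_range[0] + 1


@dataclass
class HaplotypeFreqTable:
    """Estimated block haplotype frequencies per cohort.

    ``freq_by_group`` maps cohort label -> frequency vector over
    ``haplotypes`` (allele strings), summing to 1;
    ``n_chromosomes_by_group`` the 2N chromosome counts.
    """

    block: HaplotypeBlock | None
    haplotypes: list[str]
    freq_by_group: dict[str, np.ndarray]
    n_chromosomes_by_group: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotype strings must be unique")
        for g, f in self.freq_by_group.items():
            f = np.asarray(f, dtype=float)
            self.freq_by_group[g] = f
            if f.shape != (len(self.haplotypes),):
                raise ValueError(f"frequency vector length mismatch for group {g}")
            if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-8:
                raise ValueError(f"frequencies for group {g} must be >=0 and sum to 1")

    def counts(self, group: str) -> np.ndarray:
        """Chromosome counts: round(freq x 2N), ties to even."""
        return np.rint(self.freq_by_group[group] * self.n_chromosomes_by_group[group]).astype(int)


@dataclass
class PermutationResult:
    """Observed statistic, permutation replicates and the empirical p-value.

    The empirical p uses the add-one estimator
    ``(1 + #{|perm| >= |obs|}) / (1 + n_permutations)`` (two-sided, never 0).
    """

    observed_statistic: float
    permuted_statistics: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.permuted_statistics = np.asarray(self.permuted_statistics, dtype=float)

    @property
    def n_permutations(self) -> int:
        return self.permuted_statistics.size

    @property
    def empirical_p(self) -> float:
        exceed = int(
            (np.abs(self.permuted_statistics) >= abs(self.observed_statistic) - 1e-12).sum()
        )
        return (1 + exceed) / (1 + self.n_permutations)
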