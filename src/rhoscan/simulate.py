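"""Coalescent-with-recombination synthetic data for the whole pipeline.

Haplotype panels are drawn from the standard neutral coalescent with
crossover (Hudson-style ancestral recombination graph) under a
piecewise-constant population-scaled recombination map, with infinite-sites
binary mutations, via msprime.  Rates are parameterised directly as
rho = 4*Ne*c per bp (simulations run with population_size=1, ploidy=2, so
per-bp msprime rates are rho/4) and theta = 4*Ne*mu for the whole region.
SNPs are ascertained by a minimum-MAF filter, mimicking genotyping-array
site selection.

Case-control studies are built from two independent panels whose SNP lists
are unified on a fixed window scaffold (the region is divided into equal
windows; each panel contributes its MAF-passing site nearest the window
centre, and windows empty in either panel are dropped from both), so both
cohorts share identical SNP ids and positions while the case group's map can
carry a scaled hotspot.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from .io import HAP_LEGEND, write_panel
from .model import HaplotypePanel, RecombinationMap, SnpInfo

_CHROM = "sim6"


def flat_map(region_length: float, background: float) -> RecombinationMap:
    return RecombinationMap(np.array([background]), np.array([float(region_length)]))


def hotspot_map(
    region_length: float,
    background: float,
    hotspot_start: float,
    hotspot_end: float,
    multiplier: float,
) -> RecombinationMap:
    """Piecewise map: background everywhere, one hotspot piece at multiplier x."""
    if not (0 < hotspot_start < hotspot_end < region_length):
        raise ValueError("hotspot must lie strictly inside the region")
    rates = np.array([background, background * multiplier, background])
    lengths = np.array(
        [hotspot_start, hotspot_end - hotspot_start, region_length - hotspot_end]
    )
    return RecombinationMap(rates, lengths)


@dataclass
class SimParams:
    """Generative settings for one haplotype panel.

    theta is the population-scaled mutation rate for the whole region
    (4*Ne*mu summed over bp); rho_map_true the piecewise-constant per-bp
    rho map whose lengths define the region; maf_ascertainment the minimum
    minor-allele frequency for a site to be retained.
    """

    n_haplotypes: int = 200
    theta: float = 50.0
    rho_map_true: RecombinationMap = field(
        default_factory=lambda: hotspot_map(100_000, 4e-4, 45_000, 47_000, 10.0)
    )
    maf_ascertainment: float = 0.05
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes % 2 or self.n_haplotypes < 4:
            raise ValueError("n_haplotypes must be even and >= 4")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0 <= self.maf_ascertainment < 0.5:
            raise ValueError("maf_ascertainment must be in [0, 0.5)")

    @property
    def region_length(self) -> float:
        return float(self.rho_map_true.lengths.sum())


@dataclass
class PanelTruth:
    """What the generator knows: the bp-scale map, its SNP-interval
    aggregation, and the pre-ascertainment segregating-site count."""

    bp_map: RecombinationMap
    interval_map: RecombinationMap | None
    n_raw_sites: int


@dataclass
class StudyTruth:
    """Truth record for a two-cohort study with a group-specific hotspot."""

    control_bp_map: RecombinationMap
    case_bp_map: RecombinationMap
    control_interval_map: RecombinationMap
    case_interval_map: RecombinationMap
    snps: list[SnpInfo]
    hotspot_span: tuple[int, int]  # inclusive SNP-interval index range
    hotspot_flanks: tuple[str, str]
    case_multiplier: float


@dataclass
class AlleleLinkedTruth:
    """Truth record for an allele-conditioned hotspot panel."""

    off_bp_map: RecombinationMap
    on_bp_map: RecombinationMap
    split_snp: str
    n_carrier_haplotypes: int
    snps: list[SnpInfo]
    hotspot_span: tuple[int, int]
    hotspot_flanks: tuple[str, str]


def _msprime_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0]) % (2**31 - 2) + 1


def _simulate_raw(
    n_haplotypes: int,
    theta: float,
    bp_map: RecombinationMap,
    seq: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw biallelic sites: (haplotype x site) matrix and float bp positions."""
    L = float(bp_map.lengths.sum())
    breaks = np.concatenate([[0.0], np.cumsum(bp_map.lengths)])
    breaks[-1] = L
    rate_map = msprime.RateMap(position=breaks, rate=bp_map.rates / 4.0)
    s_anc, s_mut = seq.spawn(2)
    ts = msprime.sim_ancestry(
        samples=n_haplotypes // 2,
        ploidy=2,
        population_size=1.0,
        recombination_rate=rate_map,
        sequence_length=L,
        random_seed=_msprime_seed(s_anc),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=theta / (4.0 * L),
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=_msprime_seed(s_mut),
    )
    mat = mts.genotype_matrix().T.astype(np.int8)  # haplotypes x sites
    pos = np.array([s.position for s in mts.sites()])
    return mat, pos


def _int_positions(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-based integer positions; drops sites colliding after flooring."""
    ip = np.floor(pos).astype(np.int64) + 1
    keep = np.concatenate([[True], np.diff(ip) > 0])
    return ip[keep], np.flatnonzero(keep)


def _mean_rate_over(bp_map: RecombinationMap, a: float, b: float) -> float:
    """Length-weighted mean per-bp rate of the piecewise map over [a, b)."""
    breaks = np.concatenate([[0.0], np.cumsum(bp_map.lengths)])
    total = 0.0
    for i, r in enumerate(bp_map.rates):
        lo, hi = max(a, breaks[i]), min(b, breaks[i + 1])
        if hi > lo:
            total += r * (hi - lo)
    return total / (b - a)


def interval_map_from_bp(bp_map: RecombinationMap, positions: np.ndarray) -> RecombinationMap:
    """Aggregate a bp-scale map to adjacent-SNP intervals."""
    rates = np.array(
        [
            _mean_rate_over(bp_map, float(positions[i]), float(positions[i + 1]))
            for i in range(len(positions) - 1)
        ]
    )
    return RecombinationMap(rates, np.diff(positions).astype(float))


def _make_snps(positions: np.ndarray, prefix: str = "snp") -> list[SnpInfo]:
    return [
        SnpInfo(id=f"{prefix}{i + 1:04d}", chrom=_CHROM, pos=int(p))
        for i, p in enumerate(positions)
    ]


def _paired_panel(alleles: np.ndarray, snps: list[SnpInfo], group: str, prefix: str) -> HaplotypePanel:
    n_ind = alleles.shape[0] // 2
    samples = [f"{prefix}{i:04d}" for i in range(n_ind)]
    return HaplotypePanel(
        alleles=alleles,
        snps=snps,
        sample_of_hap=[s for s in samples for _ in range(2)],
        group_of_sample={s: group for s in samples},
        allow_monomorphic=True,
    ).with_snp_metadata_maf()


def simulate_panel(
    params: SimParams, group: str = "all", sample_prefix: str = "ind"
) -> tuple[HaplotypePanel, PanelTruth]:
    """One coalescent panel with MAF-ascertained SNPs and its truth record."""
    seq = np.random.SeedSequence(0 if params.seed is None else params.seed)
    mat, pos = _simulate_raw(params.n_haplotypes, params.theta, params.rho_map_true, seq)
    n_raw = mat.shape[1]
    ip, keep = _int_positions(pos)
    mat = mat[:, keep]
    freq = mat.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    asc = maf >= params.maf_ascertainment
    if asc.sum() < 2:
        raise ValueError(
            "fewer than 2 segregating sites after MAF ascertainment; increase theta"
        )
    mat, ip = mat[:, asc], ip[asc]
    snps = _make_snps(ip)
    panel = _paired_panel(mat, snps, group, sample_prefix)
    truth = PanelTruth(
        bp_map=params.rho_map_true,
        interval_map=interval_map_from_bp(params.rho_map_true, ip),
        n_raw_sites=n_raw,
    )
    return panel, truth


# --------------------------------------------------------------------------
# scaffolded two-cohort studies
# --------------------------------------------------------------------------


def _scaffold_pick(
    positions: np.ndarray, maf: np.ndarray, edges: np.ndarray, maf_min: float
) -> np.ndarray:
    """Per window, the index of the MAF-passing site nearest the centre (-1 if none)."""
    out = np.full(edges.size - 1, -1, dtype=np.int64)
    centres = 0.5 * (edges[:-1] + edges[1:])
    for w in range(edges.size - 1):
        in_w = np.flatnonzero(
            (positions >= edges[w]) & (positions < edges[w + 1]) & (maf >= maf_min)
        )
        if in_w.size:
            out[w] = in_w[np.argmin(np.abs(positions[in_w] - centres[w]))]
    return out


def _scaffold_two_panels(
    raw_a: tuple[np.ndarray, np.ndarray],
    raw_b: tuple[np.ndarray, np.ndarray],
    region_length: float,
    n_snps: int,
    maf_min: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unify two raw panels on a common window scaffold.

    Returns (alleles_a, alleles_b, scaffold_positions); scaffold positions
    are the window centres shared by both panels.
    """
    edges = np.linspace(0.0, region_length, n_snps + 1)
    picks = []
    for mat, pos in (raw_a, raw_b):
        freq = mat.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        picks.append(_scaffold_pick(pos, maf, edges, maf_min))
    ok = (picks[0] >= 0) & (picks[1] >= 0)
    if ok.sum() < 3:
        raise ValueError("scaffold too sparse: fewer than 3 shared windows; increase theta")
    # shared scaffold position = midpoint of the two panels' true site
    # positions (within the same window), keeping positions near-true so the
    # bp-scale map aggregates faithfully onto the shared intervals
    pos_a = raw_a[1][picks[0][ok]]
    pos_b = raw_b[1][picks[1][ok]]
    shared = np.floor(0.5 * (pos_a + pos_b)).astype(np.int64) + 1
    keep = np.concatenate([[True], np.diff(shared) > 0])
    a = raw_a[0][:, picks[0][ok]][:, keep]
    b = raw_b[0][:, picks[1][ok]][:, keep]
    return a, b, shared[keep]


def _scaffold_one_panel(
    raw: tuple[np.ndarray, np.ndarray],
    region_length: float,
    n_snps: int,
    maf_min: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Window-scaffold site selection for a single panel (true positions)."""
    mat, pos = raw
    edges = np.linspace(0.0, region_length, n_snps + 1)
    freq = mat.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    picks = _scaffold_pick(pos, maf, edges, maf_min)
    ok = picks >= 0
    if ok.sum() < 3:
        raise ValueError("scaffold too sparse: fewer than 3 windows; increase theta")
    ip = np.floor(pos[picks[ok]]).astype(np.int64) + 1
    keep = np.concatenate([[True], np.diff(ip) > 0])
    return mat[:, picks[ok]][:, keep], ip[keep]


def _hotspot_span_on_snps(
    positions: np.ndarray, bp_map: RecombinationMap, piece: int
) -> tuple[int, int]:
    """SNP-interval index range carrying map piece ``piece``.

    Returns the single adjacent-SNP interval with the largest bp overlap
    with the piece (as an inclusive (i, i) range), which is how a hotspot is
    named by its flanking SNP pair.
    """
    breaks = np.concatenate([[0.0], np.cumsum(bp_map.lengths)])
    lo, hi = breaks[piece], breaks[piece + 1]
    overlaps = np.array(
        [
            max(0.0, min(hi, positions[i + 1]) - max(lo, positions[i]))
            for i in range(len(positions) - 1)
        ]
    )
    if overlaps.max() <= 0:
        raise ValueError("no SNP interval overlaps the hotspot piece")
    i = int(overlaps.argmax())
    return i, i


def scaled_map(bp_map: RecombinationMap, piece: int, multiplier: float) -> RecombinationMap:
    rates = bp_map.rates.copy()
    rates[piece] *= multiplier
    return RecombinationMap(rates, bp_map.lengths.copy())


def simulate_case_control_study(
    base: SimParams,
    hotspot_piece: int,
    case_multiplier: float,
    n_case_ind: int,
    n_ctrl_ind: int,
    seed: int | None = 0,
    n_snps: int = 30,
) -> tuple[HaplotypePanel, HaplotypePanel, StudyTruth]:
    """Two independent cohorts on one SNP scaffold, the case cohort's map
    carrying the base hotspot piece scaled by ``case_multiplier``."""
    if case_multiplier <= 0:
        raise ValueError("case_multiplier must be > 0")
    seq = np.random.SeedSequence(0 if seed is None else seed)
    s_case, s_ctrl = seq.spawn(2)
    ctrl_map = base.rho_map_true
    case_map = scaled_map(ctrl_map, hotspot_piece, case_multiplier)
    raw_case = _simulate_raw(2 * n_case_ind, base.theta, case_map, s_case)
    raw_ctrl = _simulate_raw(2 * n_ctrl_ind, base.theta, ctrl_map, s_ctrl)
    a_case, a_ctrl, scaffold_pos = _scaffold_two_panels(
        raw_case, raw_ctrl, base.region_length, n_snps, base.maf_ascertainment
    )
    snps = _make_snps(scaffold_pos, prefix="w")
    case_panel = _paired_panel(a_case, snps, "case", "case")
    ctrl_panel = _paired_panel(a_ctrl, snps, "control", "ctrl")
    span = _hotspot_span_on_snps(scaffold_pos, ctrl_map, hotspot_piece)
    truth = StudyTruth(
        control_bp_map=ctrl_map,
        case_bp_map=case_map,
        control_interval_map=interval_map_from_bp(ctrl_map, scaffold_pos),
        case_interval_map=interval_map_from_bp(case_map, scaffold_pos),
        snps=snps,
        hotspot_span=span,
        hotspot_flanks=(snps[span[0]].id, snps[span[1] + 1].id),
        case_multiplier=case_multiplier,
    )
    return case_panel, ctrl_panel, truth


def simulate_allele_linked_hotspot(
    base: SimParams,
    split_snp_maf: float,
    on_allele_multiplier: float,
    hotspot_piece: int = 1,
    seed: int | None = 0,
    n_snps: int = 30,
    split_offset_bp: float = 5000.0,
) -> tuple[HaplotypePanel, AlleleLinkedTruth]:
    """Panel whose hotspot is active only on one allelic background.

    Haplotypes carrying allele 1 at the inserted split SNP are drawn under
    the base map with the hotspot piece scaled by ``on_allele_multiplier``;
    the rest under the base map.  The carrier count is binomial around
    ``split_snp_maf``.  The two sub-panels are unified on the window
    scaffold, and the split SNP is inserted ``split_offset_bp`` centromeric
    of the hotspot piece — a flanking cis-acting marker, not a SNP inside
    the hotspot itself.
    """
    if not 0 < split_snp_maf <= 0.5:
        raise ValueError("split_snp_maf must be in (0, 0.5]")
    n = base.n_haplotypes
    seq = np.random.SeedSequence(0 if seed is None else seed)
    s_draw, s_on, s_off = seq.spawn(3)
    rng = np.random.default_rng(s_draw)
    k = int(np.clip(rng.binomial(n, split_snp_maf), 4, n - 4))
    off_map = base.rho_map_true
    on_map = scaled_map(off_map, hotspot_piece, on_allele_multiplier)
    if on_allele_multiplier == 1.0:
        # no allele-map linkage: one population, the split allele rides a
        # uniformly random subset of haplotypes (the exchangeable null)
        raw = _simulate_raw(n, base.theta, off_map, s_on)
        a_all, scaffold_pos = _scaffold_one_panel(
            raw, base.region_length, n_snps, base.maf_ascertainment
        )
        carrier_rows = rng.permutation(n)[:k]
        order_on = np.sort(carrier_rows)
        order_off = np.sort(np.setdiff1d(np.arange(n), carrier_rows))
        a_on, a_off = a_all[order_on], a_all[order_off]
    else:
        raw_on = _simulate_raw(2 * ((k + 1) // 2), base.theta, on_map, s_on)
        raw_off = _simulate_raw(2 * ((n - k + 1) // 2), base.theta, off_map, s_off)
        a_on, a_off, scaffold_pos = _scaffold_two_panels(
            raw_on, raw_off, base.region_length, n_snps, base.maf_ascertainment
        )
        a_on, a_off = a_on[:k], a_off[: n - k]
    snps = _make_snps(scaffold_pos, prefix="w")
    # insert the split SNP centromeric of the hotspot piece
    breaks = np.concatenate([[0.0], np.cumsum(off_map.lengths)])
    split_pos = int(breaks[hotspot_piece] - split_offset_bp)
    if split_pos <= 0:
        split_pos = max(1, int(breaks[hotspot_piece]) - 100)
    while split_pos in scaffold_pos:
        split_pos -= 1
    alleles = np.vstack([a_on, a_off])
    split_col = np.concatenate([np.ones(k, np.int8), np.zeros(n - k, np.int8)])
    ins = int(np.searchsorted(scaffold_pos, split_pos))
    alleles = np.insert(alleles, ins, split_col, axis=1)
    all_pos = np.insert(scaffold_pos, ins, split_pos)
    all_snps = snps[:ins] + [SnpInfo(id="split_snp", chrom=_CHROM, pos=split_pos)] + snps[ins:]
    order = rng.permutation(n)
    samples = [f"hap{i:04d}" for i in range(n)]
    panel = HaplotypePanel(
        alleles=alleles[order],
        snps=all_snps,
        sample_of_hap=[samples[i] for i in order],
        group_of_sample={s: "all" for s in samples},
        paired=False,
        allow_monomorphic=True,
    ).with_snp_metadata_maf()
    # flanks are named on the scaffold (the split SNP is a conditioning
    # marker, not a rate-map boundary)
    sspan = _hotspot_span_on_snps(scaffold_pos, off_map, hotspot_piece)
    flanks = (snps[sspan[0]].id, snps[sspan[1] + 1].id)
    ids = [s.id for s in all_snps]
    span = (ids.index(flanks[0]), ids.index(flanks[1]) - 1)
    truth = AlleleLinkedTruth(
        off_bp_map=off_map,
        on_bp_map=on_map,
        split_snp="split_snp",
        n_carrier_haplotypes=k,
        snps=all_snps,
        hotspot_span=span,
        hotspot_flanks=flanks,
    )
    return panel, truth


def attach_multiallelic_locus(
    panel: HaplotypePanel,
    block: tuple[int, int],
    allele_carriage: dict[str, dict[str, float]],
    seed: int | None = 0,
) -> dict[str, tuple[str, str]]:
    """Sample an HLA-like typing pair per individual.

    Each haplotype copy draws an allele label from the carriage distribution
    of its block haplotype string; individuals receive the unordered pair.
    """
    rng = np.random.default_rng(0 if seed is None else seed)
    sub = panel.restrict_snps(block)
    strings = sub.hap_strings()
    rows_of: dict[str, list[int]] = {}
    for i, s in enumerate(panel.sample_of_hap):
        rows_of.setdefault(s, []).append(i)
    typings: dict[str, tuple[str, str]] = {}
    for sample, rows in rows_of.items():
        if len(rows) != 2:
            raise ValueError(f"individual {sample} lacks two block haplotypes")
        drawn = []
        for r in rows:
            h = strings[r]
            if h not in allele_carriage:
                raise KeyError(f"no carriage distribution for block haplotype {h}")
            dist = allele_carriage[h]
            labels = sorted(dist)
            probs = np.array([dist[a] for a in labels], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(f"carriage for haplotype {h} does not sum to 1")
            drawn.append(labels[rng.choice(len(labels), p=probs)])
        typings[sample] = tuple(sorted(drawn))
    return typings


# --------------------------------------------------------------------------
# fixture suite
# --------------------------------------------------------------------------


def generate_fixture_suite(out_dir: str | Path, master_seed: int = 0) -> list[str]:
    """Write the standard small fixture set; byte-reproducible given the seed.

    Produces a null study, a 10x-difference study, an allele-linked panel and
    an HLA-typed cohort, plus an inventory TSV listing every file with its
    truth parameters.  Returns the list of written file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0]) % (2**31) for s in seq.spawn(4)]
    base = SimParams(n_haplotypes=80, theta=30.0, seed=None)
    inventory: list[tuple[str, str]] = []
    written: list[str] = []

    def emit(panel: HaplotypePanel, stem: str, truth: str) -> None:
        write_panel(panel, out / stem, format=HAP_LEGEND)
        for ext in (".hap", ".legend", ".samples"):
            written.append(stem + ext)
            inventory.append((stem + ext, truth))

    for stem, mult, s in (("null_study", 1.0, seeds[0]), ("diff_study", 10.0, seeds[1])):
        case, ctrl, truth = simulate_case_control_study(
            base, hotspot_piece=1, case_multiplier=mult, n_case_ind=40, n_ctrl_ind=40,
            seed=s, n_snps=20,
        )
        desc = (
            f"case_multiplier={mult};seed={s};hotspot_flanks={truth.hotspot_flanks[0]},"
            f"{truth.hotspot_flanks[1]};background={base.rho_map_true.rates[0]:g}"
        )
        emit(case, f"{stem}_case", desc)
        emit(ctrl, f"{stem}_ctrl", desc)

    panel, at = simulate_allele_linked_hotspot(
        SimParams(n_haplotypes=120, theta=30.0, seed=None),
        split_snp_maf=0.3,
        on_allele_multiplier=20.0,
        seed=seeds[2],
        n_snps=20,
    )
    # hap/legend trio for an unpaired panel
    desc = (
        f"on_allele_multiplier=20;split_snp={at.split_snp};"
        f"carriers={at.n_carrier_haplotypes};seed={seeds[2]}"
    )
    write_panel(panel, out / "allele_linked", format=HAP_LEGEND)
    for ext in (".hap", ".legend", ".samples"):
        written.append("allele_linked" + ext)
        inventory.append(("allele_linked" + ext, desc))

    typed_panel, _ = simulate_panel(
        dataclasses.replace(base, n_haplotypes=60, seed=seeds[3]), group="typed"
    )
    blk = (0, min(2, typed_panel.n_snps - 1))
    haps = sorted(set(typed_panel.restrict_snps(blk).hap_strings()))
    carriage = {
        h: {f"*{(i % 4) + 1:02d}:01": 1.0} for i, h in enumerate(haps)
    }
    typings = attach_multiallelic_locus(typed_panel, blk, carriage, seed=seeds[3])
    emit(typed_panel, "typed_cohort", f"block={blk};seed={seeds[3]}")
    with open(out / "typed_cohort.typings.tsv", "w") as fh:
        fh.write("sample\tallele1\tallele2\n")
        for s in sorted(typings):
            fh.write(f"{s}\t{typings[s][0]}\t{typings[s][1]}\n")
    written.append("typed_cohort.typings.tsv")
    inventory.append(("typed_cohort.typings.tsv", f"carriage=deterministic;block={blk}"))

    with open(out / "inventory.tsv", "w") as fh:
        fh.write("file\ttruth\n")
        for name, desc in inventory:
            fh.write(f"{name}\t{desc}\n")
    written.append("inventory.tsv")
    with open(out / "MANIFEST.txt", "w") as fh:
        fh.write(f"master_seed={master_seed}\n")
        fh.write(f"n_files={len(written)}\n")
    written.append("MANIFEST.txt")
    return written
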