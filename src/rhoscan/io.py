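"""Readers and writers: phased VCF, IMPUTE-style hap/legend, BED, TSV tables.

Coordinate conventions: SNP positions are 1-based inclusive everywhere inside
the package; BED export is 0-based half-open, so a feature flanked by SNPs at
1-based positions p_l and p_r becomes the record ``start=p_l-1, end=p_r``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pysam

from .model import (
    HaplotypeBlock,
    HaplotypePanel,
    Hotspot,
    PanelFormatError,
    SnpInfo,
    UnphasedGenotypeError,
)

PHASED_VCF = "phased-vcf"
HAP_LEGEND = "impute-hap-legend"

_GROUP_META = "rhoscan_sample_group"


def _hap_legend_paths(path: str | Path) -> tuple[Path, Path, Path]:
    p = Path(path)
    if p.suffix in {".hap", ".legend", ".samples"}:
        p = p.with_suffix("")
    return p.with_suffix(".hap"), p.with_suffix(".legend"), p.with_suffix(".samples")


def read_panel(path: str | Path, format: str = PHASED_VCF) -> HaplotypePanel:
    """Read a phased haplotype panel from ``path``.

    ``format`` is ``"phased-vcf"`` (all GT fields must be phased) or
    ``"impute-hap-legend"`` (``path`` may be the ``.hap`` file or the common
    basename of the ``.hap``/``.legend``/``.samples`` trio).  SNPs are sorted
    by position on read and MAFs recomputed from the data.
    """
    if format == PHASED_VCF:
        panel = _read_vcf(Path(path))
    elif format == HAP_LEGEND:
        panel = _read_hap_legend(path)
    else:
        raise ValueError(f"unknown panel format {format!r}")
    return panel.with_snp_metadata_maf()


def _read_vcf(path: Path) -> HaplotypePanel:
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        groups: dict[str, str] = {}
        for line in str(vcf.header).splitlines():
            if line.startswith(f"##{_GROUP_META}="):
                sample, _, label = line.split("=", 1)[1].partition(":")
                groups[sample] = label
        rows: list[np.ndarray] = []
        snps: list[SnpInfo] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise PanelFormatError(f"record {rec.id or rec.pos}: not biallelic")
            col = np.empty(2 * len(samples), dtype=np.int8)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    raise PanelFormatError(
                        f"record {rec.id or rec.pos}, sample {s}: missing genotype"
                    )
                if not call.phased:
                    raise UnphasedGenotypeError(
                        f"record {rec.id or rec.pos}, sample {s}: unphased genotype"
                    )
                if any(a not in (0, 1) for a in gt):
                    raise PanelFormatError(
                        f"record {rec.id or rec.pos}, sample {s}: allele code outside {{0,1}}"
                    )
                col[2 * j : 2 * j + 2] = gt
            rows.append(col)
            snps.append(
                SnpInfo(
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    major=str(rec.ref),
                    minor=str(rec.alts[0]),
                )
            )
    if not snps:
        raise PanelFormatError(f"{path}: no variant records")
    order = _position_order(snps)
    alleles = np.stack(rows, axis=1)[:, order]
    sample_of_hap = [s for s in samples for _ in range(2)]
    # VCF stores haplotypes sample-major; reorder rows accordingly
    return HaplotypePanel(
        alleles=alleles,
        snps=[snps[i] for i in order],
        sample_of_hap=sample_of_hap,
        group_of_sample={s: groups.get(s, "all") for s in samples},
        allow_monomorphic=True,
    )


def _position_order(snps: list[SnpInfo]) -> list[int]:
    pos = [s.pos for s in snps]
    if len(set(pos)) != len(pos):
        raise PanelFormatError("duplicate SNP positions")
    return sorted(range(len(pos)), key=pos.__getitem__)


def _read_hap_legend(path: str | Path) -> HaplotypePanel:
    hap_p, leg_p, smp_p = _hap_legend_paths(path)
    for p in (hap_p, leg_p, smp_p):
        if not p.exists():
            raise FileNotFoundError(p)
    snps: list[SnpInfo] = []
    chrom = "unknown"
    with open(leg_p) as fh:
        header = fh.readline().split()
        if header[:4] != ["id", "position", "allele0", "allele1"]:
            raise PanelFormatError(f"{leg_p}: bad legend header {header!r}")
        for line in fh:
            sid, pos, a0, a1 = line.split()
            snps.append(SnpInfo(id=sid, chrom=chrom, pos=int(pos), major=a0, minor=a1))
    sample_of_hap: list[str] = []
    groups: dict[str, str] = {}
    with open(smp_p) as fh:
        for line in fh:
            if line.startswith("#chrom="):
                chrom = line.strip().split("=", 1)[1]
                continue
            sample, group = line.split()
            sample_of_hap.append(sample)
            groups[sample] = group
    snps = [SnpInfo(s.id, chrom, s.pos, s.maf, s.major, s.minor) for s in snps]
    try:
        mat = np.loadtxt(hap_p, dtype=np.int8, ndmin=2)
    except ValueError as e:
        raise PanelFormatError(f"{hap_p}: {e}") from None
    if mat.shape[0] != len(snps):
        raise PanelFormatError(
            f"{hap_p}: {mat.shape[0]} rows but legend lists {len(snps)} SNPs"
        )
    order = _position_order(snps)
    return HaplotypePanel(
        alleles=mat.T[:, order],
        snps=[snps[i] for i in order],
        sample_of_hap=sample_of_hap,
        group_of_sample=groups,
        allow_monomorphic=True,
    )


def write_panel(panel: HaplotypePanel, path: str | Path, format: str = PHASED_VCF) -> None:
    """Write ``panel`` to ``path``; output is bit-stable and round-trips."""
    if panel.n_snps == 0:
        raise PanelFormatError("refusing to write a panel with 0 SNPs")
    if format == PHASED_VCF:
        _write_vcf(panel, Path(path))
    elif format == HAP_LEGEND:
        _write_hap_legend(panel, path)
    else:
        raise ValueError(f"unknown panel format {format!r}")


def _write_vcf(panel: HaplotypePanel, path: Path) -> None:
    if not panel.paired:
        raise PanelFormatError("VCF output requires a diploid-paired panel")
    hdr = pysam.VariantHeader()
    chroms = dict.fromkeys(s.chrom for s in panel.snps)
    maxpos = max(s.pos for s in panel.snps)
    for c in chroms:
        hdr.add_line(f"##contig=<ID={c},length={maxpos + 1}>")
    hdr.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    rows_of: dict[str, list[int]] = {}
    for i, s in enumerate(panel.sample_of_hap):
        rows_of.setdefault(s, []).append(i)
    samples = list(rows_of)
    for s in samples:
        hdr.add_line(f"##{_GROUP_META}={s}:{panel.group_of_sample[s]}")
        hdr.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=hdr) as out:
        for j, snp in enumerate(panel.snps):
            rec = out.new_record(
                contig=snp.chrom,
                start=snp.pos - 1,
                stop=snp.pos,
                alleles=(snp.major, snp.minor),
                id=snp.id,
            )
            for s in samples:
                r0, r1 = rows_of[s]
                rec.samples[s]["GT"] = (int(panel.alleles[r0, j]), int(panel.alleles[r1, j]))
                rec.samples[s].phased = True
            out.write(rec)


def _write_hap_legend(panel: HaplotypePanel, path: str | Path) -> None:
    hap_p, leg_p, smp_p = _hap_legend_paths(path)
    with open(leg_p, "w") as fh:
        fh.write("id position allele0 allele1\n")
        for s in panel.snps:
            fh.write(f"{s.id} {s.pos} {s.major} {s.minor}\n")
    with open(hap_p, "w") as fh:
        for j in range(panel.n_snps):
            fh.write(" ".join(str(int(a)) for a in panel.alleles[:, j]) + "\n")
    with open(smp_p, "w") as fh:
        fh.write(f"#chrom={panel.snps[0].chrom}\n")
        for s in panel.sample_of_hap:
            fh.write(f"{s} {panel.group_of_sample[s]}\n")


def write_intervals_bed(
    features: list[Hotspot] | list[HaplotypeBlock],
    snps: list[SnpInfo],
    path: str | Path,
) -> None:
    """Write hotspots or blocks as BED records (0-based half-open).

    Each feature spans from its left-flank SNP position - 1 to its
    right-flank SNP position.
    """
    by_id = {s.id: s for s in snps}
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for i, f in enumerate(features):
            if isinstance(f, Hotspot):
                left, right = f.left_snp, f.right_snp
                name = f"hotspot_{left}--{right}"
            elif isinstance(f, HaplotypeBlock):
                left, right = f.member_snps[0], f.member_snps[-1]
                name = f"block_{i + 1}_{left}--{right}"
            else:
                raise TypeError(f"unsupported feature type {type(f).__name__}")
            try:
                ls, rs = by_id[left], by_id[right]
            except KeyError as e:
                raise KeyError(f"feature references unknown SNP id {e.args[0]!r}") from None
            fh.write(f"{ls.chrom}\t{ls.pos - 1}\t{rs.pos}\t{name}\n")


def write_map_table(rates: np.ndarray, rel: np.ndarray, snps: list[SnpInfo], path: str | Path) -> None:
    """Point-map TSV: left_snp, right_snp, rate_per_bp, relative_rate."""
    with open(path, "w") as fh:
        fh.write("left_snp\tright_snp\trate_per_bp\trelative_rate\n")
        for i in range(len(rates)):
            fh.write(f"{snps[i].id}\t{snps[i + 1].id}\t{rates[i]:.8g}\t{rel[i]:.6g}\n")


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
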