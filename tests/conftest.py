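from __future__ import annotations

import numpy as np
import pytest

from rhoscan.model import HaplotypePanel, RecombinationMap, SnpInfo


def make_panel(
    alleles: np.ndarray,
    positions: list[int] | None = None,
    groups: dict[str, str] | None = None,
    paired: bool = True,
) -> HaplotypePanel:
    """Small helper: panel from a raw matrix with synthetic SNP metadata."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n, S = alleles.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(S)]
    snps = [SnpInfo(id=f"rs{j + 1}", chrom="chr6", pos=positions[j]) for j in range(S)]
    if paired:
        samples = [f"s{i}" for i in range(n // 2)]
        soh = [s for s in samples for _ in range(2)]
    else:
        samples = [f"h{i}" for i in range(n)]
        soh = samples
    return HaplotypePanel(
        alleles=alleles,
        snps=snps,
        sample_of_hap=soh,
        group_of_sample=groups or {s: "all" for s in samples},
        paired=paired,
        allow_monomorphic=True,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140624)


@pytest.fixture
def small_panel() -> HaplotypePanel:
    alleles = np.array(
        [
            [0, 1, 0, 1],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 0, 1, 0],
            [0, 1, 1, 1],
            [1, 0, 0, 0],
        ]
    )
    return make_panel(alleles)


@pytest.fixture
def uniform_map() -> RecombinationMap:
    return RecombinationMap(np.full(3, 2e-4), np.full(3, 1000.0))
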