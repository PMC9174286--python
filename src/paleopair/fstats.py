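"""Outgroup f3, Patterson's D and f4 statistics with block-jackknife errors.

Estimates are ratio-of-sums over complete-case sites (sites with data in
every population entering the statistic); standard errors and Z-scores come
from the weighted block jackknife. No small-sample bias correction is
applied, which keeps the estimators safe for pseudohaploid one-read
"populations". Outgroup f3 is not heterozygosity-normalized: with a fixed
outgroup, affinity ranking is invariant to that normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel
from .jackknife import BlockPartition, JackknifeResult, jackknife_ratio
from .pseudohaploid import PseudohaploidGenome

__all__ = [
    "FreqTable",
    "allele_frequencies",
    "f3_outgroup",
    "f4_statistic",
    "d_statistic",
    "rank_affinity",
]


@dataclass
class FreqTable:
    """Per-population allele-1 sample frequency and observation count per site."""

    freqs: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]

    def freq(self, pop: str) -> np.ndarray:
        try:
            return self.freqs[pop]
        except KeyError:
            raise KeyError(f"unknown population label: {pop!r}") from None

    def count(self, pop: str) -> np.ndarray:
        try:
            return self.counts[pop]
        except KeyError:
            raise KeyError(f"unknown population label: {pop!r}") from None

    def populations(self) -> list[str]:
        return list(self.freqs)

    def complete_cases(self, pops: list[str]) -> np.ndarray:
        """Boolean mask of sites with data in every listed population."""
        mask = None
        for pop in pops:
            has = self.count(pop) > 0
            mask = has if mask is None else (mask & has)
        return mask


def allele_frequencies(
    geno: GenotypePanel,
    pseudohaploids: dict[str, PseudohaploidGenome] | None = None,
) -> FreqTable:
    """Sample allele-1 frequencies per population.

    Diploid populations: freq = sum(genotypes) / (2 * n non-missing).
    Pseudohaploid individuals enter as one-sample populations contributing
    a single haploid observation (frequency 0 or 1) per called site.
    """
    freqs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    g = geno.genotypes
    for pop in geno.populations:
        cols = geno.columns_for(pop)
        sub = g[:, cols]
        present = sub != MISSING
        n_alleles = 2 * present.sum(axis=1)
        total = np.where(present, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freqs[pop] = np.where(n_alleles > 0, total / np.maximum(n_alleles, 1), np.nan)
        counts[pop] = n_alleles
    if pseudohaploids:
        for label, ph in pseudohaploids.items():
            if label in freqs:
                raise ValueError(f"duplicate population label: {label!r}")
            called = ph.calls != MISSING
            freqs[label] = np.where(called, (ph.calls == 0).astype(float), np.nan)
            counts[label] = called.astype(np.int64)
    return FreqTable(freqs=freqs, counts=counts)


def _per_site_product(
    freqs: FreqTable, pops: list[str], terms: "callable"
) -> tuple[np.ndarray, np.ndarray]:
    mask = freqs.complete_cases(pops)
    if not mask.any():
        raise ValueError(f"no sites with data in all of {pops}")
    p = {pop: freqs.freq(pop) for pop in pops}
    values = np.where(mask, terms(p), 0.0)
    return values, mask


def f3_outgroup(
    A: str, B: str, O: str, freqs: FreqTable, partition: BlockPartition
) -> JackknifeResult:
    """Outgroup f3(A, B; O) = mean (p_A - p_O)(p_B - p_O) over usable sites."""
    values, mask = _per_site_product(
        freqs, [A, B, O], lambda p: (p[A] - p[O]) * (p[B] - p[O])
    )
    num = np.array([values[idx].sum() for idx in partition.blocks])
    den = np.array([mask[idx].sum() for idx in partition.blocks], dtype=np.float64)
    if den.sum() == 0:
        raise ValueError("no usable sites inside the block partition")
    return jackknife_ratio(num, den, partition.weights, n_sites=int(mask.sum()))


def f4_statistic(
    A: str, B: str, C: str, D: str, freqs: FreqTable, partition: BlockPartition
) -> JackknifeResult:
    """f4(A, B; C, D) = mean (p_A - p_B)(p_C - p_D) over usable sites."""
    values, mask = _per_site_product(
        freqs, [A, B, C, D], lambda p: (p[A] - p[B]) * (p[C] - p[D])
    )
    num = np.array([values[idx].sum() for idx in partition.blocks])
    den = np.array([mask[idx].sum() for idx in partition.blocks], dtype=np.float64)
    return jackknife_ratio(num, den, partition.weights, n_sites=int(mask.sum()))


def d_statistic(
    W: str, X: str, Y: str, Z: str, freqs: FreqTable, partition: BlockPartition
) -> JackknifeResult:
    """Patterson's D(W, X; Y, Z), normalized f4 with jackknife Z-score."""
    mask = freqs.complete_cases([W, X, Y, Z])
    if not mask.any():
        raise ValueError(f"no sites with data in all of {[W, X, Y, Z]}")
    pW, pX = freqs.freq(W), freqs.freq(X)
    pY, pZ = freqs.freq(Y), freqs.freq(Z)
    num_site = np.where(mask, (pW - pX) * (pY - pZ), 0.0)
    den_site = np.where(
        mask,
        (pW + pX - 2 * pW * pX) * (pY + pZ - 2 * pY * pZ),
        0.0,
    )
    num = np.array([num_site[idx].sum() for idx in partition.blocks])
    den = np.array([den_site[idx].sum() for idx in partition.blocks])
    if den.sum() == 0:
        raise ValueError("D statistic undefined: denominator sums to zero")
    return jackknife_ratio(num, den, partition.weights, n_sites=int(mask.sum()))


def rank_affinity(
    test: str,
    candidates: list[str],
    outgroup: str,
    freqs: FreqTable,
    partition: BlockPartition,
) -> pd.DataFrame:
    """Outgroup-f3 affinity ranking of candidates against a test population.

    Rows sorted by f3 descending; exact ties broken lexicographically.
    """
    if not candidates:
        raise ValueError("need at least one candidate population")
    rows = []
    for cand in candidates:
        jk = f3_outgroup(test, cand, outgroup, freqs, partition)
        rows.append(
            {
                "candidate": cand,
                "f3": jk.estimate,
                "se": jk.se,
                "z": jk.z,
                "n_sites": jk.n_sites,
                "n_blocks": jk.n_blocks,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["f3", "candidate"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
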