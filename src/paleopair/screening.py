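"""Chromosomal sex from X/Y read counts and pileup phenotype screening.

Sex is called from the Ry statistic — the fraction of Y-chromosome reads
among reads mapping to either sex chromosome — with a binomial 95%
confidence interval: XX when the interval lies entirely below the female
threshold, XY when entirely above the male threshold, otherwise
indeterminate.

Variant screening genotypes configured sites (e.g. the five
lactase-persistence enhancer variants upstream of LCT) from quality-filtered
read counts and translates genotypes into phenotype calls under dominant or
recessive inheritance: a single derived allele suffices for a dominant
trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SexCall",
    "VariantSpec",
    "VariantScreenEntry",
    "LP_VARIANTS",
    "infer_sex",
    "screen_variants",
]

#: the five lactase-persistence enhancer variants (MCM6 intronic, dominant);
#: positions on chromosome 2, GRCh37. Ancestral/derived per variant label.
LP_VARIANTS = [
    dict(label="-13910C/T", chrom=2, pos=136608646, ancestral="C", derived="T",
         inheritance="dominant"),
    dict(label="-13915T/G", chrom=2, pos=136608651, ancestral="T", derived="G",
         inheritance="dominant"),
    dict(label="-14010G/C", chrom=2, pos=136608746, ancestral="G", derived="C",
         inheritance="dominant"),
    dict(label="-13907C/G", chrom=2, pos=136608643, ancestral="C", derived="G",
         inheritance="dominant"),
    dict(label="-14107G/A", chrom=2, pos=136608843, ancestral="G", derived="A",
         inheritance="dominant"),
]


@dataclass(frozen=True)
class SexCall:
    n_x: int
    n_y: int
    ry: float
    ci: tuple[float, float]
    call: str  # XX | XY | indeterminate


@dataclass(frozen=True)
class VariantSpec:
    label: str
    chrom: int
    pos: int
    ancestral: str
    derived: str
    inheritance: str = "dominant"

    def __post_init__(self) -> None:
        if self.inheritance not in ("dominant", "recessive"):
            raise ValueError(f"inheritance must be dominant/recessive: {self.inheritance!r}")


@dataclass(frozen=True)
class VariantScreenEntry:
    spec: VariantSpec
    n_derived: int
    n_ancestral: int
    genotype: str  # hom_anc | het | hom_der | no_call
    phenotype: str  # positive | negative | no_call
    note: str = ""


def infer_sex(
    n_x: int,
    n_y: int,
    min_reads: int = 100,
    xx_threshold: float = 0.016,
    xy_threshold: float = 0.075,
) -> SexCall:
    """Ry-based sex call with a normal-approximation binomial 95% CI.

    XX when the CI's upper bound is below ``xx_threshold``; XY when its
    lower bound is above ``xy_threshold``; indeterminate otherwise or when
    fewer than ``min_reads`` sex-chromosome reads are available.
    """
    if n_x < 0 or n_y < 0:
        raise ValueError("read counts must be non-negative")
    n = n_x + n_y
    if n == 0:
        return SexCall(n_x, n_y, np.nan, (np.nan, np.nan), "indeterminate")
    ry = n_y / n
    half = 1.96 * np.sqrt(ry * (1.0 - ry) / n)
    ci = (max(0.0, ry - half), min(1.0, ry + half))
    call = "indeterminate"
    if n >= min_reads:
        if ci[1] < xx_threshold:
            call = "XX"
        elif ci[0] > xy_threshold:
            call = "XY"
    return SexCall(n_x, n_y, ry, ci, call)


def _genotype_call(n_der: int, n_anc: int, min_hom: int) -> str:
    if n_der >= 1 and n_anc >= 1:
        return "het"
    if n_der >= min_hom and n_anc == 0:
        return "hom_der"
    if n_anc >= min_hom and n_der == 0:
        return "hom_anc"
    return "no_call"


def _phenotype_call(genotype: str, inheritance: str) -> str:
    if genotype == "no_call":
        return "no_call"
    if inheritance == "dominant":
        return "positive" if genotype in ("het", "hom_der") else "negative"
    return "positive" if genotype == "hom_der" else "negative"


def screen_variants(
    observations: dict[tuple[int, int], list[str]],
    variants: list[VariantSpec] | None = None,
    min_hom: int = 3,
) -> list[VariantScreenEntry]:
    """Genotype and phenotype each configured variant from filtered reads.

    ``observations`` maps (chrom, pos) to retained read bases (as produced
    by :func:`paleopair.io.read_site_observations`). Heterozygous requires
    at least one read of each allele; homozygous requires ``min_hom``
    concordant reads and none of the other allele — a single unopposed
    derived read stays a no_call for damage/error robustness. Reads that
    match neither allele are ignored for counting but noted.
    """
    if variants is None:
        variants = [VariantSpec(**v) for v in LP_VARIANTS]
    entries = []
    for spec in variants:
        bases = observations.get((spec.chrom, spec.pos), [])
        n_der = sum(1 for b in bases if b == spec.derived)
        n_anc = sum(1 for b in bases if b == spec.ancestral)
        n_other = len(bases) - n_der - n_anc
        genotype = _genotype_call(n_der, n_anc, min_hom)
        phenotype = _phenotype_call(genotype, spec.inheritance)
        note = ""
        if not bases:
            note = "no reads covering the site"
        elif n_other:
            note = f"{n_other} reads matching neither allele ignored"
        entries.append(
            VariantScreenEntry(
                spec=spec,
                n_derived=n_der,
                n_ancestral=n_anc,
                genotype=genotype,
                phenotype=phenotype,
                note=note,
            )
        )
    return entries
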