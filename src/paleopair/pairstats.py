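"""Reference-free pair analyses: pseudo-twin kinship and conditional diversity.

The kinship test compares the pairwise mismatch rate *between* two
individuals' pseudohaploid genomes with the mismatch rate *within* each
individual's pseudo-twin pair. For a pair with kinship coefficient theta
the expected ratio is 2(1 - theta): 2.0 for unrelated pairs, 1.5 for
first-degree relatives, 1.0 for identical genomes.

Conditional nucleotide diversity (CND) is the same pairwise mismatch rate
restricted to transversion sites ascertained as polymorphic in a reference
genotype panel, making it comparable across low-coverage samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fstats import allele_frequencies
from .io import MISSING, GenotypePanel, SnpPanel
from .jackknife import BlockPartition, JackknifeResult, jackknife_functional, jackknife_ratio
from .pseudohaploid import PseudohaploidGenome, PseudoTwinPair

__all__ = [
    "KinshipResult",
    "CndResult",
    "EXPECTED_RATIOS",
    "mismatch_distance",
    "kinship_test",
    "conditional_nucleotide_diversity",
    "cnd_site_set",
]

#: expected between/within ratio 2(1-theta) per classification
EXPECTED_RATIOS = {"identical": 1.0, "first_degree": 1.5, "unrelated": 2.0}


@dataclass(frozen=True)
class KinshipResult:
    d_within_i: float
    d_within_j: float
    d_between: float
    ratio: float
    se_ratio: float
    classification: str
    n_sites_between: int
    n_blocks: int


@dataclass(frozen=True)
class CndResult:
    cnd: float
    se: float
    n_sites: int
    ascertainment: str


def _mismatch_block_sums(
    g1: PseudohaploidGenome, g2: PseudohaploidGenome, partition: BlockPartition
) -> tuple[np.ndarray, np.ndarray]:
    if len(g1.calls) != len(g2.calls):
        raise ValueError("genomes are not on the same panel")
    both = (g1.calls != MISSING) & (g2.calls != MISSING)
    diff = both & (g1.calls != g2.calls)
    num = np.array([diff[idx].sum() for idx in partition.blocks], dtype=np.float64)
    den = np.array([both[idx].sum() for idx in partition.blocks], dtype=np.float64)
    return num, den


def mismatch_distance(
    g1: PseudohaploidGenome, g2: PseudohaploidGenome, partition: BlockPartition
) -> JackknifeResult:
    """Fraction of jointly-called sites where the two calls differ."""
    num, den = _mismatch_block_sums(g1, g2, partition)
    if den.sum() == 0:
        raise ValueError("no sites called in both genomes")
    return jackknife_ratio(num, den, partition.weights, n_sites=int(den.sum()))


def kinship_test(
    pair_i: PseudoTwinPair,
    pair_j: PseudoTwinPair,
    single_i: PseudohaploidGenome,
    single_j: PseudohaploidGenome,
    partition: BlockPartition,
    gate_se_multiple: float = 3.0,
) -> KinshipResult:
    """Between/within mismatch ratio with jackknife SE and classification.

    The full ratio functional — six running sums, one ratio of ratios — is
    jackknifed as a whole so block correlations between the numerator and
    denominator distances propagate into the SE. Classification picks the
    nearest expected ratio in {1.0, 1.5, 2.0} when the estimate lies
    within ``gate_se_multiple`` jackknife SEs of it, else indeterminate.
    """
    nwi, dwi = _mismatch_block_sums(pair_i.twin_a, pair_i.twin_b, partition)
    nwj, dwj = _mismatch_block_sums(pair_j.twin_a, pair_j.twin_b, partition)
    nb, db = _mismatch_block_sums(single_i, single_j, partition)
    if db.sum() == 0:
        raise ValueError("no overlapping sites between the two individuals")

    d_within_i = nwi.sum() / dwi.sum() if dwi.sum() else np.nan
    d_within_j = nwj.sum() / dwj.sum() if dwj.sum() else np.nan
    d_between = nb.sum() / db.sum()

    mean_within = 0.5 * (d_within_i + d_within_j)
    if not np.isfinite(mean_within) or mean_within == 0:
        return KinshipResult(
            d_within_i=float(d_within_i),
            d_within_j=float(d_within_j),
            d_between=float(d_between),
            ratio=np.nan,
            se_ratio=np.nan,
            classification="indeterminate",
            n_sites_between=int(db.sum()),
            n_blocks=partition.n_blocks,
        )

    def ratio_func(t: np.ndarray) -> float:
        nwi_, dwi_, nwj_, dwj_, nb_, db_ = t
        if dwi_ == 0 or dwj_ == 0 or db_ == 0:
            return np.nan
        within = 0.5 * (nwi_ / dwi_ + nwj_ / dwj_)
        if within == 0:
            return np.nan
        return (nb_ / db_) / within

    per_block = np.stack([nwi, dwi, nwj, dwj, nb, db], axis=1)
    jk = jackknife_functional(
        per_block, ratio_func, partition.weights, n_sites=int(db.sum())
    )

    classification = "indeterminate"
    if np.isfinite(jk.estimate) and np.isfinite(jk.se) and jk.se > 0:
        name = min(EXPECTED_RATIOS, key=lambda k: abs(EXPECTED_RATIOS[k] - jk.estimate))
        if abs(EXPECTED_RATIOS[name] - jk.estimate) <= gate_se_multiple * jk.se:
            classification = name
    return KinshipResult(
        d_within_i=float(d_within_i),
        d_within_j=float(d_within_j),
        d_between=float(d_between),
        ratio=jk.estimate,
        se_ratio=jk.se,
        classification=classification,
        n_sites_between=int(db.sum()),
        n_blocks=partition.n_blocks,
    )


def cnd_site_set(
    panel: SnpPanel,
    geno: GenotypePanel,
    ascertainment_pops: list[str] | None = None,
) -> np.ndarray:
    """Transversion sites polymorphic (0 < freq < 1) in the ascertainment set.

    By default the ascertainment set is the union of all panel populations
    (i.e. the array as a whole); a named subset can be supplied.
    """
    pops = ascertainment_pops or geno.populations
    freqs = allele_frequencies(geno)
    count = np.zeros(len(panel))
    total = np.zeros(len(panel))
    for pop in pops:
        f, n = freqs.freq(pop), freqs.count(pop)
        count += np.where(n > 0, f * n, 0.0)
        total += n
    with np.errstate(invalid="ignore"):
        pooled = np.where(total > 0, count / total, np.nan)
    polymorphic = (pooled > 0) & (pooled < 1)
    return np.flatnonzero(~panel.is_transition & polymorphic)


def conditional_nucleotide_diversity(
    g1: PseudohaploidGenome,
    g2: PseudohaploidGenome,
    panel: SnpPanel,
    geno: GenotypePanel,
    partition: BlockPartition,
    ascertainment_pops: list[str] | None = None,
) -> CndResult:
    """Pairwise mismatch on panel-polymorphic transversions, with jackknife SE."""
    sites = cnd_site_set(panel, geno, ascertainment_pops)
    if len(sites) == 0:
        raise ValueError("ascertainment yields an empty site set")
    keep = np.zeros(len(panel), dtype=bool)
    keep[sites] = True
    c1 = np.where(keep, g1.calls, MISSING).astype(np.int8)
    c2 = np.where(keep, g2.calls, MISSING).astype(np.int8)
    jk = mismatch_distance(
        PseudohaploidGenome(g1.individual_id, c1, g1.mask_transitions),
        PseudohaploidGenome(g2.individual_id, c2, g2.mask_transitions),
        partition,
    )
    label = (
        "transversions polymorphic in "
        + (", ".join(ascertainment_pops) if ascertainment_pops else "the whole panel")
    )
    return CndResult(cnd=jk.estimate, se=jk.se, n_sites=jk.n_sites, ascertainment=label)
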