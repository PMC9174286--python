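"""Pseudohaploid genomes and pseudo-twin pairs from filtered pileups.

A pseudohaploid genome carries one randomly sampled read allele per covered
site; a pseudo-twin pair carries two alleles sampled from two *distinct*
reads at every site with at least two retained reads. Transition sites can
be masked to guard against post-mortem deamination. Only reads matching a
panel allele (allele codes 0/1) ever produce calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, PileupData, SnpPanel

__all__ = ["PseudohaploidGenome", "PseudoTwinPair", "call_pseudohaploid", "make_pseudo_twins"]


@dataclass
class PseudohaploidGenome:
    """Per-site call in {0 (allele1), 1 (allele2), MISSING}."""

    individual_id: str
    calls: np.ndarray
    mask_transitions: bool = False

    @property
    def covered(self) -> np.ndarray:
        return self.calls != MISSING

    @property
    def n_called(self) -> int:
        return int(np.count_nonzero(self.covered))


@dataclass
class PseudoTwinPair:
    individual_id: str
    twin_a: PseudohaploidGenome
    twin_b: PseudohaploidGenome

    @property
    def usable_sites(self) -> np.ndarray:
        """Indices where both twins are called (>= 2 reads, after masking)."""
        return np.flatnonzero(self.twin_a.covered & self.twin_b.covered)


def _allelic_read_layout(
    pileup: PileupData, n_snps: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Codes of allele-matching reads, site start offsets and counts.

    Reads with code 2 ("other" base) are excluded up front.
    """
    keep = pileup.allele_code < 2
    sites = pileup.site_index[keep]
    codes = pileup.allele_code[keep]
    counts = np.bincount(sites, minlength=n_snps)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return codes, starts, counts


def call_pseudohaploid(
    pileup: PileupData,
    panel: SnpPanel,
    mask_transitions: bool = False,
    rng: np.random.Generator | None = None,
) -> PseudohaploidGenome:
    """Draw one retained read uniformly per covered site; its base is the call."""
    if rng is None:
        rng = np.random.default_rng()
    n = len(panel)
    codes, starts, counts = _allelic_read_layout(pileup, n)
    calls = np.full(n, MISSING, dtype=np.int8)
    covered = counts > 0
    pick = starts[covered] + (rng.random(covered.sum()) * counts[covered]).astype(np.int64)
    calls[covered] = codes[pick]
    if mask_transitions:
        calls[panel.is_transition] = MISSING
    return PseudohaploidGenome(
        individual_id=pileup.individual_id, calls=calls, mask_transitions=mask_transitions
    )


def make_pseudo_twins(
    pileup: PileupData,
    panel: SnpPanel,
    mask_transitions: bool = False,
    rng: np.random.Generator | None = None,
) -> PseudoTwinPair:
    """Sample two distinct reads per site with >= 2 retained reads.

    The first draw becomes twin_a's call, the second twin_b's; sites with
    fewer than two allele-matching reads stay missing in both twins.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(panel)
    codes, starts, counts = _allelic_read_layout(pileup, n)
    calls_a = np.full(n, MISSING, dtype=np.int8)
    calls_b = np.full(n, MISSING, dtype=np.int8)
    usable = counts >= 2
    m = counts[usable]
    s = starts[usable]
    first = (rng.random(len(m)) * m).astype(np.int64)
    # second draw uniform over the remaining m-1 reads
    second = (rng.random(len(m)) * (m - 1)).astype(np.int64)
    second += second >= first
    calls_a[usable] = codes[s + first]
    calls_b[usable] = codes[s + second]
    if mask_transitions:
        tr = panel.is_transition
        calls_a[tr] = MISSING
        calls_b[tr] = MISSING
    return PseudoTwinPair(
        individual_id=pileup.individual_id,
        twin_a=PseudohaploidGenome(
            f"{pileup.individual_id}.twin_a", calls_a, mask_transitions
        ),
        twin_b=PseudohaploidGenome(
            f"{pileup.individual_id}.twin_b", calls_b, mask_transitions
        ),
    )
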