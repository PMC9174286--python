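"""Synthetic panels, populations and low-coverage read data with ground truth.

The generative model is a star phylogeny: an ancestral allele-frequency
vector is drawn uniformly, each population drifts away from it under the
Balding–Nichols law (Beta with mean p0 and variance F*p0*(1-p0)), admixed
populations mix their sources' frequencies linearly before their own drift
step, diploid genotypes are binomial draws, and reads are Poisson-depth
samples of random chromosomes with optional sequencing error, C->T/G->A
damage at transition sites, and contamination from another population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypePanel, PileupData, SnpPanel

__all__ = [
    "PopSpec",
    "AdmixtureSpec",
    "PairSpec",
    "SimulationConfig",
    "SimulationTruth",
    "KINSHIP_COEFFICIENTS",
    "simulate_panel",
    "simulate_frequencies",
    "simulate_genotype_panel",
    "simulate_pair",
    "simulate_all",
]

#: kinship coefficient theta per relatedness class
KINSHIP_COEFFICIENTS = {
    "unrelated": 0.0,
    "parent_offspring": 0.25,
    "full_sib": 0.25,
    "identical": 0.5,
}

_NUC = np.array(list("ACGT"))
_PAIRS = [(a, b) for i, a in enumerate("ACGT") for b in "ACGT"[i + 1 :]]


@dataclass(frozen=True)
class PopSpec:
    label: str
    drift: float  # Balding-Nichols F in [0, 1)
    n_individuals: int

    def __post_init__(self) -> None:
        if not 0 <= self.drift < 1:
            raise ValueError(f"drift F must be in [0, 1): {self.drift}")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")


@dataclass(frozen=True)
class AdmixtureSpec:
    label: str
    sources: tuple[str, ...]
    weights: tuple[float, ...]
    drift: float = 0.0  # post-admixture drift
    n_individuals: int = 0

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.weights):
            raise ValueError("sources and weights must align")
        if any(w < 0 for w in self.weights):
            raise ValueError("admixture weights must be >= 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("admixture weights must sum to 1")
        if not 0 <= self.drift < 1:
            raise ValueError(f"drift F must be in [0, 1): {self.drift}")


@dataclass(frozen=True)
class PairSpec:
    source: str
    relatedness: str = "unrelated"
    mean_depth: float = 5.0
    error_rate: float = 0.0
    damage_rate: float = 0.0
    contamination_rate: float = 0.0
    contaminant: str | None = None

    def __post_init__(self) -> None:
        if self.relatedness not in KINSHIP_COEFFICIENTS:
            raise ValueError(f"unknown relatedness class: {self.relatedness!r}")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be > 0")
        for name in ("error_rate", "damage_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        if self.contamination_rate > 0 and self.contaminant is None:
            raise ValueError("contamination_rate > 0 requires a contaminant label")


@dataclass(frozen=True)
class SimulationConfig:
    n_snps: int
    pop_specs: tuple[PopSpec, ...]
    admixture_specs: tuple[AdmixtureSpec, ...] = ()
    pair_spec: PairSpec | None = None
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        labels = [p.label for p in self.pop_specs]
        known = set(labels)
        for spec in self.admixture_specs:
            for src in spec.sources:
                if src not in known:
                    raise ValueError(f"admixture source {src!r} not defined")
            known.add(spec.label)
            labels.append(spec.label)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        if self.pair_spec is not None:
            if self.pair_spec.source not in known:
                raise ValueError(f"pair source {self.pair_spec.source!r} not defined")
            contaminant = self.pair_spec.contaminant
            if contaminant is not None and contaminant not in known:
                raise ValueError(f"contaminant population {contaminant!r} not defined")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside generated data."""

    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    admixture_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    pair_genotypes: np.ndarray | None = None  # (n_snps, 2) counts of allele1
    kinship_theta: float | None = None
    relatedness: str | None = None


def simulate_panel(n_snps: int, rng: np.random.Generator) -> SnpPanel:
    """Draw a SNP map: ~1/3 transitions via uniform unordered allele pairs.

    Sites are laid out on two chromosome labels at 1 kb spacing; genetic
    positions are physical_pos * 1e-8 morgans.
    """
    pair_idx = rng.integers(0, len(_PAIRS), size=n_snps)
    a1 = np.array([_PAIRS[i][0] for i in pair_idx], dtype=object)
    a2 = np.array([_PAIRS[i][1] for i in pair_idx], dtype=object)
    half = n_snps - n_snps // 2
    chrom = np.concatenate(
        [np.ones(half, dtype=np.int64), np.full(n_snps - half, 2, dtype=np.int64)]
    )
    pos = np.concatenate(
        [1000 * (np.arange(half, dtype=np.int64) + 1),
         1000 * (np.arange(n_snps - half, dtype=np.int64) + 1)]
    )
    return SnpPanel(
        snp_id=np.array([f"rs{i}" for i in range(n_snps)], dtype=object),
        chromosome=chrom,
        genetic_pos=pos * 1e-8,
        physical_pos=pos,
        allele1=a1,
        allele2=a2,
    )


def _balding_nichols(
    p0: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    if F == 0:
        return p0.copy()
    scale = (1.0 - F) / F
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationTruth:
    """Draw ancestral and per-population allele-1 frequencies."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=config.n_snps)
    truth = SimulationTruth(ancestral_freq=p0, pop_freqs={})
    for spec in config.pop_specs:
        truth.pop_freqs[spec.label] = _balding_nichols(p0, spec.drift, rng)
    for spec in config.admixture_specs:
        mix = np.zeros(config.n_snps)
        for src, w in zip(spec.sources, spec.weights):
            mix += w * truth.pop_freqs[src]
        truth.pop_freqs[spec.label] = _balding_nichols(mix, spec.drift, rng)
        truth.admixture_weights[spec.label] = dict(zip(spec.sources, spec.weights))
    return truth


def simulate_genotype_panel(
    panel: SnpPanel,
    freqs: dict[str, np.ndarray],
    sample_sizes: dict[str, int],
    rng: np.random.Generator,
) -> GenotypePanel:
    """Binomial(2, p) genotypes, independent across sites and individuals."""
    individuals: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for label, n in sample_sizes.items():
        p = np.asarray(freqs[label])
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"frequencies for {label!r} outside [0, 1]")
        g = rng.binomial(2, p[:, None], size=(len(panel), n)).astype(np.int8)
        columns.append(g)
        individuals.extend((f"{label}_{i}", label) for i in range(n))
    geno = (
        np.concatenate(columns, axis=1)
        if columns
        else np.zeros((len(panel), 0), dtype=np.int8)
    )
    return GenotypePanel(panel=panel, individuals=individuals, genotypes=geno)


def _draw_diploid(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n_snps, 2) haplotypes coded 0 = allele1, 1 = allele2."""
    return (rng.random((len(p), 2)) >= p[:, None]).astype(np.int8)


def _gene_drop(
    p: np.ndarray, relatedness: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype pairs for two individuals with the requested relatedness."""
    n = len(p)
    if relatedness == "unrelated":
        return _draw_diploid(p, rng), _draw_diploid(p, rng)
    if relatedness == "identical":
        a = _draw_diploid(p, rng)
        return a, a.copy()
    mother = _draw_diploid(p, rng)
    father = _draw_diploid(p, rng)

    def child() -> np.ndarray:
        mi = rng.integers(0, 2, size=n)
        fi = rng.integers(0, 2, size=n)
        return np.stack(
            [mother[np.arange(n), mi], father[np.arange(n), fi]], axis=1
        ).astype(np.int8)

    if relatedness == "parent_offspring":
        return mother, child()
    if relatedness == "full_sib":
        return child(), child()
    raise ValueError(f"unknown relatedness class: {relatedness!r}")


def _damage_flip_target(panel: SnpPanel) -> np.ndarray:
    """Per-site allele code hit by C->T/G->A damage, or -1 at transversions.

    At a {C,T} site reads carrying C flip to T; at {G,A}, G flips to A.
    """
    target = np.full(len(panel), -1, dtype=np.int8)
    for i, (a, b) in enumerate(zip(panel.allele1, panel.allele2)):
        pair = frozenset((a, b))
        if pair == frozenset("CT"):
            target[i] = 0 if a == "C" else 1
        elif pair == frozenset("GA"):
            target[i] = 0 if a == "G" else 1
    return target


def _reads_for_individual(
    panel: SnpPanel,
    haplotypes: np.ndarray,
    spec: PairSpec,
    contaminant_freq: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(panel)
    depth = rng.poisson(spec.mean_depth, size=n)
    site_idx = np.repeat(np.arange(n, dtype=np.int64), depth)
    n_reads = len(site_idx)
    chrom_pick = rng.integers(0, 2, size=n_reads)
    codes = haplotypes[site_idx, chrom_pick]
    if spec.contamination_rate > 0:
        contaminated = rng.random(n_reads) < spec.contamination_rate
        pc = contaminant_freq[site_idx[contaminated]]
        codes = codes.copy()
        codes[contaminated] = (rng.random(contaminated.sum()) >= pc).astype(np.int8)
    if spec.error_rate > 0:
        flip = rng.random(n_reads) < spec.error_rate
        codes = np.where(flip, 1 - codes, codes).astype(np.int8)
    if spec.damage_rate > 0:
        target = _damage_flip_target(panel)[site_idx]
        hit = (codes == target) & (target >= 0) & (rng.random(n_reads) < spec.damage_rate)
        codes = np.where(hit, 1 - codes, codes).astype(np.int8)
    return site_idx, codes.astype(np.int8)


def simulate_pair(
    config: SimulationConfig,
    panel: SnpPanel,
    truth: SimulationTruth,
    rng: np.random.Generator,
    ids: tuple[str, str] = ("ind_a", "ind_b"),
) -> tuple[PileupData, PileupData]:
    """Gene-drop a pair with the configured relatedness and emit pileups.

    Per site, depth ~ Poisson(lambda); each read samples one chromosome
    uniformly, is replaced by a contaminant-population draw with
    probability c, flips alleles with probability epsilon, and at
    transition sites suffers a deamination-consistent flip with
    probability delta. Updates ``truth`` with the pair genotypes and theta.
    """
    spec = config.pair_spec
    if spec is None:
        raise ValueError("config.pair_spec is not set")
    p = truth.pop_freqs[spec.source]
    hap_a, hap_b = _gene_drop(p, spec.relatedness, rng)
    truth.pair_genotypes = np.stack(
        [2 - hap_a.sum(axis=1), 2 - hap_b.sum(axis=1)], axis=1
    )
    truth.kinship_theta = KINSHIP_COEFFICIENTS[spec.relatedness]
    truth.relatedness = spec.relatedness
    contaminant_freq = (
        truth.pop_freqs[spec.contaminant] if spec.contaminant is not None else None
    )
    pileups = []
    for ind_id, hap in zip(ids, (hap_a, hap_b)):
        site_idx, codes = _reads_for_individual(panel, hap, spec, contaminant_freq, rng)
        pileups.append(
            PileupData(
                individual_id=ind_id,
                site_index=site_idx,
                allele_code=codes,
                filters_applied={"q_min": 30, "Q_min": 30, "simulated": True},
            )
        )
    return pileups[0], pileups[1]


def simulate_all(
    config: SimulationConfig,
) -> tuple[SnpPanel, GenotypePanel, PileupData | None, PileupData | None, SimulationTruth]:
    """Run the whole generator from a config: panel, genotypes, pair, truth."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config.n_snps, rng)
    truth = simulate_frequencies(config, rng)
    sizes = {s.label: s.n_individuals for s in config.pop_specs if s.n_individuals > 0}
    sizes.update(
        {s.label: s.n_individuals for s in config.admixture_specs if s.n_individuals > 0}
    )
    geno = simulate_genotype_panel(panel, truth.pop_freqs, sizes, rng)
    if config.pair_spec is not None:
        pu1, pu2 = simulate_pair(config, panel, truth, rng)
    else:
        pu1 = pu2 = None
    return panel, geno, pu1, pu2, truth
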