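"""Readers/writers for the EIGENSTRAT trio and pileup-style site observations.

The EIGENSTRAT dialect supported here is the ASCII one: ``.snp`` with six
whitespace-separated columns (id, chromosome, genetic position in morgans,
physical position, allele1, allele2), ``.ind`` with (id, sex letter,
population), and ``.geno`` with one row per SNP and one digit per individual
(counts of allele1; ``9`` means missing).

Pileups are plain TSV with one row per read observation:
``chrom  pos  base  base_quality  mapping_quality``; lines starting with
``#`` are headers/comments.  Quality filters are applied on ingestion and
recorded on the resulting :class:`PileupData`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SnpPanel",
    "GenotypePanel",
    "PileupData",
    "FormatError",
    "MISSING",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_pileup",
    "read_site_observations",
]

#: sentinel for a missing genotype / call in in-memory arrays
MISSING = -1

_TRANSITION_PAIRS = {frozenset("CT"), frozenset("GA")}
_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SnpPanel:
    """The ascertained biallelic SNP map shared by all statistics.

    Arrays are parallel, sorted by (chromosome, physical_pos); positions
    are 1-based as in ``.snp`` files.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    genetic_pos: np.ndarray
    physical_pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        for name in ("chromosome", "genetic_pos", "physical_pos", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpPanel field {name!r} length mismatch")
        if len(set(self.snp_id)) != n:
            raise ValueError("SnpPanel snp_ids are not unique")
        if n and np.any(self.allele1 == self.allele2):
            raise ValueError("allele1 == allele2 at some site")
        order = np.lexsort((self.physical_pos, self.chromosome))
        if n and not np.array_equal(order, np.arange(n)):
            raise ValueError("SnpPanel not sorted by (chromosome, physical_pos)")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def is_transition(self) -> np.ndarray:
        """Boolean array: True where {allele1, allele2} is {C,T} or {G,A}."""
        out = np.empty(len(self), dtype=bool)
        for i, (a, b) in enumerate(zip(self.allele1, self.allele2)):
            out[i] = frozenset((a, b)) in _TRANSITION_PAIRS
        return out

    @property
    def mutation_class(self) -> np.ndarray:
        """Per-site label in {"transition", "transversion"}."""
        return np.where(self.is_transition, "transition", "transversion")

    def site_index(self) -> dict[tuple[int, int], int]:
        """Map (chromosome, physical_pos) -> row index."""
        return {
            (int(c), int(p)): i
            for i, (c, p) in enumerate(zip(self.chromosome, self.physical_pos))
        }


@dataclass(frozen=True)
class GenotypePanel:
    """Diploid genotypes (counts of allele1) per individual per panel site.

    ``genotypes`` is an int8 matrix of shape (n_snps, n_individuals) with
    values in {0, 1, 2} or :data:`MISSING`.
    """

    panel: SnpPanel
    individuals: list[tuple[str, str]]  # (individual id, population label)
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.panel), len(self.individuals)):
            raise ValueError(
                "genotype matrix shape "
                f"{self.genotypes.shape} does not match panel x individuals "
                f"({len(self.panel)}, {len(self.individuals)})"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype values outside {0, 1, 2, missing}")

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for _, pop in self.individuals:
            seen.setdefault(pop)
        return list(seen)

    def columns_for(self, population: str) -> np.ndarray:
        cols = np.array(
            [i for i, (_, pop) in enumerate(self.individuals) if pop == population],
            dtype=np.intp,
        )
        if cols.size == 0:
            raise KeyError(f"unknown population label: {population!r}")
        return cols


@dataclass
class PileupData:
    """Filtered per-site read observations for one test individual.

    ``site_index`` maps each retained read to a row of its panel;
    ``allele_code`` is 0 (allele1), 1 (allele2) or 2 (other base — retained
    but never used in allele counts). Reads are sorted by site_index.
    """

    individual_id: str
    site_index: np.ndarray
    allele_code: np.ndarray
    filters_applied: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.site_index) != len(self.allele_code):
            raise ValueError("site_index / allele_code length mismatch")
        if len(self.site_index) and np.any(np.diff(self.site_index) < 0):
            order = np.argsort(self.site_index, kind="stable")
            self.site_index = self.site_index[order]
            self.allele_code = self.allele_code[order]

    @property
    def n_observations(self) -> int:
        return len(self.site_index)

    def allele_read_counts(self, n_snps: int) -> np.ndarray:
        """(n_snps, 2) counts of allele1/allele2 reads per site."""
        counts = np.zeros((n_snps, 2), dtype=np.int64)
        for code in (0, 1):
            sel = self.site_index[self.allele_code == code]
            np.add.at(counts[:, code], sel, 1)
        return counts


def _validate_allele(ch: str, path: Path, lineno: int) -> str:
    if ch not in _NUCLEOTIDES:
        raise FormatError(f"{path}: line {lineno}: unknown allele character {ch!r}")
    return ch


def read_eigenstrat(prefix: str | Path) -> tuple[SnpPanel, GenotypePanel]:
    """Read an ASCII EIGENSTRAT trio ``prefix.{geno,snp,ind}``."""
    prefix = Path(prefix)
    snp_path = prefix.with_suffix(prefix.suffix + ".snp")
    ind_path = prefix.with_suffix(prefix.suffix + ".ind")
    geno_path = prefix.with_suffix(prefix.suffix + ".geno")

    snp_ids, chroms, gpos, ppos, a1, a2 = [], [], [], [], [], []
    with open(snp_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise FormatError(f"{snp_path}: line {lineno}: expected 6 columns")
            snp_ids.append(parts[0])
            chroms.append(int(parts[1]))
            gpos.append(float(parts[2]))
            ppos.append(int(parts[3]))
            a1.append(_validate_allele(parts[4], snp_path, lineno))
            a2.append(_validate_allele(parts[5], snp_path, lineno))

    panel = SnpPanel(
        snp_id=np.array(snp_ids, dtype=object),
        chromosome=np.array(chroms, dtype=np.int64),
        genetic_pos=np.array(gpos, dtype=np.float64),
        physical_pos=np.array(ppos, dtype=np.int64),
        allele1=np.array(a1, dtype=object),
        allele2=np.array(a2, dtype=object),
    )

    individuals: list[tuple[str, str]] = []
    with open(ind_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise FormatError(f"{ind_path}: line {lineno}: expected 3 columns")
            individuals.append((parts[0], parts[2]))

    rows: list[list[int]] = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != len(individuals):
                raise FormatError(
                    f"{geno_path}: line {lineno}: {len(line)} genotypes for "
                    f"{len(individuals)} individuals"
                )
            try:
                row = [int(ch) for ch in line]
            except ValueError:
                raise FormatError(f"{geno_path}: line {lineno}: non-digit genotype")
            if any(g not in (0, 1, 2, 9) for g in row):
                raise FormatError(f"{geno_path}: line {lineno}: genotype outside 0/1/2/9")
            rows.append(row)

    if len(rows) != len(panel):
        raise FormatError(
            f"{geno_path}: {len(rows)} genotype rows but {len(panel)} SNPs in {snp_path}"
        )
    geno = np.array(rows, dtype=np.int8).reshape(len(panel), len(individuals))
    geno[geno == 9] = MISSING
    return panel, GenotypePanel(panel=panel, individuals=individuals, genotypes=geno)


def write_eigenstrat(
    panel: SnpPanel, geno: GenotypePanel, prefix: str | Path, sex: str = "U"
) -> None:
    """Write ``prefix.{geno,snp,ind}`` in the ASCII dialect (round-trips)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(prefix.suffix + ".snp"), "w") as fh:
        for i in range(len(panel)):
            fh.write(
                f"{panel.snp_id[i]}\t{panel.chromosome[i]}\t"
                f"{panel.genetic_pos[i]:.8f}\t{panel.physical_pos[i]}\t"
                f"{panel.allele1[i]}\t{panel.allele2[i]}\n"
            )
    with open(prefix.with_suffix(prefix.suffix + ".ind"), "w") as fh:
        for ind_id, pop in geno.individuals:
            fh.write(f"{ind_id}\t{sex}\t{pop}\n")
    out = geno.genotypes.astype(np.int8).copy()
    out[out == MISSING] = 9
    with open(prefix.with_suffix(prefix.suffix + ".geno"), "w") as fh:
        for row in out:
            fh.write("".join(str(int(g)) for g in row) + "\n")


def read_site_observations(
    path: str | Path, q_min: int = 30, Q_min: int = 30
) -> tuple[dict[tuple[int, int], list[str]], dict]:
    """Parse a pileup TSV into per-(chrom, pos) base lists, applying filters.

    Panel-free helper used by phenotype screening; :func:`read_pileup` builds
    on it. Returns the observation dict and a filter-count record.
    """
    path = Path(path)
    obs: dict[tuple[int, int], list[str]] = {}
    filters = {
        "q_min": q_min,
        "Q_min": Q_min,
        "n_input_reads": 0,
        "n_fail_base_quality": 0,
        "n_fail_mapping_quality": 0,
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 columns")
            try:
                chrom = int(parts[0])
                pos = int(parts[1])
                bq = int(parts[3])
                mq = int(parts[4])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: malformed numeric field")
            base = parts[2].upper()
            if base not in _NUCLEOTIDES:
                raise FormatError(f"{path}: line {lineno}: unknown base {base!r}")
            filters["n_input_reads"] += 1
            if bq < q_min:
                filters["n_fail_base_quality"] += 1
                continue
            if mq < Q_min:
                filters["n_fail_mapping_quality"] += 1
                continue
            obs.setdefault((chrom, pos), []).append(base)
    return obs, filters


def read_pileup(
    path: str | Path,
    panel: SnpPanel,
    q_min: int = 30,
    Q_min: int = 30,
    individual_id: str | None = None,
) -> PileupData:
    """Read a pileup TSV against a panel, dropping low-quality reads.

    Reads failing either quality threshold (strictly below; thresholds are
    inclusive) are dropped and counted, as are reads at sites absent from
    the panel. Bases matching neither panel allele are retained with
    allele code 2 and tallied.
    """
    obs, filters = read_site_observations(path, q_min=q_min, Q_min=Q_min)
    index = panel.site_index()
    site_idx: list[int] = []
    codes: list[int] = []
    filters["n_not_in_panel"] = 0
    filters["n_other_base"] = 0
    for key, bases in obs.items():
        i = index.get(key)
        if i is None:
            filters["n_not_in_panel"] += len(bases)
            continue
        a1, a2 = panel.allele1[i], panel.allele2[i]
        for base in bases:
            if base == a1:
                codes.append(0)
            elif base == a2:
                codes.append(1)
            else:
                codes.append(2)
                filters["n_other_base"] += 1
            site_idx.append(i)
    if filters["n_not_in_panel"]:
        warnings.warn(
            f"{path}: {filters['n_not_in_panel']} reads at sites absent from panel",
            stacklevel=2,
        )
    return PileupData(
        individual_id=individual_id or Path(path).stem,
        site_index=np.array(site_idx, dtype=np.int64),
        allele_code=np.array(codes, dtype=np.int8),
        filters_applied=filters,
    )


def write_pileup(
    path: str | Path,
    panel: SnpPanel,
    pileup: PileupData,
    base_quality: int = 37,
    mapping_quality: int = 37,
) -> None:
    """Write a PileupData back to the TSV dialect (panel alleles only)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tbase\tbase_quality\tmapping_quality\n")
        for i, code in zip(pileup.site_index, pileup.allele_code):
            base = panel.allele1[i] if code == 0 else panel.allele2[i]
            fh.write(
                f"{panel.chromosome[i]}\t{panel.physical_pos[i]}\t{base}"
                f"\t{base_quality}\t{mapping_quality}\n"
            )
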