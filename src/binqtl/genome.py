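"""Genome specification for a biparental mapping population.

A :class:`GenomeSpec` describes the physical and genetic scale of each
chromosome together with the base-pair positions of the parental SNPs that
segregate in the population.  The default constructor
:meth:`GenomeSpec.default_maize` mirrors the physical and genetic chromosome
lengths of the maize B73-anchored bin map this package targets
(10 chromosomes, 2059.7 Mb, 1545.65 cM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["ChromosomeSpec", "GenomeSpec", "ConfigurationError", "sample_snp_positions"]


class ConfigurationError(ValueError):
    """Raised when a genome or simulation parameter is out of its domain."""


@dataclass
class ChromosomeSpec:
    """One chromosome: physical length, genetic length and SNP positions.

    Parameters
    ----------
    name:
        Chromosome label (e.g. ``"1"``).
    bp_length:
        Physical length in base pairs.
    cm_length:
        Genetic (meiotic) map length in centiMorgans.
    snp_positions:
        Strictly increasing 1-based base-pair coordinates of segregating SNPs.
    cm_to_bp:
        Optional monotone map from genetic position (cM) to physical position
        (bp).  ``None`` means the linear (uniform-recombination) relation
        ``bp = cm / cm_length * bp_length``.  A custom callable lets callers
        emulate recombination-suppressed regions such as centromeres.
    """

    name: str
    bp_length: int
    cm_length: float
    snp_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cm_to_bp: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)
        if self.bp_length <= 0:
            raise ConfigurationError(f"chromosome {self.name}: bp_length must be positive")
        if not (0 < self.cm_length < 400):
            raise ConfigurationError(
                f"chromosome {self.name}: cm_length must lie in (0, 400) cM, got {self.cm_length}"
            )
        pos = self.snp_positions
        if pos.size:
            if pos[0] < 1 or pos[-1] > self.bp_length:
                raise ConfigurationError(
                    f"chromosome {self.name}: SNP positions must lie in [1, bp_length]"
                )
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    f"chromosome {self.name}: SNP positions must be strictly increasing"
                )

    def genetic_to_physical(self, cm: np.ndarray | float) -> np.ndarray:
        """Map genetic coordinates (cM) to physical coordinates (bp)."""
        cm = np.asarray(cm, dtype=float)
        if self.cm_to_bp is not None:
            bp = np.asarray(self.cm_to_bp(cm), dtype=float)
        else:
            bp = cm / self.cm_length * self.bp_length
        return np.clip(np.rint(bp), 1, self.bp_length).astype(np.int64)


# Per-chromosome (physical Mb, genetic cM) of the maize Ye478 x Qi319 map.
_MAIZE_CHROMS: Sequence[tuple[str, float, float]] = (
    ("1", 301.43, 239.48),
    ("2", 237.89, 151.46),
    ("3", 232.23, 163.33),
    ("4", 242.03, 163.22),
    ("5", 217.93, 170.86),
    ("6", 169.38, 120.38),
    ("7", 176.81, 143.24),
    ("8", 175.35, 142.66),
    ("9", 157.02, 122.05),
    ("10", 149.63, 128.97),
)


def sample_snp_positions(rng: np.random.Generator, bp_length: int, n: int) -> np.ndarray:
    """Draw ``n`` distinct, sorted 1-based positions without materialising the genome."""
    if n > bp_length:
        raise ConfigurationError("cannot place more SNPs than base pairs")
    pos = np.unique(rng.integers(1, bp_length + 1, size=n))
    while pos.size < n:  # collisions are rare for n << bp_length
        extra = rng.integers(1, bp_length + 1, size=n - pos.size + 8)
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos


@dataclass
class GenomeSpec:
    """Ordered collection of :class:`ChromosomeSpec`."""

    chromosomes: list[ChromosomeSpec]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("GenomeSpec requires at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("chromosome names must be unique")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return int(sum(c.bp_length for c in self.chromosomes))

    @property
    def total_cm(self) -> float:
        return float(sum(c.cm_length for c in self.chromosomes))

    @property
    def total_morgans(self) -> float:
        return self.total_cm / 100.0

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int,
        bp_length: int,
        cm_length: float,
        n_snps: int,
        seed: int | None = None,
    ) -> "GenomeSpec":
        """Equal-sized chromosomes with uniformly random SNP positions.

        Convenience constructor for simulation studies and tests.
        """
        rng = np.random.default_rng(seed)
        chroms = []
        for i in range(n_chromosomes):
            pos = sample_snp_positions(rng, bp_length, n_snps)
            chroms.append(ChromosomeSpec(str(i + 1), bp_length, cm_length, pos))
        return cls(chroms)

    @classmethod
    def default_maize(cls, snps_per_mb: float = 40.0, seed: int = 0) -> "GenomeSpec":
        """The 10-chromosome maize-scale genome (2059.7 Mb, 1545.65 cM).

        SNP positions are drawn uniformly at a density of ``snps_per_mb``
        per chromosome; the default density (~82,000 SNPs genome-wide)
        approximates the post-filter marker density of a low-coverage GBS
        experiment on this population scale.
        """
        rng = np.random.default_rng(seed)
        chroms = []
        for name, mb, cm in _MAIZE_CHROMS:
            bp = int(round(mb * 1e6))
            n = int(round(mb * snps_per_mb))
            pos = sample_snp_positions(rng, bp, n)
            chroms.append(ChromosomeSpec(name, bp, cm, pos))
        return cls(chroms)
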