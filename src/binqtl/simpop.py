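"""Forward simulation of a selfed RIL population with GBS-like genotyping.

The generator emulates the statistical structure of a biparental maize RIL
experiment: F1 individuals from two fully inbred founders are advanced by
single-seed descent for a configurable number of selfing generations
(default 10, giving F11 lines), producing mosaic genomes whose expected
residual heterozygosity is ``2**-g`` and whose expected junction count per
line approaches ``2 * L`` Morgans (the Haldane–Waddington map-expansion
factor for selfed RILs).  Meiosis is interference-free: crossover counts are
Poisson with mean equal to the chromosome map length in Morgans, positions
uniform on the genetic scale and mapped to base pairs through the
chromosome's cM-to-bp relation (linear by default).

Genotyping is modelled at the call level, not the read level: each parental
SNP is observed independently with a small probability (emulating ~0.07x
coverage), an observed call equals the underlying founder allele except for
a small allele-error probability, and heterozygous segments emit either
allele with probability 1/2 (a single sparse read cannot reveal
heterozygosity).

Phenotypes are additive-QTL driven with environment main effects, a
genotype-by-environment interaction term and replicate-level residual noise,
so that broad-sense heritability on the multi-environment line-mean basis is
controlled by the planted variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from binqtl.genome import ChromosomeSpec, ConfigurationError, GenomeSpec
from binqtl.snpmatrix import CALL_A, CALL_B, CALL_H, CALL_N, SNPMatrix

__all__ = [
    "Haplotype",
    "MosaicChromosome",
    "RILMosaic",
    "QTLEffect",
    "TraitModel",
    "QTLSpecTruth",
    "simulate_gamete",
    "breed_ril_population",
    "observe_gbs",
    "simulate_phenotypes",
    "heterozygous_fraction",
    "junction_count",
    "realized_genetic_variance",
]

# mosaic labels reuse the call codes: 0=A, 1=B, 2=H
_LABELS = "ABH"


@dataclass
class Haplotype:
    """A single chromosome haplotype as a founder mosaic.

    ``ends[i]`` is the (1-based, inclusive) last base pair of segment ``i``;
    ``founders[i]`` is 0 (parent A) or 1 (parent B).  Segments tile
    ``[1, ends[-1]]`` and adjacent founders differ.
    """

    ends: np.ndarray
    founders: np.ndarray

    def founder_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, positions)
        return self.founders[idx]


def _compress(ends: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent segments with equal labels."""
    if ends.size <= 1:
        return ends, labels
    keep = np.append(labels[1:] != labels[:-1], True)
    return ends[keep], labels[keep]


@dataclass
class MosaicChromosome:
    """Combined (diploid) mosaic: segments labelled A, B or H."""

    ends: np.ndarray
    labels: np.ndarray  # codes 0=A, 1=B, 2=H

    def state_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, positions)
        return self.labels[idx]

    def segments(self) -> list[tuple[int, int, str]]:
        """(start_bp, end_bp, label) triples, 1-based inclusive."""
        starts = np.concatenate([[1], self.ends[:-1] + 1])
        return [
            (int(s), int(e), _LABELS[int(l)])
            for s, e, l in zip(starts, self.ends, self.labels)
        ]


@dataclass
class RILMosaic:
    """One RIL's true genome: a mosaic per chromosome."""

    ril_id: str
    chromosomes: dict[str, MosaicChromosome] = field(default_factory=dict)


def simulate_gamete(
    hap1: Haplotype,
    hap2: Haplotype,
    chrom: ChromosomeSpec,
    rng: np.random.Generator,
    map_length: float | None = None,
) -> Haplotype:
    """One meiotic product of the diplotype ``(hap1, hap2)``.

    The crossover count is Poisson with mean ``map_length / 100`` (Morgans);
    crossover positions are uniform on the genetic scale and mapped to base
    pairs through ``chrom``'s cM-to-bp relation.  The returned haplotype
    starts from a randomly chosen parental haplotype and alternates source
    at each crossover.
    """
    L = chrom.cm_length if map_length is None else float(map_length)
    if L <= 0:
        raise ConfigurationError(f"map length must be positive, got {L}")
    n_xo = rng.poisson(L / 100.0)
    start_with = int(rng.integers(2))
    if n_xo == 0:
        src = (hap1, hap2)[start_with]
        return Haplotype(src.ends.copy(), src.founders.copy())
    cm = np.sort(rng.uniform(0.0, L, size=n_xo))
    cuts = chrom.genetic_to_physical(cm / L * chrom.cm_length)
    # crossovers at bp c switch source after position c
    cuts = np.unique(cuts)
    cuts = cuts[cuts < chrom.bp_length]
    ends = np.unique(np.concatenate([hap1.ends, hap2.ends, cuts]))
    starts = np.concatenate([[1], ends[:-1] + 1])
    n_before = np.searchsorted(cuts, starts - 1, side="right")
    source = (start_with + n_before) % 2
    founders = np.where(
        source == 0, hap1.founder_at(starts), hap2.founder_at(starts)
    ).astype(np.int8)
    ends, founders = _compress(ends, founders)
    return Haplotype(ends, founders)


def _combine(hap1: Haplotype, hap2: Haplotype) -> MosaicChromosome:
    ends = np.unique(np.concatenate([hap1.ends, hap2.ends]))
    starts = np.concatenate([[1], ends[:-1] + 1])
    f1 = hap1.founder_at(starts)
    f2 = hap2.founder_at(starts)
    labels = np.where(f1 == f2, f1, 2).astype(np.int8)
    ends, labels = _compress(ends, labels)
    return MosaicChromosome(ends, labels)


def breed_ril_population(
    spec: GenomeSpec,
    n_rils: int = 314,
    n_selfing_generations: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> list[RILMosaic]:
    """Advance ``n_rils`` F1 individuals by single-seed descent.

    Each line descends independently through ``n_selfing_generations``
    rounds of selfing with one offspring kept per generation; per-line RNG
    streams are spawned deterministically from the root seed so populations
    are reproducible regardless of generation order.
    """
    if n_rils < 1:
        raise ConfigurationError("n_rils must be >= 1")
    if n_selfing_generations < 0:
        raise ConfigurationError("n_selfing_generations must be >= 0")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = root.spawn(n_rils)
    population: list[RILMosaic] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        mosaic = RILMosaic(f"RIL{i + 1:04d}")
        for chrom in spec.chromosomes:
            hap_a = Haplotype(
                np.array([chrom.bp_length], dtype=np.int64), np.array([0], dtype=np.int8)
            )
            hap_b = Haplotype(
                np.array([chrom.bp_length], dtype=np.int64), np.array([1], dtype=np.int8)
            )
            pair = (hap_a, hap_b)
            for _ in range(n_selfing_generations):
                g1 = simulate_gamete(pair[0], pair[1], chrom, rng)
                g2 = simulate_gamete(pair[0], pair[1], chrom, rng)
                pair = (g1, g2)
            mosaic.chromosomes[chrom.name] = _combine(pair[0], pair[1])
        population.append(mosaic)
    return population


def heterozygous_fraction(mosaic: RILMosaic) -> float:
    """Fraction of the genome (bp) residing in heterozygous segments."""
    het = 0
    total = 0
    for mc in mosaic.chromosomes.values():
        starts = np.concatenate([[1], mc.ends[:-1] + 1])
        lengths = mc.ends - starts + 1
        het += int(lengths[mc.labels == 2].sum())
        total += int(mc.ends[-1])
    return het / total


def junction_count(mosaic: RILMosaic) -> int:
    """Number of segment boundaries (true breakpoints) across the genome."""
    return sum(len(mc.labels) - 1 for mc in mosaic.chromosomes.values())


def observe_gbs(
    mosaics: list[RILMosaic],
    spec: GenomeSpec,
    observe_rate: float = 0.05,
    allele_error_rate: float = 0.002,
    seed: int | np.random.SeedSequence = 0,
) -> SNPMatrix:
    """Sparse, error-prone SNP observation of the true mosaics.

    Each parental SNP is observed independently with ``observe_rate`` per
    RIL; an observed call is the founder allele at that position, flipped
    with probability ``allele_error_rate``; heterozygous segments emit
    either allele with probability 1/2.  Unobserved entries are missing.
    """
    if not 0 <= observe_rate <= 1 or not 0 <= allele_error_rate <= 1:
        raise ConfigurationError("rates must lie in [0, 1]")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(root)
    n_rils = len(mosaics)
    chrom_col, pos_col, call_blocks = [], [], []
    for chrom in spec.chromosomes:
        pos = chrom.snp_positions
        if pos.size == 0:
            continue
        states = np.empty((pos.size, n_rils), dtype=np.int8)
        for j, mosaic in enumerate(mosaics):
            states[:, j] = mosaic.chromosomes[chrom.name].state_at(pos)
        calls = states.copy()
        het = states == CALL_H
        if het.any():
            calls[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        if allele_error_rate > 0:
            flip = rng.random(calls.shape) < allele_error_rate
            calls[flip] = 1 - calls[flip]
        observed = rng.random(calls.shape) < observe_rate
        calls[~observed] = CALL_N
        chrom_col.append(np.full(pos.size, chrom.name, dtype=object))
        pos_col.append(pos)
        call_blocks.append(calls)
    return SNPMatrix(
        np.concatenate(chrom_col),
        np.concatenate(pos_col),
        np.concatenate(call_blocks),
        [m.ril_id for m in mosaics],
    )


# --------------------------------------------------------------------------
# phenotype simulation


@dataclass
class QTLEffect:
    """A planted additive QTL: B-allele substitution effect in trait units."""

    trait: str
    chrom: str
    pos: int
    effect: float


@dataclass
class TraitModel:
    """Variance structure for one trait across environments.

    ``env_offsets`` has one entry per environment; ``gxe_sd`` is the SD of
    the line-by-environment interaction deviate, ``resid_sd`` the SD of the
    replicate-level residual, ``n_reps`` the number of replicates per
    line and environment.
    """

    name: str
    grand_mean: float
    env_offsets: list[float]
    gxe_sd: float
    resid_sd: float
    n_reps: int = 2

    @property
    def n_envs(self) -> int:
        return len(self.env_offsets)


@dataclass
class QTLSpecTruth:
    """Ground truth for phenotype simulation: trait models + planted QTL."""

    traits: list[TraitModel]
    qtl: list[QTLEffect]
    env_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.traits:
            raise ConfigurationError("at least one trait model is required")
        n_envs = {t.n_envs for t in self.traits}
        if len(n_envs) != 1:
            raise ConfigurationError("all traits must share the environment count")
        for t in self.traits:
            if t.n_reps < 1 or t.n_envs < 1:
                raise ConfigurationError("need n_reps >= 1 and >= 1 environment")
        names = {t.name for t in self.traits}
        for q in self.qtl:
            if q.trait not in names:
                raise ConfigurationError(f"QTL references unknown trait {q.trait!r}")
            if not np.isfinite(q.effect):
                raise ConfigurationError("QTL effects must be finite")
        if self.env_names is None:
            self.env_names = [f"E{i + 1}" for i in range(self.traits[0].n_envs)]

    def trait(self, name: str) -> TraitModel:
        for t in self.traits:
            if t.name == name:
                return t
        raise ConfigurationError(f"unknown trait {name!r}")

    @classmethod
    def default_architecture(cls) -> "QTLSpecTruth":
        """Default maize plant-architecture truth (PH/EH/IN, 3 environments).

        Trait means and environment offsets follow the observed scale of the
        target experiment (plant height ~209 cm, ear height ~78 cm,
        internode number ~15); a handful of additive QTL of moderate effect
        plus interaction/residual variances give line-mean heritabilities in
        the 0.80-0.92 range typical of these traits.
        """
        traits = [
            TraitModel("PH", 209.1, [-8.2, 8.5, -0.4], gxe_sd=np.sqrt(6.0), resid_sd=np.sqrt(30.0)),
            TraitModel("EH", 78.5, [1.6, -0.8, -0.7], gxe_sd=2.0, resid_sd=np.sqrt(20.0)),
            TraitModel("IN", 15.3, [-0.6, 0.3, 0.3], gxe_sd=0.25, resid_sd=np.sqrt(0.5)),
        ]
        qtl = [
            QTLEffect("PH", "1", 165_000_000, 5.0),
            QTLEffect("PH", "2", 197_000_000, 4.0),
            QTLEffect("PH", "10", 83_000_000, 6.0),
            QTLEffect("EH", "1", 95_000_000, 3.5),
            QTLEffect("EH", "3", 142_000_000, -2.5),
            QTLEffect("EH", "10", 87_000_000, 3.5),
            QTLEffect("IN", "1", 100_000_000, 0.3),
            QTLEffect("IN", "8", 110_000_000, -0.45),
            QTLEffect("IN", "10", 87_000_000, 0.4),
        ]
        return cls(traits, qtl)


def _qtl_codings(
    mosaics: list[RILMosaic], truth: QTLSpecTruth, trait: str
) -> np.ndarray:
    """(n_rils, n_qtl) coding matrix x in {-1, 0, +1} at the planted QTL."""
    qtl = [q for q in truth.qtl if q.trait == trait]
    x = np.zeros((len(mosaics), len(qtl)))
    for k, q in enumerate(qtl):
        for j, mosaic in enumerate(mosaics):
            mc = mosaic.chromosomes.get(q.chrom)
            if mc is None or q.pos > int(mc.ends[-1]) or q.pos < 1:
                raise ConfigurationError(
                    f"QTL position {q.chrom}:{q.pos} outside simulated genome"
                )
            state = int(mc.state_at(np.array([q.pos]))[0])
            x[j, k] = {CALL_A: -1.0, CALL_B: 1.0, CALL_H: 0.0}[state]
    return x


def genetic_values(
    mosaics: list[RILMosaic], truth: QTLSpecTruth, trait: str
) -> np.ndarray:
    """Per-line genetic value sum_q a_q * x_q for one trait."""
    qtl = [q for q in truth.qtl if q.trait == trait]
    x = _qtl_codings(mosaics, truth, trait)
    a = np.array([q.effect for q in qtl])
    return x @ a if a.size else np.zeros(len(mosaics))


def realized_genetic_variance(
    mosaics: list[RILMosaic], truth: QTLSpecTruth, trait: str
) -> float:
    """Realized between-line genetic variance of the planted QTL values."""
    g = genetic_values(mosaics, truth, trait)
    return float(np.var(g, ddof=1)) if g.size > 1 else 0.0


def simulate_phenotypes(
    mosaics: list[RILMosaic],
    truth: QTLSpecTruth,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Multi-environment replicated phenotypes driven by the planted QTL.

    Returns a long-format table with columns ``ril``, ``env``, ``rep`` and
    one column per trait:  ``y = mu + env + sum_q a_q x_q + gxe + eps``.
    """
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(root)
    n = len(mosaics)
    ril_ids = [m.ril_id for m in mosaics]
    env_names = truth.env_names
    frames = []
    for t in truth.traits:
        g = genetic_values(mosaics, truth, t.name)
        e, r = t.n_envs, t.n_reps
        gxe = rng.normal(0.0, t.gxe_sd, size=(n, e)) if t.gxe_sd > 0 else np.zeros((n, e))
        eps = (
            rng.normal(0.0, t.resid_sd, size=(n, e, r))
            if t.resid_sd > 0
            else np.zeros((n, e, r))
        )
        y = (
            t.grand_mean
            + np.asarray(t.env_offsets)[None, :, None]
            + g[:, None, None]
            + gxe[:, :, None]
            + eps
        )
        idx = pd.MultiIndex.from_product(
            [ril_ids, env_names[:e], range(1, r + 1)], names=["ril", "env", "rep"]
        )
        frames.append(pd.Series(y.ravel(), index=idx, name=t.name))
    out = pd.concat(frames, axis=1).reset_index()
    return out
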