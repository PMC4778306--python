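"""Segregation filtering and sliding-window genotype calling.

Sparse per-RIL SNP calls are too noisy to read recombination directly, so
genotypes are called over sliding windows of informative SNPs: a window of
``window`` consecutive non-missing homozygous calls is labelled ``A`` or
``B`` when at least ``hom_threshold`` of them come from one parent, and
heterozygous otherwise.  Maximal runs of equally-labelled windows are merged
into genotype blocks; the junction between two adjacent blocks is a
recombination breakpoint whose position is only known to lie between the
last SNP supporting the left block alone and the first SNP supporting the
right block alone.

Heterozygous and missing calls are excluded from window counts: a sparse
GBS read cannot distinguish a heterozygous site from an allele sampled off
one homologue, so unexpected calls are treated as missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from binqtl.snpmatrix import CALL_A, CALL_B, SNPMatrix

__all__ = [
    "EmptyInputError",
    "FilterReport",
    "WindowCall",
    "WindowCalls",
    "GenotypeBlock",
    "ChromosomeBlocks",
    "Breakpoint",
    "BreakpointSet",
    "filter_segregation",
    "segregation_chi2",
    "call_windows",
    "merge_blocks",
    "call_chromosome",
    "call_population",
    "extract_breakpoints",
    "mean_per_individual",
]


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable data."""


# --------------------------------------------------------------------------
# segregation-distortion filter


@dataclass
class FilterReport:
    """Summary of the chi-square segregation filter."""

    n_input: int
    n_removed_distorted: int
    n_removed_uninformative: int
    alpha: float
    per_snp: pd.DataFrame | None = None

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_distorted - self.n_removed_uninformative

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_input": [self.n_input],
                "n_removed_distorted": [self.n_removed_distorted],
                "n_removed_uninformative": [self.n_removed_uninformative],
                "n_retained": [self.n_retained],
                "alpha": [self.alpha],
            }
        )


def segregation_chi2(n_a: np.ndarray, n_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-df chi-square statistic and p-value against a 1:1 ratio.

    ``chi2 = (n_a - n_b)**2 / (n_a + n_b)`` on the two homozygous classes,
    without continuity correction.  Zero-count markers get ``chi2 = 0`` and
    ``p = 1`` here; callers should drop them as uninformative.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    total = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(total > 0, (n_a - n_b) ** 2 / np.where(total > 0, total, 1), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def filter_segregation(
    matrix: SNPMatrix, alpha: float = 0.001
) -> tuple[SNPMatrix, FilterReport]:
    """Drop SNPs whose homozygous-class ratio deviates from 1:1.

    A RIL population segregates aa x bb markers at an expected 1:1 ratio;
    SNPs with chi-square ``p < alpha`` (default 0.001) are removed as
    distorted, and SNPs with zero informative (A/B) calls as uninformative.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if matrix.n_snps == 0:
        raise EmptyInputError("SNP matrix contains no SNPs")
    n_a = (matrix.calls == CALL_A).sum(axis=1)
    n_b = (matrix.calls == CALL_B).sum(axis=1)
    chi2, p = segregation_chi2(n_a, n_b)
    uninformative = (n_a + n_b) == 0
    distorted = (p < alpha) & ~uninformative
    keep = ~(distorted | uninformative)
    per_snp = pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "pos": matrix.pos,
            "n_a": n_a,
            "n_b": n_b,
            "chi2": chi2,
            "p": p,
            "retained": keep,
        }
    )
    report = FilterReport(
        n_input=matrix.n_snps,
        n_removed_distorted=int(distorted.sum()),
        n_removed_uninformative=int(uninformative.sum()),
        alpha=alpha,
        per_snp=per_snp,
    )
    return matrix.subset_snps(keep), report


# --------------------------------------------------------------------------
# sliding-window genotype calling


@dataclass
class WindowCall:
    """One window over consecutive informative SNPs."""

    index: int
    start: int  # first informative-SNP index covered (inclusive)
    stop: int  # last informative-SNP index covered (exclusive)
    n_a: int
    n_b: int
    label: str  # 'A', 'B' or 'H'


@dataclass
class WindowCalls:
    """Vectorised sequence of window calls for one RIL chromosome.

    ``informative_idx`` maps informative-SNP indices back to indices in the
    original call vector; ``starts[i]`` is the first informative-SNP index
    covered by window ``i`` and every window covers ``sizes[i]`` SNPs.
    """

    starts: np.ndarray
    sizes: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    labels: np.ndarray  # int8 codes 0/1/2
    informative_idx: np.ndarray
    window: int
    hom_threshold: int

    def __len__(self) -> int:
        return int(self.starts.size)

    def __getitem__(self, i: int) -> WindowCall:
        return WindowCall(
            index=i,
            start=int(self.starts[i]),
            stop=int(self.starts[i] + self.sizes[i]),
            n_a=int(self.n_a[i]),
            n_b=int(self.n_b[i]),
            label="ABH"[int(self.labels[i])],
        )

    @property
    def n_informative(self) -> int:
        return int(self.informative_idx.size)


def _truncated_threshold(hom_threshold: int, window: int, n: int) -> int:
    """Scaled supermajority threshold for a single short window of n SNPs."""
    return math.ceil(hom_threshold / window * n)


def call_windows(
    calls: np.ndarray,
    window: int = 15,
    step: int = 1,
    hom_threshold: int = 11,
) -> WindowCalls:
    """Label sliding windows over the informative (A/B) calls of one RIL.

    A window is ``A`` if at least ``hom_threshold`` of its SNPs carry the A
    allele, ``B`` symmetrically, and heterozygous (``H``) otherwise.  H and
    N calls never enter the counts.  When fewer than ``window`` informative
    SNPs are available, a single truncated window is used with the
    proportionally scaled threshold ``ceil(hom_threshold / window * n)``.
    """
    if not window >= hom_threshold >= window // 2 + 1:
        raise ValueError(
            f"need window >= hom_threshold >= window//2 + 1, got {window}, {hom_threshold}"
        )
    if step != 1:
        raise NotImplementedError("only the step-of-one-SNP scheme is supported")
    calls = np.asarray(calls, dtype=np.int8)
    informative_idx = np.flatnonzero((calls == CALL_A) | (calls == CALL_B))
    v = calls[informative_idx]  # 0 = A, 1 = B
    n = v.size
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return WindowCalls(
            empty, empty, empty, empty, np.empty(0, dtype=np.int8),
            informative_idx, window, hom_threshold,
        )
    if n < window:
        n_b = int(v.sum())
        n_a = n - n_b
        thr = _truncated_threshold(hom_threshold, window, n)
        label = 0 if n_a >= thr else (1 if n_b >= thr else 2)
        return WindowCalls(
            np.array([0]), np.array([n]), np.array([n_a]), np.array([n_b]),
            np.array([label], dtype=np.int8), informative_idx, window, hom_threshold,
        )
    csum = np.concatenate([[0], np.cumsum(v)])
    n_windows = n - window + 1
    starts = np.arange(n_windows)
    n_b = csum[window:] - csum[:-window]
    n_a = window - n_b
    labels = np.full(n_windows, 2, dtype=np.int8)
    labels[n_a >= hom_threshold] = 0
    labels[n_b >= hom_threshold] = 1
    return WindowCalls(
        starts, np.full(n_windows, window), n_a.astype(np.int64),
        n_b.astype(np.int64), labels, informative_idx, window, hom_threshold,
    )


@dataclass
class GenotypeBlock:
    """A maximal run of equally-labelled windows.

    ``start_idx``/``end_idx`` index the informative-SNP subsequence (the
    partition of informative SNPs at block boundaries); ``start_bp`` and
    ``end_bp`` are the corresponding physical positions.  ``first_window``
    and ``last_window`` delimit the window run supporting the block.
    """

    label: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    first_window: int
    last_window: int

    @property
    def n_windows(self) -> int:
        return self.last_window - self.first_window + 1


@dataclass
class ChromosomeBlocks:
    """All genotype blocks of one RIL chromosome, with breakpoint geometry."""

    chrom: str
    blocks: list[GenotypeBlock]
    positions: np.ndarray  # bp of informative SNPs
    window_starts: np.ndarray
    window: int

    def breakpoint_intervals(self) -> list[tuple[int, int, str, str]]:
        """(left_bp, right_bp, left_label, right_label) per block junction.

        The transition between two window runs is localised between the
        last SNP covered only by the left run's windows and the first SNP
        covered only by the right run's windows.
        """
        out = []
        pos = self.positions
        n = pos.size
        for left, right in zip(self.blocks[:-1], self.blocks[1:]):
            left_unique = self.window_starts[right.first_window] - 1
            right_unique = min(self.window_starts[left.last_window] + self.window, n - 1)
            out.append(
                (int(pos[left_unique]), int(pos[right_unique]), left.label, right.label)
            )
        return out


def merge_blocks(windows: WindowCalls, snp_positions: np.ndarray, chrom: str = "") -> ChromosomeBlocks:
    """Combine adjacent equally-labelled windows into genotype blocks.

    ``snp_positions`` gives the bp coordinate of every SNP in the original
    call vector; informative positions are looked up through the window
    call's index map.  Blocks partition the informative SNPs: the boundary
    between two runs is drawn at the centre of the left run's final window
    (window labels flip when counts cross the supermajority threshold, so
    window centres, not starts, are symmetric around a clean junction).
    No smoothing of short runs is applied.
    """
    pos_inf = np.asarray(snp_positions, dtype=np.int64)[windows.informative_idx]
    if len(windows) == 0:
        return ChromosomeBlocks(chrom, [], pos_inf, windows.starts, windows.window)
    labels = windows.labels
    change = np.flatnonzero(labels[1:] != labels[:-1])
    run_last = np.concatenate([change, [labels.size - 1]])
    run_first = np.concatenate([[0], change + 1])
    n_inf = pos_inf.size
    half = (windows.window - 1) // 2
    blocks: list[GenotypeBlock] = []
    prev_end = -1
    for k, (fw, lw) in enumerate(zip(run_first, run_last)):
        start_idx = prev_end + 1
        if k < run_first.size - 1:
            end_idx = min(int(windows.starts[lw]) + half, n_inf - 1)
        else:
            end_idx = n_inf - 1
        end_idx = max(end_idx, start_idx)
        blocks.append(
            GenotypeBlock(
                label="ABH"[int(labels[fw])],
                start_idx=start_idx,
                end_idx=end_idx,
                start_bp=int(pos_inf[start_idx]),
                end_bp=int(pos_inf[end_idx]),
                first_window=int(fw),
                last_window=int(lw),
            )
        )
        prev_end = end_idx
    return ChromosomeBlocks(chrom, blocks, pos_inf, windows.starts, windows.window)


def call_chromosome(
    calls: np.ndarray,
    snp_positions: np.ndarray,
    chrom: str = "",
    window: int = 15,
    step: int = 1,
    hom_threshold: int = 11,
) -> ChromosomeBlocks:
    """Window-call one RIL chromosome and merge into blocks."""
    w = call_windows(calls, window=window, step=step, hom_threshold=hom_threshold)
    return merge_blocks(w, snp_positions, chrom=chrom)


def call_population(
    matrix: SNPMatrix,
    window: int = 15,
    step: int = 1,
    hom_threshold: int = 11,
) -> dict[str, dict[str, ChromosomeBlocks]]:
    """Blocks for every RIL and chromosome: ``{ril_id: {chrom: blocks}}``."""
    out: dict[str, dict[str, ChromosomeBlocks]] = {r: {} for r in matrix.ril_ids}
    for name in matrix.chromosome_names():
        sub = matrix.subset_chromosome(name)
        for j, ril in enumerate(matrix.ril_ids):
            out[ril][name] = call_chromosome(
                sub.calls[:, j], sub.pos, chrom=name,
                window=window, step=step, hom_threshold=hom_threshold,
            )
    return out


# --------------------------------------------------------------------------
# breakpoints


@dataclass
class Breakpoint:
    """A recombination junction with its physical uncertainty interval."""

    ril: str
    chrom: str
    left_bp: int
    right_bp: int
    left_label: str = ""
    right_label: str = ""

    @property
    def midpoint(self) -> int:
        """Point estimate of the junction (uniform prior over the interval)."""
        return (self.left_bp + self.right_bp) // 2


@dataclass
class BreakpointSet:
    """All breakpoints of a population with per-RIL and total counts."""

    breakpoints: list[Breakpoint]
    per_ril: dict[str, int]
    total: int = field(init=False)
    mean_per_ril: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = len(self.breakpoints)
        self.mean_per_ril = mean_per_individual(self.total, len(self.per_ril))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ril": b.ril,
                    "chrom": b.chrom,
                    "left_bp": b.left_bp,
                    "right_bp": b.right_bp,
                    "left_label": b.left_label,
                    "right_label": b.right_label,
                }
                for b in self.breakpoints
            ]
        )


def mean_per_individual(total: int, n_individuals: int) -> float:
    """Population mean count per individual (e.g. breakpoints per RIL)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return total / n_individuals


def extract_breakpoints(
    blocks_by_ril: dict[str, dict[str, ChromosomeBlocks]],
) -> BreakpointSet:
    """One breakpoint per adjacent block pair, aggregated over the population."""
    breakpoints: list[Breakpoint] = []
    per_ril: dict[str, int] = {}
    for ril, by_chrom in blocks_by_ril.items():
        count = 0
        for chrom, cb in by_chrom.items():
            for left_bp, right_bp, ll, rl in cb.breakpoint_intervals():
                breakpoints.append(Breakpoint(ril, chrom, left_bp, right_bp, ll, rl))
                count += 1
        per_ril[ril] = count
    return BreakpointSet(breakpoints, per_ril)
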