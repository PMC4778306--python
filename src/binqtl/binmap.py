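"""Population-level recombination bins and the genetic map.

A *bin marker* is a maximal run of consecutive 100-Kb genomic intervals in
which no RIL in the population carries a recombination event; every line's
genotype is constant within a bin, so the bin acts as a single marker whose
genotype vector across lines feeds the genetic map and QTL scans.

Map distances between adjacent bins are estimated from the observed RIL
mismatch frequency R, corrected for the recombination accumulated over
repeated selfing with the Haldane-Waddington relation ``R = 2r / (1 + 2r)``
(so ``r = R / (2 (1 - R))``), and converted to centiMorgans with the
Kosambi map function ``d = 25 ln((1 + 2r) / (1 - 2r))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from binqtl.calling import BreakpointSet, ChromosomeBlocks, EmptyInputError
from binqtl.genome import ConfigurationError, GenomeSpec
from binqtl.snpmatrix import CALL_N, SYMBOLS

__all__ = [
    "UndefinedRFError",
    "BinMarker",
    "BinMap",
    "GeneticMap",
    "build_bins",
    "bin_stats",
    "estimate_rf",
    "ril_correct",
    "ril_observed_rf",
    "kosambi",
    "kosambi_inverse",
    "build_genetic_map",
    "mean_marker_spacing",
    "collinearity_check",
]


class UndefinedRFError(ValueError):
    """Raised when a recombination fraction has no informative line pairs."""


# --------------------------------------------------------------------------
# bin construction


@dataclass
class BinMarker:
    """One recombination bin: grid-aligned interval + genotype vector."""

    bin_id: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int  # inclusive; last bin may be truncated at the chromosome end
    genotypes: np.ndarray  # int8 codes A/B/H/N per RIL

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def midpoint(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass
class BinMap:
    """Ordered bin markers for a population."""

    bins: list[BinMarker]
    ril_ids: list[str]

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def genotype_matrix(self) -> np.ndarray:
        """(n_bins, n_rils) int8 matrix of bin genotypes."""
        return np.stack([b.genotypes for b in self.bins])

    def chromosome_names(self) -> list[str]:
        seen: list[str] = []
        for b in self.bins:
            if b.chrom not in seen:
                seen.append(b.chrom)
        return seen

    def subset_chromosome(self, chrom: str) -> "BinMap":
        return BinMap([b for b in self.bins if b.chrom == chrom], self.ril_ids)

    def to_frame(self) -> pd.DataFrame:
        sym = np.array(list(SYMBOLS))
        rows = []
        for b in self.bins:
            row = {"bin_id": b.bin_id, "chrom": b.chrom, "start_bp": b.start_bp, "end_bp": b.end_bp}
            row.update(dict(zip(self.ril_ids, sym[b.genotypes])))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        ril_ids = [c for c in df.columns if c not in ("bin_id", "chrom", "start_bp", "end_bp")]
        sym = df[ril_ids].to_numpy(dtype=str)
        codes = np.zeros(sym.shape, dtype=np.int8)
        for i, s in enumerate(SYMBOLS):
            codes[sym == s] = i
        bins = [
            BinMarker(
                str(df["bin_id"].iat[i]), str(df["chrom"].iat[i]),
                int(df["start_bp"].iat[i]), int(df["end_bp"].iat[i]), codes[i],
            )
            for i in range(len(df))
        ]
        return cls(bins, ril_ids)


def _recombination_events(cb: ChromosomeBlocks) -> list[tuple[int, int]]:
    """Hom-to-hom transition intervals for one RIL chromosome.

    A recombination event is a change of homozygous genotype along the
    chromosome.  The sliding-window caller necessarily emits a short
    heterozygous transition run across every clean junction (counts cross
    the supermajority threshold gradually), so the event is localised
    between the last SNP of the left homozygous block and the first SNP of
    the following homozygous block of different label, skipping any
    intervening het blocks.  Hom-het-hom runs returning to the same label
    are not events.
    """
    homs = [b for b in cb.blocks if b.label in ("A", "B")]
    events = []
    for left, right in zip(homs[:-1], homs[1:]):
        if left.label != right.label:
            events.append((left.end_bp, right.start_bp))
    return events


def build_bins(
    blocks_by_ril: dict[str, dict[str, ChromosomeBlocks]],
    breakpoints: BreakpointSet | None,
    spec: GenomeSpec,
    bin_unit: int = 100_000,
    boundary_mode: str = "hom_midpoint",
) -> BinMap:
    """Partition each chromosome into recombination bins on a fixed grid.

    A grid interval is a *boundary* interval iff at least one RIL carries a
    recombination event there.  With the default ``boundary_mode
    "hom_midpoint"`` an event is a transition between consecutive
    homozygous blocks (het transition runs skipped) localised at the
    midpoint of the enclosing SNP gap; mode ``"overlap"`` instead marks
    every grid interval overlapped by any raw breakpoint uncertainty
    interval (a much more conservative rule that can merge most of a
    chromosome into one bin when uncertainty intervals are wide).

    Maximal runs of non-boundary intervals, together with the boundary run
    immediately preceding them, form bins: boundary intervals attach to the
    downstream bin so that bin starts align with recombination events.
    Each RIL's bin genotype is the label of the genotype block covering the
    majority of the bin's base pairs (``N`` when no block overlaps).
    """
    if bin_unit <= 0:
        raise ConfigurationError(f"bin_unit must be positive, got {bin_unit}")
    if boundary_mode not in ("hom_midpoint", "overlap"):
        raise ConfigurationError(f"unknown boundary_mode {boundary_mode!r}")
    ril_ids = list(blocks_by_ril.keys())
    n_rils = len(ril_ids)
    bp_by_chrom: dict[str, list] = {c.name: [] for c in spec.chromosomes}
    if boundary_mode == "overlap":
        if breakpoints is None:
            raise ConfigurationError("boundary_mode 'overlap' requires breakpoints")
        for b in breakpoints.breakpoints:
            bp_by_chrom[b.chrom].append((b.left_bp, b.right_bp))
    else:
        for by_chrom in blocks_by_ril.values():
            for chrom_name, cb in by_chrom.items():
                for left_bp, right_bp in _recombination_events(cb):
                    mid = (left_bp + right_bp) // 2
                    bp_by_chrom[chrom_name].append((mid, mid))

    bins: list[BinMarker] = []
    marker_no = 0
    for chrom in spec.chromosomes:
        L = chrom.bp_length
        n_grid = -(-L // bin_unit)  # ceil
        boundary = np.zeros(n_grid, dtype=bool)
        for left, right in bp_by_chrom[chrom.name]:
            k_lo = (max(left, 1) - 1) // bin_unit
            k_hi = (min(right, L) - 1) // bin_unit
            boundary[k_lo : k_hi + 1] = True
        # a new bin starts at grid 0 and at the first interval of each boundary run
        is_start = np.zeros(n_grid, dtype=bool)
        is_start[0] = True
        is_start[1:] |= boundary[1:] & ~boundary[:-1]
        start_grid = np.flatnonzero(is_start)
        end_grid = np.concatenate([start_grid[1:] - 1, [n_grid - 1]])
        starts_bp = start_grid * bin_unit + 1
        ends_bp = np.minimum((end_grid + 1) * bin_unit, L)

        # per-RIL majority-bp genotype for every bin on this chromosome
        geno = np.full((start_grid.size, n_rils), CALL_N, dtype=np.int8)
        for j, ril in enumerate(ril_ids):
            cb = blocks_by_ril[ril].get(chrom.name)
            if cb is None or not cb.blocks:
                continue
            overlap = np.zeros((start_grid.size, 3))
            bs = np.array([blk.start_bp for blk in cb.blocks])
            be = np.array([blk.end_bp for blk in cb.blocks])
            lab = np.array(["ABH".index(blk.label) for blk in cb.blocks])
            for blk_s, blk_e, blk_l in zip(bs, be, lab):
                i_lo = int(np.searchsorted(ends_bp, blk_s))
                i_hi = int(np.searchsorted(starts_bp, blk_e, side="right"))
                if i_lo >= i_hi:
                    continue
                ov = np.minimum(ends_bp[i_lo:i_hi], blk_e) - np.maximum(
                    starts_bp[i_lo:i_hi], blk_s
                ) + 1
                overlap[i_lo:i_hi, blk_l] += np.maximum(ov, 0)
            # homozygous coverage decides the genotype; het transition runs
            # emitted by the window caller around every junction must not
            # mask the recombination, so H wins only where no homozygous
            # block overlaps the bin (i.e. genuine residual heterozygosity)
            hom_covered = overlap[:, :2].sum(axis=1) > 0
            geno[hom_covered, j] = np.argmax(overlap[hom_covered, :2], axis=1).astype(np.int8)
            het_only = ~hom_covered & (overlap[:, 2] > 0)
            geno[het_only, j] = 2

        for i in range(start_grid.size):
            marker_no += 1
            bins.append(
                BinMarker(
                    bin_id=f"mk{marker_no}",
                    chrom=chrom.name,
                    start_bp=int(starts_bp[i]),
                    end_bp=int(ends_bp[i]),
                    genotypes=geno[i],
                )
            )
    return BinMap(bins, ril_ids)


def bin_stats(
    binmap: BinMap, histogram_edges: np.ndarray | None = None
) -> dict:
    """Length and completeness statistics of a bin map.

    Returns a dict with bin count, mean/median length (bp), the fraction of
    bins shorter than 0.5 Mb, bins longer than 10 Mb, a length histogram
    and the missing-genotype rate.
    """
    if len(binmap) == 0:
        raise EmptyInputError("bin map contains no bins")
    lengths = np.array([b.length for b in binmap.bins], dtype=float)
    if histogram_edges is None:
        histogram_edges = np.array([0, 0.1e6, 0.5e6, 1e6, 10e6, np.inf])
    counts, edges = np.histogram(lengths, bins=histogram_edges)
    geno = binmap.genotype_matrix
    return {
        "n_bins": len(binmap),
        "mean_length_bp": float(lengths.mean()),
        "median_length_bp": float(np.median(lengths)),
        "min_length_bp": float(lengths.min()),
        "max_length_bp": float(lengths.max()),
        "fraction_below_0.5Mb": float((lengths < 0.5e6).mean()),
        "bins_above_10Mb": [b.bin_id for b in binmap.bins if b.length > 10e6],
        "histogram": (counts, edges),
        "missing_rate": float((geno == CALL_N).mean()),
    }


# --------------------------------------------------------------------------
# map functions


def estimate_rf(g_i: np.ndarray, g_j: np.ndarray) -> tuple[float, int]:
    """Observed RIL recombination frequency between two genotype vectors.

    Only lines homozygous (A or B) and non-missing at *both* bins are
    informative; R-hat is the fraction of informative lines whose genotypes
    mismatch.  Returns ``(rhat, n_informative)``.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype vectors must have equal length")
    hom = (g_i <= 1) & (g_j <= 1)
    n = int(hom.sum())
    if n == 0:
        raise UndefinedRFError("no informative (double-homozygous) line pairs")
    mismatch = int((g_i[hom] != g_j[hom]).sum())
    return mismatch / n, n


def ril_correct(rhat: float, clamp: bool = True, r_max: float = 0.4999) -> float:
    """Meiotic recombination fraction from the observed RIL frequency.

    Repeated selfing accumulates recombination, inflating the observed
    mismatch frequency to ``R = 2r / (1 + 2r)`` at fixation; inverting
    gives ``r = R / (2 (1 - R))``.  With ``clamp`` (default), R-hat is
    capped at 0.49 and the result at ``r_max``, keeping downstream map
    functions in their domain.
    """
    if rhat < 0:
        raise ValueError(f"observed recombination frequency must be >= 0, got {rhat}")
    if clamp:
        rhat = min(rhat, 0.49)
    if rhat >= 1:
        return r_max if clamp else np.inf
    r = rhat / (2.0 * (1.0 - rhat))
    return min(r, r_max) if clamp else r


def ril_observed_rf(r: float) -> float:
    """Forward Haldane-Waddington relation for selfed RILs: R = 2r/(1+2r)."""
    if r < 0:
        raise ValueError(f"recombination fraction must be >= 0, got {r}")
    return 2.0 * r / (1.0 + 2.0 * r)


def kosambi(r: float | np.ndarray, clamp: bool = False) -> float | np.ndarray:
    """Kosambi map distance in cM: ``d = 25 ln((1 + 2r) / (1 - 2r))``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    if np.any(r >= 0.5):
        if not clamp:
            raise ValueError("recombination fraction must be < 0.5")
        r = np.minimum(r, 0.4999)
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from a Kosambi distance: ``r = tanh(d/50)/2``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def mean_marker_spacing(total_cm: float, n_markers: int) -> float:
    """Average adjacent-marker distance as map length over marker count.

    This is the reporting convention of the target map summaries (genetic
    length divided by the number of markers on the chromosome or genome).
    """
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return total_cm / n_markers


# --------------------------------------------------------------------------
# genetic map


@dataclass
class GeneticMap:
    """Bin markers with cM coordinates and the per-interval estimates."""

    frame: pd.DataFrame  # bin_id, chrom, start_bp, end_bp, cm, rhat, r, d_cm, n_informative
    warnings: list[str] = field(default_factory=list)

    def chromosome_names(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chromosome_cm(self, chrom: str) -> float:
        sub = self.frame[self.frame["chrom"] == chrom]
        return float(sub["cm"].max())

    @property
    def total_cm(self) -> float:
        return float(sum(self.chromosome_cm(c) for c in self.chromosome_names()))

    def summary(self) -> pd.DataFrame:
        """Per-chromosome map summary with a genome total row.

        Columns mirror the standard high-density-map table: marker count,
        physical span (Mb), genetic length (cM), average adjacent-marker
        distance (genetic length / marker count), the number of gaps of at
        least 5 cM, and the largest gap.
        """
        rows = []
        for chrom in self.chromosome_names():
            sub = self.frame[self.frame["chrom"] == chrom]
            gaps = sub["d_cm"].to_numpy()[1:]
            gaps = gaps[np.isfinite(gaps)]
            cm_len = float(sub["cm"].max())
            phys_mb = float((sub["end_bp"].max() - sub["start_bp"].min() + 1) / 1e6)
            rows.append(
                {
                    "chrom": chrom,
                    "n_markers": len(sub),
                    "physical_mb": phys_mb,
                    "genetic_cm": cm_len,
                    "avg_spacing_cm": mean_marker_spacing(cm_len, len(sub)),
                    "avg_physical_mb": phys_mb / len(sub),
                    "n_gaps_ge_5cm": int((gaps >= 5.0).sum()) if gaps.size else 0,
                    "max_gap_cm": float(gaps.max()) if gaps.size else 0.0,
                }
            )
        df = pd.DataFrame(rows)
        total = {
            "chrom": "Total",
            "n_markers": int(df["n_markers"].sum()),
            "physical_mb": float(df["physical_mb"].sum()),
            "genetic_cm": float(df["genetic_cm"].sum()),
            "avg_spacing_cm": mean_marker_spacing(
                float(df["genetic_cm"].sum()), int(df["n_markers"].sum())
            ),
            "avg_physical_mb": float(df["physical_mb"].sum()) / int(df["n_markers"].sum()),
            "n_gaps_ge_5cm": int(df["n_gaps_ge_5cm"].sum()),
            "max_gap_cm": float(df["max_gap_cm"].max()),
        }
        return pd.concat([df, pd.DataFrame([total])], ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_genetic_map(binmap: BinMap) -> GeneticMap:
    """Estimate cM positions for every bin from adjacent-bin recombination.

    Adjacent-bin distances run through ``estimate_rf`` (pairwise mismatch
    frequency over double-homozygous lines), the Haldane-Waddington RIL
    correction and the Kosambi function.  An interval with no informative
    pairs contributes 0 cM and is recorded as a map-gap warning.
    """
    if len(binmap) == 0:
        raise EmptyInputError("bin map contains no bins")
    rows = []
    warnings: list[str] = []
    for chrom in binmap.chromosome_names():
        sub = binmap.subset_chromosome(chrom)
        cm = 0.0
        prev = None
        for b in sub.bins:
            if prev is None:
                rows.append((b.bin_id, chrom, b.start_bp, b.end_bp, 0.0, np.nan, np.nan, np.nan, 0))
            else:
                try:
                    rhat, n_inf = estimate_rf(prev.genotypes, b.genotypes)
                    r = ril_correct(rhat)
                    d = kosambi(r)
                except UndefinedRFError:
                    warnings.append(
                        f"{chrom}: no informative pairs between {prev.bin_id} and {b.bin_id}"
                    )
                    rhat, r, d, n_inf = np.nan, np.nan, np.nan, 0
                cm += 0.0 if np.isnan(d) else d
                rows.append((b.bin_id, chrom, b.start_bp, b.end_bp, cm, rhat, r, d, n_inf))
            prev = b
    frame = pd.DataFrame(
        rows,
        columns=["bin_id", "chrom", "start_bp", "end_bp", "cm", "rhat", "r", "d_cm", "n_informative"],
    )
    return GeneticMap(frame, warnings)


def collinearity_check(gmap: GeneticMap) -> pd.DataFrame:
    """Rank agreement between genetic (cM) and physical (bp) marker order.

    For each chromosome reports the Spearman correlation between cM and bp
    coordinates and the number of markers whose cM rank differs from their
    bp rank (0 for an internally built map, which is ordered by
    construction).
    """
    if len(gmap.frame) == 0:
        raise EmptyInputError("genetic map is empty")
    rows = []
    for chrom in gmap.chromosome_names():
        sub = gmap.frame[gmap.frame["chrom"] == chrom]
        bp = sub["start_bp"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        if len(sub) < 2:
            rho, n_misplaced = 1.0, 0
        else:
            rho = float(stats.spearmanr(bp, cm).statistic)
            rank_bp = stats.rankdata(bp, method="ordinal")
            rank_cm = stats.rankdata(cm, method="ordinal")
            n_misplaced = int((rank_bp != rank_cm).sum())
        rows.append({"chrom": chrom, "spearman_rho": rho, "n_misplaced": n_misplaced})
    return pd.DataFrame(rows)
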