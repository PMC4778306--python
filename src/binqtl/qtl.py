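"""Single-QTL genome scans on a bin map with permutation thresholds.

The scan is a regression on genotype expectations (Haley-Knott style): bin
genotypes are coded ``x = -1`` (A homozygote), ``+1`` (B homozygote) and
``0`` (heterozygote), missing genotypes and pseudomarker positions are
replaced by their conditional expectation given the nearest flanking
homozygous bins under a Markov RIL model (Kosambi-inverted distances,
Haldane-Waddington transition probabilities), and at every evaluation point
the trait is regressed on the coding:

    LOD = (n / 2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares of the null (mean-only) model and
RSS1 of the one-QTL model.  Genome-wide significance comes from permuting
phenotypes across lines and recording the maximum LOD per permutation;
support intervals are the standard 1.5-LOD drop around a peak.  The fitted
slope is the additive effect of the B (Qi319) allele, so a positive ADD
means the B allele increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from binqtl.binmap import BinMap, GeneticMap, kosambi_inverse
from binqtl.snpmatrix import CALL_A, CALL_B, CALL_H

__all__ = [
    "EvalPoints",
    "LODProfile",
    "PermutationResult",
    "SupportInterval",
    "QTLResult",
    "PQTL",
    "genotype_expectations",
    "scan",
    "permutation_threshold",
    "support_interval",
    "summarize_qtl",
    "find_stable_qtl",
    "integrate_pleiotropic",
    "merge_intervals",
]

_CODE_TO_X = {CALL_A: -1.0, CALL_B: 1.0, CALL_H: 0.0}


@dataclass
class EvalPoints:
    """Evaluation points of a genome scan with their coding matrix.

    ``X`` is ``(n_points, n_rils)``; bin points carry the index of their
    bin marker in the source map (``bin_index``), pseudomarkers -1.
    """

    point_id: np.ndarray
    chrom: np.ndarray
    cm: np.ndarray
    bp: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray
    bin_index: np.ndarray
    X: np.ndarray
    ril_ids: list[str]

    def __len__(self) -> int:
        return int(self.cm.size)


def _pair_expectation(
    x_left: np.ndarray, r1: np.ndarray, x_right: np.ndarray, r2: np.ndarray
) -> np.ndarray:
    """E[x] between two homozygous flanks under the Markov RIL model.

    ``r1``/``r2`` are RIL-scale transition probabilities (probability the
    fixed genotype differs between the flank and the point).  Equivalent to
    enumerating the two-locus RIL genotype table for each flank pair.
    """
    p_b_left = np.where(x_left > 0, 1.0 - r1, r1)
    lik_b = np.where(x_right > 0, 1.0 - r2, r2)
    lik_a = np.where(x_right > 0, r2, 1.0 - r2)
    num = p_b_left * lik_b
    den = num + (1.0 - p_b_left) * lik_a
    p_b = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    return 2.0 * p_b - 1.0


def _transitions(d_cm: np.ndarray) -> np.ndarray:
    """P(fixed genotypes differ) across a map distance d (cM) in a RIL."""
    r = kosambi_inverse(np.maximum(d_cm, 0.0))
    return 2.0 * r / (1.0 + 2.0 * r)


def genotype_expectations(
    binmap: BinMap, gmap: GeneticMap, step: float = 1.0
) -> EvalPoints:
    """Coding matrix at every bin (and optional pseudomarker) position.

    Observed bin genotypes code to -1/+1/0; a missing genotype, or any
    pseudomarker inserted every ``step`` cM, takes the conditional
    expectation of the coding given the RIL's nearest flanking homozygous
    bins.  ``step = 0`` scans markers only.  A chromosome with fewer than
    two bins falls back to markers-only evaluation.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    n_rils = len(binmap.ril_ids)
    ids, chroms, cms, bps, sbps, ebps, bidx, xrows = [], [], [], [], [], [], [], []
    frame = gmap.frame
    for chrom in binmap.chromosome_names():
        sub = binmap.subset_chromosome(chrom)
        sub_map = frame[frame["chrom"] == chrom]
        cm_bins = sub_map["cm"].to_numpy(dtype=float)
        n_bins = len(sub.bins)
        codes = np.stack([b.genotypes for b in sub.bins])
        x_obs = np.full(codes.shape, np.nan)
        for code, val in _CODE_TO_X.items():
            x_obs[codes == code] = val

        eval_cm = cm_bins
        is_bin = np.ones(n_bins, dtype=bool)
        if step > 0 and n_bins >= 2 and cm_bins[-1] > cm_bins[0]:
            grid = np.arange(cm_bins[0] + step, cm_bins[-1], step)
            near = np.min(np.abs(grid[:, None] - cm_bins[None, :]), axis=1) if grid.size else np.empty(0)
            grid = grid[near > 1e-9]
            eval_cm = np.concatenate([cm_bins, grid])
            is_bin = np.concatenate([np.ones(n_bins, bool), np.zeros(grid.size, bool)])
            order = np.argsort(eval_cm, kind="stable")
            eval_cm = eval_cm[order]
            is_bin = is_bin[order]
            bin_of_point = np.full(eval_cm.size, -1)
            bin_of_point[is_bin] = np.arange(n_bins)[np.argsort(np.argsort(cm_bins, kind="stable"), kind="stable")]
        else:
            bin_of_point = np.arange(n_bins)

        # stable sort keeps equal-cM bins in bp order, so re-derive directly:
        if step > 0 and n_bins >= 2 and cm_bins[-1] > cm_bins[0]:
            bin_of_point = np.full(eval_cm.size, -1)
            bin_of_point[is_bin] = np.arange(n_bins)

        X = np.zeros((eval_cm.size, n_rils))
        hom = np.abs(x_obs) > 0.5  # homozygous observed bins
        for j in range(n_rils):
            obs_idx = np.flatnonzero(hom[:, j])
            if obs_idx.size == 0:
                col = np.zeros(eval_cm.size)
            else:
                obs_cm = cm_bins[obs_idx]
                obs_x = x_obs[obs_idx, j]
                right = np.searchsorted(obs_cm, eval_cm, side="left")
                left = right - 1
                has_left = left >= 0
                has_right = right < obs_idx.size
                xl = np.where(has_left, obs_x[np.clip(left, 0, None)], 0.0)
                xr = np.where(has_right, obs_x[np.clip(right, 0, obs_idx.size - 1)], 0.0)
                r1 = _transitions(eval_cm - np.where(has_left, obs_cm[np.clip(left, 0, None)], 0.0))
                r2 = _transitions(np.where(has_right, obs_cm[np.clip(right, 0, obs_idx.size - 1)], 0.0) - eval_cm)
                col = np.where(
                    has_left & has_right,
                    _pair_expectation(xl, r1, xr, r2),
                    np.where(has_left, xl * (1.0 - 2.0 * r1), xr * (1.0 - 2.0 * r2)),
                )
            # observed (incl. heterozygous) bin genotypes override expectations
            for k in np.flatnonzero(is_bin):
                b = bin_of_point[k]
                if not np.isnan(x_obs[b, j]):
                    col[k] = x_obs[b, j]
            X[:, j] = col

        for k in range(eval_cm.size):
            b = bin_of_point[k]
            if b >= 0:
                marker = sub.bins[b]
                ids.append(marker.bin_id)
                bps.append(marker.midpoint)
                sbps.append(marker.start_bp)
                ebps.append(marker.end_bp)
            else:
                ids.append(f"{chrom}@{eval_cm[k]:.2f}cM")
                frac_bp = np.interp(eval_cm[k], cm_bins, [b_.midpoint for b_ in sub.bins])
                bps.append(int(frac_bp))
                sbps.append(int(frac_bp))
                ebps.append(int(frac_bp))
            chroms.append(chrom)
            cms.append(float(eval_cm[k]))
            bidx.append(int(b))
        xrows.append(X)
    return EvalPoints(
        np.array(ids, dtype=object),
        np.array(chroms, dtype=object),
        np.array(cms),
        np.array(bps, dtype=np.int64),
        np.array(sbps, dtype=np.int64),
        np.array(ebps, dtype=np.int64),
        np.array(bidx),
        np.vstack(xrows),
        binmap.ril_ids,
    )


# --------------------------------------------------------------------------
# LOD scan


@dataclass
class LODProfile:
    """LOD, additive-effect and PVE values at every evaluation point."""

    trait: str
    env: str
    points: EvalPoints
    lod: np.ndarray
    effect: np.ndarray
    pve: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point_id": self.points.point_id,
                "chrom": self.points.chrom,
                "cm": self.points.cm,
                "bp": self.points.bp,
                "lod": self.lod,
                "effect": self.effect,
                "pve": self.pve,
            }
        )


def _lod_stats(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOD, slope and PVE for rows of Y against columns of X.

    ``Y`` is ``(m, n)`` (m phenotype vectors), ``X`` is ``(p, n)`` (p
    evaluation points).  Returns arrays of shape ``(m, p)``.
    """
    n = Y.shape[1]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", Yc, Yc)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    sxy = Yc @ Xc.T
    safe_sxx = np.where(sxx > 0, sxx, 1.0)
    rss1 = syy[:, None] - np.where(sxx > 0, sxy**2 / safe_sxx, 0.0)
    rss1 = np.maximum(rss1, np.finfo(float).tiny)
    lod = (n / 2.0) * np.log10(syy[:, None] / rss1)
    slope = np.where(sxx > 0, sxy / safe_sxx, 0.0)
    pve = 100.0 * (1.0 - rss1 / syy[:, None])
    return lod, slope, pve


def scan(
    y: np.ndarray | pd.Series,
    points: EvalPoints,
    trait: str = "",
    env: str = "",
) -> LODProfile:
    """Single-QTL regression scan of one phenotype vector.

    ``y`` is aligned with ``points.ril_ids``; missing phenotypes are
    dropped from the fit.  At each evaluation point the trait is regressed
    on the genotype coding; LOD compares the one-QTL fit to the null.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("need at least 10 non-missing phenotypes")
    yv = y[ok]
    if np.var(yv) == 0:
        raise ValueError("phenotype has zero variance")
    X = points.X[:, ok]
    lod, slope, pve = _lod_stats(yv[None, :], X)
    return LODProfile(trait, env, points, lod[0], slope[0], pve[0], int(ok.sum()))


@dataclass
class PermutationResult:
    """Genome-wide LOD threshold from a permutation null distribution."""

    threshold: float
    lod_floor: float
    max_lods: np.ndarray
    n_perm: int
    alpha: float

    @property
    def effective(self) -> float:
        """Declared threshold: the permutation quantile, floored."""
        return max(self.threshold, self.lod_floor)


def permutation_threshold(
    y: np.ndarray | pd.Series,
    points: EvalPoints,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    lod_floor: float = 3.5,
) -> PermutationResult:
    """Empirical genome-wide LOD threshold by phenotype permutation.

    Phenotypes are shuffled across lines (the same permutation applied at
    every evaluation point), the genome-wide maximum LOD recorded per
    permutation, and the threshold taken as the empirical ``1 - alpha``
    quantile.  The declared threshold never drops below ``lod_floor``
    (default 3.5).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    yv = y[ok]
    X = points.X[:, ok]
    perms = np.stack([rng.permutation(yv) for _ in range(n_perm)])
    lod, _, _ = _lod_stats(perms, X)
    max_lods = lod.max(axis=1)
    threshold = float(np.quantile(max_lods, 1.0 - alpha))
    return PermutationResult(threshold, lod_floor, max_lods, n_perm, alpha)


# --------------------------------------------------------------------------
# intervals and QTL integration


@dataclass
class SupportInterval:
    """A 1.5-LOD-drop support region around a scan peak."""

    chrom: str
    peak_index: int
    left_index: int
    right_index: int
    left_marker: str
    right_marker: str
    start_bp: int
    end_bp: int

    def contains_bp(self, bp: int) -> bool:
        return self.start_bp <= bp <= self.end_bp


def support_interval(
    profile: LODProfile, peak_index: int, drop: float = 1.5
) -> SupportInterval:
    """Maximal contiguous region around the peak with LOD >= peak - drop."""
    pts = profile.points
    chrom = pts.chrom[peak_index]
    on_chrom = np.flatnonzero(pts.chrom == chrom)
    k = int(np.flatnonzero(on_chrom == peak_index)[0])
    lod = profile.lod[on_chrom]
    floor = lod[k] - drop
    left = k
    while left > 0 and lod[left - 1] >= floor:
        left -= 1
    right = k
    while right < lod.size - 1 and lod[right + 1] >= floor:
        right += 1
    li, ri = int(on_chrom[left]), int(on_chrom[right])
    return SupportInterval(
        chrom=str(chrom),
        peak_index=peak_index,
        left_index=li,
        right_index=ri,
        left_marker=str(pts.point_id[li]),
        right_marker=str(pts.point_id[ri]),
        start_bp=int(pts.start_bp[li]),
        end_bp=int(pts.end_bp[ri]),
    )


@dataclass
class Detection:
    """One above-threshold peak in one trait x environment scan."""

    trait: str
    env: str
    chrom: str
    peak_index: int
    peak_id: str
    peak_bp: int
    lod: float
    pve: float
    add: float
    interval: SupportInterval


@dataclass
class QTLResult:
    """A named QTL: peaks of one trait merged across environments."""

    name: str
    trait: str
    environments: list[str]
    chrom: str
    peak_id: str
    peak_bp: int
    left_marker: str
    right_marker: str
    ci_start_bp: int
    ci_end_bp: int
    lod: float
    pve: float
    add: float
    detections: list[Detection] = field(default_factory=list)

    @property
    def physical_length_bp(self) -> int:
        return self.ci_end_bp - self.ci_start_bp + 1


@dataclass
class PQTL:
    """A pleiotropic region: overlapping QTL of at least two traits."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    members: list[str]
    traits: list[str]
    left_marker: str
    right_marker: str
    n_member_detections: int

    @property
    def physical_length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _find_detections(
    profile: LODProfile, threshold: float, drop: float = 1.5
) -> list[Detection]:
    """Peaks of super-threshold runs with their support intervals."""
    pts = profile.points
    out: list[Detection] = []
    for chrom in dict.fromkeys(pts.chrom):
        on = np.flatnonzero(pts.chrom == chrom)
        above = profile.lod[on] >= threshold
        i = 0
        while i < above.size:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            seg = on[i : j + 1]
            lods = profile.lod[seg]
            best = np.flatnonzero(lods == lods.max())
            # ties broken toward the lower bp coordinate
            peak = int(seg[best[np.argmin(pts.bp[seg[best]])]])
            out.append(
                Detection(
                    trait=profile.trait,
                    env=profile.env,
                    chrom=str(chrom),
                    peak_index=peak,
                    peak_id=str(pts.point_id[peak]),
                    peak_bp=int(pts.bp[peak]),
                    lod=float(profile.lod[peak]),
                    pve=float(profile.pve[peak]),
                    add=float(profile.effect[peak]),
                    interval=support_interval(profile, peak, drop=drop),
                )
            )
            i = j + 1
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _chain_components(intervals: list[tuple[int, int]]) -> list[list[int]]:
    """Connected components of the interval-overlap graph."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    comps: list[list[int]] = []
    current: list[int] = []
    reach = -1
    for i in order:
        s, e = intervals[i]
        if current and s > reach:
            comps.append(current)
            current = []
        current.append(i)
        reach = max(reach, e)
    if current:
        comps.append(current)
    return comps


def summarize_qtl(
    profiles: list[LODProfile],
    thresholds: dict[tuple[str, str], float] | float,
    drop: float = 1.5,
) -> list[QTLResult]:
    """Detect and name QTL across traits and environments.

    Each profile is scanned for super-threshold peaks; peaks of the same
    trait whose support intervals overlap across environments are merged
    into one named QTL carrying the environment tags and the mean LOD, PVE
    and additive effect over its member detections.  Names follow the
    ``q{TRAIT}{chrom}`` convention with ``-1, -2, ...`` suffixes when a
    trait has several QTL on one chromosome (ordered by position).
    """
    detections: list[Detection] = []
    for p in profiles:
        thr = thresholds if isinstance(thresholds, (int, float)) else thresholds[(p.trait, p.env)]
        detections.extend(_find_detections(p, float(thr), drop=drop))

    results: list[QTLResult] = []
    by_trait: dict[str, list[Detection]] = {}
    for d in detections:
        by_trait.setdefault(d.trait, []).append(d)
    for trait, dets in by_trait.items():
        by_chrom: dict[str, list[Detection]] = {}
        for d in dets:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, cdets in by_chrom.items():
            intervals = [(d.interval.start_bp, d.interval.end_bp) for d in cdets]
            comps = _chain_components(intervals)
            comps.sort(key=lambda c: min(intervals[i][0] for i in c))
            for k, comp in enumerate(comps):
                members = [cdets[i] for i in comp]
                envs = sorted({m.env for m in members})
                best = max(members, key=lambda m: m.lod)
                ci_start = min(m.interval.start_bp for m in members)
                ci_end = max(m.interval.end_bp for m in members)
                left = min(members, key=lambda m: m.interval.start_bp).interval.left_marker
                right = max(members, key=lambda m: m.interval.end_bp).interval.right_marker
                suffix = f"-{k + 1}" if len(comps) > 1 else ""
                results.append(
                    QTLResult(
                        name=f"q{trait}{chrom}{suffix}",
                        trait=trait,
                        environments=envs,
                        chrom=chrom,
                        peak_id=best.peak_id,
                        peak_bp=best.peak_bp,
                        left_marker=left,
                        right_marker=right,
                        ci_start_bp=ci_start,
                        ci_end_bp=ci_end,
                        lod=float(np.mean([m.lod for m in members])),
                        pve=float(np.mean([m.pve for m in members])),
                        add=float(np.mean([m.add for m in members])),
                        detections=members,
                    )
                )
    results.sort(key=lambda r: (r.trait, _chrom_key(r.chrom), r.ci_start_bp))
    return results


def _chrom_key(name: str):
    return (0, int(name)) if str(name).isdigit() else (1, str(name))


def find_stable_qtl(results: list[QTLResult], min_environments: int = 2) -> list[QTLResult]:
    """QTL detected in at least ``min_environments`` environments."""
    return [r for r in results if len(r.environments) >= min_environments]


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of intervals as a sorted list of disjoint intervals."""
    if not intervals:
        return []
    merged: list[tuple[float, float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def integrate_pleiotropic(results: list[QTLResult]) -> list[PQTL]:
    """Merge overlapping QTL of different traits into pleiotropic regions.

    Per chromosome, QTL whose confidence intervals overlap are chained
    (connected components of the overlap graph); every chain involving at
    least two traits becomes a pQTL whose interval is the union of the
    member confidence intervals.
    """
    out: list[PQTL] = []
    by_chrom: dict[str, list[QTLResult]] = {}
    for r in results:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom, key=_chrom_key):
        rs = by_chrom[chrom]
        intervals = [(r.ci_start_bp, r.ci_end_bp) for r in rs]
        comps = _chain_components(intervals)
        comps.sort(key=lambda c: min(intervals[i][0] for i in c))
        qualifying = [c for c in comps if len({rs[i].trait for i in c}) >= 2]
        for k, comp in enumerate(qualifying):
            members = [rs[i] for i in comp]
            start = min(m.ci_start_bp for m in members)
            end = max(m.ci_end_bp for m in members)
            suffix = f"-{k + 1}" if len(qualifying) > 1 else ""
            out.append(
                PQTL(
                    name=f"pQTL{chrom}{suffix}",
                    chrom=str(chrom),
                    start_bp=start,
                    end_bp=end,
                    members=[m.name for m in members],
                    traits=sorted({m.trait for m in members}),
                    left_marker=min(members, key=lambda m: m.ci_start_bp).left_marker,
                    right_marker=max(members, key=lambda m: m.ci_end_bp).right_marker,
                    n_member_detections=sum(len(m.environments) for m in members),
                )
            )
    return out
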