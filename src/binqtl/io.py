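"""Readers and writers for the pipeline's tabular interchange formats.

All formats are plain text: SNP matrices as TSV or minimal VCF (see
:mod:`binqtl.snpmatrix`), genotype blocks and breakpoints as TSV,
phenotypes as long-format CSV, bin maps and genetic maps as TSV, QTL and
pleiotropic-QTL reports as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from binqtl.calling import Breakpoint, BreakpointSet, ChromosomeBlocks, GenotypeBlock
from binqtl.qtl import PQTL, QTLResult

__all__ = [
    "write_blocks_tsv",
    "read_blocks_tsv",
    "write_breakpoints_tsv",
    "read_breakpoints_tsv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "qtl_report_frame",
    "pqtl_report_frame",
]


def write_blocks_tsv(
    blocks_by_ril: dict[str, dict[str, ChromosomeBlocks]], path: str | Path
) -> None:
    rows = []
    for ril, by_chrom in blocks_by_ril.items():
        for chrom, cb in by_chrom.items():
            for b in cb.blocks:
                rows.append(
                    {
                        "ril": ril,
                        "chrom": chrom,
                        "start_bp": b.start_bp,
                        "end_bp": b.end_bp,
                        "label": b.label,
                        "n_windows": b.n_windows,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_blocks_tsv(path: str | Path) -> dict[str, dict[str, ChromosomeBlocks]]:
    """Reload blocks written by :func:`write_blocks_tsv`.

    Window geometry is not serialised, so the reloaded blocks support bin
    building and genotyping but not re-deriving breakpoint intervals.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ril": str})
    out: dict[str, dict[str, ChromosomeBlocks]] = {}
    for (ril, chrom), sub in df.groupby(["ril", "chrom"], sort=False):
        blocks = [
            GenotypeBlock(
                label=row.label,
                start_idx=-1,
                end_idx=-1,
                start_bp=int(row.start_bp),
                end_bp=int(row.end_bp),
                first_window=-1,
                last_window=-1,
            )
            for row in sub.itertuples()
        ]
        out.setdefault(str(ril), {})[str(chrom)] = ChromosomeBlocks(
            chrom=str(chrom),
            blocks=blocks,
            positions=np.empty(0, dtype=np.int64),
            window_starts=np.empty(0, dtype=np.int64),
            window=0,
        )
    return out


def write_breakpoints_tsv(bps: BreakpointSet, path: str | Path) -> None:
    bps.to_frame().to_csv(path, sep="\t", index=False)


def read_breakpoints_tsv(path: str | Path) -> BreakpointSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ril": str})
    breakpoints = [
        Breakpoint(
            ril=str(r.ril),
            chrom=str(r.chrom),
            left_bp=int(r.left_bp),
            right_bp=int(r.right_bp),
            left_label=str(getattr(r, "left_label", "")),
            right_label=str(getattr(r, "right_label", "")),
        )
        for r in df.itertuples()
    ]
    per_ril: dict[str, int] = {}
    for b in breakpoints:
        per_ril[b.ril] = per_ril.get(b.ril, 0) + 1
    return BreakpointSet(breakpoints, per_ril)


def write_phenotypes_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"ril": str, "env": str})


def qtl_report_frame(results: list[QTLResult]) -> pd.DataFrame:
    """QTL table with the standard columns (name, environments, interval, LOD, PVE, ADD)."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "trait": r.trait,
                "environments": ",".join(r.environments),
                "chrom": r.chrom,
                "flanking_markers": f"{r.left_marker}-{r.right_marker}",
                "interval_mb": f"{r.ci_start_bp / 1e6:.2f}-{r.ci_end_bp / 1e6:.2f}",
                "physical_length_mb": round(r.physical_length_bp / 1e6, 2),
                "peak_bin": r.peak_id,
                "lod": round(r.lod, 2),
                "pve_pct": round(r.pve, 2),
                "add": round(r.add, 2),
            }
            for r in results
        ]
    )


def pqtl_report_frame(pqtls: list[PQTL]) -> pd.DataFrame:
    """Pleiotropic-QTL table: merged intervals and member QTL."""
    return pd.DataFrame(
        [
            {
                "name": p.name,
                "chrom": p.chrom,
                "flanking_markers": f"{p.left_marker}-{p.right_marker}",
                "interval_mb": f"{p.start_bp / 1e6:.2f}-{p.end_bp / 1e6:.2f}",
                "physical_length_mb": round(p.physical_length_bp / 1e6, 2),
                "n_detections": p.n_member_detections,
                "members": ",".join(p.members),
                "traits": ",".join(p.traits),
            }
            for p in pqtls
        ]
    )
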