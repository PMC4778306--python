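"""The SNP genotype matrix exchanged between simulation and calling.

Calls use a four-symbol alphabet encoded as small integers:

====== ======= =====================================
code   symbol  meaning
====== ======= =====================================
0      ``A``   homozygous for the A-parent allele
1      ``B``   homozygous for the B-parent allele
2      ``H``   heterozygous
3      ``N``   missing / not observed
====== ======= =====================================

By convention parent A is the female founder (Ye478-type) and parent B the
male founder (Qi319-type); additive effects downstream are sign-anchored so
that a positive effect means the B allele increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CALL_A", "CALL_B", "CALL_H", "CALL_N", "SYMBOLS", "SNPMatrix"]

CALL_A: int = 0
CALL_B: int = 1
CALL_H: int = 2
CALL_N: int = 3

SYMBOLS: str = "ABHN"
_SYMBOL_TO_CODE = {s: i for i, s in enumerate(SYMBOLS)}


@dataclass
class SNPMatrix:
    """Per-SNP, per-RIL biparental genotype calls.

    Attributes
    ----------
    chrom:
        Chromosome name per SNP (length ``n_snps``).
    pos:
        1-based physical position per SNP, sorted within chromosome.
    calls:
        ``(n_snps, n_rils)`` int8 array of call codes.
    ril_ids:
        Sample identifiers, one per column of ``calls``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    ril_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != self.pos.size:
            raise ValueError("calls must be (n_snps, n_rils) aligned with pos")
        if not self.ril_ids:
            self.ril_ids = [f"RIL{i + 1:04d}" for i in range(self.calls.shape[1])]
        if len(self.ril_ids) != self.calls.shape[1]:
            raise ValueError("ril_ids length must match the number of call columns")
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 3):
            raise ValueError("calls must use codes 0..3 (A/B/H/N)")
        for name in np.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {name}")

    @property
    def n_snps(self) -> int:
        return int(self.pos.size)

    @property
    def n_rils(self) -> int:
        return int(self.calls.shape[1])

    def chromosome_names(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return [str(self.chrom[i]) for i in np.sort(idx)]

    def subset_chromosome(self, name: str) -> "SNPMatrix":
        mask = self.chrom == name
        return SNPMatrix(self.chrom[mask], self.pos[mask], self.calls[mask], self.ril_ids)

    def subset_snps(self, keep: np.ndarray) -> "SNPMatrix":
        return SNPMatrix(self.chrom[keep], self.pos[keep], self.calls[keep], self.ril_ids)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        """Symbolic DataFrame: chrom, pos, then one A/B/H/N column per RIL."""
        sym = np.array(list(SYMBOLS))[self.calls]
        df = pd.DataFrame(sym, columns=self.ril_ids)
        df.insert(0, "pos", self.pos)
        df.insert(0, "chrom", self.chrom)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, symbol_map: dict[str, str] | None = None) -> "SNPMatrix":
        """Read a call matrix TSV.

        ``symbol_map`` translates foreign symbols onto the A/B/H/N alphabet
        (e.g. ``{"0": "A", "2": "B", "1": "H", "-": "N"}``).
        """
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        ril_ids = [c for c in df.columns if c not in ("chrom", "pos")]
        sym = df[ril_ids].to_numpy(dtype=str)
        if symbol_map:
            trans = np.vectorize(lambda s: symbol_map.get(s, s))
            sym = trans(sym)
        codes = np.empty(sym.shape, dtype=np.int8)
        for s, c in _SYMBOL_TO_CODE.items():
            codes[sym == s] = c
        unknown = ~np.isin(sym, list(SYMBOLS))
        if unknown.any():
            bad = sorted(set(sym[unknown].tolist()))
            raise ValueError(f"unknown genotype symbols {bad}; provide symbol_map")
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(), codes, ril_ids)

    def to_vcf(self, path: str | Path, parent_a: str = "Ye478", parent_b: str = "Qi319") -> None:
        """Write a minimal GT-only VCF with the two parents as first samples.

        REF carries the A-parent allele, ALT the B-parent allele; RIL calls
        map to ``0/0`` (A), ``1/1`` (B), ``0/1`` (H) and ``./.`` (missing).
        """
        gt = {CALL_A: "0/0", CALL_B: "1/1", CALL_H: "0/1", CALL_N: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for name in self.chromosome_names():
                fh.write(f"##contig=<ID={name}>\n")
            samples = "\t".join([parent_a, parent_b] + self.ril_ids)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            for i in range(self.n_snps):
                cols = [
                    str(self.chrom[i]),
                    str(self.pos[i]),
                    f"snp{i + 1}",
                    "A",
                    "T",
                    ".",
                    "PASS",
                    ".",
                    "GT",
                    "0/0",
                    "1/1",
                ]
                cols += [gt[int(c)] for c in self.calls[i]]
                fh.write("\t".join(cols) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path, n_parent_samples: int = 2) -> "SNPMatrix":
        """Read a GT-only biparental VCF written by :meth:`to_vcf`.

        The first ``n_parent_samples`` samples are treated as parents and
        dropped from the RIL matrix.  Uses :mod:`cyvcf2` when available and
        falls back to a plain-text reader otherwise.
        """
        try:
            from cyvcf2 import VCF  # noqa: PLC0415
        except ImportError:
            return cls._from_vcf_text(path, n_parent_samples)
        vcf = VCF(str(path), gts012=True)
        ril_ids = list(vcf.samples)[n_parent_samples:]
        chrom, pos, rows = [], [], []
        for var in vcf:
            chrom.append(var.CHROM)
            pos.append(var.POS)
            # gts012: 0=hom-ref(A), 1=het, 2=hom-alt(B), 3=missing
            g = var.gt_types[n_parent_samples:]
            row = np.full(g.shape, CALL_N, dtype=np.int8)
            row[g == 0] = CALL_A
            row[g == 2] = CALL_B
            row[g == 1] = CALL_H
            rows.append(row)
        return cls(np.array(chrom), np.array(pos), np.array(rows), ril_ids)

    @classmethod
    def _from_vcf_text(cls, path: str | Path, n_parent_samples: int = 2) -> "SNPMatrix":
        code = {"0/0": CALL_A, "1/1": CALL_B, "0/1": CALL_H, "1/0": CALL_H, "./.": CALL_N}
        chrom, pos, rows, ril_ids = [], [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    ril_ids = fields[9 + n_parent_samples :]
                    continue
                chrom.append(fields[0])
                pos.append(int(fields[1]))
                gts = fields[9 + n_parent_samples :]
                rows.append([code.get(g.split(":")[0], CALL_N) for g in gts])
        return cls(np.array(chrom), np.array(pos), np.array(rows, dtype=np.int8), ril_ids)
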