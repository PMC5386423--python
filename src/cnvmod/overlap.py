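"""Transcript-union gene intervals and deletion-by-gene carrier matrices.

A gene interval spans the minimum start to the maximum end of all its
transcripts (one interval per symbol; a symbol on two chromosomes is an
error).  A sample carries a gene deletion if any kept consensus deletion of
that sample overlaps the gene interval by at least 1 bp (1-based inclusive:
``max(starts) <= min(ends)``).  Carrier frequency is the carrier proportion
(carriers / N); the allele-count convention (carriers / 2N, heterozygous
carriers assumed) is also reported for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

__all__ = [
    "GeneInterval",
    "CarrierMatrix",
    "build_gene_intervals",
    "intersect_deletions_genes",
    "carrier_frequency",
]


@dataclass(frozen=True)
class GeneInterval:
    symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"gene {self.symbol!r}: start > end")


@dataclass
class CarrierMatrix:
    """Binary samples x genes deletion-carrier table."""

    z: pd.DataFrame  # index = samples, columns = gene symbols, values in {0,1}

    @property
    def samples(self) -> list:
        return list(self.z.index)

    @property
    def genes(self) -> list:
        return list(self.z.columns)

    @property
    def deletion_count(self) -> pd.Series:
        return self.z.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        n = len(self.z)
        carriers = self.deletion_count
        return pd.DataFrame(
            {
                "carriers": carriers,
                "n": n,
                "carrier_freq": carriers / n,
                "allele_freq": carriers / (2 * n),
            }
        )


def build_gene_intervals(transcripts: pd.DataFrame) -> list:
    """Union transcripts per symbol into one gene interval.

    ``transcripts`` needs columns symbol, chromosome, start, end (1-based
    inclusive).  A symbol annotated on two chromosomes raises an error.
    """
    out = []
    for symbol, grp in transcripts.groupby("symbol", sort=True):
        chroms = grp["chromosome"].unique()
        if len(chroms) > 1:
            raise ValidationError(
                f"gene {symbol!r} annotated on multiple chromosomes: {sorted(chroms)}"
            )
        out.append(
            GeneInterval(
                symbol=str(symbol), chromosome=str(chroms[0]),
                start=int(grp["start"].min()), end=int(grp["end"].max()),
            )
        )
    return out


def intersect_deletions_genes(calls, genes, samples=None) -> CarrierMatrix:
    """Carrier matrix from kept consensus deletions and gene intervals.

    ``z[s, g] = 1`` iff some deletion call of sample ``s`` overlaps gene
    ``g`` by >= 1 bp.  Uses an interval tree per chromosome; the result
    equals the quadratic all-pairs overlap scan.
    """
    deletions = [c for c in calls if c.direction == "deletion"]
    if samples is None:
        samples = sorted({c.sample for c in deletions})
    symbols = [g.symbol for g in genes]
    trees = {}
    for j, g in enumerate(genes):
        # intervaltree is half-open; 1-based inclusive [start, end] -> [start, end+1)
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end + 1, j)
    z = np.zeros((len(samples), len(genes)), dtype=np.int8)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for c in deletions:
        tree = trees.get(c.chromosome)
        i = sample_idx.get(c.sample)
        if tree is None or i is None:
            continue
        for hit in tree.overlap(c.start, c.end + 1):
            z[i, hit.data] = 1
    return CarrierMatrix(z=pd.DataFrame(z, index=list(samples), columns=symbols))


def carrier_frequency(z_column) -> float:
    """Carrier proportion carriers / N of a binary carrier vector."""
    z = np.asarray(z_column)
    if z.size == 0:
        raise ValidationError("empty carrier vector")
    return float(np.mean(z))
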