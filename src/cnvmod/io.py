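"""Readers and writers for the external tabular formats.

All downstream modules consume only the domain containers defined here and in
``calling``; nothing else in the package touches files.  Internal genomic
coordinates are 1-based inclusive (UCSC table semantics); BED output is
0-based half-open, converted as ``(start - 1, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "IntensityReport",
    "read_intensity_report",
    "write_intensity_report",
    "read_gene_annotation",
    "read_phenotypes",
    "write_phenotypes",
    "write_calls_bed",
    "read_calls_bed",
    "write_association_table",
    "read_association_table",
    "format_rr_ci",
]

PHENOTYPE_COLUMNS = [
    "sample",
    "age_bc_dx",
    "age_oc_dx",
    "age_mastectomy",
    "age_oophorectomy",
    "age_last_obs",
]


@dataclass
class IntensityReport:
    """Per-probe LRR/BAF signals for a set of samples.

    ``probes`` holds ``probe_id``, ``chromosome`` and 1-based ``position``,
    sorted by chromosome (order of first appearance) then position; ``lrr``
    and ``baf`` are ``(n_probes, n_samples)`` float arrays aligned to it.
    Missing values are NaN and are retained, never imputed.
    """

    probes: pd.DataFrame
    samples: list
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self):
        self._validate_and_sort()

    def _validate_and_sort(self):
        probes = self.probes.reset_index(drop=True)
        if probes["probe_id"].duplicated().any():
            dup = probes.loc[probes["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        chrom_order = {c: i for i, c in enumerate(pd.unique(probes["chromosome"]))}
        order = np.lexsort(
            (probes["position"].to_numpy(), probes["chromosome"].map(chrom_order).to_numpy())
        )
        probes = probes.iloc[order].reset_index(drop=True)
        dup_pos = probes.duplicated(subset=["chromosome", "position"])
        if dup_pos.any():
            row = probes.loc[dup_pos].iloc[0]
            raise ValidationError(
                f"duplicate position {row['chromosome']}:{row['position']} "
                f"(probe {row['probe_id']!r})"
            )
        baf = np.asarray(self.baf, dtype=float)[order]
        bad = (baf < 0) | (baf > 1)
        if np.any(bad & ~np.isnan(baf)):
            i, j = np.argwhere(bad & ~np.isnan(baf))[0]
            raise ValidationError(
                f"BAF {baf[i, j]!r} outside [0,1] at probe "
                f"{probes['probe_id'].iloc[i]!r} sample {self.samples[j]!r}"
            )
        self.probes = probes
        self.lrr = np.asarray(self.lrr, dtype=float)[order]
        self.baf = baf
        self.samples = list(self.samples)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ValidationError(f"unknown sample {sample!r}") from None

    def sample_lrr(self, sample: str) -> np.ndarray:
        return self.lrr[:, self.sample_index(sample)]

    def sample_baf(self, sample: str) -> np.ndarray:
        return self.baf[:, self.sample_index(sample)]

    def chromosomes(self) -> list:
        return list(pd.unique(self.probes["chromosome"]))

    def chromosome_mask(self, chromosome: str) -> np.ndarray:
        return (self.probes["chromosome"] == chromosome).to_numpy()

    def subset_samples(self, samples) -> "IntensityReport":
        idx = [self.sample_index(s) for s in samples]
        return IntensityReport(
            probes=self.probes.copy(), samples=list(samples),
            lrr=self.lrr[:, idx].copy(), baf=self.baf[:, idx].copy(),
        )


def read_intensity_report(path, sample_subset=None) -> IntensityReport:
    """Read a GenomeStudio-final-report-like tab-delimited intensity table.

    Expects columns ``probe_id``, ``chromosome``, ``position`` followed by
    ``<sample>.LRR`` / ``<sample>.BAF`` pairs.  Probes are sorted by position
    within chromosome; missing values are kept as NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    for col in ("probe_id", "chromosome", "position"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    lrr_samples, baf_samples = [], []
    for col in df.columns[3:]:
        if col.endswith(".LRR"):
            lrr_samples.append(col[: -len(".LRR")])
        elif col.endswith(".BAF"):
            baf_samples.append(col[: -len(".BAF")])
        else:
            raise FormatError(f"unrecognized sample column {col!r} (want <sample>.LRR/.BAF)")
    if set(lrr_samples) != set(baf_samples):
        odd = set(lrr_samples) ^ set(baf_samples)
        raise FormatError(f"samples missing an LRR or BAF column: {sorted(odd)}")
    samples = lrr_samples
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in samples]
        if missing:
            raise FormatError(f"requested samples not in file: {missing}")
        samples = list(sample_subset)
    lrr = df[[f"{s}.LRR" for s in samples]].to_numpy(dtype=float)
    baf = df[[f"{s}.BAF" for s in samples]].to_numpy(dtype=float)
    probes = df[["probe_id", "chromosome", "position"]].copy()
    probes["position"] = probes["position"].astype(np.int64)
    return IntensityReport(probes=probes, samples=samples, lrr=lrr, baf=baf)


def write_intensity_report(report: IntensityReport, path) -> None:
    out = report.probes.copy()
    for j, s in enumerate(report.samples):
        out[f"{s}.LRR"] = report.lrr[:, j]
        out[f"{s}.BAF"] = report.baf[:, j]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a transcript table (symbol, chromosome, start, end; 1-based inclusive).

    Duplicate transcripts per symbol are retained; the transcript-union gene
    interval is computed downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    for col in ("symbol", "chromosome", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    df = df[["symbol", "chromosome", "start", "end"]].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] > df["end"]
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise ValidationError(
            f"transcript of {row['symbol']!r} has start {row['start']} > end {row['end']}"
        )
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    return df[PHENOTYPE_COLUMNS].copy()


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_calls_bed(calls, path) -> None:
    """Write consensus calls as BED (0-based half-open).

    Columns: chrom, start, end, sample, support count, direction, state of
    the first member call (or '.'), comma-joined caller names.
    """
    rows = []
    for c in sorted(calls, key=lambda c: (c.chromosome, c.start, c.end, c.sample)):
        state = c.member_calls[0].state if c.member_calls else "."
        rows.append(
            (c.chromosome, c.start - 1, c.end, c.sample, len(c.support),
             c.direction, state, ",".join(sorted(c.support)))
        )
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_calls_bed(path):
    """Read consensus calls back from BED; member calls are not recoverable."""
    from .calling import ConsensusCall

    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise FormatError(f"expected 8 BED fields, got {len(fields)}")
            chrom, start0, end, sample, _, direction, _, callers = fields
            calls.append(
                ConsensusCall(
                    sample=sample, chromosome=chrom,
                    start=int(start0) + 1, end=int(end),
                    direction=direction, support=frozenset(callers.split(",")),
                    member_calls=(),
                )
            )
    return calls


ASSOCIATION_COLUMNS = [
    "gene", "n", "carriers", "carrier_freq", "allele_freq", "deletion_count",
    "U", "V", "chisq", "p_value", "rr", "rr_ci_low", "rr_ci_high", "q_value",
]


def _fmt(x):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return f"{x:.4g}"
    return str(x)


def write_association_table(table: pd.DataFrame, path) -> None:
    """Write the association results TSV with 4-significant-figure floats."""
    df = table[ASSOCIATION_COLUMNS]
    with open(path, "w") as fh:
        fh.write("\t".join(ASSOCIATION_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_association_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def format_rr_ci(rr: float, lo: float, hi: float) -> str:
    """Human-readable relative risk with 95% CI, e.g. ``"0.50 (0.20–1.27)"``."""
    return f"{rr:.2f} ({lo:.2f}–{hi:.2f})"
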