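"""Per-genome and dataset-level census statistics.

Produces the standard summary surface of a phage-genome ATPase census: one
row per genome (length, protein count, GC%, ATPase domain/protein counts),
dataset-level mean/SD/min/max, an ordinary least squares regression of
ATPase-protein count on genome length with a quantile-based normality
diagnostic, and per-category ATPase fractions for mobilome datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from mobatp.detect import AtpaseCall
from mobatp.io import gc_content
from mobatp.records import GeneRecord

#: printed p-value floor used when formatting regression reports
P_VALUE_FLOOR = 2e-16

SUMMARY_COLUMNS = [
    "length_kbp",
    "n_proteins",
    "gc_percent",
    "n_atpase_domains",
    "n_atpase_proteins",
    "n_multi_atpase",
]


@dataclass
class GenomeSummary:
    """One genome's row of the census table."""

    genome_id: str
    length_kbp: float
    n_proteins: int
    gc_percent: float
    n_atpase_domains: int
    n_atpase_proteins: int
    n_multi_atpase: int

    @property
    def atpase_percent_of_proteins(self) -> float:
        if self.n_proteins == 0:
            return 0.0
        return 100.0 * self.n_atpase_proteins / self.n_proteins

    def validate(self) -> None:
        if not (self.n_multi_atpase <= self.n_atpase_proteins <= self.n_proteins):
            raise ValueError(
                f"{self.genome_id}: inconsistent counts "
                f"(multi {self.n_multi_atpase}, atpase {self.n_atpase_proteins}, "
                f"proteins {self.n_proteins})"
            )
        if self.n_atpase_domains < self.n_atpase_proteins:
            raise ValueError(
                f"{self.genome_id}: fewer domains than ATPase proteins"
            )


@dataclass
class RegressionFit:
    """OLS fit of ATPase-protein count on genome length."""

    slope_per_100kbp: float
    intercept: float
    p_value: float
    r_squared: float
    qq_statistic: float
    qq_pass: bool
    n: int

    def formatted_p(self) -> str:
        """Report the slope p-value, flooring very small values at <2e-16."""
        if self.p_value < P_VALUE_FLOOR:
            return "< 2e-16"
        return f"{self.p_value:.3g}"


def summarize_genome(
    genes: Sequence[GeneRecord],
    calls: Sequence[AtpaseCall],
    genome_id: str = "",
    nucleotide_seq: Optional[str] = None,
    length_kbp: Optional[float] = None,
    gc_percent: Optional[float] = None,
) -> GenomeSummary:
    """Summarize one genome's gene calls and ATPase calls into a census row.

    Genome length and GC% come from ``nucleotide_seq`` when given, otherwise
    from the supplied metadata (``length_kbp`` falling back to the furthest
    gene end). Every call must reference a gene of this genome.
    """
    gene_ids = {g.gene_id for g in genes}
    foreign = sorted({c.protein_id for c in calls} - gene_ids)
    if foreign:
        raise ValueError(f"calls reference genes not in this genome: {foreign[:5]}")
    if not genome_id and genes:
        genome_id = genes[0].contig_id
    if nucleotide_seq is not None:
        length_kbp = len(nucleotide_seq) / 1000.0
        gc_percent = gc_content(nucleotide_seq)
    if length_kbp is None:
        length_kbp = max((g.end for g in genes), default=0) / 1000.0
    summary = GenomeSummary(
        genome_id=genome_id,
        length_kbp=float(length_kbp),
        n_proteins=len(genes),
        gc_percent=float(gc_percent) if gc_percent is not None else float("nan"),
        n_atpase_domains=sum(c.n_atpase_domains for c in calls),
        n_atpase_proteins=len(calls),
        n_multi_atpase=sum(1 for c in calls if c.is_multi),
    )
    summary.validate()
    return summary


def summaries_frame(summaries: Iterable[GenomeSummary]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": s.genome_id,
            "length_kbp": s.length_kbp,
            "n_proteins": s.n_proteins,
            "gc_percent": s.gc_percent,
            "n_atpase_domains": s.n_atpase_domains,
            "n_atpase_proteins": s.n_atpase_proteins,
            "n_multi_atpase": s.n_multi_atpase,
            "atpase_percent_of_proteins": s.atpase_percent_of_proteins,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows).set_index("genome_id")


def summarize_dataset(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    """Column-wise mean, sample SD, min and max over genome summaries.

    Sample (n-1) standard deviation; a single genome gets SD 0. Values are
    kept at full precision; round at the reporting layer.
    """
    if not summaries:
        raise ValueError("no genome summaries supplied")
    df = summaries_frame(summaries)[SUMMARY_COLUMNS]
    stats = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1).fillna(0.0) if len(df) > 1 else 0.0,
            "min": df.min(),
            "max": df.max(),
        }
    )
    if len(df) == 1:
        stats["sd"] = 0.0
    return stats


def fit_length_regression(
    summaries: Sequence[GenomeSummary] | None = None,
    lengths: Optional[Sequence[float]] = None,
    counts: Optional[Sequence[float]] = None,
    length_unit: str = "kbp",
    qq_threshold: float = 0.95,
) -> RegressionFit:
    """OLS of ATPase-protein count on genome length, slope per 100 kbp.

    Accepts either genome summaries or explicit (lengths, counts) arrays with
    a declared length unit ("bp" or "kbp"); the reported slope is rescaled to
    ATPase proteins per 100 kbp either way. Normality of the response is
    summarized as the correlation between its sample and theoretical normal
    quantiles (the quantitative analog of a Q-Q plot), passing at >= 0.95.
    """
    if summaries is not None:
        lengths = [s.length_kbp for s in summaries]
        counts = [s.n_atpase_proteins for s in summaries]
        length_unit = "kbp"
    if lengths is None or counts is None:
        raise ValueError("supply either summaries or lengths and counts")
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(counts, dtype=float)
    if length_unit == "bp":
        x = x / 1000.0
    elif length_unit != "kbp":
        raise ValueError(f"unknown length unit {length_unit!r}")
    if len(x) < 3:
        raise ValueError("need at least 3 genomes for a regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all genome lengths identical")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    (osm, osr), _ = scipy.stats.probplot(y, dist="norm")
    qq_r = float(np.corrcoef(osm, osr)[0, 1])
    return RegressionFit(
        slope_per_100kbp=float(model.params[1]) * 100.0,
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        qq_statistic=qq_r,
        qq_pass=qq_r >= qq_threshold,
        n=len(x),
    )


def category_census(
    category_counts: Iterable[tuple[str, int, int]]
) -> pd.DataFrame:
    """Per-category ATPase fraction table with a totals row.

    Input rows are (category, n_proteins, n_atpases); fraction_percent is
    100 x n_atpases / n_proteins rounded to 2 decimals.
    """
    rows = []
    for category, n_proteins, n_atpases in category_counts:
        if n_proteins < 0 or n_atpases < 0:
            raise ValueError(f"{category}: negative counts")
        if n_atpases > n_proteins:
            raise ValueError(
                f"{category}: {n_atpases} ATPases exceed {n_proteins} proteins"
            )
        frac = round(100.0 * n_atpases / n_proteins, 2) if n_proteins else 0.0
        rows.append((category, n_proteins, n_atpases, frac))
    if not rows:
        raise ValueError("no category counts supplied")
    df = pd.DataFrame(
        rows, columns=["category", "n_proteins", "n_atpases", "fraction_percent"]
    )
    tot_p = int(df["n_proteins"].sum())
    tot_a = int(df["n_atpases"].sum())
    total = pd.DataFrame(
        [("total", tot_p, tot_a, round(100.0 * tot_a / tot_p, 2) if tot_p else 0.0)],
        columns=df.columns,
    )
    return pd.concat([df, total], ignore_index=True)


def estimate_packaging_atp(genome_length_bp: int) -> int:
    """ATP cost of packaging a genome: ~1 ATP per 2 bp translocated."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    return round(genome_length_bp / 2)
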