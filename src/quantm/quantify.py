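"""MAPQ-filtered counting, RPM conversion, anticodon pooling and QC stats.

Counting is strict "MAPQ > threshold" (11 passes the default gate of 10,
10 does not).  RPM divides by the number of mapped reads per sample --
every primary mapped read regardless of MAPQ, so the filter applies to the
numerator only (configurable via ``denominator="passing"``).  Anticodon
pooling sums member isodecoders per (amino acid, anticodon) class, within
compartment, and conserves column totals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .reference import TRNAReference

__all__ = [
    "CountTable",
    "count_reads",
    "to_rpm",
    "pool_anticodons",
    "isodecoder_fractions",
    "compartment_fractions",
    "correlate_expression",
    "spikein_linearity",
    "SpikeinFit",
]


@dataclass
class CountTable:
    """Feature-by-sample matrix plus the per-sample mapped-read totals."""

    data: pd.DataFrame               # rows = features, columns = samples
    mapped_total: pd.Series          # primary mapped reads per sample (any MAPQ)
    mapq_min: int = 10
    kind: str = "raw"                # "raw" | "rpm"
    stats: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _count_one(
    alignments: Iterable[AlignmentRecord | None],
    names: set[str],
    mapq_min: int,
) -> tuple[pd.Series, dict]:
    counts: dict[str, int] = {}
    total = mapped = passing = 0
    for rec in alignments:
        total += 1
        if rec is None:
            continue
        if rec.ref_name not in names:
            raise ValueError(f"alignment to unknown reference entry {rec.ref_name!r}")
        mapped += 1
        if rec.mapq > mapq_min:
            passing += 1
            counts[rec.ref_name] = counts.get(rec.ref_name, 0) + 1
    return (
        pd.Series(counts, dtype="int64"),
        {"total": total, "mapped": mapped, "assigned": passing},
    )


def count_reads(
    alignments: Mapping[str, Iterable[AlignmentRecord | None]]
    | Iterable[AlignmentRecord | None],
    ref: TRNAReference,
    mapq_min: int = 10,
) -> CountTable:
    """Count MAPQ-passing primary alignments per reference entry.

    ``alignments`` is either a single iterable (one sample, named
    "sample1") or a mapping of sample name -> iterable.  Unmapped (None)
    and low-MAPQ records are tallied for the assignment-rate report kept in
    ``CountTable.stats``.
    """
    if not isinstance(alignments, Mapping):
        alignments = {"sample1": alignments}
    names = {e.display_name for e in ref}
    order = [e.display_name for e in ref]
    cols, totals, stat_rows = {}, {}, {}
    for sample, recs in alignments.items():
        series, st = _count_one(recs, names, mapq_min)
        cols[sample] = series.reindex(order, fill_value=0)
        totals[sample] = st["mapped"]
        st["assignment_rate"] = st["assigned"] / st["total"] if st["total"] else float("nan")
        stat_rows[sample] = st
    data = pd.DataFrame(cols, dtype="int64")
    data.index.name = "trna"
    return CountTable(
        data=data,
        mapped_total=pd.Series(totals, dtype="int64"),
        mapq_min=mapq_min,
        kind="raw",
        stats=pd.DataFrame(stat_rows).T,
    )


def to_rpm(raw: CountTable, denominator: str = "mapped") -> CountTable:
    """Reads-per-million: count * 1e6 / mapped reads in the sample.

    ``denominator="mapped"`` uses all primary mapped reads (any MAPQ);
    ``"passing"`` restricts to reads that also passed the MAPQ filter, in
    which case RPM columns sum to exactly 1e6.
    """
    if raw.kind != "raw":
        raise ValueError("to_rpm expects a raw count table")
    if denominator == "mapped":
        denom = raw.mapped_total.astype(float)
    elif denominator == "passing":
        denom = raw.data.sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])
        raise ValueError(f"no mapped reads in sample(s) {bad}")
    data = raw.data * 1e6 / denom
    return CountTable(
        data=data,
        mapped_total=raw.mapped_total,
        mapq_min=raw.mapq_min,
        kind="rpm",
        stats=raw.stats,
    )


def pool_anticodons(table: CountTable, ref: TRNAReference) -> CountTable:
    """Sum isodecoders into (amino acid, anticodon) classes, per compartment.

    Row labels become "AA-ANT" for cytosolic classes and "mt:AA-ANT" for
    mitochondrial ones; column totals are conserved exactly.
    """
    meta = {e.display_name: e for e in ref}
    missing = [r for r in table.data.index if r not in meta]
    if missing:
        raise ValueError(f"rows absent from reference: {missing[:5]}")

    def _label(name: str) -> str:
        e = meta[name]
        prefix = "mt:" if e.compartment == "mitochondrial" else ""
        return f"{prefix}{e.amino_acid}-{e.anticodon}"

    grouped = table.data.groupby([_label(r) for r in table.data.index]).sum()
    grouped.index.name = "anticodon_class"
    return CountTable(
        data=grouped,
        mapped_total=table.mapped_total,
        mapq_min=table.mapq_min,
        kind=table.kind,
        stats=table.stats,
    )


def isodecoder_fractions(
    table: CountTable, ref: TRNAReference, anticodon: tuple[str, str]
) -> pd.DataFrame:
    """Percent contribution of each isodecoder to one anticodon class.

    Values are member / class-sum * 100 per sample and add to 100 (up to
    float rounding).  A sample where the whole class is zero yields NaN for
    every member (flagged rather than invented).
    """
    aa, ac = anticodon
    members = [
        e.display_name for e in ref if e.amino_acid == aa and e.anticodon == ac
    ]
    if not members:
        raise ValueError(f"anticodon class {aa}-{ac} not present in reference")
    sub = table.data.loc[[m for m in members if m in table.data.index]]
    totals = sub.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = sub.div(totals.where(totals > 0), axis=1) * 100.0
    return frac


def compartment_fractions(table: CountTable, ref: TRNAReference) -> pd.DataFrame:
    """Per-sample fraction of assigned reads from each compartment."""
    meta = {e.display_name: e.compartment for e in ref}
    comp = [meta[r] for r in table.data.index]
    sums = table.data.groupby(comp).sum()
    return sums.div(table.data.sum(axis=0), axis=1)


def correlate_expression(
    a, b, log_transform: bool = False, pseudocount: float = 0.5
) -> tuple[float, float]:
    """Pearson correlation (r, r^2) between two matched expression vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be matched 1-D vectors")
    if a.size < 3:
        raise ValueError("need at least 3 matched entries")
    if log_transform:
        a = np.log10(a + pseudocount)
        b = np.log10(b + pseudocount)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero variance input")
    r = stats.pearsonr(a, b).statistic
    return float(r), float(r * r)


@dataclass
class SpikeinFit:
    slope: float
    intercept: float
    r2: float
    dynamic_range_log10: float
    n_used: int
    excluded: list[str] = field(default_factory=list)


def spikein_linearity(
    rpm: Mapping[str, float], truth: Mapping[str, float]
) -> SpikeinFit:
    """Least-squares fit of log10(RPM) against log10(input amount).

    Undetected spikes (zero RPM) are excluded from the fit and reported;
    at least 3 detected species are required.
    """
    common = [k for k in truth if k in rpm]
    if any(truth[k] <= 0 for k in common):
        raise ValueError("spike-in input amounts must be positive")
    detected = [k for k in common if rpm[k] > 0]
    excluded = [k for k in common if rpm[k] <= 0]
    if len(detected) < 3:
        raise ValueError("need at least 3 detected spike-in species")
    x = np.log10([truth[k] for k in detected])
    y = np.log10([rpm[k] for k in detected])
    fit = stats.linregress(x, y)
    return SpikeinFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        dynamic_range_log10=float(y.max() - y.min()),
        n_used=len(detected),
        excluded=excluded,
    )
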