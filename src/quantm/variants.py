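"""Per-base modification-signature tabulation from alignments.

Reverse transcriptase leaves two kinds of footprints at modified bases:
misincorporation (a mismatch, insertion or deletion in the read) and
premature termination.  Because library circularization recovers truncated
cDNAs, a termination event shows up as a read whose 5'-most aligned
reference position is internal to the tRNA -- one "stall" is counted at
that position.  Mismatches come from the MD tag, insertions are attributed
to the reference position of the preceding aligned base, and each deleted
reference base counts at its own position.  Coverage spans every reference
position the read covers (aligned or deleted; insertions add none).

The variant fraction at a base is (mismatch + insertion + deletion +
stall) / coverage; positions below a minimum coverage are masked rather
than reported as noisy zeros.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .reference import TRNAReference

__all__ = [
    "VariantTable",
    "StructureAnnotation",
    "FEATURES",
    "tabulate_variants",
    "variant_fraction",
    "filter_detectable",
    "annotate_structure",
    "bin_variants_by_feature",
    "compare_treatments",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")

#: 5' soft clips longer than this disqualify a read from stall counting
#: (likely untrimmed adapter); it still contributes coverage and mismatches.
MAX_STALL_SOFTCLIP = 3

EVENT_KINDS = ("mismatch", "insertion", "deletion", "stall")


@dataclass
class VariantTable:
    """Long-format per-(tRNA, position, sample) event counts and coverage."""

    data: pd.DataFrame  # columns: trna, pos, sample, mismatch, insertion,
    #                     deletion, stall, coverage
    mapq_min: int = 10
    skipped_reads: int = 0

    def pivot(self, column: str) -> pd.DataFrame:
        """(trna, pos) x sample matrix of one column."""
        return self.data.pivot_table(
            index=["trna", "pos"], columns="sample", values=column, fill_value=0
        )

    def variant_counts(self) -> pd.DataFrame:
        d = self.data
        total = d[list(EVENT_KINDS)].sum(axis=1)
        return d.assign(variant=total).pivot_table(
            index=["trna", "pos"], columns="sample", values="variant", fill_value=0
        )


def _md_mismatch_offsets(md: str) -> tuple[list[int], list[int]]:
    """Aligned-base offsets of mismatches, and deletion lengths, from MD.

    Offsets count M-op bases only (deletions advance the reference but not
    the aligned-base counter used here, matching how we walk the CIGAR).
    """
    mismatches: list[int] = []
    deletions: list[int] = []
    aligned = 0
    pos = 0
    for m in _MD_RE.finditer(md):
        if m.group(1) is not None:
            aligned += int(m.group(1))
        elif m.group(2) is not None:
            deletions.append(len(m.group(2)) - 1)
        else:
            mismatches.append(aligned)
            aligned += 1
        pos = m.end()
    if pos != len(md):
        raise ValueError(f"unparseable MD tag {md!r}")
    return mismatches, deletions


def _tabulate_read(
    rec: AlignmentRecord,
    arrays: dict[str, dict[str, np.ndarray]],
) -> None:
    """Add one read's events to the per-tRNA accumulator arrays."""
    a = arrays[rec.ref_name]
    mm_offsets, md_dels = _md_mismatch_offsets(rec.md)
    mm_iter = iter(mm_offsets)
    next_mm = next(mm_iter, None)

    ref_pos = rec.ref_start
    aligned_seen = 0
    first_aligned = None
    lead_clip = 0
    seen_non_clip = False
    md_del_idx = 0
    for ln_str, op in _CIGAR_RE.findall(rec.cigar):
        ln = int(ln_str)
        if op in ("S", "H"):
            if not seen_non_clip:
                lead_clip = ln
            continue
        seen_non_clip = True
        if op in ("M", "=", "X"):
            if first_aligned is None:
                first_aligned = ref_pos
            a["coverage"][ref_pos : ref_pos + ln] += 1
            while next_mm is not None and next_mm < aligned_seen + ln:
                a["mismatch"][ref_pos + (next_mm - aligned_seen)] += 1
                next_mm = next(mm_iter, None)
            aligned_seen += ln
            ref_pos += ln
        elif op == "I":
            if first_aligned is not None:
                a["insertion"][ref_pos - 1] += 1
            # an insertion before any aligned base has no anchor; dropped
        elif op == "D":
            if md_del_idx >= len(md_dels) or md_dels[md_del_idx] != ln:
                raise ValueError(
                    f"CIGAR/MD deletion mismatch for read {rec.read_id}"
                )
            md_del_idx += 1
            a["deletion"][ref_pos : ref_pos + ln] += 1
            a["coverage"][ref_pos : ref_pos + ln] += 1
            ref_pos += ln
        else:
            raise ValueError(f"unsupported CIGAR op {op!r} for read {rec.read_id}")
    if next_mm is not None or md_del_idx != len(md_dels):
        raise ValueError(f"CIGAR/MD inconsistency for read {rec.read_id}")
    if first_aligned is not None and first_aligned > 0 and lead_clip <= MAX_STALL_SOFTCLIP:
        a["stall"][first_aligned] += 1


def tabulate_variants(
    alignments: Mapping[str, Iterable[AlignmentRecord | None]]
    | Iterable[AlignmentRecord | None],
    ref: TRNAReference,
    mapq_min: int = 10,
) -> VariantTable:
    """Tabulate mismatch/insertion/deletion/stall and coverage per base.

    The same MAPQ filter as quantification applies.  A read whose CIGAR and
    MD tags disagree is skipped and counted, never silently mis-tabulated.
    """
    if not isinstance(alignments, Mapping):
        alignments = {"sample1": alignments}
    lengths = {e.display_name: len(e) for e in ref}
    rows = []
    skipped = 0
    for sample, recs in alignments.items():
        arrays = {
            name: {
                k: np.zeros(L, dtype=np.int64)
                for k in (*EVENT_KINDS, "coverage")
            }
            for name, L in lengths.items()
        }
        for rec in recs:
            if rec is None or rec.mapq <= mapq_min:
                continue
            if rec.ref_name not in arrays:
                raise ValueError(f"alignment to unknown entry {rec.ref_name!r}")
            try:
                _tabulate_read(rec, arrays)
            except ValueError:
                skipped += 1
        for name, L in lengths.items():
            a = arrays[name]
            if a["coverage"].sum() == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "trna": name,
                        "pos": np.arange(L),
                        "sample": sample,
                        **{k: a[k] for k in (*EVENT_KINDS, "coverage")},
                    }
                )
            )
    if rows:
        data = pd.concat(rows, ignore_index=True)
    else:
        data = pd.DataFrame(
            columns=["trna", "pos", "sample", *EVENT_KINDS, "coverage"]
        )
    return VariantTable(data=data, mapq_min=mapq_min, skipped_reads=skipped)


def variant_fraction(table: VariantTable, min_coverage: int = 20) -> pd.DataFrame:
    """Variant fraction per (tRNA, position) per sample; low coverage -> NaN."""
    variants = table.variant_counts()
    coverage = table.pivot("coverage")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = variants / coverage
    return frac.where(coverage >= min_coverage)


def filter_detectable(fractions: pd.DataFrame, min_fraction: float = 0.01) -> pd.Index:
    """Positions whose fraction reaches ``min_fraction`` in every sample.

    Masked (NaN) entries fail the gate: a position must be measurable and
    above threshold everywhere to count as reliably detected.
    """
    keep = (fractions >= min_fraction).all(axis=1) & fractions.notna().all(axis=1)
    return fractions.index[keep]


# ---------------------------------------------------------------------------
# cloverleaf structure annotation

FEATURES = (
    "acceptor_stem_5p",
    "d_arm",
    "d_loop",
    "anticodon_stem",
    "anticodon_loop",
    "variable_loop",
    "t_stem",
    "t_loop",
    "acceptor_stem_3p",
    "discriminator",
)


@dataclass
class StructureAnnotation:
    """Per-tRNA map of position -> cloverleaf feature."""

    features: dict[str, list[str]]
    degraded: set[str] = field(default_factory=set)

    def feature_of(self, trna: str, pos: int) -> str:
        return self.features[trna][pos]

    def positions_of(self, trna: str, feature: str) -> list[int]:
        return [i for i, f in enumerate(self.features[trna]) if f == feature]


def _annotate_one(seq: str, anticodon: str) -> tuple[list[str], bool]:
    """End-anchored cloverleaf assignment for one tRNA body (no CCA).

    Both ends are fixed by the acceptor stem geometry; the T-loop sits at a
    constant offset from the 3' end; the anticodon loop is centered on the
    annotated anticodon located in the central third of the body.  Gaps
    between anchored blocks inherit the D-arm (5' side) or variable loop
    (central) label so that every position is assigned exactly once.
    """
    L = len(seq)
    lab: list[str | None] = [None] * L

    def fill(lo: int, hi: int, name: str) -> None:
        for i in range(max(lo, 0), min(hi, L)):
            if lab[i] is None:
                lab[i] = name

    fill(L - 1, L, "discriminator")
    fill(0, 7, "acceptor_stem_5p")
    fill(L - 8, L - 1, "acceptor_stem_3p")
    fill(L - 23, L - 16, "t_loop")
    fill(L - 28, L - 23, "t_stem")   # 5' strand of the T-stem
    fill(L - 16, L - 8, "t_stem")    # 3' strand, runs to the acceptor stem

    third = (L // 3, 2 * L // 3)
    ac_at = seq.find(anticodon, third[0], third[1])
    degraded = ac_at < 0
    if not degraded:
        center = ac_at + 1
        fill(center - 3, center + 4, "anticodon_loop")
        fill(center - 8, center - 3, "anticodon_stem")
        fill(center + 4, center + 9, "anticodon_stem")
        # D-arm between acceptor stem and anticodon stem; its middle is the
        # D-loop proper (stems of ~4 bp flank it when there is room).
        d_lo, d_hi = 7, center - 8
        if d_hi - d_lo >= 9:
            fill(d_lo, d_lo + 4, "d_arm")
            fill(d_hi - 4, d_hi, "d_arm")
            fill(d_lo + 4, d_hi - 4, "d_loop")
        else:
            fill(d_lo, d_hi, "d_loop")
        fill(center + 9, L - 28, "variable_loop")
    # anything still unassigned (overlaps on short bodies, or a degraded
    # annotation) inherits the label of the nearest assigned 5' neighbour
    last = "acceptor_stem_5p" if not degraded else "variable_loop"
    for i in range(L):
        if lab[i] is None:
            lab[i] = last
        else:
            last = lab[i]
    return lab, degraded  # type: ignore[return-value]


def annotate_structure(ref: TRNAReference) -> StructureAnnotation:
    """Rule-based cloverleaf feature assignment for every reference entry."""
    features: dict[str, list[str]] = {}
    degraded: set[str] = set()
    for e in ref:
        lab, bad = _annotate_one(e.sequence, e.anticodon)
        features[e.display_name] = lab
        if bad:
            degraded.add(e.display_name)
    return StructureAnnotation(features=features, degraded=degraded)


def bin_variants_by_feature(
    positions: Sequence[tuple[str, int]], annotation: StructureAnnotation
) -> dict[str, int]:
    """Histogram of (tRNA, position) pairs over cloverleaf features."""
    hist = {f: 0 for f in FEATURES}
    for trna, pos in positions:
        if trna not in annotation.features:
            raise ValueError(f"unannotated tRNA {trna!r}")
        feats = annotation.features[trna]
        if not 0 <= pos < len(feats):
            raise ValueError(f"position {pos} outside {trna}")
        hist[feats[pos]] += 1
    return hist


def compare_treatments(
    fractions_a: pd.DataFrame, fractions_b: pd.DataFrame
) -> pd.DataFrame:
    """Paired per-base fraction differences (a - b), masking propagated.

    Samples are matched by column order (treated vs control of the same
    tissue); positions present in only one input are dropped.
    """
    shared = fractions_a.index.intersection(fractions_b.index)
    if len(shared) == 0:
        raise ValueError("no shared positions between treatments")
    a = fractions_a.loc[shared]
    b = fractions_b.loc[shared]
    if a.shape[1] != b.shape[1]:
        raise ValueError("treatment tables have different sample counts")
    return pd.DataFrame(
        a.to_numpy() - b.to_numpy(), index=shared, columns=a.columns
    )
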