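"""Local alignment of trimmed reads against the collapsed tRNA reference.

Scoring follows the local-mode conventions of short-read aligners: +2 per
match, -6 per mismatch (no base qualities supplied, so the maximum penalty
applies), -1 for positions involving N, and affine gaps costing 8 for the
first gapped base and 3 for each extension.  An alignment is reported only
when its score reaches the length-dependent gate

    f(L) = a + b * ln(L)

with (a, b) = (20, 8) as the aligner default and (1, 8) as the pipeline
setting, which lowers the smallest mappable perfect read from 23 nt to
10 nt -- short enough to keep the reads produced by reverse-transcriptase
stalling in the T-loop.

Because the reference is a few hundred sequences of at most 100 nt, the
search is an exhaustive Smith-Waterman against every entry rather than a
seeded heuristic; the best and second-best entry scores feed a documented
MAPQ bin table (ties map to 0, unique hits to >=42).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import _kernels
from .reference import TRNAReference

__all__ = [
    "ScoringScheme",
    "AlignmentRecord",
    "min_score",
    "local_align",
    "assign_mapq",
    "align_reads",
    "write_sam",
    "import_alignments",
]


@dataclass(frozen=True)
class ScoringScheme:
    match_bonus: int = 2
    mismatch_max: int = 6
    mismatch_min: int = 2
    n_penalty: int = 1
    read_gap_open: int = 5
    read_gap_extend: int = 3
    ref_gap_open: int = 5
    ref_gap_extend: int = 3
    min_score_a: float = 20.0
    min_score_b: float = 8.0

    def __post_init__(self) -> None:
        if self.match_bonus <= 0:
            raise ValueError("match_bonus must be positive")
        if self.min_score_b < 0:
            raise ValueError("min_score_b must be non-negative")

    @classmethod
    def pipeline(cls) -> "ScoringScheme":
        """The short-read-permissive gate used throughout the pipeline."""
        return cls(min_score_a=1.0, min_score_b=8.0)


@dataclass
class AlignmentRecord:
    """One local alignment of a read to one reference entry (+ strand only)."""

    read_id: str
    ref_name: str
    ref_start: int  # 0-based
    ref_end: int    # 0-based exclusive
    strand: str
    score: int
    mapq: int
    cigar: str
    md: str
    read_seq: str
    second_score: int | None = None
    nm: int = 0


def min_score(read_length: int, a: float, b: float) -> float:
    """Length-dependent minimum local-alignment score a + b*ln(L)."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    return a + b * math.log(read_length)


def min_mappable_length(scheme: ScoringScheme, max_l: int = 200) -> int:
    """Smallest L above which every perfect read clears the score gate.

    2L - (a + b*ln L) is not monotone (ln 1 = 0 lets a trivial 1-mer pass
    some gates), so this is the sustained crossing: one past the longest
    failing length.
    """
    last_fail = 0
    for L in range(1, max_l + 1):
        if scheme.match_bonus * L < min_score(L, scheme.min_score_a, scheme.min_score_b):
            last_fail = L
    if last_fail >= max_l:
        raise ValueError(f"no mappable length up to {max_l}")
    return last_fail + 1


# MAPQ bins on the normalized score gap g = (best - second) / perfect.
# Monotone non-decreasing in the gap; anchored at tie -> 0 and unique -> >=42.
_MAPQ_BINS = (
    (0.50, 40),
    (0.25, 33),
    (0.15, 27),
    (0.10, 23),
    (0.05, 17),
    (0.02, 12),
    (0.00, 5),
)


def assign_mapq(
    best_score: int,
    second_score: int | None,
    read_length: int,
    scheme: ScoringScheme = ScoringScheme(),
) -> int:
    """Phred-scaled mapping quality from the best/second-best score gap.

    q satisfies P(correct) >= 1 - 10**(-q/10); a tie is maximally ambiguous
    (q = 0) and a read with no second hit above the gate is near-certain
    (q >= 42).  Between those anchors the bins are monotone in the gap.
    """
    if second_score is not None and best_score < second_score:
        raise ValueError("best_score must be >= second_score")
    perfect = scheme.match_bonus * read_length
    if second_score is None:
        return 44 if best_score >= 0.9 * perfect else 42
    gap = best_score - second_score
    if gap <= 0:
        return 0
    g = gap / perfect
    for threshold, q in _MAPQ_BINS:
        if g > threshold:
            return q
    return 5


class _EncodedReference:
    """Reference packed into flat arrays for the alignment kernels."""

    def __init__(self, ref: TRNAReference):
        self.entries = list(ref)
        self.names = [e.display_name for e in self.entries]
        self.seqs = [e.sequence for e in self.entries]
        codes = [_kernels.encode(s) for s in self.seqs]
        self.cat = (
            np.concatenate(codes) if codes else np.empty(0, np.uint8)
        )
        lens = np.array([len(c) for c in codes], dtype=np.int64)
        self.ends = np.cumsum(lens)
        self.starts = self.ends - lens
        self.encoded = codes


def _build_cigar_md(
    read: str,
    ref_seq: str,
    read_start: int,
    read_end: int,
    ref_start: int,
    ops: np.ndarray,
    lens: np.ndarray,
) -> tuple[str, str, int]:
    """CIGAR (with soft clips) and MD tag for a traced-back alignment."""
    cigar_parts = []
    if read_start > 0:
        cigar_parts.append(f"{read_start}S")
    md_parts: list[str] = []
    match_run = 0
    nm = 0
    rpos, gpos = read_start, ref_start
    for op, ln in zip(ops, lens):
        ln = int(ln)
        if op == 0:
            cigar_parts.append(f"{ln}M")
            for _ in range(ln):
                if read[rpos] == ref_seq[gpos]:
                    match_run += 1
                else:
                    md_parts.append(str(match_run))
                    md_parts.append(ref_seq[gpos])
                    match_run = 0
                    nm += 1
                rpos += 1
                gpos += 1
        elif op == 1:
            cigar_parts.append(f"{ln}I")
            rpos += ln
            nm += ln
        else:
            cigar_parts.append(f"{ln}D")
            md_parts.append(str(match_run))
            md_parts.append("^" + ref_seq[gpos : gpos + ln])
            match_run = 0
            gpos += ln
            nm += ln
    md_parts.append(str(match_run))
    if len(read) - read_end > 0:
        cigar_parts.append(f"{len(read) - read_end}S")
    return "".join(cigar_parts), "".join(md_parts), nm


def local_align(
    read: str | tuple[str, str],
    ref: TRNAReference | _EncodedReference,
    scoring: ScoringScheme = ScoringScheme.pipeline(),
) -> AlignmentRecord | None:
    """Exhaustively align one read against every reference entry.

    Returns the best-scoring alignment if it clears min_score(L), else None.
    The second-best entry score (when itself above the gate) sets MAPQ; a
    read matching two entries equally well gets MAPQ 0.
    """
    if isinstance(read, tuple):
        read_id, seq = read
    else:
        read_id, seq = "read", read
    if not isinstance(ref, _EncodedReference):
        ref = _EncodedReference(ref)
    if not ref.entries:
        raise ValueError("empty reference")
    L = len(seq)
    if L < 1:
        return None
    gate = min_score(L, scoring.min_score_a, scoring.min_score_b)
    codes = _kernels.encode(seq)
    scores = _kernels.sw_all_scores(
        codes,
        ref.cat,
        ref.starts,
        ref.ends,
        scoring.match_bonus,
        scoring.mismatch_max,
        scoring.n_penalty,
        scoring.read_gap_open,
        scoring.read_gap_extend,
    )
    best_idx = int(np.argmax(scores))
    best = int(scores[best_idx])
    if best < gate:
        return None
    second: int | None = None
    if len(scores) > 1:
        rest = np.delete(scores, best_idx)
        s2 = int(rest.max())
        if s2 >= gate:
            second = s2
    sc, rs, re_, gs, ge_, ops, lens, n_ops = _kernels.sw_traceback(
        codes,
        ref.encoded[best_idx],
        scoring.match_bonus,
        scoring.mismatch_max,
        scoring.n_penalty,
        scoring.read_gap_open,
        scoring.read_gap_extend,
    )
    cigar, md, nm = _build_cigar_md(
        seq, ref.seqs[best_idx], rs, re_, gs, ops[:n_ops], lens[:n_ops]
    )
    return AlignmentRecord(
        read_id=read_id,
        ref_name=ref.names[best_idx],
        ref_start=gs,
        ref_end=ge_,
        strand="+",
        score=sc,
        mapq=assign_mapq(best, second, L, scoring),
        cigar=cigar,
        md=md,
        read_seq=seq,
        second_score=second,
        nm=nm,
    )


def align_reads(
    reads: Iterable[tuple[str, str]],
    ref: TRNAReference,
    scoring: ScoringScheme = ScoringScheme.pipeline(),
) -> Iterator[AlignmentRecord | None]:
    """Align a stream of (read_id, sequence) pairs; None marks unmapped."""
    enc = _EncodedReference(ref)
    for read in reads:
        yield local_align(read, enc, scoring)


def write_sam(
    records: Iterable[AlignmentRecord | None],
    ref: TRNAReference,
    path: str | Path,
) -> int:
    """Write alignments as SAM with MD/NM tags (1-based in the file)."""
    import pysam

    entries = list(ref)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": e.display_name, "LN": len(e)} for e in entries],
    }
    name_to_tid = {e.display_name: i for i, e in enumerate(entries)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            if rec is None:
                continue
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.read_seq
            a.flag = 0
            a.reference_id = name_to_tid[rec.ref_name]
            a.reference_start = rec.ref_start
            a.mapping_quality = rec.mapq
            a.cigarstring = rec.cigar
            a.set_tag("AS", rec.score)
            a.set_tag("MD", rec.md)
            a.set_tag("NM", rec.nm)
            if rec.second_score is not None:
                a.set_tag("XS", rec.second_score)
            out.write(a)
            n += 1
    return n


def _md_from_reference(read_seq: str, ref_seq: str, ref_start: int, cigartuples) -> tuple[str, int]:
    """Reconstruct an MD tag by base-wise comparison through the CIGAR."""
    md_parts: list[str] = []
    run = 0
    nm = 0
    rpos, gpos = 0, ref_start
    for op, ln in cigartuples:
        if op == 4:  # soft clip
            rpos += ln
        elif op in (0, 7, 8):  # M/=/X
            for _ in range(ln):
                if read_seq[rpos] == ref_seq[gpos]:
                    run += 1
                else:
                    md_parts.append(str(run))
                    md_parts.append(ref_seq[gpos])
                    run = 0
                    nm += 1
                rpos += 1
                gpos += 1
        elif op == 1:  # insertion
            rpos += ln
            nm += ln
        elif op == 2:  # deletion
            md_parts.append(str(run))
            md_parts.append("^" + ref_seq[gpos : gpos + ln])
            run = 0
            gpos += ln
            nm += ln
        else:
            raise ValueError(f"unsupported CIGAR op {op} in imported alignment")
    md_parts.append(str(run))
    return "".join(md_parts), nm


def import_alignments(
    path: str | Path, ref: TRNAReference | None = None
) -> tuple[list[AlignmentRecord], dict]:
    """Import SAM/BAM records produced by an external aligner.

    MD tags are taken from the file when present, otherwise reconstructed
    from ``ref`` (an error if neither is available).  Unmapped and secondary
    records are skipped and counted in the returned log dict.
    """
    import pysam

    seqs = {e.display_name: e.sequence for e in ref} if ref is not None else {}
    log = {"imported": 0, "unmapped": 0, "secondary": 0, "md_reconstructed": 0}
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                log["unmapped"] += 1
                continue
            if a.is_secondary or a.is_supplementary:
                log["secondary"] += 1
                continue
            ref_name = a.reference_name
            if ref is not None and ref_name not in seqs:
                raise ValueError(f"alignment to unknown reference entry {ref_name!r}")
            nm = int(a.get_tag("NM")) if a.has_tag("NM") else 0
            if a.has_tag("MD"):
                md = str(a.get_tag("MD"))
            else:
                if ref_name not in seqs:
                    raise ValueError(
                        "record lacks an MD tag and no reference was supplied "
                        f"(read {a.query_name})"
                    )
                md, nm = _md_from_reference(
                    a.query_sequence, seqs[ref_name], a.reference_start, a.cigartuples
                )
                log["md_reconstructed"] += 1
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    ref_name=ref_name,
                    ref_start=a.reference_start,
                    ref_end=a.reference_end,
                    strand="-" if a.is_reverse else "+",
                    score=int(a.get_tag("AS")) if a.has_tag("AS") else 0,
                    mapq=a.mapping_quality,
                    cigar=a.cigarstring,
                    md=md,
                    read_seq=a.query_sequence or "",
                    nm=nm,
                )
            )
            log["imported"] += 1
    return records, log
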