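"""Nucleotide composition across the cDNA circularization junction.

Circularizing single-stranded cDNA joins the 3' end of the cDNA (which
mirrors where reverse transcription stopped) to the 5' end of the RT
primer, whose first two bases are engineered to be random (25% each).  In
the sequenced read the junction therefore appears right at the read start:
positions 1-2 are the random bases and position 3 is the first templated
base.  Comparing the base composition predicted from cDNA band weights
(shortest bands end in A, the m1A-stall signature; full-length cDNA ends
in T) against the composition observed in reads diagnoses ligation and
PCR sequence bias.

Read-end profiling summarises the same stall phenomenology in structural
terms: each read is assigned to the cloverleaf feature of its stall
position (T-loop, anticodon loop, D-loop) or counted as full length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .variants import MAX_STALL_SOFTCLIP, StructureAnnotation, _CIGAR_RE

__all__ = [
    "BandModel",
    "EndProfile",
    "predict_junction_frequencies",
    "observed_junction_frequencies",
    "read_end_profile",
]

BASES = ("A", "C", "G", "T")
UNIFORM = {b: 0.25 for b in BASES}


@dataclass(frozen=True)
class BandModel:
    """A mixture of cDNA species: (label, weight, end-base distribution)."""

    bands: tuple[tuple[str, float, Mapping[str, float]], ...]

    def __post_init__(self) -> None:
        total = sum(w for _, w, _ in self.bands)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"band weights sum to {total}, expected 1")
        for label, _, dist in self.bands:
            if abs(sum(dist.get(b, 0.0) for b in BASES) - 1.0) > 1e-9:
                raise ValueError(f"band {label!r}: base probabilities must sum to 1")


def predict_junction_frequencies(model: BandModel) -> dict[str, float]:
    """Mixture prediction of the base at the cDNA 3' junction position."""
    return {
        b: sum(w * dist.get(b, 0.0) for _, w, dist in model.bands) for b in BASES
    }


def observed_junction_frequencies(
    reads: Iterable[str | tuple], n_positions: int = 3
) -> pd.DataFrame:
    """Base frequencies of the first ``n_positions`` bases of raw reads.

    ``reads`` yields sequences, or (id, seq, ...) tuples as produced by the
    FASTQ reader.  Reads must be pre-trim: the junction sits at the read
    start only before the fixed NN cut.  Returns a (position x base)
    DataFrame of frequencies; each row sums to 1 over observed bases.
    """
    counters = [Counter() for _ in range(n_positions)]
    n = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        for i in range(min(n_positions, len(seq))):
            counters[i][seq[i]] += 1
        n += 1
    if n == 0:
        raise ValueError("no reads supplied")
    rows = []
    for c in counters:
        total = sum(c[b] for b in BASES)
        rows.append(
            {b: (c[b] / total if total else np.nan) for b in BASES}
        )
    return pd.DataFrame(rows, index=pd.RangeIndex(n_positions, name="position"))


@dataclass
class EndProfile:
    """Per-sample fractions of reads by RT stop feature."""

    fractions: pd.DataFrame  # rows = samples, columns = t_loop, anticodon_loop,
    #                          d_loop, full_length, other


_PROFILE_FEATURES = ("t_loop", "anticodon_loop", "d_loop", "full_length", "other")


def _stall_position(rec: AlignmentRecord) -> int | None:
    """The read's 5'-most aligned reference base, or None when ineligible."""
    lead_clip = 0
    for ln, op in _CIGAR_RE.findall(rec.cigar):
        if op in ("S", "H"):
            lead_clip = int(ln)
            continue
        break
    if lead_clip > MAX_STALL_SOFTCLIP:
        return None
    return rec.ref_start


def read_end_profile(
    alignments: Mapping[str, Iterable[AlignmentRecord | None]]
    | Iterable[AlignmentRecord | None],
    annotation: StructureAnnotation,
    mapq_min: int = 10,
) -> EndProfile:
    """Fraction of reads stalling in each cloverleaf loop, per sample.

    A read whose 5'-most aligned base is reference position 0 is full
    length; otherwise its stall position's feature decides the bin.  Stalls
    in features outside the three loops land in "other", so the reported
    loop + full-length fractions sum to at most 1.
    """
    if not isinstance(alignments, Mapping):
        alignments = {"sample1": alignments}
    rows = {}
    for sample, recs in alignments.items():
        tally = {f: 0 for f in _PROFILE_FEATURES}
        total = 0
        for rec in recs:
            if rec is None or rec.mapq <= mapq_min:
                continue
            pos = _stall_position(rec)
            if pos is None:
                continue
            total += 1
            if pos == 0:
                tally["full_length"] += 1
                continue
            feature = annotation.feature_of(rec.ref_name, pos)
            tally[feature if feature in tally else "other"] += 1
        rows[sample] = {
            f: (tally[f] / total if total else np.nan) for f in _PROFILE_FEATURES
        }
    return EndProfile(fractions=pd.DataFrame(rows).T[list(_PROFILE_FEATURES)])
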