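"""Error-tolerant adapter and CCA trimming of raw reads.

The library architecture puts two engineered random bases (NN), the 5'
adapter, the tRNA body, the CCA tail and the 3' adapter on every read:

    NN + TCCAACTGGATACTGGN + body + CCA + GTATCCAGTTGGAATT...

Trimming proceeds in three fixed steps, each tolerant to substitutions and
indels at up to a 20% error rate over the matched adapter length:

1. cut the first two bases (the randomized NN),
2. remove the 5' adapter ``TCCAACTGGATACTGGN`` and everything 5' of it
   (the trailing N matches the random ribonucleotide at zero cost),
3. remove the 3' adapter ``CCAGTATCCAGTTGGAATT`` and everything 3' of it --
   its literal starts with CCA, so the tRNA's CCA tail comes off in the
   same match.

What remains is the sequenced portion of the tRNA body (full length, or a
3' suffix when reverse transcriptase stalled part-way).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from . import _kernels

__all__ = [
    "ADAPTER_5P",
    "ADAPTER_3P",
    "TrimSpec",
    "TrimmedRead",
    "find_adapter",
    "trim_read",
    "trim_reads",
    "trim_fastq",
    "read_fastq",
    "write_fastq",
]

ADAPTER_5P = "TCCAACTGGATACTGGN"
ADAPTER_3P = "CCAGTATCCAGTTGGAATT"

#: Reads trimmed below this length are emitted but flagged; they cannot pass
#: the aligner's minimum-score gate anyway.
MIN_USEFUL_LENGTH = 10


@dataclass(frozen=True)
class TrimSpec:
    """Parameters of the three-step trim recipe."""

    fixed_cut_5p: int = 2
    adapter_5p: str = ADAPTER_5P
    adapter_3p: str = ADAPTER_3P
    error_rate: float = 0.2
    min_overlap: int = 3
    #: optional standalone terminal-CCA trim for externally trimmed input;
    #: off by default because the 3' adapter match already removes CCA.
    trim_terminal_cca: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not self.adapter_5p or not self.adapter_3p:
            raise ValueError("adapters must be non-empty")


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str
    quality: str
    events: list[tuple[str, int]] = field(default_factory=list)
    flagged: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence/quality length mismatch")


def find_adapter(
    seq: str,
    adapter: str,
    error_rate: float = 0.2,
    end: str = "three_prime",
    min_overlap: int = 3,
) -> tuple[int, int, int] | None:
    """Locate the best error-tolerant occurrence of ``adapter`` in ``seq``.

    Semi-global alignment allowing substitutions and indels; the allowed
    error count is floor(error_rate * matched adapter length), and ``N`` in
    the adapter matches anything for free.  In ``five_prime`` mode a partial
    adapter may hang off the read start and the match plus everything 5' of
    it is what a trimmer would remove; ``three_prime`` mirrors that at the
    other end.  Returns (start, end, errors) in ``seq`` coordinates, or
    None when nothing acceptable is found.
    """
    if not seq:
        raise ValueError("empty sequence")
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown end: {end!r}")
    s = _kernels.encode(seq)
    a = _kernels.encode(adapter)
    if end == "five_prime":
        start, stop, errors, _ = _kernels.adapter_match(
            s, a, error_rate, min_overlap, True
        )
        if start < 0:
            return None
        return start, stop, errors
    start, stop, errors, _ = _kernels.adapter_match(
        s[::-1].copy(), a[::-1].copy(), error_rate, min_overlap, False
    )
    if start < 0:
        return None
    n = len(seq)
    return n - stop, n - start, errors


def trim_read(read: tuple[str, str, str], spec: TrimSpec = TrimSpec()) -> TrimmedRead:
    """Apply the full trim recipe to one (id, sequence, quality) record."""
    read_id, seq, qual = read
    events: list[tuple[str, int]] = []

    cut = min(spec.fixed_cut_5p, len(seq))
    seq, qual = seq[cut:], qual[cut:]
    events.append(("fixed_cut_5p", cut))
    if not seq:
        return TrimmedRead(read_id, "", "", events, flagged=True)

    hit = find_adapter(seq, spec.adapter_5p, spec.error_rate, "five_prime", spec.min_overlap)
    removed = hit[1] if hit else 0
    seq, qual = seq[removed:], qual[removed:]
    events.append(("adapter_5p", removed))

    if seq:
        hit = find_adapter(
            seq, spec.adapter_3p, spec.error_rate, "three_prime", spec.min_overlap
        )
        removed = len(seq) - hit[0] if hit else 0
        if removed:
            seq, qual = seq[: hit[0]], qual[: hit[0]]
        events.append(("adapter_3p", removed))

    if spec.trim_terminal_cca and seq.endswith("CCA"):
        seq, qual = seq[:-3], qual[:-3]
        events.append(("terminal_cca", 3))

    return TrimmedRead(
        read_id, seq, qual, events, flagged=len(seq) < MIN_USEFUL_LENGTH
    )


def trim_reads(
    reads: Iterable[tuple[str, str, str]], spec: TrimSpec = TrimSpec()
) -> Iterator[TrimmedRead]:
    for read in reads:
        yield trim_read(read, spec)


def _open_maybe_gz(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file (gz transparent)."""
    with _open_maybe_gz(path, "r") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0], seq, qual


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> int:
    n = 0
    with _open_maybe_gz(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def trim_fastq(
    in_path: str | Path, out_path: str | Path, spec: TrimSpec = TrimSpec()
) -> dict:
    """Trim a FASTQ file; returns a per-file report of reads and bases removed."""
    report = {
        "reads_in": 0,
        "reads_out": 0,
        "reads_flagged": 0,
        "bases_removed": {"fixed_cut_5p": 0, "adapter_5p": 0, "adapter_3p": 0},
    }

    def _gen():
        for read in read_fastq(in_path):
            report["reads_in"] += 1
            t = trim_read(read, spec)
            for step, nbases in t.events:
                if step in report["bases_removed"]:
                    report["bases_removed"][step] += nbases
            if t.flagged:
                report["reads_flagged"] += 1
            if t.sequence:
                report["reads_out"] += 1
                yield t.read_id, t.sequence, t.quality

    write_fastq(out_path, _gen())
    return report
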