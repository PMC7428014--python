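"""Modification-aware read simulator with ground truth.

Generates libraries with the full read architecture

    NN + TCCAACTGGATACTGG + rN + body[start:] + CCA + GTATCCAGTTGGAATT

where ``start`` is the outcome of a 3'->5' walk along the template: reverse
transcription begins at the tRNA 3' end, and at every internal position may
stall (truncating the cDNA so the read body begins there) or misincorporate
(substituting the base).  A position reached without stalling can carry a
misincorporation; a stalled position terminates the walk unmodified, so a
single site can show the mixed mutation + truncation signature typical of
T-loop 1-methyladenosine.  Uniform substitution sequencing error is applied
to the finished read.  Identical seed and configuration give byte-identical
output.

Ground truth (expected counts, planted per-position stall and
misincorporation rates, spike-in amounts) is returned alongside the reads
so every downstream module can be tested against known parameters without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import CollapsedTRNA, TRNAGene, TRNAReference, collapse_identical

__all__ = [
    "SimConfig",
    "SimTruth",
    "ModProfile",
    "make_fixture_reference",
    "draw_expression",
    "t_loop_m1a_profile",
    "simulate_reads",
    "simulate_spikeins",
    "simulate_counts",
    "buffered_two_group_expression",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ADAPTER_5P_CORE = "TCCAACTGGATACTGG"   # sequenced 5' adapter, before the rN
_ADAPTER_3P_READ = "GTATCCAGTTGGAATT"   # sequenced 3' adapter, after the CCA
#: offset of the planted T-loop m1A-like site from the 3' end of the body
M1A_OFFSET_FROM_3P = 19


@dataclass
class ModProfile:
    """Planted per-(entry, position) stall and misincorporation rates."""

    stall: dict[str, np.ndarray] = field(default_factory=dict)
    misinc: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self, ref: TRNAReference) -> None:
        for e in ref:
            for d in (self.stall, self.misinc):
                arr = d.get(e.display_name)
                if arr is None:
                    continue
                if len(arr) != len(e):
                    raise ValueError(f"profile length mismatch for {e.display_name}")
                if ((arr < 0) | (arr > 1)).any():
                    raise ValueError(f"invalid probability for {e.display_name}")

    def demethylated(self) -> "ModProfile":
        """Zeroed copy: what demethylase treatment does to the signatures."""
        return ModProfile(
            stall={k: np.zeros_like(v) for k, v in self.stall.items()},
            misinc={k: np.zeros_like(v) for k, v in self.misinc.items()},
        )


@dataclass
class SimConfig:
    reference: TRNAReference
    n_reads: int = 10_000
    seed: int = 0
    #: relative abundance per entry; None draws a log-normal profile
    expression: Mapping[str, float] | None = None
    #: log10 standard deviation of the default expression profile
    sigma_log10: float = 0.7
    mod_profile: ModProfile | None = None
    seq_error: float = 0.001
    include_cca: bool = True

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.seq_error < 1:
            raise ValueError("seq_error must be in [0, 1)")
        if self.expression is not None:
            vals = np.array(list(self.expression.values()), dtype=float)
            if (vals < 0).any() or vals.sum() <= 0:
                raise ValueError("abundances must be >= 0 and not all zero")
        if self.mod_profile is not None:
            self.mod_profile.validate(self.reference)


@dataclass
class SimTruth:
    expression: pd.Series          # normalized relative abundances
    expected_counts: pd.Series     # n_reads * abundance, sums to n_reads
    counts: pd.Series              # realized source counts
    stall_rates: dict[str, np.ndarray]
    misinc_rates: dict[str, np.ndarray]
    spike_amounts: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fixture reference

# (amino acid, anticodon) pairs for synthetic families; real class labels so
# anticodon pooling and naming behave exactly as on a genomic reference.
_FIXTURE_CLASSES = [
    ("Ala", "AGC"), ("Ala", "TGC"), ("Gly", "GCC"), ("Arg", "TCT"),
    ("Thr", "TGT"), ("Glu", "TTC"), ("Lys", "CTT"), ("Val", "AAC"),
    ("Leu", "AAG"), ("Ile", "AAT"), ("Ser", "AGA"), ("Pro", "AGG"),
    ("Asp", "GTC"), ("Phe", "GAA"), ("His", "GTG"), ("Gln", "CTG"),
]


def make_fixture_reference(
    n_families: int, isodecoders_per_family: int, seed: int = 0
) -> TRNAReference:
    """Synthetic cloverleaf-compatible reference for tests and simulations.

    Families are independent random sequences (72-90 nt, hence far beyond
    10% mutual divergence) with their anticodon planted at positions 34-36
    and an adenosine at the T-loop m1A-like site.  Family members differ at
    1-5 positions, always including one in the 3' quarter so that even
    T-loop-stalled (short) reads retain a distinguishing base.
    """
    if n_families < 1 or isodecoders_per_family < 1:
        raise ValueError("need at least one family and one member")
    if n_families > len(_FIXTURE_CLASSES):
        raise ValueError(f"at most {len(_FIXTURE_CLASSES)} families supported")
    rng = np.random.default_rng(seed)
    genes: list[TRNAGene] = []
    for fam_i in range(n_families):
        aa, ac = _FIXTURE_CLASSES[fam_i]
        L = int(rng.integers(72, 91))
        base = rng.choice(_BASES, size=L)
        base[33:36] = np.frombuffer(ac.encode(), dtype=np.uint8)
        base[L - M1A_OFFSET_FROM_3P] = ord("A")
        base[L - 1] = ord("A")  # discriminator, strongly A in real tRNA
        protected = {33, 34, 35, L - M1A_OFFSET_FROM_3P, L - 1}
        seqs = {base.tobytes()}
        for copy in range(1, isodecoders_per_family + 1):
            if copy == 1:
                member = base.copy()
            else:
                while True:
                    member = base.copy()
                    n_mut = int(rng.integers(1, 6))
                    sites = [
                        int(p)
                        for p in rng.choice(L, size=n_mut + 4, replace=False)
                        if int(p) not in protected
                    ][:n_mut]
                    tail = [p for p in range(L - 16, L - 1) if p not in protected]
                    if not any(p >= L - 16 for p in sites):
                        sites.append(int(rng.choice(tail)))
                    for p in sites:
                        member[p] = _BASES[
                            (np.searchsorted(_BASES, member[p]) + 1 + rng.integers(3)) % 4
                        ]
                    if member.tobytes() not in seqs:
                        break
                seqs.add(member.tobytes())
            genes.append(
                TRNAGene(
                    gene_name=f"tRNA-{aa}-{ac}-{fam_i + 1}-{copy}",
                    amino_acid=aa,
                    anticodon=ac,
                    family_index=fam_i + 1,
                    copy_index=copy,
                    sequence=member.tobytes().decode(),
                )
            )
    return collapse_identical(genes)


def draw_expression(
    ref: TRNAReference, seed: int = 0, sigma_log10: float = 0.7
) -> pd.Series:
    """Log-normal isodecoder abundance profile, normalized to sum 1."""
    rng = np.random.default_rng([seed, 0xEC])
    names = [e.display_name for e in ref]
    vals = 10.0 ** rng.normal(0.0, sigma_log10, size=len(names))
    expr = pd.Series(vals, index=names)
    return expr / expr.sum()


def t_loop_m1a_profile(
    ref: TRNAReference,
    seed: int = 0,
    stall_range: tuple[float, float] = (0.3, 0.6),
    misinc: float = 0.1,
) -> ModProfile:
    """Default m1A-like preset: one T-loop site per entry with stall + misinc."""
    rng = np.random.default_rng([seed, 0x3A])
    profile = ModProfile()
    for e in ref:
        L = len(e)
        stall = np.zeros(L)
        mis = np.zeros(L)
        site = L - M1A_OFFSET_FROM_3P
        stall[site] = rng.uniform(*stall_range)
        mis[site] = misinc
        profile.stall[e.display_name] = stall
        profile.misinc[e.display_name] = mis
    return profile


# ---------------------------------------------------------------------------
# read generation

def _normalized_expression(config: SimConfig) -> pd.Series:
    names = [e.display_name for e in config.reference]
    if config.expression is None:
        return draw_expression(config.reference, config.seed, config.sigma_log10)
    expr = pd.Series(
        {n: float(config.expression.get(n, 0.0)) for n in names}, index=names
    )
    return expr / expr.sum()


def _start_distribution(stall: np.ndarray) -> np.ndarray:
    """P(read body starts at p) for the 3'->5' stall walk.

    The walk visits positions L-1 down to 1; stalling at p truncates the
    body to p..end.  Position 0 cannot stall: reaching it means the read is
    full length.
    """
    L = len(stall)
    surv = 1.0  # probability of having survived all positions > p
    dist = np.zeros(L)
    for p in range(L - 1, 0, -1):
        dist[p] = surv * stall[p]
        surv *= 1.0 - stall[p]
    dist[0] = surv
    return dist


def simulate_reads(
    config: SimConfig, sample: str = "sample1", sample_index: int = 0
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Simulate one library; returns ((id, seq, qual) records, truth).

    ``sample_index`` seeds the per-sample stream so replicate libraries
    share the expression profile but not the sampling noise.
    """
    ref = config.reference
    expr = _normalized_expression(config)
    rng = np.random.default_rng([config.seed, 1 + sample_index])
    entries = list(ref)
    probs = expr.to_numpy()
    src = rng.choice(len(entries), size=config.n_reads, p=probs)

    zero = {e.display_name: np.zeros(len(e)) for e in entries}
    stall_rates = dict(zero) if config.mod_profile is None else {
        e.display_name: config.mod_profile.stall.get(
            e.display_name, np.zeros(len(e))
        )
        for e in entries
    }
    misinc_rates = (
        {k: np.zeros_like(v) for k, v in zero.items()}
        if config.mod_profile is None
        else {
            e.display_name: config.mod_profile.misinc.get(
                e.display_name, np.zeros(len(e))
            )
            for e in entries
        }
    )

    reads: list[tuple[str, str, str] | None] = [None] * config.n_reads
    counts = np.bincount(src, minlength=len(entries))
    cca = b"CCA" if config.include_cca else b""
    a5 = _ADAPTER_5P_CORE.encode()
    a3 = _ADAPTER_3P_READ.encode()
    order = np.argsort(src, kind="stable")
    pos = 0
    for ei, e in enumerate(entries):
        m = counts[ei]
        if m == 0:
            continue
        idx = order[pos : pos + m]
        pos += m
        body = np.frombuffer(e.sequence.encode(), dtype=np.uint8)
        L = len(body)
        dist = _start_distribution(stall_rates[e.display_name])
        starts = rng.choice(L, size=m, p=dist)
        mis = rng.random((m, L)) < misinc_rates[e.display_name][None, :]
        # misincorporation only at reached, non-stalled positions
        col = np.arange(L)[None, :]
        reached = col >= (starts + (starts > 0))[:, None]
        mis &= reached
        nn = rng.choice(_BASES, size=(m, 2))
        rn = rng.choice(_BASES, size=m)
        for r in range(m):
            start = int(starts[r])
            b = body[start:].copy()
            mut = np.flatnonzero(mis[r, start:])
            if mut.size:
                shifts = rng.integers(1, 4, size=mut.size)
                cur = np.searchsorted(_BASES, b[mut])
                b[mut] = _BASES[(cur + shifts) % 4]
            raw = bytearray(nn[r].tobytes())
            raw += a5
            raw.append(rn[r])
            raw += b.tobytes()
            raw += cca
            raw += a3
            if config.seq_error > 0:
                n_err = rng.binomial(len(raw), config.seq_error)
                if n_err:
                    sites = rng.choice(len(raw), size=n_err, replace=False)
                    for sidx in sites:
                        cur = np.searchsorted(_BASES, raw[sidx])
                        if cur > 3 or _BASES[cur] != raw[sidx]:
                            continue
                        raw[sidx] = _BASES[(cur + rng.integers(1, 4)) % 4]
            seq = raw.decode()
            rid = f"{sample}:{e.display_name}:{int(idx[r])}"
            reads[idx[r]] = (rid, seq, "I" * len(seq))
        # end per-entry loop
    truth = SimTruth(
        expression=expr,
        expected_counts=expr * config.n_reads,
        counts=pd.Series(counts, index=[e.display_name for e in entries]),
        stall_rates=stall_rates,
        misinc_rates=misinc_rates,
    )
    return [r for r in reads if r is not None], truth


def simulate_spikeins(
    amounts: Mapping[str, float], config: SimConfig, sample: str = "spike"
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Spike-in library: reads drawn proportional to known input amounts."""
    if len(amounts) < 2:
        raise ValueError("need at least 2 spike-in species")
    if any(v <= 0 for v in amounts.values()):
        raise ValueError("spike-in amounts must be positive")
    names = {e.display_name for e in config.reference}
    unknown = [k for k in amounts if k not in names]
    if unknown:
        raise ValueError(f"spike species not in reference: {unknown}")
    cfg = replace(config, expression=dict(amounts))
    reads, truth = simulate_reads(cfg, sample=sample)
    truth.spike_amounts = dict(amounts)
    return reads, truth


def simulate_counts(
    ref: TRNAReference,
    expression: Mapping[str, float] | pd.Series,
    n_reads: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Multinomial source counts only -- no read synthesis.

    The count-level analogue of :func:`simulate_reads` for tests of the
    quantification and differential stages, where per-base detail is not
    needed and speed is.
    """
    names = [e.display_name for e in ref]
    p = np.array([float(expression[n]) for n in names])
    p = p / p.sum()
    return pd.Series(rng.multinomial(n_reads, p), index=names)


def buffered_two_group_expression(
    ref: TRNAReference,
    fold: float = 8.0,
    n_shifted_classes: int | None = None,
    seed: int = 0,
    sigma_log10: float = 0.7,
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Two-group expression with anticodon-sum buffering.

    Group A gets a log-normal profile.  In group B, within each shifted
    anticodon class, one member is reduced ``fold``-fold and a sibling
    absorbs the difference, so every anticodon-class total is identical
    between groups while the named isodecoders shift strongly.  Returns
    (expression_a, expression_b, shifted isodecoder names).
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    expr_a = draw_expression(ref, seed, sigma_log10)
    rng = np.random.default_rng([seed, 0xBF])
    classes: dict[tuple[str, str], list[str]] = {}
    for e in ref:
        classes.setdefault((e.amino_acid, e.anticodon), []).append(e.display_name)
    multi = [names for names in classes.values() if len(names) >= 2]
    if not multi:
        raise ValueError("no anticodon class with >= 2 isodecoders")
    if n_shifted_classes is None:
        n_shifted_classes = len(multi)
    chosen = [multi[i] for i in rng.choice(len(multi), size=min(n_shifted_classes, len(multi)), replace=False)]
    expr_b = expr_a.copy()
    shifted: list[str] = []
    for names in chosen:
        down, up = names[0], names[1]
        moved = expr_a[down] * (1.0 - 1.0 / fold)
        expr_b[down] = expr_a[down] / fold
        expr_b[up] = expr_a[up] + moved
        shifted.extend([down, up])
    return expr_a, expr_b, shifted
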