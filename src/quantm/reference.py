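"""Collapsed mature-tRNA reference construction.

Mature tRNA sequences in gtRNAdb naming style are parsed, normalised to the
DNA alphabet (U->T, upper case), and collapsed so that every reference entry
carries a unique sequence.  Genes sharing an identical mature sequence are
merged into one entry; a merged entry is named ``AA-anticodon-family-x``
(e.g. ``Ala-TGC-5-x``) while a single-gene entry keeps its full name
(``Ala-TGC-6-1``).  The collapsed reference is what reads are aligned to, so
a read matching several identical gene copies still maps uniquely.

Cytosolic and mitochondrial sets are kept apart: entries are never collapsed
across compartments, and anticodon-class counting is per compartment.
"""

from __future__ import annotations

import csv
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "TRNAGene",
    "CollapsedTRNA",
    "TRNAReference",
    "ReferenceError",
    "load_trna_fasta",
    "collapse_identical",
    "count_anticodon_classes",
    "write_reference",
    "load_reference",
]

_VALID_BASES = frozenset("ACGT")

#: gtRNAdb-style gene name, optionally prefixed by a species tag
#: (e.g. "Homo_sapiens_tRNA-Ala-AGC-1-1" or plain "tRNA-Ala-AGC-1-1").
_HEADER_RE = re.compile(
    r"(?:^|[_\s])tRNA-(?P<aa>iMet|SeC|Sup|Und|[A-Z][a-z]{2})"
    r"-(?P<ac>[ACGTUacgtu]{3})-(?P<fam>\d+)-(?P<copy>\d+)"
)


class ReferenceError(ValueError):
    """Raised for malformed reference input (headers, alphabets, conflicts)."""


@dataclass(frozen=True)
class TRNAGene:
    """One mature tRNA gene: name, annotation and intron-free body sequence.

    The sequence is the mature body without the post-transcriptional CCA
    tail; CCA is a read feature handled during trimming, never stored here.
    """

    gene_name: str
    amino_acid: str
    anticodon: str
    family_index: int
    copy_index: int
    sequence: str
    compartment: str = "cytosolic"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceError(
                f"{self.gene_name}: sequence contains non-ACGT characters {sorted(bad)}"
            )
        if not 60 <= len(self.sequence) <= 100:
            raise ReferenceError(
                f"{self.gene_name}: mature tRNA length {len(self.sequence)} "
                "outside the expected 60-100 nt range"
            )
        if self.anticodon not in self.gene_name.replace("U", "T").replace("u", "t"):
            raise ReferenceError(
                f"{self.gene_name}: anticodon {self.anticodon} does not match name"
            )


@dataclass(frozen=True)
class CollapsedTRNA:
    """A unique-sequence reference entry and the gene copies it represents."""

    display_name: str
    member_genes: tuple[str, ...]
    sequence: str
    anticodon: str
    amino_acid: str
    compartment: str = "cytosolic"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TRNAReference:
    """The collapsed reference: one entry per distinct mature sequence."""

    entries: list[CollapsedTRNA] = field(default_factory=list)

    @property
    def total_entries(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, display_name: str) -> CollapsedTRNA:
        try:
            return self._by_name[display_name]
        except AttributeError:
            self._by_name = {e.display_name: e for e in self.entries}
            return self._by_name[display_name]


def _parse_header(header: str) -> tuple[str, str, int, int]:
    m = _HEADER_RE.search(header)
    if m is None:
        raise ReferenceError(f"cannot parse gtRNAdb-style header: {header!r}")
    anticodon = m.group("ac").upper().replace("U", "T")
    return m.group("aa"), anticodon, int(m.group("fam")), int(m.group("copy"))


def load_trna_fasta(path: str | Path, compartment: str = "cytosolic") -> list[TRNAGene]:
    """Load mature tRNA genes from a gtRNAdb-style FASTA file.

    Sequences are taken as-is (intron-free mature bodies), upper-cased and
    U->T normalised.  A record whose header cannot be parsed, or whose
    sequence leaves the ACGT alphabet, raises :class:`ReferenceError` naming
    the offending record.
    """
    genes: list[TRNAGene] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        aa, ac, fam, copy = _parse_header(rec.description)
        seq = str(rec.seq).upper().replace("U", "T")
        genes.append(
            TRNAGene(
                gene_name=rec.id,
                amino_acid=aa,
                anticodon=ac,
                family_index=fam,
                copy_index=copy,
                sequence=seq,
                compartment=compartment,
            )
        )
    if not genes:
        raise ReferenceError(f"no FASTA records found in {path}")
    return genes


def _display_name(members: list[TRNAGene]) -> str:
    aa, ac = members[0].amino_acid, members[0].anticodon
    if len(members) == 1:
        g = members[0]
        return f"{aa}-{ac}-{g.family_index}-{g.copy_index}"
    # Merged copies: keep the smallest (family, copy) as the name anchor.
    fam = min((g.family_index, g.copy_index) for g in members)[0]
    return f"{aa}-{ac}-{fam}-x"


def collapse_identical(genes: Iterable[TRNAGene]) -> TRNAReference:
    """Collapse genes with identical mature sequences into unique entries.

    Sequence comparison is case-insensitive (sequences are already
    normalised at load).  Genes in different compartments are never merged.
    Two genes with the same sequence but conflicting anticodon (or amino
    acid) annotations are an annotation conflict and raise.
    """
    genes = list(genes)
    if not genes:
        raise ReferenceError("cannot collapse an empty gene list")

    groups: dict[tuple[str, str], list[TRNAGene]] = defaultdict(list)
    for g in genes:
        groups[(g.compartment, g.sequence.upper())].append(g)

    entries: list[CollapsedTRNA] = []
    seen_names: dict[str, int] = {}
    for (compartment, seq), members in groups.items():
        anticodons = {g.anticodon for g in members}
        aas = {g.amino_acid for g in members}
        if len(anticodons) > 1 or len(aas) > 1:
            names = ", ".join(g.gene_name for g in members)
            raise ReferenceError(
                f"identical sequences with conflicting annotations: {names}"
            )
        members.sort(key=lambda g: (g.family_index, g.copy_index))
        name = _display_name(members)
        if name in seen_names:  # cross-family merge colliding with another group
            seen_names[name] += 1
            name = f"{name}.{seen_names[name]}"
        else:
            seen_names[name] = 0
        entries.append(
            CollapsedTRNA(
                display_name=name,
                member_genes=tuple(g.gene_name for g in members),
                sequence=seq,
                anticodon=members[0].anticodon,
                amino_acid=members[0].amino_acid,
                compartment=compartment,
            )
        )
    entries.sort(key=lambda e: (e.compartment, e.display_name))
    return TRNAReference(entries=entries)


def count_anticodon_classes(ref: TRNAReference, compartment: str = "cytosolic") -> int:
    """Number of distinct anticodons among entries of one compartment."""
    return len({e.anticodon for e in ref if e.compartment == compartment})


def write_reference(ref: TRNAReference, outdir: str | Path) -> tuple[Path, Path]:
    """Write the collapsed FASTA plus a member-mapping TSV.

    Returns (fasta_path, tsv_path).  The pair round-trips losslessly through
    :func:`load_reference`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "collapsed.fa"
    tsv_path = outdir / "members.tsv"
    with open(fasta_path, "w") as fh:
        for e in ref:
            fh.write(f">{e.display_name}\n{e.sequence}\n")
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["display_name", "member_gene", "anticodon", "amino_acid", "compartment", "length"]
        )
        for e in ref:
            for gene in e.member_genes:
                w.writerow(
                    [e.display_name, gene, e.anticodon, e.amino_acid, e.compartment, len(e)]
                )
    return fasta_path, tsv_path


def load_reference(outdir: str | Path) -> TRNAReference:
    """Re-load a reference written by :func:`write_reference`."""
    outdir = Path(outdir)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(outdir / "collapsed.fa"), "fasta")}
    meta: dict[str, dict] = {}
    with open(outdir / "members.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            d = meta.setdefault(
                row["display_name"],
                {
                    "members": [],
                    "anticodon": row["anticodon"],
                    "amino_acid": row["amino_acid"],
                    "compartment": row["compartment"],
                },
            )
            d["members"].append(row["member_gene"])
    entries = []
    for name, seq in seqs.items():
        d = meta[name]
        entries.append(
            CollapsedTRNA(
                display_name=name,
                member_genes=tuple(d["members"]),
                sequence=seq,
                anticodon=d["anticodon"],
                amino_acid=d["amino_acid"],
                compartment=d["compartment"],
            )
        )
    return TRNAReference(entries=entries)
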