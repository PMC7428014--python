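"""Variant tabulation against an independent alignment-reconstruction oracle,
structure annotation, and filtering."""

import numpy as np
import pandas as pd
import pytest

from quantm.align import AlignmentRecord, align_reads
from quantm.prep import trim_read
from quantm.simulate import SimConfig, simulate_reads, t_loop_m1a_profile
from quantm.variants import (
    FEATURES,
    annotate_structure,
    bin_variants_by_feature,
    compare_treatments,
    filter_detectable,
    tabulate_variants,
    variant_fraction,
)


def random_alignment(rng, ref_seq, read_id="r"):
    """Generate a random gapped alignment plus its true event tally.

    The generator walks the reference emitting M/I/D runs, chooses read
    bases (mismatching with probability 0.1), and builds the CIGAR and MD
    strings directly from its own walk -- an oracle independent of the
    production tabulation code.
    """
    L = len(ref_seq)
    ref_start = int(rng.integers(0, L - 15))
    max_span = L - ref_start
    events = {"mismatch": [], "insertion": [], "deletion": [], "coverage": []}
    cigar, md_parts = [], []
    read = []
    pos = ref_start
    md_run = 0
    n_ops = int(rng.integers(1, 6))
    for opi in range(n_ops):
        remaining = L - pos
        if remaining <= 0:
            break
        op = rng.choice(["M", "I", "D"], p=[0.7, 0.15, 0.15]) if opi % 2 else "M"
        if op == "M":
            ln = int(rng.integers(1, min(remaining, 20) + 1))
            for i in range(pos, pos + ln):
                events["coverage"].append(i)
                if rng.random() < 0.1:
                    base = "ACGT"[("ACGT".index(ref_seq[i]) + 1) % 4]
                    events["mismatch"].append(i)
                    md_parts.append(str(md_run))
                    md_parts.append(ref_seq[i])
                    md_run = 0
                else:
                    base = ref_seq[i]
                    md_run += 1
                read.append(base)
            cigar.append(f"{ln}M")
            pos += ln
        elif op == "I" and read:
            ln = int(rng.integers(1, 4))
            read.extend(rng.choice(list("ACGT"), size=ln))
            cigar.append(f"{ln}I")
            events["insertion"].append(pos - 1)
        elif op == "D" and read and remaining > 1:
            ln = int(rng.integers(1, min(3, remaining - 1) + 1))
            md_parts.append(str(md_run))
            md_parts.append("^" + ref_seq[pos : pos + ln])
            md_run = 0
            for i in range(pos, pos + ln):
                events["deletion"].append(i)
                events["coverage"].append(i)
            cigar.append(f"{ln}D")
            pos += ln
    if not cigar or not any(c.endswith("M") for c in cigar):
        return None
    # trailing deletion is not a valid alignment end; drop it
    while cigar and cigar[-1][-1] in "ID":
        dropped = cigar.pop()
        ln = int(dropped[:-1])
        if dropped.endswith("D"):
            md_parts.pop()
            md_parts.pop()
            for _ in range(ln):
                events["deletion"].pop()
                events["coverage"].pop()
            pos -= ln
        else:
            del read[-ln:]
            events["insertion"].pop()
    md_parts.append(str(md_run))
    rec = AlignmentRecord(
        read_id=read_id, ref_name="ref", ref_start=ref_start, ref_end=pos,
        strand="+", score=0, mapq=42, cigar="".join(cigar),
        md="".join(md_parts), read_seq="".join(read),
    )
    stall = ref_start if ref_start > 0 else None
    return rec, events, stall


class TestTabulateOracle:
    def test_full_length_perfect_read(self, tiny_ref):
        entry = tiny_ref.entries[0]
        L = len(entry)
        rec = AlignmentRecord(
            read_id="r", ref_name=entry.display_name, ref_start=0, ref_end=L,
            strand="+", score=2 * L, mapq=42, cigar=f"{L}M", md=str(L),
            read_seq=entry.sequence,
        )
        table = tabulate_variants([rec], tiny_ref)
        sub = table.data[table.data.trna == entry.display_name]
        assert (sub["coverage"] == 1).all()
        assert sub[["mismatch", "insertion", "deletion", "stall"]].sum().sum() == 0

    def test_internal_start_counts_one_stall(self, tiny_ref):
        entry = tiny_ref.entries[0]
        rec = AlignmentRecord(
            read_id="r", ref_name=entry.display_name, ref_start=57,
            ref_end=len(entry), strand="+", score=0, mapq=42,
            cigar=f"{len(entry) - 57}M", md=str(len(entry) - 57),
            read_seq=entry.sequence[57:],
        )
        table = tabulate_variants([rec], tiny_ref)
        sub = table.data[table.data.trna == entry.display_name].set_index("pos")
        assert sub.loc[57, "stall"] == 1
        assert sub["stall"].sum() == 1

    def test_worked_cigar_md_example(self, tiny_ref):
        # 10M1D5M with MD 4A5^G5: mismatch at start+4, deletion at start+10,
        # coverage spans 16 reference bases
        entry = tiny_ref.entries[0]
        start = 20
        ref_seq = entry.sequence
        read = list(ref_seq[start : start + 10]) + list(
            ref_seq[start + 11 : start + 16]
        )
        read[4] = "ACGT"[("ACGT".index(read[4]) + 1) % 4]
        md = f"4{ref_seq[start + 4]}5^{ref_seq[start + 10]}5"
        rec = AlignmentRecord(
            read_id="r", ref_name=entry.display_name, ref_start=start,
            ref_end=start + 16, strand="+", score=0, mapq=42,
            cigar="10M1D5M", md=md, read_seq="".join(read),
        )
        table = tabulate_variants([rec], tiny_ref)
        sub = table.data[table.data.trna == entry.display_name].set_index("pos")
        assert sub.loc[start + 4, "mismatch"] == 1
        assert sub.loc[start + 10, "deletion"] == 1
        assert sub["coverage"].sum() == 16

    def test_softclipped_start_not_a_stall(self, tiny_ref):
        entry = tiny_ref.entries[0]
        rec = AlignmentRecord(
            read_id="r", ref_name=entry.display_name, ref_start=30,
            ref_end=50, strand="+", score=0, mapq=42, cigar="6S20M", md="20",
            read_seq="ACGTAC" + entry.sequence[30:50],
        )
        table = tabulate_variants([rec], tiny_ref)
        sub = table.data[table.data.trna == entry.display_name]
        assert sub["stall"].sum() == 0  # 5' clip > 3 nt disqualifies
        assert sub["coverage"].sum() == 20  # but coverage still counted

    def test_inconsistent_md_skipped_and_logged(self, tiny_ref):
        entry = tiny_ref.entries[0]
        rec = AlignmentRecord(
            read_id="r", ref_name=entry.display_name, ref_start=0, ref_end=20,
            strand="+", score=0, mapq=42, cigar="20M", md="10^A9",
            read_seq=entry.sequence[:20],
        )
        table = tabulate_variants([rec], tiny_ref)
        assert table.skipped_reads == 1

    def test_randomized_reads_match_generator_truth(self, tiny_ref):
        """1000 random gapped alignments tabulate exactly as generated."""
        from quantm.reference import collapse_identical
        from tests.conftest import make_gene

        gene = make_gene("tRNA-Ala-AGC-9-1", fam=9)
        ref = collapse_identical([gene])
        name = ref.entries[0].display_name
        rng = np.random.default_rng(2024)
        expected = {
            k: np.zeros(len(gene.sequence), dtype=int)
            for k in ("mismatch", "insertion", "deletion", "stall", "coverage")
        }
        records = []
        n = 0
        while n < 1000:
            out = random_alignment(rng, gene.sequence, read_id=f"r{n}")
            if out is None:
                continue
            rec, events, stall = out
            rec = AlignmentRecord(**{**rec.__dict__, "ref_name": name})
            records.append(rec)
            for kind in ("mismatch", "insertion", "deletion", "coverage"):
                for p in events[kind]:
                    expected[kind][p] += 1
            if stall is not None:
                expected["stall"][stall] += 1
            n += 1
        table = tabulate_variants(records, ref)
        assert table.skipped_reads == 0
        sub = table.data[table.data.trna == name].set_index("pos").sort_index()
        for kind in expected:
            got = sub[kind].reindex(range(len(gene.sequence)), fill_value=0)
            assert (got.to_numpy() == expected[kind]).all(), kind


class TestFractionsAndFilters:
    def test_fraction_arithmetic_and_masking(self, tiny_ref):
        entry = tiny_ref.entries[0]
        rows = pd.DataFrame(
            {
                "trna": entry.display_name, "pos": [0, 1], "sample": "s1",
                "mismatch": [5, 1], "insertion": 0, "deletion": 0,
                "stall": 0, "coverage": [100, 5],
            }
        )
        from quantm.variants import VariantTable

        frac = variant_fraction(VariantTable(data=rows), min_coverage=20)
        assert frac.loc[(entry.display_name, 0), "s1"] == pytest.approx(0.05)
        assert np.isnan(frac.loc[(entry.display_name, 1), "s1"])

    def test_detectability_requires_all_samples(self):
        frac = pd.DataFrame(
            {
                "s1": [0.02, 0.02, 0.3],
                "s2": [0.015, 0.005, np.nan],
                "s3": [0.03, 0.04, 0.3],
            },
            index=pd.MultiIndex.from_tuples([("t", 0), ("t", 1), ("t", 2)]),
        )
        kept = filter_detectable(frac, 0.01)
        assert list(kept) == [("t", 0)]

    def test_filter_matches_brute_scan(self):
        rng = np.random.default_rng(8)
        frac = pd.DataFrame(
            rng.uniform(0, 0.05, size=(10, 4)),
            index=pd.MultiIndex.from_product([["t"], range(10)]),
            columns=list("abcd"),
        )
        kept = set(filter_detectable(frac, 0.01))
        brute = {
            i for i in frac.index if all(frac.loc[i, c] >= 0.01 for c in frac)
        }
        assert kept == brute


class TestStructureAnnotation:
    def test_canonical_76mer_t_loop(self):
        from quantm.reference import collapse_identical
        from tests.conftest import make_gene

        gene = make_gene("tRNA-Ala-AGC-1-1")
        assert len(gene.sequence) == 76
        ann = annotate_structure(collapse_identical([gene]))
        name = "Ala-AGC-1-1"
        assert ann.positions_of(name, "t_loop") == list(range(53, 60))
        assert ann.feature_of(name, 75) == "discriminator"
        assert ann.positions_of(name, "acceptor_stem_5p")[:7] == list(range(7))

    def test_anticodon_loop_centered_on_anticodon(self):
        from quantm.reference import collapse_identical
        from tests.conftest import make_gene

        gene = make_gene("tRNA-Ala-TGC-1-1", ac="TGC")
        ann = annotate_structure(collapse_identical([gene]))
        loop = ann.positions_of("Ala-TGC-1-1", "anticodon_loop")
        ac_at = gene.sequence.find("TGC", 25, 50)
        center = ac_at + 1
        assert loop == list(range(center - 3, center + 4))

    def test_every_position_assigned_once(self, small_ref):
        ann = annotate_structure(small_ref)
        for e in small_ref:
            labels = ann.features[e.display_name]
            assert len(labels) == len(e)
            assert all(lab in FEATURES for lab in labels)

    def test_many_simulated_references_fully_annotated(self):
        from quantm.simulate import make_fixture_reference

        for seed in range(10):
            ref = make_fixture_reference(2, 1, seed=seed)
            ann = annotate_structure(ref)
            for e in ref:
                assert len(ann.features[e.display_name]) == len(e)


class TestBinning:
    def test_t_loop_bin(self, small_ref):
        ann = annotate_structure(small_ref)
        name = small_ref.entries[0].display_name
        pos = ann.positions_of(name, "t_loop")[:3]
        hist = bin_variants_by_feature([(name, p) for p in pos], ann)
        assert hist["t_loop"] == 3
        assert sum(hist.values()) == 3

    def test_empty_set_all_zero(self, small_ref):
        hist = bin_variants_by_feature([], annotate_structure(small_ref))
        assert set(hist.values()) == {0}

    def test_unannotated_errors(self, small_ref):
        with pytest.raises(ValueError):
            bin_variants_by_feature([("ghost", 1)], annotate_structure(small_ref))


class TestCompareTreatments:
    def test_identical_inputs_all_zero(self):
        idx = pd.MultiIndex.from_tuples([("t", 1), ("t", 2)])
        a = pd.DataFrame({"s1": [0.1, 0.2]}, index=idx)
        diff = compare_treatments(a, a.copy())
        assert (diff == 0).all().all()

    def test_masking_propagates(self):
        idx = pd.MultiIndex.from_tuples([("t", 1), ("t", 2)])
        a = pd.DataFrame({"s1": [0.4, np.nan]}, index=idx)
        b = pd.DataFrame({"s1": [0.02, 0.3]}, index=idx)
        diff = compare_treatments(a, b)
        assert diff.loc[("t", 1), "s1"] == pytest.approx(0.38)
        assert np.isnan(diff.loc[("t", 2), "s1"])

    def test_no_shared_positions_errors(self):
        a = pd.DataFrame({"s1": [0.1]}, index=pd.MultiIndex.from_tuples([("t", 1)]))
        b = pd.DataFrame({"s1": [0.1]}, index=pd.MultiIndex.from_tuples([("u", 1)]))
        with pytest.raises(ValueError, match="shared"):
            compare_treatments(a, b)


def test_demethylation_contrast_recovers_planted_difference(small_ref):
    """Zeroing the T-loop profile moves the variant fraction by ~the stall
    rate at the modified site and nowhere else."""
    profile = t_loop_m1a_profile(small_ref, 7, stall_range=(0.4, 0.4), misinc=0.0)
    results = {}
    for label, prof in (("mock", profile), ("demeth", profile.demethylated())):
        cfg = SimConfig(
            reference=small_ref, n_reads=20000, seed=11,
            expression={e.display_name: 1.0 for e in small_ref},
            mod_profile=prof, seq_error=0.0,
        )
        reads, _ = simulate_reads(cfg)
        pairs = [(rid, trim_read((rid, s, q)).sequence) for rid, s, q in reads]
        alns = list(align_reads([p for p in pairs if p[1]], small_ref))
        table = tabulate_variants(alns, small_ref)
        results[label] = variant_fraction(table, min_coverage=20)
    diff = compare_treatments(results["mock"], results["demeth"])
    for e in small_ref:
        site = len(e) - 19
        d = diff.loc[(e.display_name, site), "sample1"]
        se = np.sqrt(0.4 * 0.6 / 500)
        assert d == pytest.approx(0.4, abs=5 * se)
    off_site = diff.drop(
        index=[(e.display_name, len(e) - 19) for e in small_ref]
    ).abs()
    assert np.nanmax(off_site.to_numpy()) < 0.05
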