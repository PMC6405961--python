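import numpy as np
import pytest
from scipy import stats as sps

from seroinkit import seqio, synth


class TestMakeProtein:
    def test_sn2_long_has_rygg_and_gly_rich_nterm(self):
        rec = synth.make_protein(synth.default_spec("Sn2", "L", seed=7))
        assert "RYGG" in rec.protein
        region = rec.protein[20:50]
        assert region.count("G") / len(region) >= 0.25

    def test_sn3_short_has_trp35_and_vyge(self):
        rec = synth.make_protein(synth.default_spec("Sn3", "T", seed=1))
        w_positions = [i for i, aa in enumerate(rec.protein) if aa == "W"]
        assert any(32 <= w < 37 for w in w_positions)
        assert "VYGE" in rec.protein

    def test_determinism(self):
        a = synth.make_protein(synth.default_spec("Sn1", "L", seed=5))
        b = synth.make_protein(synth.default_spec("Sn1", "L", seed=5))
        assert a.protein == b.protein

    def test_architecture_tiles_protein(self):
        for cls, versions in synth.CLASS_VERSIONS.items():
            for v in versions:
                rec = synth.make_protein(synth.default_spec(cls, v, seed=3))
                mods = rec.true_architecture.modules
                assert mods[0].start == 0
                assert mods[-1].end == len(rec.protein)
                for prev, nxt in zip(mods, mods[1:]):
                    assert prev.end == nxt.start
                order = [m.label for m in mods]
                canon = [l for l in synth.MODULE_ORDER if l in order]
                assert order == canon

    def test_motif_offset_outside_module_is_error(self):
        spec = synth.default_spec("Sn2", "L", seed=7)
        spec.planted_motifs = [("RYGG", "B1", spec.module_lengths["B1"] - 2)]
        with pytest.raises(ValueError, match="does not fit"):
            synth.make_protein(spec)

    def test_class_statistics_separate_by_construction(self):
        """C modules are Pro-rich vs B modules; Sn2 is Gly-rich in 20-50."""
        pro_b, pro_c, gly = {"B": [], "C": []}, [], {}
        for cls in synth.CLASSES:
            recs = [synth.make_protein(synth.default_spec(cls, "L", seed=s))
                    for s in range(20, 25)]
            for rec in recs:
                for m in rec.true_architecture.modules:
                    seq = rec.protein[m.start:m.end]
                    if m.kind == "B":
                        pro_b["B"].append(seq.count("P") / len(seq))
                    elif m.kind == "C":
                        pro_c.append(seq.count("P") / len(seq))
            gly[cls] = np.mean([
                rec.protein[20:50].count("G") / 30 for rec in recs])
        assert np.mean(pro_c) > np.mean(pro_b["B"])
        assert gly["Sn2"] > gly["Sn1"] and gly["Sn2"] > gly["Sn3"]


class TestMakeCdna:
    def test_minimal_coding(self):
        rec = synth.make_protein(synth.default_spec("Sn1", "L", seed=2))
        cdna = synth.make_cdna(rec, utr5=0, utr3=0)
        assert len(cdna) == 3 * (len(rec.protein) + 1)
        assert seqio.translate(cdna, 0) == rec.protein + "*"

    def test_longest_orf_round_trip(self):
        for cls in synth.CLASSES:
            rec = synth.make_protein(synth.default_spec(cls, "L", seed=9))
            cdna = synth.make_cdna(rec)
            orf = seqio.longest_orf(cdna)
            assert orf is not None and orf.protein == rec.protein

    def test_fixed_seed_reproducible(self):
        rec = synth.make_protein(synth.default_spec("Sn2", "C", seed=4))
        assert synth.make_cdna(rec, seed=1) == synth.make_cdna(rec, seed=1)


class TestMakeDataset:
    def test_exact_counts(self):
        records, truth = synth.make_dataset({("Sn1", "L"): 2}, seed=0)
        assert len(records) == 2
        assert all(r.spec.seroin_class == "Sn1" and r.spec.version == "L"
                   for r in records)

    def test_empty_request(self):
        records, truth = synth.make_dataset({}, seed=0)
        assert records == [] and truth.empty

    def test_unknown_cell_rejected(self):
        with pytest.raises(ValueError):
            synth.make_dataset({("Sn3", "N"): 1}, seed=0)

    def test_balanced_dataset_covers_all_versions(self, acceptance_dataset):
        records, truth = acceptance_dataset
        assert len(records) == 300
        cells = set(zip(truth["seroin_class"], truth["version"]))
        assert cells == set(synth.VERSION_PATTERNS)

    def test_byte_identical_truth_tables(self):
        _, t1 = synth.make_dataset(synth.balanced_counts(5), seed=8)
        _, t2 = synth.make_dataset(synth.balanced_counts(5), seed=8)
        assert t1.to_csv() == t2.to_csv()


class TestMakeReads:
    def test_error_free_reads_are_substrings(self):
        rec = synth.make_protein(synth.default_spec("Sn1", "L", seed=3))
        cdna = synth.make_cdna(rec)
        reads, origins = synth.make_reads({"x": cdna}, {"x": 1.0},
                                          read_len=60, n_reads=10, seed=1)
        for read in reads:
            assert (read.sequence in cdna
                    or seqio.reverse_complement(read.sequence) in cdna)

    def test_zero_weight_never_sampled(self):
        rec = synth.make_protein(synth.default_spec("Sn1", "L", seed=3))
        a = synth.make_cdna(rec, seed=1)
        b = synth.make_cdna(rec, seed=2)
        _, origins = synth.make_reads({"a": a, "b": b}, {"a": 1.0, "b": 0.0},
                                      read_len=60, n_reads=100, seed=2)
        assert set(origins["source_id"]) == {"a"}

    def test_weight_proportional_sampling_within_binomial_ci(self):
        rec = synth.make_protein(synth.default_spec("Sn1", "L", seed=3))
        a = synth.make_cdna(rec, seed=1)
        b = synth.make_cdna(rec, seed=2)
        _, origins = synth.make_reads({"a": a, "b": b}, {"a": 3.0, "b": 1.0},
                                      read_len=60, n_reads=4000, seed=5)
        n_a = (origins["source_id"] == "a").sum()
        lo, hi = sps.binom.interval(0.99, 4000, 0.75)
        assert lo <= n_a <= hi

    def test_read_len_too_large(self):
        with pytest.raises(ValueError, match="read_len"):
            synth.make_reads({"a": "ACGTACGT"}, {"a": 1.0}, read_len=100,
                             n_reads=1, seed=0)

    def test_substitution_error_rate(self):
        rec = synth.make_protein(synth.default_spec("Sn2", "L", seed=3))
        cdna = synth.make_cdna(rec)
        reads, origins = synth.make_reads({"x": cdna}, {"x": 1.0}, read_len=100,
                                          n_reads=200, error_rate=0.05, seed=9)
        mismatches = 0
        for read, (_, row) in zip(reads, origins.iterrows()):
            frag = cdna[row["start"] : row["start"] + 100]
            if row["strand"] == "-":
                frag = seqio.reverse_complement(frag)
            mismatches += sum(1 for x, y in zip(read.sequence, frag) if x != y)
        rate = mismatches / (200 * 100)
        assert 0.03 < rate < 0.07
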