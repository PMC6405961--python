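from math import exp, log

import numpy as np
import pytest

from seroinkit import quantify, seqio, synth


class TestKarlinAltschul:
    def test_lambda_closed_form_match_mismatch(self):
        """+1/-1 on a uniform 4-letter alphabet: 0.25 e^lam + 0.75 e^-lam = 1
        gives e^lam = 3, so lambda = ln 3."""
        params = quantify.karlin_altschul_params(
            score_probs={1: 0.25, -1: 0.75})
        assert params.lam == pytest.approx(log(3), abs=1e-6)

    def test_doubling_scores_halves_lambda(self):
        p1 = quantify.karlin_altschul_params(score_probs={1: 0.25, -1: 0.75})
        p2 = quantify.karlin_altschul_params(score_probs={2: 0.25, -2: 0.75})
        assert p2.lam == pytest.approx(p1.lam / 2, rel=1e-6)

    def test_all_negative_scores_rejected(self):
        with pytest.raises(ValueError, match="invalid scoring"):
            quantify.karlin_altschul_params(score_probs={-1: 0.5, -2: 0.5})

    def test_non_negative_expectation_rejected(self):
        with pytest.raises(ValueError, match="invalid scoring"):
            quantify.karlin_altschul_params(score_probs={1: 0.9, -1: 0.1})

    def test_K_closed_form_two_outcome(self):
        """K for {+1, -1} supports has the exact form (p+ - p-)^2 / p-."""
        for p in (0.1, 0.25, 0.4):
            params = quantify.karlin_altschul_params(
                score_probs={1: p, -1: 1 - p})
            assert params.K == pytest.approx((p - (1 - p)) ** 2 / (1 - p),
                                             rel=1e-9)

    def test_blosum62_parameters_match_published_values(self):
        """Ungapped BLOSUM62 with standard background frequencies:
        lambda ~ 0.3176, K ~ 0.134 (classic published values)."""
        params = quantify.karlin_altschul_params("BLOSUM62")
        assert params.lam == pytest.approx(0.3176, abs=0.001)
        assert params.K == pytest.approx(0.134, rel=0.02)

    def test_evalue_monotone_decreasing_in_score(self):
        params = quantify.karlin_altschul_params("BLOSUM62")
        evs = [params.evalue(s, 80, 50) for s in range(10, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert all(e > 0 for e in evs)


def _reference_records(seed=99):
    refs = {}
    for cls in ("Sn1", "Sn2", "Sn3"):
        rec = synth.make_protein(synth.default_spec(cls, "L", seed=seed),
                                 record_id=cls)
        rec.cdna = synth.make_cdna(rec, utr5=40, utr3=60)
        refs[cls] = rec
    return refs


def _cterm_region(rec, n_aa=80):
    """Coding nucleotides of the C-terminal n_aa residues."""
    cds_end = 40 + 3 * len(rec.protein)
    return rec.cdna[cds_end - 3 * n_aa : cds_end]


class TestLocalAlignTranslated:
    def test_exact_planted_read_passes_threshold(self):
        refs = _reference_records()
        params = quantify.karlin_altschul_params()
        rec = refs["Sn1"]
        region = _cterm_region(rec)
        read = region[:150]  # 50 identical residues
        query = quantify.cterm_query(rec.protein)
        hit = quantify.local_align_translated(read, query, params, "Sn1")
        assert hit is not None
        assert hit.evalue <= 1e-20

    def test_reverse_complement_same_score(self):
        refs = _reference_records()
        params = quantify.karlin_altschul_params()
        rec = refs["Sn2"]
        read = _cterm_region(rec)[30:150]
        query = quantify.cterm_query(rec.protein)
        fwd = quantify.local_align_translated(read, query, params)
        rev = quantify.local_align_translated(
            seqio.reverse_complement(read), query, params)
        assert fwd.score == rev.score
        assert rev.frame >= 3

    def test_short_read_skipped(self):
        params = quantify.karlin_altschul_params()
        assert quantify.local_align_translated("AC", "MKVW" * 20, params) is None

    def test_random_reads_never_reach_threshold(self):
        rng = np.random.default_rng(11)
        refs = _reference_records()
        params = quantify.karlin_altschul_params()
        query = quantify.cterm_query(refs["Sn3"].protein)
        for _ in range(50):
            read = "".join(rng.choice(list("ACGT"), size=90))
            hit = quantify.local_align_translated(read, query, params)
            assert hit is None or hit.evalue > 1e-20


class TestCountClassReads:
    def test_planted_reads_assigned_to_their_class(self):
        refs = _reference_records()
        queries = {cls: quantify.cterm_query(r.protein)
                   for cls, r in refs.items()}
        regions = {cls: _cterm_region(r) for cls, r in refs.items()}
        reads, origins = synth.make_reads(
            regions, {"Sn1": 3.0, "Sn2": 1.0, "Sn3": 1.0},
            read_len=150, n_reads=100, seed=4)
        counts = quantify.count_class_reads(reads, queries)
        truth = origins["source_id"].value_counts().to_dict()
        assert counts.counts == {cls: truth.get(cls, 0)
                                 for cls in ("Sn1", "Sn2", "Sn3")}
        assert counts.unassigned == 0

    def test_utr_reads_unassigned(self):
        refs = _reference_records()
        queries = {cls: quantify.cterm_query(r.protein)
                   for cls, r in refs.items()}
        utr5 = refs["Sn1"].cdna[:40]
        reads, _ = synth.make_reads({"u": utr5}, {"u": 1.0},
                                    read_len=40, n_reads=30, seed=6)
        counts = quantify.count_class_reads(reads, queries)
        assert counts.counts == {"Sn1": 0, "Sn2": 0, "Sn3": 0}
        assert counts.unassigned == 30

    def test_disabled_threshold_counts_any_positive_scoring_read(self):
        refs = _reference_records()
        rec = refs["Sn1"]
        query = {"Sn1": quantify.cterm_query(rec.protein)}
        rng = np.random.default_rng(3)
        reads = [seqio.SeqRecordLite(f"r{i}", "".join(rng.choice(list("ACGT"),
                                                                 size=60)))
                 for i in range(20)]
        counts = quantify.count_class_reads(reads, query,
                                            evalue_max=float("inf"))
        assert counts.counts["Sn1"] + counts.unassigned == 20
        assert counts.counts["Sn1"] > 0  # random reads score > 0 somewhere

    def test_conservation(self):
        refs = _reference_records()
        queries = {cls: quantify.cterm_query(r.protein)
                   for cls, r in refs.items()}
        cdnas = {cls: r.cdna for cls, r in refs.items()}
        reads, _ = synth.make_reads(cdnas, {c: 1.0 for c in cdnas},
                                    read_len=120, n_reads=60, seed=8)
        counts = quantify.count_class_reads(reads, queries)
        assert sum(counts.counts.values()) + counts.unassigned + \
            counts.skipped == counts.total

    def test_empty_read_set(self):
        queries = {"Sn1": "MKVW" * 20}
        counts = quantify.count_class_reads([], queries)
        assert counts.total == 0 and counts.counts == {"Sn1": 0}
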