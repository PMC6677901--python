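"""Profile construction, local alignment scoring, Gumbel calibration and
family-database search."""

import numpy as np
import pytest

from subgroupscope.profile_search import (
    FamilyDatabase,
    ProfileModel,
    batch_scores,
    build_profile,
    calibrate,
    database_background,
    evalue,
    fit_gumbel,
    profile_align,
    search,
    sequence_weights,
    _encode_seq,
)
from subgroupscope.sequence_io import AMINO_ACIDS, Alignment, SequenceRecord


def _aln(rows: dict[str, str]) -> Alignment:
    return Alignment(tuple(SequenceRecord(i, s) for i, s in rows.items()))


def _brute_local(match_scores: np.ndarray, enc: np.ndarray, go: float, ge: float) -> float:
    """Exhaustive enumeration of local alignments (start/end on a match)."""
    n_pos, n_seq = match_scores.shape[0], len(enc)
    best = 0.0

    def extend(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if last == "M":
            best = max(best, score)
        if i < n_pos and j < n_seq:
            extend(i + 1, j + 1, score + match_scores[i, enc[j]], "M")
        if i < n_pos:
            extend(i + 1, j, score + (ge if last == "D" else go), "D")
        if j < n_seq:
            extend(i, j + 1, score + (ge if last == "I" else go), "I")

    for i0 in range(n_pos):
        for j0 in range(n_seq):
            extend(i0 + 1, j0 + 1, match_scores[i0, enc[j0]], "M")
    return best


class TestSequenceWeights:
    def test_identical_rows_equal_weights(self):
        w = sequence_weights(_aln({"a": "ACDE", "b": "ACDE"}))
        assert w == {"a": pytest.approx(1.0), "b": pytest.approx(1.0)}

    def test_distinct_row_upweighted(self):
        w = sequence_weights(_aln({"a": "AAAA", "b": "AAAA", "c": "CCCC"}))
        # per column: A rows get 1/(2*2), C row 1/(2*1); normalized to sum 3
        assert w["c"] == pytest.approx(1.5)
        assert w["a"] == pytest.approx(0.75)
        assert w["c"] > w["a"] == w["b"]

    def test_weights_sum_to_row_count(self, small_dataset):
        aln = Alignment(small_dataset.alignment.rows[:9])
        w = sequence_weights(aln)
        assert sum(w.values()) == pytest.approx(9.0)


class TestBuildProfile:
    def test_background_column_zero_log_odds(self):
        # 20 rows, one of each residue: observed frequencies == uniform bg
        rows = {f"s{i}": a for i, a in enumerate(AMINO_ACIDS)}
        prof = build_profile(_aln(rows))
        assert np.allclose(prof.log_odds, 0.0, atol=1e-12)

    def test_hand_computed_pseudocounts(self):
        rows = {f"s{i}": "A" for i in range(10)}
        prof = build_profile(_aln(rows), pseudocount_alpha=0.5)
        q = 1 / 20
        p_a = (10 + 0.5 * q * 10) / (10 + 0.5 * 10)
        p_other = (0.5 * q * 10) / 15
        assert prof.log_odds[0, 0] == pytest.approx(np.log2(p_a / q))
        assert prof.log_odds[0, 1] == pytest.approx(np.log2(p_other / q))

    def test_gappy_column_excluded(self):
        # column 1 is 60% gapped: above the 0.5 threshold, excluded
        rows = {"a": "A-", "b": "A-", "c": "A-", "d": "AC", "e": "AC"}
        prof = build_profile(_aln(rows), match_gap_frac=0.5)
        assert prof.match_columns == (0,)

    def test_boundary_gap_fraction_inclusive(self):
        rows = {"a": "A-", "b": "AC"}  # 50% gaps == threshold -> kept
        prof = build_profile(_aln(rows), match_gap_frac=0.5)
        assert prof.match_columns == (0, 1)

    def test_all_gap_columns_error(self):
        with pytest.raises(ValueError, match="no match columns"):
            build_profile(_aln({"a": "--", "b": "--", "c": "AC"}), match_gap_frac=0.1)


class TestProfileAlign:
    def test_self_consistency_single_sequence(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        prof = build_profile(_aln({"a": seq}))
        score, span = profile_align(prof, SequenceRecord("q", seq))
        expected = sum(
            prof.log_odds[i, AMINO_ACIDS.index(c)] for i, c in enumerate(seq)
        )
        assert score == pytest.approx(expected)
        assert span == (0, len(seq))

    def test_nowhere_positive_scores_zero(self):
        prof = ProfileModel(
            (0, 1, 2),
            np.full((3, 20), -1.0),
            np.full(20, 1 / 20),
        )
        score, span = profile_align(prof, SequenceRecord("q", "ACDEF"))
        assert score == 0.0 and span == (0, 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        log_odds = rng.normal(size=(4, 20)) * 3
        prof = ProfileModel(
            tuple(range(4)),
            log_odds,
            np.full(20, 1 / 20),
            gap_open=-3.0,
            gap_extend=-0.5,
        )
        seq = "".join(rng.choice(list(AMINO_ACIDS), 5))
        enc = _encode_seq(seq)
        table = np.hstack([log_odds, np.zeros((4, 1))])
        expected = _brute_local(table, enc, -3.0, -0.5)
        score, _ = profile_align(prof, SequenceRecord("q", seq))
        assert score == pytest.approx(expected, abs=1e-9)
        batch = batch_scores(prof, enc[None, :])
        assert batch[0] == pytest.approx(expected, abs=1e-9)

    def test_negative_flanks_do_not_change_score(self):
        rng = np.random.default_rng(9)
        core = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVY"), 30))  # no W
        rows = {f"s{i}": core for i in range(3)}
        prof = build_profile(_aln(rows))
        assert np.all(prof.log_odds[:, AMINO_ACIDS.index("W")] < 0)
        s0, _ = profile_align(prof, SequenceRecord("q", core))
        s1, _ = profile_align(prof, SequenceRecord("q", "WWW" + core + "WWWW"))
        assert s0 == pytest.approx(s1)

    def test_gapped_query_rejected(self):
        prof = build_profile(_aln({"a": "ACDE"}))
        with pytest.raises(ValueError, match="ungapped"):
            profile_align(prof, SequenceRecord("q", "AC-E"))


class TestProfileSerialization:
    def test_tsv_round_trip(self, tmp_path, small_dataset):
        from subgroupscope.profile_search import read_profile_tsv, write_profile_tsv

        ids = [i for i, g in small_dataset.truth_subgroup.items() if g == 1]
        prof = build_profile(small_dataset.alignment.subset(ids))
        prof = calibrate(prof, length=80, n_decoys=60, seed=4)
        p = tmp_path / "prof.tsv"
        write_profile_tsv(prof, p)
        back = read_profile_tsv(p)
        assert back.match_columns == prof.match_columns
        assert np.allclose(back.log_odds, prof.log_odds, atol=1e-9)
        assert np.allclose(back.background, prof.background, atol=1e-9)
        assert back.calibration.mu == pytest.approx(prof.calibration.mu)
        assert back.calibration.lam == pytest.approx(prof.calibration.lam)
        assert (back.gap_open, back.gap_extend) == (prof.gap_open, prof.gap_extend)


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(100)
        mu, lam = 5.0, 0.7
        samples = rng.gumbel(loc=mu, scale=1 / lam, size=10_000)
        cal = fit_gumbel(samples)
        assert cal.mu == pytest.approx(mu, abs=0.1)
        assert cal.lam == pytest.approx(lam, abs=0.05)

    def test_calibrate_reproducible_and_positive_lambda(self, small_dataset):
        ids = [i for i, g in small_dataset.truth_subgroup.items() if g == 0]
        prof = build_profile(small_dataset.alignment.subset(ids))
        c1 = calibrate(prof, length=100, n_decoys=60, seed=5)
        c2 = calibrate(prof, length=100, n_decoys=60, seed=5)
        assert c1.calibration == c2.calibration
        assert c1.calibration.lam > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gumbel(np.ones(100))


class TestEvalue:
    def _calibrated(self):
        prof = build_profile(_aln({"a": "ACDEFGHIKL"}))
        return calibrate(prof, length=50, n_decoys=60, seed=3)

    def test_at_mu_analytic(self):
        prof = self._calibrated()
        e = evalue(prof, prof.calibration.mu, db_size=1000)
        assert e == pytest.approx(1000 * (1 - np.exp(-1)), rel=1e-9)

    def test_monotone_decreasing_with_limit_zero(self):
        prof = self._calibrated()
        scores = np.linspace(0, 500, 40)
        evals = [evalue(prof, s, 100) for s in scores]
        assert all(a >= b for a, b in zip(evals, evals[1:]))
        assert evalue(prof, 1e6, 100) == pytest.approx(0.0, abs=1e-12)

    def test_uncalibrated_rejected(self):
        prof = build_profile(_aln({"a": "ACDE"}))
        with pytest.raises(ValueError, match="not calibrated"):
            evalue(prof, 10.0, 100)


class TestSearch:
    def test_own_family_dominates(self, small_dataset):
        from subgroupscope.synthetic_data import generate_family_db

        db = generate_family_db(
            n_families=4,
            n_per_family=12,
            length=150,
            divergence=0.3,
            seed=3,
            seed_ancestors={
                f"relfam{g + 1}": anc
                for g, anc in enumerate(small_dataset.subgroup_ancestors)
            },
        )
        background = database_background(db.records)
        for g in range(3):
            ids = [i for i, s in small_dataset.truth_subgroup.items() if s == g]
            prof = build_profile(
                small_dataset.alignment.subset(ids), background=background
            )
            prof = calibrate(prof, length=150, n_decoys=100, seed=20 + g)
            hits = search(prof, db, e_threshold=0.1)
            assert hits.hits, "profile retrieved nothing"
            top = max(hits.distribution, key=hits.distribution.get)
            assert top == f"relfam{g + 1}"
            assert sum(hits.distribution.values()) == pytest.approx(100.0, abs=0.05)

    def test_pure_background_db_obeys_evalue_semantics(self):
        rng = np.random.default_rng(77)
        prof = build_profile(
            _aln({f"s{i}": "".join(rng.choice(list(AMINO_ACIDS), 60)) for i in range(1)})
        )
        prof = calibrate(prof, length=80, n_decoys=200, seed=8)
        records = tuple(
            SequenceRecord(f"d{i}", "".join(rng.choice(list(AMINO_ACIDS), 80)))
            for i in range(200)
        )
        db = FamilyDatabase(records, {r.id: "bg" for r in records})
        hits = search(prof, db, e_threshold=0.1)
        assert len(hits.hits) <= 5  # expect ~0.1 false hits at E < 0.1

    def test_empty_db_rejected(self):
        prof = calibrate(build_profile(_aln({"a": "ACDEFGHIKL"})), length=20, n_decoys=50, seed=1)
        with pytest.raises(ValueError, match="empty"):
            search(prof, FamilyDatabase((), {}), 0.1)
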