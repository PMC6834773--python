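"""Motif P-value machinery and track/alien feature construction.

The P-value dynamic program is checked against exhaustive word enumeration
(the independent oracle) on small matrices; best-hit scoring is checked on a
hand-analysable one-hot motif where every P-value is a count over the 64
possible words.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from mpra_leakage.core import (
    DNA_ALPHABET,
    DNA_INDEX,
    PWM,
    PWMOrder,
    Reporter,
    ReporterKind,
    SignalTrack,
    reverse_complement,
)
from mpra_leakage.features import (
    FeatureError,
    FeatureMatrix,
    alien_features,
    assemble,
    best_hit_pvalue,
    motif_features,
    pwm_pvalue_table,
    shuffle_within_reporters,
    track_features,
)

from conftest import random_di_pwm, random_mono_pwm


def enumerate_tail(pwm, table):
    """Brute-force oracle: background-weighted tail probability at every
    achievable integer score of the rounded matrix."""
    iw = table.int_weights
    if pwm.order == PWMOrder.MONO:
        width, bg = pwm.n_steps, pwm.background
        scores, probs = [], []
        for word in itertools.product(range(4), repeat=width):
            scores.append(sum(iw[p, letter] for p, letter in enumerate(word)))
            probs.append(np.prod([bg[letter] for letter in word]))
    else:
        width = pwm.width
        scores, probs = [], []
        for word in itertools.product(range(4), repeat=width):
            scores.append(
                sum(iw[s, 4 * word[s] + word[s + 1]] for s in range(width - 1))
            )
            probs.append(0.25 ** width)
    scores = np.array(scores)
    probs = np.array(probs)
    return {
        int(s): float(probs[scores >= s].sum()) for s in np.unique(scores)
    }


class TestPvalueTable:
    @pytest.mark.parametrize("seed", range(5))
    def test_mono_dp_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_mono_pwm(rng, width=rng.integers(2, 6))
        table = pwm_pvalue_table(pwm)
        for score, tail in enumerate_tail(pwm, table).items():
            assert table.pvalue_of_int(score) == pytest.approx(tail, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_di_dp_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        pwm = random_di_pwm(rng, steps=rng.integers(1, 4))
        table = pwm_pvalue_table(pwm)
        for score, tail in enumerate_tail(pwm, table).items():
            assert table.pvalue_of_int(score) == pytest.approx(tail, abs=1e-9)

    def test_all_zero_matrix_degenerates_to_p_one(self):
        pwm = PWM("zero", PWMOrder.MONO, np.zeros((3, 4)))
        table = pwm_pvalue_table(pwm, resolution=1.0)
        assert table.min_score == 0
        assert len(table.sf) == 1
        assert table.pvalue_of_int(0) == pytest.approx(1.0)

    def test_query_above_maximum_returns_best_word_probability(
        self, one_hot_acg_pwm
    ):
        table = pwm_pvalue_table(one_hot_acg_pwm, resolution=0.5)
        max_score = table.min_score + len(table.sf) - 1
        assert table.pvalue_of_int(max_score + 100) == pytest.approx(
            table.sf[-1]
        )
        # the unique best word ACG has background probability 1/64
        assert table.sf[-1] == pytest.approx(1 / 64)

    def test_pvalues_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(9)
        pwm = random_mono_pwm(rng, width=5)
        table = pwm_pvalue_table(pwm)
        assert np.all(np.diff(table.sf) <= 1e-15)
        assert np.all(table.sf > 0) and table.sf[0] == pytest.approx(1.0)


class TestBestHit:
    def test_exact_match_gives_1_of_64(self, one_hot_acg_pwm):
        table = pwm_pvalue_table(one_hot_acg_pwm, resolution=0.5)
        p = best_hit_pvalue("TACGT", 2, "C", one_hot_acg_pwm, table)
        assert p == pytest.approx(1 / 64)

    def test_destroying_substitution_raises_pvalue(self, one_hot_acg_pwm):
        table = pwm_pvalue_table(one_hot_acg_pwm, resolution=0.5)
        p_ref = best_hit_pvalue("TACGT", 2, "C", one_hot_acg_pwm, table)
        p_alt = best_hit_pvalue("TACGT", 2, "A", one_hot_acg_pwm, table)
        # oracle: windows TAA/AAG/AGT and their reverse complements all score
        # <= 2, and P(score >= 2) counts 10 of 64 words
        assert p_alt > p_ref
        assert p_alt == pytest.approx(10 / 64)

    def test_reverse_complement_match_scores_like_forward(self, one_hot_acg_pwm):
        table = pwm_pvalue_table(one_hot_acg_pwm, resolution=0.5)
        # CGT reverse-complements to ACG
        p = best_hit_pvalue("TCGTT", 2, "G", one_hot_acg_pwm, table)
        assert p == pytest.approx(1 / 64)

    def test_reference_allele_reproduces_unmodified_scan(self, one_hot_acg_pwm):
        """Substituting the reference allele back in must equal the best-hit
        call on the untouched sequence (computed here by direct window
        scanning of both strands)."""
        table = pwm_pvalue_table(one_hot_acg_pwm, resolution=0.5)
        seq = "GACGTT"
        pos, ref = 3, "G"
        assert seq[pos] == ref
        best = None
        for start in range(len(seq) - 2):
            if not (start <= pos < start + 3):
                continue
            for window in (seq[start:start + 3],
                           reverse_complement(seq[start:start + 3])):
                score = table.score_int(
                    np.array([DNA_INDEX[c] for c in window])
                )
                best = score if best is None else max(best, score)
        assert best_hit_pvalue(seq, pos, ref, one_hot_acg_pwm, table) == (
            pytest.approx(table.pvalue_of_int(best))
        )

    def test_no_fitting_window_rejected(self, one_hot_acg_pwm):
        table = pwm_pvalue_table(one_hot_acg_pwm, resolution=0.5)
        with pytest.raises(FeatureError):
            best_hit_pvalue("AC", 1, "C", one_hot_acg_pwm, table)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_joint_reverse_complement(self, seed):
        """best_hit_pvalue(seq, pos) equals the call on the reverse-complement
        sequence at the mirrored position with the complemented allele."""
        rng = np.random.default_rng(200 + seed)
        pwm = random_mono_pwm(rng, width=4)
        table = pwm_pvalue_table(pwm)
        seq = "".join(rng.choice(list(DNA_ALPHABET), size=12))
        pos = int(rng.integers(0, 12))
        ref = seq[pos]
        alt = next(c for c in DNA_ALPHABET if c != ref)
        p = best_hit_pvalue(seq, pos, alt, pwm, table)
        rc_seq = reverse_complement(seq)
        rc_pos = len(seq) - 1 - pos
        rc_alt = reverse_complement(alt)
        p_rc = best_hit_pvalue(rc_seq, rc_pos, rc_alt, pwm, table)
        assert p == pytest.approx(p_rc, abs=1e-12)


def tiny_dataset():
    """Two 3-bp reporters with hand-made SNV records."""
    from mpra_leakage.core import SNVRecord

    r1 = Reporter("r1", "ct1", ReporterKind.PROMOTER, "chrS", 100, 103, "ACG")
    r2 = Reporter("r2", "ct2", ReporterKind.ENHANCER, "chrS", 200, 203, "TTT")

    class _DS:
        reporters = [r1, r2]
        snvs = [
            SNVRecord("r1", 0, "A", "C", 0.0, 0),
            SNVRecord("r1", 1, "C", "T", 0.5, 1),
            SNVRecord("r1", 2, "G", "A", 0.0, 0),
            SNVRecord("r2", 0, "T", "G", 0.9, -1),
            SNVRecord("r2", 1, "T", "A", 0.0, 0),
            SNVRecord("r2", 2, "T", "C", 0.0, 0),
        ]

    return _DS()


class TestTrackFeatures:
    def test_minmax_scaling_per_reporter(self):
        ds = tiny_dataset()
        tracks = [
            SignalTrack("t1", "chrS", 100, np.array([1.0, 3.0, 5.0])),
            SignalTrack("t1", "chrS", 200, np.array([10.0, 10.0, 10.0])),
        ]
        fm = track_features(ds, tracks)
        assert fm.feature_names == ["t1:scaled", "t1:mean"]
        scaled = fm.df["t1:scaled"].to_numpy()
        # r1 scales [1,3,5] -> [0, .5, 1]; r2 is constant -> all 0
        assert scaled[:3] == pytest.approx([0.0, 0.5, 1.0])
        assert scaled[3:] == pytest.approx([0.0, 0.0, 0.0])
        means = fm.df["t1:mean"].to_numpy()
        assert means[:3] == pytest.approx([3.0] * 3)
        assert means[3:] == pytest.approx([10.0] * 3)

    def test_scaled_values_stay_in_unit_interval(self, small_dataset):
        fm = track_features(small_dataset, small_dataset.informative_tracks)
        for col in fm.columns_with_tag("track"):
            v = fm.df[col].to_numpy()
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_mean_columns_constant_within_reporter(self, small_dataset):
        fm = track_features(small_dataset, small_dataset.informative_tracks)
        df = fm.df.copy()
        df["rep"] = [s.reporter_id for s in small_dataset.snvs]
        for col in fm.columns_with_tag("track_mean"):
            assert (df.groupby("rep")[col].nunique() == 1).all()

    def test_uncovered_positions_contribute_zero(self):
        ds = tiny_dataset()
        tracks = [SignalTrack("t1", "chrS", 100, np.array([2.0, 4.0, 6.0]))]
        fm = track_features(ds, tracks)  # r2 entirely uncovered
        assert fm.df["t1:scaled"].to_numpy()[3:] == pytest.approx([0.0] * 3)
        assert fm.df["t1:mean"].to_numpy()[3:] == pytest.approx([0.0] * 3)


class TestAlienFeatures:
    def test_modulo_identity_and_wrap(self):
        ds = tiny_dataset()
        # alien region of 150 bases: r1 (100..103) is identity, r2 (200..203)
        # wraps to 50..53
        values = np.arange(150, dtype=float)
        alien = [SignalTrack("a1", "chrALIEN", 0, values)]
        fm = alien_features(ds, alien, 150)
        scaled = fm.df["a1:scaled"].to_numpy()
        # raw values r1: [100,101,102]; r2: [50,51,52]; both scale to [0,.5,1]
        assert scaled == pytest.approx([0.0, 0.5, 1.0, 0.0, 0.5, 1.0])
        assert fm.df["a1:mean"].to_numpy()[:3] == pytest.approx([101.0] * 3)
        assert fm.df["a1:mean"].to_numpy()[3:] == pytest.approx([51.0] * 3)

    def test_columns_tagged_alien(self, small_dataset):
        fm = alien_features(small_dataset, small_dataset.alien_tracks,
                            small_dataset.config.alien_region_length)
        assert set(fm.provenance.values()) == {"alien"}

    def test_alien_columns_locally_autocorrelated(self, small_dataset):
        fm = alien_features(small_dataset, small_dataset.alien_tracks,
                            small_dataset.config.alien_region_length)
        col = fm.df[fm.columns_with_tag("alien")[0]].to_numpy()
        rep0 = small_dataset.reporters[0]
        rows = [i for i, s in enumerate(small_dataset.snvs)
                if s.reporter_id == rep0.reporter_id]
        per_pos = col[rows][::3]  # one value per position
        rho = np.corrcoef(per_pos[:-1], per_pos[1:])[0, 1]
        assert rho >= 0.8

    def test_shuffling_destroys_autocorrelation(self, small_dataset):
        fm = alien_features(small_dataset, small_dataset.alien_tracks,
                            small_dataset.config.alien_region_length)
        rng = np.random.default_rng(0)
        shuffled = shuffle_within_reporters(fm, small_dataset, rng)
        col_name = fm.columns_with_tag("alien")[0]
        rep0 = small_dataset.reporters[0]
        rows = [i for i, s in enumerate(small_dataset.snvs)
                if s.reporter_id == rep0.reporter_id]
        per_pos = shuffled.df[col_name].to_numpy()[rows][::3]
        rho = np.corrcoef(per_pos[:-1], per_pos[1:])[0, 1]
        assert abs(rho) < 0.3
        # value multiset within the reporter is preserved
        orig = np.sort(fm.df[col_name].to_numpy()[rows])
        new = np.sort(shuffled.df[col_name].to_numpy()[rows])
        assert orig == pytest.approx(new)


class TestMotifFeatures:
    def test_two_columns_per_pwm(self, small_dataset):
        fm = motif_features(small_dataset, small_dataset.pwms)
        assert len(fm.feature_names) == 2 * len(small_dataset.pwms)
        assert set(fm.provenance.values()) == {"motif"}

    def test_fold_change_zero_when_best_hit_unchanged(self, one_hot_acg_pwm):
        # in an all-T reporter no substitution creates or destroys an ACG hit
        # better than the alternatives, except where it completes the motif;
        # the C>T SNV at a T position far from any A/G context keeps P equal
        ds = tiny_dataset()
        fm = motif_features(ds, [one_hot_acg_pwm])
        fc = fm.df["ACG:log10_fc"].to_numpy()
        # r2 = TTT, substituting the middle T with A: best hit stays at
        # score 1 (single matching base); oracle check below
        table = pwm_pvalue_table(one_hot_acg_pwm, resolution=0.5)
        p_ref = best_hit_pvalue("TTT", 1, "T", one_hot_acg_pwm, table)
        p_alt = best_hit_pvalue("TTT", 1, "A", one_hot_acg_pwm, table)
        expected = np.log10(p_alt / p_ref)
        assert fc[4] == pytest.approx(expected)

    def test_matches_best_hit_oracle_row_by_row(self, one_hot_acg_pwm):
        ds = tiny_dataset()
        fm = motif_features(ds, [one_hot_acg_pwm])
        table = pwm_pvalue_table(one_hot_acg_pwm,
                                 resolution=None)
        seqs = {"r1": "ACG", "r2": "TTT"}
        for i, snv in enumerate(ds.snvs):
            seq = seqs[snv.reporter_id]
            p_ref = best_hit_pvalue(seq, snv.position, snv.ref_allele,
                                    one_hot_acg_pwm, table)
            p_alt = best_hit_pvalue(seq, snv.position, snv.alt_allele,
                                    one_hot_acg_pwm, table)
            assert fm.df["ACG:neglog10_pref"].iloc[i] == pytest.approx(
                -np.log10(p_ref)
            )
            assert fm.df["ACG:log10_fc"].iloc[i] == pytest.approx(
                np.log10(p_alt / p_ref)
            )


class TestAssemble:
    def test_column_concatenation_preserves_order(self):
        idx = ["a", "b"]
        m1 = FeatureMatrix(pd.DataFrame({"x": [1.0, 2.0]}, index=idx),
                           {"x": "motif"})
        m2 = FeatureMatrix(pd.DataFrame({"y": [3.0, 4.0]}, index=idx),
                           {"y": "track"})
        out = assemble(m1, m2)
        assert out.feature_names == ["x", "y"]
        assert out.provenance == {"x": "motif", "y": "track"}

    def test_single_provider_identity(self):
        m1 = FeatureMatrix(pd.DataFrame({"x": [1.0]}, index=["a"]),
                           {"x": "motif"})
        out = assemble(m1)
        assert out.df.equals(m1.df)

    def test_mismatched_indices_rejected(self):
        m1 = FeatureMatrix(pd.DataFrame({"x": [1.0]}, index=["a"]),
                           {"x": "motif"})
        m2 = FeatureMatrix(pd.DataFrame({"y": [1.0]}, index=["b"]),
                           {"y": "track"})
        with pytest.raises(FeatureError):
            assemble(m1, m2)

    def test_tsv_round_trip(self, tmp_path):
        idx = ["a", "b"]
        m = FeatureMatrix(
            pd.DataFrame({"x": [1.5, 2.0], "y": [0.0, -3.25]}, index=idx),
            {"x": "motif", "y": "alien"},
        )
        path = tmp_path / "features.tsv"
        m.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.provenance == m.provenance
        assert np.allclose(back.values, m.values)
        assert back.snv_index == m.snv_index
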