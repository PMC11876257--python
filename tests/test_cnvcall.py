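"""Purity correction, confidence gating, and call-set comparison."""

import itertools

import numpy as np
import pytest

from tumorfrac.cnvcall import (
    CNVRecord,
    compare_call_sets,
    correct_copy_number,
    evaluate_confidence,
    recall_with_tcf,
    records_from_frame,
)
from tumorfrac.synthscene import cnv_cohort_pair


class TestCorrectCopyNumber:
    def test_diploid_fixed_point(self):
        for f in np.linspace(0.05, 1.0, 20):
            assert correct_copy_number(2.0, f) == pytest.approx(2.0, abs=1e-12)

    def test_identity_at_pure_tumor(self):
        assert correct_copy_number(5.3, 1.0) == pytest.approx(5.3)

    @pytest.mark.parametrize("C, f, expected", [(3.0, 0.5, 4.0), (6.0, 0.8, 7.0)])
    def test_hand_substitution(self, C, f, expected):
        assert correct_copy_number(C, f) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            correct_copy_number(3.0, 0.0)
        with pytest.raises(ValueError):
            correct_copy_number(3.0, 1.2)
        with pytest.raises(ValueError):
            correct_copy_number(-1.0, 0.5)

    def test_mixture_round_trip_on_grid(self):
        """f*x + (1-f)*2 == C to 1e-12 over a 10^4-point grid."""
        C = np.linspace(0.0, 10.0, 100)
        f = np.linspace(0.01, 1.0, 100)
        Cg, fg = np.meshgrid(C, f)
        x = (Cg - 2.0 * (1.0 - fg)) / fg
        assert np.abs(fg * x + (1.0 - fg) * 2.0 - Cg).max() < 1e-12
        # spot-check the scalar API against the vectorized identity
        for Ci, fi in [(0.5, 0.3), (7.7, 0.9), (2.0, 0.01)]:
            xi = correct_copy_number(Ci, fi)
            assert fi * xi + (1 - fi) * 2 == pytest.approx(Ci, abs=1e-12)

    def test_monotonicity_in_f(self):
        f = np.linspace(0.05, 1.0, 50)
        x_gain = np.array([correct_copy_number(3.5, fi) for fi in f])
        x_loss = np.array([correct_copy_number(1.2, fi) for fi in f])
        x_dip = np.array([correct_copy_number(2.0, fi) for fi in f])
        assert (np.diff(x_gain) < 0).all()   # C > 2: decreasing in f
        assert (np.diff(x_loss) > 0).all()   # C < 2: increasing in f
        assert np.allclose(x_dip, 2.0)

    def test_negative_x_flagged_not_clamped(self):
        rec = evaluate_confidence(CNVRecord("c", "EGFR", C=0.2, f=0.3))
        assert rec.x < 0 and rec.implausible


def _record(met) -> CNVRecord:
    """Build a record whose six criteria equal the given boolean pattern."""
    f = 0.6 if met[0] else 0.3
    # choose C so the corrected x = (C - 2(1-f))/f lands at 6 or 3
    x_target = 6.0 if met[4] else 3.0
    C = f * x_target + (1 - f) * 2.0
    return CNVRecord(
        case_id="c1",
        gene="EGFR",
        C=C,
        f=f,
        read_count=20_000 if met[1] else 500,
        mapd=0.3 if met[2] else 0.9,
        cn_conf_5=4.5 if met[3] else 1.0,
        p_value=1e-7 if met[5] else 0.05,
    )


class TestConfidenceGate:
    def test_exhaustive_patterns(self):
        """All 2^6 criterion patterns: confident iff at least five met."""
        for met in itertools.product([False, True], repeat=6):
            rec = evaluate_confidence(_record(met))
            assert rec.criteria == met
            assert rec.n_met == sum(met)
            assert rec.confident == (sum(met) >= 5)

    def test_monotone_in_each_criterion(self):
        for met in itertools.product([False, True], repeat=6):
            base = evaluate_confidence(_record(met))
            for i in range(6):
                if met[i]:
                    continue
                flipped = list(met)
                flipped[i] = True
                assert (
                    evaluate_confidence(_record(tuple(flipped))).confident
                    >= base.confident
                )

    def test_missing_qc_fields_count_unmet(self):
        rec = evaluate_confidence(
            CNVRecord("c", "MET", C=6.0, f=0.8, read_count=None, mapd=None,
                      cn_conf_5=None, p_value=None)
        )
        assert rec.criteria[1:4] == (False, False, False)
        assert rec.n_met == 2  # cellularity and level only

    def test_boundary_inclusive(self):
        rec = evaluate_confidence(
            CNVRecord("c", "MET", C=0.5 * 5.0 + 1.0, f=0.50, read_count=10_000,
                      mapd=0.5, cn_conf_5=4.0, p_value=1e-5)
        )
        assert rec.n_met == 6 and rec.confident


class TestRecall:
    def _base(self):
        return evaluate_confidence(
            CNVRecord("c27", "EGFR", C=3.5, f=0.9, read_count=20_000, mapd=0.3,
                      cn_conf_5=4.5, p_value=1e-7)
        )

    def test_idempotent_for_unchanged_f(self):
        rec = self._base()
        out = recall_with_tcf([rec], {"c27": 0.9})
        assert out[0] == rec

    def test_lowered_f_flips_level_criterion(self):
        """f 0.9 -> 0.3 with C = 3.5 lifts x from 3.67 to 7.0 and meets level>=5."""
        rec = self._base()
        assert rec.x == pytest.approx((3.5 - 0.2) / 0.9)
        assert not rec.criteria[4]
        out = recall_with_tcf([rec], {"c27": 0.3})[0]
        assert out.x == pytest.approx(7.0)
        assert out.criteria[4]
        assert rec.x == pytest.approx(3.6667, abs=1e-3)  # input untouched

    def test_diploid_unchanged_when_f_moves(self):
        rec = evaluate_confidence(CNVRecord("c", "KRAS", C=2.0, f=0.4))
        out = recall_with_tcf([rec], {"c": 0.9})[0]
        assert out.x == pytest.approx(2.0) and rec.x == pytest.approx(2.0)

    def test_missing_case_errors(self):
        with pytest.raises(KeyError, match="no revised cellularity"):
            recall_with_tcf([self._base()], {"other": 0.5})


@pytest.fixture(scope="module")
def cohort():
    before_frame, after_frame = cnv_cohort_pair(seed=1)
    before = records_from_frame(before_frame)
    new_f = dict(
        after_frame.drop_duplicates("case_id")[["case_id", "f"]].itertuples(
            index=False
        )
    )
    after = recall_with_tcf(before, new_f)
    return compare_call_sets(before, after), before, after


class TestCompareCallSets:
    def test_printed_percentages(self, cohort):
        """29->27 software calls, 7->13 confident, 7/29 discrepant."""
        cmp, before, after = cohort
        assert (cmp.software_calls_before, cmp.software_calls_after) == (29, 27)
        assert cmp.software_change_pct == pytest.approx(-6.9)
        assert (cmp.confident_before, cmp.confident_after) == (7, 13)
        assert cmp.confident_change_pct == pytest.approx(85.7)
        assert cmp.discrepancy_pct == pytest.approx(24.0)

    def test_gained_conserved(self, cohort):
        cmp, before, after = cohort
        reported_after = {(r.case_id, r.gene) for r in after if r.reported}
        reported_before = {(r.case_id, r.gene) for r in before if r.reported}
        gained = reported_after - reported_before
        unchanged = reported_after & reported_before
        assert len(gained) + len(unchanged) == len(reported_after)
        assert sorted(cmp.genes_gained) == sorted(g for _, g in gained)

    def test_key_mismatch_errors(self, cohort):
        _, before, after = cohort
        with pytest.raises(KeyError, match="keys"):
            compare_call_sets(before[:-1], after)

    def test_zero_before_calls_gives_undefined_percentages(self):
        recs = [
            evaluate_confidence(CNVRecord("c1", "EGFR", C=2.0, f=0.5,
                                          read_count=100, mapd=0.9,
                                          cn_conf_5=1.0, p_value=0.5))
        ]
        cmp = compare_call_sets(recs, recs)
        assert cmp.software_change_pct is None
        assert cmp.discrepancy_pct is None
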