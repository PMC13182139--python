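"""Support normalisation, RISK/DIST filtering, threshold optimisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quartetpol.filtering import (
    FilterThresholds,
    RETAINED,
    REJECTED_DIST,
    REJECTED_RISK,
    UNINFORMATIVE,
    apply_filters,
    compute_risk,
    optimize_thresholds,
    rejection_summary,
    score_quartet,
    species_rejection_totals,
)
from quartetpol.matrix_io import CladeAssignment
from quartetpol.quartets import (
    CladeQuartet,
    PatternCounts,
    SpeciesQuartet,
    TOPOLOGY_IDS,
)

CQ = CladeQuartet(outgroup="O", ingroups=("A", "B", "C"))


def make_quartet(tag="q"):
    return SpeciesQuartet(
        clade_quartet=CQ,
        ingroup_species=(f"{tag}a", f"{tag}b", f"{tag}c"),
        outgroup_species="out",
    )


def scored(raw, tag="q"):
    """Build a score whose raw supports equal ``raw`` (Nc = 0)."""
    na = {t: int(max(v, 0)) for t, v in zip(TOPOLOGY_IDS, raw)}
    nc = {t: float(na[t] - v) for t, v in zip(TOPOLOGY_IDS, raw)}
    pc = PatternCounts(na=na, n_usable=1000, n_informative=sum(na.values()))
    return score_quartet(make_quartet(tag), pc, nc)


class TestScoreQuartet:
    def test_positive_raw_supports_normalize(self):
        sc = scored((6, 3, 1))
        assert sc.s == pytest.approx({"x1": 0.6, "x2": 0.3, "x3": 0.1})
        assert sc.best == "x1" and sc.second == "x2"
        assert sc.sd12 == pytest.approx(0.3)

    def test_negative_raw_supports_clamped(self):
        sc = scored((5, -2, -3))
        assert sc.s == pytest.approx({"x1": 1.0, "x2": 0.0, "x3": 0.0})
        assert sc.sd12 == pytest.approx(1.0)

    def test_all_equal_gives_thirds(self):
        sc = scored((4, 4, 4))
        assert sc.s == pytest.approx({t: 1 / 3 for t in TOPOLOGY_IDS})
        assert sc.sd12 == pytest.approx(0.0)
        assert sc.best == "x1"  # canonical tie-break

    def test_all_nonpositive_marks_uninformative(self):
        sc = scored((0, -1, -5))
        assert sc.status == UNINFORMATIVE
        assert sc.s is None and sc.best is None

    def test_scores_form_probability_vector(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = tuple(rng.integers(-5, 50, size=3))
            sc = scored(raw)
            if sc.informative:
                assert sum(sc.s.values()) == pytest.approx(1.0)
                assert 0 <= sc.sd12 <= 1


class TestRisk:
    def test_simple_ratio(self):
        assert compute_risk(100, 10) == pytest.approx(0.10)

    def test_zero_na_is_infinite_and_rejected(self):
        assert math.isinf(compute_risk(0, 5))
        pc = PatternCounts(na={"x1": 0, "x2": 0, "x3": 0}, n_usable=10, n_informative=0)
        sc = score_quartet(make_quartet(), pc, {"x1": -1.0, "x2": 0.0, "x3": 0.0})
        # raw = (1, 0, 0): informative, but Na(best)=0 -> infinite RISK
        assert sc.risk == math.inf
        out = apply_filters([sc], FilterThresholds(l_dist=0.0, l_risk=1.0))
        assert out[0].status == REJECTED_RISK


class TestApplyFilters:
    def test_example_retained(self):
        sc = scored((80, 30, 10))  # sd12 = 0.5 - 0.25... construct explicitly
        th = FilterThresholds(l_dist=0.3, l_risk=0.6)
        sc2 = apply_filters([sc], th)[0]
        assert sc2.sd12 >= 0.3 and sc2.risk <= 0.6
        assert sc2.status == RETAINED

    def test_boundary_sd_is_retained(self):
        sc = scored((6, 3, 1))  # sd12 = 0.3 exactly
        out = apply_filters([sc], FilterThresholds(l_dist=0.3, l_risk=1.0))
        assert out[0].status == RETAINED

    def test_identity_thresholds_keep_everything_informative(self):
        scores = [scored((6, 3, 1)), scored((1, 1, 1)), scored((0, -1, -2))]
        out = apply_filters(scores, FilterThresholds(l_dist=0.0, l_risk=1.0))
        statuses = [sc.status for sc in out]
        assert statuses == [RETAINED, RETAINED, UNINFORMATIVE]

    def test_dist_reported_before_risk(self):
        sc = scored((5, 4, 1))  # sd12 = 0.1
        out = apply_filters([sc], FilterThresholds(l_dist=0.5, l_risk=0.0))
        assert out[0].status == REJECTED_DIST  # fails both; DIST reported

    def test_idempotent(self):
        scores = [scored((6, 3, 1)), scored((5, 4, 1))]
        th = FilterThresholds(l_dist=0.25, l_risk=0.9)
        once = apply_filters(scores, th)
        twice = apply_filters(once, th)
        assert [a.status for a in once] == [b.status for b in twice]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(-5, 60), st.integers(-5, 60), st.integers(-5, 60)),
            min_size=1,
            max_size=12,
        ),
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_retention_monotone_in_thresholds(self, raws, d1, d2, r1, r2):
        """Raising L_RISK or lowering L_DIST never shrinks the retained set."""
        scores = [scored(r, tag=f"q{i}") for i, r in enumerate(raws)]
        loose = FilterThresholds(l_dist=min(d1, d2), l_risk=max(r1, r2))
        tight = FilterThresholds(l_dist=max(d1, d2), l_risk=min(r1, r2))
        kept_loose = {
            s.quartet.id for s in apply_filters(scores, loose) if s.status == RETAINED
        }
        kept_tight = {
            s.quartet.id for s in apply_filters(scores, tight) if s.status == RETAINED
        }
        assert kept_tight <= kept_loose


class TestOptimizeThresholds:
    def test_uniform_strong_scores_keep_everything(self):
        scores = [scored((50, 2, 1), tag=f"q{i}") for i in range(8)]
        th = optimize_thresholds(scores)
        kept = [s for s in apply_filters(scores, th) if s.status == RETAINED]
        assert len(kept) == len(scores)
        assert th.l_dist <= min(s.sd12 for s in scores)

    def test_planted_partition_prefers_clean_half(self):
        rng = np.random.default_rng(5)
        clean = [
            scored((int(rng.integers(45, 60)), int(rng.integers(0, 4)), int(rng.integers(0, 4))), tag=f"c{i}")
            for i in range(10)
        ]
        noisy = [
            scored((int(rng.integers(10, 13)), int(rng.integers(9, 12)), int(rng.integers(8, 11))), tag=f"n{i}")
            for i in range(10)
        ]
        scores = clean + noisy
        th = optimize_thresholds(scores)
        kept = [s for s in apply_filters(scores, th) if s.status == RETAINED]
        frac = len(kept) / len(scores)
        assert 0 < frac < 1
        clean_ids = {s.quartet.id for s in clean}
        n_clean_kept = sum(1 for s in kept if s.quartet.id in clean_ids)
        assert n_clean_kept > len(kept) / 2

    def test_thresholds_live_in_unit_interval(self):
        rng = np.random.default_rng(6)
        scores = [
            scored(tuple(rng.integers(0, 30, size=3)), tag=f"q{i}") for i in range(15)
        ]
        th = optimize_thresholds([s for s in scores if s.informative])
        assert 0.0 <= th.l_dist <= 1.0
        assert 0.0 <= th.l_risk <= 1.0

    def test_no_informative_quartets_is_an_error(self):
        with pytest.raises(ValueError):
            optimize_thresholds([scored((0, -1, -1))])


class TestRejectionSummary:
    def make_assignment(self):
        return CladeAssignment(
            clade_of={
                "qa": "A", "qb": "B", "qc": "C", "out": "O",
                **{f"q{i}a": "A" for i in range(10)},
                **{f"q{i}b": "B" for i in range(10)},
                **{f"q{i}c": "C" for i in range(10)},
            },
            outgroup_clade="O",
        )

    def test_eighty_percent_flagged_partial(self):
        ca = CladeAssignment(
            clade_of={"qa": "A", "qb": "B", "qc": "C", "out": "O", "xa": "A"},
            outgroup_clade="O",
        )
        scores = []
        for i in range(10):
            sc = scored((6, 3, 1))
            status = REJECTED_RISK if i < 8 else RETAINED
            from dataclasses import replace

            scores.append(replace(sc, status=status))
        table = rejection_summary(scores, ca)
        row = table[table.species == "qa"].iloc[0]
        assert row.n_quartets == 10 and row.n_rejected == 8
        assert row.pct_rejected == pytest.approx(80.0)
        assert row.flag == "partial"

    def test_never_rejected_has_no_flag(self):
        ca = CladeAssignment(
            clade_of={"qa": "A", "qb": "B", "qc": "C", "out": "O"}, outgroup_clade="O"
        )
        table = rejection_summary([scored((6, 3, 1))], ca)
        assert (table.pct_rejected == 0).all()
        assert (table.flag == "").all()

    def test_totals_collapse_over_clade_quartets(self):
        ca = CladeAssignment(
            clade_of={"qa": "A", "qb": "B", "qc": "C", "out": "O"}, outgroup_clade="O"
        )
        table = rejection_summary([scored((6, 3, 1)), scored((1, 5, 1))], ca)
        totals = species_rejection_totals(table)
        assert set(totals.species) == {"qa", "qb", "qc"}
        assert (totals.n_quartets == 2).all()
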