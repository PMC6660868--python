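"""Component scores, SOA standardization, IRA aggregation and banding."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

import ivcsoa as iv

scores_15 = st.integers(min_value=1, max_value=5)


class TestScoreComponent:
    def test_published_transversal_component(self, dairy):
        record, config = dairy
        weights = {v.id: v.weight for v in config.transversal_variables()}
        vt = iv.score_component(record.transversal_scores, weights)
        assert iv.round_half_up(vt) == 3.04

    def test_published_propia_component(self, dairy):
        record, config = dairy
        weights = {v.id: v.weight for v in config.propia_variables("alimentos")}
        vp = iv.score_component(record.propia_scores, weights)
        assert iv.round_half_up(vp) == 4.27
        assert vp == pytest.approx(0.37 * 5 + 0.53 * 4 + 0.10 * 3)

    @given(c=scores_15, w=st.lists(st.floats(0.05, 1.0), min_size=1, max_size=8))
    def test_constant_scores_give_constant(self, c, w):
        total = sum(w)
        weights = {f"v{i}": x / total for i, x in enumerate(w)}
        scores = {k: c for k in weights}
        assert iv.score_component(scores, weights) == pytest.approx(c)

    def test_missing_variables_renormalize_with_warning(self):
        weights = {"a": 0.5, "b": 0.3, "c": 0.2}
        with pytest.warns(iv.MissingScoreWarning):
            value = iv.score_component({"a": 4, "b": 2}, weights)
        assert value == pytest.approx((0.5 * 4 + 0.3 * 2) / 0.8)

    def test_empty_scores_error(self):
        with pytest.raises(iv.ScoringError, match="no scorable variables"):
            iv.score_component({}, {"a": 1.0})


class TestSOA:
    def test_published_single_risk(self):
        risk = iv.SOARisk("r", severity=5, occurrence=3, affectation=5)
        assert risk.severity * risk.occurrence * risk.affectation == 75
        assert iv.round_half_up(iv.soa_score(risk)) == 4.22

    @pytest.mark.parametrize(
        "s,o,a,expected",
        [(1, 1, 1, 1.0), (5, 5, 5, 5.0), (2, 4, 4, 32 ** (1 / 3))],
    )
    def test_cube_root_against_power_oracle(self, s, o, a, expected):
        assert iv.soa_score(iv.SOARisk("r", s, o, a)) == pytest.approx(expected, abs=1e-12)

    @given(s=scores_15, o=scores_15, a=scores_15)
    def test_permutation_symmetry(self, s, o, a):
        base = iv.soa_score(iv.SOARisk("r", s, o, a))
        for p in itertools.permutations((s, o, a)):
            assert iv.soa_score(iv.SOARisk("r", *p)) == pytest.approx(base, abs=1e-12)

    def test_aggregation_modes(self):
        lo, hi = iv.SOARisk("a", 1, 1, 1), iv.SOARisk("b", 5, 5, 5)
        assert iv.soa_component([lo, hi], mode="max") == pytest.approx(5.0)
        trio = [iv.SOARisk(str(k), k, k, k) for k in (2, 3, 4)]
        # brute force: cube root of k^3 is k, mean of (2,3,4) = 3
        assert iv.soa_component(trio, mode="weighted_mean") == pytest.approx(3.0)

    def test_single_risk_mode_invariant(self):
        r = [iv.SOARisk("r", 5, 3, 5)]
        assert iv.soa_component(r, "max") == iv.soa_component(r, "weighted_mean")
        assert iv.soa_component(r, "max") == pytest.approx(4.2172, abs=5e-5)

    def test_empty_risks_error(self):
        with pytest.raises(iv.ScoringError, match="no assessed risks"):
            iv.soa_component([])


class TestIRA:
    def test_published_aggregation(self):
        assert iv.round_half_up(iv.ira(3.04, 4.27, 4.22, (0.45, 0.25, 0.30))) == 3.70

    def test_hand_arithmetic(self):
        assert iv.ira(1, 5, 1, (0.45, 0.25, 0.30)) == pytest.approx(2.00)

    @given(c=st.floats(1, 5))
    def test_convex_combination_of_equal_components(self, c):
        assert iv.ira(c, c, c, (0.45, 0.25, 0.30)) == pytest.approx(c)

    def test_unnormalized_betas_rejected(self):
        with pytest.raises(iv.ScoringError, match="not normalized"):
            iv.ira(3, 3, 3, (0.5, 0.5, 0.5))


class TestBand:
    @pytest.mark.parametrize(
        "value,band",
        [
            (3.70, iv.Band.alto),
            (1.0, iv.Band.bajo),
            (5.0, iv.Band.muy_alto),
            (4.0, iv.Band.muy_alto),  # boundary escalates
            (2.0, iv.Band.moderado),
            (3.0, iv.Band.alto),
            (1.999, iv.Band.bajo),
        ],
    )
    def test_half_open_bands(self, value, band):
        assert iv.classify_band(value) == band

    @given(x=st.floats(1, 5))
    def test_interval_membership_oracle(self, x):
        intervals = {
            iv.Band.bajo: (1.0, 2.0),
            iv.Band.moderado: (2.0, 3.0),
            iv.Band.alto: (3.0, 4.0),
        }
        band = iv.classify_band(x)
        if band is iv.Band.muy_alto:
            assert 4.0 <= x <= 5.0
        else:
            lo, hi = intervals[band]
            assert lo <= x < hi

    def test_out_of_scale_rejected(self):
        with pytest.raises(iv.ScoringError):
            iv.classify_band(0.5)
        with pytest.raises(iv.ScoringError):
            iv.classify_band(5.2)


class TestScoreEstablishment:
    def test_published_worked_example(self, dairy):
        record, config = dairy
        p = iv.score_establishment(record, config)
        assert (
            iv.round_half_up(p.vt),
            iv.round_half_up(p.vp),
            iv.round_half_up(p.soa),
            iv.round_half_up(p.ira),
            p.band,
        ) == (3.04, 4.27, 4.22, 3.70, iv.Band.alto)

    @pytest.mark.parametrize("level,band", [(1, iv.Band.bajo), (5, iv.Band.muy_alto)])
    def test_scale_endpoints(self, synth_config, level, band):
        record = iv.EstablishmentRecord(
            id="e",
            product_line="alimentos",
            transversal_scores={v.id: level for v in synth_config.transversal_variables()},
            propia_scores={v.id: level for v in synth_config.propia_variables("alimentos")},
            risks=(iv.SOARisk("r", level, level, level),),
        )
        p = iv.score_establishment(record, synth_config)
        assert (p.vt, p.vp, p.soa, p.ira) == pytest.approx((level,) * 4)
        assert p.band == band

    def test_errors_name_the_establishment(self, synth_config):
        record = iv.EstablishmentRecord(
            id="emptyrisks", product_line="alimentos",
            transversal_scores={"VT1": 3}, propia_scores={"VP1": 3}, risks=(),
        )
        with pytest.warns(iv.MissingScoreWarning):
            with pytest.raises(iv.ScoringError, match="emptyrisks"):
                iv.score_establishment(record, synth_config)


class TestPortfolioScaleAndMonotonicity:
    """Scale closure and IRA monotonicity over a large random portfolio."""

    N = 1200

    @pytest.fixture(scope="class")
    def scored(self, synth_config):
        records = iv.generate_portfolio(
            self.N, synth_config, {v.id: 0.5 for v in synth_config.variables}, seed=77
        )
        profiles, _ = iv.score_portfolio(records, synth_config)
        return records, profiles, synth_config

    def test_scale_closure(self, scored):
        _, profiles, _ = scored
        for p in profiles:
            for x in (p.vt, p.vp, p.soa, p.ira):
                assert 1.0 <= x <= 5.0

    def test_reconstruction_identity(self, scored):
        _, profiles, config = scored
        b1, b2, b3 = config.betas
        for p in profiles:
            assert p.ira == pytest.approx(b1 * p.vt + b2 * p.vp + b3 * p.soa, abs=1e-9)
            assert p.band == iv.classify_band(p.ira)

    def test_raising_any_input_never_decreases_ira(self, scored):
        import dataclasses
        import random

        records, profiles, config = scored
        rnd = random.Random(123)
        by_id = {p.establishment_id: p for p in profiles}
        for record in rnd.sample(records, 300):
            base = by_id[record.id].ira
            var_ids = list(record.transversal_scores) + list(record.propia_scores)
            choice = rnd.choice(var_ids + ["S", "O", "A"])
            if choice in ("S", "O", "A"):
                risk = record.risks[0]
                field = {"S": "severity", "O": "occurrence", "A": "affectation"}[choice]
                if getattr(risk, field) == 5:
                    continue
                bumped_risk = dataclasses.replace(risk, **{field: getattr(risk, field) + 1})
                bumped = dataclasses.replace(record, risks=(bumped_risk, *record.risks[1:]))
            else:
                tv, pv = dict(record.transversal_scores), dict(record.propia_scores)
                target = tv if choice in tv else pv
                if target[choice] == 5:
                    continue
                target[choice] += 1
                bumped = dataclasses.replace(
                    record, transversal_scores=tv, propia_scores=pv
                )
            assert iv.score_establishment(bumped, config).ira >= base - 1e-12
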