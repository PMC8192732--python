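"""Claims-based episode construction and estimation."""

import datetime
import math

import pytest

from epiflow.rwd import (PrescriptionRecord, build_episodes, combination_cost,
                         estimate_transition_probabilities, read_records_csv)

D = datetime.date


def rec(pid, date, drug, days=90, price=10_000.0):
    return PrescriptionRecord(patient_id=pid, date=date, drug_code=drug,
                              days_supplied=days, price=price)


class TestEpisodes:
    def test_single_prescription_single_episode(self):
        (ep,) = build_episodes([rec("p1", D(2016, 3, 1), "A")])
        assert ep.index_date == D(2016, 3, 1)
        assert ep.follow_up_end == D(2016, 3, 1) + datetime.timedelta(days=1096)
        assert ep.line_history == ((D(2016, 3, 1), 1),)
        assert ep.max_line == 1

    def test_same_date_addon_is_an_escalation(self):
        records = [
            rec("p1", D(2016, 1, 1), "A"),
            rec("p1", D(2016, 7, 19), "A"),   # day 200
            rec("p1", D(2016, 7, 19), "B"),
        ]
        (ep,) = build_episodes(records)
        assert ep.line_history == ((D(2016, 1, 1), 1), (D(2016, 7, 19), 2))

    def test_dropping_a_drug_does_not_lower_the_line(self):
        records = [
            rec("p1", D(2016, 1, 1), "A"),
            rec("p1", D(2016, 4, 1), "A"),
            rec("p1", D(2016, 4, 1), "B"),
            rec("p1", D(2016, 7, 1), "A"),   # de-escalation: line stays 2
        ]
        (ep,) = build_episodes(records)
        assert ep.max_line == 2
        assert ep.line_history[-1] == (D(2016, 4, 1), 2)

    def test_long_treatment_free_gap_opens_second_episode(self):
        # 30-day supply dispensed 2016-01-01 runs out 2016-01-31; the next
        # prescription comes 223 days later — beyond the 183-day washout
        records = [
            rec("p1", D(2016, 1, 1), "A", days=30),
            rec("p1", D(2016, 9, 10), "A", days=30),
        ]
        eps = build_episodes(records)
        assert len(eps) == 2
        assert [e.index_date for e in eps] == [D(2016, 1, 1), D(2016, 9, 10)]

    def test_gap_within_washout_stays_one_episode(self):
        records = [
            rec("p1", D(2016, 1, 1), "A"),   # 90-day supply
            rec("p1", D(2016, 7, 19), "A"),  # 110 days after supply end
        ]
        assert len(build_episodes(records)) == 1

    def test_records_after_follow_up_ignored(self):
        records = [
            rec("p1", D(2016, 1, 1), "A"),
            rec("p1", D(2016, 4, 1), "A"),
            # beyond index + 1096 d but within washout of the prior record?
            # no: make it far out so it also opens a fresh episode
            rec("p1", D(2019, 6, 1), "A"),
            rec("p1", D(2019, 6, 1), "B"),
        ]
        eps = build_episodes(records)
        assert len(eps) == 2
        assert eps[0].max_line == 1      # the 2019 add-on is outside follow-up
        assert eps[1].max_line == 2

    def test_non_whitelist_drugs_do_not_count(self):
        records = [
            rec("p1", D(2016, 1, 1), "A"),
            rec("p1", D(2016, 4, 1), "A"),
            rec("p1", D(2016, 4, 1), "PAINKILLER"),
        ]
        (ep,) = build_episodes(records, whitelist={"A", "B"})
        assert ep.max_line == 1

    def test_empty_input_gives_empty_output(self):
        assert build_episodes([]) == []


class TestTransitionEstimate:
    def _mono_episode(self, i, escalate_to=1):
        records = [rec(f"p{i}", D(2016, 1, 1), "A")]
        for line, drug in enumerate("BCD"[:escalate_to - 1], start=2):
            for prev in "ABC"[:line - 1]:
                records.append(rec(f"p{i}", D(2016, 1, 1)
                                   + datetime.timedelta(days=90 * (line - 1)),
                                   prev))
            records.append(rec(f"p{i}", D(2016, 1, 1)
                               + datetime.timedelta(days=90 * (line - 1)), drug))
        return records

    def test_direct_ratio(self):
        records = []
        for i in range(10):
            records += self._mono_episode(i, escalate_to=2 if i < 4 else 1)
        estimate = estimate_transition_probabilities(build_episodes(records))
        assert estimate.probabilities[0] == pytest.approx(0.4)
        assert estimate.numerators[0] == 4
        assert estimate.denominators[0] == 10

    def test_zero_denominator_reported_as_missing(self):
        records = [r for i in range(5) for r in self._mono_episode(i)]
        estimate = estimate_transition_probabilities(build_episodes(records))
        assert estimate.probabilities == (0.0, None, None)
        frame = estimate.to_frame()
        assert math.isnan(frame["probability"].iloc[1])

    def test_numerator_never_exceeds_denominator(self, synthetic_claims_20k):
        _, records = synthetic_claims_20k
        estimate = estimate_transition_probabilities(
            build_episodes(records[:20_000]))
        for num, den in zip(estimate.numerators, estimate.denominators):
            assert 0 <= num <= den

    def test_recovery_of_known_escalation_probabilities(self, synthetic_claims_20k):
        from epiflow.synth import DEFAULT_WHITELIST

        truth, records = synthetic_claims_20k
        estimate = estimate_transition_probabilities(
            build_episodes(records, whitelist=set(DEFAULT_WHITELIST)))
        denoms = estimate.denominators
        assert denoms[0] >= 20_000  # every patient contributes an episode
        for k in range(3):
            se = math.sqrt(truth[k] * (1 - truth[k]) / denoms[k])
            assert estimate.probabilities[k] == pytest.approx(truth[k],
                                                              abs=3 * se)

    def test_error_shrinks_with_sample_size(self):
        # the root-n law: 3-SE bands at two sample sizes, both satisfied
        from epiflow.synth import DEFAULT_WHITELIST, generate_prescription_records

        truth = (0.386, 0.271, 0.235)
        for n in (2_000, 8_000):
            records = generate_prescription_records(n, true_probs=truth,
                                                    seed=7)
            estimate = estimate_transition_probabilities(
                build_episodes(records, whitelist=set(DEFAULT_WHITELIST)))
            for k in range(3):
                se = math.sqrt(truth[k] * (1 - truth[k])
                               / estimate.denominators[k])
                assert estimate.probabilities[k] == pytest.approx(truth[k],
                                                                  abs=3 * se)


class TestCombinationCost:
    def test_single_combination(self):
        records = [rec("p1", D(2016, 1, 1), "A", price=100.0),
                   rec("p1", D(2016, 1, 1), "B", price=200.0)]
        combo = combination_cost(records, {"A", "B"}, 2)
        assert combo.mean_cost == pytest.approx(300.0)

    def test_frequency_weighted_mean(self):
        records = []
        for i in range(3):
            records += [rec(f"p{i}", D(2016, 1, 1), "A", price=100.0),
                        rec(f"p{i}", D(2016, 1, 1), "B", price=200.0)]
        records += [rec("p9", D(2016, 1, 1), "A", price=100.0),
                    rec("p9", D(2016, 1, 1), "C", price=600.0)]
        combo = combination_cost(records, {"A", "B", "C"}, 2)
        assert combo.mean_cost == pytest.approx((3 * 300 + 700) / 4)
        counts = dict(zip(combo.frequency_table["combination"],
                          combo.frequency_table["count"]))
        assert counts == {"A+B": 3, "A+C": 1}

    def test_prices_normalized_to_ninety_days(self):
        records = [rec("p1", D(2016, 1, 1), "A", days=30, price=100.0),
                   rec("p1", D(2016, 1, 1), "B", days=90, price=200.0)]
        combo = combination_cost(records, {"A", "B"}, 2)
        assert combo.mean_cost == pytest.approx(300.0 + 200.0)

    def test_combinations_with_other_drugs_excluded(self):
        records = [rec("p1", D(2016, 1, 1), "A"),
                   rec("p1", D(2016, 1, 1), "B"),
                   rec("p1", D(2016, 1, 1), "STEROID")]
        combo = combination_cost(records, {"A", "B"}, 2)
        assert combo.mean_cost is None

    def test_five_drug_sets_contribute_nowhere(self):
        wl = {"A", "B", "C", "D", "E"}
        records = [rec("p1", D(2016, 1, 1), d) for d in sorted(wl)]
        for n in (2, 3, 4):
            assert combination_cost(records, wl, n).mean_cost is None

    def test_invariant_to_order_and_duplication(self):
        records = [rec("p1", D(2016, 1, 1), "A", price=100.0),
                   rec("p1", D(2016, 1, 1), "B", price=200.0),
                   rec("p2", D(2016, 2, 1), "A", price=400.0),
                   rec("p2", D(2016, 2, 1), "B", price=100.0)]
        base = combination_cost(records, {"A", "B"}, 2)
        reordered = combination_cost(records[::-1], {"A", "B"}, 2)
        assert reordered.mean_cost == pytest.approx(base.mean_cost)
        doubled_records = records + [
            rec("p3", D(2016, 1, 1), "A", price=100.0),
            rec("p3", D(2016, 1, 1), "B", price=200.0),
            rec("p4", D(2016, 2, 1), "A", price=400.0),
            rec("p4", D(2016, 2, 1), "B", price=100.0)]
        doubled = combination_cost(doubled_records, {"A", "B"}, 2)
        assert doubled.mean_cost == pytest.approx(base.mean_cost)
        assert doubled.frequency_table["count"].sum() == \
            2 * base.frequency_table["count"].sum()


def test_csv_reader_drops_unparseable_dates(tmp_path, caplog):
    path = tmp_path / "records.csv"
    path.write_text(
        "patient_id,date,drug_code,days_supplied,price_jpy\n"
        "p1,2016-01-01,A,90,10000\n"
        "p1,not-a-date,A,90,10000\n"
        "p2,2016-02-01,B,30,5000\n"
    )
    with caplog.at_level("WARNING"):
        records = read_records_csv(path)
    assert len(records) == 2
    assert "dropped 1" in caplog.text


def test_record_invariants_enforced():
    with pytest.raises(ValueError):
        rec("p1", D(2016, 1, 1), "A", days=0)
    with pytest.raises(ValueError):
        rec("p1", D(2016, 1, 1), "A", price=-5.0)
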