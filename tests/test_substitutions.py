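"""Event inference from aligned pairs and substitution-type bookkeeping."""

import numpy as np
import pytest

from aacontext import (
    AlignedPair,
    GeneratorConfig,
    SubstitutionEvent,
    enumerate_types,
    events_to_table,
    filter_types,
    gen_iid,
    infer_events,
    read_events_tsv,
    substitution_profile,
    write_events_tsv,
)
from aacontext.substitutions import events_in_structure


class TestInferEvents:
    def test_single_mismatch(self):
        events = infer_events(AlignedPair("g1", "ACDEFG", "ACNEFG"))
        assert len(events) == 1
        ev = events[0]
        assert (ev.from_aa, ev.to_aa, ev.position) == ("D", "N", 3)
        assert ev.context_n == "AC"
        assert ev.context_c == "EFG"

    def test_insertion_column_yields_no_event(self):
        assert infer_events(AlignedPair("g1", "AC-EF", "ACDEF")) == []

    def test_deletion_column_yields_no_event(self):
        assert infer_events(AlignedPair("g1", "ACDEF", "AC-EF")) == []

    def test_identical_rows_yield_no_events(self):
        assert infer_events(AlignedPair("g1", "ACDEF", "ACDEF")) == []

    def test_unknown_in_either_row_yields_no_event(self):
        assert infer_events(AlignedPair("g1", "AXDEF", "AGDEF")) == []
        assert infer_events(AlignedPair("g1", "AGDEF", "AXDEF")) == []

    def test_contexts_skip_gaps_and_use_ancestral_coordinates(self):
        # ancestor ACD-FG vs descendant ACDEFG: the E column is an insertion;
        # the G->W mismatch sits at ungapped ancestral position 5
        events = infer_events(AlignedPair("g1", "ACD-FG", "ACDEFW"))
        assert len(events) == 1
        ev = events[0]
        assert (ev.from_aa, ev.to_aa, ev.position) == ("G", "W", 5)
        assert ev.context_n == "ACDF"
        assert "-" not in ev.context_n

    def test_event_count_conservation(self):
        rng = np.random.default_rng(0)
        total_mismatches = 0
        pairs = []
        for i in range(20):
            anc = "".join(rng.choice(list("ACDEFGHIKL"), 50))
            desc = list(anc)
            for j in rng.choice(50, size=5, replace=False):
                choices = [c for c in "ACDEFGHIKL" if c != anc[j]]
                desc[j] = choices[rng.integers(len(choices))]
            desc = "".join(desc)
            total_mismatches += sum(a != d for a, d in zip(anc, desc))
            pairs.append(AlignedPair(f"g{i}", anc, desc))
        inferred = [ev for p in pairs for ev in infer_events(p)]
        assert len(inferred) == total_mismatches


class TestEnumerateTypes:
    def test_all_380_ordered_types(self):
        types = enumerate_types()
        assert len(types) == 380
        assert ("A", "D") in types and ("D", "A") in types
        assert all(x != y for x, y in types)
        assert types == sorted(types)


class TestEventsToTable:
    def _event(self, n_ctx, c_ctx):
        return SubstitutionEvent(
            pair_id="g", position=len(n_ctx) + 1,
            from_aa="S", to_aa="P", context_n=n_ctx, context_c=c_ctx,
        )

    def test_full_contexts_populate_both_sides(self):
        table = events_to_table([self._event("A" * 20, "C" * 20)], window=20)
        assert table.n_side == {"N": 1, "C": 1}

    def test_short_n_side_contributes_c_only(self):
        table = events_to_table([self._event("A" * 4, "C" * 20)], window=20)
        assert table.n_side == {"N": 0, "C": 1}

    def test_innermost_window_used(self):
        table = events_to_table([self._event("ACDEF", "GHIKL")], window=3)
        assert table.store["N"] == ["DEF"]
        assert table.store["C"] == ["GHI"]

    def test_zero_events_give_empty_table(self):
        table = events_to_table([], window=5)
        assert table.n_side == {"N": 0, "C": 0}

    def test_mixed_types_rejected(self):
        other = SubstitutionEvent(
            pair_id="g", position=2, from_aa="A", to_aa="G",
            context_n="C", context_c="D",
        )
        with pytest.raises(ValueError, match="mix"):
            events_to_table([self._event("A", "C"), other], window=1)


class TestFilterTypes:
    def _tables(self, n_n, n_c, sub_type=("A", "D")):
        table = events_to_table(
            [
                SubstitutionEvent(
                    pair_id="g", position=3, from_aa=sub_type[0], to_aa=sub_type[1],
                    context_n="AC", context_c="DE",
                )
            ],
            window=2,
        )
        # widen artificially by repeating the stored flanks
        table.store["N"] *= n_n
        table.store["C"] *= n_c
        return {sub_type: table}

    def test_max_side_rule(self):
        assert filter_types(self._tables(49, 10), min_events_per_side=50) == []
        assert filter_types(self._tables(50, 10), min_events_per_side=50) == [("A", "D")]

    def test_min_one_keeps_any_type_with_data(self):
        assert filter_types(self._tables(1, 0), min_events_per_side=1) == [("A", "D")]

    def test_min_zero_keeps_everything(self):
        tables = self._tables(0, 0)
        tables[("A", "D")].store["N"].clear()
        tables[("A", "D")].store["C"].clear()
        assert filter_types(tables, min_events_per_side=0) == [("A", "D")]


class TestEventTsvRoundTrip:
    def test_round_trip(self, tmp_path):
        events = [
            SubstitutionEvent(
                pair_id="g1", branch_label="b1", position=7,
                from_aa="S", to_aa="P", context_n="ACDEF", context_c="GHIKL",
            ),
            SubstitutionEvent(
                pair_id="g2", position=1, from_aa="A", to_aa="G",
                context_n="", context_c="WYV",
            ),
        ]
        path = tmp_path / "events.tsv"
        write_events_tsv(events, path)
        assert read_events_tsv(path) == events


class TestSubstitutionProfile:
    def test_unbiased_events_give_near_zero_profile(self):
        # events sampled uniformly from S occurrences: contexts match the
        # per-offset correction background up to sampling noise
        config = GeneratorConfig(n_sequences=300, length_min=80, length_max=120, rng_seed=3)
        records = gen_iid(config)
        rng = np.random.default_rng(4)
        events = []
        for rec in records:
            for pos, aa in enumerate(rec.sequence):
                if aa == "S" and rng.random() < 0.5:
                    events.append(
                        SubstitutionEvent(
                            pair_id=rec.id, position=pos + 1, from_aa="S", to_aa="P",
                            context_n=rec.sequence[max(0, pos - 5) : pos],
                            context_c=rec.sequence[pos + 1 : pos + 6],
                        )
                    )
        table = events_to_table(events, window=5)
        prof = substitution_profile(("S", "P"), table, reference_records=records)
        n = min(table.n_side.values())
        # KL of a 20-cell multinomial sample vs its own source distribution
        # concentrates near (k-1)/(2n ln 2); stay within a generous multiple
        bound = 5 * 19 / (2 * np.log(2) * n)
        for site in prof.sites.values():
            assert 0 <= site.total < bound

    def test_empty_table_rejected(self):
        config = GeneratorConfig(n_sequences=5, length_min=30, length_max=40, rng_seed=0)
        records = gen_iid(config)
        with pytest.raises(ValueError):
            substitution_profile(("S", "P"), events_to_table([], 3), reference_records=records)


class TestEventsInStructure:
    def test_filter_by_ancestral_track(self):
        events = [
            SubstitutionEvent(pair_id="g1", position=2, from_aa="A", to_aa="G",
                              context_n="C", context_c="D"),
            SubstitutionEvent(pair_id="g1", position=4, from_aa="L", to_aa="V",
                              context_n="C", context_c="D"),
        ]
        tracks = {"g1": "HHCC"}
        kept = events_in_structure(events, tracks, "H")
        assert [ev.position for ev in kept] == [2]

    def test_missing_track_rejected(self):
        ev = SubstitutionEvent(pair_id="g9", position=1, from_aa="A", to_aa="G",
                               context_n="", context_c="D")
        with pytest.raises(ValueError, match="g9"):
            events_in_structure([ev], {}, "H")
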