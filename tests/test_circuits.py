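"""Circuit coincidence, group accounting, Fisher's exact test, donut model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cstperf.atlas import Hemisphere, Structure, Subdivision
from cstperf.circuits import (
    DIRECTION_COLORS,
    build_donut,
    detect_circuits,
    discordant_strata,
    fisher_contrast,
    summarize_group,
)
from cstperf.errors import CompletenessError

ABBREV = {"cortex": "C", "striatum": "S", "thalamus": "T"}


def status_table(direction_fn, exam_id="e1"):
    """72-row status table with directions defined by direction_fn(st, sd, h, m)."""
    rows = []
    for m in ("a_cbf", "r_cbf"):
        for st in Structure:
            for sd in Subdivision:
                for h in Hemisphere:
                    rows.append(
                        {
                            "exam_id": exam_id,
                            "structure": st.value,
                            "subdivision": sd.value,
                            "hemisphere": h.value,
                            "measure": m,
                            "direction": direction_fn(st, sd, h, m),
                        }
                    )
    return pd.DataFrame(rows)


def oracle_patterns(status):
    """Independent enumeration over all strata and structure subsets."""
    expected = set()
    for m in ("a_cbf", "r_cbf"):
        for sd in Subdivision:
            for h in Hemisphere:
                block = status[
                    (status.measure == m)
                    & (status.subdivision == sd.value)
                    & (status.hemisphere == h.value)
                ]
                for direction in ("increase", "decrease"):
                    members = frozenset(
                        ABBREV[s] for s in block.loc[block.direction == direction, "structure"]
                    )
                    if len(members) >= 2:
                        expected.add((sd.value, h.value, m, direction, members))
    return expected


class TestDetectCircuits:
    def test_left_parietal_cst_decrease(self):
        def fn(st, sd, h, m):
            if (
                m == "a_cbf"
                and sd == Subdivision.PARIETAL
                and h == Hemisphere.LEFT
            ):
                return "decrease"
            return "normal"

        patterns = detect_circuits(status_table(fn))
        assert len(patterns) == 1
        row = patterns.iloc[0]
        assert row.label == "C-S-T"
        assert row.direction == "decrease"
        assert (row.subdivision, row.hemisphere, row.measure) == ("parietal", "left", "a_cbf")

    def test_all_normal_is_empty(self):
        patterns = detect_circuits(status_table(lambda *a: "normal"))
        assert patterns.empty

    def test_matches_subset_enumeration_oracle(self, rng):
        for _ in range(25):
            directions = rng.choice(
                ["increase", "decrease", "normal"], size=72, p=[0.25, 0.25, 0.5]
            )
            it = iter(directions)
            table = status_table(lambda st, sd, h, m: next(it))
            got = detect_circuits(table)
            got_set = {
                (r.subdivision, r.hemisphere, r.measure, r.direction, frozenset(r.structures))
                for r in got.itertuples()
            }
            assert got_set == oracle_patterns(table)

    def test_no_pattern_is_subset_of_another_in_same_stratum(self, rng):
        directions = rng.choice(["increase", "decrease", "normal"], size=72)
        it = iter(directions)
        got = detect_circuits(status_table(lambda st, sd, h, m: next(it)))
        for (_, _, _), block in got.groupby(["subdivision", "hemisphere", "measure"]):
            sets = [frozenset(s) for s in block.structures]
            for a, b in itertools.permutations(sets, 2):
                assert not a < b

    def test_incomplete_table_raises(self):
        table = status_table(lambda *a: "normal").iloc[:-1]
        with pytest.raises(CompletenessError):
            detect_circuits(table)

    def test_mixed_directions_are_discordant_not_patterns(self):
        def fn(st, sd, h, m):
            if m == "a_cbf" and sd == Subdivision.OCCIPITAL and h == Hemisphere.RIGHT:
                return "increase" if st == Structure.CORTEX else "decrease"
            return "normal"

        table = status_table(fn)
        patterns = detect_circuits(table)
        assert set(patterns.label) == {"S-T"}  # the concordant pair only
        disc = discordant_strata(table)
        assert len(disc) == 1
        assert disc.iloc[0].n_increase == 1 and disc.iloc[0].n_decrease == 2


class TestSummarizeGroup:
    def test_counts_match_bookkeeping(self, rng):
        tables = []
        for e in range(14):
            directions = rng.choice(
                ["increase", "decrease", "normal"], size=72, p=[0.1, 0.2, 0.7]
            )
            it = iter(directions)
            tables.append(status_table(lambda st, sd, h, m: next(it), exam_id=f"e{e}"))
        summary = summarize_group(tables, group_id="g3")
        assert summary.total_compartments == 504
        stacked = pd.concat(tables)
        for m in ("a_cbf", "r_cbf"):
            block = stacked[stacked.measure == m]
            assert summary.changed[m]["increase"] == (block.direction == "increase").sum()
            assert summary.changed[m]["decrease"] == (block.direction == "decrease").sum()
            assert summary.changed[m]["changed"] == (
                summary.changed[m]["increase"] + summary.changed[m]["decrease"]
            )
            for st in Structure:
                expected = (
                    (block.structure == st.value)
                    & block.direction.isin(["increase", "decrease"])
                ).sum()
                assert summary.by_structure[m][st.value] == expected
            n_patterns = sum(len(detect_circuits(t[t.measure.notna()])) * 0 for t in tables)
        # circuit counts equal per-exam detection totals
        for m in ("a_cbf", "r_cbf"):
            total = sum(
                (detect_circuits(t).measure == m).sum() for t in tables
            )
            assert sum(summary.circuit_counts[m].values()) == total

    def test_percent_rounding(self):
        table_changed = status_table(
            lambda st, sd, h, m: "increase" if m == "a_cbf" else "normal"
        )
        summary = summarize_group([table_changed], group_id="g")
        assert summary.total_compartments == 36
        assert summary.percent_changed("a_cbf") == 100
        assert summary.percent_changed("r_cbf") == 0
        assert summary.to_dict()["group_id"] == "g"


class TestFisherContrast:
    def test_degenerate_column_gives_p_one(self):
        for a, b in ((3, 5), (1, 9)):
            _, p = fisher_contrast([[0, a], [0, b]])
            assert p == 1.0

    def test_symmetric_table_gives_p_one(self):
        _, p = fisher_contrast([[4, 4], [4, 4]])
        assert p == 1.0

    def test_specific_table_against_scipy(self):
        odds, p = fisher_contrast([[5, 9], [0, 8]])
        odds_ref, p_ref = stats.fisher_exact([[5, 9], [0, 8]])
        assert p == pytest.approx(p_ref, rel=1e-12)
        assert np.isinf(odds) and np.isinf(odds_ref)

    def test_random_tables_against_scipy(self, rng):
        for _ in range(100):
            table = rng.integers(0, 10, size=(2, 2))
            if table.sum() == 0:
                continue
            odds, p = fisher_contrast(table)
            odds_ref, p_ref = stats.fisher_exact(table)
            assert p == pytest.approx(float(p_ref), rel=1e-10, abs=1e-14)
            if np.isfinite(odds_ref):
                assert odds == pytest.approx(float(odds_ref))

    @pytest.mark.parametrize("bad", [[[1, -1], [0, 2]], [[0.5, 1], [1, 1]]])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_contrast(bad)


class TestDonut:
    def test_all_normal_examination(self):
        chart = build_donut(status_table(lambda *a: "normal"), "a_cbf")
        assert len(chart.cells) == 36  # 18 per hemisphere
        assert set(chart.cells.values()) == {"green"}

    def test_single_increase_cell_position(self):
        def fn(st, sd, h, m):
            if (
                m == "a_cbf"
                and st == Structure.CORTEX
                and sd == Subdivision.PREFRONTAL
                and h == Hemisphere.LEFT
            ):
                return "increase"
            return "normal"

        chart = build_donut(status_table(fn), "a_cbf")
        reds = [cell for cell, color in chart.cells.items() if color == "red"]
        assert reds == [("left", "cortex", "prefrontal")]

    def test_cell_colors_rederived_from_status(self, rng):
        directions = rng.choice(["increase", "decrease", "normal"], size=72)
        it = iter(directions)
        table = status_table(lambda st, sd, h, m: next(it))
        chart = build_donut(table, "r_cbf")
        block = table[table.measure == "r_cbf"]
        for row in block.itertuples():
            expected = DIRECTION_COLORS[row.direction]
            assert chart.color(row.hemisphere, row.structure, row.subdivision) == expected
        # lossless round trip for the 3-color encoding
        frame = chart.to_frame()
        merged = frame.merge(
            block, on=["hemisphere", "structure", "subdivision"], how="left"
        )
        assert (merged.color == merged.direction.map(DIRECTION_COLORS)).all()

    def test_render_writes_figure(self, tmp_path):
        chart = build_donut(status_table(lambda *a: "normal"), "a_cbf", exam_id="x")
        out = tmp_path / "donut.png"
        chart.render(out)
        assert out.stat().st_size > 0
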