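"""Circuit-coincidence analysis, group summaries, Fisher contrasts, donuts.

A *circuit pattern* exists when at least two of the three structures
(cortex C, striatum S, thalamus T) of the same subdivision and hemisphere
change in the same direction on the same measure; the maximal such subset is
reported with its label (C-S-T, C-S, C-T or S-T). Coincidences with mixed
directions are not circuits and are reported separately as discordant
strata.

Group-level accounting counts changed compartments out of the group total
(36 per examination), and Fisher's exact test contrasts qualitative counts
between groups. The donut-chart model encodes each examination's statuses as
three rings (C, S, T outside to inside) of six sectors (clockwise from top:
prefrontal, rostral motor, caudal motor, parietal, occipital, temporal) per
hemisphere: red = increase, blue = decrease, green = normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .atlas import Hemisphere, Structure, Subdivision
from .errors import CompletenessError

STRUCTURE_ABBREV = {
    Structure.CORTEX: "C",
    Structure.STRIATUM: "S",
    Structure.THALAMUS: "T",
}
_ABBREV_ORDER = ("C", "S", "T")

DIRECTION_COLORS = {"increase": "red", "decrease": "blue", "normal": "green"}


def _check_complete(status: pd.DataFrame) -> None:
    expected = 2 * len(Structure) * len(Subdivision) * len(Hemisphere)
    seen = status[["structure", "subdivision", "hemisphere", "measure"]].drop_duplicates()
    if len(seen) != expected or len(status) != expected:
        raise CompletenessError(
            f"status table must contain exactly {expected} unique "
            f"(structure, subdivision, hemisphere, measure) rows, got {len(status)}"
        )


def detect_circuits(status: pd.DataFrame) -> pd.DataFrame:
    """Maximal same-direction structure subsets per stratum for one exam.

    A stratum is one (subdivision, hemisphere, measure). For each direction
    (increase/decrease) the set of structures with that status is emitted as
    one pattern when it has >= 2 members; proper subsets of an emitted
    pattern are never emitted separately.
    """
    _check_complete(status)
    patterns = []
    grouped = status.groupby(["subdivision", "hemisphere", "measure"], sort=False)
    for (subdivision, hemisphere, measure), block in grouped:
        for direction in ("increase", "decrease"):
            members = sorted(
                (
                    STRUCTURE_ABBREV[Structure(st)]
                    for st in block.loc[block.direction == direction, "structure"]
                ),
                key=_ABBREV_ORDER.index,
            )
            if len(members) >= 2:
                patterns.append(
                    {
                        "subdivision": subdivision,
                        "hemisphere": hemisphere,
                        "measure": measure,
                        "direction": direction,
                        "structures": tuple(members),
                        "label": "-".join(members),
                    }
                )
    columns = ["subdivision", "hemisphere", "measure", "direction", "structures", "label"]
    return pd.DataFrame(patterns, columns=columns)


def discordant_strata(status: pd.DataFrame) -> pd.DataFrame:
    """Strata where >= 2 structures changed but not all in one direction."""
    _check_complete(status)
    rows = []
    grouped = status.groupby(["subdivision", "hemisphere", "measure"], sort=False)
    for (subdivision, hemisphere, measure), block in grouped:
        changed = block[block.direction.isin(["increase", "decrease"])]
        if len(changed) >= 2 and changed.direction.nunique() > 1:
            rows.append(
                {
                    "subdivision": subdivision,
                    "hemisphere": hemisphere,
                    "measure": measure,
                    "n_increase": int((changed.direction == "increase").sum()),
                    "n_decrease": int((changed.direction == "decrease").sum()),
                }
            )
    columns = ["subdivision", "hemisphere", "measure", "n_increase", "n_decrease"]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class GroupSummary:
    """Changed-compartment and circuit-pattern accounting for one group."""

    group_id: str
    n_examinations: int
    total_compartments: int
    #: per measure: {"changed": int, "increase": int, "decrease": int}
    changed: dict[str, dict[str, int]]
    #: per measure: {structure value: count of changed compartments}
    by_structure: dict[str, dict[str, int]]
    #: per measure: {(label, direction): count across examinations}
    circuit_counts: dict[str, dict[tuple[str, str], int]]

    def fraction_changed(self, measure: str) -> float:
        return self.changed[measure]["changed"] / self.total_compartments

    def percent_changed(self, measure: str) -> int:
        """Integer-rounded percentage, as printed in reports."""
        return round(100 * self.fraction_changed(measure))

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "n_examinations": self.n_examinations,
            "total_compartments": self.total_compartments,
            "changed": self.changed,
            "by_structure": self.by_structure,
            "circuit_counts": {
                m: {f"{label}:{direction}": n for (label, direction), n in d.items()}
                for m, d in self.circuit_counts.items()
            },
        }


def summarize_group(statuses, group_id: str = "") -> GroupSummary:
    """Aggregate per-examination status tables into group-level counts."""
    statuses = list(statuses)
    if not statuses:
        raise ValueError("need at least one examination")
    for s in statuses:
        _check_complete(s)
    n_exam = len(statuses)
    total = 36 * n_exam

    changed: dict[str, dict[str, int]] = {}
    by_structure: dict[str, dict[str, int]] = {}
    circuit_counts: dict[str, dict[tuple[str, str], int]] = {}
    stacked = pd.concat(statuses, ignore_index=True)
    for measure, block in stacked.groupby("measure", sort=False):
        is_changed = block.direction.isin(["increase", "decrease"])
        changed[measure] = {
            "changed": int(is_changed.sum()),
            "increase": int((block.direction == "increase").sum()),
            "decrease": int((block.direction == "decrease").sum()),
        }
        by_structure[measure] = {
            st.value: int((is_changed & (block.structure == st.value)).sum())
            for st in Structure
        }
        circuit_counts[measure] = {}
    for status in statuses:
        for pattern in detect_circuits(status).itertuples(index=False):
            key = (pattern.label, pattern.direction)
            bucket = circuit_counts[pattern.measure]
            bucket[key] = bucket.get(key, 0) + 1
    return GroupSummary(group_id, n_exam, total, changed, by_structure, circuit_counts)


def fisher_contrast(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table; returns (odds ratio, p).

    The two-sided p-value sums the hypergeometric probabilities of all
    tables with the observed margins whose point probability does not exceed
    the observed table's. Computed in exact integer arithmetic. Odds ratio is
    the sample odds ratio a*d / (b*c) with 0/0 -> nan and x/0 -> inf.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
        raise ValueError("table entries must be nonnegative integers")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table has no observations")

    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc

    r1, c1 = a + b, a + c
    # weight(x) proportional to the hypergeometric pmf at x, same denominator
    weight_obs = comb(r1, a) * comb(n - r1, c1 - a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    numer = sum(
        w for x in range(lo, hi + 1)
        if (w := comb(r1, x) * comb(n - r1, c1 - x)) <= weight_obs
    )
    p = numer / comb(n, c1)
    return odds, float(min(p, 1.0))


@dataclass
class DonutChart:
    """Donut-chart model for one examination and one measure.

    ``cells`` maps (hemisphere, structure, subdivision) to a color string in
    {red, blue, green}; 18 cells per hemisphere. The model — not the rendered
    image — is the canonical representation.
    """

    exam_id: str
    measure: str
    cells: dict[tuple[str, str, str], str] = field(default_factory=dict)

    def color(self, hemisphere, structure, subdivision) -> str:
        hemisphere = getattr(hemisphere, "value", hemisphere)
        structure = getattr(structure, "value", structure)
        subdivision = getattr(subdivision, "value", subdivision)
        return self.cells[(hemisphere, structure, subdivision)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"hemisphere": h, "structure": st, "subdivision": sd, "color": color}
            for (h, st, sd), color in self.cells.items()
        ]
        return pd.DataFrame(rows)

    def render(self, path=None):
        """Render the two-hemisphere nested donut with matplotlib.

        Rings outside to inside: C, S, T. Sectors clockwise from the top in
        subdivision order. Returns the Figure; writes to ``path`` if given.
        """
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        color_hex = {"red": "#d62728", "blue": "#1f77b4", "green": "#2ca02c"}
        fig, axes = plt.subplots(1, 2, figsize=(8, 4), subplot_kw={"aspect": "equal"})
        radii = {Structure.CORTEX: 1.0, Structure.STRIATUM: 0.75, Structure.THALAMUS: 0.5}
        width = 0.25
        for ax, hemi in zip(axes, Hemisphere):
            for st in Structure:
                colors = [
                    color_hex[self.color(hemi, st, sd)] for sd in Subdivision
                ]
                ax.pie(
                    [1] * len(Subdivision),
                    radius=radii[st],
                    colors=colors,
                    startangle=90,
                    counterclock=False,
                    wedgeprops={"width": width, "edgecolor": "white"},
                )
            ax.set_title(f"{hemi.value} ({self.measure})")
        fig.suptitle(f"exam {self.exam_id}")
        if path is not None:
            fig.savefig(str(path), bbox_inches="tight")
            plt.close(fig)
        return fig


def build_donut(status: pd.DataFrame, measure: str, exam_id: str | None = None) -> DonutChart:
    """Derive the donut model for one examination from its status table."""
    _check_complete(status)
    block = status[status.measure == measure]
    exam_id = exam_id or (str(block.exam_id.iloc[0]) if "exam_id" in block else "")
    cells = {}
    for row in block.itertuples(index=False):
        direction = row.direction if row.direction in DIRECTION_COLORS else "normal"
        cells[(row.hemisphere, row.structure, row.subdivision)] = DIRECTION_COLORS[direction]
    return DonutChart(exam_id=exam_id, measure=measure, cells=cells)
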