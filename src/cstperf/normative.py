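"""Single-case normative comparison of compartment CBF values.

Each patient examination contributes one A-CBF and one R-CBF value per
compartment. These are compared against a control cohort matched on scanner
and sedation exactly, and on age within a stepwise-widening window. The test
is the single-case t-test (Crawford & Howell form): a pooled-variance
independent two-sample t-test in which the patient sample has n1 = 1,

    t = (x - mean(c)) / (sd(c) * sqrt(1 + 1/n)),  df = n - 1,

with a two-sided p-value. A compartment is classified *increase* when
p < alpha and the patient value exceeds the control mean, *decrease* when
p < alpha and it is below, and *normal* otherwise. No multiple-comparison
correction is applied by default (an optional Benjamini-Hochberg flag is
available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cbf import CbfTable, ExamMetadata
from .errors import (
    DegenerateCohortError,
    InsufficientControlsError,
    InsufficientDataError,
)

MEASURES = ("a_cbf", "r_cbf")
KEY_COLUMNS = ["structure", "subdivision", "hemisphere"]


@dataclass
class MatchPolicy:
    """Control-matching policy.

    Scanner and sedation must match exactly. The age window starts at
    ``age_window_fraction`` of the patient's age and doubles until the
    minimum cohort size is reached, capped at the whole (scanner/sedation
    filtered) pool. ``alpha`` is the significance level used downstream.
    """

    min_cohort: int = 10
    age_window_fraction: float = 0.25
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "MatchPolicy":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in ("min_cohort", "age_window_fraction", "alpha")}
        return cls(**{k: v for k, v in data.items() if k in known})


def match_controls(
    patient: ExamMetadata | pd.Series,
    pool: pd.DataFrame,
    policy: MatchPolicy | None = None,
) -> pd.DataFrame:
    """Select matched controls from ``pool`` (one row per control exam).

    ``pool`` needs columns subject_id, age_months, scanner, sedation.
    Returns the selected rows; deterministic given the pool.
    """
    policy = policy or MatchPolicy()
    age = float(patient["age_months"] if isinstance(patient, pd.Series) else patient.age_months)
    scanner = patient["scanner"] if isinstance(patient, pd.Series) else patient.scanner
    sedation = bool(patient["sedation"] if isinstance(patient, pd.Series) else patient.sedation)

    hard = pool[(pool.scanner == scanner) & (pool.sedation.astype(bool) == sedation)]
    if len(hard) < policy.min_cohort:
        raise InsufficientControlsError(
            f"only {len(hard)} controls share scanner={scanner!r}, sedation={sedation}; "
            f"need {policy.min_cohort}"
        )
    gaps = (hard.age_months - age).abs()
    window = policy.age_window_fraction * age
    while True:
        selected = hard[gaps <= window]
        if len(selected) >= policy.min_cohort:
            return selected
        if window >= gaps.max():
            # window already covers the whole pool; len(hard) >= min_cohort
            return hard
        window = max(window * 2, 1e-9)


def single_case_t(patient_value: float, control_values) -> tuple[float, float, int]:
    """Single-case vs cohort t-test (pooled two-sample test with n1 = 1).

    Returns (t, two-sided p, df). Requires at least 3 controls with nonzero
    variance.
    """
    controls = np.asarray(control_values, dtype=float)
    n = controls.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 control values, got {n}")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise DegenerateCohortError("control values have zero variance")
    t = (float(patient_value) - controls.mean()) / (sd * np.sqrt(1 + 1 / n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def cohort_frame(tables) -> pd.DataFrame:
    """Stack control :class:`CbfTable` objects into one long frame."""
    return pd.concat([t.to_long() for t in tables], ignore_index=True)


def classify_compartments(
    patient: CbfTable,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    *,
    fdr: bool = False,
) -> pd.DataFrame:
    """Classify all 36 compartments x {A-CBF, R-CBF} against the cohort.

    ``cohort`` is a long frame (one row per control exam per compartment)
    with the key columns plus ``a_cbf`` and ``r_cbf``. Returns a 72-row
    status frame. Compartments whose test cannot be computed are flagged in
    the ``error`` column and classified ``normal`` is NOT assumed — their
    direction is left empty.

    With ``fdr=True`` p-values are Benjamini-Hochberg adjusted before the
    alpha cut (off by default).
    """
    stats_by_key = (
        cohort.groupby(KEY_COLUMNS, sort=False)
        .agg(
            a_mean=("a_cbf", "mean"), a_sd=("a_cbf", lambda s: s.std(ddof=1)),
            r_mean=("r_cbf", "mean"), r_sd=("r_cbf", lambda s: s.std(ddof=1)),
            n=("a_cbf", "size"),
        )
        .reset_index()
    )
    merged = patient.frame.merge(stats_by_key, on=KEY_COLUMNS, how="left", validate="1:1")

    rows = []
    for measure, mean_col, sd_col in (("a_cbf", "a_mean", "a_sd"), ("r_cbf", "r_mean", "r_sd")):
        block = pd.DataFrame(
            {
                "exam_id": patient.meta.exam_id,
                "structure": merged.structure,
                "subdivision": merged.subdivision,
                "hemisphere": merged.hemisphere,
                "measure": measure,
                "patient_value": merged[measure].astype(float),
                "control_mean": merged[mean_col].astype(float),
                "control_sd": merged[sd_col].astype(float),
                "n_controls": merged.n.fillna(0).astype(int),
            }
        )
        rows.append(block)
    status = pd.concat(rows, ignore_index=True)

    n = status.n_controls.to_numpy(dtype=float)
    sd = status.control_sd.to_numpy()
    usable = (n >= 3) & (sd > 0)
    t = np.full(len(status), np.nan)
    p = np.full(len(status), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t[usable] = (
            status.patient_value.to_numpy()[usable] - status.control_mean.to_numpy()[usable]
        ) / (sd[usable] * np.sqrt(1 + 1 / n[usable]))
        p[usable] = 2 * stats.t.sf(np.abs(t[usable]), n[usable] - 1)
    status["t"] = t
    status["p"] = p
    if fdr:
        status["p_adjusted"] = _benjamini_hochberg(p)
        p_for_cut = status["p_adjusted"].to_numpy()
    else:
        p_for_cut = p

    direction = np.where(
        usable & (p_for_cut < alpha),
        np.where(status.patient_value > status.control_mean, "increase", "decrease"),
        "normal",
    )
    status["direction"] = direction
    status["error"] = ""
    status.loc[~usable & (n < 3), "error"] = "insufficient controls"
    status.loc[~usable & (n >= 3) & ~(sd > 0), "error"] = "degenerate cohort (sd=0)"
    status.loc[status.error != "", "direction"] = ""
    return status


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    m = ok.sum()
    if m:
        order = np.argsort(p[ok])
        ranked = p[ok][order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(adj, 1.0)
        out[ok] = vals
    return out


def write_status(status: pd.DataFrame, path) -> None:
    status.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_status(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["error"] = frame.get("error", pd.Series([""] * len(frame))).fillna("")
    return frame
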