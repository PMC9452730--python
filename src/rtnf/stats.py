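"""Learning and clinical statistics.

Centrepiece is the exact one-sample Wilcoxon signed-rank test against zero:
for the small samples this protocol produces (n = 7 patients) the p-value is
computed from the exact null distribution of the positive-rank sum over all
2^n equiprobable sign assignments of the observed absolute ranks — no normal
approximation. Zero differences are dropped before ranking and ties receive
mid-ranks (the enumeration stays conditional on the observed ranks).

Also here: the one-sample z-test against 50% accuracy, per-participant
learning deltas (Run16-Run1, (Run15+16-Run1-2)/2, Day4-Day1 means), OLS
learning slopes, clinical change scores between the three evaluations
(CE1 before, CE2 after, CE3 ten days later) and the recruitment screens on
the BDI-II / Okasha instruments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

RUNS_PER_DAY = 4
N_RUNS = 16
EXACT_WILCOXON_MAX_N = 25

BDI_MAX = 63
HDRS_MAX = 52
BDI_SUICIDE_ITEM_MAX = 3
OKASHA_MAX = 12


@dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p_value: float
    sidedness: str          # "two-tailed" | "one-tailed-greater" | "one-tailed-less"
    n: int
    method: str
    note: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank

def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ = sum of positive ranks.

    Ranks may be mid-ranks (k + 0.5); doubling makes them integers, so the
    distribution is built by integer convolution — equivalent to enumerating
    all 2^n sign assignments. Returns (support of W+, counts).
    """
    doubled = np.rint(2 * ranks).astype(int)
    if not np.allclose(doubled, 2 * ranks, atol=1e-9):
        raise ValueError("ranks must be integers or half-integers")
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    keep = counts > 0
    return support[keep], counts[keep]


def wilcoxon_signed_rank_exact(
    differences: np.ndarray, sidedness: str = "two-tailed"
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of the differences against zero.

    Exact for n <= 25 (full sign-assignment null distribution); larger
    samples fall back to the normal approximation with tie correction.
    The reported statistic is W+ (sum of ranks of positive differences).
    """
    d = np.asarray(differences, float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: the test is undefined "
                         "(no nonzero differences to rank)")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())

    if n <= EXACT_WILCOXON_MAX_N:
        support, counts = _signed_rank_distribution(ranks)
        norm = counts.sum()  # == 2^n
        p_le = counts[support <= w_plus + 1e-9].sum() / norm
        p_ge = counts[support >= w_plus - 1e-9].sum() / norm
        method = "wilcoxon-signed-rank-exact"
    else:
        mu = total / 2.0
        # variance of W+ with mid-ranks: sum(rank^2)/4
        sd = np.sqrt(np.sum(ranks**2) / 4.0)
        z = (w_plus - mu) / sd
        p_le = sps.norm.cdf(z)
        p_ge = sps.norm.sf(z)
        method = "wilcoxon-signed-rank-normal-approx"

    if sidedness == "two-tailed":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif sidedness == "one-tailed-greater":
        p = p_ge
    elif sidedness == "one-tailed-less":
        p = p_le
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return TestResult(w_plus, float(p), sidedness, n, method)


def ztest_one_sample(
    values: np.ndarray | None = None,
    *,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    null_value: float = 50.0,
    sidedness: str = "one-tailed-greater",
) -> TestResult:
    """One-sample z-test against a fixed null value.

    Accepts either raw values or the (mean, sd, n) summary; sd uses ddof=1.
    z = (mean - null) / (sd / sqrt(n)), p from the standard normal.
    """
    if values is not None:
        values = np.asarray(values, float)
        n = len(values)
        if n < 2:
            raise ValueError("need at least 2 values")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
    if mean is None or sd is None or n is None:
        raise ValueError("provide either values or mean, sd and n")
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    z = (mean - null_value) / (sd / np.sqrt(n))
    if sidedness == "two-tailed":
        p = 2.0 * sps.norm.sf(abs(z))
    elif sidedness == "one-tailed-greater":
        p = sps.norm.sf(z)
    elif sidedness == "one-tailed-less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return TestResult(float(z), float(p), sidedness, int(n), "one-sample-z")


# ---------------------------------------------------------------------------
# accuracy table and learning statistics

def day_means(table: pd.DataFrame, runs_per_day: int = RUNS_PER_DAY) -> pd.DataFrame:
    """Per-day mean accuracy from a participants x runs table (columns
    ``run1``..``runN`` in session order)."""
    run_cols = [c for c in table.columns if c.startswith("run")]
    n_days = len(run_cols) // runs_per_day
    out = {}
    for d in range(n_days):
        cols = run_cols[d * runs_per_day:(d + 1) * runs_per_day]
        out[f"day{d + 1}"] = table[cols].mean(axis=1)
    return pd.DataFrame(out, index=table.index)


def learning_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant learning deltas from a complete 16-run accuracy table.

    run16_minus_run1:   last run minus first run
    last2_minus_first2: (run15 + run16 - run1 - run2) / 2
    day4_minus_day1:    mean of day-4 runs minus mean of day-1 runs
    """
    run_cols = [f"run{i}" for i in range(1, N_RUNS + 1)]
    missing = [c for c in run_cols if c not in table.columns]
    if missing:
        raise ValueError(f"accuracy table is missing runs: {missing}")
    if table[run_cols].isna().any().any():
        raise ValueError("accuracy table contains missing values")
    days = day_means(table)
    return pd.DataFrame(
        {
            "run16_minus_run1": table["run16"] - table["run1"],
            "last2_minus_first2": (
                table["run15"] + table["run16"] - table["run1"] - table["run2"]
            ) / 2.0,
            "day4_minus_day1": days["day4"] - days["day1"],
        },
        index=table.index,
    )


def learning_slope(accuracies: np.ndarray, unit: str = "run",
                   runs_per_day: int = RUNS_PER_DAY) -> float:
    """OLS slope of accuracy against the 1-based run or session index."""
    acc = np.asarray(accuracies, float)
    if unit == "session":
        n_days = len(acc) // runs_per_day
        acc = acc[: n_days * runs_per_day].reshape(n_days, runs_per_day).mean(axis=1)
    elif unit != "run":
        raise ValueError(f"unknown unit {unit!r}")
    if len(acc) < 2:
        raise ValueError("need at least 2 points for a slope")
    x = np.arange(1, len(acc) + 1, dtype=float)
    return float(np.polyfit(x, acc, 1)[0])


# ---------------------------------------------------------------------------
# clinical records

@dataclass
class ClinicalRecord:
    """Depression scores of one participant at the three evaluations:
    CE1 (day before training), CE2 (day after), CE3 (10 days later)."""

    participant: str
    bdi: tuple[int | None, int | None, int | None]    # CE1, CE2, CE3
    hdrs: tuple[int | None, int | None, int | None]
    bdi_suicide_item: int = 0
    okasha: int = 0

    def __post_init__(self) -> None:
        for v in self.bdi:
            if v is not None and not 0 <= v <= BDI_MAX:
                raise ValueError(f"BDI-II score {v} outside [0, {BDI_MAX}]")
        for v in self.hdrs:
            if v is not None and not 0 <= v <= HDRS_MAX:
                raise ValueError(f"HDRS score {v} outside [0, {HDRS_MAX}]")


def clinical_deltas(
    records: list[ClinicalRecord],
) -> tuple[pd.DataFrame, dict[str, TestResult | None]]:
    """Improvement scores between evaluations and group Wilcoxon tests.

    Deltas are earlier minus later score, so a positive value is an
    improvement (the score went down). Columns: ``<instr>_ce2_ce1``,
    ``<instr>_ce3_ce2``, ``<instr>_ce3_ce1``. Participants with a missing
    timepoint are excluded from that instrument's rows (with a warning).
    Tests that would see only zero differences (or a single participant) are
    reported as None with an explanatory note.
    """
    import warnings

    rows = {}
    for rec in records:
        row = {}
        for instr, scores in (("bdi", rec.bdi), ("hdrs", rec.hdrs)):
            if any(s is None for s in scores):
                warnings.warn(
                    f"participant {rec.participant}: missing {instr.upper()} "
                    "timepoint, excluded from that instrument"
                )
                continue
            ce1, ce2, ce3 = scores
            row[f"{instr}_ce2_ce1"] = ce1 - ce2
            row[f"{instr}_ce3_ce2"] = ce2 - ce3
            row[f"{instr}_ce3_ce1"] = ce1 - ce3
        rows[rec.participant] = row
    deltas = pd.DataFrame.from_dict(rows, orient="index")

    tests: dict[str, TestResult | None] = {}
    for col in deltas.columns:
        d = deltas[col].dropna().to_numpy()
        if len(d) < 2:
            tests[col] = None
            continue
        try:
            tests[col] = wilcoxon_signed_rank_exact(d)
        except ValueError:
            tests[col] = None  # all-zero differences: no change to test
    return deltas, tests


class Eligibility(str, enum.Enum):
    ELIGIBLE = "eligible"
    EXCLUDED_SEVERITY = "excluded_severity"
    EXCLUDED_RISK = "excluded_risk"


def screen_eligibility(bdi_total: int, bdi_suicide_item: int,
                       okasha: int) -> Eligibility:
    """Recruitment screen: mild-to-moderate severity band, no suicidality.

    Eligible iff 10 <= BDI-II <= 29 and suicide item < 2 and Okasha < 5.
    Risk exclusion takes precedence over severity when both apply.
    """
    if not 0 <= bdi_total <= BDI_MAX:
        raise ValueError(f"BDI-II total {bdi_total} outside [0, {BDI_MAX}]")
    if not 0 <= bdi_suicide_item <= BDI_SUICIDE_ITEM_MAX:
        raise ValueError("BDI-II suicide item outside instrument range")
    if not 0 <= okasha <= OKASHA_MAX:
        raise ValueError("Okasha score outside instrument range")
    if bdi_suicide_item >= 2 or okasha >= 5:
        return Eligibility.EXCLUDED_RISK
    if not 10 <= bdi_total <= 29:
        return Eligibility.EXCLUDED_SEVERITY
    return Eligibility.ELIGIBLE


class SeverityBand(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


def severity_band(bdi_total: int) -> SeverityBand:
    """BDI-II severity banding: <10 none, 10-19 mild, 20-29 moderate, >29 severe."""
    if not 0 <= bdi_total <= BDI_MAX:
        raise ValueError(f"BDI-II total {bdi_total} outside [0, {BDI_MAX}]")
    if bdi_total < 10:
        return SeverityBand.NONE
    if bdi_total <= 19:
        return SeverityBand.MILD
    if bdi_total <= 29:
        return SeverityBand.MODERATE
    return SeverityBand.SEVERE


# ---------------------------------------------------------------------------
# report formatting

def format_test_line(label: str, d: np.ndarray, result: TestResult | None) -> str:
    """Results-style summary line: median, range and the Wilcoxon p."""
    d = np.asarray(d, float)
    med = float(np.median(d))
    line = (f"{label} Median = {med:g}; Range = {d.min():g} to {d.max():g}; "
            f"Wilcoxon Test (0), 2-tailed p = ")
    if result is None:
        return line + "n/a (no nonzero differences)"
    line += f"{result.p_value:.3g}"
    if np.all(d > 0) or np.all(d < 0):
        line += (f"  [note: all {result.n} differences share one sign; the exact "
                 f"two-tailed floor at this n is {2.0 / 2**result.n:.4g}]")
    return line
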