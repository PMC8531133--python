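"""Table I/O, descriptive statistics, and report writing.

CSV dialect everywhere: UTF-8, comma-separated, header row, '.' decimal.
Descriptives follow the figures' convention — cell medians with the unscaled
median absolute deviation — and post-assessment choices are reported as counts
with integer percentages (round half away from zero, which reproduces every
printed share).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RATINGS_COLUMNS",
    "read_ratings_csv",
    "write_ratings_csv",
    "read_choices_csv",
    "write_choices_csv",
    "load_osf_ratings",
    "CellDescriptive",
    "describe_cells",
    "ChoiceSummary",
    "choice_summary",
    "round_half_away",
    "write_summary",
]

RATINGS_COLUMNS = [
    "participant_id", "group", "fear_score", "fear_z",
    "event_id", "event_type", "rating_type", "rating_raw",
]
_REQUIRED = [c for c in RATINGS_COLUMNS if c != "rating_type"]
CHOICES_COLUMNS = ["participant_id", "group", "choice"]


def validate_ratings(df: pd.DataFrame, require_rating_type: bool = False) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"ratings table missing required columns: {missing}")
    if require_rating_type and "rating_type" not in df.columns:
        raise ValueError("ratings table missing required column: ['rating_type']")

    bad = df.index[~df["rating_raw"].between(0, 100) | df["rating_raw"].isna()]
    if len(bad):
        raise ValueError(
            f"rating_raw outside [0, 100] (or missing) at rows {bad.tolist()[:10]}"
        )

    types_per_event = df.groupby("event_id")["event_type"].nunique()
    inconsistent = types_per_event.index[types_per_event > 1].tolist()
    if inconsistent:
        raise ValueError(f"event_type inconsistent across rows for events {inconsistent}")

    keys = ["participant_id", "event_id"] + (
        ["rating_type"] if "rating_type" in df.columns else []
    )
    dup = df[df.duplicated(keys, keep=False)]
    if len(dup):
        raise ValueError(
            f"duplicate (participant, event{', rating_type' if len(keys) == 3 else ''}) "
            f"rows at index {dup.index.tolist()[:10]}"
        )
    return df


def read_ratings_csv(path) -> pd.DataFrame:
    """Read and validate a long-format ratings table."""
    df = pd.read_csv(path)
    return validate_ratings(df)


def write_ratings_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in RATINGS_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in RATINGS_COLUMNS
    ]
    df[cols].to_csv(path, index=False)


def read_choices_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CHOICES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choices table missing columns: {missing}")
    bad = df.index[~df["choice"].isin(["feelings", "danger"])].tolist()
    if bad:
        raise ValueError(f"choice must be 'feelings' or 'danger'; bad rows {bad[:10]}")
    if df["participant_id"].duplicated().any():
        raise ValueError("one row per participant expected in the choices table")
    return df


def write_choices_csv(df: pd.DataFrame, path) -> None:
    df[CHOICES_COLUMNS].to_csv(path, index=False)


def load_osf_ratings(path) -> pd.DataFrame:
    """Load a locally downloaded copy of the study's deposited ratings table.

    Expects the deposit's long format mapped onto this package's schema (see
    README); raises FileNotFoundError with download instructions otherwise.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"{p}: the deposited dataset is not bundled; download it from the OSF "
            "project and export the ratings as CSV with columns "
            f"{RATINGS_COLUMNS} before calling load_osf_ratings"
        )
    return read_ratings_csv(p)


# --------------------------------------------------------------------------
# Descriptives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellDescriptive:
    cell: tuple
    median: float
    mad: float  # unscaled median absolute deviation
    n: int


def describe_cells(ratings: pd.DataFrame) -> list[CellDescriptive]:
    """Median and unscaled MAD of raw ratings per design cell
    (group x event [x rating_type])."""
    keys = ["group", "event_id"] + (
        ["rating_type"] if "rating_type" in ratings.columns else []
    )
    out = []
    for cell, sub in ratings.groupby(keys, sort=True):
        x = sub["rating_raw"].to_numpy(dtype=float)
        med = float(np.median(x))
        out.append(CellDescriptive(tuple(cell), med, float(np.median(np.abs(x - med))), len(x)))
    return out


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (89.5 -> 90)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class ChoiceSummary:
    group: str
    n_feelings: int
    n_total: int
    pct_feelings: int


def choice_summary(choices: pd.DataFrame, by_group: bool = True) -> list[ChoiceSummary]:
    """Counts and integer percentages of the 'feelings' post-assessment choice."""
    if by_group:
        groups = [(g, sub) for g, sub in choices.groupby("group", sort=True)]
    else:
        groups = [("all", choices)]
    out = []
    for g, sub in groups:
        k = int((sub["choice"] == "feelings").sum())
        n = len(sub)
        out.append(ChoiceSummary(str(g), k, n, round_half_away(100.0 * k / n)))
    return out


# --------------------------------------------------------------------------
# Report writing
# --------------------------------------------------------------------------

def write_summary(psup_results, descriptives, path, contrasts=()) -> None:
    """Write the analysis summary: a CSV of PSup posteriors (median, 95% HDI,
    % > 0.5 — the figure-annotation triple), a CSV of cell descriptives, and a
    human-readable text report. ``path`` is a directory."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "comparison": p.label,
            "median": p.median,
            "hdi_low": p.hdi_low,
            "hdi_high": p.hdi_high,
            "prop_gt_half": p.prop_gt_half,
        }
        for p in psup_results
    ]
    psup_df = pd.DataFrame(
        rows, columns=["comparison", "median", "hdi_low", "hdi_high", "prop_gt_half"]
    )
    psup_df.to_csv(d / "psup_summary.csv", index=False)

    if contrasts:
        pd.DataFrame(
            [
                {
                    "contrast": c.label,
                    "median": c.median,
                    "hdi_low": c.hdi_low,
                    "hdi_high": c.hdi_high,
                    "prop_gt_zero": c.prop_gt_zero,
                }
                for c in contrasts
            ]
        ).to_csv(d / "contrast_summary.csv", index=False)

    desc_df = pd.DataFrame(
        [
            {"cell": " / ".join(map(str, c.cell)), "median": c.median, "mad": c.mad, "n": c.n}
            for c in descriptives
        ],
        columns=["cell", "median", "mad", "n"],
    )
    desc_df.to_csv(d / "descriptives.csv", index=False)

    lines = ["Probability-of-superiority summary", "=" * 36, ""]
    for p in psup_results:
        lines.append(
            f"{p.label or 'comparison'}: median PSup {p.median:.2f} "
            f"[95% HDI {p.hdi_low:.2f}, {p.hdi_high:.2f}], {p.prop_gt_half:.0f}% > 0.5"
        )
    for c in contrasts:
        lines.append(
            f"{c.label or 'contrast'}: median {c.median:.2f} "
            f"[95% HDI {c.hdi_low:.2f}, {c.hdi_high:.2f}], {c.prop_gt_zero:.0f}% > 0"
        )
    if descriptives:
        lines += ["", "Cell descriptives (median, MAD, n)", "-" * 34]
        for c in descriptives:
            lines.append(f"{' / '.join(map(str, c.cell))}: {c.median:.1f} ({c.mad:.1f}), n={c.n}")
    (d / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
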