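"""Deterministic data preparation for the beta-regression pipeline.

Covers the 0-100 -> 0-1 rescale, the boundary "squish" transformation
``(y (N - 1) + 0.5) / N`` that pulls exact 0s and 1s strictly inside the unit
interval so the beta likelihood is defined, doubling of 0-50 bet counts to the
0-100 probability scale, covariate z-scoring, and the multiplicative
data-quality tier scores used for inclusion decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "to_unit",
    "squish",
    "unsquish",
    "bets_to_probability",
    "zscore",
    "TierScore",
    "assign_tier",
    "score_checks",
    "DEFAULT_CHECK_REGISTRY",
    "prepare_ratings",
    "SQUISHED_COL",
]

#: Column added by :func:`prepare_ratings`; its presence marks a table as
#: already squished, guarding against accidental double application.
SQUISHED_COL = "rating_squished"


def to_unit(rating_raw):
    """Map 0-100 probability ratings onto [0, 1] by dividing by 100."""
    x = np.asarray(rating_raw, dtype=float)
    if np.any((x < 0) | (x > 100)) or np.any(~np.isfinite(x)):
        bad = np.atleast_1d(x)[~(np.isfinite(np.atleast_1d(x)) & (np.atleast_1d(x) >= 0) & (np.atleast_1d(x) <= 100))]
        raise ValueError(f"ratings must lie in [0, 100]; offending values: {bad[:5]}")
    out = x / 100.0
    return float(out) if np.isscalar(rating_raw) else out


def squish(values, n_obs: int):
    """Compress unit-interval values strictly inside (0, 1).

    Applies ``(v * (N - 1) + 0.5) / N`` elementwise with N = ``n_obs``, the
    number of observations in the dataset being transformed. The map is
    strictly increasing, fixes 0.5, and sends 0 -> 0.5/N, 1 -> 1 - 0.5/N.
    """
    if n_obs < 1:
        raise ValueError(f"n_obs must be >= 1, got {n_obs}")
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)) or np.any(~np.isfinite(v)):
        raise ValueError("values must lie in [0, 1]; call to_unit first")
    out = (v * (n_obs - 1) + 0.5) / n_obs
    return float(out) if np.isscalar(values) else out


def unsquish(values, n_obs: int):
    """Invert :func:`squish`: ``(v * N - 0.5) / (N - 1)`` (N = 1 maps all to 0.5)."""
    if n_obs < 1:
        raise ValueError(f"n_obs must be >= 1, got {n_obs}")
    v = np.asarray(values, dtype=float)
    if n_obs == 1:
        raise ValueError("squish with N = 1 is constant (0.5) and not invertible")
    out = (v * n_obs - 0.5) / (n_obs - 1)
    return float(out) if np.isscalar(values) else out


def bets_to_probability(count):
    """Double 0-50 patient-count bets to the 0-100 probability scale."""
    x = np.asarray(count)
    xf = x.astype(float)
    if np.any(~np.isfinite(xf)) or np.any(xf != np.round(xf)):
        raise ValueError(f"bet counts must be integers, got {x}")
    if np.any((xf < 0) | (xf > 50)):
        raise ValueError(f"bet counts must lie in [0, 50], got {x}")
    out = 2 * xf
    return float(out) if np.isscalar(count) else out


def zscore(scores) -> np.ndarray:
    """Standardize to sample mean 0 and sample SD 1 (ddof=1)."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zscore needs a 1-d vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zscore undefined for zero-variance input")
    return (x - x.mean()) / sd


# --- inclusion tiers ---------------------------------------------------------

#: Default quality-check registry: multipliers applied when a check fails.
#: The base credit is 2 (highly reliable); a minor concern halves it; hard
#: fails zero it out. Override any entry via a config mapping.
DEFAULT_CHECK_REGISTRY: dict[str, float] = {
    "attention_check": 0.5,
    "comprehension_check": 0.5,
    "age_birthyear_consistency": 0.5,
    "country_consistency": 0.0,
    "incomplete_responses": 0.0,
    "duplicate_ip": 0.0,
}

BASE_SCORE = 2.0


@dataclass(frozen=True)
class TierScore:
    """Multiplicative quality score and the inclusion tier it implies."""

    participant_id: str
    check_scores: tuple[float, ...]
    tier_value: float
    tier: int  # 2 = main analyses, 1 = sensitivity only, 0 = excluded


def assign_tier(check_scores, participant_id: str = "") -> TierScore:
    """Combine per-check multipliers into an inclusion tier.

    tier_value = product of the multipliers; tier 2 if >= 2 (highly
    reliable), tier 1 if >= 1 (sensitivity analyses only), else excluded.
    """
    scores = tuple(float(s) for s in check_scores)
    if not scores:
        raise ValueError("check_scores must be nonempty")
    if any(s < 0 for s in scores):
        raise ValueError(f"check multipliers must be >= 0, got {scores}")
    value = float(np.prod(scores))
    tier = 2 if value >= 2 else (1 if value >= 1 else 0)
    return TierScore(participant_id, scores, value, tier)


def score_checks(
    failed_checks,
    participant_id: str = "",
    registry: dict[str, float] | None = None,
) -> TierScore:
    """Turn a list of failed check names into a TierScore via the registry."""
    reg = DEFAULT_CHECK_REGISTRY if registry is None else registry
    unknown = [c for c in failed_checks if c not in reg]
    if unknown:
        raise KeyError(f"unknown quality checks: {unknown}; registry has {sorted(reg)}")
    multipliers = [BASE_SCORE] + [reg[c] for c in failed_checks]
    return assign_tier(multipliers, participant_id)


# --- pipeline helper ---------------------------------------------------------

def prepare_ratings(ratings: pd.DataFrame, n_scope: str = "pooled") -> pd.DataFrame:
    """Rescale and squish a ratings table for model fitting.

    Adds a ``rating_squished`` column holding ``squish(rating_raw / 100, N)``.
    ``n_scope`` sets the N convention: ``"pooled"`` (default) uses all rows of
    the table; ``"per_event"`` squishes each event with its own row count (a
    sensitivity option). Raises if the table was already squished: the
    transformation is not idempotent and must be applied exactly once.
    """
    if SQUISHED_COL in ratings.columns:
        raise ValueError(
            f"table already contains {SQUISHED_COL!r}; squish must be applied exactly once"
        )
    if ratings["rating_raw"].isna().any():
        missing = ratings.index[ratings["rating_raw"].isna()].tolist()
        raise ValueError(f"missing ratings are not imputed; NaN at rows {missing[:5]}")
    out = ratings.copy()
    unit = to_unit(out["rating_raw"].to_numpy())
    if n_scope == "pooled":
        out[SQUISHED_COL] = squish(unit, len(out))
    elif n_scope == "per_event":
        vals = np.empty(len(out))
        for _, idx in out.groupby("event_id").indices.items():
            vals[idx] = squish(unit[idx], len(idx))
        out[SQUISHED_COL] = vals
    else:
        raise ValueError(f"n_scope must be 'pooled' or 'per_event', got {n_scope!r}")
    return out
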