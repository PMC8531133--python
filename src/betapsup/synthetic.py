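"""Synthetic rating experiments with the generative structure the analysis assumes.

The generator mirrors the measurement model used downstream: each participant
carries a latent logit-scale intercept, each (group, event, rating-type) cell
has a logit-scale mean shift, a standardized fear-questionnaire score enters as
a linear covariate, and observed 0-100 probability ratings are beta-distributed
around the cell mean with a common precision ``phi``.

Draw order is fixed and documented so a single integer seed reproduces every
table byte-for-byte: (1) fear scores, group A then group B; (2) participant
intercepts in participant order; (3) ratings in row order (participant, event,
rating type).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "EventSpec",
    "SimConfig",
    "DEFAULT_EVENTS",
    "simulate_ratings",
    "simulate_questionnaire_scores",
    "simulate_choices",
]


@dataclass(frozen=True)
class EventSpec:
    """One within-subject event: a label plus its objective/subjective tag."""

    event_id: str
    event_type: str  # "objective" | "subjective"

    def __post_init__(self) -> None:
        if self.event_type not in ("objective", "subjective"):
            raise ValueError(
                f"event_type must be 'objective' or 'subjective', got {self.event_type!r}"
            )


#: Three objective-threat and three subjective-threat events, as in the fear
#: experiments the generator emulates.
DEFAULT_EVENTS: tuple[EventSpec, ...] = (
    EventSpec("obj1", "objective"),
    EventSpec("obj2", "objective"),
    EventSpec("obj3", "objective"),
    EventSpec("subj1", "subjective"),
    EventSpec("subj2", "subjective"),
    EventSpec("subj3", "subjective"),
)


def _default_event_effects() -> dict[str, float]:
    # Subjective threats are endorsed much more strongly at baseline than
    # objective ones; offsets chosen to put objective events near mu ~ 0.35
    # and subjective events near mu ~ 0.7 for the reference group.
    return {
        "obj1": -0.6,
        "obj2": -0.75,
        "obj3": -0.45,
        "subj1": 0.8,
        "subj2": 1.0,
        "subj3": 0.6,
    }


def _default_group_effects() -> dict[str, float]:
    # The "reality cheque" bet manipulation lowers objective-event ratings
    # substantially and subjective-event ratings only slightly.
    return {
        "obj1": -0.55,
        "obj2": -0.55,
        "obj3": -0.55,
        "subj1": -0.12,
        "subj2": -0.12,
        "subj3": -0.12,
    }


@dataclass
class SimConfig:
    """Generative parameters for one synthetic experiment.

    Parameters
    ----------
    n_per_group
        Participants per between-subject group (group A = Control/Low fear,
        group B = Bet/High fear).
    events
        Within-subject events, each tagged objective or subjective.
    beta_intercept
        Logit-scale baseline for group A on the (alphabetically) first event
        before event offsets.
    event_effects
        Per-event logit-scale baseline shifts (shared by both groups).
    group_effects
        Per-event logit-scale shift applied to group B.
    fear_slope
        Logit-scale effect of one SD of the fear questionnaire score.
    phi
        Beta precision; observation variance is ``mu (1 - mu) / (phi + 1)``.
    sd_participant
        SD of logit-scale participant random intercepts.
    rating_type_effects
        Optional per-event logit shifts for Bet vs Belief ratings; when given,
        every participant contributes one belief and one bet rating per event.
    fear_mean_a, fear_sd_a, fear_mean_b, fear_sd_b
        Group-specific normals for the raw questionnaire score.
    fear_range
        Optional (lo, hi); when set, fear scores are clipped-resampled into the
        questionnaire's native range (truncated normal by rejection).
    p_feelings
        Probability of choosing the "feelings" post-assessment option.
    round_ratings
        Round ratings to integers, mimicking slider granularity (default off:
        the analysis model is continuous).
    seed
        Integer seed for the single RNG stream.
    """

    n_per_group: int = 50
    events: tuple[EventSpec, ...] = DEFAULT_EVENTS
    beta_intercept: float = 0.0
    event_effects: dict[str, float] = field(default_factory=_default_event_effects)
    group_effects: dict[str, float] = field(default_factory=_default_group_effects)
    fear_slope: float = 0.4
    phi: float = 4.0
    sd_participant: float = 0.75
    rating_type_effects: dict[str, float] | None = None
    fear_mean_a: float = 9.0
    fear_sd_a: float = 3.0
    fear_mean_b: float = 9.0
    fear_sd_b: float = 3.0
    fear_range: tuple[float, float] | None = None
    p_feelings: float = 0.85
    round_ratings: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if not self.events:
            raise ValueError("events must contain at least one event")
        labels = [e.event_id for e in self.events]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate event labels in events: {labels}")
        if not self.phi > 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")
        if self.sd_participant < 0:
            raise ValueError(f"sd_participant must be >= 0, got {self.sd_participant}")
        if not (0.0 <= self.p_feelings <= 1.0):
            raise ValueError(f"p_feelings must be in [0, 1], got {self.p_feelings}")
        if self.fear_sd_a <= 0 or self.fear_sd_b <= 0:
            raise ValueError("fear_sd_a and fear_sd_b must be > 0")
        for name in ("event_effects", "group_effects", "rating_type_effects"):
            d = getattr(self, name)
            if d is None:
                continue
            unknown = set(d) - set(labels)
            if unknown:
                raise ValueError(f"{name} refers to unknown events: {sorted(unknown)}")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _draw_fear_scores(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_per_group
    raw = np.concatenate(
        [
            rng.normal(cfg.fear_mean_a, cfg.fear_sd_a, size=n),
            rng.normal(cfg.fear_mean_b, cfg.fear_sd_b, size=n),
        ]
    )
    if cfg.fear_range is not None:
        lo, hi = cfg.fear_range
        bad = (raw < lo) | (raw > hi)
        while bad.any():  # rejection keeps the within-range shape normal
            means = np.where(np.arange(2 * n) < n, cfg.fear_mean_a, cfg.fear_mean_b)
            sds = np.where(np.arange(2 * n) < n, cfg.fear_sd_a, cfg.fear_sd_b)
            raw[bad] = rng.normal(means[bad], sds[bad])
            bad = (raw < lo) | (raw > hi)
    return raw


def simulate_ratings(config: SimConfig) -> pd.DataFrame:
    """Generate a long-format ratings table under ``config``.

    Returns a DataFrame with columns ``participant_id, group, fear_score,
    fear_z, event_id, event_type, rating_type, rating_raw`` (``rating_type``
    only when ``config.rating_type_effects`` is set). Ratings are strictly
    inside (0, 100) unless ``round_ratings`` is on.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    n_total = 2 * n

    fear = _draw_fear_scores(config, rng)
    fear_z = (fear - fear.mean()) / fear.std(ddof=1)  # pooled standardization

    u = rng.normal(0.0, config.sd_participant, size=n_total) if config.sd_participant > 0 else np.zeros(n_total)

    groups = np.array(["A"] * n + ["B"] * n)
    pids = np.array([f"p{i:04d}" for i in range(n_total)])

    rating_types = ["belief", "bet"] if config.rating_type_effects is not None else [None]

    rows = []
    for i in range(n_total):
        for ev in config.events:
            for rt in rating_types:
                eta = (
                    config.beta_intercept
                    + config.event_effects.get(ev.event_id, 0.0)
                    + (config.group_effects.get(ev.event_id, 0.0) if groups[i] == "B" else 0.0)
                    + config.fear_slope * fear_z[i]
                    + u[i]
                )
                if rt == "bet":
                    eta += config.rating_type_effects.get(ev.event_id, 0.0)
                mu = float(expit(eta))
                y = rng.beta(mu * config.phi, (1.0 - mu) * config.phi)
                rating = 100.0 * y
                if config.round_ratings:
                    rating = float(np.round(rating))
                row = {
                    "participant_id": pids[i],
                    "group": groups[i],
                    "fear_score": fear[i],
                    "fear_z": fear_z[i],
                    "event_id": ev.event_id,
                    "event_type": ev.event_type,
                    "rating_raw": rating,
                }
                if rt is not None:
                    row["rating_type"] = rt
                rows.append(row)

    df = pd.DataFrame(rows)
    cols = ["participant_id", "group", "fear_score", "fear_z", "event_id", "event_type"]
    if rating_types != [None]:
        cols.append("rating_type")
    cols.append("rating_raw")
    return df[cols]


def simulate_questionnaire_scores(
    n_a: int,
    n_b: int,
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    exact_moments: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two groups of questionnaire totals from group-specific normals.

    With ``exact_moments`` each vector is affinely rescaled so its *sample*
    mean and sample SD (ddof=1) equal the requested values exactly — used to
    reconstruct groups from published summary statistics.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError(f"need n >= 2 per group (sample SD undefined below), got {n_a}, {n_b}")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("sds must be > 0")
    rng = np.random.default_rng(seed)
    a = rng.normal(mean_a, sd_a, size=n_a)
    b = rng.normal(mean_b, sd_b, size=n_b)
    if exact_moments:
        a = mean_a + (a - a.mean()) * (sd_a / a.std(ddof=1))
        b = mean_b + (b - b.mean()) * (sd_b / b.std(ddof=1))
    return a, b


def simulate_choices(n: int, p_feelings: float, seed: int = 0, group: str = "A") -> pd.DataFrame:
    """Simulate the binary post-assessment ("feelings" vs "danger") choices."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not (0.0 <= p_feelings <= 1.0):
        raise ValueError(f"p_feelings must be in [0, 1], got {p_feelings}")
    rng = np.random.default_rng(seed)
    picks = rng.random(n) < p_feelings
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:04d}" for i in range(n)],
            "group": group,
            "choice": np.where(picks, "feelings", "danger"),
        }
    )
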