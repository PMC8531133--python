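"""Batch-sequential design with an HDI stopping rule, and its operating
characteristics under known generating effects.

The design mirrors the pre-registered procedure: participants arrive in
batches; from a scheduled check onward (first check after batch 5 in the
study), once at least ``min_n_per_cell`` participants per condition have
accrued, the full pipeline is run on the accumulated data (squish -> beta
mixed fit -> per-event PSup posteriors -> Objective-Subjective contrast) and
collection stops when the 95% HDI of the contrast excludes the reference
value (0), or at the financial maximum number of batches.

Interim fits use scaled-down sampler settings by default (each check refits
the model); the check is considered valid when every reported parameter has
split-Rhat <= 1.05 and the sampler recorded no excess divergences — the full
reporting contract (bulk ESS >= 4000) is a final-analysis requirement, not an
interim one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mcmc import MCMCSettings
from .model import NotConvergedWarning, build_design, fit_beta_mixed
from .preprocess import prepare_ratings, zscore
from .psup import hdi, psup_contrast, psup_posterior
from .synthetic import SimConfig, simulate_ratings

__all__ = [
    "SequentialRule",
    "CheckRecord",
    "SequentialTrialRecord",
    "SequentialResult",
    "run_sequential_trial",
    "operating_characteristics",
    "binomial_ci",
]

logger = logging.getLogger(__name__)

#: Reduced-fidelity sampler settings for interim refits.
INTERIM_MCMC = MCMCSettings(chains=4, draws=250, tune=400)
INTERIM_RHAT_MAX = 1.05


@dataclass(frozen=True)
class SequentialRule:
    """Stopping rule: at each scheduled check with enough participants per
    condition, stop when the ``level`` HDI of the contrast excludes
    ``reference``."""

    min_n_per_cell: int = 50
    check_after_batches: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    level: float = 0.95
    reference: float = 0.0
    absolute: bool = False  # apply the rule to |contrast| instead

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.min_n_per_cell < 1:
            raise ValueError("min_n_per_cell must be >= 1")
        batches = tuple(self.check_after_batches)
        if not batches or any(b2 <= b1 for b1, b2 in zip(batches, batches[1:])):
            raise ValueError("check_after_batches must be nonempty and strictly increasing")

    @property
    def max_batches(self) -> int:
        return max(self.check_after_batches)

    def excludes_reference(self, contrast_draws: np.ndarray) -> tuple[bool, float, float]:
        draws = np.abs(contrast_draws) if self.absolute else contrast_draws
        lo, hi = hdi(draws, level=self.level)
        return not (lo <= self.reference <= hi), lo, hi


@dataclass
class CheckRecord:
    batch: int
    n_per_cell: dict[str, int]
    valid: bool
    median: float | None = None
    hdi_low: float | None = None
    hdi_high: float | None = None
    stopped: bool = False
    contrast_draws: np.ndarray | None = None


@dataclass
class SequentialTrialRecord:
    """One replicate of the sequential design."""

    stop_batch: int | None  # None = censored at the batch maximum
    decision: bool  # effect detected (HDI excluded the reference)
    final_n_per_cell: dict[str, int]
    checks: list[CheckRecord] = field(default_factory=list)
    seed: int = 0

    @property
    def censored(self) -> bool:
        return self.stop_batch is None


@dataclass
class SequentialResult:
    """Aggregate over replicates for one generating configuration."""

    replicates: list[SequentialTrialRecord]
    detection_rate: float
    detection_ci: tuple[float, float]
    stop_probability_per_batch: dict[int, float]
    mean_final_n_per_cell: float


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _simulate_batch(config: SimConfig, n_a: int, n_b: int, batch: int, seed: int) -> pd.DataFrame:
    """One accrual batch (n_a group-A and n_b group-B participants)."""
    n = max(n_a, n_b)
    df = simulate_ratings(config.with_(n_per_group=n, seed=seed))
    keep_a = [f"p{i:04d}" for i in range(n_a)]
    keep_b = [f"p{i:04d}" for i in range(n, n + n_b)]
    df = df[df["participant_id"].isin(keep_a + keep_b)].copy()
    df["participant_id"] = f"b{batch:02d}_" + df["participant_id"]
    return df


def _analyze(accumulated: pd.DataFrame, rule: SequentialRule, mcmc: MCMCSettings,
             n_pred: int, seed: int) -> tuple[bool, bool, float, float, float, np.ndarray]:
    """Run the full pipeline on the accumulated table.

    Returns (valid, stop, median, lo, hi, contrast_draws).
    """
    df = accumulated.copy()
    # re-standardize the fear covariate over everyone accrued so far
    per_part = df.drop_duplicates("participant_id").set_index("participant_id")["fear_score"]
    fz = pd.Series(zscore(per_part.to_numpy()), index=per_part.index)
    df["fear_z"] = df["participant_id"].map(fz)

    prepared = prepare_ratings(df)
    design = build_design(prepared, "exp2to5")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NotConvergedWarning)
        fit = fit_beta_mixed(design, mcmc=mcmc, seed=seed)

    rhat_ok = bool((fit.diagnostics["rhat"] <= INTERIM_RHAT_MAX).all())
    div_ok = fit.n_divergent <= 0.02 * fit.n_draws
    if not (rhat_ok and div_ok):
        return False, False, np.nan, np.nan, np.nan, np.empty(0)

    ga, gb = design.group_levels  # A = control-like, B = bet-like
    rng = np.random.default_rng(seed)
    obj, subj = [], []
    for ev in design.event_levels:
        ps = psup_posterior(
            fit, (ga, ev), (gb, ev), fear_z=0.0, n_pred=n_pred,
            seed=int(rng.integers(0, 2**31 - 1)), label=ev,
        )
        (obj if design.event_types[ev] == "objective" else subj).append(ps)
    contrast = psup_contrast(obj, subj, label="objective-subjective")
    stop, lo, hi = rule.excludes_reference(contrast.draws)
    return True, stop, contrast.median, lo, hi, contrast.draws


def run_sequential_trial(
    gen_config: SimConfig,
    batch_size: int,
    rule: SequentialRule,
    seed: int = 0,
    fraction_b: float = 0.5,
    mcmc: MCMCSettings | None = None,
    n_pred: int = 200,
    keep_draws: bool = False,
) -> SequentialTrialRecord:
    """Simulate one run of the batch-sequential design.

    ``batch_size`` is the total participants accrued per batch; ``fraction_b``
    of them join group B (the study's batches were uneven; balanced accrual is
    the default). A check whose interim fit fails validity (Rhat/divergences)
    is skipped with a log message and the trial continues.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    if not (0.0 < fraction_b < 1.0):
        raise ValueError("fraction_b must be in (0, 1)")
    gen_config.validate()
    mcmc = mcmc or INTERIM_MCMC
    n_b = int(round(batch_size * fraction_b))
    n_a = batch_size - n_b
    if n_a < 1 or n_b < 1:
        raise ValueError("batch composition leaves a condition empty")

    ss = np.random.SeedSequence(seed)
    batch_seeds, fit_seeds = ss.spawn(2)
    bseeds = batch_seeds.generate_state(rule.max_batches)
    fseeds = fit_seeds.generate_state(rule.max_batches)

    chunks: list[pd.DataFrame] = []
    checks: list[CheckRecord] = []
    stop_batch: int | None = None
    decision = False

    for batch in range(1, rule.max_batches + 1):
        chunks.append(_simulate_batch(gen_config, n_a, n_b, batch, int(bseeds[batch - 1] % 2**31)))
        acc = pd.concat(chunks, ignore_index=True)
        n_per_cell = {
            str(g): int(n)
            for g, n in acc.groupby("group")["participant_id"].nunique().items()
        }

        if batch not in rule.check_after_batches:
            continue
        if min(n_per_cell.values()) < rule.min_n_per_cell:
            checks.append(CheckRecord(batch, n_per_cell, valid=False))
            continue

        valid, stop, med, lo, hi, draws = _analyze(
            acc, rule, mcmc, n_pred, int(fseeds[batch - 1] % 2**31)
        )
        rec = CheckRecord(batch, n_per_cell, valid, med, lo, hi, stopped=valid and stop)
        if keep_draws and valid:
            rec.contrast_draws = draws
        checks.append(rec)
        if not valid:
            logger.warning("interim fit at batch %d failed validity; check skipped", batch)
            continue
        if stop:
            stop_batch = batch
            decision = True
            break

    final_n = {
        str(g): int(n)
        for g, n in pd.concat(chunks, ignore_index=True)
        .groupby("group")["participant_id"].nunique().items()
    }
    return SequentialTrialRecord(stop_batch, decision, final_n, checks, seed)


def summarize_replicates(replicates: list[SequentialTrialRecord]) -> SequentialResult:
    n = len(replicates)
    k = sum(r.decision for r in replicates)
    rate = k / n if n else float("nan")
    per_batch: dict[int, float] = {}
    if n:
        stops = [r.stop_batch for r in replicates if r.stop_batch is not None]
        for b in sorted(set(stops)):
            per_batch[b] = stops.count(b) / n
    mean_n = float(np.mean([np.mean(list(r.final_n_per_cell.values())) for r in replicates])) if n else float("nan")
    return SequentialResult(replicates, rate, binomial_ci(k, n), per_batch, mean_n)


def operating_characteristics(
    gen_configs: dict[str, SimConfig] | list[SimConfig],
    batch_size: int,
    rule: SequentialRule,
    n_reps: int,
    seed: int = 0,
    **trial_kwargs,
) -> tuple[pd.DataFrame, dict[str, SequentialResult]]:
    """Monte-Carlo operating characteristics over a grid of generating effects.

    Returns an aggregate table (one row per configuration: detection rate with
    its 95% binomial interval, early-stop probability, mean final n per cell)
    and the per-configuration :class:`SequentialResult` objects.
    """
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    if isinstance(gen_configs, dict):
        items = list(gen_configs.items())
    else:
        items = [(f"config{i}", c) for i, c in enumerate(gen_configs)]

    ss = np.random.SeedSequence(seed)
    rows = []
    results: dict[str, SequentialResult] = {}
    for (label, cfg), child in zip(items, ss.spawn(len(items))):
        rep_seeds = child.generate_state(n_reps) if n_reps else []
        reps = [
            run_sequential_trial(cfg, batch_size, rule, seed=int(s % 2**31), **trial_kwargs)
            for s in rep_seeds
        ]
        res = summarize_replicates(reps)
        results[label] = res
        if n_reps:
            rows.append(
                {
                    "config": label,
                    "n_reps": n_reps,
                    "detection_rate": res.detection_rate,
                    "detection_ci_low": res.detection_ci[0],
                    "detection_ci_high": res.detection_ci[1],
                    "early_stop_rate": float(np.mean([r.stop_batch is not None for r in reps])),
                    "mean_final_n_per_cell": res.mean_final_n_per_cell,
                }
            )
    columns = ["config", "n_reps", "detection_rate", "detection_ci_low",
               "detection_ci_high", "early_stop_rate", "mean_final_n_per_cell"]
    return pd.DataFrame(rows, columns=columns), results
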