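"""Bayesian models for the rating pipeline.

Two models live here:

* A hierarchical beta regression for squished probability ratings: the mean of
  a Beta(mu*phi, (1-mu)*phi) observation is logit-linked to a cell-mean design
  (Fear Level x Rating Type x Event for the two-rating-type design, or
  fear_z + Group x Event for the two-group design), with participant random
  intercepts. Sampled with the package's NUTS sampler on an unconstrained
  parameterization (non-centered intercepts, log sd, log phi).

* A two-group normal model for questionnaire totals, yielding a posterior for
  the standardized mean difference (Cohen's d) with the pooled-SD convention.
  Sampled by Gibbs (semi-conjugate).

Convergence is reported per parameter (split-Rhat and bulk ESS); a fit that
misses the reporting contract (Rhat <= 1.01 and bulk ESS >= 4000 for every
reported parameter) is flagged, never silently returned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, expit, gammaln

from ._mcmc import MCMCSettings, diagnostics_table, sample_nuts

__all__ = [
    "DesignSpec",
    "build_design",
    "BetaRegressionPriors",
    "PosteriorDraws",
    "fit_beta_mixed",
    "posterior_predict",
    "CohensDPriors",
    "CohensDPosterior",
    "fit_cohens_d",
    "NotConvergedWarning",
]

RHAT_MAX = 1.01
ESS_MIN = 4000.0


class NotConvergedWarning(UserWarning):
    """Raised (as a warning) when a fit misses the Rhat/ESS reporting contract."""


# --------------------------------------------------------------------------
# Design construction
# --------------------------------------------------------------------------

def _event_levels(ratings: pd.DataFrame) -> list[str]:
    """Event levels with the first objective event (by label) as reference."""
    etypes = ratings.drop_duplicates("event_id").set_index("event_id")["event_type"]
    return sorted(etypes.index, key=lambda e: (etypes[e] != "objective", e))


@dataclass
class DesignSpec:
    """Full-rank treatment-coded design for one formula kind.

    ``cells`` enumerates every (group, [rating_type,] event) combination;
    ``cell_row`` maps a cell (plus a fear_z value for the covariate design)
    to its row in coefficient space.
    """

    formula_kind: str  # "exp1" | "exp2to5"
    coef_names: list[str]
    X: np.ndarray
    y: np.ndarray | None
    participant_idx: np.ndarray
    participant_ids: list[str]
    group_levels: list[str]
    event_levels: list[str]
    event_types: dict[str, str]
    rating_type_levels: list[str] | None
    cells: list[tuple]

    @property
    def n_coef(self) -> int:
        return len(self.coef_names)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def cell_row(self, cell: tuple, fear_z: float = 0.0) -> np.ndarray:
        """Coefficient-space row vector for a design cell."""
        if self.formula_kind == "exp1":
            group, rating_type, event = cell
            if (group not in self.group_levels or event not in self.event_levels
                    or rating_type not in (self.rating_type_levels or [])):
                raise KeyError(f"unknown cell {cell!r}")
            g = 1.0 if group == self.group_levels[1] else 0.0
            r = 1.0 if rating_type == self.rating_type_levels[1] else 0.0
            ev = np.array([1.0 if event == e else 0.0 for e in self.event_levels[1:]])
            row = np.concatenate(
                [[1.0, g, r], ev, [g * r], g * ev, r * ev, g * r * ev]
            )
        elif self.formula_kind == "exp2to5":
            group, event = cell
            if group not in self.group_levels or event not in self.event_levels:
                raise KeyError(f"unknown cell {cell!r}")
            g = 1.0 if group == self.group_levels[1] else 0.0
            ev = np.array([1.0 if event == e else 0.0 for e in self.event_levels[1:]])
            row = np.concatenate([[1.0, float(fear_z), g], ev, g * ev])
        else:  # pragma: no cover - guarded at construction
            raise ValueError(self.formula_kind)
        return row

    def to_dict(self) -> dict:
        return {
            "formula_kind": self.formula_kind,
            "coef_names": self.coef_names,
            "participant_ids": self.participant_ids,
            "group_levels": self.group_levels,
            "event_levels": self.event_levels,
            "event_types": self.event_types,
            "rating_type_levels": self.rating_type_levels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        if d["formula_kind"] == "exp1":
            cells = [
                (g, r, e)
                for g in d["group_levels"]
                for r in d["rating_type_levels"]
                for e in d["event_levels"]
            ]
        else:
            cells = [(g, e) for g in d["group_levels"] for e in d["event_levels"]]
        return cls(
            formula_kind=d["formula_kind"],
            coef_names=list(d["coef_names"]),
            X=np.zeros((0, len(d["coef_names"]))),
            y=None,
            participant_idx=np.zeros(0, dtype=int),
            participant_ids=list(d["participant_ids"]),
            group_levels=list(d["group_levels"]),
            event_levels=list(d["event_levels"]),
            event_types=dict(d["event_types"]),
            rating_type_levels=(
                list(d["rating_type_levels"]) if d["rating_type_levels"] else None
            ),
            cells=cells,
        )


def build_design(ratings: pd.DataFrame, formula_kind: str) -> DesignSpec:
    """Build the treatment-coded design for ``formula_kind``.

    Reference levels: first group level (Control / Low fear), 'belief' rating
    type, and the first objective event. Requires a ``rating_squished`` column
    when present to carry the response (see :func:`betapsup.preprocess.prepare_ratings`);
    otherwise ``y`` is left unset and must be passed to the fitter.
    """
    if formula_kind not in ("exp1", "exp2to5"):
        raise ValueError(f"formula_kind must be 'exp1' or 'exp2to5', got {formula_kind!r}")
    required = {"participant_id", "group", "event_id", "event_type"}
    missing_cols = required - set(ratings.columns)
    if missing_cols:
        raise ValueError(f"ratings table missing columns: {sorted(missing_cols)}")

    group_levels = sorted(ratings["group"].unique())
    if len(group_levels) != 2:
        raise ValueError(f"need exactly 2 group levels, found {group_levels}")
    event_levels = _event_levels(ratings)
    event_types = (
        ratings.drop_duplicates("event_id").set_index("event_id")["event_type"].to_dict()
    )

    rt_levels: list[str] | None = None
    if formula_kind == "exp1":
        if "rating_type" not in ratings.columns:
            raise ValueError("exp1 design requires a rating_type column")
        found = set(ratings["rating_type"].unique())
        want = ["belief", "bet"]
        missing = [lv for lv in want if lv not in found]
        if missing:
            raise ValueError(f"exp1 design missing rating_type levels: {missing}")
        rt_levels = want
    else:
        if "fear_z" not in ratings.columns:
            raise ValueError("exp2to5 design requires a fear_z column")

    pid_levels = list(pd.unique(ratings["participant_id"]))
    pid_map = {p: i for i, p in enumerate(pid_levels)}
    participant_idx = ratings["participant_id"].map(pid_map).to_numpy()

    ev_rest = event_levels[1:]
    if formula_kind == "exp1":
        coef_names = (
            ["Intercept", f"group[{group_levels[1]}]", "rating_type[bet]"]
            + [f"event[{e}]" for e in ev_rest]
            + [f"group[{group_levels[1]}]:rating_type[bet]"]
            + [f"group[{group_levels[1]}]:event[{e}]" for e in ev_rest]
            + [f"rating_type[bet]:event[{e}]" for e in ev_rest]
            + [f"group[{group_levels[1]}]:rating_type[bet]:event[{e}]" for e in ev_rest]
        )
        cells = [(g, r, e) for g in group_levels for r in rt_levels for e in event_levels]
    else:
        coef_names = (
            ["Intercept", "fear_z", f"group[{group_levels[1]}]"]
            + [f"event[{e}]" for e in ev_rest]
            + [f"group[{group_levels[1]}]:event[{e}]" for e in ev_rest]
        )
        cells = [(g, e) for g in group_levels for e in event_levels]

    spec = DesignSpec(
        formula_kind=formula_kind,
        coef_names=coef_names,
        X=np.zeros((0, 0)),
        y=None,
        participant_idx=participant_idx,
        participant_ids=pid_levels,
        group_levels=group_levels,
        event_levels=event_levels,
        event_types=event_types,
        rating_type_levels=rt_levels,
        cells=cells,
    )

    rows = np.empty((len(ratings), len(coef_names)))
    if formula_kind == "exp1":
        keys = zip(ratings["group"], ratings["rating_type"], ratings["event_id"])
        for i, cell in enumerate(keys):
            rows[i] = spec.cell_row(cell)
    else:
        fz = ratings["fear_z"].to_numpy(dtype=float)
        keys = zip(ratings["group"], ratings["event_id"])
        for i, cell in enumerate(keys):
            rows[i] = spec.cell_row(cell, fear_z=fz[i])
    spec.X = rows

    from .preprocess import SQUISHED_COL

    if SQUISHED_COL in ratings.columns:
        spec.y = ratings[SQUISHED_COL].to_numpy(dtype=float)
    return spec


# --------------------------------------------------------------------------
# Hierarchical beta regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaRegressionPriors:
    """Weakly informative defaults on the logit scale: Normal(0, 1.5) slopes
    keep cell means inside a plausible probability range; Half-Normal(1) on
    the intercept SD; Gamma(2, rate 0.1) on phi (mode 10, long right tail)."""

    coef_sd: float = 1.5
    sd_participant_scale: float = 1.0
    phi_shape: float = 2.0
    phi_rate: float = 0.1


@dataclass
class PosteriorDraws:
    """Posterior draws from the beta mixed model, flattened across chains."""

    design: DesignSpec
    coef_draws: np.ndarray  # (n_draws, n_coef)
    sd_participant_draws: np.ndarray  # (n_draws,)
    phi_draws: np.ndarray  # (n_draws,)
    participant_intercept_draws: np.ndarray  # (n_draws, n_participants)
    diagnostics: pd.DataFrame
    n_chains: int
    converged: bool
    n_divergent: int
    seed: int

    @property
    def n_draws(self) -> int:
        return self.coef_draws.shape[0]

    def coef(self, name: str) -> np.ndarray:
        try:
            j = self.design.coef_names.index(name)
        except ValueError:
            raise KeyError(f"unknown coefficient {name!r}; have {self.design.coef_names}")
        return self.coef_draws[:, j]

    def summary(self) -> pd.DataFrame:
        """Posterior median and 95% HDI for every reported parameter."""
        from .psup import hdi

        rows = []
        for j, name in enumerate(self.design.coef_names):
            lo, hi = hdi(self.coef_draws[:, j])
            rows.append({"parameter": name, "median": float(np.median(self.coef_draws[:, j])),
                         "hdi_low": lo, "hdi_high": hi})
        for name, arr in (("sd_participant", self.sd_participant_draws), ("phi", self.phi_draws)):
            lo, hi = hdi(arr)
            rows.append({"parameter": name, "median": float(np.median(arr)),
                         "hdi_low": lo, "hdi_high": hi})
        return pd.DataFrame(rows)

    # -- plain-text persistence for the CLI ---------------------------------
    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = self.design.to_dict()
        meta.update(
            n_chains=self.n_chains,
            converged=bool(self.converged),
            n_divergent=int(self.n_divergent),
            seed=int(self.seed),
        )
        (d / "design.json").write_text(json.dumps(meta, indent=1))
        n = self.n_draws
        per_chain = n // self.n_chains
        chain = np.repeat(np.arange(self.n_chains), per_chain)
        draw = np.tile(np.arange(per_chain), self.n_chains)
        frames = [
            pd.DataFrame({"chain": chain, "draw": draw,
                          "parameter": name, "value": self.coef_draws[:, j]})
            for j, name in enumerate(self.design.coef_names)
        ]
        frames.append(pd.DataFrame({"chain": chain, "draw": draw,
                                    "parameter": "sd_participant",
                                    "value": self.sd_participant_draws}))
        frames.append(pd.DataFrame({"chain": chain, "draw": draw,
                                    "parameter": "phi", "value": self.phi_draws}))
        for k, pid in enumerate(self.design.participant_ids):
            frames.append(pd.DataFrame({"chain": chain, "draw": draw,
                                        "parameter": f"u[{pid}]",
                                        "value": self.participant_intercept_draws[:, k]}))
        pd.concat(frames, ignore_index=True).to_csv(d / "draws.csv", index=False)
        self.diagnostics.to_csv(d / "diagnostics.csv", index=False)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "design.json").read_text())
        design = DesignSpec.from_dict(meta)
        long = pd.read_csv(d / "draws.csv")
        wide = long.pivot_table(index=["chain", "draw"], columns="parameter",
                                values="value", sort=False).sort_index()
        coef = np.column_stack([wide[name].to_numpy() for name in design.coef_names])
        u = np.column_stack([wide[f"u[{pid}]"].to_numpy() for pid in design.participant_ids])
        return cls(
            design=design,
            coef_draws=coef,
            sd_participant_draws=wide["sd_participant"].to_numpy(),
            phi_draws=wide["phi"].to_numpy(),
            participant_intercept_draws=u,
            diagnostics=pd.read_csv(d / "diagnostics.csv"),
            n_chains=int(meta["n_chains"]),
            converged=bool(meta["converged"]),
            n_divergent=int(meta["n_divergent"]),
            seed=int(meta["seed"]),
        )


def _beta_mixed_logp_and_grad(X, y, pidx, n_part, priors):
    """Closure returning (logp, grad) of the unconstrained joint posterior.

    theta = [beta (p), z (J), log_sd, log_phi]; u = sd * z (non-centered).
    """
    logy = np.log(y)
    log1my = np.log1p(-y)
    logit_y = logy - log1my
    p = X.shape[1]
    c_var = priors.coef_sd**2
    s_scale2 = priors.sd_participant_scale**2

    n_obs = X.shape[0]
    XT = np.ascontiguousarray(X.T)
    stacked = np.empty(2 * n_obs)  # reused buffer for [a, b]

    def logp_and_grad(theta):
        beta = theta[:p]
        z = theta[p : p + n_part]
        log_sd = theta[-2]
        log_phi = theta[-1]
        sd = np.exp(log_sd)
        phi = np.exp(log_phi)

        eta = X @ beta + sd * z[pidx]
        mu = expit(eta)
        np.clip(mu, 1e-12, 1 - 1e-12, out=mu)
        a = np.multiply(mu, phi, out=stacked[:n_obs])
        b = np.multiply(1.0 - mu, phi, out=stacked[n_obs:])

        lg = gammaln(stacked)
        dig = digamma(stacked)
        dig_a, dig_b = dig[:n_obs], dig[n_obs:]

        ll = (n_obs * gammaln(phi) - lg.sum()
              + np.dot(a - 1.0, logy) + np.dot(b - 1.0, log1my))

        dmu = phi * (logit_y - dig_a + dig_b)
        g = dmu * mu * (1.0 - mu)

        gbeta = XT @ g
        g_by_part = np.bincount(pidx, weights=g, minlength=n_part)
        gz = sd * g_by_part
        g_log_sd = sd * np.dot(g, z[pidx])
        g_log_phi = phi * (
            n_obs * digamma(phi) - np.dot(mu, dig_a - logy) - np.dot(1.0 - mu, dig_b - log1my)
        )

        # priors (with log-jacobians for the log transforms)
        lp = ll
        lp += -0.5 * np.sum(beta * beta) / c_var
        gbeta += -beta / c_var
        lp += -0.5 * np.sum(z * z)
        gz += -z
        lp += -0.5 * sd * sd / s_scale2 + log_sd  # half-normal + jacobian
        g_log_sd += -sd * sd / s_scale2 + 1.0
        lp += priors.phi_shape * log_phi - priors.phi_rate * phi  # gamma + jacobian
        g_log_phi += priors.phi_shape - priors.phi_rate * phi

        grad = np.concatenate([gbeta, gz, [g_log_sd, g_log_phi]])
        return lp, grad

    return logp_and_grad


def fit_beta_mixed(
    design: DesignSpec,
    y: np.ndarray | None = None,
    priors: BetaRegressionPriors | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the hierarchical beta regression posterior.

    ``y`` must already be squished strictly inside (0, 1); pass it explicitly
    or let the design carry it. The model seed is independent of any data
    seed and is recorded on the result.
    """
    if y is None:
        y = design.y
    if y is None:
        raise ValueError("no response found: pass y or build the design from a prepared table")
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError(
            "responses must lie strictly in (0, 1); apply preprocess.prepare_ratings "
            "(the squish transformation) before fitting"
        )
    priors = priors or BetaRegressionPriors()
    mcmc = mcmc or MCMCSettings()

    X = design.X
    pidx = design.participant_idx
    n_part = design.n_participants
    p = X.shape[1]
    dim = p + n_part + 2
    f = _beta_mixed_logp_and_grad(X, y, pidx, n_part, priors)

    # MAP initialization (shared across chains; chains jitter around it)
    x0 = np.zeros(dim)
    ybar = float(np.mean(y))
    x0[0] = np.log(ybar / (1.0 - ybar))
    x0[-2] = -1.0
    mom_phi = ybar * (1 - ybar) / max(np.var(y), 1e-4) - 1.0
    x0[-1] = np.log(np.clip(mom_phi, 1.0, 100.0))
    res = optimize.minimize(
        lambda t: tuple(-v for v in f(t)), x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 300},
    )
    x_map = res.x if np.isfinite(res.fun) else x0

    # diagonal Hessian at the mode -> initial inverse mass (posterior variances)
    h = 1e-4
    _, g0 = f(x_map)
    hess_diag = np.empty(dim)
    for i in range(dim):
        xp = x_map.copy()
        xp[i] += h
        _, gi = f(xp)
        hess_diag[i] = -(gi[i] - g0[i]) / h
    inv_mass0 = 1.0 / np.clip(hess_diag, 1e-2, 1e6)

    result = sample_nuts(f, x_map, mcmc, seed=seed, init_inv_mass=inv_mass0)

    flat = result.draws.reshape(-1, dim)
    coef = flat[:, :p]
    z = flat[:, p : p + n_part]
    sd = np.exp(flat[:, -2])
    phi = np.exp(flat[:, -1])
    u = sd[:, None] * z

    named = {
        name: result.draws[:, :, j] for j, name in enumerate(design.coef_names)
    }
    named["sd_participant"] = np.exp(result.draws[:, :, -2])
    named["phi"] = np.exp(result.draws[:, :, -1])
    diag = diagnostics_table(named)
    converged = bool(
        (diag["rhat"] <= RHAT_MAX).all() and (diag["ess_bulk"] >= ESS_MIN).all()
        and result.n_divergent == 0
    )
    if not converged:
        warnings.warn(
            "fit did not meet the reporting contract "
            f"(max Rhat {diag['rhat'].max():.3f}, min bulk ESS {diag['ess_bulk'].min():.0f}, "
            f"{result.n_divergent} divergences)",
            NotConvergedWarning,
        )

    return PosteriorDraws(
        design=design,
        coef_draws=coef,
        sd_participant_draws=sd,
        phi_draws=phi,
        participant_intercept_draws=u,
        diagnostics=diag,
        n_chains=mcmc.chains,
        converged=converged,
        n_divergent=result.n_divergent,
        seed=seed,
    )


def posterior_predict(
    draws: PosteriorDraws,
    cell: tuple,
    fear_z: float = 0.0,
    n_new: int = 1000,
    new_participants: bool = True,
    seed: int = 0,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior-predictive ratings for one design cell: (n_draws, n_new).

    Each prediction includes beta observation noise and participant-intercept
    variation — new intercepts drawn from Normal(0, sd_participant) per draw
    when ``new_participants``, resampled fitted intercepts otherwise. Pass a
    precomputed ``u`` to couple predictions across cells (within-subject
    comparisons share the same intercepts).
    """
    if not np.isfinite(fear_z):
        raise ValueError(f"fear_z must be finite, got {fear_z}")
    row = draws.design.cell_row(cell, fear_z=fear_z)
    eta0 = draws.coef_draws @ row
    rng = np.random.default_rng(seed)
    nd = draws.n_draws
    if u is None:
        if new_participants:
            u = draws.sd_participant_draws[:, None] * rng.standard_normal((nd, n_new))
        else:
            idx = rng.integers(0, draws.participant_intercept_draws.shape[1], size=(nd, n_new))
            u = np.take_along_axis(draws.participant_intercept_draws, idx, axis=1)
    mu = expit(eta0[:, None] + u)
    np.clip(mu, 1e-12, 1 - 1e-12, out=mu)
    phi = draws.phi_draws[:, None]
    return rng.beta(mu * phi, (1.0 - mu) * phi)


# --------------------------------------------------------------------------
# Two-group normal model (Bayesian Cohen's d)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohensDPriors:
    """Semi-conjugate priors. ``None`` fields are resolved against the data:
    group-mean prior centered at the pooled mean with scale 10x the pooled SD,
    variance prior InvGamma(0.5, 0.5 * mean within-group variance) — about
    half a pseudo-observation, effectively diffuse at the study's sizes."""

    mean_loc: float | None = None
    mean_scale: float | None = None
    var_shape: float = 0.5
    var_rate: float | None = None


@dataclass
class CohensDPosterior:
    """Posterior for (mu_a - mu_b) / sigma_pooled (first minus second group)."""

    d_draws: np.ndarray
    median: float
    hdi_low: float
    hdi_high: float
    diagnostics: pd.DataFrame
    n_chains: int
    converged: bool


def _gibbs_two_group(ya, yb, priors, n_draws, tune, chains, seed):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([ya, yb])
    m0 = priors.mean_loc if priors.mean_loc is not None else float(pooled.mean())
    s0 = priors.mean_scale if priors.mean_scale is not None else 10.0 * float(pooled.std(ddof=1))
    a0 = priors.var_shape
    b0 = (priors.var_rate if priors.var_rate is not None
          else 0.5 * float((ya.var(ddof=1) + yb.var(ddof=1)) / 2.0))

    out_mu = np.empty((chains, n_draws, 2))
    out_var = np.empty((chains, n_draws, 2))
    groups = [(ya, len(ya)), (yb, len(yb))]
    for c in range(chains):
        mu = np.array([ya.mean(), yb.mean()])
        var = np.array([ya.var(ddof=1), yb.var(ddof=1)])
        for it in range(tune + n_draws):
            for g, (yg, ng) in enumerate(groups):
                prec = ng / var[g] + 1.0 / s0**2
                mean = (ng * yg.mean() / var[g] + m0 / s0**2) / prec
                mu[g] = rng.normal(mean, 1.0 / np.sqrt(prec))
                sse = float(np.sum((yg - mu[g]) ** 2))
                var[g] = 1.0 / rng.gamma(a0 + ng / 2.0, 1.0 / (b0 + sse / 2.0))
            if it >= tune:
                out_mu[c, it - tune] = mu
                out_var[c, it - tune] = var
    return out_mu, out_var


def fit_cohens_d(
    scores_a,
    scores_b,
    priors: CohensDPriors | None = None,
    n_draws: int = 2000,
    tune: int = 500,
    chains: int = 4,
    seed: int = 0,
) -> CohensDPosterior:
    """Posterior of the standardized mean difference between two groups.

    Independent normal likelihoods per group with semi-conjugate priors; d is
    computed per draw as (mu_a - mu_b) over the pooled SD with (n-1) weights.
    """
    ya = np.asarray(scores_a, dtype=float)
    yb = np.asarray(scores_b, dtype=float)
    if ya.size < 2 or yb.size < 2:
        raise ValueError("each group needs n >= 2")
    if ya.std(ddof=1) == 0 and yb.std(ddof=1) == 0:
        raise ValueError("degenerate input: both groups have zero variance")
    priors = priors or CohensDPriors()

    mu, var = _gibbs_two_group(ya, yb, priors, n_draws, tune, chains, seed)
    na, nb = ya.size, yb.size
    pooled_sd = np.sqrt(((na - 1) * var[..., 0] + (nb - 1) * var[..., 1]) / (na + nb - 2))
    d = (mu[..., 0] - mu[..., 1]) / pooled_sd  # (chains, draws)

    diag = diagnostics_table({"d": d, "mu_a": mu[..., 0], "mu_b": mu[..., 1]})
    converged = bool((diag["rhat"] <= RHAT_MAX).all() and (diag["ess_bulk"] >= ESS_MIN).all())
    if not converged:
        warnings.warn(
            f"Cohen's d fit missed the reporting contract (max Rhat {diag['rhat'].max():.3f}, "
            f"min bulk ESS {diag['ess_bulk'].min():.0f})",
            NotConvergedWarning,
        )

    from .psup import hdi

    d_flat = d.reshape(-1)
    lo, hi = hdi(d_flat)
    return CohensDPosterior(
        d_draws=d_flat,
        median=float(np.median(d_flat)),
        hdi_low=lo,
        hdi_high=hi,
        diagnostics=diag,
        n_chains=chains,
        converged=converged,
    )
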