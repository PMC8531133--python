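"""Gradient-based MCMC machinery: a No-U-Turn sampler with dual-averaging
step-size adaptation and windowed diagonal mass-matrix estimation, plus
convergence diagnostics via arviz.

The sampler takes an arbitrary differentiable log-density ``logp_and_grad``
(returning ``(logp, grad)`` on an unconstrained parameter vector) and is the
engine behind both the hierarchical beta regression and any future model; it
knows nothing about the statistical models themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import arviz as az
import numpy as np
import pandas as pd

__all__ = ["MCMCSettings", "NUTSResult", "sample_nuts", "diagnostics_table"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class MCMCSettings:
    """Sampler controls. Defaults target the full-fidelity reporting contract
    (four chains, enough draws for bulk ESS >= 4000 on well-mixing models);
    scaled-down settings are used inside simulation loops."""

    chains: int = 4
    draws: int = 4000
    tune: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = 9
    jitter: float = 1.0  # scale of per-chain init jitter (in mass-matrix units)


@dataclass
class NUTSResult:
    draws: np.ndarray  # (chains, draws, dim)
    accept_rate: np.ndarray  # per chain mean acceptance statistic
    n_divergent: int
    step_sizes: np.ndarray
    logp: np.ndarray = field(default=None)  # (chains, draws)


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_and_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_reasonable_epsilon(logp_and_grad, q0, inv_mass, rng):
    eps = 1.0
    logp0, grad0 = logp_and_grad(q0)
    p0 = rng.normal(size=q0.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(inv_mass * p0 * p0)
    q, p, logp, _ = _leapfrog(logp_and_grad, q0, p0, grad0, eps, inv_mass)
    h = logp - 0.5 * np.sum(inv_mass * p * p)
    if not np.isfinite(h):
        h = -np.inf
    direction = 1.0 if (h - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q, p, logp, _ = _leapfrog(logp_and_grad, q0, p0, grad0, eps, inv_mass)
        h = logp - 0.5 * np.sum(inv_mass * p * p)
        if not np.isfinite(h):
            h = -np.inf
        if direction * (h - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-8)


class _TreeState:
    __slots__ = (
        "q_minus", "p_minus", "grad_minus", "q_plus", "p_plus", "grad_plus",
        "q_prop", "logp_prop", "grad_prop", "log_sum_weight", "sum_accept",
        "n_leapfrog", "divergent", "turning",
    )


def _build_tree(logp_and_grad, q, p, grad, log_u_unused, direction, depth, eps,
                inv_mass, h0, rng):
    """Multinomial NUTS doubling; returns a _TreeState."""
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_and_grad, q, p, grad, direction * eps, inv_mass)
        h = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h):
            h = -np.inf
        s = _TreeState()
        s.q_minus = s.q_plus = s.q_prop = q1
        s.p_minus = s.p_plus = p1
        s.grad_minus = s.grad_plus = s.grad_prop = grad1
        s.logp_prop = logp1
        s.log_sum_weight = h - h0
        s.sum_accept = min(1.0, np.exp(min(0.0, h - h0)))
        s.n_leapfrog = 1
        s.divergent = (h0 - h) > _MAX_ENERGY_ERROR
        s.turning = False
        return s

    first = _build_tree(logp_and_grad, q, p, grad, log_u_unused, direction, depth - 1,
                        eps, inv_mass, h0, rng)
    if first.divergent or first.turning:
        return first
    if direction == 1:
        second = _build_tree(logp_and_grad, first.q_plus, first.p_plus, first.grad_plus,
                             log_u_unused, direction, depth - 1, eps, inv_mass, h0, rng)
        first.q_plus, first.p_plus, first.grad_plus = second.q_plus, second.p_plus, second.grad_plus
    else:
        second = _build_tree(logp_and_grad, first.q_minus, first.p_minus, first.grad_minus,
                             log_u_unused, direction, depth - 1, eps, inv_mass, h0, rng)
        first.q_minus, first.p_minus, first.grad_minus = second.q_minus, second.p_minus, second.grad_minus

    total = np.logaddexp(first.log_sum_weight, second.log_sum_weight)
    if np.log(rng.random()) < second.log_sum_weight - total:
        first.q_prop, first.logp_prop, first.grad_prop = second.q_prop, second.logp_prop, second.grad_prop
    first.log_sum_weight = total
    first.sum_accept += second.sum_accept
    first.n_leapfrog += second.n_leapfrog
    first.divergent = second.divergent
    dq = first.q_plus - first.q_minus
    first.turning = (
        second.turning
        or np.dot(dq, inv_mass * first.p_minus) < 0
        or np.dot(dq, inv_mass * first.p_plus) < 0
    )
    return first


def _nuts_step(logp_and_grad, q, logp, grad, eps, inv_mass, max_depth, rng):
    p0 = rng.normal(size=q.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(inv_mass * p0 * p0)

    q_minus = q_plus = q
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    q_prop, logp_prop, grad_prop = q, logp, grad
    log_sum_weight = 0.0
    sum_accept, n_leapfrog = 0.0, 0
    divergent = False

    for depth in range(max_depth):
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_and_grad, q_plus, p_plus, grad_plus, None, 1,
                              depth, eps, inv_mass, h0, rng)
            q_plus, p_plus, grad_plus = sub.q_plus, sub.p_plus, sub.grad_plus
        else:
            sub = _build_tree(logp_and_grad, q_minus, p_minus, grad_minus, None, -1,
                              depth, eps, inv_mass, h0, rng)
            q_minus, p_minus, grad_minus = sub.q_minus, sub.p_minus, sub.grad_minus

        sum_accept += sub.sum_accept
        n_leapfrog += sub.n_leapfrog
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # biased progressive sampling: prefer the new subtree
        if np.log(rng.random()) < sub.log_sum_weight - log_sum_weight:
            q_prop, logp_prop, grad_prop = sub.q_prop, sub.logp_prop, sub.grad_prop
        log_sum_weight = np.logaddexp(log_sum_weight, sub.log_sum_weight)
        dq = q_plus - q_minus
        if np.dot(dq, inv_mass * p_minus) < 0 or np.dot(dq, inv_mass * p_plus) < 0:
            break

    accept_stat = sum_accept / max(n_leapfrog, 1)
    return q_prop, logp_prop, grad_prop, accept_stat, divergent


class _DualAveraging:
    """Nesterov dual averaging of log step size (gamma/t0/kappa as in the
    standard NUTS reference implementation)."""

    def __init__(self, eps0, target):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 1

    def update(self, accept_stat):
        m = self.count
        self.h_bar = (1 - 1 / (m + 10.0)) * self.h_bar + (self.target - accept_stat) / (m + 10.0)
        self.log_eps = self.mu - np.sqrt(m) / 0.05 * self.h_bar
        w = m ** (-0.75)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        self.count += 1
        return np.exp(self.log_eps)


def _adaptation_windows(tune: int) -> list[int]:
    """Iteration indices at which the mass matrix is re-estimated (ends of
    expanding windows between an initial and a terminal step-size buffer)."""
    init_buf, term_buf, base = 75, 50, 25
    if tune < init_buf + term_buf + base:
        return [int(0.6 * tune)] if tune >= 20 else []
    ends, start, w = [], init_buf, base
    while True:
        end = start + w
        if end + term_buf >= tune or end + 2 * w + term_buf > tune:
            ends.append(tune - term_buf)
            break
        ends.append(end)
        start, w = end, 2 * w
    return ends


def sample_nuts(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    settings: MCMCSettings,
    seed: int,
    init_inv_mass: np.ndarray | None = None,
) -> NUTSResult:
    """Run ``settings.chains`` independent NUTS chains from jittered ``x0``."""
    dim = x0.size
    rng_master = np.random.default_rng(seed)
    chain_seeds = rng_master.integers(0, 2**31 - 1, size=settings.chains)

    all_draws = np.empty((settings.chains, settings.draws, dim))
    all_logp = np.empty((settings.chains, settings.draws))
    accept_rates = np.empty(settings.chains)
    step_sizes = np.empty(settings.chains)
    n_div = 0

    windows = _adaptation_windows(settings.tune)

    for c in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[c])
        inv_mass = np.ones(dim) if init_inv_mass is None else init_inv_mass.copy()
        q = x0 + settings.jitter * 0.1 * rng.normal(size=dim) * np.sqrt(inv_mass)
        logp, grad = logp_and_grad(q)
        if not np.isfinite(logp):
            q = x0.copy()
            logp, grad = logp_and_grad(q)

        eps = _find_reasonable_epsilon(logp_and_grad, q, inv_mass, rng)
        da = _DualAveraging(eps, settings.target_accept)

        mean = np.zeros(dim)
        m2 = np.zeros(dim)
        n_acc = 0

        for it in range(settings.tune):
            q, logp, grad, a_stat, div = _nuts_step(
                logp_and_grad, q, logp, grad, eps, inv_mass, settings.max_treedepth, rng
            )
            eps = da.update(a_stat)
            n_acc += 1
            delta = q - mean
            mean += delta / n_acc
            m2 += delta * (q - mean)
            if it + 1 in windows:
                var = m2 / max(n_acc - 1, 1)
                # Stan-style regularization toward a small diagonal
                var = (n_acc / (n_acc + 5.0)) * var + (5.0 / (n_acc + 5.0)) * 1e-3
                inv_mass = np.maximum(var, 1e-10)
                mean[:] = 0.0
                m2[:] = 0.0
                n_acc = 0
                eps = _find_reasonable_epsilon(logp_and_grad, q, inv_mass, rng)
                da = _DualAveraging(eps, settings.target_accept)

        eps = np.exp(da.log_eps_bar)
        step_sizes[c] = eps

        acc_sum = 0.0
        for it in range(settings.draws):
            q, logp, grad, a_stat, div = _nuts_step(
                logp_and_grad, q, logp, grad, eps, inv_mass, settings.max_treedepth, rng
            )
            n_div += int(div)
            acc_sum += a_stat
            all_draws[c, it] = q
            all_logp[c, it] = logp
        accept_rates[c] = acc_sum / settings.draws

    return NUTSResult(all_draws, accept_rates, n_div, step_sizes, all_logp)


def diagnostics_table(named_draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-parameter Rhat and bulk ESS from (chain, draw) arrays."""
    ds = az.convert_to_dataset({k: v for k, v in named_draws.items()})
    rhat = az.rhat(ds)
    ess = az.ess(ds, method="bulk")
    rows = []
    for name, arr in named_draws.items():
        r = np.atleast_1d(np.asarray(rhat[name]))
        e = np.atleast_1d(np.asarray(ess[name]))
        if r.size == 1:
            rows.append({"parameter": name, "rhat": float(r[0]), "ess_bulk": float(e[0])})
        else:
            for i, (ri, ei) in enumerate(zip(r.ravel(), e.ravel())):
                rows.append({"parameter": f"{name}[{i}]", "rhat": float(ri), "ess_bulk": float(ei)})
    return pd.DataFrame(rows)
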