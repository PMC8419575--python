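"""Population Monte-Carlo approximate Bayesian computation.

Likelihood-free fitting of the six learning parameters: simulations are
run at proposed parameter values, summarised by the seven normalised
summary statistics, and accepted when their Euclidean distance to the
observed summary vector falls within a threshold ε that is tightened over
successive rounds (the default ladder is {6, 5.5, 5, 4.5, 4, 3.5, 3,
2.75, 2.5}).  Round 1 samples the prior; later rounds resample the
previous round's particles by weight, perturb them with a component-wise
Gaussian kernel whose variance is twice the weighted empirical variance
of the previous round (log10 space for log-uniform parameters), and
reweight with the usual importance ratio prior/(Σ w_j K_j).

The priors follow the published fit: N_t, P_n, μ and L_sm log-uniform on
{1,20}, {1e-7,0.25}, {1e-10,1e-3} and {1,100}; P_d and P_i uniform on
{1,20} and {0.2,6}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_core import LearningParams
from .summary_stats import distance, normalize, reference_sds

PARAM_NAMES = ("N_t", "P_n", "mu", "L_sm", "P_d", "P_i")
DEFAULT_EPS_SCHEDULE = (6.0, 5.5, 5.0, 4.5, 4.0, 3.5, 3.0, 2.75, 2.5)


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior law ("loguniform" or "uniform") and bounds."""

    laws: dict = field(
        default_factory=lambda: {
            "N_t": ("loguniform", 1.0, 20.0),
            "P_n": ("loguniform", 1e-7, 0.25),
            "mu": ("loguniform", 1e-10, 1e-3),
            "L_sm": ("loguniform", 1.0, 100.0),
            "P_d": ("uniform", 1.0, 20.0),
            "P_i": ("uniform", 0.2, 6.0),
        }
    )

    def __post_init__(self):
        for name in PARAM_NAMES:
            law, lo, hi = self.laws[name]
            if law == "loguniform":
                ok = 0 < lo < hi
            elif law == "uniform":
                ok = lo < hi
            else:
                ok = False
            if not ok:
                raise ValueError(f"bad prior for {name}: {self.laws[name]}")

    def is_log(self, name: str) -> bool:
        return self.laws[name][0] == "loguniform"

    def transformed_bounds(self) -> np.ndarray:
        """Bounds in sampling space: log10 for log-uniform parameters."""
        out = []
        for name in PARAM_NAMES:
            law, lo, hi = self.laws[name]
            if law == "loguniform":
                out.append((math.log10(lo), math.log10(hi)))
            else:
                out.append((lo, hi))
        return np.asarray(out)

    def to_natural(self, theta: np.ndarray) -> np.ndarray:
        out = np.asarray(theta, dtype=float).copy()
        for i, name in enumerate(PARAM_NAMES):
            if self.is_log(name):
                out[..., i] = 10.0 ** out[..., i]
        return out

    def to_transformed(self, natural: np.ndarray) -> np.ndarray:
        out = np.asarray(natural, dtype=float).copy()
        for i, name in enumerate(PARAM_NAMES):
            if self.is_log(name):
                out[..., i] = np.log10(out[..., i])
        return out

    def params_from_theta(self, theta: np.ndarray, **kwargs) -> LearningParams:
        nat = self.to_natural(np.asarray(theta, dtype=float))
        return LearningParams(*[float(x) for x in nat], **kwargs)


def sample_prior(spec: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    """One draw in transformed space (uniform there by construction)."""
    b = spec.transformed_bounds()
    return rng.uniform(b[:, 0], b[:, 1])


@dataclass
class Particle:
    theta: np.ndarray  # transformed space
    weight: float
    distance: float
    round_index: int

    def natural(self, spec: PriorSpec) -> np.ndarray:
        return spec.to_natural(self.theta)


def kernel_sigma(thetas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Component-wise kernel s.d.: sqrt of twice the weighted variance."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mean = (w[:, None] * thetas).sum(axis=0)
    var = (w[:, None] * (thetas - mean) ** 2).sum(axis=0)
    return np.sqrt(2.0 * var)


def perturb(
    theta: np.ndarray,
    sigma: np.ndarray,
    bounds: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    """Gaussian jitter in transformed space; out-of-prior proposals are redrawn.

    A degenerate (zero-variance) kernel component falls back to a minimal
    jitter of 1e-9 times the prior width so the sampler cannot stall.
    """
    sigma = np.asarray(sigma, dtype=float).copy()
    width = bounds[:, 1] - bounds[:, 0]
    floor = 1e-9 * width
    sigma = np.where(sigma > 0, sigma, floor)
    for _ in range(max_tries):
        prop = theta + sigma * rng.standard_normal(len(theta))
        if np.all((prop >= bounds[:, 0]) & (prop <= bounds[:, 1])):
            return prop
    return np.clip(theta, bounds[:, 0], bounds[:, 1])


def _kernel_density_matrix(new: np.ndarray, old: np.ndarray, sigma: np.ndarray):
    """K[i, j] = product of component normal densities of new_i around old_j."""
    sigma = np.where(sigma > 0, sigma, 1e-300)
    z = (new[:, None, :] - old[None, :, :]) / sigma[None, None, :]
    logk = -0.5 * (z**2) - np.log(sigma)[None, None, :]
    return np.exp(logk.sum(axis=2))


@dataclass
class ABCConfig:
    prior: PriorSpec
    runner: Callable[[LearningParams, int], np.ndarray]
    reference_sds: np.ndarray
    eps_schedule: Sequence[float] = DEFAULT_EPS_SCHEDULE
    n_accept: int = 1000
    max_sims_per_round: int = 200_000
    min_acceptance: float = 1e-4
    seed: int = 0
    out_dir: Path | None = None
    insert_rule: str = "scaled"

    def __post_init__(self):
        eps = list(self.eps_schedule)
        if any(b >= a for a, b in zip(eps, eps[1:])):
            raise ValueError("eps schedule must be strictly decreasing")


class RoundAborted(RuntimeError):
    """Raised when a PMC round's acceptance rate falls below the floor."""

    def __init__(self, round_index, eps, accepted, simulated):
        self.round_index, self.eps = round_index, eps
        self.accepted, self.simulated = accepted, simulated
        super().__init__(
            f"round {round_index} (eps={eps}): only {accepted} acceptances "
            f"in {simulated} simulations"
        )


def pmc_round(
    prev_particles,
    eps: float,
    observed_norm: np.ndarray,
    config: ABCConfig,
    round_index: int,
) -> tuple[list[Particle], dict]:
    """One PMC round: propose, simulate, accept at ``distance <= eps``, reweight."""
    rng = np.random.default_rng((config.seed, 100 + round_index))
    bounds = config.prior.transformed_bounds()
    if prev_particles:
        old = np.array([p.theta for p in prev_particles])
        old_w = np.array([p.weight for p in prev_particles])
        old_w = old_w / old_w.sum()
        sigma = kernel_sigma(old, old_w)
    accepted_thetas: list[np.ndarray] = []
    accepted_d: list[float] = []
    n_sim = 0
    while len(accepted_thetas) < config.n_accept:
        if n_sim >= config.max_sims_per_round:
            raise RoundAborted(round_index, eps, len(accepted_thetas), n_sim)
        if n_sim >= 1000 and len(accepted_thetas) < config.min_acceptance * n_sim:
            raise RoundAborted(round_index, eps, len(accepted_thetas), n_sim)
        if not prev_particles:
            theta = sample_prior(config.prior, rng)
        else:
            j = rng.choice(len(prev_particles), p=old_w)
            theta = perturb(old[j], sigma, bounds, rng)
        params = config.prior.params_from_theta(theta, insert_rule=config.insert_rule)
        sim_seed = int(rng.integers(2**31))
        vec = config.runner(params, sim_seed)
        n_sim += 1
        d = distance(normalize(vec, config.reference_sds), observed_norm)
        if d <= eps:
            accepted_thetas.append(theta)
            accepted_d.append(d)
    thetas = np.array(accepted_thetas)
    if not prev_particles:
        weights = np.full(len(thetas), 1.0 / len(thetas))
    else:
        K = _kernel_density_matrix(thetas, old, sigma)
        denom = K @ old_w
        weights = 1.0 / np.maximum(denom, 1e-300)  # prior density is constant
        weights = weights / weights.sum()
    particles = [
        Particle(t, float(w), float(d), round_index)
        for t, w, d in zip(thetas, weights, accepted_d)
    ]
    ess = float(1.0 / np.sum(weights**2))
    info = {
        "round": round_index,
        "eps": float(eps),
        "n_sim": n_sim,
        "acceptance_rate": len(particles) / n_sim,
        "ess": ess,
    }
    return particles, info


@dataclass
class ABCResult:
    rounds: list  # list[list[Particle]]
    diagnostics: list  # per-round info dicts
    prior: PriorSpec

    @property
    def posterior(self) -> list:
        return self.rounds[-1]

    def summary(self) -> pd.DataFrame:
        return posterior_summary(self.posterior, self.prior)


def particles_to_frame(particles, prior: PriorSpec) -> pd.DataFrame:
    nat = np.array([p.natural(prior) for p in particles])
    df = pd.DataFrame(nat, columns=list(PARAM_NAMES))
    df["weight"] = [p.weight for p in particles]
    df["distance"] = [p.distance for p in particles]
    df["round"] = [p.round_index for p in particles]
    return df


def _load_round(path: Path, prior: PriorSpec, round_index: int):
    df = pd.read_csv(path)
    thetas = prior.to_transformed(df[list(PARAM_NAMES)].to_numpy())
    return [
        Particle(t, float(w), float(d), round_index)
        for t, w, d in zip(thetas, df["weight"], df["distance"])
    ]


def fit(observed_transformed, config: ABCConfig) -> ABCResult:
    """Iterate PMC rounds over the ε ladder against an observed summary vector.

    ``observed_transformed`` is the square-root-transformed (not yet
    normalised) observed summary vector; normalisation uses the same
    reference SDs as the simulations.  Completed rounds are persisted to
    ``config.out_dir`` (one CSV per round) and reloaded on re-entry.
    """
    observed_norm = normalize(observed_transformed, config.reference_sds)
    rounds: list[list[Particle]] = []
    infos: list[dict] = []
    prev: list[Particle] = []
    for ri, eps in enumerate(config.eps_schedule, start=1):
        path = (
            config.out_dir / f"round_{ri:02d}.csv" if config.out_dir else None
        )
        if path is not None and path.exists():
            particles = _load_round(path, config.prior, ri)
            info = {"round": ri, "eps": float(eps), "resumed": True}
        else:
            particles, info = pmc_round(prev, eps, observed_norm, config, ri)
            if path is not None:
                path.parent.mkdir(parents=True, exist_ok=True)
                particles_to_frame(particles, config.prior).to_csv(path, index=False)
        rounds.append(particles)
        infos.append(info)
        prev = particles
    if config.out_dir:
        summary = posterior_summary(rounds[-1], config.prior)
        (config.out_dir / "posterior_summary.json").write_text(
            json.dumps(
                {
                    "median": summary["median"].to_dict(),
                    "cri_low": summary["cri_low"].to_dict(),
                    "cri_high": summary["cri_high"].to_dict(),
                    "rounds": infos,
                },
                indent=2,
                default=float,
            )
        )
    return ABCResult(rounds, infos, config.prior)


def weighted_quantile(values, quantiles, weights) -> np.ndarray:
    """Weighted empirical quantiles (interpolated, weights need not sum to 1)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    sorter = np.argsort(values)
    v, w = values[sorter], weights[sorter]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(quantiles, cum, v)


def posterior_summary(particles, prior: PriorSpec) -> pd.DataFrame:
    """Weighted median and central 95% credible interval per parameter."""
    nat = np.array([p.natural(prior) for p in particles])
    w = np.array([p.weight for p in particles])
    rows = {}
    for i, name in enumerate(PARAM_NAMES):
        lo, med, hi = weighted_quantile(nat[:, i], [0.025, 0.5, 0.975], w)
        rows[name] = {"median": med, "cri_low": lo, "cri_high": hi}
    return pd.DataFrame(rows).T


def compute_reference(
    runner, prior: PriorSpec, n_sims: int, seed: int, insert_rule: str = "scaled"
) -> tuple[np.ndarray, np.ndarray]:
    """Reference SDs from ``n_sims`` prior-predictive simulations.

    Returns ``(sds, vectors)`` where ``vectors`` stacks the transformed
    summary vectors; the SDs are meant to be persisted and reused across
    all ABC rounds fitted against the same scenario.
    """
    rng = np.random.default_rng((seed, 7))
    vecs = []
    for _ in range(n_sims):
        theta = sample_prior(prior, rng)
        params = prior.params_from_theta(theta, insert_rule=insert_rule)
        vecs.append(runner(params, int(rng.integers(2**31))))
    vectors = np.asarray(vecs)
    return reference_sds(vectors), vectors


def cross_validate(
    samples,
    n_leave_out: int,
    prior: PriorSpec,
    eps: float | None = None,
    min_neighbours: int = 20,
) -> pd.DataFrame:
    """Leave-one-out validation of the rejection step.

    ``samples`` is a sequence of ``(theta_transformed, normalized_vector)``
    pairs.  Each held-out sample's parameters are re-estimated as the
    median over the samples whose summary vectors fall within ``eps`` of
    the held-out vector (falling back to the ``min_neighbours`` nearest
    when the ε-ball is sparse).  Returns one row per held-out sample with
    the per-parameter estimation errors in transformed space.
    """
    if len(samples) < 2:
        raise ValueError("cross-validation needs at least 2 samples")
    thetas = np.array([np.asarray(t, dtype=float) for t, _ in samples])
    vecs = np.array([np.asarray(v, dtype=float) for _, v in samples])
    n_leave_out = min(n_leave_out, len(samples))
    rows = []
    for i in range(n_leave_out):
        d = np.linalg.norm(vecs - vecs[i], axis=1)
        d[i] = np.inf
        if eps is not None:
            neigh = np.flatnonzero(d <= eps)
            if len(neigh) < min_neighbours:
                neigh = np.argsort(d)[:min_neighbours]
        else:
            neigh = np.argsort(d)[:min_neighbours]
        est = np.median(thetas[neigh], axis=0)
        rows.append(est - thetas[i])
    return pd.DataFrame(rows, columns=[f"err_{n}" for n in PARAM_NAMES])
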