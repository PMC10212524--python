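"""Inverse problem: estimating p13C, substrate purity q, and the pathway
distribution z from observed isotopologue envelopes.

The labeling fit minimizes the unweighted sum of squared residuals between
the observed normalized envelope and the forward model. The simplex
constraint on z (z >= 0, sum z = 1) is enforced by reparameterization:
z_i = u_i^2 / sum_j u_j^2 with u unconstrained, so a standard bounded
trust-region least-squares solver can be used. q is bounded to [0, 1].

The parameterization has one gauge degree of freedom (the overall scale of
u); standard errors are propagated through the reparameterization with a
pseudo-inverse, which projects out the gauge direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import binom

from .errors import DataError, DomainError
from .model import (
    CompoundSpec,
    Envelope,
    ModelConfig,
    PathwayDistribution,
    PrecursorSpec,
    mixture_deuterium_distribution,
    truncated_c13_envelope,
)

# solver constants (documented): relative step/objective tolerance and the
# evaluation budget of every nonlinear fit in this module
FTOL = 1e-12
XTOL = 1e-12
GTOL = 1e-14
MAX_NFEV = 5000

#: observed intensity beyond the model support is tolerated (trimmed and
#: renormalized) up to this total fraction — it is the float-tail left by
#: the 13C truncation — and is a data error above it.
SUPPORT_SLACK = 1e-9

#: RSS above which the labeling fit is retried from random starts; chosen
#: above the ~1e-6 residual floor of 1e6-ion counting noise so that noisy
#: but converged fits do not trigger restarts.
RESTART_RSS_THRESHOLD = 1e-5
N_RESTARTS = 10


class P13CEstimate(NamedTuple):
    """Result of the global natural-13C-abundance fit.

    ``curvature`` is the Gauss-Newton information J'J at the optimum; it adds
    across envelopes, which is what makes a joint fit sharper than either
    single-envelope fit at a common noise level.
    """

    value: float
    se: float
    rss: float
    converged: bool
    n_envelopes: int
    curvature: float = 0.0


@dataclass
class LabelFit:
    """Result of a per-experiment (q, z) deconvolution fit."""

    q_hat: float
    z_hat: PathwayDistribution
    p13C_fixed: float
    rss: float
    se_q: float
    se_z: np.ndarray
    n_params: int
    converged: bool
    n_obs: int
    compound: str = ""
    precursor: str = ""
    purity_mode: str = "unit"
    q_fixed: bool = False
    n_restarts_used: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        """JSON-serializable report of the fit."""
        return {
            "compound": self.compound,
            "precursor": self.precursor,
            "purity_mode": self.purity_mode,
            "q_hat": float(self.q_hat),
            "q_fixed": bool(self.q_fixed),
            "se_q": float(self.se_q),
            "z_hat": [float(v) for v in self.z_hat.z],
            "se_z": [float(v) for v in self.se_z],
            "p13C_fixed": float(self.p13C_fixed),
            "rss": float(self.rss),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "message": self.message,
        }


@dataclass
class IsotopologueGrid:
    """Joint distribution P(k_D, k_13C): rows index the deuterium-atom count,
    columns the 13C count. Collapsing anti-diagonals (Δm = k_D + k_13C)
    reproduces the fitted envelope."""

    matrix: np.ndarray

    def deuterium_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def c13_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def envelope(self) -> Envelope:
        """Anti-diagonal collapse onto the Δm grid."""
        n_d, n_c = self.matrix.shape
        out = np.zeros(n_d + n_c - 1)
        for kd in range(n_d):
            out[kd: kd + n_c] += self.matrix[kd]
        return Envelope(out / out.sum(), normalized=True)


# ---------------------------------------------------------------------------
# p13C global fit
# ---------------------------------------------------------------------------

def estimate_p13C(native: Sequence[tuple[Envelope, int]], p0: float = 0.011) -> P13CEstimate:
    """Global fit of a single 13C abundance shared across native envelopes.

    Each native (unlabeled) envelope of a compound with ``n`` carbons is
    modeled as Binomial(n, p); one ``p`` minimizes the summed squared
    residuals over all spectra. The standard error comes from the curvature
    of the objective (Gauss-Newton approximation).
    """
    if len(native) == 0:
        raise DataError("estimate_p13C requires at least one native envelope")
    pairs = []
    for env, n_carbons in native:
        e = env if env.normalized else env.normalize()
        pairs.append((e.intensities, int(n_carbons)))

    def residuals(x: np.ndarray) -> np.ndarray:
        p = x[0]
        parts = []
        for obs, n in pairs:
            k = np.arange(len(obs))
            parts.append(obs - binom.pmf(k, n, p))
        return np.concatenate(parts)

    res = least_squares(
        residuals, x0=[p0], bounds=([0.0], [0.5]),
        ftol=FTOL, xtol=XTOL, gtol=GTOL, max_nfev=MAX_NFEV,
    )
    p_hat = float(res.x[0])
    rss = float(res.cost * 2)
    # boundary polish: a monoisotopic-only spectrum has its optimum exactly
    # at p = 0, which the trust-region solver only approaches
    rss_zero = float(np.sum(residuals(np.array([0.0])) ** 2))
    if rss_zero <= rss:
        p_hat, rss = 0.0, rss_zero
    m = sum(len(obs) for obs, _ in pairs)
    dof = max(m - 1, 1)
    jtj = float(np.squeeze(res.jac.T @ res.jac))
    se = float(np.sqrt(rss / dof / jtj)) if jtj > 0 else float("inf")
    return P13CEstimate(
        value=p_hat, se=se, rss=rss,
        converged=bool(res.status > 0), n_envelopes=len(pairs),
        curvature=jtj,
    )


# ---------------------------------------------------------------------------
# labeling fit
# ---------------------------------------------------------------------------

def _z_from_u(u: np.ndarray) -> np.ndarray:
    s = u @ u
    if s == 0:
        raise DomainError("degenerate z parameterization (all-zero amplitudes)")
    return u * u / s


def _z_jacobian(u: np.ndarray) -> np.ndarray:
    """d z_i / d u_j for z = u^2 / |u|^2."""
    s = u @ u
    z = u * u / s
    return (2.0 / s) * (np.diag(u) - np.outer(z, u))


def _model_envelope(
    u: np.ndarray, q: float, c13: np.ndarray,
    precursor_d: int, n_units: int, purity_mode: str, n_obs: int,
) -> np.ndarray:
    z = PathwayDistribution(_z_from_u(u))
    prec = PrecursorSpec("fit", precursor_d, float(np.clip(q, 0.0, 1.0)))
    deut = mixture_deuterium_distribution(z, prec, purity_mode)
    env = np.convolve(c13, deut)
    env = env / env.sum()
    if len(env) < n_obs:
        env = np.pad(env, (0, n_obs - len(env)))
    return env[:n_obs]


def fit_labeling(
    observed: Envelope,
    compound: CompoundSpec,
    precursor: PrecursorSpec,
    config: ModelConfig = ModelConfig(),
    q_fixed: float | None = None,
    weights: np.ndarray | None = None,
    restart_seed: int = 0,
) -> LabelFit:
    """Estimate (q, z) for one labeling experiment by constrained nonlinear
    least squares against the forward envelope model.

    ``q_fixed`` holds the substrate impurity at a known value (the standard
    protocol for competitive experiments, where q and z are partially
    confounded: fix q from the single-precursor fits). ``weights`` enables
    optional Poisson-variance weighting (w_k multiplies residual k); the
    default is unweighted.

    Initialization is z uniform, q = 0.01; if the first solution's RSS
    exceeds ``RESTART_RSS_THRESHOLD``, ten seeded random restarts are run
    and the best RSS wins (ties broken by the lowest q_hat).
    """
    obs = (observed if observed.normalized else observed.normalize()).intensities
    n_units = compound.n_units
    d = precursor.d
    c13 = truncated_c13_envelope(compound.n_carbons, config.p13C)
    model_support = len(c13) - 1 + d * n_units
    if len(obs) - 1 > model_support:
        tail = obs[model_support + 1:]
        if tail.sum() > SUPPORT_SLACK:
            bad = int(np.nonzero(tail > 0)[0][0] + model_support + 1)
            raise DataError(
                f"observed envelope has intensity at Δm={bad}, beyond the model's "
                f"maximal shift {model_support} for {compound.name}/{precursor.name}"
            )
        obs = obs[: model_support + 1]
        obs = obs / obs.sum()
    n_obs = len(obs)
    w = np.ones(n_obs) if weights is None else np.asarray(weights, dtype=float)
    fit_q = q_fixed is None

    def unpack(x: np.ndarray) -> tuple[np.ndarray, float]:
        if fit_q:
            return x[1:], float(x[0])
        return x, float(q_fixed)

    def residuals(x: np.ndarray) -> np.ndarray:
        u, q = unpack(x)
        env = _model_envelope(u, q, c13, d, n_units, config.purity_mode, n_obs)
        return w * (obs - env)

    u0 = np.full(n_units + 1, 1.0 / np.sqrt(n_units + 1))
    x0 = np.concatenate(([0.01], u0)) if fit_q else u0
    if fit_q:
        lb = np.concatenate(([0.0], np.full(n_units + 1, -np.inf)))
        ub = np.concatenate(([1.0], np.full(n_units + 1, np.inf)))
    else:
        lb, ub = -np.inf, np.inf

    def solve(x_init: np.ndarray):
        return least_squares(
            residuals, x_init, bounds=(lb, ub),
            ftol=FTOL, xtol=XTOL, gtol=GTOL, max_nfev=MAX_NFEV, method="trf",
        )

    best = solve(x0)
    restarts_used = 0
    if 2 * best.cost > RESTART_RSS_THRESHOLD:
        rng = np.random.default_rng(restart_seed)
        for _ in range(N_RESTARTS):
            restarts_used += 1
            u_r = np.sqrt(rng.dirichlet(np.ones(n_units + 1)))
            x_r = np.concatenate(([rng.uniform(0.0, 0.05)], u_r)) if fit_q else u_r
            cand = solve(x_r)
            better = cand.cost < best.cost - 1e-15
            tie = abs(cand.cost - best.cost) <= 1e-15
            if better or (tie and fit_q and cand.x[0] < best.x[0]):
                best = cand

    u_hat, q_hat = unpack(best.x)
    z_hat = PathwayDistribution(_z_from_u(u_hat))
    rss = float(2 * best.cost)

    # standard errors: delta method through z = u^2/|u|^2, pinv for the gauge
    n_params = 1 + (n_units + 1)
    dof = max(n_obs - (n_params if fit_q else n_units + 1), 1)
    s2 = rss / dof
    jtj = best.jac.T @ best.jac
    cov_x = s2 * np.linalg.pinv(jtj, rcond=1e-12)
    if fit_q:
        se_q = float(np.sqrt(max(cov_x[0, 0], 0.0)))
        cov_u = cov_x[1:, 1:]
    else:
        se_q = 0.0
        cov_u = cov_x
    g = _z_jacobian(u_hat)
    cov_z = g @ cov_u @ g.T
    se_z = np.sqrt(np.clip(np.diag(cov_z), 0.0, None))

    return LabelFit(
        q_hat=float(np.clip(q_hat, 0.0, 1.0)),
        z_hat=z_hat,
        p13C_fixed=config.p13C,
        rss=rss,
        se_q=se_q,
        se_z=se_z,
        n_params=n_params,
        converged=bool(best.status > 0),
        n_obs=n_obs,
        compound=compound.name,
        precursor=precursor.name,
        purity_mode=config.purity_mode,
        q_fixed=not fit_q,
        n_restarts_used=restarts_used,
        message=str(best.message),
    )


def deconvolute_grid(
    fit: LabelFit,
    compound: CompoundSpec,
    precursor: PrecursorSpec,
    config: ModelConfig = ModelConfig(),
) -> IsotopologueGrid:
    """2-D joint isotopologue distribution implied by a converged fit:
    P(k_D, k_13C) = D(k_D) · Binomial(n_carbons, p13C)(k_13C), where D is the
    deuterium-count distribution implied by (z_hat, q_hat).

    This is the model behind the "deconvoluted spectrum" view: every
    deuterated isotopologue replicates the compound's 13C envelope, offset
    by its deuterium count.
    """
    if not fit.converged:
        raise DataError("deconvolute_grid requires a converged labeling fit")
    prec = PrecursorSpec(precursor.name, precursor.d, fit.q_hat)
    deut = mixture_deuterium_distribution(fit.z_hat, prec, fit.purity_mode)
    c13 = truncated_c13_envelope(compound.n_carbons, config.p13C)
    return IsotopologueGrid(np.outer(deut, c13))
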