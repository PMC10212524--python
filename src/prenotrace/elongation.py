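"""Mechanistic chain-elongation model for deuteriation patterns.

A step-by-step elongation process with a constant per-step probability p of
drawing the next isoprene unit from the labeled pathway produces a power-law
deuteriation pattern

    y(k) = a + (b - a) * p**k        (MVA orientation)
    y(k) = a + (b - a) * p**(N - k)  (MEP orientation)

where a and b are the asymptotic populations of natural-abundance and fully
deuterated chains, and k counts deuterated isoprene units. The monoisotopic
point k = 0 is always excluded from fitting: it aggregates molecules that
never entered the labeled pool and is diagnostic for a separate unlabeled
pool (see :func:`pool_discrepancy`). An estimated p > 1 is mechanistically
impossible and flags the model as inapplicable for that experiment (observed
for Pren-11 under mevalonolactone feeding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, DomainError
from .metrics import DeuteriationPattern

FTOL = 1e-12
XTOL = 1e-12
MAX_NFEV = 5000

#: default multiple of the extrapolation SE above which the intercept
#: discrepancy is called a second, unlabeled-only pool
POOL_SE_MULTIPLE = 3.0
#: absolute floor on the verdict threshold, guarding the SE ~ 0 case of
#: noiseless constructed patterns against float round-off
POOL_ABS_FLOOR = 1e-8

#: default residual threshold (pattern fraction) for initial-unit deviations
DEVIATION_THRESHOLD = 0.01


@dataclass
class ElongationFit:
    """Fitted parameters of the elongation power law."""

    a: float
    b: float
    p: float
    orientation: str  # "MVA" | "MEP"
    window: tuple[int, ...]
    n_units: int
    se: dict
    rss: float
    converged: bool
    cov: np.ndarray | None = None

    @property
    def p_gt_1(self) -> bool:
        return self.p > 1.0

    def predict(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        expo = k if self.orientation == "MVA" else self.n_units - k
        return self.a + (self.b - self.a) * self.p ** expo

    def to_dict(self) -> dict:
        return {
            "a": float(self.a),
            "b": float(self.b),
            "p": float(self.p),
            "orientation": self.orientation,
            "window": list(self.window),
            "se_a": float(self.se.get("a", float("nan"))),
            "se_b": float(self.se.get("b", float("nan"))),
            "se_p": float(self.se.get("p", float("nan"))),
            "rss": float(self.rss),
            "p_gt_1": bool(self.p_gt_1),
            "converged": bool(self.converged),
        }


def normalize_pattern(pattern: DeuteriationPattern) -> DeuteriationPattern:
    """Rescale a nonnegative pattern to total population 1 (idempotent)."""
    return pattern.normalized()


def default_window(n_units: int) -> tuple[int, ...]:
    """Default fit window k = 1..min(6, N-1): the initial turns of the
    elongation machinery, excluding the monoisotopic point."""
    return tuple(range(1, min(6, n_units - 1) + 1))


def fit_elongation(
    pattern: DeuteriationPattern,
    orientation: str = "MVA",
    window: tuple[int, ...] | None = None,
    exclude_full: bool = False,
) -> ElongationFit:
    """Least-squares fit of (a, b, p) to a deuteriation pattern.

    ``window`` is the set of k values used (default ``default_window``);
    k = 0 is never allowed. ``exclude_full`` drops k = N from the window
    (where b dominates). Initialization takes p0 from the log-linear slope
    of the window when all its values are positive, so exactly flat patterns
    converge to p = 1 deterministically.
    """
    if orientation not in ("MVA", "MEP"):
        raise DomainError(f"orientation must be 'MVA' or 'MEP', got {orientation!r}")
    pat = pattern if pattern.is_normalized() else pattern.normalized()
    n = pat.n_units
    win = tuple(window) if window is not None else default_window(n)
    if any(k < 1 or k > n for k in win):
        raise DomainError(f"window {win} must lie within 1..{n}")
    if exclude_full:
        win = tuple(k for k in win if k != n)
    if len(win) < 3:
        raise DataError(f"elongation fit needs >= 3 window points, got {len(win)}")
    k = np.asarray(win, dtype=float)
    y = pat.values[list(win)]
    expo = k if orientation == "MVA" else n - k

    # initial values: slope of ln y when usable, otherwise a mild decay
    pos = y > 0
    if pos.all() and len(set(expo)) > 1:
        slope = np.polyfit(expo, np.log(y), 1)[0]
        p0 = float(np.clip(np.exp(slope), 1e-3, 1e3))
    else:
        p0 = 0.5
    b0 = float(max(y[np.argmin(expo)] / max(p0 ** expo.min(), 1e-300), 1e-12))
    a0 = 0.0

    def residuals(x: np.ndarray) -> np.ndarray:
        a, b, p = x
        return y - (a + (b - a) * p ** expo)

    res = least_squares(
        residuals, x0=[a0, b0, p0],
        bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
        ftol=FTOL, xtol=XTOL, max_nfev=MAX_NFEV,
    )
    rss = float(2 * res.cost)
    dof = max(len(win) - 3, 1)
    cov = rss / dof * np.linalg.pinv(res.jac.T @ res.jac, rcond=1e-12)
    se = {name: float(np.sqrt(max(cov[i, i], 0.0))) for i, name in enumerate("abp")}
    return ElongationFit(
        a=float(res.x[0]), b=float(res.x[1]), p=float(res.x[2]),
        orientation=orientation, window=win, n_units=n,
        se=se, rss=rss, converged=bool(res.status > 0), cov=cov,
    )


def elongation_probability_loglinear(
    pattern: DeuteriationPattern,
    window: tuple[int, ...] | None = None,
    weighted: bool = False,
) -> float:
    """Per-step elongation probability as exp(slope) of the ordinary
    least-squares regression of ln(pattern(k)) on k over the window.

    ``weighted`` applies variance-stabilizing weights proportional to
    pattern(k) (the delta-method variance of ln y is ~1/y for counting
    noise). Interpretation of p > 1 is the caller's concern.
    """
    pat = pattern if pattern.is_normalized() else pattern.normalized()
    win = tuple(window) if window is not None else default_window(pat.n_units)
    y = pat.values[list(win)]
    bad = [int(k) for k, v in zip(win, y) if v <= 0]
    if bad:
        raise DataError(
            f"log-linear fit requires positive pattern values; "
            f"nonpositive at k={bad}"
        )
    k = np.asarray(win, dtype=float)
    w = y if weighted else np.ones_like(y)
    slope = np.polyfit(k, np.log(y), 1, w=np.sqrt(w))[0]
    return float(np.exp(slope))


def pool_discrepancy(
    fit: ElongationFit,
    observed_unlabeled: float,
    se_multiple: float = POOL_SE_MULTIPLE,
) -> tuple[float, str]:
    """Excess of observed unlabeled molecules over the elongation-model
    extrapolation at k = 0.

    Returns ``(discrepancy, verdict)`` with discrepancy =
    observed_unlabeled - model(0) and verdict ``"two-pool"`` when
    |discrepancy| strictly exceeds ``se_multiple`` times the extrapolation's
    standard error (with a small absolute floor), else ``"single-pool"``.
    A large positive discrepancy indicates a second pool of molecules that
    never draws from the labeled precursor.
    """
    if not fit.converged:
        raise DataError("pool_discrepancy requires a converged elongation fit")
    y0 = float(fit.predict(0))
    discrepancy = float(observed_unlabeled) - y0
    expo = 0.0 if fit.orientation == "MVA" else float(fit.n_units)
    pe = fit.p ** expo
    # gradient of y0 = a + (b-a) p^expo w.r.t. (a, b, p)
    grad = np.array([
        1.0 - pe,
        pe,
        (fit.b - fit.a) * expo * fit.p ** (expo - 1.0) if expo > 0 else 0.0,
    ])
    se_y0 = 0.0
    if fit.cov is not None:
        se_y0 = float(np.sqrt(max(grad @ fit.cov @ grad, 0.0)))
    threshold = max(se_multiple * se_y0, POOL_ABS_FLOOR)
    verdict = "two-pool" if abs(discrepancy) > threshold else "single-pool"
    return discrepancy, verdict


def initial_unit_deviation(
    pattern: DeuteriationPattern,
    fit: ElongationFit,
    threshold: float = DEVIATION_THRESHOLD,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Residual profile (observed - model) over k = 1..N and flagged ranges.

    Contiguous runs of >= 2 same-signed residuals with |residual| >
    ``threshold`` are returned as inclusive (k_start, k_end) ranges. A run
    at low k signals a systematic pathway preference for the initial units
    of the chain that the constant-probability model cannot express.
    """
    if not fit.converged:
        raise DataError("initial_unit_deviation requires a converged elongation fit")
    pat = pattern if pattern.is_normalized() else pattern.normalized()
    k = np.arange(1, pat.n_units + 1)
    residuals = pat.values[1:] - fit.predict(k)
    flagged: list[tuple[int, int]] = []
    run_start = None
    run_sign = 0
    for idx, r in zip(k, residuals):
        sign = 0 if abs(r) <= threshold else (1 if r > 0 else -1)
        if sign != 0 and sign == run_sign:
            continue
        if run_sign != 0 and run_start is not None and idx - run_start >= 2:
            flagged.append((int(run_start), int(idx - 1)))
        run_start = idx if sign != 0 else None
        run_sign = sign
    if run_sign != 0 and run_start is not None and pat.n_units - run_start + 1 >= 2:
        flagged.append((int(run_start), int(pat.n_units)))
    return residuals, flagged
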