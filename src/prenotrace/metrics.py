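"""Labeling metrics derived from a deconvolution fit.

The central object is the deuteriation pattern: the fraction of molecules
carrying exactly k deuterated isoprene units, k = 0..N. It is obtained from
the fitted pathway distribution z by binomial thinning with the substrate
impurity q (a pathway-labeled unit fails to carry deuterium when its
precursor molecule was unlabeled). All summary metrics — deuteriation
level, average number of labeled units, unlabeled/partial/full population
fractions — are functionals of the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .deconv import LabelFit
from .errors import DataError, DomainError
from .model import PrecursorSpec

_NORM_TOL = 1e-9


@dataclass
class DeuteriationPattern:
    """Fraction of molecules with exactly k deuterated units, k = 0..N.

    ``axis`` records what k counts: isoprene units (unit-level purity mode)
    or deuterium atoms (site-level mode, where intact-unit counts are not
    defined).
    """

    values: np.ndarray
    axis: str = "isoprene_units"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if np.any(arr < -1e-12):
            raise DomainError("pattern entries must be nonnegative")
        self.values = np.clip(arr, 0.0, None)

    @property
    def n_units(self) -> int:
        return len(self.values) - 1

    def normalized(self) -> "DeuteriationPattern":
        total = self.values.sum()
        if total <= 0:
            raise DataError("cannot normalize an all-zero deuteriation pattern")
        return DeuteriationPattern(self.values / total, axis=self.axis)

    def is_normalized(self) -> bool:
        return abs(self.values.sum() - 1.0) <= _NORM_TOL

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, k):
        return self.values[k]


def deuteriation_pattern(fit: LabelFit, precursor: PrecursorSpec) -> DeuteriationPattern:
    """Deuteriation pattern implied by a converged fit.

    Unit-level mode: pattern(j) = sum_i z(i) C(i, j) (1-q)^j q^(i-j) — the
    pathway-labeled unit count thinned by substrate impurity. Site-level
    mode: the pattern is returned over deuterium-atom counts instead and
    flagged via ``axis``.
    """
    if not fit.converged:
        raise DataError("deuteriation_pattern requires a converged fit")
    z = fit.z_hat.z
    n = len(z) - 1
    q = fit.q_hat
    if fit.purity_mode == "site":
        from .model import PathwayDistribution, mixture_deuterium_distribution

        deut = mixture_deuterium_distribution(
            PathwayDistribution(z), PrecursorSpec(precursor.name, precursor.d, q), "site"
        )
        return DeuteriationPattern(deut, axis="deuterium_atoms")
    i = np.arange(n + 1)
    # thin[i, j] = P(j of i labeled units carry deuterium)
    thin = comb(i[:, None], i[None, :]) * (1.0 - q) ** i[None, :] \
        * np.where(i[:, None] - i[None, :] >= 0, q ** np.clip(i[:, None] - i[None, :], 0, None), 0.0)
    thin[i[:, None] < i[None, :]] = 0.0
    pattern = z @ thin
    return DeuteriationPattern(pattern / pattern.sum(), axis="isoprene_units")


def deuteriation_level(pattern: DeuteriationPattern) -> float:
    """Percentage of molecules with at least one deuterated unit:
    100 * (1 - pattern(0))."""
    p = pattern if pattern.is_normalized() else pattern.normalized()
    return 100.0 * (1.0 - float(p[0]))


def average_labeled_units(pattern: DeuteriationPattern) -> float:
    """Mean number of deuterated isoprene units per molecule."""
    p = pattern if pattern.is_normalized() else pattern.normalized()
    return float(np.arange(len(p)) @ p.values)


def population_fractions(pattern: DeuteriationPattern) -> tuple[float, float, float]:
    """(unlabeled %, partially labeled %, fully labeled %); sums to 100."""
    p = pattern if pattern.is_normalized() else pattern.normalized()
    unlabeled = 100.0 * float(p[0])
    full = 100.0 * float(p[p.n_units])
    partial = 100.0 * float(p.values[1:-1].sum())
    return unlabeled, partial, full


def pathway_view(
    pattern: DeuteriationPattern, precursor: PrecursorSpec
) -> DeuteriationPattern:
    """Re-index the pattern as a contribution of the MEP pathway.

    For DX labeling k already counts MEP-derived units (identity). For MVL
    labeling k counts MVA-derived units, so the MEP contribution is the
    reversed index k -> N - k. The map is an involution, hence also its own
    inverse.
    """
    if precursor.name.upper().startswith("MVL"):
        return DeuteriationPattern(pattern.values[::-1].copy(), axis=pattern.axis)
    return DeuteriationPattern(pattern.values.copy(), axis=pattern.axis)


def metrics_row(
    fit: LabelFit, precursor: PrecursorSpec, tissue: str = ""
) -> dict:
    """One delimited-table row of summary metrics for a fitted experiment.

    Percentages are rounded to integers and the average to one decimal for
    reporting; use the metric functions directly for full precision.
    """
    pattern = deuteriation_pattern(fit, precursor)
    unlabeled, partial, full = population_fractions(pattern)
    return {
        "compound": fit.compound,
        "tissue": tissue,
        "precursor": fit.precursor,
        "non_deuteriated_pct": round(unlabeled),
        "partially_deuteriated_pct": round(partial),
        "fully_deuteriated_pct": round(full),
        "deuteriation_level_pct": round(deuteriation_level(pattern)),
        "average_deuteriated_units": round(average_labeled_units(pattern), 1),
    }
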