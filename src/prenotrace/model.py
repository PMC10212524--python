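"""Domain types and the forward isotopologue-envelope model.

The observed isotopic envelope of a metabolically deuterated polyisoprenoid
is modeled as the discrete convolution of three independent distributions
over integer nominal mass shift Δm (relative to the monoisotopic unlabeled
ion):

1. natural ``13C`` abundance — Binomial(n_carbons, p13C) over the number of
   13C atoms;
2. substrate deuterium purity — each isoprene unit drawn from the labeled
   precursor carries its d deuterium atoms unless the precursor molecule was
   unlabeled (probability ``q``);
3. pathway mixing — the cross-talk distribution ``z(i)``, i = 0..N, of the
   number of isoprene units derived from the deuterated precursor's pathway
   (MEP for deoxyxylulose, MVA for mevalonolactone).

Each 13C and each 2H substitution contributes +1 to Δm (unit-mass grid; the
~3 mDa 13C/2H mass-defect difference is far below unit resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .errors import ContractViolation, DomainError
from .masses import adduct_mz

_NORM_TOL = 1e-12

#: cumulative-tail cutoff used to truncate the 13C binomial support and bound
#: convolution cost; the discarded mass is redistributed by renormalization.
TAIL_TRUNCATION = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecursorSpec:
    """A deuterated pathway-specific precursor.

    Parameters
    ----------
    name:
        Label, e.g. ``"DX"`` (deoxyxylulose, MEP pathway) or ``"MVL"``
        (mevalonolactone, MVA pathway).
    d:
        Deuterium atoms delivered per isoprene unit (2 for 2H2-DX,
        3 for 2H3-MVL).
    q:
        Fraction of unlabeled (all-1H) molecules in the labeled substrate,
        dimensionless in [0, 1].
    """

    name: str
    d: int
    q: float

    def __post_init__(self) -> None:
        if self.d < 1:
            raise DomainError(f"precursor {self.name}: d must be >= 1, got {self.d}")
        if not 0.0 <= self.q <= 1.0:
            raise DomainError(f"precursor {self.name}: q must lie in [0, 1], got {self.q}")


@dataclass(frozen=True)
class CompoundSpec:
    """An analyte whose envelope is modeled.

    ``n_units`` is the number of label-bearing isoprene units N (11 for
    Pren-11, 16 for Dol-16; configurable for sterols, whose triterpene
    skeleton does not map 1:1 onto intact C5 units). ``n_carbons`` defaults
    to the carbon count of ``formula`` and must equal 5·N for polyprenols
    and dolichols.
    """

    name: str
    family: str  # polyprenol | dolichol | sterol | generic
    n_units: int
    formula: dict[str, int] = field(hash=False)
    adducts: tuple[str, ...] = ("M+",)
    n_carbons: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise DomainError(f"{self.name}: n_units must be >= 1")
        nc = self.formula.get("C", 0) if self.n_carbons is None else self.n_carbons
        object.__setattr__(self, "n_carbons", nc)
        if "C" in self.formula and self.formula["C"] != nc:
            raise ContractViolation(
                f"{self.name}: n_carbons={nc} inconsistent with formula carbon count "
                f"{self.formula['C']}"
            )
        if self.family in ("polyprenol", "dolichol") and nc != 5 * self.n_units:
            raise ContractViolation(
                f"{self.name}: {self.family} requires n_carbons = 5 N "
                f"({5 * self.n_units}), got {nc}"
            )

    def base_mz(self, adduct: str) -> float:
        """Monoisotopic m/z of the unlabeled ion for ``adduct``."""
        return adduct_mz(self.formula, adduct)


@dataclass(frozen=True)
class ModelConfig:
    """Forward-model configuration.

    ``purity_mode``:

    * ``"unit"`` (default) — substrate impurity acts per precursor molecule:
      a pathway-labeled unit carries all d deuteriums with probability 1−q,
      none otherwise (all-or-none).
    * ``"site"`` — impurity acts per deuterium site: each of the d·i sites is
      deuterated independently with probability 1−q.
    """

    p13C: float = 0.0102
    purity_mode: str = "unit"
    max_shift: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p13C <= 1.0:
            raise DomainError(f"p13C must lie in [0, 1], got {self.p13C}")
        if self.purity_mode not in ("unit", "site"):
            raise DomainError(f"purity_mode must be 'unit' or 'site', got {self.purity_mode!r}")


class Envelope:
    """Nonnegative intensity vector over integer Δm = 0..K.

    ``normalized`` envelopes sum to 1 within 1e-12.
    """

    __slots__ = ("intensities", "normalized")

    def __init__(self, intensities, normalized: bool = False):
        arr = np.asarray(intensities, dtype=float)
        if arr.ndim != 1:
            raise ContractViolation("envelope intensities must be one-dimensional")
        if np.any(arr < 0):
            raise DomainError("envelope intensities must be nonnegative")
        if normalized and abs(arr.sum() - 1.0) > 1e-9:
            raise ContractViolation(
                f"envelope flagged normalized but sums to {arr.sum()!r}"
            )
        self.intensities = arr
        self.normalized = bool(normalized)

    def normalize(self) -> "Envelope":
        total = self.intensities.sum()
        if total <= 0:
            raise DomainError("cannot normalize an all-zero envelope")
        return Envelope(self.intensities / total, normalized=True)

    def __len__(self) -> int:
        return len(self.intensities)

    def __getitem__(self, i):
        return self.intensities[i]

    def mean_shift(self) -> float:
        """First moment E[Δm] of the (normalized) envelope."""
        env = self if self.normalized else self.normalize()
        return float(np.arange(len(env)) @ env.intensities)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Envelope(K={len(self) - 1}, normalized={self.normalized})"


class PathwayDistribution:
    """Probability vector z(i), i = 0..N, of units derived from the labeled
    precursor's pathway (the MEP/MVA cross-talk distribution)."""

    __slots__ = ("z",)

    def __init__(self, z):
        arr = np.asarray(z, dtype=float)
        if arr.ndim != 1 or len(arr) < 1:
            raise ContractViolation("z must be a one-dimensional vector of length N+1")
        if np.any(arr < -_NORM_TOL):
            raise DomainError("z entries must be nonnegative")
        arr = np.clip(arr, 0.0, None)
        if abs(arr.sum() - 1.0) > 1e-9:
            raise DomainError(f"z must sum to 1, sums to {arr.sum()!r}")
        self.z = arr / arr.sum()

    @property
    def n_units(self) -> int:
        return len(self.z) - 1

    def mean(self) -> float:
        return float(np.arange(len(self.z)) @ self.z)

    @classmethod
    def delta(cls, i: int, n_units: int) -> "PathwayDistribution":
        z = np.zeros(n_units + 1)
        z[i] = 1.0
        return cls(z)

    def __len__(self) -> int:
        return len(self.z)

    def __getitem__(self, i):
        return self.z[i]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def binomial_envelope(n_trials: int, p: float) -> Envelope:
    """Binomial(n_trials, p) mass distribution as a normalized envelope.

    Models the number of heavy-isotope substitutions among ``n_trials``
    exchangeable positions (e.g. 13C atoms among n carbons).
    """
    if n_trials < 0:
        raise DomainError(f"n_trials must be >= 0, got {n_trials}")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must lie in [0, 1], got {p}")
    pmf = binom.pmf(np.arange(n_trials + 1), n_trials, p)
    return Envelope(pmf / pmf.sum(), normalized=True)


def truncated_c13_envelope(n_carbons: int, p13C: float) -> np.ndarray:
    """13C binomial envelope truncated where the upper tail < TAIL_TRUNCATION.

    Returned renormalized; bounds the convolution support for long-chain
    compounds (Dol-24 has 120 carbons but only ~10 relevant 13C bins).
    """
    pmf = binom.pmf(np.arange(n_carbons + 1), n_carbons, p13C)
    cum = np.cumsum(pmf)
    keep = int(np.searchsorted(cum, 1.0 - TAIL_TRUNCATION) + 1)
    pmf = pmf[: min(keep + 1, n_carbons + 1)]
    return pmf / pmf.sum()


def deuterium_count_distribution(
    i_labeled: int, precursor: PrecursorSpec, mode: str = "unit"
) -> np.ndarray:
    """Distribution of the deuterium-atom count for a molecule with
    ``i_labeled`` pathway-labeled isoprene units.

    unit mode: count = d·j with j ~ Binomial(i_labeled, 1−q) (all-or-none
    molecule-level impurity). site mode: count ~ Binomial(d·i_labeled, 1−q).
    """
    if i_labeled < 0:
        raise DomainError(f"i_labeled must be >= 0, got {i_labeled}")
    d, q = precursor.d, precursor.q
    if mode == "unit":
        out = np.zeros(d * i_labeled + 1)
        j = np.arange(i_labeled + 1)
        out[d * j] = binom.pmf(j, i_labeled, 1.0 - q)
    elif mode == "site":
        k = np.arange(d * i_labeled + 1)
        out = binom.pmf(k, d * i_labeled, 1.0 - q)
    else:
        raise DomainError(f"unknown purity mode {mode!r}")
    return out / out.sum()


def mixture_deuterium_distribution(
    z: PathwayDistribution, precursor: PrecursorSpec, mode: str = "unit"
) -> np.ndarray:
    """z-mixture of per-i deuterium-count distributions, length d·N + 1."""
    n_units = z.n_units
    out = np.zeros(precursor.d * n_units + 1)
    for i, w in enumerate(z.z):
        if w == 0.0:
            continue
        d_i = deuterium_count_distribution(i, precursor, mode)
        out[: len(d_i)] += w * d_i
    return out


def forward_envelope(
    compound: CompoundSpec,
    precursor: PrecursorSpec,
    z: PathwayDistribution,
    config: ModelConfig = ModelConfig(),
) -> Envelope:
    """Theoretical isotopologue envelope for a labeling experiment.

    Convolution of the (truncated) 13C binomial with the z-mixture of
    deuterium-count distributions; normalized; support bounded by
    n_carbons + d·N.
    """
    if z.n_units != compound.n_units:
        raise ContractViolation(
            f"z has N={z.n_units} but compound {compound.name} has N={compound.n_units}"
        )
    c13 = truncated_c13_envelope(compound.n_carbons, config.p13C)
    deut = mixture_deuterium_distribution(z, precursor, config.purity_mode)
    env = np.convolve(c13, deut)
    if config.max_shift is not None:
        if len(env) - 1 > config.max_shift and env[config.max_shift + 1:].sum() > 1e-9:
            raise ContractViolation(
                f"model support {len(env) - 1} exceeds configured max_shift "
                f"{config.max_shift}"
            )
        env = env[: config.max_shift + 1]
    return Envelope(env / env.sum(), normalized=True)


def expected_max_shift(compound: CompoundSpec, precursor: PrecursorSpec) -> int:
    """Maximal expected envelope shift Δm = d·N for a fully labeled molecule
    (e.g. +48 for Dol-16 fed trideuterated mevalonolactone)."""
    return precursor.d * compound.n_units


def adduct_base_mz(compound: CompoundSpec, adduct: str) -> float:
    """Monoisotopic m/z of the unlabeled ion of ``compound`` under ``adduct``."""
    return compound.base_mz(adduct)


def analytic_mean_shift(
    compound: CompoundSpec,
    precursor: PrecursorSpec,
    z: PathwayDistribution,
    config: ModelConfig = ModelConfig(),
) -> float:
    """Closed-form envelope mean: n_carbons·p13C + d·(1−q)·E[z].

    Holds for both purity modes; used as a moment cross-check on the
    convolution and on sampled spectra.
    """
    return compound.n_carbons * config.p13C + precursor.d * (1.0 - precursor.q) * z.mean()
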