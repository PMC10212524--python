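"""Synthetic labeling experiments: ground-truth parameter sets, sampled peak
lists, and a default study design.

The generator emulates hydroponic precursor-feeding experiments on
Arabidopsis: each condition is a (tissue, compound, precursor, single or
competitive feeding) cell with a ground-truth pathway distribution z,
substrate impurity q and 13C abundance. A spectrum is a multinomial draw of
ion counts from the forward envelope placed on the adduct's m/z grid, with
optional Gaussian m/z jitter and multiplicative intensity noise.

Default truths mirror the published quantitative picture for these
experiments (unlabeled/fully-labeled fractions per condition and the fitted
q and p13C values); they are editable fixtures describing plausible
cross-talk distributions, not measured ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .model import (
    CompoundSpec,
    ModelConfig,
    PathwayDistribution,
    PrecursorSpec,
    forward_envelope,
)
from .presets import get_compound, get_precursor

DEFAULT_P13C = 0.0102
DEFAULT_Q = {"DX": 0.029, "MVL": 0.007}
DEFAULT_N_IONS = 1_000_000
DEFAULT_MZ_JITTER_SD = 0.05   # Da, when jitter is enabled
DEFAULT_INTENSITY_CV = 0.02   # multiplicative noise, when enabled


@dataclass(frozen=True)
class NoiseSettings:
    """Sampling noise beyond multinomial ion counting (both off by default)."""

    mz_jitter_sd: float = 0.0
    intensity_cv: float = 0.0


@dataclass
class Truth:
    """Ground-truth parameters of one simulated condition."""

    z: PathwayDistribution
    q: float
    p13C: float = DEFAULT_P13C
    purity_mode: str = "unit"


@dataclass
class PeakList:
    """A simulated or ingested centroid peak list (m/z, intensity)."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.mz) != len(self.intensity):
            raise DomainError("m/z and intensity arrays must have equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise DomainError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise DomainError("intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class Condition:
    """One cell of a study design."""

    label: str
    tissue: str
    compound: str
    precursor: str
    mode: str  # "single" | "competitive"
    z0: float          # truth: unlabeled-pathway fraction z(0)
    zN: float          # truth: fully labeled fraction z(N)
    shape: float       # geometric ratio of the middle of z (>1 skews to N)


@dataclass
class StudyDesign:
    """A bundle of simulated conditions sharing sampling settings."""

    conditions: tuple[Condition, ...]
    n_ions: int = DEFAULT_N_IONS
    noise: NoiseSettings = NoiseSettings()
    adduct: str = "[M+Na]+"
    master_seed: int = 0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ConfigurationError(f"duplicate condition labels: {dupes}")


def geometric_z(
    n_units: int, z0: float, zN: float, shape: float
) -> PathwayDistribution:
    """Cross-talk distribution with fixed end masses and a geometric middle.

    The interior i = 1..N-1 carries weight proportional to shape**i, scaled
    to 1 - z0 - zN; shape > 1 skews labeling toward fully labeled chains.
    """
    if z0 < 0 or zN < 0 or z0 + zN > 1 + 1e-12:
        raise DomainError("z0 and zN must be nonnegative with z0 + zN <= 1")
    z = np.zeros(n_units + 1)
    z[0], z[-1] = z0, zN
    mid = shape ** np.arange(1, n_units, dtype=float)
    if mid.sum() > 0:
        z[1:-1] = (1.0 - z0 - zN) * mid / mid.sum()
    return PathwayDistribution(z / z.sum())


def condition_truth(cond: Condition) -> Truth:
    compound = get_compound(cond.compound)
    return Truth(
        z=geometric_z(compound.n_units, cond.z0, cond.zN, cond.shape),
        q=DEFAULT_Q[cond.precursor],
        p13C=DEFAULT_P13C,
    )


def child_seed(master_seed: int, label: str) -> int:
    """Deterministic per-condition seed: BLAKE2b of (master_seed, label),
    reduced below 2**31."""
    digest = hashlib.blake2b(f"{master_seed}:{label}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def simulate_peaklist(
    compound: CompoundSpec,
    precursor: PrecursorSpec,
    truth: Truth,
    adduct: str = "[M+Na]+",
    n_ions: int = DEFAULT_N_IONS,
    noise: NoiseSettings = NoiseSettings(),
    seed: int = 0,
) -> PeakList:
    """Sample one spectrum: multinomial(n_ions) ion counts over the forward
    envelope, placed at base m/z + Δm on the unit-mass grid.

    Zero-count bins are dropped from the peak list. With only counting noise
    the intensities sum exactly to ``n_ions``. Identical seeds yield
    bit-identical peak lists.
    """
    if n_ions < 1:
        raise DomainError("n_ions must be >= 1")
    rng = np.random.default_rng(seed)
    config = ModelConfig(p13C=truth.p13C, purity_mode=truth.purity_mode)
    env = forward_envelope(compound, precursor, truth.z, config)
    counts = rng.multinomial(n_ions, env.intensities).astype(float)
    base = compound.base_mz(adduct)
    mz = base + np.arange(len(counts), dtype=float)
    if noise.mz_jitter_sd > 0:
        mz = mz + rng.normal(0.0, noise.mz_jitter_sd, size=len(mz))
    if noise.intensity_cv > 0:
        counts = counts * np.clip(
            1.0 + rng.normal(0.0, noise.intensity_cv, size=len(counts)), 0.0, None
        )
    keep = counts > 0
    order = np.argsort(mz[keep], kind="stable")
    return PeakList(
        mz=mz[keep][order],
        intensity=counts[keep][order],
        metadata={
            "compound": compound.name,
            "precursor": precursor.name,
            "adduct": adduct,
            "seed": int(seed),
            "n_ions": int(n_ions),
        },
    )


def default_design(master_seed: int = 0, n_ions: int = DEFAULT_N_IONS) -> StudyDesign:
    """The default 12-spectrum study grid: Pren-11 in leaves and Dol-16 in
    leaves and roots, each under single and competitive feeding with DX and
    MVL.

    z end masses mirror the published unlabeled/fully-labeled fractions for
    each condition; competitive conditions never exceed their matched
    single-precursor condition in fully labeled mass (isotopic dilution).
    """
    rows = [
        #       tissue   compound   prec  mode           z0    zN    shape
        ("leaves", "Pren-11", "DX",  "single",      0.76, 0.00, 0.55),
        ("leaves", "Pren-11", "DX",  "competitive", 0.68, 0.00, 0.62),
        ("leaves", "Pren-11", "MVL", "single",      0.98, 0.00, 0.40),
        ("leaves", "Pren-11", "MVL", "competitive", 0.73, 0.00, 0.55),
        ("leaves", "Dol-16",  "DX",  "single",      0.63, 0.00, 0.62),
        ("leaves", "Dol-16",  "DX",  "competitive", 0.50, 0.00, 0.58),
        ("leaves", "Dol-16",  "MVL", "single",      0.19, 0.47, 1.25),
        ("leaves", "Dol-16",  "MVL", "competitive", 0.08, 0.07, 1.20),
        ("roots",  "Dol-16",  "DX",  "single",      0.21, 0.19, 1.10),
        ("roots",  "Dol-16",  "DX",  "competitive", 0.13, 0.00, 1.05),
        ("roots",  "Dol-16",  "MVL", "single",      0.05, 0.29, 1.25),
        ("roots",  "Dol-16",  "MVL", "competitive", 0.29, 0.04, 1.10),
    ]
    conditions = tuple(
        Condition(
            label=f"{tissue}_{compound}_{prec}_{mode}",
            tissue=tissue, compound=compound, precursor=prec, mode=mode,
            z0=z0, zN=zN, shape=shape,
        )
        for tissue, compound, prec, mode, z0, zN, shape in rows
    )
    return StudyDesign(conditions=conditions, n_ions=n_ions, master_seed=master_seed)


def generate_study(design: StudyDesign) -> tuple[dict[str, PeakList], list[dict]]:
    """Simulate every condition of a design.

    Returns ``(peaklists, truth_table)``: peak lists keyed by condition
    label (child seeds derived deterministically from the master seed) and
    the ground-truth table for recovery testing, one row per condition with
    the full z vector, q and p13C.
    """
    peaklists: dict[str, PeakList] = {}
    truth_rows: list[dict] = []
    for cond in design.conditions:
        compound = get_compound(cond.compound)
        precursor = get_precursor(cond.precursor)
        truth = condition_truth(cond)
        seed = child_seed(design.master_seed, cond.label)
        peaklists[cond.label] = simulate_peaklist(
            compound, precursor, truth,
            adduct=design.adduct, n_ions=design.n_ions,
            noise=design.noise, seed=seed,
        )
        truth_rows.append({
            "label": cond.label,
            "tissue": cond.tissue,
            "compound": cond.compound,
            "precursor": cond.precursor,
            "mode": cond.mode,
            "q": truth.q,
            "p13C": truth.p13C,
            "seed": seed,
            **{f"z{i}": float(v) for i, v in enumerate(truth.z.z)},
        })
    return peaklists, truth_rows
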