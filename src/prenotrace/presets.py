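"""Compound and precursor presets loaded from the plain-text registry.

The registry (``data/compounds.yaml``) ships Pren-9..12, Dol-15..24 and the
three major Arabidopsis phytosterols, plus the two deuterated precursors
with their default substrate-purity values (q = 0.029 for 2H2-DX,
q = 0.007 for 2H3-MVL).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .errors import ConfigurationError
from .model import CompoundSpec, PrecursorSpec


@lru_cache(maxsize=1)
def _registry() -> dict:
    text = resources.files("prenotrace").joinpath("data/compounds.yaml").read_text()
    return yaml.safe_load(text)


def registry_version() -> int:
    return int(_registry()["registry_version"])


def list_compounds() -> list[str]:
    return sorted(_registry()["compounds"])


def list_precursors() -> list[str]:
    return sorted(_registry()["precursors"])


def get_compound(name: str, n_units: int | None = None) -> CompoundSpec:
    """Look up a compound preset; ``n_units`` overrides the registry value
    (meaningful for sterols, whose maximum-label unit count is a modeling
    choice rather than a structural constant)."""
    entry = _registry()["compounds"].get(name)
    if entry is None:
        raise ConfigurationError(
            f"unknown compound preset {name!r}; available: {', '.join(list_compounds())}"
        )
    return CompoundSpec(
        name=name,
        family=entry["family"],
        n_units=int(n_units if n_units is not None else entry["n_units"]),
        formula=dict(entry["formula"]),
        adducts=tuple(entry["adducts"]),
    )


def get_precursor(name: str, q: float | None = None) -> PrecursorSpec:
    """Look up a precursor preset; ``q`` overrides the default unlabeled
    fraction (use a fitted value from a single-precursor experiment)."""
    entry = _registry()["precursors"].get(name)
    if entry is None:
        raise ConfigurationError(
            f"unknown precursor preset {name!r}; available: {', '.join(list_precursors())}"
        )
    return PrecursorSpec(name=name, d=int(entry["d"]), q=float(q if q is not None else entry["q"]))


def precursor_pathway(name: str) -> str:
    """Pathway fed by the precursor: MEP for DX, MVA for MVL."""
    entry = _registry()["precursors"].get(name)
    if entry is None:
        raise ConfigurationError(f"unknown precursor preset {name!r}")
    return entry["pathway"]
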