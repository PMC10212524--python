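"""Peak-list text IO and envelope ingestion.

Peak lists are two-column delimited text (m/z, intensity; comma, tab or
whitespace separated) with an optional commented ``# key: value`` metadata
header. Ingestion bins peaks onto the integer Δm grid anchored at the
adduct's monoisotopic m/z; peaks farther than the tolerance from any grid
position are reported as unassigned, never silently dropped, so intensity
is conserved: sum(binned) + sum(unassigned) = sum(input).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AdductMismatchError, DataError, DomainError
from .model import CompoundSpec, Envelope
from .synthdata import PeakList

DEFAULT_TOLERANCE = 0.3  # Da; unit-resolution envelopes

_SPLIT = re.compile(r"[,\t;]|\s+")


def read_peaklist(path: str | Path) -> PeakList:
    """Parse a delimited peak list; duplicate m/z rows are summed.

    Malformed rows raise :class:`DataError` naming the line number.
    """
    path = Path(path)
    mz: list[float] = []
    intensity: list[float] = []
    metadata: dict = {"source": str(path)}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            fields = [f for f in _SPLIT.split(line) if f]
            if len(fields) != 2:
                raise DataError(
                    f"{path}:{lineno}: expected two columns (m/z, intensity), "
                    f"got {len(fields)}: {line!r}"
                )
            try:
                mz.append(float(fields[0]))
                intensity.append(float(fields[1]))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
    if not mz:
        raise DataError(f"{path}: no peaks found")
    mz_arr = np.asarray(mz)
    int_arr = np.asarray(intensity)
    if np.any(int_arr < 0):
        bad = int(np.argmax(int_arr < 0))
        raise DataError(f"{path}: negative intensity at m/z {mz_arr[bad]}")
    # sum duplicates, sort by m/z
    uniq, inverse = np.unique(mz_arr, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, int_arr)
    return PeakList(mz=uniq, intensity=summed, metadata=metadata)


def write_peaklist(peaklist: PeakList, path: str | Path, delimiter: str = "\t") -> None:
    """Write a peak list as two-column delimited text with a commented
    metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in peaklist.metadata.items():
            fh.write(f"# {key}: {value}\n")
        for m, i in zip(peaklist.mz, peaklist.intensity):
            fh.write(f"{m:.6f}{delimiter}{i:.6f}\n")


@dataclass
class IngestResult:
    """Outcome of binning a peak list onto the envelope grid."""

    envelope: Envelope
    binned: np.ndarray                       # raw intensity per Δm bin
    unassigned: list[tuple[float, float]] = field(default_factory=list)
    base_mz: float = 0.0

    @property
    def assigned_total(self) -> float:
        return float(self.binned.sum())

    @property
    def unassigned_total(self) -> float:
        return float(sum(i for _, i in self.unassigned))


def envelope_from_peaklist(
    peaklist: PeakList,
    compound: CompoundSpec,
    adduct: str,
    tolerance: float = DEFAULT_TOLERANCE,
    floor: float = 0.0,
    max_shift: int | None = None,
) -> IngestResult:
    """Bin peaks onto the integer Δm grid at base(adduct) + Δm.

    ``floor`` zeroes bins below that fraction of the base (most intense)
    bin. ``max_shift`` bounds the grid (default: n_carbons + 3·N, generous
    for either precursor). Raises :class:`AdductMismatchError` when no peak
    lands on the grid at all.
    """
    if tolerance <= 0:
        raise DomainError("tolerance must be > 0")
    base = compound.base_mz(adduct)
    k_max = max_shift if max_shift is not None else compound.n_carbons + 3 * compound.n_units
    binned = np.zeros(k_max + 1)
    unassigned: list[tuple[float, float]] = []
    for m, i in zip(peaklist.mz, peaklist.intensity):
        delta = m - base
        k = int(round(delta))
        if 0 <= k <= k_max and abs(delta - k) <= tolerance:
            binned[k] += i
        else:
            unassigned.append((float(m), float(i)))
    if binned.sum() <= 0:
        raise AdductMismatchError(
            f"no peak within ±{tolerance} Da of the {adduct} grid of "
            f"{compound.name} (base m/z {base:.4f}); wrong adduct?"
        )
    kept = binned.copy()
    if floor > 0:
        kept[kept < floor * kept.max()] = 0.0
    # trim trailing empty bins so the envelope support is data-driven
    last = int(np.nonzero(kept)[0][-1])
    envelope = Envelope(kept[: last + 1] / kept[: last + 1].sum(), normalized=True)
    return IngestResult(envelope=envelope, binned=binned, unassigned=unassigned, base_mz=base)
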