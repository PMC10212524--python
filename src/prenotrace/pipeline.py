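"""End-to-end analysis pipeline: ingest -> p13C -> labeling fit -> metrics
-> elongation -> serialized reports.

The pipeline is deterministic given its configuration and inputs; stage
failures propagate with the stage name attached and no partial silent
output is written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .deconv import LabelFit, estimate_p13C, fit_labeling
from .elongation import (
    elongation_probability_loglinear,
    fit_elongation,
    initial_unit_deviation,
    pool_discrepancy,
)
from .errors import ConfigurationError, PrenotraceError
from .metrics import deuteriation_pattern, metrics_row
from .model import ModelConfig
from .peaklist import DEFAULT_TOLERANCE, envelope_from_peaklist, read_peaklist
from .presets import get_compound, get_precursor


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    input_path: str
    compound: str
    precursor: str
    adduct: str = "[M+Na]+"
    tissue: str = ""
    purity_mode: str = "unit"
    p13C: float | None = None            # fixed value ...
    native_paths: tuple[str, ...] = ()   # ... or native spectra to fit it from
    q_fixed: float | None = None
    tolerance: float = DEFAULT_TOLERANCE
    floor: float = 0.0
    orientation: str = "MVA"
    elongation_window: tuple[int, ...] | None = None
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.p13C is None and not self.native_paths:
            raise ConfigurationError(
                "provide either a p13C value or native spectra paths to fit it from"
            )

    def digest(self) -> str:
        """Short provenance hash of the configuration."""
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.blake2b(payload.encode(), digest_size=8).hexdigest()


class StageError(PrenotraceError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


@dataclass
class PipelineResult:
    """All artifacts of one run, serializable as a report bundle."""

    config: RunConfig
    p13C_used: float
    fit: LabelFit
    metrics: dict
    pattern: list[float]
    elongation: dict
    unassigned: list[tuple[float, float]] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "provenance": {
                "input": self.config.input_path,
                "compound": self.config.compound,
                "precursor": self.config.precursor,
                "adduct": self.config.adduct,
                "config_hash": self.config.digest(),
            },
            "p13C_used": self.p13C_used,
            "fit": self.fit.to_dict(),
            "deuteriation_pattern": self.pattern,
            "metrics": self.metrics,
            "elongation": self.elongation,
            "unassigned_peaks": [list(p) for p in self.unassigned],
        }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis for one labeling spectrum."""
    compound = get_compound(config.compound)
    precursor = get_precursor(config.precursor)

    peaks = _stage("ingest")(read_peaklist)(config.input_path)
    ingest = _stage("ingest")(envelope_from_peaklist)(
        peaks, compound, config.adduct,
        tolerance=config.tolerance, floor=config.floor,
    )

    if config.p13C is not None:
        p13C = config.p13C
    else:
        def _fit_native():
            native = []
            for path in config.native_paths:
                npeaks = read_peaklist(path)
                ning = envelope_from_peaklist(
                    npeaks, compound, config.adduct, tolerance=config.tolerance
                )
                native.append((ning.envelope, compound.n_carbons))
            return estimate_p13C(native).value
        p13C = _stage("p13C")(_fit_native)()

    model_config = ModelConfig(p13C=p13C, purity_mode=config.purity_mode)
    fit = _stage("fit_labeling")(fit_labeling)(
        ingest.envelope, compound, precursor, model_config,
        q_fixed=config.q_fixed, restart_seed=config.seed,
    )

    pattern = _stage("metrics")(deuteriation_pattern)(fit, precursor)
    metrics = _stage("metrics")(metrics_row)(fit, precursor, tissue=config.tissue)

    def _elongation() -> dict:
        efit = fit_elongation(
            pattern, orientation=config.orientation, window=config.elongation_window
        )
        discrepancy, verdict = pool_discrepancy(efit, float(pattern[0]))
        residuals, flagged = initial_unit_deviation(pattern, efit)
        out = efit.to_dict()
        try:
            out["p_loglinear"] = elongation_probability_loglinear(pattern, efit.window)
        except PrenotraceError:
            out["p_loglinear"] = None
        out.update({
            "pool_discrepancy": discrepancy,
            "pool_verdict": verdict,
            "flagged_deviation_ranges": [list(r) for r in flagged],
            "residuals": [float(r) for r in residuals],
        })
        return out

    elong = _stage("elongation")(_elongation)()

    result = PipelineResult(
        config=config,
        p13C_used=p13C,
        fit=fit,
        metrics=metrics,
        pattern=[float(v) for v in pattern.values],
        elongation=elong,
        unassigned=ingest.unassigned,
    )

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = Path(config.input_path).stem
        with open(outdir / f"{stem}_report.json", "w") as fh:
            json.dump(result.report(), fh, indent=2)
    return result
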