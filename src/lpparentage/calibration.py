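"""Baseline calibration and verdict classification.

The decision statistic (inconsistent rate of base-type inheritance) has a
nonzero baseline in confirmed-biological families, driven by genotyping
error at low coverage.  A reporting cutoff is therefore set empirically:
mean + Z·SD of the rates observed in confirmed-biological analyses, with
Z = 3 for trio mode and the stricter Z = 5 for duo mode (whose biological
vs non-biological gap is wider, affording a stricter threshold).  Rates at
or above the cutoff are reported as not-confirmed parentage; the boundary
itself is treated as not-confirmed, the conservative choice for a QC test.

The shipped default cutoffs are 24.5% (trio) and 25.6% (duo); local
recalibration with :func:`calibrate_cutoff` overrides them.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from typing import IO, Sequence

from .inheritance import DUO, TRIO, InheritanceResult

BIOLOGICAL = "biological"
NOT_CONFIRMED = "not_confirmed"
INCONCLUSIVE = "inconclusive"

#: default reporting cutoffs (%), overridable by local calibration
DEFAULT_CUTOFFS = {TRIO: 24.5, DUO: 25.6}
DEFAULT_Z = {TRIO: 3.0, DUO: 5.0}


class CalibrationError(ValueError):
    """Not enough baseline rates to calibrate a cutoff."""


@dataclass(frozen=True)
class BaselineModel:
    """Baseline statistics and derived cutoff for one analysis mode.

    All rate quantities are percentages in [0, 100].
    """

    mode: str
    rates: tuple[float, ...]
    mean: float
    sd: float
    z: float
    cutoff: float

    @property
    def n(self) -> int:
        return len(self.rates)

    def to_json(self, dest: str | IO[str]) -> None:
        payload = {
            "mode": self.mode,
            "mean": self.mean,
            "sd": self.sd,
            "z": self.z,
            "cutoff": self.cutoff,
            "n": self.n,
            "rates": list(self.rates),
        }
        if hasattr(dest, "write"):
            json.dump(payload, dest, indent=1)
        else:
            with open(dest, "w") as fh:
                json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, source: str | IO[str]) -> "BaselineModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            mode=payload["mode"],
            rates=tuple(payload["rates"]),
            mean=payload["mean"],
            sd=payload["sd"],
            z=payload["z"],
            cutoff=payload["cutoff"],
        )


def calibrate_cutoff(
    rates: Sequence[float],
    z: float,
    mode: str = TRIO,
    population_sd: bool = False,
) -> BaselineModel:
    """Fit a baseline model: cutoff = mean + z * SD of the given rates.

    ``rates`` are inconsistent rates (%) from confirmed-biological
    analyses.  SD is the sample (n-1) estimator by default;
    ``population_sd`` switches to the n-denominator form.
    """
    if len(rates) < 2:
        raise CalibrationError(
            f"need at least 2 baseline rates, got {len(rates)}"
        )
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    if any(not 0.0 <= r <= 100.0 for r in rates):
        raise ValueError("baseline rates must be percentages in [0, 100]")
    mean = statistics.fmean(rates)
    sd = statistics.pstdev(rates) if population_sd else statistics.stdev(rates)
    return BaselineModel(
        mode=mode,
        rates=tuple(float(r) for r in rates),
        mean=mean,
        sd=sd,
        z=float(z),
        cutoff=mean + z * sd,
    )


def default_model(mode: str) -> BaselineModel:
    """The shipped cutoff constants wrapped as a (rate-less) model."""
    if mode not in DEFAULT_CUTOFFS:
        raise ValueError(f"unknown mode {mode!r}")
    cutoff = DEFAULT_CUTOFFS[mode]
    z = DEFAULT_Z[mode]
    return BaselineModel(
        mode=mode, rates=(cutoff, cutoff), mean=cutoff, sd=0.0, z=z, cutoff=cutoff
    )


def classify(result: InheritanceResult, model: BaselineModel) -> str:
    """Verdict for one comparison: biological / not_confirmed / inconclusive.

    A rate strictly below the cutoff supports biological parentage; a rate
    at or above it is reported as not confirmed.  Inconclusive results
    (too few informative loci) pass through unchanged.
    """
    if result.mode != model.mode:
        raise ValueError(
            f"mode mismatch: result is {result.mode}, model is {model.mode}"
        )
    if result.inconclusive:
        return INCONCLUSIVE
    return BIOLOGICAL if result.rate_percent < model.cutoff else NOT_CONFIRMED


def fraction_percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded for reporting."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def cohort_summary(verdicts: Sequence[str]) -> dict:
    """Misattributed-parentage (MP) rate over per-family verdicts.

    A family counts as MP if its verdict is not_confirmed.  Returns
    n_families, n_mp and mp_rate_percent (2 decimals).
    """
    if len(verdicts) == 0:
        raise ValueError("cohort_summary needs at least one family verdict")
    n_mp = sum(1 for v in verdicts if v == NOT_CONFIRMED)
    return {
        "n_families": len(verdicts),
        "n_mp": n_mp,
        "mp_rate_percent": fraction_percent(n_mp, len(verdicts)),
    }
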