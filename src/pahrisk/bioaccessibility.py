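"""Bioaccessible-fraction computation from desorption data.

The bioaccessible fraction F_bioa of a particle-bound PAH is the fraction of
the total particle load released into simulated lung fluid — operationally,
the total (maximal cumulative) extent of desorption divided by the total
load. No kinetic model is fitted: the series maximum is the estimate.

Also provides the loading-efficiency QC check used when spiking particles
with labelled PAH, and the solid–fluid distribution coefficient K_d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .registry import BioaccessibilityMeasurement

__all__ = [
    "DesorptionSeries",
    "DistributionCoefficient",
    "LoadingEfficiency",
    "compute_fbioa",
    "fbioa_from_series",
    "loading_efficiency",
    "compute_kd",
]


@dataclass(frozen=True)
class DesorptionSeries:
    """Cumulative release of one analyte from one matrix into one fluid.

    timepoints are (time_h, cumulative_released_ng) pairs, time-ordered.
    Invariants (checked by :meth:`validate`): total_mass > 0; cumulative
    release non-decreasing and within [0, total_mass] at every point. Noisy
    series that momentarily decrease are rejected, not monotonized.
    """

    analyte: str
    fluid: str
    matrix: str
    total_mass: float  # ng
    timepoints: tuple[tuple[float, float], ...]

    def validate(self) -> None:
        if not self.total_mass > 0:
            raise ValueError(f"total_mass must be > 0, got {self.total_mass}")
        if len(self.timepoints) == 0:
            raise ValueError("desorption series has no timepoints")
        prev_t = -float("inf")
        prev_c = 0.0
        for t, c in self.timepoints:
            if t < 0:
                raise ValueError(f"negative time {t} h in series {self._label()}")
            if t < prev_t:
                raise ValueError(f"timepoints out of order in series {self._label()}")
            if c < prev_c:
                raise ValueError(
                    f"cumulative release decreases at t={t} h in series {self._label()}"
                )
            if c < 0 or c > self.total_mass:
                raise ValueError(
                    f"cumulative release {c} ng outside [0, total={self.total_mass}] "
                    f"in series {self._label()}"
                )
            prev_t, prev_c = t, c

    def _label(self) -> str:
        return f"({self.analyte}, {self.fluid}, {self.matrix})"


@dataclass(frozen=True)
class DistributionCoefficient:
    """Solid–fluid distribution coefficient K_d in L/kg."""

    kd: float
    analyte: str = ""
    matrix: str = ""
    fluid: str = ""


@dataclass(frozen=True)
class LoadingEfficiency:
    """Recovered/applied mass ratio with an attached QC flag."""

    efficiency: float
    threshold: float
    warning: Optional[str] = None

    @property
    def flagged(self) -> bool:
        return self.warning is not None


def compute_fbioa(released_mass: float, total_mass: float) -> float:
    """Bioaccessible fraction: mass released into lung fluid over total mass.

    Both masses in ng. Raises ValueError on a non-positive total or on
    released > total (a released mass exceeding the load signals a
    measurement inconsistency, never a fraction above 1).
    """
    if not total_mass > 0:
        raise ValueError(f"total_mass must be > 0, got {total_mass}")
    if released_mass < 0:
        raise ValueError(f"released_mass must be >= 0, got {released_mass}")
    if released_mass > total_mass:
        raise ValueError(
            f"released_mass {released_mass} exceeds total_mass {total_mass}: "
            "inconsistent measurement"
        )
    return released_mass / total_mass


def fbioa_from_series(series: DesorptionSeries) -> BioaccessibilityMeasurement:
    """Reduce a desorption time series to its bioaccessible fraction.

    F_bioa is the total extent of desorption: the maximal cumulative release
    divided by the total load. For a valid (monotone) series this is the
    final point.
    """
    series.validate()
    released = max(c for _, c in series.timepoints)
    return BioaccessibilityMeasurement(
        analyte=series.analyte,
        fluid=series.fluid,
        matrix=series.matrix,
        f_bioa=compute_fbioa(released, series.total_mass),
    )


def loading_efficiency(
    applied_mass: float, recovered_mass: float, threshold: float = 0.9
) -> LoadingEfficiency:
    """QC check that spiked PAH was fully loaded onto the particles.

    Returns recovered/applied with a warning attached when the ratio falls
    below ``threshold`` (default 0.9).
    """
    if not applied_mass > 0:
        raise ValueError(f"applied_mass must be > 0, got {applied_mass}")
    if recovered_mass < 0:
        raise ValueError(f"recovered_mass must be >= 0, got {recovered_mass}")
    eff = recovered_mass / applied_mass
    warning = None
    if eff < threshold:
        warning = f"loading efficiency {eff:.3g} below QC threshold {threshold:.3g}"
    return LoadingEfficiency(efficiency=eff, threshold=threshold, warning=warning)


def compute_kd(
    sorbed_conc: float,
    aqueous_conc: float,
    analyte: str = "",
    matrix: str = "",
    fluid: str = "",
) -> DistributionCoefficient:
    """Distribution coefficient K_d = sorbed / aqueous concentration.

    sorbed_conc in ng/g, aqueous_conc in ng/L; the ratio (L/g) is converted
    to the conventional L/kg (x1000).
    """
    if not aqueous_conc > 0:
        raise ValueError(f"aqueous_conc must be > 0, got {aqueous_conc}")
    if sorbed_conc < 0:
        raise ValueError(f"sorbed_conc must be >= 0, got {sorbed_conc}")
    kd = sorbed_conc / aqueous_conc * 1000.0
    return DistributionCoefficient(kd=kd, analyte=analyte, matrix=matrix, fluid=fluid)
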