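"""Daily-intake (DI) risk model for inhaled particle-bound PAHs.

Exposure is compared with an acceptable daily intake derived from a target
lifetime cancer risk:

    ADI = CR / (IPF_BaP x TEF)                        [ng/kg/day]

Two intake routes are supported, each in a "total" mode (F_bioa = 1, the
conventional assumption that everything inhaled is solubilised) and a
"bioaccessible" mode (measured F_bioa):

    matrix route  : DI = q_PAH x F_bioa x TR x C_particle x V_resp / BW
    ambient route : DI = C_PAH x F_bioa x TR x V_resp / BW

with q_PAH the PAH mass fraction in the particle (ng/g), C_particle the
particle concentration in air (g/m3) and C_PAH the ambient PAH
concentration (ng/m3). A DI strictly above the ADI is classified risky;
equality is acceptable (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

from .registry import ExposureScenario, PAHRegistry, ToxicityParameters

__all__ = [
    "IntakeResult",
    "IntakeSummary",
    "compute_adi",
    "compute_di_matrix",
    "compute_di_ambient",
    "classify_intake",
    "assess_intake_table",
    "summarize_intake",
    "di_ratio",
    "NOT_ASSESSED",
]

Mode = Literal["total", "bioaccessible"]
Route = Literal["matrix", "ambient"]

#: Note attached to bioaccessible-mode results whose F_bioa is missing.
NOT_ASSESSED = "not assessed (missing F_bioa)"


@dataclass(frozen=True)
class IntakeResult:
    """Per-analyte DI vs ADI outcome for one mode.

    ``di`` and ``risky`` are None when the analyte could not be assessed in
    this mode (missing bioaccessibility measurement); ``note`` then says so.
    """

    analyte: str
    mode: Mode
    di: Optional[float]  # ng/kg/day
    adi: float  # ng/kg/day
    risky: Optional[bool]
    route: Route
    fluid: Optional[str] = None
    matrix: Optional[str] = None
    note: str = ""


def compute_adi(tox: ToxicityParameters, tef: float) -> float:
    """Acceptable daily intake CR / (IPF_BaP x TEF), ng/kg/day."""
    if not tef > 0:
        raise ValueError(f"tef must be > 0 for an ADI, got {tef}")
    return tox.cr / (tox.ipf_bap * tef)


def _check_fraction(f_bioa: float) -> None:
    if not 0 <= f_bioa <= 1:
        raise ValueError(f"f_bioa must lie in [0, 1], got {f_bioa}")


def compute_di_matrix(
    q_pah: float, f_bioa: float, scenario: ExposureScenario
) -> float:
    """Daily intake for the particle-matrix route, ng/kg/day.

    q_pah in ng/g; requires the scenario's particle concentration (g/m3).
    """
    if scenario.c_particle is None:
        raise ValueError(
            "matrix-route DI requires ExposureScenario.c_particle (g/m3)"
        )
    if q_pah < 0:
        raise ValueError(f"q_pah must be >= 0, got {q_pah}")
    _check_fraction(f_bioa)
    return (
        q_pah * f_bioa * scenario.tr * scenario.c_particle * scenario.v_resp
        / scenario.bw
    )


def compute_di_ambient(
    c_pah: float, f_bioa: float, scenario: ExposureScenario
) -> float:
    """Daily intake for the ambient-concentration route, ng/kg/day.

    c_pah in ng/m3.
    """
    if c_pah < 0:
        raise ValueError(f"c_pah must be >= 0, got {c_pah}")
    _check_fraction(f_bioa)
    return c_pah * f_bioa * scenario.tr * scenario.v_resp / scenario.bw


def classify_intake(di: float, adi: float, tie_acceptable: bool = True) -> bool:
    """True iff the daily intake exceeds the acceptable daily intake.

    A DI exactly equal to the ADI is acceptable by default ("below the
    threshold is acceptable, otherwise not" read with equality on the
    acceptable side); pass ``tie_acceptable=False`` for the strict reading.
    """
    if not adi > 0:
        raise ValueError(f"adi must be > 0, got {adi}")
    return di > adi if tie_acceptable else di >= adi


def di_ratio(f_bioa: float) -> float:
    """Ratio of total-based to bioaccessibility-based DI: 1 / F_bioa.

    For identical inputs DI(bioaccessible) = F_bioa x DI(total), so the
    overestimation factor of the conventional model is exactly 1/F_bioa.
    """
    if not 0 < f_bioa <= 1:
        raise ValueError(f"f_bioa must lie in (0, 1], got {f_bioa}")
    return 1.0 / f_bioa


def assess_intake_table(
    registry: PAHRegistry,
    concentrations: Mapping[str, float],
    fbioa_map: Mapping[str, Optional[float]],
    scenario: ExposureScenario,
    tox: ToxicityParameters,
    mode: Literal["total", "bioaccessible", "both"] = "both",
    route: Route = "ambient",
    tie_acceptable: bool = True,
) -> list[IntakeResult]:
    """Assess a table of analytes in the requested mode(s).

    ``concentrations`` maps analyte abbreviation to ambient concentration
    (ng/m3, route="ambient") or particle loading (ng/g, route="matrix").
    ``fbioa_map`` maps abbreviation to a fraction of 1 or None (missing).
    Analytes with a missing F_bioa yield a "not assessed" result in
    bioaccessible mode — never a silent zero. Unknown abbreviations raise
    KeyError.
    """
    modes: Sequence[Mode] = ("total", "bioaccessible") if mode == "both" else (mode,)
    results: list[IntakeResult] = []
    for abbrev, conc in concentrations.items():
        record = registry.get(abbrev)
        adi = compute_adi(tox, record.tef)
        for m in modes:
            if m == "total":
                f: Optional[float] = 1.0
            else:
                f = fbioa_map.get(abbrev)
            if f is None:
                results.append(
                    IntakeResult(
                        analyte=record.abbreviation,
                        mode=m,
                        di=None,
                        adi=adi,
                        risky=None,
                        route=route,
                        note=NOT_ASSESSED,
                    )
                )
                continue
            if route == "matrix":
                di = compute_di_matrix(conc, f, scenario)
            else:
                di = compute_di_ambient(conc, f, scenario)
            results.append(
                IntakeResult(
                    analyte=record.abbreviation,
                    mode=m,
                    di=di,
                    adi=adi,
                    risky=classify_intake(di, adi, tie_acceptable),
                    route=route,
                )
            )
    return results


@dataclass(frozen=True)
class IntakeSummary:
    """Headline numbers for a batch of intake results.

    ``di_ratio_range`` is the (min, max) overestimation factor 1/F_bioa over
    analytes classified risky in both modes (None when no such analyte or a
    single mode was run).
    """

    min_di: dict[str, float] = field(default_factory=dict)
    max_di: dict[str, float] = field(default_factory=dict)
    risky: dict[str, tuple[str, ...]] = field(default_factory=dict)
    not_assessed: tuple[str, ...] = ()
    di_ratio_range: Optional[tuple[float, float]] = None


def summarize_intake(results: Sequence[IntakeResult]) -> IntakeSummary:
    """Min/max DI and risky sets per mode, plus the total/bioaccessible ratio
    range over analytes risky in both modes."""
    min_di: dict[str, float] = {}
    max_di: dict[str, float] = {}
    risky: dict[str, list[str]] = {}
    not_assessed: list[str] = []
    by_mode_risky: dict[str, set[str]] = {"total": set(), "bioaccessible": set()}
    di_by_key: dict[tuple[str, str, Optional[str], Optional[str]], dict[str, float]] = {}

    for r in results:
        if r.di is None:
            not_assessed.append(r.analyte)
            continue
        min_di[r.mode] = min(min_di.get(r.mode, r.di), r.di)
        max_di[r.mode] = max(max_di.get(r.mode, r.di), r.di)
        if r.risky:
            risky.setdefault(r.mode, []).append(r.analyte)
            by_mode_risky[r.mode].add(r.analyte)
        di_by_key.setdefault((r.analyte, r.route, r.fluid, r.matrix), {})[r.mode] = r.di

    ratio_range = None
    both_risky = by_mode_risky["total"] & by_mode_risky["bioaccessible"]
    ratios = [
        dis["total"] / dis["bioaccessible"]
        for key, dis in di_by_key.items()
        if key[0] in both_risky
        and "total" in dis
        and "bioaccessible" in dis
        and dis["bioaccessible"] > 0
    ]
    if ratios:
        ratio_range = (min(ratios), max(ratios))

    return IntakeSummary(
        min_di=min_di,
        max_di=max_di,
        risky={m: tuple(v) for m, v in risky.items()},
        not_assessed=tuple(dict.fromkeys(not_assessed)),
        di_ratio_range=ratio_range,
    )
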