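"""BaP toxic-equivalency (TEQ) concentration model.

Each analyte's ambient concentration is judged against an acceptable
concentration derived from the acceptable BaP-equivalent quantity:

    ATEQ   = CR / UR                 [ng BaP-eq/m3]
    AC_PAH = ATEQ / TEF              [ng/m3]
    TEQ    = TC_PAH x TEF            [ng BaP-eq/m3]
    BC_PAH = TC_PAH x F_bioa         [ng/m3]

Comparing a concentration with AC per analyte is algebraically identical to
comparing its TEQ with ATEQ in BaP-equivalent space; both views are
reported. Risk is flagged for the total concentration (TC > AC) and, when a
bioaccessibility measurement exists, for the bioaccessible concentration
(BC > AC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .intake import NOT_ASSESSED
from .registry import PAHRegistry, ToxicityParameters

__all__ = [
    "TeqResult",
    "compute_ateq",
    "compute_ac",
    "compute_bc",
    "compute_teq",
    "classify_teq",
    "assess_teq_table",
]


@dataclass(frozen=True)
class TeqResult:
    """Per-analyte TEQ-model outcome.

    ``bc`` and ``risky_bioaccessible`` are None when no bioaccessibility
    measurement exists for the analyte (``note`` says so).
    """

    analyte: str
    tc: float  # total concentration, ng/m3
    bc: Optional[float]  # bioaccessible concentration, ng/m3
    ac: float  # acceptable concentration, ng/m3
    teq: float  # ng BaP-eq/m3
    risky_total: bool
    risky_bioaccessible: Optional[bool]
    note: str = ""


def compute_ateq(tox: ToxicityParameters) -> float:
    """Acceptable BaP-equivalent concentration CR / UR, ng/m3."""
    if not tox.ur > 0:
        raise ValueError(f"ur must be > 0, got {tox.ur}")
    return tox.cr / tox.ur


def compute_ac(tox: ToxicityParameters, tef: float) -> float:
    """Acceptable concentration of one analyte, ATEQ / TEF, ng/m3."""
    if not tef > 0:
        raise ValueError(f"tef must be > 0 for an acceptable concentration, got {tef}")
    return compute_ateq(tox) / tef


def compute_bc(tc: float, f_bioa: float) -> float:
    """Bioaccessible concentration TC x F_bioa, ng/m3."""
    if tc < 0:
        raise ValueError(f"tc must be >= 0, got {tc}")
    if not 0 <= f_bioa <= 1:
        raise ValueError(f"f_bioa must lie in [0, 1], got {f_bioa}")
    return tc * f_bioa


def compute_teq(tc: float, tef: float) -> float:
    """BaP-equivalent concentration TC x TEF, ng BaP-eq/m3."""
    if tc < 0:
        raise ValueError(f"tc must be >= 0, got {tc}")
    if tef < 0:
        raise ValueError(f"tef must be >= 0, got {tef}")
    return tc * tef


def classify_teq(conc: float, ac: float, tie_acceptable: bool = True) -> bool:
    """True iff a concentration exceeds the acceptable concentration.

    Same boundary convention as the intake model: equality is acceptable.
    """
    if not ac > 0:
        raise ValueError(f"ac must be > 0, got {ac}")
    return conc > ac if tie_acceptable else conc >= ac


def assess_teq_table(
    registry: PAHRegistry,
    tc_map: Mapping[str, float],
    fbioa_map: Mapping[str, Optional[float]],
    tox: ToxicityParameters,
    tie_acceptable: bool = True,
) -> list[TeqResult]:
    """Assess a table of total concentrations under the TEQ model.

    ``tc_map`` maps analyte abbreviation to total concentration (ng/m3);
    ``fbioa_map`` to a bioaccessible fraction of 1 or None (missing — the
    bioaccessible side is then reported as not assessed, never imputed).
    Unknown abbreviations raise KeyError.
    """
    results: list[TeqResult] = []
    for abbrev, tc in tc_map.items():
        record = registry.get(abbrev)
        ac = compute_ac(tox, record.tef)
        teq = compute_teq(tc, record.tef)
        f = fbioa_map.get(abbrev)
        if f is None:
            bc: Optional[float] = None
            risky_b: Optional[bool] = None
            note = NOT_ASSESSED
        else:
            bc = compute_bc(tc, f)
            risky_b = classify_teq(bc, ac, tie_acceptable)
            note = ""
        results.append(
            TeqResult(
                analyte=record.abbreviation,
                tc=tc,
                bc=bc,
                ac=ac,
                teq=teq,
                risky_total=classify_teq(tc, ac, tie_acceptable),
                risky_bioaccessible=risky_b,
                note=note,
            )
        )
    return results
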