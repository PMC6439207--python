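"""Analyte registry, toxicity constants and exposure parameters.

Single source of truth for every symbol used by the intake (DI/ADI) and
BaP-TEQ models: the assessed PAH analytes with their toxic equivalency
factors (TEF, potency relative to benzo[a]pyrene), the toxicity constants
(target cancer risk CR, benzo[a]pyrene inhalation potency factor IPF,
unit risk UR) and the inhalation exposure scenario (tracheobronchial
retention TR, inhalation rate V_resp, body weight BW, optional particle
concentration and loading).

Canonical internal units: mass in ng, air volume in m3, particle mass in g,
body mass in kg, time in day. Fractions (TR, F_bioa) are fractions of 1;
percent appears only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import yaml

__all__ = [
    "PAHRecord",
    "ToxicityParameters",
    "ExposureScenario",
    "BioaccessibilityMeasurement",
    "PAHRegistry",
    "Violation",
    "load_default_registry",
    "validate_registry",
    "registry_to_yaml",
    "registry_from_yaml",
    "normalize_fluid",
    "normalize_abbreviation",
    "GAMBLE",
    "ALF",
    "SELF",
]

# Canonical simulated-lung-fluid identifiers. Gamble's solution mimics the
# neutral extracellular lining fluid, ALF the acidic lysosomal environment
# inside macrophages, SELF a refined epithelial lining fluid. Any other
# free-text label is kept as-is (lowercased).
GAMBLE = "gamble"
ALF = "alf"
SELF = "self"

_FLUID_ALIASES = {
    "gamble": GAMBLE,
    "gamble's": GAMBLE,
    "gamble's solution": GAMBLE,
    "gambles solution": GAMBLE,
    "alf": ALF,
    "artificial lysosomal fluid": ALF,
    "self": SELF,
    "self_fluid": SELF,
    "simulated epithelial lung fluid": SELF,
}


def normalize_fluid(fluid: str) -> str:
    """Map a free-text fluid label onto a canonical identifier."""
    key = fluid.strip().lower()
    return _FLUID_ALIASES.get(key, key)


def normalize_abbreviation(abbrev: str) -> str:
    """Canonicalise an analyte abbreviation for lookup.

    Case-insensitive; internal whitespace is removed so that the combined
    congener pair is matched whether written ``BbF+BkF`` or ``BbF + BkF``.
    """
    return "".join(abbrev.split()).lower()


@dataclass(frozen=True)
class PAHRecord:
    """One assessed analyte.

    Parameters
    ----------
    name : full chemical name.
    abbreviation : short label used in tables and CSV files (e.g. ``BaP``).
    tef : toxic equivalency factor relative to benzo[a]pyrene (TEF = 1 for
        BaP itself); dimensionless, >= 0.
    combined : True only for a congener pair reported as one analyte
        (benzo[b]- plus benzo[k]fluoranthene).
    rings : number of fused aromatic rings, if known.
    """

    name: str
    abbreviation: str
    tef: float
    combined: bool = False
    rings: Optional[int] = None


@dataclass(frozen=True)
class ToxicityParameters:
    """Constants converting intake or concentration into lifetime cancer risk.

    cr : target (acceptable) incremental lifetime cancer risk, dimensionless.
    cr_range : closed interval of risk levels considered acceptable.
    ipf_bap : inhalation potency factor for benzo[a]pyrene, (ng/kg/day)^-1.
    ur : unit risk per unit ambient BaP-equivalent concentration, (ng/m3)^-1
        (lifetime, 70-year exposure assumption; metadata only, no
        time-integration is performed here).
    """

    cr: float = 1e-6
    cr_range: tuple[float, float] = (1e-6, 1e-4)
    ipf_bap: float = 3.9e-3
    ur: float = 8.7e-5

    @property
    def ateq(self) -> float:
        """Acceptable BaP-equivalent concentration CR / UR, ng/m3."""
        return self.cr / self.ur


@dataclass(frozen=True)
class ExposureScenario:
    """Inhalation exposure parameters.

    tr : tracheobronchial retention, fraction of inhaled particles retained.
    v_resp : inhalation rate, m3/day (adult default 20).
    bw : body weight, kg (adult default 60).
    c_particle : particle concentration in air, g/m3 (required for the
        particle-matrix intake route; 5.6e-3 g/m3 is the extreme
        biochar-pollution scenario).
    q_pah : PAH mass fraction in the particle, ng/g (optional default
        loading for the matrix route).
    """

    tr: float = 0.75
    v_resp: float = 20.0
    bw: float = 60.0
    c_particle: Optional[float] = None
    q_pah: Optional[float] = None

    @classmethod
    def extreme_biochar(cls, **overrides) -> "ExposureScenario":
        """Default scenario with the extreme 5.6 mg/m3 particle concentration."""
        kwargs = {"c_particle": 5.6e-3}
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def unit_intake_factor(self) -> float:
        """TR x V_resp / BW, the intake per unit air concentration (m3/kg/day)."""
        return self.tr * self.v_resp / self.bw


@dataclass(frozen=True)
class BioaccessibilityMeasurement:
    """A bioaccessible fraction for one (analyte, fluid, matrix) triple.

    ``f_bioa`` is a fraction of 1, or None when the measurement is missing
    (the registry never imputes a missing value).
    """

    analyte: str
    fluid: str
    matrix: str
    f_bioa: Optional[float]


class PAHRegistry:
    """Ordered collection of :class:`PAHRecord` with tolerant lookup."""

    def __init__(self, records: Iterable[PAHRecord]):
        self.records: list[PAHRecord] = list(records)
        self._by_key = {normalize_abbreviation(r.abbreviation): r for r in self.records}
        if len(self._by_key) != len(self.records):
            raise ValueError("duplicate analyte abbreviations in registry")

    def get(self, abbreviation: str) -> PAHRecord:
        key = normalize_abbreviation(abbreviation)
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"unknown analyte abbreviation: {abbreviation!r}") from None

    def __contains__(self, abbreviation: str) -> bool:
        return normalize_abbreviation(abbreviation) in self._by_key

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.records]


# The 15 assessed analytes (BbF and BkF reported as one combined congener
# pair) with TEFs relative to benzo[a]pyrene.
_DEFAULT_PAHS: list[PAHRecord] = [
    PAHRecord("naphthalene", "Nap", 0.001, rings=2),
    PAHRecord("acenaphthylene", "Acl", 0.001, rings=3),
    PAHRecord("acenaphthene", "Ace", 0.001, rings=3),
    PAHRecord("fluorene", "Flu", 0.001, rings=3),
    PAHRecord("phenanthrene", "Phe", 0.001, rings=3),
    PAHRecord("anthracene", "Ant", 0.001, rings=3),
    PAHRecord("fluoranthene", "FA", 0.01, rings=4),
    PAHRecord("pyrene", "Pyr", 0.001, rings=4),
    PAHRecord("benzo[a]anthracene", "BaA", 0.1, rings=4),
    PAHRecord("chrysene", "Chr", 0.01, rings=4),
    PAHRecord(
        "benzo[b]fluoranthene + benzo[k]fluoranthene",
        "BbF + BkF",
        0.2,
        combined=True,
        rings=5,
    ),
    PAHRecord("benzo[a]pyrene", "BaP", 1.0, rings=5),
    PAHRecord("indeno[1,2,3-cd]pyrene", "Ind", 0.1, rings=6),
    PAHRecord("dibenz[a,h]anthracene", "DBahA", 1.0, rings=5),
    PAHRecord("benzo[g,h,i]perylene", "BghiP", 0.01, rings=6),
]


def load_default_registry() -> tuple[PAHRegistry, ToxicityParameters, ExposureScenario]:
    """Return the default analytes, toxicity constants and exposure scenario.

    The exposure scenario carries the extreme biochar particle concentration
    (5.6e-3 g/m3) so the matrix intake route works out of the box; the
    ambient route ignores it.
    """
    return (
        PAHRegistry(_DEFAULT_PAHS),
        ToxicityParameters(),
        ExposureScenario.extreme_biochar(),
    )


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which object, which field, which rule."""

    subject: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.subject}.{self.field}: {self.rule}"


def validate_registry(
    records: Iterable[PAHRecord],
    tox: ToxicityParameters,
    scenario: ExposureScenario,
) -> list[Violation]:
    """Check all type invariants; violations are returned as data, not raised."""
    out: list[Violation] = []
    seen: dict[str, str] = {}
    for rec in records:
        label = f"PAHRecord({rec.abbreviation})"
        if not rec.tef > 0:
            out.append(Violation(label, "tef", "must be > 0 for risk computation"))
        key = normalize_abbreviation(rec.abbreviation)
        if key in seen:
            out.append(Violation(label, "abbreviation", f"duplicate of {seen[key]!r}"))
        else:
            seen[key] = rec.abbreviation

    lo, hi = tox.cr_range
    if not (tox.cr > 0):
        out.append(Violation("ToxicityParameters", "cr", "must be > 0"))
    if not (lo > 0 and hi > 0 and lo <= hi):
        out.append(Violation("ToxicityParameters", "cr_range", "must be a positive closed interval"))
    elif not (lo <= tox.cr <= hi):
        out.append(Violation("ToxicityParameters", "cr", "must lie within cr_range"))
    if not (tox.ipf_bap > 0):
        out.append(Violation("ToxicityParameters", "ipf_bap", "must be > 0"))
    if not (tox.ur > 0):
        out.append(Violation("ToxicityParameters", "ur", "must be > 0"))

    if not (0 < scenario.tr <= 1):
        out.append(Violation("ExposureScenario", "tr", "must satisfy 0 < tr <= 1"))
    if not (scenario.v_resp > 0):
        out.append(Violation("ExposureScenario", "v_resp", "must be > 0"))
    if not (scenario.bw > 0):
        out.append(Violation("ExposureScenario", "bw", "must be > 0"))
    if scenario.c_particle is not None and not (scenario.c_particle >= 0):
        out.append(Violation("ExposureScenario", "c_particle", "must be >= 0 when present"))
    if scenario.q_pah is not None and not (scenario.q_pah >= 0):
        out.append(Violation("ExposureScenario", "q_pah", "must be >= 0 when present"))
    return out


# ---------------------------------------------------------------------------
# Config round-trip (YAML). Units are stated in the file; values are stored
# in the canonical internal units so a round-trip is exact.

def registry_to_yaml(
    records: Iterable[PAHRecord],
    tox: ToxicityParameters,
    scenario: ExposureScenario,
) -> str:
    doc = {
        "units": {
            "tef": "dimensionless (BaP = 1)",
            "cr": "dimensionless lifetime risk",
            "ipf_bap": "(ng/kg/day)^-1",
            "ur": "(ng/m3)^-1",
            "tr": "fraction of 1",
            "v_resp": "m3/day",
            "bw": "kg",
            "c_particle": "g/m3",
            "q_pah": "ng/g",
        },
        "pahs": [asdict(r) for r in records],
        "toxicity": {
            "cr": tox.cr,
            "cr_range": list(tox.cr_range),
            "ipf_bap": tox.ipf_bap,
            "ur": tox.ur,
        },
        "exposure": {
            "tr": scenario.tr,
            "v_resp": scenario.v_resp,
            "bw": scenario.bw,
            "c_particle": scenario.c_particle,
            "q_pah": scenario.q_pah,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def registry_from_yaml(
    text: str,
) -> tuple[PAHRegistry, ToxicityParameters, ExposureScenario]:
    doc = yaml.safe_load(text)
    records = [PAHRecord(**p) for p in doc.get("pahs", [])]
    t = doc.get("toxicity", {})
    tox = ToxicityParameters(
        cr=float(t.get("cr", 1e-6)),
        cr_range=tuple(float(x) for x in t.get("cr_range", (1e-6, 1e-4))),
        ipf_bap=float(t.get("ipf_bap", 3.9e-3)),
        ur=float(t.get("ur", 8.7e-5)),
    )
    e = doc.get("exposure", {})
    scenario = ExposureScenario(
        tr=float(e.get("tr", 0.75)),
        v_resp=float(e.get("v_resp", 20.0)),
        bw=float(e.get("bw", 60.0)),
        c_particle=None if e.get("c_particle") is None else float(e["c_particle"]),
        q_pah=None if e.get("q_pah") is None else float(e["q_pah"]),
    )
    return PAHRegistry(records), tox, scenario
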