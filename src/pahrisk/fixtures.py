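"""Bundled reference datasets and the synthetic desorption-series generator.

Three fixture tables ship with the package (all units as printed in the
source tables; percent bioaccessibilities, μg/g loadings):

``table1``
    Bioaccessible fractions of phenanthrene and pyrene from 12 biochar fine
    particles in Gamble's solution and ALF at a 10 μg/g loading, with the
    daily intakes printed alongside them (expected-output column).
``table2``
    The same two analytes in Gamble's solution for three biochars at
    10/50/100 μg/g loadings.
``pm25``
    The 15 assessed PM2.5 analytes (BbF+BkF combined): TEF, mean ambient
    concentration, bioaccessible fraction in simulated epithelial lung
    fluid, plus every printed expected-output column of the intake and TEQ
    assessments. Columns suffixed ``_printed`` or ``_display`` are rounded
    display values from the source tables and serve only as regression
    oracles; the unsuffixed ``fbioa_percent`` column is the canonical
    higher-precision measurement that all computation uses. Naphthalene's
    bioaccessibility was not measured and is left empty.

The desorption generator emulates first-order single-compartment release to
a plateau. Only the plateau carries scientific meaning (it is the
bioaccessible fraction); the exponential shape is a modelling convenience,
not a claim about real kinetics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .bioaccessibility import DesorptionSeries

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "fixture_path",
    "load_manifest",
    "verify_fixtures",
    "SyntheticDesorptionConfig",
    "generate_desorption",
]

_FILES = {
    "table1": "table1_biochar.csv",
    "table2": "table2_biochar_loading.csv",
    "pm25": "pm25_pahs.csv",
}

FIXTURE_NAMES = tuple(_FILES)


def fixture_path(name: str):
    """Traversable path of a bundled fixture CSV."""
    try:
        filename = _FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FILES)}"
        ) from None
    return resources.files("pahrisk.data") / filename


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled fixture with units normalised to internal conventions.

    Adds ``fbioa`` (fraction of 1; NaN where the measurement is missing)
    next to the verbatim ``fbioa_percent`` column, and ``q_ng_g`` next to
    μg/g loadings. Printed display columns are passed through untouched.
    """
    with fixture_path(name).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    df["fbioa"] = df["fbioa_percent"] / 100.0
    if "q_ug_g" in df.columns:
        df["q_ng_g"] = df["q_ug_g"] * 1000.0
    return df


def load_manifest() -> pd.DataFrame:
    """The fixture manifest: file names, provenance, units, sha256."""
    with (resources.files("pahrisk.data") / "manifest.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def verify_fixtures() -> list[str]:
    """Check every bundled fixture against its manifest checksum.

    Returns a list of mismatch descriptions (empty when all files match).
    """
    problems: list[str] = []
    manifest = load_manifest()
    for row in manifest.itertuples():
        path = resources.files("pahrisk.data") / row.filename
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != row.sha256:
            problems.append(f"{row.filename}: sha256 {digest} != manifest {row.sha256}")
    return problems


@dataclass(frozen=True)
class SyntheticDesorptionConfig:
    """Parameters of the synthetic first-order desorption generator.

    plateau_fraction : asymptotic released fraction of the total load,
        in (0, 1] — this is the F_bioa the series encodes.
    rate_per_h : first-order release rate constant (1/h).
    n_timepoints : number of sampling times, evenly spaced over the horizon.
    horizon_h : duration of the experiment (h); a horizon much longer than
        1/rate puts the final point at the plateau.
    noise_sigma : multiplicative measurement noise applied per release
        increment (monotonicity-safe: negative increments are clipped).
    seed : RNG seed; identical configs produce identical series.
    """

    plateau_fraction: float
    rate_per_h: float = 0.35
    n_timepoints: int = 24
    horizon_h: float = 24.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.plateau_fraction <= 1:
            raise ValueError(
                f"plateau_fraction must lie in (0, 1], got {self.plateau_fraction}"
            )
        if not self.rate_per_h > 0:
            raise ValueError(f"rate_per_h must be > 0, got {self.rate_per_h}")
        if self.n_timepoints < 1:
            raise ValueError(f"n_timepoints must be >= 1, got {self.n_timepoints}")
        if not self.horizon_h > 0:
            raise ValueError(f"horizon_h must be > 0, got {self.horizon_h}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def generate_desorption(
    config: SyntheticDesorptionConfig,
    total_mass: float,
    analyte: str = "Phe",
    fluid: str = "gamble",
    matrix: str = "synthetic",
) -> DesorptionSeries:
    """Simulate a cumulative desorption series.

    The noiseless release follows total x plateau x (1 - exp(-rate t)).
    Noise multiplies each release increment by (1 + eps), eps ~ N(0, sigma),
    with negative increments clipped to zero, so the cumulative series is
    monotone by construction and the plateau estimate stays unbiased up to
    the clipping (negligible at small sigma). The series is clipped at the
    total load.
    """
    config.validate()
    if not total_mass > 0:
        raise ValueError(f"total_mass must be > 0, got {total_mass}")
    rng = np.random.default_rng(config.seed)
    times = config.horizon_h * np.arange(1, config.n_timepoints + 1) / config.n_timepoints
    ideal = (
        total_mass
        * config.plateau_fraction
        * (1.0 - np.exp(-config.rate_per_h * times))
    )
    increments = np.diff(ideal, prepend=0.0)
    if config.noise_sigma > 0:
        increments = increments * (
            1.0 + config.noise_sigma * rng.standard_normal(increments.shape)
        )
        increments = np.clip(increments, 0.0, None)
    cumulative = np.minimum(np.cumsum(increments), total_mass)
    return DesorptionSeries(
        analyte=analyte,
        fluid=fluid,
        matrix=matrix,
        total_mass=total_mass,
        timepoints=tuple(zip(times.tolist(), cumulative.tolist())),
    )
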