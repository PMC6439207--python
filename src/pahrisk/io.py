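"""CSV and config I/O plus plain-text report rendering.

CSV dialect: UTF-8, comma-separated, ``.`` decimal, header mandatory.
Analyte matching is case-insensitive on the abbreviation, with
``BbF+BkF`` and ``BbF + BkF`` both accepted. Percent values appear only in
files; everything handed to the models is a fraction of 1.

The report renderer performs no arithmetic: every number it prints comes
from a model operation or a summary object.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .bioaccessibility import DesorptionSeries, fbioa_from_series
from .intake import (
    IntakeResult,
    IntakeSummary,
    classify_intake,
    compute_adi,
    compute_di_matrix,
    NOT_ASSESSED,
)
from .registry import (
    ExposureScenario,
    PAHRegistry,
    ToxicityParameters,
    load_default_registry,
    normalize_fluid,
    registry_from_yaml,
)
from .rounding import round_half_up
from .teq import TeqResult

logger = logging.getLogger("pahrisk")

__all__ = [
    "InputError",
    "load_config",
    "read_ambient_csv",
    "read_matrix_csv",
    "read_bioaccessibility_csv",
    "read_desorption_csv",
    "write_desorption_csv",
    "write_bioaccessibility_csv",
    "write_intake_csv",
    "write_teq_csv",
    "assess_matrix_frame",
    "render_intake_report",
    "render_teq_report",
]


class InputError(ValueError):
    """Malformed or schema-violating input file."""


def load_config(
    path: Optional[str | Path],
) -> tuple[PAHRegistry, ToxicityParameters, ExposureScenario]:
    """Load a YAML registry/toxicity/exposure config, or the defaults."""
    if path is None:
        return load_default_registry()
    text = Path(path).read_text(encoding="utf-8")
    return registry_from_yaml(text)


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"analyte": str})
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty input file (header required)") from None
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed CSV ({exc})") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found {', '.join(df.columns)}"
        )
    if len(df) == 0:
        raise InputError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, column: str, path: str | Path) -> pd.Series:
    try:
        return pd.to_numeric(df[column])
    except (ValueError, TypeError):
        coerced = pd.to_numeric(df[column], errors="coerce")
        bad = df.index[coerced.isna() & df[column].notna()]
        # +2: 1-based data rows after the header line
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise InputError(
            f"{path}: non-numeric value in column {column!r} at line(s) {lines}"
        ) from None


def _fbioa_fraction(df: pd.DataFrame, path: str | Path) -> pd.Series:
    percent = _numeric(df, "fbioa_percent", path)
    frac = percent / 100.0
    bad = df.index[(frac < 0) | (frac > 1)]
    if len(bad):
        raise InputError(
            f"{path}: fbioa_percent outside [0, 100] at line(s) "
            + ", ".join(str(i + 2) for i in bad[:5])
        )
    return frac


def read_ambient_csv(
    path: str | Path,
) -> tuple[dict[str, float], dict[str, Optional[float]]]:
    """Read ``analyte,c_ng_m3,fbioa_percent`` into (tc_map, fbioa_map).

    An empty ``fbioa_percent`` field marks a missing measurement (None).
    """
    df = _read_csv(path, ["analyte", "c_ng_m3", "fbioa_percent"])
    conc = _numeric(df, "c_ng_m3", path)
    frac = _fbioa_fraction(df, path)
    tc_map: dict[str, float] = {}
    fbioa_map: dict[str, Optional[float]] = {}
    for i, row in df.iterrows():
        tc_map[row["analyte"]] = float(conc[i])
        fbioa_map[row["analyte"]] = None if pd.isna(frac[i]) else float(frac[i])
    return tc_map, fbioa_map


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read ``analyte,matrix,fluid,q_ug_g,fbioa_percent`` rows.

    Loadings are converted to the canonical ng/g (``q_ng_g``) and percent
    bioaccessibilities to fractions (``fbioa``).
    """
    df = _read_csv(path, ["analyte", "matrix", "fluid", "q_ug_g", "fbioa_percent"])
    df = df.copy()
    df["q_ng_g"] = _numeric(df, "q_ug_g", path) * 1000.0
    df["fbioa"] = _fbioa_fraction(df, path)
    df["fluid"] = df["fluid"].map(normalize_fluid)
    return df


def read_bioaccessibility_csv(path: str | Path) -> pd.DataFrame:
    """Read direct ``analyte,fluid,matrix,fbioa_percent`` measurements."""
    df = _read_csv(path, ["analyte", "fluid", "matrix", "fbioa_percent"])
    df = df.copy()
    df["fbioa"] = _fbioa_fraction(df, path)
    df["fluid"] = df["fluid"].map(normalize_fluid)
    return df


def read_desorption_csv(path: str | Path) -> list[DesorptionSeries]:
    """Read desorption time series, one row per timepoint.

    Columns: ``analyte,fluid,matrix,total_ng,time_h,cum_released_ng``.
    Each (analyte, fluid, matrix) group becomes one validated series;
    invariant violations (non-monotone release, release above the load)
    raise :class:`InputError` naming the series.
    """
    df = _read_csv(
        path, ["analyte", "fluid", "matrix", "total_ng", "time_h", "cum_released_ng"]
    )
    for col in ("total_ng", "time_h", "cum_released_ng"):
        df[col] = _numeric(df, col, path)
    out: list[DesorptionSeries] = []
    for (analyte, fluid, matrix), group in df.groupby(
        ["analyte", "fluid", "matrix"], sort=False
    ):
        totals = group["total_ng"].unique()
        if len(totals) != 1:
            raise InputError(
                f"{path}: inconsistent total_ng within series "
                f"({analyte}, {fluid}, {matrix})"
            )
        group = group.sort_values("time_h")
        series = DesorptionSeries(
            analyte=analyte,
            fluid=normalize_fluid(fluid),
            matrix=matrix,
            total_mass=float(totals[0]),
            timepoints=tuple(
                zip(group["time_h"].tolist(), group["cum_released_ng"].tolist())
            ),
        )
        try:
            series.validate()
        except ValueError as exc:
            raise InputError(f"{path}: {exc}") from None
        out.append(series)
    return out


def write_desorption_csv(series_list: Sequence[DesorptionSeries], path: str | Path) -> None:
    rows = [
        {
            "analyte": s.analyte,
            "fluid": s.fluid,
            "matrix": s.matrix,
            "total_ng": s.total_mass,
            "time_h": t,
            "cum_released_ng": c,
        }
        for s in series_list
        for t, c in s.timepoints
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_bioaccessibility_csv(series_list: Sequence[DesorptionSeries], path: str | Path) -> None:
    """Reduce each series to F_bioa and write one percent row per series."""
    rows = []
    for s in series_list:
        m = fbioa_from_series(s)
        rows.append(
            {
                "analyte": m.analyte,
                "fluid": m.fluid,
                "matrix": m.matrix,
                "fbioa_percent": m.f_bioa * 100.0,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def assess_matrix_frame(
    registry: PAHRegistry,
    frame: pd.DataFrame,
    scenario: ExposureScenario,
    tox: ToxicityParameters,
    mode: str = "both",
    tie_acceptable: bool = True,
) -> list[IntakeResult]:
    """Assess matrix-route rows (one per analyte x matrix x fluid x loading)."""
    modes = ("total", "bioaccessible") if mode == "both" else (mode,)
    results: list[IntakeResult] = []
    for row in frame.itertuples():
        record = registry.get(row.analyte)
        adi = compute_adi(tox, record.tef)
        for m in modes:
            f = 1.0 if m == "total" else (None if pd.isna(row.fbioa) else float(row.fbioa))
            if f is None:
                results.append(
                    IntakeResult(
                        analyte=record.abbreviation,
                        mode=m,
                        di=None,
                        adi=adi,
                        risky=None,
                        route="matrix",
                        fluid=row.fluid,
                        matrix=row.matrix,
                        note=NOT_ASSESSED,
                    )
                )
                continue
            di = compute_di_matrix(float(row.q_ng_g), f, scenario)
            results.append(
                IntakeResult(
                    analyte=record.abbreviation,
                    mode=m,
                    di=di,
                    adi=adi,
                    risky=classify_intake(di, adi, tie_acceptable),
                    route="matrix",
                    fluid=row.fluid,
                    matrix=row.matrix,
                )
            )
    return results


def _fmt(x: Optional[float], decimals: Optional[int]) -> str:
    if x is None:
        return ""
    if decimals is None:
        return f"{x:.10g}"
    return f"{round_half_up(x, decimals):.{decimals}f}"


def write_intake_csv(
    results: Sequence[IntakeResult],
    path: str | Path,
    printed_precision: Optional[int] = None,
) -> None:
    """Write intake results (``printed_precision`` rounds half-up like the
    published tables, for regression diffing)."""
    rows = [
        {
            "analyte": r.analyte,
            "matrix": r.matrix or "",
            "fluid": r.fluid or "",
            "mode": r.mode,
            "di_ng_kg_day": _fmt(r.di, printed_precision),
            "adi_ng_kg_day": _fmt(r.adi, printed_precision),
            "risky": "" if r.risky is None else str(bool(r.risky)),
            "note": r.note,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_teq_csv(
    results: Sequence[TeqResult],
    path: str | Path,
    printed_precision: Optional[int] = None,
) -> None:
    rows = [
        {
            "analyte": r.analyte,
            "tc_ng_m3": _fmt(r.tc, printed_precision),
            "bc_ng_m3": _fmt(r.bc, printed_precision),
            "ac_ng_m3": _fmt(r.ac, printed_precision),
            "teq_ng_m3": _fmt(r.teq, printed_precision),
            "risky_total": str(bool(r.risky_total)),
            "risky_bioaccessible": ""
            if r.risky_bioaccessible is None
            else str(bool(r.risky_bioaccessible)),
            "note": r.note,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _echo_constants(
    scenario: ExposureScenario, tox: ToxicityParameters, lines: list[str]
) -> None:
    lines.append("# Exposure scenario")
    lines.append(f"#   TR (tracheobronchial retention) = {scenario.tr:.10g}")
    lines.append(f"#   V_resp (inhalation rate)        = {scenario.v_resp:.10g} m3/day")
    lines.append(f"#   BW (body weight)                = {scenario.bw:.10g} kg")
    if scenario.c_particle is not None:
        lines.append(
            f"#   C_particle                      = {scenario.c_particle:.10g} g/m3"
        )
    lines.append("# Toxicity constants")
    lines.append(f"#   CR (target risk)                = {tox.cr:.10g}")
    lines.append(f"#   IPF_BaP                         = {tox.ipf_bap:.10g} (ng/kg/day)^-1")
    lines.append(
        f"#   UR (unit risk, lifetime 70 y)   = {tox.ur:.10g} (ng/m3)^-1"
    )
    for line in lines:
        logger.info(line.lstrip("# "))


def render_intake_report(
    results: Sequence[IntakeResult],
    summary: IntakeSummary,
    scenario: ExposureScenario,
    tox: ToxicityParameters,
) -> str:
    """Plain-text DI/ADI report: constants echo, per-analyte rows, summary."""
    lines: list[str] = ["# Daily-intake (DI vs ADI) assessment"]
    _echo_constants(scenario, tox, lines)
    lines.append("")
    lines.append("analyte  matrix  fluid  mode  DI(ng/kg/day)  ADI(ng/kg/day)  risky")
    for r in results:
        di = "-" if r.di is None else f"{r.di:.6g}"
        risky = "not assessed" if r.risky is None else ("RISKY" if r.risky else "ok")
        lines.append(
            f"{r.analyte}  {r.matrix or '-'}  {r.fluid or '-'}  {r.mode}  "
            f"{di}  {r.adi:.6g}  {risky}"
        )
    lines.append("")
    lines.append("# Summary")
    for m in sorted(summary.min_di):
        lines.append(
            f"#   {m}: DI range {summary.min_di[m]:.6g} to {summary.max_di[m]:.6g} ng/kg/day"
        )
    for m, names in summary.risky.items():
        uniq = sorted(set(names))
        lines.append(f"#   risky ({m}): {', '.join(uniq) if uniq else 'none'}")
    if summary.not_assessed:
        lines.append(f"#   not assessed: {', '.join(summary.not_assessed)}")
    if summary.di_ratio_range is not None:
        lo, hi = summary.di_ratio_range
        lines.append(
            f"#   total/bioaccessible DI ratio over always-risky analytes: "
            f"{lo:.3g} to {hi:.3g}"
        )
    return "\n".join(lines) + "\n"


def render_teq_report(
    results: Sequence[TeqResult],
    scenario: ExposureScenario,
    tox: ToxicityParameters,
    ateq: float,
) -> str:
    """Plain-text TEQ report; both the per-analyte AC view and the
    BaP-equivalent (TEQ vs ATEQ) view of the same classification."""
    lines: list[str] = ["# BaP-TEQ concentration assessment"]
    _echo_constants(scenario, tox, lines)
    lines.append(f"#   ATEQ = CR/UR                    = {ateq:.6g} ng/m3")
    lines.append("")
    lines.append(
        "analyte  TC(ng/m3)  BC(ng/m3)  AC(ng/m3)  TEQ(ngBaP-eq/m3)  "
        "risky_total  risky_bioaccessible"
    )
    risky_total: list[str] = []
    risky_bioa: list[str] = []
    for r in results:
        bc = "-" if r.bc is None else f"{r.bc:.6g}"
        rb = "not assessed" if r.risky_bioaccessible is None else (
            "RISKY" if r.risky_bioaccessible else "ok"
        )
        lines.append(
            f"{r.analyte}  {r.tc:.6g}  {bc}  {r.ac:.6g}  {r.teq:.6g}  "
            f"{'RISKY' if r.risky_total else 'ok'}  {rb}"
        )
        if r.risky_total:
            risky_total.append(r.analyte)
        if r.risky_bioaccessible:
            risky_bioa.append(r.analyte)
    lines.append("")
    lines.append("# Summary")
    lines.append(
        f"#   risky (total concentration): "
        f"{', '.join(risky_total) if risky_total else 'none'}"
    )
    lines.append(
        f"#   risky (bioaccessible concentration): "
        f"{', '.join(risky_bioa) if risky_bioa else 'none'}"
    )
    return "\n".join(lines) + "\n"
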