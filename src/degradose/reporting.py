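"""Report rendering and display rounding.

All arithmetic elsewhere in the package is unrounded; this module owns the
display conventions:

* doses (EED, TI) — 3 significant figures, half-up, thousands separators in
  rendered text only;
* margins of safety — one decimal below 10, half-up integers at 10 and above;
* machine-readable CSV exports — full precision, no separators.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .config import RoundingProfile
from .exposure import SCENARIOS
from .risk import RiskReport, ScreenFlag


# Relative nudge applied before half-up rounding so a value whose exact
# (rational) form sits on a .5 boundary but lands a few ulps below it in
# floating point still rounds up (e.g. 1500/(180000/1860) = 15.5 exactly but
# 15.499999999999998 in floats). Far too small to move any non-boundary digit.
_BOUNDARY_GUARD = Decimal("1e-12")


def _guarded(x: float) -> Decimal:
    d = Decimal(repr(abs(x)))
    return d * (1 + _BOUNDARY_GUARD)


def format_sig3(x: float) -> str:
    """Format a dose to 3 significant figures, half-up, with thousands commas."""
    if x == 0:
        return "0"
    d = _guarded(x)
    exp = d.adjusted()
    decimals = 2 - exp
    q = Decimal(1).scaleb(-decimals)
    rounded = d.quantize(q, rounding=ROUND_HALF_UP)
    if rounded.adjusted() > exp:  # rounding crossed a power of ten (99.96 -> 100)
        decimals -= 1
        rounded = d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    sign = "-" if x < 0 else ""
    if decimals <= 0:
        return sign + f"{int(rounded):,}"
    return sign + f"{rounded:,.{max(decimals, 0)}f}"


def format_mos(m: float | None) -> str:
    """Margin-of-safety display: NA when no exposure; one decimal below 10;
    half-up integer (with thousands commas) at 10 and above."""
    if m is None:
        return "NA"
    sign = "-" if m < 0 else ""
    if abs(m) < 10:
        d = _guarded(m).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        return f"{sign}{d}"
    d = _guarded(m).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return f"{sign}{int(d):,}"


def _fmt(x: float, profile: RoundingProfile, kind: str) -> str:
    if profile is RoundingProfile.none:
        return repr(x)
    return format_mos(x) if kind == "mos" else format_sig3(x)


def _md_table(headers: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(headers) + " |"]
    lines.append("|" + "|".join(" --- " for _ in headers) + "|")
    for row in rows:
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines)


_SCEN_HEAD = ["≤1 d", "2–30 d", "31–365 d", "≥366 d"]


def composition_table(report: RiskReport) -> pd.DataFrame:
    """Per-constituent total quantities (unrounded)."""
    return pd.DataFrame(
        {
            "constituent_name": [c.constituent_name for c in report.constituents],
            "constituent_cas": [c.constituent_cas for c in report.constituents],
            "tq_comp_mg": [c.tq_comp_mg for c in report.constituents],
            "tq_max_mg": [c.tq_max_mg for c in report.constituents],
            "source_polymers": ["; ".join(c.source_polymers) for c in report.constituents],
        }
    )


def ti_table(report: RiskReport) -> pd.DataFrame:
    """Per-constituent tolerable intakes and modifying factors (unrounded)."""
    rows = []
    for ti in report.tis:
        pod = ti.pod_source
        row = {
            "constituent_name": pod.constituent_name,
            "constituent_cas": ti.constituent_cas,
            "pod_mg_per_kg_day": pod.pod_mg_per_kg_day,
            "study_duration_class": pod.study_duration_class.value,
            "surrogate_of": pod.surrogate_of or "",
        }
        for s in SCENARIOS:
            row[f"mf_{s.value}"] = ti.mf[s]
            row[f"ti_{s.value}"] = ti.ti_ug_per_kg_day[s]
        rows.append(row)
    return pd.DataFrame(rows)


def eed_table(report: RiskReport) -> pd.DataFrame:
    """Per-constituent estimated exposure doses (unrounded)."""
    rows = []
    for rec in report.exposures:
        row = {
            "constituent_name": rec.constituent_name,
            "constituent_cas": rec.constituent_cas,
            "tq_max_mg": rec.tq_max_mg,
        }
        for s in SCENARIOS:
            row[f"eed_{s.value}"] = rec.eed_ug_per_kg_day[s]
        rows.append(row)
    return pd.DataFrame(rows)


def mos_table(report: RiskReport) -> pd.DataFrame:
    """Per-constituent margins of safety with flags and refined values."""
    rows = []
    for rec in report.mos_records:
        row = {
            "constituent_name": rec.constituent_name,
            "constituent_cas": rec.constituent_cas,
        }
        for s in SCENARIOS:
            row[f"mos_{s.value}"] = rec.mos[s] if rec.mos[s] is not None else math.nan
            row[f"flag_{s.value}"] = rec.flags[s].value
            row[f"refined_mos_{s.value}"] = rec.refined_mos.get(s, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_tables(report: RiskReport, outdir: str | Path) -> list[Path]:
    """Write the four tabular surfaces as full-precision CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("composition", composition_table(report)),
        ("tolerable_intake", ti_table(report)),
        ("exposure", eed_table(report)),
        ("margin_of_safety", mos_table(report)),
    ):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written


def render_report(report: RiskReport, format: str = "markdown") -> str:
    """Render the assessment as a markdown document (byte-stable for fixed
    inputs). ``format="csv"`` returns the four tables concatenated as CSV
    blocks instead."""
    if format == "csv":
        parts = []
        for name, df in (
            ("composition", composition_table(report)),
            ("tolerable_intake", ti_table(report)),
            ("exposure", eed_table(report)),
            ("margin_of_safety", mos_table(report)),
        ):
            parts.append(f"# {name}\n" + df.to_csv(index=False))
        return "\n".join(parts)
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")

    p = report.config.rounding_profile
    doc = [f"# Toxicological risk assessment — {report.device.device_name}", ""]
    doc.append(
        f"Scaling factor {report.device.scaling_factor}; body weight "
        f"{report.config.body_weight_kg:g} kg; refinement window "
        f"{report.config.refinement_window_days:g} d; review band upper bound "
        f"{report.config.review_band_upper:g}."
    )
    doc += ["", "## Constituent total quantities", ""]
    doc.append(
        _md_table(
            ["Constituent", "CAS RN", "TQ_comp (mg/device)", "TQ_max (mg/patient)", "Source polymers"],
            [
                [
                    c.constituent_name,
                    c.constituent_cas,
                    _fmt(c.tq_comp_mg, p, "dose"),
                    _fmt(c.tq_max_mg, p, "dose"),
                    "; ".join(c.source_polymers),
                ]
                for c in report.constituents
            ],
        )
    )
    doc += ["", "## Tolerable intakes (µg/kg/day)", ""]
    rows = []
    for ti in report.tis:
        pod = ti.pod_source
        name = pod.constituent_name
        if pod.surrogate_of:
            name += f" (read-across: {pod.surrogate_of})"
        rows.append(
            [name, ti.constituent_cas]
            + [_fmt(ti.ti_ug_per_kg_day[s], p, "dose") for s in SCENARIOS]
        )
    doc.append(_md_table(["Constituent", "CAS RN"] + [f"TI {h}" for h in _SCEN_HEAD], rows))
    doc.append("")
    doc.append(
        "PODs (mg/kg/day) and modifying factors: "
        + "; ".join(
            f"{ti.pod_source.constituent_name}: POD {ti.pod_source.pod_mg_per_kg_day:g} "
            f"({ti.pod_source.study_duration_class.value}), MF "
            + "/".join(f"{ti.mf[s]:g}" for s in SCENARIOS)
            for ti in report.tis
        )
        + ". Duration and data-quality uncertainty factors beyond the two "
        "conventional factors of 10 are carried as a combined residual."
    )
    doc += ["", "## Estimated exposure doses (µg/kg/day)", ""]
    doc.append(
        _md_table(
            ["Constituent", "CAS RN", "TQ_max (mg)"] + [f"EED {h}" for h in _SCEN_HEAD],
            [
                [rec.constituent_name, rec.constituent_cas, _fmt(rec.tq_max_mg, p, "dose")]
                + [_fmt(rec.eed_ug_per_kg_day[s], p, "dose") for s in SCENARIOS]
                for rec in report.exposures
            ],
        )
    )
    doc += ["", "## Margins of safety", ""]
    rows = []
    for rec in report.mos_records:
        cells = []
        for s in SCENARIOS:
            cell = _fmt(rec.mos[s], p, "mos") if rec.mos[s] is not None else "NA"
            if rec.flags[s] is ScreenFlag.refine_needed:
                cell = f"**{cell}**"
            cells.append(cell)
        rows.append([rec.constituent_name, rec.constituent_cas] + cells)
    doc.append(_md_table(["Constituent", "CAS RN"] + [f"MOS {h}" for h in _SCEN_HEAD], rows))
    doc.append("")
    doc.append(
        "Bold: MOS < 1 (refinement trigger). Margins are computed from "
        "unrounded TI and EED values; display rounding is applied last."
    )

    doc += ["", "## Refinement", ""]
    if report.narratives:
        for n in report.narratives:
            doc.append(f"- {n}")
    else:
        doc.append("No refinement was required: all margins screened at or above 1.")
    if report.unresolved:
        doc.append("")
        doc.append(
            "Unresolved risk: "
            + "; ".join(f"{cas} ({s.value})" for cas, s in report.unresolved)
            + " — margin of safety below 1 without resolving degradation data."
        )

    doc += ["", "## Audit", ""]
    doc.append(
        _md_table(
            ["Quantity", "Formula", "Inputs", "Value"],
            [
                [
                    e.quantity,
                    f"`{e.formula}`",
                    ", ".join(f"{k}={v:g}" for k, v in e.inputs.items()),
                    repr(e.value),
                ]
                for e in report.audit
            ],
        )
    )
    doc.append("")
    return "\n".join(doc)
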