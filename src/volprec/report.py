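"""Study-style report generation from a longitudinal volume series.

Mirrors the reporting layout of a CT volumetry repeatability study: a
per-organ mean-volume/COV table with cohort aggregates, a paired-organ r²
table, the COV-vs-volume trend fit, and detectable-change results for each
series.  All numbers are computed at full precision; rounding (half away
from zero, percents and volumes to 1 decimal) happens only in the display
columns and the plain-text summary.
"""

from __future__ import annotations

import dataclasses
import decimal
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .contours import read_series, write_series
from .detect import DetectableChangeResult, min_detectable_volume_change
from .errors import ValidationError
from .phantom import PhantomSpec, simulate_longitudinal_series
from .precision import (
    OrganSeries,
    cohort_cov_summary,
    cov_volume_trend,
    paired_series_r2,
    series_summary,
    split_series,
    TrendFit,
)

log = logging.getLogger("volprec")


def round_display(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of the printed tables."""
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclasses.dataclass(frozen=True)
class ReportConfig:
    alphas: tuple[float, ...] = (0.05, 0.01)
    trend_form: str = "linear"
    independent_noise: bool = True
    min_scans: int = 2


@dataclasses.dataclass(eq=False)
class ReportBundle:
    summary_table: pd.DataFrame  # one row per (patient, organ)
    cohort_table: pd.DataFrame  # one row per organ label
    r2_table: pd.DataFrame  # one row per patient with a paired organ
    trend: TrendFit | None
    detectable: list[DetectableChangeResult]
    metadata: dict


def _summaries(series_list: Sequence[OrganSeries], min_scans: int):
    kept, rows = [], []
    for s in series_list:
        if len(s) < min_scans:
            log.warning(
                "excluding %s/%s: only %d scan(s); unilateral or single-scan "
                "series carry no precision information",
                s.patient_id, s.organ_label, len(s),
            )
            continue
        ps = series_summary(s)
        kept.append((s, ps))
        rows.append(
            {
                "patient_id": s.patient_id,
                "organ_label": s.organ_label,
                "n_scans": ps.n,
                "mean_cm3": ps.mean,
                "sd_cm3": ps.sd,
                "cov": ps.cov,
                "mean_cm3_display": round_display(ps.mean, 1),
                "cov_pct_display": round_display(100 * ps.cov, 1),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "organ_label", "n_scans", "mean_cm3", "sd_cm3",
            "cov", "mean_cm3_display", "cov_pct_display",
        ],
    )
    return kept, table


def build_report(frame: pd.DataFrame, config: ReportConfig | None = None) -> ReportBundle:
    """Compute the full report bundle from a series DataFrame."""
    config = config or ReportConfig()
    if frame.empty:
        raise ValidationError("series input is empty")
    series_list = split_series(frame)
    kept, summary_table = _summaries(series_list, config.min_scans)
    if not kept:
        raise ValidationError("no series with enough scans to analyse")

    cohort_rows = []
    for organ, g in summary_table.groupby("organ_label", sort=True):
        cs = cohort_cov_summary(g["cov"].tolist())
        cohort_rows.append(
            {
                "organ_label": organ,
                "n_patients": cs.n,
                "mean_cov": cs.mean,
                "sd_cov": cs.sd,
                "mean_volume_cm3": g["mean_cm3"].mean(),
                "mean_cov_pct_display": round_display(100 * cs.mean, 1),
            }
        )
    cohort_table = pd.DataFrame(cohort_rows)

    r2_rows = []
    by_patient: dict[str, list[OrganSeries]] = {}
    for s, _ in kept:
        by_patient.setdefault(s.patient_id, []).append(s)
    for pid in sorted(by_patient):
        organs = sorted(by_patient[pid], key=lambda s: s.organ_label)
        if len(organs) < 2:
            continue
        a, b = organs[0], organs[1]
        m = min(len(a), len(b))
        try:
            r2 = paired_series_r2(a.volumes[:m], b.volumes[:m])
        except ValidationError as exc:
            log.warning("no r² for patient %s: %s", pid, exc)
            continue
        r2_rows.append(
            {
                "patient_id": pid,
                "organ_a": a.organ_label,
                "organ_b": b.organ_label,
                "n_pairs": m,
                "r_squared": r2,
            }
        )
    r2_table = pd.DataFrame(
        r2_rows, columns=["patient_id", "organ_a", "organ_b", "n_pairs", "r_squared"]
    )

    trend = None
    points = [(row["mean_cm3"], row["cov"]) for _, row in summary_table.iterrows()]
    if len(points) >= 3 and len({p[0] for p in points}) > 1:
        trend = cov_volume_trend(points, form=config.trend_form)

    detectable = [
        min_detectable_volume_change(
            ps.mean, ps.sd, ps.n, alpha, independent_noise=config.independent_noise
        )
        for _, ps in kept
        for alpha in config.alphas
    ]

    metadata = {
        "volprec_version": __version__,
        "config": dataclasses.asdict(config),
        "n_series_analysed": len(kept),
        "n_rows_input": int(len(frame)),
    }
    return ReportBundle(summary_table, cohort_table, r2_table, trend, detectable, metadata)


def _summary_text(bundle: ReportBundle) -> str:
    lines = ["volume-measurement precision report", ""]
    for _, r in bundle.summary_table.iterrows():
        lines.append(
            f"  {r.patient_id} {r.organ_label}: n={r.n_scans}, "
            f"mean {r.mean_cm3_display:.1f} cm3, COV {r.cov_pct_display:.1f}%"
        )
    lines.append("")
    for _, r in bundle.cohort_table.iterrows():
        lines.append(
            f"cohort {r.organ_label}: mean COV {r.mean_cov_pct_display:.1f}% "
            f"over {r.n_patients} patients"
        )
    if not bundle.r2_table.empty:
        lines.append("")
        for _, r in bundle.r2_table.iterrows():
            lines.append(
                f"paired r^2 {r.patient_id} ({r.organ_a} vs {r.organ_b}): "
                f"{r.r_squared:.3f}"
            )
        lines.append(
            f"mean paired r^2: {bundle.r2_table['r_squared'].mean():.3f}"
        )
    if bundle.trend is not None:
        lines.append("")
        lines.append(
            f"COV-vs-volume trend ({bundle.trend.form}): slope "
            f"{bundle.trend.slope:.4f} per cm3, r^2 {bundle.trend.r_squared:.3f}"
        )
    if bundle.detectable:
        lines.append("")
        for d in bundle.detectable:
            lines.append(
                f"detectable change (mean {d.mean:.2f}, sd {d.sd:.2f}, n {d.n}, "
                f"alpha {d.alpha:g}): volume "
                f"{round_display(100 * d.min_detectable_volume_fraction, 1):.1f}%, "
                f"linear {round_display(100 * d.equivalent_linear_fraction, 1):.1f}%"
            )
    lines.append("")
    return "\n".join(lines)


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the bundle's tables as CSV plus a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summary_table.to_csv(out / "summary_by_organ.csv", index=False, float_format="%.9g")
    bundle.cohort_table.to_csv(out / "cohort_cov.csv", index=False, float_format="%.9g")
    bundle.r2_table.to_csv(out / "paired_r2.csv", index=False, float_format="%.9g")
    rows = [
        {
            "patient_or_series": f"{d.mean:.6f}/{d.sd:.6f}/{d.n}",
            "alpha": d.alpha,
            "min_detectable_volume_fraction": d.min_detectable_volume_fraction,
            "equivalent_linear_fraction": d.equivalent_linear_fraction,
        }
        for d in bundle.detectable
    ]
    pd.DataFrame(rows).to_csv(out / "detectable_change.csv", index=False, float_format="%.9g")
    if bundle.trend is not None:
        pd.DataFrame([dataclasses.asdict(bundle.trend)]).to_csv(
            out / "trend.csv", index=False, float_format="%.9g"
        )
    (out / "summary.txt").write_text(_summary_text(bundle))


def run_report(
    series_csv: str | Path | pd.DataFrame,
    out_dir: str | Path | None = None,
    config: ReportConfig | None = None,
) -> ReportBundle:
    """Read a series CSV, compute the report, optionally write it out.

    Nothing is written unless the whole report computes, so a failing input
    leaves no partial files.
    """
    frame = series_csv if isinstance(series_csv, pd.DataFrame) else read_series(series_csv)
    bundle = build_report(frame, config)
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def run_end_to_end(
    spec: PhantomSpec,
    out_dir: str | Path | None = None,
    config: ReportConfig | None = None,
) -> ReportBundle:
    """Simulate a phantom study and report on it in one call.

    simulate → contours → volumes → precision → detectable change; the seed
    lives in the spec and is recorded in the metadata.
    """
    series, _stacks = simulate_longitudinal_series(spec, out_dir=out_dir)
    frame = pd.DataFrame(
        {
            "patient_id": series.patient_id,
            "scan_id": [m.scan_id for m in series.measurements],
            "scan_date": pd.NA,
            "organ_label": series.organ_label,
            "volume_cm3": [m.volume_cm3 for m in series.measurements],
        }
    )
    bundle = build_report(frame, config)
    bundle.metadata["seed"] = spec.seed
    bundle.metadata["phantom"] = repr(spec)
    if out_dir is not None:
        write_report(bundle, out_dir)
        write_series(frame, Path(out_dir) / "series.csv")
    return bundle
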