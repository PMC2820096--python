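"""End-to-end study orchestration and table-style reports.

``run_avalanche_study`` executes the full pipeline — standardize,
high-pass, detect peaks, bin into avalanches, fit both tail laws with
KS-selected ``x_min``, bootstrap goodness-of-fit, log-likelihood-ratio
comparison — for every requested condition (polarity x threshold x
original/shuffled x size mode) and collects one report row per condition.
``analyze_sample`` is the single-sample core, reused verbatim for
avalanche samples from any source (e.g. the SOC network's size lists).

Report rows serialize to JSON, CSV and markdown with the classic column
layout ``Exponential fit | Power-Law fit | Log Likelihood ratio``
(lambda, KS, p-val, % | alpha, KS, p-val, % | LLR, p-val, Result).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from . import peaks as pk
from .tail import (
    DegenerateTailError,
    GofResult,
    TailFit,
    TailSample,
    gof_pvalue,
    llr_compare,
    select_x_min,
)

__all__ = ["FitSummary", "ReportRow", "AnalysisReport",
           "analyze_sample", "run_avalanche_study", "render_report",
           "report_from_json"]

CSV_COLUMNS = [
    "label", "condition",
    "lam", "ks_exp", "pval_exp", "pct_exp",
    "alpha", "ks_pl", "pval_pl", "pct_pl",
    "llr", "llr_pval", "result",
]


@dataclass(frozen=True)
class FitSummary:
    """One law's fit condensed to the table columns."""

    law: str
    param: float
    x_min: float
    ks: float
    p_val: float
    pct: float  # 100 * n_tail / n, the tail fraction the fit explains
    n_tail: int

    @classmethod
    def from_fit(cls, fit: TailFit, gof: GofResult) -> "FitSummary":
        return cls(fit.law, fit.param, fit.x_min, fit.ks, gof.p_value,
                   100.0 * fit.tail_fraction, fit.n_tail)


@dataclass(frozen=True)
class ReportRow:
    label: str
    condition: str
    n: int = 0
    exp: Optional[FitSummary] = None
    pl: Optional[FitSummary] = None
    llr: float = math.nan
    llr_pval: float = math.nan
    verdict: str = "no data"
    seed: int = 0


@dataclass(frozen=True)
class AnalysisReport:
    rows: tuple[ReportRow, ...]
    provenance: dict = field(default_factory=dict)


def analyze_sample(
    sample: TailSample,
    label: str,
    condition: str = "",
    min_tail: int = 10,
    gof_replicates: int = 1000,
    seed: int = 0,
    significance_threshold: float = 0.05,
) -> ReportRow:
    """Fit both laws (KS-selected ``x_min``), bootstrap their GOF p-values
    and run the log-likelihood-ratio comparison on one size sample."""
    fit_exp = select_x_min(sample, "exponential", min_tail=min_tail)
    fit_pl = select_x_min(sample, "powerlaw", min_tail=min_tail)
    gof_exp = gof_pvalue(sample, fit_exp, gof_replicates, seed=seed)
    gof_pl = gof_pvalue(sample, fit_pl, gof_replicates, seed=seed + 1)
    llr = llr_compare(sample, fit_pl, fit_exp, significance_threshold)
    return ReportRow(
        label=label, condition=condition, n=sample.n,
        exp=FitSummary.from_fit(fit_exp, gof_exp),
        pl=FitSummary.from_fit(fit_pl, gof_pl),
        llr=llr.llr, llr_pval=llr.significance, verdict=llr.verdict,
        seed=seed,
    )


def run_avalanche_study(
    signal: pk.MultiChannelSignal,
    thresholds: Optional[dict[str, float]] = None,
    polarities: Sequence[str] = ("negative", "positive"),
    bin_width: float = 0.008,
    modes: Sequence[str] = ("amplitude",),
    cutoff_hz: float = 15.0,
    include_shuffled: bool = True,
    min_tail: int = 10,
    gof_replicates: int = 200,
    seed: int = 0,
    significance_threshold: float = 0.05,
) -> AnalysisReport:
    """Full avalanche study over every requested condition.

    Pipeline per condition: standardize -> high-pass (``cutoff_hz``) ->
    detect peaks (polarity, threshold) -> bin at ``bin_width`` and cluster
    -> fit/GOF/compare. Shuffled-surrogate arms redo the binning on a
    time-randomized raster. Conditions that produce no events or too few
    avalanches yield a ``"no data"`` row; the run continues.
    """
    thresholds = thresholds or {"low": 1.5, "high": 3.0}
    std = pk.standardize(signal)
    filt = pk.highpass(std, cutoff_hz)
    rows: list[ReportRow] = []
    idx = 0
    for polarity in polarities:
        for tname, thr in thresholds.items():
            raster = pk.detect_peaks(filt, std, thr, polarity)  # type: ignore[arg-type]
            variants = [("", raster)]
            if include_shuffled:
                variants.append(
                    ("shuffled", pk.shuffle_times(raster, seed + 7919 * (idx + 1)))
                )
            for vname, r in variants:
                for mode in modes:
                    condition = "/".join(
                        x for x in (polarity, tname, vname, mode) if x
                    )
                    row_seed = seed + 1000 * idx
                    idx += 1
                    sample_ok = r.n_events > 0
                    if sample_ok:
                        av = pk.bin_and_cluster(r, bin_width, mode)  # type: ignore[arg-type]
                        sample_ok = av.sizes.size >= max(min_tail, 2)
                    if not sample_ok:
                        rows.append(ReportRow(label="signal", condition=condition,
                                              seed=row_seed))
                        continue
                    try:
                        rows.append(
                            analyze_sample(
                                av.to_tail_sample(), "signal", condition,
                                min_tail=min_tail,
                                gof_replicates=gof_replicates,
                                seed=row_seed,
                                significance_threshold=significance_threshold,
                            )
                        )
                    except DegenerateTailError:
                        rows.append(ReportRow(label="signal", condition=condition,
                                              seed=row_seed))
    provenance = {
        "seed": seed,
        "thresholds": thresholds,
        "bin_width_s": bin_width,
        "cutoff_hz": cutoff_hz,
        "modes": list(modes),
        "polarities": list(polarities),
        "gof_replicates": gof_replicates,
        "min_tail": min_tail,
        "n_channels": signal.n_channels,
        "rate_hz": signal.rate,
    }
    return AnalysisReport(rows=tuple(rows), provenance=provenance)


# ---------------------------------------------------------------------------
# rendering


def _row_cells(row: ReportRow) -> list[str]:
    def num(x, fmt="{:.6g}"):
        return "" if x is None or (isinstance(x, float) and math.isnan(x)) else fmt.format(x)

    e, p = row.exp, row.pl
    return [
        row.label, row.condition,
        num(e.param if e else None), num(e.ks if e else None),
        num(e.p_val if e else None), num(e.pct if e else None),
        num(p.param if p else None), num(p.ks if p else None),
        num(p.p_val if p else None), num(p.pct if p else None),
        num(row.llr), num(row.llr_pval), row.verdict,
    ]


def render_report(
    report: AnalysisReport,
    format: Literal["json", "csv", "markdown"] = "json",
    path=None,
) -> str:
    """Serialize a report; JSON is lossless and byte-stable for fixed seeds."""
    if format == "json":
        text = json.dumps(dataclasses.asdict(report), indent=1, sort_keys=True,
                          allow_nan=True)
    elif format == "csv":
        lines = [",".join(CSV_COLUMNS)]
        lines += [",".join(_row_cells(r)) for r in report.rows]
        text = "\n".join(lines) + "\n"
    elif format == "markdown":
        header = "| " + " | ".join(CSV_COLUMNS) + " |"
        sep = "|" + "|".join(["---"] * len(CSV_COLUMNS)) + "|"
        body = ["| " + " | ".join(_row_cells(r)) + " |" for r in report.rows]
        text = "\n".join([header, sep] + body) + "\n"
    else:
        raise ValueError(f"unknown format {format!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def report_from_json(text: str) -> AnalysisReport:
    """Inverse of ``render_report(..., "json")``."""
    raw = json.loads(text)
    rows = []
    for r in raw["rows"]:
        exp = FitSummary(**r["exp"]) if r["exp"] else None
        pl = FitSummary(**r["pl"]) if r["pl"] else None
        llr = r["llr"] if r["llr"] is not None else math.nan
        llr_p = r["llr_pval"] if r["llr_pval"] is not None else math.nan
        rows.append(ReportRow(r["label"], r["condition"], r["n"], exp, pl,
                              llr, llr_p, r["verdict"], r["seed"]))
    return AnalysisReport(rows=tuple(rows), provenance=raw["provenance"])
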