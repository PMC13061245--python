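"""Agreement statistics between measured and predicted contact-force curves.

Per trial: Pearson correlation, RMSE, absolute peak difference, the two
errors as percentages of the trial's maximum measured force, and a
qualitative correlation rank (poor / moderate / good / excellent). Across
trials: Bland-Altman analysis of the peak forces (bias and 1.96-SD limits
of agreement, overall and per engagement technique) and grouped
mean +/- SD tables by technique or by front-row shoulder, with percentages
renormalised to the group's maximum measured force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_preprocess import ShapeError


class EvaluationError(ValueError):
    pass


RANKS = ("poor", "moderate", "good", "excellent")


@dataclass
class AgreementRecord:
    trial_id: str
    technique: str
    shoulder: str  # A1-L .. A3-R
    correlation: float
    rmse: float  # newtons
    nrmse_pct: float  # % of the trial's max measured force
    peak_diff: float  # newtons, absolute
    npeak_pct: float  # %
    rank: str
    peak_measured: float = np.nan
    peak_predicted: float = np.nan


@dataclass
class BlandAltmanResult:
    bias: float  # mean(predicted - measured), newtons
    loa_lower: float
    loa_upper: float
    n: int
    by_group: dict = field(default_factory=dict)  # label -> BlandAltmanResult


@dataclass
class GroupedReport:
    group: str
    n: int
    correlation_mean: float
    correlation_sd: float
    rmse_mean: float
    rmse_sd: float
    nrmse_pct_mean: float
    nrmse_pct_sd: float
    peak_diff_mean: float
    peak_diff_sd: float
    npeak_pct_mean: float
    npeak_pct_sd: float
    group_max_force: float  # normalisation basis for the group percentages


def rank_correlation(r: float) -> str:
    """Qualitative band for a Pearson correlation.

    Bands: poor [-1, 0.5], moderate (0.5, 0.75], good (0.75, 0.9],
    excellent (0.9, 1]. The published band edges overlap, so each shared
    endpoint is assigned to the lower band; in particular exactly 0.9 is
    'good' and exactly 0.75 is 'moderate'.
    """
    if not -1.0 <= r <= 1.0:
        raise EvaluationError(f"correlation {r} outside [-1, 1]")
    if r <= 0.5:
        return "poor"
    if r <= 0.75:
        return "moderate"
    if r <= 0.9:
        return "good"
    return "excellent"


def pairing_to_shoulder(pairing: str) -> str:
    """'A2R-B2' -> 'A2-R': the instrumented player's shoulder label."""
    player = pairing.split("-")[0]
    return f"{player[:2]}-{player[2]}"


def agreement(measured: np.ndarray, predicted: np.ndarray, meta: dict | None = None) -> AgreementRecord:
    """Per-trial agreement between a measured and a predicted force curve.

    Percentages normalise RMSE and the absolute peak difference by the
    maximum of the measured curve, so they are invariant to rescaling both
    curves by a common positive factor.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.ndim != 1 or len(measured) < 3:
        raise ShapeError(
            f"curves must be equal-length 1-D series of >= 3 samples; got {measured.shape} and {predicted.shape}"
        )
    if np.ptp(measured) == 0:
        raise EvaluationError("correlation undefined for a constant measured curve")
    meta = meta or {}
    r = float(stats.pearsonr(measured, predicted).statistic)
    rmse = float(np.sqrt(np.mean((measured - predicted) ** 2)))
    peak_m, peak_p = float(measured.max()), float(predicted.max())
    peak_diff = abs(peak_m - peak_p)
    pairing = meta.get("pairing", "")
    return AgreementRecord(
        trial_id=str(meta.get("trial_id", "?")),
        technique=meta.get("technique", "?"),
        shoulder=pairing_to_shoulder(pairing) if pairing else meta.get("shoulder", "?"),
        correlation=r,
        rmse=rmse,
        nrmse_pct=100.0 * rmse / peak_m,
        peak_diff=peak_diff,
        npeak_pct=100.0 * peak_diff / peak_m,
        rank=rank_correlation(r),
        peak_measured=peak_m,
        peak_predicted=peak_p,
    )


def bland_altman(
    peaks_measured: Sequence[float],
    peaks_predicted: Sequence[float],
    group_labels: Sequence[str] | None = None,
) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement on peak forces.

    Differences are ``predicted - measured`` (positive bias means the model
    overestimates); limits are bias +/- 1.96 * SD with the n-1 denominator.
    ``group_labels`` (e.g. engagement techniques) yield per-group
    sub-results on the label subsets.
    """
    m = np.asarray(peaks_measured, dtype=float)
    p = np.asarray(peaks_predicted, dtype=float)
    if m.shape != p.shape:
        raise ShapeError(f"peak lists differ in length: {m.shape[0]} vs {p.shape[0]}")
    if len(m) < 2:
        raise EvaluationError("need >= 2 peak pairs for limits of agreement")
    d = p - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    res = BlandAltmanResult(bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd, n=len(d))
    if group_labels is not None:
        labels = np.asarray(group_labels)
        if labels.shape[0] != len(d):
            raise ShapeError("group_labels length mismatch")
        for lab in dict.fromkeys(labels.tolist()):
            sel = labels == lab
            if sel.sum() >= 2:
                res.by_group[lab] = bland_altman(m[sel], p[sel])
    return res


def grouped_report(
    records: Sequence[AgreementRecord],
    by: str,
    measured_curves: Sequence[np.ndarray],
) -> list[GroupedReport]:
    """Mean +/- SD of every agreement metric per technique or per shoulder.

    ``by`` is 'technique' or 'shoulder'. Group percentages are recomputed
    against the maximum force across the group's measured curves (not the
    per-trial maxima), matching how the published summary tables normalise.
    ``measured_curves`` must align with ``records``.
    """
    if by not in ("technique", "shoulder"):
        raise EvaluationError(f"can group by 'technique' or 'shoulder', not {by!r}")
    if len(measured_curves) != len(records):
        raise ShapeError("measured_curves must align with records")
    labels = [getattr(rec, by) for rec in records]
    if any(lab in ("?", "", None) for lab in labels):
        raise EvaluationError(f"every record needs a {by} label for grouping")
    reports = []
    for lab in dict.fromkeys(labels):
        idx = [i for i, l in enumerate(labels) if l == lab]
        sub = [records[i] for i in idx]
        gmax = float(max(np.max(measured_curves[i]) for i in idx))
        corr = np.array([r.correlation for r in sub])
        rmse = np.array([r.rmse for r in sub])
        peak = np.array([r.peak_diff for r in sub])
        sd = lambda x: float(x.std(ddof=1)) if len(x) > 1 else 0.0
        reports.append(
            GroupedReport(
                group=lab,
                n=len(sub),
                correlation_mean=float(corr.mean()),
                correlation_sd=sd(corr),
                rmse_mean=float(rmse.mean()),
                rmse_sd=sd(rmse),
                nrmse_pct_mean=float((100 * rmse / gmax).mean()),
                nrmse_pct_sd=sd(100 * rmse / gmax),
                peak_diff_mean=float(peak.mean()),
                peak_diff_sd=sd(peak),
                npeak_pct_mean=float((100 * peak / gmax).mean()),
                npeak_pct_sd=sd(100 * peak / gmax),
                group_max_force=gmax,
            )
        )
    return reports
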