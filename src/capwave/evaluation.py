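"""Reconstruction accuracy metrics, feature extraction, and model comparison.

Per-record waveform metrics (all in mmHg except the dimensionless SCC):

    MAE  = mean |y_i - y^_i|
    RMSE = sqrt(mean (y_i - y^_i)^2)
    MAX  = max |y_i - y^_i|
    SCC  = Spearman rank correlation, 1 - 6 sum d_i^2 / (N (N^2 - 1))
           with d_i the rank difference; ties get average (fractional)
           ranks, in which case the coefficient is computed as the Pearson
           correlation of the rank vectors (identical to the closed form
           when there are no ties).

Clinical point features SBP/DBP/MAP are scalars per record, so their
per-record MAE, RMSE and MAX all equal the absolute error — which is why a
cohort comparison table shows identical MAE and RMSE columns for them.
Aggregation is mean +/- SD of per-record values over the test set, and
model pairs are compared with a classical paired t-test on per-record
errors (two-sided; * p<0.05, ** p<0.01, n.s. otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PairedRecord
from .errors import DegenerateInputError, ValidationError
from .preprocessing import NormalizationScheme
from .waveform import PressureWaveform

__all__ = [
    "waveform_metrics",
    "extract_features",
    "spearman",
    "paired_ttest",
    "ModelMetrics",
    "ComparisonReport",
    "evaluate_model",
    "evaluate_models",
]

BP_ROWS = ("TW", "SBP", "DBP", "MAP")
ERROR_COLS = ("MAE", "RMSE", "MAX")


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Fractional ranks (1-based); tied values share the mean of their ranks."""
    _, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    ends = np.cumsum(counts)
    starts = ends - counts + 1
    return ((starts + ends) / 2.0)[inverse]


def spearman(y, y_hat) -> float:
    """Spearman rank correlation with average ranks for ties."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 2:
        raise ValidationError("sequences must be 1-D with equal length >= 2")
    ry = _average_ranks(y)
    rh = _average_ranks(y_hat)
    dy = ry - ry.mean()
    dh = rh - rh.mean()
    denom = np.sqrt((dy ** 2).sum() * (dh ** 2).sum())
    if denom == 0:
        raise DegenerateInputError("rank correlation undefined for a constant sequence")
    return float((dy * dh).sum() / denom)


def waveform_metrics(y, y_hat) -> tuple[float, float, float, float]:
    """(MAE, RMSE, MAX, SCC) between a measured and an estimated waveform."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 2:
        raise ValidationError("sequences must be 1-D with equal length >= 2")
    err = y - y_hat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mx = float(np.max(np.abs(err)))
    try:
        scc = spearman(y, y_hat)
    except DegenerateInputError:
        scc = float("nan")  # a constant sequence has no rank ordering
    return mae, rmse, mx, scc


def extract_features(w: PressureWaveform | np.ndarray,
                     map_method: str = "mean") -> tuple[float, float, float]:
    """(SBP, DBP, MAP) in mmHg.

    SBP is the waveform maximum, DBP the minimum.  MAP defaults to the
    time average over the record; ``map_method='formula'`` uses the
    DBP + PP/3 estimator instead.
    """
    values = w.values if isinstance(w, PressureWaveform) else np.asarray(w, float)
    if values.ndim != 1 or values.size == 0:
        raise ValidationError("waveform must be non-empty and 1-D")
    sbp = float(values.max())
    dbp = float(values.min())
    if map_method == "mean":
        mean_ap = float(values.mean())
    elif map_method == "formula":
        mean_ap = dbp + (sbp - dbp) / 3.0
    else:
        raise ValidationError(f"unknown MAP method {map_method!r}")
    return sbp, dbp, mean_ap


def paired_ttest(errors_a, errors_b) -> tuple[float, int, float]:
    """Classical paired t-test on per-record differences.

    Returns (t, df, two-sided p); raises :class:`DegenerateInputError`
    when all differences are identical (zero variance).
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("paired samples must be 1-D with equal length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance differences in paired t-test")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


@dataclass
class ModelMetrics:
    """Per-record and aggregated metrics for one model on one test set."""

    name: str
    per_record: pd.DataFrame   # columns: record_id, TW_MAE..MAP_MAX, SCC
    scc_mean: float

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SD table: rows TW/SBP/DBP/MAP, columns MAE/RMSE/MAX."""
        rows = {}
        for bp in BP_ROWS:
            rows[bp] = {}
            for col in ERROR_COLS:
                v = self.per_record[f"{bp}_{col}"].to_numpy()
                rows[bp][col] = (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0)
        return pd.DataFrame(rows).T[list(ERROR_COLS)]


@dataclass
class ComparisonReport:
    """Side-by-side comparison of two models with significance annotations."""

    metrics_a: ModelMetrics
    metrics_b: ModelMetrics
    significance: dict[tuple[str, str], str]  # (BP row, error col) -> annotation
    pvalues: dict[tuple[str, str], float | None]

    def to_table(self) -> str:
        lines = [f"{'Methods':<16}{'BP':<6}" + "".join(f"{c:<18}" for c in ERROR_COLS)]
        for m, annotate in ((self.metrics_a, False), (self.metrics_b, True)):
            agg = m.aggregate()
            for bp in BP_ROWS:
                cells = []
                for col in ERROR_COLS:
                    mean, sd = agg.loc[bp, col]
                    star = self.significance[(bp, col)] if annotate else ""
                    star = "" if star == "n.s." else star
                    cells.append(f"{mean:.2f} ± {sd:.2f}{star}")
                name = m.name if bp == BP_ROWS[0] else ""
                lines.append(f"{name:<16}{bp:<6}" + "".join(f"{c:<18}" for c in cells))
        lines.append(f"SCC (TW mean): {self.metrics_a.name} {self.metrics_a.scc_mean:.4f}, "
                     f"{self.metrics_b.name} {self.metrics_b.scc_mean:.4f}")
        lines.append("* p < 0.05, ** p < 0.01 (paired t-test on per-record errors)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def agg_dict(m: ModelMetrics):
            agg = m.aggregate()
            return {bp: {col: {"mean": agg.loc[bp, col][0], "sd": agg.loc[bp, col][1]}
                         for col in ERROR_COLS} for bp in BP_ROWS}
        return {
            "models": {
                self.metrics_a.name: {"aggregate": agg_dict(self.metrics_a),
                                      "scc_mean": self.metrics_a.scc_mean},
                self.metrics_b.name: {"aggregate": agg_dict(self.metrics_b),
                                      "scc_mean": self.metrics_b.scc_mean},
            },
            "significance": {f"{bp}/{col}": self.significance[(bp, col)]
                             for bp in BP_ROWS for col in ERROR_COLS},
            "pvalues": {f"{bp}/{col}": self.pvalues[(bp, col)]
                        for bp in BP_ROWS for col in ERROR_COLS},
        }


def evaluate_model(predict: Callable[[np.ndarray], np.ndarray],
                   records: Sequence[PairedRecord],
                   scheme: NormalizationScheme | None = None,
                   name: str = "model") -> ModelMetrics:
    """Reconstruct every test record and collect per-record metrics in mmHg.

    ``predict`` maps a normalized radial sequence to a normalized aortic
    estimate (a trained :class:`~capwave.model.TCNAttention` works
    directly); predictions are denormalized through ``scheme`` before the
    metrics are computed.
    """
    records = list(records)
    if not records:
        raise ValidationError("test set is empty")
    scheme = scheme or NormalizationScheme()
    rows = []
    for rec in records:
        y = rec.aortic.values
        y_hat = scheme.invert(np.asarray(predict(scheme.apply(rec.radial.values))))
        if len(y_hat) != len(y):
            raise ValidationError("prediction length differs from target length")
        mae, rmse, mx, scc = waveform_metrics(y, y_hat)
        row = {"record_id": rec.record_id, "TW_MAE": mae, "TW_RMSE": rmse,
               "TW_MAX": mx, "SCC": scc}
        feats_y = extract_features(y)
        feats_h = extract_features(y_hat)
        for bp, fy, fh in zip(("SBP", "DBP", "MAP"), feats_y, feats_h):
            err = abs(fy - fh)  # scalar feature: MAE = RMSE = MAX = |error|
            row[f"{bp}_MAE"] = err
            row[f"{bp}_RMSE"] = err
            row[f"{bp}_MAX"] = err
        rows.append(row)
    df = pd.DataFrame(rows)
    return ModelMetrics(name=name, per_record=df, scc_mean=float(df["SCC"].mean()))


def evaluate_models(model_a, model_b, records: Sequence[PairedRecord],
                    scheme: NormalizationScheme | None = None,
                    names: tuple[str, str] = ("TCN", "TCN-Attention")
                    ) -> ComparisonReport:
    """Evaluate two models on the same test set and annotate significance.

    Each cell of the 4x3 error table gets a paired t-test between the two
    models' per-record errors; zero-variance differences (e.g. identical
    models) are annotated ``n.s.`` by contract.
    """
    ma = evaluate_model(model_a, records, scheme, name=names[0])
    mb = evaluate_model(model_b, records, scheme, name=names[1])
    significance: dict[tuple[str, str], str] = {}
    pvalues: dict[tuple[str, str], float | None] = {}
    for bp in BP_ROWS:
        for col in ERROR_COLS:
            key = f"{bp}_{col}"
            try:
                _, _, p = paired_ttest(ma.per_record[key].to_numpy(),
                                       mb.per_record[key].to_numpy())
            except (DegenerateInputError, ValidationError):
                p = None
            pvalues[(bp, col)] = p
            if p is None or p >= 0.05:
                significance[(bp, col)] = "n.s."
            elif p < 0.01:
                significance[(bp, col)] = "**"
            else:
                significance[(bp, col)] = "*"
    return ComparisonReport(metrics_a=ma, metrics_b=mb,
                            significance=significance, pvalues=pvalues)
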