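"""Cross-run retention-time calibration against a reference run.

Each sample's rt scale is mapped onto the reference sample's scale by
LOWESS (locally weighted scatterplot smoothing) regression on peptides
matched between the two runs by exact sequence identity.  The fitted
curve is made non-decreasing by isotonic post-adjustment and extended
beyond the observed rt range by constant-offset extrapolation from the
nearest endpoint, so the mapping is monotone and total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import CalibrationError
from .io_formats import PeptideRecord, StudyDesign


class RetentionTimeCalibrator(BaseEstimator, RegressorMixin):
    """LOWESS rt-mapping regressor (sample rt -> reference rt).

    Parameters
    ----------
    frac : float in (0, 1]
        LOWESS span (fraction of points in each local fit).
    iterations : int >= 0
        Robustifying reweighting iterations.
    min_pairs : int
        Minimum number of matched peptide pairs required to fit.

    Attributes
    ----------
    n_pairs_ : int
        Number of matched pairs the curve was fitted on.
    curve_x_, curve_y_ : ndarray
        Monotone interpolation grid (unique sample rt, mapped rt).
    median_abs_residual_ : float
        Median |fit(rt_sample) - rt_reference| over the training pairs,
        in minutes.
    """

    def __init__(self, frac: float = 0.3, iterations: int = 3, min_pairs: int = 10):
        self.frac = frac
        self.iterations = iterations
        self.min_pairs = min_pairs

    def fit(self, X, y):
        if not 0.0 < self.frac <= 1.0:
            raise ValueError("frac must lie in (0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if x.size < self.min_pairs:
            raise CalibrationError(
                f"need at least {self.min_pairs} matched pairs, got {x.size}"
            )
        if np.any(x <= 0) or np.any(y <= 0):
            raise CalibrationError("rt values must be positive")
        if np.ptp(x) == 0:
            raise CalibrationError("degenerate pairs: all sample rt identical")
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        fitted = lowess(
            ys, xs, frac=self.frac, it=self.iterations, return_sorted=False
        )
        # isotonic post-adjustment keeps the map monotone (non-decreasing)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        mono = iso.fit_transform(xs, fitted)
        grid_x, idx = np.unique(xs, return_index=True)
        self.curve_x_ = grid_x
        self.curve_y_ = mono[idx]
        self.n_pairs_ = int(x.size)
        self.median_abs_residual_ = float(np.median(np.abs(self._map(x) - y)))
        return self

    def _map(self, rt: np.ndarray) -> np.ndarray:
        x0, xn = self.curve_x_[0], self.curve_x_[-1]
        y0, yn = self.curve_y_[0], self.curve_y_[-1]
        out = np.interp(rt, self.curve_x_, self.curve_y_)
        # constant-offset extrapolation from the nearest endpoint
        lo, hi = rt < x0, rt > xn
        out[lo] = rt[lo] + (y0 - x0)
        out[hi] = rt[hi] + (yn - xn)
        return out

    def predict(self, X):
        if not hasattr(self, "curve_x_"):
            raise CalibrationError("calibrator is not fitted")
        rt = np.asarray(X, dtype=float).reshape(-1)
        return self._map(rt)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted rt mapping for one sample (identity for the reference)."""

    sample_id: str
    calibrator: RetentionTimeCalibrator | None  # None -> identity map
    n_pairs: int
    frac: float
    median_abs_residual: float

    def __call__(self, rt):
        rt = np.asarray(rt, dtype=float)
        if self.calibrator is None:
            return rt.copy()
        return self.calibrator.predict(rt.reshape(-1)).reshape(rt.shape)


def match_to_reference(
    sample: list[PeptideRecord], reference: list[PeptideRecord]
) -> list[tuple[float, float]]:
    """Matched (rt_sample, rt_reference) pairs by exact sequence identity.

    Sequences occurring more than once in either run are excluded (their
    correspondence is ambiguous); pairs are sorted by sample rt.
    """
    if not sample or not reference:
        raise CalibrationError("both record lists must be non-empty")
    s_counts = Counter(r.sequence for r in sample)
    r_counts = Counter(r.sequence for r in reference)
    s_rt = {r.sequence: r.rt for r in sample if s_counts[r.sequence] == 1}
    r_rt = {r.sequence: r.rt for r in reference if r_counts[r.sequence] == 1}
    shared = s_rt.keys() & r_rt.keys()
    return sorted((s_rt[seq], r_rt[seq]) for seq in shared)


def fit_lowess(
    pairs: list[tuple[float, float]],
    fraction: float = 0.3,
    iterations: int = 3,
    min_pairs: int = 10,
    sample_id: str = "",
) -> CalibrationModel:
    """Fit the LOWESS rt mapping on matched pairs for one sample."""
    if len(pairs) < min_pairs:
        raise CalibrationError(
            f"sample {sample_id or '?'}: only {len(pairs)} matched pairs "
            f"(minimum {min_pairs})"
        )
    arr = np.asarray(pairs, dtype=float)
    cal = RetentionTimeCalibrator(
        frac=fraction, iterations=iterations, min_pairs=min_pairs
    )
    cal.fit(arr[:, 0], arr[:, 1])
    return CalibrationModel(
        sample_id=sample_id,
        calibrator=cal,
        n_pairs=cal.n_pairs_,
        frac=fraction,
        median_abs_residual=cal.median_abs_residual_,
    )


def apply_calibration(
    records: list[PeptideRecord], model: CalibrationModel
) -> list[PeptideRecord]:
    """Replace every record's rt by the calibrated rt; other fields kept."""
    if not records:
        return []
    rts = model(np.array([r.rt for r in records], dtype=float))
    return [r.with_rt(float(rt)) for r, rt in zip(records, rts)]


def calibrate_study(
    records_by_sample: dict[str, list[PeptideRecord]],
    design: StudyDesign,
    fraction: float = 0.3,
    iterations: int = 3,
    min_pairs: int = 10,
) -> tuple[dict[str, list[PeptideRecord]], pd.DataFrame]:
    """Calibrate every sample against the design's reference run.

    The reference sample is mapped by identity.  Returns the calibrated
    records and a per-sample report (pair counts, LOWESS span, median
    absolute residual in minutes).
    """
    ref_id = design.reference_id
    reference = records_by_sample[ref_id]
    calibrated: dict[str, list[PeptideRecord]] = {}
    rows = []
    for sample_id in sorted(records_by_sample):
        records = records_by_sample[sample_id]
        if sample_id == ref_id:
            model = CalibrationModel(sample_id, None, len(records), fraction, 0.0)
        else:
            pairs = match_to_reference(records, reference)
            model = fit_lowess(
                pairs,
                fraction=fraction,
                iterations=iterations,
                min_pairs=min_pairs,
                sample_id=sample_id,
            )
        calibrated[sample_id] = apply_calibration(records, model)
        rows.append(
            {
                "sample_id": sample_id,
                "n_pairs": model.n_pairs,
                "lowess_frac": model.frac,
                "median_abs_residual_min": model.median_abs_residual,
                "is_reference": sample_id == ref_id,
            }
        )
    report = pd.DataFrame(rows).set_index("sample_id")
    return calibrated, report


def suggest_reference(records_by_sample: dict[str, list[PeptideRecord]]) -> str:
    """Suggest a reference run: widest joint mass/rt coverage, ties by
    record count then sample id."""
    def coverage(records: list[PeptideRecord]) -> tuple[float, int]:
        if not records:
            return (0.0, 0)
        rts = [r.rt for r in records]
        ms = [r.measured_mass for r in records]
        return ((max(rts) - min(rts)) * (max(ms) - min(ms)), len(records))

    return max(sorted(records_by_sample), key=lambda s: coverage(records_by_sample[s]))
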