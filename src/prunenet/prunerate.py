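"""Developmental pruning-rate estimation from synapse-density time series.

Given per-sample measurements of synapse density (synapses per unit area)
against postnatal age, the pipeline is:

1. fit a spline to per-age (or per-bin) mean densities;
2. divide the pruning window into ``k`` equally spaced intervals and compute
   the percentage of peak density pruned in each interval;
3. assess whether the rate is decreasing with a leave-one-out
   cross-validation: refit with one sample (or one time-point bin) held out,
   recompute the interval percentages, and compare successive intervals'
   fold values with an unpaired two-sample t-test.

The default spline is a cubic smoothing spline on the per-age means with
the smoothing parameter chosen by generalized cross-validation; an
exact-interpolation mode is available.  Percentages are always expressed
relative to the density at the start of the window (the developmental
peak), so they are invariant to rescaling the density units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "DensitySeries",
    "DensityCurve",
    "RateReport",
    "fit_density_curve",
    "percent_pruned",
    "loo_rate_test",
    "adjust_3d",
    "load_reference_density",
    "CANONICAL_BINS",
]

# Canonical 2-day binning of postnatal-day samples used for time-point
# cross-validation (ages sharing a bin are merged into one time-point).
CANONICAL_BINS: tuple[tuple[int, ...], ...] = (
    (14,), (17,), (19,), (21, 22), (23, 24), (26,), (28,), (30,),
    (32, 33), (34, 36), (38,), (40,),
)


@dataclass
class DensitySeries:
    """Per-sample (age, density) records."""

    frame: pd.DataFrame  # columns: sample_id, age_days, density

    def __post_init__(self) -> None:
        required = {"sample_id", "age_days", "density"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"density table missing columns {sorted(missing)}")
        if (self.frame["age_days"] <= 0).any():
            raise ValueError("ages must be positive")
        if (self.frame["density"] < 0).any():
            raise ValueError("densities must be nonnegative")
        if self.frame["age_days"].nunique() < 2:
            raise ValueError("need at least 2 distinct ages")

    @classmethod
    def from_tsv(cls, text: str) -> "DensitySeries":
        import io

        frame = pd.read_csv(io.StringIO(text), sep="\t")
        return cls(frame)

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t", index=False)

    def ages(self) -> np.ndarray:
        return np.sort(self.frame["age_days"].unique())

    def bin_of(self, age: float) -> int:
        """Index of the canonical bin containing ``age`` (nearest member)."""
        for i, members in enumerate(CANONICAL_BINS):
            if age in members:
                return i
        # fall back to nearest bin representative for non-canonical ages
        reps = [np.mean(m) for m in CANONICAL_BINS]
        return int(np.argmin([abs(age - r) for r in reps]))


class DensityCurve:
    """Fitted density-vs-age curve, evaluable only inside the data range."""

    def __init__(self, fn, lo: float, hi: float, kind: str):
        self._fn = fn
        self.lo = float(lo)
        self.hi = float(hi)
        self.kind = kind

    def __call__(self, age):
        a = np.asarray(age, dtype=float)
        if np.any(a < self.lo - 1e-9) or np.any(a > self.hi + 1e-9):
            raise ValueError(
                f"age outside fitted range [{self.lo}, {self.hi}]"
            )
        return self._fn(a)


def fit_density_curve(
    series: DensitySeries, mode: str = "smooth"
) -> DensityCurve:
    """Fit a cubic spline through per-age mean densities.

    ``mode='smooth'`` (default) uses a cubic smoothing spline with
    GCV-selected smoothing; ``mode='interpolate'`` forces exact
    interpolation.  With fewer than 4 distinct ages the fit degrades to
    linear interpolation with a warning.
    """
    means = (
        series.frame.groupby("age_days")["density"].mean().sort_index()
    )
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    if len(x) < 4:
        warnings.warn(
            f"only {len(x)} distinct ages: falling back to linear interpolation",
            stacklevel=2,
        )
        fn = lambda a: np.interp(a, x, y)
        return DensityCurve(fn, x[0], x[-1], "linear")
    if mode == "interpolate" or len(x) < 5:
        spline = CubicSpline(x, y)
        return DensityCurve(spline, x[0], x[-1], "cubic-interpolating")
    if mode != "smooth":
        raise ValueError(f"unknown fit mode {mode!r}")
    spline = make_smoothing_spline(x, y)  # lam chosen by GCV
    return DensityCurve(spline, x[0], x[-1], "cubic-smoothing")


def percent_pruned(
    curve: DensityCurve, start_age: float, end_age: float, k_intervals: int
) -> np.ndarray:
    """Percent of peak density lost in each of k equally spaced intervals.

    Interval ``i`` contributes ``100 * (f(t_i) - f(t_{i+1})) / f(start)``,
    so the values sum to ``100 * (1 - f(end)/f(start))``.
    """
    if not start_age < end_age:
        raise ValueError("need start_age < end_age")
    if k_intervals < 2:
        raise ValueError("need k_intervals >= 2")
    bounds = np.linspace(start_age, end_age, k_intervals + 1)
    vals = curve(bounds)
    peak = vals[0]
    if peak <= 0:
        raise ValueError("density at window start must be positive")
    return 100.0 * -np.diff(vals) / peak


@dataclass
class RateReport:
    """Leave-one-out interval pruning percentages and their statistics."""

    boundaries: np.ndarray
    fold_values: np.ndarray  # shape (folds, intervals)
    interval_means: np.ndarray
    interval_sds: np.ndarray
    scheme: str
    skipped_folds: int
    tests: list[dict] = field(default_factory=list)  # successive-interval t-tests

    def to_dict(self) -> dict:
        return {
            "boundaries": self.boundaries.tolist(),
            "interval_means": self.interval_means.tolist(),
            "interval_sds": self.interval_sds.tolist(),
            "n_folds": int(self.fold_values.shape[0]),
            "skipped_folds": self.skipped_folds,
            "scheme": self.scheme,
            "tests": self.tests,
        }


def loo_rate_test(
    series: DensitySeries,
    k_intervals: int = 2,
    scheme: str = "sample",
    start_age: float = 19.0,
    end_age: float = 39.0,
    mode: str = "smooth",
) -> RateReport:
    """Leave-one-out cross-validated interval pruning percentages.

    ``scheme='sample'`` drops one sample per fold; ``scheme='timepoint'``
    drops one canonical time-point bin per fold.  Each fold refits the
    density curve on the remaining data and recomputes
    :func:`percent_pruned`; successive intervals are compared with an
    unpaired two-sample t-test over fold values.  Folds whose remaining
    data cannot cover the analysis window are skipped with a warning.
    """
    if scheme not in ("sample", "timepoint"):
        raise ValueError(f"unknown scheme {scheme!r}")
    frame = series.frame
    if scheme == "sample":
        fold_keys = list(frame["sample_id"].unique())
        key_of = frame["sample_id"]
    else:
        key_of = frame["age_days"].map(series.bin_of)
        fold_keys = sorted(key_of.unique())
    if len(fold_keys) < 3:
        raise ValueError(f"need >= 3 folds, got {len(fold_keys)}")

    rows = []
    skipped = 0
    for key in fold_keys:
        rest = frame[key_of != key]
        try:
            sub = DensitySeries(rest.reset_index(drop=True))
            curve = fit_density_curve(sub, mode=mode)
            rows.append(percent_pruned(curve, start_age, end_age, k_intervals))
        except ValueError as err:
            warnings.warn(f"skipping fold {key!r}: {err}", stacklevel=2)
            skipped += 1
    if len(rows) < 2:
        raise ValueError("fewer than 2 usable folds")
    fold_values = np.vstack(rows)
    means = fold_values.mean(axis=0)
    sds = fold_values.std(axis=0, ddof=1)
    tests = []
    for i in range(k_intervals - 1):
        t, pval = stats.ttest_ind(fold_values[:, i], fold_values[:, i + 1])
        tests.append(
            {"intervals": (i, i + 1), "t": float(t), "p": float(pval)}
        )
    return RateReport(
        boundaries=np.linspace(start_age, end_age, k_intervals + 1),
        fold_values=fold_values,
        interval_means=means,
        interval_sds=sds,
        scheme=scheme,
        skipped_folds=skipped,
        tests=tests,
    )


def adjust_3d(
    series: DensitySeries,
    section_thickness: float,
    object_diameter,
) -> DensitySeries:
    """Stereological size-correction of areal densities.

    Rescales every density by ``T / (T + D)`` where ``T`` is the section
    thickness and ``D`` the mean object (synapse) diameter, the standard
    thickness correction for counts in physical sections.  ``object_diameter``
    may be a scalar or a callable of age (diameters can grow with age).
    Relative comparisons — and hence :func:`percent_pruned` — are unchanged
    when the diameter is age-independent.
    """
    if section_thickness <= 0:
        raise ValueError("section thickness must be positive")
    frame = series.frame.copy()
    if callable(object_diameter):
        diam = frame["age_days"].map(object_diameter).to_numpy(dtype=float)
    else:
        diam = np.full(len(frame), float(object_diameter))
    if np.any(diam < 0):
        raise ValueError("object diameter must be nonnegative")
    factor = section_thickness / (section_thickness + diam)
    frame["density"] = frame["density"] * factor
    return DensitySeries(frame)


def load_reference_density() -> DensitySeries:
    """Packaged per-timepoint mean synapse densities (mouse barrel cortex,
    P14-P40, synapses per EM image)."""
    text = (
        resources.files("prunenet")
        .joinpath("data/cortical_density.tsv")
        .read_text()
    )
    return DensitySeries.from_tsv(text)
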