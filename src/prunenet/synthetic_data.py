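"""Synthetic fixture generators.

Everything the test-bench needs that is not derived analytically is
generated here, seed-deterministically:

* per-animal synapse-density series with a controllable decay shape
  (exponential, linear, or piecewise-linear with prescribed per-interval
  percentages), Gaussian per-animal noise truncated at zero, sampled on
  the canonical P14-P40 postnatal time-points;
* Zipf-distributed origin-destination traffic matrices emulating airline
  passenger counts between top city pairs.

Defaults mirror the observed cortical data scale: peak density ~3.3
synapses/image at P19 decaying to a plateau of ~1.6 by P40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import PairDistribution, read_traffic_csv
from .prunerate import DensitySeries

__all__ = ["DensityGenSpec", "TrafficGenSpec", "gen_density", "gen_traffic"]

CANONICAL_AGES = (14, 17, 19, 21, 22, 23, 24, 26, 28, 30, 32, 33, 34, 36, 38, 40)


@dataclass
class DensityGenSpec:
    """Data-generating process for developmental density curves."""

    shape: str = "exponential"  # exponential | linear | piecewise
    peak: float = 3.3
    plateau: float = 1.6
    peak_age: float = 19.0
    end_age: float = 40.0
    noise_sd: float = 0.25
    animals_per_timepoint: int = 3
    timepoints: tuple = CANONICAL_AGES
    # for shape='piecewise': percent of peak pruned per equal interval
    interval_percentages: tuple = ()

    def __post_init__(self) -> None:
        if not self.peak > self.plateau >= 0:
            raise ValueError("need peak > plateau >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.shape not in ("exponential", "linear", "piecewise"):
            raise ValueError(f"unknown decay shape {self.shape!r}")
        if self.shape == "piecewise" and len(self.interval_percentages) < 2:
            raise ValueError("piecewise shape needs interval_percentages")

    def curve(self, age: float) -> float:
        """Noise-free density at ``age`` (flat at peak before peak_age)."""
        t = max(float(age), self.peak_age)
        span = self.end_age - self.peak_age
        if self.shape == "exponential":
            # decay constant puts the curve ~e^-3 of the way to plateau at end
            lam = 3.0 / span
            return self.plateau + (self.peak - self.plateau) * np.exp(
                -lam * (t - self.peak_age)
            )
        if self.shape == "linear":
            frac = min((t - self.peak_age) / span, 1.0)
            return self.peak - (self.peak - self.plateau) * frac
        # piecewise: prescribed percent-of-peak drops per equal interval
        pct = np.asarray(self.interval_percentages, dtype=float)
        bounds = np.linspace(self.peak_age, self.end_age, len(pct) + 1)
        values = self.peak - self.peak * np.concatenate([[0.0], np.cumsum(pct)]) / 100.0
        return float(np.interp(t, bounds, values))


def gen_density(spec: DensityGenSpec, rng: np.random.Generator) -> DensitySeries:
    """Per-animal noisy densities on the spec's time-points.

    density = shape(age) + N(0, noise_sd), truncated at 0; sample ids are
    ``a<age>_<replicate>``.
    """
    rows = []
    for age in spec.timepoints:
        base = spec.curve(age)
        for k in range(spec.animals_per_timepoint):
            d = base + rng.normal(0.0, spec.noise_sd) if spec.noise_sd else base
            rows.append((f"a{age}_{k}", age, max(float(d), 0.0)))
    frame = pd.DataFrame(rows, columns=["sample_id", "age_days", "density"])
    return DensitySeries(frame)


@dataclass
class TrafficGenSpec:
    """Zipf-like origin-destination traffic matrix."""

    cities: int = 122
    pair_count: int = 1000
    zipf_exponent: float = 1.0
    total_passengers: int = 1_000_000

    def __post_init__(self) -> None:
        if self.pair_count > self.cities * (self.cities - 1):
            raise ValueError("pair_count exceeds the number of ordered pairs")
        if self.cities < 2 or self.pair_count < 1:
            raise ValueError("need >= 2 cities and >= 1 pair")


def gen_traffic(spec: TrafficGenSpec, rng: np.random.Generator) -> str:
    """CSV text (``source,target,count``) over sampled ordered city pairs.

    Pair ranks get heavy-tailed counts proportional to ``rank^-a`` (near
    uniform at a = 0); every count is at least 1.  The output parses via
    :func:`prunenet.distributions.read_traffic_csv`.
    """
    n = spec.cities
    idx = rng.choice(n * (n - 1), size=spec.pair_count, replace=False)
    width = len(str(n - 1))
    weights = (np.arange(1, spec.pair_count + 1, dtype=float)) ** (
        -spec.zipf_exponent
    )
    weights /= weights.sum()
    counts = np.maximum(
        1, np.round(weights * spec.total_passengers).astype(np.int64)
    )
    lines = ["source,target,count"]
    for k, cnt in zip(idx, counts):
        u, r = divmod(int(k), n - 1)
        v = r if r < u else r + 1
        lines.append(f"C{u:0{width}d},C{v:0{width}d},{cnt}")
    return "\n".join(lines) + "\n"


def gen_traffic_distribution(
    spec: TrafficGenSpec, rng: np.random.Generator
) -> PairDistribution:
    """Convenience wrapper: generate and immediately parse a traffic matrix."""
    return read_traffic_csv(gen_traffic(spec, rng))
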