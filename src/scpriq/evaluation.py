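"""Standard-design accuracy diagnostics for reporter-ion quantification.

These are the desk versions of the classic isobaric benchmarks: the
intrascan dilution-series linearity fit (mean log10 channel intensity vs
log10 concentration), the missing-value profile across a dilution series,
two-proteome spike-in ratio accuracy (expected 1:5:10 within channel
triplets), and the carrier-effect curve (a known ratio tracked as the
carrier load grows, flat in the linear regime and compressing toward unity
when the carrier dominates the shared ion budget).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import QuantMatrix

__all__ = [
    "DilutionDesign",
    "LinearityResult",
    "linearity",
    "missing_profile",
    "ratio_accuracy",
    "carrier_curve",
]


@dataclass
class DilutionDesign:
    """Channel label -> relative concentration, with optional replicate
    triplets (groups of channels sharing a concentration level)."""

    concentration: dict[str, float]
    replicates: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentration.values()):
            raise ValueError("concentrations must be positive")
        if len(set(self.concentration.values())) < 2:
            raise ValueError("need >=2 distinct concentrations")

    def levels(self) -> dict[float, list[str]]:
        """Channels grouped by concentration level, ascending."""
        out: dict[float, list[str]] = {}
        for label, conc in self.concentration.items():
            out.setdefault(conc, []).append(label)
        return dict(sorted(out.items()))


@dataclass
class LinearityResult:
    r_squared: float
    slope: float
    intercept: float
    channel_mean_log10: pd.Series


def _channel_columns(matrix: QuantMatrix, label: str) -> list[tuple[str, str]]:
    return [c for c in matrix.data.columns if c[1] == label]


def linearity(matrix: QuantMatrix, design: DilutionDesign) -> LinearityResult:
    """Least-squares fit of mean log10 channel intensity vs log10 concentration.

    Requires >=3 distinct concentration levels present in the matrix.
    Missing values are excluded from channel means.  A perfectly
    proportional matrix gives slope 1 and R² = 1.
    """
    xs, ys, chan_means = [], [], {}
    for label, conc in design.concentration.items():
        cols = _channel_columns(matrix, label)
        if not cols:
            continue
        vals = matrix.data[cols].to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.size == 0:
            continue
        mean_log = float(np.mean(np.log10(vals)))
        chan_means[label] = mean_log
        xs.append(np.log10(conc))
        ys.append(mean_log)
    if len(set(np.round(xs, 12))) < 3:
        raise ValueError("need >=3 distinct concentration levels with data")
    xs, ys = np.array(xs), np.array(ys)
    if np.allclose(ys, ys[0]):
        slope, intercept, r2 = 0.0, float(ys[0]), 0.0
    else:
        fit = stats.linregress(xs, ys)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return LinearityResult(r2, slope, intercept, pd.Series(chan_means, name="mean_log10"))


def missing_profile(matrix: QuantMatrix, design: DilutionDesign) -> pd.DataFrame:
    """Fraction of missing feature values per channel, paired with the
    design concentration (for plotting missing rate vs dilution)."""
    rows = []
    for label, conc in design.concentration.items():
        cols = _channel_columns(matrix, label)
        if not cols:
            continue
        block = matrix.data[cols]
        frac = float(block.isna().to_numpy().mean())
        rows.append({"channel": label, "concentration": conc, "missing_fraction": frac})
    return pd.DataFrame(rows).set_index("channel")


def ratio_accuracy(
    matrix: QuantMatrix,
    design: DilutionDesign,
    spike_features: Sequence[str],
    aggregate: str = "median",
) -> tuple[pd.Series, pd.DataFrame]:
    """Observed spike-in ratios per concentration level vs expected.

    Per spiked feature, the mean intensity over each level's channels is
    normalized to the lowest level; the aggregate (median by default, mean
    optionally) across features gives the observed ratio tuple — e.g.
    (1, 5, 10) for a perfect 1:5:10 series.  Returns (aggregate per level,
    per-feature table).
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    present = [f for f in spike_features if f in matrix.data.index]
    if not present:
        raise ValueError("no spike features present in matrix")
    levels = design.levels()
    per_feature = {}
    for conc, labels in levels.items():
        cols = [c for l in labels for c in _channel_columns(matrix, l)]
        per_feature[conc] = matrix.data.loc[present, cols].mean(axis=1, skipna=True)
    table = pd.DataFrame(per_feature)
    base_conc = min(levels)
    norm = table.div(table[base_conc], axis=0)
    agg = norm.median(axis=0) if aggregate == "median" else norm.mean(axis=0)
    agg.name = "observed_ratio"
    return agg, norm


def carrier_curve(
    matrices: Sequence[QuantMatrix],
    carrier_levels: Sequence[float],
    known_ratio: float,
    numer_channels: Sequence[str],
    denom_channels: Sequence[str],
    features: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Observed ratio of a known-ratio standard at each carrier load.

    One matrix per carrier level; per feature the ratio of mean intensity in
    the numerator channels to the denominator channels is formed and the
    median across features reported.  In the linear regime the curve is flat
    at ``known_ratio``; when the carrier saturates the shared ion-sampling
    budget the observed ratio compresses toward 1.
    """
    if len(matrices) != len(carrier_levels):
        raise ValueError("need exactly one matrix per carrier level")
    rows = []
    for level, m in zip(carrier_levels, matrices):
        num_cols = [c for l in numer_channels for c in _channel_columns(m, l)]
        den_cols = [c for l in denom_channels for c in _channel_columns(m, l)]
        if not num_cols or not den_cols:
            raise ValueError("compared channels absent from a matrix")
        df = m.data if features is None else m.data.loc[[f for f in features if f in m.data.index]]
        num = df[num_cols].mean(axis=1, skipna=True)
        den = df[den_cols].mean(axis=1, skipna=True)
        ratio = (num / den).replace([np.inf, -np.inf], np.nan).dropna()
        rows.append(
            {
                "carrier_level": level,
                "observed_ratio": float(ratio.median()) if len(ratio) else np.nan,
                "expected_ratio": known_ratio,
                "n_features": int(len(ratio)),
            }
        )
    return pd.DataFrame(rows)
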