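"""Feature x channel quantification matrices and ratio statistics.

A :class:`QuantMatrix` is a pandas DataFrame (features on the index, a
(run, channel) MultiIndex on the columns) plus per-channel roles from the
plex design.  Values are non-negative reporter intensity sums; absence of
evidence is NaN (missing), never zero.

Ratio roll-up follows the pairwise-peptide scheme: a feature's ratio between
two channel groups is the median over all pairwise value ratios, clamped to
a cap (100-fold by default, the ceiling quantitative tools typically apply),
with a p-value from the log2 ratio distribution against 1.  Features found
in only one of the two groups are reported at the cap, so presence/absence
patterns (the DAP1-type signature) survive the roll-up.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reporters import PlexDesign, ReporterVector

__all__ = [
    "QuantMatrix",
    "RatioTable",
    "assemble",
    "exclude_channels",
    "total_sum_normalize",
    "compute_ratios",
    "normalize_ptm_to_protein",
    "export_3d",
]


@dataclass
class QuantMatrix:
    """Feature x (run, channel) abundance matrix with channel roles."""

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("columns must be a (run, channel) MultiIndex")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("matrix values must be non-negative")

    @property
    def channels(self) -> list[str]:
        return [c[1] for c in self.data.columns]

    def columns_with_role(self, roles: set[str]) -> list[tuple[str, str]]:
        return [c for c in self.data.columns if self.roles.get(c[1]) in roles]

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy(), dict(self.roles))

    def to_table(self, path: str | Path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{r}:{c}" for r, c in flat.columns]
        flat.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_table(
        cls, path: str | Path, roles: Optional[Mapping[str, str]] = None
    ) -> "QuantMatrix":
        """Read a matrix written by :meth:`to_table` (columns ``run:channel``).

        Channels absent from ``roles`` default to the single_cell role.
        """
        df = pd.read_csv(path, sep="\t", index_col="feature", comment="#")
        cols = [tuple(c.split(":", 1)) for c in df.columns]
        df.columns = pd.MultiIndex.from_tuples(cols, names=["run", "channel"])
        all_roles = {c[1]: "single_cell" for c in cols}
        if roles:
            all_roles.update(roles)
        return cls(df, all_roles)


@dataclass
class RatioTable:
    """Per-feature capped ratios (group_a / group_b) with optional p-values."""

    ratios: pd.Series
    p_values: Optional[pd.Series] = None
    cap: float = 100.0

    def __post_init__(self) -> None:
        if ((self.ratios < 1.0 / self.cap - 1e-12) | (self.ratios > self.cap + 1e-12)).any():
            raise ValueError("ratios must lie within [1/cap, cap]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"ratio": self.ratios})
        if self.p_values is not None:
            df["p_value"] = self.p_values
        return df


def assemble(
    vectors: Sequence[ReporterVector],
    id_table: Mapping[str, str] | Sequence[tuple[str, str]],
    design: PlexDesign,
    min_avg_intensity: float = 10.0,
    run_id: str = "run",
) -> QuantMatrix:
    """Build a feature x channel matrix from reporter vectors.

    ``id_table`` maps spectrum id -> feature id (peptide/protein/PTM site);
    unidentified spectra are ignored, duplicate (spectrum, feature) pairs
    raise.  Per feature and channel, intensities are summed over that
    feature's spectra (missing stays missing when no spectrum contributed).
    Features whose mean intensity across detected channels falls below
    ``min_avg_intensity`` (10 by default) are dropped.
    """
    if min_avg_intensity < 0:
        raise ValueError("min_avg_intensity must be >= 0")
    if isinstance(id_table, Mapping):
        pairs = list(id_table.items())
    else:
        pairs = list(id_table)
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (spectrum, feature) pairs in id_table")
    if len({s for s, _ in pairs}) != len(pairs):
        raise ValueError("a spectrum may map to only one feature")
    spec_to_feat = dict(pairs)

    labels = design.labels
    sums: dict[str, np.ndarray] = {}
    seen: dict[str, np.ndarray] = {}
    for vec in vectors:
        feat = spec_to_feat.get(vec.spectrum_id)
        if feat is None:
            continue
        if feat not in sums:
            sums[feat] = np.zeros(len(labels))
            seen[feat] = np.zeros(len(labels), dtype=bool)
        for k, l in enumerate(labels):
            v = vec.intensity.get(l)
            if v is not None:
                sums[feat][k] += v
                seen[feat][k] = True
    features = sorted(sums)
    arr = np.full((len(features), len(labels)), np.nan)
    for i, f in enumerate(features):
        arr[i, seen[f]] = sums[f][seen[f]]
    cols = pd.MultiIndex.from_tuples([(run_id, l) for l in labels],
                                     names=["run", "channel"])
    df = pd.DataFrame(arr, index=pd.Index(features, name="feature"), columns=cols)
    mean_across = df.mean(axis=1, skipna=True)
    df = df[mean_across >= min_avg_intensity]
    return QuantMatrix(df, dict(design.roles))


def exclude_channels(matrix: QuantMatrix, labels: Sequence[str]) -> QuantMatrix:
    """Drop channels (e.g. a distorted 133N next to a 134N carrier) from the
    matrix; rows left all-missing are dropped too."""
    drop = set(labels)
    unknown = drop - set(matrix.channels)
    if unknown:
        raise ValueError(f"unknown channel labels: {sorted(unknown)}")
    keep = [c for c in matrix.data.columns if c[1] not in drop]
    df = matrix.data[keep]
    df = df.dropna(how="all")
    roles = {l: r for l, r in matrix.roles.items() if l not in drop}
    return QuantMatrix(df, roles)


def total_sum_normalize(
    matrix: QuantMatrix,
    roles: set[str] = frozenset({"single_cell"}),
) -> QuantMatrix:
    """Total-sum scaling of the selected-role columns.

    Each selected column is rescaled so its (missing-ignored) sum equals the
    mean of the pre-scaling column sums, equalising loading between cells.
    Zero-sum columns are left unscaled with a warning.
    """
    cols = matrix.columns_with_role(set(roles))
    if not cols:
        raise ValueError(f"no columns with roles {sorted(roles)}")
    df = matrix.data.copy()
    sums = df[cols].sum(axis=0, skipna=True)
    target = float(sums.mean())
    for c in cols:
        s = float(sums[c])
        if s <= 0:
            warnings.warn(f"zero-sum column {c} left unscaled")
            continue
        df[c] = df[c] * (target / s)
    return QuantMatrix(df, dict(matrix.roles))


def _pairwise_ratios(a: np.ndarray, b: np.ndarray) -> list[float]:
    out = []
    for x, y in itertools.product(a, b):
        if np.isfinite(x) and np.isfinite(y) and y > 0 and x > 0:
            out.append(x / y)
    return out


def compute_ratios(
    matrix: QuantMatrix,
    group_a: Sequence[tuple[str, str]],
    group_b: Sequence[tuple[str, str]],
    cap: float = 100.0,
    level: str = "peptide_pairwise",
    feature_map: Optional[Mapping[str, str]] = None,
) -> RatioTable:
    """Capped group_a / group_b ratios per feature.

    ``peptide_pairwise``: per feature, the median of all pairwise value
    ratios between group_a and group_b columns, rolled up over peptides when
    ``feature_map`` (row id -> parent feature) is given; the p-value is a
    two-sided one-sample t-test of the log2 pairwise ratios against 0.
    ``feature_mean``: mean(a) / mean(b) per row.  Ratios are clamped to
    [1/cap, cap]; features detected only in group_a are reported at cap,
    only in group_b at 1/cap; features in neither group are omitted.
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    if level not in ("peptide_pairwise", "feature_mean"):
        raise ValueError("level must be 'peptide_pairwise' or 'feature_mean'")
    if cap <= 0:
        raise ValueError("cap must be > 0")

    df = matrix.data
    rows_by_feature: dict[str, list[str]] = {}
    for rid in df.index:
        feat = feature_map.get(rid, None) if feature_map else rid
        if feat is None:
            continue
        rows_by_feature.setdefault(feat, []).append(rid)

    ratios, pvals = {}, {}
    for feat, rids in rows_by_feature.items():
        a_vals = df.loc[rids, ga].to_numpy(dtype=float).ravel()
        b_vals = df.loc[rids, gb].to_numpy(dtype=float).ravel()
        a_present = np.isfinite(a_vals).any()
        b_present = np.isfinite(b_vals).any()
        if not a_present and not b_present:
            continue
        if a_present and not b_present:
            ratios[feat], pvals[feat] = cap, np.nan
            continue
        if b_present and not a_present:
            ratios[feat], pvals[feat] = 1.0 / cap, np.nan
            continue
        if level == "feature_mean":
            r = np.nanmean(a_vals) / np.nanmean(b_vals)
            pr = []
        else:
            if feature_map:
                pr = []
                for rid in rids:  # pair within each peptide row
                    pr.extend(
                        _pairwise_ratios(
                            df.loc[rid, ga].to_numpy(dtype=float),
                            df.loc[rid, gb].to_numpy(dtype=float),
                        )
                    )
            else:
                pr = _pairwise_ratios(a_vals, b_vals)
            if not pr:
                ratios[feat], pvals[feat] = cap, np.nan
                continue
            # median taken on the log scale: ratios are multiplicative, and
            # this keeps ratio(a,b) = 1/ratio(b,a) exact for even pair counts
            r = float(np.exp(np.median(np.log(pr))))
        ratios[feat] = float(np.clip(r, 1.0 / cap, cap))
        if len(pr) >= 2 and np.std(np.log2(pr)) > 0:
            pvals[feat] = float(stats.ttest_1samp(np.log2(pr), 0.0).pvalue)
        else:
            pvals[feat] = np.nan
    idx = pd.Index(sorted(ratios), name="feature")
    return RatioTable(
        pd.Series({k: ratios[k] for k in idx}, name="ratio"),
        pd.Series({k: pvals[k] for k in idx}, name="p_value"),
        cap=cap,
    )


def normalize_ptm_to_protein(
    ptm_ratios: RatioTable,
    protein_ratios: RatioTable,
    mapping: Mapping[str, str],
) -> RatioTable:
    """Normalize PTM-site ratios by their parent-protein ratios.

    normalized = ptm_ratio / protein_ratio, with the cap re-applied, so a
    site's apparent change is separated from whole-protein abundance change.
    PTMs without a mapped protein ratio are omitted with a warning.  Callers
    should supply protein ratios built from >1 unique unmodified peptide.
    """
    out = {}
    for ptm, r in ptm_ratios.ratios.items():
        prot = mapping.get(ptm)
        if prot is None or prot not in protein_ratios.ratios.index:
            warnings.warn(f"PTM feature {ptm!r} has no mapped protein ratio; omitted")
            continue
        denom = protein_ratios.ratios[prot]
        out[ptm] = float(np.clip(r / denom, 1.0 / ptm_ratios.cap, ptm_ratios.cap))
    return RatioTable(pd.Series(out, name="ratio").sort_index(), cap=ptm_ratios.cap)


def export_3d(
    matrix: QuantMatrix,
    conditions: Mapping[tuple[str, str], str],
) -> pd.DataFrame:
    """Long-form (feature, cell, condition, abundance) export.

    One row per (feature, single-cell column) including missing values, with
    a log10-scaled abundance column, for 3-D cell x condition x abundance
    viewers.  Every single-cell column must have a condition assigned.
    """
    cells = matrix.columns_with_role({"single_cell"}) or list(matrix.data.columns)
    missing = [c for c in cells if c not in conditions]
    if missing:
        raise ValueError(f"no condition assigned for columns: {missing}")
    rows = []
    for feat in matrix.data.index:
        for i, col in enumerate(cells):
            v = matrix.data.loc[feat, col]
            rows.append(
                {
                    "feature": feat,
                    "cell_index": i,
                    "run": col[0],
                    "channel": col[1],
                    "condition": conditions[col],
                    "abundance": v,
                    "log10_abundance": np.log10(v) if v and v > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
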