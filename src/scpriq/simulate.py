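"""Synthetic TIMS-TOF-like MS2 spectra and single-cell quant matrices with
known ground truth.

The spectrum generator emulates the statistical structure of multiplexed
reporter-ion MS2 data: per-channel reporter intensities drawn from a Poisson
counting model around design abundances, isotopic-impurity leakage applied
to the expected signal before counting noise, Gaussian ppm mass error plus
an optional systematic offset, backbone fragment and uniform noise peaks, an
optional many-fold carrier channel, a 126 method-blank channel, and an
optional acetyl-lysine diagnostic ion (126.0913 Th) in a fraction of
spectra.  An optional shared ion-sampling budget plus an additive
co-isolation background floor reproduces carrier-driven ratio compression:
signal counts scale as budget/(budget + total ions) while the floor does
not, so known ratios flatten toward 1 as the carrier grows.

The matrix generator plants cell-cycle stage labels (stage markers elevated
by a fold factor), treatment effects (uniform fold changes or
subpopulation-exclusive expression), and abundance-dependent logistic
dropout, so recovery can be checked against truth.

Everything is deterministic given the seed (numpy Generator stream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cellcycle import MarkerPanel
from .quant import QuantMatrix
from .reporters import (
    ACETYL_LYSINE_DIAGNOSTIC_MZ,
    ImpurityMatrix,
    PlexDesign,
    two_proteome_9plex,
)
from .spectra import Peak, SpectrumRecord

__all__ = ["SimParams", "SimTruth", "TreatmentEffect", "simulate_run", "simulate_matrix"]


@dataclass
class SimParams:
    """Parameters of the spectrum generator.

    ``abundance`` gives per-channel relative amounts (defaults to the
    design's expected amounts, else 1.0); ``occupancy`` the per-channel
    probability that a spectrum carries analyte in that channel.
    ``mean_ions_top_channel`` is the Poisson mean of the most abundant
    channel.  ``ion_budget``/``background_ions`` enable the shared-budget
    compression model; both default to off (purely linear generator).
    """

    n_spectra: int = 100
    design: PlexDesign = field(default_factory=two_proteome_9plex)
    abundance: Optional[dict[str, float]] = None
    occupancy: Optional[dict[str, float]] = None
    mean_ions_top_channel: float = 1e4
    ppm_error_sigma: float = 3.0
    systematic_offset_ppm: float = 0.0
    n_noise_peaks: int = 20
    backbone_peaks: int = 30
    impurities: Optional[ImpurityMatrix] = None
    carrier_level: float = 0.0
    ion_budget: Optional[float] = None
    background_ions: float = 0.0
    diagnostic_ion_fraction: float = 0.0
    n_features: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spectra < 0 or self.n_noise_peaks < 0 or self.backbone_peaks < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.diagnostic_ion_fraction <= 1.0:
            raise ValueError("diagnostic_ion_fraction must lie in [0, 1]")
        if self.mean_ions_top_channel <= 0:
            raise ValueError("mean_ions_top_channel must be > 0")
        if self.carrier_level < 0 or self.background_ions < 0:
            raise ValueError("carrier_level / background_ions must be >= 0")
        if self.ion_budget is not None and self.ion_budget <= 0:
            raise ValueError("ion_budget must be > 0 when set")
        for d in (self.abundance, self.occupancy):
            if d is not None:
                unknown = set(d) - set(self.design.labels)
                if unknown:
                    raise ValueError(f"unknown channels in params: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with the emitted spectra or matrix cells."""

    spectra: Optional[pd.DataFrame] = None  # per-spectrum occupancy / intensities
    offset_ppm: float = 0.0
    cells: Optional[pd.DataFrame] = None  # per-cell stage / condition (matrix mode)
    planted: dict = field(default_factory=dict)


def _channel_expectations(params: SimParams, rng: np.random.Generator,
                          labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Expected pre-noise intensity and occupancy mask for one spectrum."""
    abundance = params.abundance or {}
    default_amounts = params.design.expected_amount
    rel = np.array(
        [abundance.get(l, default_amounts.get(l, 1.0)) for l in labels], dtype=float
    )
    for k, l in enumerate(labels):
        role = params.design.roles.get(l)
        if role == "blank":
            rel[k] = abundance.get(l, 0.0)
        elif role == "excluded":
            rel[k] = 0.0
        elif role == "carrier":
            rel[k] = params.carrier_level if params.carrier_level > 0 else rel[k]
    top = rel.max() if params.carrier_level == 0 else max(
        rel[k] for k, l in enumerate(labels) if params.design.roles.get(l) != "carrier"
    )
    if top <= 0:
        top = 1.0
    expected = rel / top * params.mean_ions_top_channel
    occ_map = params.occupancy or {}
    mask = np.array(
        [rng.random() < occ_map.get(l, 1.0) if expected[k] > 0 else False
         for k, l in enumerate(labels)]
    )
    return expected, mask


def simulate_run(params: SimParams) -> tuple[list[SpectrumRecord], SimTruth]:
    """Generate a run of synthetic multiplexed MS2 spectra plus ground truth.

    Reporter peaks appear at theoretical m/z * (1 + (offset + N(0, sigma)) *
    1e-6) with Poisson-distributed intensities; impurity leakage is applied
    to the expected signal before the counting noise.  Noise peaks are
    uniform over m/z 100-1700.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    labels = params.design.labels
    theo = params.design.theoretical_mz()
    theo_arr = np.array([theo[l] for l in labels])
    records: list[SpectrumRecord] = []
    truth_rows = []
    n_feat = params.n_features or params.n_spectra
    for i in range(params.n_spectra):
        expected, mask = _channel_expectations(params, rng, labels)
        signal = expected * mask
        if params.ion_budget is not None:
            total = signal.sum()
            signal = signal * (params.ion_budget / (params.ion_budget + total))
        if params.background_ions > 0:
            signal = signal + params.background_ions
        if params.impurities is not None:
            if params.impurities.labels != labels:
                raise ValueError("impurity matrix labels must match design labels")
            signal = params.impurities.matrix @ signal
        counts = rng.poisson(signal).astype(float)

        peaks: list[Peak] = []
        ppm_err = params.systematic_offset_ppm + rng.normal(
            0.0, params.ppm_error_sigma, size=len(labels)
        )
        for k in range(len(labels)):
            if counts[k] > 0:
                peaks.append(Peak(theo_arr[k] * (1 + ppm_err[k] * 1e-6), counts[k]))
        has_diag = rng.random() < params.diagnostic_ion_fraction
        if has_diag:
            derr = params.systematic_offset_ppm + rng.normal(0.0, params.ppm_error_sigma)
            peaks.append(
                Peak(
                    ACETYL_LYSINE_DIAGNOSTIC_MZ * (1 + derr * 1e-6),
                    float(rng.poisson(max(params.mean_ions_top_channel / 5, 1.0)) + 1),
                )
            )
        for _ in range(params.backbone_peaks):
            peaks.append(
                Peak(rng.uniform(200.0, 1700.0),
                     float(np.round(rng.exponential(params.mean_ions_top_channel / 10) + 1, 4)))
            )
        # noise stays outside the reporter/diagnostic guard bands so the
        # emitted occupancy truth aligns exactly with extractable signal
        guard = np.append(theo_arr, ACETYL_LYSINE_DIAGNOSTIC_MZ)
        for _ in range(params.n_noise_peaks):
            mz = rng.uniform(100.0, 1700.0)
            while np.abs(guard - mz).min() < 0.02:
                mz = rng.uniform(100.0, 1700.0)
            peaks.append(Peak(mz, float(np.round(rng.exponential(30.0) + 1, 4))))

        sid = f"scan={i}"
        feat = f"PEP{i % n_feat:05d}"
        records.append(
            SpectrumRecord(
                spectrum_id=sid,
                precursor_mz=float(np.round(rng.uniform(400.0, 1200.0), 5)),
                charge=int(rng.choice([2, 3])),
                retention_time=float(np.round(i * 0.5 + rng.uniform(0, 0.2), 4)),
                inv_k0=float(np.round(rng.uniform(0.8, 1.3), 4)),
                peaks=peaks,
            )
        )
        row = {"spectrum_id": sid, "feature_id": feat, "diagnostic_ion": has_diag}
        for k, l in enumerate(labels):
            row[f"occupied_{l}"] = bool(mask[k])
            row[f"true_{l}"] = float(signal[k])
            row[f"counts_{l}"] = float(counts[k])
        truth_rows.append(row)
    truth = SimTruth(
        spectra=pd.DataFrame(truth_rows), offset_ppm=params.systematic_offset_ppm
    )
    return records, truth


@dataclass
class TreatmentEffect:
    """A planted treatment response for one feature.

    ``fold`` multiplies the feature in affected treated cells (values < 1
    model decreases).  ``affected_fraction`` selects the responding subset
    of treated cells.  ``exclusive`` plants presence/absence structure: the
    feature is expressed only in the affected treated cells and missing
    everywhere else (the small-subpopulation pattern).
    """

    fold: float = 1.0
    affected_fraction: float = 1.0
    exclusive: bool = False

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")


def simulate_matrix(
    n_cells: int = 100,
    n_proteins: int = 300,
    panel: Optional[MarkerPanel] = None,
    stage_effect: float = 4.0,
    treatment_effects: Optional[Mapping[str, TreatmentEffect]] = None,
    treated_fraction: float = 0.5,
    base_log10_mean: float = 4.0,
    base_log10_sd: float = 0.5,
    cell_noise_sd: float = 0.15,
    dropout_midpoint: float = 2.0,
    dropout_scale: float = 0.3,
    seed: int = 0,
) -> tuple[QuantMatrix, SimTruth]:
    """Generate a single-cell protein x cell matrix with planted structure.

    Baselines are log-normal (log10 mean/sd as given).  Each cell gets a
    cycle stage drawn uniformly from the panel's stages; that stage's
    markers are elevated ``stage_effect``-fold.  The last
    ``treated_fraction`` of cells are "treated" and receive the planted
    treatment effects.  Detection follows a logistic in log10 abundance
    (midpoint/scale as given) so low-abundance values drop out first.
    """
    rng = np.random.default_rng(seed)
    panel = panel if panel is not None else _default_panel()
    effects = dict(treatment_effects or {})

    proteins = list(panel.markers)
    k = 0
    while len(proteins) < n_proteins:
        name = f"PROT{k:04d}"
        if name not in panel.markers:
            proteins.append(name)
        k += 1
    for f in effects:
        if f not in proteins:
            proteins.append(f)

    n_treated = int(round(n_cells * treated_fraction))
    conditions = ["control"] * (n_cells - n_treated) + ["treated"] * n_treated
    stages = list(rng.choice(panel.stages, size=n_cells))
    cell_ids = [f"cell{i:03d}" for i in range(n_cells)]

    baseline = 10 ** rng.normal(base_log10_mean, base_log10_sd, size=len(proteins))
    values = np.outer(baseline, np.ones(n_cells))
    for i, prot in enumerate(proteins):
        stage = panel.markers.get(prot)
        if stage is not None and stage_effect != 1.0:
            for j in range(n_cells):
                if stages[j] == stage:
                    values[i, j] *= stage_effect

    treated_idx = [j for j, c in enumerate(conditions) if c == "treated"]
    planted: dict[str, dict] = {}
    express_only: dict[int, set[int]] = {}
    for feat, eff in effects.items():
        i = proteins.index(feat)
        n_aff = int(round(eff.affected_fraction * len(treated_idx)))
        affected = sorted(rng.choice(treated_idx, size=n_aff, replace=False))
        planted[feat] = {"affected_cells": [cell_ids[j] for j in affected],
                         "fold": eff.fold, "exclusive": eff.exclusive}
        if eff.exclusive:
            express_only[i] = set(affected)
        else:
            for j in affected:
                values[i, j] *= eff.fold

    values = values * 10 ** rng.normal(0.0, cell_noise_sd, size=values.shape)

    with np.errstate(divide="ignore"):
        p_detect = 1.0 / (1.0 + np.exp(-(np.log10(values) - dropout_midpoint) / dropout_scale))
    detected = rng.random(values.shape) < p_detect
    for i, keep in express_only.items():
        for j in range(n_cells):
            detected[i, j] = detected[i, j] and (j in keep)
    data = np.where(detected, values, np.nan)

    cols = pd.MultiIndex.from_tuples([("sim", c) for c in cell_ids],
                                     names=["run", "channel"])
    df = pd.DataFrame(data, index=pd.Index(proteins, name="feature"), columns=cols)
    roles = {c: "single_cell" for c in cell_ids}
    matrix = QuantMatrix(df, roles)
    truth = SimTruth(
        cells=pd.DataFrame(
            {"cell": cell_ids, "stage": stages, "condition": conditions}
        ).set_index("cell"),
        planted=planted,
    )
    return matrix, truth


def _default_panel() -> MarkerPanel:
    from .cellcycle import packaged_panel

    return packaged_panel()
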