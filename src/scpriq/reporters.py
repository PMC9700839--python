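"""Reporter-ion channel definitions, extraction, impurity correction and
diagnostic-ion detection for isobaric (TMT / TMTPro) multiplexed MS2 spectra.

Reporter cations are defined by elemental composition; their theoretical m/z
is the monoisotopic mass of the composition minus one electron mass.  The
packaged table (``data/reporter_channels.tsv``) covers the TMT 11-plex and
TMTPro (18-plex) reporter series, whose adjacent N/C channels differ by the
(13C-12C) - (15N-14N) neutron-mass discrepancy of ~0.0063 Th.

The acetyl-lysine immonium-derived diagnostic ion (C7H12NO+, 126.0913 Th)
sits only 0.0364 Th below the 126 reporter (C8H16N+, 126.1277 Th);
:func:`detect_diagnostic_ion` resolves the two by nearest-mass assignment.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy.optimize import nnls

from .spectra import Peak, SpectrumRecord

__all__ = [
    "ELECTRON_MASS",
    "ACETYL_LYSINE_DIAGNOSTIC_MZ",
    "ReporterChannel",
    "PlexDesign",
    "ReporterVector",
    "ImpurityMatrix",
    "parse_formula",
    "channel_mz",
    "composition_mz",
    "packaged_channels",
    "extract_reporters",
    "apply_impurities",
    "correct_impurities",
    "interference_free_index",
    "detect_diagnostic_ion",
]

ELECTRON_MASS = 0.000548579909065  # Da (CODATA)

ROLES = frozenset({"blank", "single_cell", "carrier", "standard", "excluded"})

_FORMULA_TOKEN = re.compile(r"^(\d*)([A-Z][a-z]?)(\d*)$")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a space-separated formula such as ``"C4 13C4 H16 15N1"``.

    A leading integer on a token selects an isotope (``13C`` = carbon-13);
    a trailing integer is the atom count (default 1).  Returns a map from
    element token to count.  Unknown element symbols raise ``ValueError``.
    """
    comp: dict[str, int] = {}
    for token in formula.split():
        m = _FORMULA_TOKEN.match(token)
        if not m:
            raise ValueError(f"unparseable formula token: {token!r}")
        iso, elem, count = m.groups()
        if elem not in _pmass.nist_mass:
            raise ValueError(f"unknown element symbol: {elem!r}")
        if iso and int(iso) not in _pmass.nist_mass[elem]:
            raise ValueError(f"unknown isotope {iso} of {elem}")
        key = f"{iso}{elem}" if iso else elem
        comp[key] = comp.get(key, 0) + (int(count) if count else 1)
    return comp


def composition_mz(composition: Mapping[str, int]) -> float:
    """Monoisotopic m/z of a singly charged cation with the given composition.

    Sums standard atomic masses (specific isotope when the token carries a
    leading mass number, else the most abundant isotope) and subtracts one
    electron mass.
    """
    if not composition:
        raise ValueError("composition must be non-empty")
    total = 0.0
    for token, count in composition.items():
        m = _FORMULA_TOKEN.match(token)
        if not m:
            raise ValueError(f"bad composition token {token!r}")
        iso, elem, _ = m.groups()
        if elem not in _pmass.nist_mass:
            raise ValueError(f"unknown element symbol: {elem!r}")
        isotope = int(iso) if iso else 0  # 0 = most abundant in nist_mass
        total += _pmass.nist_mass[elem][isotope][0] * count
    return total - ELECTRON_MASS


# C7H12NO+ immonium-derived fragment of acetylated lysine
ACETYL_LYSINE_DIAGNOSTIC_MZ = composition_mz(parse_formula("C7 H12 N1 O1"))


@dataclass(frozen=True)
class ReporterChannel:
    """A labeled reporter cation (e.g. TMTPro 127N) with known composition."""

    label: str
    composition: Mapping[str, int]
    plex: str = "TMTPro"

    @property
    def theoretical_mz(self) -> float:
        return composition_mz(self.composition)


def channel_mz(channel: ReporterChannel) -> float:
    """Theoretical m/z of a reporter channel's cation."""
    return channel.theoretical_mz


def packaged_channels(plex: str = "TMTPro") -> list[ReporterChannel]:
    """Load the packaged reporter-channel table for a reagent family."""
    text = resources.files("scpriq.data").joinpath("reporter_channels.tsv").read_text()
    out = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        if row["plex"] == plex:
            out.append(ReporterChannel(row["label"], parse_formula(row["formula"]), plex))
    if not out:
        raise ValueError(f"unknown plex family: {plex!r}")
    return out


@dataclass
class PlexDesign:
    """An ordered set of reporter channels with per-channel role and,
    for standards, an expected relative amount.

    Roles: blank, single_cell, carrier, standard, excluded.  Labels are
    unique and at most one channel is the carrier.
    """

    channels: list[ReporterChannel]
    roles: dict[str, str]
    expected_amount: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        missing = set(labels) - set(self.roles)
        if missing:
            raise ValueError(f"roles missing for channels: {sorted(missing)}")
        bad = set(self.roles.values()) - ROLES
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if sum(1 for r in self.roles.values() if r == "carrier") > 1:
            raise ValueError("at most one carrier channel allowed")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channels_with_role(self, role: str) -> list[str]:
        return [c.label for c in self.channels if self.roles[c.label] == role]

    def theoretical_mz(self) -> dict[str, float]:
        return {c.label: c.theoretical_mz for c in self.channels}

    def subset(self, labels: Sequence[str]) -> "PlexDesign":
        keep = set(labels)
        return PlexDesign(
            [c for c in self.channels if c.label in keep],
            {l: r for l, r in self.roles.items() if l in keep},
            {l: a for l, a in self.expected_amount.items() if l in keep},
        )

    @classmethod
    def from_table(cls, path: str | Path, plex: str = "TMTPro") -> "PlexDesign":
        """Read a channel-design table (columns: label, role[, amount])."""
        df = pd.read_csv(path, sep="\t", dtype={"label": str})
        by_label = {c.label: c for c in packaged_channels(plex)}
        channels, roles, amounts = [], {}, {}
        for _, row in df.iterrows():
            label = str(row["label"])
            if label not in by_label:
                raise ValueError(f"unknown channel label {label!r} for {plex}")
            channels.append(by_label[label])
            roles[label] = str(row["role"])
            if "amount" in df.columns and not pd.isna(row["amount"]):
                amounts[label] = float(row["amount"])
        return cls(channels, roles, amounts)


def single_cell_9plex() -> PlexDesign:
    """The unit-resolution TMTPro 9-plex single-cell layout: 126 method
    blank, 127N-131N single cells, 132N/133N auxiliary, 134N carrier."""
    by_label = {c.label: c for c in packaged_channels("TMTPro")}
    labels = ["126", "127N", "128N", "129N", "130N", "131N", "132N", "133N", "134N"]
    roles = {"126": "blank", "134N": "carrier", "132N": "standard", "133N": "excluded"}
    for l in ["127N", "128N", "129N", "130N", "131N"]:
        roles[l] = "single_cell"
    return PlexDesign([by_label[l] for l in labels], roles)


def two_proteome_9plex(ratios: Sequence[float] = (1.0, 5.0, 10.0)) -> PlexDesign:
    """Unit-resolution 9-plex standard with a spike dilution series repeated
    over three channel triplets (default 1:5:10)."""
    by_label = {c.label: c for c in packaged_channels("TMTPro")}
    labels = ["126", "127N", "128N", "129N", "130N", "131N", "132N", "133N", "134N"]
    amounts = {l: float(ratios[i % len(ratios)]) for i, l in enumerate(labels)}
    roles = {l: "standard" for l in labels}
    return PlexDesign([by_label[l] for l in labels], roles, amounts)


@dataclass
class ReporterVector:
    """Per-spectrum reporter intensities: intensity and matched m/z per
    channel, both missing (``None``) when no in-window peak was found."""

    spectrum_id: str
    intensity: dict[str, Optional[float]]
    matched_mz: dict[str, Optional[float]]

    def __post_init__(self) -> None:
        for label in self.intensity:
            if (self.intensity[label] is None) != (self.matched_mz.get(label) is None):
                raise ValueError(f"intensity/matched_mz presence mismatch for {label}")


@dataclass
class ImpurityMatrix:
    """Square channel x channel matrix; entry (i, j) is the fraction of
    channel j's signal observed in channel i (diagonal = retained fraction)."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("impurity matrix must be square over labels")
        if (self.matrix < 0).any() or (self.matrix > 1).any():
            raise ValueError("impurity entries must lie in [0, 1]")
        if (self.matrix.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("impurity column sums must be <= 1")
        diag = np.diag(self.matrix)
        if (diag < self.matrix.max(axis=0) - 1e-12).any():
            raise ValueError("impurity matrix must be diagonally dominant")

    @classmethod
    def identity(cls, labels: Sequence[str]) -> "ImpurityMatrix":
        return cls(list(labels), np.eye(len(labels)))

    @classmethod
    def from_table(cls, path: str | Path) -> "ImpurityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("impurity table rows and columns must match")
        return cls(list(df.index), df.to_numpy())

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_reporters(
    spectrum: SpectrumRecord,
    design: PlexDesign,
    tol_value: float = 0.005,
    tol_unit: str = "Da",
) -> ReporterVector:
    """Extract one reporter intensity per channel from a spectrum.

    Per channel the most intense peak within the tolerance window of the
    channel's theoretical m/z is taken (ties broken by nearest m/z); a peak
    is eligible for at most one channel — the one whose theoretical m/z it is
    nearest.  Channels with no in-window peak, or a zero-intensity peak, are
    missing.  Default window 0.005 Da.
    """
    if tol_value <= 0:
        raise ValueError("tol_value must be > 0")
    if tol_unit not in ("ppm", "Da"):
        raise ValueError("tol_unit must be 'ppm' or 'Da'")
    theo = design.theoretical_mz()
    labels = list(theo)
    intensity: dict[str, Optional[float]] = {l: None for l in labels}
    matched: dict[str, Optional[float]] = {l: None for l in labels}
    if spectrum.peaks:
        theo_arr = np.array([theo[l] for l in labels])
        for p in spectrum.peaks:
            dists = np.abs(theo_arr - p.mz)
            k = int(np.argmin(dists))
            tol = tol_value if tol_unit == "Da" else theo_arr[k] * tol_value * 1e-6
            if dists[k] <= tol and p.intensity > 0:
                label = labels[k]
                cur = intensity[label]
                if (
                    cur is None
                    or p.intensity > cur
                    or (p.intensity == cur
                        and abs(p.mz - theo[label]) < abs(matched[label] - theo[label]))
                ):
                    intensity[label] = p.intensity
                    matched[label] = p.mz
    return ReporterVector(spectrum.spectrum_id, intensity, matched)


# ---------------------------------------------------------------------------
# Isotopic impurity correction
# ---------------------------------------------------------------------------

def apply_impurities(vector: ReporterVector, impurities: ImpurityMatrix) -> ReporterVector:
    """Forward model: distribute true channel signal by the impurity matrix
    (observed = M @ true). Used by the simulator and in closed-loop tests."""
    true = np.array([vector.intensity.get(l) or 0.0 for l in impurities.labels])
    obs = impurities.matrix @ true
    intensity = {l: (float(v) if vector.intensity.get(l) is not None or v > 0 else None)
                 for l, v in zip(impurities.labels, obs)}
    matched = {l: (vector.matched_mz.get(l) if intensity[l] is not None else None)
               for l in impurities.labels}
    # peaks gaining signal purely by leakage have no matched peak of their own
    for l in impurities.labels:
        if intensity[l] is not None and matched[l] is None:
            matched[l] = None
            intensity[l] = None
    return ReporterVector(vector.spectrum_id, intensity, matched)


def correct_impurities(vector: ReporterVector, impurities: ImpurityMatrix) -> ReporterVector:
    """Invert isotopic-impurity leakage on a reporter vector.

    Solves observed = M @ true for the true signal with a non-negativity
    constraint (NNLS).  Missing channels are treated as zero during the
    solve and restored to missing afterwards.  An identity matrix returns
    the input unchanged; a singular matrix raises ``ValueError``.
    """
    labels = impurities.labels
    extra = set(vector.intensity) - set(labels)
    if extra:
        raise ValueError(f"vector channels not in impurity matrix: {sorted(extra)}")
    M = impurities.matrix
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("impurity matrix is singular")
    observed = np.array([vector.intensity.get(l) or 0.0 for l in labels])
    if np.allclose(M, np.eye(len(labels))):
        true = observed
    else:
        true, _ = nnls(M, observed)
    intensity = {}
    matched = {}
    for l, v in zip(labels, true):
        if vector.intensity.get(l) is None:
            intensity[l] = None
            matched[l] = None
        else:
            intensity[l] = float(v)
            matched[l] = vector.matched_mz.get(l)
    return ReporterVector(vector.spectrum_id, intensity, matched)


# ---------------------------------------------------------------------------
# Interference-free index
# ---------------------------------------------------------------------------

def interference_free_index(
    rows: pd.DataFrame,
    ko_channels: Sequence[str],
    parent_channels: Sequence[str],
) -> pd.Series:
    """Per-row interference-free index for a knockout-standard design.

    IFI = 1 - mean(knockout-channel intensities) / mean(parent-channel
    intensities), clamped to [0, 1].  Missing values count as zero in the
    means.  Rows whose parent channels carry no signal are undefined (NaN).
    Column labels may be plain channel labels or (run, channel) tuples whose
    second element is matched.
    """
    ko = set(ko_channels)
    parent = set(parent_channels)
    if not ko or not parent:
        raise ValueError("channel sets must be non-empty")
    if ko & parent:
        raise ValueError("knockout and parent channel sets must be disjoint")

    def _select(which: set[str]) -> pd.DataFrame:
        if isinstance(rows.columns, pd.MultiIndex):
            cols = [c for c in rows.columns if c[1] in which]
        else:
            cols = [c for c in rows.columns if c in which]
        if not cols:
            raise ValueError(f"no matrix columns for channels {sorted(which)}")
        return rows[cols]

    ko_mean = _select(ko).fillna(0.0).mean(axis=1)
    parent_mean = _select(parent).fillna(0.0).mean(axis=1)
    ifi = 1.0 - ko_mean / parent_mean.where(parent_mean > 0)
    return ifi.clip(lower=0.0, upper=1.0)


# ---------------------------------------------------------------------------
# Diagnostic (immonium-type) ion detection
# ---------------------------------------------------------------------------

def detect_diagnostic_ion(
    spectrum: SpectrumRecord,
    ion_mz: float = ACETYL_LYSINE_DIAGNOSTIC_MZ,
    tol_ppm: float = 50.0,
    exclusion_mz: Optional[float] = None,
) -> Optional[Peak]:
    """Find a PTM diagnostic ion while excluding a nearby reporter ion.

    Returns the most intense peak within ``tol_ppm`` of ``ion_mz`` that is
    strictly closer to ``ion_mz`` than to ``exclusion_mz`` (typically the 126
    reporter, 0.0364 Th above the acetyl-lysine ion).  If the tolerance
    window reaches the exclusion mass the call is ambiguous and raises.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    tol = ion_mz * tol_ppm * 1e-6
    if exclusion_mz is not None and abs(exclusion_mz - ion_mz) <= tol:
        raise ValueError(
            "tolerance window includes the exclusion mass; use a smaller tolerance"
        )
    best: Optional[Peak] = None
    for p in spectrum.peaks:
        if abs(p.mz - ion_mz) > tol:
            continue
        if exclusion_mz is not None and abs(p.mz - ion_mz) >= abs(p.mz - exclusion_mz):
            continue
        if best is None or p.intensity > best.intensity:
            best = p
    return best
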