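"""MGF spectrum I/O and spectrum-level structural filters.

Centroided MS2 spectra are held as :class:`SpectrumRecord` objects carrying
precursor metadata (m/z, charge, retention time and, for trapped-ion-mobility
instruments, the reduced inverse mobility 1/k0) plus a peak list sorted by m/z.

Reading uses :mod:`pyteomics.mgf`; writing is done with a fixed numeric format
(m/z to 5 decimal places) so that a write -> read -> write cycle is
byte-identical and records survive a round trip at the printed precision.
The 1/k0 value travels in an ``ION_MOBILITY`` header line and is simply
omitted (and read back as unknown) when absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "Peak",
    "SpectrumRecord",
    "read_mgf",
    "write_mgf",
    "top_n_filter",
    "merge_redundant_spectra",
    "MGFError",
]

MZ_DECIMALS = 5
INTENSITY_DECIMALS = 4
RT_DECIMALS = 4


class MGFError(ValueError):
    """Raised for malformed MGF content, naming the offending block."""


class Peak(NamedTuple):
    """A single centroided peak: m/z in Thomson, intensity in arbitrary counts."""

    mz: float
    intensity: float


@dataclass
class SpectrumRecord:
    """One centroided MS2 spectrum with precursor metadata.

    Invariants: peaks sorted ascending by m/z, no NaNs, retention_time >= 0.
    ``charge`` and ``inv_k0`` are ``None`` when unknown.
    """

    spectrum_id: str
    precursor_mz: float
    charge: Optional[int] = None
    retention_time: float = 0.0
    inv_k0: Optional[float] = None
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if math.isnan(self.precursor_mz) or math.isnan(self.retention_time):
            raise ValueError("precursor_mz / retention_time must not be NaN")
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        pk = [Peak(float(m), float(i)) for m, i in self.peaks]
        for p in pk:
            if math.isnan(p.mz) or math.isnan(p.intensity):
                raise ValueError("peak values must not be NaN")
            if p.mz <= 0 or p.intensity < 0:
                raise ValueError("require mz > 0 and intensity >= 0")
        pk.sort(key=lambda p: (p.mz, p.intensity))
        self.peaks = pk

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def with_peaks(self, peaks: Iterable[Peak]) -> "SpectrumRecord":
        return replace(self, peaks=list(peaks))


# ---------------------------------------------------------------------------
# MGF reading / writing
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF file into a list of :class:`SpectrumRecord`.

    Peaks are sorted ascending by m/z regardless of file order.  Missing
    optional fields (charge, 1/k0) come back as ``None``.  A block without a
    parseable PEPMASS, or with an unparseable peak line, raises
    :class:`MGFError` naming the (0-based) block index.  An empty file yields
    an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SpectrumRecord] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        idx = -1
        while True:
            idx += 1
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # unparseable peak line etc.
                raise MGFError(f"malformed MGF block {idx} in {path.name}: {exc}") from exc
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MGFError(f"malformed MGF block {idx} in {path.name}: missing PEPMASS")
            charge = None
            ch = params.get("charge")
            if ch:
                charge = int(ch[0])
            rt = float(params.get("rtinseconds", 0.0))
            ik0 = params.get("ion_mobility")
            inv_k0 = float(ik0) if ik0 is not None else None
            title = str(params.get("title", f"index={idx}"))
            peaks = [Peak(float(m), float(i))
                     for m, i in zip(entry["m/z array"], entry["intensity array"])]
            records.append(
                SpectrumRecord(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    retention_time=rt,
                    inv_k0=inv_k0,
                    peaks=peaks,
                )
            )
    return records


def _fmt(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def write_mgf(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write records as standard MGF.

    Emits TITLE, PEPMASS, CHARGE (when known), RTINSECONDS and an auxiliary
    ION_MOBILITY line for 1/k0 when present.  m/z values are printed with 5
    decimal places; the fixed format makes write∘read∘write byte-stable.
    """
    path = Path(path)
    lines: list[str] = []
    for rec in records:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={rec.spectrum_id}")
        lines.append(f"PEPMASS={_fmt(rec.precursor_mz, MZ_DECIMALS)}")
        if rec.charge is not None:
            sign = "+" if rec.charge >= 0 else "-"
            lines.append(f"CHARGE={abs(rec.charge)}{sign}")
        lines.append(f"RTINSECONDS={_fmt(rec.retention_time, RT_DECIMALS)}")
        if rec.inv_k0 is not None:
            lines.append(f"ION_MOBILITY={_fmt(rec.inv_k0, RT_DECIMALS)}")
        for p in rec.peaks:
            lines.append(f"{_fmt(p.mz, MZ_DECIMALS)} {_fmt(p.intensity, INTENSITY_DECIMALS)}")
        lines.append("END IONS")
        lines.append("")
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Structural filters
# ---------------------------------------------------------------------------

def top_n_filter(spectrum: SpectrumRecord, n: int) -> SpectrumRecord:
    """Keep only the ``n`` most intense peaks of a spectrum.

    Mirrors converter-side noise filtering that retains the most intense
    fragment ions of each MS/MS spectrum (200 by default in that context).
    Intensity ties are broken in favour of the lower m/z peak so the result
    is deterministic.  The input record is not modified.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(spectrum.peaks) <= n:
        return spectrum.with_peaks(spectrum.peaks)
    ranked = sorted(spectrum.peaks, key=lambda p: (-p.intensity, p.mz))
    kept = sorted(ranked[:n], key=lambda p: p.mz)
    return spectrum.with_peaks(kept)


def _within(a: Optional[float], b: Optional[float], tol: float) -> bool:
    if a is None and b is None:
        return True
    if a is None or b is None:
        return False
    return abs(a - b) <= tol


def merge_redundant_spectra(
    records: Sequence[SpectrumRecord],
    rt_tol: float = 5.0,
    im_tol: float = 0.1,
    prec_tol: float = 0.05,
    frag_tol: float = 0.02,
) -> list[SpectrumRecord]:
    """Merge spectra that repeat the same precursor.

    Two records are linked when their precursor m/z, retention time and 1/k0
    all agree within the given tolerances (defaults: 5 s, 0.1 1/k0, 0.05 Da —
    the converter's merge criteria).  Merging is transitive within a connected
    group.  Peaks from a group are clustered within ``frag_tol`` Da and their
    intensities summed; merged precursor fields are intensity-weighted means.
    A record whose 1/k0 is unknown only links to other unknown-1/k0 records.
    """
    for name, tol in (("rt_tol", rt_tol), ("im_tol", im_tol),
                      ("prec_tol", prec_tol), ("frag_tol", frag_tol)):
        if tol <= 0:
            raise ValueError(f"{name} must be > 0")
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if (
                abs(a.precursor_mz - b.precursor_mz) <= prec_tol
                and abs(a.retention_time - b.retention_time) <= rt_tol
                and _within(a.inv_k0, b.inv_k0, im_tol)
            ):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[SpectrumRecord] = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = [records[i] for i in sorted(groups[root])]
        if len(members) == 1:
            merged.append(members[0])
            continue
        merged.append(_merge_group(members, frag_tol))
    return merged


def _merge_group(members: list[SpectrumRecord], frag_tol: float) -> SpectrumRecord:
    weights = np.array([sum(p.intensity for p in m.peaks) or 1.0 for m in members])
    weights = weights / weights.sum()
    prec = float(np.dot(weights, [m.precursor_mz for m in members]))
    rt = float(np.dot(weights, [m.retention_time for m in members]))
    if all(m.inv_k0 is not None for m in members):
        ik0 = float(np.dot(weights, [m.inv_k0 for m in members]))
    else:
        ik0 = None
    charges = {m.charge for m in members if m.charge is not None}
    charge = charges.pop() if len(charges) == 1 else None

    all_peaks = sorted((p for m in members for p in m.peaks), key=lambda p: p.mz)
    clusters: list[list[Peak]] = []
    for p in all_peaks:
        if clusters and p.mz - clusters[-1][0].mz <= frag_tol:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out_peaks = []
    for cl in clusters:
        tot = sum(p.intensity for p in cl)
        if tot > 0:
            mz = sum(p.mz * p.intensity for p in cl) / tot
        else:
            mz = sum(p.mz for p in cl) / len(cl)
        out_peaks.append(Peak(mz, tot))
    return SpectrumRecord(
        spectrum_id=";".join(m.spectrum_id for m in members),
        precursor_mz=prec,
        charge=charge,
        retention_time=rt,
        inv_k0=ik0,
        peaks=out_peaks,
    )
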