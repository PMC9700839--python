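"""Single-cell QC filtering of MS2 spectra (DIDAR-style).

Three operations: retain only spectra showing at least one reporter ion from
a well that contained a single cell (0.005 Da window by default); reject
whole runs whose single-cell reporter evidence does not exceed a multiple
(3x by default) of the method-blank channel's; and reduce spectral
complexity by keeping the k most intense fragments per fixed m/z window
(12 per 100 Da by default, as used upstream of database search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .reporters import PlexDesign, extract_reporters
from .spectra import SpectrumRecord

__all__ = [
    "RunQCSummary",
    "filter_by_reporter_presence",
    "flag_failed_runs",
    "bin_top_k",
    "FILTERED_PREFIX",
]

FILTERED_PREFIX = "Filtered"


@dataclass
class RunQCSummary:
    """Per-run QC metrics from reporter-presence filtering.

    ``per_channel`` counts spectra with a matched reporter in each channel;
    ``n_cell_spectra`` counts spectra with a match in at least one
    single-cell channel; ``passed`` is set by :func:`flag_failed_runs`.
    """

    run_id: str
    per_channel: dict[str, int] = field(default_factory=dict)
    n_cell_spectra: int = 0
    total_ms2: int = 0
    retained_ms2: int = 0
    passed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.retained_ms2 > self.total_ms2:
            raise ValueError("retained count cannot exceed total")
        if self.total_ms2 < 0 or any(v < 0 for v in self.per_channel.values()):
            raise ValueError("counts must be >= 0")


def filter_by_reporter_presence(
    spectra: Sequence[SpectrumRecord],
    design: PlexDesign,
    required_channels: Sequence[str],
    tol_da: float = 0.005,
    run_id: str = "run",
) -> tuple[list[SpectrumRecord], RunQCSummary]:
    """Retain spectra carrying >=1 required-channel reporter ion.

    A spectrum is kept iff at least one channel in ``required_channels``
    (typically the single-cell wells, 127N-131N) has a peak within
    ``tol_da`` of its exact reporter mass.  The summary counts matched
    spectra for every design channel plus the union over single-cell
    channels, feeding the blank-based run rejection.
    """
    required = set(required_channels)
    if not required:
        raise ValueError("required_channels must be non-empty")
    unknown = required - set(design.labels)
    if unknown:
        raise ValueError(f"required channels not in design: {sorted(unknown)}")
    if tol_da <= 0:
        raise ValueError("tol_da must be > 0")

    cell_channels = set(design.channels_with_role("single_cell")) or required
    per_channel = {l: 0 for l in design.labels}
    n_cell = 0
    retained: list[SpectrumRecord] = []
    for spec in spectra:
        vec = extract_reporters(spec, design, tol_value=tol_da, tol_unit="Da")
        present = {l for l, v in vec.intensity.items() if v is not None}
        for l in present:
            per_channel[l] += 1
        if present & cell_channels:
            n_cell += 1
        if present & required:
            retained.append(spec)
    summary = RunQCSummary(
        run_id=run_id,
        per_channel=per_channel,
        n_cell_spectra=n_cell,
        total_ms2=len(spectra),
        retained_ms2=len(retained),
    )
    return retained, summary


def flag_failed_runs(
    summaries: Sequence[RunQCSummary],
    blank_channel: str = "126",
    factor: float = 3.0,
) -> list[RunQCSummary]:
    """Set ``passed`` on each run summary via the blank-based rejection rule.

    A run passes iff the number of spectra with signal in any single-cell
    channel strictly exceeds ``factor`` times the number of spectra with
    signal in the method-blank channel.  Counts (not intensities) are
    compared.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = []
    for s in summaries:
        if blank_channel not in s.per_channel:
            raise ValueError(f"run {s.run_id}: unknown blank channel {blank_channel!r}")
        s.passed = s.n_cell_spectra > factor * s.per_channel[blank_channel]
        out.append(s)
    return out


def bin_top_k(spectrum: SpectrumRecord, k: int = 12, window_da: float = 100.0) -> SpectrumRecord:
    """Keep the k most intense peaks in each fixed m/z window.

    Windows are contiguous half-open bins anchored at m/z 0:
    [0, w), [w, 2w), ...  Within each bin only the ``k`` most intense peaks
    survive (ties broken by lower m/z); output stays sorted by m/z.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if window_da <= 0:
        raise ValueError("window_da must be > 0")
    bins: dict[int, list] = {}
    for p in spectrum.peaks:
        bins.setdefault(int(p.mz // window_da), []).append(p)
    kept = []
    for peaks in bins.values():
        peaks.sort(key=lambda p: (-p.intensity, p.mz))
        kept.extend(peaks[:k])
    kept.sort(key=lambda p: p.mz)
    return spectrum.with_peaks(kept)
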