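"""Inter-pulse-interval statistics and the five-variable SPI feature summary.

The inter-pulse-interval (IPI) of pulse ``i`` is ``t_i - t_{i-1}``, reported
in milliseconds.  A 120-s window of a recording is summarized by five
features: total pulse count, number of runs, the mode IPI (tallest bin of a
2-ms histogram), and the longest and shortest interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pulse_io import PulseTrain, extract_window

__all__ = [
    "IPISequence",
    "IPIHistogram",
    "PopulationHistogram",
    "SPIFeatures",
    "compute_ipis",
    "ipi_histogram",
    "average_histograms",
    "count_runs",
    "extract_features",
    "features_table",
    "histogram_peaks",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["total_eods", "n_runs", "mode_ipi_ms", "range_high_ms", "range_low_ms"]


@dataclass
class IPISequence:
    """Ordered inter-pulse-intervals in milliseconds."""

    intervals: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1:
            raise ValueError("intervals must be a 1-D array")
        if iv.size and iv.min() <= 0:
            raise ValueError("all intervals must be positive")
        self.intervals = iv

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def median_ms(self) -> float:
        return float(np.median(self.intervals))


@dataclass
class IPIHistogram:
    """Relative-frequency IPI histogram on uniform, left-closed bins.

    Bins start at 0 ms and extend one bin past the largest interval, so an
    interval lying exactly on a bin edge always falls into the bin to its
    right.
    """

    bin_edges: np.ndarray
    rel_freq: np.ndarray
    n_intervals: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        freq = np.asarray(self.rel_freq, dtype=float)
        if edges.size != freq.size + 1:
            raise ValueError("bin_edges must have one more entry than rel_freq")
        widths = np.diff(edges)
        if widths.size == 0 or widths.min() <= 0:
            raise ValueError("bin width must be positive")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=0):
            raise ValueError("bin width must be uniform")
        if self.n_intervals > 0 and abs(freq.sum() - 1.0) > 1e-12:
            raise ValueError("relative frequencies must sum to 1")
        self.bin_edges = edges
        self.rel_freq = freq

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode_ms(self) -> float:
        """Center of the tallest bin (lowest bin wins ties)."""
        return float(self.bin_centers[int(np.argmax(self.rel_freq))])


@dataclass
class PopulationHistogram:
    """Per-bin mean, SEM and STD of several individual histograms."""

    bin_edges: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    std: np.ndarray
    n_histograms: int


@dataclass
class SPIFeatures:
    """The five-variable summary of one analysis window of a pulse train."""

    total_eods: int
    n_runs: int
    mode_ipi_ms: float
    range_high_ms: float
    range_low_ms: float
    individual_id: str = ""
    species_label: str = ""
    sex: str = "unknown"
    phase: str = "synthetic"

    def __post_init__(self) -> None:
        if not (self.range_low_ms <= self.range_high_ms):
            raise ValueError("range_low_ms must not exceed range_high_ms")
        if self.total_eods >= 3 and not (1 <= self.n_runs <= self.total_eods - 2):
            raise ValueError("n_runs must lie in [1, total_eods - 2]")


def compute_ipis(train: PulseTrain) -> IPISequence:
    """Successive timestamp differences, converted to milliseconds."""
    if train.n_events < 2:
        raise ValueError("at least 2 events are required to form intervals")
    return IPISequence(np.diff(train.timestamps) * 1000.0, source_id=train.individual_id)


def ipi_histogram(seq: IPISequence, bin_width_ms: float = 2.0) -> IPIHistogram:
    """Relative-frequency histogram with uniform bins starting at 0 ms."""
    if len(seq) == 0:
        raise ValueError("cannot histogram an empty IPI sequence")
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(math.floor(seq.intervals.max() / bin_width_ms)) + 1
    edges = bin_width_ms * np.arange(n_bins + 1, dtype=float)
    counts, _ = np.histogram(seq.intervals, bins=edges)
    return IPIHistogram(edges, counts / len(seq), n_intervals=len(seq))


def average_histograms(hists: list[IPIHistogram]) -> PopulationHistogram:
    """Arithmetic per-bin mean with SEM and STD across individuals.

    Shorter histograms are zero-padded to the widest span; all inputs must
    share the same bin width.
    """
    if len(hists) < 2:
        raise ValueError("need at least 2 histograms to average")
    width = hists[0].bin_width
    for h in hists[1:]:
        if not math.isclose(h.bin_width, width, rel_tol=1e-9):
            raise ValueError("histograms have mixed bin widths")
    n_bins = max(h.rel_freq.size for h in hists)
    stack = np.zeros((len(hists), n_bins))
    for i, h in enumerate(hists):
        stack[i, : h.rel_freq.size] = h.rel_freq
    std = stack.std(axis=0, ddof=1)
    return PopulationHistogram(
        bin_edges=width * np.arange(n_bins + 1, dtype=float),
        mean=stack.mean(axis=0),
        sem=std / math.sqrt(len(hists)),
        std=std,
        n_histograms=len(hists),
    )


def count_runs(seq: IPISequence, tie_tol_ms: float = 0.0) -> int:
    """Number of runs in the interval sequence.

    Each adjacent interval pair is classed as positive, negative or equal
    (differences of magnitude <= ``tie_tol_ms`` count as equal); a run is a
    maximal streak of one class, as in the classical runs test.
    """
    if len(seq) < 2:
        raise ValueError("at least 2 intervals are required to count runs")
    diffs = np.diff(seq.intervals)
    classes = np.sign(diffs)
    classes[np.abs(diffs) <= tie_tol_ms] = 0
    return int(1 + np.count_nonzero(classes[1:] != classes[:-1]))


def extract_features(
    train: PulseTrain,
    window_start_s: float = 0.0,
    window_length_s: float | None = 120.0,
    bin_width_ms: float = 2.0,
    tie_tol_ms: float = 0.0,
) -> SPIFeatures:
    """Compute the five SPI features on a declared analysis window.

    ``window_length_s=None`` analyses the whole train.  The mode IPI is the
    center of the tallest histogram bin, so a constant 50-ms train reports a
    mode of 51 ms (center of bin [50, 52)).
    """
    if window_length_s is not None:
        train = extract_window(train, window_start_s, window_length_s)
    if train.n_events < 3:
        raise ValueError("feature extraction needs at least 3 events in the window")
    seq = compute_ipis(train)
    hist = ipi_histogram(seq, bin_width_ms=bin_width_ms)
    return SPIFeatures(
        total_eods=train.n_events,
        n_runs=count_runs(seq, tie_tol_ms=tie_tol_ms),
        mode_ipi_ms=hist.mode_ms,
        range_high_ms=float(seq.intervals.max()),
        range_low_ms=float(seq.intervals.min()),
        individual_id=train.individual_id,
        species_label=train.species_label,
        sex=train.sex,
        phase=train.phase,
    )


def histogram_peaks(
    hist: IPIHistogram, n_peaks: int = 2, min_separation_ms: float = 6.0
) -> np.ndarray:
    """Centers of the ``n_peaks`` tallest mutually separated histogram bins.

    Bins are taken greedily in order of height; a candidate closer than
    ``min_separation_ms`` to an already-selected peak is skipped, so two
    adjacent bins of one broad mode are not reported as two peaks.
    Returned sorted by height (tallest first).
    """
    order = np.argsort(hist.rel_freq)[::-1]
    centers = hist.bin_centers
    chosen: list[float] = []
    for idx in order:
        c = float(centers[idx])
        if all(abs(c - prev) >= min_separation_ms for prev in chosen):
            chosen.append(c)
        if len(chosen) == n_peaks:
            break
    return np.asarray(chosen)


def features_table(features: list[SPIFeatures]) -> pd.DataFrame:
    """Assemble per-individual features into the pipeline's tabular format."""
    rows = [
        {
            "individual_id": f.individual_id,
            "species_label": f.species_label,
            "sex": f.sex,
            "phase": f.phase,
            "total_eods": f.total_eods,
            "n_runs": f.n_runs,
            "mode_ipi_ms": f.mode_ipi_ms,
            "range_high_ms": f.range_high_ms,
            "range_low_ms": f.range_low_ms,
        }
        for f in features
    ]
    return pd.DataFrame(rows)
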