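"""Genome-size estimation from a k-mer depth spectrum.

A k-mer spectrum is the histogram of distinct k-mer counts by sequencing
depth.  For a single individual sequenced to fold-coverage lambda, the
genomic k-mers form a Poisson-like main peak near lambda while sequencing
errors pile up as a spike at depth 1-3.  With ``K_num`` the total number of
k-mer instances attributable to the main peak and ``Peak_depth`` the
expected k-mer depth of that peak, the genome size is::

    G = K_num / Peak_depth

Error k-mers are excluded by cutting the spectrum at the first local minimum
(the trough between the error spike and the main peak).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EstimationError, ParseError


@dataclass(frozen=True)
class KmerHistogram:
    """Depth -> distinct-k-mer-count spectrum.

    Parameters
    ----------
    k:
        k-mer length used to build the spectrum.
    entries:
        Mapping ``depth -> number of distinct k-mers observed at that depth``.
        Depths are positive integers, counts non-negative.
    """

    k: int
    entries: dict[int, int]

    def __post_init__(self):
        if not self.entries:
            raise EstimationError("empty k-mer histogram")
        if any(d < 1 for d in self.entries):
            raise EstimationError("k-mer depths must be >= 1")
        if any(c < 0 for c in self.entries.values()):
            raise EstimationError("k-mer counts must be >= 0")
        if not any(c > 0 for c in self.entries.values()):
            raise EstimationError("k-mer histogram has no nonzero count")

    @property
    def total_instances(self) -> int:
        """Total number of k-mer instances, sum of depth*count."""
        return int(sum(d * c for d, c in self.entries.items()))

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Densified (depths, counts) arrays spanning min..max observed depth."""
        dmin = min(self.entries)
        dmax = max(self.entries)
        depths = np.arange(dmin, dmax + 1)
        counts = np.zeros(depths.shape, dtype=float)
        for d, c in self.entries.items():
            counts[d - dmin] = c
        return depths, counts


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Result of :func:`estimate_genome_size`; ``G = k_num_used / peak_depth``."""

    G: float
    peak_depth: int
    error_cutoff: int
    k_num_used: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "genome_size_bp": self.G,
                "peak_depth": self.peak_depth,
                "error_cutoff": self.error_cutoff,
                "k_num_used": self.k_num_used,
            }
        )


def read_histogram(path: str | Path, k: int = 17) -> KmerHistogram:
    """Read a two-column whitespace-separated ``depth count`` text file.

    Blank lines and ``#`` comments are skipped; anything else that does not
    parse as two integers raises :class:`ParseError` with its line number.
    """
    entries: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"expected 2 fields, got {len(fields)}", lineno)
            try:
                depth, count = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ParseError(f"non-integer field in {fields!r}", lineno) from exc
            if depth in entries:
                raise ParseError(f"duplicate depth {depth}", lineno)
            entries[depth] = count
    if not entries:
        raise ParseError("empty histogram file", None)
    return KmerHistogram(k=k, entries=entries)


def write_histogram(hist: KmerHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in sorted(hist.entries):
            fh.write(f"{d} {hist.entries[d]}\n")


def _smooth(counts: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge replication; guards trough/peak detection
    against bin-to-bin sampling noise."""
    padded = np.concatenate([counts[:1], counts, counts[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def find_peak(hist: KmerHistogram) -> tuple[int, int]:
    """Locate the error cutoff and main-peak depth of a spectrum.

    The error cutoff is the first local minimum scanning the (smoothed)
    spectrum upward from its lowest depth — the trough separating the error
    spike from the genomic peak.  The peak is first located as the argmax of
    the smoothed counts above the cutoff and then refined to the rounded
    count-weighted mean depth within +/-50% of that argmax, i.e. the expected
    depth of the main peak.  Ties resolve to the lower depth.

    Returns
    -------
    (error_cutoff, peak_depth)

    Raises
    ------
    EstimationError
        If the spectrum has fewer than 3 bins or decreases monotonically
        (no main peak).
    """
    depths, counts = hist.to_arrays()
    if depths.size < 3:
        raise EstimationError("need at least 3 depth bins")
    s = _smooth(counts)
    if s[0] <= s[1]:
        # no descending error spike: the spectrum opens flat or rising, so
        # nothing below the first bin needs excluding
        error_cutoff = int(depths[0])
    else:
        # descending spike: first local minimum is the error/genomic trough
        cutoff_idx = None
        for i in range(s.size - 1):
            if s[i] < s[i + 1]:
                cutoff_idx = i
                break
        if cutoff_idx is None:
            raise EstimationError(
                "no main peak: histogram decreases monotonically"
            )
        error_cutoff = int(depths[cutoff_idx])

    above = depths > error_cutoff
    if not above.any() or not counts[above].any():
        raise EstimationError("no main peak above the error cutoff")
    s_above = np.where(above, s, -np.inf)
    argmax_depth = int(depths[int(np.argmax(s_above))])  # first (lowest) max

    lo = max(error_cutoff + 1, int(np.floor(argmax_depth * 0.5)))
    hi = int(np.ceil(argmax_depth * 1.5))
    win = (depths >= lo) & (depths <= hi)
    w = counts[win]
    d = depths[win]
    peak_depth = int(round(float((d * w).sum() / w.sum())))
    if peak_depth <= error_cutoff:  # degenerate spectra
        peak_depth = argmax_depth
    return error_cutoff, peak_depth


def estimate_genome_size(hist: KmerHistogram) -> GenomeSizeEstimate:
    """Estimate genome size as ``G = K_num / Peak_depth``.

    ``K_num`` counts k-mer instances (depth x count) strictly above the error
    cutoff, so the error spike does not inflate the estimate.
    """
    error_cutoff, peak_depth = find_peak(hist)
    k_num = int(
        sum(d * c for d, c in hist.entries.items() if d > error_cutoff)
    )
    return GenomeSizeEstimate(
        G=k_num / peak_depth,
        peak_depth=peak_depth,
        error_cutoff=error_cutoff,
        k_num_used=k_num,
    )
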