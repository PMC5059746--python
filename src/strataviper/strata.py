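"""Windowed evidence tracks along the Z chromosome and their segmentation
into evolutionary strata.

An evolutionary stratum is a block of the sex chromosome whose Z-W
recombination stopped in one event, so windowed evidence — female:autosome
depth ratio, Z/W sequence divergence, identifiable-W-fragment density,
cross-species conservation, repeat density — is piecewise constant along the
chromosome with changepoints at stratum boundaries.  Segmentation is
multivariate least-squares changepoint detection: each track is z-scored,
NaN windows are imputed from their nearest informative neighbour (for
segmentation only), and breakpoints are found by binary segmentation, with an
exact dynamic program available as an oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError, ParseError


@dataclass(frozen=True)
class WindowTrack:
    """Windowed values along one chromosome on a regular grid.

    ``starts`` are 0-based half-open window starts with constant step
    ``window_size``; NaN marks windows without data.
    """

    chrom: str
    window_size: int
    starts: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "values", values)
        if starts.shape != values.shape:
            raise InputError("starts and values must have equal length")
        if starts.size > 1:
            steps = np.diff(starts)
            if not (steps == self.window_size).all():
                raise InputError(
                    "starts must increase in constant steps of window_size"
                )

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.starts + self.window_size,
                "value": self.values,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_track(path: str | Path) -> WindowTrack:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "start", "end", "value"}.issubset(df.columns):
        raise ParseError("track TSV needs columns chrom,start,end,value")
    window = int(df["end"].iloc[0] - df["start"].iloc[0])
    return WindowTrack(str(df["chrom"].iloc[0]), window,
                       df["start"].to_numpy(), df["value"].to_numpy())


@dataclass(frozen=True)
class StratumSegment:
    start: int
    end: int
    label: str  # PAR, S1 (oldest), S2, ... or UNRANKED
    mean_divergence: float
    mean_depth_ratio: float


def make_grid(chrom_len: int, window_size: int) -> np.ndarray:
    return np.arange(0, chrom_len, window_size, dtype=np.int64)


def _window_means(starts: np.ndarray, window_size: int,
                  ivals: Iterable[tuple[int, int, float]]) -> np.ndarray:
    """Length-weighted mean of interval values per window; NaN if no overlap."""
    num = np.zeros(starts.size)
    den = np.zeros(starts.size)
    grid_end = starts[-1] + window_size if starts.size else 0
    for s, e, v in ivals:
        s = max(int(s), 0)
        e = min(int(e), int(grid_end))
        if e <= s or np.isnan(v):
            continue
        i0 = s // window_size
        i1 = (e - 1) // window_size
        for i in range(i0, i1 + 1):
            ws = starts[i]
            overlap = min(e, ws + window_size) - max(s, ws)
            num[i] += v * overlap
            den[i] += overlap
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted((int(s), int(e)) for s, e in intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _coverage_per_window(starts: np.ndarray, window_size: int,
                         intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    cov = np.zeros(starts.size)
    grid_end = starts[-1] + window_size if starts.size else 0
    for s, e in merge_intervals(intervals):
        s = max(s, 0)
        e = min(e, int(grid_end))
        if e <= s:
            continue
        for i in range(s // window_size, (e - 1) // window_size + 1):
            ws = starts[i]
            cov[i] += min(e, ws + window_size) - max(s, ws)
    return cov / window_size


def depth_ratio_track(
    depth: pd.DataFrame,
    chrom: str,
    chrom_len: int,
    window_size: int,
    autosomal_median: float,
) -> WindowTrack:
    """Window mean depth relative to the autosomal median depth.

    ``depth`` carries chromosome-coordinate rows (columns start, end, depth);
    values near 1 indicate recombining/pseudoautosomal sequence in a female,
    near 0.5 a fully sex-linked hemizygous region.
    """
    if autosomal_median <= 0:
        raise NormalizationError("autosomal median depth must be positive")
    starts = make_grid(chrom_len, window_size)
    vals = _window_means(
        starts, window_size,
        ((r.start, r.end, r.depth) for r in depth.itertuples(index=False)),
    )
    return WindowTrack(chrom, window_size, starts, vals / autosomal_median)


def project_to_chrom(depth: pd.DataFrame,
                     scaffold_coords: dict[str, tuple[str, int]],
                     chrom: str) -> pd.DataFrame:
    """Lift scaffold-coordinate depth windows onto chromosome coordinates."""
    d = depth.loc[depth["scaffold"].map(
        lambda s: scaffold_coords.get(s, ("", 0))[0] == chrom
    )].copy()
    offs = d["scaffold"].map(lambda s: scaffold_coords[s][1])
    d["start"] = d["start"] + offs
    d["end"] = d["end"] + offs
    return d[["start", "end", "depth"]]


def divergence_track(
    alignments: Sequence,
    chrom: str,
    chrom_len: int,
    window_size: int,
    model: str = "p",
) -> WindowTrack:
    """Length-weighted mean Z/W divergence per window.

    ``alignments`` are objects with ``z_start``, ``z_end``, ``seq_z`` and
    ``seq_w`` (or precomputed ``divergence``); windows without any alignment
    are NaN.  ``model`` is 'p' (p-distance) or 'k2p'.
    """
    from .gametologs import pairwise_divergence

    starts = make_grid(chrom_len, window_size)
    ivals = []
    for aln in alignments:
        if not 0 <= aln.z_start < aln.z_end <= chrom_len:
            raise InputError(
                f"alignment anchor [{aln.z_start}, {aln.z_end}) outside chromosome"
            )
        if hasattr(aln, "divergence") and aln.divergence is not None:
            d = float(aln.divergence)
        else:
            d = pairwise_divergence(aln.seq_z, aln.seq_w, model=model)
        ivals.append((aln.z_start, aln.z_end, d))
    return WindowTrack(chrom, window_size, starts,
                       _window_means(starts, window_size, ivals))


def wfragment_density_track(
    placements: Sequence[tuple[int, int]],
    chrom: str,
    chrom_len: int,
    window_size: int = 1_000_000,
) -> WindowTrack:
    """Fraction of each window covered by identifiable W-derived fragments
    (merged before computing coverage); high density marks recently
    suppressed strata."""
    starts = make_grid(chrom_len, window_size)
    vals = _coverage_per_window(starts, window_size, placements)
    return WindowTrack(chrom, window_size, starts, vals)


def toy_align_score(seq_a: str, seq_b: str) -> float:
    """Per-bp alignment score of two equal-length aligned sequences:
    match +1, mismatch -1, gap -2.  A stand-in scorer for synthetic data;
    real conservation scores are ingested, not computed."""
    if len(seq_a) != len(seq_b):
        raise InputError("toy_align_score needs equal-length aligned sequences")
    if not seq_a:
        return float("nan")
    score = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == "-" or b == "-":
            score -= 2
        elif a == b:
            score += 1
        else:
            score -= 1
    return score / len(seq_a)


def conservation_track(
    scores: pd.DataFrame,
    chrom: str,
    chrom_len: int,
    window_size: int,
) -> WindowTrack:
    """Ingest a per-window (or per-interval) alignment-score table with
    columns start, end, value; length-weighted mean per grid window."""
    starts = make_grid(chrom_len, window_size)
    vals = _window_means(
        starts, window_size,
        ((r.start, r.end, r.value) for r in scores.itertuples(index=False)),
    )
    return WindowTrack(chrom, window_size, starts, vals)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6+2 file (family in column 7, divergence in column 8)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 fields", lineno)
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                family = fields[6] if len(fields) > 6 else name
                divergence = float(fields[7]) if len(fields) > 7 else np.nan
            except ValueError as exc:
                raise ParseError(f"malformed BED fields: {exc}", lineno) from exc
            if end < start:
                raise ParseError("BED end < start", lineno)
            rows.append((chrom, start, end, name, family, divergence))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "family", "divergence"]
    )


def repeat_density_track(
    bed: pd.DataFrame,
    chrom: str,
    chrom_len: int,
    window_size: int = 100_000,
    family: str | None = None,
) -> WindowTrack:
    """Covered-bp fraction per window for one repeat family (intervals merged
    before coverage; 100-kb non-overlapping windows by default)."""
    df = bed.loc[bed["chrom"] == chrom]
    if family is not None:
        df = df.loc[df["family"] == family]
    starts = make_grid(chrom_len, window_size)
    ivals = list(zip(df["start"].astype(int), df["end"].astype(int)))
    return WindowTrack(chrom, window_size, starts,
                       _coverage_per_window(starts, window_size, ivals))


def repeat_divergence_profile(
    bed: pd.DataFrame,
    segments: Sequence[StratumSegment],
    bin_width: float = 0.02,
    chrom: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-segment histogram of repeat divergence-from-consensus in
    ``bin_width``-wide bins (2% by default).  A repeat interval is assigned to
    the segment containing its midpoint."""
    df = bed.dropna(subset=["divergence"])
    if chrom is not None:
        df = df.loc[df["chrom"] == chrom]
    max_div = float(df["divergence"].max()) if len(df) else bin_width
    edges = np.arange(0.0, max_div + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    out = {}
    mids = (df["start"] + df["end"]) // 2
    for seg in segments:
        sel = df.loc[(mids >= seg.start) & (mids < seg.end), "divergence"]
        counts, _ = np.histogram(sel, bins=edges)
        out[seg.label] = pd.DataFrame(
            {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
        )
    return out


# ---------------------------------------------------------------------------
# segmentation


def _impute_nearest(values: np.ndarray) -> np.ndarray:
    """Replace NaN by the nearest non-NaN neighbour (segmentation only)."""
    v = values.astype(float).copy()
    n = v.size
    ok = ~np.isnan(v)
    if not ok.any():
        raise InputError("track is all-NaN; nothing to segment")
    idx = np.arange(n)
    pos = idx[ok]
    nearest = pos[np.abs(pos[None, :] - idx[~ok, None]).argmin(axis=1)]
    v[~ok] = values[nearest]
    return v


def _stack_tracks(tracks: Sequence[WindowTrack]) -> np.ndarray:
    if not tracks:
        raise InputError("no tracks supplied")
    ref = tracks[0]
    for t in tracks[1:]:
        if (t.window_size != ref.window_size or t.n_windows != ref.n_windows
                or not np.array_equal(t.starts, ref.starts)):
            raise InputError("all tracks must share the same window grid")
    cols = []
    for t in tracks:
        v = _impute_nearest(t.values)
        sd = v.std()
        cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
    return np.column_stack(cols)


def _prefix_sums(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.vstack([np.zeros((1, X.shape[1])), np.cumsum(X, axis=0)])
    s2 = np.vstack([np.zeros((1, X.shape[1])), np.cumsum(X**2, axis=0)])
    return s1, s2


def _segment_cost(s1, s2, i, j) -> float:
    """Within-segment SSE of X[i:j], summed over tracks."""
    n = j - i
    if n <= 0:
        return 0.0
    tot = s1[j] - s1[i]
    tot2 = s2[j] - s2[i]
    return float((tot2 - tot**2 / n).sum())


def binary_segmentation(X: np.ndarray, n_bkps: int) -> list[int]:
    """Greedy top-down least-squares changepoint detection; returns sorted
    breakpoint indices (window index of the first window after each break)."""
    n = X.shape[0]
    if n < n_bkps + 1:
        raise InputError("fewer windows than breakpoints + 1")
    s1, s2 = _prefix_sums(X)
    bkps: list[int] = []
    for _ in range(n_bkps):
        bounds = [0] + sorted(bkps) + [n]
        best = None
        for a, b in zip(bounds[:-1], bounds[1:]):
            base = _segment_cost(s1, s2, a, b)
            for k in range(a + 1, b):
                gain = base - _segment_cost(s1, s2, a, k) - _segment_cost(s1, s2, k, b)
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, k)
        if best is None:
            break
        bkps.append(best[1])
    return sorted(bkps)


def dp_segmentation(X: np.ndarray, n_bkps: int) -> list[int]:
    """Exact minimum-SSE segmentation by dynamic programming (oracle mode;
    O(k n^2), intended for <= ~200 windows)."""
    n = X.shape[0]
    if n < n_bkps + 1:
        raise InputError("fewer windows than breakpoints + 1")
    s1, s2 = _prefix_sums(X)
    cost = np.array([[_segment_cost(s1, s2, i, j) if j > i else np.inf
                      for j in range(n + 1)] for i in range(n + 1)])
    k_segs = n_bkps + 1
    D = np.full((k_segs + 1, n + 1), np.inf)
    back = np.zeros((k_segs + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for k in range(1, k_segs + 1):
        for j in range(k, n + 1):
            cands = D[k - 1, k - 1:j] + cost[k - 1:j, j]
            best = int(np.argmin(cands))
            D[k, j] = cands[best]
            back[k, j] = best + k - 1
    bkps = []
    j = n
    for k in range(k_segs, 0, -1):
        i = back[k, j]
        if k > 1:
            bkps.append(int(i))
        j = i
    return sorted(bkps)


def segmentation_cost(X: np.ndarray, bkps: Sequence[int]) -> float:
    s1, s2 = _prefix_sums(X)
    bounds = [0] + sorted(bkps) + [X.shape[0]]
    return sum(_segment_cost(s1, s2, a, b) for a, b in zip(bounds[:-1], bounds[1:]))


def segment_strata(
    tracks: Sequence[WindowTrack],
    n_bkps: int | None = 2,
    penalty: float | None = None,
    method: str = "binseg",
    weights: Sequence[float] | None = None,
) -> list[int]:
    """Segment shared-grid tracks into strata; returns breakpoints in bp.

    Each track is z-scored (NaN imputed from the nearest window) and the
    per-window vectors segmented by least squares.  Either ``n_bkps`` fixes
    the number of breakpoints, or ``penalty`` selects it by minimizing
    cost + n_bkps * penalty (a BIC-style penalty; pass
    ``penalty='bic'`` for 2 * n_tracks * log(n)).  ``method`` is 'binseg' or
    'dp' (exact, small instances).
    """
    X = _stack_tracks(tracks)
    if weights is not None:
        if len(weights) != X.shape[1]:
            raise InputError("one weight per track required")
        X = X * np.sqrt(np.asarray(weights, dtype=float))
    n = X.shape[0]
    algo = {"binseg": binary_segmentation, "dp": dp_segmentation}.get(method)
    if algo is None:
        raise InputError(f"unknown method {method!r}")

    if penalty is not None:
        pen = 2.0 * X.shape[1] * np.log(n) if penalty == "bic" else float(penalty)
        best_k, best_score, best_bkps = 0, segmentation_cost(X, []), []
        for k in range(1, min(n - 1, 10) + 1):
            bkps = algo(X, k)
            score = segmentation_cost(X, bkps) + pen * k
            if score < best_score - 1e-12:
                best_k, best_score, best_bkps = k, score, bkps
        idx = best_bkps
    else:
        idx = algo(X, int(n_bkps))
    window = tracks[0].window_size
    return [int(tracks[0].starts[i]) for i in idx]


def label_strata(
    breakpoints_bp: Sequence[int],
    divergence: WindowTrack,
    depth_ratio: WindowTrack,
    chrom_len: int | None = None,
    par_band: tuple[float, float] = (0.8, 1.2),
) -> list[StratumSegment]:
    """Label segments between breakpoints.

    Segments whose mean female depth ratio falls inside ``par_band`` are PAR
    (still recombining); the rest are ranked by mean Z/W divergence,
    descending, as S1 (oldest), S2, ...  A non-PAR segment with all-NaN
    divergence is labelled UNRANKED.
    """
    window = divergence.window_size
    end = chrom_len if chrom_len is not None else int(divergence.starts[-1] + window)
    bounds = [0] + sorted(int(b) for b in breakpoints_bp) + [end]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = (divergence.starts >= a) & (divergence.starts < b)
        div_vals = divergence.values[sel]
        ratio_vals = depth_ratio.values[
            (depth_ratio.starts >= a) & (depth_ratio.starts < b)
        ]
        mean_div = float(np.nanmean(div_vals)) if np.isfinite(div_vals).any() else np.nan
        mean_ratio = (
            float(np.nanmean(ratio_vals)) if np.isfinite(ratio_vals).any() else np.nan
        )
        segs.append([a, b, mean_div, mean_ratio])

    labelled: list[StratumSegment] = []
    non_par = []
    for a, b, mdiv, mratio in segs:
        if np.isfinite(mratio) and par_band[0] <= mratio <= par_band[1]:
            labelled.append(StratumSegment(a, b, "PAR", mdiv, mratio))
        else:
            non_par.append((a, b, mdiv, mratio))
    ranked = sorted(
        [s for s in non_par if np.isfinite(s[2])], key=lambda s: -s[2]
    )
    rank_of = {(s[0], s[1]): i + 1 for i, s in enumerate(ranked)}
    for a, b, mdiv, mratio in non_par:
        label = f"S{rank_of[(a, b)]}" if (a, b) in rank_of else "UNRANKED"
        labelled.append(StratumSegment(a, b, label, mdiv, mratio))
    return sorted(labelled, key=lambda s: s.start)
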