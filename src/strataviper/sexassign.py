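"""Coverage-based classification of scaffolds as Z-linked, W-linked,
autosomal or unassigned.

A fully Z-linked scaffold is diploid in males (ZZ) and hemizygous in females
(ZW), so its male:female depth ratio — after normalizing each sex by its
autosomal median depth to remove library-size differences — is expected to be
2; scaffolds whose scaled ratio deviates less than 20% from that expectation
(1.6-2.4, boundaries inclusive) are called Z.  W-linked scaffolds are
female-limited: well covered by female reads (>80% of their length) and
nearly absent from the male (<20%).  Scaffolds shorter than 500 bp or with
<80% alignment coverage are excluded from ratio-based calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds; defaults are the published rules."""

    min_len: int = 500
    min_cov: float = 0.8
    z_window: tuple[float, float] = (1.6, 2.4)
    auto_window: tuple[float, float] = (0.8, 1.2)
    w_f_cov: float = 0.8
    w_m_cov: float = 0.2


@dataclass(frozen=True)
class CoverageStats:
    scaffold_id: str
    length: int
    covered_frac_f: float
    covered_frac_m: float
    mean_depth_f: float
    mean_depth_m: float

    def __post_init__(self):
        for name in ("covered_frac_f", "covered_frac_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} out of [0,1] for {self.scaffold_id}")
        if self.mean_depth_f < 0 or self.mean_depth_m < 0:
            raise InputError(f"negative depth for {self.scaffold_id}")


@dataclass(frozen=True)
class SexCall:
    scaffold_id: str
    label: str  # Z / W / AUTO / UNASSIGNED
    mf_scaled_ratio: float
    evidence: str


def _normalize_depth_table(depth: pd.DataFrame) -> pd.DataFrame:
    """Accept either per-base `chrom pos depth` (samtools depth-like) or
    windowed `scaffold start end depth` tables; return the windowed form."""
    cols = list(depth.columns)
    if {"scaffold", "start", "end", "depth"}.issubset(cols):
        return depth[["scaffold", "start", "end", "depth"]]
    if len(cols) == 3:
        out = depth.copy()
        out.columns = ["scaffold", "pos", "depth"]
        out["start"] = out["pos"] - 1
        out["end"] = out["pos"]
        return out[["scaffold", "start", "end", "depth"]]
    raise InputError(
        "depth table must have columns (scaffold,start,end,depth) or "
        "3 columns (chrom,pos,depth)"
    )


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read a depth TSV; header optional for the 3-column per-base form."""
    first = pd.read_csv(path, sep="\t", nrows=1)
    header = 0 if any(not str(c).lstrip("-").isdigit() for c in first.columns) else None
    df = pd.read_csv(path, sep="\t", header=header)
    return _normalize_depth_table(df)


def summarize_coverage(
    depth_f: pd.DataFrame,
    depth_m: pd.DataFrame,
    lengths: Mapping[str, int],
    gap_bp: Mapping[str, int] | None = None,
) -> list[CoverageStats]:
    """Per-scaffold coverage fraction and mean depth for both sexes.

    ``lengths`` must contain every scaffold present in either depth table;
    ``gap_bp`` (assembly gap bases per scaffold) is excluded from coverage
    denominators.  Mean depth is length-weighted over windows; uncovered
    remainder of a scaffold counts as depth 0.
    """
    gap_bp = gap_bp or {}
    per_sex: dict[str, pd.DataFrame] = {}
    for sex, table in (("f", depth_f), ("m", depth_m)):
        t = _normalize_depth_table(table).copy()
        missing = set(t["scaffold"]) - set(lengths)
        if missing:
            raise InputError(
                f"scaffolds in depth table absent from lengths: {sorted(missing)[:5]}"
            )
        t["span"] = t["end"] - t["start"]
        t["bases"] = t["depth"] * t["span"]
        t["cov_bp"] = np.where(t["depth"] >= 1, t["span"], 0)
        per_sex[sex] = t.groupby("scaffold")[["bases", "cov_bp"]].sum()

    out = []
    for scaf in sorted(lengths):
        L = lengths[scaf]
        eff_len = max(L - gap_bp.get(scaf, 0), 1)
        vals = {}
        for sex in ("f", "m"):
            g = per_sex[sex]
            if scaf in g.index:
                vals[f"mean_{sex}"] = float(g.loc[scaf, "bases"]) / eff_len
                vals[f"frac_{sex}"] = min(float(g.loc[scaf, "cov_bp"]) / eff_len, 1.0)
            else:
                vals[f"mean_{sex}"] = 0.0
                vals[f"frac_{sex}"] = 0.0
        out.append(
            CoverageStats(
                scaffold_id=scaf,
                length=L,
                covered_frac_f=vals["frac_f"],
                covered_frac_m=vals["frac_m"],
                mean_depth_f=vals["mean_f"],
                mean_depth_m=vals["mean_m"],
            )
        )
    return out


def scaled_mf_ratio(stats: CoverageStats, norm_f: float, norm_m: float) -> float:
    """Scaled male:female depth ratio, (m/norm_m)/(f/norm_f).

    Each sex is normalized by its autosomal median depth, so an autosomal
    scaffold expects 1 and a fully Z-linked scaffold expects 2 regardless of
    sequencing effort.  Female depth 0 returns +inf (W-absent-from-male cases
    return 0).
    """
    if norm_f <= 0 or norm_m <= 0:
        raise NormalizationError("autosomal median depths must be positive")
    if stats.mean_depth_f == 0:
        return math.inf
    return (stats.mean_depth_m / norm_m) / (stats.mean_depth_f / norm_f)


def classify_scaffold(
    stats: CoverageStats,
    ratio: float,
    thresholds: Thresholds = Thresholds(),
) -> SexCall:
    """Apply the classification rules to one scaffold.

    Order: the W rule first (it depends only on coverage fractions and W
    scaffolds fail male coverage by construction), then the length /
    alignment-coverage eligibility filter, then the Z window, then the AUTO
    window; anything else is UNASSIGNED with the rule trace in ``evidence``.
    """
    t = thresholds
    if stats.covered_frac_f > t.w_f_cov and stats.covered_frac_m < t.w_m_cov:
        return SexCall(stats.scaffold_id, "W", ratio,
                       f"female coverage >{t.w_f_cov:.0%}, male <{t.w_m_cov:.0%}")
    if stats.length < t.min_len:
        return SexCall(stats.scaffold_id, "UNASSIGNED", ratio,
                       f"excluded: length < {t.min_len} bp")
    if stats.covered_frac_f < t.min_cov or stats.covered_frac_m < t.min_cov:
        return SexCall(stats.scaffold_id, "UNASSIGNED", ratio,
                       f"excluded: alignment coverage < {t.min_cov:.0%}")
    if t.z_window[0] <= ratio <= t.z_window[1]:
        return SexCall(stats.scaffold_id, "Z", ratio,
                       f"scaled M:F ratio in [{t.z_window[0]}, {t.z_window[1]}]")
    if t.auto_window[0] <= ratio <= t.auto_window[1]:
        return SexCall(stats.scaffold_id, "AUTO", ratio,
                       f"scaled M:F ratio in [{t.auto_window[0]}, {t.auto_window[1]}]")
    return SexCall(stats.scaffold_id, "UNASSIGNED", ratio,
                   "ratio outside Z and AUTO windows")


def autosomal_norms(
    stats: Sequence[CoverageStats],
    auto_ids: Iterable[str] | None = None,
) -> tuple[float, float]:
    """Median depth per sex over the given scaffolds (all if auto_ids None)."""
    pool = list(stats)
    if auto_ids is not None:
        ids = set(auto_ids)
        pool = [s for s in pool if s.scaffold_id in ids]
    if not pool:
        raise NormalizationError("no scaffolds available for normalization")
    norm_f = float(np.median([s.mean_depth_f for s in pool]))
    norm_m = float(np.median([s.mean_depth_m for s in pool]))
    if norm_f <= 0 or norm_m <= 0:
        raise NormalizationError("autosomal median depth is zero")
    return norm_f, norm_m


def _provisional_autosomes(
    stats: Sequence[CoverageStats], thresholds: Thresholds
) -> list[str]:
    """Pass-1 autosome detection from raw M:F depth ratios (no norms).

    W-like scaffolds are set aside via the coverage-fraction rule; among the
    rest, autosomes form the lowest raw-ratio cluster (Z sits at twice the
    effort ratio), so scaffolds within the AUTO tolerance window of the
    lower-quartile ratio are provisionally autosomal.  Assumes at least ~a
    quarter of eligible scaffolds are autosomal, which holds for any
    genome-representative input.
    """
    t = thresholds
    pool = [
        s for s in stats
        if not (s.covered_frac_f > t.w_f_cov and s.covered_frac_m < t.w_m_cov)
        and s.mean_depth_f > 0 and s.mean_depth_m > 0
        and s.length >= t.min_len
    ]
    if not pool:
        return []
    ratios = np.array([s.mean_depth_m / s.mean_depth_f for s in pool])
    r_ref = float(np.percentile(ratios, 25))
    lo, hi = t.auto_window
    sel = (ratios >= lo * r_ref) & (ratios <= hi * r_ref)
    return [s.scaffold_id for s, keep in zip(pool, sel) if keep]


def classify_all(
    stats: Sequence[CoverageStats],
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[SexCall], dict]:
    """Classify every scaffold with two-pass normalization and summarize.

    Pass 1 finds provisionally autosomal scaffolds without any norm: after
    setting aside W-like scaffolds (the W rule needs no normalization), the
    raw per-scaffold M:F depth ratio clusters at the sequencing-effort ratio
    for autosomes and at twice that for Z-linked scaffolds, so scaffolds
    within 20% of the lower-quartile ratio are provisionally autosomal.
    Pass 2 normalizes each sex by its median depth over that provisional set
    and applies the full rules; this stays correct even when sex-linked
    scaffolds are the majority of the input.  The summary gives scaffold
    count, total bp and N50 per label.
    """
    if not stats:
        raise InputError("empty coverage-stats input")
    stats = sorted(stats, key=lambda s: s.scaffold_id)  # order-invariant

    auto_ids = _provisional_autosomes(stats, thresholds)
    norm_f, norm_m = autosomal_norms(stats, auto_ids if auto_ids else None)
    calls = [
        classify_scaffold(s, scaled_mf_ratio(s, norm_f, norm_m), thresholds)
        for s in stats
    ]

    lengths = {s.scaffold_id: s.length for s in stats}
    summary: dict = {"norm_f": norm_f, "norm_m": norm_m, "labels": {}}
    for label in ("Z", "W", "AUTO", "UNASSIGNED"):
        lens = [lengths[c.scaffold_id] for c in calls if c.label == label]
        summary["labels"][label] = {
            "n": len(lens),
            "total_bp": int(sum(lens)),
            "n50": compute_n50(lens) if lens else 0,
        }
    return calls, summary


def compute_n50(lengths: Sequence[int]) -> int:
    """Largest L such that scaffolds of length >= L total at least half the
    assembly."""
    if not lengths:
        raise InputError("empty length list")
    if any(x <= 0 for x in lengths):
        raise InputError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def build_pseudochromosome(
    order: Sequence[tuple[str, str]],
    sequences: Mapping[str, str],
    gap_n: int = 600,
) -> tuple[str, pd.DataFrame]:
    """Concatenate ordered, oriented scaffolds into a pseudo-chromosome with
    ``gap_n`` 'N's between adjacent scaffolds.

    ``order`` is a sequence of (scaffold_id, orientation) with orientation in
    {'+', '-'}; '-' scaffolds are reverse-complemented.  Returns the sequence
    and an AGP-like coordinate map with each scaffold's half-open interval.
    Output length = sum of scaffold lengths + gap_n * (n - 1).
    """
    seen = set()
    parts: list[str] = []
    rows = []
    pos = 0
    for i, (scaf, orient) in enumerate(order):
        if scaf in seen:
            raise InputError(f"duplicate scaffold id {scaf!r} in order table")
        seen.add(scaf)
        if scaf not in sequences:
            raise InputError(f"no sequence for scaffold {scaf!r}")
        if orient not in ("+", "-"):
            raise InputError(f"orientation must be '+' or '-', got {orient!r}")
        if i > 0:
            parts.append("N" * gap_n)
            pos += gap_n
        seq = sequences[scaf]
        if orient == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        parts.append(seq)
        rows.append((scaf, orient, pos, pos + len(seq)))
        pos += len(seq)
    coord_map = pd.DataFrame(rows, columns=["scaffold", "orientation",
                                            "start", "end"])
    return "".join(parts), coord_map
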