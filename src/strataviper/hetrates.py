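"""Sex-contrasted heterozygosity under depth/quality variant filters.

Variants are kept iff their read depth lies in [10, 120] and their quality is
at least 100 (all bounds inclusive and configurable).  Heterozygosity is
reported as het sites per *callable* site, where callable sites are those
whose depth falls in the same bounds — the female Z of a differentiated ZW
pair is hemizygous, so its het rate collapses toward the error floor while
autosomes show the same rate in both sexes.  Paired per-window rates between
sexes are compared with a Wilcoxon signed-rank test (exact enumeration for
small n, normal approximation with continuity correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_DEPTH_BOUNDS = (10, 120)
DEFAULT_MIN_QUAL = 100.0


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into the variant-table form (scaffold, pos, qual, depth,
    genotype).  GT is parsed from the first sample; any genotype with two
    distinct alleles (0/1, 1/2, ...) is het.  Malformed records are counted
    and reported as a warning, never silently dropped."""
    import pysam

    rows = []
    n_bad = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                sample = rec.samples[0]
                alleles = sample.get("GT", (None,))
                if alleles is None or any(a is None for a in alleles):
                    n_bad += 1
                    continue
                genotype = "het" if len(set(alleles)) > 1 else "hom"
                depth = rec.info.get("DP", None)
                if depth is None:
                    depth = sample.get("DP", 0)
                rows.append(
                    (rec.chrom, rec.pos, float(rec.qual or 0.0), int(depth),
                     genotype)
                )
            except (KeyError, ValueError, IndexError):
                n_bad += 1
    if n_bad:
        warnings.warn(f"{n_bad} malformed VCF records skipped", stacklevel=2)
    return pd.DataFrame(rows,
                        columns=["scaffold", "pos", "qual", "depth", "genotype"])


def filter_variants(
    variants: pd.DataFrame,
    depth_bounds: tuple[int, int] = DEFAULT_DEPTH_BOUNDS,
    min_qual: float = DEFAULT_MIN_QUAL,
) -> pd.DataFrame:
    """Keep variants with depth in [lo, hi] and quality >= min_qual
    (inclusive).  Idempotent."""
    lo, hi = depth_bounds
    keep = (
        (variants["depth"] >= lo)
        & (variants["depth"] <= hi)
        & (variants["qual"] >= min_qual)
    )
    return variants.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class HetRateSummary:
    region_class: str  # AUTO / Z / W
    sex: str
    n_callable: int
    n_het: int

    @property
    def rate(self) -> float:
        return self.n_het / self.n_callable if self.n_callable else float("nan")

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.rate

    @property
    def defined(self) -> bool:
        return self.n_callable > 0


def callable_sites(
    depth: pd.DataFrame,
    region_map: Mapping[str, str],
    depth_bounds: tuple[int, int] = DEFAULT_DEPTH_BOUNDS,
) -> dict[str, int]:
    """Callable sites per region class from a windowed depth table: the sum
    of window lengths whose depth lies within the variant-filter bounds."""
    lo, hi = depth_bounds
    d = depth.copy()
    d["region"] = d["scaffold"].map(region_map)
    d = d.dropna(subset=["region"])
    ok = (d["depth"] >= lo) & (d["depth"] <= hi)
    d["callable"] = np.where(ok, d["end"] - d["start"], 0)
    return d.groupby("region")["callable"].sum().astype(int).to_dict()


def het_rate(
    variants: pd.DataFrame,
    n_callable: Mapping[str, int],
    region_map: Mapping[str, str],
    sex: str,
) -> list[HetRateSummary]:
    """One heterozygosity summary per region class for one sex.

    ``variants`` should already be filtered; het sites on scaffolds absent
    from ``region_map`` are ignored.  A class with zero callable sites yields
    a summary flagged undefined (rate NaN)."""
    v = variants.copy()
    v["region"] = v["scaffold"].map(region_map)
    hets = (
        v.loc[(v["genotype"] == "het") & v["region"].notna()]
        .groupby("region")
        .size()
        .to_dict()
    )
    out = []
    for region in sorted(set(n_callable) | set(hets)):
        out.append(
            HetRateSummary(
                region_class=region,
                sex=sex,
                n_callable=int(n_callable.get(region, 0)),
                n_het=int(hets.get(region, 0)),
            )
        )
    return out


def windowed_het_rates(
    variants: pd.DataFrame,
    depth: pd.DataFrame,
    scaffolds: Sequence[str],
    window_size: int = 1_000_000,
    depth_bounds: tuple[int, int] = DEFAULT_DEPTH_BOUNDS,
) -> pd.DataFrame:
    """Per-window het rates over the given scaffolds (pairing unit for the
    signed-rank test).  Returns columns scaffold, window_start, n_callable,
    n_het, rate; windows with no callable sites are dropped."""
    scafs = set(scaffolds)
    lo, hi = depth_bounds
    d = depth.loc[depth["scaffold"].isin(scafs)].copy()
    d["window_start"] = (d["start"] // window_size) * window_size
    ok = (d["depth"] >= lo) & (d["depth"] <= hi)
    d["callable"] = np.where(ok, d["end"] - d["start"], 0)
    call = d.groupby(["scaffold", "window_start"])["callable"].sum()

    v = variants.loc[
        variants["scaffold"].isin(scafs) & (variants["genotype"] == "het")
    ].copy()
    v["window_start"] = ((v["pos"] - 1) // window_size) * window_size
    hets = v.groupby(["scaffold", "window_start"]).size()

    df = pd.DataFrame({"n_callable": call}).fillna(0)
    df["n_het"] = hets.reindex(df.index).fillna(0).astype(int)
    df = df.loc[df["n_callable"] > 0]
    df["rate"] = df["n_het"] / df["n_callable"]
    return df.reset_index()


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


def _exact_sf_table(ranks: np.ndarray) -> tuple[np.ndarray, float]:
    """Distribution of W+ over all sign assignments via DP convolution.

    Tied ranks are mid-ranks (multiples of 0.5), so ranks are doubled to
    integers; returns (pmf over doubled W+ values 0..sum, doubling factor)."""
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf, 2.0


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_max_n: int = 25,
) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are excluded (Wilcoxon's original rule); ties in
    |difference| get mid-ranks.  With ``mode='auto'`` the exact null
    distribution (DP enumeration over sign assignments) is used for
    n <= ``exact_max_n`` and the normal approximation with continuity and tie
    correction beyond that.  If every difference is zero, p = 1 with a
    warning.

    Returns dict with keys ``statistic`` (W+), ``pvalue``, ``n`` (nonzero
    pairs) and ``method``.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return {"statistic": 0.0, "pvalue": 1.0, "n": 0, "method": "degenerate"}
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= exact_max_n)
    if mode not in ("auto", "exact", "approx"):
        raise InputError(f"unknown mode {mode!r}")
    if use_exact:
        pmf, scale = _exact_sf_table(ranks)
        w2 = int(round(w_plus * scale))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        diff = w_plus - mean
        cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
        z = (diff - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal-approx"
    return {"statistic": w_plus, "pvalue": p, "n": int(n), "method": method}


def compare_het(rates_a: Sequence[float], rates_b: Sequence[float],
                min_pairs: int = 6) -> dict:
    """Signed-rank comparison of paired per-window het rates of two samples
    (e.g. female vs male Z windows)."""
    if len(rates_a) != len(rates_b):
        raise InputError("windowed rates must be paired (equal length)")
    if len(rates_a) < min_pairs:
        raise InputError(f"need at least {min_pairs} paired windows")
    return wilcoxon_signed_rank(rates_a, rates_b)
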