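"""Synthetic ZW genome generator with known ground truth.

Emulates the data a two-individual (one male ZZ, one female ZW) resequencing
study of a snake-like genome produces, at the level the downstream analyses
consume: windowed read depths, variant tables, Z/W gametolog alignments,
intergenic Z/W alignment fragments, repeat annotations and k-mer spectra.

The female Z is hemizygous and the W is female-limited, so expected window
depth is Poisson with mean ``copy_number/2 * mean_depth``.  The Z carries
evolutionary strata: contiguous blocks whose Z-W divergence reflects the time
since recombination stopped in that block.  The default preset mirrors a
viper-like 77-Mb Z with three strata laid out S2 (0-42 Mb), S1 (42-56 Mb,
oldest) and S3 (56 Mb-end, youngest); identifiable W-derived fragments are
densest in the youngest stratum, while the oldest stratum carries the most,
and the most diverged, Gypsy-class repeats.

Everything is deterministic under ``SimConfig.seed``: independent named
substreams are derived from the seed so each product (depths, variants, ...)
is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .kmersize import KmerHistogram, write_histogram

# named RNG substreams, all spawned from SimConfig.seed
_STREAMS = {
    "genome": 1,
    "depth_F": 2,
    "depth_M": 3,
    "variants_F": 4,
    "variants_M": 5,
    "gametologs": 6,
    "kmer": 7,
    "repeats": 8,
    "walign": 9,
    "sequence": 10,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def jc_distance(p: float) -> float:
    """Jukes-Cantor substitutions/site for an observed proportion p of
    differing sites: d = -3/4 ln(1 - 4p/3)."""
    if not 0 <= p < 0.75:
        raise ValueError(f"p-distance {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_p(d: float) -> float:
    """Expected p-distance after evolving a JC distance of d subs/site."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass(frozen=True)
class SimConfig:
    """All generative quantities of a synthetic ZW study.

    Defaults are the viper-like preset: a 77-Mb Z with strata boundaries at
    42 and 56 Mb, 80x sequencing of each sex, autosomal per-site
    heterozygosity 0.1%, and three advanced-snake-like species whose splits
    postdate every recombination-suppression event (shared strata).

    ``stratum_divergence`` maps stratum labels to target Z-W *p*-distances and
    must be non-increasing in age rank (S1 oldest); ``strata_layout`` gives
    the positional order of those labels along the Z.  Species are
    ``(label, split_depth)`` pairs, split depths in substitutions/site from
    the present, resolved as a caterpillar tree (deepest split first).
    """

    n_autosomes: int = 2
    autosome_len: int = 20_000_000
    z_len: int = 77_000_000
    strata_boundaries: tuple[int, ...] = (42_000_000, 56_000_000)
    strata_layout: tuple[str, ...] = ("S2", "S1", "S3")
    stratum_divergence: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 0.25, "S2": 0.15, "S3": 0.05}
    )
    par_fraction: float = 0.0
    mean_depth_f: float = 80.0
    mean_depth_m: float = 80.0
    het_auto: float = 0.001
    het_z_male: float = 0.0008
    seq_error: float = 0.001
    mismap_rate: float = 0.0
    w_disruption_rate: float = 4.0
    n_gametolog_genes: int = 24
    gametolog_len: int = 1200
    species: tuple[tuple[str, float], ...] = (
        ("garter", 0.012),
        ("cobra", 0.008),
        ("viper", 0.008),
    )
    k: int = 17
    scaffold_len: int = 1_000_000
    depth_window: int = 1_000
    w_frag_density: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 0.05, "S2": 0.15, "S3": 0.5}
    )
    w_frag_mean_len: int = 50_000
    w_aln_max_len: int = 2_000
    gypsy_density: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 0.35, "S2": 0.15, "S3": 0.08}
    )
    repeat_divergence_mean: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 0.18, "S2": 0.10, "S3": 0.06}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_autosomes < 1:
            raise ConfigError("n_autosomes: must be >= 1")
        for name in ("autosome_len", "z_len", "scaffold_len", "depth_window",
                     "gametolog_len", "w_frag_mean_len", "w_aln_max_len", "k"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        if self.gametolog_len % 3 != 0 or self.gametolog_len < 9:
            raise ConfigError("gametolog_len: must be a multiple of 3, >= 9")
        b = self.strata_boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigError("strata_boundaries: must be strictly increasing")
        if b and b[-1] >= self.non_par_len:
            raise ConfigError(
                "strata_boundaries: must lie inside the non-PAR part of the Z"
            )
        if len(self.strata_layout) != len(b) + 1:
            raise ConfigError(
                "strata_layout: needs exactly len(strata_boundaries)+1 labels"
            )
        missing = [s for s in self.strata_layout if s not in self.stratum_divergence]
        if missing:
            raise ConfigError(f"stratum_divergence: missing labels {missing}")
        ranked = sorted(self.strata_layout)  # S1, S2, ... age rank order
        divs = [self.stratum_divergence[s] for s in ranked]
        if any(divs[i] < divs[i + 1] for i in range(len(divs) - 1)):
            raise ConfigError(
                "stratum_divergence: must be non-increasing from S1 (oldest)"
            )
        for name in ("par_fraction", "het_auto", "het_z_male", "seq_error",
                     "mismap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")
        for s, p in self.stratum_divergence.items():
            if not 0.0 <= p < 0.75:
                raise ConfigError(f"stratum_divergence[{s}]: must be in [0, 0.75)")
        if self.mean_depth_f <= 0 or self.mean_depth_m <= 0:
            raise ConfigError("mean_depth_f/mean_depth_m: must be positive")
        if len(self.species) < 1:
            raise ConfigError("species: at least one required")
        names = [s for s, _ in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("species: duplicate labels")

    @property
    def non_par_len(self) -> int:
        return int(round(self.z_len * (1.0 - self.par_fraction)))

    @property
    def stratum_age(self) -> dict[str, float]:
        """Time (subs/site from the present) of each stratum's Z-W split;
        half the JC distance corresponding to the target p-distance."""
        return {s: jc_distance(p) / 2.0 for s, p in self.stratum_divergence.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stratum_divergence"] = dict(self.stratum_divergence)
        d["w_frag_density"] = dict(self.w_frag_density)
        d["gypsy_density"] = dict(self.gypsy_density)
        d["repeat_divergence_mean"] = dict(self.repeat_divergence_mean)
        return d


@dataclass(frozen=True)
class Scaffold:
    id: str
    length: int
    true_label: str  # AUTO / Z / W
    chrom: str
    chrom_start: int
    stratum: str | None = None
    in_par: bool = False

    @property
    def chrom_end(self) -> int:
        return self.chrom_start + self.length


@dataclass(frozen=True)
class GenomeModel:
    """Ground-truth scaffold layout: which scaffolds are autosomal, Z-linked
    (with their stratum) or identifiable W-derived fragments (anchored at
    their homologous Z coordinates)."""

    scaffolds: tuple[Scaffold, ...]
    strata_map: tuple[tuple[int, int, str], ...]
    config: SimConfig

    def by_label(self, label: str) -> list[Scaffold]:
        return [s for s in self.scaffolds if s.true_label == label]

    def stratum_at(self, z_pos: int) -> str:
        for start, end, name in self.strata_map:
            if start <= z_pos < end:
                return name
        raise InputError(f"Z position {z_pos} outside [0, z_len)")


def _tile(total: int, piece: int) -> list[tuple[int, int]]:
    starts = list(range(0, total, piece))
    return [(s, min(s + piece, total)) for s in starts]


def _place_fragments(rng, seg_start, seg_end, density, mean_len):
    """Non-overlapping intervals covering ~density of [seg_start, seg_end),
    placed by random spacings so the target coverage is hit exactly."""
    seg_len = seg_end - seg_start
    target = density * seg_len
    if target < 1:
        return []
    lens = []
    while sum(lens) < target:
        lens.append(int(np.clip(rng.exponential(mean_len), 5_000, 200_000)))
    # trim the last fragment to land on the target coverage
    excess = sum(lens) - int(target)
    if lens[-1] - excess >= 5_000:
        lens[-1] -= excess
    slack = seg_len - sum(lens)
    if slack < 0:  # density too high for this segment; drop fragments
        while slack < 0 and lens:
            slack += lens.pop()
    gaps = rng.random(len(lens) + 1)
    gaps = gaps / gaps.sum() * slack
    out, pos = [], float(seg_start)
    for g, ln in zip(gaps, lens):
        pos += g
        out.append((int(pos), int(pos) + ln))
        pos += ln
    return out


def simulate_genome(config: SimConfig) -> GenomeModel:
    """Lay out autosomal, Z and W scaffolds plus the stratum map.

    Z scaffolds partition [0, z_len); W scaffolds are the identifiable
    W-derived fragments, present only for non-PAR strata, anchored on Z
    coordinates with per-stratum density (younger strata retain more
    alignable W sequence).
    """
    config.validate()
    rng = _rng(config, "genome")

    bounds = (0,) + tuple(config.strata_boundaries) + (config.non_par_len,)
    strata: list[tuple[int, int, str]] = [
        (bounds[i], bounds[i + 1], config.strata_layout[i])
        for i in range(len(config.strata_layout))
    ]
    if config.non_par_len < config.z_len:
        strata.append((config.non_par_len, config.z_len, "PAR"))

    scaffolds: list[Scaffold] = []
    for a in range(config.n_autosomes):
        chrom = f"chr{a + 1}"
        for i, (s, e) in enumerate(_tile(config.autosome_len, config.scaffold_len)):
            scaffolds.append(
                Scaffold(f"{chrom}_scaf{i:04d}", e - s, "AUTO", chrom, s)
            )
    for i, (s, e) in enumerate(_tile(config.z_len, config.scaffold_len)):
        mid = (s + e) // 2
        stratum = next(name for a, b, name in strata if a <= mid < b)
        scaffolds.append(
            Scaffold(
                f"Z_scaf{i:04d}", e - s, "Z", "chrZ", s,
                stratum=None if stratum == "PAR" else stratum,
                in_par=stratum == "PAR",
            )
        )
    w_i = 0
    for seg_start, seg_end, name in strata:
        if name == "PAR":
            continue
        dens = config.w_frag_density.get(name, 0.0)
        for fs, fe in _place_fragments(rng, seg_start, seg_end, dens,
                                       config.w_frag_mean_len):
            scaffolds.append(
                Scaffold(f"W_scaf{w_i:04d}", fe - fs, "W", "chrZ", fs,
                         stratum=name)
            )
            w_i += 1

    return GenomeModel(tuple(scaffolds), tuple(strata), config)


def _copy_number(scaffold: Scaffold, sex: str) -> float:
    if scaffold.true_label == "AUTO" or scaffold.in_par:
        return 2.0
    if scaffold.true_label == "Z":
        return 2.0 if sex == "M" else 1.0
    if scaffold.true_label == "W":
        return 0.0 if sex == "M" else 1.0
    raise InputError(f"unknown scaffold label {scaffold.true_label!r}")


def _check_sex(sex: str) -> str:
    if sex not in ("M", "F"):
        raise InputError(f"unknown sex label {sex!r}; expected 'M' or 'F'")
    return sex


def simulate_depth(model: GenomeModel, sex: str, config: SimConfig | None = None
                   ) -> pd.DataFrame:
    """Per-window sequencing depth for one sex.

    Window depth ~ Poisson(copy_number/2 * mean_depth): autosomes are diploid
    in both sexes, the (non-PAR) Z is diploid in males and hemizygous in
    females, the W is female-limited (male depth 0, plus optional mismapping
    noise at ``mismap_rate * mean_depth_m``).

    Returns a DataFrame with columns ``scaffold, start, end, depth``.
    """
    config = config or model.config
    _check_sex(sex)
    rng = _rng(config, f"depth_{sex}")
    mean_depth = config.mean_depth_m if sex == "M" else config.mean_depth_f

    scaf_col, start_col, end_col, lam_col = [], [], [], []
    for sc in model.scaffolds:
        windows = _tile(sc.length, config.depth_window)
        lam = _copy_number(sc, sex) / 2.0 * mean_depth
        if sc.true_label == "W" and sex == "M":
            lam += config.mismap_rate * mean_depth
        scaf_col.extend([sc.id] * len(windows))
        start_col.extend(w[0] for w in windows)
        end_col.extend(w[1] for w in windows)
        lam_col.extend([lam] * len(windows))
    lam_arr = np.asarray(lam_col)
    depth = rng.poisson(lam_arr)
    return pd.DataFrame(
        {"scaffold": scaf_col, "start": start_col, "end": end_col, "depth": depth}
    )


def _true_het_rate(scaffold: Scaffold, sex: str, config: SimConfig) -> float:
    if scaffold.true_label == "AUTO" or scaffold.in_par:
        return config.het_auto
    if scaffold.true_label == "Z":
        return config.het_z_male if sex == "M" else 0.0
    return 0.0  # single-copy W: true heterozygosity impossible


def simulate_variants(model: GenomeModel, sex: str,
                      config: SimConfig | None = None) -> pd.DataFrame:
    """Variant table for one sex (columns: scaffold, pos, ref, alt, qual,
    depth, genotype).

    True heterozygous sites arise at ``het_auto`` on diploid sequence (and
    ``het_z_male`` on the male Z); hemizygous female Z and single-copy W never
    carry true heterozygotes — only error-driven apparent hets at
    ``seq_error`` per site, with low quality scores.  Homozygous-alt variants
    occur at ``het_auto/2`` on any present sequence.  Per-variant depth is
    Poisson as in :func:`simulate_depth`; quality decreases with error
    evidence (true variants ~N(250,40), error calls ~N(40,15)).
    """
    config = config or model.config
    _check_sex(sex)
    rng = _rng(config, f"variants_{sex}")
    mean_depth = config.mean_depth_m if sex == "M" else config.mean_depth_f

    rows: list[pd.DataFrame] = []
    for sc in model.scaffolds:
        copy = _copy_number(sc, sex)
        if copy == 0:
            continue
        lam = copy / 2.0 * mean_depth
        classes = (
            ("het", _true_het_rate(sc, sex, config), 250.0, 40.0),
            ("hom", config.het_auto / 2.0, 250.0, 40.0),
            ("het", config.seq_error, 40.0, 15.0),  # error-driven
        )
        pos_list, gt_list, qual_list = [], [], []
        for gt, rate, qmean, qsd in classes:
            if rate <= 0:
                continue
            n = rng.binomial(sc.length, rate)
            if n == 0:
                continue
            pos = rng.choice(sc.length, size=n, replace=False) + 1
            pos_list.append(pos)
            gt_list.append(np.repeat(gt, n))
            qual_list.append(np.clip(rng.normal(qmean, qsd, n), 1.0, None))
        if not pos_list:
            continue
        pos = np.concatenate(pos_list)
        gt = np.concatenate(gt_list)
        qual = np.concatenate(qual_list)
        # drop duplicate positions across classes (keep first)
        _, keep = np.unique(pos, return_index=True)
        pos, gt, qual = pos[keep], gt[keep], qual[keep]
        n = pos.size
        ref_i = rng.integers(0, 4, n)
        alt_i = (ref_i + rng.integers(1, 4, n)) % 4
        rows.append(
            pd.DataFrame(
                {
                    "scaffold": sc.id,
                    "pos": pos,
                    "ref": _BASES[ref_i].astype("U1"),
                    "alt": _BASES[alt_i].astype("U1"),
                    "qual": np.round(qual, 2),
                    "depth": rng.poisson(lam, n),
                    "genotype": gt,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["scaffold", "pos", "ref", "alt", "qual", "depth", "genotype"]
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["scaffold", "pos"], ignore_index=True)


# ---------------------------------------------------------------------------
# gametologs


@dataclass(frozen=True)
class Disruption:
    kind: str  # "premature_stop" | "frameshift"
    z_pos: int  # 0-based position in Z CDS coordinates (codon start for stops)


@dataclass(frozen=True)
class SimulatedGene:
    gene_id: str
    stratum: str
    target_divergence: float
    z_anchor: tuple[int, int]
    seqs: dict[str, str]  # tip name ("{species}_Z"/"{species}_W") -> aligned seq
    disruptions: dict[str, tuple[Disruption, ...]]  # species -> truth


@dataclass(frozen=True)
class GametologSet:
    genes: tuple[SimulatedGene, ...]
    config: SimConfig


def _random_orf(rng: np.random.Generator, length: int) -> np.ndarray:
    """ATG + random non-stop codons + TAA, as a char array."""
    n_codons = length // 3
    seq = np.empty(length, dtype="S1")
    seq[:3] = np.frombuffer(b"ATG", dtype="S1")
    for c in range(1, n_codons - 1):
        while True:
            codon = _BASES[rng.integers(0, 4, 3)]
            if codon.tobytes().decode() not in _STOPS:
                break
        seq[3 * c:3 * c + 3] = codon
    seq[-3:] = np.frombuffer(b"TAA", dtype="S1")
    return seq


def _evolve_cds(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One-step Jukes-Cantor evolution by d subs/site with exact expected
    p-distance 3/4(1-exp(-4d/3)); conditional on change, the new base is
    uniform over the other three.  Start and terminal codons are frozen and
    substitutions creating an internal in-frame stop are reverted, modelling
    purifying selection on intact reading frames."""
    if d <= 0:
        return seq.copy()
    p = jc_p(d)
    out = seq.copy()
    hit = rng.random(seq.size) < p
    hit[:3] = False
    hit[-3:] = False
    idx = np.nonzero(hit)[0]
    if idx.size:
        cur = np.searchsorted(_BASES, out[idx])
        new = (cur + rng.integers(1, 4, idx.size)) % 4
        out[idx] = _BASES[new]
    # revert substitutions that created an internal stop codon
    n_codons = seq.size // 3
    codons = out[: 3 * n_codons].reshape(n_codons, 3)
    strs = codons.view("S3").ravel()
    for c in range(1, n_codons - 1):
        if strs[c].decode() in _STOPS:
            out[3 * c:3 * c + 3] = seq[3 * c:3 * c + 3]
    return out


def _evolve_clade(anc: np.ndarray, species: Sequence[tuple[str, float]],
                  root_age: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve a clade from its root (at ``root_age``) down a caterpillar
    species tree given (label, split_depth) pairs; every tip sits at total
    path length ``root_age`` from the root."""
    ordered = sorted(species, key=lambda st: -st[1])
    tips: dict[str, np.ndarray] = {}
    node = anc
    age = root_age
    for i, (name, t) in enumerate(ordered):
        if i == len(ordered) - 1:
            tips[name] = _evolve_cds(node, age, rng)
            break
        t = min(t, age)
        node = _evolve_cds(node, age - t, rng)
        tips[name] = _evolve_cds(node, t, rng)
        age = t
    return tips


def _apply_disruptions(seq: np.ndarray, rate: float, divergence: float,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, tuple[Disruption, ...]]:
    """Insert ORF disruptions into a W copy: Poisson(rate*divergence) events,
    each with equal probability a single-base deletion (frameshift, shown as
    an alignment gap) or a stop-codon substitution, at distinct interior
    codons."""
    n_codons = seq.size // 3
    n = rng.poisson(rate * divergence)
    n = min(n, max(n_codons - 2, 0))
    if n == 0:
        return seq, ()
    out = seq.astype("S1").copy()
    codons = rng.choice(np.arange(1, n_codons - 1), size=n, replace=False)
    events = []
    for c in sorted(int(x) for x in codons):
        if rng.random() < 0.5:
            stop = _STOPS[rng.integers(0, len(_STOPS))]
            out[3 * c:3 * c + 3] = np.frombuffer(stop.encode(), dtype="S1")
            events.append(Disruption("premature_stop", 3 * c))
        else:
            off = int(rng.integers(0, 3))
            out[3 * c + off] = b"-"
            events.append(Disruption("frameshift", 3 * c + off))
    return out, tuple(events)


def simulate_gametologs(config: SimConfig,
                        model: GenomeModel | None = None) -> GametologSet:
    """Aligned Z/W CDS pairs for every species and gene, with ground truth.

    For each gene the Z and W copies split at their stratum's age and the
    species split afterwards (shared strata) within each clade, so the Z-W
    divergence matches the stratum target for every species pair while Z
    copies of different species stay mutually closer.  W copies additionally
    acquire frameshift/premature-stop disruptions at
    ``w_disruption_rate * divergence`` expected events per gene.
    """
    config.validate()
    if model is None:
        model = simulate_genome(config)
    rng = _rng(config, "gametologs")
    non_par = [seg for seg in model.strata_map if seg[2] != "PAR"]
    ages = config.stratum_age
    genes = []
    for g in range(config.n_gametolog_genes):
        seg_start, seg_end, stratum = non_par[g % len(non_par)]
        p_target = config.stratum_divergence[stratum]
        anchor_start = int(rng.integers(seg_start, max(seg_start + 1,
                                                       seg_end - config.gametolog_len)))
        anc = _random_orf(rng, config.gametolog_len)
        root_age = ages[stratum]
        z_anc = anc if root_age == 0 else anc
        z_tips = _evolve_clade(z_anc, config.species, root_age, rng)
        w_tips = _evolve_clade(anc, config.species, root_age, rng)
        seqs: dict[str, str] = {}
        disruptions: dict[str, tuple[Disruption, ...]] = {}
        for sp, _ in config.species:
            seqs[f"{sp}_Z"] = z_tips[sp].tobytes().decode()
            w_seq, events = _apply_disruptions(
                w_tips[sp], config.w_disruption_rate, p_target, rng
            )
            seqs[f"{sp}_W"] = w_seq.tobytes().decode()
            disruptions[sp] = events
        genes.append(
            SimulatedGene(
                gene_id=f"gene{g:04d}",
                stratum=stratum,
                target_divergence=p_target,
                z_anchor=(anchor_start, anchor_start + config.gametolog_len),
                seqs=seqs,
                disruptions=disruptions,
            )
        )
    return GametologSet(tuple(genes), config)


# ---------------------------------------------------------------------------
# intergenic Z/W alignments, repeats, k-mer spectrum


@dataclass(frozen=True)
class WAlignment:
    """A representative intergenic Z/W alignment for one W fragment, anchored
    at the fragment's homologous Z interval (first ``w_aln_max_len`` bp)."""

    z_start: int
    z_end: int
    stratum: str
    seq_z: str
    seq_w: str


def simulate_zw_alignments(model: GenomeModel,
                           config: SimConfig | None = None) -> list[WAlignment]:
    """One ungapped alignment per W fragment whose realized p-distance equals
    the fragment's stratum divergence in expectation (per-site difference
    probability = target p)."""
    config = config or model.config
    rng = _rng(config, "walign")
    out = []
    for sc in model.by_label("W"):
        p = config.stratum_divergence[sc.stratum]
        L = min(sc.length, config.w_aln_max_len)
        z = _BASES[rng.integers(0, 4, L)]
        w = z.copy()
        hit = np.nonzero(rng.random(L) < p)[0]
        if hit.size:
            cur = np.searchsorted(_BASES, w[hit])
            w[hit] = _BASES[(cur + rng.integers(1, 4, hit.size)) % 4]
        out.append(
            WAlignment(sc.chrom_start, sc.chrom_start + L, sc.stratum,
                       z.tobytes().decode(), w.tobytes().decode())
        )
    return out


def simulate_repeats(model: GenomeModel,
                     config: SimConfig | None = None) -> pd.DataFrame:
    """Repeat annotation (BED6+2-shaped DataFrame) for the Z chromosome and
    autosomes.  Gypsy density and divergence-from-consensus are highest in
    the oldest stratum; autosomes/PAR get the youngest-stratum baseline."""
    config = config or model.config
    rng = _rng(config, "repeats")
    youngest = min(config.stratum_divergence, key=config.stratum_divergence.get)
    regions: list[tuple[str, int, int, str]] = [
        ("chrZ", s, e, name) for s, e, name in model.strata_map
    ]
    for a in range(config.n_autosomes):
        regions.append((f"chr{a + 1}", 0, config.autosome_len, youngest))
    rows = []
    for chrom, s, e, stratum in regions:
        key = youngest if stratum == "PAR" else stratum
        for fam, dens_scale in (("Gypsy", 1.0), ("CR1", 0.5)):
            dens = config.gypsy_density.get(key, 0.05) * dens_scale
            mean_div = config.repeat_divergence_mean.get(key, 0.08)
            for fs, fe in _place_fragments(rng, s, e, dens, 3_000):
                div = float(np.clip(rng.normal(mean_div, 0.03), 0.0, 0.5))
                rows.append((chrom, fs, fe, fam, 0, "+", fam, round(div, 4)))
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "family", "divergence"],
    )
    return df.sort_values(["chrom", "start"], ignore_index=True)


def simulate_kmer_histogram(config: SimConfig,
                            genome_size: int | None = None,
                            depth: float | None = None) -> KmerHistogram:
    """Male-like k-mer spectrum: an error spike at low depth plus a
    Poisson-shaped main peak.

    A per-base error rate ``e`` corrupts a fraction ``1-(1-e)^k`` of k-mer
    instances; those instances move from the main peak into near-singleton
    error k-mers, so total k-mer instances stay ~= genome_size * depth.
    """
    config.validate()
    from scipy import stats

    G = genome_size if genome_size is not None else (
        config.n_autosomes * config.autosome_len + config.z_len
    )
    lam = depth if depth is not None else config.mean_depth_m
    if lam <= 0:
        raise InputError("k-mer depth must be positive")
    rng = _rng(config, "kmer")
    f_err = 1.0 - (1.0 - config.seq_error) ** config.k
    lam_eff = lam * (1.0 - f_err)
    dmax = int(lam_eff + 10 * math.sqrt(lam_eff) + 10)
    depths = np.arange(1, dmax + 1)
    expected = G * stats.poisson.pmf(depths, lam_eff)
    counts = rng.poisson(expected).astype(np.int64)
    if f_err > 0:
        n_err_instances = G * lam * f_err
        rho = 0.3
        a = n_err_instances * (1 - rho) ** 2
        for d in range(1, 9):
            counts[d - 1] += rng.poisson(a * rho ** (d - 1))
    entries = {int(d): int(c) for d, c in zip(depths, counts) if c > 0}
    return KmerHistogram(k=config.k, entries=entries)


# ---------------------------------------------------------------------------
# bundle output


@dataclass
class SimBundle:
    """Everything one synthetic study produces, held in memory."""

    model: GenomeModel
    depth_f: pd.DataFrame
    depth_m: pd.DataFrame
    variants_f: pd.DataFrame
    variants_m: pd.DataFrame
    gametologs: GametologSet
    walignments: list[WAlignment]
    repeats: pd.DataFrame
    kmer_histogram: KmerHistogram

    @property
    def config(self) -> SimConfig:
        return self.model.config


def generate_bundle(config: SimConfig) -> SimBundle:
    """Run every generator under one config (deterministic in config.seed)."""
    model = simulate_genome(config)
    return SimBundle(
        model=model,
        depth_f=simulate_depth(model, "F"),
        depth_m=simulate_depth(model, "M"),
        variants_f=simulate_variants(model, "F"),
        variants_m=simulate_variants(model, "M"),
        gametologs=simulate_gametologs(config, model),
        walignments=simulate_zw_alignments(model),
        repeats=simulate_repeats(model),
        kmer_histogram=simulate_kmer_histogram(config),
    )


def _write_fasta(model: GenomeModel, path: Path, rng: np.random.Generator) -> None:
    with open(path, "w") as fh:
        for sc in model.scaffolds:
            seq = _BASES[rng.integers(0, 4, sc.length)].tobytes().decode()
            fh.write(f">{sc.id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def _write_vcf(variants: pd.DataFrame, scaffolds: Iterable[Scaffold],
               sample: str, path: Path) -> None:
    lengths = {sc.id: sc.length for sc in scaffolds}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf in sorted(set(variants["scaffold"])):
            fh.write(f"##contig=<ID={scaf},length={lengths.get(scaf, 0)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for row in variants.itertuples(index=False):
            gt = "0/1" if row.genotype == "het" else "1/1"
            fh.write(
                f"{row.scaffold}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual}\t.\tDP={row.depth}\tGT\t{gt}\n"
            )


def write_bundle(bundle: SimBundle, outdir: str | Path,
                 include_fasta: bool = True) -> dict[str, Path]:
    """Write the bundle to text files.

    Produces scaffold FASTA (random sequence, layout per the model), per-sex
    depth TSVs and VCFs, repeat BED, per-gene aligned gametolog FASTAs,
    intergenic Z/W alignment TSV, k-mer histo, and a ground-truth JSON with
    every scaffold's true label, the stratum map and all simulated ORF
    disruptions.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {outdir}: {exc}") from exc
    model = bundle.model
    files: dict[str, Path] = {}

    if include_fasta:
        files["fasta"] = outdir / "scaffolds.fa"
        _write_fasta(model, files["fasta"], _rng(bundle.config, "sequence"))

    for sex, depth in (("f", bundle.depth_f), ("m", bundle.depth_m)):
        p = outdir / f"depth_{sex}.tsv"
        depth.to_csv(p, sep="\t", index=False)
        files[f"depth_{sex}"] = p
    for sex, var in (("f", bundle.variants_f), ("m", bundle.variants_m)):
        p = outdir / f"variants_{sex}.vcf"
        _write_vcf(var, model.scaffolds, f"sample_{sex}", p)
        files[f"variants_{sex}"] = p

    p = outdir / "repeats.bed"
    bundle.repeats.to_csv(p, sep="\t", index=False, header=False)
    files["repeats"] = p

    gdir = outdir / "gametologs"
    gdir.mkdir(exist_ok=True)
    for gene in bundle.gametologs.genes:
        with open(gdir / f"{gene.gene_id}.fasta", "w") as fh:
            for tip in sorted(gene.seqs):
                fh.write(f">{tip}\n{gene.seqs[tip]}\n")
    files["gametologs_dir"] = gdir

    p = outdir / "zw_alignments.tsv"
    pd.DataFrame(
        [
            (a.z_start, a.z_end, a.stratum, a.seq_z, a.seq_w)
            for a in bundle.walignments
        ],
        columns=["z_start", "z_end", "stratum", "seq_z", "seq_w"],
    ).to_csv(p, sep="\t", index=False)
    files["zw_alignments"] = p

    files["histo"] = outdir / "male.histo"
    write_histogram(bundle.kmer_histogram, files["histo"])

    truth = {
        "config": bundle.config.to_dict(),
        "strata_map": [list(seg) for seg in model.strata_map],
        "scaffolds": [
            {
                "id": sc.id, "length": sc.length, "label": sc.true_label,
                "chrom": sc.chrom, "chrom_start": sc.chrom_start,
                "stratum": sc.stratum, "in_par": sc.in_par,
            }
            for sc in model.scaffolds
        ],
        "gametologs": [
            {
                "gene_id": g.gene_id, "stratum": g.stratum,
                "target_divergence": g.target_divergence,
                "z_anchor": list(g.z_anchor),
                "disruptions": {
                    sp: [[d.kind, d.z_pos] for d in evs]
                    for sp, evs in g.disruptions.items()
                },
            }
            for g in bundle.gametologs.genes
        ],
    }
    files["truth"] = outdir / "truth.json"
    with open(files["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return files
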