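"""End-to-end orchestration of the synthetic study.

``run_all`` chains simulate -> sex-assign -> het -> strata -> gametologs ->
k-mer size on one generated bundle and returns a machine-readable summary
including recovered strata versus ground truth.  W-fragment anchor
coordinates and scaffold chromosome placements come from the simulation's
ground truth (in a real study these come from homology mapping, which is out
of scope here).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import gametologs as gm
from . import hetrates, kmersize, sexassign, simzw, strata


def small_preset(seed: int = 0, **overrides) -> simzw.SimConfig:
    """A desk-scale version of the viper-like preset (7.7-Mb Z, 100-kb
    scaffolds) with the same proportional stratum layout."""
    params = dict(
        n_autosomes=2,
        autosome_len=2_000_000,
        z_len=7_700_000,
        strata_boundaries=(4_200_000, 5_600_000),
        scaffold_len=100_000,
        depth_window=1_000,
        w_frag_mean_len=20_000,
        n_gametolog_genes=12,
        seed=seed,
    )
    params.update(overrides)
    return simzw.SimConfig(**params)


def viper_preset(seed: int = 0, **overrides) -> simzw.SimConfig:
    """The full viper-like preset: 77-Mb Z, strata boundaries at 42/56 Mb."""
    return simzw.SimConfig(seed=seed, **overrides)


def _sex_assign_stage(bundle: simzw.SimBundle) -> tuple[list, dict, dict]:
    model = bundle.model
    lengths = {sc.id: sc.length for sc in model.scaffolds}
    stats = sexassign.summarize_coverage(bundle.depth_f, bundle.depth_m, lengths)
    calls, summary = sexassign.classify_all(stats)
    truth = {sc.id: sc.true_label for sc in model.scaffolds}
    by_label = {c.scaffold_id: c.label for c in calls}
    n_z_true = sum(1 for sc in model.scaffolds if sc.true_label == "Z")
    n_z_correct = sum(
        1 for sc in model.scaffolds
        if sc.true_label == "Z" and by_label[sc.id] == "Z"
    )
    n_auto_as_sex = sum(
        1 for sc in model.scaffolds
        if sc.true_label == "AUTO" and by_label[sc.id] in ("Z", "W")
    )
    summary["truth_eval"] = {
        "true_z": n_z_true,
        "true_z_called_z": n_z_correct,
        "autosomes_called_sex_linked": n_auto_as_sex,
    }
    return calls, summary, truth


def _het_stage(bundle: simzw.SimBundle, calls) -> dict:
    region_map = {c.scaffold_id: c.label for c in calls
                  if c.label in ("AUTO", "Z", "W")}
    out: dict = {}
    for sex, variants, depth in (
        ("F", bundle.variants_f, bundle.depth_f),
        ("M", bundle.variants_m, bundle.depth_m),
    ):
        filt = hetrates.filter_variants(variants)
        ncall = hetrates.callable_sites(depth, region_map)
        for s in hetrates.het_rate(filt, ncall, region_map, sex):
            out[f"{s.region_class}_{sex}"] = {
                "n_callable": s.n_callable,
                "n_het": s.n_het,
                "rate_percent": s.rate_percent if s.defined else None,
            }
    # paired female-vs-male comparison on Z windows
    z_scafs = [c.scaffold_id for c in calls if c.label == "Z"]
    window = min(1_000_000, bundle.config.scaffold_len)
    wf = hetrates.windowed_het_rates(
        hetrates.filter_variants(bundle.variants_f), bundle.depth_f, z_scafs,
        window_size=window)
    wm = hetrates.windowed_het_rates(
        hetrates.filter_variants(bundle.variants_m), bundle.depth_m, z_scafs,
        window_size=window)
    merged = wf.merge(wm, on=["scaffold", "window_start"],
                      suffixes=("_f", "_m"))
    if len(merged) >= 6:
        test = hetrates.compare_het(merged["rate_f"], merged["rate_m"])
        out["z_female_vs_male"] = {
            "W": test["statistic"], "p": test["pvalue"], "n": test["n"],
            "method": test["method"],
        }
    return out


def _strata_stage(bundle: simzw.SimBundle, calls,
                  window_size: int | None = None) -> dict:
    model = bundle.model
    config = bundle.config
    window = window_size or max(config.z_len // 77, config.depth_window)
    called = {c.scaffold_id: c.label for c in calls}

    coords = {sc.id: (sc.chrom, sc.chrom_start) for sc in model.scaffolds}
    z_ids = [sc.id for sc in model.scaffolds
             if sc.true_label == "Z" and called.get(sc.id) in ("Z", "AUTO")]
    depth_f = bundle.depth_f
    z_rows = depth_f.loc[depth_f["scaffold"].isin(z_ids)]
    z_chrom = strata.project_to_chrom(z_rows, coords, "chrZ")

    auto_ids = [c.scaffold_id for c in calls if c.label == "AUTO"]
    auto_depth = depth_f.loc[depth_f["scaffold"].isin(auto_ids), "depth"]
    auto_median = float(np.median(auto_depth))

    ratio = strata.depth_ratio_track(z_chrom, "chrZ", config.z_len, window,
                                     auto_median)
    div = strata.divergence_track(bundle.walignments, "chrZ", config.z_len,
                                  window)
    w_placements = [(sc.chrom_start, sc.chrom_end)
                    for sc in model.by_label("W")]
    dens = strata.wfragment_density_track(w_placements, "chrZ", config.z_len,
                                          window)
    n_bkps = len(config.strata_boundaries)
    bkps = strata.segment_strata([dens, div], n_bkps=n_bkps)
    segments = strata.label_strata(bkps, div, ratio, chrom_len=config.z_len)
    gypsy = strata.repeat_density_track(bundle.repeats, "chrZ", config.z_len,
                                        window_size=max(window // 10, 10_000),
                                        family="Gypsy")
    profile = strata.repeat_divergence_profile(bundle.repeats, segments,
                                               chrom="chrZ")
    return {
        "window_size": window,
        "breakpoints_bp": [int(b) for b in bkps],
        "true_boundaries_bp": list(config.strata_boundaries),
        "segments": [
            {"start": s.start, "end": s.end, "label": s.label,
             "mean_divergence": None if np.isnan(s.mean_divergence)
             else round(float(s.mean_divergence), 5),
             "mean_depth_ratio": None if np.isnan(s.mean_depth_ratio)
             else round(float(s.mean_depth_ratio), 4)}
            for s in segments
        ],
        "n_strata_excl_par": sum(1 for s in segments if s.label != "PAR"),
        "gypsy_density_mean": round(float(np.nanmean(gypsy.values)), 4),
        "repeat_divergence_means": {
            label: round(float(
                np.average((df["bin_low"] + df["bin_high"]) / 2,
                           weights=df["count"])), 4)
            for label, df in profile.items() if df["count"].sum() > 0
        },
    }


def _gametolog_stage(bundle: simzw.SimBundle) -> dict:
    focal = ("viper" if any(s == "viper" for s, _ in bundle.config.species)
             else bundle.config.species[0][0])
    statuses = []
    divergences: dict[str, list[float]] = {}
    clusterings: dict[str, int] = {"by_chromosome": 0, "by_species": 0,
                                   "unresolved": 0}
    n_used = 0
    for gene in bundle.gametologs.genes:
        z = gene.seqs[f"{focal}_Z"]
        w = gene.seqs[f"{focal}_W"]
        disruptions = gm.scan_orf(z, w)
        statuses.append("pseudogene" if disruptions else "intact")
        cleaned = gm.clean_alignment([z, w])
        if gm.passes_length_filter(cleaned):
            d = gm.pairwise_divergence(cleaned[0], cleaned[1])
            divergences.setdefault(gene.stratum, []).append(d)
        cleaned_all_names = sorted(gene.seqs)
        cleaned_all = gm.clean_alignment([gene.seqs[n] for n in cleaned_all_names])
        if not gm.passes_length_filter(cleaned_all):
            continue
        names, D = gm.distance_matrix(dict(zip(cleaned_all_names, cleaned_all)))
        tree = gm.nj_tree(names, D)
        labels = {
            n: (n.rsplit("_", 1)[0], n.rsplit("_", 1)[1]) for n in names
        }
        res = gm.cluster_by_chromosome_test(tree, labels, gene_id=gene.gene_id)
        clusterings[res.clustering] += 1
        n_used += 1
    frac = gm.pseudogene_fraction(statuses)
    return {
        "focal_species": focal,
        "pseudogenes": frac,
        "mean_divergence_by_stratum": {
            s: round(float(np.mean(v)), 5) for s, v in sorted(divergences.items())
        },
        "tree_clustering": clusterings,
        "n_genes_in_trees": n_used,
    }


def run_all(config: simzw.SimConfig, outdir: str | Path,
            include_fasta: bool = True,
            window_size: int | None = None) -> dict:
    """Generate a bundle, write it, run every analysis stage on it and write
    ``summary.json``; returns the summary dict."""
    outdir = Path(outdir)
    bundle = simzw.generate_bundle(config)
    simzw.write_bundle(bundle, outdir, include_fasta=include_fasta)

    calls, call_summary, _ = _sex_assign_stage(bundle)
    pd.DataFrame(
        [(c.scaffold_id, c.label, c.mf_scaled_ratio, c.evidence) for c in calls],
        columns=["scaffold", "label", "mf_scaled_ratio", "evidence"],
    ).to_csv(outdir / "sex_calls.tsv", sep="\t", index=False)

    est = kmersize.estimate_genome_size(bundle.kmer_histogram)
    true_g = config.n_autosomes * config.autosome_len + config.z_len

    summary = {
        "seed": config.seed,
        "sex_assignment": call_summary,
        "genome_size": {
            "estimate_bp": est.G,
            "peak_depth": est.peak_depth,
            "error_cutoff": est.error_cutoff,
            "true_bp": true_g,
        },
        "heterozygosity": _het_stage(bundle, calls),
        "strata": _strata_stage(bundle, calls, window_size=window_size),
        "gametologs": _gametolog_stage(bundle),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
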