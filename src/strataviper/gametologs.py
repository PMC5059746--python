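"""Gametolog degeneration and strata dating.

Gametologs are the Z- and W-linked descendants of one ancestral autosomal
locus.  After recombination suppression the W copy degenerates: this module
quantifies Z-W divergence on cleaned alignments, scans W ORFs for
pseudogenizing disruptions (premature stops, frameshifts) against their
intact Z partner, and dates strata by whether per-gene trees cluster by
chromosome (all Z copies together — suppression predates the species splits)
or by species (lineage-specific suppression).  Trees are built by neighbor
joining on pairwise distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, SaturationError

_STOPS = {"TAA", "TAG", "TGA"}
_GOOD = set("ACGT")
_PURINES = {"A", "G"}


@dataclass(frozen=True)
class GametologPair:
    """An aligned Z/W gametolog pair for one gene in one species."""

    gene_id: str
    species: str
    z_seq: str
    w_seq: str
    divergence: float = float("nan")
    disruptions: tuple = ()

    def __post_init__(self):
        if len(self.z_seq) != len(self.w_seq):
            raise InputError(
                f"{self.gene_id}/{self.species}: aligned sequences differ in length"
            )

    @property
    def aligned_len(self) -> int:
        """Non-gap columns (gap-free in both sequences)."""
        return sum(
            1 for a, b in zip(self.z_seq, self.w_seq) if a != "-" and b != "-"
        )

    @property
    def w_status(self) -> str:
        return "pseudogene" if self.disruptions else "intact"


@dataclass(frozen=True)
class StrataDatingResult:
    gene_id: str
    tree: str  # newick
    clustering: str  # by_chromosome / by_species / unresolved


def clean_alignment(seqs: Sequence[str]) -> list[str]:
    """Remove every column containing a gap or ambiguous base in any sequence
    (a stricter stand-in for gblocks-style cleaning)."""
    if not seqs:
        raise InputError("empty alignment")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise InputError("alignment sequences have unequal lengths")
    upper = [s.upper() for s in seqs]
    keep = [
        i for i in range(L) if all(s[i] in _GOOD for s in upper)
    ]
    return ["".join(s[i] for i in keep) for s in upper]


def passes_length_filter(cleaned: Sequence[str], min_len: int = 300) -> bool:
    """Alignments must exceed ``min_len`` bp after cleaning to be used."""
    return bool(cleaned) and len(cleaned[0]) > min_len


def pairwise_divergence(seq_a: str, seq_b: str, model: str = "p") -> float:
    """Pairwise divergence of two aligned sequences.

    'p' is the proportion of differing sites over gap-free columns; 'k2p'
    applies the Kimura two-parameter correction from transition/transversion
    counts and raises :class:`SaturationError` when the correction's
    logarithms are undefined.
    """
    if len(seq_a) != len(seq_b):
        raise InputError("sequences must be aligned (equal length)")
    a_up, b_up = seq_a.upper(), seq_b.upper()
    n = ts = tv = 0
    for a, b in zip(a_up, b_up):
        if a not in _GOOD or b not in _GOOD:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise InputError("no comparable (gap-free) columns")
    if model == "p":
        return (ts + tv) / n
    if model == "k2p":
        P, Q = ts / n, tv / n
        x = 1.0 - 2.0 * P - Q
        y = 1.0 - 2.0 * Q
        if x <= 0 or y <= 0:
            raise SaturationError("K2P undefined: substitution saturation")
        return -0.5 * math.log(x) - 0.25 * math.log(y)
    raise InputError(f"unknown divergence model {model!r}")


@dataclass(frozen=True)
class Disruption:
    kind: str  # premature_stop / frameshift
    z_pos: int  # 0-based Z CDS coordinate (codon start for stops)


def _validate_z_orf(z_nogap: str) -> None:
    if len(z_nogap) % 3 != 0:
        raise InputError("reference ORF invalid: length not a multiple of 3")
    if not z_nogap.startswith("ATG"):
        raise InputError("reference ORF invalid: does not start with ATG")
    codons = [z_nogap[i:i + 3] for i in range(0, len(z_nogap) - 3, 3)]
    if any(c in _STOPS for c in codons):
        raise InputError("reference ORF invalid: internal stop codon")


def scan_orf(z_aligned: str, w_aligned: str) -> list[Disruption]:
    """Scan a W sequence, aligned to an intact Z ORF, for pseudogenizing
    disruptions; the reading frame is taken from Z.

    * ``frameshift``: any maximal indel run whose net insertion-minus-deletion
      length is not divisible by 3 (each such run changes the reading-frame
      offset), reported at the Z coordinate where the run starts.  The
      cumulative net offset is also tracked, so runs that merely absorb or
      restore a multiple-of-3 shift never flag downstream codons.
    * ``premature_stop``: a stop triplet read off the W sequence at a Z
      codon's alignment columns (the Z reading frame), before the terminal
      codon; gapped codons are skipped (those columns are indel events).

    Positions are 0-based Z CDS coordinates.  Raises if Z is not itself an
    intact ORF.
    """
    if len(z_aligned) != len(w_aligned):
        raise InputError("sequences must be aligned (equal length)")
    z_up, w_up = z_aligned.upper(), w_aligned.upper()
    z_nogap = z_up.replace("-", "")
    _validate_z_orf(z_nogap)

    disruptions: list[Disruption] = []

    # ---- frameshifts: walk maximal indel runs tracking net indel length
    i = 0
    L = len(z_up)
    z_pos = 0  # Z coordinate of current column
    while i < L:
        zc, wc = z_up[i], w_up[i]
        if zc != "-" and wc != "-":
            z_pos += 1
            i += 1
            continue
        run_z_pos = z_pos
        run_net = 0
        while i < L and (z_up[i] == "-" or w_up[i] == "-"):
            if w_up[i] == "-" and z_up[i] != "-":
                run_net -= 1  # deletion in W
                z_pos += 1
            elif z_up[i] == "-" and w_up[i] != "-":
                run_net += 1  # insertion in W
            else:  # gap in both: shared gap column, ignore
                pass
            i += 1
        if run_net % 3 != 0:
            disruptions.append(Disruption("frameshift", run_z_pos))

    # ---- premature stops in the Z reading frame
    z_cols = [i for i, c in enumerate(z_up) if c != "-"]
    n_codons = len(z_cols) // 3
    for c in range(1, n_codons - 1):  # skip start codon and terminal codon
        cols = z_cols[3 * c:3 * c + 3]
        triplet = "".join(w_up[j] for j in cols)
        if "-" in triplet:
            continue
        if triplet in _STOPS:
            disruptions.append(Disruption("premature_stop", 3 * c))

    return sorted(disruptions, key=lambda d: d.z_pos)


def pseudogene_fraction(pairs: Sequence[GametologPair] | Sequence[str]) -> dict:
    """Count pseudogenized W copies; percent = 100 * n_pseudo / n_total,
    rounded to 2 decimals."""
    if not len(pairs):
        raise InputError("no gametolog pairs")
    statuses = [
        p if isinstance(p, str) else p.w_status for p in pairs
    ]
    bad = [s for s in statuses if s not in ("intact", "pseudogene")]
    if bad:
        raise InputError(f"unknown W status {bad[0]!r}")
    n_pseudo = sum(1 for s in statuses if s == "pseudogene")
    return {
        "n_total": len(statuses),
        "n_pseudo": n_pseudo,
        "percent": round(100.0 * n_pseudo / len(statuses), 2),
    }


# ---------------------------------------------------------------------------
# trees


def distance_matrix(
    seqs: Mapping[str, str], model: str = "p"
) -> tuple[list[str], np.ndarray]:
    """Pairwise distance matrix over named aligned sequences (pairwise
    deletion of gapped columns); taxa returned in sorted name order."""
    names = sorted(seqs)
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_divergence(
                seqs[names[i]], seqs[names[j]], model=model
            )
    return names, D


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(
            f"{child.newick()}:{bl:.6f}" for child, bl in self.children
        )
        return f"({inner})"


def nj_tree(labels: Sequence[str], matrix: np.ndarray) -> str:
    """Neighbor-joining tree from a symmetric distance matrix; returns an
    unrooted newick string.

    Negative branch lengths are clamped to 0.  Pair selection ties break
    deterministically by the sorted names of the joined clusters, so the
    topology is independent of input order.
    """
    D = np.asarray(matrix, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise InputError("matrix shape must match the number of labels")
    if not np.allclose(D, D.T, atol=1e-9) or not np.isfinite(D).all():
        raise InputError("distance matrix must be symmetric and finite")
    if len(labels) < 3:
        raise InputError("neighbor joining needs at least 3 taxa")

    order = np.argsort(np.asarray(labels, dtype=object))
    nodes = [_Node(labels[i]) for i in order]
    keys = [str(labels[i]) for i in order]  # tie-break keys
    D = D[np.ix_(order, order)].copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, min(keys[i], keys[j]), max(keys[i], keys[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        bi = max(0.0, 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2)))
        bj = max(0.0, dij - bi)
        new = _Node(children=[(nodes[i], bi), (nodes[j], bj)])
        new_key = min(keys[i], keys[j])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new_key]

    # final 3-way join (unrooted star)
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b0 = max(0.0, (d01 + d02 - d12) / 2)
    b1 = max(0.0, (d01 + d12 - d02) / 2)
    b2 = max(0.0, (d02 + d12 - d01) / 2)
    root = _Node(children=[(nodes[0], b0), (nodes[1], b1), (nodes[2], b2)])
    return root.newick() + ";"


def _bipartitions(newick: str, taxa: set[str]) -> list[frozenset]:
    """Non-trivial splits of an unrooted tree, each as the side not holding
    an arbitrary reference taxon."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.encode_bipartitions()
    ref = min(taxa)
    out = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.parent_node is None:
            continue
        side = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        if ref in side:
            side = frozenset(taxa - side)
        out.append(side)
    return out


def _is_split(newick: str, tipset: set[str], taxa: set[str]) -> bool:
    """True iff the tip set is separable by a single edge of the unrooted
    tree (it or its complement equals one side of some bipartition)."""
    if not 0 < len(tipset) < len(taxa):
        return False
    if len(tipset) in (1, len(taxa) - 1):
        return True  # pendant edges always separate singletons
    target = frozenset(tipset)
    comp = frozenset(taxa - tipset)
    return any(s in (target, comp) for s in _bipartitions(newick, taxa))


def cluster_by_chromosome_test(
    newick: str,
    tip_labels: Mapping[str, tuple[str, str]],
    gene_id: str = "",
) -> StrataDatingResult:
    """Classify a gametolog gene tree's topology.

    ``tip_labels`` maps every tip name to (species, chromosome) with
    chromosome in {'Z', 'W'}.  ``by_chromosome``: the Z tips form one
    edge-separable cluster on the unrooted tree (equivalently the W tips do)
    — recombination suppression predates the species splits.  ``by_species``:
    each species' {Z, W} pair is edge-separable.  Anything else is
    ``unresolved``.
    """
    taxa = set(tip_labels)
    if len(taxa) < 4:
        raise InputError("need at least 2 species (4 tips)")
    chroms = {c for _, c in tip_labels.values()}
    if not chroms <= {"Z", "W"}:
        raise InputError(f"chromosome labels must be Z or W, got {chroms}")
    species = {sp for sp, _ in tip_labels.values()}
    if len(species) < 2:
        raise InputError("need at least 2 species")
    z_tips = {t for t, (_, c) in tip_labels.items() if c == "Z"}
    w_tips = taxa - z_tips
    if not z_tips or not w_tips:
        raise InputError("tree must contain both Z and W tips")

    if _is_split(newick, z_tips, taxa):
        clustering = "by_chromosome"
    elif all(
        _is_split(newick, {t for t, (sp2, _) in tip_labels.items() if sp2 == sp},
                  taxa)
        for sp in species
    ):
        clustering = "by_species"
    else:
        clustering = "unresolved"
    return StrataDatingResult(gene_id=gene_id, tree=newick, clustering=clustering)


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into {name: sequence} via Biopython."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise InputError(f"no sequences in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise InputError(f"unequal aligned lengths in {path}")
    return seqs
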