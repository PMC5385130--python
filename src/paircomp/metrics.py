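"""Genome-pair statistics: ANI, two-way AAI, shared genes, COG summaries.

ANI is the unweighted mean percent identity over reciprocal best-hit gene
pairs passing the conventional 70% identity / 70% shorter-gene coverage
filters; AAI is the protein analogue over proteins of at least 100 aa, with
the two-way value the mean of the two directional means.  Percent shared
genes follows the printed two-way formula 100*2n/(nA+nB).  Homolog
inventories are directional (a gene is shared if it has any qualifying hit in
the other genome), which is deliberately looser than the reciprocal pairing
used for ANI/AAI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (
    HitFilters,
    HomologyMap,
    ReciprocalPairSet,
    ScoringScheme,
    SubjectIndex,
    best_hits,
    reciprocal_best_hits,
)
from .simulate import Genome

__all__ = [
    "MetricThresholds",
    "AniResult",
    "AaiResult",
    "PairMetrics",
    "COG_CATEGORIES",
    "compute_ani",
    "compute_aai",
    "percent_shared_genes",
    "homolog_inventory",
    "cog_summary",
    "metagenome_profile",
    "compare_genomes",
]

COG_CATEGORIES = tuple("ABCDEFGHIJKLMNOPQRSTUV")


@dataclass(frozen=True)
class MetricThresholds:
    """Filter bounds used by the pair statistics (defaults are standard)."""

    ani_min_identity: float = 70.0
    ani_min_cov_shorter: float = 0.70
    aai_min_protein_len: int = 100
    homolog_max_evalue: float = 1e-5
    homolog_min_identity: float = 30.0
    profile_max_evalue: float = 1e-5
    profile_min_identity: float = 70.0


@dataclass
class AniResult:
    ani_ab: float
    ani_ba: float
    n_pairs: int
    pairs: ReciprocalPairSet | None = None

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


@dataclass
class AaiResult:
    aai_two_way: float
    aai_ab: float
    aai_ba: float
    n_proteins: int
    n_prots_a: int  # proteins >= length floor in genome A
    n_prots_b: int
    pairs: ReciprocalPairSet | None = None

    @property
    def defined(self) -> bool:
        return self.n_proteins > 0


@dataclass
class PairMetrics:
    """The full statistics bundle for one genome pair."""

    genome_a: str
    genome_b: str
    ani: AniResult
    aai: AaiResult
    percent_shared: float
    shared_a: set[str] = field(default_factory=set)
    unique_a: set[str] = field(default_factory=set)
    shared_b: set[str] = field(default_factory=set)
    unique_b: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "genome_a": self.genome_a,
            "genome_b": self.genome_b,
            "ani_ab": self.ani.ani_ab,
            "ani_ba": self.ani.ani_ba,
            "n_ani_pairs": self.ani.n_pairs,
            "aai_two_way": self.aai.aai_two_way,
            "aai_ab": self.aai.aai_ab,
            "aai_ba": self.aai.aai_ba,
            "n_aai_proteins": self.aai.n_proteins,
            "percent_shared_genes": self.percent_shared,
            "n_shared_a": len(self.shared_a),
            "n_unique_a": len(self.unique_a),
            "n_shared_b": len(self.shared_b),
            "n_unique_b": len(self.unique_b),
        }


def _reciprocal_pairs(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    scheme: ScoringScheme,
    filters: HitFilters,
    names: tuple[str, str],
) -> ReciprocalPairSet:
    idx_b = SubjectIndex(seqs_b, scheme.seed_k)
    idx_a = SubjectIndex(seqs_a, scheme.seed_k)
    map_ab = best_hits(seqs_a, seqs_b, scheme, filters, direction=names, index=idx_b)
    map_ba = best_hits(
        seqs_b, seqs_a, scheme, filters, direction=(names[1], names[0]), index=idx_a
    )
    return reciprocal_best_hits(map_ab, map_ba)


def compute_ani(
    genes_a: dict[str, str],
    genes_b: dict[str, str],
    scheme: ScoringScheme | None = None,
    thresholds: MetricThresholds | None = None,
    names: tuple[str, str] = ("A", "B"),
) -> AniResult:
    """ANI over reciprocal best-hit gene pairs (unweighted mean per direction).

    Pairs must reach ``ani_min_identity`` percent identity with at least
    ``ani_min_cov_shorter`` coverage of the shorter gene.  With no qualifying
    pair the result is undefined (NaN values, ``n_pairs`` 0), never 0.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    thresholds = thresholds or MetricThresholds()
    filters = HitFilters(
        min_identity=thresholds.ani_min_identity,
        min_coverage=thresholds.ani_min_cov_shorter,
        coverage_of="shorter",
    )
    rbh = _reciprocal_pairs(genes_a, genes_b, scheme, filters, names)
    if not rbh.pairs:
        return AniResult(math.nan, math.nan, 0, rbh)
    ani_ab = float(np.mean([h_ab.percent_identity for _, _, h_ab, _ in rbh.pairs]))
    ani_ba = float(np.mean([h_ba.percent_identity for _, _, _, h_ba in rbh.pairs]))
    return AniResult(ani_ab, ani_ba, len(rbh.pairs), rbh)


def compute_aai(
    prots_a: dict[str, str],
    prots_b: dict[str, str],
    scheme: ScoringScheme | None = None,
    thresholds: MetricThresholds | None = None,
    names: tuple[str, str] = ("A", "B"),
) -> AaiResult:
    """Two-way AAI over reciprocal best-hit protein pairs (>= 100 aa).

    Proteins shorter than ``aai_min_protein_len`` are dropped before the
    search; pairs are filtered at the homolog e-value/identity bounds; the
    two-way value is the mean of the two directional means.
    """
    scheme = scheme or ScoringScheme.protein()
    thresholds = thresholds or MetricThresholds()
    pa = {k: v for k, v in prots_a.items() if len(v) >= thresholds.aai_min_protein_len}
    pb = {k: v for k, v in prots_b.items() if len(v) >= thresholds.aai_min_protein_len}
    if not pa or not pb:
        return AaiResult(math.nan, math.nan, math.nan, 0, len(pa), len(pb))
    filters = HitFilters(
        min_identity=thresholds.homolog_min_identity,
        max_evalue=thresholds.homolog_max_evalue,
    )
    rbh = _reciprocal_pairs(pa, pb, scheme, filters, names)
    if not rbh.pairs:
        return AaiResult(math.nan, math.nan, math.nan, 0, len(pa), len(pb), rbh)
    aai_ab = float(np.mean([h_ab.percent_identity for _, _, h_ab, _ in rbh.pairs]))
    aai_ba = float(np.mean([h_ba.percent_identity for _, _, _, h_ba in rbh.pairs]))
    return AaiResult(
        (aai_ab + aai_ba) / 2.0, aai_ab, aai_ba, len(rbh.pairs), len(pa), len(pb), rbh
    )


def percent_shared_genes(
    n_pairs_two_way: int, n_prots_a: int, n_prots_b: int
) -> float:
    """100 * (2 * two-way pairs) / (qualifying proteins of A + of B)."""
    if n_prots_a + n_prots_b <= 0:
        raise ValueError("denominator counts must be > 0")
    return 100.0 * (2.0 * n_pairs_two_way) / (n_prots_a + n_prots_b)


def homolog_inventory(
    prots_a: dict[str, str],
    prots_b: dict[str, str],
    scheme: ScoringScheme | None = None,
    thresholds: MetricThresholds | None = None,
) -> tuple[set[str], set[str], set[str], set[str]]:
    """Directional shared/unique partitions of both proteomes.

    A gene of A is shared iff it has at least one hit in B passing the homolog
    e-value and identity bounds (and vice versa); unique is the complement.
    """
    scheme = scheme or ScoringScheme.protein()
    thresholds = thresholds or MetricThresholds()
    filters = HitFilters(
        min_identity=thresholds.homolog_min_identity,
        max_evalue=thresholds.homolog_max_evalue,
    )
    map_ab = best_hits(prots_a, prots_b, scheme, filters, direction=("A", "B"))
    map_ba = best_hits(prots_b, prots_a, scheme, filters, direction=("B", "A"))
    shared_a = set(map_ab.best_hit)
    shared_b = set(map_ba.best_hit)
    return (
        shared_a,
        set(prots_a) - shared_a,
        shared_b,
        set(prots_b) - shared_b,
    )


def cog_summary(
    inventories: dict[str, set[str]], annotations: dict[str, str]
) -> pd.DataFrame:
    """Per-COG-category relative abundance for each gene set.

    ``annotations`` maps gene id -> one-letter COG category (A..V); the table
    may be partial.  Rows are the 22 categories plus an ``unannotated`` count
    row; per set, category abundances sum to 1 over annotated genes.
    """
    for gid, cat in annotations.items():
        if cat not in COG_CATEGORIES:
            raise ValueError(f"unknown COG category {cat!r} for gene {gid!r}")
    cols = {}
    unannotated = {}
    for set_name, genes in inventories.items():
        counts = dict.fromkeys(COG_CATEGORIES, 0)
        n_annot = 0
        for gid in genes:
            cat = annotations.get(gid)
            if cat is None:
                continue
            counts[cat] += 1
            n_annot += 1
        if n_annot:
            cols[set_name] = {c: counts[c] / n_annot for c in COG_CATEGORIES}
        else:
            cols[set_name] = {c: 0.0 for c in COG_CATEGORIES}
        unannotated[set_name] = len(genes) - n_annot
    frame = pd.DataFrame(cols).reindex(list(COG_CATEGORIES))
    frame.loc["unannotated"] = pd.Series(unannotated, dtype=float)
    frame.index.name = "category"
    return frame


def metagenome_profile(
    genome_genes: dict[str, str],
    metagenome_genes: dict[str, str],
    scheme: ScoringScheme | None = None,
    thresholds: MetricThresholds | None = None,
    per: str = "genome",
) -> float:
    """Fraction of genome genes with a qualifying hit in a metagenome gene set.

    With ``per="metagenome"`` the count is normalized by the metagenome gene
    count instead (the alternative reading of "relative frequency").
    """
    if not metagenome_genes:
        raise ValueError("metagenome gene set must be non-empty")
    scheme = scheme or ScoringScheme.nucleotide()
    thresholds = thresholds or MetricThresholds()
    filters = HitFilters(
        min_identity=thresholds.profile_min_identity,
        max_evalue=thresholds.profile_max_evalue,
    )
    hits = best_hits(
        genome_genes, metagenome_genes, scheme, filters, direction=("genome", "mg")
    )
    n_hit = len(hits.best_hit)
    if per == "metagenome":
        return n_hit / len(metagenome_genes)
    return n_hit / len(genome_genes)


def compare_genomes(
    genome_a: Genome,
    genome_b: Genome,
    nt_scheme: ScoringScheme | None = None,
    aa_scheme: ScoringScheme | None = None,
    thresholds: MetricThresholds | None = None,
) -> PairMetrics:
    """End-to-end pair statistics: ANI, AAI, percent shared, inventories."""
    thresholds = thresholds or MetricThresholds()
    names = (genome_a.genome_id, genome_b.genome_id)
    ani = compute_ani(
        genome_a.gene_seqs(), genome_b.gene_seqs(), nt_scheme, thresholds, names
    )
    prots_a, prots_b = genome_a.proteins(), genome_b.proteins()
    aai = compute_aai(prots_a, prots_b, aa_scheme, thresholds, names)
    shared = (
        percent_shared_genes(aai.n_proteins, aai.n_prots_a, aai.n_prots_b)
        if aai.n_prots_a + aai.n_prots_b > 0
        else math.nan
    )
    sa, ua, sb, ub = homolog_inventory(prots_a, prots_b, aa_scheme, thresholds)
    return PairMetrics(
        genome_a=names[0],
        genome_b=names[1],
        ani=ani,
        aai=aai,
        percent_shared=shared,
        shared_a=sa,
        unique_a=ua,
        shared_b=sb,
        unique_b=ub,
    )
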