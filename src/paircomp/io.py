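"""Standard-format I/O: FASTA/FASTQ, CDS-only GFF3, hit tables, reports.

Coordinates are 0-based half-open internally and 1-based inclusive in GFF3
and the 12-column hit table, the conventions of those formats.  Every emitted
table carries a header comment recording the tool version and a hash of the
run configuration, so outputs are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .align import AlignmentHit
from .recruit import ReadAssignment, RecruitmentResult, SweepCurve
from .simulate import Gene, Genome, Read, ReadSet, TruthRecord, translate

logger = logging.getLogger("paircomp")

HIT_TABLE_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "score",
]


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.md5(payload).hexdigest()[:12]


def _header(config: dict | None) -> str:
    return f"# paircomp v{__version__} config={config_hash(config or {})}\n"


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


def write_genome(genome: Genome, prefix: str | Path) -> dict[str, Path]:
    """Emit PREFIX.fna (contigs), PREFIX.gff3 (CDS models), PREFIX.faa."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(".fna"),
        "gff": prefix.with_suffix(".gff3"),
        "proteins": prefix.with_suffix(".faa"),
    }
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, paths["fasta"], "fasta")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(
                f"{g.contig}\tpaircomp\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )

    prots = [
        SeqRecord(Seq(genome.gene_protein(g)), id=g.gene_id, description="")
        for g in genome.genes
    ]
    SeqIO.write(prots, paths["proteins"], "fasta")
    return paths


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    protein_path: str | Path | None = None,
    genome_id: str | None = None,
) -> Genome:
    """Load a genome from FASTA + CDS GFF3 (+ optional protein FASTA).

    Validates coordinates against contig bounds, rejects duplicate gene ids
    and end < start, and (when proteins are given) checks each CDS translates
    to the supplied protein, logging a warning per mismatch.
    """
    fasta_path = Path(fasta_path)
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not contigs:
        raise ValueError(f"no sequences in {fasta_path}")

    gff = pd.read_csv(
        gff_path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
        dtype={"start": int, "end": int},
    )
    gff = gff[gff["type"] == "CDS"]

    genes: list[Gene] = []
    seen: set[str] = set()
    for row in gff.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        gid = attrs.get("ID")
        if gid is None:
            raise ValueError(f"CDS on {row.seqid} at {row.start} lacks an ID attribute")
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} in {gff_path}")
        seen.add(gid)
        if row.seqid not in contigs:
            raise ValueError(f"gene {gid!r}: unknown contig {row.seqid!r}")
        if row.end < row.start:
            raise ValueError(f"gene {gid!r}: end {row.end} < start {row.start}")
        if row.start < 1 or row.end > len(contigs[row.seqid]):
            raise ValueError(
                f"gene {gid!r}: coordinates {row.start}..{row.end} outside contig "
                f"{row.seqid!r} (length {len(contigs[row.seqid])})"
            )
        genes.append(Gene(gid, row.seqid, int(row.start) - 1, int(row.end), row.strand))

    genome = Genome(
        genome_id or fasta_path.stem, contigs, sorted(genes, key=lambda g: (g.contig, g.start))
    )

    if protein_path is not None:
        prots = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_path), "fasta")
        }
        for g in genome.genes:
            expected = prots.get(g.gene_id)
            if expected is None:
                continue
            got = genome.gene_protein(g)
            if got != expected:
                logger.warning(
                    "gene %s: CDS translation differs from supplied protein", g.gene_id
                )
    return genome


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def write_reads(reads: ReadSet, path: str | Path, fmt: str = "fasta") -> Path:
    """Write reads as FASTA (default) or FASTQ with fixed quality 40."""
    path = Path(path)
    records = []
    for r in reads.reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(r.seq)
        records.append(rec)
    SeqIO.write(records, path, fmt)
    return path


def read_reads(path: str | Path) -> dict[str, str]:
    """Read FASTA/FASTQ reads (format by extension; qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)}


def write_read_labels(reads: ReadSet, path: str | Path, config: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("read_id\tsource\n")
        for r in reads.reads:
            fh.write(f"{r.read_id}\t{r.source}\n")
    return path


# ---------------------------------------------------------------------------
# truth / tables
# ---------------------------------------------------------------------------


def write_truth(truth: TruthRecord, path: str | Path, config: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write(f"# programmed_ani={truth.programmed_ani:.4f}\n")
        fh.write(
            f"# programmed_shared_fraction_a={truth.programmed_shared_fraction_a:.4f}"
            f"\tprogrammed_shared_fraction_b={truth.programmed_shared_fraction_b:.4f}\n"
        )
        fh.write(f"# realized_site_divergence={truth.realized_site_divergence:.6f}\n")
        fh.write("gene_a\tgene_b\tnt_identity\taa_identity\n")
        for a, b in truth.ortholog_pairs:
            fh.write(
                f"{a}\t{b}\t{truth.per_gene_identity[(a, b)]:.4f}"
                f"\t{truth.per_gene_protein_identity[(a, b)]:.4f}\n"
            )
    return path


def hit_row(hit: AlignmentHit) -> list:
    """One 12-column tabular row (1-based coordinates; minus-strand hits have
    sstart > send, BLAST style)."""
    if hit.subject_strand == "-":
        sstart, send = hit.subject_end, hit.subject_start + 1
    else:
        sstart, send = hit.subject_start + 1, hit.subject_end
    return [
        hit.query_id,
        hit.subject_id,
        round(hit.percent_identity, 2),
        hit.alignment_length,
        hit.mismatches,
        hit.gap_opens,
        hit.query_start + 1,
        hit.query_end,
        sstart,
        send,
        f"{hit.evalue:.3g}",
        hit.score,
    ]


def write_hit_table(
    hits: list[AlignmentHit], path: str | Path, config: dict | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for hit in hits:
            fh.write("\t".join(str(x) for x in hit_row(hit)) + "\n")
    return path


def write_assignments(
    assignments: list[ReadAssignment], path: str | Path, config: dict | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("read_id\treference\t" + "\t".join(HIT_TABLE_COLUMNS[1:]) + "\n")
        for asg in assignments:
            if asg.hit is None:
                continue
            row = hit_row(asg.hit)
            fh.write(asg.read_id + "\t" + str(asg.reference) + "\t")
            fh.write("\t".join(str(x) for x in row[1:]) + "\n")
    return path


def write_sweep(curve: SweepCurve, path: str | Path, config: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("threshold\tsource\ttarget\tkind\tfrequency\n")
        for (src, tgt), freqs in curve.cross_map_freq.items():
            for t in curve.thresholds:
                fh.write(f"{t}\t{src}\t{tgt}\tcross\t{freqs[t]:.6f}\n")
        for src, freqs in curve.self_map_freq.items():
            for t in curve.thresholds:
                fh.write(f"{t}\t{src}\t{src}\tself\t{freqs[t]:.6f}\n")
    return path


def write_recruitment(
    result: RecruitmentResult, path: str | Path, config: dict | None = None
) -> Path:
    path = Path(path)
    ratio = result.ratio_ab
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("genome\tmapped_reads\n")
        for gid, n in result.counts.items():
            fh.write(f"{gid}\t{n}\n")
        fh.write(f"unmapped\t{result.unmapped}\n")
        fh.write(f"# threshold_used={result.threshold_used:g}\n")
        fh.write(
            "# ratio_ab="
            + ("NA" if ratio is None else ("inf" if ratio == float("inf") else f"{ratio:.4f}"))
            + "\n"
        )
    return path


def write_inventory(
    shared: set[str], unique: set[str], path: str | Path, config: dict | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("gene_id\tstatus\n")
        for gid in sorted(shared):
            fh.write(f"{gid}\tshared\n")
        for gid in sorted(unique):
            fh.write(f"{gid}\tunique\n")
    return path


def write_link_table(
    pairs,
    genome_a: Genome,
    genome_b: Genome,
    path: str | Path,
    config: dict | None = None,
) -> Path:
    """Reciprocal-pair link table for circular-plot tooling."""
    genes_a = {g.gene_id: g for g in genome_a.genes}
    genes_b = {g.gene_id: g for g in genome_b.genes}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("contig_a\tstart_a\tend_a\tcontig_b\tstart_b\tend_b\tidentity\n")
        rows = []
        for a, b, hit_ab, _ in pairs.pairs:
            ga, gb = genes_a[a], genes_b[b]
            rows.append(
                (ga.contig, ga.start, ga.end, gb.contig, gb.start, gb.end,
                 round(hit_ab.percent_identity, 2))
            )
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


def write_json_report(data: dict, path: str | Path, config: dict | None = None) -> Path:
    path = Path(path)
    payload = {
        "tool": "paircomp",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        **data,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
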