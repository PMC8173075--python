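"""Reference context for editing-site discovery.

Loads and indexes the genome, gene models, repeat mask, known germline
variants and known editing sites, and answers the positional queries the
artifact-filter cascade asks: homopolymer run lengths, distance to splice
junctions, genic overlap, and coding consequence of a substitution.

All public coordinates are 1-based (VCF/GTF/pileup convention); BED input
is converted from 0-based half-open on load.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

DEFAULT_MITO_NAMES = frozenset({"chrM", "MT"})

#: consequence category labels
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
STOP_GAIN = "stop-gain"
STOP_LOST = "stop-lost"
UTR5 = "5'UTR"
UTR3 = "3'UTR"
NON_CODING_EXON = "non-coding-exon"
INTRON = "intron"

_VALID_BASES = frozenset("ACGTN")


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass
class ReferenceGenome:
    """Genome as uppercase contig sequences plus the set of mitochondrial names."""

    contigs: dict[str, str]
    mito_names: frozenset[str] = DEFAULT_MITO_NAMES

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ReferenceError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def base_at(self, contig: str, pos: int) -> str:
        """Reference base at 1-based ``pos``."""
        seq = self.contigs[contig]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside {contig} (length {len(seq)})")
        return seq[pos - 1]

    def is_mito(self, contig: str) -> bool:
        return contig in self.mito_names


@dataclass
class GeneModel:
    """Single-transcript gene model: exons plus optional CDS intervals.

    Intervals are 1-based closed ``(start, end)`` tuples, sorted by start.
    """

    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ReferenceError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ReferenceError(f"gene {self.gene_id}: exon ({s},{e}) inverted")
            if prev_end is not None and s <= prev_end:
                raise ReferenceError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ReferenceError(
                    f"gene {self.gene_id}: CDS ({cs},{ce}) not contained in any exon"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def junctions(self) -> list[int]:
        """Splice-junction positions: internal exon boundaries."""
        out: list[int] = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.extend((e1, s2))
        return out

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)


class AnnotationSet:
    """Indexed collection of gene models on a genome."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        self._gene_trees: dict[str, IntervalTree] = {}
        self._junctions: dict[str, list[int]] = {}
        for g in self.genes:
            tree = self._gene_trees.setdefault(g.contig, IntervalTree())
            s, e = g.span
            tree[s : e + 1] = g
            if len(g.exons) > 1:
                self._junctions.setdefault(g.contig, []).extend(g.junctions)
        for contig in self._junctions:
            self._junctions[contig] = sorted(set(self._junctions[contig]))

    def genes_at(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self._gene_trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[pos]]
        return sorted(hits, key=lambda g: g.gene_id)

    def junctions_on(self, contig: str) -> list[int]:
        return self._junctions.get(contig, [])


@dataclass
class RepeatMask:
    """Simple-repeat intervals per contig, 1-based closed."""

    intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for contig, ivs in self.intervals.items():
            tree = IntervalTree()
            for s, e in sorted(ivs):
                tree[s : e + 1] = True
            self._trees[contig] = tree

    def contains(self, contig: str, pos: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree is not None and tree[pos])


class KnownVariantSet:
    """dbSNP-style lookup, exact on (contig, pos, ref, alt)."""

    def __init__(self, records: set[tuple[str, int, str, str]]):
        self._records = set(records)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._records

    def __len__(self) -> int:
        return len(self._records)


class KnownEditingSet:
    """REDIportal-style lookup by (contig, pos) only; entries carry strand and type."""

    def __init__(self, records: dict[tuple[str, int], tuple[str, str]]):
        self._records = dict(records)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._records

    def get(self, key: tuple[str, int]):
        return self._records.get(key)

    def __len__(self) -> int:
        return len(self._records)


@dataclass
class ReferenceBundle:
    """Everything the filter cascade queries about a site."""

    genome: ReferenceGenome
    annotation: AnnotationSet
    repeats: RepeatMask
    known_variants: KnownVariantSet
    known_editing: KnownEditingSet


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_reference(fasta_path: str | Path,
                   mito_names: frozenset[str] = DEFAULT_MITO_NAMES) -> ReferenceGenome:
    """Load a FASTA file into an uppercase in-memory genome."""
    fasta_path = Path(fasta_path)
    records = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ReferenceError(f"duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            line_no = _find_bad_line(fasta_path, bad)
            raise ReferenceError(
                f"contig {rec.id!r}: invalid characters {sorted(bad)}"
                f" (first offending line {line_no})"
            )
        records[rec.id] = seq
    if not records:
        raise ReferenceError(f"no records in {fasta_path}")
    return ReferenceGenome(records, mito_names)


def _find_bad_line(path: Path, bad: set[str]) -> int:
    probe = {c.upper() for c in bad} | {c.lower() for c in bad}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.rstrip()) & probe:
                return i
    return -1


def load_annotation(gtf_path: str | Path) -> AnnotationSet:
    """Load gene/exon/CDS features from a GTF into an :class:`AnnotationSet`.

    Requires one ``gene`` feature per gene_id; exon and CDS features are
    grouped onto their gene by the ``gene_id`` attribute.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("exon"):
        exons.setdefault(feat.attributes["gene_id"][0], []).append((feat.start, feat.end))
    for feat in db.features_of_type("CDS"):
        cds.setdefault(feat.attributes["gene_id"][0], []).append((feat.start, feat.end))

    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        name = feat.attributes.get("gene_name", [gid])[0]
        biotype = feat.attributes.get("gene_biotype", [""])[0]
        if feat.strand not in {"+", "-"}:
            raise ReferenceError(f"gene {gid}: unknown strand {feat.strand!r}")
        genes.append(GeneModel(
            gene_id=gid, gene_name=name, contig=feat.seqid, strand=feat.strand,
            exons=exons.get(gid, [(feat.start, feat.end)]),
            cds=cds.get(gid, []), biotype=biotype,
        ))
    return AnnotationSet(genes)


def load_repeat_mask(bed_path: str | Path) -> RepeatMask:
    """Load a BED3 repeat mask (0-based half-open), converting to 1-based closed."""
    try:
        df = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["contig", "start", "end"])
    except pd.errors.EmptyDataError:
        return RepeatMask({})
    intervals: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        intervals.setdefault(str(row.contig), []).append((int(row.start) + 1, int(row.end)))
    return RepeatMask(intervals)


def load_known_variants(vcf_path: str | Path) -> KnownVariantSet:
    """Load a sites-only VCF of known germline variants (dbSNP-style)."""
    records: set[tuple[str, int, str, str]] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                records.add((rec.contig, rec.pos, rec.ref, alt))
    return KnownVariantSet(records)


def load_known_editing(tsv_path: str | Path) -> KnownEditingSet:
    """Load a known-editing table (TSV with header contig/pos/strand/type)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"contig": str})
    required = {"contig", "pos", "strand", "type"}
    missing = required - set(df.columns)
    if missing:
        raise ReferenceError(f"known-editing table missing columns: {sorted(missing)}")
    return KnownEditingSet({
        (str(r.contig), int(r.pos)): (str(r.strand), str(r.type))
        for r in df.itertuples(index=False)
    })


def load_bundle(fasta: str | Path, gtf: str | Path, repeats_bed: str | Path,
                known_variants_vcf: str | Path, known_editing_tsv: str | Path,
                mito_names: frozenset[str] = DEFAULT_MITO_NAMES) -> ReferenceBundle:
    return ReferenceBundle(
        genome=load_reference(fasta, mito_names),
        annotation=load_annotation(gtf),
        repeats=load_repeat_mask(repeats_bed),
        known_variants=load_known_variants(known_variants_vcf),
        known_editing=load_known_editing(known_editing_tsv),
    )


# ---------------------------------------------------------------------------
# positional queries
# ---------------------------------------------------------------------------

def homopolymer_run_length(genome: ReferenceGenome, contig: str, pos: int,
                           adjacency: int = 1) -> int:
    """Longest maximal single-base run containing ``pos`` or within ``adjacency`` of it.

    Substitution artifacts cluster at run edges, so a site immediately
    abutting a long run is treated as being in it.
    """
    seq = genome.contigs[contig]
    n = len(seq)
    if not 1 <= pos <= n:
        raise IndexError(f"position {pos} outside {contig} (length {n})")

    best = 0
    for p in range(max(1, pos - adjacency), min(n, pos + adjacency) + 1):
        i = p - 1
        base = seq[i]
        lo = i
        while lo > 0 and seq[lo - 1] == base:
            lo -= 1
        hi = i
        while hi < n - 1 and seq[hi + 1] == base:
            hi += 1
        best = max(best, hi - lo + 1)
    return best


def distance_to_splice_junction(ann: AnnotationSet, contig: str, pos: int) -> int | None:
    """Minimum |pos - junction| on the contig; None when no junctions exist."""
    junctions = ann.junctions_on(contig)
    if not junctions:
        return None
    i = bisect.bisect_left(junctions, pos)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(junctions):
            d = abs(pos - junctions[j])
            best = d if best is None else min(best, d)
    return best


def classify_genic(ann: AnnotationSet, contig: str, pos: int) -> list[GeneModel]:
    """Genes whose exonic span (introns included) contains pos; empty = intergenic."""
    return ann.genes_at(contig, pos)


def annotate_consequence(genome: ReferenceGenome, gene: GeneModel, pos: int,
                         ref_allele: str, alt_allele: str) -> str:
    """Coding consequence of a single-base substitution within a gene.

    CDS positions are classified by translating the affected codon of the
    spliced CDS (reverse-complemented for minus-strand genes); exonic
    non-CDS positions become UTRs (or non-coding-exon when the gene has no
    CDS); everything else within the span is intronic.
    """
    if genome.base_at(gene.contig, pos) != ref_allele.upper():
        raise ReferenceError(
            f"reference discordance at {gene.contig}:{pos}: genome has "
            f"{genome.base_at(gene.contig, pos)}, call says {ref_allele}"
        )
    if not gene.contains(pos):
        raise ValueError(f"position {pos} outside span of gene {gene.gene_id}")

    if gene.in_cds(pos):
        return _cds_consequence(genome, gene, pos, alt_allele.upper())
    if gene.in_exon(pos):
        if not gene.cds:
            return NON_CODING_EXON
        cds_start, cds_end = gene.cds[0][0], gene.cds[-1][1]
        if pos < cds_start:
            return UTR5 if gene.strand == "+" else UTR3
        if pos > cds_end:
            return UTR3 if gene.strand == "+" else UTR5
        # within CDS genomic bounds but not in a CDS interval -> spliced out
        return INTRON
    return INTRON


def _cds_consequence(genome: ReferenceGenome, gene: GeneModel, pos: int,
                     alt: str) -> str:
    seq = genome.contigs[gene.contig]
    cds_seq = "".join(seq[s - 1:e] for s, e in gene.cds)
    offset = 0
    idx = None
    for s, e in gene.cds:
        if s <= pos <= e:
            idx = offset + (pos - s)
            break
        offset += e - s + 1
    assert idx is not None

    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        idx = len(cds_seq) - 1 - idx
        alt = str(Seq(alt).complement())

    codon_i = idx // 3
    within = idx % 3
    codon = cds_seq[codon_i * 3: codon_i * 3 + 3]
    if len(codon) < 3:
        raise ReferenceError(
            f"gene {gene.gene_id}: CDS length {len(cds_seq)} leaves an incomplete codon"
        )
    alt_codon = codon[:within] + alt + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        return SYNONYMOUS
    if alt_aa == "*":
        return STOP_GAIN
    if ref_aa == "*":
        return STOP_LOST
    return MISSENSE
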