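"""High-confidence G-to-A editing events from per-sample variant calls.

A candidate site survives when it is genic, its substitution reads G-to-A on
the transcript strand, none of six artifact/germline flags applies (unless
the site is a known editing site, which voids all flags), and it is either
detected in at least ``min_discovery_samples`` discovery samples or
replicated in the reference cohort at an editing level of at least 1%.

The six flags, computed independently of one another:

1. repeat_or_homopolymer — in the repeat mask, or in/abutting a
   single-base run of >= 5 nt;
2. mitochondrial — on a mitochondrial contig;
3. near_splice — within 6 nt of a splice junction;
4. near_indel — within 1 nt of an indel called in a sample that also
   detected the site;
5. dbsnp_known — exact (contig, pos, ref, alt) match in the known-variant set;
6. germline_pattern — more than 90% of callable discovery samples show an
   allele fraction of exactly 1.0 or within [0.40, 0.60], the signature of a
   homozygous or heterozygous germline variant rather than editing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pileup import SampleCalls
from .refmodel import (
    ReferenceBundle,
    annotate_consequence,
    classify_genic,
    distance_to_splice_junction,
    homopolymer_run_length,
)

STRAND_AMBIGUOUS = "strand-ambiguous"

FLAG_REPEAT = "repeat_or_homopolymer"
FLAG_MITO = "mitochondrial"
FLAG_SPLICE = "near_splice"
FLAG_INDEL = "near_indel"
FLAG_DBSNP = "dbsnp_known"
FLAG_GERMLINE = "germline_pattern"

PROVENANCE_MULTI = "multi-sample"
PROVENANCE_REPLICATION = "replication"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class CascadeConfig:
    """Thresholds of the filter cascade and the admission rule."""

    homopolymer_min_run: int = 5
    homopolymer_adjacency: int = 1
    splice_max_dist: int = 6
    indel_max_dist: int = 1
    germline_sample_frac: float = 0.90
    het_band: tuple[float, float] = (0.40, 0.60)
    hom_value: float = 1.00
    replication_min_level: float = 0.01
    min_discovery_samples: int = 2
    min_callable_depth: int = 10             # depth for a sample to count as callable
    germline_denominator: str = "callable"   # or "all"

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("het_band must be within [0, 1]")
        if not 0.0 < self.germline_sample_frac <= 1.0:
            raise ValueError("germline_sample_frac must be in (0, 1]")


@dataclass
class EditingCandidate:
    """A genomic site under evaluation as a G-to-A editing event."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    edit_type: str
    gene_ids: list[str] = field(default_factory=list)
    gene_id: str | None = None          # attribution gene (alphabetical tie-break)
    consequence: str | None = None
    levels: dict[str, float | None] = field(default_factory=dict)
    cohort_levels: dict[str, float] = field(default_factory=dict)
    detected_in: set[str] = field(default_factory=set)
    filter_flags: set[str] = field(default_factory=set)
    rescued: bool = False
    provenance: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)

    @property
    def effective_flags(self) -> set[str]:
        return set() if self.rescued else set(self.filter_flags)


@dataclass
class HighConfidenceSet:
    events: list[EditingCandidate]
    rejected: list[EditingCandidate]
    strand_ambiguous: list[EditingCandidate]
    discovery_samples: list[str]

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {e.key for e in self.events}


def classify_edit_type(ref_allele: str, alt_allele: str, gene_strand: str) -> str:
    """Edit type on the transcript (sense) strand, e.g. ``G-to-A``.

    A genomic C>T inside a minus-strand gene is a transcript-strand G-to-A.
    """
    ref, alt = ref_allele.upper(), alt_allele.upper()
    if gene_strand == "+":
        return f"{ref}-to-{alt}"
    if gene_strand == "-":
        return f"{_COMPLEMENT[ref]}-to-{_COMPLEMENT[alt]}"
    raise ValueError(f"gene_strand must be '+' or '-', got {gene_strand!r}")


def germline_pattern_filter(levels: list[float], cfg: CascadeConfig,
                            n_total: int | None = None) -> bool:
    """True when the cross-sample allele-fraction pattern looks germline.

    ``levels`` are AAFs of callable samples only; with none, the pattern is
    unevaluable and the site is kept (it will fail admission regardless).
    ``n_total`` overrides the denominator (all-samples mode).
    """
    if not levels:
        return False
    lo, hi = cfg.het_band
    eps = 1e-9
    n_band = sum(1 for x in levels
                 if abs(x - cfg.hom_value) < eps or (lo - eps) <= x <= (hi + eps))
    denom = n_total if n_total else len(levels)
    return n_band / denom > cfg.germline_sample_frac


def apply_site_filters(cand: EditingCandidate, ref: ReferenceBundle,
                       indel_positions: dict[str, dict[str, list[int]]],
                       cfg: CascadeConfig) -> EditingCandidate:
    """Compute the six flags and the known-editing rescue on one candidate.

    ``indel_positions`` maps sample_id -> contig -> indel call positions.
    Flags are independent; evaluation order never matters.
    """
    flags = set(cand.filter_flags)

    if (ref.repeats.contains(cand.contig, cand.pos)
            or homopolymer_run_length(ref.genome, cand.contig, cand.pos,
                                      cfg.homopolymer_adjacency)
            >= cfg.homopolymer_min_run):
        flags.add(FLAG_REPEAT)

    if ref.genome.is_mito(cand.contig):
        flags.add(FLAG_MITO)

    dist = distance_to_splice_junction(ref.annotation, cand.contig, cand.pos)
    if dist is not None and dist <= cfg.splice_max_dist:
        flags.add(FLAG_SPLICE)

    for sample_id in cand.detected_in:
        positions = indel_positions.get(sample_id, {}).get(cand.contig, [])
        if any(abs(p - cand.pos) <= cfg.indel_max_dist for p in positions):
            flags.add(FLAG_INDEL)
            break

    if (cand.contig, cand.pos, cand.ref_allele, cand.alt_allele) in ref.known_variants:
        flags.add(FLAG_DBSNP)

    callable_levels = [x for x in cand.levels.values() if x is not None]
    n_total = len(cand.levels) if cfg.germline_denominator == "all" else None
    if germline_pattern_filter(callable_levels, cfg, n_total):
        flags.add(FLAG_GERMLINE)

    cand.filter_flags = flags
    cand.rescued = (cand.contig, cand.pos) in ref.known_editing
    return cand


def build_high_confidence_set(discovery: dict[str, SampleCalls],
                              reference_cohort: dict[str, SampleCalls],
                              ref: ReferenceBundle,
                              cfg: CascadeConfig | None = None,
                              edit_type: str = "G-to-A") -> HighConfidenceSet:
    """Run the full cascade over the union of discovery calls.

    Detection (for the >=2-samples rule) is sample-level: a post-fpfilter
    call exists in that sample. Flags are site-level and shared. Candidate
    editing levels are quality-filtered AAFs in every callable discovery
    sample, whether or not that sample produced a call.
    """
    if not discovery:
        raise ValueError("no samples: discovery input is empty")
    cfg = cfg or CascadeConfig()

    keys: set[tuple[str, int, str, str]] = set()
    for sc in discovery.values():
        keys.update(k for k, c in sc.snvs.items() if c.kind == "SNV")

    indel_positions = {sid: sc.indel_positions for sc in discovery.values()
                       for sid in [sc.sample_id]}
    for sc in reference_cohort.values():
        indel_positions[sc.sample_id] = sc.indel_positions

    events, rejected, ambiguous = [], [], []
    for key in sorted(keys):
        contig, pos, ref_a, alt_a = key
        cand = EditingCandidate(contig, pos, ref_a, alt_a, edit_type="")
        cand.detected_in = {sid for sid, sc in discovery.items() if key in sc.snvs}
        # callable = quality-filtered depth meets the calling minimum; an
        # uncovered or thin sample carries no genotype evidence
        cand.levels = {
            sid: (sc.aaf_at(contig, pos, alt_a)
                  if sc.site_depth.get((contig, pos), 0) >= cfg.min_callable_depth
                  else None)
            for sid, sc in discovery.items()
        }
        cand.cohort_levels = {
            sid: sc.snvs[key].aaf for sid, sc in reference_cohort.items()
            if key in sc.snvs
        }

        genes = classify_genic(ref.annotation, contig, pos)
        cand.gene_ids = [g.gene_id for g in genes]
        if not genes:
            cand.edit_type = "intergenic"
            rejected.append(cand)
            continue

        strands = {g.strand for g in genes}
        if len(strands) > 1:
            cand.edit_type = STRAND_AMBIGUOUS
            ambiguous.append(cand)
            continue
        strand = strands.pop()
        cand.edit_type = classify_edit_type(ref_a, alt_a, strand)
        cand.gene_id = min(g.gene_id for g in genes)
        gene = next(g for g in genes if g.gene_id == cand.gene_id)
        try:
            cand.consequence = annotate_consequence(ref.genome, gene, pos,
                                                    ref_a, alt_a)
        except Exception:
            cand.consequence = None

        apply_site_filters(cand, ref, indel_positions, cfg)

        admitted = (
            cand.edit_type == edit_type
            and not cand.effective_flags
            and _admission(cand, cfg)
        )
        if admitted:
            events.append(cand)
        else:
            rejected.append(cand)

    return HighConfidenceSet(events, rejected, ambiguous, sorted(discovery))


def _admission(cand: EditingCandidate, cfg: CascadeConfig) -> bool:
    if len(cand.detected_in) >= cfg.min_discovery_samples:
        cand.provenance = PROVENANCE_MULTI
        return True
    if any(lvl >= cfg.replication_min_level for lvl in cand.cohort_levels.values()):
        cand.provenance = PROVENANCE_REPLICATION
        return True
    return False


def aggregate_per_gene(hcs: HighConfidenceSet) -> dict[str, int]:
    """Event count per attributed gene (alphabetically first overlapping gene)."""
    counts: dict[str, int] = {}
    for ev in hcs.events:
        if ev.gene_id is not None:
            counts[ev.gene_id] = counts.get(ev.gene_id, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def events_table(hcs: HighConfidenceSet) -> pd.DataFrame:
    """Flat TSV-ready table of admitted events."""
    rows = []
    for ev in hcs.events:
        row = {
            "contig": ev.contig, "pos": ev.pos, "ref": ev.ref_allele,
            "alt": ev.alt_allele, "edit_type": ev.edit_type,
            "gene_id": ev.gene_id, "consequence": ev.consequence,
            "provenance": ev.provenance, "rescued": ev.rescued,
            "flags": ",".join(sorted(ev.filter_flags)),
            "n_detected": len(ev.detected_in),
        }
        for sid in hcs.discovery_samples:
            lvl = ev.levels.get(sid)
            row[f"level_{sid}"] = "" if lvl is None else round(lvl, 6)
        rows.append(row)
    cols = (["contig", "pos", "ref", "alt", "edit_type", "gene_id", "consequence",
             "provenance", "rescued", "flags", "n_detected"]
            + [f"level_{sid}" for sid in hcs.discovery_samples])
    return pd.DataFrame(rows, columns=cols)


def write_events_tsv(hcs: HighConfidenceSet, path: str | Path) -> None:
    events_table(hcs).to_csv(path, sep="\t", index=False)


def write_events_vcf(hcs: HighConfidenceSet, path: str | Path,
                     contig_lengths: dict[str, int] | None = None) -> None:
    """Sites-only VCF 4.2 of admitted events."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ET,Number=1,Type=String,Description="Edit type">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Attributed gene">\n')
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Samples detected">\n')
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for ev in sorted(hcs.events, key=lambda e: (e.contig, e.pos)):
            info = f"ET={ev.edit_type};GENE={ev.gene_id};NS={len(ev.detected_in)}"
            fh.write(f"{ev.contig}\t{ev.pos}\t.\t{ev.ref_allele}\t"
                     f"{ev.alt_allele}\t.\tPASS\t{info}\n")
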