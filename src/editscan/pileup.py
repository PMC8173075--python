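"""Parsing of samtools-mpileup text and per-sample variant calling.

The calling criteria follow the discovery thresholds used throughout the
pipeline: base quality >= 25 to count an observation, quality-filtered
depth >= 10, alternative allele depth >= 2, alternative allele frequency
(AAF) >= 1%. A false-positive filter removes calls with one-sided strand
support or depressed alternative-allele base quality — the two checks of a
VarScan-fpfilter-style screen that are computable from pileup text alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

SNV = "SNV"
INS = "INS"
DEL = "DEL"

_SPECIAL = re.compile(r"[^.,]")  # fast-path probe: pure ref-match base strings


class PileupParseError(ValueError):
    pass


@dataclass
class PileupSite:
    """One parsed mpileup record: per-observation bases, strands and qualities.

    ``bases`` holds upper-cased observation symbols aligned with ``quals``
    and ``strands``: '.' for reference, 'A/C/G/T/N' for substitutions,
    '*' for deletion placeholders, '>' for reference skips. ``indels``
    maps observation index -> '+SEQ' / '-SEQ' attached to that read.
    """

    contig: str
    pos: int
    ref_base: str
    depth: int
    bases: list[str]
    strands: list[str]          # '+' or '-'
    quals: list[int]            # Phred scores
    indels: dict[int, str] = field(default_factory=dict)


@dataclass
class AlleleStats:
    fwd: int = 0
    rev: int = 0
    qual_sum: float = 0.0

    @property
    def count(self) -> int:
        return self.fwd + self.rev

    @property
    def mean_qual(self) -> float | None:
        return self.qual_sum / self.count if self.count else None


@dataclass
class SiteSummary:
    """Quality-filtered per-allele counts at one site of one sample."""

    contig: str
    pos: int
    ref_base: str
    raw_depth: int
    alleles: dict[str, AlleleStats]   # 'A'.. 'T', 'N', '+SEQ', '-SEQ'
    q_min: int
    mean_read_pos: dict[str, float] | None = None  # not derivable from pileup text

    @property
    def qualified_depth(self) -> int:
        """Base observations (ref + substitutions) passing the quality cut."""
        return sum(st.count for al, st in self.alleles.items()
                   if len(al) == 1 and al != "*")


@dataclass
class VariantCall:
    sample_id: str
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    total_depth: int
    alt_depth: int
    aaf: float
    kind: str
    alt_fwd: int = 0
    alt_rev: int = 0
    ref_fwd: int = 0
    ref_rev: int = 0
    mean_alt_qual: float | None = None
    mean_ref_qual: float | None = None

    def __post_init__(self) -> None:
        assert 0 <= self.alt_depth <= self.total_depth
        assert 0.0 <= self.aaf <= 1.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class CallThresholds:
    """Variant-calling criteria: Q>=25, depth>=10, alt depth>=2, AAF>=1%."""

    q_min: int = 25
    min_depth: int = 10
    min_alt_depth: int = 2
    min_aaf: float = 0.01

    def __post_init__(self) -> None:
        if min(self.q_min, self.min_depth, self.min_alt_depth) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 < self.min_aaf <= 1.0:
            raise ValueError("min_aaf must be in (0, 1]")


@dataclass
class FpFilterParams:
    """Pileup-computable false-positive screen parameters."""

    strand_min_alt: int = 4     # one-sided alt support triggers only at this depth
    max_qual_deficit: float = 10.0  # alt mean quality may trail ref by at most this


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_pileup_line(line: str) -> PileupSite:
    """Parse one 6-column mpileup record into per-observation form."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PileupParseError(f"expected 6 columns, got {len(fields)}: {line!r}")
    contig, pos_s, ref, depth_s, bases_s, quals_s = fields[:6]
    pos, depth = int(pos_s), int(depth_s)
    ref = ref.upper()

    obs: list[str] = []
    strands: list[str] = []
    indels: dict[int, str] = {}
    i, n = 0, len(bases_s)
    while i < n:
        c = bases_s[i]
        if c == "^":
            i += 2  # caret + mapping-quality char, no observation
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = re.match(r"[+-](\d+)", bases_s[i:])
            if m is None:
                raise PileupParseError(
                    f"{contig}:{pos}: malformed indel at base-string offset {i}")
            length = int(m.group(1))
            seq = bases_s[i + m.end(): i + m.end() + length]
            if len(seq) != length:
                raise PileupParseError(
                    f"{contig}:{pos}: truncated indel sequence at offset {i}")
            if not obs:
                raise PileupParseError(
                    f"{contig}:{pos}: indel with no preceding observation")
            indels[len(obs) - 1] = c + seq.upper()
            i += m.end() + length
            continue
        if c in ".,":
            obs.append(".")
            strands.append("+" if c == "." else "-")
        elif c in "ACGTN":
            obs.append(c)
            strands.append("+")
        elif c in "acgtn":
            obs.append(c.upper())
            strands.append("-")
        elif c in "*#":
            obs.append("*")
            strands.append("+" if c == "*" else "-")
        elif c in "><":
            obs.append(">")
            strands.append("+" if c == ">" else "-")
        else:
            raise PileupParseError(
                f"{contig}:{pos}: unexpected pileup character {c!r} at offset {i}")
        i += 1

    if len(obs) != len(quals_s):
        raise PileupParseError(
            f"{contig}:{pos}: {len(obs)} observations but {len(quals_s)} qualities")
    quals = [ord(q) - 33 for q in quals_s]
    return PileupSite(contig, pos, ref, depth, obs, strands, quals, indels)


def summarize_site(site: PileupSite, q_min: int) -> SiteSummary:
    """Quality-filtered per-allele counts; deletion placeholders and reference
    skips contribute to raw depth only."""
    alleles: dict[str, AlleleStats] = {}
    for i, (b, strand, q) in enumerate(zip(site.bases, site.strands, site.quals)):
        if q < q_min:
            continue
        if b in "*>":
            pass  # placeholder: neither ref nor alt
        else:
            allele = site.ref_base if b == "." else b
            st = alleles.setdefault(allele, AlleleStats())
            if strand == "+":
                st.fwd += 1
            else:
                st.rev += 1
            st.qual_sum += q
        indel = site.indels.get(i)
        if indel is not None:
            st = alleles.setdefault(indel, AlleleStats())
            if strand == "+":
                st.fwd += 1
            else:
                st.rev += 1
            st.qual_sum += q
    return SiteSummary(site.contig, site.pos, site.ref_base, site.depth,
                       alleles, q_min)


def _fast_summarize(contig: str, pos: int, ref: str, bases: str, quals: str,
                    q_min: int) -> SiteSummary:
    """Fast path for base strings containing only '.' and ','."""
    st = AlleleStats()
    qcut = chr(q_min + 33)
    for b, q in zip(bases, quals):
        if q < qcut:
            continue
        if b == ".":
            st.fwd += 1
        else:
            st.rev += 1
        st.qual_sum += ord(q) - 33
    return SiteSummary(contig, pos, ref, len(bases), {ref: st}, q_min)


def iter_pileup(path: str | Path, q_min: int = 25) -> Iterator[SiteSummary]:
    """Stream SiteSummaries from a single-sample mpileup file."""
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise PileupParseError(f"expected 6 columns: {line!r}")
            contig, pos_s, ref, _depth, bases_s, quals_s = fields[:6]
            if _SPECIAL.search(bases_s) is None and len(bases_s) == len(quals_s):
                yield _fast_summarize(contig, int(pos_s), ref.upper(),
                                      bases_s, quals_s, q_min)
            else:
                yield summarize_site(parse_pileup_line(line), q_min)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_variants(summary: SiteSummary, thr: CallThresholds,
                  sample_id: str = "") -> list[VariantCall]:
    """One SNV call per non-reference base allele passing all thresholds.

    AAF is computed on the quality-filtered base depth, so the thresholds
    see the same denominator the editing level will use.
    """
    total = summary.qualified_depth
    if total < thr.min_depth:
        return []
    ref_stats = summary.alleles.get(summary.ref_base, AlleleStats())
    calls = []
    for allele in sorted(summary.alleles):
        if len(allele) != 1 or allele == summary.ref_base or allele == "N":
            continue
        st = summary.alleles[allele]
        if st.count < thr.min_alt_depth:
            continue
        aaf = st.count / total
        if aaf < thr.min_aaf:
            continue
        calls.append(VariantCall(
            sample_id=sample_id, contig=summary.contig, pos=summary.pos,
            ref_allele=summary.ref_base, alt_allele=allele,
            total_depth=total, alt_depth=st.count, aaf=aaf, kind=SNV,
            alt_fwd=st.fwd, alt_rev=st.rev,
            ref_fwd=ref_stats.fwd, ref_rev=ref_stats.rev,
            mean_alt_qual=st.mean_qual, mean_ref_qual=ref_stats.mean_qual,
        ))
    return calls


def call_indels(summary: SiteSummary, thr: CallThresholds,
                sample_id: str = "") -> list[VariantCall]:
    """Indel calls under the same thresholds; deletions are anchored at the
    base before the deleted run (mpileup convention)."""
    total = summary.qualified_depth
    if total < thr.min_depth:
        return []
    ref_stats = summary.alleles.get(summary.ref_base, AlleleStats())
    calls = []
    for allele in sorted(summary.alleles):
        if len(allele) <= 1:
            continue
        st = summary.alleles[allele]
        if st.count < thr.min_alt_depth:
            continue
        aaf = st.count / total
        if aaf < thr.min_aaf:
            continue
        seq = allele[1:]
        if allele[0] == "+":
            ref_a, alt_a, kind = summary.ref_base, summary.ref_base + seq, INS
        else:
            ref_a, alt_a, kind = summary.ref_base + seq, summary.ref_base, DEL
        calls.append(VariantCall(
            sample_id=sample_id, contig=summary.contig, pos=summary.pos,
            ref_allele=ref_a, alt_allele=alt_a,
            total_depth=total, alt_depth=st.count, aaf=aaf, kind=kind,
            alt_fwd=st.fwd, alt_rev=st.rev,
            ref_fwd=ref_stats.fwd, ref_rev=ref_stats.rev,
            mean_alt_qual=st.mean_qual, mean_ref_qual=ref_stats.mean_qual,
        ))
    return calls


def false_positive_filter(call: VariantCall,
                          params: FpFilterParams | None = None) -> tuple[bool, str | None]:
    """Screen a call for pileup-detectable false-positive signatures.

    Returns ``(passed, reason)``; reason is ``"strand_bias"`` when all alt
    observations sit on one strand (with enough of them to matter) while
    reference observations occur on both, or ``"low_alt_quality"`` when the
    alt mean base quality trails the ref mean by more than the allowed
    deficit.
    """
    params = params or FpFilterParams()
    one_sided = (call.alt_fwd == 0) != (call.alt_rev == 0)
    if (one_sided and call.alt_depth >= params.strand_min_alt
            and call.ref_fwd > 0 and call.ref_rev > 0):
        return False, "strand_bias"
    if (call.mean_alt_qual is not None and call.mean_ref_qual is not None
            and call.mean_alt_qual < call.mean_ref_qual - params.max_qual_deficit):
        return False, "low_alt_quality"
    return True, None


# ---------------------------------------------------------------------------
# per-sample pipeline
# ---------------------------------------------------------------------------

@dataclass
class SampleCalls:
    """All calling output for one sample, plus site-level lookups the
    downstream cascade needs (AAF at arbitrary sites, indel positions)."""

    sample_id: str
    snvs: dict[tuple[str, int, str, str], VariantCall]
    indels: list[VariantCall]
    failed: list[tuple[VariantCall, str]]
    site_depth: dict[tuple[str, int], int]                 # qualified depth
    site_allele_counts: dict[tuple[str, int], dict[str, int]]

    @property
    def indel_positions(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for c in self.indels:
            out.setdefault(c.contig, []).append(c.pos)
        return out

    def aaf_at(self, contig: str, pos: int, alt: str) -> float | None:
        """Quality-filtered AAF of ``alt`` at a site, called or not.

        None when the sample has no pileup record there.
        """
        depth = self.site_depth.get((contig, pos))
        if depth is None or depth == 0:
            return None
        counts = self.site_allele_counts.get((contig, pos), {})
        return counts.get(alt, 0) / depth


def process_sample(pileup_path: str | Path, sample_id: str,
                   thr: CallThresholds | None = None,
                   fp: FpFilterParams | None = None) -> SampleCalls:
    """Parse, summarize, call and fp-filter one sample's pileup file."""
    thr = thr or CallThresholds()
    snvs: dict[tuple[str, int, str, str], VariantCall] = {}
    indels: list[VariantCall] = []
    failed: list[tuple[VariantCall, str]] = []
    site_depth: dict[tuple[str, int], int] = {}
    site_counts: dict[tuple[str, int], dict[str, int]] = {}

    for summary in iter_pileup(pileup_path, thr.q_min):
        key = (summary.contig, summary.pos)
        site_depth[key] = summary.qualified_depth
        base_counts = {al: st.count for al, st in summary.alleles.items()
                       if len(al) == 1 and al != "*"}
        if len(base_counts) > 1 or any(al != summary.ref_base for al in base_counts):
            site_counts[key] = base_counts
        for call in call_variants(summary, thr, sample_id):
            ok, reason = false_positive_filter(call, fp)
            if ok:
                snvs[call.key] = call
            else:
                failed.append((call, reason))
        indels.extend(call_indels(summary, thr, sample_id))
    return SampleCalls(sample_id, snvs, indels, failed, site_depth, site_counts)


def synthesize_pileup_line(contig: str, pos: int, ref: str,
                           counts: dict[str, tuple[int, int]],
                           qual: int = 35) -> str:
    """Build an mpileup line from per-allele (fwd, rev) counts (test/round-trip aid)."""
    bases = []
    for allele, (fwd, rev) in counts.items():
        if allele == ref:
            bases.append("." * fwd + "," * rev)
        else:
            bases.append(allele.upper() * fwd + allele.lower() * rev)
    base_s = "".join(bases)
    qual_s = chr(qual + 33) * len(base_s)
    return f"{contig}\t{pos}\t{ref}\t{len(base_s)}\t{base_s}\t{qual_s}"
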