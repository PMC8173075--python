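"""Self-contained synthetic study generator.

Builds a small random genome with multi-exon genes on both strands, plants
editing sites (transcript-strand G-to-A: genomic G>A in plus-strand genes,
C>T in minus-strand genes), heterozygous and homozygous germline SNPs,
homopolymer / near-junction / mitochondrial artifact sites, and then
synthesizes per-sample mpileup text for a discovery design (control,
emotional-stress and physical-stress groups) plus an independent reference
cohort. The matching reference files (FASTA, GTF, repeat BED, known-variant
VCF, known-editing TSV) and a ground-truth table are written alongside, so
the whole pipeline can be exercised and scored without any external data.

Noise model: per-site depth ~ negative binomial; edited/variant reads ~
binomial(depth, level); sequencing errors replace a read's base uniformly
at the base error rate; base qualities ~ normal(35, 4) clipped to [2, 40];
read strands are fair coin flips except at strand-biased artifact sites,
whose alternative reads all land on the forward strand.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import HighConfidenceSet

GROUP_CONTROL = "control"
GROUP_ES = "es"
GROUP_PS = "ps"
GROUP_COHORT = "cohort"

ART_HOMOPOLYMER = "homopolymer"
ART_JUNCTION = "near_junction"
ART_MITO = "mitochondrial"

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# fixed gene architecture (1-based offsets relative to gene start)
_EXON_LEN = 300
_INTRON_LEN = 150
_N_EXONS = 3
_UTR_LEN = 60
_GENE_SPAN = _N_EXONS * _EXON_LEN + (_N_EXONS - 1) * _INTRON_LEN  # 1200
_GENE_SLOT = _GENE_SPAN + 300


@dataclass
class SimulationConfig:
    """Study design and noise parameters of the synthetic experiment.

    Defaults emulate the discovery design (three animals per group) with a
    larger independent reference cohort, sequencing depth around 50x, and a
    0.1% base-call error rate.
    """

    seed: int = 0
    n_control: int = 3
    n_csds_es: int = 3
    n_csds_ps: int = 3
    n_reference_cohort: int = 44
    n_genes: int = 10
    contig_length: int = 20_000
    mito_length: int = 1_000
    depth_mean: float = 50.0
    depth_dispersion: float = 8.0     # negative-binomial size parameter
    base_error_rate: float = 0.001
    qual_mean: float = 35.0
    qual_sd: float = 4.0
    n_edit_sites: int = 60
    n_diff_sites: int = 15
    diff_base_level: float = 0.10
    diff_delta: float = 0.20
    edit_level_range: tuple[float, float] = (0.02, 0.35)
    known_level_range: tuple[float, float] = (0.02, 0.90)
    n_germline_het: int = 20
    n_germline_hom: int = 10
    n_artifact_homopolymer: int = 5
    n_artifact_near_junction: int = 5
    n_artifact_mito: int = 2
    artifact_level: float = 0.20
    fraction_known: float = 0.30

    def __post_init__(self) -> None:
        for name in ("n_control", "n_csds_es", "n_csds_ps", "n_reference_cohort",
                     "n_genes", "n_edit_sites", "n_diff_sites", "n_germline_het",
                     "n_germline_hom", "n_artifact_homopolymer",
                     "n_artifact_near_junction", "n_artifact_mito"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_diff_sites > self.n_edit_sites:
            raise ValueError("n_diff_sites cannot exceed n_edit_sites")
        needed = 500 + self.n_genes * _GENE_SLOT
        if self.contig_length < needed:
            raise ValueError(
                f"contig_length {self.contig_length} too small for "
                f"{self.n_genes} genes; need at least {needed}")
        for lvl in (self.diff_base_level, self.diff_delta, self.artifact_level,
                    self.fraction_known):
            if not 0.0 <= lvl <= 1.0:
                raise ValueError("levels and fractions must lie in [0, 1]")


@dataclass
class PlantedSite:
    contig: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    strand: str
    level_control: float = 0.0
    level_es: float = 0.0
    level_ps: float = 0.0
    known: bool = False
    diff: bool = False
    category: str = "edit"            # edit | snp | artifact
    zygosity: str = ""                # het | hom for snps
    artifact_class: str = ""

    def level_for(self, group: str) -> float:
        if self.category == "snp":
            return 0.5 if self.zygosity == "het" else 1.0
        if group == GROUP_ES:
            return self.level_es
        if group == GROUP_PS:
            return self.level_ps
        return self.level_control      # control and reference cohort


@dataclass
class GroundTruth:
    edit_sites: list[PlantedSite] = field(default_factory=list)
    snps: list[PlantedSite] = field(default_factory=list)
    artifacts: list[PlantedSite] = field(default_factory=list)

    @property
    def all_sites(self) -> list[PlantedSite]:
        return self.edit_sites + self.snps + self.artifacts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.all_sites])


@dataclass
class GeneLayout:
    gene_id: str
    contig: str
    strand: str
    start: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def junctions(self) -> list[int]:
        out = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.extend((e1, s2))
        return out

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _gene_layouts(cfg: SimulationConfig) -> list[GeneLayout]:
    layouts = []
    for i in range(cfg.n_genes):
        start = 500 + i * _GENE_SLOT + 1
        exons = [(start + j * (_EXON_LEN + _INTRON_LEN),
                  start + j * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN - 1)
                 for j in range(_N_EXONS)]
        cds = [(exons[0][0] + _UTR_LEN, exons[0][1]),
               *[(s, e) for s, e in exons[1:-1]],
               (exons[-1][0], exons[-1][1] - _UTR_LEN)]
        total = sum(e - s + 1 for s, e in cds)
        trim = total % 3
        if trim:
            s_last, e_last = cds[-1]
            cds[-1] = (s_last, e_last - trim)
        layouts.append(GeneLayout(
            gene_id=f"gene{i:03d}", contig="chr1",
            strand="+" if i % 2 == 0 else "-", start=start,
            exons=exons, cds=cds))
    # one single-exon gene on the mitochondrial contig
    m_start, m_end = 201, 680
    layouts.append(GeneLayout(
        gene_id="mtgene", contig="chrM", strand="+", start=m_start,
        exons=[(m_start, m_end)], cds=[(m_start + 30, m_start + 30 + 420 - 1)]))
    return layouts


def _run_len_around(seq: list[str], pos0: int) -> int:
    """Longest run containing pos0 or an immediate neighbour (0-based)."""
    n = len(seq)
    best = 0
    for p in range(max(0, pos0 - 1), min(n - 1, pos0 + 1) + 1):
        b = seq[p]
        lo = p
        while lo > 0 and seq[lo - 1] == b:
            lo -= 1
        hi = p
        while hi < n - 1 and seq[hi + 1] == b:
            hi += 1
        best = max(best, hi - lo + 1)
    return best


class _Planter:
    """Draws non-interfering exonic positions and sets the required base."""

    def __init__(self, rng: np.random.Generator, seq: dict[str, list[str]],
                 layouts: list[GeneLayout]):
        self.rng = rng
        self.seq = seq
        self.layouts = [g for g in layouts if g.contig == "chr1"]
        self.mito = [g for g in layouts if g.contig == "chrM"]
        self.used: set[tuple[str, int]] = set()

    def _free(self, contig: str, pos: int, pad: int = 7) -> bool:
        return all((contig, p) not in self.used
                   for p in range(pos - pad, pos + pad + 1))

    def _reserve(self, contig: str, pos: int) -> None:
        self.used.add((contig, pos))

    def _eligible(self, gene: GeneLayout, margin: int = 8) -> list[int]:
        out = []
        for s, e in gene.exons:
            out.extend(range(s + margin, e - margin + 1))
        return out

    def plant(self, gene: GeneLayout, base_on_plus: str,
              positions: list[int] | None = None) -> int | None:
        """Place one site in `gene`, forcing the genomic base so the
        substitution reads G-to-A on the transcript strand."""
        want = base_on_plus if gene.strand == "+" else _COMP[base_on_plus]
        pool = positions if positions is not None else self._eligible(gene)
        pool = list(pool)
        self.rng.shuffle(pool)
        seq = self.seq[gene.contig]
        for pos in pool:
            if not self._free(gene.contig, pos):
                continue
            old = seq[pos - 1]
            seq[pos - 1] = want
            if _run_len_around(seq, pos - 1) >= 5:
                seq[pos - 1] = old
                continue
            self._reserve(gene.contig, pos)
            return pos
        return None

    def plant_homopolymer_adjacent(self, gene: GeneLayout) -> int | None:
        """Write a 5-nt run and place the site immediately abutting it."""
        want = "G" if gene.strand == "+" else "C"
        run_base = "A" if want != "A" else "T"
        pool = self._eligible(gene, margin=14)
        self.rng.shuffle(pool)
        seq = self.seq[gene.contig]
        for pos in pool:
            if not all(self._free(gene.contig, p) for p in (pos, pos + 6)):
                continue
            seq[pos - 1] = want
            for k in range(5):
                seq[pos + k] = run_base        # positions pos+1 .. pos+5
            # guard against the run merging with identical neighbours
            if seq[pos + 5] == run_base:
                seq[pos + 5] = want if want != run_base else "C"
            for p in range(pos - 1, pos + 7):
                self._reserve(gene.contig, p)
            return pos
        return None


def simulate_reference(cfg: SimulationConfig,
                       outdir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Write the reference bundle files and return their paths plus the
    planted ground truth. Deterministic in (cfg, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    seq = {
        "chr1": list(rng.choice(_BASES, size=cfg.contig_length)),
        "chrM": list(rng.choice(_BASES, size=cfg.mito_length)),
    }
    layouts = _gene_layouts(cfg)
    planter = _Planter(rng, seq, layouts)
    truth = GroundTruth()
    chr1_genes = planter.layouts

    def pick_gene() -> GeneLayout:
        return chr1_genes[int(rng.integers(len(chr1_genes)))]

    # --- artifacts -------------------------------------------------------
    for _ in range(cfg.n_artifact_homopolymer):
        gene = pick_gene()
        pos = planter.plant_homopolymer_adjacent(gene)
        if pos is None:
            continue
        ref = seq[gene.contig][pos - 1]
        alt = "A" if gene.strand == "+" else "T"
        truth.artifacts.append(PlantedSite(
            gene.contig, pos, ref, alt, gene.gene_id, gene.strand,
            category="artifact", artifact_class=ART_HOMOPOLYMER,
            level_control=cfg.artifact_level, level_es=cfg.artifact_level,
            level_ps=cfg.artifact_level))

    for _ in range(cfg.n_artifact_near_junction):
        gene = pick_gene()
        junction = gene.junctions[int(rng.integers(len(gene.junctions)))]
        offsets = [junction + d for d in range(-6, 7) if d != 0]
        exonic = [p for p in offsets
                  if any(s <= p <= e for s, e in gene.exons)]
        pos = planter.plant(gene, "G", positions=exonic)
        if pos is None:
            continue
        truth.artifacts.append(PlantedSite(
            gene.contig, pos, seq[gene.contig][pos - 1],
            "A" if gene.strand == "+" else "T", gene.gene_id, gene.strand,
            category="artifact", artifact_class=ART_JUNCTION,
            level_control=cfg.artifact_level, level_es=cfg.artifact_level,
            level_ps=cfg.artifact_level))

    for _ in range(cfg.n_artifact_mito):
        gene = planter.mito[0]
        pos = planter.plant(gene, "G")
        if pos is None:
            continue
        truth.artifacts.append(PlantedSite(
            gene.contig, pos, "G", "A", gene.gene_id, gene.strand,
            category="artifact", artifact_class=ART_MITO,
            level_control=cfg.artifact_level, level_es=cfg.artifact_level,
            level_ps=cfg.artifact_level))

    # --- editing sites ---------------------------------------------------
    known_flags = rng.random(cfg.n_edit_sites) < cfg.fraction_known
    for i in range(cfg.n_edit_sites):
        gene = pick_gene()
        pos = planter.plant(gene, "G")
        if pos is None:
            continue
        is_diff = i < cfg.n_diff_sites
        known = bool(known_flags[i])
        if is_diff:
            lv_ctrl = cfg.diff_base_level
            lv_es = lv_ps = cfg.diff_base_level + cfg.diff_delta
        else:
            lo, hi = cfg.known_level_range if known else cfg.edit_level_range
            lv_ctrl = lv_es = lv_ps = float(rng.uniform(lo, hi))
        truth.edit_sites.append(PlantedSite(
            gene.contig, pos, seq[gene.contig][pos - 1],
            "A" if gene.strand == "+" else "T", gene.gene_id, gene.strand,
            level_control=lv_ctrl, level_es=lv_es, level_ps=lv_ps,
            known=known, diff=is_diff))

    # --- germline SNPs (transcript-strand G>A, so they must be filtered) -
    for zyg, count in (("het", cfg.n_germline_het), ("hom", cfg.n_germline_hom)):
        for _ in range(count):
            gene = pick_gene()
            pos = planter.plant(gene, "G")
            if pos is None:
                continue
            truth.snps.append(PlantedSite(
                gene.contig, pos, seq[gene.contig][pos - 1],
                "A" if gene.strand == "+" else "T", gene.gene_id, gene.strand,
                category="snp", zygosity=zyg))

    # --- write files -----------------------------------------------------
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "repeats": outdir / "repeats.bed",
        "known_variants": outdir / "known_variants.vcf",
        "known_editing": outdir / "known_editing.tsv",
        "truth": outdir / "truth.tsv",
    }

    with open(paths["fasta"], "w") as fh:
        for contig in ("chr1", "chrM"):
            fh.write(f">{contig}\n")
            s = "".join(seq[contig])
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")

    with open(paths["gtf"], "w") as fh:
        for g in layouts:
            span = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id.upper()}"; gene_biotype "protein_coding";'
            fh.write(f"{g.contig}\tsim\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.contig}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.cds:
                fh.write(f"{g.contig}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t{attrs}\n")

    with open(paths["repeats"], "w") as fh:
        # repeats sit in introns/intergenic space, away from planted sites
        for g in chr1_genes[:3]:
            intron_start = g.exons[0][1] + 5
            fh.write(f"chr1\t{intron_start - 1}\t{intron_start + 30}\n")
        fh.write(f"chr1\t10\t60\n")

    with open(paths["known_variants"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##contig=<ID=chr1,length={cfg.contig_length}>\n')
        fh.write(f'##contig=<ID=chrM,length={cfg.mito_length}>\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(truth.snps, key=lambda x: (x.contig, x.pos)):
            fh.write(f"{s.contig}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\n")

    with open(paths["known_editing"], "w") as fh:
        fh.write("contig\tpos\tstrand\ttype\n")
        for s in truth.edit_sites:
            if s.known:
                fh.write(f"{s.contig}\t{s.pos}\t{s.strand}\tG-to-A\n")

    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths, truth


# ---------------------------------------------------------------------------
# pileup synthesis
# ---------------------------------------------------------------------------

def sample_sheet(cfg: SimulationConfig) -> dict[str, str]:
    """sample_id -> group for all simulated samples."""
    sheet = {}
    for i in range(cfg.n_control):
        sheet[f"control_{i+1}"] = GROUP_CONTROL
    for i in range(cfg.n_csds_es):
        sheet[f"es_{i+1}"] = GROUP_ES
    for i in range(cfg.n_csds_ps):
        sheet[f"ps_{i+1}"] = GROUP_PS
    for i in range(cfg.n_reference_cohort):
        sheet[f"ref_{i+1}"] = GROUP_COHORT
    return sheet


def simulate_pileups(cfg: SimulationConfig, truth: GroundTruth,
                     outdir: str | Path) -> dict[str, Path]:
    """Write one mpileup file per sample over all genic positions.

    Returns sample_id -> pileup path. Depth, strand, error and quality draws
    are consumed in a fixed order, so outputs are byte-identical for a given
    (cfg, truth, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)

    genome = _read_fasta_as_lists(outdir)
    layouts = _gene_layouts(cfg)
    positions: list[tuple[str, int]] = []
    for g in layouts:
        s, e = g.span
        positions.extend((g.contig, p) for p in range(s, e + 1))
    positions = sorted(set(positions))

    special = {(s.contig, s.pos): s for s in truth.all_sites}
    sheet = sample_sheet(cfg)
    nb_p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)

    paths = {}
    for sample_id, group in sheet.items():
        n = len(positions)
        depths = rng.negative_binomial(cfg.depth_dispersion, nb_p, size=n)
        total = int(depths.sum())
        quals = np.clip(np.rint(rng.normal(cfg.qual_mean, cfg.qual_sd, size=total)),
                        2, 40).astype(np.uint8)
        qual_bytes = (quals + 33).tobytes()
        offsets = np.concatenate([[0], np.cumsum(depths)])
        kf = rng.binomial(depths, 0.5)
        n_err = rng.binomial(depths, cfg.base_error_rate)

        path = outdir / f"{sample_id}.pileup"
        with open(path, "w") as fh:
            for i, (contig, pos) in enumerate(positions):
                d = int(depths[i])
                if d == 0:
                    continue
                qual_s = qual_bytes[offsets[i]:offsets[i] + d].decode("ascii")
                site = special.get((contig, pos))
                ref = genome[contig][pos - 1]
                if site is None and n_err[i] == 0:
                    k = int(kf[i])
                    base_s = "." * k + "," * (d - k)
                else:
                    level = site.level_for(group) if site is not None else 0.0
                    alt = site.alt if site is not None else "A"
                    biased = (site is not None
                              and site.artifact_class == ART_HOMOPOLYMER)
                    base_s = _simulate_reads(rng, d, level, alt, ref,
                                             cfg.base_error_rate, biased)
                fh.write(f"{contig}\t{pos}\t{ref}\t{d}\t{base_s}\t{qual_s}\n")
        paths[sample_id] = path
    return paths


def _simulate_reads(rng: np.random.Generator, depth: int, level: float,
                    alt: str, ref: str, error_rate: float,
                    strand_biased: bool) -> str:
    out = []
    for _ in range(depth):
        base = alt if rng.random() < level else ref
        if rng.random() < error_rate:
            others = [b for b in "ACGT" if b != base]
            base = others[int(rng.integers(3))]
        if strand_biased and base == alt:
            fwd = True
        else:
            fwd = bool(rng.random() < 0.5)
        if base == ref:
            out.append("." if fwd else ",")
        else:
            out.append(base if fwd else base.lower())
    return "".join(out)


def _read_fasta_as_lists(outdir: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(outdir / "genome.fa") as fh:
        for line in fh:
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].strip().split()[0], []
            else:
                chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def simulate_counts(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Simple gene-expression counts table (genes x samples) for the TPM path."""
    outdir = Path(outdir)
    rng = np.random.default_rng(cfg.seed + 2)
    layouts = _gene_layouts(cfg)
    sheet = sample_sheet(cfg)
    genes = [g.gene_id for g in layouts]
    lengths = {g.gene_id: sum(e - s + 1 for s, e in g.exons) for g in layouts}
    counts = pd.DataFrame(
        rng.negative_binomial(10, 10 / (10 + 200.0), size=(len(genes), len(sheet))),
        index=genes, columns=list(sheet))
    counts.insert(0, "length", [lengths[g] for g in genes])
    path = outdir / "counts.tsv"
    counts.to_csv(path, sep="\t", index_label="gene_id")
    return path


def simulate_study(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """One-call generator: reference bundle + pileups + counts + manifest."""
    outdir = Path(outdir)
    ref_paths, truth = simulate_reference(cfg, outdir)
    pileups = simulate_pileups(cfg, truth, outdir)
    counts = simulate_counts(cfg, outdir)
    sheet = sample_sheet(cfg)
    sheet_path = outdir / "samples.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in sheet.items():
            fh.write(f"{sid}\t{grp}\n")
    manifest = {
        "config": dataclasses.asdict(cfg),
        "reference": {k: str(v) for k, v in ref_paths.items()},
        "pileups": {k: str(v) for k, v in pileups.items()},
        "counts": str(counts),
        "samples": str(sheet_path),
        "groups": sheet,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["truth"] = truth
    return manifest


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(truth: GroundTruth, hcs: HighConfidenceSet,
                      diff: pd.DataFrame | None = None,
                      min_true_level: float = 0.1,
                      alpha: float = 0.05) -> dict:
    """Score pipeline output against the planted ground truth.

    Site metrics use exact position matching; differential metrics treat a
    planted shifted site as recovered when it is admitted and significant.
    """
    admitted = {(e.contig, e.pos) for e in hcs.events}
    edit_pos = {(s.contig, s.pos) for s in truth.edit_sites}
    target = {(s.contig, s.pos) for s in truth.edit_sites
              if max(s.level_control, s.level_es, s.level_ps) >= min_true_level}
    snp_pos = {(s.contig, s.pos) for s in truth.snps}
    artifact_pos = {(s.contig, s.pos) for s in truth.artifacts}

    tp = len(admitted & target)
    fp = len(admitted - edit_pos)
    metrics = {
        "n_admitted": len(admitted),
        "n_target_sites": len(target),
        "site_sensitivity": tp / len(target) if target else float("nan"),
        "site_fdr": fp / len(admitted) if admitted else 0.0,
        "n_snps_planted": len(snp_pos),
        "germline_removal_rate": (1.0 - len(admitted & snp_pos) / len(snp_pos)
                                  if snp_pos else float("nan")),
        "n_artifacts_admitted": len(admitted & artifact_pos),
        "n_artifacts_planted": len(artifact_pos),
    }

    if diff is not None:
        sig_pos = set()
        for event in diff.index[diff["significant"].fillna(False)]:
            contig, pos, _ = event.split(":", 2)
            sig_pos.add((contig, int(pos)))
        diff_true = {(s.contig, s.pos) for s in truth.edit_sites if s.diff}
        null_true = (edit_pos - diff_true) & admitted
        metrics.update({
            "n_diff_planted": len(diff_true),
            "diff_sensitivity": (len(sig_pos & diff_true) / len(diff_true)
                                 if diff_true else float("nan")),
            "n_null_admitted": len(null_true),
            "diff_fpr": (len(sig_pos & null_true) / len(null_true)
                         if null_true else float("nan")),
        })
    return metrics
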