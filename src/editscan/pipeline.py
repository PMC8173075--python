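"""End-to-end orchestration: pileups -> calls -> high-confidence events ->
differential editing -> enrichment.

Thin glue over the per-stage modules, so a whole study can be processed in
a few calls (or one, :func:`run_study`). The CLI wraps these functions.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .differential import (
    EditingMatrix,
    EnrichmentResult,
    compare_groups,
    multi_event_enrichment,
)
from .filters import (
    CascadeConfig,
    HighConfidenceSet,
    aggregate_per_gene,
    build_high_confidence_set,
)
from .pileup import CallThresholds, FpFilterParams, SampleCalls, process_sample
from .refmodel import ReferenceBundle, load_bundle
from .simulate import GROUP_COHORT


def load_manifest(run_dir: str | Path) -> dict:
    run_dir = Path(run_dir)
    path = run_dir / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"missing manifest: {path}")
    with open(path) as fh:
        return json.load(fh)


def bundle_from_manifest(manifest: dict) -> ReferenceBundle:
    ref = manifest["reference"]
    return load_bundle(ref["fasta"], ref["gtf"], ref["repeats"],
                       ref["known_variants"], ref["known_editing"])


def call_all_samples(pileups: dict[str, str | Path],
                     thr: CallThresholds | None = None,
                     fp: FpFilterParams | None = None) -> dict[str, SampleCalls]:
    """Run calling + false-positive filtering on every sample's pileup."""
    return {sid: process_sample(path, sid, thr, fp)
            for sid, path in sorted(pileups.items())}


def split_discovery_cohort(calls: dict[str, SampleCalls],
                           groups: dict[str, str]) -> tuple[dict, dict]:
    discovery = {sid: sc for sid, sc in calls.items()
                 if groups.get(sid) != GROUP_COHORT}
    cohort = {sid: sc for sid, sc in calls.items()
              if groups.get(sid) == GROUP_COHORT}
    return discovery, cohort


def identify_events(calls: dict[str, SampleCalls], groups: dict[str, str],
                    bundle: ReferenceBundle,
                    cfg: CascadeConfig | None = None) -> HighConfidenceSet:
    discovery, cohort = split_discovery_cohort(calls, groups)
    return build_high_confidence_set(discovery, cohort, bundle, cfg)


def differential_editing(hcs: HighConfidenceSet, groups: dict[str, str],
                         g1: str, g2: str, alpha: float = 0.05,
                         collapse_csds: bool = False,
                         fdr: bool = False) -> tuple[EditingMatrix, pd.DataFrame]:
    """Editing matrix over discovery samples plus the per-event t-test table.

    With ``collapse_csds`` the emotional- and physical-stress groups are
    pooled under the label ``csds`` before comparison.
    """
    labels = dict(groups)
    if collapse_csds:
        labels = {sid: ("csds" if grp in ("es", "ps") else grp)
                  for sid, grp in labels.items()}
    mat = EditingMatrix.from_high_confidence(hcs, labels)
    results = compare_groups(mat, g1, g2, alpha=alpha, fdr=fdr)
    return mat, results


def enrichment_from_results(hcs: HighConfidenceSet,
                            diff: pd.DataFrame) -> EnrichmentResult:
    """Table-style enrichment of differential editing in multi-event genes."""
    gene_counts = aggregate_per_gene(hcs)
    key_to_gene = {f"{e.contig}:{e.pos}:{e.ref_allele}>{e.alt_allele}": e.gene_id
                   for e in hcs.events}
    diff_genes = {key_to_gene[k] for k in diff.index[diff["significant"].fillna(False)]
                  if key_to_gene.get(k)}
    return multi_event_enrichment(gene_counts, diff_genes)


def run_study(run_dir: str | Path, g1: str = "control", g2: str = "csds",
              thr: CallThresholds | None = None,
              cascade: CascadeConfig | None = None,
              alpha: float = 0.05) -> dict:
    """Full pipeline on a simulated (or equivalently laid out) run directory."""
    manifest = load_manifest(run_dir)
    bundle = bundle_from_manifest(manifest)
    calls = call_all_samples(manifest["pileups"], thr)
    hcs = identify_events(calls, manifest["groups"], bundle, cascade)
    mat, diff = differential_editing(hcs, manifest["groups"], g1, g2,
                                     alpha=alpha, collapse_csds=(g2 == "csds"))
    enrich = (enrichment_from_results(hcs, diff) if hcs.events else None)
    return {"manifest": manifest, "bundle": bundle, "calls": calls,
            "events": hcs, "matrix": mat, "differential": diff,
            "enrichment": enrich}
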