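"""Differential editing between groups: t-tests, overlap, PCA, correlation.

Editing levels of admitted events are compared between control and stressed
samples with a pooled-variance Student's t-test (p < 0.05, uncorrected),
and the significant events are summarized by PCA.
"""

import numpy as np

from editscan import SimulationConfig, detection_overlap, simulate_study, spearman_correlation
from editscan.differential import pca_events
from editscan.pipeline import (
    bundle_from_manifest,
    call_all_samples,
    differential_editing,
    identify_events,
)

cfg = SimulationConfig(seed=11, n_reference_cohort=8)
manifest = simulate_study(cfg, "scratch_example_run")
bundle = bundle_from_manifest(manifest)
calls = call_all_samples(manifest["pileups"])
hcs = identify_events(calls, manifest["groups"], bundle)

mat, diff = differential_editing(hcs, manifest["groups"], "control", "csds",
                                 collapse_csds=True)
sig = diff.index[diff["significant"]].tolist()
up = (diff.loc[sig, "direction"] == "up").sum()
print(f"{len(sig)} of {len(diff)} events differ at p<0.05 "
      f"({up} up in stress, {len(sig) - up} down)")

scores, frac = pca_events(mat, sig)
print(f"PCA of differential events: PC1 explains {100 * frac[0]:.1f}% of variance")
print(scores.iloc[:, :2].round(3))

# detection overlap between two samples' event sets
s1, s2 = mat.levels.columns[:2]
set1 = set(mat.levels.index[mat.levels[s1].notna()])
set2 = set(mat.levels.index[mat.levels[s2].notna()])
print("overlap:", detection_overlap(set1, set2))

# editing levels of two samples from the same group correlate strongly
pair = mat.levels[[s1, s2]].dropna()
rho = spearman_correlation(pair[s1], pair[s2])
print(f"Spearman rho between {s1} and {s2}: {rho:.3f}")
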