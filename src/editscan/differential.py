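"""Group comparisons of editing levels and the multi-event-gene enrichment test.

Per-event differences in editing level between groups are tested with the
classic two-sample Student's t-test (pooled variance), significant at
p < 0.05 with no multiple-testing correction by default; an optional
Benjamini-Hochberg FDR is available. Enrichment of differential editing in
genes carrying more than one event is assessed with a two-sided Fisher's
exact test on a 2x2 table plus an odds ratio with a Woolf log-interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, exp, log, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .filters import HighConfidenceSet

UP = "up"
DOWN = "down"
NONE = "none"


# ---------------------------------------------------------------------------
# editing matrix
# ---------------------------------------------------------------------------

@dataclass
class EditingMatrix:
    """Events x samples editing levels (fractions in [0,1], NaN = missing)."""

    levels: pd.DataFrame               # index: event key strings, columns: samples
    groups: pd.Series                  # sample -> group label

    def __post_init__(self) -> None:
        if not set(self.levels.columns) <= set(self.groups.index):
            raise ValueError("every sample column needs a group label")
        vals = self.levels.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("editing levels must lie in [0, 1]")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.levels.columns if self.groups.get(s) == group]

    @classmethod
    def from_high_confidence(cls, hcs: HighConfidenceSet,
                             groups: dict[str, str]) -> "EditingMatrix":
        rows = {}
        for ev in hcs.events:
            key = f"{ev.contig}:{ev.pos}:{ev.ref_allele}>{ev.alt_allele}"
            rows[key] = {sid: (np.nan if lvl is None else lvl)
                         for sid, lvl in ev.levels.items()}
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=hcs.discovery_samples, dtype=float)
        return cls(df, pd.Series(groups))

    def to_tsv(self, path: str | Path) -> None:
        out = self.levels.copy()
        out.index.name = "event"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, groups: dict[str, str]) -> "EditingMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df, pd.Series(groups))


# ---------------------------------------------------------------------------
# per-event two-group comparison
# ---------------------------------------------------------------------------

def compare_groups(mat: EditingMatrix, g1: str, g2: str,
                   alpha: float = 0.05, min_n: int = 2,
                   welch: bool = False, fdr: bool = False) -> pd.DataFrame:
    """Student's t-test per event between two groups.

    Events with fewer than ``min_n`` non-missing values in either group are
    reported untestable. Zero pooled variance is handled deterministically:
    p = 1 (t = 0) for equal means, p = 0 for different means, flagged
    ``degenerate``. Direction is the sign of mean(g2) - mean(g1).
    """
    s1, s2 = mat.samples_in(g1), mat.samples_in(g2)
    if not s1:
        raise ValueError(f"group {g1!r} absent from matrix")
    if not s2:
        raise ValueError(f"group {g2!r} absent from matrix")

    rows = []
    for event, row in mat.levels.iterrows():
        x = row[s1].dropna().to_numpy(dtype=float)
        y = row[s2].dropna().to_numpy(dtype=float)
        rec = {"event": event, "n_g1": len(x), "n_g2": len(y),
               "mean_g1": x.mean() if len(x) else np.nan,
               "mean_g2": y.mean() if len(y) else np.nan,
               "t": np.nan, "p": np.nan, "direction": NONE,
               "testable": len(x) >= min_n and len(y) >= min_n,
               "degenerate": False}
        if rec["testable"]:
            diff = rec["mean_g2"] - rec["mean_g1"]
            if _is_constant(x) and _is_constant(y):
                rec["degenerate"] = True
                rec["t"] = 0.0 if diff == 0 else np.inf * np.sign(diff)
                rec["p"] = 1.0 if diff == 0 else 0.0
            else:
                t, p = stats.ttest_ind(y, x, equal_var=not welch)
                rec["t"], rec["p"] = float(t), float(p)
            rec["direction"] = UP if diff > 0 else (DOWN if diff < 0 else NONE)
        rows.append(rec)

    out = pd.DataFrame(rows).set_index("event")
    if fdr:
        mask = out["testable"] & out["p"].notna()
        out["p_adj"] = np.nan
        out.loc[mask, "p_adj"] = _bh_adjust(out.loc[mask, "p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["testable"] & (out["p"] < alpha)
    return out


def _is_constant(v: np.ndarray) -> bool:
    # variance of numerically identical values is not exactly 0 in floats
    scale = max(1.0, float(np.abs(v).max(initial=0.0)))
    return float(v.var(ddof=1)) <= (1e-12 * scale) ** 2


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# set overlap, PCA, correlation
# ---------------------------------------------------------------------------

def detection_overlap(set_a: set, set_b: set) -> dict:
    """Shared / A-only / B-only counts with fractions of the union."""
    shared = set_a & set_b
    a_only = set_a - set_b
    b_only = set_b - set_a
    union = len(set_a | set_b)
    frac = (lambda k: k / union if union else 0.0)
    return {
        "shared": len(shared), "a_only": len(a_only), "b_only": len(b_only),
        "union": union,
        "frac_shared": frac(len(shared)),
        "frac_a_only": frac(len(a_only)),
        "frac_b_only": frac(len(b_only)),
    }


def pca_events(mat: EditingMatrix,
               events: list[str] | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over (a subset of) events.

    Missing entries are imputed with the event-wise mean; the matrix is
    centered but not scaled. Returns sample scores and variance-explained
    fractions over all components.
    """
    df = mat.levels if events is None else mat.levels.loc[events]
    X = df.to_numpy(dtype=float).T          # samples x events
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    col_means = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(col_means, idx[1])
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValueError("degenerate: zero variance across samples")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    scores = pd.DataFrame(u * s, index=df.columns,
                          columns=[f"PC{i+1}" for i in range(len(s))])
    return scores, frac


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation with average ranks for ties; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# Fisher's exact test and odds ratio
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """Rows: gene not differential / differential; columns: 1 event / >1 event."""

    a: int  # not differential, single event
    b: int  # not differential, multiple events
    c: int  # differential, single event
    d: int  # differential, multiple events

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p: sum of hypergeometric probabilities of all
    tables with the observed margins that are no more probable than the
    observed one. Exact integer arithmetic; no rounding until the final ratio.
    """
    a, b, c, d = table.cells
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    total = comb(n, c1)
    acc = sum(w for w in weights.values() if w <= obs)
    return acc / total


def odds_ratio_with_ci(table: ContingencyTable2x2,
                       level: float = 0.95) -> tuple[float, float, float, bool]:
    """Sample odds ratio (a*d)/(b*c) with a Woolf log-method interval.

    A zero cell triggers the Haldane-Anscombe +0.5 correction on all cells;
    the returned flag reports whether the correction was applied.
    """
    a, b, c, d = table.cells
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    orr = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = exp(log(orr) - z * se)
    hi = exp(log(orr) + z * se)
    return orr, lo, hi, corrected


@dataclass
class EnrichmentResult:
    table: ContingencyTable2x2
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False


def multi_event_enrichment(gene_counts: dict[str, int],
                           diff_genes: set[str],
                           level: float = 0.95) -> EnrichmentResult:
    """Test whether differentially edited genes are enriched among genes
    carrying more than one editing event.
    """
    if not gene_counts:
        raise ValueError("gene_counts is empty")
    unknown = diff_genes - set(gene_counts)
    if unknown:
        raise ValueError(f"differential genes missing from counts: {sorted(unknown)[:5]}")
    a = sum(1 for g, k in gene_counts.items() if g not in diff_genes and k == 1)
    b = sum(1 for g, k in gene_counts.items() if g not in diff_genes and k > 1)
    c = sum(1 for g, k in gene_counts.items() if g in diff_genes and k == 1)
    d = sum(1 for g, k in gene_counts.items() if g in diff_genes and k > 1)
    table = ContingencyTable2x2(a, b, c, d)
    p = fisher_exact_two_sided(table)
    orr, lo, hi, corrected = odds_ratio_with_ci(table, level)
    return EnrichmentResult(table, p, orr, lo, hi, corrected)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def tpm_from_counts(counts: dict[str, int] | pd.Series,
                    lengths: dict[str, int] | pd.Series) -> pd.Series:
    """Transcripts per million from raw counts and gene lengths (nt).

    rate_g = counts_g / length_kb; TPM_g = 1e6 * rate_g / sum(rates).
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive length")
    rates = counts / (lengths / 1000.0)
    total = rates.sum()
    if total == 0:
        import warnings
        warnings.warn("all-zero counts: TPM undefined, returning zeros")
        return rates * 0.0
    return 1e6 * rates / total


def compare_expression(tpm: pd.DataFrame, groups: dict[str, str],
                       g1: str, g2: str, alpha: float = 0.05,
                       min_n: int = 2) -> pd.DataFrame:
    """Per-gene t-test of log2(TPM+1) between groups (same machinery as
    compare_groups)."""
    logged = np.log2(tpm + 1.0)
    # reuse compare_groups by wrapping in a matrix without the [0,1] constraint
    mat = EditingMatrix.__new__(EditingMatrix)
    mat.levels = logged
    mat.groups = pd.Series(groups)
    return compare_groups(mat, g1, g2, alpha=alpha, min_n=min_n)
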