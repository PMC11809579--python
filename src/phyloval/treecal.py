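"""Tree-space validation: reference-tree distance ranking and clade coverage.

Two procedures lift coverage validation and rank-uniformity validation
from scalars into tree space:

1. *Reference-tree distance ranking.*  A reference tree drawn from the
   same tree prior maps every tree to a scalar — its distance (here the
   rooted Robinson--Foulds distance, but any ``(tree, tree) -> real``
   metric plugs in) to the reference.  The true tree's distance is then
   ranked among the distances of its posterior samples exactly as a scalar
   parameter would be; tie randomization is essential because small trees
   admit few distinct RF values.

2. *Clade-support coverage.*  Pooling (clade, posterior support, is-true)
   records across replicates of equal tip count, true clades should appear
   among clades of support u at rate u: clades with support ~0.1 should be
   true ~10% of the time.  Each support bin gets a binomial test against
   the mean support of the clades it contains, Bonferroni-corrected.

A scalar bridge (``functional_replicates``) runs the ordinary machinery on
root ages, tree lengths, etc.  The shared-clade Poisson law quantifies why
RF-based checks lose power on large trees: two independent random trees
share a near-Poisson(cherries / 2s) number of clades, which for Yule trees
asymptotes to rate 1/6 — an ~85% chance of sharing none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import (
    CoverageReport,
    RankRecord,
    ReplicateResult,
    coverage_count,
    sbc_rank,
)
from .treekit import Clade, PhyloTree, TaxonMismatchError, clade_set, rf_distance

__all__ = [
    "TreeReplicate",
    "CladeCalibration",
    "reference_tree_ranks",
    "tree_coverage",
    "functional_replicates",
    "shared_clade_law",
    "yule_asymptotic_shared_clade_rate",
    "prob_no_shared_clades",
    "clade_support",
    "clade_calibration",
]


@dataclass
class TreeReplicate:
    """True tree, its L posterior tree samples, and the reference tree."""

    index: int
    true_tree: PhyloTree
    samples: list[PhyloTree]
    reference: PhyloTree | None = None

    def check_taxa(self) -> None:
        taxa = self.true_tree.taxa
        for t in self.samples:
            if t.taxa != taxa:
                raise TaxonMismatchError(
                    f"replicate {self.index}: sample taxon set differs from the true tree"
                )
        if self.reference is not None and self.reference.taxa != taxa:
            raise TaxonMismatchError(
                f"replicate {self.index}: reference taxon set differs from the true tree"
            )


Metric = Callable[[PhyloTree, PhyloTree], float]


def reference_tree_ranks(
    replicates: Sequence[TreeReplicate],
    rng: np.random.Generator,
    metric: Metric = rf_distance,
) -> list[RankRecord]:
    """Rank each true tree's reference distance among its samples' distances."""
    ranks = []
    for rep in replicates:
        if rep.reference is None:
            raise ValueError(f"replicate {rep.index} has no reference tree")
        rep.check_taxa()
        d0 = float(metric(rep.reference, rep.true_tree))
        dj = np.array([metric(rep.reference, t) for t in rep.samples], dtype=float)
        ranks.append(sbc_rank(d0, dj, rng))
    return ranks


def tree_coverage(
    replicates: Sequence[TreeReplicate],
    metric: Metric = rf_distance,
    alpha: float = 0.95,
    parameter: str = "rf_to_reference",
) -> CoverageReport:
    """HPD coverage of the true tree's reference distance, per replicate."""
    results = []
    for rep in replicates:
        if rep.reference is None:
            raise ValueError(f"replicate {rep.index} has no reference tree")
        rep.check_taxa()
        d0 = float(metric(rep.reference, rep.true_tree))
        dj = np.array([metric(rep.reference, t) for t in rep.samples], dtype=float)
        results.append(ReplicateResult(rep.index, d0, dj))
    return coverage_count(results, alpha, parameter=parameter)


def functional_replicates(
    replicates: Sequence[TreeReplicate],
    functional: Callable[[PhyloTree], float],
) -> list[ReplicateResult]:
    """Map tree replicates to scalar replicates so calibrate ops apply unchanged."""
    out = []
    for rep in replicates:
        out.append(
            ReplicateResult(
                rep.index,
                float(functional(rep.true_tree)),
                np.array([functional(t) for t in rep.samples], dtype=float),
            )
        )
    return out


# ----------------------------------------------------------------------
# shared-clade law
# ----------------------------------------------------------------------

def shared_clade_law(n_tips: int, cherries: int) -> float:
    """Poisson rate for the clades shared by two independent random s-tip trees.

    For large s the shared-clade count is approximately Poisson with rate
    cherries / (2 * s).  With the Yule cherry-count asymptote s/3 the rate
    tends to 1/6.
    """
    if n_tips < 4:
        raise ValueError("law stated for n_tips >= 4")
    if not 1 <= cherries <= n_tips / 2:
        raise ValueError(f"cherry count {cherries} impossible for {n_tips} tips")
    return cherries / (2.0 * n_tips)


def yule_asymptotic_shared_clade_rate() -> float:
    """Limit rate (s/3) / (2s) = 1/6 for two large independent Yule trees."""
    return 1.0 / 6.0


def prob_no_shared_clades(rate: float) -> float:
    """Zero class of the Poisson shared-clade law (~0.85 at rate 1/6)."""
    return math.exp(-rate)


# ----------------------------------------------------------------------
# clade support and calibration
# ----------------------------------------------------------------------

def clade_support(samples: Sequence[PhyloTree]) -> dict[Clade, float]:
    """Posterior support (occurrence fraction) of every sampled nontrivial clade.

    All samples must share one taxon set.  Supports over all clades sum to
    s - 2 exactly, since each binary rooted sample contributes s - 2
    nontrivial clades.
    """
    if not samples:
        raise ValueError("need at least one tree sample")
    taxa = samples[0].taxa
    counts: dict[Clade, int] = {}
    for t in samples:
        if t.taxa != taxa:
            raise TaxonMismatchError("tree samples mix different taxon sets")
        for c in clade_set(t):
            counts[c] = counts.get(c, 0) + 1
    L = len(samples)
    return {c: k / L for c, k in sorted(counts.items())}


@dataclass
class CladeCalibration:
    table: pd.DataFrame   # bin_lo, bin_hi, n_clades, n_true, frac_true, target, p, p_corrected
    passed: bool
    n_records: int
    records: pd.DataFrame = field(repr=False, default=None)


def clade_calibration(
    replicates: Sequence[TreeReplicate],
    bin_width: float = 0.1,
    reject_level: float = 0.05,
) -> CladeCalibration:
    """Calibration of clade posterior support against the true-clade fraction.

    Pools (clade, support, is-true) records over replicates (all of the
    same tip count — the procedure is undefined otherwise), bins supports
    into left-open right-closed bins of ``bin_width``, and per bin tests
    ``#true ~ Binomial(#clades, mean support in bin)`` with a two-sided
    exact test, Bonferroni-corrected across occupied bins.  The mean
    in-bin support (not the bin midpoint) is the correct target because
    sampled supports are far from uniform within a bin.
    """
    sizes = {len(rep.true_tree.tips()) for rep in replicates}
    if len(sizes) != 1:
        raise ValueError(
            "clade calibration requires that the tree model only generates "
            f"trees of the same size; got tip counts {sorted(sizes)}"
        )
    nbins = round(1.0 / bin_width)
    if abs(nbins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin width must divide 1")
    rows = []
    for rep in replicates:
        rep.check_taxa()
        true_clades = clade_set(rep.true_tree)
        for clade, support in clade_support(rep.samples).items():
            rows.append(
                (rep.index, clade.mask, support, clade in true_clades)
            )
    records = pd.DataFrame(rows, columns=["replicate", "clade", "support", "is_true"])
    out = []
    all_pass = True
    for b in range(nbins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        sel = records[(records.support > lo + 1e-12) & (records.support <= hi + 1e-12)]
        n = len(sel)
        if n == 0:
            out.append((lo, hi, 0, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        k = int(sel.is_true.sum())
        target = float(sel.support.mean())
        p = float(stats.binomtest(k, n, min(max(target, 1e-12), 1 - 1e-12)).pvalue)
        out.append((lo, hi, n, k, k / n, target, p, np.nan))
    table = pd.DataFrame(
        out,
        columns=["bin_lo", "bin_hi", "n_clades", "n_true", "frac_true", "target", "p", "p_corrected"],
    )
    occupied = table.n_clades > 0
    n_tests = int(occupied.sum())
    table.loc[occupied, "p_corrected"] = np.minimum(1.0, table.loc[occupied, "p"] * n_tests)
    all_pass = bool((table.loc[occupied, "p_corrected"] >= reject_level).all())
    return CladeCalibration(table=table, passed=all_pass, n_records=len(records), records=records)
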