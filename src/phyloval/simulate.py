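"""Direct simulators for the generative models, and simulator moment checks.

The models covered are the ones the validation scenarios are built from:

* log-normal hyperpriors for the birth rate ``lambda`` and the trait
  evolutionary rate ``r``;
* the Yule (pure-birth) tree process, conditioned either on a target tip
  count ``s`` or on an origin age ``tau``;
* the Kingman coalescent with effective population size ``Ne``;
* phylogenetic Brownian motion (one continuous trait per tip, variance
  accumulating at rate ``r`` per unit branch length, started at the root
  state ``y0``; the stem branch carries no trait evolution).

All simulators draw from a caller-supplied :class:`numpy.random.Generator`
and are byte-reproducible given the same seed.  ``moment_check`` implements
the batch confidence-interval protocol used to validate a simulator against
a closed-form expectation (e.g. the Yule root-height formula
``E[t_root] = sum_{i=2}^{s} 1/(i*lambda)``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .treekit import PhyloTree, TreeNode, root_height, tip_count, write_newick, parse_newick

__all__ = [
    "LogNormalParams",
    "YuleParams",
    "CoalescentParams",
    "BMParams",
    "RejectionRule",
    "RejectionError",
    "sample_lognormal",
    "simulate_yule",
    "simulate_yule_ntips",
    "simulate_yule_origin",
    "simulate_coalescent",
    "simulate_phylo_bm",
    "rejection_sample",
    "tip_count_rule",
    "yule_root_height_expectation",
    "moment_check",
    "MomentCheckResult",
    "SimulatedReplicate",
    "write_replicate_set",
    "read_replicate_set",
]


# ----------------------------------------------------------------------
# parameter blocks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormalParams:
    """log(x) ~ Normal(m, s^2); median exp(m), mean exp(m + s^2/2)."""

    m: float
    s: float

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("log-normal scale s must be > 0")


@dataclass(frozen=True)
class YuleParams:
    """Pure-birth process with per-lineage rate ``birth_rate``.

    Exactly one conditioning mode must be set: a target tip count
    ``n_tips`` (the process is stopped when the next birth would create
    tip ``n_tips + 1``) or an origin age ``origin_age`` (the process runs
    from a single stem lineage for that much time; the tip count is then
    random and geometric).
    """

    birth_rate: float
    n_tips: int | None = None
    origin_age: float | None = None

    def __post_init__(self):
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be > 0")
        if (self.n_tips is None) == (self.origin_age is None):
            raise ValueError("set exactly one of n_tips / origin_age")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("tip-count conditioning requires n_tips >= 2")
        if self.origin_age is not None and self.origin_age <= 0:
            raise ValueError("origin age must be > 0")


@dataclass(frozen=True)
class CoalescentParams:
    n_tips: int
    ne: float = 1.0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("coalescent requires >= 2 tips")
        if self.ne <= 0:
            raise ValueError("effective population size must be > 0")


@dataclass(frozen=True)
class BMParams:
    """Brownian-motion trait model: rate ``r`` (variance/time), root state ``y0``."""

    r: float
    y0: float = 0.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("BM rate must be > 0")


class RejectionError(RuntimeError):
    """Rejection sampler exhausted its attempt budget."""


@dataclass(frozen=True)
class RejectionRule:
    predicate: Callable[[PhyloTree], bool]
    max_attempts: int = 100_000
    description: str = ""

    def __post_init__(self):
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def tip_count_rule(lo: int, hi: int, max_attempts: int = 100_000) -> RejectionRule:
    """Keep trees whose tip count is in [lo, hi] (inclusive)."""
    return RejectionRule(
        predicate=lambda t: lo <= tip_count(t) <= hi,
        max_attempts=max_attempts,
        description=f"tip count in [{lo}, {hi}]",
    )


# ----------------------------------------------------------------------
# scalar draws
# ----------------------------------------------------------------------

def sample_lognormal(params: LogNormalParams, rng: np.random.Generator, size=None):
    return np.exp(rng.normal(params.m, params.s, size=size))


# ----------------------------------------------------------------------
# tree simulators
# ----------------------------------------------------------------------

def _label_tips(tips: list[TreeNode], rng: np.random.Generator) -> None:
    # uniform random assignment: labels are exchangeable under Yule/coalescent
    n = len(tips)
    perm = rng.permutation(n)
    for i, tip in enumerate(tips):
        tip.label = f"t{perm[i] + 1}"


def simulate_yule(params: YuleParams, rng: np.random.Generator) -> PhyloTree:
    """Dispatch on the conditioning mode of ``params``."""
    if params.n_tips is not None:
        return simulate_yule_ntips(params.birth_rate, params.n_tips, rng)
    return simulate_yule_origin(params.birth_rate, params.origin_age, rng)


def simulate_yule_ntips(birth_rate: float, n_tips: int, rng: np.random.Generator) -> PhyloTree:
    """Forward pure-birth run stopped at ``n_tips`` extant lineages.

    While ``k`` lineages are alive the next split happens after an
    Exponential(k * birth_rate) wait, with the splitting lineage chosen
    uniformly.  After the split creating tip ``n_tips``, one further wait
    (the time until the birth that would create tip ``n_tips + 1``) is run
    out without splitting, so the present lies inside the ``n_tips``-lineage
    epoch and ``E[t_root] = sum_{i=2}^{s} 1/(i * birth_rate)``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    t = 0.0
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    while len(active) <= n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        if k == n_tips:
            break  # the (s+1)-th birth marks the present; do not execute it
        idx = int(rng.integers(k))
        node, birth = active[idx]
        node.length = t - birth
        left, right = TreeNode(), TreeNode()
        node.add_child(left)
        node.add_child(right)
        active[idx] = (left, t)
        active.append((right, t))
    for node, birth in active:
        node.length = t - birth
    stem = root.length
    root.length = None
    _label_tips([n for n, _ in active], rng)
    tree = PhyloTree(root, origin_age=t)
    assert abs((t - stem) - root_height(tree)) <= 1e-9 * max(t, 1.0)
    return tree


def simulate_yule_origin(birth_rate: float, origin_age: float, rng: np.random.Generator) -> PhyloTree:
    """Forward pure-birth run from one stem lineage for ``origin_age`` time units.

    The number of surviving tips N is geometric:
    P(N = k) = exp(-b*tau) * (1 - exp(-b*tau))^(k-1).  A single-tip tree
    (the root is the tip) is a legal outcome.
    """
    if birth_rate <= 0 or origin_age <= 0:
        raise ValueError("birth rate and origin age must be > 0")
    t = 0.0
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    while True:
        k = len(active)
        w = rng.exponential(1.0 / (k * birth_rate))
        if t + w >= origin_age:
            break
        t += w
        idx = int(rng.integers(k))
        node, birth = active[idx]
        node.length = t - birth
        left, right = TreeNode(), TreeNode()
        node.add_child(left)
        node.add_child(right)
        active[idx] = (left, t)
        active.append((right, t))
    for node, birth in active:
        node.length = origin_age - birth
    root.length = None
    _label_tips([n for n, _ in active], rng)
    return PhyloTree(root, origin_age=origin_age)


def simulate_coalescent(params: CoalescentParams, rng: np.random.Generator) -> PhyloTree:
    """Standard Kingman coalescent: k lineages merge at rate k(k-1)/(2*Ne)."""
    s, ne = params.n_tips, params.ne
    t = 0.0
    active: list[tuple[TreeNode, float]] = [(TreeNode(f"t{i + 1}"), 0.0) for i in range(s)]
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 * ne / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False).tolist())
        (a, age_a), (b, age_b) = active[i], active[j]
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        a.length = t - age_a
        b.length = t - age_b
        active[i] = (parent, t)
        del active[j]
    root = active[0][0]
    root.length = None
    return PhyloTree(root, origin_age=None)


def simulate_phylo_bm(
    tree: PhyloTree, params: BMParams, rng: np.random.Generator
) -> dict[str, float]:
    """Simulate one continuous trait per tip by recursive Brownian motion.

    Equivalent to a multivariate-normal draw with mean ``y0`` and covariance
    ``r * C`` where C[i, j] is the root-to-MRCA shared path length of tips
    i and j.  Returns ``{tip label: value}``.
    """
    values: dict[TreeNode, float] = {tree.root: params.y0}
    for node in tree.preorder():
        if node is tree.root:
            continue
        values[node] = values[node.parent] + rng.normal(
            0.0, math.sqrt(params.r * node.length)
        )
    return {tip.label: values[tip] for tip in tree.tips()}


def rejection_sample(
    simulator: Callable[[np.random.Generator], PhyloTree],
    rule: RejectionRule,
    rng: np.random.Generator,
) -> tuple[PhyloTree, int]:
    """Draw from ``simulator`` until ``rule.predicate`` holds.

    Returns the accepted draw and the number of attempts (1 = first draw
    accepted), so callers can track the empirical rejection fraction.
    """
    for attempt in range(1, rule.max_attempts + 1):
        tree = simulator(rng)
        if rule.predicate(tree):
            return tree, attempt
    raise RejectionError(
        f"no draw satisfied predicate {rule.description or rule.predicate!r} "
        f"in {rule.max_attempts} attempts"
    )


# ----------------------------------------------------------------------
# moment validation
# ----------------------------------------------------------------------

def yule_root_height_expectation(birth_rate: float, n_tips: int) -> float:
    """Closed-form expected root height of a Yule tree with ``n_tips`` tips."""
    if n_tips < 2:
        raise ValueError("expectation defined for n_tips >= 2")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    return sum(1.0 / (i * birth_rate) for i in range(2, n_tips + 1))


@dataclass
class MomentCheckResult:
    covered_fraction: float
    n_batches: int          # batches actually used (degenerate ones excluded)
    n_excluded: int
    records: pd.DataFrame   # batch, mean, se, lower, upper, covered

    @property
    def covered_count(self) -> int:
        return int(round(self.covered_fraction * self.n_batches))


def moment_check(
    simulator: Callable[[np.random.Generator], Any],
    statistic: Callable[[Any], float],
    theoretical: float,
    batches: int,
    batch_size: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> MomentCheckResult:
    """Batch CI protocol for validating a simulator against a known moment.

    For each batch, ``batch_size`` independent draws are reduced to the
    statistic, and a normal-approximation interval mean +/- z(level)*SE is
    formed; the result records how often the theoretical value is covered.
    Under a correct simulator the covered count is ~ Binomial(batches,
    level), so it should fall inside the central binomial bounds for that
    level (e.g. 90..99 out of 100 at the 95% level).
    """
    from scipy.stats import norm

    if batches < 2 or batch_size < 2:
        raise ValueError("need at least 2 batches of at least 2 draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    excluded = 0
    for b in range(batches):
        vals = np.array([statistic(simulator(rng)) for _ in range(batch_size)])
        sd = vals.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"batch {b}: zero-variance statistic, excluded from coverage")
            excluded += 1
            rows.append((b, vals.mean(), 0.0, vals.mean(), vals.mean(), None))
            continue
        se = sd / math.sqrt(batch_size)
        lo, hi = vals.mean() - z * se, vals.mean() + z * se
        rows.append((b, vals.mean(), se, lo, hi, bool(lo <= theoretical <= hi)))
    df = pd.DataFrame(rows, columns=["batch", "mean", "se", "lower", "upper", "covered"])
    used = df[df.covered.notna()]
    frac = float(used.covered.mean()) if len(used) else float("nan")
    return MomentCheckResult(frac, len(used), excluded, df)


# ----------------------------------------------------------------------
# replicate-set I/O
# ----------------------------------------------------------------------

@dataclass
class SimulatedReplicate:
    """One draw of the hierarchical model: parameters, tree, tip traits."""

    index: int
    params: dict[str, float]            # e.g. lambda, r, tau, y0
    tree: PhyloTree
    traits: dict[str, float] = field(default_factory=dict)


def write_replicate_set(
    outdir: str | Path,
    replicates: Sequence[SimulatedReplicate],
    manifest: dict | None = None,
) -> Path:
    """Write a replicate set: per-replicate Newick + trait TSV, a parameter
    table, and a JSON manifest with seeds/settings."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in replicates:
        (out / f"rep{rep.index:04d}.nwk").write_text(write_newick(rep.tree) + "\n")
        if rep.traits:
            df = pd.DataFrame(
                {"taxon": list(rep.traits), "value": list(rep.traits.values())}
            )
            df.to_csv(out / f"rep{rep.index:04d}_traits.tsv", sep="\t", index=False)
        rows.append({"replicate": rep.index, **rep.params})
    pd.DataFrame(rows).to_csv(out / "parameters.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(manifest or {}, indent=2, sort_keys=True) + "\n"
    )
    return out


def read_replicate_set(indir: str | Path) -> list[SimulatedReplicate]:
    ind = Path(indir)
    params = pd.read_csv(ind / "parameters.tsv", sep="\t")
    reps = []
    for row in params.to_dict("records"):
        i = int(row.pop("replicate"))
        tree = parse_newick((ind / f"rep{i:04d}.nwk").read_text())
        traits_path = ind / f"rep{i:04d}_traits.tsv"
        traits = {}
        if traits_path.exists():
            tdf = pd.read_csv(traits_path, sep="\t")
            traits = dict(zip(tdf.taxon.astype(str), tdf.value.astype(float)))
        reps.append(SimulatedReplicate(i, {k: float(v) for k, v in row.items()}, tree, traits))
    return reps
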