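"""Tree-aware and classical statistics.

The central quantity is the *phylogenetically informed mean*: the intercept
of an intercept-only generalised least squares fit whose residual covariance
is the Brownian-motion (BM) covariance of the species tree,

    mu_hat = (1' V^-1 1)^-1 1' V^-1 y,      V_ij = depth of MRCA(i, j).

This is the BM root/ancestral-state estimate; on a star tree it reduces to
the arithmetic mean, and in general it down-weights clusters of closely
related species so that a radiation of similar values does not dominate the
order-level mean.

Also here: OLS regression, the two-way ANOVA for the order x DNA-type table
of phylogenetically informed means (one observation per cell, no
interaction), and its Tukey HSD post-hoc test on the studentized range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "PhyloTree",
    "BMCovariance",
    "OLSResult",
    "AnovaResult",
    "bm_covariance",
    "phylo_mean",
    "phylo_mean_per_sco",
    "ols",
    "two_way_anova",
    "tukey_hsd",
    "pearson",
]

logger = logging.getLogger(__name__)


class PhyloTree:
    """A rooted species tree with branch lengths (thin wrapper over dendropy)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
        )
        return cls(tree)

    def _validate(self) -> None:
        tips = self.tips
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        root = self._tree.seed_node
        if len(root.child_nodes()) < 2 and len(tips) > 1:
            raise ValueError("tree root must have >= 2 children (rooted tree required)")
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                label = node.taxon.label if node.taxon else "(internal node)"
                raise ValueError(f"missing branch length at {label}")
            if node.edge.length < 0:
                label = node.taxon.label if node.taxon else "(internal node)"
                raise ValueError(f"negative branch length at {label}")

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def pruned_to(self, species: Iterable[str]) -> "PhyloTree":
        """Subtree induced by the given tips; root-to-MRCA depths preserved."""
        keep = set(species)
        missing = keep - set(self.tips)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return PhyloTree(sub)

    def tip_depths(self) -> dict[str, float]:
        out = {}
        for leaf in self._tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out


@dataclass(frozen=True)
class BMCovariance:
    """Brownian-motion covariance of a tree: V_ij = depth of MRCA(i, j)."""

    species: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        V = self.matrix
        if V.shape != (len(self.species),) * 2:
            raise ValueError("covariance shape does not match species list")
        if not np.allclose(V, V.T):
            raise ValueError("covariance not symmetric")


def bm_covariance(tree: PhyloTree, jitter: float | None = None) -> BMCovariance:
    """BM covariance matrix of a rooted tree with branch lengths.

    ``jitter`` (default ``1e-8 x max depth`` when any terminal branch has
    zero length) is added to the diagonal of zero-length-terminal tips to
    keep V invertible for duplicated tips.
    """
    dt = tree._tree
    leaves = list(dt.leaf_node_iter())
    species = tuple(leaf.taxon.label for leaf in leaves)
    n = len(species)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    V = np.zeros((n, n))

    depth = {dt.seed_node: 0.0}
    tipset: dict[dendropy.Node, list[dendropy.Node]] = {}
    for node in dt.preorder_node_iter():
        if node is not dt.seed_node:
            depth[node] = depth[node.parent_node] + node.edge.length
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            tipset[node] = [node]
            V[index[node], index[node]] = depth[node]
        else:
            children = node.child_nodes()
            for a_i, a in enumerate(children):
                for b in children[a_i + 1 :]:
                    for la in tipset[a]:
                        for lb in tipset[b]:
                            V[index[la], index[lb]] = depth[node]
                            V[index[lb], index[la]] = depth[node]
            tipset[node] = [l for c in children for l in tipset[c]]

    diags = np.diag(V)
    if np.any(diags <= 0) and n > 1:
        bad = [species[i] for i in np.nonzero(diags <= 0)[0]]
        raise ValueError(f"zero root-to-tip depth for {bad}")
    zero_terminal = [i for i, leaf in enumerate(leaves) if n > 1 and leaf.edge.length == 0]
    if zero_terminal:
        eps = jitter if jitter is not None else 1e-8 * float(diags.max())
        logger.info(
            "jittering %d zero-length terminal branches by %g", len(zero_terminal), eps
        )
        for i in zero_terminal:
            V[i, i] += eps
    return BMCovariance(species, V)


def phylo_mean(tree: PhyloTree, tip_values: Mapping[str, float]) -> float:
    """GLS intercept-only estimate of the mean under BM on the tree.

    Tree tips and value keys must match exactly.  The estimate always lies
    within [min(y), max(y)].
    """
    tips = set(tree.tips)
    keys = set(tip_values)
    if tips != keys:
        missing = sorted(tips - keys)
        extra = sorted(keys - tips)
        raise KeyError(f"tip/value mismatch: missing values for {missing}, extra {extra}")
    if len(tips) == 1:
        return float(next(iter(tip_values.values())))
    cov = bm_covariance(tree)
    y = np.array([tip_values[s] for s in cov.species], dtype=float)
    try:
        c, low = linalg.cho_factor(cov.matrix)
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular BM covariance: {exc}") from exc
    ones = np.ones_like(y)
    Vinv_1 = linalg.cho_solve((c, low), ones)
    return float(Vinv_1 @ y / (Vinv_1 @ ones))


def phylo_mean_per_sco(
    tree: PhyloTree,
    per_og_values: Mapping[str, Mapping[str, tuple[float, float]]],
    min_species: int = 3,
) -> dict[str, tuple[float, float]]:
    """Per-orthogroup phylogenetically informed (mean gc3, mean distance).

    ``per_og_values`` maps og_id -> {species: (gc3, distance)}.  Species
    missing from an orthogroup are pruned from its tree; orthogroups with
    fewer than ``min_species`` species left are skipped (logged).
    """
    out: dict[str, tuple[float, float]] = {}
    for og_id, values in per_og_values.items():
        species = [s for s in values if s in set(tree.tips)]
        if len(species) < min_species:
            logger.info("skipping %s: only %d species with values", og_id, len(species))
            continue
        sub = tree.pruned_to(species)
        gc3_mean = phylo_mean(sub, {s: values[s][0] for s in species})
        dist_mean = phylo_mean(sub, {s: values[s][1] for s in species})
        out[og_id] = (gc3_mean, dist_mean)
    return out


# ---------------------------------------------------------------------------
# Classical statistics


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    stderr: float
    n: int


def ols(x: Sequence[float], y: Sequence[float]) -> OLSResult:
    """Simple least-squares regression with the two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("ols needs n >= 3")
    if np.var(x) == 0:
        raise ValueError("ols: zero variance in x")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    t = fit.slope / fit.stderr if fit.stderr > 0 else math.inf
    return OLSResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        f_statistic=float(t * t),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=len(x),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided p; (NaN, NaN) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA on a complete one-observation-per-cell table, no
    interaction (residual df = (a-1)(b-1))."""

    factor_a: str
    factor_b: str
    f_a: float
    f_b: float
    df_a: int
    df_b: int
    df_resid: int
    p_a: float
    p_b: float
    mse: float
    grand_mean: float
    means_a: Mapping[str, float]
    means_b: Mapping[str, float]


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
) -> AnovaResult:
    """Two-way ANOVA of a levels-of-A x levels-of-B value table.

    ``table`` rows are levels of factor A, columns levels of factor B, each
    cell one observation.  Classical sums of squares (the design is balanced
    so type I/II/III coincide); F = MS_factor / MSE with MSE on
    (a-1)(b-1) df.  When MSE is exactly 0 the F statistics are undefined
    and reported as NaN.
    """
    values = table.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a complete table with >= 2 levels per factor")
    if np.isnan(values).any():
        raise ValueError("missing cell in ANOVA table")
    a, b = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    df_a, df_b = a - 1, b - 1
    df_e = df_a * df_b

    long = pd.DataFrame(
        {
            "value": values.ravel(),
            "A": np.repeat([str(i) for i in table.index], b),
            "B": np.tile([str(c) for c in table.columns], a),
        }
    )
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    fit = smf.ols("value ~ C(A) + C(B)", data=long).fit()
    tab = anova_lm(fit, typ=2)
    ss_e = float(tab.loc["Residual", "sum_sq"])
    mse = ss_e / df_e
    if mse <= 0 or ss_e < 1e-12 * max(1.0, float((values**2).sum())):
        # degenerate residual: F is 0/0 unless the factor itself has no
        # sum of squares, in which case it is exactly 0
        scale = 1e-12 * max(1.0, float((values**2).sum()))
        ss_a = float(tab.loc["C(A)", "sum_sq"])
        ss_b = float(tab.loc["C(B)", "sum_sq"])
        if ss_a < scale and ss_b < scale:  # no variation anywhere: 0/0
            f_a = f_b = p_a = p_b = math.nan
        else:
            f_a, p_a = (0.0, 1.0) if ss_a < scale else (math.nan, math.nan)
            f_b, p_b = (0.0, 1.0) if ss_b < scale else (math.nan, math.nan)
        mse = 0.0
    else:
        f_a = float(tab.loc["C(A)", "F"])
        f_b = float(tab.loc["C(B)", "F"])
        p_a = float(tab.loc["C(A)", "PR(>F)"])
        p_b = float(tab.loc["C(B)", "PR(>F)"])
    return AnovaResult(
        factor_a=factor_a,
        factor_b=factor_b,
        f_a=f_a,
        f_b=f_b,
        df_a=df_a,
        df_b=df_b,
        df_resid=df_e,
        p_a=p_a,
        p_b=p_b,
        mse=mse,
        grand_mean=float(grand),
        means_a=dict(zip(table.index.astype(str), row_means)),
        means_b=dict(zip(table.columns.astype(str), col_means)),
    )


def tukey_hsd(anova: AnovaResult, factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of one factor's level means.

    Uses the ANOVA's pooled MSE, SE = sqrt(MSE / n_per_level) where
    n_per_level is the number of levels of the other factor, and adjusted
    p-values from the studentized range distribution on the residual df.
    """
    if factor == anova.factor_a:
        means, n_per_level = anova.means_a, anova.df_b + 1
    elif factor == anova.factor_b:
        means, n_per_level = anova.means_b, anova.df_a + 1
    else:
        raise ValueError(f"unknown factor {factor!r}")
    if len(means) < 2:
        raise ValueError("Tukey HSD needs >= 2 levels")
    if not anova.mse > 0:
        raise ValueError("Tukey HSD undefined with zero residual mean square")
    k = len(means)
    se = math.sqrt(anova.mse / n_per_level)
    rows = []
    levels = list(means)
    for i, la in enumerate(levels):
        for lb in levels[i + 1 :]:
            diff = means[lb] - means[la]
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, anova.df_resid))
            rows.append((la, lb, diff, q, min(p_adj, 1.0)))
    return pd.DataFrame(rows, columns=["level_1", "level_2", "difference", "q", "p_adj"])
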