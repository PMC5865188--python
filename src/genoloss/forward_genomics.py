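"""Phylogeny-aware screen for genes preferentially lost in species
sharing a derived phenotype.

For each gene the %intact value is regressed on a binary trait
indicator with phylogenetic generalized least squares (pGLS): the error
covariance is the Brownian-motion covariance implied by the species
tree (cov(i, j) = shared root-to-MRCA path length), so related species
do not masquerade as independent observations.  Genes are ranked by the
p value of the slope; a gene is selected when p < 1e-6 and %intact is
lower in the trait-group-1 (derived-phenotype) species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import SpeciesTree

__all__ = [
    "PGLSResult",
    "brownian_covariance",
    "gene_prefilter",
    "pgls_fit",
    "rank_and_select",
    "screen",
    "P_THRESHOLD",
]

P_THRESHOLD = 1e-6

# group-2 intactness prefilters
MISSING_FRACTION = 0.5     # max fraction of a trait group with missing data
T2_INTACT_FRACTION = 0.9   # >= this fraction of group 2 must be near-intact
T2_INTACT_CUT = 90.0       # ... meaning %intact >= 90
T2_BROKEN_FRACTION = 0.05  # < this fraction of group 2 may look lost
T2_BROKEN_CUT = 60.0       # ... meaning %intact < 60


@dataclass
class PGLSResult:
    gene_id: str
    slope: float = float("nan")
    stderr: float = float("nan")
    tstat: float = float("nan")
    pvalue: float = float("nan")
    n: int = 0
    excluded_reason: str = ""

    @property
    def tested(self) -> bool:
        return self.excluded_reason == ""


def brownian_covariance(tree: SpeciesTree, leaves: Sequence[str]) -> pd.DataFrame:
    """Brownian-motion covariance of the leaf values implied by the tree.

    Entry (i, j) is the branch length shared by the root-to-leaf paths
    of i and j, i.e. the root-to-MRCA(i, j) distance; the diagonal holds
    root-to-leaf path lengths.  Symmetric positive semidefinite.
    """
    leaves = list(leaves)
    missing = set(leaves) - set(tree.leaf_names())
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")

    t = tree.tree
    pdm = t.phylogenetic_distance_matrix()
    depths = tree.root_distances()
    total = sum(depths.values())
    if total == 0:
        raise ValueError("tree has zero total branch length")

    taxa = {tx.label: tx for tx in t.taxon_namespace}
    n = len(leaves)
    C = np.zeros((n, n))
    for i, a in enumerate(leaves):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = leaves[j]
            # depth of MRCA = (depth_a + depth_b - patristic distance)/2
            d = pdm.patristic_distance(taxa[a], taxa[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
    C[np.abs(C) < 1e-12] = 0.0
    return pd.DataFrame(C, index=leaves, columns=leaves)


def gene_prefilter(
    pct_intact: pd.Series,
    groups: dict[str, int],
    missing: Optional[pd.Series] = None,
) -> str:
    """Decide whether a gene enters the regression; '' means tested.

    A gene is excluded when more than half of either trait group is
    missing data ("missing_t1"/"missing_t2"), or when the background
    group is not convincingly intact: fewer than 90% of trait-group-2
    species with %intact >= 90, or at least 5% of them with %intact
    < 60 ("t2_not_intact").
    """
    g1 = [sp for sp, g in groups.items() if g == 1]
    g2 = [sp for sp, g in groups.items() if g == 2]
    if not g1 or not g2:
        raise ValueError("both trait groups must be non-empty")
    if missing is None:
        missing = pct_intact.isna()

    for name, grp in (("missing_t1", g1), ("missing_t2", g2)):
        miss = np.mean([bool(missing.get(sp, True)) for sp in grp])
        if miss > MISSING_FRACTION:
            return name

    g2_vals = np.array(
        [pct_intact[sp] for sp in g2 if not bool(missing.get(sp, True))], dtype=float
    )
    if len(g2_vals) == 0:
        return "missing_t2"
    if np.mean(g2_vals >= T2_INTACT_CUT) < T2_INTACT_FRACTION:
        return "t2_not_intact"
    if np.mean(g2_vals < T2_BROKEN_CUT) >= T2_BROKEN_FRACTION:
        return "t2_not_intact"
    return ""


def pgls_fit(
    y: np.ndarray, x: np.ndarray, C: np.ndarray, gene_id: str = ""
) -> PGLSResult:
    """Generalized least squares of y on [1, x] with error covariance ~ C.

    Returns the slope, its standard error, t = slope/SE, and the
    two-sided p value from the t distribution with n - 2 degrees of
    freedom.  With C = I this reduces exactly to ordinary least squares.
    A constant y gives slope 0 and p = 1 by convention.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = np.asarray(C, dtype=float)
    n = len(y)
    if not (len(x) == n and C.shape == (n, n)):
        raise ValueError("dimension mismatch")
    if n < 3:
        return PGLSResult(gene_id, excluded_reason="too_few_species")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return PGLSResult(gene_id, slope=0.0, stderr=float("nan"),
                          tstat=0.0, pvalue=1.0, n=n)
    if np.linalg.cond(C) > 1e12:
        raise np.linalg.LinAlgError("singular phylogenetic covariance")

    X = sm.add_constant(x)
    fit = sm.GLS(y, X, sigma=C).fit()
    return PGLSResult(
        gene_id=gene_id,
        slope=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        tstat=float(fit.tvalues[1]),
        pvalue=float(fit.pvalues[1]),
        n=n,
    )


def rank_and_select(
    results: Sequence[PGLSResult], p_threshold: float = P_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Rank tested genes by p value; select p < threshold with the loss
    direction (lower %intact in trait group 1, i.e. negative slope for
    an x coded 1 in group 1)."""
    rows = [
        {
            "gene": r.gene_id,
            "slope": r.slope,
            "stderr": r.stderr,
            "t": r.tstat,
            "p": r.pvalue,
            "n": r.n,
            "excluded_reason": r.excluded_reason,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            by=["excluded_reason", "p"], na_position="last"
        ).reset_index(drop=True)
    selected = [
        r.gene_id
        for r in results
        if r.tested and r.pvalue < p_threshold and r.slope < 0
    ]
    return table, selected


def screen(
    matrix: pd.DataFrame,
    tree: SpeciesTree,
    groups: dict[str, int],
    p_threshold: float = P_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full screen on a gene x species %intact matrix.

    ``matrix`` has genes as rows and species as columns; NaN marks
    missing data.  Missing species are dropped row-wise from each
    gene's regression, with the covariance subset accordingly.
    """
    species = [sp for sp in matrix.columns if sp in groups]
    unknown = set(groups) - set(matrix.columns)
    if unknown:
        raise ValueError(f"trait species missing from matrix: {sorted(unknown)}")
    C_full = brownian_covariance(tree, species)
    x_full = pd.Series({sp: 1.0 if groups[sp] == 1 else 0.0 for sp in species})

    results = []
    for gene, row in matrix[species].iterrows():
        reason = gene_prefilter(row, {sp: groups[sp] for sp in species})
        if reason:
            results.append(PGLSResult(str(gene), excluded_reason=reason))
            continue
        used = [sp for sp in species if not pd.isna(row[sp])]
        res = pgls_fit(
            row[used].to_numpy(float),
            x_full[used].to_numpy(float),
            C_full.loc[used, used].to_numpy(float),
            gene_id=str(gene),
        )
        results.append(res)
    return rank_and_select(results, p_threshold)
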