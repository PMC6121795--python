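"""Weighted coexpression networks: adjacency, topological overlap, module
detection, eigengenes, group tests, and cross-dataset module overlap.

This is a compact re-statement of the WGCNA recipe: an unsigned adjacency
a_ij = |cor(i,j)|^beta, the topological overlap similarity

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage clustering of 1 - TOM with a static cut height (dynamic
tree cut is intentionally not reproduced), and module eigengenes as first
principal components of the standardized module expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionConfig:
    beta: float = 6.0
    cut_height: float = 0.9  # static tree cut, fraction of max merge height
    min_module_size: int = 10

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.cut_height <= 0:
            raise ValueError("cut height must be positive")
        if self.min_module_size < 2:
            raise ValueError("min module size must be >= 2")


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module label or "unassigned"

    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


@dataclass
class Eigengene:
    module: str
    scores: pd.Series  # per-sample, unit norm
    variance_explained: float


def adjacency_tom(
    expr: pd.DataFrame, config: CoexpressionConfig = CoexpressionConfig()
) -> pd.DataFrame:
    """Topological overlap similarity of a gene x sample expression matrix.

    Constant genes are removed with a warning (correlation undefined).
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    variances = expr.var(axis=1)
    keep = variances > 0
    if not keep.all():
        warnings.warn(f"removed {(~keep).sum()} constant gene(s)")
        expr = expr.loc[keep]
    genes = expr.index
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    a = np.abs(cor) ** config.beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    num = a @ a + a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=genes, columns=genes)


def detect_modules(
    tom: pd.DataFrame, config: CoexpressionConfig = CoexpressionConfig()
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static cut.

    The cut height is ``config.cut_height`` times the maximum merge height;
    clusters smaller than ``min_module_size`` become unassigned.  Module
    labels M1, M2, ... are ordered by decreasing size.
    """
    genes = tom.index
    if len(genes) < config.min_module_size:
        return ModuleAssignment(pd.Series(UNASSIGNED, index=genes))
    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    height = config.cut_height * z[:, 2].max()
    raw = fcluster(z, t=height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    sizes = pd.Series(raw).value_counts()
    ordered = sizes[sizes >= config.min_module_size].index
    for rank, cluster_id in enumerate(ordered, start=1):
        labels[raw == cluster_id] = f"M{rank}"
    return ModuleAssignment(labels)


def module_eigengene(
    expr: pd.DataFrame, assignment: ModuleAssignment, module: str
) -> Eigengene:
    """First principal component of the module's standardized expression,
    unit norm, oriented to correlate non-negatively with the module mean."""
    genes = assignment.genes_in(module)
    if not genes:
        raise ValueError(f"module {module!r} is empty")
    sub = expr.loc[genes].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError(f"module {module!r} has rank-0 expression")
    scores = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    module_mean = z.mean(axis=0)
    if np.dot(scores, module_mean) < 0:
        scores = -scores
    return Eigengene(
        module=module,
        scores=pd.Series(scores, index=expr.columns, name=module),
        variance_explained=var_explained,
    )


def eigengene_group_test(
    eigengenes: Sequence[Eigengene],
    sample_groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Two-sided two-sample t-test of each module eigengene between two
    sample groups, Bonferroni-corrected across modules."""
    rows = []
    for eg in eigengenes:
        g = sample_groups.loc[eg.scores.index]
        a = eg.scores[g == group_a]
        b = eg.scores[g == group_b]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"module {eg.module}: group too small, skipped")
            continue
        t, p = stats.ttest_ind(a, b)
        rows.append({"module": eg.module, "t_statistic": float(t), "p_value": float(p)})
    out = pd.DataFrame(rows, columns=["module", "t_statistic", "p_value"])
    if len(out):
        out["bonferroni_p"] = np.minimum(out["p_value"] * len(out), 1.0)
        out["significant"] = out["bonferroni_p"] < 0.05
    else:
        out["bonferroni_p"] = []
        out["significant"] = []
    out.attrs["comparison"] = f"{group_a} vs {group_b}"
    return out


def module_overlap_fisher(
    assign_a: ModuleAssignment, assign_b: ModuleAssignment
) -> pd.DataFrame:
    """Fisher's exact test of gene overlap for every pair of modules from
    two assignments over a shared universe, Bonferroni over all pairs."""
    universe = assign_a.labels.index.intersection(assign_b.labels.index)
    if len(universe) == 0:
        raise ValueError("assignments share no genes")
    la = assign_a.labels.loc[universe]
    lb = assign_b.labels.loc[universe]
    mods_a, mods_b = assign_a.modules(), assign_b.modules()
    rows = []
    n = len(universe)
    for ma in mods_a:
        in_a = la == ma
        for mb in mods_b:
            in_b = lb == mb
            both = int((in_a & in_b).sum())
            only_a = int(in_a.sum()) - both
            only_b = int(in_b.sum()) - both
            neither = n - both - only_a - only_b
            _odds, p = stats.fisher_exact(
                [[both, only_a], [only_b, neither]], alternative="two-sided"
            )
            rows.append(
                {"module_a": ma, "module_b": mb, "overlap": both, "p_value": float(p)}
            )
    out = pd.DataFrame(rows, columns=["module_a", "module_b", "overlap", "p_value"])
    n_tests = max(len(rows), 1)
    out["bonferroni_p"] = np.minimum(out["p_value"] * n_tests, 1.0)
    out["significant"] = out["bonferroni_p"] < 0.05
    return out
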