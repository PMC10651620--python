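"""Correlation-network module discovery in the WGCNA style.

Pipeline: Spearman correlation between log2 metabolites → signed
soft-thresholded adjacency ``a_ij = ((1+ρ_ij)/2)^β`` → topological overlap
matrix (TOM) → average-linkage hierarchical clustering of ``1 − TOM`` →
flat modules by a static height cut, discarding clusters below a minimum
size.  Each module is summarized by its hub (the member with the largest
intramodular connectivity) and an eigen-metabolite: the first principal
component of the module's standardized abundance submatrix, sign-oriented
to correlate positively with the module's mean profile.

Defaults follow signed-network WGCNA convention (β = 6); clustering uses a
deterministic static cut (default height 0.75 on the 1 − TOM dissimilarity
scale) rather than dynamic tree cut.  Tight blocks merge well below 0.75
while unstructured metabolites merge near 1, so the fixed cut separates the
two regimes; a merge-height quantile rule is available via
``cut_height=None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkConfig",
    "ModuleAssignment",
    "spearman_matrix",
    "soft_adjacency",
    "topological_overlap",
    "detect_modules",
    "hub_metabolite",
    "module_scores",
    "module_group_lme",
]


@dataclass
class NetworkConfig:
    """Knobs of the module-detection pipeline."""

    beta: int = 6
    signed: bool = True
    cut_height: float | None = 0.75  # None -> quantile of merge heights
    cut_quantile: float = 0.98
    min_module_size: int = 5

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("soft power beta must be >= 1")
        if self.cut_height is not None and not 0 < self.cut_height < 1:
            raise ValueError("cut height must lie in (0, 1)")


@dataclass
class ModuleAssignment:
    """Metabolite→module map plus per-module summaries (0 = unassigned)."""

    modules: pd.Series                 # metabolite -> module id
    hubs: dict[int, str]               # module id -> hub metabolite
    scores: pd.DataFrame | None = None        # visits × modules, PC1 scores
    variance_explained: dict[int, float] | None = None


def spearman_matrix(log2_panel: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between metabolites (pairwise-complete).

    Raises naming any constant metabolite, whose rank correlation is
    undefined.
    """
    X = log2_panel.to_numpy(float)
    const = [c for c, v in zip(log2_panel.columns, np.nanvar(X, axis=0)) if v == 0]
    if const:
        raise ValueError(f"constant metabolites have undefined correlation: {const[:5]}")
    if np.isnan(X).any():
        rho = (
            pd.DataFrame(X, columns=log2_panel.columns)
            .corr(method="spearman", min_periods=3)
            .to_numpy()
        )
    else:
        rho = stats.spearmanr(X).statistic
        rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=log2_panel.columns, columns=log2_panel.columns)


def soft_adjacency(cor: pd.DataFrame, beta: int = 6, signed: bool = True) -> pd.DataFrame:
    """Soft-thresholded adjacency; zero diagonal for connectivity sums."""
    rho = cor.to_numpy(float)
    a = ((1.0 + rho) / 2.0) ** beta if signed else np.abs(rho) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)``
    with ``k_i = Σ_u a_iu``; unit diagonal.  Measures shared network
    neighborhoods rather than direct connection strength alone.
    """
    A = adjacency.to_numpy(float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    # zero diagonal makes A@A equal Σ_{u≠i,j} a_iu a_uj off-diagonal
    shared = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + A) / (kmin + 1.0 - A)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig | None = None) -> ModuleAssignment:
    """Average-linkage clustering of ``1 − TOM`` with a static height cut.

    Clusters smaller than ``min_module_size`` become module 0 (unassigned);
    surviving modules are renumbered 1, 2, … by decreasing size (ties by
    smallest member name for determinism).
    """
    config = config or NetworkConfig()
    names = list(tom.index)
    d = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    h = config.cut_height if config.cut_height is not None else float(
        np.quantile(heights, config.cut_quantile)
    )
    flat = hierarchy.fcluster(Z, t=h, criterion="distance")
    modules = pd.Series(0, index=names, name="module")
    sizes = pd.Series(flat).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    # renumber by decreasing size, ties by lexicographically smallest member
    keyed = sorted(
        keep,
        key=lambda c: (-sizes[c], min(n for n, f in zip(names, flat) if f == c)),
    )
    for new_id, c in enumerate(keyed, start=1):
        modules[np.asarray(flat) == c] = new_id
    return ModuleAssignment(modules=modules, hubs={})


def hub_metabolite(assignment: ModuleAssignment, adjacency: pd.DataFrame) -> dict[int, str]:
    """Hub per module: the member with maximal intramodular connectivity.

    Connectivity is the sum of within-module adjacency to the other
    members; ties break by metabolite name order.
    """
    hubs: dict[int, str] = {}
    for mod in sorted(set(assignment.modules) - {0}):
        members = sorted(assignment.modules.index[assignment.modules == mod])
        sub = adjacency.loc[members, members]
        conn = sub.sum(axis=1)
        hubs[mod] = str(conn.index[int(np.argmax(conn.to_numpy()))])
    assignment.hubs = hubs
    return hubs


def module_scores(
    log2_panel: pd.DataFrame, assignment: ModuleAssignment
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Eigen-metabolite (PC1) score per visit for each module.

    Columns are standardized (zero mean, unit variance) before PCA, so the
    decomposition is of the module's correlation structure; the score sign
    is oriented to correlate positively with the module's mean standardized
    profile.  Returns the score table and PC1 variance explained per module.
    """
    scores = {}
    varex = {}
    for mod in sorted(set(assignment.modules) - {0}):
        members = [m for m in log2_panel.columns if assignment.modules.get(m) == mod]
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 members")
        X = log2_panel[members].to_numpy(float)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [m for m, s in zip(members, sd) if s == 0]
            raise ValueError(f"zero-variance metabolites in module {mod}: {bad}")
        Xs = (X - X.mean(axis=0)) / sd
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        pc1 = U[:, 0] * S[0]
        mean_profile = Xs.mean(axis=1)
        if np.dot(pc1, mean_profile) < 0:
            pc1 = -pc1
        scores[mod] = pc1
        varex[mod] = float(S[0] ** 2 / np.sum(S**2))
    table = pd.DataFrame(scores, index=log2_panel.index)
    assignment.scores = table
    assignment.variance_explained = varex
    return table, varex


def module_group_lme(scores: pd.DataFrame, design) -> pd.DataFrame:
    """Group modeling of module scores through the screening mixed model.

    Each module's eigen-metabolite score is the response in the same
    REML random-intercept model used per metabolite; reports the pairwise
    group×time contrasts at raw p (no FDR across a handful of modules).
    """
    from .screen import screen_all

    for mod in scores.columns:
        if np.ptp(scores[mod].to_numpy(float)) == 0:
            raise ValueError(f"module {mod} score is constant; degenerate fit")
    table = screen_all(scores, design, apply_bh=False)
    return table.rename(columns={"metabolite": "module"})
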