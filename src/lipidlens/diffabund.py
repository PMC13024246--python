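"""Differential abundance, PCA and hierarchical clustering.

Case-control comparisons use the two-sided Wilcoxon-Mann-Whitney test with
Benjamini-Hochberg correction applied within each annotation level
(species-level tests form one family, each stratification another). Effect
sizes are pseudo fold changes -- ratios of group medians stabilised by a
small additive constant when zeros occur -- reported as log2(case/control),
so positive values mean higher abundance in cases. A feature is called
significant when its BH-adjusted p-value falls below ``alpha`` AND its fold
change magnitude max(fc, 1/fc) exceeds ``fc_threshold``.

Stratified analyses aggregate each sample's concentrations by summing over
the member species of a stratum (total class abundance), then test strata
exactly like species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.stats.multitest import multipletests

from .cohort import AbundanceTable

__all__ = [
    "DERecord",
    "PCAResult",
    "ClusterResult",
    "InsufficientDataError",
    "UndefinedFoldChangeError",
    "LEVELS",
    "preprocess",
    "wilcoxon_mw",
    "bh_adjust",
    "pseudo_fold_change",
    "de_by_level",
    "pca",
    "hier_cluster",
]


class InsufficientDataError(ValueError):
    """Raised when a group has fewer than two observations."""


class UndefinedFoldChangeError(ZeroDivisionError):
    """Raised when both medians and the stabilising constant are zero."""


#: Annotation levels accepted by :func:`de_by_level`, mapped to the column
#: of the species annotation table that defines the stratum label.
LEVELS: dict[str, str] = {
    "species": "raw_name",
    "class": "lipid_class",
    "category": "category",
    "subcategory": "subcategory",
    "subclass": "subclass",
    "total_fa": "total_fa_label",
    "total_c": "total_c",
    "total_oh": "total_oh",
    "ether_bond": "ether_bond",
    "saturation": "saturation_class",
    "bilayer_thickness": "bilayer_thickness",
    "lateral_diffusion": "lateral_diffusion",
    "intrinsic_curvature": "intrinsic_curvature",
    "function": "function",
    "cellular_component": "cellular_component",
}

#: Exact Wilcoxon null enumeration is used up to this combined sample size
#: (and only without ties); beyond it the normal approximation with tie and
#: continuity correction applies.
EXACT_WILCOXON_MAX_N = 16


@dataclass(frozen=True)
class DERecord:
    """One differential-abundance result row (species or stratum)."""

    feature_id: str
    level: str
    median_case: float
    median_control: float
    pseudo_fc: float
    log2fc: float
    p_value: float
    adj_p: float
    significant: bool


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_fraction: np.ndarray  # per-component fraction of total variance
    loadings: pd.DataFrame  # species x components


@dataclass
class ClusterResult:
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray
    sample_order: list[str]
    feature_order: list[str]


def preprocess(table: AbundanceTable) -> tuple[pd.DataFrame, dict[str, float]]:
    """log2-transform concentrations, stabilising zeros per species.

    For a species containing zeros, delta = half its smallest positive value
    is added before the log; all-positive species use delta = 0. Species
    that are entirely zero carry no information and are dropped with a
    warning. Returns the transformed table and the delta used per species.
    """
    values = table.abundance
    deltas: dict[str, float] = {}
    kept: dict[str, np.ndarray] = {}
    for species in values.columns:
        col = values[species].to_numpy(dtype=float)
        positive = col[col > 0]
        if positive.size == 0:
            warnings.warn(f"species {species!r} is all zeros; dropped", stacklevel=2)
            continue
        delta = 0.0 if (col > 0).all() else float(positive.min() / 2.0)
        deltas[species] = delta
        kept[species] = np.log2(col + delta)
    transformed = pd.DataFrame(kept, index=values.index)
    return transformed, deltas


def wilcoxon_mw(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value for a group comparison.

    The exact null distribution (full enumeration) is used when the
    combined sample size is at most 16 and the pooled values are tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction is used.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(result.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pseudo_fold_change(
    case_values: Sequence[float],
    control_values: Sequence[float],
    epsilon: float | None = None,
) -> tuple[float, float]:
    """Median-based pseudo fold change (case over control) and its log2.

    ``epsilon`` defaults to 0 when both medians are positive, else to half
    the smallest positive value pooled across both groups.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    med_case = float(np.median(x))
    med_control = float(np.median(y))
    if epsilon is None:
        if med_case > 0 and med_control > 0:
            epsilon = 0.0
        else:
            pooled = np.concatenate([x, y])
            positive = pooled[pooled > 0]
            epsilon = float(positive.min() / 2.0) if positive.size else 0.0
    if med_case + epsilon == 0 or med_control + epsilon == 0:
        raise UndefinedFoldChangeError(
            "fold change undefined: a group median and the pseudocount are both zero"
        )
    fc = (med_case + epsilon) / (med_control + epsilon)
    return fc, float(np.log2(fc))


def _stratum_values(
    table: AbundanceTable, annot: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Per-sample stratum abundances: sums over member species."""
    column = LEVELS[level]
    if level == "species":
        return table.abundance.copy()
    missing = [s for s in table.species if s not in annot.index]
    if missing:
        raise KeyError(f"species not annotated: {missing}")
    labels = annot.loc[list(table.species), column].astype(str)
    return table.abundance.T.groupby(labels.values).sum().T


def de_by_level(
    table: AbundanceTable,
    annot: pd.DataFrame | None,
    level: str = "species",
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential abundance at one annotation level.

    For levels other than ``species`` each sample's stratum value is the sum
    of its concentrations over member species. BH correction runs within
    the level (one family per level). Returns one row per feature with the
    :class:`DERecord` columns, ordered by ascending adjusted p.
    """
    if level not in LEVELS:
        raise ValueError(
            f"unknown level {level!r}; valid levels: {', '.join(LEVELS)}"
        )
    if level != "species" and annot is None:
        raise ValueError("an annotation table is required for stratified levels")
    strata = _stratum_values(table, annot, level)
    case_mask = (table.groups == "case").values
    records = []
    for feature in strata.columns:
        col = strata[feature].to_numpy(dtype=float)
        x, y = col[case_mask], col[~case_mask]
        fc, log2fc = pseudo_fold_change(x, y)
        records.append(
            {
                "feature_id": str(feature),
                "level": level,
                "median_case": float(np.median(x)),
                "median_control": float(np.median(y)),
                "pseudo_fc": fc,
                "log2fc": log2fc,
                "p_value": wilcoxon_mw(x, y),
            }
        )
    frame = pd.DataFrame.from_records(records)
    frame["adj_p"] = bh_adjust(frame["p_value"].values)
    magnitude = np.maximum(frame["pseudo_fc"], 1.0 / frame["pseudo_fc"])
    frame["significant"] = (frame["adj_p"] < alpha) & (magnitude > fc_threshold)
    return frame.sort_values("adj_p", kind="stable").reset_index(drop=True)


def _drop_constant(transformed: pd.DataFrame) -> pd.DataFrame:
    std = transformed.std(axis=0, ddof=0)
    constant = std[std == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping constant features before standardization: {constant}",
            stacklevel=3,
        )
        return transformed.drop(columns=constant)
    return transformed


def pca(transformed: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of feature-standardized (zero-mean, unit-variance) log abundances."""
    if transformed.shape[0] < 2 or transformed.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 samples and 2 features")
    data = _drop_constant(transformed)
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=0)
    n_components = min(n_components, min(z.shape))
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(z.values)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=z.index, columns=comp_names),
        explained_fraction=model.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(model.components_.T, index=z.columns, columns=comp_names),
    )


def hier_cluster(
    transformed: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of samples and features on z-scored values.

    Features are z-scored per species before computing distances; constant
    features are left at zero deviation rather than dropped so that both
    trees cover the full input.
    """
    if transformed.shape[0] < 2:
        raise InsufficientDataError("clustering needs at least 2 samples")
    std = transformed.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (transformed - transformed.mean(axis=0)) / std
    sample_linkage = hierarchy.linkage(z.values, method=method, metric=metric)
    feature_linkage = hierarchy.linkage(z.values.T, method=method, metric=metric)
    sample_order = [
        transformed.index[i] for i in hierarchy.leaves_list(sample_linkage)
    ]
    feature_order = [
        transformed.columns[i] for i in hierarchy.leaves_list(feature_linkage)
    ]
    return ClusterResult(
        sample_linkage=sample_linkage,
        feature_linkage=feature_linkage,
        sample_order=sample_order,
        feature_order=feature_order,
    )
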