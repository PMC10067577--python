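"""Single-cell OMI statistics: effect sizes, group tests, heatmaps, clustering.

Comparisons between cell populations use the unpaired two-sided Mann–Whitney
U test together with Glass's Δ,

    Δ = |M1 − M2| / σ_control,

the difference of group means standardised by the *control* group's sample
standard deviation.  With thousands of single cells nearly any difference is
"significant" by p-value, so Δ > 0.8 is the practical significance gate and
no multiple-testing correction is applied — the report carries both numbers
and says so.

Heatmap matrices are per-parameter z-scores over all cells jointly, clipped
at ±4 SD; hierarchical clustering of the z-rows uses Ward's criterion on
Euclidean distances, with metadata (cell type, tissue, mouse) excluded from
the distance computation and carried only for annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, ward as scipy_ward
from scipy.stats import mannwhitneyu

from .exceptions import (
    ConfigError,
    DataError,
    InsufficientDataError,
    InvalidParameterError,
)
from .features import OMI_PARAMETERS

logger = logging.getLogger(__name__)

__all__ = [
    "GLASS_DELTA_SIGNIFICANCE",
    "GroupComparison",
    "ZScoreMatrix",
    "ClusteringResult",
    "glass_delta",
    "mann_whitney_p",
    "compare_groups",
    "zscore_matrix",
    "ward_cluster",
]

#: Effect-size threshold treated as practically significant.
GLASS_DELTA_SIGNIFICANCE = 0.8

META_KEYS = ("cell_type", "tissue", "mouse_id")


def glass_delta(experimental, control) -> float:
    """Absolute Glass's Δ: ``|mean(experimental) − mean(control)| / sd(control)``.

    The control SD is the sample (n−1) standard deviation.  Note the
    asymmetry: swapping the groups changes which SD standardises the
    difference, so Δ(a, b) generally differs from Δ(b, a).
    """
    x = np.asarray(experimental, dtype=float)
    c = np.asarray(control, dtype=float)
    if c.size < 2:
        raise InsufficientDataError("control group needs n >= 2 for an SD")
    sd = c.std(ddof=1)
    if sd == 0:
        raise InvalidParameterError("degenerate control group: zero standard deviation")
    return abs(x.mean() - c.mean()) / sd


def mann_whitney_p(x, y, exact_max_n: int = 20) -> float:
    """Two-sided Mann–Whitney p-value.

    Exact enumeration when both samples have at most ``exact_max_n``
    observations and no ties; the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and no_ties) else "asymptotic"
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """One parameter's experimental-vs-control comparison."""

    parameter: str
    mean_experimental: float
    mean_control: float
    sd_control: float
    glass_delta_abs: float
    mw_p: float
    n_experimental: int
    n_control: int
    control_label: str

    @property
    def significant_effect(self) -> bool:
        return self.glass_delta_abs > GLASS_DELTA_SIGNIFICANCE


def compare_groups(
    table: pd.DataFrame,
    split_key: str,
    control_label: str,
    parameters: tuple[str, ...] = OMI_PARAMETERS,
) -> list[GroupComparison]:
    """Mann–Whitney + Glass's Δ for every OMI parameter between two groups.

    ``split_key`` names the grouping column (e.g. ``tissue`` with control
    ``"spleen"``, or ``cell_type`` within the tumour with control
    ``"immune"``).  Exactly two groups must be present; the non-control one
    is the experimental group.
    """
    groups = table[split_key].unique().tolist()
    if control_label not in groups:
        raise ConfigError(f"control label {control_label!r} not found in {split_key!r}")
    experimental_labels = [g for g in groups if g != control_label]
    if len(experimental_labels) != 1:
        raise ConfigError(
            f"need exactly one experimental group, found {experimental_labels}"
        )
    exp_label = experimental_labels[0]
    ctrl = table[table[split_key] == control_label]
    exp = table[table[split_key] == exp_label]
    out = []
    for param in parameters:
        x = exp[param].dropna().to_numpy(dtype=float)
        c = ctrl[param].dropna().to_numpy(dtype=float)
        if x.size == 0 or c.size == 0:
            raise InsufficientDataError(f"empty group for parameter {param!r}")
        out.append(
            GroupComparison(
                parameter=param,
                mean_experimental=float(x.mean()),
                mean_control=float(c.mean()),
                sd_control=float(c.std(ddof=1)),
                glass_delta_abs=glass_delta(x, c),
                mw_p=mann_whitney_p(x, c),
                n_experimental=int(x.size),
                n_control=int(c.size),
                control_label=control_label,
            )
        )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tidy frame of a comparison report (one row per parameter)."""
    return pd.DataFrame(
        [
            {
                "parameter": c.parameter,
                "mean_experimental": c.mean_experimental,
                "mean_control": c.mean_control,
                "sd_control": c.sd_control,
                "glass_delta_abs": c.glass_delta_abs,
                "mw_p": c.mw_p,
                "n_experimental": c.n_experimental,
                "n_control": c.n_control,
                "control_label": c.control_label,
                "significant_effect": c.significant_effect,
            }
            for c in comparisons
        ]
    )


@dataclass
class ZScoreMatrix:
    """Cells × parameters z-score matrix, clipped at ±4 SD, plus row metadata."""

    values: pd.DataFrame
    meta: pd.DataFrame
    clip: float = 4.0

    def to_frame(self) -> pd.DataFrame:
        meta = self.meta.add_prefix("meta_")
        return pd.concat([meta.reset_index(drop=True), self.values.reset_index(drop=True)], axis=1)


def zscore_matrix(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = OMI_PARAMETERS,
    clip: float = 4.0,
) -> ZScoreMatrix:
    """Standardise each parameter over *all* cells jointly, then clip to ±4 SD.

    Standardisation uses the sample (n−1) SD.  Constant columns cannot be
    standardised and become all-zero with a logged warning so that
    degenerate fixtures still run.
    """
    if len(table) < 2:
        raise InsufficientDataError("z-score matrix needs at least 2 cells")
    raw = table[list(parameters)].astype(float)
    if raw.isna().any().any():
        raise DataError("NaN values in feature columns; clean or exclude cells first")
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    z = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        if sd[col] == 0:
            logger.warning("constant parameter column %r: z-scores set to 0", col)
            z[col] = 0.0
        else:
            z[col] = (raw[col] - mu[col]) / sd[col]
    z = z.clip(lower=-clip, upper=clip)
    meta_cols = [k for k in META_KEYS if k in table.columns]
    meta = table[meta_cols].copy() if meta_cols else pd.DataFrame(index=table.index)
    return ZScoreMatrix(values=z, meta=meta, clip=clip)


@dataclass
class ClusteringResult:
    """Ward linkage over cells plus convenience accessors."""

    linkage: np.ndarray
    leaf_order: np.ndarray
    n_leaves: int

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat labels (1..n_clusters) at the requested cut."""
        return fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "n_members"]
        )


def ward_cluster(z: ZScoreMatrix | pd.DataFrame | np.ndarray) -> ClusteringResult:
    """Agglomerative clustering of cells with Ward's minimum-variance criterion.

    Distances are Euclidean on the z-scored parameter rows; metadata never
    enters the distance computation.
    """
    if isinstance(z, ZScoreMatrix):
        mat = z.values.to_numpy(dtype=float)
    elif isinstance(z, pd.DataFrame):
        mat = z.to_numpy(dtype=float)
    else:
        mat = np.asarray(z, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise InsufficientDataError("clustering needs a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(mat)):
        raise DataError("NaN/inf in z-score matrix")
    linkage = scipy_ward(mat)
    return ClusteringResult(
        linkage=linkage, leaf_order=leaves_list(linkage), n_leaves=mat.shape[0]
    )


def plot_heatmap(z: ZScoreMatrix, clustering: ClusteringResult | None = None, path=None):
    """Minimal clustered-heatmap export (cells as columns, parameters as rows)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clustering.leaf_order if clustering is not None else np.arange(len(z.values))
    mat = z.values.to_numpy(dtype=float)[order].T
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(mat, aspect="auto", cmap="coolwarm", vmin=-z.clip, vmax=z.clip)
    ax.set_yticks(range(mat.shape[0]))
    ax.set_yticklabels(z.values.columns, fontsize=6)
    ax.set_xlabel("cells (clustered order)" if clustering is not None else "cells")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
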