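"""Shannon-entropy scoring of cell-type specificity for expression matrices.

For a feature with expression E_i over N cell types, F_i = E_i / sum(E_j),
H = -sum(F_i log2 F_i) (0 when expressed in one type, log2 N when uniform)
and the per-type specificity Q_i = H - log2(F_i) (small Q_i: the feature is
specific to type i). Features pass a 2-D gate in (H, max E_i): H must stay
below a bound that relaxes linearly with log10 expression, since highly
expressed features tolerate more entropy. Applies to any non-negative
feature x cell-type matrix (gene RPKM, miRNA RPM, lincRNAs ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

DEFAULT_H_MAX = 1.0        # bits
DEFAULT_EXPR_MIN = 1.0     # RPKM / RPM
DEFAULT_SLOPE = 0.25       # bits per decade of expression above expr_min


@dataclass
class EntropyScores:
    """Per-feature H (bits), per-type fractions F, specificity Q and max expression."""

    H: pd.Series
    F: pd.DataFrame
    Q: pd.DataFrame  # +inf where F_i = 0 ("not expressed in this type")
    max_expr: pd.Series

    @property
    def n_types(self) -> int:
        return self.F.shape[1]


def entropy_scores(matrix: pd.DataFrame) -> EntropyScores:
    """Compute entropy specificity scores for a features x cell-types matrix.

    Features with zero total expression get H = NaN (excluded downstream).
    Negative values are an error; N >= 2 columns required.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative expression value")
    totals = vals.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = vals / totals[:, None]
        logF = np.where(F > 0, np.log2(np.where(F > 0, F, 1.0)), 0.0)
        H = np.maximum(-(F * logF).sum(axis=1), 0.0)  # clamp float noise / -0.0
        H = np.where(totals > 0, H, np.nan)
        Q = H[:, None] - np.where(F > 0, np.log2(np.where(F > 0, F, 1.0)), -np.inf)
    idx, cols = matrix.index, matrix.columns
    return EntropyScores(
        H=pd.Series(H, index=idx, name="H"),
        F=pd.DataFrame(F, index=idx, columns=cols),
        Q=pd.DataFrame(Q, index=idx, columns=cols),
        max_expr=pd.Series(vals.max(axis=1), index=idx, name="max_expr"),
    )


def specificity_threshold(scores: EntropyScores, h_max: float = DEFAULT_H_MAX,
                          expr_min: float = DEFAULT_EXPR_MIN,
                          slope: float = DEFAULT_SLOPE) -> pd.DataFrame:
    """Apply the 2-D (entropy, expression) gate and assign the specific type.

    A feature is cell-type-specific iff max_expr >= expr_min and
    H <= h_max + slope * log10(max_expr / expr_min). With slope 0 this is a
    rectangular gate. Passing features are assigned to argmax_i F_i.
    Returns feature, H, max_expr, cell_type for passing features.
    """
    ok = (scores.max_expr >= expr_min) & scores.H.notna()
    bound = h_max + slope * np.log10(scores.max_expr.where(ok, expr_min) / expr_min)
    ok &= scores.H <= bound
    assigned = scores.F.idxmax(axis=1)
    out = pd.DataFrame({
        "feature": scores.H.index,
        "H": scores.H.to_numpy(),
        "max_expr": scores.max_expr.to_numpy(),
        "cell_type": assigned.to_numpy(),
    })
    return out[ok.to_numpy()].reset_index(drop=True)


def cluster_Q(scores: EntropyScores, features: pd.Index | list | None = None,
              method: str = "average", metric: str = "euclidean"):
    """Hierarchically cluster Q row-vectors of (passing) features.

    Infinite Q entries (F_i = 0) are clipped to the matrix's maximum finite
    value — the "not expressed in this type" sentinel rendered as the heatmap
    maximum. Returns (ordered Q DataFrame, linkage matrix); deterministic for
    a fixed input order. A single feature yields a trivial one-leaf output.
    """
    Q = scores.Q if features is None else scores.Q.loc[features]
    Q = Q[scores.H.loc[Q.index].notna()]
    vals = Q.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    clipval = float(finite.max()) if len(finite) else 0.0
    vals = np.where(np.isfinite(vals), vals, clipval)
    if len(Q) < 2:
        return Q.copy(), None
    Z = linkage(pdist(vals, metric=metric), method=method)
    order = leaves_list(Z)
    return pd.DataFrame(vals, index=Q.index, columns=Q.columns).iloc[order], Z


def cut_clusters(Z, k: int) -> np.ndarray:
    """Flat cluster labels from a linkage matrix at k clusters."""
    return fcluster(Z, t=k, criterion="maxclust")
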