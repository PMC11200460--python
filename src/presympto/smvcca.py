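"""Supervised multiview CCA over region views plus a one-hot label view.

The M region blocks Z_m of the completed feature matrix (N x D each) and the
one-hot class-label view Z_l (N x D_l, D_l = 2) are jointly projected by
maximizing the sum of between-view covariances subject to per-view unit
variance, which reduces to the generalized eigenvalue problem

    C_bar V = eps (C_under + eta I) V

where C_bar carries the between-view cross-product blocks
C_{a,b} = Z_a^T Z_b (zero diagonal blocks), C_under is the block-diagonal of
the within-view blocks, and eta is a ridge regularizer.  Views are
column-centered by default and scaled by 1/sqrt(N-1) so the blocks are on a
covariance scale; neither choice changes the eigenvalue problem's optima but
centering is required for the correlation reading of the cross-loadings and
the scaling keeps eta's meaning stable across N.

Brain regions are ranked by their cross-loading: the mean absolute Pearson
correlation between each of the region's D feature columns and the label
view's leading projection z_l1 (the canonical variate of the largest
eigenvalue).  Eigenvector signs are fixed by requiring the label-view
block's first nonzero coefficient to be positive, and the default
aggregation uses absolute correlations, so the ranking is invariant to the
inherent sign ambiguity of canonical directions.

On the real recordings this ranking orders the sources
THL > PAG > PL > AMY > S1 > ACC > BR > NAc > EMG; that ordering is the
documented reference behavior for cohorts with graded region effects.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConfigurationError, DataError, NumericalError

#: Residual bound enforced on every generalized eigen solution.
EIGEN_RESIDUAL_TOL = 1e-8

#: Fixed label-view column order.
LABEL_COLUMN_ORDER = ("wild", "diseased")


def build_label_view(labels: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    """One-hot label view Z_l (N x D_l) with a fixed column order.

    For the canonical two-class cohort the order is (wild, diseased); other
    label sets are ordered alphabetically.  Returns (Z_l, class_order).
    """
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise DataError(
            f"label view needs >= 2 classes, got {classes}"
        )
    if set(classes) == set(LABEL_COLUMN_ORDER):
        classes = list(LABEL_COLUMN_ORDER)
    index = {c: k for k, c in enumerate(classes)}
    Z_l = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Z_l[i, index[lab]] = 1.0
    return Z_l, tuple(classes)


@dataclass
class ViewSet:
    """Region views plus the label view, sharing N rows."""

    views: list[np.ndarray]
    label_view: np.ndarray
    region_names: tuple[str, ...]
    centering: bool = True

    def __post_init__(self) -> None:
        n_rows = {v.shape[0] for v in self.views}
        n_rows.add(self.label_view.shape[0])
        if len(n_rows) != 1:
            raise DataError(f"views disagree on N: {sorted(n_rows)}")
        if len(self.views) != len(self.region_names):
            raise DataError("one region name per view required")

    @property
    def n(self) -> int:
        return self.label_view.shape[0]


def make_viewset(Z: np.ndarray, regions: Sequence[str], d: int,
                 row_labels: Sequence[str], centering: bool = True) -> ViewSet:
    """Split a completed matrix into its region blocks and build the label view."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != d * len(regions):
        raise DataError(
            f"matrix has {Z.shape[1]} columns, expected {d * len(regions)}"
        )
    views = [Z[:, m * d:(m + 1) * d] for m in range(len(regions))]
    label_view, _ = build_label_view(row_labels)
    return ViewSet(views=views, label_view=label_view,
                   region_names=tuple(regions), centering=centering)


@dataclass
class BlockMatrices:
    """Assembled block matrices of the generalized eigenproblem."""

    C_bar: np.ndarray
    C_under: np.ndarray
    eta: float
    block_slices: list[slice]
    means: list[np.ndarray]
    scale: float
    centering: bool


def build_block_matrices(viewset: ViewSet, eta: float = 0.01) -> BlockMatrices:
    """Cross-product blocks C_{a,b} with zero diagonal in C_bar, block-diagonal C_under."""
    if eta < 0:
        raise ConfigurationError(f"eta must be >= 0, got {eta}")
    n = viewset.n
    scale = 1.0 / np.sqrt(max(n - 1, 1))
    processed = []
    means = []
    for V in [*viewset.views, viewset.label_view]:
        V = np.asarray(V, dtype=float)
        mean = V.mean(axis=0) if viewset.centering else np.zeros(V.shape[1])
        processed.append((V - mean) * scale)
        means.append(mean)
    widths = [V.shape[1] for V in processed]
    offsets = np.concatenate([[0], np.cumsum(widths)])
    slices = [slice(offsets[k], offsets[k + 1]) for k in range(len(widths))]
    T = np.hstack(processed)
    C = T.T @ T
    C_under = np.zeros_like(C)
    C_bar = C.copy()
    for sl in slices:
        C_under[sl, sl] = C[sl, sl]
        C_bar[sl, sl] = 0.0
    C_bar = 0.5 * (C_bar + C_bar.T)
    return BlockMatrices(
        C_bar=C_bar, C_under=C_under, eta=float(eta),
        block_slices=slices, means=means, scale=scale,
        centering=viewset.centering,
    )


@dataclass
class MVCCASolution:
    """Top-D_p generalized eigenvectors, split into per-view blocks."""

    V_blocks: list[np.ndarray]
    eigenvalues: np.ndarray
    d_p: int
    eta: float
    residual: float
    block_slices: list[slice]
    means: list[np.ndarray]
    centering: bool

    @property
    def V(self) -> np.ndarray:
        return np.vstack(self.V_blocks)


def solve_smvcca(blocks: BlockMatrices, d_p: int = 2) -> MVCCASolution:
    """Solve C_bar V = eps (C_under + eta I) V; keep the top d_p eigenpairs.

    Eigenvalues are returned in descending order; eigenvectors are normalized
    so V^T (C_under + eta I) V = I and signed so the label-view block's first
    nonzero coefficient is positive.
    """
    d_l = blocks.block_slices[-1].stop - blocks.block_slices[-1].start
    d_min = min(
        min(sl.stop - sl.start for sl in blocks.block_slices[:-1]), d_l
    )
    if not 1 <= d_p <= d_min:
        raise ConfigurationError(
            f"d_p must lie in [1, {d_min}], got {d_p}"
        )
    B = blocks.C_under + blocks.eta * np.eye(blocks.C_under.shape[0])
    try:
        eigvals, eigvecs = scipy.linalg.eigh(blocks.C_bar, B)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise NumericalError(
            f"generalized eigensolve failed ({exc}); try a larger eta"
        ) from exc
    order = np.argsort(eigvals)[::-1][:d_p]
    eps = eigvals[order]
    V = eigvecs[:, order]

    label_sl = blocks.block_slices[-1]
    for c in range(V.shape[1]):
        col = V[label_sl, c]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        ref = col[nz[0]] if nz.size else V[np.argmax(np.abs(V[:, c])), c]
        if ref < 0:
            V[:, c] = -V[:, c]

    num = blocks.C_bar @ V - B @ V @ np.diag(eps)
    denom = np.linalg.norm(blocks.C_bar @ V)
    residual = float(np.linalg.norm(num) / denom) if denom > 0 else 0.0
    if residual > EIGEN_RESIDUAL_TOL:
        raise NumericalError(
            f"generalized eigen residual {residual:.3e} exceeds "
            f"{EIGEN_RESIDUAL_TOL:.0e}"
        )
    V_blocks = [np.asarray(V[sl]) for sl in blocks.block_slices]
    return MVCCASolution(
        V_blocks=V_blocks, eigenvalues=eps, d_p=d_p, eta=blocks.eta,
        residual=residual, block_slices=blocks.block_slices,
        means=blocks.means, centering=blocks.centering,
    )


@dataclass
class ProjectedFeatures:
    """Per-view projections Z_hat_m (N x D_p) and their region-order concatenation."""

    per_view: list[np.ndarray]
    label_projection: np.ndarray
    region_names: tuple[str, ...]
    d_p: int

    @property
    def concatenated(self) -> np.ndarray:
        return np.hstack(self.per_view)


def project_views(solution: MVCCASolution, viewset: ViewSet) -> ProjectedFeatures:
    """Z_hat_m = (Z_m - mean_m) V_hat_m for every view, plus the label projection."""
    all_views = [*viewset.views, viewset.label_view]
    if len(all_views) != len(solution.V_blocks):
        raise DataError("viewset does not match the fitted solution")
    projected = []
    for V, block, mean in zip(all_views, solution.V_blocks, solution.means):
        V = np.asarray(V, dtype=float)
        if V.shape[1] != block.shape[0]:
            raise DataError(
                f"view width {V.shape[1]} != projection rows {block.shape[0]}"
            )
        centered = V - mean if solution.centering else V
        projected.append(centered @ block)
    return ProjectedFeatures(
        per_view=projected[:-1],
        label_projection=projected[-1],
        region_names=viewset.region_names,
        d_p=solution.d_p,
    )


def pearson(g: np.ndarray, h: np.ndarray) -> float:
    """Pearson correlation; 0 (with a warning) for constant inputs."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    gc = g - g.mean()
    hc = h - h.mean()
    denom = np.sqrt(np.sum(gc ** 2) * np.sum(hc ** 2))
    if denom == 0:
        warnings.warn("constant column in cross-loading: correlation set to 0",
                      stacklevel=2)
        return 0.0
    return float(np.sum(gc * hc) / denom)


def cross_loading(view: np.ndarray, z_l1: np.ndarray,
                  aggregation: str = "abs_mean") -> tuple[np.ndarray, float]:
    """Per-dimension correlations with z_l1 and their aggregate CL_m.

    ``abs_mean`` (default) averages absolute correlations, making CL_m
    invariant to the sign ambiguity of the canonical variate; ``signed_mean``
    averages the raw correlations.
    """
    view = np.asarray(view, dtype=float)
    z_l1 = np.asarray(z_l1, dtype=float)
    if view.shape[0] < 3:
        raise DataError(f"need N >= 3 samples, got {view.shape[0]}")
    if aggregation not in ("abs_mean", "signed_mean"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    corrs = np.array([pearson(view[:, d], z_l1) for d in range(view.shape[1])])
    if aggregation == "abs_mean":
        cl = float(np.abs(corrs).mean())
    else:
        cl = float(corrs.mean())
    return corrs, cl


def cross_loading_report(
    viewset: ViewSet,
    projected: ProjectedFeatures,
    feature_names: Sequence[str] | None = None,
    aggregation: str = "abs_mean",
) -> pd.DataFrame:
    """Cross-loading table: one row per region, per-dimension correlations,
    the aggregate CL and the resulting rank (1 = highest CL)."""
    z_l1 = projected.label_projection[:, 0]
    rows = []
    for region, view in zip(viewset.region_names, viewset.views):
        corrs, cl = cross_loading(view, z_l1, aggregation=aggregation)
        rows.append((region, *corrs, cl))
    d = len(rows[0]) - 2
    names = list(feature_names) if feature_names is not None else [
        f"dim_{i}" for i in range(d)
    ]
    report = pd.DataFrame(rows, columns=["region", *names, "CL"])
    report.attrs["aggregation"] = aggregation
    order = np.argsort(-report["CL"].to_numpy(), kind="stable")
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    report["rank"] = rank
    return report


def rank_regions(report: pd.DataFrame) -> list[str]:
    """Regions in descending CL order; ties keep the canonical region order."""
    order = np.argsort(-report["CL"].to_numpy(), kind="stable")
    return [report["region"].iloc[i] for i in order]
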