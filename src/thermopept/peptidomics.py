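"""MALDI-TOF peptidome analysis.

Spectra are baseline-subtracted, binned onto a common m/z grid (which
doubles as spectrum alignment), replicate spots are averaged per sample,
and the resulting feature matrix is scaled (mean-centred or Pareto) for
PCA and discriminant PCA.  Differential bins are found by unpaired
two-tailed t-tests (or a three-group one-way F test) and each candidate
mass receives a group-abundance pattern call such as
"Absent in Control; Cerv Ca = CIN 2".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from sklearn.decomposition import PCA as _SKPCA

from .synthetic import MS_GROUPS, Spectrum

#: the peptidome analysis m/z range
MZ_RANGE = (900.0, 3000.0)
DEFAULT_BIN_WIDTH = 1.0

#: canonical tie-break priority for pattern strings
DEFAULT_TIE_ORDER = ("Cerv Ca", "CIN 2", "Control")


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples x m/z-bins intensity matrix after binning and averaging."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    bin_centers: np.ndarray
    values: np.ndarray
    scaling_state: str = "raw"

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.scaling_state not in ("raw", "mean_centered", "pareto"):
            raise ValueError(f"unknown scaling_state {self.scaling_state!r}")
        if values.shape != (len(self.sample_ids), centers.size):
            raise ValueError("values shape inconsistent with ids and bins")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("bin centers must be ascending")


@dataclass(frozen=True)
class PCAResult:
    """Principal components of a scaled feature matrix."""

    scores: np.ndarray              # samples x components
    loadings: np.ndarray            # bins x components, orthonormal columns
    explained_variance: np.ndarray  # per component, non-increasing


@dataclass(frozen=True)
class DPCAResult:
    """Discriminant PCA (PCA followed by Fisher LDA on the scores)."""

    scores: np.ndarray        # samples x discriminant axes (2-D)
    groups: tuple[str, ...]
    purity: float             # nearest-centroid agreement with own group
    degenerate: bool = False


@dataclass(frozen=True)
class DifferentialPeptide:
    """One tested m/z bin."""

    mz_bin: float
    comparison: str
    t_statistic: float
    p_value: float
    significant: bool
    pattern: str = ""


def subtract_spectrum_baseline(
    spectrum: Spectrum, window_width: float = 50.0
) -> Spectrum:
    """Remove the slowly varying chemical baseline of a spectrum.

    The baseline is a moving minimum followed by a moving average, both
    over ``window_width`` m/z; residual negative intensities are clipped
    to zero.
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    if spectrum.mz.size == 0:
        raise ValueError("empty spectrum")
    spacing = float(np.median(np.diff(spectrum.mz)))
    size = max(3, int(round(window_width / spacing)))
    floor = minimum_filter1d(spectrum.intensity, size=size, mode="nearest")
    baseline = uniform_filter1d(floor, size=size, mode="nearest")
    corrected = np.clip(spectrum.intensity - baseline, 0.0, None)
    return replace(spectrum, intensity=corrected)


def bin_edges(
    bin_width: float = DEFAULT_BIN_WIDTH,
    mz_range: tuple[float, float] = MZ_RANGE,
) -> np.ndarray:
    n_bins = int(np.ceil((mz_range[1] - mz_range[0]) / bin_width))
    return mz_range[0] + bin_width * np.arange(n_bins + 1)


def bin_spectrum(
    spectrum: Spectrum,
    bin_width: float = DEFAULT_BIN_WIDTH,
    mz_range: tuple[float, float] = MZ_RANGE,
) -> np.ndarray:
    """Sum intensities into half-open bins [edge, edge + width).

    Points outside ``mz_range`` are discarded; a point exactly on an edge
    goes to the higher bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = bin_edges(bin_width, mz_range)
    n_bins = edges.size - 1
    idx = np.floor((spectrum.mz - mz_range[0]) / bin_width).astype(int)
    keep = (idx >= 0) & (idx < n_bins)
    return np.bincount(
        idx[keep], weights=spectrum.intensity[keep], minlength=n_bins
    )


def average_replicates(vectors) -> np.ndarray:
    """Elementwise mean of the replicate (spot) feature vectors."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("no replicate vectors")
    if any(v.shape != vectors[0].shape for v in vectors):
        raise ValueError("replicate vectors are on inconsistent bin grids")
    return np.mean(vectors, axis=0)


def build_feature_matrix(
    spectra: list[Spectrum],
    bin_width: float = DEFAULT_BIN_WIDTH,
    mz_range: tuple[float, float] = MZ_RANGE,
    baseline_window: float | None = 50.0,
) -> FeatureMatrix:
    """Baseline-subtract, bin and replicate-average a set of spectra.

    Spectrum alignment is by shared binning on the common grid.  One row
    per sample, replicate spots averaged.
    """
    by_sample: dict[str, dict] = {}
    for sp in spectra:
        if baseline_window is not None:
            sp = subtract_spectrum_baseline(sp, baseline_window)
        vec = bin_spectrum(sp, bin_width, mz_range)
        entry = by_sample.setdefault(
            sp.sample_id, {"group": sp.group, "vectors": []}
        )
        entry["vectors"].append(vec)
    sample_ids = tuple(by_sample)
    groups = tuple(by_sample[s]["group"] for s in sample_ids)
    values = np.array(
        [average_replicates(by_sample[s]["vectors"]) for s in sample_ids]
    )
    edges = bin_edges(bin_width, mz_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FeatureMatrix(
        sample_ids=sample_ids,
        groups=groups,
        bin_centers=centers,
        values=values,
        scaling_state="raw",
    )


def scale_features(matrix: FeatureMatrix, method: str = "pareto") -> FeatureMatrix:
    """No-weighting preprocessing: mean-centre or Pareto-scale columns.

    Pareto scaling divides centred columns by the square root of their
    standard deviation; zero-variance columns are left centred only.
    """
    if method not in ("mean_center", "pareto"):
        raise ValueError(f"unknown scaling method {method!r}")
    if len(matrix.sample_ids) < 2:
        raise ValueError("scaling needs at least two samples")
    centered = matrix.values - matrix.values.mean(axis=0)
    if method == "mean_center":
        return replace(matrix, values=centered, scaling_state="mean_centered")
    sd = matrix.values.std(axis=0, ddof=1)
    scale = np.sqrt(np.where(sd > 0, sd, 1.0))
    return replace(matrix, values=centered / scale, scaling_state="pareto")


def pca(matrix: FeatureMatrix, n_components: int) -> PCAResult:
    """Principal components of the scaled matrix, via SVD.

    The sign of each component is fixed so its largest-magnitude loading
    is positive, making results deterministic.
    """
    if matrix.scaling_state == "raw":
        raise ValueError("scale the feature matrix before PCA")
    max_rank = min(len(matrix.sample_ids) - 1, matrix.bin_centers.size)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must lie in [1, {max_rank}], got {n_components}"
        )
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.values)
    loadings = model.components_.T  # bins x components
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                             np.arange(n_components)])
    signs[signs == 0] = 1.0
    return PCAResult(
        scores=scores * signs,
        loadings=loadings * signs,
        explained_variance=model.explained_variance_,
    )


def _fisher_axes(scores, lab, uniq, n_axes, ridge):
    """Fisher LDA axes of labelled score vectors; returns (axes, s_b, s_w)."""
    grand = scores.mean(axis=0)
    d = scores.shape[1]
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    for g in uniq:
        xg = scores[lab == g]
        mu = xg.mean(axis=0)
        dev = xg - mu
        s_w += dev.T @ dev
        diff = (mu - grand)[:, None]
        s_b += xg.shape[0] * (diff @ diff.T)
    s_w_reg = s_w + ridge * max(np.trace(s_w), 1.0) / d * np.eye(d)
    eigvals, eigvecs = linalg.eigh(s_b, s_w_reg)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order[:n_axes]]
    return axes, s_b, s_w


def _loo_purity(values, lab, uniq, n_pcs, n_axes, ridge):
    """Leave-one-out nearest-centroid purity of the dPCA construction."""
    n = values.shape[0]
    hits = 0
    for i in range(n):
        train = np.delete(np.arange(n), i)
        x_tr = values[train]
        mu = x_tr.mean(axis=0)
        xc = x_tr - mu
        k = min(n_pcs, len(train) - 1)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        load = vt[:k].T
        scores_tr = xc @ load
        axes, _, _ = _fisher_axes(scores_tr, lab[train], uniq, n_axes, ridge)
        disc_tr = scores_tr @ axes
        cents = np.array(
            [disc_tr[lab[train] == g].mean(axis=0) for g in uniq]
        )
        disc_te = ((values[i] - mu) @ load) @ axes
        nearest = np.argmin(np.linalg.norm(cents - disc_te, axis=1))
        hits += uniq[nearest] == lab[i]
    return hits / n


def discriminant_pca(
    matrix: FeatureMatrix,
    labels=None,
    n_pcs: int | None = None,
    n_axes: int = 2,
    ridge: float = 1e-8,
    cross_validate: bool = False,
) -> DPCAResult:
    """PCA-DA: Fisher discriminant axes on the retained PCA scores.

    ``n_pcs`` defaults to the largest usable score space,
    ``min(10, n_samples - n_groups - 1)``, retaining as much variance as
    the discriminant step can bear at small n.  Returns the 2-D
    discriminant scores and the nearest-centroid purity (fraction of
    samples whose nearest group centroid, in discriminant space, belongs
    to their own group).  In-sample purity flatters random labels at
    small n; ``cross_validate=True`` computes leave-one-out purity
    instead (PCA and discriminant axes refitted without each sample),
    the appropriate chance-level control for permutation checks.  A
    singular within-group scatter is ridge-regularised with a warning;
    vanishing between-group scatter flags the result degenerate.
    """
    labels = tuple(matrix.groups if labels is None else labels)
    if len(labels) != len(matrix.sample_ids):
        raise ValueError("one label per sample required")
    uniq = sorted(set(labels))
    counts = {g: labels.count(g) for g in uniq}
    if len(uniq) < 2 or min(counts.values()) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = len(labels)
    if n_pcs is None:
        n_pcs = min(10, n - len(uniq) - 1)
    if not 1 <= n_pcs < n - len(uniq):
        raise ValueError(
            f"n_pcs must be in [1, {n - len(uniq) - 1}]"
        )

    lab = np.array(labels)
    n_axes = min(n_axes, len(uniq) - 1, n_pcs)
    scores = pca(matrix, n_pcs).scores
    axes, s_b, s_w = _fisher_axes(scores, lab, uniq, n_axes, ridge)

    degenerate = False
    if np.trace(s_b) <= 1e-12 * max(np.trace(s_w), 1.0):
        degenerate = True
        warnings.warn("between-group scatter vanishes; dPCA degenerate",
                      stacklevel=2)
    cond = np.linalg.cond(s_w) if np.trace(s_w) > 0 else np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "within-group scatter is singular; ridge-regularising",
            stacklevel=2,
        )
    disc = scores @ axes

    if cross_validate:
        purity = float(
            _loo_purity(matrix.values, lab, uniq, n_pcs, n_axes, ridge)
        )
    else:
        centroids = {g: disc[lab == g].mean(axis=0) for g in uniq}
        cents = np.array([centroids[g] for g in uniq])
        nearest = np.argmin(
            np.linalg.norm(disc[:, None, :] - cents[None, :, :], axis=2),
            axis=1,
        )
        purity = float(
            np.mean([uniq[k] == g for k, g in zip(nearest, labels)])
        )
    return DPCAResult(
        scores=disc, groups=labels, purity=purity, degenerate=degenerate
    )


def differential_t_test(
    matrix: FeatureMatrix,
    labels=None,
    group_pair: tuple[str, str] = ("Control", "Cerv Ca"),
    alpha: float = 0.05,
) -> list[DifferentialPeptide]:
    """Unpaired two-tailed pooled-variance t-test for every m/z bin.

    Bins where both groups have zero variance and equal means give p = 1.
    """
    labels = np.array(matrix.groups if labels is None else labels)
    ga, gb = group_pair
    xa = matrix.values[labels == ga]
    xb = matrix.values[labels == gb]
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(xa, xb, axis=0, equal_var=True)
    # identical constant bins (nan t): no evidence of difference
    degenerate = np.isnan(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_val = np.where(degenerate, 1.0, p_val)
    comparison = f"{ga} vs {gb}"
    return [
        DifferentialPeptide(
            mz_bin=float(mz),
            comparison=comparison,
            t_statistic=float(t),
            p_value=float(p),
            significant=bool(p < alpha),
        )
        for mz, t, p in zip(matrix.bin_centers, t_stat, p_val)
    ]


def differential_f_test(
    matrix: FeatureMatrix, labels=None, alpha: float = 0.05
) -> list[DifferentialPeptide]:
    """One-way F test across all groups for every m/z bin (3-group call)."""
    labels = np.array(matrix.groups if labels is None else labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [matrix.values[labels == g] for g in uniq]
    if any(s.shape[0] < 2 for s in samples):
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p_val = stats.f_oneway(*samples, axis=0)
    degenerate = np.isnan(f_stat)
    f_stat = np.where(degenerate, 0.0, f_stat)
    p_val = np.where(degenerate, 1.0, p_val)
    comparison = " vs ".join(uniq)
    return [
        DifferentialPeptide(
            mz_bin=float(mz),
            comparison=comparison,
            t_statistic=float(f),
            p_value=float(p),
            significant=bool(p < alpha),
        )
        for mz, f, p in zip(matrix.bin_centers, f_stat, p_val)
    ]


def classify_pattern(
    group_means: dict[str, float],
    absence_threshold: float | None = None,
    fold_tolerance: float = 0.7,
    tie_order: tuple[str, ...] = DEFAULT_TIE_ORDER,
) -> str:
    """Call a group-abundance pattern string for one m/z bin.

    Groups with mean below ``absence_threshold`` (default: 10% of the
    largest group mean, accommodating residual baseline in empty bins) are
    reported "Absent in <G>"; remaining groups are ordered by decreasing
    mean and joined with "=" when within ``fold_tolerance`` on the log2
    scale, else ">".  Groups inside an "=" run are reordered by the fixed
    ``tie_order`` priority so calls are deterministic.
    """
    if len(group_means) < 2:
        raise ValueError("need at least two groups")
    means = dict(group_means)
    peak = max(means.values())
    if absence_threshold is None:
        absence_threshold = 0.10 * peak
    if peak < absence_threshold or peak <= 0:
        warnings.warn("all groups below the absence threshold", stacklevel=2)
        return "; ".join(f"Absent in {g}" for g in _order(means, tie_order))

    absent = [g for g, m in means.items() if m < absence_threshold]
    present = {g: m for g, m in means.items() if m >= absence_threshold}

    ranked = sorted(present, key=lambda g: -present[g])
    # split into maximal runs of "equal" (within fold_tolerance) groups
    runs: list[list[str]] = [[ranked[0]]]
    for g in ranked[1:]:
        prev = runs[-1][-1]
        if abs(np.log2(present[g] / present[prev])) < fold_tolerance:
            runs[-1].append(g)
        else:
            runs.append([g])
    chain = ">".join(
        " = ".join(_order({g: None for g in run}, tie_order)) for run in runs
    )
    clauses = [f"Absent in {g}" for g in _order({g: None for g in absent},
                                                tie_order)]
    clauses.append(chain)
    return "; ".join(clauses)


def _order(groups: dict, tie_order: tuple[str, ...]) -> list[str]:
    known = [g for g in tie_order if g in groups]
    extra = sorted(g for g in groups if g not in tie_order)
    return known + extra


def group_bin_means(
    matrix: FeatureMatrix,
    mz: float,
    labels=None,
    cluster: int = 1,
    background_flank: tuple[int, int] = (3, 6),
) -> dict[str, float]:
    """Mean peak-cluster intensity per group around ``mz``.

    The cluster is the target bin plus ``cluster`` bins on each side, so a
    peak falling near a bin edge is captured whole (the "peak cluster area"
    convention).  A per-sample local background — the median of the flanking
    bins ``background_flank`` bins away on either side — is subtracted from
    each cluster bin, removing the residual noise floor that survives
    spectrum-level baseline subtraction; negative results clip to zero.
    Set ``background_flank=None`` to skip the local correction.
    """
    labels = np.array(matrix.groups if labels is None else labels)
    idx = int(np.argmin(np.abs(matrix.bin_centers - mz)))
    lo = max(0, idx - cluster)
    hi = min(matrix.bin_centers.size, idx + cluster + 1)
    cluster_sum = matrix.values[:, lo:hi].sum(axis=1)
    if background_flank is not None:
        near, far = background_flank
        flank_idx = [
            j
            for j in range(idx - far, idx + far + 1)
            if abs(j - idx) >= near and 0 <= j < matrix.bin_centers.size
        ]
        local_bg = np.median(matrix.values[:, flank_idx], axis=1)
        cluster_sum = np.clip(cluster_sum - (hi - lo) * local_bg, 0.0, None)
    return {
        g: float(cluster_sum[labels == g].mean()) for g in sorted(set(labels))
    }
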