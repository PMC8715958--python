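"""Voxelwise and ROI group statistics, GDS item tests, subsampled ANOVA.

Group comparisons of SUVr volumes run a per-voxel general linear model
with the group indicator plus nuisance covariates (age, sex, education,
ApoE4), giving a t-map that is thresholded by Bonferroni family-wise
error control or Benjamini-Hochberg FDR and cleaned with a
cluster-extent filter (18-neighbour connectivity, extent strictly
greater than 5 voxels).

Mental-state analyses: per-item 2x2 chi-squared tests of the 15 binary
GDS responses against a grouping factor (Bonferroni threshold 0.05/16
across the 15 items plus the total score), and a balanced two-way ANOVA
of the GDS total on certainty x impairment, repeated over random
balanced subsamples with the mean p-value reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthetic import RoiAtlas

COVARIATE_COLUMNS = ("age", "sex", "education", "apoe4")


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# voxelwise GLM


@dataclass
class StatMap:
    """Per-voxel t statistics with significance masks."""

    t: np.ndarray
    df: int
    brain_mask: np.ndarray
    p: np.ndarray
    masks: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def n_voxels(self) -> int:
        return int(self.brain_mask.sum())


def _design_matrix(group, covariates) -> tuple[np.ndarray, list[str]]:
    group = np.asarray(group, dtype=float)
    cols = [np.ones_like(group), group]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = pd.DataFrame(covariates).copy()
        for name in cov.columns:
            col = cov[name]
            if col.dtype == object:
                col = col.map({"M": 0.0, "F": 1.0}).astype(float)
            cols.append(np.asarray(col, dtype=float))
            names.append(str(name))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(name)
        raise StatsError(f"rank-deficient design; collinear columns: {bad}")
    return X, names


def _glm_t(X: np.ndarray, Y: np.ndarray, coef_index: int = 1):
    """t statistic of one design column, fitted by least squares.

    ``Y`` is (n, V); returns (t-values (V,), df)."""
    n, p = X.shape
    if n <= p:
        raise StatsError(f"need more samples ({n}) than design columns ({p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_index, coef_index], 0.0))
    # residual variance at float-roundoff level means a degenerate fit
    floor = 1e-10 * (np.abs(Y).max(axis=0) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > floor, beta[coef_index] / se, 0.0)
    return t, df


def glm_tmap(volumes, group, covariates=None, brain_mask=None) -> StatMap:
    """Voxelwise GLM t-map of a binary group effect, adjusting covariates.

    ``volumes`` is an (n, X, Y, Z) stack (or list of BrainVolume) on a
    shared grid; ``brain_mask`` restricts the fit (taken from the first
    BrainVolume if not given).  Covariates: age, sex (M/F or 0/1),
    education, apoe4.
    """
    from .petprep import BrainVolume

    if not isinstance(volumes, np.ndarray):
        if brain_mask is None and isinstance(volumes[0], BrainVolume):
            brain_mask = volumes[0].mask
        volumes = np.stack([
            v.data if isinstance(v, BrainVolume) else np.asarray(v)
            for v in volumes
        ])
    if brain_mask is None:
        brain_mask = np.ones(volumes.shape[1:], dtype=bool)
    X, _ = _design_matrix(group, covariates)
    Y = volumes[:, brain_mask].astype(np.float64)
    t, df = _glm_t(X, Y)
    t_grid = np.zeros(volumes.shape[1:])
    t_grid[brain_mask] = t
    p_grid = np.ones(volumes.shape[1:])
    p_grid[brain_mask] = 2.0 * stats.t.sf(np.abs(t), df)
    return StatMap(t=t_grid, df=df, brain_mask=brain_mask, p=p_grid)


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejections at level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) / m) * alpha
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.flatnonzero(below).max()
        reject[order[: k + 1]] = True
    return reject


def threshold_map(stat_map: StatMap, method: str = "fwe", alpha: float = 0.05) -> StatMap:
    """Set the FWE (Bonferroni) or FDR (Benjamini-Hochberg) mask in place.

    Both work on the two-sided per-voxel p-values inside the brain mask;
    the Bonferroni per-voxel threshold is ``alpha / V``.
    """
    if not (0.0 < alpha < 1.0):
        raise StatsError("alpha must lie in (0, 1)")
    mask = stat_map.brain_mask
    p = stat_map.p[mask]
    if method == "fwe":
        sig = p < (alpha / stat_map.n_voxels)
    elif method == "fdr":
        sig = bh_fdr(p, alpha)
    else:
        raise StatsError(f"unknown correction method {method!r}")
    grid = np.zeros(mask.shape, dtype=bool)
    grid[mask] = sig
    stat_map.masks[method] = grid
    stat_map.alpha = alpha
    return stat_map


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_filter(
    mask: np.ndarray,
    min_extent: int = 5,
    connectivity: int = 18,
    values: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep connected components strictly larger than ``min_extent`` voxels.

    Returns the filtered mask and a cluster table (size, peak voxel).  The
    peak is the in-cluster maximum of ``|values|`` when a value grid (for
    example the t-map) is supplied, otherwise the first voxel in scan
    order.
    """
    if connectivity not in _STRUCTURES:
        raise StatsError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    keep = np.zeros_like(mask)
    rows = []
    for lab in range(1, n + 1):
        members = labels == lab
        size = int(members.sum())
        if size > min_extent:
            keep |= members
            coords = np.argwhere(members)
            if values is not None:
                vals = np.abs(np.asarray(values)[members])
                peak = coords[int(np.argmax(vals))]
            else:
                peak = coords[0]
            rows.append({
                "size": size,
                "peak_x": int(peak[0]), "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
            })
    table = pd.DataFrame(rows, columns=["size", "peak_x", "peak_y", "peak_z"])
    return keep, table


def roi_compare(
    volumes, atlas: RoiAtlas, group, covariates=None, exclude=("pons",),
) -> pd.DataFrame:
    """Per-ROI group comparison of subject-level mean SUVr.

    Each subject's SUVr is averaged over the ROI, then the same GLM as the
    voxelwise map is fitted; p-values are Bonferroni-corrected across the
    tested (non-empty) ROIs.
    """
    from .petprep import BrainVolume

    if not isinstance(volumes, np.ndarray):
        volumes = np.stack([
            v.data if isinstance(v, BrainVolume) else np.asarray(v)
            for v in volumes
        ])
    X, _ = _design_matrix(group, covariates)
    group = np.asarray(group)
    rows = []
    for label, name in sorted(atlas.names.items()):
        if name in exclude:
            continue
        roi = atlas.labels == label
        if not roi.any():
            rows.append({"roi": name, "n_voxels": 0, "skipped": True})
            continue
        means = volumes[:, roi].mean(axis=1).astype(np.float64)
        t, df = _glm_t(X, means[:, None])
        p = float(2.0 * stats.t.sf(abs(float(t[0])), df))
        rows.append({
            "roi": name, "n_voxels": int(roi.sum()), "skipped": False,
            "mean_group0": float(means[group == 0].mean()),
            "mean_group1": float(means[group == 1].mean()),
            "t": float(t[0]), "p": p,
        })
    table = pd.DataFrame(rows)
    tested = int((~table["skipped"]).sum())
    if tested:
        table.loc[~table["skipped"], "p_corrected"] = np.minimum(
            table.loc[~table["skipped"], "p"] * tested, 1.0
        )
        table["significant"] = table.get("p_corrected", np.nan) < 0.05
    return table


# --------------------------------------------------------------------------
# GDS item battery


def gds_itemwise(cohort: pd.DataFrame, factor: str) -> tuple[pd.DataFrame, float]:
    """Chi-squared test of every GDS item against a binary factor.

    ``factor`` is ``"impairment"`` (diagnosed/true impaired vs healthy)
    or ``"certainty"`` (certain vs uncertain triage).  Each binary item is
    tested with a 2x2 chi-squared without continuity correction; the GDS
    total with a Welch t-test.  The family-wise threshold is 0.05 / 16
    (15 items + total), i.e. 0.0031 to two significant figures.
    """
    from .synthetic import GDS_ITEMS

    if factor == "impairment":
        diag = cohort.get("diagnosis")
        if diag is not None and (diag != "none").any():
            levels = np.where(
                diag.ne("none"), diag, cohort["true_state"]
            )
        else:
            levels = cohort["true_state"].to_numpy()
        binary = np.asarray(levels) == "impaired"
    elif factor == "certainty":
        binary = cohort["triage_label"].ne("uncertain").to_numpy()
    else:
        raise StatsError("factor must be 'impairment' or 'certainty'")
    if binary.all() or not binary.any():
        raise StatsError(f"both levels of {factor} must be present")

    n_tests = len(GDS_ITEMS) + 1
    threshold = 0.05 / n_tests
    rows = []
    for item in GDS_ITEMS:
        resp = cohort[f"gds_{item}"].to_numpy().astype(int)
        table = np.array([
            [((resp == 1) & binary).sum(), ((resp == 1) & ~binary).sum()],
            [((resp == 0) & binary).sum(), ((resp == 0) & ~binary).sum()],
        ])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if (expected == 0).any():
            rows.append({"item": item, "stat": np.nan, "p": np.nan,
                         "skipped": True, "significant": False})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"item": item, "stat": float(chi2), "p": float(p),
                     "skipped": False, "significant": p < threshold})
    total = cohort["gds_total"].to_numpy(dtype=float)
    t, p = stats.ttest_ind(total[binary], total[~binary], equal_var=False)
    rows.append({"item": "total", "stat": float(t), "p": float(p),
                 "skipped": False, "significant": p < threshold})
    return pd.DataFrame(rows), threshold


# --------------------------------------------------------------------------
# balanced subsampled two-way ANOVA


@dataclass
class AnovaResult:
    mean_p: dict
    p_lists: dict
    subsample_size: int
    repeats: int


def _balanced_twoway_anova(y: np.ndarray) -> dict:
    """Closed-form balanced 2x2 ANOVA with interaction.

    ``y`` has shape (2, 2, r): factors A, B with r replicates per cell.
    Returns p-values for both main effects and the interaction; degenerate
    (zero within-cell variance) gives NaN.
    """
    a, b, r = y.shape
    assert a == 2 and b == 2
    grand = y.mean()
    cell_means = y.mean(axis=2)
    a_means = y.mean(axis=(1, 2))
    b_means = y.mean(axis=(0, 2))
    ss_a = b * r * ((a_means - grand) ** 2).sum()
    ss_b = a * r * ((b_means - grand) ** 2).sum()
    ss_cells = r * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = ((y - cell_means[:, :, None]) ** 2).sum()
    df_e = a * b * (r - 1)
    if df_e <= 0 or ss_e <= 0:
        return {"A": np.nan, "B": np.nan, "AB": np.nan}
    ms_e = ss_e / df_e
    out = {}
    for name, ss in (("A", ss_a), ("B", ss_b), ("AB", ss_ab)):
        f = (ss / 1.0) / ms_e
        out[name] = float(stats.f.sf(f, 1, df_e))
    return out


def anova_subsampled(
    cohort: pd.DataFrame,
    response: str = "gds_total",
    repeats: int = 100,
    seed: int = 0,
) -> AnovaResult:
    """Two-way ANOVA of a response on certainty x impairment, repeated on
    random balanced subsamples.

    All four cells are subsampled without replacement down to the smallest
    cell size before each ANOVA; the mean p-value over ``repeats`` draws
    is reported per effect (certainty, impairment, interaction).
    """
    certain = cohort["triage_label"].ne("uncertain").to_numpy()
    diag = cohort.get("diagnosis")
    if diag is not None and (diag != "none").any():
        state = np.where(diag.ne("none"), diag, cohort["true_state"])
    else:
        state = cohort["true_state"].to_numpy()
    impaired = np.asarray(state) == "impaired"
    y = cohort[response].to_numpy(dtype=float)

    cells = {}
    for ci, cval in ((0, False), (1, True)):
        for ii, ival in ((0, False), (1, True)):
            idx = np.flatnonzero((certain == cval) & (impaired == ival))
            if idx.size == 0:
                raise StatsError(
                    f"empty cell certainty={cval} impairment={ival}"
                )
            cells[(ci, ii)] = idx
    size = min(len(v) for v in cells.values())

    rng = np.random.default_rng(seed)
    p_lists = {"certainty": [], "impairment": [], "interaction": []}
    for _ in range(repeats):
        block = np.empty((2, 2, size))
        for (ci, ii), idx in cells.items():
            take = rng.choice(idx, size=size, replace=False)
            block[ci, ii] = y[take]
        p = _balanced_twoway_anova(block)
        p_lists["certainty"].append(p["A"])
        p_lists["impairment"].append(p["B"])
        p_lists["interaction"].append(p["AB"])
    mean_p = {
        k: (float(np.mean(v)) if not np.isnan(v).all() else float("nan"))
        for k, v in p_lists.items()
    }
    return AnovaResult(
        mean_p=mean_p, p_lists=p_lists, subsample_size=size, repeats=repeats,
    )
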