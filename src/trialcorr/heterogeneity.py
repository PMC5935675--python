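"""Diversity, spatial and immune-infiltrate statistics over cell tables.

Per-slide summaries carry the four population fractions, Shannon entropy
(natural log by default, base-2 option), and CD8/GZMB infiltrate measures.
Group comparisons use exact small-sample Wilcoxon tests (rank-sum for
unpaired, signed-rank for paired, with a paired-t alternative), pooled
counts use a chi-square test of homogeneity, and the diversity-infiltrate
association is an OLS regression with a pointwise 95% confidence band.
The topology map grids cells into bins and reports per-bin population
counts and the dominant label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from trialcorr.records import POPULATIONS
from trialcorr.stats import (
    ComparisonResult,
    paired_t_test,
    rank_sum_test,
    signed_rank_test,
)

LN4 = math.log(4.0)

TIMEPOINTS = ("baseline", "cycle2", "primary", "metastasis")


def shannon_entropy(fractions, base: float = math.e) -> float:
    """-sum p log p over nonzero fractions (p log p -> 0 as p -> 0)."""
    p = np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("fractions sum to zero")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(base))


@dataclass(frozen=True)
class SlideSummary:
    slide_id: str
    n_cells: int
    fractions: tuple[float, float, float, float]
    shannon: float
    cd8_per_montage: float
    gzmb_fraction: float       # NaN when no CD8+ cells
    timepoint: str = "baseline"

    def __post_init__(self):
        if self.n_cells > 0:
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")
            if not (-1e-12 <= self.shannon <= LN4 + 1e-12):
                raise ValueError("shannon outside [0, ln 4]")


def summarize_slide(cells: pd.DataFrame, slide_id: str = "slide",
                    montages: np.ndarray | None = None,
                    timepoint: str = "baseline",
                    entropy_base: float = math.e) -> SlideSummary:
    """Population fractions, Shannon diversity and infiltrate summaries.

    ``montages`` optionally assigns each cell to an imaging field; CD8
    counts are then averaged across fields, mirroring count-per-montage
    quantification. Without it the whole slide is one field.
    """
    if cells.empty:
        raise ValueError("empty cell table has no defined summary")
    n = len(cells)
    counts = np.array([(cells["population"] == p).sum() for p in POPULATIONS],
                      dtype=float)
    if counts.sum() != n:
        raise ValueError("cells with unknown population labels")
    fractions = counts / n
    h = shannon_entropy(fractions, base=entropy_base)
    cd8 = cells["cd8"].to_numpy(dtype=bool) if "cd8" in cells else \
        np.zeros(n, dtype=bool)
    gzmb = cells["gzmb"].to_numpy(dtype=bool) if "gzmb" in cells else \
        np.zeros(n, dtype=bool)
    if montages is not None:
        montages = np.asarray(montages)
        if montages.shape[0] != n:
            raise ValueError("montage assignment length mismatch")
        cd8_per = float(pd.Series(cd8).groupby(montages).sum().mean())
    else:
        cd8_per = float(cd8.sum())
    n_cd8 = int(cd8.sum())
    gzmb_frac = float((gzmb & cd8).sum() / n_cd8) if n_cd8 else float("nan")
    return SlideSummary(slide_id=slide_id, n_cells=n,
                        fractions=tuple(fractions), shannon=h,
                        cd8_per_montage=cd8_per, gzmb_fraction=gzmb_frac,
                        timepoint=timepoint)


def summaries_frame(summaries: list[SlideSummary]) -> pd.DataFrame:
    """Flatten summaries to a table (one row per slide)."""
    rows = []
    for s in summaries:
        row = {"slide_id": s.slide_id, "n_cells": s.n_cells,
               "shannon": s.shannon, "cd8_per_montage": s.cd8_per_montage,
               "gzmb_fraction": s.gzmb_fraction, "timepoint": s.timepoint}
        for name, f in zip(POPULATIONS, s.fractions):
            row[f"frac_{name}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def compare_fractions(group_a: list[SlideSummary],
                      group_b: list[SlideSummary],
                      population: int,
                      paired: bool = False,
                      method: str = "wilcoxon") -> ComparisonResult:
    """Compare one population's fraction between two groups of slides.

    Unpaired: Wilcoxon rank-sum (exact for small groups). Paired: Wilcoxon
    signed-rank by default; ``method="t"`` selects the paired t-test.
    Paired groups must be equal-length and matched by ``slide_id`` prefix
    order (identical ordering is the caller's contract; mismatched ids are
    rejected).
    """
    if not (0 <= population < 4):
        raise ValueError("population index must be 0..3")
    a = np.array([s.fractions[population] for s in group_a])
    b = np.array([s.fractions[population] for s in group_b])
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length groups")
        if method == "t":
            return paired_t_test(a, b)
        return signed_rank_test(a, b)
    if method == "t":
        raise ValueError("unpaired t not offered here; use wilcoxon")
    return rank_sum_test(a, b)


def compare_shannon(group_a: list[SlideSummary], group_b: list[SlideSummary],
                    paired: bool = False,
                    method: str = "wilcoxon") -> ComparisonResult:
    """Same machinery as :func:`compare_fractions`, on the Shannon index."""
    a = np.array([s.shannon for s in group_a])
    b = np.array([s.shannon for s in group_b])
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length groups")
        return paired_t_test(a, b) if method == "t" else signed_rank_test(a, b)
    return rank_sum_test(a, b)


def compare_pooled_counts(counts_a, counts_b) -> ComparisonResult:
    """Chi-square homogeneity test on pooled 4-population counts (df <= 3).

    Populations empty in both groups are collapsed out with a warning
    (they contribute no information and would break the expected counts).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != (4,) or b.shape != (4,):
        raise ValueError("expected 4-vectors of counts")
    if (a < 0).any() or (b < 0).any() or a.sum() == 0 or b.sum() == 0:
        raise ValueError("counts must be nonnegative with positive totals")
    keep = (a + b) > 0
    if keep.sum() < 4:
        warnings.warn("collapsing zero-margin populations", stacklevel=2)
    if keep.sum() < 2:
        return ComparisonResult(statistic=0.0, p_value=1.0,
                                test_name="chi_square",
                                n=int(a.sum() + b.sum()),
                                extra={"df": 0})
    table = np.vstack([a[keep], b[keep]])
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return ComparisonResult(statistic=float(stat), p_value=float(p),
                            test_name="chi_square",
                            n=int(a.sum() + b.sum()), extra={"df": int(dof)})


@dataclass(frozen=True)
class RegressionFit:
    slope: float | None
    intercept: float | None
    r: float | None
    p_value: float | None
    n: int
    band: pd.DataFrame | None   # x, fit, ci_low, ci_high

    @property
    def defined(self) -> bool:
        return self.slope is not None


def diversity_cd8_regression(summaries: list[SlideSummary],
                             stratum: str = "all",
                             alpha: float = 0.05) -> RegressionFit:
    """OLS of CD8 count per montage on Shannon diversity, with CI band.

    ``stratum`` filters on the summaries' timepoint ("all" keeps
    everything). Constant diversity makes the slope undefined.
    """
    if stratum == "all":
        sel = list(summaries)
    else:
        sel = [s for s in summaries if s.timepoint == stratum]
    if len(sel) < 3:
        raise ValueError("need at least 3 slides in the stratum")
    x = np.array([s.shannon for s in sel])
    y = np.array([s.cd8_per_montage for s in sel])
    if np.ptp(x) == 0:
        return RegressionFit(slope=None, intercept=None, r=None,
                             p_value=None, n=len(sel), band=None)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=alpha)
    band = pd.DataFrame({"x": grid, "fit": pred["mean"].to_numpy(),
                         "ci_low": pred["mean_ci_lower"].to_numpy(),
                         "ci_high": pred["mean_ci_upper"].to_numpy()})
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionFit(slope=float(fit.params[1]),
                         intercept=float(fit.params[0]), r=r,
                         p_value=float(fit.pvalues[1]), n=len(sel),
                         band=band)


EMPTY_BIN = -1


@dataclass(frozen=True)
class TopologyMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray      # (ny, nx, 4)
    dominant: np.ndarray    # (ny, nx) population index, EMPTY_BIN if empty

    def points_by_population(self, cells: pd.DataFrame
                             ) -> dict[str, np.ndarray]:
        """Plot-ready layered point sets keyed by population label."""
        return {p: cells.loc[cells["population"] == p, ["x", "y"]]
                .to_numpy(dtype=float) for p in POPULATIONS}


def topology_map(cells: pd.DataFrame, bin_size: float = 64.0,
                 width: float | None = None,
                 height: float | None = None) -> TopologyMap:
    """Grid cells into square bins; per-bin counts and dominant population.

    Ties for dominance go to the lower population index (deterministic).
    Bins with no cells carry the explicit EMPTY_BIN marker.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)
    w = width if width is not None else (float(x.max()) + 1 if x.size else bin_size)
    h = height if height is not None else (float(y.max()) + 1 if y.size else bin_size)
    x_edges = np.arange(0, w + bin_size, bin_size)
    y_edges = np.arange(0, h + bin_size, bin_size)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    counts = np.zeros((ny, nx, 4), dtype=int)
    pop_idx = np.array([POPULATIONS.index(p) for p in cells["population"]])
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, nx - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, ny - 1)
    np.add.at(counts, (iy, ix, pop_idx), 1)
    total = counts.sum(axis=2)
    dominant = np.where(total > 0, counts.argmax(axis=2), EMPTY_BIN)
    return TopologyMap(x_edges=x_edges, y_edges=y_edges, counts=counts,
                       dominant=dominant)


def plot_topology(cells: pd.DataFrame, tmap: TopologyMap, path=None):
    """Layered point-pattern figure of the four populations (optional PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    colors = ("#888888", "#d62728", "#1f77b4", "#9467bd")
    for (pop, pts), color in zip(
            tmap.points_by_population(cells).items(), colors):
        if pts.size:
            ax.scatter(pts[:, 0], pts[:, 1], s=8, c=color, label=pop)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.legend(fontsize=7, loc="upper right")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
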