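"""Group statistics and figures.

Fold changes of the four composition metrics relative to week 0 per
(bone, region), two-tailed t-tests with configurable significance-star
thresholds, radial visualization of the metric quadruple, and mean +/- SD
spectrum overlays per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SpectrumSet, ValidationError

__all__ = [
    "METRICS",
    "STARS_COARSE",
    "STARS_FINE",
    "fold_changes",
    "compare_groups",
    "GroupComparison",
    "radial_coordinates",
    "RADIAL_ANCHORS",
    "summarize_spectra",
    "plot_mean_spectra",
    "plot_fold_changes",
    "plot_radial",
]

METRICS = ("mineral_to_matrix", "phos_to_carb", "carb_to_matrix", "crystallinity")

#: Two published star conventions; coarse: * p<0.05, ** p<0.005;
#: fine: * p<0.05, ** p<0.01, *** p<0.001.
STARS_COARSE = ((0.005, "**"), (0.05, "*"))
STARS_FINE = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------


def fold_changes(
    metrics: pd.DataFrame,
    baseline_week: int = 0,
    sd_method: str = "delta",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (bone, region, week, metric): mean ratio to the baseline-week mean.

    The ratio SD is propagated by the delta method from the two independent
    group means (``sd_method="bootstrap"`` resamples both groups instead);
    the baseline week's fold change is exactly 1.
    """
    if sd_method not in ("delta", "bootstrap"):
        raise ValidationError("sd_method must be 'delta' or 'bootstrap'")
    rng = np.random.default_rng(seed)
    ok = metrics[metrics[list(METRICS)].notna().all(axis=1)]
    rows = []
    for (bone, region), sub in ok.groupby(["bone", "region"], sort=True):
        base = sub[sub["week"] == baseline_week]
        if base.empty:
            raise ValidationError(f"no baseline week {baseline_week} for ({bone}, {region})")
        for week, grp in sub.groupby("week", sort=True):
            for metric in METRICS:
                b = base[metric].to_numpy(float)
                g = grp[metric].to_numpy(float)
                mb, mg = b.mean(), g.mean()
                fc = 1.0 if week == baseline_week else mg / mb
                if week == baseline_week:
                    sd = 0.0
                elif sd_method == "delta":
                    se_b = b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else 0.0
                    se_g = g.std(ddof=1) / np.sqrt(g.size) if g.size > 1 else 0.0
                    sd = abs(fc) * np.sqrt((se_g / mg) ** 2 + (se_b / mb) ** 2)
                else:
                    bi = rng.integers(0, b.size, (n_boot, b.size))
                    gi = rng.integers(0, g.size, (n_boot, g.size))
                    sd = float(np.std(g[gi].mean(axis=1) / b[bi].mean(axis=1), ddof=1))
                rows.append(
                    dict(bone=bone, region=region, week=week, metric=metric,
                         fold_change=fc, sd=sd, n=g.size)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    t: float
    p: float
    stars: str
    n_a: int
    n_b: int


def star_label(p: float, thresholds=STARS_FINE) -> str:
    for cut, label in sorted(thresholds):
        if p < cut:
            return label
    return "n.s."


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    metric: str = "",
    names: tuple[str, str] = ("A", "B"),
    thresholds=STARS_FINE,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample two-sided t-test (Student by default, Welch optional).

    Two groups with zero variance and equal means give t = 0, p = 1 by
    convention rather than a division error.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        metric=metric, group_a=names[0], group_b=names[1],
        t=float(t), p=float(p), stars=star_label(float(p), thresholds),
        n_a=a.size, n_b=b.size,
    )


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values for a family of comparisons."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    n = p.size
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (n - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def compare_weeks_table(
    metrics: pd.DataFrame,
    baseline_week: int = 0,
    thresholds=STARS_FINE,
    equal_var: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """Every (bone, region, week vs baseline, metric) comparison as a table.

    Raw per-comparison p-values by default; ``holm`` additionally applies the
    Holm step-down correction across the whole table and labels stars from
    the adjusted values.
    """
    ok = metrics[metrics[list(METRICS)].notna().all(axis=1)]
    rows = []
    for (bone, region), sub in ok.groupby(["bone", "region"], sort=True):
        base = sub[sub["week"] == baseline_week]
        for week, grp in sub.groupby("week", sort=True):
            if week == baseline_week:
                continue
            for metric in METRICS:
                c = compare_groups(
                    grp[metric].to_numpy(), base[metric].to_numpy(),
                    metric=metric, names=(f"week{week}", f"week{baseline_week}"),
                    thresholds=thresholds, equal_var=equal_var,
                )
                rows.append(
                    dict(bone=bone, region=region, week=week, metric=metric,
                         t=c.t, p=c.p, stars=c.stars, n=c.n_a, n_baseline=c.n_b)
                )
    table = pd.DataFrame(rows)
    if holm and len(table):
        table["p_holm"] = holm_adjust(table["p"].to_numpy())
        table["stars_holm"] = [star_label(p, thresholds) for p in table["p_holm"]]
    return table


# ---------------------------------------------------------------------------
# Radial visualization
# ---------------------------------------------------------------------------

#: Anchor angles (degrees) for the four metrics, in METRICS order.
RADIAL_ANCHORS = (90.0, 0.0, 270.0, 180.0)


def radial_coordinates(
    metrics: pd.DataFrame, anchor_order: tuple[str, ...] = METRICS
) -> pd.DataFrame:
    """Project each sample's metric quadruple into the unit disk.

    Each metric is min-max normalized to [0, 1] over the whole table
    (a constant metric maps to 0.5 by convention); the sample's point is the
    normalized-weight average of the four unit-circle anchor positions, so
    all points lie inside the anchors' convex hull.  A sample whose four
    normalized values are all zero maps to the origin.
    """
    vals = metrics[list(anchor_order)].to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValidationError("radial visualization needs finite metrics")
    lo, hi = vals.min(axis=0), vals.max(axis=0)
    span = hi - lo
    norm = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1.0), 0.5)
    ang = np.deg2rad(RADIAL_ANCHORS[: len(anchor_order)])
    anchors = np.column_stack([np.cos(ang), np.sin(ang)])
    weight = norm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        pts = (norm @ anchors) / weight
    pts[weight[:, 0] == 0] = 0.0
    out = metrics[[c for c in ("spectrum_id", "subject_id", "week", "bone", "region")
                   if c in metrics.columns]].copy()
    out["x"] = pts[:, 0]
    out["y"] = pts[:, 1]
    return out


# ---------------------------------------------------------------------------
# Spectrum summaries
# ---------------------------------------------------------------------------


def summarize_spectra(sset: SpectrumSet, by: list[str] | str = "week") -> pd.DataFrame:
    """Channelwise mean and SD spectrum per metadata group.

    Returns a long table with columns ``group, wavenumber_cm1, mean, sd``.
    """
    if isinstance(by, str):
        by = [by]
    rows = []
    for key, sub in sset.meta.groupby(by, sort=True):
        label = key if isinstance(key, str) else "/".join(str(k) for k in np.atleast_1d(key))
        block = sset.intensities[sub.index.to_numpy()]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0) if block.shape[0] > 1 else np.zeros(block.shape[1])
        rows.append(
            pd.DataFrame(
                {"group": label, "wavenumber_cm1": sset.axis, "mean": mean, "sd": sd}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def _agg():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_mean_spectra(summary: pd.DataFrame, path, offset: float = 0.5) -> None:
    """Vertically offset mean +/- SD overlays, one trace per group."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(7, 5))
    for i, (label, sub) in enumerate(summary.groupby("group", sort=True)):
        y = sub["mean"].to_numpy() + i * offset
        ax.plot(sub["wavenumber_cm1"], y, label=str(label), lw=1)
        ax.fill_between(
            sub["wavenumber_cm1"], y - sub["sd"], y + sub["sd"], alpha=0.3, lw=0
        )
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("normalized intensity (offset)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_fold_changes(fc: pd.DataFrame, path) -> None:
    """Grouped bars of fold change per metric and week, one panel per region."""
    plt = _agg()
    regions = list(dict.fromkeys(zip(fc["bone"], fc["region"])))
    fig, axes = plt.subplots(1, len(regions), figsize=(3.2 * len(regions), 3.4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (bone, region) in zip(axes, regions):
        sub = fc[(fc["bone"] == bone) & (fc["region"] == region)]
        weeks = sorted(sub["week"].unique())
        width = 0.8 / len(weeks)
        for k, week in enumerate(weeks):
            row = sub[sub["week"] == week].set_index("metric").reindex(list(METRICS))
            x = np.arange(len(METRICS)) + k * width
            ax.bar(x, row["fold_change"], width, yerr=row["sd"], label=f"wk {week}", capsize=2)
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_xticks(np.arange(len(METRICS)) + 0.4)
        ax.set_xticklabels(METRICS, rotation=45, ha="right", fontsize=7)
        ax.set_title(f"{bone} {region}", fontsize=9)
    axes[0].set_ylabel("fold change vs week 0")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_radial(points: pd.DataFrame, path, color_by: str = "week") -> None:
    """Samples in the unit disk with the four metric anchors marked."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="gray", lw=0.8)
    ang = np.deg2rad(RADIAL_ANCHORS)
    for name, a in zip(METRICS, ang):
        ax.annotate(name, (1.06 * np.cos(a), 1.06 * np.sin(a)), ha="center", fontsize=8)
    for val, sub in points.groupby(color_by, sort=True):
        ax.scatter(sub["x"], sub["y"], s=18, label=f"{color_by} {val}", alpha=0.8)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(fontsize=8, loc="lower left")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
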