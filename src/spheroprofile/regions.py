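"""Microregion partitioning and cohort statistics.

As a spheroid grows it develops concentric microregions: a necrotic core,
a quiescent middle zone, and a proliferative edge. On the normalised
radial axis these occupy fixed fractions of the M profile points that
depend on the spheroid's size class:

    small (0-200 um):   core 25%, quiescent 50%, edge 25%
    large (201-400 um): core 60%, quiescent 30%, edge 10%

Regional marker values are read either at the midpoint sample of each
block (default) or as the block mean. Cohorts are compared with an
ordinary two-way ANOVA (region x size class) followed by Tukey's HSD, and
marker-vs-diameter relationships with simple linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RegionPartition",
    "RegionSummary",
    "PARTITION_FRACTIONS",
    "SIZE_BOUNDS_UM",
    "classify_size",
    "build_partition",
    "extract_regions",
    "compare_regions",
    "diameter_correlation",
]

REGIONS = ("core", "quiescent", "edge")

#: Fraction of radial profile points per microregion, by size class.
PARTITION_FRACTIONS = {
    "small": (0.25, 0.50, 0.25),
    "large": (0.60, 0.30, 0.10),
}

#: Upper diameter bound (um, inclusive) of each size class.
SIZE_BOUNDS_UM = {"small": 200.0, "large": 400.0}


@dataclass
class RegionPartition:
    """Assignment of M radial profile points to the three microregions.

    Blocks are contiguous and ordered centroid -> boundary (core,
    quiescent, edge). Rounding remainders go to the middle (quiescent)
    block so the printed core/edge fractions are preserved exactly when
    they divide M.
    """

    size_class: str
    fractions: tuple[float, float, float]
    labels: np.ndarray  # (M,) of region names
    block_sizes: tuple[int, int, int]
    representative_points: tuple[int, int, int]  # midpoint index of each block

    @property
    def M(self) -> int:
        return len(self.labels)


@dataclass
class RegionSummary:
    """Per-region values extracted from one normalised profile."""

    spheroid_id: str
    marker: str
    core: float
    quiescent: float
    edge: float
    mode: str
    excluded: bool = False


def classify_size(diameter_um: float, bounds: dict | None = None) -> str:
    """Assign a spheroid to a diameter class.

    <= 200 um -> ``small``; (200, 400] -> ``large``; beyond 400 um ->
    ``out_of_range`` with a warning (such spheroids are excluded from the
    regional statistics, which are defined for the two printed classes).
    """
    if not (diameter_um > 0):
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    if bounds is None:
        bounds = SIZE_BOUNDS_UM
    if diameter_um <= bounds["small"]:
        return "small"
    if diameter_um <= bounds["large"]:
        return "large"
    warnings.warn(
        f"diameter {diameter_um:.1f} um exceeds the large-class bound "
        f"({bounds['large']} um); classified out_of_range and excluded "
        "from regional statistics",
        stacklevel=2,
    )
    return "out_of_range"


def build_partition(size_class: str, M: int) -> RegionPartition:
    """Partition M profile points into core / quiescent / edge blocks.

    Core and edge sizes are ``round(fraction * M)``; the quiescent block
    absorbs the remainder. The representative point of a block of size n
    starting at s is ``s + (n - 1) // 2``.
    """
    if M < 4:
        raise ValueError("M must be >= 4")
    if size_class not in PARTITION_FRACTIONS:
        raise ValueError(
            f"unknown size class {size_class!r}; expected one of "
            f"{sorted(PARTITION_FRACTIONS)}"
        )
    f_core, f_quiescent, f_edge = PARTITION_FRACTIONS[size_class]
    n_core = int(round(f_core * M))
    n_edge = int(round(f_edge * M))
    n_quiescent = M - n_core - n_edge
    if min(n_core, n_quiescent, n_edge) < 1:
        raise ValueError(f"M={M} too small for a {size_class} partition")
    labels = np.array(
        ["core"] * n_core + ["quiescent"] * n_quiescent + ["edge"] * n_edge
    )
    starts = (0, n_core, n_core + n_quiescent)
    sizes = (n_core, n_quiescent, n_edge)
    reps = tuple(s + (n - 1) // 2 for s, n in zip(starts, sizes))
    return RegionPartition(
        size_class=size_class,
        fractions=PARTITION_FRACTIONS[size_class],
        labels=labels,
        block_sizes=sizes,
        representative_points=reps,  # type: ignore[arg-type]
    )


def extract_regions(profile: np.ndarray, partition: RegionPartition,
                    mode: str = "midpoint", spheroid_id: str = "",
                    marker: str = "", degenerate: bool = False) -> RegionSummary:
    """Extract one value per microregion from a normalised profile.

    ``midpoint`` (default) reads the sample at each block's representative
    midpoint; ``block_mean`` averages over the block. Degenerate
    (constant, un-normalisable) profiles yield an excluded summary.
    """
    profile = np.asarray(profile, float)
    if profile.shape != (partition.M,):
        raise ValueError(
            f"profile length {profile.size} != partition M {partition.M}"
        )
    if mode not in ("midpoint", "block_mean"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    if mode == "midpoint":
        values = [float(profile[i]) for i in partition.representative_points]
    else:
        values = [
            float(profile[partition.labels == region].mean()) for region in REGIONS
        ]
    return RegionSummary(
        spheroid_id=spheroid_id,
        marker=marker,
        core=values[0],
        quiescent=values[1],
        edge=values[2],
        mode=mode,
        excluded=degenerate,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Long-format table (one row per spheroid x region) for statistics."""
    rows = []
    for s in summaries:
        if s.excluded:
            continue
        for region in REGIONS:
            rows.append({
                "spheroid_id": s.spheroid_id,
                "marker": s.marker,
                "region": region,
                "value": getattr(s, region),
            })
    return pd.DataFrame(rows)


def compare_regions(table: pd.DataFrame, alpha: float = 0.05,
                    posthoc: bool = True) -> dict:
    """Two-way fixed-effects ANOVA (region x size class) with Tukey HSD.

    ``table`` needs columns ``value``, ``region``, ``size_class``, with at
    least two observations in each of the 2 x 3 cells. Tukey comparisons
    are run pairwise between regions within each size class and between
    size classes within each region; pass ``posthoc=False`` to skip them
    (e.g. in large simulation studies of the main effects). Zero-variance
    (degenerate) tables are reported as such rather than raising.
    """
    required = {"value", "region", "size_class"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    cells = table.groupby(["size_class", "region"], observed=True).size()
    expected = [(sc, r) for sc in sorted(table["size_class"].unique())
                for r in REGIONS]
    missing = [cell for cell in expected if cell not in cells.index]
    if missing:
        raise ValueError(f"empty design cells: {missing}")
    if (cells < 2).any():
        small = list(cells[cells < 2].index)
        raise ValueError(f"need >= 2 observations per cell; short cells: {small}")

    if np.ptp(table["value"].to_numpy()) == 0:
        return {
            "degenerate": True,
            "anova": None,
            "tukey": pd.DataFrame(),
            "alpha": alpha,
            "note": "zero variance in all cells; F statistics undefined",
        }

    model = smf.ols("value ~ C(region) * C(size_class)", data=table).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = sm.stats.anova_lm(model, typ=2)

    def _effect(name):
        row = anova.loc[name]
        return {"F": float(row["F"]), "p": float(row["PR(>F)"]),
                "df": float(row["df"])}

    anova_report = {
        "region": _effect("C(region)"),
        "size_class": _effect("C(size_class)"),
        "interaction": _effect("C(region):C(size_class)"),
        "residual_df": float(anova.loc["Residual", "df"]),
    }

    if not posthoc:
        return {"degenerate": False, "anova": anova_report,
                "tukey": pd.DataFrame(), "alpha": alpha}

    tukey_rows = []
    for sc, sub in table.groupby("size_class", observed=True):
        res = pairwise_tukeyhsd(sub["value"], sub["region"], alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        frame.insert(0, "scope", f"size_class={sc}")
        tukey_rows.append(frame)
    for region, sub in table.groupby("region", observed=True):
        if sub["size_class"].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(sub["value"], sub["size_class"], alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        frame.insert(0, "scope", f"region={region}")
        tukey_rows.append(frame)
    tukey = pd.concat(tukey_rows, ignore_index=True)

    return {"degenerate": False, "anova": anova_report, "tukey": tukey,
            "alpha": alpha}


def diameter_correlation(diameters, values) -> dict:
    """Simple linear regression of a metric on spheroid diameter.

    Returns slope, two-sided slope p-value, R^2, intercept and n.
    """
    x = np.asarray(diameters, float)
    y = np.asarray(values, float)
    if x.size != y.size:
        raise ValueError("diameters and values must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in diameter")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": int(x.size),
    }
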