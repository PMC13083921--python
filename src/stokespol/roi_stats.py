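"""ROI-based quantitative comparison of scalar maps.

The protocol: square regions of interest of fixed physical side (48.6 um,
~900 px at the 4x sampling density of 0.617 px/um) are placed on a
retardation or depolarisation map; per-ROI means feed a two-group
comparison that is normality-gated — a two-tailed unpaired t-test (Welch)
when both groups pass Shapiro-Wilk at alpha = 0.05, a two-sided
Mann-Whitney U otherwise.  Significance is declared at p <= 0.05.

Welch's variant is the default because equal variances are not guaranteed
between, say, lesion and substrate ROIs; a pooled option is provided.  No
multiple-testing correction is applied by default (raw p-values are
reported); :func:`holm_correction` is available when several comparisons
are made jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.ma as ma
import pandas as pd
from scipy import stats

__all__ = [
    "RoiSpec",
    "RoiValues",
    "Summary",
    "GroupComparison",
    "roi_side_pixels",
    "extract_rois",
    "summarise",
    "test_normality",
    "compare_groups",
    "holm_correction",
    "read_roi_csv",
    "boxplot_groups",
]

NORMALITY_ALPHA = 0.05
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class RoiSpec:
    """A square ROI: centre in pixel coordinates, side in um or pixels."""

    label: str
    cx: float
    cy: float
    side_um: float | None = None
    side_px: int | None = None

    def __post_init__(self) -> None:
        if (self.side_um is None) == (self.side_px is None):
            raise ValueError("specify exactly one of side_um or side_px")
        side = self.side_um if self.side_um is not None else self.side_px
        if side <= 0:
            raise ValueError("ROI side must be positive")


@dataclass
class RoiValues:
    """Unmasked pixel values extracted from one ROI."""

    spec: RoiSpec
    values: np.ndarray
    n_masked: int

    @property
    def n(self) -> int:
        return self.values.size


def roi_side_pixels(side_um: float, pixel_size_um: float) -> int:
    """Physical side length converted to pixels, rounded to nearest.

    48.6 um at 1.621 um/px (0.617 px/um) -> 30 px, i.e. a 900-pixel ROI.
    """
    if side_um <= 0 or pixel_size_um <= 0:
        raise ValueError("side and pixel size must be positive")
    return int(round(side_um / pixel_size_um))


def extract_rois(map_2d, specs: list, pixel_size_um: float | None = None) -> list:
    """Extract per-ROI value vectors; masked pixels are excluded and counted.

    Raises ``ValueError`` for ROIs falling outside the image or fully
    masked.  ``pixel_size_um`` is required when any spec gives its side in
    micrometres.
    """
    data = ma.asarray(map_2d, dtype=float)
    h, w = data.shape
    out = []
    for spec in specs:
        if spec.side_px is not None:
            side = spec.side_px
        else:
            if pixel_size_um is None:
                raise ValueError(f"ROI {spec.label!r} has side_um; pixel_size_um required")
            side = roi_side_pixels(spec.side_um, pixel_size_um)
        r0 = int(round(spec.cy - side / 2))
        c0 = int(round(spec.cx - side / 2))
        if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
            raise ValueError(f"ROI {spec.label!r} ({side}x{side} px at "
                             f"({spec.cx}, {spec.cy})) falls outside the {h}x{w} image")
        sub = data[r0:r0 + side, c0:c0 + side]
        values = sub.compressed() if isinstance(sub, ma.MaskedArray) else np.ravel(sub)
        n_masked = side * side - values.size
        if values.size == 0:
            raise ValueError(f"ROI {spec.label!r} is fully masked")
        out.append(RoiValues(spec=spec, values=np.asarray(values, dtype=float),
                             n_masked=int(n_masked)))
    return out


@dataclass
class Summary:
    mean: float
    sd: float
    n: int


def summarise(values: np.ndarray) -> Summary:
    """Mean and sample standard deviation (n-1 denominator).

    ``sd`` is NaN for a single value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("cannot summarise an empty vector")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return Summary(mean=float(values.mean()), sd=sd, n=int(values.size))


def test_normality(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value; requires 3 <= n <= 5000 and non-constant data."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={values.size}")
    if np.ptp(values) == 0:
        raise ValueError("normality test undefined for constant data")
    return float(stats.shapiro(values).pvalue)


@dataclass
class GroupComparison:
    """Outcome of the normality-gated two-group comparison."""

    label_a: str
    label_b: str
    summary_a: Summary
    summary_b: Summary
    shapiro_p_a: float
    shapiro_p_b: float
    test_name: str
    statistic: float
    p_value: float
    significant: bool

    def summary(self) -> str:
        return (f"{self.label_a} (n={self.summary_a.n}, mean={self.summary_a.mean:.4g}, "
                f"SD={self.summary_a.sd:.4g}) vs {self.label_b} (n={self.summary_b.n}, "
                f"mean={self.summary_b.mean:.4g}, SD={self.summary_b.sd:.4g}): "
                f"{self.test_name}, statistic={self.statistic:.4g}, p={self.p_value:.4g}"
                f"{' *' if self.significant else ''}")


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # exact null distribution on small tie-free samples, normal approximation
    # with tie correction otherwise
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(a: np.ndarray, b: np.ndarray,
                   labels: tuple = ("a", "b"),
                   normality_alpha: float = NORMALITY_ALPHA,
                   alpha: float = SIGNIFICANCE_ALPHA,
                   equal_var: bool = False) -> GroupComparison:
    """Normality-gated unpaired two-group comparison.

    Both groups passing Shapiro-Wilk at ``normality_alpha`` selects the
    two-tailed unpaired t-test (Welch by default; ``equal_var=True`` pools);
    otherwise the two-sided Mann-Whitney U.  Degenerate zero-variance groups
    bypass the gate: identical constants give p = 1, differing constants
    p = 0 (documented special case; no distributional test applies).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    sa, sb = summarise(a), summarise(b)

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
        return GroupComparison(labels[0], labels[1], sa, sb, float("nan"), float("nan"),
                               "degenerate", float("nan"), p, p <= alpha)

    try:
        pa = test_normality(a)
    except ValueError:
        pa = 0.0  # constant group: certainly non-normal for gating purposes
    try:
        pb = test_normality(b)
    except ValueError:
        pb = 0.0

    if pa > normality_alpha and pb > normality_alpha:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "t-test"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        statistic, p = _mwu(a, b)
        name = "Mann-Whitney U"
    return GroupComparison(labels[0], labels[1], sa, sb, pa, pb, name,
                           statistic, p, p <= alpha)


def holm_correction(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def read_roi_csv(path) -> list:
    """ROI specs from CSV with columns label, cx, cy and side_um (or side_px).

    Raises ``ValueError`` with the offending line number on malformed rows.
    """
    df = pd.read_csv(path)
    required = {"label", "cx", "cy"}
    if not required <= set(df.columns):
        raise ValueError(f"ROI CSV must have columns {sorted(required)} plus side_um/side_px")
    if "side_um" not in df.columns and "side_px" not in df.columns:
        raise ValueError("ROI CSV needs a side_um or side_px column")
    specs = []
    for i, row in df.iterrows():
        try:
            kwargs = {"label": str(row["label"]), "cx": float(row["cx"]),
                      "cy": float(row["cy"])}
            if "side_um" in df.columns and not pd.isna(row["side_um"]):
                kwargs["side_um"] = float(row["side_um"])
            elif "side_px" in df.columns and not pd.isna(row["side_px"]):
                kwargs["side_px"] = int(row["side_px"])
            specs.append(RoiSpec(**kwargs))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"ROI CSV line {i + 2}: {exc}") from exc
    return specs


def boxplot_groups(groups: dict, path=None, ylabel: str = ""):
    """Tukey box plots (1.5 x IQR whiskers) of per-group value vectors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(1.2 * max(2, len(groups)), 3.2), dpi=150)
    ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()), whis=1.5)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig, ax
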