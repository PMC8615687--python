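"""Fold-change/t-test analytics, SEM-threshold volcano classification,
class summaries, Fisher direction test and the 2^-ddCq qPCR utility.

The central construction is *percent of reference*: for each species,
every sample's normalized ratio is divided by the reference-group mean
and multiplied by 100, so 100% means unchanged.  The treated group's
mean of these relative values is the reported effect, with its SEM as
the uncertainty.  A species counts as increased/decreased "beyond SEM"
when its percent of reference falls outside 100 plus/minus the class
average SEM — the vertical lines of the volcano plots — which retains
consistently shifted species that miss per-species significance at
small n.

Per-species significance is the classical two-tailed pooled-variance
Student's t-test on the raw group values.  The class-level p-value is a
one-sample t-test of the member species' percents against 100.  The
cross-experiment comparison counts increased vs decreased species per
experiment and applies Fisher's exact test to the resulting 2x2 table.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateStatisticsError, MissingDataError
from .quantify import NormalizedProfile

__all__ = [
    "AnalysisConfig",
    "TTestResult",
    "QpcrSample",
    "students_ttest",
    "species_fold_change",
    "classify_direction",
    "differential_table",
    "class_summary",
    "class_summaries",
    "ratio_group_change",
    "direction_fisher",
    "build_direction_table",
    "ddcq_fold_change",
    "volcano_table",
    "format_p",
]

logger = logging.getLogger(__name__)

DIFFERENTIAL_COLUMNS = [
    "species", "lipid_class", "percent_of_reference", "sem_percent",
    "t", "df", "p", "p_adj", "direction", "stars",
]

UP = "UP_BEYOND_SEM"
DOWN = "DOWN_BEYOND_SEM"
WITHIN = "WITHIN_SEM"


@dataclass(frozen=True)
class AnalysisConfig:
    """Differential-analysis settings.

    ``alpha_levels`` are the star thresholds (one, two, three stars),
    strictly decreasing; ``welch`` switches the per-species test from
    pooled-variance Student to Welch; ``direction_filter`` controls
    which species enter the Fisher direction counts (``"all"`` = sign
    of percent-100 for every species, ``"sem"`` = beyond-SEM only).
    """

    reference_group: str
    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001)
    p_report_decimals: int = 3
    welch: bool = False
    direction_filter: str = "all"

    def __post_init__(self) -> None:
        levels = self.alpha_levels
        if not levels or any(not (0.0 < a < 1.0) for a in levels):
            raise ValueError("alpha levels must lie in (0, 1)")
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("alpha levels must be strictly decreasing")
        if self.direction_filter not in ("all", "sem"):
            raise ValueError("direction_filter must be 'all' or 'sem'")

    def stars(self, p: float) -> str:
        count = sum(p <= a for a in self.alpha_levels)
        return "*" * count if count else "n.s."


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def students_ttest(group_a, group_b, welch: bool = False) -> TTestResult:
    """Two-tailed two-sample t-test (pooled variance unless ``welch``).

    Degenerate zero-variance inputs are resolved explicitly: equal means
    give t = 0, p = 1; unequal means give p = 0 flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateStatisticsError("each group needs >= 2 values")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    df = float(a.size + b.size - 2)
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        logger.warning("zero pooled variance with unequal means; p floored at 0")
        sign = math.copysign(1.0, a.mean() - b.mean())
        return TTestResult(sign * math.inf, df, 0.0, degenerate=True)
    with warnings.catch_warnings():
        # Near-identical groups (differences at the last ulp) trigger a
        # scipy precision warning; the resulting p ~ O(1) is still valid.
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def species_fold_change(profile: NormalizedProfile,
                        config: AnalysisConfig) -> pd.DataFrame:
    """Percent of reference and its SEM for every species.

    Returns a frame indexed by species with columns
    ``percent_of_reference`` and ``sem_percent``.  A zero reference mean
    yields NaN for that species (logged as undefined).
    """
    ref, other = _split_groups(profile, config)
    ref_mean = profile.values[ref].mean(axis=1)
    zero = ref_mean == 0.0
    if zero.any():
        logger.warning("%d species have zero reference mean; fold change "
                       "undefined", int(zero.sum()))
    rel = 100.0 * profile.values[other].div(ref_mean.replace(0.0, np.nan),
                                            axis=0)
    out = pd.DataFrame({
        "percent_of_reference": rel.mean(axis=1),
        "sem_percent": rel.std(axis=1, ddof=1) / math.sqrt(len(other)),
    })
    return out


def _split_groups(profile: NormalizedProfile,
                  config: AnalysisConfig) -> tuple[list[str], list[str]]:
    ref = profile.samples_in_group(config.reference_group)
    other = [s for s in profile.values.columns if s not in ref]
    if len(ref) < 2 or len(other) < 2:
        raise DegenerateStatisticsError(
            "both groups need >= 2 biological samples "
            f"(reference {len(ref)}, other {len(other)})"
        )
    groups = {profile.sample_groups[s] for s in other}
    if len(groups) > 1:
        raise DegenerateStatisticsError(
            f"expected exactly two groups, found extra groups {sorted(groups)}"
        )
    return ref, other


def classify_direction(percent_of_reference: float, p: float,
                       class_mean_sem: float,
                       config: AnalysisConfig) -> tuple[str, bool, str]:
    """Volcano direction call, significance flag and star string."""
    if class_mean_sem < 0:
        raise ValueError("class mean SEM must be >= 0")
    if np.isnan(percent_of_reference):
        direction = WITHIN
    elif percent_of_reference > 100.0 + class_mean_sem:
        direction = UP
    elif percent_of_reference < 100.0 - class_mean_sem:
        direction = DOWN
    else:
        direction = WITHIN
    significant = bool(p <= config.alpha_levels[0])
    return direction, significant, config.stars(p)


def differential_table(profile: NormalizedProfile,
                       config: AnalysisConfig) -> pd.DataFrame:
    """Full per-species differential frame (one row per species).

    Columns: species, lipid_class, percent_of_reference, sem_percent,
    t, df, p, p_adj (Benjamini–Hochberg, informational only),
    direction, stars.
    """
    ref, other = _split_groups(profile, config)
    fc = species_fold_change(profile, config)

    t_vals, df_vals, p_vals = [], [], []
    for name in profile.values.index:
        res = students_ttest(profile.values.loc[name, ref],
                             profile.values.loc[name, other],
                             welch=config.welch)
        t_vals.append(res.t)
        df_vals.append(res.df)
        p_vals.append(res.p)

    out = pd.DataFrame({
        "species": profile.values.index,
        "lipid_class": [profile.species_classes[n].value
                        for n in profile.values.index],
        "percent_of_reference": fc["percent_of_reference"].to_numpy(),
        "sem_percent": fc["sem_percent"].to_numpy(),
        "t": t_vals,
        "df": df_vals,
        "p": p_vals,
    })
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]

    class_mean_sem = out.groupby("lipid_class")["sem_percent"].transform("mean")
    directions, stars = [], []
    for pct, p, thr in zip(out["percent_of_reference"], out["p"],
                           class_mean_sem):
        d, _, s = classify_direction(pct, p, thr, config)
        directions.append(d)
        stars.append(s)
    out["direction"] = directions
    out["stars"] = stars
    return out[DIFFERENTIAL_COLUMNS]


def class_summary(records: pd.DataFrame) -> dict:
    """Bar-chart summary for one class from its differential rows.

    Mean and SEM over the member species' percents of reference, with a
    two-tailed one-sample t-test of those percents against 100.  The
    ``mean_sem_threshold`` is the class average of the per-species SEMs
    (the volcano vertical-line offset).
    """
    percents = records["percent_of_reference"].dropna().to_numpy(dtype=float)
    if percents.size < 2:
        raise DegenerateStatisticsError("class summary needs >= 2 species")
    mean = float(percents.mean())
    sem = float(percents.std(ddof=1) / math.sqrt(percents.size))
    if sem == 0.0:
        p = 1.0 if mean == 100.0 else 0.0
        if p == 0.0:
            logger.warning("degenerate class summary: identical percents != 100")
        t_stat = 0.0 if mean == 100.0 else math.copysign(math.inf, mean - 100.0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_1samp(percents, 100.0)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "lipid_class": str(records["lipid_class"].iloc[0]),
        "n_species": int(percents.size),
        "mean_percent": mean,
        "sem_percent": sem,
        "t": t_stat,
        "df": int(percents.size - 1),
        "p": p,
        "mean_sem_threshold": float(records["sem_percent"].mean()),
    }


def class_summaries(diff: pd.DataFrame) -> pd.DataFrame:
    """One :func:`class_summary` row per lipid class, panel order."""
    rows = [class_summary(sub) for _, sub in
            diff.groupby("lipid_class", sort=False)]
    return pd.DataFrame(rows)[
        ["lipid_class", "n_species", "mean_percent", "sem_percent",
         "p", "mean_sem_threshold"]
    ]


def ratio_group_change(values: pd.Series, sample_groups: dict[str, str],
                       config: AnalysisConfig) -> tuple[float, float, float]:
    """Percent-of-reference, SEM and p for one derived per-sample quantity.

    ``values`` is indexed by sample id (saturation ratio, category mol%
    or carnitine ratio).  NaN samples (undefined ratios) are dropped
    pairwise with a logged count.
    """
    values = values.astype(float)
    n_nan = int(values.isna().sum())
    if n_nan:
        logger.warning("dropping %d undefined sample values from group "
                       "comparison", n_nan)
        values = values.dropna()
    ref = values[[s for s in values.index
                  if sample_groups[s] == config.reference_group]]
    other = values[[s for s in values.index
                    if sample_groups[s] != config.reference_group]]
    if len(ref) < 2 or len(other) < 2:
        raise DegenerateStatisticsError(
            "both groups need >= 2 defined values for a ratio comparison")
    ref_mean = ref.mean()
    if ref_mean == 0.0:
        raise DegenerateStatisticsError("reference mean is zero")
    rel = 100.0 * other / ref_mean
    sem = float(rel.std(ddof=1) / math.sqrt(len(other)))
    p = students_ttest(ref.to_numpy(), other.to_numpy(), welch=config.welch).p
    return float(rel.mean()), sem, float(p)


def direction_fisher(table) -> float:
    """Two-sided Fisher exact p for a 2x2 increased/decreased table.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    Computed in exact integer arithmetic, so the comparison has no
    floating-point tolerance at all.  Degenerate margins give p = 1.
    """
    arr = np.asarray(table, dtype=object)
    if arr.shape != (2, 2):
        raise ValueError("direction table must be 2x2")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    if min(a, b, c, d) < 0:
        raise ValueError("direction table entries must be >= 0")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0:
        raise ValueError("direction table must have a positive margin")
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    observed = math.comb(r1, a) * math.comb(r2, c)
    total = math.comb(n, c1)
    tail = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        weight = math.comb(r1, x) * math.comb(r2, c1 - x)
        if weight <= observed:
            tail += weight
    return tail / total


def build_direction_table(diff_a: pd.DataFrame, diff_b: pd.DataFrame,
                          direction_filter: str = "all") -> np.ndarray:
    """Increased/decreased counts for two experiments on shared species.

    Rows = experiments, columns = (increased, decreased).  With
    ``direction_filter="all"`` the sign of percent-100 counts every
    species (exact 100 excluded); ``"sem"`` counts only beyond-SEM
    calls.
    """
    shared = sorted(set(diff_a["species"]) & set(diff_b["species"]))
    if len(shared) < 2:
        raise MissingDataError(
            f"experiments share only {len(shared)} species (need >= 2)")

    def _counts(diff: pd.DataFrame) -> tuple[int, int]:
        sub = diff.set_index("species").loc[shared]
        if direction_filter == "sem":
            return (int((sub["direction"] == UP).sum()),
                    int((sub["direction"] == DOWN).sum()))
        pct = sub["percent_of_reference"]
        return int((pct > 100.0).sum()), int((pct < 100.0).sum())

    return np.array([_counts(diff_a), _counts(diff_b)], dtype=int)


@dataclass(frozen=True)
class QpcrSample:
    """Quantification cycles for one qPCR sample (target + housekeeping)."""

    cq_target: float
    cq_reference: float

    def __post_init__(self) -> None:
        for v in (self.cq_target, self.cq_reference):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Cq values must be finite and > 0, got {v}")

    @property
    def delta_cq(self) -> float:
        return self.cq_target - self.cq_reference


def ddcq_fold_change(treated, control) -> float:
    """Relative expression by the 2^-ddCq method.

    dCq = Cq(target) - Cq(housekeeping) per sample; ddCq = mean dCq of
    the treated collection minus mean dCq of the control collection.
    """
    treated = [s if isinstance(s, QpcrSample) else QpcrSample(*s)
               for s in treated]
    control = [s if isinstance(s, QpcrSample) else QpcrSample(*s)
               for s in control]
    if not treated or not control:
        raise ValueError("each qPCR collection needs >= 1 sample")
    ddcq = (float(np.mean([s.delta_cq for s in treated]))
            - float(np.mean([s.delta_cq for s in control])))
    return float(2.0 ** (-ddcq))


def volcano_table(records: pd.DataFrame, summary: dict,
                  config: AnalysisConfig) -> pd.DataFrame:
    """Volcano-plot coordinates for one class.

    One row per species: fold change on the ratio scale (1.0 =
    unchanged), -log10 p, direction and stars, plus the class's
    vertical-line offsets (1 +/- mean SEM / 100) and the horizontal
    significance line (first alpha level) repeated on every row so the
    CSV is self-contained.
    """
    if records.empty:
        raise MissingDataError("volcano table needs >= 1 species")
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(records["p"].to_numpy(dtype=float))
    thr = summary["mean_sem_threshold"] / 100.0
    return pd.DataFrame({
        "species": records["species"].to_numpy(),
        "lipid_class": records["lipid_class"].to_numpy(),
        "fold_change": records["percent_of_reference"].to_numpy() / 100.0,
        "neg_log10_p": neg_log10_p,
        "direction": records["direction"].to_numpy(),
        "stars": records["stars"].to_numpy(),
        "vline_low": 1.0 - thr,
        "vline_high": 1.0 + thr,
        "p_threshold": config.alpha_levels[0],
    })


def format_p(p: float, decimals: int = 3) -> str:
    """Display rounding with a printed floor, e.g. p = 0.0004 -> "0.000"."""
    if np.isnan(p):
        return "NA"
    return f"{p:.{decimals}f}"


def plot_volcano(volcano: pd.DataFrame, path, title: str | None = None) -> None:
    """Optional basic volcano image (matplotlib, saved to ``path``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = volcano["direction"].map(
        {UP: "firebrick", DOWN: "steelblue", WITHIN: "0.6"})
    ax.scatter(volcano["fold_change"], volcano["neg_log10_p"],
               c=colors, s=18, edgecolors="none")
    ax.axvline(volcano["vline_low"].iloc[0], color="0.3", lw=0.8, ls="--")
    ax.axvline(volcano["vline_high"].iloc[0], color="0.3", lw=0.8, ls="--")
    ax.axhline(-math.log10(volcano["p_threshold"].iloc[0]),
               color="0.3", lw=0.8)
    ax.set_xlabel("fold change (1 = unchanged)")
    ax.set_ylabel("-log10 p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
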