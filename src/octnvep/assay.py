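"""From raw uptake replicates to %WT function, LOF calls and group summaries.

The central normalization expresses a variant's transport as a percentage of
wild type after subtracting empty-vector background::

    function_pct = 100 * (variant - EV) / (WT - EV)

Replicate structure follows the usual transport-assay design: technical wells
(same plate) are averaged within each biological replicate first, then the
mean and SEM are taken across biological replicates.  Loss of function (LOF)
is called when function falls strictly below a threshold, 20 %WT by default —
the level associated with susceptibility to carnitine transporter deficiency.
Values below 0 or above 100 %WT are retained as measured, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Default %WT threshold below which a variant is called loss-of-function.
LOF_THRESHOLD: float = 20.0

#: Reserved control labels in raw assay tables.
WT_LABEL, EV_LABEL = "WT", "EV"

LOCALIZATION_CLASSES = ("membrane", "mixed", "intracellular")


class DegenerateControlError(ValueError):
    """Wild-type signal does not exceed empty-vector background."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicates on one side of a comparison."""


@dataclass
class AssayRecord:
    """Raw uptake measurements for one construct in one batch.

    ``replicates`` maps biological-replicate id -> technical-well uptake
    values (counts per microgram protein).
    """

    variant: str
    batch: str
    replicates: dict[object, list[float]]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"{self.variant}: no biological replicates")
        for rep, wells in self.replicates.items():
            arr = np.asarray(wells, dtype=float)
            if arr.size == 0 or not np.isfinite(arr).all():
                raise ValueError(
                    f"{self.variant} replicate {rep}: empty or non-finite uptake values"
                )

    def bio_means(self) -> pd.Series:
        """Technical wells averaged within each biological replicate."""
        cached = getattr(self, "_bio_means", None)
        if cached is None:
            cached = pd.Series(
                {
                    rep: float(np.mean(wells))
                    for rep, wells in sorted(
                        self.replicates.items(), key=lambda kv: str(kv[0])
                    )
                }
            )
            object.__setattr__(self, "_bio_means", cached)
        return cached


def normalize_uptake(variant_mean: float, wt_mean: float, ev_mean: float) -> float:
    """Uptake as %WT after empty-vector background subtraction.

    May legitimately fall below 0 or exceed 100.  Raises
    :class:`DegenerateControlError` when WT does not exceed EV.
    """
    if wt_mean <= ev_mean:
        raise DegenerateControlError(
            f"wild-type signal ({wt_mean}) must exceed empty-vector background ({ev_mean})"
        )
    return 100.0 * (variant_mean - ev_mean) / (wt_mean - ev_mean)


def summarize_replicates(
    rec: AssayRecord,
    wt: AssayRecord | None = None,
    ev: AssayRecord | None = None,
) -> tuple[float, float]:
    """Mean and SEM across biological replicates.

    Technical wells are averaged within each biological replicate first.
    When WT and EV control records are supplied, each biological replicate is
    normalized to %WT against the control means of the *same* biological
    replicate (paired within batch), and the mean/SEM are of those %WT values;
    otherwise they are of the raw per-replicate means.

    With a single biological replicate the SEM is undefined and returned as
    NaN with a warning.
    """
    values = rec.bio_means()
    if wt is not None or ev is not None:
        if wt is None or ev is None:
            raise ValueError("supply both WT and EV control records, or neither")
        wt_means, ev_means = wt.bio_means(), ev.bio_means()
        common = values.index.intersection(wt_means.index).intersection(ev_means.index)
        if len(common) == 0:
            raise ValueError(
                f"{rec.variant}: no biological replicates shared with controls"
            )
        values = pd.Series(
            {
                rep: normalize_uptake(values[rep], wt_means[rep], ev_means[rep])
                for rep in common
            }
        )
    mean = float(values.mean())
    if len(values) < 2:
        warnings.warn(
            f"{rec.variant}: single biological replicate, SEM undefined",
            stacklevel=2,
        )
        return mean, float("nan")
    sem = float(values.std(ddof=1) / np.sqrt(len(values)))
    return mean, sem


def test_vs_wt(
    variant_reps: Sequence[float],
    wt_reps: Sequence[float],
    n_tests: int = 1,
    *,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[float, bool]:
    """Two-sided two-sample t test against wild type, Bonferroni-adjusted.

    ``significant`` is True when p < alpha / n_tests.  The classical
    equal-variance test is the default; pass ``equal_var=False`` for Welch.
    """
    v = np.asarray(variant_reps, dtype=float)
    w = np.asarray(wt_reps, dtype=float)
    if len(v) < 2 or len(w) < 2:
        raise InsufficientReplicatesError(
            f"need >=2 replicates per side, got {len(v)} and {len(w)}"
        )
    p = float(stats.ttest_ind(v, w, equal_var=equal_var).pvalue)
    if np.isnan(p):  # zero variance on both sides with equal means
        p = 1.0
    return p, p < alpha / n_tests


def call_lof(function_pct: float, threshold: float = LOF_THRESHOLD) -> bool:
    """LOF iff function is strictly below the threshold (a variant at exactly
    the threshold is classified functional)."""
    return function_pct < threshold


# ---------------------------------------------------------------------------
# Raw-table characterization

def read_raw_assay_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "batch", "bio_rep", "tech_rep", "uptake_counts_per_ug"}
    if not required.issubset(df.columns):
        raise ValueError(f"raw assay TSV needs columns {sorted(required)}")
    return df


def records_from_table(df: pd.DataFrame) -> dict[str, dict[str, AssayRecord]]:
    """Group a raw assay table into records: batch -> variant -> AssayRecord."""
    out: dict[str, dict[str, AssayRecord]] = {}
    for (batch, variant), grp in df.groupby(["batch", "variant"], sort=True):
        reps = {
            rep: sub["uptake_counts_per_ug"].tolist()
            for rep, sub in grp.groupby("bio_rep")
        }
        out.setdefault(str(batch), {})[str(variant)] = AssayRecord(
            variant=str(variant), batch=str(batch), replicates=reps
        )
    return out


def characterize(
    raw: pd.DataFrame,
    *,
    lof_threshold: float = LOF_THRESHOLD,
    n_tests: int | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full raw-to-characterized pipeline.

    For every non-control variant: per-biological-replicate %WT values paired
    with the batch's WT/EV controls, mean and SEM, a t test of the variant's
    %WT replicate values against WT's own normalized replicates (WT is 100 on
    average by construction, with replicate noise), Bonferroni significance
    over ``n_tests`` comparisons (defaults to the number of variants), and the
    LOF call.
    """
    by_batch = records_from_table(raw)
    variants = sorted(
        {v for batch in by_batch.values() for v in batch if v not in (WT_LABEL, EV_LABEL)}
    )
    dup = raw.loc[~raw["variant"].isin([WT_LABEL, EV_LABEL])]
    per_batch_counts = dup.groupby("variant")["batch"].nunique()
    multi = per_batch_counts[per_batch_counts > 1]
    if len(multi):
        raise ValueError(
            f"variant(s) measured in more than one batch: {multi.index.tolist()}; "
            "duplicate labels must be resolved upstream"
        )
    if n_tests is None:
        n_tests = len(variants)
    ctrl_cache: dict[str, tuple[pd.Series, pd.Series, list[float]]] = {}
    for batch, recs in by_batch.items():
        for ctrl in (WT_LABEL, EV_LABEL):
            if ctrl not in recs:
                raise ValueError(f"batch {batch!r} lacks {ctrl} control measurements")
        wt_means = recs[WT_LABEL].bio_means()
        ev_means = recs[EV_LABEL].bio_means()
        wt_pct = [
            normalize_uptake(wt_means[r], wt_means.mean(), ev_means.mean())
            for r in wt_means.index
        ]
        ctrl_cache[batch] = (wt_means, ev_means, wt_pct)
    rows = []
    for variant in variants:
        batch = next(b for b, recs in by_batch.items() if variant in recs)
        recs = by_batch[batch]
        wt_means, ev_means, wt_pct = ctrl_cache[batch]
        rec = recs[variant]
        mean_pct, sem = summarize_replicates(
            rec, wt=recs[WT_LABEL], ev=recs[EV_LABEL]
        )
        rec_means = rec.bio_means()
        common = rec_means.index.intersection(wt_means.index).intersection(
            ev_means.index
        )
        v_pct = [
            normalize_uptake(rec_means[r], wt_means[r], ev_means[r]) for r in common
        ]
        p, sig = test_vs_wt(v_pct, wt_pct, n_tests=n_tests, equal_var=equal_var)
        rows.append(
            {
                "variant": variant,
                "function_pct": mean_pct,
                "sem": sem,
                "p_value": p,
                "significant": sig,
                "lof": call_lof(mean_pct, lof_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("variant")


def read_characterized_tsv(path: str | Path) -> pd.DataFrame:
    """Read a characterized-variant table (one row per variant).

    Expected columns: variant, function_pct; optional sem, p_value,
    localization, group and per-population allele-frequency columns (af_*).
    Duplicate variant labels are a hard error.
    """
    df = pd.read_csv(path, sep="\t")
    if "variant" not in df.columns or "function_pct" not in df.columns:
        raise ValueError("characterized TSV needs at least variant, function_pct")
    if df["variant"].duplicated().any():
        dupes = df.loc[df["variant"].duplicated(), "variant"].tolist()
        raise ValueError(f"duplicate variant labels: {dupes}")
    return df.set_index("variant")


# ---------------------------------------------------------------------------
# Group and localization summaries

@dataclass
class GroupSummary:
    """Per-group functional summary with omnibus and post-hoc tests."""

    table: pd.DataFrame  # per group: n, median, q1, q3, n_below, frac_below
    anova_f: float
    anova_p: float
    posthoc: pd.DataFrame  # pairwise p-values (Tukey HSD or Games-Howell)
    excluded_groups: list[str] = field(default_factory=list)

    @property
    def min_posthoc_p(self) -> float:
        return float(self.posthoc["p_value"].min())


def _per_group_table(
    values: pd.Series, labels: pd.Series, threshold: float
) -> pd.DataFrame:
    rows = []
    for g, sub in values.groupby(labels):
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "median": float(sub.median()),
                "q1": float(sub.quantile(0.25)),
                "q3": float(sub.quantile(0.75)),
                "n_below": int((sub < threshold).sum()),
                "frac_below": float((sub < threshold).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def group_summary(
    table: pd.DataFrame,
    *,
    group_col: str = "group",
    value_col: str = "function_pct",
    threshold: float = LOF_THRESHOLD,
) -> GroupSummary:
    """Ancestry-group summary: medians/IQR, LOF fractions, one-way ANOVA and
    Tukey HSD pairwise comparisons."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table.dropna(subset=[group_col, value_col])
    sizes = df.groupby(group_col).size()
    excluded = sizes[sizes < 2].index.tolist()
    if excluded:
        warnings.warn(f"groups with n<2 excluded from tests: {excluded}", stacklevel=2)
    summary = _per_group_table(df[value_col], df[group_col], threshold)
    test_df = df[~df[group_col].isin(excluded)]
    groups = [sub[value_col].to_numpy() for _, sub in test_df.groupby(group_col)]
    if len(groups) < 2:
        raise ValueError("need at least two groups with n>=2 for the omnibus test")
    f, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(
        test_df[value_col].to_numpy(), test_df[group_col].to_numpy()
    )
    rows = tk.summary().data[1:]
    posthoc = pd.DataFrame(
        {
            "group1": [r[0] for r in rows],
            "group2": [r[1] for r in rows],
            "p_value": list(tk.pvalues),
        }
    )
    return GroupSummary(
        table=summary,
        anova_f=float(f),
        anova_p=float(p),
        posthoc=posthoc,
        excluded_groups=excluded,
    )


def localization_summary(
    table: pd.DataFrame,
    *,
    loc_col: str = "localization",
    value_col: str = "function_pct",
    threshold: float = LOF_THRESHOLD,
) -> GroupSummary:
    """Localization-class summary: counts, per-class medians, Welch's ANOVA
    (unequal variances) and Games-Howell pairwise comparisons."""
    import pingouin as pg

    df = table.dropna(subset=[loc_col, value_col])
    sizes = df.groupby(loc_col).size()
    excluded = sizes[sizes < 2].index.tolist()
    if excluded:
        warnings.warn(f"classes with n<2 excluded from tests: {excluded}", stacklevel=2)
    summary = _per_group_table(df[value_col], df[loc_col], threshold)
    test_df = df[~df[loc_col].isin(excluded)].reset_index()
    if test_df[loc_col].nunique() < 2:
        raise ValueError("need at least two classes with n>=2 for Welch's ANOVA")
    wa = pg.welch_anova(data=test_df, dv=value_col, between=loc_col)
    gh = pg.pairwise_gameshowell(data=test_df, dv=value_col, between=loc_col)
    posthoc = pd.DataFrame(
        {"group1": gh["A"], "group2": gh["B"], "p_value": gh["pval"]}
    )
    return GroupSummary(
        table=summary,
        anova_f=float(wa.loc[0, "F"]),
        anova_p=float(wa.loc[0, "p_unc"]),
        posthoc=posthoc,
        excluded_groups=excluded,
    )
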