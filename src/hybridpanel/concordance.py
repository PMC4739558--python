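"""Mito-nuclear concordance, spatial contrasts, literature tabulation,
and whole-dataset headline summaries.

The mito-nuclear model is a logistic regression of the indicator "fish
carries the WCT mitotype" on the percentage of WCT nuclear alleles
(0-100 scale), fitted by maximum likelihood among WCT x RT hybrids
only: parental fish and fish carrying YCT alleles are excluded, as are
configurable problem sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .model import SITE_CLASS_ORDER, TAXA, GenotypeRecord, MarkerPanel

#: Streams with stocked headwater lakes, excluded from the paired
#: upstream/downstream contrast by default.
DEFAULT_PAIRED_EXCLUSIONS: frozenset = frozenset({"Rock", "Overwhich"})


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    n_used: int
    excluded: Dict[str, int]
    converged: bool
    se_intercept: Optional[float] = None
    se_slope: Optional[float] = None
    separation: bool = False

    def predict(self, x) -> np.ndarray:
        return logistic_predict(self.intercept, self.slope, x)


def logistic_predict(intercept: float, slope: float, x) -> np.ndarray:
    """P(WCT mitotype) at x percent WCT nuclear alleles."""
    return expit(intercept + slope * np.asarray(x, dtype=float))


def fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticFit:
    """ML logistic fit of binary y on a single predictor (plus intercept)."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct predictor values")
    X = sm.add_constant(x)
    separation = False
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params = res.params
        bse = res.bse
    except Exception:
        # perfect separation: report the direction via a penalized refit
        separation = True
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        converged = False
        params = res.params
        bse = res.bse
    if not separation and (np.abs(params) > 50).any():
        separation = True
    return LogisticFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        n_used=len(y),
        excluded={},
        converged=converged,
        se_intercept=float(bse[0]),
        se_slope=float(bse[1]),
        separation=separation,
    )


def fit_mito_logistic(
    table: pd.DataFrame,
    excluded_sites: Iterable[str] = ("McCormick PIBO",),
) -> LogisticFit:
    """Fit the mito-nuclear concordance model from a per-fish table.

    ``table`` needs columns ``pct_wct`` (percent WCT nuclear alleles),
    ``mitotype``, ``is_parental`` (bool), ``has_yct`` (bool) and
    ``site_id``.  Exclusions follow the study design: parental fish,
    fish with YCT introgression, fish with unresolved mitotype, and any
    site in ``excluded_sites`` (by default the one site dominated by
    putatively stocked F1s).
    """
    excluded_sites = set(excluded_sites)
    excluded = {"parental": 0, "yct": 0, "site": 0, "mito_missing": 0}
    keep = np.ones(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples(index=False)):
        if row.site_id in excluded_sites:
            excluded["site"] += 1
            keep[i] = False
        elif bool(row.is_parental):
            excluded["parental"] += 1
            keep[i] = False
        elif bool(row.has_yct):
            excluded["yct"] += 1
            keep[i] = False
        elif row.mitotype not in TAXA:
            excluded["mito_missing"] += 1
            keep[i] = False
    sub = table[keep]
    fit = fit_logistic(sub["pct_wct"].to_numpy(), (sub["mitotype"] == "WCT").to_numpy())
    fit.excluded = excluded
    return fit


@dataclass
class PairedContrast:
    n_streams: int
    mean_upstream: float
    mean_downstream: float
    t_statistic: float
    p_value: float
    excluded_streams: List[str] = field(default_factory=list)
    upstream: np.ndarray = field(default_factory=lambda: np.array([]))
    downstream: np.ndarray = field(default_factory=lambda: np.array([]))


def paired_upstream_downstream(
    sites: pd.DataFrame,
    exclusions: Iterable[str] = DEFAULT_PAIRED_EXCLUSIONS,
    value_col: str = "pct_wct",
) -> PairedContrast:
    """Paired t contrast of the upstream-most vs downstream-most site
    per stream.

    ``sites`` needs columns ``stream`` (or ``stream_key``),
    ``rt_native``, ``site_class`` and ``value_col``.  Streams are
    ordered Low < PIBO < Middle < Headwater; a stream with two sites of
    the same class has no defined extremes and is excluded with a
    warning, as are single-site streams and the explicit exclusion list.
    """
    exclusions = set(exclusions)
    df = sites.copy()
    key_col = "stream_key" if "stream_key" in df.columns else "stream"
    df["_order"] = df["site_class"].map(SITE_CLASS_ORDER)
    if df["_order"].isna().any():
        raise ValueError("unknown site class in input")
    up, down, skipped = [], [], []
    for (stream, native), g in df.groupby([key_col, "rt_native"], sort=True):
        base_name = g["stream"].iloc[0] if "stream" in g.columns else stream
        if len(g) < 2:
            continue
        if base_name in exclusions or stream in exclusions:
            skipped.append(str(stream))
            continue
        if g["_order"].duplicated().any():
            skipped.append(f"{stream} (ambiguous site ordering)")
            continue
        g = g.sort_values("_order")
        down.append(float(g.iloc[0][value_col]))
        up.append(float(g.iloc[-1][value_col]))
    if len(up) < 2:
        raise ValueError("need at least two usable stream pairs")
    up_arr, down_arr = np.asarray(up), np.asarray(down)
    diffs = up_arr - down_arr
    if np.std(diffs, ddof=1) == 0.0:
        # degenerate: identical differences everywhere
        t, p = (0.0, 1.0) if diffs.mean() == 0 else (np.inf * np.sign(diffs.mean()), 0.0)
    else:
        t, p = stats.ttest_rel(up_arr, down_arr)
    return PairedContrast(
        n_streams=len(up),
        mean_upstream=float(up_arr.mean()),
        mean_downstream=float(down_arr.mean()),
        t_statistic=float(t),
        p_value=float(p),
        excluded_streams=skipped,
        upstream=up_arr,
        downstream=down_arr,
    )


@dataclass
class RangeContrast:
    n_inside: int
    n_outside: int
    mean_inside: float
    mean_outside: float
    t_statistic: float
    p_value: float


def range_contrast(
    sites: pd.DataFrame,
    site_class: Optional[str] = None,
    value_col: str = "pct_wct",
) -> RangeContrast:
    """Equal-variance two-sample t contrast of site-level values inside
    vs outside the historical range of rainbow trout."""
    df = sites if site_class is None else sites[sites["site_class"] == site_class]
    inside = df.loc[df["rt_native"].astype(bool), value_col].to_numpy(dtype=float)
    outside = df.loc[~df["rt_native"].astype(bool), value_col].to_numpy(dtype=float)
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("need at least two sites per group")
    if np.var(inside, ddof=1) == 0 and np.var(outside, ddof=1) == 0 and inside.mean() == outside.mean():
        t, p = 0.0, 1.0
    elif np.var(np.concatenate([inside - inside.mean(), outside - outside.mean()]), ddof=0) == 0:
        raise ValueError("zero pooled variance")
    else:
        t, p = stats.ttest_ind(inside, outside, equal_var=True)
    return RangeContrast(
        n_inside=len(inside),
        n_outside=len(outside),
        mean_inside=float(inside.mean()),
        mean_outside=float(outside.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )


@dataclass
class LiteratureTotals:
    n_studies: int
    n_samples_present: int
    n_no_parentals: int
    n_no_parentals_yct_involved: int
    n_absent: int


def tabulate_literature(table1: pd.DataFrame) -> LiteratureTotals:
    """Column totals of the literature-review table; the YCT-involved
    subset is rows whose species pair includes Yellowstone cutthroat."""
    if len(table1) == 0:
        return LiteratureTotals(0, 0, 0, 0, 0)
    yct = table1["species_pair"].str.contains("YCT")
    return LiteratureTotals(
        n_studies=len(table1),
        n_samples_present=int(table1["n_present"].sum()),
        n_no_parentals=int(table1["n_no_parentals"].sum()),
        n_no_parentals_yct_involved=int(table1.loc[yct, "n_no_parentals"].sum()),
        n_absent=int(table1["n_absent"].sum()),
    )


def table2_headlines(table2: pd.DataFrame) -> Dict[str, float]:
    """Headline survey statistics recomputed from the site table."""
    n_fish = int(table2["n"].sum())
    n_pwct = int(table2["parentals_wct"].sum())
    n_prt = int(table2["parentals_rt"].sum())
    n_sites = len(table2)
    no_parental = (table2["parentals_wct"] == 0) & (table2["parentals_rt"] == 0)
    prt_native = int(table2.loc[table2["rt_native"], "parentals_rt"].sum())
    return {
        "n_sites": n_sites,
        "n_fish": n_fish,
        "n_parental_wct": n_pwct,
        "n_parental_rt": n_prt,
        "n_admixed": n_fish - n_pwct - n_prt,
        "pct_fish_parental_wct": 100.0 * n_pwct / n_fish,
        "pct_fish_parental_rt": 100.0 * n_prt / n_fish,
        "n_no_parental_sites": int(no_parental.sum()),
        "pct_sites_wct_ge95": 100.0 * float((table2["pct_wct"] >= 95).mean()),
        "pct_sites_wct_ge99": 100.0 * float((table2["pct_wct"] >= 99).mean()),
        "pct_sites_all_parental_wct": 100.0
        * float((table2["parentals_wct"] == table2["n"]).mean()),
        "pct_parental_rt_in_native_range": 100.0 * prt_native / n_prt,
    }


def dataset_summary(site_summaries: Sequence, thresholds=(95.0, 99.0)) -> Dict[str, float]:
    """Headline report over computed :class:`~hybridpanel.swarm.SiteSummary` objects."""
    n_fish = sum(s.n for s in site_summaries)
    n_parental = {t: sum(s.parental_counts[t] for s in site_summaries) for t in TAXA}
    n_f1 = sum(sum(1 for c in s.classes if c.label == "F1") for s in site_summaries)
    n_admixed = n_fish - sum(n_parental.values())
    n_sites = len(site_summaries)
    out: Dict[str, float] = {
        "n_sites": n_sites,
        "n_fish": n_fish,
        "n_admixed": n_admixed,
        "n_f1": n_f1,
        "n_swarm_sites": sum(1 for s in site_summaries if s.is_swarm),
        "n_no_parental_sites": sum(
            1 for s in site_summaries if sum(s.parental_counts.values()) == 0
        ),
    }
    for t in TAXA:
        out[f"n_parental_{t.lower()}"] = n_parental[t]
    for thr in thresholds:
        frac = np.mean([s.allele_percentages["WCT"] >= thr for s in site_summaries])
        out[f"pct_sites_wct_ge{int(thr)}"] = 100.0 * float(frac)
    out["pct_sites_all_parental_wct"] = 100.0 * float(
        np.mean([s.parental_counts["WCT"] == s.n for s in site_summaries])
    )
    return out
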