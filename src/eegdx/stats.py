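"""Per-feature omnibus tests across diagnostic groups with post hoc pairs.

Routing: each group is checked for normality (Shapiro-Wilk at alpha=0.05).
If every group looks normal (and none is degenerate) the parametric route is
taken — one-way ANOVA followed by Tukey's HSD; otherwise the nonparametric
route — Kruskal-Wallis followed by Dunn's z-tests with Bonferroni correction
over all unordered group pairs.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class TestResult:
    feature_name: str
    route: str                       # "parametric" | "nonparametric"
    omnibus_p: float
    posthoc: list = field(default_factory=list)
    # posthoc entries: (group_a, group_b, adjusted_p, significant)


def _group_arrays(values, groups):
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ConfigurationError("values and groups must have equal length")
    names = [g for g in pd.unique(groups)]
    arrays = {g: values[groups == g] for g in names}
    if len(names) < 2:
        raise ConfigurationError("need at least two groups")
    for g, arr in arrays.items():
        if arr.size < 3:
            raise ConfigurationError(
                f"group {g!r} has {arr.size} subjects; need >= 3")
    return names, arrays


def _route(arrays) -> str:
    for g, arr in arrays.items():
        if np.var(arr) == 0:
            logger.warning("group %r has zero variance; routing nonparametric",
                           g)
            return "nonparametric"
        if spstats.shapiro(arr).pvalue <= ALPHA:
            return "nonparametric"
    return "parametric"


def omnibus_test(values, groups, feature_name: str = "") -> TestResult:
    """Normality-routed omnibus test: ANOVA or Kruskal-Wallis."""
    names, arrays = _group_arrays(values, groups)
    route = _route(arrays)
    samples = [arrays[g] for g in names]
    if route == "parametric":
        p = float(spstats.f_oneway(*samples).pvalue)
    else:
        p = float(spstats.kruskal(*samples).pvalue)
    return TestResult(feature_name=feature_name, route=route, omnibus_p=p)


def _dunn_pairs(names, arrays) -> list:
    """Dunn's rank-based z-tests, Bonferroni-adjusted over all pairs."""
    pooled = np.concatenate([arrays[g] for g in names])
    ranks = spstats.rankdata(pooled)
    N = pooled.size
    offsets = np.cumsum([0] + [arrays[g].size for g in names])
    mean_ranks = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                  for i, g in enumerate(names)}
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = []
    for a, b in itertools.combinations(names, 2):
        na, nb = arrays[a].size, arrays[b].size
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * spstats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        out.append((a, b, float(p_adj), p_adj < ALPHA))
    return out


def _tukey_pairs(names, arrays) -> list:
    res = spstats.tukey_hsd(*[arrays[g] for g in names])
    out = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        out.append((names[i], names[j], p, p < ALPHA))
    return out


def posthoc(values, groups, route: str) -> list:
    """Pairwise comparisons: Tukey HSD (parametric) or Dunn+Bonferroni."""
    names, arrays = _group_arrays(values, groups)
    if route == "parametric":
        return _tukey_pairs(names, arrays)
    if route == "nonparametric":
        return _dunn_pairs(names, arrays)
    raise ConfigurationError(f"unknown route {route!r}")


def analyze_feature(values, groups, feature_name: str = "") -> TestResult:
    """Omnibus test plus the matching post hoc table for one feature."""
    result = omnibus_test(values, groups, feature_name)
    result.posthoc = posthoc(values, groups, result.route)
    return result


def run_feature_tests(feature_matrix) -> pd.DataFrame:
    """Apply the omnibus + post hoc route to every feature column.

    Returns a long-format table with one row per (feature, pair).
    """
    df = feature_matrix.to_dataframe()
    groups = df["group"].to_numpy()
    rows = []
    for name in feature_matrix.feature_names:
        res = analyze_feature(df[name].to_numpy(float), groups, name)
        for a, b, p_adj, sig in res.posthoc:
            rows.append({"feature": name, "route": res.route,
                         "omnibus_p": res.omnibus_p, "group_a": a,
                         "group_b": b, "adjusted_p": p_adj,
                         "significant": bool(sig)})
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> dict:
    """Counts: features with a significant omnibus test, and how many times
    each group appears in a significant post hoc pair."""
    per_feature = table.groupby("feature")["omnibus_p"].first()
    n_signif = int((per_feature < ALPHA).sum())
    sig = table[table["significant"] &
                (table["omnibus_p"] < ALPHA)]
    diff_counts: dict[str, int] = {}
    for col in ("group_a", "group_b"):
        for g, c in sig[col].value_counts().items():
            diff_counts[g] = diff_counts.get(g, 0) + int(c)
    return {"n_significant_features": n_signif,
            "per_group_difference_counts": diff_counts}


def write_results(table: pd.DataFrame, csv_path, json_path=None) -> None:
    table.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summarize(table), indent=2))
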