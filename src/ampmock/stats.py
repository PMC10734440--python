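"""Observed-vs-expected quantitation statistics.

Per-strain observed abundances come from true_strain OTU counts; bias is
summarised by fold differences, one-sample two-tailed t-tests against the
expected percent, one-way ANOVA with Fisher's LSD compact letter display
over GC clusters, and per-library Pearson correlation between observed and
expected abundances.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import MockDesign
from .otu import OtuTable


def observed_abundances(table: OtuTable, design: MockDesign) -> pd.DataFrame:
    """Percent of each strain per library, pooling its true_strain OTUs.

    Rows = strain_id, columns = library_id; strains with no OTU get 0
    (recorded "not detected" downstream).
    """
    strain_ids = [s.strain_id for s in design.strains]
    col_totals = table.counts.sum(axis=0)
    out = pd.DataFrame(0.0, index=strain_ids, columns=table.counts.columns)
    for otu_id, cls in table.classification.items():
        if not cls.startswith("true_strain:"):
            continue
        sid = cls.split(":", 1)[1]
        if sid not in out.index:
            continue
        out.loc[sid] += table.counts.loc[otu_id]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * out / col_totals
    return out.fillna(0.0)


def t_test_vs_expected(values: Sequence[float], expected: float) -> tuple[float, float]:
    """One-sample two-tailed t-test of mean(values) against ``expected``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    if np.allclose(values.std(ddof=1), 0.0):
        warnings.warn("zero variance in t-test; degenerate p value")
        if np.isclose(values.mean(), expected):
            return 0.0, 1.0
        return np.inf if values.mean() > expected else -np.inf, 0.0
    t, p = sps.ttest_1samp(values, popmean=expected)
    return float(t), float(p)


def _lsd_pairwise_p(groups: dict[str, np.ndarray], mse: float, df_err: int
                    ) -> dict[tuple[str, str], float]:
    out = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        t = (groups[a].mean() - groups[b].mean()) / se
        out[(a, b)] = out[(b, a)] = 2.0 * sps.t.sf(abs(t), df_err)
    return out


def compact_letter_display(means: Mapping[str, float],
                           pairwise_p: Mapping[tuple[str, str], float],
                           alpha: float = 0.05) -> dict[str, str]:
    """Greedy letters by descending mean; groups share a letter iff every
    pair inside the letter class is non-significant."""
    order = sorted(means, key=lambda g: -means[g])
    letter_classes: list[list[str]] = []
    for g in order:
        placed = False
        for cls in letter_classes:
            if all(pairwise_p[(g, h)] >= alpha for h in cls):
                cls.append(g)
                placed = True
        if not placed:
            letter_classes.append([g])
    letters = {g: "" for g in order}
    for letter, cls in zip(string.ascii_lowercase, letter_classes):
        for g in cls:
            letters[g] += letter
    return letters


def anova_lsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05,
              protected: bool = True) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA plus Fisher's LSD compact letter display.

    ``protected`` runs the LSD only when the ANOVA rejects at ``alpha``
    (all groups share "a" otherwise); set False for unprotected LSD.
    """
    gs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(gs) < 2 or any(len(v) < 2 for v in gs.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.allclose(v.std(ddof=1), 0.0) for v in gs.values()):
        warnings.warn("zero within-group variance everywhere; ANOVA degenerate")
        means = {k: v.mean() for k, v in gs.items()}
        if np.allclose(list(means.values()), np.mean(list(means.values()))):
            return 0.0, 1.0, {k: "a" for k in gs}
        return np.inf, 0.0, {k: string.ascii_lowercase[i]
                             for i, k in enumerate(sorted(gs, key=lambda g: -means[g]))}
    f, p = sps.f_oneway(*gs.values())
    n_total = sum(len(v) for v in gs.values())
    df_err = n_total - len(gs)
    grand = np.concatenate(list(gs.values())).mean()
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in gs.values())
    mse = ss_err / df_err
    means = {k: v.mean() for k, v in gs.items()}
    if protected and p >= alpha:
        letters = {k: "a" for k in gs}
    else:
        pw = _lsd_pairwise_p(gs, mse, df_err)
        letters = compact_letter_display(means, pw, alpha)
    return float(f), float(p), letters


def pearson_observed_expected(observed: Sequence[float],
                              expected: Sequence[float]) -> float:
    """Sample Pearson correlation between observed and expected abundances."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if len(observed) != len(expected) or len(observed) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.allclose(observed.std(), 0) or np.allclose(expected.std(), 0):
        raise ValueError("constant vector: correlation undefined")
    return float(sps.pearsonr(observed, expected)[0])


@dataclass
class BiasReport:
    per_strain: pd.DataFrame
    per_cluster: pd.DataFrame
    pearson_per_library: pd.DataFrame
    pearson_mean: float
    pearson_sd: float


def bias_report(table: OtuTable, design: MockDesign,
                alpha: float = 0.05) -> BiasReport:
    """Full observed-vs-expected report for one community's libraries."""
    obs = observed_abundances(table, design)
    exp = design.expected_abundance
    strain_rows = []
    cluster_of = {s.strain_id: s.gc_cluster for s in design.strains}
    for sid in obs.index:
        vals = obs.loc[sid].to_numpy(dtype=float)
        e = exp.get(sid, 0.0)
        mean = float(vals.mean())
        detected = bool((vals > 0).any())
        strain_rows.append({
            "strain_id": sid,
            "gc_cluster": cluster_of.get(sid),
            "expected_percent": e,
            "observed_mean": mean,
            "observed_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "fold_difference": mean / e if e > 0 else np.nan,
            "detected": detected,
        })
    per_strain = pd.DataFrame(strain_rows).set_index("strain_id")

    cluster_rows = []
    groups: dict[str, np.ndarray] = {}
    for cluster in ("low", "medium", "high"):
        sids = [s for s, c in cluster_of.items() if c == cluster and s in obs.index]
        if not sids:
            continue
        vals = obs.loc[sids].to_numpy(dtype=float).ravel()
        groups[cluster] = vals
        e = float(np.mean([exp[s] for s in sids]))
        try:
            t, p = t_test_vs_expected(vals, e)
        except ValueError:
            t, p = np.nan, np.nan
        cluster_rows.append({"gc_cluster": cluster, "expected_percent": e,
                             "observed_mean": float(vals.mean()),
                             "observed_sd": float(vals.std(ddof=1)),
                             "t": t, "p_vs_expected": p})
    letters: dict[str, str] = {}
    if len(groups) >= 2:
        try:
            _, _, letters = anova_lsd(groups, alpha=alpha)
        except ValueError:
            letters = {}
    per_cluster = pd.DataFrame(cluster_rows).set_index("gc_cluster")
    per_cluster["lsd_letter"] = [letters.get(c, "") for c in per_cluster.index]

    rs = []
    for lib in obs.columns:
        o = obs[lib].to_numpy(dtype=float)
        e = np.array([exp.get(s, 0.0) for s in obs.index])
        try:
            rs.append({"library": lib, "r": pearson_observed_expected(o, e)})
        except ValueError:
            rs.append({"library": lib, "r": np.nan})
    pearson = pd.DataFrame(rs).set_index("library")
    valid = pearson["r"].dropna()
    return BiasReport(
        per_strain=per_strain,
        per_cluster=per_cluster,
        pearson_per_library=pearson,
        pearson_mean=float(valid.mean()) if len(valid) else np.nan,
        pearson_sd=float(valid.std(ddof=1)) if len(valid) > 1 else 0.0,
    )
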