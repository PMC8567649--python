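"""Cutpoint selection and group-level association tests.

Survival cutpoints follow the maximally-selected-rank-statistics idea: for
every candidate split of a continuous marker that leaves at least a
``minprop`` fraction of patients on each side, compute the standardized
two-sample log-rank statistic |Z| for (marker > c) vs (marker <= c) and
take the candidate maximizing |Z|.  Binary-outcome cutpoints (for durable
clinical benefit) maximize the Youden index J = sensitivity +
specificity - 1 over all observed thresholds, calling positive when the
score is strictly above the threshold.

The joint marker grouping follows the strict-inequality convention:
"high" means strictly above the cutpoint, so a value equal to the
cutpoint is "low".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError

JOINT_LABELS = ("both_low", "single_high", "both_high")


@dataclass(frozen=True)
class CutpointResult:
    variable: str
    cutpoint: float
    statistic: float          # standardized log-rank |Z| at the chosen split
    n_candidates: int
    n_high: int
    n_low: int


@dataclass(frozen=True)
class ROCCutpoint:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: str = ">"      # positive call iff score `direction` threshold


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: groups; cols: (DCB, NDB)
    proportions: tuple[float, float]
    method: str
    statistic: float
    p: float


@dataclass(frozen=True)
class AssociationResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    df: int
    p: float


def logrank_z(times: np.ndarray, events: np.ndarray, in_high: np.ndarray) -> float:
    """Standardized log-rank statistic Z = (O - E) / sqrt(V) for the
    high group, with hypergeometric variance at each event time.

    Positive Z means the high group experienced more events than expected
    (worse survival).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    in_high = np.asarray(in_high, dtype=bool)
    if events.sum() == 0:
        raise DegenerateInputError("log-rank undefined with zero events")
    order = np.argsort(times, kind="mergesort")
    t, e, g = times[order], events[order], in_high[order]
    n = len(t)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    at_risk = n
    at_risk_high = int(g.sum())
    while i < n:
        j = i
        d = d_high = removed = removed_high = 0
        while j < n and t[j] == t[i]:
            d += e[j]
            d_high += e[j] * g[j]
            removed += 1
            removed_high += int(g[j])
            j += 1
        if d > 0 and at_risk > 1:
            frac = at_risk_high / at_risk
            o_minus_e += d_high - d * frac
            var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        at_risk -= removed
        at_risk_high -= removed_high
        i = j
    if var <= 0:
        raise DegenerateInputError("log-rank variance is zero (one group has no risk time)")
    return o_minus_e / math.sqrt(var)


def maxstat_cutpoint(values, times, events, minprop: float = 0.1,
                     variable: str = "marker") -> CutpointResult:
    """Optimal survival cutpoint by maximally selected rank statistics.

    Candidates are the distinct observed marker values whose induced split
    (value > c vs value <= c) leaves at least ceil(minprop*n) patients on
    each side.  Ties in |Z| break toward the smallest candidate.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(values)
    if n < 10:
        raise InputError(f"need at least 10 observations for a cutpoint scan, got {n}")
    if not (0 < minprop < 0.5):
        raise InputError("minprop must lie in (0, 0.5)")
    if events.sum() < 1:
        raise DegenerateInputError("cutpoint scan needs at least one event")
    min_side = math.ceil(minprop * n)
    candidates = [c for c in np.unique(values)
                  if min_side <= int((values > c).sum()) and min_side <= int((values <= c).sum())]
    if not candidates:
        raise DegenerateInputError(
            f"no valid cutpoint candidate for {variable!r} "
            "(constant marker or minprop too extreme)")
    best_c, best_z = None, -np.inf
    for c in candidates:  # ascending; strict > keeps the smallest on ties
        try:
            z = abs(logrank_z(times, events, values > c))
        except DegenerateInputError:
            continue
        if z > best_z + 1e-12:
            best_z, best_c = z, c
    if best_c is None:
        raise DegenerateInputError(f"all candidate splits for {variable!r} are degenerate")
    return CutpointResult(variable=variable, cutpoint=float(best_c), statistic=float(best_z),
                          n_candidates=len(candidates),
                          n_high=int((values > best_c).sum()),
                          n_low=int((values <= best_c).sum()))


def youden_cutpoint(scores, binary_outcome, auto_flip: bool = True) -> ROCCutpoint:
    """ROC-optimal threshold by the Youden index.

    A positive call is score strictly above the threshold; candidates are
    the distinct observed scores, ties in J break toward the smallest
    threshold.  When the marker is anti-associated with the outcome
    (AUC < 0.5) the direction is flipped with a warning, unless
    ``auto_flip`` is disabled.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(binary_outcome, dtype=int)
    pos = outcome == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("Youden cutpoint needs both outcome classes present")
    # rank-based AUC of "higher score -> positive"
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    direction = ">"
    if auc < 0.5 and auto_flip:
        warnings.warn(f"score is anti-associated with outcome (AUC={auc:.3f}); "
                      "flipping call direction to '<='", stacklevel=2)
        direction = "<="
    best = None
    for c in np.unique(scores):
        called_pos = scores > c if direction == ">" else scores <= c
        sens = float((called_pos & pos).sum() / n_pos)
        spec = float((~called_pos & ~pos).sum() / n_neg)
        j = sens + spec - 1
        if best is None or j > best.youden_j + 1e-12:
            best = ROCCutpoint(threshold=float(c), sensitivity=sens,
                               specificity=spec, youden_j=j, direction=direction)
    return best


def assign_joint_group(hed: float, tmb: float,
                       hed_cut: float = 8.61, tmb_cut: float = 5.22) -> str:
    """Three-level joint marker group from two strict-inequality flags."""
    for name, v in (("hed_cut", hed_cut), ("tmb_cut", tmb_cut)):
        if not np.isfinite(v):
            raise InputError(f"{name} must be finite")
    if pd.isna(hed) or pd.isna(tmb):
        raise InputError("missing marker value; exclude the record upstream")
    n_high = int(hed > hed_cut) + int(tmb > tmb_cut)
    return JOINT_LABELS[n_high]


def assign_joint_groups(table: pd.DataFrame, hed_col: str = "hed_b", tmb_col: str = "tmb",
                        hed_cut: float = 8.61, tmb_cut: float = 5.22) -> pd.Series:
    """Vector form of :func:`assign_joint_group`; rows with a missing
    marker are excluded with a warning."""
    ok = table[hed_col].notna() & table[tmb_col].notna()
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} record(s) with missing markers excluded "
                      "from joint grouping", stacklevel=2)
    out = [assign_joint_group(h, t, hed_cut, tmb_cut)
           for h, t in zip(table.loc[ok, hed_col], table.loc[ok, tmb_col])]
    return pd.Series(pd.Categorical(out, categories=list(JOINT_LABELS)),
                     index=table.index[ok], name="joint_group")


def dcb_contingency_test(group_labels, dcb_labels, method: str = "auto") -> ContingencyResult:
    """Compare DCB rates between two groups.

    ``method``: "fisher" (two-sided exact, hypergeometric enumeration),
    "chi2" (Pearson, no continuity correction), or "auto" (Fisher when any
    expected cell count is below 5, chi-square otherwise).
    """
    group_labels = pd.Series(group_labels).astype(str)
    dcb_labels = pd.Series(dcb_labels).astype(str)
    groups = sorted(group_labels.unique())
    if len(groups) != 2:
        raise InputError(f"expected exactly 2 groups, got {groups}")
    table = np.zeros((2, 2), dtype=int)
    for i, g in enumerate(groups):
        in_g = group_labels.to_numpy() == g
        table[i, 0] = int(((dcb_labels.to_numpy() == "DCB") & in_g).sum())
        table[i, 1] = int(((dcb_labels.to_numpy() != "DCB") & in_g).sum())
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateInputError("a contingency margin is empty")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "fisher":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        statistic = float(odds)
    elif method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        statistic = float(chi2)
    else:
        raise InputError(f"unknown method {method!r}")
    props = tuple(table[i, 0] / table[i].sum() for i in range(2))
    return ContingencyResult(table=tuple(map(tuple, table)), proportions=props,
                             method=method, statistic=statistic, p=float(p))


def spearman_assoc(x, y) -> AssociationResult:
    """Two-sided Spearman rank correlation (midrank ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    if len(x) < 4:
        raise InputError("Spearman correlation needs n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(rho=float(rho), p=float(p), n=len(x))


def compare_driver_genes(mutation_flags: pd.DataFrame, group_labels,
                         high_label: str = "high") -> pd.DataFrame:
    """Per-gene mutation-frequency comparison between marker-high and -low
    patients: two-sided Fisher exact test and odds ratio.

    ``mutation_flags`` is genes x patients (boolean).  Genes with no
    contrast (mutated in everyone or in no one) are omitted, with a
    warning naming them.  No multiplicity adjustment is applied; the
    result is sorted by raw p.
    """
    labels = pd.Series(group_labels).astype(str)
    common = [p for p in mutation_flags.columns if p in labels.index]
    if len(common) < len(mutation_flags.columns):
        warnings.warn(f"{len(mutation_flags.columns) - len(common)} patient(s) without "
                      "group labels dropped from gene comparison", stacklevel=2)
    flags = mutation_flags[common].astype(bool)
    labels = labels.loc[common]
    high = labels == high_label
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise InputError("both marker groups must be non-empty")
    rows, skipped = [], []
    for gene, row in flags.iterrows():
        mut_high = int(row[high.to_numpy()].sum())
        mut_low = int(row[~high.to_numpy()].sum())
        if (mut_high + mut_low == 0) or (mut_high == n_high and mut_low == n_low):
            skipped.append(gene)
            continue
        table = [[mut_high, n_high - mut_high], [mut_low, n_low - mut_low]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"gene": gene, "mut_high": mut_high, "n_high": n_high,
                     "mut_low": mut_low, "n_low": n_low,
                     "odds_ratio": float(odds), "p": float(p)})
    if skipped:
        warnings.warn(f"gene(s) without mutation contrast skipped: {skipped}", stacklevel=2)
    return pd.DataFrame(rows, columns=["gene", "mut_high", "n_high", "mut_low",
                                       "n_low", "odds_ratio", "p"]).sort_values(
        "p", ignore_index=True)


def kruskal_test(*grouped_values) -> KruskalResult:
    """Kruskal-Wallis H test across two or more groups (midrank ties,
    chi-square reference with k-1 df).

    All-identical values across every group is a documented degenerate
    case: H = 0, p = 1.
    """
    if len(grouped_values) < 2:
        raise InputError("Kruskal-Wallis needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in grouped_values]
    if any(len(g) == 0 for g in groups):
        raise InputError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KruskalResult(statistic=0.0, df=len(groups) - 1, p=1.0)
    h, p = stats.kruskal(*groups)
    return KruskalResult(statistic=float(h), df=len(groups) - 1, p=float(p))
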