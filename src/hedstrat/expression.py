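"""Immune gene-panel normalization, differential expression and enrichment.

The panel pipeline is: raw background-subtracted read counts -> reads per
million within the panel (RPM) -> housekeeping-ratio normalization
against an internal control sample (nRPM) -> log2(nRPM + 1).  The
per-sample normalization ratio is

    ratio_s = geomean(control HK RPM) / geomean(sample HK RPM)

so that after scaling every sample's housekeeping geometric mean equals
the control's.  Differential expression between marker-high and -low
groups uses an empirical-Bayes moderated t statistic (per-gene pooled
variances shrunk toward a panel-wide prior fitted by moment matching on
the log-variances); a plain Welch t is available as an alternative.
A gene is called differentially expressed when |log2 fold change| >
0.5849 (a 1.5-fold change) and raw p < 0.05 — no multiplicity adjustment
at this step; Benjamini-Hochberg is applied only in the gene-set
over-representation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InputError

LOG2_FC_THRESHOLD = 0.5849   # log2 of a 1.5-fold change
P_THRESHOLD = 0.05
PSEUDOCOUNT = 1.0


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million within the panel: per sample, counts * 1e6 / total."""
    counts = counts.astype(float)
    if (counts < 0).any().any():
        raise InputError("raw counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateInputError(f"sample(s) with zero total counts: {list(zero.index)}")
    return counts * 1e6 / totals


def _geomean_positive(values: np.ndarray, label: str) -> float:
    positive = values[values > 0]
    if len(positive) == 0:
        raise DegenerateInputError(f"all housekeeping RPM values are zero for {label}")
    if len(positive) < len(values):
        warnings.warn(f"{len(values) - len(positive)} zero housekeeping value(s) "
                      f"excluded from geometric mean for {label}", stacklevel=3)
    return float(np.exp(np.mean(np.log(positive))))


def hk_normalize(rpm: pd.DataFrame, hk_genes, control_profile: pd.Series) -> pd.DataFrame:
    """Housekeeping-ratio normalization against an internal control.

    ``control_profile`` maps housekeeping genes to their RPM in the control
    sample.  Zero-RPM housekeeping genes are excluded from the geometric
    mean with a warning.
    """
    hk = list(hk_genes)
    missing = [g for g in hk if g not in rpm.index]
    if missing:
        raise InputError(f"housekeeping gene(s) absent from count matrix: {missing}")
    missing_c = [g for g in hk if g not in control_profile.index]
    if missing_c:
        raise InputError(f"housekeeping gene(s) absent from control profile: {missing_c}")
    control_gm = _geomean_positive(control_profile.loc[hk].to_numpy(dtype=float), "control")
    out = {}
    for sample in rpm.columns:
        sample_gm = _geomean_positive(rpm.loc[hk, sample].to_numpy(), str(sample))
        out[sample] = rpm[sample] * (control_gm / sample_gm)
    return pd.DataFrame(out, index=rpm.index)


def log_transform(nrpm: pd.DataFrame, pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    return np.log2(nrpm + pseudocount)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return np.inf
    trigamma = lambda x: float(special.polygamma(1, x))
    lo, hi = 1e-4, 1e7
    if y >= trigamma(lo):
        return lo
    if y <= trigamma(hi):
        return hi
    return float(optimize.brentq(lambda x: trigamma(x) - y, lo, hi, xtol=1e-10))


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed per-gene pooled variances, on the log scale."""
    s2 = np.maximum(s2, 1e-12)
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = var_e - float(special.polygamma(1, df / 2))
    if excess <= 0:
        return np.inf, float(np.exp(mean_e))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2 * half_d0
    s0_2 = float(np.exp(mean_e + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


@dataclass(frozen=True)
class DEGTable:
    table: pd.DataFrame       # gene, log2_fc, statistic, p, passes
    method: str
    prior_df: float
    prior_var: float


def differential_expression(log_matrix: pd.DataFrame, group_labels,
                            high_label: str = "high",
                            method: str = "moderated",
                            lfc_threshold: float = LOG2_FC_THRESHOLD,
                            p_threshold: float = P_THRESHOLD) -> DEGTable:
    """Per-gene two-sample test on log2-normalized expression.

    log2 fold change is mean(high) - mean(low).  ``method="moderated"``
    shrinks per-gene pooled variances toward the fitted panel-wide prior
    and refers t to df + prior_df; ``method="welch"`` is the unpooled
    alternative.  The pass flag applies the strict |log2FC| and raw-p
    thresholds.
    """
    labels = pd.Series(group_labels).astype(str)
    common = [c for c in log_matrix.columns if c in labels.index]
    mat = log_matrix[common]
    labels = labels.loc[common]
    high = (labels == high_label).to_numpy()
    n1, n2 = int(high.sum()), int((~high).sum())
    if n1 < 3 or n2 < 3:
        raise InputError(f"need >= 3 samples per group, got high={n1}, low={n2}")
    x_high = mat.loc[:, high].to_numpy(dtype=float)
    x_low = mat.loc[:, ~high].to_numpy(dtype=float)
    lfc = x_high.mean(axis=1) - x_low.mean(axis=1)

    if method == "moderated":
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * x_high.var(axis=1, ddof=1)
                  + (n2 - 1) * x_low.var(axis=1, ddof=1)) / df
        d0, s0_2 = _fit_variance_prior(pooled, df)
        if np.isinf(d0):
            s2_post = np.full_like(pooled, s0_2)
            total_df = np.inf
        else:
            s2_post = (d0 * s0_2 + df * pooled) / (d0 + df)
            total_df = df + d0
        se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / se
        p = (2 * stats.norm.sf(np.abs(t)) if np.isinf(total_df)
             else 2 * stats.t.sf(np.abs(t), total_df))
        prior_df, prior_var = d0, s0_2
    elif method == "welch":
        t, p = stats.ttest_ind(x_high, x_low, axis=1, equal_var=False)
        prior_df, prior_var = 0.0, float("nan")
    else:
        raise InputError(f"unknown DE method {method!r}")

    p = np.where(np.isnan(p), 1.0, p)
    passes = (np.abs(lfc) > lfc_threshold) & (p < p_threshold)
    table = pd.DataFrame({"gene": mat.index, "log2_fc": lfc,
                          "statistic": np.asarray(t, dtype=float),
                          "p": p, "passes": passes}).reset_index(drop=True)
    return DEGTable(table=table, method=method,
                    prior_df=float(prior_df), prior_var=float(prior_var))


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = {g for g in parts[2:] if g}
    if not sets:
        raise InputError(f"no gene sets parsed from {path}")
    return sets


def ora_test(deg_genes, universe, gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of DEGs in each gene set.

    Sets are intersected with the universe; upper-tail p-values are
    Benjamini-Hochberg adjusted across sets.  Sets with no universe
    overlap are skipped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty gene universe")
    deg = set(deg_genes)
    stray = deg - universe
    if stray:
        raise InputError(f"DEG gene(s) outside the universe: {sorted(stray)[:5]}")
    big_n, n_deg = len(universe), len(deg)
    rows, skipped = [], []
    for name, members in gene_sets.items():
        in_universe = members & universe
        if not in_universe:
            skipped.append(name)
            continue
        k = len(in_universe & deg)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(in_universe), n_deg))
        rows.append({"set": name, "set_size": len(in_universe),
                     "overlap": k, "p": p})
    if skipped:
        warnings.warn(f"gene set(s) with no universe overlap skipped: {skipped}",
                      stacklevel=2)
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", ignore_index=True)
    else:
        out["p_adjusted"] = []
    return out
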