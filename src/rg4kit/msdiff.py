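"""Quantitative RP-MS differential binding: WT vs 7dG label-free analysis.

The pipeline mirrors the standard Perseus-style workflow for paired pull-down
LFQ data: contaminant/reverse filtering, log2 transform, a valid-value filter
(>= 3 observed intensities in at least one condition), missing-not-at-random
imputation from a downshifted Gaussian (width 0.3 x and downshift 1.8 x the
per-sample sd of observed values), a paired sign-flip permutation test with
SAM-style q-values, and classification of significant proteins into RG4-BPs
(WT-preferring, fold >= 1.5) and G-rich-BPs (7dG-preferring, fold <= 1/1.5)
after background subtraction.

Input tables are MaxQuant-proteinGroups-like: ``protein_id``,
``contaminant_flag``, ``reverse_flag`` and intensity columns named
``WT_<pair>`` / ``7dG_<pair>``; zero or empty intensities are missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("WT", "7dG")

CLASSES = ("RG4-BP", "G-rich-BP", "unclassified", "background", "excluded")


@dataclass(frozen=True)
class MSConfig:
    min_valid_per_condition: int = 3
    impute_width: float = 0.3       # fraction of per-sample sd
    impute_downshift: float = 1.8   # multiples of per-sample sd
    q_cutoff: float = 0.05
    fold_cutoff: float = 1.5
    n_permutations: int | str = "exhaustive"
    # SAM-style variance-stabilisation offset (log2 units). A small positive
    # value damps spuriously large t from near-zero sample sd at few pairs;
    # 0 recovers the plain paired t.
    s0: float = 0.1
    seed: int = 0
    require_both_conditions: bool = False  # strict "3 valid in each group" mode
    ratio_from_imputed: bool = True

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must be > 1")
        if not 0 < self.q_cutoff < 1:
            raise ValueError("q_cutoff must be in (0, 1)")
        if self.min_valid_per_condition < 2:
            raise ValueError("min_valid_per_condition must be >= 2")


def _condition_columns(columns) -> dict[str, list[str]]:
    """Split intensity columns by condition and validate replicate pairing."""
    by_cond: dict[str, dict[str, str]] = {c: {} for c in CONDITIONS}
    for col in columns:
        for cond in CONDITIONS:
            prefix = cond + "_"
            if col.startswith(prefix):
                by_cond[cond][col[len(prefix):]] = col
    pairs_wt = sorted(by_cond["WT"])
    pairs_7dg = sorted(by_cond["7dG"])
    if pairs_wt != pairs_7dg:
        raise ValueError(
            f"unpaired replicate labels: WT pairs {pairs_wt} vs 7dG pairs {pairs_7dg}"
        )
    if not pairs_wt:
        raise ValueError("no WT_*/7dG_* intensity columns found")
    return {
        "pairs": pairs_wt,
        "WT": [by_cond["WT"][p] for p in pairs_wt],
        "7dG": [by_cond["7dG"][p] for p in pairs_wt],
    }


def preprocess(raw: pd.DataFrame, config: MSConfig = MSConfig()):
    """Filter and log2-transform a raw LFQ table.

    Returns (log2 matrix indexed by protein_id, excluded frame with reasons,
    column layout dict). Zero or missing intensities become NaN; contaminant
    and reverse rows are dropped; proteins with fewer than
    ``min_valid_per_condition`` observed values in every condition (or, in
    strict mode, in any condition) are excluded.
    """
    layout = _condition_columns(raw.columns)
    df = raw.copy()
    if df["protein_id"].duplicated().any():
        raise ValueError("duplicate protein_id values")
    df = df.set_index("protein_id")
    intensity_cols = layout["WT"] + layout["7dG"]
    mat = df[intensity_cols].apply(pd.to_numeric, errors="coerce")
    mat = mat.where(mat > 0)  # 0 or empty = missing (MaxQuant dialect)
    log2 = np.log2(mat)

    excluded = []
    flagged = pd.Series(False, index=df.index)
    for flag in ("contaminant_flag", "reverse_flag"):
        if flag in df.columns:
            truthy = df[flag].astype(str).str.strip().isin({"+", "1", "True", "true"})
            flagged |= truthy
    for pid in df.index[flagged]:
        excluded.append({"protein_id": pid, "reason": "contaminant/reverse"})
    log2 = log2[~flagged]

    n_wt = log2[layout["WT"]].notna().sum(axis=1)
    n_7dg = log2[layout["7dG"]].notna().sum(axis=1)
    if config.require_both_conditions:
        keep = (n_wt >= config.min_valid_per_condition) & (
            n_7dg >= config.min_valid_per_condition
        )
    else:
        keep = (n_wt >= config.min_valid_per_condition) | (
            n_7dg >= config.min_valid_per_condition
        )
    for pid in log2.index[~keep]:
        excluded.append({"protein_id": pid, "reason": "too few valid values"})
    log2 = log2[keep]
    excluded_df = pd.DataFrame(excluded, columns=["protein_id", "reason"])
    return log2, excluded_df, layout


def impute_mnar(
    matrix: pd.DataFrame, config: MSConfig = MSConfig(), rng=None
) -> pd.DataFrame:
    """Replace missing log2 intensities column-wise with draws from a
    downshifted Gaussian.

    For a sample column with observed mean m and sd s (ddof=1), each missing
    entry is an independent draw from
    Normal(m - downshift*s, (width*s)^2). Observed entries are untouched.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = matrix.copy()
    for col in matrix.columns:
        observed = matrix[col].dropna()
        if len(observed) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 observed values")
        n_missing = int(matrix[col].isna().sum())
        if n_missing == 0:
            continue
        m = float(observed.mean())
        s = float(observed.std(ddof=1))
        draws = rng.normal(
            m - config.impute_downshift * s, config.impute_width * s, size=n_missing
        )
        out.loc[matrix[col].isna(), col] = draws
    return out


def sign_patterns(n: int, n_permutations: int | str, rng=None) -> np.ndarray:
    """Sign-flip patterns (K x n of +-1). Exhaustive 2^n when requested and
    n <= 12; otherwise random patterns (the identity pattern is always
    included so p-values are never zero)."""
    if n_permutations == "exhaustive":
        if n > 12:
            raise ValueError("exhaustive sign-flip null limited to n <= 12 pairs")
        return np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    k = int(n_permutations)
    if k < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    pats = rng.choice((1.0, -1.0), size=(k, n))
    pats[0] = 1.0
    return pats


def _paired_t(d: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    """t statistics for difference matrix d (P x n) under sign patterns s
    (K x n): t = mean / (s0 + sd/sqrt(n)). Sign flips leave sum(d^2)
    unchanged, so the per-pattern sd follows from the flipped mean alone."""
    n = d.shape[1]
    means = d @ s.T / n                              # P x K
    ssq = (d**2).sum(axis=1, keepdims=True)          # P x 1
    var = np.maximum(ssq - n * means**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / (s0 + np.sqrt(var) / np.sqrt(n))
    t[np.isnan(t)] = 0.0  # 0/0: all differences exactly zero -> no evidence
    return t


def paired_permutation_test(
    matrix: pd.DataFrame,
    config: MSConfig = MSConfig(),
    layout: dict | None = None,
    patterns: np.ndarray | None = None,
) -> pd.DataFrame:
    """Paired sign-flip permutation test with SAM-style q-values.

    Per protein the paired differences d_i = log2 WT_i - log2 7dG_i give
    t = mean(d) / (s0 + sd(d)/sqrt(n)). The null is built by applying each
    sign pattern identically to all proteins. FDR(theta) = (mean count of
    null |t| >= theta across patterns) / (observed count of |t| >= theta);
    q_i is the minimum FDR over thresholds <= |t_i| (hence monotone
    non-decreasing in rank), capped at 1.

    The identity pattern and its sign-complement reproduce |t_obs| exactly
    for every protein, so with a small exhaustive ensemble they would place
    every true effect in its own null and floor the FDR at 2/2^n; they are
    therefore excluded from the FDR null (they still count in the
    per-protein permutation p, which keeps perm_p > 0).

    Returns a frame with t_stat, q_value, perm_p (per-protein two-sided
    permutation p) and a zero_variance flag.
    """
    if layout is None:
        layout = _condition_columns(matrix.columns)
    n = len(layout["pairs"])
    if n < 2:
        raise ValueError("paired test needs at least 2 replicate pairs")
    wt = matrix[layout["WT"]].to_numpy(dtype=float)
    dg = matrix[layout["7dG"]].to_numpy(dtype=float)
    if np.isnan(wt).any() or np.isnan(dg).any():
        raise ValueError("matrix must be complete (impute first)")
    d = wt - dg
    if patterns is None:
        patterns = sign_patterns(
            n, config.n_permutations, np.random.default_rng(config.seed)
        )
    t_null = _paired_t(d, patterns, config.s0)       # P x K
    t_obs = _paired_t(d, np.ones((1, n)), config.s0)[:, 0]
    abs_obs = np.abs(t_obs)
    abs_null = np.abs(t_null)

    perm_p = (abs_null >= abs_obs[:, None]).mean(axis=1)

    trivial = np.abs(patterns).min(axis=1) == 1.0
    trivial &= np.abs(patterns.sum(axis=1)) == n  # identity or its complement
    fdr_null = abs_null[:, ~trivial]
    k_pat = fdr_null.shape[1]
    if k_pat == 0:
        raise ValueError("no non-trivial sign patterns for the FDR null")
    null_sorted = np.sort(fdr_null.ravel())
    obs_sorted_asc = np.sort(abs_obs)
    order = np.argsort(-abs_obs, kind="stable")
    q = np.empty(len(abs_obs))
    fdr_desc = np.empty(len(abs_obs))
    for rank, idx in enumerate(order):
        theta = abs_obs[idx]
        n_null = len(null_sorted) - np.searchsorted(null_sorted, theta, side="left")
        n_obs = len(obs_sorted_asc) - np.searchsorted(
            obs_sorted_asc, theta, side="left"
        )
        fdr_desc[rank] = (n_null / k_pat) / n_obs
    # q at rank k = min FDR over this and all weaker thresholds
    suffix_min = np.minimum.accumulate(fdr_desc[::-1])[::-1]
    q[order] = np.minimum(suffix_min, 1.0)

    return pd.DataFrame(
        {
            "t_stat": t_obs,
            "q_value": q,
            "perm_p": perm_p,
            "zero_variance": ~np.isfinite(t_obs),
        },
        index=matrix.index,
    )


def unpaired_permutation_test(
    matrix: pd.DataFrame,
    config: MSConfig = MSConfig(),
    layout: dict | None = None,
) -> pd.DataFrame:
    """Two-sample (ignoring pairing) permutation test, for comparison with
    the paired design. Labels are permuted by exhaustive balanced splits of
    the 2n samples; q-values use the same SAM-style estimator."""
    if layout is None:
        layout = _condition_columns(matrix.columns)
    n = len(layout["pairs"])
    x = matrix[layout["WT"] + layout["7dG"]].to_numpy(dtype=float)
    m = 2 * n
    splits = [
        np.isin(np.arange(m), idx) for idx in itertools.combinations(range(m), n)
    ]
    t_cols = []
    for wt_mask in splits:
        a = x[:, wt_mask]
        b = x[:, ~wt_mask]
        diff = a.mean(axis=1) - b.mean(axis=1)
        sp = np.sqrt((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_cols.append(diff / (config.s0 + sp * np.sqrt(2.0 / n)))
    t_all = np.column_stack(t_cols)
    obs_idx = 0  # first split is WT columns in order
    t_obs = t_all[:, obs_idx]
    abs_obs = np.abs(t_obs)
    abs_null = np.abs(t_all)
    abs_null[np.isnan(abs_null)] = np.inf
    null_sorted = np.sort(abs_null.ravel())
    obs_sorted_asc = np.sort(abs_obs)
    order = np.argsort(-abs_obs, kind="stable")
    fdr_desc = np.empty(len(abs_obs))
    for rank, idx in enumerate(order):
        theta = abs_obs[idx]
        n_null = len(null_sorted) - np.searchsorted(null_sorted, theta, side="left")
        n_obs = len(obs_sorted_asc) - np.searchsorted(
            obs_sorted_asc, theta, side="left"
        )
        fdr_desc[rank] = (n_null / len(splits)) / n_obs
    suffix_min = np.minimum.accumulate(fdr_desc[::-1])[::-1]
    q = np.empty(len(abs_obs))
    q[order] = np.minimum(suffix_min, 1.0)
    return pd.DataFrame({"t_stat": t_obs, "q_value": q}, index=matrix.index)


def classify_binders(
    results: pd.DataFrame,
    config: MSConfig = MSConfig(),
    background_ids: set[str] | None = None,
) -> pd.Series:
    """Assign each protein to exactly one class.

    background list -> 'background'; significant (q <= cutoff) with linear
    WT/7dG ratio >= fold_cutoff -> 'RG4-BP'; significant with ratio <=
    1/fold_cutoff -> 'G-rich-BP'; everything else 'unclassified'.
    """
    background_ids = set(background_ids or ())
    log2_cut = np.log2(config.fold_cutoff)
    classes = []
    for pid, row in results.iterrows():
        if pid in background_ids:
            classes.append("background")
        elif row["q_value"] <= config.q_cutoff and row["log2_ratio"] >= log2_cut:
            classes.append("RG4-BP")
        elif row["q_value"] <= config.q_cutoff and row["log2_ratio"] <= -log2_cut:
            classes.append("G-rich-BP")
        else:
            classes.append("unclassified")
    return pd.Series(classes, index=results.index, name="class")


def run_differential(
    raw: pd.DataFrame,
    config: MSConfig = MSConfig(),
    background_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: preprocess -> impute -> paired permutation test ->
    classify. Returns the per-protein result table (excluded proteins
    appended with class 'excluded') and summary counts."""
    log2, excluded, layout = preprocess(raw, config)
    rng = np.random.default_rng(config.seed)
    imputed = impute_mnar(log2, config, rng)
    stats = paired_permutation_test(imputed, config, layout)

    n_valid_wt = log2[layout["WT"]].notna().sum(axis=1)
    n_valid_7dg = log2[layout["7dG"]].notna().sum(axis=1)
    ratio_imputed = imputed[layout["WT"]].mean(axis=1) - imputed[layout["7dG"]].mean(
        axis=1
    )
    ratio_observed = log2[layout["WT"]].mean(axis=1) - log2[layout["7dG"]].mean(axis=1)
    results = pd.DataFrame(
        {
            "log2_ratio": ratio_imputed if config.ratio_from_imputed else ratio_observed,
            "log2_ratio_observed": ratio_observed,
            "t_stat": stats["t_stat"],
            "q_value": stats["q_value"],
            "perm_p": stats["perm_p"],
            "zero_variance": stats["zero_variance"],
            "n_valid_wt": n_valid_wt,
            "n_valid_7dg": n_valid_7dg,
        }
    )
    results["class"] = classify_binders(results, config, background_ids)
    if len(excluded):
        pad = pd.DataFrame(index=excluded["protein_id"])
        pad["class"] = "excluded"
        results = pd.concat([results, pad])
    results.index.name = "protein_id"

    counts = results["class"].value_counts().to_dict()
    n_pairs = len(layout["pairs"])
    summary = {
        "n_input": int(len(raw)),
        "n_tested": int(len(stats)),
        "n_pairs": n_pairs,
        "n_significant": int(
            ((results["q_value"] <= config.q_cutoff) & results["q_value"].notna()).sum()
        ),
        "n_valid_all_replicates": int(
            ((n_valid_wt == n_pairs) & (n_valid_7dg == n_pairs)).sum()
        ),
        "class_counts": {c: int(counts.get(c, 0)) for c in CLASSES},
    }
    # classes must partition the table
    assert results["class"].isin(CLASSES).all()
    return results, summary
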