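"""Condition comparisons: net index changes, splice-site ratio shifts,
competing-site type I/II ratios, pair-type fractions, and regulated-exon
enrichment.

The experimental design is NT (untreated) vs KCl (depolarization) vs
KCl + 5-azaC, in triplicate; comparisons are run pairwise (KCl vs NT,
KCl+5azaC vs KCl). The headline statistic is the mean absolute net change
mean(|B - A|) over shared units, tested with a one-sample t-test against 0.
Because |delta| is nonnegative that t-test is anti-conservative, so a
replicate-label permutation baseline is reported alongside when
replicate-level values are available: replicate values are shuffled between
the two conditions within each unit and the mean |delta| recomputed, giving
an honest null for "is the shift larger than replicate noise".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "net_changes",
    "ss_ratios",
    "ratio_shift_filter",
    "competing_site_ratios",
    "rise_adjacent_enrichment",
    "pair_type_fractions",
]


def _condition_mean_frame(
    table: pd.DataFrame, id_col: str, value_col: str, replicate_col: str | None
) -> pd.DataFrame:
    if replicate_col is None:
        return table[[id_col, value_col]].set_index(id_col)[value_col].to_frame("mean")
    g = table.groupby(id_col)[value_col]
    return pd.DataFrame({"mean": g.mean(), "n_rep": g.size()})


def _replicate_matrix(
    table: pd.DataFrame, id_col: str, value_col: str, units: pd.Index
) -> np.ndarray | None:
    """Unit x replicate value matrix, or None if replicate counts are ragged."""
    counts = table.groupby(id_col)[value_col].size()
    if counts.reindex(units).isna().any() or counts.nunique() != 1:
        return None
    wide = table.sort_values(id_col).groupby(id_col)[value_col].apply(list)
    return np.array(wide.reindex(units).tolist(), dtype=float)


def net_changes(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    id_col: str = "unit_id",
    value_col: str = "value",
    replicate_col: str | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Per-unit net changes delta = B - A and the mean |delta| summary.

    ``table_a``/``table_b`` hold one condition each, as ``[id_col,
    value_col]`` rows — one row per unit, or one per (unit, replicate) when
    ``replicate_col`` names the replicate column (condition means are then
    taken per unit). Units are matched on ``id_col``; only shared units
    enter.

    Returns per-unit values, mean ± SEM of |delta|, the one-sample t-test of
    |delta| against 0, and — when replicate-level values were given — the
    replicate-permutation baseline p for mean |delta|.
    """
    mean_a = _condition_mean_frame(table_a, id_col, value_col, replicate_col)
    mean_b = _condition_mean_frame(table_b, id_col, value_col, replicate_col)
    shared = mean_a.index.intersection(mean_b.index)
    if len(shared) == 0:
        raise ValueError("no shared units between the two condition tables")
    a = mean_a.loc[shared, "mean"].to_numpy(float)
    b = mean_b.loc[shared, "mean"].to_numpy(float)
    delta = b - a
    abs_delta = np.abs(delta)
    units = pd.DataFrame(
        {
            id_col: shared,
            "value_a": a,
            "value_b": b,
            "delta": delta,
            "abs_delta": abs_delta,
        }
    )
    n = len(shared)
    mean_abs = float(abs_delta.mean())
    sem_abs = float(stats.sem(abs_delta)) if n >= 2 else np.nan
    if n >= 2 and abs_delta.std(ddof=1) > 0:
        t_stat, p_t = stats.ttest_1samp(abs_delta, 0.0)
        t_stat, p_t = float(t_stat), float(p_t)
    else:
        t_stat, p_t = np.nan, np.nan

    p_perm = None
    if replicate_col is not None:
        mat_a = _replicate_matrix(table_a, id_col, value_col, shared)
        mat_b = _replicate_matrix(table_b, id_col, value_col, shared)
        if mat_a is not None and mat_b is not None:
            p_perm = _permutation_baseline(mat_a, mat_b, mean_abs, n_perm, seed)
        else:
            logger.info("ragged replicate counts; permutation baseline skipped")
    return {
        "units": units,
        "n": n,
        "mean_abs_delta": mean_abs,
        "sem_abs_delta": sem_abs,
        "t_statistic": t_stat,
        "p_t_test": p_t,
        "p_permutation": p_perm,
    }


def _permutation_baseline(
    mat_a: np.ndarray, mat_b: np.ndarray, observed: float, n_perm: int, seed
) -> float:
    """Shuffle replicate values between conditions within each unit."""
    rng = np.random.default_rng(seed)
    ra = mat_a.shape[1]
    pooled = np.concatenate([mat_a, mat_b], axis=1)
    n_units, total = pooled.shape
    null = np.empty(n_perm)
    for i in range(n_perm):
        order = np.argsort(rng.random((n_units, total)), axis=1)
        perm = np.take_along_axis(pooled, order, axis=1)
        null[i] = np.abs(perm[:, ra:].mean(axis=1) - perm[:, :ra].mean(axis=1)).mean()
    return float((1 + int(np.sum(null >= observed))) / (1 + n_perm))


def ss_ratios(pairs: pd.DataFrame, condition: str) -> pd.DataFrame:
    """5'SS/3'SS index ratio per pair for one condition (both-detected only)."""
    sub = pairs[pairs[f"both_detected_{condition}"]]
    return pd.DataFrame(
        {
            "unit_id": sub["pair_id"].to_numpy(),
            "pair_type": sub["pair_type"].to_numpy(),
            "value": (
                sub[f"idx5_{condition}"] / sub[f"idx3_{condition}"]
            ).to_numpy(float),
        }
    )


def ratio_shift_filter(
    pairs: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    min_rel_change: float = 0.20,
) -> pd.DataFrame:
    """Pairs whose 5'SS/3'SS ratio moved by more than ``min_rel_change``
    of the ``cond_a`` ratio, in either direction.

    Pairs must be both-detected in both conditions; a pair with a zero
    ``cond_a`` ratio cannot define a relative change and is skipped (logged).
    """
    sub = pairs[
        pairs[f"both_detected_{cond_a}"] & pairs[f"both_detected_{cond_b}"]
    ].copy()
    ratio_a = sub[f"idx5_{cond_a}"] / sub[f"idx3_{cond_a}"]
    ratio_b = sub[f"idx5_{cond_b}"] / sub[f"idx3_{cond_b}"]
    zero = ratio_a == 0
    if zero.any():
        logger.info("%d pairs with zero %s ratio skipped", int(zero.sum()), cond_a)
        sub, ratio_a, ratio_b = sub[~zero], ratio_a[~zero], ratio_b[~zero]
    keep = (ratio_b - ratio_a).abs() > min_rel_change * ratio_a
    out = sub[keep].copy()
    out[f"ratio_{cond_a}"] = ratio_a[keep]
    out[f"ratio_{cond_b}"] = ratio_b[keep]
    out["rel_change"] = (ratio_b[keep] - ratio_a[keep]) / ratio_a[keep]
    return out


def competing_site_ratios(
    pairs: pd.DataFrame, conditions: list[str]
) -> pd.DataFrame:
    """Type I vs type II index ratios at competing splice sites.

    When a splice site belongs to both a type I and a type II pair, the two
    pairings compete: the shared site can pair with its same-intron partner
    (intron definition) or its cross-exon partner (exon definition). For a
    shared 5'SS the competing partners are the two 3'SSs and the statistic is
    I3'SS/II3'SS; for a shared 3'SS it is I5'SS/II5'SS. A shift of the ratio
    between conditions indicates redistribution of splicing-intermediate
    reads between the two definitions.

    Returns one row per mixed configuration with ``ratio_<cond>`` per
    condition (NaN when either pair is not both-detected there). Units whose
    denominator index is 0 in a condition are skipped for that condition.
    """
    type_i = pairs[pairs["pair_type"] == "I"]
    type_ii = pairs[pairs["pair_type"] == "II"]
    rows = []
    for shared_col, num_col, kind in (
        ("five_site_id", "idx3", "I3SS/II3SS"),
        ("three_site_id", "idx5", "I5SS/II5SS"),
    ):
        merged = type_i.merge(
            type_ii, on=shared_col, suffixes=("_I", "_II"), how="inner"
        )
        for r in merged.itertuples(index=False):
            d = r._asdict()
            row = {
                "unit_id": f"{d['pair_id_I']}~{d['pair_id_II']}",
                "kind": kind,
                "gene_id": d["gene_id_I"],
                "shared_site_id": d[shared_col],
            }
            for c in conditions:
                ok = d[f"both_detected_{c}_I"] and d[f"both_detected_{c}_II"]
                num = d[f"{num_col}_{c}_I"]
                den = d[f"{num_col}_{c}_II"]
                if ok and den == 0:
                    logger.info(
                        "unit %s: zero denominator index in %s; skipped",
                        row["unit_id"],
                        c,
                    )
                    ok = False
                row[f"ratio_{c}"] = num / den if ok else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def rise_adjacent_enrichment(
    usage_table: pd.DataFrame,
    rise_adjacent_exon_ids: dict[str, set],
    alpha: float = 0.05,
    tail: str = "upper",
    pvalue_col: str = "pvalue",
    feature_col: str = "featureID",
) -> pd.DataFrame:
    """Enrichment of condition-regulated exons among RISE-adjacent exons.

    The background rate is the fraction of all tested exons with usage
    p < ``alpha``. For each named exon set (typically per pair type), fold =
    set rate / background rate, and the p-value is the hypergeometric upper
    tail P(X >= k) with population N (all tested exons), K regulated among
    them, n drawn (set size), k regulated in the set. ``tail="density"``
    reports the point probability P(X = k) instead.
    """
    if tail not in ("upper", "density"):
        raise ValueError(f"unknown tail {tail!r}")
    tested = usage_table.dropna(subset=[pvalue_col])
    n_total = len(tested)
    regulated = set(tested.loc[tested[pvalue_col] < alpha, feature_col])
    background = len(regulated) / n_total if n_total else np.nan
    rows = []
    for name, ids in rise_adjacent_exon_ids.items():
        ids = set(ids) & set(tested[feature_col])
        n_set = len(ids)
        k = len(ids & regulated)
        if n_set == 0:
            rows.append(
                {
                    "set": name,
                    "n_set": 0,
                    "k_regulated": 0,
                    "rate": np.nan,
                    "background_rate": background,
                    "fold": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        rate = k / n_set
        if tail == "upper":
            p = float(stats.hypergeom.sf(k - 1, n_total, len(regulated), n_set))
        else:
            p = float(stats.hypergeom.pmf(k, n_total, len(regulated), n_set))
        rows.append(
            {
                "set": name,
                "n_set": n_set,
                "k_regulated": k,
                "rate": rate,
                "background_rate": background,
                "fold": rate / background if background else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def pair_type_fractions(pairs) -> dict:
    """Counts and percentages of type I vs type II pairs.

    Accepts the pairs DataFrame or a ``(count_I, count_II)`` tuple. Percent
    values are reported both at full precision and rounded to integer
    percent.
    """
    if isinstance(pairs, pd.DataFrame):
        count_i = int((pairs["pair_type"] == "I").sum())
        count_ii = int((pairs["pair_type"] == "II").sum())
    else:
        count_i, count_ii = int(pairs[0]), int(pairs[1])
    total = count_i + count_ii
    if total == 0:
        raise ValueError("no pairs to summarize")
    pct_i = 100.0 * count_i / total
    pct_ii = 100.0 * count_ii / total
    return {
        "count_I": count_i,
        "count_II": count_ii,
        "pct_I": pct_i,
        "pct_II": pct_ii,
        "pct_I_rounded": round(pct_i),
        "pct_II_rounded": round(pct_ii),
    }
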