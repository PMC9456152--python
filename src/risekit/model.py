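"""Model/results facade tying the RISE stages together.

:class:`RiseModel` is built from an annotation, per-(condition, replicate)
coverage tracks, and an optional exon-usage table; :meth:`RiseModel.fit`
runs index computation, pairing, correlation, and condition statistics and
returns a :class:`RiseResults` carrying every stage table plus a
``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, parse_gtf
from .condition import (
    competing_site_ratios,
    net_changes,
    pair_type_fractions,
    ss_ratios,
)
from .coverage import (
    CoverageTrack,
    RiseThresholds,
    compute_rise_indexes,
    condition_means,
)
from .pairing import classify_pairs, pair_correlation, permutation_null

__all__ = ["RiseModel", "RiseResults"]


class RiseModel:
    """Splicing-intermediate (RISE) analysis of one experiment.

    Parameters
    ----------
    annotation : GenomeAnnotation
    coverage : dict
        ``(condition, replicate) -> CoverageTrack``.
    usage_table : DataFrame, optional
        Differential-exon-usage table (groupID, featureID, exonBaseMean,
        pvalue, log2fold, usage_<condition> columns). When absent, exon base
        means fall back to coverage.
    thresholds : RiseThresholds
        Detection filters.
    """

    def __init__(
        self,
        annotation: GenomeAnnotation,
        coverage: dict[tuple[str, str], CoverageTrack],
        usage_table: pd.DataFrame | None = None,
        thresholds: RiseThresholds = RiseThresholds(),
    ):
        self.annotation = annotation
        self.coverage = coverage
        self.usage_table = usage_table
        self.thresholds = thresholds
        self.conditions = sorted({c for c, _ in coverage})

    @classmethod
    def from_files(
        cls,
        gtf: str,
        coverage_paths: dict[tuple[str, str], str],
        usage_tsv: str | None = None,
        thresholds: RiseThresholds = RiseThresholds(),
        **coverage_kwargs,
    ) -> "RiseModel":
        from .coverage import per_base_coverage

        annotation = parse_gtf(gtf)
        coverage = {
            key: per_base_coverage(path, contig_lengths=annotation.contigs, **coverage_kwargs)
            for key, path in coverage_paths.items()
        }
        usage = pd.read_csv(usage_tsv, sep="\t") if usage_tsv else None
        return cls(annotation, coverage, usage, thresholds)

    @classmethod
    def from_simulation(cls, config=None, seed: int | None = None):
        """Simulate an experiment and return ``(model, truth)``."""
        from .simulate import SimConfig, simulate_coverage, simulate_site_delays, simulate_annotation

        config = config or SimConfig()
        base = config.seed if seed is None else seed
        annotation, _genome = simulate_annotation(config, seed=base)
        truth = simulate_site_delays(config, annotation, seed=base + 1)
        coverage, usage = simulate_coverage(truth, annotation, config, seed=base + 2)
        return cls(annotation, coverage, usage), truth

    def fit(self, permutation: bool = False, n_perm: int = 999, seed: int | None = None) -> "RiseResults":
        """Run the full analysis.

        ``permutation=True`` additionally computes the global randomization
        null for each pair type in each condition (slower).
        """
        replicate_table = compute_rise_indexes(
            self.annotation, self.coverage, self.usage_table, self.thresholds
        )
        sites = condition_means(replicate_table, self.thresholds)
        pairs, site_classes = classify_pairs(sites, self.annotation)

        correlations: dict = {}
        nulls: dict = {}
        for cond in self.conditions:
            for ptype in ("I", "II"):
                if pairs.empty:
                    continue
                sub = pairs[pairs["pair_type"] == ptype]
                if int(sub[f"both_detected_{cond}"].sum()) < 3:
                    continue
                correlations[(ptype, cond)] = pair_correlation(
                    pairs, cond, pair_type=ptype
                )
                if permutation:
                    nulls[(ptype, cond)] = permutation_null(
                        pairs, cond, scope="global", n_perm=n_perm, seed=seed,
                        pair_type=ptype,
                    )

        fractions = pair_type_fractions(pairs) if not pairs.empty else None

        # canonical ordering NT -> KCl -> KCl+5azaC when those labels exist,
        # otherwise adjacent pairs in sorted label order
        ordered = [c for c in ("NT", "KCl", "KCl_5azaC") if c in self.conditions]
        if len(ordered) < 2:
            ordered = self.conditions
        comparisons: dict = {}
        for cond_a, cond_b in zip(ordered, ordered[1:]):
            comparisons[(cond_a, cond_b)] = self._compare(
                replicate_table, sites, pairs, cond_a, cond_b, n_perm, seed
            )

        competing = (
            competing_site_ratios(pairs, self.conditions) if not pairs.empty else pd.DataFrame()
        )

        return RiseResults(
            model=self,
            replicate_table=replicate_table,
            sites=sites,
            pairs=pairs,
            site_classes=site_classes,
            correlations=correlations,
            permutation_nulls=nulls,
            fractions=fractions,
            comparisons=comparisons,
            competing=competing,
        )

    def _compare(self, replicate_table, sites, pairs, cond_a, cond_b, n_perm, seed):
        det = sites[sites["detected"]]
        shared = set(det.loc[det["condition"] == cond_a, "site_id"]) & set(
            det.loc[det["condition"] == cond_b, "site_id"]
        )
        out: dict = {"n_shared_sites": len(shared)}
        if shared:
            rt = replicate_table[replicate_table["site_id"].isin(shared)]
            out["site_index"] = net_changes(
                rt[rt["condition"] == cond_a],
                rt[rt["condition"] == cond_b],
                id_col="site_id",
                value_col="index",
                replicate_col="replicate",
                n_perm=n_perm,
                seed=seed,
            )
        if not pairs.empty:
            ra = ss_ratios(pairs, cond_a)
            rb = ss_ratios(pairs, cond_b)
            common = set(ra["unit_id"]) & set(rb["unit_id"])
            if common:
                out["ss_ratio"] = net_changes(
                    ra[ra["unit_id"].isin(common)],
                    rb[rb["unit_id"].isin(common)],
                    id_col="unit_id",
                    value_col="value",
                )
        return out


@dataclass
class RiseResults:
    """Fitted RISE analysis: stage tables, statistics, and a text summary."""

    model: RiseModel
    replicate_table: pd.DataFrame
    sites: pd.DataFrame
    pairs: pd.DataFrame
    site_classes: pd.DataFrame
    correlations: dict
    permutation_nulls: dict
    fractions: dict | None
    comparisons: dict
    competing: pd.DataFrame
    extras: dict = dataclass_field(default_factory=dict)

    @property
    def n_detected(self) -> int:
        return int(self.sites["detected"].sum()) if len(self.sites) else 0

    def detected_sites(self, condition: str) -> pd.DataFrame:
        return self.sites[(self.sites["condition"] == condition) & self.sites["detected"]]

    def summary(self) -> str:
        lines = ["RISE analysis summary", "=" * 21, ""]
        lines.append(f"Conditions: {', '.join(self.model.conditions)}")
        lines.append(f"Detected (site, condition) records: {self.n_detected}")
        if self.fractions:
            f = self.fractions
            lines.append(
                f"Pairs: {f['count_I']} type I ({f['pct_I_rounded']}%), "
                f"{f['count_II']} type II ({f['pct_II_rounded']}%)"
            )
        if self.correlations:
            lines.append("")
            lines.append("Paired-index correlations (log10, Pearson r):")
            for (ptype, cond), res in sorted(self.correlations.items()):
                line = f"  type {ptype:2s} {cond:10s} r = {res['r']:+.3f} (n = {res['n']})"
                null = self.permutation_nulls.get((ptype, cond))
                if null:
                    line += (
                        f"  [null mean r = {null['null_mean_r']:+.3f}, "
                        f"p = {null['p_value']:.4g}]"
                    )
                lines.append(line)
        for (a, b), comp in self.comparisons.items():
            lines.append("")
            lines.append(f"Condition comparison {b} vs {a}:")
            for unit in ("site_index", "ss_ratio"):
                if unit in comp:
                    s = comp[unit]
                    line = (
                        f"  {unit:10s} mean |delta| = {s['mean_abs_delta']:.4f} "
                        f"+/- {s['sem_abs_delta']:.4f} (n = {s['n']}), "
                        f"one-sample t p = {s['p_t_test']:.3g}"
                    )
                    if s.get("p_permutation") is not None:
                        line += f", permutation baseline p = {s['p_permutation']:.3g}"
                    lines.append(line)
        if len(self.competing):
            lines.append("")
            lines.append(f"Competing-site (mixed I/II) configurations: {len(self.competing)}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<RiseResults: {self.n_detected} detected site-conditions, "
            f"{len(self.pairs)} pairs>"
        )
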