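"""Library normalization, NB differential expression, and the multi-omic
integration that defines Tet target genes.

The differential stage fits, per gene, a negative-binomial model with a
method-of-moments dispersion shrunk toward a fitted mean-dispersion
trend, and tests the log2 fold change with a Wald statistic. A gene is
called changed when |fold change| >= 2 and the Benjamini-Hochberg
adjusted p-value is < 0.05.

Integration intersects four gene sets: bound (Tet ChIP consensus),
modified (>= 1 5hmrC peak), reduced (>= 1 Tet-null-reduced peak) and the
differential calls; the target list is bound AND modified AND reduced AND
expression-unchanged genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import CountMatrix, ValidationError


@dataclass
class DEConfig:
    fold_change_threshold: float = 2.0  # two-sided: fc >= 2 or <= -2
    adj_p_threshold: float = 0.05
    min_mean_count: float = 0.0

    def __post_init__(self):
        if self.fold_change_threshold <= 0 or self.adj_p_threshold <= 0:
            raise ValidationError("thresholds must be > 0")


@dataclass
class DEResult:
    table: pd.DataFrame  # gene_id, base_mean, log2fc, stat, pvalue, padj, direction
    excluded: list[str]  # all-zero (or below min mean) genes
    conditions: tuple[str, str]

    def genes(self, direction: str) -> set[str]:
        t = self.table
        return set(t.loc[t["direction"] == direction, "gene_id"])


def normalize_counts(m: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Scale every sample to the mean library total.

    size factor s_j = mean_total / total_j; returns (scaled matrix,
    size factors). Scaled counts are floats stored in the same container.
    """
    totals = m.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = [m.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValidationError(f"zero-total sample(s): {bad}")
    target = totals.mean()
    factors = target / totals
    scaled = CountMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        conditions=list(m.conditions),
        counts=np.zeros_like(m.counts),
    )
    scaled.counts = m.counts * factors  # bypass int validation deliberately
    return scaled, factors


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu on genes with a positive raw estimate and
    return the trend values (floored at a small positive constant)."""
    ok = (alpha > 0) & (mu > 0)
    if ok.sum() < 10:
        base = float(np.median(alpha[ok])) if ok.any() else 0.01
        return np.full_like(mu, max(base, 1e-4))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    trend = coef[0] + coef[1] / np.maximum(mu, 1e-9)
    return np.maximum(trend, 1e-4)


def differential_expression(
    m: CountMatrix,
    config: Optional[DEConfig] = None,
    condition_pair: Optional[tuple[str, str]] = None,
) -> DEResult:
    """NB-Wald differential expression between two conditions.

    ``condition_pair`` = (reference, treatment); defaults to the first two
    distinct condition labels in sample order. log2fc > 0 means higher in
    the treatment. Genes with zero counts everywhere are excluded and
    reported.
    """
    config = config or DEConfig()
    conds = list(dict.fromkeys(m.conditions))
    if condition_pair is None:
        if len(conds) < 2:
            raise ValidationError("need two conditions")
        condition_pair = (conds[0], conds[1])
    ref, trt = condition_pair
    i_ref = [i for i, c in enumerate(m.conditions) if c == ref]
    i_trt = [i for i, c in enumerate(m.conditions) if c == trt]
    if len(i_ref) < 2 or len(i_trt) < 2:
        raise ValidationError("need >= 2 replicates per condition")

    norm, _ = normalize_counts(m)
    counts = np.asarray(norm.counts, dtype=float)
    a = counts[:, i_ref]
    b = counts[:, i_trt]
    keep = (a.sum(axis=1) + b.sum(axis=1)) > 0
    keep &= (np.concatenate([a, b], axis=1).mean(axis=1) >= config.min_mean_count)
    excluded = [g for g, k in zip(m.gene_ids, keep) if not k]
    a, b = a[keep], b[keep]
    genes = [g for g, k in zip(m.gene_ids, keep) if k]

    n1, n2 = a.shape[1], b.shape[1]
    mu1, mu2 = a.mean(axis=1), b.mean(axis=1)
    mu = (mu1 * n1 + mu2 * n2) / (n1 + n2)

    # method-of-moments dispersion from within-condition variance:
    # Var = mu + alpha mu^2  =>  alpha = (Var - mu) / mu^2
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    pooled_var = (v1 * (n1 - 1) + v2 * (n2 - 1)) / (n1 + n2 - 2)
    raw_alpha = (pooled_var - mu) / np.maximum(mu, 1e-9) ** 2
    trend = _dispersion_trend(mu, raw_alpha)
    # shrink the noisy per-gene estimate toward the trend
    alpha = np.maximum(0.25 * np.maximum(raw_alpha, 0.0) + 0.75 * trend, 1e-6)

    eps = 0.5
    lfc = np.log2((mu2 + eps) / (mu1 + eps))
    # delta method: Var(log2 mean) = (1/mu + alpha) / (n ln2^2)
    ln2sq = np.log(2.0) ** 2
    var_lfc = (
        (1.0 / np.maximum(mu1, eps) + alpha) / (n1 * ln2sq)
        + (1.0 / np.maximum(mu2, eps) + alpha) / (n2 * ln2sq)
    )
    stat = lfc / np.sqrt(var_lfc)
    pv = 2.0 * stats.norm.sf(np.abs(stat))
    padj = stats.false_discovery_control(pv, method="bh")

    lfc_thr = np.log2(config.fold_change_threshold)
    direction = np.where(
        (padj < config.adj_p_threshold) & (lfc >= lfc_thr),
        "up",
        np.where(
            (padj < config.adj_p_threshold) & (lfc <= -lfc_thr), "down", "unchanged"
        ),
    )
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": mu,
            "log2fc": lfc,
            "stat": stat,
            "pvalue": pv,
            "padj": padj,
            "direction": direction,
        }
    )
    return DEResult(table=table, excluded=excluded, conditions=(ref, trt))


@dataclass
class GeneSets:
    bound: set[str]
    modified: set[str]
    reduced: set[str]
    up: set[str]
    down: set[str]
    unresolved: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "bound": self.bound,
            "modified": self.modified,
            "reduced": self.reduced,
            "up": self.up,
            "down": self.down,
        }


def build_gene_sets(
    bound_genes: Sequence[str],
    modified_transcripts: Sequence[str],
    reduced_transcripts: Sequence[str],
    de: Optional[DEResult],
    gene_map: Mapping[str, str],
) -> GeneSets:
    """Resolve transcript/gene ids through ``gene_map`` (transcript id ->
    gene id; gene ids map to themselves) into the four integration sets.
    Unresolvable ids are collected, not dropped silently."""
    values = list(gene_map.values())
    if len(set(gene_map.keys())) != len(gene_map):
        raise ValidationError("duplicate ids in gene_map")
    known_genes = set(values)

    unresolved: set[str] = set()

    def resolve(ids: Sequence[str]) -> set[str]:
        out = set()
        for i in ids:
            if i in gene_map:
                out.add(gene_map[i])
            elif i in known_genes:
                out.add(i)
            else:
                unresolved.add(i)
        return out

    return GeneSets(
        bound=resolve(bound_genes),
        modified=resolve(modified_transcripts),
        reduced=resolve(reduced_transcripts),
        up=de.genes("up") if de else set(),
        down=de.genes("down") if de else set(),
        unresolved=unresolved,
    )


@dataclass
class IntegrationReport:
    sets: dict[str, set[str]]
    pairwise: pd.DataFrame  # set_a, set_b, n_a, n_b, n_intersection, fraction_of_a
    targets: pd.DataFrame  # gene-level evidence table
    cross_stage: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "sets": {k: sorted(v) for k, v in sorted(self.sets.items())},
            "pairwise": self.pairwise.to_dict(orient="records"),
            "targets": sorted(self.targets["gene_id"]),
            "cross_stage": self.cross_stage,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def integration_report(
    sets: GeneSets,
    cross_stage_sets: Optional[Mapping[str, set[str]]] = None,
    evidence: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> IntegrationReport:
    """All pairwise intersection fractions plus the final target list:
    bound AND modified AND reduced AND not differentially expressed."""
    d = sets.as_dict()
    names = sorted(d)
    rows = []
    for a in names:
        for b in names:
            if a >= b:
                continue
            inter = d[a] & d[b]
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "n_a": len(d[a]),
                    "n_b": len(d[b]),
                    "n_intersection": len(inter),
                    "fraction_of_a": (len(inter) / len(d[a])) if d[a] else 0.0,
                }
            )
    pairwise = pd.DataFrame(rows)

    changed = sets.up | sets.down
    target_genes = sorted((sets.bound & sets.modified & sets.reduced) - changed)
    ev_rows = []
    for g in target_genes:
        row = {
            "gene_id": g,
            "bound": True,
            "modified": True,
            "reduced": True,
            "de_direction": "unchanged",
        }
        if evidence and g in evidence:
            row.update(evidence[g])
        ev_rows.append(row)
    targets = pd.DataFrame(
        ev_rows,
        columns=["gene_id", "bound", "modified", "reduced", "de_direction"]
        if not ev_rows
        else None,
    )

    cross: dict[str, float] = {}
    if cross_stage_sets:
        for name, other in sorted(cross_stage_sets.items()):
            base = d.get("bound", set())
            cross[name] = (len(base & other) / len(base)) if base else 0.0
    return IntegrationReport(sets=d, pairwise=pairwise, targets=targets, cross_stage=cross)


def write_report(report: IntegrationReport, tsv_path, json_path) -> None:
    report.pairwise.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        fh.write(report.to_json() + "\n")
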