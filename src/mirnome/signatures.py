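"""Signature overlap and GSEA-style enrichment between comparisons.

Two differential signatures (up/down miRNA sets from two condition
contrasts) are compared by exact set overlap, reported as a percentage of
the first set, and by a classic unweighted Kolmogorov-Smirnov running-sum
enrichment of one signature's members in the other's fold-change ranking.
Significance comes from a gene-set permutation null: random id sets of the
same size drawn from the ranking, with the standard add-one permutation
p-value. No replicate phenotypes exist in this design, so phenotype
permutation is not an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Signature:
    label: str
    up_set: frozenset
    down_set: frozenset
    fold_by_id: dict

    def __post_init__(self):
        if self.up_set & self.down_set:
            raise ValueError("up and down sets overlap")
        missing = (self.up_set | self.down_set) - set(self.fold_by_id)
        if missing:
            raise ValueError(f"signature members without fold values: {missing}")


@dataclass(frozen=True)
class OverlapResult:
    size_a: int
    size_b: int
    intersection: int
    percent_of_a: float


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    p_value: float
    n_permutations: int
    seed: int


def overlap(set_a, set_b) -> OverlapResult:
    """Exact intersection size, as a percentage of ``set_a``."""
    set_a, set_b = set(set_a), set(set_b)
    if not set_a:
        raise ValueError("set_a is empty; percentage undefined")
    inter = len(set_a & set_b)
    return OverlapResult(len(set_a), len(set_b), inter, 100.0 * inter / len(set_a))


def overlap_from_counts(size_a: int, intersection: int) -> float:
    """Percentage 100 * intersection / size_a for externally reported counts."""
    if size_a <= 0:
        raise ValueError("set size must be positive")
    if intersection > size_a:
        raise ValueError("intersection exceeds set size")
    return 100.0 * intersection / size_a


def _running_es(hits: np.ndarray) -> float:
    """Signed maximum deviation of the unweighted KS running sum."""
    n_hit = int(hits.sum())
    n_miss = hits.size - n_hit
    steps = np.where(hits, 1.0 / n_hit, -1.0 / n_miss)
    path = np.cumsum(steps)
    k = int(np.argmax(np.abs(path)))
    return float(path[k])


def gsea_enrichment(
    ranked_ids: list,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Unweighted KS enrichment of ``gene_set`` in ``ranked_ids``.

    ``ranked_ids`` must be ordered by descending ranking metric (e.g. log
    fold change). ES is the signed maximum deviation of cumulative hit
    fraction minus cumulative miss fraction; p is the add-one two-sided
    permutation p-value over uniformly drawn random sets of the same size.
    """
    gene_set = set(gene_set)
    n = len(ranked_ids)
    if not gene_set:
        raise ValueError("gene set is empty")
    if not gene_set < set(ranked_ids):
        raise ValueError("gene set must be a proper subset of the ranking")
    hits = np.array([rid in gene_set for rid in ranked_ids], dtype=bool)
    es = _running_es(hits)
    k = int(hits.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        if abs(_running_es(perm)) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return EnrichmentResult(es, p, n_perm, seed)


def rank_by_fold(fold_by_id: dict) -> list:
    """Ids ordered by descending fold change, ties broken by id."""
    return [k for k, _ in sorted(fold_by_id.items(), key=lambda kv: (-kv[1], kv[0]))]


def signature_report(
    signatures: list[Signature],
    overlaps: dict[str, OverlapResult],
    enrichments: dict[str, EnrichmentResult],
    novel_summary: dict | None = None,
) -> dict:
    """Headline JSON document: per-comparison counts, overlap percentages
    (rounded to 1 decimal for display, raw retained), ES/p, and novel
    candidate tallies."""
    novel_summary = novel_summary or {}
    return {
        "signatures": {
            s.label: {"n_up": len(s.up_set), "n_down": len(s.down_set)}
            for s in signatures
        },
        "overlaps": {
            label: {
                "size_a": o.size_a,
                "size_b": o.size_b,
                "intersection": o.intersection,
                "percent_of_a": o.percent_of_a,
                "percent_of_a_display": round(o.percent_of_a, 1),
            }
            for label, o in overlaps.items()
        },
        "enrichments": {
            label: {
                "es": e.es,
                "p_value": e.p_value,
                "n_permutations": e.n_permutations,
                "seed": e.seed,
            }
            for label, e in enrichments.items()
        },
        "novel": {
            "n_candidates": int(novel_summary.get("n_candidates", 0)),
            "n_consensus": int(novel_summary.get("n_consensus", 0)),
            "n_ago_verified": int(novel_summary.get("n_ago_verified", 0)),
        },
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
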