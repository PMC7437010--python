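"""Selection classification, cross-condition set overlaps, and enrichment.

Between two timepoints of a condition a mutant is called

* ``lost``      - final count below the loss threshold (default 10), the
                  detection floor of the assay, regardless of trend;
* ``depleted``  - still detected but its relative abundance dropped by at
                  least ``depletion_fraction`` (default 50%);
* ``enriched``  - relative abundance rose by at least ``enrichment_fold``
                  (default 2x);
* ``retained``  - everything else.

Gene lists from these calls feed a full inclusion-exclusion (Venn) partition
across conditions and an upper-tail hypergeometric term-enrichment test with
Benjamini-Hochberg FDR control. The enrichment background defaults to the
post-filter gene universe — the genes the experiment could actually have
observed — rather than a whole genome, to avoid detection-bias inflation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .barcode_quant import AbundanceTable, CountTable

STATUSES = ("lost", "depleted", "enriched", "retained")


@dataclass(frozen=True)
class SelectionCall:
    gene: str
    condition: str
    window: tuple[float, float]
    status: str
    count_from: int
    count_to: int
    ab_from: float
    ab_to: float
    fold_change: float


@dataclass(frozen=True)
class SetComparison:
    """One region of the inclusion-exclusion partition across conditions."""

    conditions: tuple[str, ...]
    genes: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationMap:
    """Local gene -> term annotation with an explicit background universe."""

    term_descriptions: dict[str, str]
    gene_terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        outside = set(self.gene_terms) - set(self.background)
        if outside:
            raise ValueError(
                f"annotated genes not in background: {sorted(outside)[:5]}"
            )

    def genes_for(self, term: str) -> frozenset[str]:
        return frozenset(
            g for g, terms in self.gene_terms.items() if term in terms
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, background: Iterable[str] | None = None
    ) -> "AnnotationMap":
        """Columns ``gene``, ``term`` and optionally ``description``."""
        frame = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene", "term"} - set(frame.columns)
        if required:
            raise ValueError(f"annotation TSV missing columns {sorted(required)}")
        descriptions: dict[str, str] = {}
        gene_terms: dict[str, set[str]] = {}
        for _, row in frame.iterrows():
            gene_terms.setdefault(str(row["gene"]), set()).add(str(row["term"]))
            if "description" in frame.columns and pd.notna(row.get("description")):
                descriptions[str(row["term"])] = str(row["description"])
        bg = frozenset(background) if background is not None else frozenset(gene_terms)
        return cls(
            term_descriptions=descriptions,
            gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
            background=bg,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    k: int  # hits in list
    n_list: int
    K: int  # hits in background
    N: int  # background size
    fold_enrichment: float
    p: float
    q: float


def _sample_at(table_meta: pd.DataFrame, condition: str, time_h: float) -> str:
    mask = (table_meta["condition"] == condition) & np.isclose(
        table_meta["time_h"].astype(float), time_h
    )
    hits = list(table_meta.index[mask])
    if not hits:
        raise KeyError(f"no sample for condition {condition!r} at {time_h} h")
    if len(hits) > 1:
        raise ValueError(
            f"ambiguous samples for {condition!r} at {time_h} h: {hits}"
        )
    return hits[0]


def classify_selection(
    counts: CountTable,
    abundances: AbundanceTable,
    condition: str,
    t_from: float,
    t_to: float,
    loss_threshold: int = 10,
    depletion_fraction: float = 0.5,
    enrichment_fold: float = 2.0,
) -> list[SelectionCall]:
    """Classify every gene between two timepoints of one condition.

    Statuses are mutually exclusive and exhaustive; the loss rule takes
    precedence over the abundance rules because a count under the detection
    floor carries no reliable abundance information.
    """
    if counts.genes != abundances.genes:
        raise ValueError("count and abundance tables must share the gene universe")
    sid_from = _sample_at(counts.meta, condition, t_from)
    sid_to = _sample_at(counts.meta, condition, t_to)
    c_from = counts.counts.loc[sid_from]
    c_to = counts.counts.loc[sid_to]
    a_from = abundances.abundance.loc[sid_from]
    a_to = abundances.abundance.loc[sid_to]

    calls: list[SelectionCall] = []
    for gene in counts.genes:
        af, at = float(a_from[gene]), float(a_to[gene])
        ct = int(c_to[gene])
        if ct < loss_threshold:
            status = "lost"
        elif at <= (1.0 - depletion_fraction) * af:
            status = "depleted"
        elif at >= enrichment_fold * af:
            status = "enriched"
        else:
            status = "retained"
        calls.append(
            SelectionCall(
                gene=gene,
                condition=condition,
                window=(float(t_from), float(t_to)),
                status=status,
                count_from=int(c_from[gene]),
                count_to=ct,
                ab_from=af,
                ab_to=at,
                fold_change=at / af,
            )
        )
    return calls


def calls_frame(calls: list[SelectionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "condition": [c.condition for c in calls],
            "t_from_h": [c.window[0] for c in calls],
            "t_to_h": [c.window[1] for c in calls],
            "status": [c.status for c in calls],
            "count_from": [c.count_from for c in calls],
            "count_to": [c.count_to for c in calls],
            "ab_from": [c.ab_from for c in calls],
            "ab_to": [c.ab_to for c in calls],
            "fold_change": [c.fold_change for c in calls],
        }
    )


def compare_conditions(
    calls_by_condition: Mapping[str, Iterable[SelectionCall] | Iterable[str]],
    statuses: Sequence[str] = ("lost", "depleted"),
) -> list[SetComparison]:
    """Full inclusion-exclusion partition of per-condition gene sets.

    Accepts per-condition lists of :class:`SelectionCall` (filtered to the
    requested statuses, with a shared-universe check) or plain gene
    collections. Returns all ``2^c - 1`` regions, empty ones included; the
    region sizes sum to the size of the union.
    """
    conditions = list(calls_by_condition)
    if len(conditions) < 2:
        raise ValueError("need >=2 conditions to compare")
    sets: dict[str, frozenset[str]] = {}
    universes: dict[str, frozenset[str]] = {}
    for cond, items in calls_by_condition.items():
        items = list(items)
        if items and isinstance(items[0], SelectionCall):
            universes[cond] = frozenset(c.gene for c in items)
            sets[cond] = frozenset(
                c.gene for c in items if c.status in statuses
            )
        else:
            sets[cond] = frozenset(items)  # type: ignore[arg-type]
    if universes and len(set(universes.values())) > 1:
        raise ValueError("mismatched gene universes across conditions")

    regions: list[SetComparison] = []
    for r in range(1, len(conditions) + 1):
        for subset in itertools.combinations(conditions, r):
            inside = frozenset.intersection(*(sets[c] for c in subset))
            outside = frozenset().union(
                *(sets[c] for c in conditions if c not in subset)
            )
            regions.append(
                SetComparison(conditions=subset, genes=inside - outside)
            )
    return regions


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` over the sorted p-values, capped
    at 1. Order-preserving: ties and the original ordering are respected.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_enrichment(
    gene_list: Iterable[str], annotation: AnnotationMap
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric term enrichment with BH correction.

    For each annotation term with at least one hit in the list,
    ``p = sum_{i >= k} C(K, i) C(N - K, n - i) / C(N, n)`` where N is the
    background size, K the term's background hits, n the list size and k the
    list hits; ``fold = (k / n) / (K / N)``. q-values are BH-adjusted across
    the tested terms only, and results are sorted by (q, p, term).
    """
    genes = frozenset(gene_list)
    if not genes:
        raise ValueError("gene list is empty")
    offenders = genes - annotation.background
    if offenders:
        raise ValueError(
            f"genes absent from the background: {sorted(offenders)}"
        )
    N = len(annotation.background)
    n = len(genes)
    terms: dict[str, tuple[int, int]] = {}
    for term in {t for g in annotation.gene_terms.values() for t in g}:
        member = annotation.genes_for(term)
        k = len(member & genes)
        if k >= 1:
            terms[term] = (k, len(member))
    if not terms:
        return []
    names = sorted(terms)
    ps = [
        float(hypergeom.sf(terms[t][0] - 1, N, terms[t][1], n)) for t in names
    ]
    qs = bh_adjust(ps)
    results = [
        EnrichmentResult(
            term=t,
            description=annotation.term_descriptions.get(t, ""),
            k=terms[t][0],
            n_list=n,
            K=terms[t][1],
            N=N,
            fold_enrichment=(terms[t][0] / n) / (terms[t][1] / N),
            p=p,
            q=float(q),
        )
        for t, p, q in zip(names, ps, qs)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "description": [r.description for r in results],
            "k": [r.k for r in results],
            "n_list": [r.n_list for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
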