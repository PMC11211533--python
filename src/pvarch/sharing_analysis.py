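"""Allele-sharing analysis: direct cohort comparison and the ancient-intermediate
three-way classification.

The classification interprets each pathogenic variant observed in ancient
(Eurasian, hence post-out-of-Africa) genomes by its presence in the two
modern cohorts: presence in non-African but absence in African marks a
variant that most plausibly arose after the out-of-Africa migration, while
presence in both (or in African only) marks an older, ancestral origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .catalog_io import GeneCatalog
from .errors import ValidationError
from .pv_extraction import PopulationPVDataset, PVRecord, round_half_up

logger = logging.getLogger(__name__)


class SharingPattern(Enum):
    """Three-way sharing of an ancient variant against the modern cohorts.

    UNSHARED covers ancient variants found in neither modern cohort; they
    are retained in outputs even where headline percentages are computed
    over the shared subset only.
    """

    AFRICAN_ONLY = "AFRICAN_ONLY"
    BOTH = "BOTH"
    NONAFRICAN_ONLY = "NONAFRICAN_ONLY"
    UNSHARED = "UNSHARED"


@dataclass
class ComparisonPartition:
    """Set-algebra partition of two variant-key sets with headline percents."""

    a_only: set
    shared: set
    b_only: set
    percentages: dict[str, float]

    @property
    def counts(self) -> dict[str, int]:
        return {"a_only": len(self.a_only), "shared": len(self.shared),
                "b_only": len(self.b_only)}


def direct_compare(set_a: Iterable[Hashable], set_b: Iterable[Hashable]
                   ) -> ComparisonPartition:
    """Partition two cohort variant-key sets into private and shared parts.

    The reported percentages are the fraction of each side NOT shared with
    the other (one decimal, half-up) — the quantity used to argue that most
    non-African variants are absent from African.
    """
    a, b = set(set_a), set(set_b)
    shared = a & b
    a_only, b_only = a - shared, b - shared
    pct = {
        "a_not_shared": round_half_up(100.0 * len(a_only) / len(a)) if a else 0.0,
        "b_not_shared": round_half_up(100.0 * len(b_only) / len(b)) if b else 0.0,
    }
    return ComparisonPartition(a_only=a_only, shared=shared, b_only=b_only,
                               percentages=pct)


def classify_with_ancient(ancient: Iterable[Hashable],
                          african: Iterable[Hashable],
                          nonafrican: Iterable[Hashable]
                          ) -> dict[Hashable, SharingPattern]:
    """Classify every ancient variant key by modern-cohort membership.

    Pure function of membership: AFRICAN_ONLY iff present in African and
    absent from non-African; BOTH iff in both; NONAFRICAN_ONLY iff only in
    non-African; UNSHARED iff in neither.
    """
    afr, nonafr = set(african), set(nonafrican)
    out: dict[Hashable, SharingPattern] = {}
    for key in ancient:
        in_a, in_n = key in afr, key in nonafr
        if in_a and in_n:
            out[key] = SharingPattern.BOTH
        elif in_a:
            out[key] = SharingPattern.AFRICAN_ONLY
        elif in_n:
            out[key] = SharingPattern.NONAFRICAN_ONLY
        else:
            out[key] = SharingPattern.UNSHARED
    return out


def pattern_summary(patterns: Mapping[Hashable, SharingPattern],
                    gene_of: Optional[Mapping[Hashable, str]] = None
                    ) -> dict:
    """Counts and percentages per sharing pattern, overall and per gene.

    Two percentage bases are reported: over all classified variants, and
    over the shared subset (UNSHARED excluded) — the latter is the basis
    headline sharing figures use. When nothing is shared the shared-basis
    percents are absent (None).
    """
    counts = {p: 0 for p in SharingPattern}
    for p in patterns.values():
        counts[p] += 1
    total = len(patterns)
    n_shared = total - counts[SharingPattern.UNSHARED]
    pct_all = {p: round_half_up(100.0 * n / total) if total else 0.0
               for p, n in counts.items()}
    pct_shared = {
        p: (round_half_up(100.0 * counts[p] / n_shared) if n_shared else None)
        for p in SharingPattern if p is not SharingPattern.UNSHARED
    }
    per_gene: dict[str, dict[SharingPattern, int]] = {}
    if gene_of is not None:
        for key, p in patterns.items():
            gene = gene_of.get(key, "?")
            per_gene.setdefault(gene, {q: 0 for q in SharingPattern})[p] += 1
    return {"counts": counts, "total": total, "n_shared": n_shared,
            "percent_all": pct_all, "percent_shared": pct_shared,
            "per_gene": per_gene}


def shared_fraction(n_shared: int, n_group: int) -> int:
    """Whole-percent fraction of a group's variants shared with another group."""
    if n_group <= 0:
        raise ValueError("n_group must be positive")
    if not 0 <= n_shared <= n_group:
        raise ValueError("need 0 <= n_shared <= n_group")
    return int(round_half_up(100.0 * n_shared / n_group, 0))


def gene_pathway_tally(dataset: PopulationPVDataset, catalog: GeneCatalog
                       ) -> pd.DataFrame:
    """Per-pathway summary: total genes, genes with >=1 PV (with percent), PV count.

    A PV in a gene belonging to several pathways is counted in each of
    them; the totals row counts distinct genes and distinct PVs once.
    """
    for pv in dataset.pvs:
        if pv.gene not in catalog:
            raise ValidationError(f"PV gene {pv.gene} absent from catalog")
    genes_hit: dict[str, set[str]] = {pw: set() for pw in catalog.pathways}
    pv_count: dict[str, int] = {pw: 0 for pw in catalog.pathways}
    for pv in dataset.pvs:
        for pw in catalog[pv.gene].pathways:
            genes_hit[pw].add(pv.gene)
            pv_count[pw] += 1
    rows = []
    for pw in sorted(catalog.pathways):
        n_genes = len(catalog.pathways[pw])
        n_hit = len(genes_hit[pw])
        rows.append((pw, n_genes, n_hit,
                     round_half_up(100.0 * n_hit / n_genes) if n_genes else 0.0,
                     pv_count[pw]))
    distinct_genes = len({g for gs in catalog.pathways.values() for g in gs})
    distinct_hit = len({pv.gene for pv in dataset.pvs})
    rows.append(("Total", distinct_genes, distinct_hit,
                 round_half_up(100.0 * distinct_hit / distinct_genes)
                 if distinct_genes else 0.0,
                 len(dataset.pvs)))
    return pd.DataFrame(
        rows, columns=["pathway", "n_genes", "n_genes_with_pvs", "percent", "n_pvs"])


# ---------------------------------------------------------------------------
# HGVS-keyed fixtures: literature tables identify variants by (gene, cDNA change)
# rather than genomic coordinates, so the classifier also accepts such keys.

@dataclass(frozen=True)
class HgvsKey:
    """Fallback matching key for variants known only by gene + cDNA HGVS."""

    gene: str
    hgvs_c: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        object.__setattr__(self, "hgvs_c", self.hgvs_c.strip())


def classify_flagged_table(rows: Sequence[Mapping]) -> dict[HgvsKey, SharingPattern]:
    """Classify a transcribed sharing table whose rows carry membership flags.

    Each row needs ``gene``, ``hgvs_c`` and boolean-ish ``african`` /
    ``nonafrican`` flags ("+"/"-" accepted). The flags define the modern
    membership sets; classification is then the ordinary four-cell rule.
    """
    def flag(x) -> bool:
        if isinstance(x, str):
            return x.strip() in {"+", "1", "true", "True", "yes"}
        return bool(x)

    keys, african, nonafrican = [], set(), set()
    for r in rows:
        k = HgvsKey(r["gene"], r["hgvs_c"])
        keys.append(k)
        if flag(r["african"]):
            african.add(k)
        if flag(r["nonafrican"]):
            nonafrican.add(k)
    return classify_with_ancient(keys, african, nonafrican)
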