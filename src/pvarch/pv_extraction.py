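"""Pathogenic-variant selection and population-level dataset assembly.

A PV here is a single-base substitution inside a catalog gene's coding
interval whose clinical interpretation is Pathogenic or Likely Pathogenic.
Variants with conflicting interpretations are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog_io import (ClinicalAssertion, ClinicalClass, CohortVariantTable,
                         GeneCatalog, GenomicVariant, assign_gene)
from .errors import AnalysisError, ConfigurationError

logger = logging.getLogger(__name__)


class Consequence(Enum):
    NONSYNONYMOUS_SNV = "nonsynonymous SNV"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    STARTLOSS = "startloss"
    SYNONYMOUS_SNV = "synonymous SNV"
    OTHER = "other"


def parse_consequence(raw: str) -> Consequence:
    """Map a raw annotation string onto the consequence vocabulary."""
    label = raw.strip().lower().replace("_", " ").replace("-", " ")
    mapping = {
        "nonsynonymous snv": Consequence.NONSYNONYMOUS_SNV,
        "missense": Consequence.NONSYNONYMOUS_SNV,
        "stopgain": Consequence.STOPGAIN,
        "stop gain": Consequence.STOPGAIN,
        "stoploss": Consequence.STOPLOSS,
        "stop loss": Consequence.STOPLOSS,
        "startloss": Consequence.STARTLOSS,
        "start loss": Consequence.STARTLOSS,
        "synonymous snv": Consequence.SYNONYMOUS_SNV,
    }
    return mapping.get(label, Consequence.OTHER)


def classify_significance(raw_label: str) -> ClinicalClass:
    """Collapse a free-text clinical significance label to a clinical class.

    Case-insensitive keyword rules: any mention of "conflicting" dominates;
    "pathogenic" without "benign" is PV (this covers "Likely pathogenic"
    and "Pathogenic/Likely pathogenic"); "benign" without "pathogenic" is
    BV; "uncertain" is VUS; anything else is OTHER.
    """
    label = raw_label.strip().lower()
    if "conflicting" in label:
        return ClinicalClass.CONFLICTING
    has_path = "pathogenic" in label
    has_benign = "benign" in label
    if has_path and not has_benign:
        return ClinicalClass.PV
    if has_benign and not has_path:
        return ClinicalClass.BV
    if has_path and has_benign:
        return ClinicalClass.CONFLICTING
    if "uncertain" in label:
        return ClinicalClass.VUS
    return ClinicalClass.OTHER


@dataclass(frozen=True)
class PVRecord:
    """A selected pathogenic variant with its gene context and cohort counts."""

    variant: GenomicVariant
    gene: str
    pathway: str
    consequence: Consequence
    per_population: tuple[tuple[str, int, int], ...] = ()
    clinical_class: ClinicalClass = field(default=ClinicalClass.PV, compare=False)

    def __post_init__(self) -> None:
        if self.clinical_class is not ClinicalClass.PV:
            raise ValueError("PVRecord requires clinical_class PV")

    def allele_count(self, population: Optional[str] = None) -> int:
        if population is None:
            return sum(ac for _, ac, _ in self.per_population)
        return sum(ac for pop, ac, _ in self.per_population if pop == population)


@dataclass
class PopulationPVDataset:
    """PVs pooled over one population group (e.g. African, non-African, or a subgroup)."""

    group_label: str
    sample_size: int
    pvs: set[PVRecord]

    @property
    def variant_keys(self) -> set[GenomicVariant]:
        return {pv.variant for pv in self.pvs}


def select_pvs(cohort: CohortVariantTable,
               assertions: Mapping[GenomicVariant, ClinicalAssertion],
               catalog: GeneCatalog) -> set[PVRecord]:
    """Apply the three selection rules to a cohort table.

    A row survives iff it (i) is a SNV (guaranteed by the reader), (ii)
    lies inside a catalog coding interval and (iii) carries a PV clinical
    class. Per-rule exclusion tallies are logged. Idempotent: re-selecting
    from its own output changes nothing.
    """
    kept: set[PVRecord] = set()
    n_noncoding = n_nonpv = 0
    for variant, ac, an, csq in cohort.rows:
        hit = assign_gene(variant, catalog)
        if hit is None:
            n_noncoding += 1
            continue
        assertion = assertions.get(variant)
        if assertion is None or assertion.clinical_class is not ClinicalClass.PV:
            n_nonpv += 1
            continue
        gene, _ = hit
        kept.add(PVRecord(
            variant=variant, gene=gene, pathway=catalog[gene].pathway,
            consequence=parse_consequence(csq),
            per_population=((cohort.population_label, ac, an),)))
    logger.info("%s: %d PVs kept; excluded %d non-coding, %d non-pathogenic",
                cohort.population_label, len(kept), n_noncoding, n_nonpv)
    return kept


def combine_populations(sources: Sequence[tuple[str, set[PVRecord], int]],
                        grouping: Mapping[str, str]
                        ) -> list[PopulationPVDataset]:
    """Pool per-source PV sets into group-level datasets.

    ``sources`` holds (source_label, pv_set, sample_size). Within a group,
    variant keys are unioned and allele counts/numbers summed per source
    population label; sample sizes are summed. Per-source datasets are also
    emitted (one dataset per source label) so subgroup analyses see the
    same record shape.
    """
    missing = [label for label, _, _ in sources if label not in grouping]
    if missing:
        raise ConfigurationError(f"sources missing from grouping: {', '.join(missing)}")
    datasets: list[PopulationPVDataset] = []
    groups: dict[str, list[tuple[str, set[PVRecord], int]]] = {}
    for label, pvs, n in sources:
        groups.setdefault(grouping[label], []).append((label, pvs, n))
        datasets.append(PopulationPVDataset(group_label=label, sample_size=n, pvs=set(pvs)))
    for group_label, members in groups.items():
        merged: dict[GenomicVariant, PVRecord] = {}
        for _, pvs, _ in members:
            for pv in pvs:
                if pv.variant in merged:
                    prev = merged[pv.variant]
                    merged[pv.variant] = PVRecord(
                        variant=prev.variant, gene=prev.gene, pathway=prev.pathway,
                        consequence=prev.consequence,
                        per_population=_sum_pops(prev.per_population, pv.per_population))
                else:
                    merged[pv.variant] = pv
        datasets.append(PopulationPVDataset(
            group_label=group_label,
            sample_size=sum(n for _, _, n in members),
            pvs=set(merged.values())))
    return datasets


def _sum_pops(a: tuple[tuple[str, int, int], ...],
              b: tuple[tuple[str, int, int], ...]) -> tuple[tuple[str, int, int], ...]:
    acc: dict[str, list[int]] = {}
    for pop, ac, an in (*a, *b):
        cur = acc.setdefault(pop, [0, 0])
        cur[0] += ac
        cur[1] += an
    return tuple((pop, ac, an) for pop, (ac, an) in sorted(acc.items()))


def ethnic_presence_matrix(datasets: Sequence[PopulationPVDataset],
                           min_group_size: int = 1000,
                           presence_threshold: int = 1) -> pd.DataFrame:
    """Binary presence/absence matrix (groups x variant keys).

    Groups smaller than ``min_group_size`` individuals are dropped and
    reported; a cell is 1 iff the group's allele count for that variant is
    at least ``presence_threshold``. At least two groups must survive.
    """
    excluded = [d.group_label for d in datasets if d.sample_size < min_group_size]
    kept = [d for d in datasets if d.sample_size >= min_group_size]
    if excluded:
        logger.info("excluded groups below %d individuals: %s",
                    min_group_size, ", ".join(excluded))
    if len(kept) < 2:
        raise AnalysisError(
            f"need >=2 groups of >= {min_group_size} individuals, have {len(kept)}")
    all_keys = sorted({pv.variant for d in kept for pv in d.pvs},
                      key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    cols = [f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}" for v in all_keys]
    mat = np.zeros((len(kept), len(all_keys)), dtype=np.int8)
    index = {v: j for j, v in enumerate(all_keys)}
    for i, d in enumerate(kept):
        for pv in d.pvs:
            if pv.allele_count() >= presence_threshold:
                mat[i, index[pv.variant]] = 1
    return pd.DataFrame(mat, index=[d.group_label for d in kept], columns=cols)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero, matching reported percents."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def variation_type_tally(pvs: Iterable[PVRecord]
                         ) -> dict[Consequence, tuple[int, float]]:
    """Count PVs per consequence class with one-decimal percentages."""
    counts: dict[Consequence, int] = {}
    for pv in pvs:
        counts[pv.consequence] = counts.get(pv.consequence, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {csq: (n, round_half_up(100.0 * n / total))
            for csq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].value))}
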