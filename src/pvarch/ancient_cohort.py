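"""Dated ancient samples, their pathogenic-variant observations, and epoch binning.

Dates are integer years before present (BP); larger is older. The
"earliest" carrier of a variant is therefore the carrier with the maximum
BP date. Undated samples are carried with an absent date, never zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .catalog_io import (ClinicalAssertion, ClinicalClass, GeneCatalog,
                         GenomicVariant, assign_gene, normalize_variant)
from .errors import NotASNVError, ValidationError
from .pv_extraction import round_half_up

logger = logging.getLogger(__name__)

#: Default epoch bin edges in years BP (inclusive lower bounds).
DEFAULT_BIN_EDGES = (2000, 4000, 6000, 8000, 10000)


@dataclass
class AncientSample:
    sample_id: str
    date_bp: Optional[int] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    observed_variants: set[GenomicVariant] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.date_bp is not None and self.date_bp < 0:
            raise ValidationError(f"{self.sample_id}: negative date {self.date_bp}")


@dataclass
class AncientPVObservation:
    """One distinct pathogenic variant with the set of ancient carriers."""

    variant: GenomicVariant
    gene: str
    carriers: set[str]
    earliest_bp: Optional[int]


def _parse_bp(raw: str) -> Optional[int]:
    """Parse a BP value, tolerating thousands separators; blank/NA means undated."""
    text = raw.strip().replace(",", "")
    if text == "" or text.upper() in {"NA", "NAN", "NONE"}:
        return None
    return int(float(text))


def _parse_float(raw: str) -> Optional[float]:
    text = raw.strip()
    return float(text) if text else None


def read_ancient_manifest(path: str | Path) -> list[AncientSample]:
    """Read a sample manifest TSV: sample_id, date_bp, optional lat/lon,
    optional inline ``variants`` column of comma-separated chrom:pos:ref>alt keys.

    Non-SNV entries in a variant list are dropped with a logged count;
    duplicate sample ids are a validation error.
    """
    path = Path(path)
    samples: list[AncientSample] = []
    seen: set[str] = set()
    n_dropped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValidationError(f"{path}: manifest needs a sample_id column")
        for row in reader:
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            variants: set[GenomicVariant] = set()
            for token in (row.get("variants") or "").split(","):
                token = token.strip()
                if not token:
                    continue
                try:
                    loc, alleles = token.rsplit(":", 1)
                    chrom, pos = loc.split(":")
                    ref, alt = alleles.split(">")
                    variants.add(normalize_variant(chrom, int(pos), ref, alt))
                except (ValueError, NotASNVError, ValidationError):
                    n_dropped += 1
            samples.append(AncientSample(
                sample_id=sid,
                date_bp=_parse_bp(row.get("date_bp") or ""),
                latitude=_parse_float(row.get("lat") or ""),
                longitude=_parse_float(row.get("lon") or ""),
                observed_variants=variants))
    if n_dropped:
        logger.info("%s: dropped %d non-SNV or unparseable variant tokens", path, n_dropped)
    return samples


def ancient_pv_observations(samples: Sequence[AncientSample],
                            assertions: Mapping[GenomicVariant, ClinicalAssertion],
                            catalog: GeneCatalog) -> list[AncientPVObservation]:
    """Collapse per-sample variant calls into per-PV carrier observations.

    The PV filter is identical to modern-cohort selection: SNV (already
    guaranteed), inside a catalog coding interval, clinical class PV.
    """
    by_date = {s.sample_id: s.date_bp for s in samples}
    carriers: dict[GenomicVariant, set[str]] = {}
    genes: dict[GenomicVariant, str] = {}
    for sample in samples:
        for variant in sample.observed_variants:
            hit = assign_gene(variant, catalog)
            if hit is None:
                continue
            assertion = assertions.get(variant)
            if assertion is None or assertion.clinical_class is not ClinicalClass.PV:
                continue
            carriers.setdefault(variant, set()).add(sample.sample_id)
            genes[variant] = hit[0]
    out = []
    for variant in sorted(carriers, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        ids = carriers[variant]
        dated = [by_date[i] for i in ids if by_date[i] is not None]
        out.append(AncientPVObservation(
            variant=variant, gene=genes[variant], carriers=ids,
            earliest_bp=max(dated) if dated else None))
    return out


def earliest_carrier_date(obs: "AncientPVObservation | Iterable[Optional[int]]",
                          samples: Optional[Sequence[AncientSample]] = None
                          ) -> Optional[int]:
    """Oldest (maximum years-BP) date among dated carriers; None if none dated.

    Accepts either an observation plus the sample manifest, or a bare
    iterable of carrier dates.
    """
    if isinstance(obs, AncientPVObservation):
        if samples is None:
            raise ValueError("samples required when passing an observation")
        by_date = {s.sample_id: s.date_bp for s in samples}
        dates: Iterable[Optional[int]] = (by_date.get(i) for i in obs.carriers)
    else:
        dates = obs
    dated = [d for d in dates if d is not None]
    return max(dated) if dated else None


def _bin_label(lo: int, hi: Optional[int]) -> str:
    if hi is None:
        return f">={lo:,}"
    return f"{lo:,}–{hi - 1:,}"


def bin_dates(samples: Sequence[AncientSample],
              edges: Sequence[int] = DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Tabulate sample ages into epoch bins with inclusive lower bounds.

    The default scheme is <2000, 2000–3,999, 4,000–5,999, 6,000–7,999,
    8,000–9,999 and an open top bin from 10,000 BP. Undated samples are an
    "NA" row; percentages use the grand total including undated, rounded
    half-up to one decimal. Rows are ordered oldest first, then NA, then a
    totals row.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing")
    dated = [s.date_bp for s in samples if s.date_bp is not None]
    n_undated = len(samples) - len(dated)
    total = len(samples)
    bins: list[tuple[str, int]] = []
    # open top bin
    top = edges[-1]
    bins.append((_bin_label(top, None), sum(d >= top for d in dated)))
    for lo, hi in zip(reversed(edges[:-1]), reversed(edges[1:])):
        bins.append((_bin_label(lo, hi), sum(lo <= d < hi for d in dated)))
    bins.append((f"<{edges[0]:,}", sum(d < edges[0] for d in dated)))
    bins.append(("NA", n_undated))
    rows = [(label, n, round_half_up(100.0 * n / total) if total else 0.0)
            for label, n in bins]
    rows.append(("Total", total, 100.0 if total else 0.0))
    return pd.DataFrame(rows, columns=["timing_bp", "count", "percent"])
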