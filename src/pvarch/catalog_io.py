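"""Domain types and I/O for variants, gene catalogs, cohorts and clinical assertions.

Coordinate conventions: positions are 1-based (VCF style) on the type
boundary; gene coding intervals are 0-based half-open internally.
Chromosome names are stored without a ``chr`` prefix.
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import FormatError, NotASNVError, ValidationError

logger = logging.getLogger(__name__)

ASSEMBLY = "hg38"
_BASES = frozenset("ACGT")

#: Closed vocabulary of DNA-damage-repair pathway names used by the catalog.
PATHWAYS = (
    "Homologous Recombination",
    "DNA damage response",
    "Fanconi anemia",
    "Mismatch Repair",
    "Nonhomologous end joining",
    "Nucleotide excision repair",
    "Base excision repair",
    "DNA replication",
)


class ClinicalClass(Enum):
    """Five-tier clinical interpretation, collapsed to the classes the pipeline acts on."""

    PV = "PV"
    VUS = "VUS"
    BV = "BV"
    CONFLICTING = "CONFLICTING"
    OTHER = "OTHER"


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide variant keyed by (chrom, pos, ref, alt).

    ``pos`` is 1-based. HGVS labels are carried for reporting and for
    matching literature tables that identify variants only by cDNA change;
    they never enter equality or hashing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: Optional[str] = field(default=None, compare=False)
    hgvs_p: Optional[str] = field(default=None, compare=False)
    assembly: str = field(default=ASSEMBLY, compare=False)

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise NotASNVError(f"not a SNV: {self.ref}>{self.alt}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(f"non-ACGT allele: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValidationError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      hgvs_c: Optional[str] = None,
                      hgvs_p: Optional[str] = None) -> GenomicVariant:
    """Canonicalize a raw variant description into a :class:`GenomicVariant`.

    Strips any ``chr`` prefix, uppercases alleles and rejects anything that
    is not a strict single-base substitution. Idempotent on its own output.
    """
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    ref = str(ref).strip().upper()
    alt = str(alt).strip().upper()
    return GenomicVariant(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                          hgvs_c=hgvs_c, hgvs_p=hgvs_p)


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent 0-based half-open intervals, sorted by (chrom, start)."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if start >= end:
            raise ValidationError(f"empty interval {chrom}:{start}-{end}")
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


@dataclass
class GeneRecord:
    """A catalog gene: symbol, its pathways, and merged coding intervals."""

    symbol: str
    pathways: tuple[str, ...]
    coding_intervals: list[tuple[str, int, int]]

    @property
    def pathway(self) -> str:
        """Primary pathway (first listed); genes may belong to several."""
        return self.pathways[0]

    @property
    def total_span(self) -> int:
        return sum(e - s for _, s, e in self.coding_intervals)


class GeneCatalog:
    """The DNA-damage-repair gene panel: symbol lookup and pathway rosters.

    Symbols are case-insensitive and stored uppercase. Interval containment
    queries are answered from per-chromosome sorted interval lists.
    """

    def __init__(self, genes: dict[str, GeneRecord]):
        self.genes = {sym.upper(): rec for sym, rec in genes.items()}
        self.pathways: dict[str, set[str]] = {}
        for rec in self.genes.values():
            for pw in rec.pathways:
                self.pathways.setdefault(pw, set()).add(rec.symbol)
        # per-chromosome sorted (start, end, symbol) for containment queries
        self._index: dict[str, list[tuple[int, int, str]]] = {}
        for rec in self.genes.values():
            for chrom, start, end in rec.coding_intervals:
                self._index.setdefault(chrom, []).append((start, end, rec.symbol))
        for chrom in self._index:
            self._index[chrom].sort()
        self._starts = {c: [iv[0] for iv in ivs] for c, ivs in self._index.items()}

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self.genes[symbol.upper()]

    def __len__(self) -> int:
        return len(self.genes)

    def genes_overlapping(self, chrom: str, pos0: int) -> list[str]:
        """All gene symbols whose merged intervals contain 0-based ``pos0``."""
        ivs = self._index.get(chrom)
        if not ivs:
            return []
        hi = bisect_right(self._starts[chrom], pos0)
        return [sym for start, end, sym in ivs[:hi] if start <= pos0 < end]


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a tab-delimited catalog (gene, pathway, chrom, start, end; one
    row per coding interval, 0-based half-open).

    A gene listed under several pathways appears once in the catalog with
    all its pathway memberships. Unknown pathway labels are collected and
    reported together.
    """
    path = Path(path)
    rows = _read_tsv_rows(path, required={"gene", "pathway", "chrom", "start", "end"})
    if not rows:
        raise FormatError(f"{path}: catalog file has no data rows")
    per_gene_pathways: dict[str, list[str]] = {}
    per_gene_intervals: dict[str, list[tuple[str, int, int]]] = {}
    bad_pathways = sorted({r["pathway"] for r in rows} - set(PATHWAYS))
    if bad_pathways:
        raise ValidationError(f"{path}: unknown pathway labels: {', '.join(bad_pathways)}")
    for r in rows:
        sym = r["gene"].strip().upper()
        pw = r["pathway"]
        pws = per_gene_pathways.setdefault(sym, [])
        if pw not in pws:
            pws.append(pw)
        chrom = r["chrom"]
        if chrom.lower().startswith("chr"):
            chrom = chrom[3:]
        per_gene_intervals.setdefault(sym, []).append(
            (chrom, int(r["start"]), int(r["end"])))
    genes = {
        sym: GeneRecord(symbol=sym, pathways=tuple(per_gene_pathways[sym]),
                        coding_intervals=merge_intervals(per_gene_intervals[sym]))
        for sym in per_gene_pathways
    }
    catalog = GeneCatalog(genes)
    logger.info("catalog: %d genes across %d pathways", len(catalog), len(catalog.pathways))
    return catalog


def assign_gene(variant: GenomicVariant, catalog: GeneCatalog
                ) -> Optional[tuple[str, bool]]:
    """Assign a variant to the catalog gene whose coding interval contains it.

    The 1-based position is converted to 0-based before the containment
    test. When several genes overlap the site, the gene with the smallest
    total coding span wins, ties broken lexicographically by symbol.
    Returns ``None`` when no interval contains the site.
    """
    pos0 = variant.pos - 1
    hits = catalog.genes_overlapping(variant.chrom, pos0)
    if not hits:
        return None
    best = min(hits, key=lambda sym: (catalog[sym].total_span, sym))
    return best, True


@dataclass
class ClinicalAssertion:
    variant: GenomicVariant
    significance: str
    clinical_class: ClinicalClass


@dataclass
class CohortVariantTable:
    """Per-population variant table with allele counts.

    ``rows`` holds ``(variant, allele_count, allele_number, consequence)``
    sorted by (chrom, pos); ``sample_size`` counts individuals.
    """

    population_label: str
    sample_size: int
    rows: list[tuple[GenomicVariant, int, int, str]]

    def __post_init__(self) -> None:
        if self.sample_size <= 0:
            raise ValidationError(f"sample_size must be positive, got {self.sample_size}")
        seen: set[tuple] = set()
        for v, ac, an, _ in self.rows:
            if ac < 0 or an <= 0 or ac > an:
                raise ValidationError(
                    f"{self.population_label}: bad counts AC={ac} AN={an} at {v.chrom}:{v.pos}")
            if an > 2 * self.sample_size:
                raise ValidationError(
                    f"{self.population_label}: AN={an} exceeds 2x sample size at {v.chrom}:{v.pos}")
            if v.key in seen:
                raise ValidationError(
                    f"{self.population_label}: duplicate variant {v.chrom}:{v.pos} {v.ref}>{v.alt}")
            seen.add(v.key)

    @property
    def variants(self) -> set[GenomicVariant]:
        return {v for v, _, _, _ in self.rows}


def _read_tsv_rows(path: Path, required: set[str]) -> list[dict[str, str]]:
    try:
        handle = open(path, newline="")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = required - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns: {', '.join(sorted(missing))}")
        return list(reader)


def _iter_vcf_records(path: Path, ac_field: str, an_field: str,
                      csq_field: Optional[str]):
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            info = rec.info
            acs = info.get(ac_field)
            an = info.get(an_field)
            if acs is None or an is None:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks {ac_field}/{an_field}")
            if not isinstance(acs, tuple):
                acs = (acs,)
            csq = ""
            if csq_field:
                try:  # pysam raises on keys absent from the header
                    csq = str(info.get(csq_field, "") or "")
                except (KeyError, ValueError):
                    csq = ""
            for alt, ac in zip(rec.alts, acs):
                yield rec.chrom, rec.pos, rec.ref, alt, int(ac), int(an), csq


def read_cohort_variants(path: str | Path, population_label: str,
                         sample_size: int, *, ac_field: str = "AC",
                         an_field: str = "AN",
                         consequence_field: Optional[str] = "CSQ"
                         ) -> CohortVariantTable:
    """Read a cohort variant table from VCF (uncompressed or bgzip) or TSV.

    Only rows that normalize to single-base substitutions are retained;
    skipped rows are counted in the log. Allele counts are kept verbatim,
    including AC=0 rows — presence thresholds are applied downstream.

    A TSV source needs columns chrom, pos, ref, alt, allele_count,
    allele_number and optionally consequence.
    """
    path = Path(path)
    rows: list[tuple[GenomicVariant, int, int, str]] = []
    n_skipped = 0
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        source = _iter_vcf_records(path, ac_field, an_field, consequence_field)
        records = ((c, p, r, a, ac, an, csq, i + 1)
                   for i, (c, p, r, a, ac, an, csq) in enumerate(source))
    else:
        tsv = _read_tsv_rows(path, required={"chrom", "pos", "ref", "alt",
                                             "allele_count", "allele_number"})
        records = ((r["chrom"], int(r["pos"]), r["ref"], r["alt"],
                    int(r["allele_count"]), int(r["allele_number"]),
                    r.get("consequence", ""), i + 2)
                   for i, r in enumerate(tsv))
    for chrom, pos, ref, alt, ac, an, csq, lineno in records:
        try:
            variant = normalize_variant(chrom, pos, ref, alt)
        except (NotASNVError, ValidationError):
            n_skipped += 1
            continue
        if ac > an:
            raise ValidationError(
                f"{path} line {lineno}: AC={ac} exceeds AN={an}")
        rows.append((variant, ac, an, csq))
    rows.sort(key=lambda r: (r[0].chrom, r[0].pos, r[0].ref, r[0].alt))
    logger.info("%s: %d SNV rows kept, %d non-SNV rows skipped",
                population_label, len(rows), n_skipped)
    return CohortVariantTable(population_label=population_label,
                              sample_size=sample_size, rows=rows)


def write_cohort_variants(table: CohortVariantTable, path: str | Path) -> None:
    """Write a cohort table to the TSV schema ``read_cohort_variants`` accepts."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "allele_count",
                         "allele_number", "consequence"])
        for v, ac, an, csq in table.rows:
            writer.writerow([v.chrom, v.pos, v.ref, v.alt, ac, an, csq])


def read_clinvar_table(path: str | Path) -> dict[GenomicVariant, ClinicalAssertion]:
    """Read a clinical-assertion TSV (chrom, pos, ref, alt, significance).

    Duplicate keys with identical labels collapse to one assertion;
    duplicate keys with conflicting labels become CONFLICTING with a
    logged warning.
    """
    from .pv_extraction import classify_significance

    path = Path(path)
    rows = _read_tsv_rows(path, required={"chrom", "pos", "ref", "alt", "significance"})
    out: dict[GenomicVariant, ClinicalAssertion] = {}
    for r in rows:
        try:
            v = normalize_variant(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        except (NotASNVError, ValidationError):
            continue
        label = r["significance"].strip()
        if v in out and out[v].significance != label:
            logger.warning("conflicting significance for %s:%s %s>%s: %r vs %r",
                           v.chrom, v.pos, v.ref, v.alt, out[v].significance, label)
            out[v] = ClinicalAssertion(v, f"{out[v].significance}; {label}",
                                       ClinicalClass.CONFLICTING)
        elif v not in out:
            out[v] = ClinicalAssertion(v, label, classify_significance(label))
    return out
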