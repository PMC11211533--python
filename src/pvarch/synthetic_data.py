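"""Forward simulation of an out-of-Africa demography with known variant ages.

The generator produces study-shaped inputs — modern African and
non-African cohort tables, a clinical-assertion table, a dated ancient
sample manifest — together with a truth table recording when and on which
lineage every variant arose. It exists so the ancient-intermediate sharing
classifier can be validated against known arising epochs without any
external downloads.

Model: a single ancestral diploid population evolves under neutral
Wright–Fisher drift; at the split (default 60,000 years BP, 30-year
generations, hence 2,000 generations) a small founder group buds off to
found the non-African branch while the African branch continues the
ancestral population. New pathogenic variants arise as a Poisson process
on each branch and drift to loss or fixation; there is no migration after
the split and no selection (the variants modelled are too recent for
selection to act appreciably). Modern cohorts are binomial samples of
terminal frequencies; ancient individuals are diploid draws from the
non-African branch at their dated generations, with per-call missingness
mimicking poor ancient-DNA coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .catalog_io import (ClinicalAssertion, ClinicalClass, CohortVariantTable,
                         GeneCatalog, GeneRecord, GenomicVariant, PATHWAYS,
                         write_cohort_variants)
from .ancient_cohort import AncientSample
from .errors import ConfigurationError


class Lineage(Enum):
    ANCESTRAL = "ANCESTRAL"
    AFRICAN_BRANCH = "AFRICAN_BRANCH"
    NONAFRICAN_BRANCH = "NONAFRICAN_BRANCH"


@dataclass(frozen=True)
class TruthRecord:
    variant: GenomicVariant
    arising_generation: int          # generations before present
    arising_lineage: Lineage
    arising_years_bp: int


#: Ancient sampling schedule shaped like the empirical dating profile of
#: published ancient Eurasian genomes: ~80% within the last 6,000 years,
#: a thin tail beyond 10,000 BP. (date_bp, n_samples, missing_call_prob)
DEFAULT_ANCIENT_SAMPLING: tuple[tuple[int, int, float], ...] = (
    (1000, 22, 0.3),
    (3000, 96, 0.3),
    (5000, 46, 0.3),
    (7000, 28, 0.3),
    (9000, 6, 0.3),
    (12000, 6, 0.3),
)


@dataclass(frozen=True)
class SimulationParams:
    """Demographic and sampling parameters, scaled for desk-size studies.

    Sizes are diploid individuals. ``*_sizes`` are change-point schedules
    of (years_bp, size): the population takes each size from that time
    forward until the next change-point. ``mutation_rate`` is the expected
    number of new pathogenic variants arising per generation per branch.
    """

    n_ancestral: int = 800
    n_founders: int = 120
    t_split_years: int = 60_000
    generation_years: int = 30
    ancestral_generations: int = 800
    african_sizes: tuple[tuple[int, int], ...] = ((60_000, 800), (10_000, 2000))
    nonafrican_sizes: tuple[tuple[int, int], ...] = (
        (60_000, 120), (10_000, 1200), (2_000, 4000))
    mutation_rate: float = 1.0
    detection_threshold: int = 1
    african_cohort_size: int = 2000
    nonafrican_cohorts: tuple[tuple[str, int], ...] = (
        ("European", 5000), ("EastAsian", 3000), ("SouthAsian", 1200))
    ancient_sampling: tuple[tuple[int, int, float], ...] = DEFAULT_ANCIENT_SAMPLING
    init_frequency: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral < 2 or self.n_founders < 2:
            raise ConfigurationError("population sizes must be >= 2")
        if self.t_split_years <= 0 or self.generation_years <= 0:
            raise ConfigurationError("split time and generation time must be positive")
        for _, n, miss in self.ancient_sampling:
            if not 0.0 <= miss <= 1.0:
                raise ConfigurationError("missing-call probability must be in [0,1]")
            if n < 0:
                raise ConfigurationError("ancient sample counts must be >= 0")
        if self.init_frequency is not None and not 0.0 < self.init_frequency <= 1.0:
            raise ConfigurationError("init_frequency must be in (0,1]")

    @property
    def t_split_generations(self) -> int:
        return round(self.t_split_years / self.generation_years)


@dataclass
class SimulatedStudy:
    """Bundle of simulator outputs in exactly the shapes the pipeline consumes."""

    params: SimulationParams
    catalog: GeneCatalog
    african_cohort: CohortVariantTable
    nonafrican_cohorts: list[CohortVariantTable]
    assertions: dict[GenomicVariant, ClinicalAssertion]
    ancient_samples: list[AncientSample]
    truth: list[TruthRecord]

    def cohort_presence(self, table: CohortVariantTable,
                        threshold: Optional[int] = None) -> set[GenomicVariant]:
        thr = self.params.detection_threshold if threshold is None else threshold
        return {v for v, ac, _, _ in table.rows if ac >= thr}

    def african_keys(self) -> set[GenomicVariant]:
        return self.cohort_presence(self.african_cohort)

    def nonafrican_keys(self) -> set[GenomicVariant]:
        thr = self.params.detection_threshold
        totals: dict[GenomicVariant, int] = {}
        for table in self.nonafrican_cohorts:
            for v, ac, _, _ in table.rows:
                totals[v] = totals.get(v, 0) + ac
        return {v for v, ac in totals.items() if ac >= thr}

    def ancient_keys(self) -> set[GenomicVariant]:
        return {v for s in self.ancient_samples for v in s.observed_variants}


def wright_fisher_trajectory(p0: float, sizes: Sequence[int],
                             rng: np.random.Generator) -> np.ndarray:
    """Neutral Wright–Fisher frequency path under a per-generation size schedule.

    Each generation resamples 2N allele copies binomially from the current
    frequency. The path includes the initial frequency, so its length is
    ``len(sizes) + 1``. Frequencies 0 and 1 are absorbing.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("initial frequency must be in [0,1]")
    path = np.empty(len(sizes) + 1, dtype=float)
    path[0] = p = p0
    for i, n in enumerate(sizes, start=1):
        if n < 1:
            raise ValueError("population size must be >= 1")
        if p in (0.0, 1.0):
            path[i:] = p
            break
        p = rng.binomial(2 * n, p) / (2 * n)
        path[i] = p
    return path


def _size_schedule(changepoints: Sequence[tuple[int, int]], start_gen: int,
                   generation_years: int) -> np.ndarray:
    """Per-generation sizes for generations start_gen-1 ... 0 (forward in time)."""
    pts = sorted(changepoints, key=lambda t: -t[0])
    sizes = np.empty(start_gen, dtype=np.int64)
    for i, gen in enumerate(range(start_gen - 1, -1, -1)):
        years = gen * generation_years
        size = pts[0][1]
        for t_years, n in pts:
            if years <= t_years:
                size = n
        sizes[i] = size
    return sizes


def _toy_catalog(n_variants: int, n_genes: int = 12) -> tuple[GeneCatalog, list[tuple[str, int]]]:
    """Synthetic gene catalog sized to host ``n_variants`` variant sites.

    Returns the catalog and the (gene, position) slot for each variant id.
    """
    per_gene = max(n_variants // n_genes + 1, 8)
    genes: dict[str, GeneRecord] = {}
    slots: list[tuple[str, int]] = []
    for g in range(n_genes):
        sym = f"SIM{g + 1:03d}"
        start = 10_000 + g * (per_gene + 100)
        genes[sym] = GeneRecord(symbol=sym,
                                pathways=(PATHWAYS[g % len(PATHWAYS)],),
                                coding_intervals=[("1", start, start + per_gene)])
    for i in range(n_variants):
        g = i % n_genes
        sym = f"SIM{g + 1:03d}"
        start = 10_000 + g * (per_gene + 100)
        slots.append((sym, start + i // n_genes + 1))  # 1-based position inside interval
    return GeneCatalog(genes), slots


def simulate_study(params: SimulationParams) -> SimulatedStudy:
    """Run the forward simulation and package a complete synthetic study.

    Fully reproducible: all randomness flows through one generator seeded
    from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)

    def p_init(n: int) -> float:
        # a new variant enters as a single copy unless an explicit entry
        # frequency is configured (the no-drift validation regime)
        return params.init_frequency if params.init_frequency is not None \
            else 1.0 / (2 * n)

    t_split = params.t_split_generations
    gy = params.generation_years
    sim_start = t_split + params.ancestral_generations

    for date_bp, n, _ in params.ancient_sampling:
        if n > 0 and round(date_bp / gy) >= t_split:
            raise ConfigurationError(
                f"ancient sampling at {date_bp} BP predates the non-African branch")

    # --- mutation arrivals ------------------------------------------------
    arise_gen: list[int] = []
    arise_lineage: list[Lineage] = []
    for gen in range(sim_start, t_split, -1):
        for _ in range(rng.poisson(params.mutation_rate)):
            arise_gen.append(gen)
            arise_lineage.append(Lineage.ANCESTRAL)
    post_split_events: list[tuple[int, Lineage]] = []
    for gen in range(t_split, 0, -1):
        for br in (Lineage.AFRICAN_BRANCH, Lineage.NONAFRICAN_BRANCH):
            for _ in range(rng.poisson(params.mutation_rate)):
                post_split_events.append((gen, br))

    # --- ancestral epoch --------------------------------------------------
    arrivals_anc: dict[int, list[int]] = {}
    for i, g in enumerate(arise_gen):
        arrivals_anc.setdefault(g, []).append(i)
    next_id = len(arise_gen)
    freqs = np.zeros(0, dtype=float)
    ids = np.zeros(0, dtype=np.int64)
    for gen in range(sim_start, t_split, -1):
        for vid in arrivals_anc.get(gen, []):
            ids = np.append(ids, vid)
            freqs = np.append(freqs, p_init(params.n_ancestral))
        if freqs.size:
            active = (freqs > 0) & (freqs < 1)
            if active.any():
                freqs[active] = rng.binomial(
                    2 * params.n_ancestral, freqs[active]) / (2 * params.n_ancestral)

    # --- split ------------------------------------------------------------
    afr_ids, afr_freq = ids.copy(), freqs.copy()
    nonafr_ids = ids.copy()
    nonafr_freq = np.where(
        (freqs > 0) & (freqs < 1),
        rng.binomial(2 * params.n_founders, np.clip(freqs, 0, 1)) / (2 * params.n_founders),
        freqs)

    for gen, br in post_split_events:
        arise_gen.append(gen)
        arise_lineage.append(br)
    arrivals_post: dict[tuple[int, Lineage], list[int]] = {}
    for vid, (gen, br) in enumerate(post_split_events, start=next_id):
        arrivals_post.setdefault((gen, br), []).append(vid)

    afr_sizes = _size_schedule(params.african_sizes, t_split, gy)
    nonafr_sizes = _size_schedule(params.nonafrican_sizes, t_split, gy)
    ancient_gens = sorted({round(d / gy) for d, n, _ in params.ancient_sampling if n > 0},
                          reverse=True)
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for step, gen in enumerate(range(t_split - 1, -1, -1)):
        for vid in arrivals_post.get((gen + 1, Lineage.AFRICAN_BRANCH), []):
            afr_ids = np.append(afr_ids, vid)
            afr_freq = np.append(afr_freq, p_init(afr_sizes[step]))
        for vid in arrivals_post.get((gen + 1, Lineage.NONAFRICAN_BRANCH), []):
            nonafr_ids = np.append(nonafr_ids, vid)
            nonafr_freq = np.append(nonafr_freq, p_init(nonafr_sizes[step]))
        for freq, size in ((afr_freq, afr_sizes[step]), (nonafr_freq, nonafr_sizes[step])):
            active = (freq > 0) & (freq < 1)
            if active.any():
                freq[active] = rng.binomial(2 * size, freq[active]) / (2 * size)
        if gen in ancient_gens:
            snapshots[gen] = (nonafr_ids.copy(), nonafr_freq.copy())

    # --- identities and truth --------------------------------------------
    n_variants = len(arise_gen)
    catalog, slots = _toy_catalog(max(n_variants, 1))
    bases = np.array(list("ACGT"))
    variants: list[GenomicVariant] = []
    for i in range(n_variants):
        gene, pos = slots[i]
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(GenomicVariant(chrom="1", pos=pos,
                                       ref=str(bases[ref]), alt=str(bases[alt]),
                                       hgvs_c=f"c.{i + 1}N>N"))
    truth = [TruthRecord(variant=variants[i], arising_generation=arise_gen[i],
                         arising_lineage=arise_lineage[i],
                         arising_years_bp=arise_gen[i] * gy)
             for i in range(n_variants)]

    # --- modern cohort sampling ------------------------------------------
    def sample_cohort(label: str, n_ind: int, id_arr: np.ndarray,
                      freq_arr: np.ndarray) -> CohortVariantTable:
        rows = []
        an = 2 * n_ind
        for vid, p in zip(id_arr, freq_arr):
            if p <= 0.0:
                continue
            ac = int(rng.binomial(an, min(p, 1.0)))
            if ac > 0:
                v = variants[int(vid)]
                rows.append((v, ac, an, "nonsynonymous SNV"))
        rows.sort(key=lambda r: (r[0].chrom, r[0].pos, r[0].ref, r[0].alt))
        return CohortVariantTable(population_label=label, sample_size=n_ind, rows=rows)

    african = sample_cohort("African", params.african_cohort_size, afr_ids, afr_freq)
    nonafrican = [sample_cohort(label, n, nonafr_ids, nonafr_freq)
                  for label, n in params.nonafrican_cohorts]

    # --- ancient sampling -------------------------------------------------
    ancient: list[AncientSample] = []
    counter = 0
    for date_bp, n_samples, miss in params.ancient_sampling:
        gen = round(date_bp / gy)
        id_arr, freq_arr = snapshots.get(gen, (np.zeros(0, np.int64), np.zeros(0)))
        carrier_pool = [(int(vid), float(p)) for vid, p in zip(id_arr, freq_arr) if p > 0]
        for _ in range(n_samples):
            counter += 1
            observed: set[GenomicVariant] = set()
            for vid, p in carrier_pool:
                copies = rng.binomial(2, min(p, 1.0))
                if copies > 0 and rng.random() >= miss:
                    observed.add(variants[vid])
            ancient.append(AncientSample(sample_id=f"ANC{counter:05d}",
                                         date_bp=date_bp,
                                         observed_variants=observed))

    assertions = {v: ClinicalAssertion(v, "Pathogenic", ClinicalClass.PV)
                  for v in variants}
    return SimulatedStudy(params=params, catalog=catalog, african_cohort=african,
                          nonafrican_cohorts=nonafrican, assertions=assertions,
                          ancient_samples=ancient, truth=truth)


def evaluate_epoch_recovery(truth: Sequence[TruthRecord],
                            patterns: dict) -> tuple[dict, float]:
    """Confront sharing classifications with true arising lineages.

    Returns (confusion, accuracy): ``confusion[lineage][pattern]`` counts
    classified variants, and accuracy is the fraction of classified
    variants recovered correctly — a non-African-branch variant classified
    NONAFRICAN_ONLY, or an ancestral variant classified BOTH or
    AFRICAN_ONLY.
    """
    from .sharing_analysis import SharingPattern

    by_variant = {t.variant: t for t in truth}
    missing = [v for v in patterns if v not in by_variant]
    if missing:
        raise ConfigurationError(
            f"{len(missing)} classified variants missing from truth")
    confusion = {lin: {pat: 0 for pat in SharingPattern} for lin in Lineage}
    n_correct = 0
    for v, pat in patterns.items():
        lin = by_variant[v].arising_lineage
        confusion[lin][pat] += 1
        if lin is Lineage.NONAFRICAN_BRANCH and pat is SharingPattern.NONAFRICAN_ONLY:
            n_correct += 1
        elif lin is Lineage.ANCESTRAL and pat in (SharingPattern.BOTH,
                                                  SharingPattern.AFRICAN_ONLY):
            n_correct += 1
    accuracy = n_correct / len(patterns) if patterns else 0.0
    return confusion, accuracy


def classify_study(study: SimulatedStudy) -> dict:
    """Convenience: run the ancient-intermediate classifier on a simulated study."""
    from .sharing_analysis import classify_with_ancient

    return classify_with_ancient(study.ancient_keys(), study.african_keys(),
                                 study.nonafrican_keys())


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Serialize a study to the text formats the pipeline readers consume."""
    import csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "cohort_African.tsv"
    write_cohort_variants(study.african_cohort, p)
    paths["cohort_African"] = p
    for table in study.nonafrican_cohorts:
        p = outdir / f"cohort_{table.population_label}.tsv"
        write_cohort_variants(table, p)
        paths[f"cohort_{table.population_label}"] = p

    p = outdir / "clinvar.tsv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "significance"])
        for v in sorted(study.assertions, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            w.writerow([v.chrom, v.pos, v.ref, v.alt, study.assertions[v].significance])
    paths["clinvar"] = p

    p = outdir / "ancient_manifest.tsv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "date_bp", "lat", "lon", "variants"])
        for s in study.ancient_samples:
            tokens = ",".join(f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"
                              for v in sorted(s.observed_variants,
                                              key=lambda v: (v.chrom, v.pos)))
            w.writerow([s.sample_id, "" if s.date_bp is None else s.date_bp,
                        "", "", tokens])
    paths["manifest"] = p

    p = outdir / "catalog.tsv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "pathway", "chrom", "start", "end"])
        for sym in sorted(study.catalog.genes):
            rec = study.catalog[sym]
            for pw in rec.pathways:
                for chrom, start, end in rec.coding_intervals:
                    w.writerow([sym, pw, chrom, start, end])
    paths["catalog"] = p

    p = outdir / "truth.tsv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "arising_generation",
                    "arising_lineage", "arising_years_bp"])
        for t in study.truth:
            w.writerow([t.variant.chrom, t.variant.pos, t.variant.ref,
                        t.variant.alt, t.arising_generation,
                        t.arising_lineage.value, t.arising_years_bp])
    paths["truth"] = p
    return paths
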