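"""Forward-time Mendelian gene-drop simulator of trout hybrid zones.

Individuals carry two haplotypes over the nuclear panel; each haplotype
records, per locus, the taxon of origin of the allele, so true ancestry
(q_true) is exact bookkeeping rather than an estimate.  The observable
dosage at a locus diagnostic for taxon T is the number of haplotypes
whose origin at that locus is T.  Mitochondria are inherited from the
designated maternal parent.  Loci transmit independently (the panel is
genome-dispersed, and the site-level null model being exercised assumes
binomial allele counts); physical linkage in real salmonid genomes is a
deliberate simplification.  Discrete, non-overlapping generations; no
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    TAXA,
    TAXON_INDEX,
    GenotypeRecord,
    MarkerPanel,
)


@dataclass
class SimConfig:
    """Parameterization of one simulated hybrid-zone site.

    founder_composition maps taxon (or "F1:<A>x<B>") to founder counts;
    ``migration`` maps taxon to per-generation parental immigrant
    counts.  ``allele_miscall_rate`` flips each observed allele
    independently; ``missing_rate`` blanks whole locus calls.  The seed
    fully determines the output.
    """

    founder_composition: Mapping[str, int]
    generations: int = 0
    population_size: int = 100
    mating: str = "random"  # or "assortative"
    assortative_sigma: float = 0.1
    migration: Mapping[str, int] = field(default_factory=dict)
    allele_miscall_rate: float = 0.0
    missing_rate: float = 0.0
    sample_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.allele_miscall_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass
class Population:
    """origins: (n, 2, L) int8 array of per-allele taxon origins."""

    origins: np.ndarray
    mito: np.ndarray  # (n,) int8 taxon index
    panel: MarkerPanel

    @property
    def size(self) -> int:
        return self.origins.shape[0]

    def q_true(self) -> np.ndarray:
        """(n, 3) true ancestry fractions from allele-origin bookkeeping."""
        n, _, L = self.origins.shape
        out = np.empty((n, 3))
        for t in range(3):
            out[:, t] = (self.origins == t).sum(axis=(1, 2)) / (2 * L)
        return out

    def dosages(self) -> np.ndarray:
        """(n, L) observed diagnostic-allele dosages."""
        return (self.origins == self.panel.taxon_of[None, None, :]).sum(axis=1).astype(np.int8)


def _parental_individual(taxon: str, L: int) -> Tuple[np.ndarray, int]:
    t = TAXON_INDEX[taxon]
    return np.full((2, L), t, dtype=np.int8), t


def found_population(panel: MarkerPanel, composition: Mapping[str, int]) -> Population:
    """Build founders: parental fish are homozygous for their own taxon's
    origin everywhere; "F1:AxB" founders carry one full haplotype from
    each parent with the first taxon maternal."""
    L = panel.n_nuclear
    origins: List[np.ndarray] = []
    mito: List[int] = []
    for kind, count in composition.items():
        if count < 0:
            raise ValueError("negative founder count")
        for _ in range(count):
            if kind in TAXA:
                o, m = _parental_individual(kind, L)
            elif kind.startswith("F1:"):
                a, b = kind[3:].split("x")
                o = np.vstack(
                    [
                        np.full((1, L), TAXON_INDEX[a], dtype=np.int8),
                        np.full((1, L), TAXON_INDEX[b], dtype=np.int8),
                    ]
                )
                m = TAXON_INDEX[a]
            else:
                raise ValueError(f"unknown founder kind {kind!r}")
            origins.append(o)
            mito.append(m)
    if not origins:
        raise ValueError("empty founder composition")
    return Population(np.stack(origins), np.array(mito, dtype=np.int8), panel)


def found_admixed_population(
    panel: MarkerPanel,
    size: int,
    pool: Mapping[str, float],
    rng: np.random.Generator,
) -> Population:
    """Found an established admixed population from a well-mixed gene pool.

    Each allele origin is drawn iid from ``pool`` (taxon -> fraction),
    and each mitochondrion from the same proportions — the state a
    hybrid swarm converges to, where ancestry is randomly distributed
    both within and among individuals.  Use :func:`found_population`
    for parental founders when the transient approach to this state is
    the object of study.
    """
    if size < 2:
        raise ValueError("population size must be >= 2")
    fracs = np.zeros(3)
    for t, f in pool.items():
        fracs[TAXON_INDEX[t]] = f
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("pool fractions must sum to 1")
    L = panel.n_nuclear
    origins = rng.choice(3, size=(size, 2, L), p=fracs).astype(np.int8)
    mito = rng.choice(3, size=size, p=fracs).astype(np.int8)
    return Population(origins, mito, panel)


def advance_generation(
    population: Population,
    rng: np.random.Generator,
    n_offspring: Optional[int] = None,
    mating: str = "random",
    assortative_sigma: float = 0.1,
    migration: Optional[Mapping[str, int]] = None,
) -> Population:
    """One discrete generation of mating, then immigration.

    Mothers are drawn uniformly.  Under random mating fathers are
    uniform among the other individuals; under assortative mating the
    father is drawn with weight exp(-(dq)^2 / sigma^2) on the distance
    between candidate admixture fractions.  Each locus transmits one
    uniformly chosen allele per parent, independently across loci; the
    mitochondrion copies from the mother.  Parental immigrants are
    appended after reproduction.
    """
    n = population.size
    if n < 2:
        raise ValueError("need at least two individuals to mate")
    if n_offspring is None:
        n_offspring = n
    L = population.panel.n_nuclear
    mothers = rng.integers(0, n, size=n_offspring)
    if mating == "random":
        # uniform among all individuals except the mother
        fathers = rng.integers(0, n - 1, size=n_offspring)
        fathers[fathers >= mothers] += 1
    elif mating == "assortative":
        q = population.q_true()
        admix = 1.0 - q[:, TAXON_INDEX["WCT"]]
        fathers = np.empty(n_offspring, dtype=int)
        for i, m in enumerate(mothers):
            w = np.exp(-((admix - admix[m]) ** 2) / assortative_sigma**2)
            w[m] = 0.0
            w = w / w.sum()
            fathers[i] = rng.choice(n, p=w)
    else:
        raise ValueError(f"unknown mating model {mating!r}")
    pick_m = rng.integers(0, 2, size=(n_offspring, L))
    pick_f = rng.integers(0, 2, size=(n_offspring, L))
    cols = np.arange(L)[None, :]
    hap_m = population.origins[mothers[:, None], pick_m, cols]
    hap_f = population.origins[fathers[:, None], pick_f, cols]
    origins = np.stack([hap_m, hap_f], axis=1).astype(np.int8)
    mito = population.mito[mothers].copy()
    pop = Population(origins, mito, population.panel)
    if migration:
        extra_o, extra_m = [], []
        for taxon, count in migration.items():
            for _ in range(count):
                o, m = _parental_individual(taxon, L)
                extra_o.append(o)
                extra_m.append(m)
        if extra_o:
            pop = Population(
                np.concatenate([pop.origins, np.stack(extra_o)]),
                np.concatenate([pop.mito, np.array(extra_m, dtype=np.int8)]),
                population.panel,
            )
    return pop


def apply_genotyping_noise(
    dosages: np.ndarray,
    e: float,
    m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-allele miscalls at rate ``e`` and per-locus dropout at ``m``.

    A miscall flips one allele between the diagnostic and alternative
    state: dosage d gains Binomial(2-d, e) spurious diagnostic alleles
    and loses Binomial(d, e) real ones.
    """
    if not (0.0 <= e <= 1.0 and 0.0 <= m <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    d = dosages.astype(np.int8).copy()
    if e > 0:
        loss = rng.binomial(np.maximum(d, 0), e)
        gain = rng.binomial(2 - np.maximum(d, 0), e)
        d = (d - loss + gain).astype(np.int8)
    if m > 0:
        mask = rng.random(d.shape) < m
        d[mask] = MISSING
    return d


def sample_site(
    population: Population,
    n: int,
    rng: np.random.Generator,
    site_id: str = "sim-site",
    stream_id: str = "sim-stream",
    site_class: str = "PIBO",
    rt_native: bool = False,
    allele_miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> Tuple[List[GenotypeRecord], pd.DataFrame]:
    """Simple random sample of ``n`` fish, emitted as genotype records
    plus a ground-truth table (true q per taxon and mitotype)."""
    if n > population.size:
        raise ValueError(f"sample size {n} exceeds population size {population.size}")
    idx = rng.choice(population.size, size=n, replace=False)
    dosages = population.dosages()[idx]
    noisy = apply_genotyping_noise(dosages, allele_miscall_rate, missing_rate, rng)
    q = population.q_true()[idx]
    records = []
    truth_rows = []
    for i, (row, mito_idx) in enumerate(zip(noisy, population.mito[idx])):
        ind = f"{site_id}-{i:03d}"
        records.append(
            GenotypeRecord(
                individual_id=ind,
                stream_id=stream_id,
                site_id=site_id,
                site_class=site_class,
                rt_native=rt_native,
                mitotype=TAXA[mito_idx],
                calls=row,
            )
        )
        truth_rows.append(
            {
                "individual_id": ind,
                "q_wct": q[i, 0],
                "q_rt": q[i, 1],
                "q_yct": q[i, 2],
                "mitotype": TAXA[mito_idx],
            }
        )
    return records, pd.DataFrame(truth_rows)


SCENARIOS = ("pure_parental", "recent_contact", "swarm", "three_way", "longitudinal_gradient")


def scenario(
    name: str,
    panel: MarkerPanel,
    seed: int = 0,
    **params,
) -> Tuple[List[GenotypeRecord], pd.DataFrame]:
    """Canned hybrid-zone archetypes.

    pure_parental(taxon, n): a single-taxon site.
    recent_contact(n_wct, n_rt, n_f1): parentals plus F1s, no mixing.
    swarm(generations, p0, population_size, n): random mating from an
        initial nonnative fraction p0.
    three_way(generations, n_wct, n_rt, n_yct, n): all three taxa mixing.
    longitudinal_gradient(n_sites, ...): sites with upstream-attenuating
        rainbow trout immigration.
    """
    rng = np.random.default_rng(seed)
    e = params.pop("allele_miscall_rate", 0.0)
    m = params.pop("missing_rate", 0.0)
    if name == "pure_parental":
        taxon = params.pop("taxon", "WCT")
        n = params.pop("n", 30)
        pop = found_population(panel, {taxon: max(n, 2)})
        return sample_site(pop, n, rng, site_id=f"pure-{taxon}",
                           allele_miscall_rate=e, missing_rate=m)
    if name == "recent_contact":
        n_wct = params.pop("n_wct", 20)
        n_rt = params.pop("n_rt", 5)
        n_f1 = params.pop("n_f1", 5)
        pop = found_population(
            panel, {"WCT": n_wct, "RT": n_rt, "F1:WCTxRT": n_f1}
        )
        return sample_site(pop, pop.size, rng, site_id="recent-contact",
                           allele_miscall_rate=e, missing_rate=m)
    if name == "swarm":
        g = params.pop("generations", 10)
        p0 = params.pop("p0", 0.3)
        pop_size = params.pop("population_size", 1000)
        n = params.pop("n", 30)
        founders = params.pop("founders", "pool")
        if founders == "parental":
            n_rt = int(round(p0 * pop_size))
            pop = found_population(panel, {"RT": n_rt, "WCT": pop_size - n_rt})
        else:
            pop = found_admixed_population(panel, pop_size, {"RT": p0, "WCT": 1 - p0}, rng)
        for _ in range(g):
            pop = advance_generation(pop, rng, n_offspring=pop_size)
        return sample_site(pop, n, rng, site_id="swarm",
                           allele_miscall_rate=e, missing_rate=m)
    if name == "three_way":
        g = params.pop("generations", 10)
        n_wct = params.pop("n_wct", 100)
        n_rt = params.pop("n_rt", 50)
        n_yct = params.pop("n_yct", 50)
        n = params.pop("n", 30)
        pop = found_population(panel, {"WCT": n_wct, "RT": n_rt, "YCT": n_yct})
        size = pop.size
        for _ in range(g):
            pop = advance_generation(pop, rng, n_offspring=size)
        return sample_site(pop, n, rng, site_id="three-way",
                           allele_miscall_rate=e, missing_rate=m)
    if name == "longitudinal_gradient":
        n_sites = params.pop("n_sites", 4)
        g = params.pop("generations", 8)
        pop_size = params.pop("population_size", 100)
        n = params.pop("n", 25)
        base_migration = params.pop("base_migration", 8)
        records: List[GenotypeRecord] = []
        truths = []
        classes = ["Low", "PIBO", "Middle", "Headwater"]
        for s in range(n_sites):
            mig = max(base_migration >> s, 0)  # halve immigrant pressure upstream
            pop = found_population(panel, {"WCT": pop_size})
            for _ in range(g):
                pop = advance_generation(
                    pop, rng, n_offspring=pop_size, migration={"RT": mig}
                )
            recs, truth = sample_site(
                pop,
                min(n, pop.size),
                rng,
                site_id=f"gradient-{s}",
                stream_id="gradient",
                site_class=classes[min(s, 3)],
                allele_miscall_rate=e,
                missing_rate=m,
            )
            truth["site_id"] = f"gradient-{s}"
            records.extend(recs)
            truths.append(truth)
        return records, pd.concat(truths, ignore_index=True)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
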