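"""Synthetic-data generators with the structure the analyses assume.

Every pipeline input can be generated here: mating-trial records with
configurable per-cell mounting probabilities and log-normal mount
durations, genital-feature tables as group-mean multivariate normals with
a shared allometric component, and diploid genotype matrices built by
pairing haploid tags simulated under a secondary-contact demographic
model.  All generators are deterministic given their seed and emit exactly
the CSV/VCF/FASTA dialects the analysis modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mating import TrialRecord, SPECIES, LOCATIONS
from .demography import DemographicModel, TagDataset, simulate_tags
from .popgen import GenotypeMatrix

# default per-cell mounting probabilities: the published trial outcomes
# (counts / totals per female x male cell)
_DEFAULT_MOUNT_PROB = {
    "sympatric": [[54 / 117, 4 / 115], [28 / 117, 33 / 119]],
    "allopatric": [[38 / 118, 40 / 117], [49 / 118, 86 / 119]],
}

# log-minute duration parameters: conspecific mounts long, heterospecific
# mounts short in sympatry only (the displacement signal in duration)
_DEFAULT_DURATION = {
    "sympatric": [[(4.0, 1.0), (2.0, 1.0)], [(2.0, 1.0), (4.0, 1.0)]],
    "allopatric": [[(4.0, 1.0), (3.5, 1.0)], [(3.5, 1.0), (4.0, 1.0)]],
}

_SIZE_DIST = {  # shell length, mm: (male mean, female mean, sd)
    "cingulata": (17.0, 18.0, 2.5),
    "filosa": (20.0, 22.0, 3.0),
}


@dataclass
class TrialSimConfig:
    """Generator settings for no-choice mating trials."""

    mount_prob: dict = field(default_factory=lambda: {k: np.array(v) for k, v in _DEFAULT_MOUNT_PROB.items()})
    duration_lognormal: dict = field(default_factory=lambda: _DEFAULT_DURATION)
    insertion_prob_given_mount: float = 0.675
    sperm_logit_intercept: float = -2.4
    sperm_logit_slope: float = 0.59
    n_trials_per_cell: int = 60
    batch_size: int = 20
    researchers: tuple = ("R1", "R2")


def gen_trials(cfg: TrialSimConfig, seed: int) -> list[TrialRecord]:
    """Generate mating-trial records under the configured cell probabilities.

    Mounts are Bernoulli per cell, durations log-normal per cell, penis
    insertion Bernoulli given a mount, and sperm-in-bursa follows a
    logistic model in the log mean duration.  Researcher and time block are
    assigned in balanced batches (three morning and three afternoon batches
    per simulated day, alternating researcher).
    """
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    cells = [
        (loc, fi, mi)
        for loc in LOCATIONS
        for fi in range(2)
        for mi in range(2)
    ]
    trials = [cell for cell in cells for _ in range(cfg.n_trials_per_cell)]
    order = rng.permutation(len(trials))
    for k, t in enumerate(order):
        loc, fi, mi = trials[t]
        f_sp, m_sp = SPECIES[fi], SPECIES[mi]
        batch = k // cfg.batch_size
        time_block = "AM" if (batch % 6) < 3 else "PM"
        researcher = cfg.researchers[batch % len(cfg.researchers)]
        p = float(np.asarray(cfg.mount_prob[loc])[fi, mi])
        mounted = bool(rng.random() < p)
        durations: list[float] = []
        insertion = None
        sperm = None
        if mounted:
            mu, sig = cfg.duration_lognormal[loc][fi][mi]
            n_mounts = 1 + rng.poisson(0.3)
            durations = list(np.exp(rng.normal(mu, sig, size=n_mounts)))
            insertion = bool(rng.random() < cfg.insertion_prob_given_mount)
            eta = cfg.sperm_logit_intercept + cfg.sperm_logit_slope * np.log(np.mean(durations))
            sperm = bool(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
        m_mean, f_mean, sd = _SIZE_DIST[m_sp][0], _SIZE_DIST[f_sp][1], 2.5
        sites = {"sympatric": ("S1", "S2"), "allopatric": ("A1", "A2")}[loc]
        ms, fs = (sites if rng.random() < 0.5 else sites[::-1])
        records.append(
            TrialRecord(
                trial_id=f"T{k:05d}",
                male_species=m_sp,
                female_species=f_sp,
                male_site=ms,
                female_site=fs,
                location_class=loc,
                mounted=mounted,
                mount_durations=durations,
                insertion_observed=insertion,
                sperm_in_bursa=sperm,
                male_size_mm=float(rng.normal(m_mean, sd)),
                female_size_mm=float(rng.normal(f_mean, sd)),
                female_maturity=str(rng.choice(["maturing", "mature", "spent"], p=[0.2, 0.7, 0.1])),
                researcher=researcher,
                time_block=time_block,
                male_id=f"M{k:05d}",
            )
        )
    return records


@dataclass
class MorphSimConfig:
    """Generator settings for genital-feature tables (labels A..K, mm).

    Feature A is overall length; the other ten follow a shared allometric
    slope on A plus a group mean (species x location) and multivariate
    normal noise with a shared covariance.  ``sympatry_offset_scale``
    multiplies the species difference vector in sympatry (1.0 = no
    character displacement).
    """

    n_per_group: int = 30
    length_mean: dict = field(default_factory=lambda: {"cingulata": 5.0, "filosa": 5.5})
    length_sd: float = 0.5
    base_mean: np.ndarray = field(default_factory=lambda: np.linspace(0.6, 2.4, 10))
    species_offset: np.ndarray = field(default_factory=lambda: np.full(10, 0.15))
    sympatry_offset_scale: float = 1.0
    allometric_slope: np.ndarray = field(default_factory=lambda: np.full(10, 0.2))
    noise_cov: np.ndarray = field(default_factory=lambda: np.eye(10) * 0.01)

    def __post_init__(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")


def gen_morph(cfg: MorphSimConfig, seed: int) -> pd.DataFrame:
    """Generate a morphometric feature table (columns male_id, species,
    location, A..K)."""
    if cfg.n_per_group == 0:
        raise ValueError("n_per_group must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    labels = list("BCDEFGHIJK")
    k = 0
    for loc in LOCATIONS:
        for sp in SPECIES:
            scale = cfg.sympatry_offset_scale if loc == "sympatric" else 1.0
            group_mean = cfg.base_mean + (cfg.species_offset * scale if sp == "filosa" else 0.0)
            A = rng.normal(cfg.length_mean[sp], cfg.length_sd, size=cfg.n_per_group)
            noise = rng.multivariate_normal(np.zeros(10), cfg.noise_cov, size=cfg.n_per_group)
            feats = group_mean + cfg.allometric_slope * (A[:, None] - 5.0) + noise
            feats = np.clip(feats, 1e-3, None)
            for i in range(cfg.n_per_group):
                row = dict(male_id=f"P{k:05d}", species=sp, location=loc, A=float(A[i]))
                row.update({lab: float(feats[i, j]) for j, lab in enumerate(labels)})
                rows.append(row)
                k += 1
    return pd.DataFrame(rows)


def gen_genotypes(
    model: DemographicModel,
    n_indiv_per_pop: int = 15,
    n_tags: int = 500,
    seed: int = None,
    mu: float = 1e-8,
    missing_rate: float = 0.0,
    **sim_kwargs,
) -> tuple[GenotypeMatrix, TagDataset]:
    """Diploid genotypes from paired haploid tags under a demographic model.

    Simulates ``2 * n_indiv_per_pop`` haploid tag sequences per population
    and pairs consecutive haploids within a population into diploids
    (random pairing under the coalescent; consistent with Hardy-Weinberg
    within each region).  Returns the genotype matrix (with tag/position
    locus metadata) and the underlying haploid tag dataset.
    """
    if seed is None:
        raise ValueError("a seed is required")
    tags = simulate_tags(model, n_tags=n_tags, n_per_pop=2 * n_indiv_per_pop, mu=mu, seed=seed, **sim_kwargs)
    rng = np.random.default_rng(seed + 1)
    n_pops = len(dict.fromkeys(tags.sample_pops))
    cols, loci_rows = [], []
    for tag, G, pos in zip(tags.tag_ids, tags.genotypes, tags.positions):
        ipos = np.floor(pos).astype(int)
        # unique integer coordinates within the tag (collisions dropped)
        _, first = np.unique(ipos, return_index=True)
        for s in sorted(first):
            dip = G[s].reshape(-1, 2).sum(axis=1)  # pair consecutive haploids
            cols.append(dip.astype(np.int8))
            loci_rows.append(dict(locus_id=f"{tag}_{ipos[s]}", tag_id=tag, pos_in_tag=int(ipos[s]), ref="A", alt="T"))
    if not cols:
        raise ValueError("no polymorphic sites simulated; increase n_tags or mu")
    g = np.array(cols).T
    if missing_rate > 0:
        mask = rng.random(g.shape) < missing_rate
        g = np.where(mask, -1, g)
    pops = list(tags.sample_pops[::2])
    species = ["cingulata" if p.startswith("C") else "filosa" for p in pops]
    region = ["sympatric" if "symp" in p else "allopatric" for p in pops]
    samples = pd.DataFrame(
        dict(
            indiv=[f"{p}_d{i % n_indiv_per_pop}" for i, p in enumerate(pops)],
            species=species,
            site=pops,
            region=region,
        )
    )
    gm = GenotypeMatrix(g, samples, pd.DataFrame(loci_rows))
    return gm, tags
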