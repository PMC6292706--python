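"""Coalescent simulation of secondary-contact demographic models.

Four populations are sampled: allopatric and sympatric regions of each of
two species (order ``C_allo, C_symp, F_symp, F_allo``).  Backwards in time,
regions merge into their species' ancestor at ``t_reg_c`` / ``t_reg_f`` and
the species merge at ``t_sp``; current populations have size ``n_now`` and
ancestral branches ``n_anc``.  Regions within a species exchange
``m_intra`` migrants per generation until they merge.  The four competing
models differ only in interspecific migration between the two sympatric
populations after secondary contact at ``t_sc``:

* ``NM`` - no migration at any time;
* ``CM`` - constant migration throughout ``[0, t_sc]``;
* ``RM`` - recent migration only, on ``[0, t_rm]`` with ``t_rm < t_sc``;
* ``AM`` - ancient migration only, on ``[t_am, t_sc]`` with ``0 < t_am < t_sc``.

Loci are short non-recombining sequence tags (82 bp by default), mutated
under the infinite-sites model, sampled as one haploid allele per
individual.  Times are generations, sizes are haploid effective population
sizes, and migration is given in migrants per generation (converted
internally to the fraction of a population replaced per generation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

POPULATIONS = ("C_allo", "C_symp", "F_symp", "F_allo")
MODEL_IDS = ("NM", "CM", "RM", "AM")
TAG_LENGTH = 82

_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 4)]
PAIR_NAMES = [f"{POPULATIONS[i]}:{POPULATIONS[j]}" for i, j in _PAIRS]


@dataclass
class DemographicModel:
    """One secondary-contact scenario with its parameter vector."""

    model_id: str
    t_sp: float
    t_reg_c: float
    t_reg_f: float
    n_now: float
    n_anc: float
    m_intra: float = 0.0
    t_sc: float = 1e4
    m_inter: float = 0.0
    t_rm: float | None = None   # RM only: migration on [0, t_rm]
    t_am: float | None = None   # AM only: migration on [t_am, t_sc]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if not (0 < self.t_reg_c < self.t_sp and 0 < self.t_reg_f < self.t_sp):
            raise ValueError("require 0 < t_reg_* < t_sp")
        if not (0 <= self.t_sc <= min(self.t_reg_c, self.t_reg_f)):
            raise ValueError("require 0 <= t_sc <= min(t_reg_c, t_reg_f)")
        if self.n_now <= 0 or self.n_anc <= 0:
            raise ValueError("population sizes must be positive")
        if self.m_intra < 0 or self.m_inter < 0:
            raise ValueError("migration rates must be non-negative")
        if self.model_id == "NM" and self.m_inter != 0:
            raise ValueError("NM model has no interspecific migration")
        if self.model_id == "RM":
            if self.t_rm is None or not (0 < self.t_rm < self.t_sc):
                raise ValueError("RM requires 0 < t_rm < t_sc")
        if self.model_id == "AM":
            if self.t_am is None or not (0 < self.t_am < self.t_sc):
                raise ValueError("AM requires 0 < t_am < t_sc")

    def with_params(self, **kwargs) -> "DemographicModel":
        return replace(self, **kwargs)


def build_demography(model: DemographicModel):
    """Translate a :class:`DemographicModel` into an msprime Demography."""
    import msprime

    model.validate()
    dem = msprime.Demography()
    for name in POPULATIONS:
        dem.add_population(name=name, initial_size=model.n_now)
    dem.add_population(name="anc_c", initial_size=model.n_anc)
    dem.add_population(name="anc_f", initial_size=model.n_anc)
    dem.add_population(name="anc", initial_size=model.n_anc)

    # migrants/generation -> per-generation replacement fraction
    r_intra = model.m_intra / model.n_now
    r_inter = model.m_inter / model.n_now
    if r_intra > 0:
        dem.set_symmetric_migration_rate(["C_allo", "C_symp"], r_intra)
        dem.set_symmetric_migration_rate(["F_allo", "F_symp"], r_intra)
    inter = ("C_symp", "F_symp")
    if model.model_id == "CM" and r_inter > 0:
        dem.set_symmetric_migration_rate(inter, r_inter)
        dem.add_symmetric_migration_rate_change(model.t_sc, inter, 0.0)
    elif model.model_id == "RM" and r_inter > 0:
        dem.set_symmetric_migration_rate(inter, r_inter)
        dem.add_symmetric_migration_rate_change(model.t_rm, inter, 0.0)
    elif model.model_id == "AM" and r_inter > 0:
        dem.add_symmetric_migration_rate_change(model.t_am, inter, r_inter)
        dem.add_symmetric_migration_rate_change(model.t_sc, inter, 0.0)

    dem.add_population_split(model.t_reg_c, derived=["C_allo", "C_symp"], ancestral="anc_c")
    dem.add_population_split(model.t_reg_f, derived=["F_allo", "F_symp"], ancestral="anc_f")
    dem.add_population_split(model.t_sp, derived=["anc_c", "anc_f"], ancestral="anc")
    dem.sort_events()
    return dem


# ---------------------------------------------------------------------------
# Tag dataset
# ---------------------------------------------------------------------------

@dataclass
class TagDataset:
    """Biallelic variation at non-recombining haploid sequence tags.

    ``genotypes`` holds one (n_sites x n_samples) 0/1 array per polymorphic
    tag; ``positions`` the corresponding within-tag coordinates.  Samples
    are haploid (one allele per individual) and ``sample_pops`` assigns each
    column to a population label.
    """

    genotypes: list[np.ndarray]
    positions: list[np.ndarray]
    tag_ids: list[str]
    sample_pops: np.ndarray
    sample_ids: list[str]
    tag_length: int = TAG_LENGTH
    n_monomorphic: int = 0

    @property
    def n_tags(self) -> int:
        return len(self.genotypes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_pops)

    def to_fasta(self, path) -> None:
        """Write tags as FASTA, one record per sample per tag.

        Headers are ``>tagID|indiv|pop``.  The ancestral base is written as
        ``A`` and the derived base as ``T``; sites at the same (floored)
        integer coordinate keep the first variant (collisions are rare
        under the infinite-sites model on continuous coordinates).
        """
        with open(path, "w") as fh:
            for tag, G, pos in zip(self.tag_ids, self.genotypes, self.positions):
                ipos = np.floor(pos).astype(int)
                _, first = np.unique(ipos, return_index=True)
                for k in range(self.n_samples):
                    seq = np.full(self.tag_length, "A")
                    carried = first[G[first, k] == 1] if len(first) else []
                    seq[ipos[carried]] = "T"
                    fh.write(f">{tag}|{self.sample_ids[k]}|{self.sample_pops[k]}\n")
                    fh.write("".join(seq) + "\n")

    @classmethod
    def from_fasta(cls, path, tag_length: int = TAG_LENGTH) -> "TagDataset":
        """Read a tag FASTA with ``>tagID|indiv|pop`` headers."""
        per_tag: dict[str, list[tuple[str, str, str]]] = {}
        records: list[tuple[str, str, str, str]] = []
        header, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if header is not None:
                        records.append((*header, "".join(chunks)))
                    tag, indiv, pop = line[1:].split("|")
                    header, chunks = (tag, indiv, pop), []
                else:
                    chunks.append(line)
            if header is not None:
                records.append((*header, "".join(chunks)))
        for tag, indiv, pop, seq in records:
            per_tag.setdefault(tag, []).append((indiv, pop, seq))
        first = next(iter(per_tag.values()))
        sample_ids = [r[0] for r in first]
        sample_pops = np.array([r[1] for r in first])
        genotypes, positions, tag_ids = [], [], []
        n_mono = 0
        for tag, rows in per_tag.items():
            M = np.array([list(r[2]) for r in rows]).T  # sites x samples
            seg = np.array([len(set(row)) > 1 for row in M])
            if not seg.any():
                n_mono += 1
                continue
            sites = np.where(seg)[0]
            G = np.zeros((len(sites), len(rows)), dtype=np.int8)
            for si, s in enumerate(sites):
                # minor/derived allele = anything not equal to the ancestral 'A'
                G[si] = (M[s] != "A").astype(np.int8)
            genotypes.append(G)
            positions.append(sites.astype(float))
            tag_ids.append(tag)
        return cls(genotypes, positions, tag_ids, sample_pops, sample_ids,
                   tag_length=tag_length, n_monomorphic=n_mono)


def simulate_tags(
    model: DemographicModel,
    n_tags: int = 200,
    n_per_pop: int = 5,
    mu: float = 1e-8,
    seed: int | None = None,
    theta_per_tag: float | None = None,
    rate_gamma_shape: float | None = 2.0,
    tag_length: int = TAG_LENGTH,
    exclude_monomorphic: bool = True,
    populations: tuple[str, ...] = POPULATIONS,
) -> TagDataset:
    """Simulate haploid sequence tags under a secondary-contact model.

    Each tag is an independent non-recombining coalescent genealogy for
    ``n_per_pop`` haploid samples per population, mutated under the
    infinite-sites model at per-site rate ``mu`` (alternatively pass
    ``theta_per_tag`` = 2 * n_now * mu * tag_length).  Mutation-rate
    heterogeneity across tags is Gamma-distributed with shape
    ``rate_gamma_shape`` and mean ``mu`` (pass ``None`` for a constant
    rate).  Monomorphic tags are excluded (counted) by default, matching
    the treatment of observed tag data.
    """
    import msprime

    if seed is None:
        raise ValueError("a seed is required")
    model.validate()
    if theta_per_tag is not None:
        mu = theta_per_tag / (2.0 * model.n_now * tag_length)
    rng = np.random.default_rng(seed)
    dem = build_demography(model)
    sample_sets = [msprime.SampleSet(n_per_pop, population=p, ploidy=1) for p in populations]
    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        ploidy=1,
        sequence_length=tag_length,
        num_replicates=n_tags,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    if rate_gamma_shape is not None:
        rates = mu * rng.gamma(rate_gamma_shape, 1.0 / rate_gamma_shape, size=n_tags)
    else:
        rates = np.full(n_tags, mu)

    n_samples = n_per_pop * len(populations)
    genotypes, positions, tag_ids = [], [], []
    n_mono = 0
    for j, ts in enumerate(reps):
        # infinite-sites mutations placed directly on the genealogy: the
        # number of mutations is Poisson in (rate x tag length x total branch
        # length) and each falls on a branch with probability proportional to
        # its length, at a fresh uniform position
        tree = ts.first()
        parent = tree.parent_array[: ts.num_nodes]
        times = ts.nodes_time
        has_parent = parent >= 0
        blen = np.where(has_parent, times[np.clip(parent, 0, None)] - times, 0.0)
        total = blen.sum()
        n_mut = rng.poisson(rates[j] * tag_length * total)
        if n_mut == 0:
            n_mono += 1
            if not exclude_monomorphic:
                genotypes.append(np.zeros((0, n_samples), dtype=np.int8))
                positions.append(np.zeros(0))
                tag_ids.append(f"tag{j:06d}")
            continue
        branch_nodes = rng.choice(len(blen), size=n_mut, p=blen / total)
        pos = np.sort(rng.uniform(0, tag_length, size=n_mut))
        G = np.zeros((n_mut, n_samples), dtype=np.int8)
        for si, v in enumerate(branch_nodes):
            G[si, np.fromiter(tree.samples(int(v)), dtype=np.int64)] = 1
        genotypes.append(G)
        positions.append(pos)
        tag_ids.append(f"tag{j:06d}")

    sample_pops = np.repeat(populations, n_per_pop)
    sample_ids = [f"{p}_{i}" for p in populations for i in range(n_per_pop)]
    if exclude_monomorphic and n_mono:
        logger.debug("excluded %d monomorphic tag(s)", n_mono)
    return TagDataset(genotypes, positions, tag_ids, sample_pops, sample_ids,
                      tag_length=tag_length, n_monomorphic=n_mono)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _tajd_constants(n: int):
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def summary_stat_names(populations=POPULATIONS) -> list[str]:
    names = []
    pops = list(populations)
    for p in pops:
        for s in ("S", "pi", "tajd"):
            names += [f"{s}_mean_{p}", f"{s}_var_{p}"]
        names += [f"pi_q10_{p}", f"pi_q90_{p}"]
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pair = f"{pops[i]}:{pops[j]}"
            for s in ("fst", "dxy", "shared", "priv1", "priv2"):
                names += [f"{s}_mean_{pair}", f"{s}_var_{pair}"]
            names += [f"fst_q10_{pair}", f"fst_q90_{pair}",
                      f"dxy_q10_{pair}", f"dxy_q90_{pair}"]
    return names


def summarize(tags: TagDataset) -> "pd.Series":
    """Fixed-length summary-statistic vector over a tag dataset.

    Per population: mean and variance across tags of the number of
    segregating sites S, nucleotide diversity pi (mean pairwise differences
    per tag), and Tajima's D (over tags where it is defined), plus the
    lower and upper deciles of pi.  Per population pair: mean and variance
    of Hudson's F_ST (ratio of sums within tag), d_xy, and counts of shared
    and private polymorphisms, plus the deciles of F_ST and d_xy (the
    low-divergence tail is where recent gene flow shows).  Deterministic
    given the input; undefined per-tag values are skipped.
    """
    import pandas as pd

    pops = list(dict.fromkeys(tags.sample_pops))
    K = tags.n_tags
    names = summary_stat_names(pops)
    if K == 0:
        return pd.Series(np.zeros(len(names)), index=names)

    A = np.concatenate(tags.genotypes, axis=0) if K else np.zeros((0, tags.n_samples))
    tag_idx = np.repeat(np.arange(K), [g.shape[0] for g in tags.genotypes])
    cols = {p: np.where(tags.sample_pops == p)[0] for p in pops}
    n_per = {p: len(cols[p]) for p in pops}

    d = {p: A[:, cols[p]].sum(axis=1).astype(float) for p in pops}
    out: dict[str, float] = {}

    def mv(prefix, vals):
        out[f"{prefix}_mean"] = float(np.mean(vals)) if len(vals) else 0.0
        out[f"{prefix}_var"] = float(np.var(vals)) if len(vals) else 0.0

    seg = {}
    S_tag, pi_tag = {}, {}
    for p in pops:
        n = n_per[p]
        dp = d[p]
        seg[p] = (dp > 0) & (dp < n)
        S = np.bincount(tag_idx, weights=seg[p].astype(float), minlength=K)
        h = dp * (n - dp) / (n * (n - 1) / 2.0)
        pi = np.bincount(tag_idx, weights=h, minlength=K)
        S_tag[p], pi_tag[p] = S, pi
        mv(f"S_{p}", S)
        mv(f"pi_{p}", pi)
        out[f"pi_{p}_q10"] = float(np.quantile(pi, 0.10)) if len(pi) else 0.0
        out[f"pi_{p}_q90"] = float(np.quantile(pi, 0.90)) if len(pi) else 0.0
        a1, e1, e2 = _tajd_constants(n)
        has = S > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            var_d = e1 * S + e2 * S * (S - 1)
            tajd = (pi - S / a1) / np.sqrt(var_d)
        mv(f"tajd_{p}", tajd[has & np.isfinite(tajd)])

    for i, j in [(a, b) for a in range(len(pops)) for b in range(a + 1, len(pops))]:
        p, q = pops[i], pops[j]
        pair = f"{p}:{q}"
        n1, n2 = n_per[p], n_per[q]
        f1, f2 = d[p] / n1, d[q] / n2
        dxy_site = f1 * (1 - f2) + f2 * (1 - f1)
        dxy = np.bincount(tag_idx, weights=dxy_site, minlength=K)
        mv(f"dxy_{pair}", dxy)
        num_site = (f1 - f2) ** 2 - f1 * (1 - f1) / (n1 - 1) - f2 * (1 - f2) / (n2 - 1)
        num = np.bincount(tag_idx, weights=num_site, minlength=K)
        den = np.bincount(tag_idx, weights=dxy_site, minlength=K)
        ok = den > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.clip(num[ok] / den[ok], -1.0, 1.0)
        mv(f"fst_{pair}", fst)
        # lower/upper deciles: gene flow leaves a tail of low-divergence tags
        # that the means and variances wash out
        out[f"fst_{pair}_q10"] = float(np.quantile(fst, 0.10)) if len(fst) else 0.0
        out[f"fst_{pair}_q90"] = float(np.quantile(fst, 0.90)) if len(fst) else 0.0
        out[f"dxy_{pair}_q10"] = float(np.quantile(dxy, 0.10)) if len(dxy) else 0.0
        out[f"dxy_{pair}_q90"] = float(np.quantile(dxy, 0.90)) if len(dxy) else 0.0
        sh = np.bincount(tag_idx, weights=(seg[p] & seg[q]).astype(float), minlength=K)
        pr1 = np.bincount(tag_idx, weights=(seg[p] & ~seg[q]).astype(float), minlength=K)
        pr2 = np.bincount(tag_idx, weights=(seg[q] & ~seg[p]).astype(float), minlength=K)
        mv(f"shared_{pair}", sh)
        mv(f"priv1_{pair}", pr1)
        mv(f"priv2_{pair}", pr2)

    ordered = {}
    for name in names:
        parts = name.split("_")
        stat, kind = parts[0], parts[1]
        rest = "_".join(parts[2:])
        ordered[name] = out[f"{stat}_{rest}_{kind}"]
    return pd.Series(ordered)


def simulate_summary_stats(model: DemographicModel, seed: int, **sim_kwargs) -> "pd.Series":
    """Simulate one tag dataset under ``model`` and summarize it."""
    return summarize(simulate_tags(model, seed=seed, **sim_kwargs))
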