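"""Genotype QC, genotype PCA, Nei pairwise F_ST and hybrid diagnosis.

Entry point is a biallelic genotype matrix (individuals x loci, alternate
allele dosage 0/1/2, missing = -1) with per-locus tag metadata from
reduced-representation sequencing.  Filtering keeps the first SNP per tag,
drops loci out of Hardy-Weinberg equilibrium (exact test, mid-P by default)
in any region, and drops loci with low call rate.  F_ST between samples
uses Nei's heterozygosity partition, and a putative hybrid is classified
from its genotypes at species-diagnostic SNPs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


class GenotypeMatrix:
    """Individuals x biallelic loci, alternate-allele dosage coding.

    ``samples`` is a DataFrame with at least columns ``indiv, species, site,
    region``; ``loci`` a DataFrame with ``locus_id, tag_id, pos_in_tag`` (and
    optionally ``ref, alt``); ``genotypes`` an (n_indiv, n_loci) int8 array
    with entries in {0, 1, 2, -1}.
    """

    def __init__(self, genotypes, samples: pd.DataFrame, loci: pd.DataFrame):
        g = np.asarray(genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        bad = ~np.isin(g, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if len(samples) != g.shape[0] or len(loci) != g.shape[1]:
            raise ValueError("metadata shapes do not match the genotype matrix")
        if (loci["tag_id"].astype(str) == "").any():
            raise ValueError("empty tag_id")
        self.genotypes = g
        self.samples = samples.reset_index(drop=True)
        self.loci = loci.reset_index(drop=True)

    @property
    def n_indiv(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.genotypes[:, idx], self.samples, self.loci.iloc[idx])

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        """Read the packed genotype CSV (indiv,species,site,region + loci columns)."""
        df = pd.read_csv(path, dtype={"indiv": str})
        meta_cols = ["indiv", "species", "site", "region"]
        locus_cols = [c for c in df.columns if c not in meta_cols]
        g = df[locus_cols].fillna(MISSING).to_numpy()
        loci = pd.DataFrame(
            {
                "locus_id": locus_cols,
                "tag_id": [c.rsplit("_", 1)[0] for c in locus_cols],
                "pos_in_tag": [int(c.rsplit("_", 1)[1]) for c in locus_cols],
            }
        )
        return cls(g.astype(np.int8), df[meta_cols], loci)

    def to_csv(self, path) -> None:
        df = self.samples[["indiv", "species", "site", "region"]].copy()
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        names = [f"{t}_{p}" for t, p in zip(self.loci["tag_id"], self.loci["pos_in_tag"])]
        df = pd.concat([df, pd.DataFrame(g, columns=names)], axis=1)
        df.to_csv(path, index=False, float_format="%.0f")

    @classmethod
    def from_vcf(cls, vcf_path, meta: pd.DataFrame) -> "GenotypeMatrix":
        """Read biallelic SNPs from a VCF; tag_id is taken from CHROM.

        Multiallelic records are skipped with a warning.  ``meta`` must carry
        ``indiv, species, site, region`` for every VCF sample.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(vcf_path))
        order = {s: i for i, s in enumerate(vcf.samples)}
        meta = meta.set_index("indiv").loc[vcf.samples].reset_index()
        cols, rows = [], []
        n_multi = 0
        for var in vcf:
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            gt = var.gt_types  # 0=homref,1=het,2=unknown,3=homalt in cyvcf2
            g = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
            rows.append(g.astype(np.int8))
            cols.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
        if n_multi:
            warnings.warn(f"skipped {n_multi} multiallelic record(s)")
        loci = pd.DataFrame(cols, columns=["tag_id", "pos_in_tag", "ref", "alt"])
        loci.insert(0, "locus_id", loci["tag_id"] + "_" + loci["pos_in_tag"].astype(str))
        return cls(np.array(rows, dtype=np.int8).T, meta, loci)

    def write_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 text file (one record per locus)."""
        samples = list(self.samples["indiv"])
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for tag in dict.fromkeys(self.loci["tag_id"]):
                fh.write(f"##contig=<ID={tag}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            ref = self.loci.get("ref", pd.Series(["A"] * self.n_loci))
            alt = self.loci.get("alt", pd.Series(["T"] * self.n_loci))
            for j in range(self.n_loci):
                row = self.loci.iloc[j]
                gts = "\t".join(gt_str[int(g)] for g in self.genotypes[:, j])
                fh.write(
                    f"{row['tag_id']}\t{int(row['pos_in_tag']) + 1}\t{row['locus_id']}\t"
                    f"{ref.iloc[j]}\t{alt.iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n"
                )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int, mid_p: bool = True) -> float:
    """Exact Hardy-Weinberg test for one biallelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one.  With
    ``mid_p`` (default) the observed outcome contributes half its
    probability, which improves calibration at small sample sizes.
    """
    from scipy.special import gammaln

    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if len(hets) == 1:  # monomorphic or otherwise single attainable outcome
        return 1.0
    n_a, n_b = n_rare, 2 * n - n_rare
    hom_r = (n_a - hets) // 2
    hom_c = (n_b - hets) // 2
    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(n_b + 1))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(np.where(hets == n_het)[0][0])
    p_obs = probs[obs]
    le = probs <= p_obs * (1 + 1e-12)
    p = probs[le].sum()
    if mid_p:
        p -= 0.5 * p_obs
    return float(min(1.0, max(p, 0.0)))


# ---------------------------------------------------------------------------
# Locus filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input_loci: int
    n_after_first_per_tag: int
    n_after_hwe: int
    n_after_callrate: int
    dropped_not_first: list[str] = field(default_factory=list)
    dropped_hwe: list[str] = field(default_factory=list)
    dropped_callrate: list[str] = field(default_factory=list)
    n_hwe_tests_skipped: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def filter_loci(
    gm: GenotypeMatrix,
    hwe_alpha: float = 0.01,
    call_rate: float = 0.80,
    region_col: str = "region",
    mid_p: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """First-SNP-per-tag, HWE-by-region, and call-rate filtering.

    A locus is dropped if its exact HWE p-value falls below ``hwe_alpha`` in
    any region x species group, or if it is genotyped in no more than
    ``call_rate`` of all individuals.  Regions with fewer than 2 genotyped
    individuals at a locus are skipped for that locus's HWE test (counted in
    the report).
    """
    loci = gm.loci
    ids = loci["locus_id"].astype(str).to_numpy()

    order = np.lexsort((loci["pos_in_tag"].to_numpy(), loci["tag_id"].to_numpy()))
    seen: set = set()
    first_idx = []
    for k in order:
        t = loci["tag_id"].iloc[k]
        if t not in seen:
            seen.add(t)
            first_idx.append(k)
    first_idx = np.sort(np.array(first_idx, dtype=int))
    dropped_not_first = sorted(set(ids) - set(ids[first_idx]))
    gm1 = gm.take_loci(first_idx)

    groups = gm1.samples[region_col].astype(str) + "/" + gm1.samples["species"].astype(str)
    keep_hwe = []
    dropped_hwe = []
    n_skipped = 0
    for j in range(gm1.n_loci):
        g = gm1.genotypes[:, j]
        ok = True
        for grp in groups.unique():
            sel = (groups == grp).to_numpy()
            gg = g[sel]
            gg = gg[gg != MISSING]
            if len(gg) < 2:
                n_skipped += 1
                continue
            p = hwe_exact_test(
                int((gg == 1).sum()), int((gg == 0).sum()), int((gg == 2).sum()), mid_p=mid_p
            )
            if p < hwe_alpha:
                ok = False
                break
        if ok:
            keep_hwe.append(j)
        else:
            dropped_hwe.append(str(gm1.loci["locus_id"].iloc[j]))
    gm2 = gm1.take_loci(keep_hwe)

    called = (gm2.genotypes != MISSING).mean(axis=0)
    keep_cr = np.where(called > call_rate)[0]
    dropped_cr = [str(x) for x in gm2.loci["locus_id"].iloc[np.where(called <= call_rate)[0]]]
    gm3 = gm2.take_loci(keep_cr)

    report = FilterReport(
        n_input_loci=gm.n_loci,
        n_after_first_per_tag=gm1.n_loci,
        n_after_hwe=gm2.n_loci,
        n_after_callrate=gm3.n_loci,
        dropped_not_first=dropped_not_first,
        dropped_hwe=dropped_hwe,
        dropped_callrate=dropped_cr,
        n_hwe_tests_skipped=n_skipped,
    )
    logger.info(
        "locus filtering: %d -> %d (first per tag) -> %d (HWE) -> %d (call rate)",
        report.n_input_loci, report.n_after_first_per_tag,
        report.n_after_hwe, report.n_after_callrate,
    )
    return gm3, report


# ---------------------------------------------------------------------------
# PCA and F_ST
# ---------------------------------------------------------------------------

def genotype_pca(gm: GenotypeMatrix, n_components: int | None = None):
    """Centered genotype PCA with per-locus mean imputation of missing calls.

    Returns (scores DataFrame with sample metadata, variance fractions).
    """
    g = gm.genotypes.astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    inds = np.where(np.isnan(g))
    g[inds] = mu[inds[1]]
    Xc = g - g.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size and s.max() > 0 else 0.0
    k = int(np.sum(s > tol))
    if n_components is not None:
        k = min(k, n_components)
    var = s**2 / max(1, gm.n_indiv - 1)
    frac = var / var.sum() if var.sum() > 0 else var
    scores = (U * s)[:, :k]
    out = gm.samples[["indiv", "species", "site", "region"]].copy()
    for i in range(k):
        out[f"PC{i + 1}"] = scores[:, i]
    return out, frac[:k]


@dataclass
class FstMatrix:
    values: pd.DataFrame
    clamped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def nei_fst(gm: GenotypeMatrix, grouping: str | pd.Series = "site") -> FstMatrix:
    """Nei pairwise F_ST between sample groups.

    Per locus, F_ST = (H_T - H_S) / H_T with H_S the unweighted mean of the
    two groups' expected heterozygosities and H_T the expected
    heterozygosity at the mean allele frequency; loci are combined as a
    ratio of sums (numerators over denominators), retaining negative
    per-locus components.  A final negative entry is clamped to 0 and the
    pair flagged.  Only observed (non-missing) allele counts contribute.
    """
    if isinstance(grouping, str):
        labels = gm.samples[grouping].astype(str)
    else:
        labels = pd.Series(grouping).astype(str)
    names = list(dict.fromkeys(labels))
    g = gm.genotypes
    freqs, ns = {}, {}
    for name in names:
        sel = (labels == name).to_numpy()
        gg = g[sel].astype(float)
        called = gg != MISSING
        alt = np.where(called, gg, 0).sum(axis=0)
        n_al = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[name] = np.where(n_al > 0, alt / np.maximum(n_al, 1), np.nan)
        ns[name] = n_al
    K = len(names)
    M = np.zeros((K, K))
    clamped = []
    for a in range(K):
        for b in range(a + 1, K):
            p1, p2 = freqs[names[a]], freqs[names[b]]
            ok = ~np.isnan(p1) & ~np.isnan(p2)
            p1, p2 = p1[ok], p2[ok]
            pbar = (p1 + p2) / 2
            ht = 2 * pbar * (1 - pbar)
            hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
            poly = ht > 0
            denom = ht[poly].sum()
            if denom == 0:
                fst = 0.0
            else:
                fst = float((ht[poly] - hs[poly]).sum() / denom)
            if fst < 0:
                clamped.append((names[a], names[b]))
                fst = 0.0
            M[a, b] = M[b, a] = min(fst, 1.0)
    return FstMatrix(pd.DataFrame(M, index=names, columns=names), clamped)


# ---------------------------------------------------------------------------
# Hybrid classification
# ---------------------------------------------------------------------------

@dataclass
class HybridCall:
    individual: str
    n_diagnostic_loci: int
    n_het: int
    n_homo_sp1: int
    n_homo_sp2: int
    verdict: str

    def summary(self) -> str:
        return (
            f"{self.individual}: {self.n_het}/{self.n_diagnostic_loci} heterozygous, "
            f"{self.n_homo_sp1} homozygous sp1, {self.n_homo_sp2} homozygous sp2 "
            f"-> {self.verdict}"
        )


def diagnostic_loci(
    gm: GenotypeMatrix,
    species_col: str = "species",
    min_freq_diff: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Loci near-fixed for alternate alleles between the two species panels.

    Returns (locus indices, alt-allele dosage of species 1's diagnostic
    homozygote at each locus, i.e. 0 or 2).
    """
    sp = gm.samples[species_col].astype(str)
    species = list(dict.fromkeys(sp))
    if len(species) != 2:
        raise ValueError("diagnostic loci need exactly two species panels")
    freqs = []
    for s in species:
        gg = gm.genotypes[(sp == s).to_numpy()].astype(float)
        called = gg != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(called, gg, 0).sum(0) / np.maximum(2 * called.sum(0), 1)
        f[called.sum(0) == 0] = np.nan
        freqs.append(f)
    diff = np.abs(freqs[0] - freqs[1])
    idx = np.where(diff >= min_freq_diff)[0]
    sp1_dosage = np.where(freqs[0][idx] > 0.5, 2, 0)
    return idx, sp1_dosage


def classify_hybrid(
    genotypes: np.ndarray,
    sp1_dosage: np.ndarray,
    individual: str = "query",
    min_loci: int = 5,
) -> HybridCall:
    """Classify an individual from its genotypes at diagnostic loci.

    ``genotypes`` is the alt-allele dosage at each diagnostic locus (missing
    = -1); ``sp1_dosage`` the homozygous dosage characteristic of species 1
    at each locus.  F1 iff heterozygous at every genotyped diagnostic locus
    (at least ``min_loci`` of them); parental iff homozygous for one
    species' alleles throughout; a het/parental-homozygote mixture is
    backcross-like; anything else (including both parental homozygote
    classes) is ambiguous.
    """
    genotypes = np.asarray(genotypes)
    sp1_dosage = np.asarray(sp1_dosage)
    ok = genotypes != MISSING
    g = genotypes[ok]
    d1 = sp1_dosage[ok]
    n = len(g)
    n_het = int((g == 1).sum())
    n_h1 = int((g == d1).sum())
    n_h2 = int((g == 2 - d1).sum())
    if n < min_loci:
        verdict = "ambiguous"
    elif n_het == n:
        verdict = "F1"
    elif n_h1 == n:
        verdict = "parental_sp1"
    elif n_h2 == n:
        verdict = "parental_sp2"
    elif n_het > 0 and n_h1 + n_het == n:
        verdict = "backcross-like"
    elif n_het > 0 and n_h2 + n_het == n:
        verdict = "backcross-like"
    else:
        verdict = "ambiguous"
    return HybridCall(
        individual=individual,
        n_diagnostic_loci=n,
        n_het=n_het,
        n_homo_sp1=n_h1,
        n_homo_sp2=n_h2,
        verdict=verdict,
    )
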