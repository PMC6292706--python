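"""Assortative mating and reproductive character displacement in mate choice.

No-choice mating trials between two species (``cingulata`` and ``filosa``)
sampled in sympatric and allopatric regions are summarised as 2x2 tables of
trials with/without mounting per (female species x male species) cell.  From
the mated pairs the joint isolation index I_PSI is estimated, with bootstrap
uncertainty; reproductive character displacement is tested as the
male species x female species x location interaction in GLMs for mounting
probability and mount duration.

I_PSI is built from PSI pair coefficients: for each pair type (i, j) the
observed number of matings is divided by the number expected under random
mating, where expected counts come from the products of the mating-event
marginals, ``E_ij = row_i * col_j / T``.  Then

    I_PSI = (psi_CC + psi_FF - psi_CF - psi_FC) / (psi_CC + psi_FF + psi_CF + psi_FC)

which is 0 under random mating and 1 under complete assortment, and is not
affected by sexual selection (a uniform excess of matings by one type
cancels between numerator and denominator).
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("cingulata", "filosa")
LOCATIONS = ("sympatric", "allopatric")
MATURITY_LEVELS = ("immature", "maturing", "mature", "spent")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One no-choice mating trial.

    ``mounted`` may be None for trials that yielded no usable data; such
    records are dropped (and counted) before tabulation.  When ``mounted``
    is True, ``mount_durations`` holds the duration in minutes of every
    mounting observed during the trial.
    """

    trial_id: str
    male_species: str
    female_species: str
    male_site: str
    female_site: str
    location_class: str
    mounted: bool | None
    mount_durations: list[float] = field(default_factory=list)
    insertion_observed: bool | None = None
    sperm_in_bursa: bool | None = None
    male_size_mm: float | None = None
    female_size_mm: float | None = None
    female_maturity: str | None = None
    researcher: str | None = None
    time_block: str | None = None
    male_id: str | None = None

    def __post_init__(self) -> None:
        if self.male_species not in SPECIES or self.female_species not in SPECIES:
            raise ValueError(f"unknown species in trial {self.trial_id}")
        if self.location_class not in LOCATIONS:
            raise ValueError(f"unknown location class {self.location_class!r}")
        if self.male_site == self.female_site:
            raise ValueError(
                f"trial {self.trial_id}: male and female share site {self.male_site!r}; "
                "trials always pair individuals from different sites"
            )
        if any(d <= 0 for d in self.mount_durations):
            raise ValueError(f"trial {self.trial_id}: non-positive mount duration")
        if self.mounted is True and not self.mount_durations:
            raise ValueError(f"trial {self.trial_id}: mounted but no durations")
        if self.mounted is False and self.mount_durations:
            raise ValueError(f"trial {self.trial_id}: durations without mounting")

    @property
    def usable(self) -> bool:
        return self.mounted is not None

    @property
    def mean_duration(self) -> float | None:
        if not self.mount_durations:
            return None
        return float(np.mean(self.mount_durations))


class MatingCountTable:
    """2x2 table of mating-trial outcomes for one location class.

    ``counts[i, j]`` is the number of trials with at least one mounting for
    female species i x male species j (species order ``("cingulata",
    "filosa")``); ``totals`` the number of trials conducted per cell.
    """

    def __init__(self, counts, totals, location_class: str):
        self.counts = np.asarray(counts, dtype=float).reshape(2, 2)
        self.totals = np.asarray(totals, dtype=float).reshape(2, 2)
        if location_class not in LOCATIONS:
            raise ValueError(f"unknown location class {location_class!r}")
        self.location_class = location_class
        if np.any(self.counts < 0) or np.any(self.counts > self.totals):
            raise ValueError("require 0 <= counts <= totals in every cell")

    @property
    def n_matings(self) -> int:
        return int(self.counts.sum())

    @property
    def n_trials(self) -> int:
        return int(self.totals.sum())

    def cell(self, female: str, male: str) -> tuple[int, int]:
        i, j = SPECIES.index(female), SPECIES.index(male)
        return int(self.counts[i, j]), int(self.totals[i, j])

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(SPECIES, name="female")
        cols = pd.Index(SPECIES, name="male")
        return pd.DataFrame(self.counts, index=idx, columns=cols)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MatingCountTable({self.location_class}, counts={self.counts.ravel().astype(int).tolist()}, "
            f"totals={self.totals.ravel().astype(int).tolist()})"
        )


@dataclass
class IsolationEstimate:
    """Point (and optionally bootstrap) estimate of the joint isolation index."""

    psi: np.ndarray
    i_psi: float
    n_matings: int
    location_class: str
    se_boot: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    p_value_normal: float | None = None
    n_boot: int | None = None
    n_redrawn: int = 0
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            f"Joint isolation index ({self.location_class})",
            "-" * 44,
            f"I_PSI          {self.i_psi: .4f}",
            f"n matings      {self.n_matings:d}",
        ]
        psi = self.psi
        for i, f in enumerate(SPECIES):
            for j, m in enumerate(SPECIES):
                lines.append(f"PSI {f[0].upper()}x{m[0].upper()}        {psi[i, j]: .4f}")
        if self.se_boot is not None:
            lines += [
                f"SE (bootstrap) {self.se_boot: .4f}   (n_boot={self.n_boot}, seed={self.seed})",
                f"t = I/SE       {self.t_stat: .3f}",
                f"P (bootstrap)  {self.p_value: .4g}",
                f"P (normal)     {self.p_value_normal: .4g}",
            ]
        return "\n".join(lines)


@dataclass
class InteractionTestResult:
    """Likelihood-ratio test of the species x species x location interaction."""

    chi2: float
    df: int
    p_value: float
    response: str
    model_terms: list[str]
    n_obs: int
    separation_flag: bool = False

    def summary(self) -> str:
        return (
            f"LR test, 3-way interaction ({self.response}): "
            f"chi2 = {self.chi2:.3f}, df = {self.df}, P = {self.p_value:.4g}, n = {self.n_obs}"
            + ("  [separation flagged]" if self.separation_flag else "")
        )


@dataclass
class BursaModelResult:
    """Logistic regression of sperm-in-bursa on log mean mount duration."""

    slope_logit: float
    se: float
    chi2: float
    df: int
    p_value: float
    n_obs: int
    separation_flag: bool = False

    def summary(self) -> str:
        return (
            f"sperm-in-bursa ~ log(duration): b = {self.slope_logit:.3f} +/- {self.se:.3f} "
            f"(logit scale), chi2 = {self.chi2:.3f}, df = {self.df}, P = {self.p_value:.4g}"
            + ("  [separation flagged]" if self.separation_flag else "")
        )


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def tabulate_trials(records: Sequence[TrialRecord], location_class: str) -> MatingCountTable:
    """Tabulate trials with >= 1 mounting per (female x male) species cell.

    Records lacking outcome data (``mounted is None``) are dropped and the
    number dropped is logged.  Every one of the four cells must contain at
    least one conducted trial.
    """
    records = [r for r in records if r.location_class == location_class]
    if not records:
        raise ValueError("no trials")
    n_dropped = sum(not r.usable for r in records)
    if n_dropped:
        logger.info("dropped %d trial(s) without usable outcome data", n_dropped)
    records = [r for r in records if r.usable]
    if not records:
        raise ValueError("no trials")
    counts = np.zeros((2, 2))
    totals = np.zeros((2, 2))
    for r in records:
        i, j = SPECIES.index(r.female_species), SPECIES.index(r.male_species)
        totals[i, j] += 1
        if r.mounted:
            counts[i, j] += 1
    if np.any(totals == 0):
        empty = [
            f"{SPECIES[i]} female x {SPECIES[j]} male"
            for i in range(2)
            for j in range(2)
            if totals[i, j] == 0
        ]
        raise ValueError(f"no trials in cell(s): {', '.join(empty)}")
    return MatingCountTable(counts, totals, location_class)


def insertion_rate(records: Iterable[TrialRecord]) -> float:
    """Fraction of mountings for which penis insertion was observed."""
    mounted = [r for r in records if r.usable and r.mounted and r.insertion_observed is not None]
    if not mounted:
        raise ValueError("no mounted trials with insertion data")
    return float(np.mean([bool(r.insertion_observed) for r in mounted]))


# ---------------------------------------------------------------------------
# I_PSI
# ---------------------------------------------------------------------------

def _psi_matrix(counts: np.ndarray, expected: np.ndarray | None = None) -> np.ndarray:
    counts = np.asarray(counts, dtype=float).reshape(2, 2)
    if expected is None:
        T = counts.sum()
        row = counts.sum(axis=1)
        col = counts.sum(axis=0)
        if T <= 0:
            raise ValueError("PSI undefined: no matings")
        if np.any(row == 0) or np.any(col == 0):
            raise ValueError("PSI undefined for empty marginal")
        expected = np.outer(row, col) / T
    return counts / expected


def _ipsi_from_psi(psi: np.ndarray) -> float:
    num = psi[0, 0] + psi[1, 1] - psi[0, 1] - psi[1, 0]
    den = psi.sum()
    return float(num / den)


def compute_ipsi(table: MatingCountTable) -> IsolationEstimate:
    """Point estimate of I_PSI from a mating count table.

    Expected pair counts under random mating are products of the
    mating-event marginals divided by the total number of matings.
    """
    psi = _psi_matrix(table.counts)
    return IsolationEstimate(
        psi=psi,
        i_psi=_ipsi_from_psi(psi),
        n_matings=table.n_matings,
        location_class=table.location_class,
    )


def bootstrap_ipsi(
    table: MatingCountTable,
    n_boot: int = 10_000,
    seed: int | None = None,
    recompute_expected: bool = False,
    max_redraws: int = 100,
) -> IsolationEstimate:
    """Bootstrap inference for I_PSI by resampling mated pairs.

    The T observed matings are resampled with replacement from the
    multinomial over the four pair types and I_PSI recomputed per replicate.
    By default the PSI expected frequencies are held at the observed table's
    values (the premating reference treated as fixed data, the convention of
    the mating-frequency literature); with ``recompute_expected=True`` the
    expected counts are rebuilt from each replicate's marginals, and
    replicates with an empty marginal are redrawn (up to ``max_redraws``
    attempts each, the redraw count being reported).

    The two-tailed p-value is taken from the bootstrap distribution of
    I_PSI centered at zero; a normal-approximation p (t against N(0,1)) is
    reported alongside.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if seed is None:
        raise ValueError("a seed is required for bootstrap inference")
    point = compute_ipsi(table)
    rng = np.random.default_rng(seed)
    T = table.n_matings
    p = table.counts.ravel() / T
    fixed_expected = None
    if not recompute_expected:
        row = table.counts.sum(axis=1)
        col = table.counts.sum(axis=0)
        fixed_expected = np.outer(row, col) / T

    draws = rng.multinomial(T, p, size=n_boot).astype(float)
    reps = np.empty(n_boot)
    n_redrawn = 0
    for k in range(n_boot):
        d = draws[k].reshape(2, 2)
        if recompute_expected:
            attempts = 0
            while np.any(d.sum(axis=0) == 0) or np.any(d.sum(axis=1) == 0):
                attempts += 1
                if attempts > max_redraws:
                    raise RuntimeError(
                        "bootstrap replicate kept producing an empty marginal "
                        f"after {max_redraws} redraws"
                    )
                d = rng.multinomial(T, p).astype(float).reshape(2, 2)
            if attempts:
                n_redrawn += 1
        reps[k] = _ipsi_from_psi(_psi_matrix(d, fixed_expected))
    if n_redrawn:
        logger.info("redrew %d bootstrap replicate(s) with empty marginals", n_redrawn)

    se = float(np.std(reps, ddof=1))
    t_stat = point.i_psi / se if se > 0 else math.inf * np.sign(point.i_psi)
    centered = reps - reps.mean()
    p_boot = float((1 + np.sum(np.abs(centered) >= abs(point.i_psi))) / (n_boot + 1))
    from scipy import stats

    p_norm = float(2 * stats.norm.sf(abs(point.i_psi) / se)) if se > 0 else 0.0
    return IsolationEstimate(
        psi=point.psi,
        i_psi=point.i_psi,
        n_matings=T,
        location_class=table.location_class,
        se_boot=se,
        t_stat=float(t_stat),
        p_value=p_boot,
        p_value_normal=p_norm,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        seed=seed,
    )


class IsolationIndexModel:
    """Joint isolation index model for a mating count table.

    Statsmodels-style wrapper: build from a :class:`MatingCountTable` (or
    trial records), call :meth:`fit` for point + bootstrap inference.
    """

    def __init__(self, table: MatingCountTable):
        self.table = table

    @classmethod
    def from_records(cls, records: Sequence[TrialRecord], location_class: str) -> "IsolationIndexModel":
        return cls(tabulate_trials(records, location_class))

    def fit(self, n_boot: int = 10_000, seed: int | None = None, **kwargs) -> IsolationEstimate:
        if n_boot == 0:
            return compute_ipsi(self.table)
        return bootstrap_ipsi(self.table, n_boot=n_boot, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# GLM tests for character displacement
# ---------------------------------------------------------------------------

def _records_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                trial_id=r.trial_id,
                male_species=r.male_species,
                female_species=r.female_species,
                location=r.location_class,
                mounted=None if r.mounted is None else int(r.mounted),
                mean_duration=r.mean_duration,
                insertion=r.insertion_observed,
                sperm=r.sperm_in_bursa,
                male_size=r.male_size_mm,
                female_size=r.female_size_mm,
                maturity=r.female_maturity,
                researcher=r.researcher,
                time_block=r.time_block,
                male_id=r.male_id,
            )
        )
    return pd.DataFrame(rows)


_THREE_WAY = "C(male_species):C(female_species):C(location)"


def three_way_interaction_test(
    records: Sequence[TrialRecord], response: str = "mounting"
) -> InteractionTestResult:
    """LR test of the male species x female species x location interaction.

    ``response="mounting"`` fits a binomial GLM of the mounting indicator
    with researcher and time block as covariates; ``response="log_duration"``
    fits a Normal-error model of the natural log of the per-trial mean mount
    duration (mounted trials only) with male size, female size, their
    difference and female maturity as covariates.  Either way the statistic
    is twice the log-likelihood difference between the models with and
    without the three-way interaction (df = 1).
    """
    import statsmodels.formula.api as smf
    import statsmodels.api as sm
    from scipy import stats

    df = _records_frame([r for r in records if r.usable])
    if df.empty:
        raise ValueError("no usable trials")
    base = "C(male_species) + C(female_species) + C(location)"
    base += (
        " + C(male_species):C(female_species) + C(male_species):C(location)"
        " + C(female_species):C(location)"
    )
    separation = False
    if response == "mounting":
        covars = []
        if df["researcher"].notna().any() and df["researcher"].nunique() > 1:
            covars.append("C(researcher)")
        if df["time_block"].notna().any() and df["time_block"].nunique() > 1:
            covars.append("C(time_block)")
        rhs = " + ".join([base] + covars)
        full_f = f"mounted ~ {rhs} + {_THREE_WAY}"
        red_f = f"mounted ~ {rhs}"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            full = smf.glm(full_f, data=df, family=sm.families.Binomial()).fit()
            red = smf.glm(red_f, data=df, family=sm.families.Binomial()).fit()
            separation = any("separat" in str(w.message).lower() for w in caught)
        if np.any(np.abs(full.params) > 15):
            separation = True
    elif response == "log_duration":
        sub = df[df["mounted"] == 1].copy()
        if len(sub) < 8:
            raise ValueError("too few mounted trials for the duration model")
        sub["log_duration"] = np.log(sub["mean_duration"].astype(float))
        covars = []
        if sub["male_size"].notna().all() and sub["female_size"].notna().all():
            sub["size_diff"] = sub["male_size"] - sub["female_size"]
            covars += ["male_size", "female_size", "size_diff"]
        if sub["maturity"].notna().all() and sub["maturity"].nunique() > 1:
            covars.append("C(maturity)")
        rhs = " + ".join([base] + covars)
        full = smf.ols(f"log_duration ~ {rhs} + {_THREE_WAY}", data=sub).fit()
        red = smf.ols(f"log_duration ~ {rhs}", data=sub).fit()
        df = sub
    else:
        raise ValueError("response must be 'mounting' or 'log_duration'")

    chi2 = float(max(0.0, 2 * (full.llf - red.llf)))
    ddf = int(full.df_model - red.df_model)
    if ddf < 1:
        raise ValueError(
            "three-way interaction not estimable (empty or collinear cells)"
        )
    p = float(stats.chi2.sf(chi2, ddf))
    return InteractionTestResult(
        chi2=chi2,
        df=ddf,
        p_value=p,
        response=response if response != "log_duration" else "log_duration",
        model_terms=list(full.params.index),
        n_obs=int(full.nobs),
        separation_flag=separation,
    )


def sperm_duration_test(records: Sequence[TrialRecord]) -> BursaModelResult:
    """Logistic regression of sperm-in-bursa on the log mean mount duration.

    Long mounts should inseminate: the slope on the logit scale measures
    the per-log-minute increase in the odds of finding sperm in the female's
    bursa at the end of a trial.
    """
    import statsmodels.api as sm
    from scipy import stats

    usable = [
        r
        for r in records
        if r.usable and r.mounted and r.sperm_in_bursa is not None and r.mean_duration
    ]
    if len(usable) < 10:
        raise ValueError(f"need >= 10 usable trials, got {len(usable)}")
    y = np.array([float(r.sperm_in_bursa) for r in usable])
    x = np.log([r.mean_duration for r in usable])
    X = sm.add_constant(x)
    separation = False
    if y.min() == y.max():
        # degenerate response: slope unidentifiable
        return BursaModelResult(
            slope_logit=math.nan,
            se=math.nan,
            chi2=0.0,
            df=1,
            p_value=1.0,
            n_obs=len(usable),
            separation_flag=True,
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
        separation = any("separat" in str(w.message).lower() for w in caught)
    if abs(full.params[1]) > 15:
        separation = True
    chi2 = float(max(0.0, 2 * (full.llf - null.llf)))
    return BursaModelResult(
        slope_logit=float(full.params[1]),
        se=float(full.bse[1]),
        chi2=chi2,
        df=1,
        p_value=float(stats.chi2.sf(chi2, 1)),
        n_obs=len(usable),
        separation_flag=separation,
    )


# conventional aliases
test_three_way_interaction = three_way_interaction_test
test_sperm_vs_duration = sperm_duration_test


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "trial_id", "male_species", "female_species", "male_site", "female_site",
    "location", "mounted", "durations_min", "insertion", "sperm_bursa",
    "male_size_mm", "female_size_mm", "maturity", "researcher", "time_block",
]


def _parse_bool(s: str) -> bool | None:
    if s == "":
        return None
    if s.lower() in ("1", "true", "t", "yes"):
        return True
    if s.lower() in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"unparseable boolean {s!r}")


def read_trials_csv(path) -> list[TrialRecord]:
    """Read trial records from the canonical trials CSV dialect."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"trials CSV missing columns: {sorted(missing)}")
        for row in reader:
            durations = [float(d) for d in row["durations_min"].split(";") if d.strip()]
            records.append(
                TrialRecord(
                    trial_id=row["trial_id"],
                    male_species=row["male_species"],
                    female_species=row["female_species"],
                    male_site=row["male_site"],
                    female_site=row["female_site"],
                    location_class=row["location"],
                    mounted=_parse_bool(row["mounted"]),
                    mount_durations=durations,
                    insertion_observed=_parse_bool(row["insertion"]),
                    sperm_in_bursa=_parse_bool(row["sperm_bursa"]),
                    male_size_mm=float(row["male_size_mm"]) if row["male_size_mm"] else None,
                    female_size_mm=float(row["female_size_mm"]) if row["female_size_mm"] else None,
                    female_maturity=row["maturity"] or None,
                    researcher=row["researcher"] or None,
                    time_block=row["time_block"] or None,
                    male_id=row.get("male_id") or None,
                )
            )
    return records


def write_trials_csv(records: Iterable[TrialRecord], path) -> None:
    def fmt_bool(b):
        return "" if b is None else str(bool(b)).lower()

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.trial_id, r.male_species, r.female_species, r.male_site,
                    r.female_site, r.location_class, fmt_bool(r.mounted),
                    ";".join(f"{d:g}" for d in r.mount_durations),
                    fmt_bool(r.insertion_observed), fmt_bool(r.sperm_in_bursa),
                    "" if r.male_size_mm is None else f"{r.male_size_mm:g}",
                    "" if r.female_size_mm is None else f"{r.female_size_mm:g}",
                    r.female_maturity or "", r.researcher or "", r.time_block or "",
                ]
            )
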