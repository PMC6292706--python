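"""Genital-trait morphometrics: size adjustment and trajectory analysis.

Eleven linear measurements (labelled A..K, with A the overall length) are
taken per male.  After dropping any feature that could not be measured in
all specimens, the remaining features are adjusted to the grand mean length
by pooled linear regression on A.  Character displacement in penis form is
then tested by trajectory analysis: the vector from the mean form of one
species to the other is computed separately in allopatry and sympatry, and
the difference in vector magnitude (path distance) and direction (angle) is
assessed against a residual-randomization permutation null, alongside a
two-factor multivariate species x location interaction F.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_LABELS = list("ABCDEFGHIJK")
LENGTH_FEATURE = "A"
SPECIES = ("cingulata", "filosa")
LOCATIONS = ("sympatric", "allopatric")

_META_COLS = ["male_id", "species", "location"]


def validate_morph_frame(df: pd.DataFrame) -> list[str]:
    """Check a morphometric table and return its feature columns (in order)."""
    for c in _META_COLS:
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")
    feats = [c for c in df.columns if c in FEATURE_LABELS]
    if not feats:
        raise ValueError("no feature columns (A..K) present")
    bad_sp = set(df["species"]) - set(SPECIES)
    if bad_sp:
        raise ValueError(f"unknown species {sorted(bad_sp)}")
    bad_loc = set(df["location"]) - set(LOCATIONS)
    if bad_loc:
        raise ValueError(f"unknown locations {sorted(bad_loc)}")
    vals = df[feats].to_numpy(float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("features must be positive and finite")
    return feats


def read_morph_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_morph_frame(df)
    return df


@dataclass
class AdjustedMorphDataset:
    """Length-adjusted feature table plus the adjustment regression slopes."""

    data: pd.DataFrame            # male_id, species, location + adjusted features
    features: list[str]
    slopes: dict[str, float]
    reference_length: float

    def group_matrix(self, species: str, location: str) -> np.ndarray:
        sel = (self.data["species"] == species) & (self.data["location"] == location)
        return self.data.loc[sel, self.features].to_numpy(float)


def length_adjust(
    df: pd.DataFrame,
    length_feature: str = LENGTH_FEATURE,
    drop_feature: str | None = None,
) -> AdjustedMorphDataset:
    """Adjust features to the mean overall length by pooled linear regression.

    For each feature y, ``adjusted_y_i = y_i - b (A_i - mean(A))`` with b the
    slope of the pooled ordinary regression of y on A over all individuals.
    A single pooled slope (rather than per-group slopes) keeps group
    differences out of the size correction.
    """
    feats = validate_morph_frame(df)
    if length_feature not in feats:
        raise ValueError(f"length feature {length_feature!r} not present")
    if len(df) < 3:
        raise ValueError("need >= 3 records for length adjustment")
    keep = [f for f in feats if f not in (length_feature, drop_feature)]
    A = df[length_feature].to_numpy(float)
    if np.ptp(A) == 0:
        raise ValueError(f"zero variance in length feature {length_feature!r}")
    Abar = float(A.mean())
    Ac = A - Abar
    denom = float(Ac @ Ac)
    out = df[_META_COLS].copy()
    slopes: dict[str, float] = {}
    for f in keep:
        y = df[f].to_numpy(float)
        b = float(Ac @ (y - y.mean()) / denom)
        slopes[f] = b
        out[f] = y - b * Ac
    return AdjustedMorphDataset(out, keep, slopes, Abar)


# ---------------------------------------------------------------------------
# Trajectory analysis
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryResult:
    d_allopatry: float
    d_sympatry: float
    magnitude_diff: float
    p_magnitude: float
    angle_deg: float
    p_direction: float
    f_interaction: float
    p_interaction: float
    n_permutations: int
    seed: int
    group_sizes: dict = field(default_factory=dict)

    def summary(self) -> str:
        return "\n".join(
            [
                "Trajectory analysis of species difference vectors",
                "-" * 50,
                f"centroid distance, allopatry  {self.d_allopatry:.4f}",
                f"centroid distance, sympatry   {self.d_sympatry:.4f}",
                f"|d_symp - d_allo|             {self.magnitude_diff:.4f}   P = {self.p_magnitude:.4g}",
                f"angle between vectors (deg)   {self.angle_deg:.2f}   P = {self.p_direction:.4g}",
                f"species x location F          {self.f_interaction:.3f}   P = {self.p_interaction:.4g}",
                f"(n_perm = {self.n_permutations}, seed = {self.seed})",
            ]
        )


def _trajectory_stats(X: np.ndarray, gidx: np.ndarray, n_groups: int = 4):
    """(magnitude_diff, angle_deg, F_interaction, d_allo, d_symp).

    Group index order: 0 = (cingulata, sympatric), 1 = (filosa, sympatric),
    2 = (cingulata, allopatric), 3 = (filosa, allopatric).
    """
    n, p = X.shape
    sums = np.zeros((n_groups, p))
    np.add.at(sums, gidx, X)
    cnt = np.bincount(gidx, minlength=n_groups).astype(float)
    means = sums / cnt[:, None]
    v_symp = means[1] - means[0]
    v_allo = means[3] - means[2]
    d_s = float(np.linalg.norm(v_symp))
    d_a = float(np.linalg.norm(v_allo))
    mag = abs(d_s - d_a)
    if d_s == 0 and d_a == 0:
        ang = 0.0
    elif d_s == 0 or d_a == 0:
        ang = 90.0
    else:
        c = float(v_symp @ v_allo / (d_s * d_a))
        ang = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    # two-factor multivariate SS decomposition (trace form, cell-mean based)
    grand = X.mean(axis=0)
    sp_of = np.array([0, 1, 0, 1])
    loc_of = np.array([0, 0, 1, 1])
    w = cnt / cnt.sum()
    m_sp = np.stack(
        [(means[sp_of == s] * (cnt[sp_of == s, None] / cnt[sp_of == s].sum())).sum(axis=0) for s in (0, 1)]
    )
    m_loc = np.stack(
        [(means[loc_of == l] * (cnt[loc_of == l, None] / cnt[loc_of == l].sum())).sum(axis=0) for l in (0, 1)]
    )
    int_dev = means - m_sp[sp_of] - m_loc[loc_of] + grand
    ss_int = float((cnt[:, None] * int_dev**2).sum())
    resid = X - means[gidx]
    ss_res = float((resid**2).sum())
    df_res = n - n_groups
    f_int = (ss_int / 1.0) / (ss_res / df_res) if ss_res > 0 else np.inf
    return mag, ang, f_int, d_a, d_s


def _group_index(data: pd.DataFrame) -> np.ndarray:
    key = {
        ("cingulata", "sympatric"): 0,
        ("filosa", "sympatric"): 1,
        ("cingulata", "allopatric"): 2,
        ("filosa", "allopatric"): 3,
    }
    return np.array([key[(s, l)] for s, l in zip(data["species"], data["location"])])


class TrajectoryModel:
    """Permutation-based trajectory analysis over an adjusted morph dataset."""

    def __init__(self, dataset: AdjustedMorphDataset):
        self.dataset = dataset
        self._gidx = _group_index(dataset.data)
        cnt = np.bincount(self._gidx, minlength=4)
        if np.any(cnt < 3):
            raise ValueError("all four species x location groups need >= 3 members")

    def fit(self, n_perm: int = 999, seed: int | None = None) -> TrajectoryResult:
        """Observed statistics plus residual-randomization permutation p-values.

        The null model holds species and location main effects (fitted by
        additive least squares); its residuals are permuted across all
        individuals and added back to the fitted values, so the permuted
        datasets share the common species offset but carry no
        location-specific change in it.  p = (1 + #{perm >= obs}) / (1 + B).
        """
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if seed is None:
            raise ValueError("a seed is required for permutation inference")
        X = self.dataset.data[self.dataset.features].to_numpy(float)
        gidx = self._gidx
        n = len(X)
        # additive (reduced) model fit: design [1, species, location]
        sp = np.array([0, 1, 0, 1])[gidx]
        loc = np.array([0, 0, 1, 1])[gidx]
        D = np.column_stack([np.ones(n), sp, loc])
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        fitted = D @ beta
        resid = X - fitted

        obs_mag, obs_ang, obs_f, d_a, d_s = _trajectory_stats(X, gidx)
        rng = np.random.default_rng(seed)
        ge_mag = ge_ang = ge_f = 1  # observed counted in numerator
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Xp = fitted + resid[perm]
            m, a, f, *_ = _trajectory_stats(Xp, gidx)
            ge_mag += m >= obs_mag
            ge_ang += a >= obs_ang
            ge_f += f >= obs_f
        denom = n_perm + 1
        cnt = np.bincount(gidx, minlength=4)
        return TrajectoryResult(
            d_allopatry=d_a,
            d_sympatry=d_s,
            magnitude_diff=obs_mag,
            p_magnitude=ge_mag / denom,
            angle_deg=obs_ang,
            p_direction=ge_ang / denom,
            f_interaction=obs_f,
            p_interaction=ge_f / denom,
            n_permutations=n_perm,
            seed=seed,
            group_sizes={
                "cingulata/sympatric": int(cnt[0]),
                "filosa/sympatric": int(cnt[1]),
                "cingulata/allopatric": int(cnt[2]),
                "filosa/allopatric": int(cnt[3]),
            },
        )


def trajectory_analysis(
    dataset: AdjustedMorphDataset, n_perm: int = 999, seed: int | None = None
) -> TrajectoryResult:
    return TrajectoryModel(dataset).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PCA and per-trait tests
# ---------------------------------------------------------------------------

def pca_scores(dataset: AdjustedMorphDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariance-matrix PCA of the adjusted features.

    Returns per-individual scores (orthogonal columns PC1, PC2, ...) and the
    variance fractions.  Features stay in mm (no per-feature scaling), the
    geometric-morphometric convention.  PC1 is oriented so the filosa mean
    score is positive.  Rank-deficient inputs are truncated to the
    numerically nonzero components.
    """
    X = dataset.data[dataset.features].to_numpy(float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("need >= 2 features and >= 3 individuals")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(n, p) * np.finfo(float).eps if s.size else 0.0
    k = int(np.sum(s > tol))
    if k == 0:
        raise ValueError("all features constant")
    s, Vt, U = s[:k], Vt[:k], U[:, :k]
    var = s**2 / (n - 1)
    frac = var / var.sum()
    scores = U * s
    filosa = (dataset.data["species"] == "filosa").to_numpy()
    if filosa.any() and scores[filosa, 0].mean() < 0:
        scores[:, 0] *= -1
        Vt[0] *= -1
    out = dataset.data[_META_COLS].copy()
    for i in range(k):
        out[f"PC{i + 1}"] = scores[:, i]
    return out, frac


def per_trait_tests(dataset: AdjustedMorphDataset) -> pd.DataFrame:
    """Per-feature two-way species x location interaction tests.

    Ordinary two-factor linear model per feature; the interaction F (1 df)
    and its p-value, plus Bonferroni-adjusted p over the tested features.
    Constant features are skipped with a warning.
    """
    from scipy import stats

    data = dataset.data
    gidx = _group_index(data)
    rows = []
    tested = []
    for f in dataset.features:
        y = data[f].to_numpy(float)
        if np.ptp(y) == 0:
            warnings.warn(f"feature {f} is constant; test skipped")
            rows.append(dict(feature=f, f_stat=np.nan, p_raw=np.nan, p_bonferroni=np.nan))
            continue
        mag, ang, fint, *_ = _trajectory_stats(y[:, None], gidx)
        dfr = len(y) - 4
        p = float(stats.f.sf(fint, 1, dfr))
        rows.append(dict(feature=f, f_stat=float(fint), p_raw=p, p_bonferroni=np.nan))
        tested.append(len(rows) - 1)
    m = len(tested)
    for i in tested:
        rows[i]["p_bonferroni"] = min(1.0, rows[i]["p_raw"] * m)
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] < 0.05
    return out


@dataclass
class DurationPC1Result:
    f_interaction: float
    df_num: int
    df_den: int
    p_value: float
    slope_cingulata: float
    slope_filosa: float
    n_obs: int

    def summary(self) -> str:
        return (
            f"log duration ~ male species x PC1: F_{self.df_num},{self.df_den} = "
            f"{self.f_interaction:.3f}, P = {self.p_value:.4g}; slopes "
            f"cingulata {self.slope_cingulata:.3f}, filosa {self.slope_filosa:.3f}"
        )


def duration_vs_pc1(trial_records, pc_scores: pd.DataFrame) -> DurationPC1Result:
    """Interaction of male species with penis-form PC1 on log mount duration.

    Trial records are matched to male PC1 scores via ``male_id``; the model
    is ``log(mean duration) ~ male_species * PC1 + location`` and the test is
    the partial F for the interaction term.
    """
    import statsmodels.formula.api as smf

    score_by_id = dict(zip(pc_scores["male_id"], pc_scores["PC1"]))
    rows = []
    for r in trial_records:
        if r.usable and r.mounted and r.male_id in score_by_id:
            rows.append(
                dict(
                    log_duration=np.log(r.mean_duration),
                    male_species=r.male_species,
                    location=r.location_class,
                    pc1=score_by_id[r.male_id],
                )
            )
    df = pd.DataFrame(rows)
    if len(df) < 8:
        raise ValueError("too few mounted trials with matched PC1 scores")
    if np.ptp(df["pc1"].to_numpy()) == 0:
        raise ValueError("PC1 has zero variance")
    full = smf.ols("log_duration ~ C(male_species) * pc1 + C(location)", data=df).fit()
    red = smf.ols("log_duration ~ C(male_species) + pc1 + C(location)", data=df).fit()
    from scipy import stats

    df_num = int(full.df_model - red.df_model)
    df_den = int(full.df_resid)
    f = float(((red.ssr - full.ssr) / df_num) / (full.ssr / df_den))
    p = float(stats.f.sf(f, df_num, df_den))
    slope_c = float(full.params["pc1"])
    inter = [k for k in full.params.index if "pc1" in k and "male_species" in k]
    slope_f = slope_c + float(full.params[inter[0]]) if inter else slope_c
    return DurationPC1Result(
        f_interaction=f,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        slope_cingulata=slope_c,
        slope_filosa=slope_f,
        n_obs=len(df),
    )
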