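"""Centroid-size statistics, allometry and Procrustes shape variance.

Size is analysed separately from shape: a one-way ANOVA compares mean
centroid size across species, followed by Bonferroni-adjusted pairwise
t-tests.  Allometry — the dependence of shape on size — is tested by a
multivariate regression of the tangent shape variables on log centroid
size with a permutation null.  Procrustes variance (disparity) is the
mean squared distance of group members to their group mean in shape
space; comparing the variance across repeated digitizations of the same
specimen with the variance across conspecific specimens quantifies
observer error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gpa import generalized_procrustes, tangent_projection
from .io import LandmarkDataset


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def anova_centroid_size(sizes, labels) -> AnovaResult:
    """One-way fixed-effects ANOVA of centroid size across groups."""
    sizes = np.asarray(sizes, dtype=float)
    labels = np.asarray(labels)
    groups = [sizes[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in zip(pd.unique(labels), groups):
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance: F undefined")
    f, p = stats.f_oneway(*groups)
    return AnovaResult(float(f), len(groups) - 1,
                       len(sizes) - len(groups), float(p))


def pairwise_t_bonferroni(sizes, labels) -> pd.DataFrame:
    """Bonferroni-adjusted two-sample t-test p-values for all group pairs.

    For g groups the m = g(g-1)/2 raw p-values are multiplied by m and
    capped at 1; the returned matrix is symmetric with a unit diagonal.
    """
    sizes = np.asarray(sizes, dtype=float)
    labels = np.asarray(labels)
    names = sorted(pd.unique(labels))
    m = len(names) * (len(names) - 1) // 2
    mat = pd.DataFrame(np.ones((len(names), len(names))),
                       index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = sizes[labels == a], sizes[labels == b]
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError(f"group {a if len(xa) < 2 else b!r} "
                                 "has fewer than 2 specimens")
            _, raw = stats.ttest_ind(xa, xb, equal_var=True)
            mat.loc[a, b] = mat.loc[b, a] = min(1.0, m * float(raw))
    return mat


@dataclass
class AllometryResult:
    """Shape-on-size regression summary with a permutation p-value."""
    r_squared: float
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    slope: np.ndarray = None              # per shape variable


def allometry_test(shapes, sizes, n_permutations: int = 500,
                   seed: int | None = None) -> AllometryResult:
    """Permutation test of the multivariate shape ~ log(size) regression.

    R^2 is the fraction of total summed squared shape variation (over
    all tangent variables) explained by log centroid size; the F ratio
    uses 1 and n-2 degrees of freedom.  The null distribution permutes
    the specimen-to-size assignment; the reported p is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``, so the minimum
    attainable p with 500 permutations is 1/501.
    """
    Y = np.asarray(shapes, dtype=float)
    x = np.log(np.asarray(sizes, dtype=float))
    n = len(x)
    if Y.shape[0] != n:
        raise ValueError("shapes and sizes disagree in length")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    xc = x - x.mean()
    xtx = float(xc @ xc)
    if xtx <= 0:
        raise ValueError("centroid sizes are constant: regressor degenerate")
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc ** 2).sum())
    proj = Yc.T @ xc                       # (p,)
    ss_model = min(float(proj @ proj) / xtx, ss_total)

    def f_ratio(model_ss):
        resid = np.clip(ss_total - model_ss, 0.0, None)
        with np.errstate(divide="ignore"):
            return np.where(resid == 0, np.inf,
                            model_ss / (resid / (n - 2)))

    f_obs = float(f_ratio(np.asarray(ss_model)))

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    Xp = xc[order]                        # (n_perm, n)
    num = Yc.T @ Xp.T                     # (p, n_perm)
    ss_model_p = np.minimum((num ** 2).sum(axis=0) / xtx, ss_total)
    f_perm = f_ratio(ss_model_p)
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_permutations)
    return AllometryResult(ss_model / ss_total, float(f_obs), float(p),
                           n_permutations, seed, proj / xtx)


@dataclass
class DisparityResult:
    """Per-group Procrustes variance and the mean across groups."""
    per_group_variance: dict
    grand_mean_variance: float


def shape_variance(shapes, labels, ddof: int = 0) -> DisparityResult:
    """Procrustes variance per group: mean squared distance to group mean.

    ``shapes`` is an (n, p) tangent shape matrix (use
    :func:`wingmorph.gpa.tangent_projection`).  The denominator is the
    group size n by default (``ddof=0``), the convention of the R
    morphometrics software family; singleton groups are excluded with a
    warning because their variance is undefined under any convention
    that intends a dispersion estimate.
    """
    shapes = np.asarray(shapes, dtype=float)
    labels = np.asarray(labels)
    variances = {}
    for g in pd.unique(labels):
        rows = shapes[labels == g]
        if len(rows) < 2:
            warnings.warn(f"group {g!r} has a single member; excluded")
            continue
        dev = rows - rows.mean(axis=0)
        variances[g] = float((dev ** 2).sum() / (len(rows) - ddof))
    if not variances:
        raise ValueError("no group with at least two members")
    return DisparityResult(variances,
                           float(np.mean(list(variances.values()))))


@dataclass
class ObserverErrorReport:
    """Observer (repeatability) variance versus species-level variance."""
    observer_variance: float              # mean per-specimen, across replicates
    species_variance: float               # mean per-species, original data
    ratio: float
    n_replicated_specimens: int
    n_observers: int
    per_specimen: dict
    per_species: dict


def observer_error_report(original: LandmarkDataset,
                          replicates: LandmarkDataset) -> ObserverErrorReport:
    """Compare digitization error across observers with species variance.

    Originals and observer replicates are superimposed jointly in one
    GPA; for every replicated specimen the Procrustes variance across
    its observer replicates is computed (denominator n), and averaged
    over specimens.  The species-level variance uses only the original
    specimens.  A ratio well below 1 indicates that observer error is
    small relative to the within-species shape variation the classifier
    relies on.
    """
    if replicates.n_specimens == 0:
        raise ValueError("no replicate configurations given")
    rep_meta = replicates.meta
    obs_per_spec = rep_meta.groupby("specimen_id")["observer"].nunique()
    if (obs_per_spec < 2).all():
        raise ValueError("replicates need >= 2 observers per specimen")
    joint = LandmarkDataset.concat([original, replicates])
    aligned = generalized_procrustes(joint)
    shapes = tangent_projection(aligned)
    n_orig = original.n_specimens
    orig_shapes, rep_shapes = shapes[:n_orig], shapes[n_orig:]

    per_specimen = {}
    for spec_id in pd.unique(rep_meta["specimen_id"]):
        rows = rep_shapes[(rep_meta["specimen_id"] == spec_id).to_numpy()]
        if len(rows) < 2:
            continue
        dev = rows - rows.mean(axis=0)
        per_specimen[spec_id] = float((dev ** 2).sum() / len(rows))
    species_disp = shape_variance(orig_shapes, original.species)
    observer_var = float(np.mean(list(per_specimen.values())))
    species_var = species_disp.grand_mean_variance
    return ObserverErrorReport(
        observer_var, species_var,
        observer_var / species_var if species_var > 0 else np.inf,
        len(per_specimen), int(obs_per_spec.max()),
        per_specimen, species_disp.per_group_variance)
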