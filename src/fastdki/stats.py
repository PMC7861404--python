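"""Group statistics: Kruskal-Wallis, Dunn's pairwise test with Bonferroni
adjustment, non-enhancing-lesion pooling, Pearson correlations, and a
multinomial logistic regression with patient-clustered standard errors.

The sampling unit is the per-lesion / per-ROI mean (MKT, or MD in
10^-3 mm^2/s).  Several lesions come from the same patient, so the
multinomial model's covariance is the cluster-robust sandwich with
per-patient score sums; the naive ML covariance is available for
comparison.  MD enters all models in its native units; the x100 factor is
a display convention only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupSample",
    "KruskalResult",
    "MultinomialFit",
    "DegenerateDataError",
    "SeparationError",
    "kruskal_wallis",
    "dunn_pairwise",
    "pool_nonenhancing",
    "pearson_r",
    "md_display_scale",
    "fit_multinomial",
]

MULTINOMIAL_CATEGORIES = ("FLAIR-L", "NAWM", "CE-L", "BH")


class DegenerateDataError(ValueError):
    """Data admit no well-defined statistic (all ties, constant predictor...)."""


class SeparationError(RuntimeError):
    """Perfect separation: a predictor's coefficient diverges."""


@dataclass(frozen=True)
class GroupSample:
    """One category's per-lesion/ROI values with aligned patient ids."""

    label: str
    values: np.ndarray
    patient_ids: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.size < 1 or not np.all(np.isfinite(v)):
            raise ValueError(f"group '{self.label}' needs >= 1 finite value")
        if self.patient_ids is not None:
            pid = np.asarray(self.patient_ids)
            if pid.shape != v.shape:
                raise ValueError("patient ids must align with values")
            object.__setattr__(self, "patient_ids", pid)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    df: int
    pvalue: float


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal-Wallis one-way analysis of variance on ranks (tie-corrected).

    H is referred to a chi-square distribution with k-1 degrees of freedom.
    All-identical samples leave H undefined (tie-correction denominator 0).
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [g.values for g in groups]
    if sum(a.size for a in arrays) < 3:
        raise ValueError("Kruskal-Wallis needs total N >= 3")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise DegenerateDataError(
            "all values identical: tie-correction denominator is zero")
    with np.errstate(invalid="ignore"):
        h, p = sps.kruskal(*arrays)
    if not np.isfinite(h):
        raise DegenerateDataError("Kruskal-Wallis H undefined for this sample")
    return KruskalResult(statistic=float(h), df=len(groups) - 1, pvalue=float(p))


def dunn_pairwise(groups, alpha: float = 0.05, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    For groups i, j with mean ranks Rbar on the pooled mid-ranks of N values,

        z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]

    with tie term T = sum(t^3 - t) over tie groups.  Two-sided normal
    p-values; Bonferroni-adjusted p = min(1, m*p) over the m = C(k,2) pairs.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment '{adjust}'")
    pooled = np.concatenate([g.values for g in groups])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    if var_base <= 0:
        raise DegenerateDataError("all values identical; Dunn variance is zero")

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.n].mean())
        sizes.append(g.n)
        start += g.n

    rows = []
    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    m = len(pairs)
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, m * p) if adjust == "bonferroni" else p
        rows.append({
            "group_a": groups[i].label, "group_b": groups[j].label,
            "z": z, "p_raw": p, "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        })
    return pd.DataFrame(rows)


def pool_nonenhancing(flair_sample: GroupSample, bh_sample: GroupSample,
                      label: str = "NE-L") -> GroupSample:
    """Pool FLAIR-L and BH into the non-enhancing lesion (NE-L) group.

    Pure concatenation: the pooled mean is the size-weighted mean of the two
    group means, and the total count is preserved.
    """
    def _pid(g):
        return g.patient_ids if g.patient_ids is not None else np.full(g.n, "", object)

    if flair_sample.n == 0:
        return GroupSample(label, bh_sample.values, bh_sample.patient_ids)
    if bh_sample.n == 0:
        return GroupSample(label, flair_sample.values, flair_sample.patient_ids)
    values = np.concatenate([flair_sample.values, bh_sample.values])
    pids = None
    if flair_sample.patient_ids is not None or bh_sample.patient_ids is not None:
        pids = np.concatenate([_pid(flair_sample), _pid(bh_sample)])
    return GroupSample(label, values, pids)


def pearson_r(x, y):
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two aligned samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def md_display_scale(md_values):
    """Display-layer scaling of MD by 100 (stored values stay in 10^-3 mm^2/s)."""
    out = np.asarray(md_values, float) * 100.0
    return out if out.ndim else float(out)


@dataclass
class MultinomialFit:
    """Multinomial logit of lesion category (reference FLAIR-L) on MK, MD and
    covariates, with patient-clustered (sandwich) standard errors."""

    reference: str
    categories: list            # non-reference outcome categories, model order
    terms: list                 # exog column names
    params: pd.DataFrame        # terms x categories
    bse: pd.DataFrame
    pvalues: pd.DataFrame
    odds_ratios: pd.DataFrame   # long table: category, term, OR, CI, p
    cov_type: str
    converged: bool
    llf: float
    n_obs: int

    def table(self, term: str) -> pd.DataFrame:
        """Odds-ratio rows for one predictor across outcome categories."""
        return self.odds_ratios[self.odds_ratios["term"] == term].reset_index(drop=True)


_DEFAULT_TERMS = ("mean_mkt", "mean_md", "age_years", "disease_duration_years",
                  "edss", "voxel_count")


def fit_multinomial(
    records: pd.DataFrame,
    reference: str = "FLAIR-L",
    cluster: str | None = "patient_id",
    terms=_DEFAULT_TERMS,
    categories=MULTINOMIAL_CATEGORIES,
) -> MultinomialFit:
    """Fit the lesion-category multinomial logit.

    ``records`` is the lesion table merged with patient covariates; rows are
    restricted to ``categories`` (NAWM, CE-L, BH and the FLAIR-L reference).
    The fit is maximum likelihood by Newton iterations; with
    ``cluster=None`` the naive ML covariance is reported, otherwise the
    cluster-robust sandwich over the given grouping column.
    """
    if reference not in categories:
        raise ValueError("reference must be one of the modeled categories")
    df = records[records["category"].isin(categories)].copy()
    present = df["category"].unique()
    if len(present) < 2:
        raise ValueError("need at least two outcome categories present")
    order = [reference] + [c for c in categories if c != reference and c in present]
    df["category"] = pd.Categorical(df["category"], categories=order, ordered=False)

    terms = [t for t in terms if t in df.columns]
    x = df[terms].astype(float)
    bad = [t for t in terms if np.ptp(x[t].to_numpy()) == 0]
    if bad:
        raise DegenerateDataError(f"predictor(s) with zero variance: {bad}")
    exog = sm.add_constant(x, has_constant="add")
    endog = df["category"].cat.codes.to_numpy()

    model = sm.MNLogit(endog, exog)
    fit_kwds = dict(method="newton", maxiter=100, disp=0, tol=1e-10)
    if cluster is not None:
        groups = df[cluster].to_numpy()
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups}, **fit_kwds)
        cov_type = "cluster"
    else:
        res = model.fit(**fit_kwds)
        cov_type = "nonrobust"

    converged = bool(res.mle_retvals.get("converged", False))
    params = np.asarray(res.params)          # (k_exog, k_cat-1)
    if not converged:
        raise SeparationError(
            f"multinomial fit did not converge in {res.mle_retvals.get('iterations')} "
            f"iterations; max |beta| = {np.abs(params).max():.3g}"
        )
    if np.abs(params).max() > 1e2 * max(1.0, np.abs(np.median(params))):
        i, j = np.unravel_index(np.argmax(np.abs(params)), params.shape)
        raise SeparationError(
            f"coefficient for '{exog.columns[i]}' (category {order[j + 1]}) "
            f"diverged ({params[i, j]:.3g}); likely perfect separation"
        )

    cat_labels = order[1:]
    term_labels = list(exog.columns)
    params_df = pd.DataFrame(params, index=term_labels, columns=cat_labels)
    bse_df = pd.DataFrame(np.asarray(res.bse), index=term_labels, columns=cat_labels)
    pval_df = pd.DataFrame(np.asarray(res.pvalues), index=term_labels, columns=cat_labels)

    zcrit = sps.norm.ppf(0.975)
    rows = []
    for c in cat_labels:
        for t in term_labels:
            beta = params_df.loc[t, c]
            se = bse_df.loc[t, c]
            rows.append({
                "category": c, "term": t,
                "coef": beta, "se": se,
                "odds_ratio": np.exp(beta),
                "ci_low": np.exp(beta - zcrit * se),
                "ci_high": np.exp(beta + zcrit * se),
                "p": pval_df.loc[t, c],
            })
    or_df = pd.DataFrame(rows)

    return MultinomialFit(
        reference=reference,
        categories=cat_labels,
        terms=term_labels,
        params=params_df,
        bse=bse_df,
        pvalues=pval_df,
        odds_ratios=or_df,
        cov_type=cov_type,
        converged=converged,
        llf=float(res.llf),
        n_obs=int(res.nobs),
    )
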