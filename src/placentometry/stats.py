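"""Cohort statistics for diet × sex biometry and qPCR expression.

The biometry design is a two-diet (control vs low-protein), two-sex cohort
with litters as the natural experimental unit.  Weights are analysed by
ANCOVA with mean-centred predictors, all two-way interactions among the
predictors, and maternal weight and litter size as covariates; backward
elimination removes non-significant interaction terms (never main effects)
one at a time.  Where normality/homoscedasticity fail, a litter-stratified
case bootstrap of the regression coefficients provides percentile CIs and
p-values.  Relative qPCR expression uses the ΔΔCt method against a
reference gene, with the control group's geometric-mean fold at 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import BiometryRecord, CtRecord


@dataclass
class EfficiencyRecord:
    """Placental efficiency: fetal weight / placental weight."""

    conceptus_id: str
    fp_ratio: float


@dataclass
class AncovaResult:
    retained_terms: list
    coefficients: dict
    p_values: dict
    dropped_interactions: list  # in drop order
    nobs: int


@dataclass
class BootstrapResult:
    term: str
    coefficient: float  # point estimate on the full data
    n_resamples: int
    ci_95: tuple
    p_value: float
    seed: Optional[int] = None


@dataclass
class TukeyResult:
    f_statistic: float
    anova_p: float
    table: pd.DataFrame  # pairwise comparisons
    letters: dict  # group -> letter string; shared letter = not different


# ---------------------------------------------------------------------------
# placental efficiency


def fp_ratio(biometry: Sequence[BiometryRecord]) -> list[EfficiencyRecord]:
    out = []
    for r in biometry:
        if r.placental_weight <= 0:
            raise ValueError(f"{r.conceptus_id}: zero placental weight")
        out.append(
            EfficiencyRecord(
                conceptus_id=r.conceptus_id,
                fp_ratio=r.fetal_weight / r.placental_weight,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ANCOVA with backward elimination of interactions


def _encode(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Numeric encoding: diet -> I(LP), sex -> I(F); others passed through."""
    out = pd.DataFrame(index=df.index)
    for c in cols:
        if c == "diet":
            out["diet"] = (df["diet"] == "LP").astype(float)
        elif c == "sex":
            out["sex"] = (df["sex"] == "F").astype(float)
        else:
            out[c] = df[c].astype(float)
    return out


def ancova_backward(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str] = ("diet", "sex", "placental_weight"),
    covariates: Sequence[str] = ("maternal_weight", "litter_size"),
    alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA with stepwise backward elimination of interaction terms.

    The full model contains every predictor (mean-centred), all two-way
    interactions among the predictors, and the covariates.  At each step
    the interaction with the largest p-value ≥ alpha is removed (ties
    broken by term name) and the model refit; main effects and covariates
    are never removed.  Centring leaves the drop decisions unchanged but
    makes main-effect coefficients interpretable at average predictor
    values.
    """
    predictors = [p for p in predictors if p != response]
    X0 = _encode(data, list(predictors) + list(covariates))
    X0 = X0 - X0.mean()  # predictors centred on a mean of zero
    y = data[response].astype(float).to_numpy()

    terms: dict[str, np.ndarray] = {c: X0[c].to_numpy() for c in X0.columns}
    interactions = []
    for a, b in itertools.combinations(predictors, 2):
        name = f"{a}:{b}"
        terms[name] = X0[a].to_numpy() * X0[b].to_numpy()
        interactions.append(name)

    def fit(active: list[str]):
        X = np.column_stack([np.ones(len(y))] + [terms[t] for t in active])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify aliased columns by incremental rank
            aliased = []
            cols = [np.ones(len(y))]
            for t in active:
                cand = np.column_stack(cols + [terms[t]])
                if np.linalg.matrix_rank(cand) == len(cols):
                    aliased.append(t)
                else:
                    cols.append(terms[t])
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
        model = sm.OLS(y, X).fit()
        names = ["Intercept"] + active
        return model, names

    active = list(predictors) + list(covariates) + interactions
    dropped: list[str] = []
    while True:
        model, names = fit(active)
        pvals = dict(zip(names, model.pvalues))
        worst, worst_p = None, alpha
        for t in sorted(i for i in interactions if i in active):
            if pvals[t] >= worst_p:
                # strictly larger p wins; ties keep the first in name order
                if worst is None or pvals[t] > pvals[worst]:
                    worst = t
        if worst is None:
            break
        active.remove(worst)
        dropped.append(worst)

    model, names = fit(active)
    coefs = dict(zip(names, model.params))
    pvals = dict(zip(names, model.pvalues))
    return AncovaResult(
        retained_terms=names[1:],
        coefficients=coefs,
        p_values=pvals,
        dropped_interactions=dropped,
        nobs=len(y),
    )


# ---------------------------------------------------------------------------
# litter-stratified case bootstrap of regression coefficients


def bootstrap_coefficients(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str] = ("diet", "sex"),
    n_resamples: int = 10000,
    seed: Optional[int] = None,
    stratify: Optional[str] = "litter_id",
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> dict[str, BootstrapResult]:
    """Case-resampling bootstrap of OLS coefficients, stratified by litter.

    Cases are resampled with replacement within each litter (preserving the
    litter structure the cohort design controls for), the model
    ``response ~ predictors`` is refit on every resample, and each
    coefficient gets a percentile 95% CI and the two-sided p-value
    2 × min(P(β* ≤ 0), P(β* ≥ 0)) under the null of no group difference.
    Resamples in which a predictor collapses to a single level are redrawn
    (up to ``max_redraws`` rounds, then an error).
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    rng = np.random.default_rng(seed)
    Xdf = _encode(data, predictors)
    X = np.column_stack([np.ones(len(Xdf))] + [Xdf[c].to_numpy() for c in predictors])
    y = data[response].astype(float).to_numpy()
    n, p = X.shape

    if stratify is not None and stratify in data.columns:
        strata = [np.flatnonzero(data[stratify].to_numpy() == g)
                  for g in pd.unique(data[stratify])]
    else:
        strata = [np.arange(n)]

    def draw(count: int) -> np.ndarray:
        cols = [s[rng.integers(0, len(s), size=(count, len(s)))] for s in strata]
        return np.concatenate(cols, axis=1)  # (count, n)

    idx = draw(n_resamples)
    for _ in range(max_redraws):
        Xb = X[idx]  # (B, n, p)
        # degenerate resample: any non-intercept column constant
        spread = Xb[:, :, 1:].max(axis=1) - Xb[:, :, 1:].min(axis=1)
        bad = (spread <= 0).any(axis=1)
        if not bad.any():
            break
        idx[bad] = draw(int(bad.sum()))
    else:
        raise ValueError("could not draw resamples with both group levels")

    Xb = X[idx]
    yb = y[idx]
    xtx = np.einsum("bni,bnj->bij", Xb, Xb)
    xty = np.einsum("bni,bn->bi", Xb, yb)
    betas = np.linalg.solve(xtx, xty[..., None])[..., 0]  # (B, p)

    point = np.linalg.lstsq(X, y, rcond=None)[0]
    out: dict[str, BootstrapResult] = {}
    for j, term in enumerate(predictors, start=1):
        b = betas[:, j]
        lo, hi = np.percentile(b, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        pval = 2 * min(float(np.mean(b <= 0)), float(np.mean(b >= 0)))
        out[term] = BootstrapResult(
            term=term,
            coefficient=float(point[j]),
            n_resamples=n_resamples,
            ci_95=(float(lo), float(hi)),
            p_value=min(1.0, pval),
            seed=seed,
        )
    return out


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD with compact letter display


def _letters(groups: list, not_different: set) -> dict:
    """Compact letter display from the set of non-different pairs.

    Maximal cliques of the "not significantly different" graph each get a
    letter; groups sharing any letter are statistically indistinguishable.
    Brute-force over subsets (fine for the handful of groups used here).
    """
    k = len(groups)
    adj = {g: {g} for g in groups}
    for a, b in not_different:
        adj[a].add(b)
        adj[b].add(a)
    cliques = []
    for r in range(k, 0, -1):
        for combo in itertools.combinations(groups, r):
            s = set(combo)
            if all(s <= adj[g] for g in combo):
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in groups:
            if g in clique:
                letters[g] += letter
    return letters


def anova_tukey(groups: dict) -> TukeyResult:
    """One-way ANOVA followed by Tukey's HSD with letter labels.

    ``groups`` maps group name to a 1-D array of observations.  Groups that
    share a letter are not significantly different at the 5% level (the
    display convention used for gestational-stage comparisons).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = sorted(groups, key=lambda g: float(np.mean(groups[g])))
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    f, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    table = pd.DataFrame(
        data=tk._results_table.data[1:], columns=tk._results_table.data[0]
    )
    not_different = {
        (row["group1"], row["group2"])
        for _, row in table.iterrows()
        if not row["reject"]
    }
    letters = _letters(names, not_different)
    return TukeyResult(
        f_statistic=float(f), anova_p=float(p), table=table, letters=letters
    )


def kruskal_wallis(groups: dict) -> tuple[float, float]:
    """Kruskal–Wallis H test (used where ANOVA assumptions fail)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    h, p = sps.kruskal(*[np.asarray(v, dtype=float) for v in groups.values()])
    return float(h), float(p)


# ---------------------------------------------------------------------------
# ΔΔCt relative expression


def ddct(
    ct_records: Sequence[CtRecord],
    control_group: str = "Con",
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    Per gene: ΔCt = Ct_target − Ct_reference; ΔΔCt = ΔCt − mean(ΔCt of the
    control group); fold = (1 + efficiency)^(−ΔΔCt) (2^−ΔΔCt at the default
    perfect efficiency).  The control group's geometric-mean fold is 1 by
    construction.  A natural-log log1p transform of the fold is emitted
    alongside.  ΔΔCt is invariant to adding a constant to every Ct value.
    """
    if not ct_records:
        raise ValueError("no Ct records")
    rows = []
    for r in ct_records:
        if r.ct_reference is None or (isinstance(r.ct_reference, float) and math.isnan(r.ct_reference)):
            raise ValueError(f"{r.sample_id}: missing reference Ct")
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "sex": r.sex,
                "embryonic_day": r.embryonic_day,
                "gene": r.gene,
                "dct": r.ct_target - r.ct_reference,
            }
        )
    df = pd.DataFrame(rows)
    base = 1.0 + efficiency
    out = []
    for gene, sub in df.groupby("gene"):
        con = sub.loc[sub["group"] == control_group, "dct"]
        if con.empty:
            raise ValueError(f"gene {gene}: no {control_group} samples")
        ddct_vals = sub["dct"] - con.mean()
        fold = base ** (-ddct_vals)
        sub = sub.assign(ddct=ddct_vals, fold=fold, log1p_fold=np.log1p(fold))
        out.append(sub)
    return pd.concat(out, ignore_index=True)
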