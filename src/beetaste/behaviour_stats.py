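"""Inferential statistics on per-bee behavioural summaries.

* Preference assay — two-tailed one-sample Wilcoxon signed-rank test of the
  arcsine-sqrt-transformed tastant surface response rates against the
  chance value asin(sqrt(0.5)) = pi/4 (0.79 to two decimals).  The null
  distribution is computed exactly by enumerating sign assignments (via a
  rank-sum convolution, which also handles midrank ties) when the number of
  non-zero differences is at most 25, otherwise by normal approximation
  with continuity correction.

* Training phase — Gaussian GLMs on transformed ten-visit-interval success
  rates, with AIC selection over a candidate family crossing group
  structure (all groups alike / control vs conditioned / all three
  distinct) with presence of an experience (visit-interval) term and its
  group interaction.  The simplest model within two AIC units of the
  minimum is selected (parsimony rule).

* Test phase — one-way ANOVA on transformed test-phase success across the
  control, tastant-positive and tastant-negative groups, with Tukey HSD
  pairwise comparisons and compact letter display groupings.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .behaviour import arcsine_sqrt

__all__ = [
    "PreferenceTestResult",
    "LearningModelSet",
    "TestPhaseResult",
    "CHANCE_TRANSFORMED",
    "wilcoxon_vs_random",
    "fit_learning_models",
    "test_phase_anova",
    "letter_groupings",
]

#: arcsine-sqrt of the random-choice proportion 0.5 (exact value, pi/4)
CHANCE_TRANSFORMED = float(np.arcsin(np.sqrt(0.5)))
ALPHA = 0.05
#: largest sample size for which the exact signed-rank null is enumerated
EXACT_N_MAX = 25


@dataclass
class PreferenceTestResult:
    tastant: str
    n: int
    median: float
    minimum: float
    maximum: float
    W: float
    p: float
    degenerate: bool = False
    method: str = "exact"


@dataclass
class LearningModelSet:
    table: pd.DataFrame  # model_id, formula, n_params, aic, delta_aic
    selected: str
    note: str = ""

    @property
    def delta_group_vs_same(self) -> float:
        """AIC advantage of the best group-separating model with an
        experience term over the best group-blind model (positive means the
        separating model wins)."""
        t = self.table
        grouped = t[t["has_group"] & t["has_experience"]]["aic"].min()
        same = t[~t["has_group"]]["aic"].min()
        return float(same - grouped)


@dataclass
class TestPhaseResult:
    tastant: str
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame = field(repr=False)
    letters: dict[str, str] = field(default_factory=dict)
    group_means: pd.Series = field(repr=False, default=None)


def _signed_rank_exact_p(ranks: np.ndarray, w: float) -> float:
    """Two-tailed p for W+ = ``w`` by enumerating all sign assignments.

    ``ranks`` are the (mid)ranks of the non-zero |differences|; the null
    distribution of W+ is built by convolution over signs, so ties pose no
    problem.  Midranks are multiples of 1/2, so doubling gives integers.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w))
    if w2 * 2 == total:
        return 1.0
    lo, hi = min(w2, total - w2), max(w2, total - w2)
    return float(min(1.0, dist[: lo + 1].sum() + dist[hi:].sum()))


def wilcoxon_vs_random(
    rates: np.ndarray | list[float],
    mu: float = CHANCE_TRANSFORMED,
    tastant: str = "",
) -> PreferenceTestResult:
    """One-sample two-tailed Wilcoxon signed-rank test of transformed
    response rates against the chance baseline.

    Raw proportions in ``rates`` are arcsine-sqrt transformed; zero
    differences are dropped.  W is the sum of ranks of positive
    differences (the convention of Table-style summaries).
    """
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    if n < 5:
        raise ValueError("need at least 5 bees for the signed-rank test")
    t = arcsine_sqrt(rates)
    d = t - mu
    nz = d[d != 0]
    if len(nz) == 0:
        return PreferenceTestResult(
            tastant, n, float(np.median(rates)), float(rates.min()),
            float(rates.max()), W=0.0, p=1.0, degenerate=True, method="degenerate",
        )
    ranks = stats.rankdata(np.abs(nz))
    W = float(ranks[nz > 0].sum())
    if len(nz) <= EXACT_N_MAX:
        p = _signed_rank_exact_p(ranks, W)
        method = "exact"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.wilcoxon(
                nz, alternative="two-sided", correction=True, method="approx"
            )
        p = float(p)
        method = "normal-approx"
    return PreferenceTestResult(
        tastant,
        n,
        float(np.median(rates)),
        float(rates.min()),
        float(rates.max()),
        W=W,
        p=p,
        degenerate=False,
        method=method,
    )


_CANDIDATES = [
    # (model_id, formula RHS, has_group, has_experience)
    ("null", "1", False, False),
    ("experience", "experience", False, True),
    ("conditioned", "conditioned", True, False),
    ("conditioned+experience", "conditioned + experience", True, True),
    ("conditioned*experience", "conditioned * experience", True, True),
    ("group", "C(group)", True, False),
    ("group+experience", "C(group) + experience", True, True),
    ("group*experience", "C(group) * experience", True, True),
]


def _interval_long(summaries: pd.DataFrame, control_label: str) -> pd.DataFrame:
    cols = [f"s{k}_t" for k in range(10, 80, 10)]
    missing = [c for c in cols if c not in summaries.columns]
    if missing:
        raise ValueError(f"summaries missing transformed interval columns {missing}")
    long = summaries.melt(
        id_vars=["bee_id", "group"], value_vars=cols,
        var_name="interval_col", value_name="y",
    )
    long["experience"] = long["interval_col"].str.extract(r"s(\d+)_t").astype(int) / 70.0
    long["conditioned"] = (long["group"] != control_label).astype(int)
    return long


def fit_learning_models(
    summaries: pd.DataFrame, control_label: str = "control"
) -> LearningModelSet:
    """AIC selection over the learning-curve candidate family.

    ``summaries`` holds one row per bee with transformed interval success
    columns s10_t..s70_t and a ``group`` column covering the control,
    tastant-positive and tastant-negative groups of one tastant.  Gaussian
    GLMs (identity link; the arcsine-sqrt transform stabilizes the
    variance) are fit to the long-format interval data for every candidate;
    the simplest model within delta-AIC <= 2 of the minimum is selected.
    """
    groups = set(summaries["group"].unique())
    if control_label not in groups or len(groups) < 3:
        raise ValueError(
            f"need control plus two conditioned groups; got {sorted(groups)}"
        )
    long = _interval_long(summaries, control_label)
    rows = []
    for model_id, rhs, has_group, has_exp in _CANDIDATES:
        fit = smf.glm(f"y ~ {rhs}", data=long, family=sm.families.Gaussian()).fit()
        rows.append(
            {
                "model_id": model_id,
                "formula": f"y ~ {rhs}",
                "n_params": len(fit.params),
                "aic": float(fit.aic),
                "has_group": has_group,
                "has_experience": has_exp,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    within = table[table["delta_aic"] <= 2.0]
    selected = within.sort_values(["n_params", "aic"]).iloc[0]["model_id"]
    note = (
        "simplest model within 2 AIC units of the minimum"
        if selected != table.sort_values("aic").iloc[0]["model_id"]
        else "minimum-AIC model"
    )
    return LearningModelSet(table=table, selected=str(selected), note=note)


def letter_groupings(
    labels: list[str], p_matrix: pd.DataFrame, alpha: float = ALPHA,
    order_by: pd.Series | None = None,
) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different (p >= alpha), via maximal cliques of the non-difference graph."""
    adj = {
        (a, b): bool(p_matrix.loc[a, b] >= alpha)
        for a in labels for b in labels if a != b
    }
    cliques = []
    for r in range(len(labels), 0, -1):
        for subset in itertools.combinations(labels, r):
            if all(adj[(a, b)] for a, b in itertools.combinations(subset, 2)):
                if not any(set(subset) <= set(c) for c in cliques):
                    cliques.append(subset)
    if order_by is not None:
        cliques.sort(key=lambda c: -max(order_by[g] for g in c))
    letters = {g: "" for g in labels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def test_phase_anova(
    summaries: pd.DataFrame, tastant: str = "", alpha: float = ALPHA
) -> TestPhaseResult:
    """One-way ANOVA with Tukey HSD on transformed test-phase success.

    With ten bees in each of the three groups the F statistic carries
    (2, 27) degrees of freedom.
    """
    if "test_t" not in summaries.columns:
        raise ValueError("summaries must contain a test_t column")
    groups = sorted(summaries["group"].unique())
    samples = [summaries.loc[summaries["group"] == g, "test_t"].to_numpy() for g in groups]
    if any(len(s) < 2 for s in samples):
        small = [g for g, s in zip(groups, samples) if len(s) < 2]
        raise ValueError(f"groups with fewer than 2 bees: {small}")
    F, p = stats.f_oneway(*samples)
    if not np.isfinite(F):  # constant data across all groups
        F, p = 0.0, 1.0
    n = sum(len(s) for s in samples)
    res = stats.tukey_hsd(*samples)
    rows = []
    pmat = pd.DataFrame(1.0, index=groups, columns=groups)
    for i, g1 in enumerate(groups):
        for j, g2 in enumerate(groups):
            if j <= i:
                continue
            pij = float(res.pvalue[i, j])
            pmat.loc[g1, g2] = pmat.loc[g2, g1] = pij
            rows.append(
                {
                    "contrast": f"{g1} - {g2}",
                    "estimate": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": pij,
                }
            )
    means = pd.Series({g: float(s.mean()) for g, s in zip(groups, samples)})
    letters = letter_groupings(groups, pmat, alpha=alpha, order_by=means)
    return TestPhaseResult(
        tastant=tastant,
        F=float(F),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
        p=float(p),
        tukey=pd.DataFrame(rows),
        letters=letters,
        group_means=means,
    )
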