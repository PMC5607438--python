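"""Equivalence analyses: random-intercept mixed models, planned t tests, summaries.

The outcome is a scored data set with two theta scores per participant —
one per administration (paper vs. electronic device, Form A vs. Form B).
Equivalence of forms and modalities is examined the way mode-comparison
studies usually do:

* a linear mixed model ``theta ~ modality + form (+ modality:form)`` with a
  per-participant random intercept, fit by REML; Wald F tests per fixed
  term with containment-style denominator degrees of freedom
  (``N_subjects - (number of fixed terms + 1)``), i.e. the within-subject
  error stratum for a design with two observations per subject;
* planned repeated-measures t tests (Form A vs B; paper vs phone; paper vs
  tablet) and an independent-groups t test (phone vs tablet), each with
  Cohen's d computed from the two original group standard deviations — not
  from the standard deviation of the paired differences.

Both the interaction model and the main-effects model are always fitted:
dropping the interaction is a reported reduction step, not a data-dependent
branch.  A sensitivity re-analysis excludes flagged participants entirely
(both of their rows); the default flag rule marks participants with a
boundary theta estimate, and is pluggable because flagging criteria are
study-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "SCORED_COLUMNS",
    "FTest",
    "MixedModelResult",
    "TTestResult",
    "validate_scored",
    "flag_participants",
    "boundary_flag_rule",
    "fit_equivalence_models",
    "paired_t",
    "independent_t",
    "independent_t_from_summary",
    "summarize_scores",
    "proportion_agree",
]

SCORED_COLUMNS = ["participant_id", "modality", "form", "theta", "se", "flagged"]
ANALYSIS_MODALITIES = ("paper", "mobile_phone", "tablet")


@dataclass(frozen=True)
class FTest:
    f: float
    df_num: int
    df_den: float
    p: float


@dataclass(frozen=True)
class MixedModelResult:
    """Wald F tests and variance components of one random-intercept fit."""

    terms: dict[str, FTest]
    fixed_effects: dict[str, float]
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_subjects: int
    converged: bool


@dataclass(frozen=True)
class TTestResult:
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    mean_diff: float
    sd_diff: float  # SD of paired differences; pooled SD for independent groups
    t: float
    df: int
    p: float
    cohen_d: float


def validate_scored(df: pd.DataFrame) -> None:
    """Check the scored-dataset contract: columns, two rows per participant,
    thetas on the reporting scale."""
    missing = [c for c in SCORED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scored dataset missing columns: {missing}")
    counts = df["participant_id"].value_counts()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(f"every participant needs exactly 2 rows; offenders: {list(bad.index[:5])}")
    if not df["theta"].between(-4.0, 4.0).all():
        raise ValueError("theta values must lie in [-4, 4]")
    unknown = set(df["modality"]) - set(ANALYSIS_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modality levels: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Flagging
# ---------------------------------------------------------------------------

def boundary_flag_rule(df: pd.DataFrame) -> pd.Series:
    """Row-level flag: theta pinned to a scale bound or SE unavailable."""
    at_bound = df["theta"].abs() >= 4.0
    no_se = df["se"].isna()
    if "boundary" in df.columns:
        return df["boundary"].astype(bool) | at_bound | no_se
    return at_bound | no_se


def flag_participants(
    df: pd.DataFrame, rule: Callable[[pd.DataFrame], pd.Series] = boundary_flag_rule
) -> pd.DataFrame:
    """Set the participant-level ``flagged`` column from a row-level rule.

    A participant is flagged if *any* of their administrations is flagged;
    exclusion then removes both rows (participant-level exclusion).
    """
    out = df.copy()
    row_flags = rule(out)
    flagged_ids = set(out.loc[row_flags.astype(bool), "participant_id"])
    out["flagged"] = out["participant_id"].isin(flagged_ids)
    return out


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, with_interaction: bool):
    """Treatment-coded design matrix (reference: paper, Form A) and term map."""
    mod_mp = (df["modality"] == "mobile_phone").astype(float).to_numpy()
    mod_tab = (df["modality"] == "tablet").astype(float).to_numpy()
    form_b = (df["form"] == "B").astype(float).to_numpy()
    cols = {
        "Intercept": np.ones(len(df)),
        "modality[mobile_phone]": mod_mp,
        "modality[tablet]": mod_tab,
        "form[B]": form_b,
    }
    terms = {"modality": [1, 2], "form": [3]}
    if with_interaction:
        cols["modality[mobile_phone]:form[B]"] = mod_mp * form_b
        cols["modality[tablet]:form[B]"] = mod_tab * form_b
        terms["modality:form"] = [4, 5]
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), terms


def _fit_one(df: pd.DataFrame, with_interaction: bool, df_method: str) -> MixedModelResult:
    X, names, terms = _design(df, with_interaction)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design (a factor level is empty or confounded)")
    y = df["theta"].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    model = MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        # near-zero variance components trip harmless optimiser warnings
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit(reml=True, method="lbfgs")

    k_fe = X.shape[1]
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    n_subjects = len(np.unique(groups))
    n_obs = len(df)
    if df_method == "containment":
        df_den = float(n_subjects - (len(terms) + 1))
    elif df_method == "residual":
        df_den = float(n_obs - k_fe)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")

    ftests: dict[str, FTest] = {}
    for term, idx in terms.items():
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        q = len(idx)
        try:
            fstat = float(b @ np.linalg.solve(V, b) / q)
        except np.linalg.LinAlgError:
            fstat = float(b @ np.linalg.pinv(V) @ b / q)
        if not np.isfinite(fstat) and np.allclose(b, 0.0, atol=1e-10):
            fstat = 0.0  # zero contrast with a collapsed variance estimate
        p = float(stats.f.sf(fstat, q, df_den))
        ftests[term] = FTest(fstat, q, df_den, p)

    return MixedModelResult(
        terms=ftests,
        fixed_effects=dict(zip(names, beta.tolist())),
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        residual_var=float(fit.scale),
        n_obs=n_obs,
        n_subjects=n_subjects,
        converged=bool(fit.converged),
    )


def fit_equivalence_models(
    data: pd.DataFrame, use_flagged: bool = True, df_method: str = "containment"
) -> tuple[MixedModelResult, MixedModelResult]:
    """Fit the interaction model and the main-effects model.

    ``theta ~ modality + form + modality:form`` and then
    ``theta ~ modality + form``, each with a participant random intercept
    (REML).  With ``use_flagged=False`` flagged participants are removed
    entirely before fitting.  Returns ``(interaction_model, main_model)``.
    """
    validate_scored(data)
    df = data if use_flagged else data[~data["flagged"].astype(bool)]
    if df["modality"].nunique() < 2 or df["form"].nunique() < 2:
        raise ValueError("need at least two modality levels and both forms to fit the models")
    interaction = _fit_one(df, with_interaction=True, df_method=df_method)
    main = _fit_one(df, with_interaction=False, df_method=df_method)
    return interaction, main


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    return float(np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)))


PAIRED_COMPARISONS = ("formA_vs_formB", "paper_vs_phone", "paper_vs_tablet")


def paired_t(data: pd.DataFrame, comparison: str) -> TTestResult:
    """Repeated-measures t test on within-participant theta differences.

    ``formA_vs_formB`` pairs each participant's two forms;
    ``paper_vs_phone`` / ``paper_vs_tablet`` pair paper with the electronic
    score within the corresponding device subgroup.  Cohen's d uses the
    pooled SD of the two original groups, not the difference SD.
    """
    validate_scored(data)
    if comparison == "formA_vs_formB":
        wide = data.pivot(index="participant_id", columns="form", values="theta")
        x1, x2 = wide["A"], wide["B"]
        g1, g2 = "Form A", "Form B"
    elif comparison in ("paper_vs_phone", "paper_vs_tablet"):
        device = "mobile_phone" if comparison == "paper_vs_phone" else "tablet"
        sub = data[data["modality"].isin(["paper", device])]
        sub = sub.groupby("participant_id").filter(lambda g: set(g["modality"]) == {"paper", device})
        wide = sub.pivot(index="participant_id", columns="modality", values="theta")
        x1, x2 = wide["paper"], wide[device]
        g1, g2 = "Paper", device.replace("_", " ").title()
    else:
        raise ValueError(f"unknown comparison {comparison!r}; choose from {PAIRED_COMPARISONS}")

    both = pd.concat([x1, x2], axis=1).dropna()
    if len(both) < 2:
        raise ValueError("need at least 2 complete pairs")
    v1, v2 = both.iloc[:, 0].to_numpy(), both.iloc[:, 1].to_numpy()
    n = len(both)
    diff = v1 - v2
    if diff.std(ddof=1) == 0.0:
        # degenerate but well-defined: identical vectors carry no evidence
        t = 0.0 if diff.mean() == 0.0 else np.inf * np.sign(diff.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = stats.ttest_rel(v1, v2)
    sp = _pooled_sd(v1.std(ddof=1), n, v2.std(ddof=1), n)
    d = abs(v1.mean() - v2.mean()) / sp if sp > 0 else 0.0
    return TTestResult(
        group1=g1, group2=g2, n1=n, n2=n,
        mean1=float(v1.mean()), mean2=float(v2.mean()),
        sd1=float(v1.std(ddof=1)), sd2=float(v2.std(ddof=1)),
        mean_diff=float(diff.mean()), sd_diff=float(diff.std(ddof=1)),
        t=float(t), df=n - 1, p=float(p), cohen_d=float(d),
    )


def independent_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    group1: str = "group1", group2: str = "group2",
) -> TTestResult:
    """Pooled-variance Student t from group summary statistics.

    ``sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2)``;
    ``t = (mean1-mean2) / (sp sqrt(1/n1 + 1/n2))``, df = n1+n2-2,
    Cohen's d = |mean1-mean2| / sp.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    sp = _pooled_sd(sd1, n1, sd2, n2)
    return TTestResult(
        group1=group1, group2=group2, n1=n1, n2=n2,
        mean1=float(mean1), mean2=float(mean2), sd1=float(sd1), sd2=float(sd2),
        mean_diff=float(mean1 - mean2), sd_diff=sp,
        t=float(t), df=n1 + n2 - 2, p=float(p),
        cohen_d=abs(mean1 - mean2) / sp,
    )


def independent_t(
    x1: Sequence[float], x2: Sequence[float], group1: str = "group1", group2: str = "group2"
) -> TTestResult:
    """Pooled-variance Student t from raw score vectors."""
    v1 = np.asarray(x1, dtype=float)
    v2 = np.asarray(x2, dtype=float)
    return independent_t_from_summary(
        v1.mean(), v1.std(ddof=1), len(v1), v2.mean(), v2.std(ddof=1), len(v2),
        group1=group1, group2=group2,
    )


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def summarize_scores(data: pd.DataFrame) -> pd.DataFrame:
    """N / mean / SD of theta overall, by modality, by form, and by cell."""

    def row(condition: str, values: pd.Series) -> dict:
        n = len(values)
        return {
            "condition": condition,
            "n": n,
            "mean": float(values.mean()) if n else float("nan"),
            "sd": float(values.std(ddof=1)) if n > 1 else float("nan"),
        }

    rows = [row("Overall", data["theta"])]
    for m in ANALYSIS_MODALITIES:
        sub = data.loc[data["modality"] == m, "theta"]
        if len(sub):
            rows.append(row(f"Modality: {m}", sub))
    for f in ("A", "B"):
        rows.append(row(f"Form: {f}", data.loc[data["form"] == f, "theta"]))
    for m in ANALYSIS_MODALITIES:
        for f in ("A", "B"):
            sub = data.loc[(data["modality"] == m) & (data["form"] == f), "theta"]
            if len(sub):
                rows.append(row(f"{m} x {f}", sub))
    return pd.DataFrame(rows)


def proportion_agree(count: int, total: int) -> int:
    """Percentage ``100 * count / total`` rounded to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return int(round(100.0 * count / total))
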