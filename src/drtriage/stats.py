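"""Reader-study validation statistics.

One-vs-rest confusion tables against a gold standard, Cohen's kappa with
its large-sample standard error and agreement bands, sensitivity and
specificity with score confidence intervals, a single-operating-point
binary AUC, subgroup stratification with an AUC comparison z-test, and a
noncentral-chi-square sample-size calculation.

Missing reader responses are excluded pairwise from every table (never
imputed).  Iteration order is deterministic (sorted reader then image id)
so reports are byte-stable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .grading import ReferralCategory

__all__ = [
    "StudyDataset",
    "ConfusionTable2x2",
    "AgreementResult",
    "DiagnosticResult",
    "AucComparison",
    "build_confusion",
    "cohens_kappa",
    "kappa_band",
    "diagnostics",
    "stratify",
    "compare_auc",
    "sample_size_chisq",
    "evaluate_study",
    "load_pilot_confusion",
    "read_study",
    "write_study",
]

MISSING = "NA"

CATEGORIES = (
    ReferralCategory.RED_IMMEDIATE,
    ReferralCategory.YELLOW_REVIEW_6_MONTHS,
    ReferralCategory.GREEN_REVIEW_1_YEAR,
)


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDataset:
    """Gold labels, reader responses (possibly missing) and reader attributes.

    ``gold`` maps image_id -> referral token; ``responses`` has columns
    (reader_id, image_id, response) with ``NA`` for missing; ``reader_attrs``
    is indexed by reader_id with columns ``group`` and ``prior_grading``.
    """

    gold: pd.Series
    responses: pd.DataFrame
    reader_attrs: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = set(self.responses["image_id"]) - set(self.gold.index)
        if unknown:
            raise ValueError(f"responses reference unknown image ids: {sorted(unknown)[:5]}")
        bad = set(self.responses["response"].unique()) - {"green", "yellow", "red", MISSING}
        if bad:
            raise ValueError(f"unknown response tokens: {sorted(bad)}")

    @property
    def n_readers(self) -> int:
        return self.responses["reader_id"].nunique()

    @property
    def n_images(self) -> int:
        return len(self.gold)

    @property
    def expected_responses(self) -> int:
        return self.n_readers * self.n_images

    @property
    def n_missing(self) -> int:
        return int((self.responses["response"] == MISSING).sum())

    @property
    def actual_responses(self) -> int:
        return int((self.responses["response"] != MISSING).sum())

    def sorted_responses(self) -> pd.DataFrame:
        return self.responses.sort_values(
            ["reader_id", "image_id"], kind="mergesort"
        ).reset_index(drop=True)


@dataclass(frozen=True)
class ConfusionTable2x2:
    """One-vs-rest counts: a (gold-/reader-), b (gold-/reader+),
    c (gold+/reader-), d (gold+/reader+)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def __add__(self, other: "ConfusionTable2x2") -> "ConfusionTable2x2":
        return ConfusionTable2x2(
            self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    se_kappa: float
    p_observed: float
    p_expected: float
    band: str


@dataclass(frozen=True)
class DiagnosticResult:
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    percent_correct: float  # 100*d/(c+d), rounded to one decimal


@dataclass(frozen=True)
class AucComparison:
    statistic: float
    se_diff: float
    p_value: float
    method: str = "independent-groups z-test, Hanley-McNeil SEs"


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def build_confusion(ds: StudyDataset, category: ReferralCategory) -> ConfusionTable2x2:
    """One-vs-rest table for ``category``; missing responses excluded."""
    resp = ds.responses[ds.responses["response"] != MISSING]
    if resp.empty:
        raise ValueError("no non-missing responses in dataset")
    token = category.token
    gold_pos = ds.gold.loc[resp["image_id"]].to_numpy() == token
    reader_pos = resp["response"].to_numpy() == token
    a = int(np.sum(~gold_pos & ~reader_pos))
    b = int(np.sum(~gold_pos & reader_pos))
    c = int(np.sum(gold_pos & ~reader_pos))
    d = int(np.sum(gold_pos & reader_pos))
    return ConfusionTable2x2(a, b, c, d)


def kappa_band(kappa: float) -> str:
    """Agreement band after rounding kappa to two decimals.

    [0.01,0.20] slight, [0.21,0.40] fair, [0.41,0.60] moderate,
    [0.61,0.80] substantial, [0.81,0.99] almost perfect; values rounding
    outside [0.01, 0.99] are unclassified.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    k = round(kappa, 2)
    if 0.01 <= k <= 0.20:
        return "slight agreement"
    if 0.21 <= k <= 0.40:
        return "fair agreement"
    if 0.41 <= k <= 0.60:
        return "moderate agreement"
    if 0.61 <= k <= 0.80:
        return "substantial agreement"
    if 0.81 <= k <= 0.99:
        return "almost perfect agreement"
    return f"unclassified ({kappa:.3f})"


def cohens_kappa(t: ConfusionTable2x2) -> AgreementResult:
    """Chance-corrected agreement with its large-sample standard error."""
    n = t.n
    if n == 0:
        raise ValueError("empty confusion table")
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe >= 1.0:
        raise ValueError("degenerate marginals: expected agreement is 1")
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    return AgreementResult(
        kappa=kappa, se_kappa=se, p_observed=po, p_expected=pe, band=kappa_band(kappa)
    )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    # Hanley & McNeil (1982) SE for an AUC with n_pos/n_neg class sizes
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be non-empty to compute an AUC SE")
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def diagnostics(t: ConfusionTable2x2, ci_method: str = "wilson") -> DiagnosticResult:
    """Sensitivity, specificity, single-point binary AUC and 95% CIs.

    ``ci_method`` is ``wilson`` (score, default) or ``wald`` (normal).
    The AUC is (Se+Sp)/2 — the trapezoid under the one-operating-point
    ROC — with a Hanley-McNeil normal CI.
    """
    if t.c + t.d == 0:
        raise ValueError("undefined sensitivity: no gold-positive responses (c+d == 0)")
    if t.a + t.b == 0:
        raise ValueError("undefined specificity: no gold-negative responses (a+b == 0)")
    if ci_method not in ("wilson", "wald"):
        raise ValueError(f"ci_method must be 'wilson' or 'wald', got {ci_method!r}")
    method = "wilson" if ci_method == "wilson" else "normal"
    se_val = t.d / (t.c + t.d)
    sp_val = t.a / (t.a + t.b)
    se_ci = proportion_confint(t.d, t.c + t.d, alpha=0.05, method=method)
    sp_ci = proportion_confint(t.a, t.a + t.b, alpha=0.05, method=method)
    auc = (se_val + sp_val) / 2
    auc_se = _hanley_mcneil_se(auc, t.c + t.d, t.a + t.b)
    z = sps.norm.ppf(0.975)
    auc_ci = (max(0.0, auc - z * auc_se), min(1.0, auc + z * auc_se))
    return DiagnosticResult(
        sensitivity=se_val,
        specificity=sp_val,
        sensitivity_ci=(float(se_ci[0]), float(se_ci[1])),
        specificity_ci=(float(sp_ci[0]), float(sp_ci[1])),
        auc=auc,
        auc_ci=auc_ci,
        percent_correct=round(100 * t.d / (t.c + t.d), 1),
    )


def stratify(
    ds: StudyDataset, by: Union[str, tuple[str, int]]
) -> dict[str, StudyDataset]:
    """Partition a dataset by a reader attribute or by ordered image blocks.

    ``by`` is a reader-attribute column name, or ``("image-block", K)``
    to split the sorted image ids into consecutive blocks of size K.
    The groups' responses union to the input exactly.
    """
    out: dict[str, StudyDataset] = {}
    if isinstance(by, tuple):
        kind, k = by
        if kind != "image-block":
            raise ValueError(f"unknown stratification rule: {by!r}")
        if k <= 0:
            raise ValueError("block size must be positive")
        images = sorted(ds.gold.index)
        for block_idx in range(0, math.ceil(len(images) / k)):
            block = images[block_idx * k:(block_idx + 1) * k]
            mask = ds.responses["image_id"].isin(block)
            out[f"block{block_idx + 1}"] = StudyDataset(
                gold=ds.gold.loc[block],
                responses=ds.responses[mask].reset_index(drop=True),
                reader_attrs=ds.reader_attrs,
            )
        return out
    if by not in ds.reader_attrs.columns:
        raise ValueError(f"unknown reader attribute {by!r}")
    attr = ds.reader_attrs[by]
    if attr.isna().any():
        raise ValueError(f"attribute {by!r} undefined for some readers")
    for value in sorted(attr.unique(), key=str):
        readers = attr.index[attr == value]
        mask = ds.responses["reader_id"].isin(readers)
        out[str(value)] = StudyDataset(
            gold=ds.gold,
            responses=ds.responses[mask].reset_index(drop=True),
            reader_attrs=ds.reader_attrs.loc[readers],
        )
    return out


def compare_auc(
    auc1: float,
    n_pos1: int,
    n_neg1: int,
    auc2: float,
    n_pos2: int,
    n_neg2: int,
) -> AucComparison:
    """Two-sided z-test on an AUC difference between independent groups."""
    se1 = _hanley_mcneil_se(auc1, n_pos1, n_neg1)
    se2 = _hanley_mcneil_se(auc2, n_pos2, n_neg2)
    se_diff = math.hypot(se1, se2)
    if se_diff == 0.0:
        if auc1 == auc2:
            return AucComparison(statistic=0.0, se_diff=0.0, p_value=1.0)
        raise ValueError("zero-variance groups with unequal AUCs")
    z = (auc1 - auc2) / se_diff
    p = 2 * sps.norm.sf(abs(z))
    return AucComparison(statistic=z, se_diff=se_diff, p_value=float(p))


def sample_size_chisq(alpha: float, effect_size_w: float, power: float, df: int = 1) -> int:
    """Smallest N whose noncentral-chi-square power reaches the target.

    The test statistic under the alternative is noncentral chi-square with
    noncentrality N*w**2; for df=1 this matches the normal closed form
    ceil((z_{1-alpha/2} + z_{power})**2 / w**2).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if effect_size_w <= 0:
        raise ValueError("effect size w must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    crit = sps.chi2.ppf(1 - alpha, df)

    def achieved(n: int) -> float:
        return float(sps.ncx2.sf(crit, df, n * effect_size_w**2))

    # start near the df=1 normal approximation, then search exactly
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    n = max(1, math.ceil((z_a + z_b) ** 2 / effect_size_w**2))
    while achieved(n) < power:
        n += 1
        if n > 10**8:
            raise ValueError("required sample size exceeds feasible range")
    while n > 1 and achieved(n - 1) >= power:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _report_row(
    subgroup: str, category: ReferralCategory, t: ConfusionTable2x2, ci_method: str
) -> dict:
    agree = cohens_kappa(t)
    diag = diagnostics(t, ci_method=ci_method)
    return {
        "subgroup": subgroup,
        "category": category.token,
        "a": t.a,
        "b": t.b,
        "c": t.c,
        "d": t.d,
        "n": t.n,
        "kappa": agree.kappa,
        "se_kappa": agree.se_kappa,
        "band": agree.band,
        "sensitivity": diag.sensitivity,
        "specificity": diag.specificity,
        "sensitivity_ci_low": diag.sensitivity_ci[0],
        "sensitivity_ci_high": diag.sensitivity_ci[1],
        "specificity_ci_low": diag.specificity_ci[0],
        "specificity_ci_high": diag.specificity_ci[1],
        "auc": diag.auc,
        "auc_ci_low": diag.auc_ci[0],
        "auc_ci_high": diag.auc_ci[1],
        "percent_correct": diag.percent_correct,
        # display columns at the printed precisions
        "kappa_3dp": f"{agree.kappa:.3f}",
        "sensitivity_pct": int(100 * diag.sensitivity),  # truncated toward zero
        "specificity_pct": int(100 * diag.specificity),
    }


def evaluate_study(
    ds: StudyDataset,
    by: Optional[Union[str, tuple[str, int]]] = None,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Per-category agreement and diagnostic report, overall and per subgroup.

    Returns one row per referral category x subgroup (subgroup ``all``
    always included), with full-precision statistics plus display columns
    formatted at the conventional precisions.
    """
    rows = [
        _report_row("all", cat, build_confusion(ds, cat), ci_method)
        for cat in CATEGORIES
    ]
    if by is not None:
        for name, sub in stratify(ds, by).items():
            rows.extend(
                _report_row(name, cat, build_confusion(sub, cat), ci_method)
                for cat in CATEGORIES
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures and CSV I/O
# ---------------------------------------------------------------------------

def load_pilot_confusion() -> dict[ReferralCategory, ConfusionTable2x2]:
    """The packaged one-vs-rest confusion counts for the three referral types."""
    path = resources.files("drtriage").joinpath("data/pilot_confusion.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    out = {}
    for _, row in df.iterrows():
        out[ReferralCategory.from_token(row["category"])] = ConfusionTable2x2(
            int(row["gold_neg_reader_neg"]),
            int(row["gold_neg_reader_pos"]),
            int(row["gold_pos_reader_neg"]),
            int(row["gold_pos_reader_pos"]),
        )
    return out


def read_study(gold_path: str, responses_path: str, readers_path: str) -> StudyDataset:
    """Load a study from the three CSVs (gold, responses, readers).

    Referral tokens are case-insensitive; missing responses are ``NA``.
    """
    gold_df = pd.read_csv(gold_path, dtype=str)
    gold = pd.Series(
        gold_df["referral"].str.strip().str.lower().to_numpy(),
        index=gold_df["image_id"].to_numpy(),
        name="referral",
    )
    resp = pd.read_csv(responses_path, dtype=str, keep_default_na=False)
    resp["response"] = resp["referral"].str.strip().str.lower().replace({"na": MISSING})
    resp = resp[["reader_id", "image_id", "response"]]
    readers = pd.read_csv(readers_path, dtype=str).set_index("reader_id")
    if "prior_grading" in readers.columns:
        readers["prior_grading"] = readers["prior_grading"].str.strip().str.lower().isin(
            ("true", "1", "yes")
        )
    return StudyDataset(gold=gold, responses=resp, reader_attrs=readers)


def write_study(ds: StudyDataset, gold_path: str, responses_path: str, readers_path: str) -> None:
    """Write the three study CSVs; inverse of :func:`read_study`."""
    pd.DataFrame({"image_id": ds.gold.index, "referral": ds.gold.to_numpy()}).to_csv(
        gold_path, index=False
    )
    resp = ds.sorted_responses().rename(columns={"response": "referral"})
    resp.to_csv(responses_path, index=False)
    readers = ds.reader_attrs.sort_index().reset_index()
    readers.to_csv(readers_path, index=False)
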