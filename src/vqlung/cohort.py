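"""Cohort-level association analysis between dose metrics and lung toxicity.

Radiation-induced lung toxicity (RILT) is recorded as a CTCAE grade 0–5 and
binarized as event = grade >= 2. Each of the six dosimetric metrics is
correlated with the binary event using the tie-corrected Spearman rank
correlation (ranks with average tie handling, Pearson correlation of the
ranks). P-values come from the usual t approximation on n-2 degrees of
freedom, or from a seeded permutation test. The analysis is repeated within
clinically defined strata (COPD, pulmonary function, tumor location, stage),
and within each stratum the anatomical (CT), perfusion (Q) and ventilation
(V) metric families are summarized into an ordered dominance label such as
``"V ≈ Q > CT"``.

No multiple-testing correction is applied by default; a Holm-adjusted column
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import MetricRecord

SEX_LEVELS = ("male", "female")
HISTOLOGY_LEVELS = ("squamous", "adenocarcinoma")
STAGE_LEVELS = ("I", "II", "III")
LOCATION_LEVELS = ("central", "peripheral")
YESNO_LEVELS = ("yes", "no")
PFT_LEVELS = ("worse", "good")
CHEMO_LEVELS = ("none", "docetaxel_platinum", "pemetrexed_platinum", "gemcitabine_platinum")
AGE_GROUP_LEVELS = ("<70", ">70")

#: Covariate -> allowed levels, in the cohort-table row order.
COVARIATE_LEVELS = {
    "sex": SEX_LEVELS,
    "age_group": AGE_GROUP_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "stage": STAGE_LEVELS,
    "location": LOCATION_LEVELS,
    "copd": YESNO_LEVELS,
    "pft": PFT_LEVELS,
    "chemo": CHEMO_LEVELS,
}

#: Canonical cohort CSV header (bit-exact).
COHORT_CSV_COLUMNS = [
    "patient_id", "V20", "MLD", "Q_V20", "Q_MLD", "V_V20", "V_MLD",
    "sex", "age_years", "histology", "stage", "location", "copd", "pft",
    "chemo", "rilt_grade",
]

#: Metric family -> member metrics, for dominance summaries.
METRIC_FAMILIES = {
    "CT": ("V20", "MLD"),
    "Q": ("Q_V20", "Q_MLD"),
    "V": ("V_V20", "V_MLD"),
}
#: Print order inside an exact tie: ventilation, perfusion, anatomical.
FAMILY_TIEBREAK = ("V", "Q", "CT")


class ConstantInputError(ValueError):
    """A correlation input vector has fewer than two distinct values."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's metrics, clinical covariates and RILT grade."""

    patient_id: str
    metrics: MetricRecord
    sex: str
    age_years: int
    histology: str
    stage: str
    location: str
    copd: str
    pft: str
    chemo: str
    rilt_grade: int

    def __post_init__(self):
        if self.rilt_grade not in range(6):
            raise ValueError(f"rilt_grade must be 0..5, got {self.rilt_grade}")
        for name in ("sex", "histology", "stage", "location", "copd", "pft", "chemo"):
            val = getattr(self, name)
            if val not in COVARIATE_LEVELS[name]:
                raise ValueError(
                    f"{name}={val!r} not in allowed levels {COVARIATE_LEVELS[name]}"
                )
        if self.age_years == 70:
            raise ValueError("age_years=70 cannot be placed in the <70 / >70 dichotomy")

    @property
    def age_group(self) -> str:
        return "<70" if self.age_years < 70 else ">70"

    @property
    def rilt_event(self) -> int:
        return rilt_event(self.rilt_grade)


def rilt_event(grade: int) -> int:
    """Binarize a CTCAE grade: 1 iff grade >= 2 (the RILT group)."""
    if grade not in range(6):
        raise ValueError(f"RILT grade must be an integer 0..5, got {grade!r}")
    return int(grade >= 2)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman r, p and n for one metric in one (sub)group."""

    metric_name: str
    r: float
    p: float
    n: int
    subgroup: str = "all"
    computable: bool = True
    reason: str | None = None

    def __post_init__(self):
        if self.computable:
            if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
                raise ValueError(f"|r| > 1: {self.r}")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"p outside [0, 1]: {self.p}")
            if self.n < 3:
                raise ValueError("computable results require n >= 3")


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman(
    x,
    y,
    p_method: str = "t_approx",
    n_perm: int = 10000,
    seed: int | None = None,
    metric_name: str = "",
    subgroup: str = "all",
) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Ranks use average tie handling; r is the Pearson correlation of the rank
    vectors. ``t_approx`` uses t = r sqrt((n-2)/(1-r^2)) on n-2 df;
    ``permutation`` uses the add-one estimator
    (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1) over seeded permutations of y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1D vectors, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    for name, v in (("x", x), ("y", y)):
        if np.unique(v).size < 2:
            raise ConstantInputError(f"{name} is constant; Spearman r is undefined")
    rx, ry = _rank(x), _rank(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    r = float(rxc @ ryc / np.sqrt((rxc @ rxc) * (ryc @ ryc)))
    r = min(1.0, max(-1.0, r))
    if p_method == "t_approx":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    elif p_method == "permutation":
        if seed is None:
            raise ValueError("permutation p-values require an explicit seed")
        rng = np.random.default_rng(seed)
        denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
        hits = 0
        for _ in range(n_perm):
            r_perm = rxc @ rng.permutation(ryc) / denom
            if abs(r_perm) >= abs(r) - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult(metric_name=metric_name, r=r, p=p, n=n, subgroup=subgroup)


def _not_computable(metric: str, subgroup: str, n: int, reason: str) -> CorrelationResult:
    return CorrelationResult(
        metric_name=metric, r=float("nan"), p=float("nan"), n=n,
        subgroup=subgroup, computable=False, reason=reason,
    )


def dominance_label(results, epsilon: float = 0.05) -> str:
    """Ordered comparison of the CT / Q / V metric families by mean |r|.

    Each family is summarized by the mean |r| of its two metrics; families are
    sorted descending and adjacent pairs within ``epsilon`` are joined with
    "≈", otherwise ">". At exact equality the print order is V, Q, CT. Any
    not-computable constituent yields ``"n/a"``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    by_name = {res.metric_name: res for res in results}
    missing = [m for fam in METRIC_FAMILIES.values() for m in fam if m not in by_name]
    if missing:
        raise ValueError(f"missing correlation results for {missing}")
    if any(not by_name[m].computable for fam in METRIC_FAMILIES.values() for m in fam):
        return "n/a"
    means = {
        fam: float(np.mean([abs(by_name[m].r) for m in members]))
        for fam, members in METRIC_FAMILIES.items()
    }
    order = sorted(METRIC_FAMILIES, key=lambda f: (-means[f], FAMILY_TIEBREAK.index(f)))
    parts = [order[0]]
    for prev, cur in zip(order, order[1:]):
        parts.append("≈" if means[prev] - means[cur] <= epsilon else ">")
        parts.append(cur)
    return " ".join(parts)


def dominance_groups(label: str) -> list[frozenset]:
    """Parse a dominance label into its ordered ≈-tied groups.

    ``"V ≈ Q > CT"`` -> ``[{"V", "Q"}, {"CT"}]``. The ≈ relation is symmetric,
    so two labels describe the same ordering iff their group lists are equal.
    """
    if label == "n/a":
        return []
    groups, current = [], []
    tokens = label.split()
    current = [tokens[0]]
    for sep, fam in zip(tokens[1::2], tokens[2::2]):
        if sep == "≈":
            current.append(fam)
        else:
            groups.append(frozenset(current))
            current = [fam]
    groups.append(frozenset(current))
    return groups


#: Stratifier name -> (record attribute, ordered stratum levels).
STRATIFIERS = {
    "copd": ("copd", ("yes", "no")),
    "pft": ("pft", ("worse", "good")),
    "location": ("location", ("central", "peripheral")),
    "stage": ("stage_group", ("I-II", "III")),
}


def _stage_group(record: PatientRecord) -> str:
    return "I-II" if record.stage in ("I", "II") else "III"


def _stratum_value(record: PatientRecord, attr: str) -> str:
    if attr == "stage_group":
        return _stage_group(record)
    return getattr(record, attr)


@dataclass(frozen=True)
class SubgroupTable:
    """All correlation rows plus a dominance label per stratum."""

    results: tuple
    labels: dict
    epsilon: float = 0.05

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "subgroup": res.subgroup,
                "metric": res.metric_name,
                "r": res.r,
                "p": res.p,
                "n": res.n,
                "computable": res.computable,
                "reason": res.reason or "",
                "comparison": self.labels[res.subgroup],
            }
            for res in self.results
        ]
        return pd.DataFrame(rows)


def _correlate_stratum(records, subgroup, outcome, p_method, n_perm, seed):
    out = []
    n = len(records)
    y = np.array([outcome(rec) for rec in records], dtype=float)
    for metric in MetricRecord.METRIC_NAMES:
        if n < 3:
            out.append(_not_computable(metric, subgroup, n, "fewer than 3 patients"))
            continue
        if np.unique(y).size < 2:
            out.append(_not_computable(metric, subgroup, n, "constant outcome"))
            continue
        xv = np.array([getattr(rec.metrics, metric) for rec in records], dtype=float)
        if np.unique(xv).size < 2:
            out.append(_not_computable(metric, subgroup, n, "constant metric"))
            continue
        out.append(
            spearman(xv, y, p_method=p_method, n_perm=n_perm, seed=seed,
                     metric_name=metric, subgroup=subgroup)
        )
    return out


def subgroup_correlations(
    cohort,
    strata=("copd", "pft", "location", "stage"),
    epsilon: float = 0.05,
    p_method: str = "t_approx",
    n_perm: int = 10000,
    seed: int | None = None,
    outcome: str = "event",
) -> SubgroupTable:
    """Per-stratum Spearman correlations of the six metrics with RILT.

    The outcome is the binary event (grade >= 2) by default; ``outcome="grade"``
    switches to the ordinal grade. Strata with n < 3 or a constant outcome are
    flagged not-computable rather than dropped. The all-patients stratum is
    always included first.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    unknown = [s for s in strata if s not in STRATIFIERS]
    if unknown:
        raise ValueError(f"unknown stratifier(s) {unknown}; known: {sorted(STRATIFIERS)}")
    if outcome == "event":
        out_fn = lambda rec: rec.rilt_event
    elif outcome == "grade":
        out_fn = lambda rec: rec.rilt_grade
    else:
        raise ValueError(f"outcome must be 'event' or 'grade', got {outcome!r}")

    results, labels = [], {}
    groups = [("all", list(cohort))]
    for name in strata:
        attr, levels = STRATIFIERS[name]
        for level in levels:
            sub = [rec for rec in cohort if _stratum_value(rec, attr) == level]
            groups.append((f"{name}={level}", sub))
    for subgroup, records in groups:
        rows = _correlate_stratum(records, subgroup, out_fn, p_method, n_perm, seed)
        results.extend(rows)
        labels[subgroup] = dominance_label(rows, epsilon=epsilon)
    return SubgroupTable(results=tuple(results), labels=labels, epsilon=epsilon)


def chi2_2x2_yates(table) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table (textbook Yates form).

    chi2 = n (max(0, |ad - bc| - n/2))^2 / ((a+b)(c+d)(a+c)(b+d)); the
    correction is clamped at zero, so near-perfectly homogeneous tables give
    chi2 = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("table has an empty margin")
    chi2 = n * max(0.0, abs(a * d - b * c) - n / 2.0) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def compare_characteristics(
    cohort,
    covariates=("sex", "age_group", "histology", "stage", "location", "copd", "pft", "chemo"),
    holm: bool = False,
) -> pd.DataFrame:
    """Baseline-characteristic comparison between RILT and non-RILT groups.

    For each categorical covariate a 2 x k contingency table (event x levels)
    is tested: 2x2 tables use the continuity-corrected chi-square, switching
    to Fisher's exact test when any expected cell count is below 5; k > 2
    tables use the plain chi-square with a small-sample warning flag when
    expected counts are low. Single-level covariates are flagged
    not-computable. ``holm=True`` appends Holm-adjusted p-values.
    """
    events = np.array([rec.rilt_event for rec in cohort])
    if events.min() == events.max():
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for cov in covariates:
        levels = COVARIATE_LEVELS[cov]
        vals = [getattr(rec, cov) for rec in cohort]
        present = [lv for lv in levels if lv in vals]
        if len(present) < 2:
            rows.append(
                {"covariate": cov, "test": "none", "p": float("nan"),
                 "computable": False, "small_sample": False,
                 "reason": "single observed level"}
            )
            continue
        table = np.array(
            [[sum(1 for v, e in zip(vals, events) if v == lv and e == grp)
              for lv in present] for grp in (1, 0)],
            dtype=float,
        )
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        small = bool((expected < 5).any())
        if table.shape[1] == 2:
            if small:
                _, p = stats.fisher_exact(table)
                test = "fisher_exact"
            else:
                _, p = chi2_2x2_yates(table)
                test = "chi2_yates"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            test = "chi2"
        rows.append(
            {"covariate": cov, "test": test, "p": float(p),
             "computable": True, "small_sample": small, "reason": ""}
        )
    df = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests  # optional path

        ok = df["computable"].to_numpy()
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok] = multipletests(df.loc[ok, "p"], method="holm")[1]
        df["p_holm"] = adj
    return df


def records_to_dataframe(cohort) -> pd.DataFrame:
    """Cohort as a DataFrame with the canonical CSV column order."""
    rows = []
    for rec in cohort:
        row = {"patient_id": rec.patient_id}
        row.update(rec.metrics.as_dict())
        row.update(
            sex=rec.sex, age_years=rec.age_years, histology=rec.histology,
            stage=rec.stage, location=rec.location, copd=rec.copd, pft=rec.pft,
            chemo=rec.chemo, rilt_grade=rec.rilt_grade,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def write_cohort_csv(cohort, path) -> None:
    records_to_dataframe(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Load a cohort table, validating the canonical schema."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        metrics = MetricRecord(
            V20=float(row["V20"]), MLD=float(row["MLD"]),
            Q_V20=float(row["Q_V20"]), Q_MLD=float(row["Q_MLD"]),
            V_V20=float(row["V_V20"]), V_MLD=float(row["V_MLD"]),
        )
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]), metrics=metrics,
                sex=row["sex"], age_years=int(row["age_years"]),
                histology=row["histology"], stage=str(row["stage"]),
                location=row["location"], copd=row["copd"], pft=row["pft"],
                chemo=row["chemo"], rilt_grade=int(row["rilt_grade"]),
            )
        )
    return out
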