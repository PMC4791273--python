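"""Clinical statistics for the tissue-microarray cohort.

Covers the survival-analysis stage of the pipeline: group medians of
immunopositivity (IP), Mann–Whitney U comparisons, Youden-optimal cutoff
dichotomization into marker-negative/-positive groups, Kaplan–Meier curves
with the log-rank test, a univariate Cox proportional-hazards fit of the
binary marker, and the marker-vs-ploidy binary (logistic) regression.

The 28-record cohort printed in the source study's TMA table ships as a
fixture (10 normal mucosa, 9 diploid and 9 aneuploid carcinomas, with
survival in months, vital status, and thymosin-beta-4 IP on [0, 1]).

The Cox partial likelihood is maximized by Newton–Raphson for a single
(typically binary) covariate, with Breslow (default) or Efron handling of
tied event times; the 95% Wald interval uses the observed-information
standard error and the exact normal quantile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CohortRecord",
    "CutoffResult",
    "CoxResult",
    "MWUResult",
    "load_tma_cohort",
    "load_cohort_csv",
    "group_median",
    "mann_whitney_u",
    "optimal_cutoff",
    "dichotomize",
    "kaplan_meier",
    "logrank",
    "cox_univariate",
    "binary_regression",
]

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class CohortRecord:
    """One patient of the tissue-microarray cohort."""

    id: str
    sex: str                      # "m" | "w"
    age: int
    group: str                    # "normal" | "tumor"
    ploidy: str | None            # "diploid" | "aneuploid" | None for normals
    t: str | None = None
    n: str | None = None
    m: str | None = None
    g: str | None = None
    uicc: str | None = None
    survival_months: float | None = None
    status: str | None = None     # "dead" | "alive"
    ip: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ip <= 1.0):
            raise ValueError(f"ip out of [0,1]: {self.ip}")
        if self.group == "tumor":
            if self.ploidy not in ("diploid", "aneuploid"):
                raise ValueError("tumor records need a ploidy label")
            if self.survival_months is None or self.status not in ("dead", "alive"):
                raise ValueError("tumor records need survival and vital status")
        elif self.group == "normal":
            if self.ploidy is not None:
                raise ValueError("normal records carry no ploidy label")

    @property
    def event(self) -> bool:
        return self.status == "dead"


def _round_half_up(value: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# checksum over the fixture's IP column, exact sum of the printed 4-decimal values
_FIXTURE_IP_SUM = Decimal("6.7615")


def load_cohort_csv(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV with the fixture's header set."""
    records: list[CohortRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            surv = row.get("survival_months", "")
            records.append(
                CohortRecord(
                    id=row["id"],
                    sex=row["sex"],
                    age=int(row["age"]),
                    group=row["group"],
                    ploidy=row["ploidy"] or None,
                    t=row.get("T") or None,
                    n=row.get("N") or None,
                    m=row.get("M") or None,
                    g=row.get("G") or None,
                    uicc=row.get("UICC") or None,
                    survival_months=float(surv) if surv else None,
                    status=row.get("status") or None,
                    ip=float(row["ip"]),
                )
            )
    return records


def load_tma_cohort() -> list[CohortRecord]:
    """Load the 28-record TMA fixture and verify its integrity.

    Exactly 10 normal, 9 diploid-tumor and 9 aneuploid-tumor records; the
    sum of the printed IP values acts as a checksum.
    """
    with resources.as_file(
        resources.files("ploidyims.fixtures") / "tma_cohort.csv"
    ) as p:
        records = load_cohort_csv(p)
        ip_sum = sum(Decimal(line.rsplit(",", 1)[-1]) for line in
                     p.read_text().strip().splitlines()[1:])
    counts = {
        "normal": sum(r.group == "normal" for r in records),
        "diploid": sum(r.ploidy == "diploid" for r in records),
        "aneuploid": sum(r.ploidy == "aneuploid" for r in records),
    }
    if counts != {"normal": 10, "diploid": 9, "aneuploid": 9}:
        raise ValueError(f"fixture group counts corrupted: {counts}")
    if ip_sum != _FIXTURE_IP_SUM:
        raise ValueError(f"fixture checksum mismatch: {ip_sum}")
    return records


def select(records: Sequence[CohortRecord], which: str) -> list[CohortRecord]:
    """Convenience subsetting: normal | tumor | diploid | aneuploid | all."""
    if which == "all":
        return list(records)
    if which in ("normal", "tumor"):
        return [r for r in records if r.group == which]
    if which in ("diploid", "aneuploid"):
        return [r for r in records if r.ploidy == which]
    raise ValueError(f"unknown selector {which!r}")


def group_median(
    records: Sequence[CohortRecord],
    selector: str | Callable[[CohortRecord], bool] = "all",
) -> float:
    """Median IP of the selected records, rounded half-up to 4 decimals.

    Even-sized selections report the mean of the two central order
    statistics, computed in decimal arithmetic so the printed rounding of
    e.g. 0.03945 -> 0.0395 is exact.
    """
    if callable(selector):
        sel = [r for r in records if selector(r)]
    else:
        sel = select(records, selector)
    if not sel:
        raise ValueError("empty selection")
    vals = sorted(Decimal(repr(r.ip)) for r in sel)
    k = len(vals)
    if k % 2:
        med = vals[k // 2]
    else:
        med = (vals[k // 2 - 1] + vals[k // 2]) / 2
    return float(med.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass
class MWUResult:
    u: float
    p: float
    method: str   # "exact" | "normal-approximation-with-tie-correction"


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> MWUResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when the combined sample is small (n1 + n2 <= 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 12 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal-approximation-with-tie-correction"
    return MWUResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float            # fraction in [0, 1]
    specificity: float
    sensitivity_pct: int          # half-up integer percent, as reported
    specificity_pct: int

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def optimal_cutoff(
    values: Sequence[float], labels: Sequence[int | bool]
) -> CutoffResult:
    """Youden-optimal dichotomization cutoff.

    Candidate cutoffs are the midpoints between adjacent distinct sorted
    values; a case is marker-positive iff value > cutoff (strict).  The
    cutoff maximizing sensitivity + specificity wins, ties broken toward
    higher specificity, then toward the lower cutoff.  The cutoff is
    reported rounded half-up to 4 decimals (midpoints computed in decimal
    arithmetic), sensitivity/specificity additionally as half-up integer
    percentages.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.size != y.size:
        raise ValueError("values and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    distinct = sorted(set(float(x) for x in v))
    if len(distinct) < 2:
        raise ValueError("all values identical")
    pos = v[y]
    neg = v[~y]
    # midpoints between adjacent values, plus the all-negative boundary cutoff
    # at the maximum (so a non-discriminating marker scores Youden 0, never <0)
    candidates = [
        (Decimal(repr(lo_v)) + Decimal(repr(hi_v))) / 2
        for lo_v, hi_v in zip(distinct[:-1], distinct[1:])
    ]
    candidates.append(Decimal(repr(distinct[-1])))
    best = None
    for mid in candidates:
        c = float(mid)
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        key = (sens + spec, spec, -c)
        if best is None or key > best[0]:
            best = (key, mid, sens, spec)
    _, mid, sens, spec = best
    cutoff = float(mid.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))
    return CutoffResult(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        sensitivity_pct=int(_round_half_up(100 * sens, 0)),
        specificity_pct=int(_round_half_up(100 * spec, 0)),
    )


def dichotomize(
    records: Sequence[CohortRecord], cutoff: float
) -> dict[str, bool]:
    """Marker status per record id: positive iff ip > cutoff (strict).

    A value exactly equal to the cutoff is assigned negative (the two strict
    inequalities of the scoring rule leave equality undefined; this is the
    declared convention).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return {r.id: r.ip > cutoff for r in records}


def kaplan_meier(times: Sequence[float], events: Sequence[bool], label: str = "KM"):
    """Product-limit survival estimate (lifelines ``KaplanMeierFitter``)."""
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty input")
    if t.min() < 0:
        raise ValueError("negative times")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(t, event_observed=np.asarray(events, dtype=bool))
    return kmf


def logrank(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]):
    """Log-rank test across >= 2 groups; returns (chi2 statistic, p)."""
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        times.extend(float(x) for x in t)
        events.extend(bool(x) for x in e)
        labels.extend([gi] * len(list(t)))
    if not any(events):
        raise ValueError("no events")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    ties_method: str
    beta: float
    se: float
    converged: bool = True


def _cox_score_info(
    beta: float,
    t: np.ndarray,
    e: np.ndarray,
    x: np.ndarray,
    ties_method: str,
) -> tuple[float, float]:
    """Score U(beta) and observed information I(beta) of the partial likelihood."""
    eta = np.exp(beta * x)
    U = 0.0
    I = 0.0
    # risk-set sums via descending-time cumulative sums
    order = np.argsort(-t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    etas = eta[order]
    c0 = np.cumsum(etas)
    c1 = np.cumsum(etas * xs)
    c2 = np.cumsum(etas * xs * xs)
    # for event time ti, risk set = all with t >= ti = first k entries of the
    # descending order where ts[k-1] >= ti
    event_times = np.unique(t[e])
    for ti in event_times:
        k = int(np.searchsorted(-ts, -ti, side="right"))
        s0, s1, s2 = c0[k - 1], c1[k - 1], c2[k - 1]
        tied = e & (t == ti)
        d = int(tied.sum())
        sx = float(x[tied].sum())
        if ties_method == "breslow":
            U += sx - d * s1 / s0
            I += d * (s2 / s0 - (s1 / s0) ** 2)
        elif ties_method == "efron":
            eta_d = eta[tied]
            xd = x[tied]
            d0 = float(eta_d.sum())
            d1 = float((eta_d * xd).sum())
            d2 = float((eta_d * xd * xd).sum())
            for r in range(d):
                f = r / d
                a0 = s0 - f * d0
                a1 = s1 - f * d1
                a2 = s2 - f * d2
                U += sx / d - a1 / a0
                I += a2 / a0 - (a1 / a0) ** 2
        else:
            raise ValueError(f"unknown ties_method {ties_method!r}")
    return U, I


def cox_univariate(
    times: Sequence[float],
    events: Sequence[bool],
    x: Sequence[float],
    ties_method: str = "breslow",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton–Raphson.

    HR = exp(beta); the 95% CI is exp(beta +/- z * SE) with the exact 97.5%
    normal quantile and SE from the observed information; p is the Wald test.
    A diverging coefficient (monotone likelihood, e.g. all events in one arm
    of a separated binary covariate) is flagged ``converged=False``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    xv = np.asarray(x, dtype=float)
    if not e.any():
        raise ValueError("no events")
    if np.unique(xv).size < 2:
        raise ValueError("covariate is constant")

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        U, I = _cox_score_info(beta, t, e, xv, ties_method)
        if I <= 0:
            break
        step = U / I
        beta += step
        if abs(beta) > 50:
            break
        if abs(step) < tol:
            converged = True
            break
    _, I = _cox_score_info(beta, t, e, xv, ties_method)
    se = float(1.0 / np.sqrt(I)) if I > 0 else float("inf")
    z = beta / se if se > 0 and np.isfinite(se) else float("inf")
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p=p,
        n_events=int(e.sum()),
        ties_method=ties_method,
        beta=float(beta),
        se=se,
        converged=converged,
    )


def binary_regression(
    x: Sequence[int | bool], y: Sequence[int | bool]
) -> dict:
    """Logistic regression of binary y on binary x.

    Returns the odds ratio with Wald p (Newton-fitted logistic model via
    statsmodels) plus Fisher's exact p for the 2x2 table.  A zero cell
    triggers the Haldane–Anscombe 0.5 correction on the counts (flagged),
    with the OR and Wald p computed from the corrected table.
    """
    xv = np.asarray(x, dtype=int)
    yv = np.asarray(y, dtype=int)
    a = int(np.sum((xv == 1) & (yv == 1)))
    b = int(np.sum((xv == 1) & (yv == 0)))
    c = int(np.sum((xv == 0) & (yv == 1)))
    d = int(np.sum((xv == 0) & (yv == 0)))
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("a margin of the 2x2 table is empty")
    _, p_fisher = stats.fisher_exact([[a, b], [c, d]])
    flagged = 0 in (a, b, c, d)
    if flagged:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
        or_ = (aa * dd) / (bb * cc)
        se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
        p_wald = float(2 * stats.norm.sf(abs(np.log(or_)) / se))
    else:
        import statsmodels.api as sm

        X = sm.add_constant(xv.astype(float))
        fit = sm.Logit(yv, X).fit(disp=False)
        or_ = float(np.exp(fit.params[1]))
        p_wald = float(fit.pvalues[1])
    return {
        "odds_ratio": float(or_),
        "p": p_wald,
        "p_fisher": float(p_fisher),
        "table": (a, b, c, d),
        "continuity_corrected": flagged,
    }
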