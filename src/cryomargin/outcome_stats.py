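"""Cohort outcome statistics for ablation-margin studies.

Per-case records (morphometry, minimal treatment margin, covariates, local
tumor progression and follow-up) are compared between outcome groups with
the classical battery: Mann-Whitney U for continuous variables, exact
contingency-table tests (Fisher 2x2 and its Freeman-Halton r x c
generalization) for categorical ones, Spearman rank correlation for the
size-margin association, univariable Cox proportional-hazards regression
for progression predictors, and the Kaplan-Meier product-limit estimate of
progression-free survival.

Exact tests use the two-sided "probability method": the p-value sums the
null probabilities of all tables with the observed margins whose
probability does not exceed the observed table's (with a 1e-7 relative
slack for floating-point ties), matching the convention of mainstream
statistical packages.  The Cox partial likelihood uses Breslow tie handling
by default, with an Efron switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from math import lgamma
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CapacityError,
    InestimableError,
    InputError,
    UndefinedCorrelationError,
)

_TIE_SLACK = 1e-7  # relative slack when comparing table probabilities
_Z975 = 1.959963984540054

SEX_VALUES = ("male", "female")
ASA_VALUES = ("II", "III")
RENAL_VALUES = ("low", "moderate", "high")


@dataclass
class CaseRecord:
    """One treated tumor: morphometry, margin, covariates and outcome."""

    case_id: str
    tumor_diameter_mm: float
    tumor_volume_ml: float
    iceball_volume_ml: float
    n_probes: int
    mtm_raw_mm: float
    mtm_mm: int
    sex: str
    asa: str
    renal_category: str
    ltp: bool
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise InputError(f"{self.case_id}: time_months must be >= 0")
        if self.event and not self.ltp:
            raise InputError(f"{self.case_id}: event implies ltp")
        for name, value, domain in (
            ("sex", self.sex, SEX_VALUES),
            ("asa", self.asa, ASA_VALUES),
            ("renal_category", self.renal_category, RENAL_VALUES),
        ):
            if value not in domain:
                raise InputError(f"{self.case_id}: {name}={value!r} not in {domain}")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class CoxResult:
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_events: int
    coef: float
    se: float
    covariate: str
    unit: str
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "case_id", "tumor_diameter_mm", "tumor_volume_ml", "iceball_volume_ml",
    "n_probes", "mtm_raw_mm", "mtm_mm", "sex", "asa", "renal_category",
    "ltp", "time_months", "event",
]


def records_to_frame(records: list[CaseRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=_COHORT_COLUMNS)


def write_cohort_csv(records: list[CaseRecord], path: str | Path) -> None:
    # %.17g keeps float fields bit-exact across a write/read cycle
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path: str | Path) -> list[CaseRecord]:
    """Parse a cohort CSV into validated records; reports all offending rows."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"cohort CSV missing columns: {sorted(missing)}")
    records, problems = [], []
    for i, row in df.iterrows():
        try:
            records.append(CaseRecord(
                case_id=str(row["case_id"]),
                tumor_diameter_mm=float(row["tumor_diameter_mm"]),
                tumor_volume_ml=float(row["tumor_volume_ml"]),
                iceball_volume_ml=float(row["iceball_volume_ml"]),
                n_probes=int(row["n_probes"]),
                mtm_raw_mm=float(row["mtm_raw_mm"]),
                mtm_mm=int(row["mtm_mm"]),
                sex=str(row["sex"]),
                asa=str(row["asa"]),
                renal_category=str(row["renal_category"]),
                ltp=_parse_bool(row["ltp"]),
                time_months=float(row["time_months"]),
                event=_parse_bool(row["event"]),
            ))
        except (InputError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise InputError("invalid cohort rows:\n" + "\n".join(problems))
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {v!r}")


# ---------------------------------------------------------------------------
# rank tests and correlation
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact p by full enumeration of the null permutation distribution when
    ``n_x * n_y <= 400`` and there are no ties between or within samples;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size * y.size <= 400) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney-u-{method}",
        n=(x.size, y.size),
    )


def spearman_rho(x, y) -> TestResult:
    """Midrank Spearman correlation; two-sided p via the t approximation (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("samples must be paired")
    if x.size < 3:
        raise InputError("need n >= 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman-rho", (x.size,))


# ---------------------------------------------------------------------------
# exact contingency-table tests
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    """Log multivariate-hypergeometric probability of a table with fixed margins."""
    return log_const - sum(lgamma(v + 1.0) for v in table.flat)


def _margin_log_const(table: np.ndarray) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return (
        sum(lgamma(v + 1.0) for v in r)
        + sum(lgamma(v + 1.0) for v in c)
        - lgamma(n + 1.0)
    )


def _enumerate_tables(row_sums: np.ndarray, col_sums: np.ndarray):
    """Yield all nonnegative integer tables with the given margins.

    Depth-first over cells, constraining the last cell of each row and the
    last row by the margins.
    """
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)
    col_rem = col_sums.copy()

    def fill_row(i: int):
        if i == r - 1:
            # final row forced by column remainders
            if np.all(col_rem >= 0) and col_rem.sum() == row_sums[i]:
                table[i] = col_rem
                yield table
            return
        yield from fill_cell(i, 0, row_sums[i])

    def fill_cell(i: int, j: int, row_rem: int):
        if j == c - 1:
            if row_rem <= col_rem[j]:
                table[i, j] = row_rem
                col_rem[j] -= row_rem
                yield from fill_row(i + 1)
                col_rem[j] += row_rem
            return
        for v in range(min(row_rem, col_rem[j]) + 1):
            table[i, j] = v
            col_rem[j] -= v
            yield from fill_cell(i, j + 1, row_rem - v)
            col_rem[j] += v

    yield from fill_row(0)


def _validated_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise InputError(f"contingency table must be 2D, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t64 = np.asarray(table, dtype=float)
        if np.any(t64 < 0) or np.any(t64 != np.round(t64)):
            raise InputError("table cells must be nonnegative integers")
        t = t64.astype(np.int64)
    if t.sum() < 1:
        raise InputError("table grand total must be >= 1")
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table, probability method.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is at most the observed table's.
    """
    t = _validated_table(table)
    if t.shape != (2, 2):
        raise InputError(f"expected a 2x2 table, got {t.shape}")
    return _exact_fixed_margin_test(t, "fisher-exact")


def freeman_halton(table, method: str = "exact", n_draws: int = 100_000,
                   seed: int | None = None) -> TestResult:
    """Fisher-Freeman-Halton exact test on an r x c table.

    Full enumeration over tables with the observed margins under the
    multivariate hypergeometric null, feasible for ``r*c <= 12`` and grand
    total <= 200.  Beyond that, ``method="monte-carlo"`` estimates the
    p-value from ``n_draws`` seeded draws of margin-preserving tables.
    """
    t = _validated_table(table)
    too_big = t.size > 12 or t.sum() > 200
    if method == "exact":
        if too_big:
            raise CapacityError(
                f"table {t.shape} with total {t.sum()} exceeds the exact enumeration "
                "bound (r*c <= 12, total <= 200); call with method='monte-carlo'"
            )
        return _exact_fixed_margin_test(t, "freeman-halton")
    if method == "monte-carlo":
        return _monte_carlo_fixed_margin_test(t, n_draws, seed)
    raise InputError(f"unknown method {method!r}")


def _exact_fixed_margin_test(t: np.ndarray, name: str) -> TestResult:
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0) or min(t.shape) == 1:
        # a degenerate margin fixes the whole table: the observed table is certain
        return TestResult(0.0, 1.0, name, tuple(int(v) for v in row_sums))
    log_const = _margin_log_const(t)
    log_obs = _log_table_prob(t, log_const)
    cutoff = log_obs + np.log1p(_TIE_SLACK)
    p = 0.0
    for cand in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(cand, log_const)
        if lp <= cutoff:
            p += np.exp(lp)
    return TestResult(
        statistic=float(np.exp(log_obs)),
        p_value=float(min(p, 1.0)),
        method=name,
        n=tuple(int(v) for v in row_sums),
    )


def _monte_carlo_fixed_margin_test(t: np.ndarray, n_draws: int,
                                   seed: int | None) -> TestResult:
    rng = np.random.default_rng(seed)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    log_const = _margin_log_const(t)
    cutoff = _log_table_prob(t, log_const) + np.log1p(_TIE_SLACK)
    # draw margin-preserving tables by shuffling row labels against fixed columns
    labels = np.repeat(np.arange(len(row_sums)), row_sums)
    col_edges = np.concatenate([[0], np.cumsum(col_sums)])
    hits = 0
    cand = np.empty_like(t)
    for _ in range(n_draws):
        rng.shuffle(labels)
        for j in range(len(col_sums)):
            seg = labels[col_edges[j]:col_edges[j + 1]]
            cand[:, j] = np.bincount(seg, minlength=len(row_sums))
        if _log_table_prob(cand, log_const) <= cutoff:
            hits += 1
    # add-one estimate keeps p in (0, 1]
    p = (hits + 1) / (n_draws + 1)
    return TestResult(
        statistic=float(np.exp(_log_table_prob(t, log_const))),
        p_value=float(p),
        method="freeman-halton-monte-carlo",
        n=tuple(int(v) for v in row_sums),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariable)
# ---------------------------------------------------------------------------

_COX_UNITS = {"mtm_raw_mm": "per mm", "mtm_mm": "per mm", "tumor_diameter_mm": "per cm"}
# |log-hazard| beyond this is only reachable under a monotone partial
# likelihood (perfect separation); the coefficient is capped and flagged
_MAX_ABS_COEF = 15.0


def cox_univariable(
    records: list[CaseRecord],
    covariate: str,
    ties: str = "breslow",
) -> CoxResult:
    """Univariable Cox proportional-hazards fit by Newton-Raphson.

    The partial likelihood uses Breslow tie handling by default
    (``ties="efron"`` switches to Efron's correction).  Tumor diameter is
    entered per cm, margins per mm; the hazard ratio, Wald 95% CI and
    two-sided p-value refer to that unit.  A monotone likelihood (perfect
    separation) yields a capped coefficient with a divergence warning.
    """
    if not records:
        raise InputError("no records")
    times = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    x = np.array([getattr(r, covariate) for r in records], dtype=float)
    unit = _COX_UNITS.get(covariate, "per unit")
    if covariate == "tumor_diameter_mm":
        x = x / 10.0  # per-cm hazard scale
    return _cox_fit(times, events, x, ties=ties, covariate=covariate, unit=unit)


def _cox_fit(times, events, x, ties="breslow", covariate="x", unit="per unit") -> CoxResult:
    n_events = int(events.sum())
    if n_events == 0:
        raise InestimableError("no events; hazard ratio is inestimable")
    if np.std(x[events | (times >= times[events].min())]) == 0:
        raise InestimableError(f"covariate {covariate} has zero variance among at-risk subjects")
    if ties not in ("breslow", "efron"):
        raise InputError(f"unknown tie handling {ties!r}")

    beta = 0.0
    prev_ll = _cox_loglik(beta, times, events, x, ties)[0]
    converged = False
    warns: list[str] = []
    for _ in range(100):
        ll, score, info = _cox_loglik(beta, times, events, x, ties)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > _MAX_ABS_COEF:
            beta = np.sign(beta) * _MAX_ABS_COEF
            warns.append(
                "monotone partial likelihood (perfect separation); coefficient capped"
            )
            warnings.warn(warns[-1], stacklevel=2)
            break
        ll_new = _cox_loglik(beta, times, events, x, ties)[0]
        if abs(ll_new - prev_ll) < 1e-9 * max(abs(prev_ll), 1.0):
            converged = True
            prev_ll = ll_new
            break
        prev_ll = ll_new

    if converged and abs(beta) >= _MAX_ABS_COEF:
        converged = False
        warns.append(
            "monotone partial likelihood (perfect separation); coefficient capped"
        )
        warnings.warn(warns[-1], stacklevel=2)
        beta = float(np.sign(beta) * _MAX_ABS_COEF)

    _, _, info = _cox_loglik(beta, times, events, x, ties)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    hr = float(np.exp(beta))
    with np.errstate(over="ignore"):
        ci = (float(np.exp(beta - _Z975 * se)), float(np.exp(beta + _Z975 * se)))
    return CoxResult(
        hazard_ratio=hr, ci95=ci, p_value=p, n_events=n_events,
        coef=float(beta), se=se, covariate=covariate, unit=unit,
        converged=converged, warnings=warns,
    )


def _cox_loglik(beta: float, times, events, x, ties: str):
    """Log partial likelihood, score and information for a scalar covariate.

    Subjects are scanned in decreasing time order so the risk-set sums of
    exp(beta*x), x*exp(beta*x) and x^2*exp(beta*x) are running totals;
    subjects with tied times enter the risk set together.
    """
    order = np.argsort(-times, kind="stable")
    t_s, e_s, x_s = times[order], events[order], x[order]
    # stabilize exponentials
    xc = x_s - x_s.mean()
    w = np.exp(beta * xc)
    ll = score = info = 0.0
    s0 = s1 = s2 = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # everyone at this tied time joins the risk set before events are scored
        blk = slice(i, j)
        s0 += w[blk].sum()
        s1 += (xc[blk] * w[blk]).sum()
        s2 += (xc[blk] ** 2 * w[blk]).sum()
        ev = blk.start + np.nonzero(e_s[blk])[0]
        d = len(ev)
        if d:
            sx = xc[ev].sum()
            if ties == "breslow" or d == 1:
                ll += beta * sx - d * np.log(s0)
                score += sx - d * s1 / s0
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            else:  # efron
                wd = w[ev].sum()
                s1d = (xc[ev] * w[ev]).sum()
                s2d = (xc[ev] ** 2 * w[ev]).sum()
                ll += beta * sx
                for k in range(d):
                    f = k / d
                    d0 = s0 - f * wd
                    d1 = s1 - f * s1d
                    d2 = s2 - f * s2d
                    ll -= np.log(d0)
                    score -= d1 / d0
                    info += d2 / d0 - (d1 / d0) ** 2
        i = j
    return ll, score, info


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_event_free(records: list[CaseRecord], horizons_months) -> list[float]:
    """Kaplan-Meier progression-free probability at each horizon (right-continuous)."""
    from lifelines import KaplanMeierFitter

    if not records:
        raise InputError("no records")
    horizons = np.asarray(horizons_months, dtype=float)
    if np.any(horizons < 0):
        raise InputError("horizons must be >= 0")
    times = [r.time_months for r in records]
    events = [r.event for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return [float(kmf.predict(h)) for h in horizons]
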