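"""Statistics for the artificial-parasitism rejection experiment.

Nests receive one of three treatments — increased intraclutch color
variation (IV), decreased variation (DV), or unmanipulated control
(UNM) — and the binary outcome is whether the model parasitic egg was
rejected.  The analysis chain: treatment x outcome contingency table;
Fisher's exact test (full enumeration, probability-ordering rule) and
its Monte-Carlo version (2000 replicates by default); Cramér's V as
effect size; noncentral chi-square power and required sample size; and
a binomial logistic GLM of rejection on treatment plus covariates
(nesting stage, Julian date, clutch size, year as a nominal fixed
effect), fitted by iteratively reweighted least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "TREATMENTS",
    "OUTCOMES",
    "OutcomeRecord",
    "ContingencyTable",
    "FisherResult",
    "EffectAndPower",
    "GLMFit",
    "read_outcomes",
    "records_to_frame",
    "tabulate",
    "fisher_exact",
    "fisher_mc",
    "cramers_v",
    "chisq_power",
    "required_n",
    "fit_binomial_glm",
]

TREATMENTS = ("IV", "DV", "UNM")
OUTCOMES = ("reject", "accept")
STAGES = ("laying", "incubation")

#: Fisher p-values count tables whose probability is <= the observed
#: table's, up to this relative tolerance (guards against float ties).
_PROB_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class OutcomeRecord:
    """One nest's treatment, outcome and covariates."""

    nest_id: str
    treatment: str
    outcome: str
    julian_date: int
    stage: str
    clutch_size: int
    year: str

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; expected {TREATMENTS}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected {OUTCOMES}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected {STAGES}")
        if self.clutch_size < 1:
            raise ValueError("clutch size must be >= 1")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2:
            raise ValueError("counts must be 2-d")
        if np.any(c < 0) or c.sum() == 0:
            raise ValueError("counts must be non-negative with a positive total")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths must match the count matrix")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class FisherResult:
    p_exact: float | None = None
    p_mc: float | None = None
    replicates: int | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.p_exact is None and self.p_mc is None:
            raise ValueError("at least one p-value must be present")


@dataclass(frozen=True)
class EffectAndPower:
    chi2: float
    V: float
    w: float
    df: int
    N: int
    alpha: float | None = None
    power: float | None = None


@dataclass(frozen=True)
class GLMFit:
    """Logistic-regression fit summary: one row per model term."""

    params: pd.DataFrame  # index = term, columns = estimate, se, z, p
    terms: tuple[str, ...]
    n: int
    converged: bool
    n_iter: int
    deviance: float
    deviance_history: tuple[float, ...] = field(default_factory=tuple)


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    """Read a behavioral outcome table from delimited text."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"nest_id", "treatment", "outcome", "julian_date",
                "stage", "clutch_size", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns {sorted(missing)}")
    return [
        OutcomeRecord(
            nest_id=str(r.nest_id), treatment=str(r.treatment), outcome=str(r.outcome),
            julian_date=int(r.julian_date), stage=str(r.stage),
            clutch_size=int(r.clutch_size), year=str(r.year),
        )
        for r in df.itertuples()
    ]


def records_to_frame(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def tabulate(records: Sequence[OutcomeRecord]) -> ContingencyTable:
    """Count outcomes by treatment in fixed (IV, DV, UNM) x (reject, accept) order."""
    if not records:
        raise ValueError("no records to tabulate")
    counts = np.zeros((len(TREATMENTS), len(OUTCOMES)), dtype=int)
    for r in records:
        counts[TREATMENTS.index(r.treatment), OUTCOMES.index(r.outcome)] += 1
    return ContingencyTable(counts=counts, row_labels=TREATMENTS, col_labels=OUTCOMES)


def _log_table_prob(counts: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a margin-fixed table."""
    counts = np.asarray(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    N = counts.sum()
    return float(special.gammaln(row + 1).sum() + special.gammaln(col + 1).sum()
                 - special.gammaln(N + 1) - special.gammaln(counts + 1).sum())


def _enumerate_tables(row: np.ndarray, col: np.ndarray):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(row), len(col)

    def rec(i: int, remaining_col: np.ndarray, partial: list[np.ndarray]):
        if i == r - 1:
            last = remaining_col
            if np.all(last >= 0) and last.sum() == row[-1]:
                yield np.vstack(partial + [last])
            return
        # enumerate row i cell by cell
        def cells(j: int, left_in_row: int, rem: np.ndarray, this_row: list[int]):
            if j == c - 1:
                if 0 <= left_in_row <= rem[-1]:
                    yield this_row + [left_in_row]
                return
            hi = min(left_in_row, rem[j])
            for x in range(hi + 1):
                yield from cells(j + 1, left_in_row - x, rem, this_row + [x])

        for this_row in cells(0, int(row[i]), remaining_col, []):
            tr = np.array(this_row)
            yield from rec(i + 1, remaining_col - tr, partial + [tr])

    yield from rec(0, col.copy(), [])


def fisher_exact(table: ContingencyTable | np.ndarray, max_n: int = 200) -> float:
    """Two-sided Fisher exact p by full enumeration of margin-fixed tables.

    The two-sided p is the total probability of tables no more probable
    than the observed one (probability-ordering rule), under the
    multivariate hypergeometric null with both margins fixed.  Works
    for any small r x c table; for totals above ``max_n`` enumeration
    is refused — use :func:`fisher_mc`.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    # Rows/columns that are entirely zero carry no information and would
    # stall the enumeration; drop them.
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0:
        raise ValueError("empty table")
    if min(counts.shape) == 1:
        return 1.0  # a single row or column is always exactly its margins
    N = int(counts.sum())
    if N > max_n:
        raise ValueError(f"N = {N} too large to enumerate (max {max_n}); use fisher_mc")
    row, col = counts.sum(axis=1), counts.sum(axis=0)
    logp_obs = _log_table_prob(counts)
    cutoff = logp_obs + abs(logp_obs) * _PROB_TIE_RTOL + 1e-12
    p = 0.0
    for t in _enumerate_tables(row, col):
        lp = _log_table_prob(t)
        if lp <= cutoff:
            p += np.exp(lp)
    return float(min(p, 1.0))


def fisher_mc(
    table: ContingencyTable | np.ndarray,
    replicates: int = 2000,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo Fisher p from margin-fixed resampling.

    Samples ``replicates`` tables uniformly from the margin-fixed null
    (equivalent to permuting column labels against row labels) and
    applies the add-one estimator p = (1 + B) / (replicates + 1), where
    B counts simulated tables no more probable than the observed one.
    Never returns exactly zero; deterministic for a given seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0:
        raise ValueError("empty table")
    if min(counts.shape) == 1:
        return 1.0
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    row, col = counts.sum(axis=1), counts.sum(axis=0)
    sampler = stats.random_table(row, col)
    sims = sampler.rvs(replicates, random_state=rng)  # (B, r, c)
    logp_obs = _log_table_prob(counts)
    cutoff = logp_obs + abs(logp_obs) * _PROB_TIE_RTOL + 1e-12
    lp = (special.gammaln(row + 1).sum() + special.gammaln(col + 1).sum()
          - special.gammaln(counts.sum() + 1)
          - special.gammaln(sims + 1).sum(axis=(1, 2)))
    B = int(np.sum(lp <= cutoff))
    return (1 + B) / (replicates + 1)


def cramers_v(table: ContingencyTable | np.ndarray) -> EffectAndPower:
    """Pearson chi-square and Cramér's V = sqrt(chi2 / (N (min(r,c)-1))).

    For a table with two columns V coincides with Cohen's w effect size
    used in the chi-square power analysis.  Zero-margin rows or columns
    are dropped with a warning (their expected counts are zero).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    keep_r, keep_c = counts.sum(axis=1) > 0, counts.sum(axis=0) > 0
    if not (keep_r.all() and keep_c.all()):
        warnings.warn("dropping zero-margin rows/columns before chi-square",
                      stacklevel=2)
        counts = counts[keep_r][:, keep_c]
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("need at least 2 rows and 2 columns with data")
    N = int(counts.sum())
    chi2, _, df, _ = stats.chi2_contingency(counts, correction=False)
    V = float(np.sqrt(chi2 / (N * (min(r, c) - 1))))
    return EffectAndPower(chi2=float(chi2), V=V, w=V, df=int(df), N=N)


def chisq_power(w: float, N: float, df: int, alpha: float = 0.05) -> float:
    """Power of the chi-square test at effect size w (noncentral chi-square).

    The test statistic under the alternative is noncentral chi-square
    with noncentrality N * w^2; power is its mass above the central
    (1 - alpha) quantile.  At w = 0 this returns alpha exactly.
    """
    if w < 0 or N < 1:
        raise ValueError("need w >= 0 and N >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = stats.chi2.ppf(1 - alpha, df)
    if w == 0:
        return float(alpha)
    return float(stats.ncx2.sf(q, df, N * w**2))


def required_n(
    w: float,
    target_power: float = 0.8,
    df: int = 2,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Smallest N achieving the target power at effect size w.

    Root-solves the continuous relaxation of :func:`chisq_power` in N;
    returns ``(n_continuous, n_rounded_up)``.
    """
    if not 0 < target_power < 1:
        raise ValueError("target power must be in (0, 1)")
    if w <= 0:
        raise ValueError("unattainable: power exceeds alpha only for w > 0")
    f = lambda N: chisq_power(w, N, df, alpha) - target_power
    hi = 2.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e9:
            raise RuntimeError("required sample size exceeds 1e9")
    n_cont = float(optimize.brentq(f, 1.0, hi, xtol=1e-9))
    return n_cont, int(np.ceil(n_cont - 1e-9))


# ---------------------------------------------------------------------------
# Binomial logistic GLM (IRLS with step-halving)

DEFAULT_TERMS = ("treatment", "stage", "julian_date", "clutch_size", "year")


def _design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["Intercept"]
    for term in terms:
        if term == "treatment":
            # reference level DV: reported contrasts are IV and Con (UNM)
            for level, label in (("IV", "Treatment (IV)"), ("UNM", "Treatment (Con)")):
                if (df["treatment"] == level).any():
                    cols.append((df["treatment"] == level).to_numpy(float))
                    names.append(label)
        elif term == "stage":
            cols.append((df["stage"] == "incubation").to_numpy(float))
            names.append("Nesting stage")
        elif term == "julian_date":
            cols.append(df["julian_date"].to_numpy(float))
            names.append("Julian date")
        elif term == "clutch_size":
            cols.append(df["clutch_size"].to_numpy(float))
            names.append("Clutch size")
        elif term == "year":
            levels = sorted(df["year"].astype(str).unique())
            for lv in levels[1:]:  # first level is the reference
                cols.append((df["year"].astype(str) == lv).to_numpy(float))
                names.append(f"Year ({lv})")
        else:
            raise ValueError(f"unknown model term {term!r}")
    return np.column_stack(cols), names


def _bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_binomial_glm(
    records: Sequence[OutcomeRecord] | pd.DataFrame,
    terms: Sequence[str] = DEFAULT_TERMS,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GLMFit:
    """Logistic regression of rejection (1) vs acceptance (0) on covariates.

    Treatment enters with DV as the reference level, so the reported
    contrasts are "Treatment (IV)" and "Treatment (Con)"; year enters
    as a nominal fixed effect (a year with a single level contributes
    no column and the fit equals the model without year).  Fitting is
    Newton/IRLS with step-halving, so the deviance is non-increasing
    across iterations; convergence is a relative deviance change below
    ``tol``.  Wald standard errors, z and two-sided p per term.

    Complete separation (diverging coefficients or vanishing curvature)
    is flagged: ``converged=False`` and coefficients withheld (NaN).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    y = (df["outcome"] == "reject").to_numpy(float)
    X, names = _design_matrix(df, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} records cannot identify {p} coefficients")

    beta = np.zeros(p)
    mu = np.full(n, 0.5)
    dev = _bernoulli_deviance(y, mu)
    history = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Wdiag = mu * (1 - mu)
        if np.min(Wdiag) < 1e-10 and np.max(np.abs(beta)) > 15:
            break  # separation: fitted probabilities pinned at 0/1
        XtW = X.T * Wdiag
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # step-halving: never accept an increase in deviance
        new_dev = np.inf
        for _ in range(30):
            cand = beta + step
            eta = X @ cand
            mu_c = 1 / (1 + np.exp(-eta))
            new_dev = _bernoulli_deviance(y, mu_c)
            if new_dev <= dev + 1e-12:
                break
            step /= 2
        else:
            break
        beta, mu = cand, mu_c
        history.append(new_dev)
        if abs(dev - new_dev) / (abs(dev) + 1e-12) < tol:
            converged = True
            dev = new_dev
            break
        dev = new_dev

    if converged and np.max(np.abs(beta)) > 15:
        converged = False  # numerically converged onto a separated fit

    if converged:
        Wdiag = mu * (1 - mu)
        cov = np.linalg.inv((X.T * Wdiag) @ X)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        params = pd.DataFrame({"estimate": beta, "se": se, "z": z, "p": pvals},
                              index=names)
    else:
        warnings.warn("logistic fit did not converge (possible complete separation); "
                      "coefficients withheld", stacklevel=2)
        params = pd.DataFrame({"estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan},
                              index=names)
    return GLMFit(params=params, terms=tuple(terms), n=n, converged=converged,
                  n_iter=it, deviance=float(history[-1]),
                  deviance_history=tuple(history))
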