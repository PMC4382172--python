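"""Within- versus between-clutch variation in perceived egg color.

The analysis asks whether egg color varies more between females'
clutches than within them, from the bird's own point of view: per-egg
proportional receptor catches are compared across clutches with
heteroscedastic (Welch) one-way tests, and chromatic JNDs from a
single-use random pairing of eggs are compared within vs between
clutches.  Welch's statistic is used because grouped color data are
routinely heteroscedastic across clutches; its denominator degrees of
freedom are non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .visual import (
    Illuminant,
    NoiseVector,
    QuantumCatches,
    ReceptorSet,
    achromatic_jnd,
    chromatic_jnd,
    quantum_catch,
    receptor_noise,
    RECEPTOR_ORDER,
)

__all__ = [
    "ProportionalCatches",
    "ComparisonRecord",
    "WelchTestResult",
    "proportional_catches",
    "pairwise_jnds",
    "sample_disjoint_pairs",
    "welch_oneway",
    "classic_oneway",
    "clutch_variation_report",
]


@dataclass(frozen=True)
class ProportionalCatches:
    """Per-egg catch proportions Pr_i = Q_i / sum_j Q_j (single cones only)."""

    Pr: np.ndarray
    egg_id: str | None = None
    clutch_id: str | None = None

    def __post_init__(self) -> None:
        pr = np.asarray(self.Pr, dtype=float)
        object.__setattr__(self, "Pr", pr)
        if pr.shape != (4,):
            raise ValueError("Pr must hold four proportions")
        if np.any(pr < 0) or np.any(pr > 1) or abs(pr.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must lie in [0,1] and sum to 1")


@dataclass(frozen=True)
class ComparisonRecord:
    """One unordered egg pair with its clutch label and contrasts."""

    egg_a: str
    egg_b: str
    same_clutch: bool
    delta_s: float
    delta_l: float

    def __post_init__(self) -> None:
        if self.egg_a == self.egg_b:
            raise ValueError("a comparison needs two distinct eggs")


@dataclass(frozen=True)
class WelchTestResult:
    F: float
    df1: int
    df2: float
    p: float

    def __post_init__(self) -> None:
        if self.F < 0 or self.df1 < 1 or self.df2 <= 0 or not 0 <= self.p <= 1:
            raise ValueError("invalid Welch test result")


def proportional_catches(q: QuantumCatches) -> ProportionalCatches:
    """Normalize the four single-cone catches to sum to one."""
    total = q.Q.sum()
    if total <= 0:
        raise ValueError(f"all-zero catches for egg {q.egg_id!r}")
    return ProportionalCatches(Pr=q.Q / total, egg_id=q.egg_id, clutch_id=q.clutch_id)


def pairwise_jnds(
    eggs: Sequence[QuantumCatches],
    noise: NoiseVector,
    achromatic_weber: float = 0.1,
) -> list[ComparisonRecord]:
    """Chromatic and achromatic JNDs for every unordered pair of eggs."""
    if len(eggs) < 2:
        raise ValueError("need at least two eggs to compare")
    if any(e.clutch_id is None for e in eggs):
        raise ValueError("every egg needs a clutch id")
    records = []
    for a, b in combinations(eggs, 2):
        records.append(ComparisonRecord(
            egg_a=str(a.egg_id), egg_b=str(b.egg_id),
            same_clutch=a.clutch_id == b.clutch_id,
            delta_s=chromatic_jnd(a, b, noise),
            delta_l=achromatic_jnd(a, b, achromatic_weber),
        ))
    return records


def sample_disjoint_pairs(
    records: Sequence[ComparisonRecord],
    rng_seed: int | np.random.Generator = 0,
    within_first: bool = False,
) -> list[ComparisonRecord]:
    """Draw a uniformly random greedy maximal matching of egg pairs.

    Each egg enters the selected comparisons at most once, avoiding
    pseudoreplication when pairwise JNDs are analyzed as independent
    observations: repeatedly draw a pair uniformly among pairs whose
    eggs are both still unused, until none remains.  For a complete
    pairwise set over e eggs this returns floor(e/2) records (one egg
    left over when e is odd).  Deterministic for a given seed.

    With ``within_first`` the matching is stratified and balanced:
    within-clutch pairs are matched first (uniformly at random, up to
    one quarter of the eggs, i.e. half of the final comparisons), then
    the remaining eggs are matched across clutches.  For many small
    clutches a fully uniform matching contains almost no within-clutch
    pair, which leaves the within-vs-between comparison undefined;
    stratifying guarantees within pairs, and the equal split maximizes
    the power of the two-group contrast, while keeping every egg
    single-use.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    def greedy(pool: list[ComparisonRecord], used: set[str],
               cap: float = np.inf) -> list[ComparisonRecord]:
        pool = [r for r in pool if r.egg_a not in used and r.egg_b not in used]
        selected: list[ComparisonRecord] = []
        while pool and len(selected) < cap:
            rec = pool[int(rng.integers(len(pool)))]
            used.update((rec.egg_a, rec.egg_b))
            selected.append(rec)
            pool = [r for r in pool if r.egg_a not in used and r.egg_b not in used]
        return selected

    used: set[str] = set()
    selected: list[ComparisonRecord] = []
    if within_first:
        n_eggs = len({e for r in records for e in (r.egg_a, r.egg_b)})
        selected += greedy([r for r in records if r.same_clutch], used,
                           cap=n_eggs // 4)
        selected += greedy([r for r in records if not r.same_clutch], used)
    # final pass over everything keeps the matching maximal
    selected += greedy(list(records), used)
    return selected


def welch_oneway(groups: Iterable[Sequence[float]]) -> WelchTestResult:
    """Welch's heteroscedastic one-way test across k groups.

    With group sizes n_j, means m_j and variances s_j^2, let
    w_j = n_j / s_j^2, W = sum w_j, xbar = sum w_j m_j / W and
    Lambda = sum (1 - w_j/W)^2 / (n_j - 1).  Then

        F   = [sum w_j (m_j - xbar)^2 / (k-1)]
              / [1 + 2 (k-2) Lambda / (k^2 - 1)]
        df1 = k - 1
        df2 = (k^2 - 1) / (3 Lambda)

    and p is the upper tail of F(df1, df2).  For k = 2 this reduces to
    the squared Welch t statistic with the Welch-Satterthwaite df.
    """
    data = [np.asarray(g, dtype=float) for g in groups]
    k = len(data)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.size for g in data])
    if np.any(n < 2):
        raise ValueError("each group needs at least two observations")
    m = np.array([g.mean() for g in data])
    s2 = np.array([g.var(ddof=1) for g in data])
    if np.any(s2 <= 0):
        j = int(np.argmax(s2 <= 0))
        raise ValueError(
            f"group {j} has zero variance; add measurement jitter or exclude it"
        )
    w = n / s2
    W = w.sum()
    xbar = (w * m).sum() / W
    lam = ((1 - w / W) ** 2 / (n - 1)).sum()
    F = ((w * (m - xbar) ** 2).sum() / (k - 1)) / (1 + 2 * (k - 2) * lam / (k**2 - 1))
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(F, df1, df2))
    return WelchTestResult(F=float(F), df1=df1, df2=float(df2), p=p)


def classic_oneway(groups: Iterable[Sequence[float]]) -> WelchTestResult:
    """Equal-variance one-way ANOVA, for comparison with the Welch test."""
    data = [np.asarray(g, dtype=float) for g in groups]
    F, p = stats.f_oneway(*data)
    k = len(data)
    N = sum(g.size for g in data)
    return WelchTestResult(F=float(F), df1=k - 1, df2=float(N - k), p=float(p))


def _group_by_clutch(values: Sequence[float], clutches: Sequence[str]) -> list[np.ndarray]:
    s = pd.Series(values, index=pd.Index(clutches, name="clutch"))
    return [grp.to_numpy() for _, grp in s.groupby(level="clutch")]


def clutch_variation_report(
    eggs: Sequence,  # Spectrum, one per egg (replicates already averaged)
    receptors: ReceptorSet,
    light: Illuminant,
    rng_seed: int = 0,
    min_clutch_size: int = 2,
    within_first: bool = True,
) -> pd.DataFrame:
    """Run the full perceptual variation analysis and tabulate it.

    One row per response: the four proportional catches and the
    achromatic catch tested across clutches with Welch's one-way test,
    and chromatic JNDs from disjoint random pairs tested within vs
    between clutches with a two-group Welch test.  Columns: response,
    group means with standard errors, df1, df2, F, p.  The pairing is
    stratified by default (``within_first=True``) so that both within-
    and between-clutch comparisons exist even when clutches are small.

    Clutches with fewer than ``min_clutch_size`` eggs are excluded from
    the across-clutch tests (Welch needs a variance per group); if the
    number of eggs is odd, the unpaired egg is dropped from the JND
    comparison.  Both exclusions are recorded in the ``note`` column.
    """
    catches = [quantum_catch(e, receptors, light) for e in eggs]
    clutch_ids = [c.clutch_id for c in catches]
    if len(set(clutch_ids)) < 2:
        raise ValueError("need eggs from at least two clutches")
    noise = receptor_noise(receptors)
    props = [proportional_catches(c) for c in catches]

    counts = pd.Series(clutch_ids).value_counts()
    keep = set(counts[counts >= min_clutch_size].index)
    kept = [i for i, cid in enumerate(clutch_ids) if cid in keep]
    n_excluded = len(catches) - len(kept)

    rows = []
    for ri, rname in enumerate(RECEPTOR_ORDER):
        vals = [props[i].Pr[ri] for i in kept]
        groups = _group_by_clutch(vals, [clutch_ids[i] for i in kept])
        res = welch_oneway(groups)
        rows.append({
            "response": f"Pr{rname}",
            "mean": float(np.mean(vals)),
            "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
            "df1": res.df1, "df2": res.df2, "F": res.F, "p": res.p,
            "note": f"{n_excluded} eggs in clutches < {min_clutch_size} excluded"
                    if n_excluded else "",
        })

    qa = [catches[i].Q_A for i in kept]
    res = welch_oneway(_group_by_clutch(qa, [clutch_ids[i] for i in kept]))
    rows.append({
        "response": "Achrom",
        "mean": float(np.mean(qa)),
        "se": float(np.std(qa, ddof=1) / np.sqrt(len(qa))),
        "df1": res.df1, "df2": res.df2, "F": res.F, "p": res.p, "note": "",
    })

    records = pairwise_jnds(catches, noise, receptors.achromatic_weber)
    chosen = sample_disjoint_pairs(records, rng_seed, within_first=within_first)
    within = np.array([r.delta_s for r in chosen if r.same_clutch])
    between = np.array([r.delta_s for r in chosen if not r.same_clutch])
    if within.size < 2 or between.size < 2:
        raise ValueError(
            "the random pairing produced fewer than two within- or "
            "between-clutch comparisons; rerun with another seed or more eggs"
        )
    res = welch_oneway([within, between])
    dropped = len(catches) - 2 * len(chosen)
    for label, arr in (("W", within), ("B", between)):
        rows.append({
            "response": f"ChromJND_{label}",
            "mean": float(arr.mean()),
            "se": float(arr.std(ddof=1) / np.sqrt(arr.size)),
            "df1": res.df1, "df2": res.df2, "F": res.F, "p": res.p,
            "note": (f"{len(chosen)} disjoint comparisons; "
                     f"{dropped} unpaired egg(s) dropped"),
        })
    return pd.DataFrame(rows)
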