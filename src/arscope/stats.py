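"""Trial validation statistics: correction distances, summaries, rank tests.

The clinical outcome of interest is the correction distance ||d_i|| between
the preoperative pen mark P_i and the actual incision P_i* = P_i + d_i for
each of the four trocars. Per-trocar means and sample standard deviations are
compared between a control arm and an AR-assisted arm; trocars whose
distances are statistically indistinguishable (two-sided Mann-Whitney U,
5% level) are pooled into a global accuracy figure, and the between-arm
improvement is reported as a percentage change of the pooled mean (accuracy)
and SD (variability).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import UndefinedMetricError

ARMS = ("control", "ar")
TROCARS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ErrorBudget:
    """Named displacement components (cm 3-vectors) summing to a record's d.

    Real measurements only ever observe the sum; the decomposition is
    bookkeeping for simulated data (pneumoperitoneum, patient anatomy,
    surgeon skill, registration, segmentation, residual terms).
    """

    components: dict

    def __post_init__(self):
        object.__setattr__(self, "components",
                           {k: np.asarray(v, dtype=float).reshape(3)
                            for k, v in self.components.items()})

    def total(self) -> np.ndarray:
        return np.sum(list(self.components.values()), axis=0)


@dataclass(frozen=True)
class CorrectionRecord:
    """One trocar measurement: pen mark P, incision P_star = P + d (cm)."""

    patient_id: str
    arm: str
    trocar: int
    P: np.ndarray
    P_star: np.ndarray
    budget: ErrorBudget | None = None

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if self.trocar not in TROCARS:
            raise ValueError(f"trocar must be in {TROCARS}")
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float).reshape(3))
        object.__setattr__(self, "P_star",
                           np.asarray(self.P_star, dtype=float).reshape(3))

    @classmethod
    def from_offset(cls, patient_id, arm, trocar, P, d, budget=None):
        P = np.asarray(P, dtype=float).reshape(3)
        d = np.asarray(d, dtype=float).reshape(3)
        return cls(patient_id=patient_id, arm=arm, trocar=trocar,
                   P=P, P_star=P + d, budget=budget)

    @property
    def d(self) -> np.ndarray:
        return self.P_star - self.P

    @property
    def d_norm(self) -> float:
        return float(np.linalg.norm(self.d))


def correction_distance(P, P_star):
    """Offset vector d = P_star - P and its Euclidean norm."""
    P = np.asarray(P, dtype=float).reshape(3)
    P_star = np.asarray(P_star, dtype=float).reshape(3)
    d = P_star - P
    return d, float(np.linalg.norm(d))


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round-half-up rendering used for report tables (2.005 -> 2.01)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSummary:
    """Per-trocar and pooled mean/SD of ||d|| for a single arm (cm).

    SD uses the n-1 denominator. ``pooled_*`` aggregate the raw distances of
    ``trocar_subset``; with equal n per trocar the pooled mean equals the
    mean of the per-trocar means.
    """

    arm: str
    per_trocar: dict  # trocar -> (mean, sd, n)
    trocar_subset: tuple
    pooled_mean: float
    pooled_sd: float
    pooled_n: int

    def to_text(self) -> str:
        cols = sorted(self.per_trocar)
        head = "\t".join(["", *[f"d{t}" for t in cols]])
        means = "\t".join(["Average (cm)",
                           *[f"{round_half_up(self.per_trocar[t][0]):.2f}" for t in cols]])
        sds = "\t".join(["Stan. deviat. (cm)",
                         *[f"{round_half_up(self.per_trocar[t][1]):.2f}" for t in cols]])
        pooled = (f"Pooled {self.trocar_subset}: "
                  f"{round_half_up(self.pooled_mean):.2f} +/- "
                  f"{round_half_up(self.pooled_sd):.2f} (n={self.pooled_n})")
        return "\n".join([head, means, sds, pooled])


def summarize(records: Sequence[CorrectionRecord],
              trocar_subset: Iterable[int] | None = None) -> ExperimentSummary:
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    arms = {r.arm for r in records}
    if len(arms) != 1:
        raise ValueError("summarize expects records from a single arm")
    subset = tuple(sorted(trocar_subset)) if trocar_subset else TROCARS
    if not subset:
        raise ValueError("trocar subset must be non-empty")
    per_trocar = {}
    for t in sorted({r.trocar for r in records}):
        vals = np.array([r.d_norm for r in records if r.trocar == t])
        if len(vals) < 2:
            raise UndefinedMetricError(
                f"sample SD undefined for trocar {t} with n={len(vals)}")
        per_trocar[t] = (float(vals.mean()), float(vals.std(ddof=1)), len(vals))
    pooled = np.array([r.d_norm for r in records if r.trocar in subset])
    if len(pooled) < 2:
        raise UndefinedMetricError("pooled SD undefined with fewer than 2 records")
    return ExperimentSummary(arm=arms.pop(), per_trocar=per_trocar,
                             trocar_subset=subset,
                             pooled_mean=float(pooled.mean()),
                             pooled_sd=float(pooled.std(ddof=1)),
                             pooled_n=len(pooled))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

class MannWhitneyResult(NamedTuple):
    U: float
    p: float
    method: str
    degenerate: bool = False


def _exact_rank_distribution(doubled_ranks: np.ndarray, n_a: int):
    """Exact null distribution of the (doubled) rank sum of sample A.

    Dynamic programming over the multiset of doubled mid-ranks: dp[k][s] =
    number of k-subsets with doubled-rank sum s. Equivalent to enumerating
    every assignment of the pooled ranks to group A.
    """
    total = int(doubled_ranks.sum())
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(n_a, 0, -1):
            dp[k, r:] += dp[k - 1, :total + 1 - r]
    return dp[n_a]


def mann_whitney_u(sample_a, sample_b, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of equal medians.

    ``mode``: 'exact' enumerates the full permutation null of the rank sum
    (mid-ranks for ties); 'approx' uses the normal approximation with tie and
    continuity corrections; 'auto' picks exact when both samples have at most
    12 observations. Two-sided p is 2 x min(tail) capped at 1. If every value
    is identical across both samples the result is flagged degenerate with
    p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    n_a, n_b = len(a), len(b)

    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    W_a = float(ranks[:n_a].sum())
    U_a = W_a - n_a * (n_a + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(U=U_a, p=1.0, method="degenerate", degenerate=True)

    if mode == "auto":
        mode = "exact" if max(n_a, n_b) <= 12 else "approx"

    if mode == "exact":
        doubled = np.rint(2 * ranks).astype(np.int64)
        dist = _exact_rank_distribution(doubled, n_a)
        total = dist.sum()
        w_obs = int(round(2 * W_a))
        p_le = dist[: w_obs + 1].sum() / total
        p_ge = dist[w_obs:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(U=U_a, p=float(p), method="exact")

    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
    return MannWhitneyResult(U=U_a, p=float(res.pvalue), method="approx")


# ---------------------------------------------------------------------------
# Between-arm comparison and pairwise pooling tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmComparison:
    """Relative improvement of the AR arm versus the control arm (percent)."""

    accuracy_improvement: float
    variability_reduction: float

    def render(self) -> str:
        acc = int(round_half_up(self.accuracy_improvement, 0))
        var = int(round_half_up(self.variability_reduction, 0))
        return (f"accuracy improvement: {acc}%\n"
                f"variability reduction: {var}%")


def improvement_metrics(mean_control: float, sd_control: float,
                        mean_ar: float, sd_ar: float) -> ArmComparison:
    if mean_control == 0 or sd_control == 0:
        raise UndefinedMetricError("zero control mean/SD: improvement undefined")
    return ArmComparison(
        accuracy_improvement=(mean_control - mean_ar) / mean_control * 100.0,
        variability_reduction=(sd_control - sd_ar) / sd_control * 100.0,
    )


def compare_arms(summary_control: ExperimentSummary,
                 summary_ar: ExperimentSummary) -> ArmComparison:
    """Pooled-mean/SD improvement metrics between the two arms (unrounded %)."""
    if summary_control.trocar_subset != summary_ar.trocar_subset:
        raise ValueError("summaries must pool the same trocar subset")
    return improvement_metrics(summary_control.pooled_mean, summary_control.pooled_sd,
                               summary_ar.pooled_mean, summary_ar.pooled_sd)


def pairwise_distance_tests(records: Sequence[CorrectionRecord],
                            alpha: float = 0.05, mode: str = "auto") -> pd.DataFrame:
    """Mann-Whitney p for each pair of trocars within one arm.

    Returns a tidy frame with one row per unordered pair and a ``poolable``
    flag (p > alpha), the pooling rule used to justify a global summary over
    trocars with indistinguishable distance distributions.
    """
    records = list(records)
    if len({r.arm for r in records}) != 1:
        raise ValueError("pairwise tests expect records from a single arm")
    groups = {t: np.array([r.d_norm for r in records if r.trocar == t])
              for t in sorted({r.trocar for r in records})}
    for t, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"need >=2 records per trocar (trocar {t} has {len(vals)})")
    rows = []
    for t1, t2 in combinations(sorted(groups), 2):
        res = mann_whitney_u(groups[t1], groups[t2], mode=mode)
        rows.append(dict(trocar_a=t1, trocar_b=t2, U=res.U, p=res.p,
                         poolable=res.p > alpha, method=res.method))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["patient_id", "arm", "trocar",
                "Px", "Py", "Pz", "Px_star", "Py_star", "Pz_star"]


def write_records(records: Sequence[CorrectionRecord], path) -> None:
    rows = [dict(patient_id=r.patient_id, arm=r.arm, trocar=r.trocar,
                 Px=r.P[0], Py=r.P[1], Pz=r.P[2],
                 Px_star=r.P_star[0], Py_star=r.P_star[1], Pz_star=r.P_star[2])
            for r in records]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_records(path) -> list[CorrectionRecord]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns {sorted(missing)}")
    return [CorrectionRecord(patient_id=str(row.patient_id), arm=row.arm,
                             trocar=int(row.trocar),
                             P=(row.Px, row.Py, row.Pz),
                             P_star=(row.Px_star, row.Py_star, row.Pz_star))
            for row in df.itertuples()]
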