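"""Diagnostic statistics: ROC/Youden cutoffs, exact rank tests, and the
MALT-lymphoma association and decision-rule layer.

The abnormal 53BP1 fraction is used as a one-dimensional diagnostic score.
For a monotone scalar predictor the ROC of a logistic model equals the
empirical ROC of the score itself, so the AUC is computed directly through
the Mann-Whitney U relation (ties counted half) with a DeLong confidence
interval, and the operating cutoff maximizes Youden's J = sensitivity +
specificity - 1 over observed scores.

The two-sample comparison used throughout is the exact (permutation)
Wilcoxon rank-sum test with mid-ranks for ties; the two-sided p-value is
P(|S - E[S]| >= |s_obs - E[S]|) under the permutation null.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STATUS_TOKENS = frozenset({"+", "-", "+/-", "NS", "ND", "DT"})

#: Abnormal fractions measured in the two areas of the one mantle-cell
#: lymphoma case that contained both morphologies: the indolent classical
#: area versus the aggressive blastoid area (percent of nuclei).
MCL_AREA_ABNORMAL_PCT = {"classical": 52.6, "blastoid": 21.9}


def fold_change(numerator: float, denominator: float) -> float:
    """Simple ratio of two percentages (e.g. classical / blastoid area)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return numerator / denominator


@dataclass
class RocResult:
    auc: float
    ci_lo: float
    ci_hi: float
    cutoff: float           # percent
    sensitivity: float      # percent
    specificity: float      # percent
    youden: float


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Published operating cutoffs (percent abnormal nuclei) by contrast."""

    follicular_cutoff: float = 27.2
    small_cell_cutoff: float = 33.6
    large_cell_cutoff: float = 22.9

    def __post_init__(self) -> None:
        for v in (self.follicular_cutoff, self.small_cell_cutoff,
                  self.large_cell_cutoff):
            if not 0 < v < 100:
                raise ValueError("cutoffs must be in (0, 100)")


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    r = stats.rankdata(scores)
    u = r[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """(cutoff, sensitivity%, specificity%, J) maximizing Youden's index.

    Every observed score is tried as a ``predict positive when score >=
    threshold`` rule; ties in J break toward the lowest threshold (higher
    sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        sens = np.mean(pred[labels == 1])
        spec = np.mean(~pred[labels == 0])
        j = sens + spec - 1.0
        if best is None or j > best[3] + 1e-12:
            best = (float(t), 100.0 * sens, 100.0 * spec, float(j))
    return best


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float,
               alpha: float = 0.05) -> tuple[float, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) \
        + (np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return max(auc - half, 0.0), min(auc + half, 1.0)


def roc_auc(scores, labels) -> RocResult:
    """ROC summary of a scalar score for a binary contrast.

    AUC via the Mann-Whitney U relation, DeLong 95% CI clipped to [0, 1],
    and the Youden-optimal operating point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    auc = _auc_mann_whitney(scores, labels)
    ci_lo, ci_hi = _delong_ci(scores, labels, auc)
    cutoff, sens, spec, j = youden_cutoff(scores, labels)
    return RocResult(auc=auc, ci_lo=ci_lo, ci_hi=ci_hi, cutoff=cutoff,
                     sensitivity=sens, specificity=spec, youden=j)


@dataclass
class GroupComparison:
    statistic: float        # mid-rank sum of the first sample
    p_two_sided: float
    n_a: int
    n_b: int
    method: str             # "exact" or "normal_approx"


def exact_wilcoxon(sample_a, sample_b, max_exact_n: int = 30) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test, exact under the permutation null.

    Mid-ranks handle ties; the exact distribution of the rank sum is built
    by dynamic programming over doubled (integer) mid-ranks, enumerating all
    C(n, n_a) group assignments implicitly.  Above ``max_exact_n`` combined
    observations a tie-corrected normal approximation with continuity
    correction is used and flagged in ``method``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n = a.size, a.size + b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    s_obs = float(ranks[:n1].sum())
    e_s = n1 * (n + 1) / 2.0

    if n <= max_exact_n:
        r2 = np.rint(2 * ranks).astype(np.int64)   # doubled mid-ranks: integers
        total = int(r2.sum())
        # dp[k, s] = number of k-subsets with doubled-rank sum s
        dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
        dp[0, 0] = 1.0
        for r in r2:
            for k in range(n1, 0, -1):      # downward: each item used once
                dp[k, r:] += dp[k - 1, :total + 1 - r]
        d_obs = abs(s_obs - e_s)
        sums = np.arange(total + 1) / 2.0
        extreme = np.abs(sums - e_s) >= d_obs - 1e-9
        p = float(dp[n1, extreme].sum() / math.comb(n, n1))
        method = "exact"
    else:
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = (n1 * (n - n1) / 12.0) * (
            (n + 1) - ((tie_sizes**3 - tie_sizes).sum()) / (n * (n - 1)))
        d = abs(s_obs - e_s)
        z = max(d - 0.5, 0.0) / math.sqrt(var) if var > 0 else 0.0
        p = float(2 * stats.norm.sf(z))
        method = "normal_approx"
    return GroupComparison(statistic=s_obs, p_two_sided=min(p, 1.0),
                           n_a=int(n1), n_b=int(n - n1), method=method)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks; p by t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ordinal_trend(groups: list) -> tuple[float, float]:
    """Least-squares trend of values over ordered grades.

    ``groups`` is a list of value arrays in grade order (scores 1..k);
    returns (slope per grade step, two-sided p for slope = 0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two ordered groups")
    xs, ys = [], []
    for grade, vals in enumerate(groups, start=1):
        for v in np.asarray(vals, dtype=float):
            xs.append(grade)
            ys.append(v)
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.pvalue)


def load_table4() -> pd.DataFrame:
    """The packaged 19-case MALT lymphoma table (abnormal %, FISH, therapy)."""
    ref = importlib.resources.files("lymphofoci").joinpath("data/table4.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, dtype={"t1118": str, "trisomy18q21": str,
                                      "eradication": str, "radiation": str,
                                      "response": str})


@dataclass
class MaltAssociationReport:
    n_cases: int
    cutoff: float
    n_high: int
    pct_high: float
    high_t1118_positive: int
    high_t1118_positive_pct: float
    high_trisomy_positive: int
    n_low: int
    low_t1118_positive: int
    low_wild: int
    low_no_signal: int
    n_aberration_positive: int
    association: GroupComparison
    therapy_high_n: int
    therapy_high_responders: int
    therapy_low_n: int
    therapy_low_responders: int

    @property
    def therapy_high_response_pct(self) -> float:
        return 100.0 * self.therapy_high_responders / self.therapy_high_n

    @property
    def therapy_low_response_pct(self) -> float:
        return 100.0 * self.therapy_low_responders / self.therapy_low_n


def malt_association_analysis(table: pd.DataFrame | None = None,
                              thresholds: DiagnosticThresholds = DiagnosticThresholds()
                              ) -> MaltAssociationReport:
    """Association of high abnormal 53BP1 fraction with chromosomal
    aberrations and therapy response in MALT lymphoma cases.

    ``table`` needs columns (abnormal_pct, t1118, trisomy18q21, eradication,
    radiation, response) with statuses in {+, -, +/-, NS, ND, DT}; the
    packaged reference table is used when omitted.  Cases are split at the
    small-cell cutoff; the association test compares abnormal fractions
    between translocation-positive and translocation-negative cases with
    no-signal (NS) cases excluded; the therapy summary excludes cases with
    no data (ND) or still under therapy (DT).
    """
    t = load_table4() if table is None else table.copy()
    for col in ("t1118", "trisomy18q21", "eradication", "radiation", "response"):
        bad = set(t[col].astype(str)) - STATUS_TOKENS
        if bad:
            raise ValueError(f"unknown status token(s) {bad} in column {col!r}")

    cutoff = thresholds.small_cell_cutoff
    high = t["abnormal_pct"] >= cutoff
    n_high = int(high.sum())
    high_t = t.loc[high]
    low_t = t.loc[~high]

    aberration_pos = (t["t1118"] == "+") | t["trisomy18q21"].isin(["+", "+/-"])
    informative = t["t1118"] != "NS"
    grp_pos = t.loc[informative & (t["t1118"] == "+"), "abnormal_pct"]
    grp_neg = t.loc[informative & (t["t1118"] != "+"), "abnormal_pct"]
    if len(grp_pos) == 0 or len(grp_neg) == 0:
        assoc = GroupComparison(statistic=math.nan, p_two_sided=1.0,
                                n_a=len(grp_pos), n_b=len(grp_neg),
                                method="degenerate")
    else:
        assoc = exact_wilcoxon(grp_pos, grp_neg)

    scored = ~t["response"].isin(["ND", "DT"])
    resp = t["response"] == "+"
    return MaltAssociationReport(
        n_cases=len(t), cutoff=cutoff, n_high=n_high,
        pct_high=100.0 * n_high / len(t),
        high_t1118_positive=int((high_t["t1118"] == "+").sum()),
        high_t1118_positive_pct=(100.0 * (high_t["t1118"] == "+").sum()
                                 / max(n_high, 1)),
        high_trisomy_positive=int((high_t["trisomy18q21"] == "+").sum()),
        n_low=len(low_t),
        low_t1118_positive=int((low_t["t1118"] == "+").sum()),
        low_wild=int(((low_t["t1118"] == "-")
                      & (low_t["trisomy18q21"] == "-")).sum()),
        low_no_signal=int((low_t["t1118"] == "NS").sum()),
        n_aberration_positive=int(aberration_pos.sum()),
        association=assoc,
        therapy_high_n=int((scored & high).sum()),
        therapy_high_responders=int((scored & high & resp).sum()),
        therapy_low_n=int((scored & ~high).sum()),
        therapy_low_responders=int((scored & ~high & resp).sum()))


@dataclass
class Diagnosis:
    label: str
    trace: list[str] = field(default_factory=list)


def diagnose_lesion(context: str, abnormal_pct: float,
                    thresholds: DiagnosticThresholds = DiagnosticThresholds(),
                    fish=None) -> Diagnosis:
    """Rule engine over the abnormal fraction and optional FISH result.

    ``context`` selects the branch: ``follicular`` (FL vs GC/PF),
    ``small_cell`` (MCL/FL vs PF/MM/LA), ``large_cell`` (DLBCL vs GC) or
    ``malt`` (requires a FISH case result; translocation marks the
    eradication-resistant "high-risk" group).  Every decision is recorded in
    the trace.
    """
    if not 0 <= abnormal_pct <= 100:
        raise ValueError("abnormal_pct must be in [0, 100]")
    trace: list[str] = []
    if context == "follicular":
        cut = thresholds.follicular_cutoff
        hit = abnormal_pct >= cut
        trace.append(f"abnormal {abnormal_pct:.1f}% "
                     f"{'>=' if hit else '<'} follicular cutoff {cut}%")
        return Diagnosis("FL-suspect" if hit else "benign-follicular (GC/PF)",
                         trace)
    if context == "small_cell":
        cut = thresholds.small_cell_cutoff
        hit = abnormal_pct >= cut
        trace.append(f"abnormal {abnormal_pct:.1f}% "
                     f"{'>=' if hit else '<'} small-cell cutoff {cut}%")
        return Diagnosis("small-B-cell-lymphoma-suspect (MCL/FL)" if hit
                         else "benign-small-cell (PF/MM/LA)", trace)
    if context == "large_cell":
        cut = thresholds.large_cell_cutoff
        hit = abnormal_pct >= cut
        trace.append(f"abnormal {abnormal_pct:.1f}% "
                     f"{'>=' if hit else '<'} large-cell cutoff {cut}%")
        return Diagnosis("DLBCL-suspect" if hit else "benign-large-cell (GC)",
                         trace)
    if context == "malt":
        if fish is None:
            raise ValueError("MALT branch requires a FISH case result")
        call = getattr(fish, "case_call", fish)
        trace.append(f"abnormal {abnormal_pct:.1f}% vs small-cell cutoff "
                     f"{thresholds.small_cell_cutoff}%")
        trace.append(f"FISH case call: {call}")
        if call == "translocation":
            return Diagnosis("high-risk MALT (t(11;18)+, eradication-"
                             "resistant)", trace)
        return Diagnosis("low-risk MALT", trace)
    raise ValueError(f"unknown context {context!r}")
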