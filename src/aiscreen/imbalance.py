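"""Somatic allelic-imbalance (AI) analysis from tumour/normal peak heights.

In a patient heterozygous for a risk SNP, somatic selection during tumour
development may amplify the risk allele or delete the protective ("neutral")
allele.  Both leave the same footprint: the two allele peak heights, measured
from sequencing chromatograms of tumour DNA, become unequal relative to the
matched normal tissue.  The statistic used here is the ratio of allele ratios

    AI = (tumour_risk / tumour_neutral) / (normal_risk / normal_neutral)

with the risk allele always in the numerator.  Normalising by the normal-tissue
ratio cancels allele-specific amplification or dye bias, so AI = 1 is perfect
balance regardless of how unequally the two alleles amplify.  Ratios below 0.6
are called loss of the risk allele and ratios above 1.67 loss of the neutral
allele; values in between (thresholds included) are balanced.

Whether imbalance preferentially targets one allele is tested with a two-sided
exact binomial test on the direction of loss among imbalanced tumours, under
the null that either allele is lost with probability one half.

The screening design mirrors common practice for large tumour series: a first
batch of pairs is analysed and the locus is only extended to the full cohort if
a trend towards directional imbalance appears (`two_stage_screen`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _util

__all__ = [
    "BALANCED",
    "LOSS_RISK",
    "LOSS_NEUTRAL",
    "DEFAULT_LOW",
    "DEFAULT_HIGH",
    "PeakRecord",
    "AICall",
    "LocusAISummary",
    "TwoStageResult",
    "NonEvaluableRecordError",
    "compute_ai_ratio",
    "classify_ai",
    "binom_exact_two_sided",
    "summarize_locus",
    "fisher_exact",
    "two_stage_screen",
    "AllelicImbalanceModel",
    "AllelicImbalanceResults",
]

BALANCED = "balanced"
LOSS_RISK = "loss_risk"
LOSS_NEUTRAL = "loss_neutral"

DEFAULT_LOW = 0.6
DEFAULT_HIGH = 1.67


class NonEvaluableRecordError(ValueError):
    """Raised when an AI ratio is requested for a record that cannot be scored."""


@dataclass(frozen=True)
class PeakRecord:
    """One patient x SNP measurement: four peak heights plus allele orientation.

    Heights are in arbitrary fluorescence units.  A record is evaluable only if
    all four heights are strictly positive and the two alleles differ (i.e. the
    patient is heterozygous in normal tissue).
    """

    patient_id: str
    snp_id: str
    risk_allele: str
    neutral_allele: str
    normal_h_risk: float
    normal_h_neutral: float
    tumor_h_risk: float
    tumor_h_neutral: float
    stage: str | None = None   # Duke's stage A-D, optional
    grade: str | None = None   # histological grade 1-3, optional

    def __post_init__(self) -> None:
        if self.risk_allele == self.neutral_allele:
            raise ValueError(
                f"record {self.patient_id}/{self.snp_id}: risk and neutral "
                f"alleles are identical ({self.risk_allele!r}); only "
                "heterozygous records are evaluable"
            )

    @property
    def heights(self) -> tuple[float, float, float, float]:
        return (
            self.normal_h_risk,
            self.normal_h_neutral,
            self.tumor_h_risk,
            self.tumor_h_neutral,
        )

    @property
    def is_evaluable(self) -> bool:
        return all(h is not None and not math.isnan(h) and h > 0 for h in self.heights)


@dataclass(frozen=True)
class AICall:
    """AI ratio (risk allele in the numerator) and its three-way classification."""

    ratio: float
    call: str
    thresholds_used: tuple[float, float]

    @property
    def is_imbalanced(self) -> bool:
        return self.call != BALANCED


@dataclass
class LocusAISummary:
    """Per-locus aggregate: imbalance counts by direction and the binomial P."""

    snp_id: str
    n_informative: int
    n_imbalanced: int
    n_loss_neutral: int
    n_loss_risk: int
    binom_p: float
    no_imbalance: bool = False   # flag: P is 1 by convention, nothing to test

    @property
    def fraction_imbalanced(self) -> float:
        return self.n_imbalanced / self.n_informative if self.n_informative else 0.0

    @property
    def percent_imbalanced(self) -> int:
        """Imbalance fraction as integer percent, rounded half away from zero."""
        return int(_util.round_half_away(100.0 * self.fraction_imbalanced, 0))


def compute_ai_ratio(record: PeakRecord) -> float:
    """Allelic-imbalance ratio: tumour risk/neutral over normal risk/neutral.

    Raises
    ------
    NonEvaluableRecordError
        If any of the four heights is missing or not strictly positive.
    """
    if not record.is_evaluable:
        raise NonEvaluableRecordError(
            f"record {record.patient_id}/{record.snp_id} is not evaluable: "
            f"peak heights {record.heights} must all be > 0"
        )
    return (record.tumor_h_risk / record.tumor_h_neutral) / (
        record.normal_h_risk / record.normal_h_neutral
    )


def classify_ai(
    ratio: float, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> AICall:
    """Classify an AI ratio as balanced, loss of risk, or loss of neutral allele.

    Thresholds are strict: a ratio exactly at `low` or `high` is balanced.
    With the risk allele in the numerator, ratio < low means the risk allele is
    under-represented in tumour (loss of risk), ratio > high loss of neutral.
    """
    if not ratio > 0:
        raise ValueError(f"AI ratio must be positive, got {ratio}")
    if not (0 < low < 1 < high):
        raise ValueError(f"thresholds must satisfy 0 < low < 1 < high, got ({low}, {high})")
    if ratio < low:
        call = LOSS_RISK
    elif ratio > high:
        call = LOSS_NEUTRAL
    else:
        call = BALANCED
    return AICall(ratio=ratio, call=call, thresholds_used=(low, high))


def binom_exact_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial P by minimum-likelihood summation.

    Sums Binom(n, p0) mass over every outcome whose point probability does not
    exceed that of the observed count `k` (within a small relative tolerance
    guarding against floating-point ties).  For p0 = 0.5 this coincides with
    doubling the smaller tail probability, capped at 1, up to the handling of
    the central term; a maximally central observation returns exactly 1.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0 <= p0 <= 1:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    # relative tolerance mirrors the convention of R's binom.test
    p = pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()
    return float(min(1.0, p))


def summarize_locus(calls: Sequence[AICall], snp_id: str) -> LocusAISummary:
    """Aggregate per-pair AI calls at one locus and test directionality.

    The binomial test is applied to min(loss_neutral, loss_risk) out of the
    imbalanced tumours against p0 = 0.5.  With zero imbalanced tumours there is
    nothing to test: P is reported as 1 with the `no_imbalance` flag set.
    """
    n_ln = sum(1 for c in calls if c.call == LOSS_NEUTRAL)
    n_lr = sum(1 for c in calls if c.call == LOSS_RISK)
    n_imb = n_ln + n_lr
    if n_imb == 0:
        return LocusAISummary(snp_id, len(calls), 0, 0, 0, binom_p=1.0, no_imbalance=True)
    p = binom_exact_two_sided(min(n_ln, n_lr), n_imb, 0.5)
    return LocusAISummary(snp_id, len(calls), n_imb, n_ln, n_lr, binom_p=p)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact P for a 2xK contingency table.

    Conditions on both margins and sums the probability of every table whose
    conditional (multivariate hypergeometric) probability is at most that of
    the observed table.  For K = 2 this is the classical hypergeometric test;
    larger K is handled by full enumeration of the first row, which is feasible
    for the small clinicopathological tables this package meets.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise ValueError(f"expected a 2xK table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("table entries must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("every row and column margin must be non-zero")

    n = int(arr.sum())
    r1 = int(row[0])
    from scipy.special import gammaln

    def log_comb(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = log_comb(n, r1)

    def log_prob(x: tuple[int, ...]) -> float:
        return float(log_comb(col, np.asarray(x)).sum() - denom)

    lp_obs = log_prob(tuple(int(v) for v in arr[0]))
    total = 0.0
    k = arr.shape[1]

    # enumerate first rows consistent with the margins, depth-first
    def rec(j: int, remaining: int, prefix: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = log_prob(tuple(prefix + [remaining]))
                if lp <= lp_obs + 1e-9:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(int(col[j]), remaining)
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, prefix + [x])

    rec(0, r1, [])
    return float(min(1.0, total))


@dataclass
class TwoStageResult:
    """Outcome of the two-stage locus screen."""

    decision: str                 # "stage1_only" or "extended"
    stage1: LocusAISummary
    final: LocusAISummary
    stage1_n: int
    trend_p: float


def two_stage_screen(
    calls: Sequence[AICall],
    snp_id: str,
    trend_p: float,
    stage1_n: int = 90,
) -> TwoStageResult:
    """Two-stage design: test a first batch, extend to all pairs on a trend.

    The first `stage1_n` evaluable pairs (input order) are summarised; if the
    stage-1 binomial P falls below `trend_p` the locus is extended and the
    final summary covers all pairs, otherwise stage 1 stands.  `trend_p` has no
    default on purpose — what counts as "a trend towards imbalance" is a study
    design decision — and `trend_p >= 1` always extends (degenerate threshold).
    """
    if len(calls) < 1:
        raise ValueError("at least one evaluable record is required")
    if stage1_n < 1:
        raise ValueError(f"stage1_n must be >= 1, got {stage1_n}")
    if not 0 <= trend_p:
        raise ValueError(f"trend_p must be non-negative, got {trend_p}")
    stage1 = summarize_locus(calls[:stage1_n], snp_id)
    if stage1.binom_p < trend_p or trend_p >= 1.0:
        return TwoStageResult("extended", stage1, summarize_locus(calls, snp_id),
                              stage1_n, trend_p)
    return TwoStageResult("stage1_only", stage1, stage1, stage1_n, trend_p)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = [
    "patient_id", "snp_id", "risk_allele", "neutral_allele",
    "normal_h_risk", "normal_h_neutral", "tumor_h_risk", "tumor_h_neutral",
]


class AllelicImbalanceModel:
    """Allelic-imbalance analysis over a table of tumour/normal peak heights.

    Parameters
    ----------
    peaks : pandas.DataFrame
        One row per patient x SNP with the columns
        ``patient_id, snp_id, risk_allele, neutral_allele, normal_h_risk,
        normal_h_neutral, tumor_h_risk, tumor_h_neutral``.  Extra columns are
        carried through untouched.
    low, high : float
        Classification thresholds (strict inequalities).  Defaults (0.6, 1.67).
    reciprocal : bool
        If true, use the swap-symmetric pair (low, 1/low) instead of `high`,
        so relabelling the alleles exactly swaps the two loss calls.
    clinic : pandas.DataFrame, optional
        Per-patient ``patient_id, stage, grade`` for the clinicopathological
        comparison of the two loss directions (Fisher exact).
    """

    def __init__(
        self,
        peaks: pd.DataFrame,
        *,
        low: float = DEFAULT_LOW,
        high: float | None = None,
        reciprocal: bool = False,
        clinic: pd.DataFrame | None = None,
    ) -> None:
        missing = [c for c in _PEAK_COLUMNS if c not in peaks.columns]
        if missing:
            raise ValueError(f"peak table is missing columns: {missing}")
        if reciprocal and high is not None:
            raise ValueError("give either high= or reciprocal=True, not both")
        self.peaks = peaks.reset_index(drop=True)
        self.low = float(low)
        self.high = 1.0 / float(low) if reciprocal else float(DEFAULT_HIGH if high is None else high)
        self.reciprocal = bool(reciprocal)
        self.clinic = clinic

    @classmethod
    def from_records(cls, records: Iterable[PeakRecord], **kwargs) -> "AllelicImbalanceModel":
        rows = [
            {c: getattr(r, c) for c in _PEAK_COLUMNS} | {"stage": r.stage, "grade": r.grade}
            for r in records
        ]
        return cls(pd.DataFrame(rows), **kwargs)

    def fit(
        self,
        stage1_n: int | None = None,
        trend_p: float | None = None,
    ) -> "AllelicImbalanceResults":
        """Score every evaluable record and summarise each locus.

        If `stage1_n` is given, `trend_p` is required and each locus goes
        through the two-stage screen instead of a single full-cohort summary.
        """
        if (stage1_n is None) != (trend_p is None):
            raise ValueError("stage1_n and trend_p must be given together")
        calls_rows: list[dict] = []
        excluded: list[dict] = []
        calls_by_snp: dict[str, list[AICall]] = {}
        rec_by_snp: dict[str, list[int]] = {}
        for idx, row in self.peaks.iterrows():
            rec = PeakRecord(
                patient_id=str(row["patient_id"]),
                snp_id=str(row["snp_id"]),
                risk_allele=str(row["risk_allele"]),
                neutral_allele=str(row["neutral_allele"]),
                normal_h_risk=float(row["normal_h_risk"]),
                normal_h_neutral=float(row["normal_h_neutral"]),
                tumor_h_risk=float(row["tumor_h_risk"]),
                tumor_h_neutral=float(row["tumor_h_neutral"]),
                stage=row.get("stage"),
                grade=row.get("grade"),
            )
            if not rec.is_evaluable:
                excluded.append({"row": int(idx), "patient_id": rec.patient_id,
                                 "snp_id": rec.snp_id,
                                 "reason": "non-positive or missing peak height"})
                continue
            call = classify_ai(compute_ai_ratio(rec), self.low, self.high)
            calls_by_snp.setdefault(rec.snp_id, []).append(call)
            rec_by_snp.setdefault(rec.snp_id, []).append(int(idx))
            calls_rows.append({
                "patient_id": rec.patient_id, "snp_id": rec.snp_id,
                "ratio": call.ratio, "call": call.call,
            })
        loci: dict[str, LocusAISummary] = {}
        screens: dict[str, TwoStageResult] = {}
        for snp_id, calls in calls_by_snp.items():
            if stage1_n is not None:
                res = two_stage_screen(calls, snp_id, trend_p=trend_p, stage1_n=stage1_n)
                screens[snp_id] = res
                loci[snp_id] = res.final
            else:
                loci[snp_id] = summarize_locus(calls, snp_id)
        clinic_tests = self._clinic_tests(calls_rows) if self.clinic is not None else {}
        return AllelicImbalanceResults(
            model=self,
            calls=pd.DataFrame(calls_rows, columns=["patient_id", "snp_id", "ratio", "call"]),
            loci=loci,
            screens=screens,
            excluded=pd.DataFrame(excluded, columns=["row", "patient_id", "snp_id", "reason"]),
            clinic_tests=clinic_tests,
        )

    def _clinic_tests(self, calls_rows: list[dict]) -> dict[str, float]:
        """Fisher exact comparison of loss directions across stage and grade."""
        calls = pd.DataFrame(calls_rows)
        imb = calls[calls["call"] != BALANCED].merge(self.clinic, on="patient_id", how="left")
        out: dict[str, float] = {}
        for col in ("stage", "grade"):
            if col not in imb.columns:
                continue
            sub = imb.dropna(subset=[col])
            if sub.empty:
                continue
            tab = pd.crosstab(sub["call"], sub[col])
            if tab.shape[0] == 2 and (tab.to_numpy().sum(axis=0) > 0).all():
                out[col] = fisher_exact(tab.to_numpy())
        return out


class AllelicImbalanceResults:
    """Fit output: per-record calls, per-locus summaries, diagnostics."""

    def __init__(self, model, calls, loci, screens, excluded, clinic_tests) -> None:
        self.model = model
        self.calls = calls
        self.loci = loci
        self.screens = screens
        self.excluded = excluded
        self.clinic_tests = clinic_tests

    def summary(self) -> pd.DataFrame:
        """Per-locus table at display precision, one row per SNP.

        Columns mirror the classic AI results table: imbalanced/informative
        with an integer percentage, the split by lost allele, and the
        two-sided exact binomial P printed to 2 decimals.
        """
        rows = []
        for snp_id, s in self.loci.items():
            row = {
                "snp_id": snp_id,
                "imbalance": f"{s.n_imbalanced}/{s.n_informative} ({s.percent_imbalanced}%)",
                "loss_neutral": s.n_loss_neutral,
                "loss_risk": s.n_loss_risk,
                "P": _util.fmt_p(s.binom_p),
            }
            if snp_id in self.screens:
                row["decision"] = self.screens[snp_id].decision
            rows.append(row)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Per-locus summary at full precision (machine-readable)."""
        return pd.DataFrame(
            [
                {
                    "snp_id": s.snp_id,
                    "n_informative": s.n_informative,
                    "n_imbalanced": s.n_imbalanced,
                    "n_loss_neutral": s.n_loss_neutral,
                    "n_loss_risk": s.n_loss_risk,
                    "fraction_imbalanced": s.fraction_imbalanced,
                    "binom_p": s.binom_p,
                    "no_imbalance": s.no_imbalance,
                }
                for s in self.loci.values()
            ]
        )
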