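"""Case-control allelic association: OR, Woolf CI, chi-squared, Bonferroni.

Each biallelic SNP yields a 2x2 allele-count table (case/control x allele).
The allelic odds ratio is the cross-product ratio of that table, reported by
convention for the allele enriched in cases, so the printed OR is always >= 1
whether the case minor-allele frequency sits above or below the control one.
The 95% confidence interval is the Woolf (logit) interval,
``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``, and the P-value comes from
the 1-df Pearson chi-squared statistic on the same table without continuity
correction.  Monomorphic SNPs (one allele absent from cases and controls
combined) are flagged and excluded from estimation.  A Bonferroni correction
(min(1, m*p)) is available for multiple tested SNPs, and a helper reconstructs
allele counts from published minor-allele frequencies and sample sizes so that
CI and P can be recomputed from a printed table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _util

__all__ = [
    "MISSING_ALLELE",
    "AlleleCountTable",
    "AssociationResult",
    "ZeroCellError",
    "count_alleles",
    "detect_monomorphic",
    "allelic_or",
    "or_from_frequencies",
    "woolf_ci",
    "pearson_chisq",
    "reconstruct_counts_from_maf",
    "bonferroni",
    "duplicate_concordance",
    "AllelicAssociationModel",
    "AssociationResults",
]

MISSING_ALLELE = "0"


class ZeroCellError(ValueError):
    """A zero allele count makes the plain OR/CI undefined.

    Re-run with ``continuity=True`` to add 0.5 to every cell (Haldane-Anscombe
    correction); results computed that way are flagged.
    """


@dataclass
class AlleleCountTable:
    """2x2 case-control allele counts for one SNP.

    ``allele1`` is by convention the minor allele in controls (ties broken
    lexicographically); counts satisfy case_a1 + case_a2 = 2 * n_cases.
    """

    snp_id: str
    case_a1: int
    case_a2: int
    ctrl_a1: int
    ctrl_a2: int
    n_cases: int
    n_controls: int
    allele1: str = "A"
    allele2: str = "B"

    def __post_init__(self) -> None:
        for name in ("case_a1", "case_a2", "ctrl_a1", "ctrl_a2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.snp_id}: {name} must be non-negative")
        if self.case_a1 + self.case_a2 != 2 * self.n_cases:
            raise ValueError(
                f"{self.snp_id}: case allele counts must sum to 2*n_cases "
                f"({self.case_a1}+{self.case_a2} != {2 * self.n_cases})"
            )
        if self.ctrl_a1 + self.ctrl_a2 != 2 * self.n_controls:
            raise ValueError(
                f"{self.snp_id}: control allele counts must sum to 2*n_controls"
            )

    @property
    def maf_cases(self) -> float:
        return self.case_a1 / (2 * self.n_cases) if self.n_cases else float("nan")

    @property
    def maf_controls(self) -> float:
        return self.ctrl_a1 / (2 * self.n_controls) if self.n_controls else float("nan")


@dataclass
class AssociationResult:
    """Association estimates for one SNP (NaNs when monomorphic)."""

    snp_id: str
    maf_cases: float
    maf_controls: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    chi2: float
    oriented_allele: str
    monomorphic: bool
    n_cases: int
    n_controls: int
    continuity_used: bool = False
    p_bonferroni: float | None = None


def count_alleles(genotypes: pd.DataFrame, snp_id: str) -> AlleleCountTable:
    """Tally case/control allele counts for one SNP from a genotype table.

    Samples with either allele missing (code "0") at this SNP are dropped
    (complete-case per SNP, so genotyped n varies across SNPs).  More than two
    distinct alleles is an error: the model is strictly biallelic, and repeat
    polymorphisms must be collapsed to two length classes upstream.
    """
    sub = genotypes[genotypes["snp_id"].astype(str) == str(snp_id)]
    if sub.empty:
        raise ValueError(f"no genotype rows for SNP {snp_id!r}")
    a1 = sub["allele1"].astype(str)
    a2 = sub["allele2"].astype(str)
    keep = (a1 != MISSING_ALLELE) & (a2 != MISSING_ALLELE)
    sub = sub[keep]
    if sub.empty:
        raise ValueError(f"all samples missing at SNP {snp_id!r}")
    alleles = sorted(set(sub["allele1"].astype(str)) | set(sub["allele2"].astype(str)))
    if len(alleles) > 2:
        raise ValueError(f"SNP {snp_id!r} has >2 alleles: {alleles} (biallelic model)")
    if len(alleles) == 1:
        # monomorphic: invent a placeholder second symbol for bookkeeping
        alleles = alleles + [f"non-{alleles[0]}"]
    groups = sub["group"].astype(str)
    cases = sub[groups == "case"]
    ctrls = sub[groups == "control"]

    def tally(frame: pd.DataFrame, allele: str) -> int:
        return int((frame["allele1"].astype(str) == allele).sum()
                   + (frame["allele2"].astype(str) == allele).sum())

    # minor allele in controls; lexicographic tie-break
    c0 = tally(ctrls, alleles[0])
    c1 = tally(ctrls, alleles[1])
    minor, major = (alleles[0], alleles[1]) if c0 <= c1 else (alleles[1], alleles[0])
    return AlleleCountTable(
        snp_id=str(snp_id),
        case_a1=tally(cases, minor),
        case_a2=tally(cases, major),
        ctrl_a1=tally(ctrls, minor),
        ctrl_a2=tally(ctrls, major),
        n_cases=len(cases),
        n_controls=len(ctrls),
        allele1=minor,
        allele2=major,
    )


def detect_monomorphic(table: AlleleCountTable) -> bool:
    """True iff one allele is absent from cases and controls combined."""
    return (table.case_a1 + table.ctrl_a1 == 0) or (table.case_a2 + table.ctrl_a2 == 0)


def _oriented_cells(
    table: AlleleCountTable, continuity: bool = False, orient: bool = True
) -> tuple[float, float, float, float, str]:
    """Return (a, b, c, d, allele) oriented so the OR for `allele` is >= 1.

    a/b are case counts of the reported/other allele, c/d the control counts.
    With ``orient=False`` the table keeps allele1 in the numerator regardless
    of direction (useful when the allele of interest is fixed a priori).
    """
    if detect_monomorphic(table):
        raise ValueError(f"SNP {table.snp_id!r} is monomorphic; no OR is defined")
    a, b, c, d = (float(table.case_a1), float(table.case_a2),
                  float(table.ctrl_a1), float(table.ctrl_a2))
    allele = table.allele1
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ZeroCellError(
                f"SNP {table.snp_id!r} has a zero allele-count cell; pass "
                "continuity=True for the 0.5-corrected estimate"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if orient and a * d < b * c:   # allele1 is case-depleted: report the other
        a, b, c, d = b, a, d, c
        allele = table.allele2
    return a, b, c, d, allele


def allelic_or(
    table: AlleleCountTable, continuity: bool = False, orient: bool = True
) -> tuple[float, str]:
    """Allelic odds ratio (case-enrichment orientation) and the reported allele."""
    a, b, c, d, allele = _oriented_cells(table, continuity, orient)
    return (a * d) / (b * c), allele


def or_from_frequencies(p_case: float, p_ctrl: float) -> float:
    """Allelic OR from the two allele frequencies alone, oriented >= 1."""
    for name, p in (("p_case", p_case), ("p_ctrl", p_ctrl)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be strictly inside (0, 1), got {p}")
    r = (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))
    return max(r, 1.0 / r)


def woolf_ci(
    table: AlleleCountTable, level: float = 0.95, continuity: bool = False,
    orient: bool = True,
) -> tuple[float, float]:
    """Woolf (logit) confidence interval for the oriented allelic OR."""
    if not 0 <= level < 1:
        raise ValueError(f"level must be in [0, 1), got {level}")
    a, b, c, d, _ = _oriented_cells(table, continuity, orient)
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def pearson_chisq(table: AlleleCountTable, continuity: bool = False) -> tuple[float, float]:
    """1-df Pearson chi-squared on the 2x2 allele table and its upper-tail P.

    No continuity correction by default (the convention that reproduces
    published allelic-test P-values); ``continuity=True`` applies Yates'
    |ad-bc| - n/2 correction.  An expected cell below 1 only logs a warning.
    """
    if detect_monomorphic(table):
        raise ValueError(f"SNP {table.snp_id!r} is monomorphic; chi-squared undefined")
    a, b = float(table.case_a1), float(table.case_a2)
    c, d = float(table.ctrl_a1), float(table.ctrl_a2)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    expected_min = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    if expected_min < 1:
        import logging
        logging.getLogger(__name__).warning(
            "SNP %s: smallest expected allele count %.3f < 1; "
            "chi-squared approximation is unreliable", table.snp_id, expected_min)
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2)
    statistic = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def reconstruct_counts_from_maf(maf: float, n_samples: int) -> tuple[int, int]:
    """Minor/major allele counts implied by a printed MAF and sample count.

    minor = round-half-away-from-zero(maf * 2n); major = 2n - minor.  This is
    the inverse of the rounding used when frequencies are printed to a few
    decimals, and lets CI/P be recomputed from published tables.
    """
    if not 0 <= maf <= 1:
        raise ValueError(f"maf must be in [0, 1], got {maf}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    minor = int(_util.round_half_away(maf * 2 * n_samples, 0))
    return minor, 2 * n_samples - minor


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P: min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, m * p)


def duplicate_concordance(
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
) -> tuple[float, int, int]:
    """Concordance rate between duplicate genotype calls.

    Each element is a pair of genotypes, each an (allele, allele) tuple; calls
    agree when the unordered allele sets match.  Returns (percentage rounded to
    2 decimals, concordant count, total count).
    """
    if not pairs:
        raise ValueError("no duplicate pairs given")
    concordant = 0
    for g1, g2 in pairs:
        if MISSING_ALLELE in g1 or MISSING_ALLELE in g2:
            raise ValueError(f"duplicate pair has a missing call: {g1} vs {g2}")
        if sorted(g1) == sorted(g2):
            concordant += 1
    rate = _util.round_half_away(100.0 * concordant / len(pairs), 2)
    return rate, concordant, len(pairs)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

_GENO_COLUMNS = ["sample_id", "group", "snp_id", "allele1", "allele2"]


class AllelicAssociationModel:
    """Allelic case-control association across the SNPs of a genotype table.

    Parameters
    ----------
    genotypes : pandas.DataFrame
        One row per sample x SNP: ``sample_id, group, snp_id, allele1,
        allele2`` with group in {case, control} and "0" for a missing allele.
    snp_ids : sequence of str, optional
        Restrict / order the analysis; default is order of first appearance.
    """

    def __init__(self, genotypes: pd.DataFrame, snp_ids: Sequence[str] | None = None) -> None:
        missing = [c for c in _GENO_COLUMNS if c not in genotypes.columns]
        if missing:
            raise ValueError(f"genotype table is missing columns: {missing}")
        bad = set(genotypes["group"].astype(str)) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.genotypes = genotypes.reset_index(drop=True)
        if snp_ids is None:
            snp_ids = list(dict.fromkeys(self.genotypes["snp_id"].astype(str)))
        self.snp_ids = list(snp_ids)

    @classmethod
    def from_counts(cls, tables: Iterable[AlleleCountTable]) -> "_CountsModel":
        """Build directly from pre-tallied allele-count tables."""
        return _CountsModel(list(tables))

    @classmethod
    def from_maf(
        cls,
        snp_id: str,
        maf_cases: float,
        maf_controls: float,
        n_cases: int,
        n_controls: int,
    ) -> "_CountsModel":
        """Build from printed MAFs and sample sizes via count reconstruction."""
        ka, ma = reconstruct_counts_from_maf(maf_cases, n_cases)
        kc, mc = reconstruct_counts_from_maf(maf_controls, n_controls)
        return _CountsModel([
            AlleleCountTable(snp_id, ka, ma, kc, mc, n_cases, n_controls)
        ])

    def _tables(self) -> list[AlleleCountTable]:
        return [count_alleles(self.genotypes, s) for s in self.snp_ids]

    def fit(
        self,
        continuity: bool = False,
        bonferroni_m: int | None = None,
        level: float = 0.95,
    ) -> "AssociationResults":
        return _fit_tables(self._tables(), continuity, bonferroni_m, level, model=self)


class _CountsModel(AllelicAssociationModel):
    """Association model over explicit allele-count tables (no genotype rows)."""

    def __init__(self, tables: list[AlleleCountTable]) -> None:  # noqa: D401
        self.tables = tables
        self.snp_ids = [t.snp_id for t in tables]
        self.genotypes = None

    def _tables(self) -> list[AlleleCountTable]:
        return self.tables


def _fit_tables(tables, continuity, bonferroni_m, level, model) -> "AssociationResults":
    results: list[AssociationResult] = []
    for t in tables:
        if detect_monomorphic(t):
            results.append(AssociationResult(
                snp_id=t.snp_id, maf_cases=float("nan"), maf_controls=float("nan"),
                or_value=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                p_value=float("nan"), chi2=float("nan"), oriented_allele="",
                monomorphic=True, n_cases=t.n_cases, n_controls=t.n_controls))
            continue
        used_continuity = False
        try:
            orv, allele = allelic_or(t, continuity=continuity)
            lo, hi = woolf_ci(t, level=level, continuity=continuity)
            used_continuity = continuity
        except ZeroCellError:
            orv, allele = allelic_or(t, continuity=True)
            lo, hi = woolf_ci(t, level=level, continuity=True)
            used_continuity = True
        chi2, p = pearson_chisq(t)
        pb = bonferroni(p, bonferroni_m) if bonferroni_m else None
        results.append(AssociationResult(
            snp_id=t.snp_id, maf_cases=t.maf_cases, maf_controls=t.maf_controls,
            or_value=orv, ci_low=lo, ci_high=hi, p_value=p, chi2=chi2,
            oriented_allele=allele, monomorphic=False,
            n_cases=t.n_cases, n_controls=t.n_controls,
            continuity_used=used_continuity, p_bonferroni=pb))
    return AssociationResults(model, tables, results)


class AssociationResults:
    """Fit output: one AssociationResult per SNP plus summary tables."""

    def __init__(self, model, tables, results: list[AssociationResult]) -> None:
        self.model = model
        self.tables = {t.snp_id: t for t in tables}
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, snp_id: str) -> AssociationResult:
        for r in self.results:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def summary(self) -> pd.DataFrame:
        """Association table at display precision (MAFs 3 d.p., OR/CI/P 2 d.p.)."""
        rows = []
        for r in self.results:
            if r.monomorphic:
                rows.append({"snp_id": r.snp_id, "maf_controls": "monomorphic",
                             "maf_cases": "", "OR": "", "CI95": "", "P": "",
                             "n_cases": r.n_cases, "n_controls": r.n_controls})
                continue
            row = {
                "snp_id": r.snp_id,
                "maf_controls": f"{r.maf_controls:.3f}",
                "maf_cases": f"{r.maf_cases:.3f}",
                "OR": _util.fmt_or(r.or_value),
                "CI95": f"{_util.fmt_or(r.ci_low)}-{_util.fmt_or(r.ci_high)}",
                "P": _util.fmt_p(r.p_value),
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
            if r.p_bonferroni is not None:
                row["P_bonferroni"] = _util.fmt_p(r.p_bonferroni)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Full-precision results (machine-readable)."""
        return pd.DataFrame([vars(r) for r in self.results])
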