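"""In-silico screen for regulatory candidate variants at risk loci.

The screen consumes predicted enhancer elements (scored genomic intervals) and
predicted transcription-factor binding sites inside them, and selects the
variants worth genotyping: those lying (1) inside a defined linkage-
disequilibrium region around a tag SNP, (2) inside a binding-site footprint,
(3) whose parent element scores at or above a cutoff (default 300).  Each hit
is annotated with the site's factor, consensus pattern and, when a position
weight matrix is available, per-allele log-odds scores; a variant is called
*disruptive* when exactly one of its two alleles is compatible with the site
(consensus match, or PWM score above the site threshold).

Coordinates are 1-based inclusive throughout; BED input (0-based half-open) is
converted at the IO boundary.  A simple log-odds PWM scanner over both strands
is included as a self-contained site predictor for building test fixtures and
re-screening sequences; it is not a reimplementation of any comparative-
genomics enhancer predictor, whose output this module merely consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC",
    "GenomicInterval",
    "EnhancerElement",
    "BindingSite",
    "Variant",
    "PWM",
    "SiteAnnotation",
    "CandidateHit",
    "DisruptionReport",
    "ScreenConfigurationError",
    "DEFAULT_MIN_SCORE",
    "reverse_complement",
    "iupac_match",
    "restrict_to_ld_region",
    "filter_elements_by_score",
    "variants_at_binding_sites",
    "allele_disruption",
    "scan_pwm",
    "read_jaspar_pfm",
    "EnhancerScreen",
    "ScreenResults",
]

DEFAULT_MIN_SCORE = 300.0

IUPAC: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class ScreenConfigurationError(ValueError):
    """Inconsistent screen inputs (e.g. a binding site outside every element)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval on a chromosome, 1-based inclusive at both ends."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.label or self.chrom}: coordinates must be >= 1")
        if self.start > self.end:
            raise ValueError(
                f"{self.label or self.chrom}: start {self.start} > end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (other.chrom == self.chrom
                and self.start <= other.start and other.end <= self.end)


@dataclass(frozen=True)
class EnhancerElement:
    """Predicted enhancer element: an interval with a prediction score."""

    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"element {self.interval.label!r}: score must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """Predicted TF binding site with its consensus pattern, strand-aware.

    ``pattern`` is given 5'->3' on ``strand``; for a minus-strand site the
    plus-strand footprint sequence must be reverse-complemented before
    matching.  ``score``, when present, is the predictor's site score.
    """

    interval: GenomicInterval
    tf_name: str
    pattern: str
    strand: str = "+"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"site {self.tf_name}: strand must be '+' or '-'")
        if self.pattern and len(self.pattern) != len(self.interval):
            raise ValueError(
                f"site {self.tf_name} at {self.interval.chrom}:{self.interval.start}: "
                f"pattern length {len(self.pattern)} != interval length "
                f"{len(self.interval)}"
            )


@dataclass(frozen=True)
class Variant:
    """Biallelic variant; alleles are stored on the + strand."""

    chrom: str
    pos: int
    snp_id: str
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(sequence: str, pattern: str) -> bool:
    """True iff each base falls in the degeneracy set of the pattern symbol."""
    sequence = sequence.upper()
    pattern = pattern.upper()
    if len(sequence) != len(pattern):
        raise ValueError(
            f"sequence length {len(sequence)} != pattern length {len(pattern)}"
        )
    bad_base = next((b for b in sequence if b not in _BASES), None)
    if bad_base is not None:
        raise ValueError(f"invalid base {bad_base!r} in sequence")
    bad_sym = next((s for s in pattern if s not in IUPAC), None)
    if bad_sym is not None:
        raise ValueError(f"invalid IUPAC symbol {bad_sym!r} in pattern")
    return all(base in IUPAC[sym] for base, sym in zip(sequence, pattern))


def restrict_to_ld_region(
    variants: Sequence[Variant], region: GenomicInterval
) -> list[Variant]:
    """Keep variants inside the region (both ends inclusive), preserving order.

    Variants on another chromosome are excluded silently but counted in the
    module log: boundary exclusions are deliberately surfaced rather than the
    region widened.
    """
    kept: list[Variant] = []
    n_other_chrom = 0
    for v in variants:
        if v.chrom != region.chrom:
            n_other_chrom += 1
            continue
        if region.start <= v.pos <= region.end:
            kept.append(v)
    if n_other_chrom:
        logger.info(
            "restrict_to_ld_region(%s): %d variant(s) on other chromosomes excluded",
            region.label or region.chrom, n_other_chrom)
    logger.info(
        "restrict_to_ld_region(%s): kept %d of %d variants",
        region.label or region.chrom, len(kept), len(variants))
    return kept


def filter_elements_by_score(
    elements: Sequence[EnhancerElement], min_score: float = DEFAULT_MIN_SCORE
) -> list[EnhancerElement]:
    """Keep elements with score >= min_score (cutoff inclusive)."""
    return [e for e in elements if e.score >= min_score]


@dataclass(frozen=True)
class SiteAnnotation:
    """One (site, parent element) annotation attached to a candidate variant."""

    site: BindingSite
    element: EnhancerElement
    offset: int          # 0-based offset of the variant within the site, + strand


@dataclass
class CandidateHit:
    """A variant inside >= 1 binding site of a passing element."""

    variant: Variant
    annotations: list[SiteAnnotation] = field(default_factory=list)


def _parent_element(
    site: BindingSite, elements: Sequence[EnhancerElement]
) -> EnhancerElement | None:
    for e in elements:
        if e.interval.contains_interval(site.interval):
            return e
    return None


def variants_at_binding_sites(
    variants: Sequence[Variant],
    sites: Sequence[BindingSite],
    elements: Sequence[EnhancerElement],
    exclude_ids: Sequence[str] = (),
    *,
    all_elements: Sequence[EnhancerElement] | None = None,
) -> list[CandidateHit]:
    """Variants lying in binding sites whose parent element passed the filter.

    ``elements`` is the score-filtered element list; ``all_elements`` (default:
    same list) is the universe used to assign each site its parent element — a
    site contained in no element of that universe is a configuration error.
    One candidate per variant (de-duplicated by snp_id, input order preserved)
    with an annotation row per overlapping eligible site; explicitly excluded
    IDs (e.g. previously genotyped markers) are dropped.
    """
    universe = elements if all_elements is None else all_elements
    passing = set(id(e) for e in elements)
    parents: list[tuple[BindingSite, EnhancerElement]] = []
    for s in sites:
        parent = _parent_element(s, universe)
        if parent is None:
            raise ScreenConfigurationError(
                f"binding site {s.tf_name} at {s.interval.chrom}:"
                f"{s.interval.start}-{s.interval.end} is contained in no "
                "enhancer element"
            )
        parents.append((s, parent))

    excluded = set(exclude_ids)
    hits: list[CandidateHit] = []
    by_id: dict[str, CandidateHit] = {}
    n_excluded = 0
    for v in variants:
        annotations = [
            SiteAnnotation(site=s, element=e, offset=v.pos - s.interval.start)
            for (s, e) in parents
            if id(e) in passing and s.interval.contains(v.chrom, v.pos)
        ]
        if not annotations:
            continue
        if v.snp_id in excluded:
            n_excluded += 1
            continue
        if v.snp_id in by_id:
            by_id[v.snp_id].annotations.extend(annotations)
            continue
        hit = CandidateHit(variant=v, annotations=annotations)
        by_id[v.snp_id] = hit
        hits.append(hit)
    if n_excluded:
        logger.info("variants_at_binding_sites: %d in-site variant(s) excluded by ID",
                    n_excluded)
    return hits


@dataclass
class DisruptionReport:
    """Per-allele compatibility of a variant with one binding site."""

    snp_id: str
    tf_name: str
    pattern: str
    allele_a: str
    allele_b: str
    match_a: bool
    match_b: bool
    score_a: float | None = None
    score_b: float | None = None
    disruptive: bool = False

    @property
    def pwm_delta(self) -> float | None:
        if self.score_a is None or self.score_b is None:
            return None
        return self.score_a - self.score_b


def allele_disruption(
    variant: Variant,
    site: BindingSite,
    site_sequence: str,
    pwm: "PWM | None" = None,
    pwm_threshold: float | None = None,
) -> DisruptionReport:
    """Substitute each allele into the site and report consensus/PWM status.

    ``site_sequence`` is the + strand sequence of the site footprint (carrying
    either allele).  Each allele is substituted at the variant's offset on the
    + strand; for minus-strand sites the sequence is reverse-complemented
    before matching, so alleles never need to be complemented by the caller.
    A variant is disruptive iff exactly one allele matches the consensus (or,
    when a PWM and threshold are given, iff exactly one allele scores at or
    above the threshold).
    """
    site_sequence = site_sequence.upper()
    if len(site_sequence) != len(site.interval):
        raise ValueError(
            f"site sequence length {len(site_sequence)} != site length "
            f"{len(site.interval)}"
        )
    offset = variant.pos - site.interval.start
    if not 0 <= offset < len(site_sequence):
        raise ValueError(
            f"variant {variant.snp_id} at {variant.chrom}:{variant.pos} lies "
            f"outside site {site.interval.chrom}:{site.interval.start}-"
            f"{site.interval.end}"
        )

    def oriented(allele: str) -> str:
        seq = site_sequence[:offset] + allele.upper() + site_sequence[offset + 1:]
        return reverse_complement(seq) if site.strand == "-" else seq

    seq_a, seq_b = oriented(variant.allele_a), oriented(variant.allele_b)
    match_a = iupac_match(seq_a, site.pattern) if site.pattern else False
    match_b = iupac_match(seq_b, site.pattern) if site.pattern else False
    score_a = score_b = None
    if pwm is not None:
        score_a = pwm.score(seq_a)
        score_b = pwm.score(seq_b)
    if pwm is not None and pwm_threshold is not None:
        disruptive = (score_a >= pwm_threshold) != (score_b >= pwm_threshold)
    else:
        disruptive = match_a != match_b
    return DisruptionReport(
        snp_id=variant.snp_id, tf_name=site.tf_name, pattern=site.pattern,
        allele_a=variant.allele_a, allele_b=variant.allele_b,
        match_a=match_a, match_b=match_b,
        score_a=score_a, score_b=score_b, disruptive=disruptive,
    )


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------


@dataclass
class PWM:
    """Position count/weight matrix over A, C, G, T.

    ``counts`` is 4 x L in fixed A, C, G, T row order.  Probabilities are
    formed with a background-split pseudocount — column j gives base b the
    probability (count + pseudocount * bg_b) / (column_total + pseudocount) —
    and log-odds are log2(p / bg_b).  Defaults (pseudocount 0.8, uniform
    background) follow common JASPAR practice.
    """

    tf_name: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2:
            raise ValueError(f"PWM {self.tf_name}: counts must be 4 x L")
        if (self.counts < 0).any():
            raise ValueError(f"PWM {self.tf_name}: counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError(f"PWM {self.tf_name}: pseudocount must be positive")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
            raise ValueError(f"PWM {self.tf_name}: background must be 4 positive "
                             "frequencies summing to 1")

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        bg = np.asarray(self.background)[:, None]
        totals = self.counts.sum(axis=0, keepdims=True)
        return (self.counts + self.pseudocount * bg) / (totals + self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        bg = np.asarray(self.background)[:, None]
        return np.log2(self.probabilities / bg)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))

    def score(self, window: str) -> float:
        """Log-odds score of one window (length must equal the motif length)."""
        window = window.upper()
        if len(window) != len(self):
            raise ValueError(f"window length {len(window)} != motif length {len(self)}")
        lo = self.log_odds
        try:
            return float(sum(lo[_BASE_INDEX[b], j] for j, b in enumerate(window)))
        except KeyError as exc:
            raise ValueError(f"degenerate base {exc.args[0]!r} in window") from None

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf_name, self.counts[::-1, ::-1],
                   self.pseudocount, self.background)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold: float,
    chrom: str = "seq",
) -> list[BindingSite]:
    """Scan both strands with a log-odds PWM; report sites scoring >= threshold.

    Sites are reported in forward (1-based inclusive) coordinates; a minus-
    strand hit keeps its forward footprint but carries strand "-" and the
    motif consensus read 5'->3' on the minus strand.  Windows containing
    degenerate bases are skipped and counted in the log.
    """
    sequence = sequence.upper()
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(
            f"sequence length {len(sequence)} < motif length {L}"
        )
    rc = pwm.reverse_complement()
    sites: list[BindingSite] = []
    n_skipped = 0
    for start in range(len(sequence) - L + 1):
        window = sequence[start:start + L]
        if any(b not in _BASE_INDEX for b in window):
            n_skipped += 1
            continue
        for strand, mat in (("+", pwm), ("-", rc)):
            s = mat.score(window)
            if s >= threshold:
                # the pattern reads 5'->3' on the site's strand, which for both
                # strands is the motif consensus itself
                sites.append(BindingSite(
                    interval=GenomicInterval(chrom, start + 1, start + L,
                                             label=pwm.tf_name),
                    tf_name=pwm.tf_name,
                    pattern=pwm.consensus,
                    strand=strand,
                    score=s,
                ))
    if n_skipped:
        logger.info("scan_pwm(%s): skipped %d window(s) with degenerate bases",
                    pwm.tf_name, n_skipped)
    return sites


def read_jaspar_pfm(text: str, **pwm_kwargs) -> PWM:
    """Parse one JASPAR-format position frequency matrix.

    Accepts the common dialects: a ``>ID name`` header followed by four count
    rows, either labelled (``A [ 4 19 0 0 0 ]`` / ``A 4 19 0 0 0``, any row
    order, brackets optional) or unlabelled (assumed A, C, G, T order).
    Errors carry the 1-based line number of the offending row.
    """
    tf_name = "PWM"
    rows: dict[str, list[float]] = {}
    unlabelled: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            tf_name = parts[-1] if len(parts) > 1 else (parts[0] if parts else "PWM")
            continue
        tokens = line.replace("[", " ").replace("]", " ").split()
        label = None
        if tokens and tokens[0].upper() in _BASES and not _is_number(tokens[0]):
            label = tokens[0].upper()
            tokens = tokens[1:]
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: cannot parse count {exc.args[0]}") from None
        if not values:
            raise ValueError(f"line {lineno}: empty matrix row")
        if any(v < 0 for v in values):
            raise ValueError(f"line {lineno}: negative count in matrix row")
        if label is not None:
            if label in rows:
                raise ValueError(f"line {lineno}: duplicate row for base {label}")
            rows[label] = values
        else:
            unlabelled.append(values)

    if rows and unlabelled:
        raise ValueError("mix of labelled and unlabelled matrix rows")
    if rows:
        missing = [b for b in _BASES if b not in rows]
        if missing:
            raise ValueError(f"missing matrix row(s) for base(s): {missing}")
        ordered = [rows[b] for b in _BASES]
    else:
        if len(unlabelled) != 4:
            raise ValueError(f"expected 4 matrix rows, found {len(unlabelled)}")
        ordered = unlabelled
    lengths = {len(r) for r in ordered}
    if len(lengths) != 1:
        raise ValueError(f"ragged matrix rows, lengths {sorted(lengths)}")
    return PWM(tf_name=tf_name, counts=np.array(ordered), **pwm_kwargs)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Pipeline object
# ---------------------------------------------------------------------------


class EnhancerScreen:
    """End-to-end screen: LD restriction, score filter, site overlap, annotation.

    Parameters
    ----------
    variants, sites, elements
        The screen substrate (see the module types).
    regions : sequence of GenomicInterval, optional
        LD regions; when given, variants are first restricted to their union.
    min_score : float
        Element score cutoff, inclusive (default 300).
    exclude_ids : sequence of str
        Variant IDs to drop from the candidate list (e.g. already genotyped).
    sequences : mapping chrom -> str, optional
        + strand sequences; enables per-allele disruption annotation.
    pwms : mapping tf_name -> PWM, optional
        Matrices for log-odds annotation of each allele.
    pwm_threshold : float, optional
        Site-level log-odds threshold for PWM-based disruption calls.
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        sites: Sequence[BindingSite],
        elements: Sequence[EnhancerElement],
        *,
        regions: Sequence[GenomicInterval] | None = None,
        min_score: float = DEFAULT_MIN_SCORE,
        exclude_ids: Sequence[str] = (),
        sequences: Mapping[str, str] | None = None,
        pwms: Mapping[str, PWM] | None = None,
        pwm_threshold: float | None = None,
    ) -> None:
        self.variants = list(variants)
        self.sites = list(sites)
        self.elements = list(elements)
        self.regions = list(regions) if regions is not None else None
        self.min_score = float(min_score)
        self.exclude_ids = list(exclude_ids)
        self.sequences = sequences
        self.pwms = pwms or {}
        self.pwm_threshold = pwm_threshold

    def run(self) -> "ScreenResults":
        variants = self.variants
        if self.regions is not None:
            kept: list[Variant] = []
            seen: set[str] = set()
            for region in self.regions:
                for v in restrict_to_ld_region(variants, region):
                    if v.snp_id not in seen:
                        seen.add(v.snp_id)
                        kept.append(v)
            variants = kept
        passing = filter_elements_by_score(self.elements, self.min_score)
        hits = variants_at_binding_sites(
            variants, self.sites, passing,
            exclude_ids=self.exclude_ids, all_elements=self.elements)
        reports: dict[str, list[DisruptionReport]] = {}
        if self.sequences is not None:
            for hit in hits:
                v = hit.variant
                seq = self.sequences.get(v.chrom)
                if seq is None:
                    continue
                for ann in hit.annotations:
                    site = ann.site
                    site_seq = seq[site.interval.start - 1:site.interval.end]
                    pwm = self.pwms.get(site.tf_name)
                    reports.setdefault(v.snp_id, []).append(allele_disruption(
                        v, site, site_seq, pwm=pwm,
                        pwm_threshold=self.pwm_threshold))
        return ScreenResults(self, hits, reports)


class ScreenResults:
    """Candidate variants with per-site annotations and disruption reports."""

    def __init__(self, screen, hits: list[CandidateHit],
                 reports: dict[str, list[DisruptionReport]]) -> None:
        self.screen = screen
        self.hits = hits
        self.reports = reports

    @property
    def candidate_ids(self) -> list[str]:
        return [h.variant.snp_id for h in self.hits]

    def __len__(self) -> int:
        return len(self.hits)

    def to_frame(self) -> pd.DataFrame:
        """One row per (candidate, site) annotation."""
        rows = []
        for hit in self.hits:
            v = hit.variant
            reps = {(r.tf_name, r.pattern): r for r in self.reports.get(v.snp_id, [])}
            for ann in hit.annotations:
                site = ann.site
                rep = reps.get((site.tf_name, site.pattern))
                rows.append({
                    "snp_id": v.snp_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "allele_a": v.allele_a,
                    "allele_b": v.allele_b,
                    "tf_name": site.tf_name,
                    "pattern": site.pattern,
                    "strand": site.strand,
                    "offset_in_site": ann.offset,
                    "element_score": ann.element.score,
                    "allele_a_match": None if rep is None else rep.match_a,
                    "allele_b_match": None if rep is None else rep.match_b,
                    "disruptive": None if rep is None else rep.disruptive,
                    "pwm_delta": None if rep is None else rep.pwm_delta,
                })
        cols = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "tf_name",
                "pattern", "strand", "offset_in_site", "element_score",
                "allele_a_match", "allele_b_match", "disruptive", "pwm_delta"]
        return pd.DataFrame(rows, columns=cols)
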