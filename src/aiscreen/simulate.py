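"""Synthetic data with the statistical structure the analyses assume.

Three generators, all driven by one :class:`SimulationConfig` and one master
seed, emulate the three inputs of the pipeline:

* **Tumour/normal peak heights.**  Normal tissue is diploid heterozygous, so
  each allele contributes one copy; the tumour is a mixture of tumour cells
  (fraction ``purity``) carrying ``(risk_copies, neutral_copies)`` of the two
  alleles and contaminating normal cells carrying one of each.  The expected
  peak height of an allele is proportional to its average copy dosage in the
  mixture, and every measured peak carries independent multiplicative
  lognormal noise (unit mean, coefficient of variation ``noise_cv``) — peak
  heights are positive and their error scales with magnitude.  Purities are
  drawn from a truncated normal and a quota then guarantees that at least a
  configured fraction of tumours has >= 70% carcinoma content, mirroring how
  such cohorts are described.

* **Case-control genotypes.**  Controls are Hardy-Weinberg at the configured
  allele frequency; cases are Hardy-Weinberg at the frequency implied by the
  configured allelic odds ratio, ``p_case = OR * odds_ctrl / (1 + OR *
  odds_ctrl)``.

* **Screen fixtures.**  A random background sequence with planted motif
  instances, elements scored on both sides of the 300 cutoff, and variants in
  three labelled strata: inside a site of a high-scoring element, inside a
  site of a low-scoring element, and outside any site — so every branch of the
  screen logic can be asserted against ground truth.

Every generator derives its own RNG stream deterministically from the master
seed, so the three outputs are individually and jointly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen import (
    IUPAC,
    BindingSite,
    EnhancerElement,
    GenomicInterval,
    Variant,
)

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "ScreenFixture",
    "expected_tumor_ratio",
    "simulate_tumor_normal_peaks",
    "simulate_case_control_genotypes",
    "simulate_screen_fixture",
]


class ConfigurationError(ValueError):
    """An invalid SimulationConfig field; the message names the field."""


# deterministic sub-stream keys per generator
_STREAM_PEAKS = 1
_STREAM_GENOTYPES = 2
_STREAM_SCREEN = 3


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Defaults are the study conditions the analyses were designed around: a
    first-stage cohort of 90 tumour/normal pairs, tumour purity centred at
    0.75 with at least 64% of tumours at >= 0.70 carcinoma content, 15%
    multiplicative peak noise, and a case-control panel of 913 cases / 821
    controls at a risk-allele frequency of 0.431 with allelic OR 1.13 (a
    typical low-penetrance locus).
    """

    n_pairs: int = 90
    purity_mean: float = 0.75
    purity_sd: float = 0.10
    carcinoma_min_fraction: float = 0.64
    copy_state_probs: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {(1, 1): 1.0})
    noise_cv: float = 0.15
    baseline_height: float = 1000.0
    amplification_bias: float = 1.0   # per-SNP factor on the risk-allele peak,
                                      # applied identically in tumour and normal
    n_cases: int = 913
    n_controls: int = 821
    snp_specs: Sequence[tuple[float, float]] = ((0.431, 1.13),)
    # screen fixture geometry
    screen_patterns: Sequence[str] = ("YATCC", "GTRTCT", "TAAATRTA")
    n_variants_in_high: int = 13
    n_variants_in_low: int = 3
    n_variants_outside: int = 4
    screen_chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ConfigurationError(f"n_pairs must be >= 1, got {self.n_pairs}")
        for name in ("purity_mean", "carcinoma_min_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.purity_sd < 0:
            raise ConfigurationError(f"purity_sd must be >= 0, got {self.purity_sd}")
        if not self.copy_state_probs:
            raise ConfigurationError("copy_state_probs must be non-empty")
        total = 0.0
        for state, p in self.copy_state_probs.items():
            cr, cn = state
            if cr < 0 or cn < 0 or int(cr) != cr or int(cn) != cn:
                raise ConfigurationError(
                    f"copy_state_probs: copy counts must be non-negative "
                    f"integers, got {state}")
            if cr == 0 and cn == 0:
                raise ConfigurationError(
                    "copy_state_probs: state (0, 0) (both alleles lost) is not "
                    "modelled")
            if p < 0:
                raise ConfigurationError(
                    f"copy_state_probs: probability for {state} is negative")
            total += p
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(
                f"copy_state_probs must sum to 1, got {total}")
        if self.noise_cv < 0:
            raise ConfigurationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.baseline_height <= 0:
            raise ConfigurationError(
                f"baseline_height must be > 0, got {self.baseline_height}")
        if self.amplification_bias <= 0:
            raise ConfigurationError(
                f"amplification_bias must be > 0, got {self.amplification_bias}")
        for name in ("n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for i, (freq, orv) in enumerate(self.snp_specs):
            if not 0 <= freq <= 1:
                raise ConfigurationError(
                    f"snp_specs[{i}]: frequency must be in [0, 1], got {freq}")
            if orv <= 0:
                raise ConfigurationError(
                    f"snp_specs[{i}]: OR must be > 0, got {orv}")
            if freq in (0.0, 1.0) and orv != 1.0:
                raise ConfigurationError(
                    f"snp_specs[{i}]: monomorphic frequency {freq} requires OR "
                    f"exactly 1, got {orv}")
        for name in ("n_variants_in_high", "n_variants_in_low", "n_variants_outside"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for p in self.screen_patterns:
            bad = [s for s in p.upper() if s not in IUPAC]
            if bad:
                raise ConfigurationError(
                    f"screen_patterns: invalid IUPAC symbol(s) {bad} in {p!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimulationConfig":
        """Build a config from a flat key:value mapping (e.g. a parsed YAML file).

        ``copy_state_probs`` keys may be "risk,neutral" strings; ``snp_specs``
        entries may be [freq, OR] pairs or "freq,OR" strings.
        """
        d = dict(mapping)
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "copy_state_probs" in d:
            parsed = {}
            for key, p in dict(d["copy_state_probs"]).items():
                if isinstance(key, str):
                    cr, cn = (int(x) for x in key.replace("(", "").replace(")", "").split(","))
                else:
                    cr, cn = (int(x) for x in key)
                parsed[(cr, cn)] = float(p)
            d["copy_state_probs"] = parsed
        if "snp_specs" in d:
            specs = []
            for item in d["snp_specs"]:
                if isinstance(item, str):
                    freq, orv = (float(x) for x in item.split(","))
                else:
                    freq, orv = (float(x) for x in item)
                specs.append((freq, orv))
            d["snp_specs"] = specs
        return cls(**d)

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-generator RNG derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,)))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def expected_tumor_ratio(purity: float, risk_copies: int, neutral_copies: int) -> float:
    """Noise-free AI ratio implied by tumour purity and allele copy numbers.

    The tumour sample mixes tumour cells carrying (risk_copies,
    neutral_copies) with normal diploid cells carrying one copy of each
    allele, so the expected allele dosage ratio is

        (purity * risk + (1 - purity)) / (purity * neutral + (1 - purity)).

    Since the matched normal ratio is 1, this is also the expected AI ratio.
    A fully lost neutral allele in a pure tumour gives an infinite ratio,
    returned as ``math.inf``.
    """
    if not 0 <= purity <= 1:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    if risk_copies < 0 or neutral_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    num = purity * risk_copies + (1 - purity)
    den = purity * neutral_copies + (1 - purity)
    if den == 0:
        if num == 0:
            raise ValueError(
                "purity 1 with both copy numbers 0 leaves no signal (0/0)")
        return math.inf
    return num / den


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV (exact 1 at cv=0)."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def _draw_purities(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    purity = rng.normal(config.purity_mean, config.purity_sd, size=config.n_pairs)
    purity = np.clip(purity, 0.0, 1.0)
    # carcinoma-content quota: raise the smallest purities to 0.70 until the
    # required fraction of tumours has >= 70% carcinoma tissue
    needed = math.ceil(config.carcinoma_min_fraction * config.n_pairs)
    have = int((purity >= 0.70).sum())
    if have < needed:
        order = np.argsort(purity)
        below = [i for i in order if purity[i] < 0.70]
        for i in below[: needed - have]:
            purity[i] = 0.70
    return purity


def simulate_tumor_normal_peaks(
    config: SimulationConfig, snp_id: str = "snp_sim", risk_allele: str = "A",
    neutral_allele: str = "G",
) -> pd.DataFrame:
    """Simulate one locus of tumour/normal allele peak heights.

    Returns a table with the standard peak columns plus ground truth
    (``truth_purity, truth_copy_risk, truth_copy_neutral``) so that the
    accuracy of downstream imbalance calls is measurable.
    """
    config.validate()
    rng = config.rng(_STREAM_PEAKS)
    n = config.n_pairs
    purity = _draw_purities(rng, config)
    states = list(config.copy_state_probs.keys())
    probs = np.array([config.copy_state_probs[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    state_idx = rng.choice(len(states), size=n, p=probs)
    c_risk = np.array([states[i][0] for i in state_idx], dtype=float)
    c_neutral = np.array([states[i][1] for i in state_idx], dtype=float)

    dose_risk = purity * c_risk + (1 - purity)
    dose_neutral = purity * c_neutral + (1 - purity)
    noise = _lognormal_factors(rng, config.noise_cv, (n, 4))
    b = config.baseline_height
    amp = config.amplification_bias
    df = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "snp_id": snp_id,
        "risk_allele": risk_allele,
        "neutral_allele": neutral_allele,
        "normal_h_risk": b * amp * noise[:, 0],
        "normal_h_neutral": b * noise[:, 1],
        "tumor_h_risk": b * amp * dose_risk * noise[:, 2],
        "tumor_h_neutral": b * dose_neutral * noise[:, 3],
        "truth_purity": purity,
        "truth_copy_risk": c_risk.astype(int),
        "truth_copy_neutral": c_neutral.astype(int),
    })
    return df


def case_frequency(ctrl_freq: float, allelic_or: float) -> float:
    """Case allele frequency implied by a control frequency and allelic OR."""
    if not 0 < ctrl_freq < 1:
        # monomorphic with OR 1 passes through unchanged
        return ctrl_freq
    odds = allelic_or * ctrl_freq / (1 - ctrl_freq)
    return odds / (1 + odds)


def simulate_case_control_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Simulate Hardy-Weinberg case-control genotypes for every configured SNP.

    One row per sample x SNP: ``sample_id, group, snp_id, allele1, allele2``.
    Allele "A" is the allele whose control frequency is specified; "G" is the
    other allele.
    """
    config.validate()
    rng = config.rng(_STREAM_GENOTYPES)
    frames = []
    sample_ids = [f"CA{i + 1:05d}" for i in range(config.n_cases)] + [
        f"CO{i + 1:05d}" for i in range(config.n_controls)]
    groups = ["case"] * config.n_cases + ["control"] * config.n_controls
    for j, (freq, orv) in enumerate(config.snp_specs):
        snp_id = f"snp{j + 1}"
        p_case = case_frequency(freq, orv)
        p = np.concatenate([
            np.full(config.n_cases, p_case), np.full(config.n_controls, freq)])
        draws = rng.random((len(p), 2)) < p[:, None]
        alleles = np.where(draws, "A", "G")
        frames.append(pd.DataFrame({
            "sample_id": sample_ids,
            "group": groups,
            "snp_id": snp_id,
            "allele1": alleles[:, 0],
            "allele2": alleles[:, 1],
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class ScreenFixture:
    """A fully labelled synthetic substrate for the enhancer screen."""

    sequence: str
    chrom: str
    elements: list[EnhancerElement]
    sites: list[BindingSite]
    variants: list[Variant]
    truth: pd.DataFrame          # snp_id, stratum in {in_high, in_low, outside}
    exclude_id: str | None      # suggested previously-genotyped exclusion

    @property
    def sequences(self) -> dict[str, str]:
        return {self.chrom: self.sequence}


def _instantiate_pattern(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC[s])) for s in pattern.upper())


def simulate_screen_fixture(config: SimulationConfig) -> ScreenFixture:
    """Build a labelled screen fixture with planted sites and stratified variants.

    Layout: the sequence is divided into fixed-width slots; each in-site
    variant gets its own slot holding one enhancer element, one planted motif
    instance inside it, and the variant inside the motif footprint.  Elements
    of the ``in_high`` stratum score in [300, 450] (the first exactly at the
    300 cutoff), ``in_low`` elements in [150, 300).  ``outside`` variants are
    placed in high-scoring elements but outside any site footprint.  Variant
    alleles are the planted base plus, where the pattern symbol is not fully
    degenerate, a base outside the symbol's set — so the allele-disruption
    report has signal by construction.
    """
    config.validate()
    rng = config.rng(_STREAM_SCREEN)
    patterns = [p.upper() for p in config.screen_patterns]
    longest = max((len(p) for p in patterns), default=0)
    slot = max(120, longest + 60)
    n_slots = (config.n_variants_in_high + config.n_variants_in_low
               + config.n_variants_outside)
    length = max(slot * n_slots + slot, 2 * slot)
    if longest > length:
        raise ConfigurationError("screen_patterns: pattern longer than sequence")
    seq = list(rng.choice(list("ACGT"), size=length))

    elements: list[EnhancerElement] = []
    sites: list[BindingSite] = []
    variants: list[Variant] = []
    truth_rows: list[dict] = []
    chrom = config.screen_chrom

    strata = (["in_high"] * config.n_variants_in_high
              + ["in_low"] * config.n_variants_in_low
              + ["outside"] * config.n_variants_outside)
    n_high_seen = 0
    for k, stratum in enumerate(strata):
        base0 = k * slot                      # 0-based slot origin
        pattern = patterns[k % len(patterns)]
        elem_start = base0 + 11               # 1-based: base0+11 .. base0+slot-10
        elem_end = base0 + slot - 10
        if stratum == "in_low":
            score = float(rng.uniform(150.0, 299.9))
        else:
            n_high_seen += 1
            # pin the first high element exactly at the inclusive cutoff
            score = 300.0 if n_high_seen == 1 else float(rng.uniform(300.0, 450.0))
        interval = GenomicInterval(chrom, elem_start, elem_end, label=f"elem{k + 1}")
        elements.append(EnhancerElement(interval=interval, score=score))

        site_start = base0 + 41               # 1-based
        site_end = site_start + len(pattern) - 1
        instance = _instantiate_pattern(rng, pattern)
        seq[site_start - 1:site_end] = list(instance)
        site = BindingSite(
            interval=GenomicInterval(chrom, site_start, site_end, label=f"site{k + 1}"),
            tf_name=f"TF{(k % len(patterns)) + 1}",
            pattern=pattern,
            strand="+",
        )
        sites.append(site)

        snp_id = f"sim_{stratum}_{k + 1:02d}"
        if stratum == "outside":
            pos = site_end + 10               # inside the element, outside the site
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
        else:
            # prefer a degenerate pattern position so one allele can stay a match
            degenerate = [i for i, s in enumerate(pattern) if len(IUPAC[s]) > 1]
            offset = degenerate[0] if degenerate else 0
            pos = site_start + offset
            ref = seq[pos - 1]
            outside_set = [b for b in "ACGT" if b not in IUPAC[pattern[offset]]]
            alt = rng.choice(outside_set) if outside_set else rng.choice(
                [b for b in "ACGT" if b != ref])
        variants.append(Variant(chrom=chrom, pos=int(pos), snp_id=snp_id,
                                allele_a=str(ref), allele_b=str(alt)))
        truth_rows.append({"snp_id": snp_id, "stratum": stratum,
                           "element_score": score, "pattern": pattern})

    exclude_id = next((v.snp_id for v in variants
                       if v.snp_id.startswith("sim_in_high")), None)
    return ScreenFixture(
        sequence="".join(seq),
        chrom=chrom,
        elements=elements,
        sites=sites,
        variants=variants,
        truth=pd.DataFrame(truth_rows),
        exclude_id=exclude_id,
    )
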