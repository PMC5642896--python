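"""Seeded synthetic cohort generator for the NAT2 / INH-DILI analysis.

The generator emulates a retrospective multi-ethnic case-control study of
isoniazid-induced liver injury: per ethnic stratum it draws two NAT2
haplotypes per person from a stratum-specific haplotype distribution,
derives the latent acetylator class (RA/IA/SA) from the implied panel
dosages, sets the tag SNP rs1495741 to the class-concordant genotype with a
configurable concordance probability, adds unlinked background SNPs with
stratum-perturbed allele frequencies in Hardy-Weinberg proportions, and
assigns disease status from a logistic model in slow-acetylator status and
female sex.  Case/control totals per stratum are enforced exactly, as in a
retrospective design with fixed margins: statuses are drawn by Bernoulli
sampling over a candidate pool and exactly the configured number of cases
and controls is then subsampled uniformly from each status class, which
preserves the status-conditional genotype distribution.

Haplotype frequencies, not per-SNP frequencies, are the generative unit
because acetylator status is a diplotype property.  The packaged default
frequency tables are synthetic stand-ins calibrated so that control-group
marginal minor-allele frequencies land near the values observed in the
Singaporean study population this generator emulates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .nat2 import PANEL_4SNP, TAG_SNP, phenotype_from_panel_dosages
from .types import MISSING, GenotypeMatrix, SampleRecord, VariantRecord

# ---------------------------------------------------------------------------
# NAT2 locus layout (chromosome 8; GRCh37-era coordinates, informative only)
# ---------------------------------------------------------------------------

#: The seven common NAT2 coding SNPs, in genomic order.
NAT2_SNPS: tuple[str, ...] = (
    "rs1801279",   # 191G>A
    "rs1041983",   # 282C>T (synonymous)
    "rs1801280",   # 341T>C
    "rs1799929",   # 481C>T (synonymous)
    "rs1799930",   # 590G>A
    "rs1208",      # 803A>G
    "rs1799931",   # 857G>A
)

_NAT2_VARIANTS: tuple[VariantRecord, ...] = (
    VariantRecord("rs1801279", "8", 18257854, "A", "G", gene="NAT2"),
    VariantRecord("rs1041983", "8", 18257945, "T", "C", gene="NAT2"),
    VariantRecord("rs1801280", "8", 18258004, "C", "T", gene="NAT2"),
    VariantRecord("rs1799929", "8", 18258144, "T", "C", gene="NAT2"),
    VariantRecord("rs1799930", "8", 18258253, "A", "G", gene="NAT2"),
    VariantRecord("rs1208", "8", 18258466, "G", "A", gene="NAT2"),
    VariantRecord("rs1799931", "8", 18258520, "A", "G", gene="NAT2"),
)

#: Tag SNP 14.5 kb 3' of NAT2.  Counted allele G; dosage 0 is the AA class
#: that proxies the slow-acetylator phenotype.
_TAG_VARIANT = VariantRecord(TAG_SNP, "8", 18272881, "G", "A", gene="NAT2 (3' tag)")

#: Named NAT2 haplotypes over the seven coding SNPs (variant-allele pattern),
#: with their enzymatic class.  Slow haplotypes each carry exactly one panel
#: variant, so the diplotype rules classify SA == two slow haplotypes.
HAPLOTYPES: dict[str, tuple[int, ...]] = {
    "NAT2*4":   (0, 0, 0, 0, 0, 0, 0),   # reference, rapid
    "NAT2*13A": (0, 1, 0, 0, 0, 0, 0),   # rapid (synonymous only)
    "NAT2*5A":  (0, 0, 1, 0, 0, 0, 0),   # slow
    "NAT2*5B":  (0, 0, 1, 1, 0, 1, 0),   # slow
    "NAT2*6A":  (0, 1, 0, 0, 1, 0, 0),   # slow
    "NAT2*7B":  (0, 1, 0, 0, 0, 0, 1),   # slow
    "NAT2*14A": (1, 0, 0, 0, 0, 0, 0),   # slow, rare outside Africa
}

#: Conditional split of the tag genotype among non-AA classes (AG vs GG),
#: the Hardy-Weinberg proportions 2pq : q^2 at a G frequency of 0.55.
_TAG_NON_AA_SPLIT = (0.62, 0.38)


@dataclass(frozen=True)
class StratumConfig:
    """One ethnic stratum: sample quotas and generative frequencies."""

    label: str
    n_cases: int
    n_controls: int
    haplotype_freqs: dict[str, float]
    female_frac: float = 0.34
    background_divergence: float = 0.35

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("stratum sample counts must be >= 0")
        unknown = set(self.haplotype_freqs) - set(HAPLOTYPES)
        if unknown:
            raise ValueError(f"unknown haplotypes: {sorted(unknown)}")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"haplotype frequencies for {self.label!r} sum to {total}, not 1"
            )
        if any(f < 0 for f in self.haplotype_freqs.values()):
            raise ValueError("haplotype frequencies must be non-negative")
        if not 0.0 <= self.female_frac <= 1.0:
            raise ValueError("female_frac must be in [0,1]")


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration.

    Defaults reproduce the emulated study's scale: a 24-case / 79-control
    cohort across four self-reported ethnic strata, ~1/3 slow acetylators,
    a slow-acetylator log-odds ratio of ln(10) for DILI, female excess among
    cases, and 98% tag-SNP/phenotype concordance.
    """

    strata: tuple[StratumConfig, ...]
    tag_concordance: float = 0.98
    n_background_snps: int = 300
    beta0: float = -4.6
    beta_sa: float = log(10.0)
    beta_female: float = 1.59
    grade_probs: dict[int, float] = field(
        default_factory=lambda: {2: 10 / 24, 3: 13 / 24, 4: 1 / 24}
    )
    grade_genotype_trend: float = 0.0
    missing_rate: float = 0.0
    seed: int = 2017

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum is required")
        if not 0.0 <= self.tag_concordance <= 1.0:
            raise ValueError("tag_concordance must be in [0,1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if set(self.grade_probs) - {2, 3, 4}:
            raise ValueError("grades must be within {2,3,4}")
        if abs(sum(self.grade_probs.values()) - 1.0) > 1e-9:
            raise ValueError("grade probabilities must sum to 1")
        if self.n_background_snps < 0:
            raise ValueError("n_background_snps must be >= 0")

    @property
    def n_cases(self) -> int:
        return sum(s.n_cases for s in self.strata)

    @property
    def n_controls(self) -> int:
        return sum(s.n_controls for s in self.strata)


def default_config(**overrides) -> SimConfig:
    """Packaged default configuration at the emulated study's scale.

    The base haplotype table is calibrated to control-group marginal MAFs of
    roughly 0.37 (rs1041983), 0.22 (rs1799930), 0.14 (rs1799931), 0.095
    (rs1801280) and 0.076 (rs1799929); the Indian stratum shifts mass toward
    NAT2*5B, as seen in South Asian populations.  Keyword overrides replace
    top-level :class:`SimConfig` fields.
    """
    base = {
        "NAT2*4": 0.538,
        "NAT2*13A": 0.006,
        "NAT2*5A": 0.019,
        "NAT2*5B": 0.076,
        "NAT2*6A": 0.222,
        "NAT2*7B": 0.139,
    }
    indian = {
        "NAT2*4": 0.45,
        "NAT2*13A": 0.01,
        "NAT2*5A": 0.02,
        "NAT2*5B": 0.30,
        "NAT2*6A": 0.17,
        "NAT2*7B": 0.05,
    }
    strata = (
        StratumConfig("Chinese", 12, 57, dict(base), background_divergence=0.25),
        StratumConfig("Malay", 5, 10, dict(base), background_divergence=0.35),
        StratumConfig("Indian", 1, 7, dict(indian), background_divergence=0.9),
        StratumConfig("Others", 6, 5, dict(base), background_divergence=0.45),
    )
    return SimConfig(strata=strata, **overrides)


# ---------------------------------------------------------------------------
# Latent truth
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Per-sample latent state plus the per-stratum true allele frequencies."""

    stratum: np.ndarray            # str per sample
    sex: np.ndarray                # 'M'/'F'
    haplotypes: np.ndarray         # (n, 2) haplotype names
    acetylator: np.ndarray         # 'RA'/'IA'/'SA'
    sa: np.ndarray                 # bool
    tag_concordant: np.ndarray     # bool: tag class agrees with latent class
    background_freqs: pd.DataFrame  # stratum x background SNP true frequency

    @property
    def n(self) -> int:
        return len(self.stratum)


@dataclass
class SimulatedCohort:
    """A generated cohort: genotypes, sample sheet, and latent truth."""

    genotypes: GenotypeMatrix
    samples: list[SampleRecord]
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Generation internals
# ---------------------------------------------------------------------------


def _background_freqs(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-stratum background allele frequencies.

    Base frequencies are Uniform(0.05, 0.5); each stratum perturbs them on
    the logit scale by N(0, divergence^2), an F_ST-like divergence.
    """
    m = config.n_background_snps
    base = rng.uniform(0.05, 0.5, size=m)
    logit = np.log(base / (1 - base))
    rows = {}
    for st in config.strata:
        shift = rng.normal(0.0, st.background_divergence, size=m)
        f = 1.0 / (1.0 + np.exp(-(logit + shift)))
        rows[st.label] = f
    cols = [f"bg{j + 1:04d}" for j in range(m)]
    return pd.DataFrame(rows, index=cols).T


def _draw_latent(
    st: StratumConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw n individuals' haplotype pairs, sex, class and SA flag."""
    names = sorted(st.haplotype_freqs)
    probs = np.array([st.haplotype_freqs[h] for h in names])
    idx = rng.choice(len(names), size=(n, 2), p=probs)
    haps = np.array(names, dtype=object)[idx]
    pat = np.array([HAPLOTYPES[h] for h in names], dtype=np.int16)
    dosage7 = pat[idx[:, 0]] + pat[idx[:, 1]]
    panel_cols = [NAT2_SNPS.index(s) for s in PANEL_4SNP]
    classes = np.array(
        [phenotype_from_panel_dosages(row[panel_cols]) for row in dosage7],
        dtype=object,
    )
    sex = np.where(rng.random(n) < st.female_frac, "F", "M")
    return haps, sex, classes, classes == "SA"


def _nat2_dosages(haps: np.ndarray) -> np.ndarray:
    """(n, 7) variant-allele dosages from haplotype-name pairs."""
    pat = np.array([HAPLOTYPES[h] for h in haps.ravel()], dtype=np.int16)
    pat = pat.reshape(len(haps), 2, len(NAT2_SNPS))
    return pat.sum(axis=1)


def _tag_dosages(
    sa: np.ndarray, concordance: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Tag-SNP G dosages (0 = AA class) and per-sample concordance flags.

    The tag is modelled as a direct class-flip: with probability
    ``concordance`` the tag class matches the latent acetylator class
    (AA for SA, AG/GG for non-SA); otherwise it takes a discordant class.
    """
    n = len(sa)
    concordant = rng.random(n) < concordance
    ag_vs_gg = rng.random(n) < _TAG_NON_AA_SPLIT[0]
    non_aa = np.where(ag_vs_gg, 1, 2)
    want_aa = np.where(concordant, sa, ~sa)
    dos = np.where(want_aa, 0, non_aa)
    return dos.astype(np.int16), concordant


def simulate_genotypes(
    config: SimConfig,
    n_per_stratum: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw an unconditional sample of genotypes plus latent truth.

    By default each stratum contributes ``n_cases + n_controls`` samples;
    ``n_per_stratum`` overrides the per-stratum draw size (used internally
    for the candidate pools of :func:`generate_cohort`).  Missingness at
    ``config.missing_rate`` is applied independently per call.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bg = _background_freqs(config, rng)
    per_stratum: list[tuple[StratumConfig, int]] = []
    for st in config.strata:
        n = (
            n_per_stratum[st.label]
            if n_per_stratum is not None
            else st.n_cases + st.n_controls
        )
        per_stratum.append((st, n))

    blocks, strat, sexes, haps_all, classes_all = [], [], [], [], []
    conc_all = []
    for st, n in per_stratum:
        haps, sex, classes, sa = _draw_latent(st, n, rng)
        nat2 = _nat2_dosages(haps)
        tag, conc = _tag_dosages(sa, config.tag_concordance, rng)
        f = bg.loc[st.label].to_numpy()
        bg_calls = rng.binomial(2, f[None, :], size=(n, len(f))).astype(np.int16)
        blocks.append(np.column_stack([nat2, tag[:, None], bg_calls]))
        strat.extend([st.label] * n)
        sexes.append(sex)
        haps_all.append(haps)
        classes_all.append(classes)
        conc_all.append(conc)

    calls = np.vstack(blocks) if blocks else np.empty((0, 0), dtype=np.int16)
    if config.missing_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    n_total = calls.shape[0]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    variants = list(_NAT2_VARIANTS) + [_TAG_VARIANT]
    alleles = ("A", "C", "G", "T")
    for j, vid in enumerate(bg.columns):
        a, b = rng.choice(4, size=2, replace=False)
        variants.append(
            VariantRecord(vid, str(1 + j % 22), 10_000 + 100 * j, alleles[a], alleles[b])
        )
    matrix = GenotypeMatrix(sample_ids, variants, calls)
    truth = SimTruth(
        stratum=np.array(strat, dtype=object),
        sex=np.concatenate(sexes) if sexes else np.array([], dtype=object),
        haplotypes=np.vstack(haps_all) if haps_all else np.empty((0, 2), dtype=object),
        acetylator=np.concatenate(classes_all)
        if classes_all
        else np.array([], dtype=object),
        sa=np.concatenate(classes_all) == "SA"
        if classes_all
        else np.array([], dtype=bool),
        tag_concordant=np.concatenate(conc_all)
        if conc_all
        else np.array([], dtype=bool),
        background_freqs=bg,
    )
    return matrix, truth


def case_probability(truth: SimTruth, config: SimConfig) -> np.ndarray:
    """Per-sample DILI probability under the logistic disease model."""
    lin = (
        config.beta0
        + config.beta_sa * truth.sa.astype(float)
        + config.beta_female * (truth.sex == "F").astype(float)
    )
    return 1.0 / (1.0 + np.exp(-lin))


def assign_phenotypes(
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw case status over a candidate pool and enforce stratum quotas.

    Statuses are Bernoulli draws from the logistic model; exactly
    ``n_cases`` cases and ``n_controls`` controls per stratum are then
    subsampled uniformly from the drawn status classes (retrospective
    fixed-margin sampling).  Returns ``(selected indices, is_case flags)``
    ordered cases-first within stratum.

    Raises ``RuntimeError`` when the pool does not contain enough samples of
    either status in some stratum (the caller should enlarge the pool).
    """
    p = case_probability(truth, config)
    is_case = rng.random(truth.n) < p
    sel_idx: list[int] = []
    sel_case: list[bool] = []
    for st in config.strata:
        in_st = truth.stratum == st.label
        cases = np.flatnonzero(in_st & is_case)
        controls = np.flatnonzero(in_st & ~is_case)
        if len(cases) < st.n_cases or len(controls) < st.n_controls:
            raise RuntimeError(
                f"stratum {st.label!r}: pool yielded {len(cases)} cases / "
                f"{len(controls)} controls, need {st.n_cases}/{st.n_controls}"
            )
        take_cases = rng.choice(cases, size=st.n_cases, replace=False)
        take_controls = rng.choice(controls, size=st.n_controls, replace=False)
        sel_idx.extend(take_cases.tolist())
        sel_case.extend([True] * st.n_cases)
        sel_idx.extend(take_controls.tolist())
        sel_case.extend([False] * st.n_controls)
    return np.array(sel_idx, dtype=int), np.array(sel_case, dtype=bool)


def _assign_grades(
    n_cases: int,
    sa_flags: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw DILI grades for cases.

    With ``grade_genotype_trend`` t > 0, the grade distribution among SA
    cases is tilted toward higher grades by exp(t * rank) reweighting;
    by default grade is independent of genotype.
    """
    grades = np.array(sorted(config.grade_probs))
    base = np.array([config.grade_probs[g] for g in grades])
    out = np.empty(n_cases, dtype=int)
    for i in range(n_cases):
        w = base.copy()
        if config.grade_genotype_trend != 0 and sa_flags[i]:
            w = w * np.exp(config.grade_genotype_trend * np.arange(len(grades)))
            w = w / w.sum()
        out[i] = rng.choice(grades, p=w)
    return out


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a complete cohort with exact per-stratum case/control counts.

    Deterministic for a fixed ``config.seed``.  A candidate pool several
    times the requested size is drawn per stratum and doubled until the
    Bernoulli status draws cover both quotas.
    """
    rng = np.random.default_rng(config.seed)
    factor = 16
    for _ in range(12):
        pool_sizes = {
            st.label: max(factor * (st.n_cases + st.n_controls), 50)
            for st in config.strata
        }
        matrix, truth = simulate_genotypes(config, n_per_stratum=pool_sizes, rng=rng)
        try:
            idx, is_case = assign_phenotypes(truth, config, rng)
        except RuntimeError:
            factor *= 2
            continue
        break
    else:
        raise RuntimeError(
            "could not reach the configured case/control quotas; "
            "check beta0 against the requested counts"
        )

    sub = matrix.subset(samples=[matrix.sample_ids[i] for i in idx])
    sub.sample_ids = [f"S{i + 1:04d}" for i in range(len(idx))]
    sa_cases = truth.sa[idx[is_case]]
    grades_cases = _assign_grades(int(is_case.sum()), sa_cases, config, rng)
    ages = np.clip(rng.normal(51.1, 14.5, size=len(idx)), 21, 95)

    samples: list[SampleRecord] = []
    gi = 0
    for k, i in enumerate(idx):
        case = bool(is_case[k])
        grade = int(grades_cases[gi]) if case else 0
        if case:
            gi += 1
        samples.append(
            SampleRecord(
                sample_id=sub.sample_ids[k],
                sex=str(truth.sex[i]),
                ethnicity=str(truth.stratum[i]),
                status="case" if case else "control",
                grade=grade,
                age=float(round(ages[k], 1)),
            )
        )
    sel_truth = SimTruth(
        stratum=truth.stratum[idx],
        sex=truth.sex[idx],
        haplotypes=truth.haplotypes[idx],
        acetylator=truth.acetylator[idx],
        sa=truth.sa[idx],
        tag_concordant=truth.tag_concordant[idx],
        background_freqs=truth.background_freqs,
    )
    return SimulatedCohort(genotypes=sub, samples=samples, truth=sel_truth, config=config)
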