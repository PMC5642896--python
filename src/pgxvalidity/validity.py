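"""Clinical-validity calculus for a binary genetic test.

From a 2x2 exposure-by-outcome table the module derives sensitivity and
specificity (kept as exact fractions of integer counts; rounding happens
only in the report formatter), projects positive and negative predictive
values to an assumed population prevalence via Bayes' theorem, and derives
the population attributable fraction (PAF), the number needed to test
(NNT), and Youden's J.

Two PAF estimators are provided and co-reported:

* ``incidence`` — (IP_t - IP_o) / IP_t with IP_t the population incidence
  (the assumed prevalence) and IP_o the incidence among the unexposed
  (1 - NPV under the Bayes construction);
* ``case_based`` — p_c * (OR - 1) / OR with p_c the exposed fraction among
  cases and OR the exposure odds ratio.

NNT is the reciprocal of the risk difference between exposed and unexposed
(risk_exposed - risk_unexposed = PPV - (1 - NPV)); when the difference is
not positive the NNT is undefined and flagged rather than reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

from .types import ContingencyTable2x2, SampleRecord


def exposure_table(
    exposure: dict[str, bool],
    samples: list[SampleRecord],
    exposure_label: str = "SA",
) -> ContingencyTable2x2:
    """Cross-tabulate an exposure flag against case status.

    ``exposure`` maps sample_id -> bool; samples whose flag is None or
    absent are excluded (e.g. refused acetylator calls).
    """
    a = b = c = d = 0
    n_eval = 0
    for s in samples:
        e = exposure.get(s.sample_id)
        if e is None:
            continue
        n_eval += 1
        if e and s.is_case:
            a += 1
        elif e:
            b += 1
        elif s.is_case:
            c += 1
        else:
            d += 1
    if n_eval == 0:
        raise ValueError("no evaluable samples")
    table = ContingencyTable2x2(a, b, c, d, exposure_label=exposure_label)
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("need at least one case and one control")
    return table


def sens_spec(table: ContingencyTable2x2) -> tuple[Fraction, Fraction]:
    """Sensitivity and specificity as exact fractions of the table counts."""
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("case and control margins must be positive")
    return (
        Fraction(table.a, table.n_cases),
        Fraction(table.d, table.n_controls),
    )


def bayes_predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV at an assumed prevalence via Bayes' theorem."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    se, sp, pr = float(sensitivity), float(specificity), float(prevalence)
    pos = se * pr + (1 - sp) * (1 - pr)
    neg = (1 - se) * pr + sp * (1 - pr)
    ppv = se * pr / pos if pos > 0 else np.nan
    npv = sp * (1 - pr) / neg if neg > 0 else np.nan
    return ppv, npv


def prevalence_sweep(
    sensitivity: float, specificity: float, grid
) -> pd.DataFrame:
    """PPV/NPV at each prevalence on the grid (sensitivity analysis)."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty prevalence grid")
    rows = []
    for prev in grid:
        ppv, npv = bayes_predictive_values(sensitivity, specificity, prev)
        rows.append({"prevalence": float(prev), "ppv": ppv, "npv": npv})
    return pd.DataFrame(rows)


def paf(method: str, **kwargs) -> float:
    """Population attributable fraction.

    ``paf("incidence", ip_total=..., ip_unexposed=...)`` or
    ``paf("case_based", exposed_case_fraction=..., odds_ratio=...)``.
    """
    if method == "incidence":
        ip_t = float(kwargs["ip_total"])
        ip_o = float(kwargs["ip_unexposed"])
        if ip_t <= 0:
            raise ValueError("total incidence must be positive")
        return (ip_t - ip_o) / ip_t
    if method == "case_based":
        pc = float(kwargs["exposed_case_fraction"])
        or_ = float(kwargs["odds_ratio"])
        if or_ <= 0:
            raise ValueError("odds ratio must be positive")
        return pc * (or_ - 1.0) / or_
    raise ValueError(f"unknown PAF method {method!r}")


@dataclass(frozen=True)
class NntResult:
    value: float | None
    arr: float
    defined: bool


def nnt(risk_exposed: float, risk_unexposed: float) -> NntResult:
    """Number needed to test: 1 / (risk_exposed - risk_unexposed)."""
    for name, v in (("risk_exposed", risk_exposed), ("risk_unexposed", risk_unexposed)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    arr = float(risk_exposed) - float(risk_unexposed)
    if arr <= 0:
        return NntResult(None, arr, defined=False)
    return NntResult(1.0 / arr, arr, defined=True)


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    return float(sensitivity) + float(specificity) - 1.0


@dataclass
class ValidityMeasures:
    """All clinical-validity quantities for one exposure definition."""

    exposure_label: str
    table: ContingencyTable2x2
    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float
    risk_exposed: float      # = PPV under the Bayes construction
    risk_unexposed: float    # = 1 - NPV
    ip_total: float          # population incidence = prevalence
    paf_incidence: float
    paf_case_based: float | None
    paf_method: str
    arr: float
    nnt: float | None
    nnt_defined: bool
    youden_j: float

    @property
    def paf_value(self) -> float:
        if self.paf_method == "case_based" and self.paf_case_based is not None:
            return self.paf_case_based
        return self.paf_incidence


def clinical_validity(
    table: ContingencyTable2x2,
    prevalence: float = 0.10,
    odds_ratio: float | None = None,
    paf_method: str = "case_based",
) -> ValidityMeasures:
    """Full validity calculus for one exposure table at one prevalence.

    ``odds_ratio`` feeds the case-based PAF estimator; when omitted the
    table's cross-product OR is used, and when that is degenerate only the
    incidence-formula PAF is reported.
    """
    se, sp = sens_spec(table)
    ppv, npv = bayes_predictive_values(float(se), float(sp), prevalence)
    risk_exp, risk_unexp = ppv, 1.0 - npv
    paf_inc = paf("incidence", ip_total=prevalence, ip_unexposed=risk_unexp) \
        if prevalence > 0 else np.nan
    or_ = odds_ratio
    if or_ is None:
        denom = table.b * table.c
        or_ = (table.a * table.d) / denom if denom else None
    pc = table.a / table.n_cases
    paf_cb = paf("case_based", exposed_case_fraction=pc, odds_ratio=or_) \
        if or_ and np.isfinite(or_) and or_ > 0 else None
    res_nnt = nnt(risk_exp, risk_unexp)
    return ValidityMeasures(
        exposure_label=table.exposure_label,
        table=table,
        sensitivity=float(se),
        specificity=float(sp),
        prevalence=prevalence,
        ppv=ppv,
        npv=npv,
        risk_exposed=risk_exp,
        risk_unexposed=risk_unexp,
        ip_total=prevalence,
        paf_incidence=paf_inc,
        paf_case_based=paf_cb,
        paf_method=paf_method if paf_cb is not None else "incidence",
        arr=res_nnt.arr,
        nnt=res_nnt.value,
        nnt_defined=res_nnt.defined,
        youden_j=youden(float(se), float(sp)),
    )


def validity_report(
    exposures: dict[str, dict[str, bool]],
    samples: list[SampleRecord],
    prevalence: float = 0.10,
    sweep_grid=None,
    odds_ratios: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One report row per exposure definition x prevalence.

    ``exposures`` maps an exposure label to a sample_id -> bool flag map;
    ``odds_ratios`` optionally supplies covariate-adjusted ORs for the
    case-based PAF (falling back to each table's cross-product OR).
    """
    prevalences = [prevalence] + [p for p in (sweep_grid or []) if p != prevalence]
    rows = []
    for label, flags in exposures.items():
        table = exposure_table(flags, samples, exposure_label=label)
        or_ = (odds_ratios or {}).get(label)
        for prev in prevalences:
            m = clinical_validity(table, prev, odds_ratio=or_)
            rows.append(
                {
                    "exposure": label,
                    "prevalence": prev,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv,
                    "npv": m.npv,
                    "paf_incidence": m.paf_incidence,
                    "paf_case_based": m.paf_case_based,
                    "arr": m.arr,
                    "nnt": m.nnt,
                    "youden_j": m.youden_j,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report-time rounding (stored values stay full precision)
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, the convention of printed clinical tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(x: float, ndigits: int = 0) -> float:
    """Proportion -> percentage with half-up rounding."""
    return round_half_up(100.0 * x, ndigits)
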