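"""NAT2 acetylator phenotype inference and tag-SNP classification.

Acetylator status is inferred from a panel of acetylation-slowing coding
variants with a simple diplotype rule set: rapid acetylators (RA) carry no
variant allele at any panel SNP, intermediate acetylators (IA) are
heterozygous at exactly one, and slow acetylators (SA) are heterozygous at
two or more panel SNPs or homozygous variant at any one.  The default panel
is the 4-SNP set rs1801280, rs1799930, rs1799931, rs1801279; rs1801279 is
essentially monomorphic in East/Southeast and South Asian populations and a
missing call there is imputed as homozygous reference (flagged), while a
missing call at any other panel SNP refuses the call under the default
policy.

The tag SNP rs1495741 lies 3' of NAT2; its AA genotype class proxies the SA
phenotype and AG/GG proxy non-SA.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, SampleRecord, samples_to_frame

#: Default acetylator inference panel (slow-allele dosage orientation).
PANEL_4SNP: tuple[str, ...] = ("rs1801280", "rs1799930", "rs1799931", "rs1801279")

#: Panel SNPs whose missing calls may be imputed as homozygous reference.
IMPUTABLE_REFERENCE: frozenset[str] = frozenset({"rs1801279"})

#: Default tag SNP used to proxy acetylator status.
TAG_SNP = "rs1495741"

PHENOTYPES = ("RA", "IA", "SA")


def phenotype_from_panel_dosages(dosages) -> str:
    """Apply the diplotype rule set to a complete panel dosage vector.

    Parameters
    ----------
    dosages : sequence of int
        Slow-allele dosages in {0, 1, 2} for each panel SNP, no missing.
    """
    d = np.asarray(dosages, dtype=int)
    if d.size == 0:
        raise ValueError("empty panel dosage vector")
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("panel dosages must be complete and in {0,1,2}")
    n_het = int((d == 1).sum())
    any_hom_var = bool((d == 2).any())
    if any_hom_var or n_het >= 2:
        return "SA"
    if n_het == 1:
        return "IA"
    return "RA"


@dataclass(frozen=True)
class AcetylatorCall:
    """Inferred acetylator phenotype for one sample, with evidence."""

    sample_id: str
    phenotype: str | None           # RA / IA / SA, or None when refused
    dosages: dict                   # panel SNP -> dosage used (after imputation)
    imputed_snps: frozenset         # panel SNPs defaulted to dosage 0
    refused_reason: str | None = None

    @property
    def exposure(self) -> bool | None:
        """SA-vs-rest exposure flag (None when the call was refused)."""
        return None if self.phenotype is None else self.phenotype == "SA"


def infer_acetylator(
    matrix: GenotypeMatrix,
    panel: tuple[str, ...] = PANEL_4SNP,
    missing_policy: str = "default",
) -> list[AcetylatorCall]:
    """Infer acetylator phenotype for every sample in the matrix.

    ``missing_policy``:

    * ``"default"`` — impute a missing call as homozygous reference (flagged)
      only for SNPs in :data:`IMPUTABLE_REFERENCE`; refuse the call when any
      other panel SNP is missing.
    * ``"strict"`` — same, i.e. any non-imputable missing call refuses.
    * ``"impute_all"`` — impute every missing panel SNP as reference (flagged).
    """
    if missing_policy not in ("default", "strict", "impute_all"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    cols = {snp: matrix.dosages(snp) for snp in panel}
    calls: list[AcetylatorCall] = []
    for i, sid in enumerate(matrix.sample_ids):
        dosages: dict[str, int] = {}
        imputed: set[str] = set()
        refused = None
        for snp in panel:
            v = cols[snp][i]
            if np.isnan(v):
                if snp in IMPUTABLE_REFERENCE or missing_policy == "impute_all":
                    dosages[snp] = 0
                    imputed.add(snp)
                else:
                    refused = f"missing genotype at {snp}"
                    break
            else:
                dosages[snp] = int(v)
        if refused is not None:
            calls.append(
                AcetylatorCall(sid, None, {}, frozenset(), refused_reason=refused)
            )
        else:
            pheno = phenotype_from_panel_dosages([dosages[s] for s in panel])
            calls.append(AcetylatorCall(sid, pheno, dosages, frozenset(imputed)))
    return calls


def calls_to_frame(calls: list[AcetylatorCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "phenotype": [c.phenotype for c in calls],
            "exposure": [c.exposure for c in calls],
            "imputed_snps": [",".join(sorted(c.imputed_snps)) for c in calls],
            "refused_reason": [c.refused_reason for c in calls],
        }
    )


@dataclass(frozen=True)
class TagClass:
    """Tag-SNP genotype class for one sample and its predicted phenotype."""

    sample_id: str
    genotype_class: str          # 'AA', 'AG', 'GG' or 'missing'
    predicted_sa: bool | None    # None when missing

def classify_by_tag(matrix: GenotypeMatrix, tag: str = TAG_SNP) -> list[TagClass]:
    """Classify samples by tag-SNP genotype; AA predicts SA, AG/GG non-SA.

    The genotype string is rebuilt from the dosage and the variant's
    counted/other allele orientation, so the AA class is recognised whether
    the counted allele is A or G.
    """
    var = matrix.variant(tag)
    dos = matrix.dosages(tag)
    out: list[TagClass] = []
    for sid, d in zip(matrix.sample_ids, dos):
        if np.isnan(d):
            out.append(TagClass(sid, "missing", None))
            continue
        d = int(d)
        alleles = [var.counted_allele] * d + [var.other_allele] * (2 - d)
        cls = "".join(sorted(alleles))
        out.append(TagClass(sid, cls, cls == "AA"))
    return out


def tags_to_frame(tags: list[TagClass]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in tags],
            "tag_class": [t.genotype_class for t in tags],
            "predicted_sa": [t.predicted_sa for t in tags],
        }
    )


def tag_concordance(
    calls: list[AcetylatorCall], tags: list[TagClass]
) -> tuple[float, pd.DataFrame]:
    """Fraction of samples where the tag AA class agrees with the SA call.

    Samples with a missing tag genotype or a refused acetylator call are
    excluded.  Returns (concordant fraction, 2x2 cross-table with SA status
    in rows and tag class in columns).
    """
    call_by_id = {c.sample_id: c for c in calls}
    tag_by_id = {t.sample_id: t for t in tags}
    shared = [s for s in call_by_id if s in tag_by_id]
    if not shared:
        raise ValueError("no shared sample ids between calls and tags")
    rows = []
    for sid in shared:
        c, t = call_by_id[sid], tag_by_id[sid]
        if c.phenotype is None or t.predicted_sa is None:
            continue
        rows.append((c.exposure, t.predicted_sa))
    if not rows:
        raise ValueError("no evaluable samples (all missing or refused)")
    actual = np.array([r[0] for r in rows])
    predicted = np.array([r[1] for r in rows])
    table = pd.crosstab(
        pd.Series(np.where(actual, "SA", "non-SA"), name="acetylator"),
        pd.Series(np.where(predicted, "AA", "AG/GG"), name="tag"),
    ).reindex(index=["SA", "non-SA"], columns=["AA", "AG/GG"], fill_value=0)
    frac = float((actual == predicted).mean())
    return frac, table


def risk_allele_freq_by_grade(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    variant_id: str | None = None,
    exposure: dict[str, bool] | None = None,
    grades: tuple[int, ...] = (0, 2, 3, 4),
) -> pd.DataFrame:
    """Risk-allele frequency (or SA exposure fraction) by DILI grade.

    Exactly one of ``variant_id`` (counted-allele frequency among non-missing
    calls) or ``exposure`` (sample_id -> bool, fraction exposed) must be
    given.  Grades with no samples are omitted from the output, not reported
    as zero.
    """
    if (variant_id is None) == (exposure is None):
        raise ValueError("give exactly one of variant_id or exposure")
    frame = samples_to_frame(samples)
    bad = set(frame["grade"]) - set(grades)
    if bad:
        raise ValueError(f"grades outside the declared set: {sorted(bad)}")
    rows = []
    for g in grades:
        ids = frame.loc[frame["grade"] == g, "sample_id"].tolist()
        if not ids:
            continue
        if variant_id is not None:
            dos = matrix.subset(samples=ids).dosages(variant_id)
            n_called = int(np.sum(~np.isnan(dos)))
            freq = float(np.nansum(dos) / (2 * n_called)) if n_called else np.nan
            rows.append({"grade": g, "n": len(ids), "n_called": n_called, "freq": freq})
        else:
            flags = [exposure[s] for s in ids if exposure.get(s) is not None]
            freq = float(np.mean(flags)) if flags else np.nan
            rows.append({"grade": g, "n": len(ids), "n_called": len(flags), "freq": freq})
    return pd.DataFrame(rows)
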