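"""Sample- and variant-level genotype quality control and PCA.

The QC stage mirrors a standard array-genotyping workflow: samples and
variants are filtered on call rate, variants are tested for Hardy-Weinberg
equilibrium within a designated reference stratum (a single well-sampled
ethnic group, so population mixture does not masquerade as genotyping
error), duplicate or related samples are flagged by identity-by-state, and
outlying heterozygosity is flagged.  Population structure is summarised by
PCA on standardized dosages and the leading components are used downstream
as regression covariates.

Sex checks from raw array intensities are out of scope; a mismatch list
produced elsewhere can be injected via :func:`sex_mismatch_filter`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import MISSING, GenotypeMatrix, SampleRecord


@dataclass
class QcReport:
    """Accumulated QC evidence and removal decisions.

    Every removal carries exactly one primary reason; retained plus removed
    equals the input set at each step.
    """

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    sample_call_rate: pd.Series | None = None
    variant_call_rate: pd.Series | None = None
    hwe_p: pd.Series | None = None
    het_rate: pd.Series | None = None
    ibs: pd.DataFrame | None = None
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    flagged_het_samples: list[str] = field(default_factory=list)

    def removed_sample_ids(self) -> set[str]:
        return {s for s, _ in self.removed_samples}

    def removed_variant_ids(self) -> set[str]:
        return {v for v, _ in self.removed_variants}

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_samples, columns=["sample_id", "reason"])

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_variants, columns=["variant_id", "reason"])


def call_rate_filter(
    matrix: GenotypeMatrix,
    sample_threshold: float = 0.95,
    variant_threshold: float = 0.95,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples, then variants, whose call rate falls below threshold.

    Within a round samples are filtered first (their call rate judged on the
    currently retained variants), then variants on the retained samples; a
    call rate exactly at the threshold is retained.  Rounds repeat until
    nothing more is removed, so the filter is idempotent and every retained
    sample and variant meets its threshold on the final retained set.
    The reported call rates are those of the first round (the input matrix).
    """
    if not 0 < sample_threshold <= 1 or not 0 < variant_threshold <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise ValueError("empty genotype matrix")
    if report is None:
        report = QcReport()
    report.sample_call_rate = matrix.sample_call_rate()
    report.variant_call_rate = matrix.variant_call_rate()
    current = matrix
    while True:
        scr = current.sample_call_rate()
        keep_s = scr >= sample_threshold
        for sid in scr.index[~keep_s]:
            report.removed_samples.append((sid, "call_rate"))
        m1 = current.subset(samples=keep_s.to_numpy().tolist())
        vcr = m1.variant_call_rate()
        keep_v = vcr >= variant_threshold
        for vid in vcr.index[~keep_v]:
            report.removed_variants.append((vid, "call_rate"))
        m2 = m1.subset(variants=keep_v.to_numpy().tolist())
        if keep_s.all() and keep_v.all():
            return m2, report
        if m2.n_samples == 0 or m2.n_variants == 0:
            return m2, report
        current = m2


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditional on the sample size N and the minor-allele count, the number
    of heterozygotes h has probability

        P(h) = N! / (n_AA! (h)! n_aa!) * 2^h * r! (2N-r)! / (2N)!

    where r is the minor-allele count.  The two-sided p-value sums the
    probabilities of all attainable heterozygote counts whose probability
    does not exceed that of the observed count.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = sum(counts)
    if n == 0:
        raise ValueError("total genotype count must be positive")
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0  # monomorphic: a single attainable table
    # attainable heterozygote counts share the parity of the rare count
    hets = np.arange(rare % 2, rare + 1, 2)
    hets = hets[(rare - hets) % 2 == 0]
    hets = hets[hets <= 2 * n - rare]
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(np.flatnonzero(hets == n_het)[0])
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_filter(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    reference_stratum: str = "Chinese",
    alpha: float = 1e-6,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants deviating from HWE within the reference stratum."""
    if report is None:
        report = QcReport()
    ids = [s.sample_id for s in samples if s.ethnicity == reference_stratum]
    ids = [s for s in ids if s in set(matrix.sample_ids)]
    if len(ids) < 2:
        raise ValueError(
            f"reference stratum {reference_stratum!r} has fewer than 2 genotyped samples"
        )
    sub = matrix.subset(samples=ids)
    pvals = {}
    keep = []
    for vid in matrix.variant_ids:
        dos = sub.dosages(vid)
        dos = dos[~np.isnan(dos)]
        if dos.size == 0:
            pvals[vid] = np.nan
            keep.append(True)  # untestable in the stratum: retain
            continue
        p = hwe_exact_test(
            int((dos == 0).sum()), int((dos == 1).sum()), int((dos == 2).sum())
        )
        pvals[vid] = p
        ok = p >= alpha
        keep.append(ok)
        if not ok:
            report.removed_variants.append((vid, "hwe"))
    report.hwe_p = pd.Series(pvals, name="hwe_p")
    return matrix.subset(variants=keep), report


def pairwise_ibs(
    matrix: GenotypeMatrix,
    threshold: float = 0.9,
    report: QcReport | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Mean identity-by-state similarity for every sample pair.

    Per shared non-missing variant the contribution is (2 - |d_i - d_j|)/2;
    pairs with no shared calls get NaN and are reported as undefined rather
    than flagged.  Pairs at or above ``threshold`` are flagged.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for IBS")
    if report is None:
        report = QcReport()
    calls = matrix.calls.astype(float)
    calls[calls == MISSING] = np.nan
    rows = []
    n = matrix.n_samples
    for i in range(n):
        di = calls[i]
        for j in range(i + 1, n):
            dj = calls[j]
            ok = ~np.isnan(di) & ~np.isnan(dj)
            shared = int(ok.sum())
            if shared == 0:
                sim = np.nan
            else:
                sim = float(np.mean((2.0 - np.abs(di[ok] - dj[ok])) / 2.0))
            rows.append(
                {
                    "sample_i": matrix.sample_ids[i],
                    "sample_j": matrix.sample_ids[j],
                    "n_shared": shared,
                    "ibs": sim,
                }
            )
            if shared > 0 and sim >= threshold:
                report.flagged_pairs.append(
                    (matrix.sample_ids[i], matrix.sample_ids[j], sim)
                )
    table = pd.DataFrame(rows)
    report.ibs = table
    return table, report


def heterozygosity_check(
    matrix: GenotypeMatrix,
    sd_multiplier: float = 3.0,
    report: QcReport | None = None,
) -> tuple[pd.Series, QcReport]:
    """Flag samples whose heterozygous fraction is an outlier.

    The heterozygous fraction is computed over non-missing calls per sample;
    samples beyond mean +/- ``sd_multiplier`` * SD are flagged.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for a heterozygosity screen")
    if report is None:
        report = QcReport()
    called = matrix.calls != MISSING
    het = (matrix.calls == 1).sum(axis=1) / np.maximum(called.sum(axis=1), 1)
    rates = pd.Series(het, index=matrix.sample_ids, name="het_rate")
    mu, sd = float(rates.mean()), float(rates.std(ddof=1))
    if sd > 0:
        out = rates.index[np.abs(rates - mu) > sd_multiplier * sd]
        report.flagged_het_samples = list(out)
    report.het_rate = rates
    return rates, report


def sex_mismatch_filter(
    matrix: GenotypeMatrix,
    mismatched_ids: list[str],
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove samples flagged elsewhere as sex-discordant.

    Intensity-based sex inference is not reproducible from dosage data, so
    this stage accepts an externally produced mismatch list.
    """
    if report is None:
        report = QcReport()
    present = set(matrix.sample_ids)
    for sid in mismatched_ids:
        if sid in present:
            report.removed_samples.append((sid, "sex_mismatch"))
    keep = [s for s in matrix.sample_ids if s not in set(mismatched_ids)]
    return matrix.subset(samples=keep), report


@dataclass
class PcaResult:
    """Leading principal components of the standardized dosage matrix."""

    eigenvalues: np.ndarray          # descending, length K
    coordinates: pd.DataFrame        # samples x PC1..PCK scores
    n_variants_used: int

    def covariates(self, k: int) -> pd.DataFrame:
        return self.coordinates.iloc[:, :k]


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of mean-imputed, per-variant standardized dosages.

    Missing dosages are imputed with the per-variant mean; variants with
    zero variance are dropped.  Components are ordered by eigenvalue of the
    sample covariance; the sign convention makes the largest-magnitude
    variant loading positive.  Scores are the projections U*S of the
    standardized matrix.
    """
    if matrix.n_samples < n_components:
        raise ValueError("retained samples must be >= n_components")
    X = matrix.calls.astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all variants have zero variance")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, len(S))
    # sign convention: largest-magnitude loading positive per component
    for c in range(k):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * S[:k]
    eigvals = (S[:k] ** 2) / Z.shape[1]
    coords = pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(eigenvalues=eigvals, coordinates=coords, n_variants_used=int(keep.sum()))


def run_qc(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    sample_call_rate: float = 0.95,
    variant_call_rate: float = 0.95,
    hwe_stratum: str = "Chinese",
    hwe_alpha: float = 1e-6,
    ibs_threshold: float = 0.9,
    het_sd_multiplier: float = 3.0,
    sex_mismatch_ids: list[str] | None = None,
    n_pcs: int = 10,
) -> tuple[GenotypeMatrix, QcReport, PcaResult]:
    """Full QC pass: sex-mismatch removal, call-rate and HWE filters,
    IBS and heterozygosity flags, then PCA on the retained set."""
    report = QcReport()
    m = matrix
    if sex_mismatch_ids:
        m, report = sex_mismatch_filter(m, sex_mismatch_ids, report)
    m, report = call_rate_filter(m, sample_call_rate, variant_call_rate, report)
    m, report = hwe_filter(m, samples, hwe_stratum, hwe_alpha, report)
    if m.n_samples >= 2:
        pairwise_ibs(m, ibs_threshold, report)
    if m.n_samples >= 3:
        heterozygosity_check(m, het_sd_multiplier, report)
    result = pca(m, n_components=min(n_pcs, m.n_samples))
    return m, report, result
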