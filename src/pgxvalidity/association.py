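"""Candidate-SNP association testing and multiplicity adjustment.

Each candidate SNP is tested under additive, dominant and recessive codings
by logistic regression of case status on the coded genotype with sex and
leading principal components as covariates.  The family of correlated tests
is adjusted by the multivariate-normal rectangle method: for each test with
two-sided raw p and normal quantile z, the adjusted p is
1 - Pr(|Z_j| <= z for all j) under a zero-mean multivariate normal whose
correlation matrix is estimated from the covariate-residualized coded
predictor vectors (a score-test correlation approximation).  At zero
correlation the adjustment reduces to the Sidak bound and at perfect
correlation to no adjustment.

Also provided: the exact two-sided Fisher test with the sample cross-product
odds ratio, clinical covariate comparisons (t / Mann-Whitney / chi-square /
Fisher), ethnic-subgroup analyses, and a simulation-based allelic power
calculation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ContingencyTable2x2, GenotypeMatrix, SampleRecord, samples_to_frame

GENETIC_MODELS = ("additive", "dominant", "recessive")


def code_genetic_model(dosage, model: str):
    """Code a dosage (array or scalar) under a genetic model.

    additive -> dosage; dominant -> carrier indicator; recessive ->
    homozygous-variant indicator.  NaN (missing) propagates.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    d = np.asarray(dosage, dtype=float)
    if model == "additive":
        out = d.copy()
    elif model == "dominant":
        out = np.where(np.isnan(d), np.nan, (d >= 1).astype(float))
    else:
        out = np.where(np.isnan(d), np.nan, (d == 2).astype(float))
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Exact 2x2 test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float        # sample cross-product OR; inf/0 on zero cells
    degenerate: bool = False  # a margin was zero (p = 1 by convention)
    zero_cell: bool = False   # OR involved a zero cell


def fisher_exact_2x2(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test with the cross-product odds ratio.

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding the observed table's
    probability (the point-probability convention).  A zero margin makes
    the table degenerate: p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        or_, zero = _cross_product_or(a, b, c, d)
        return FisherResult(1.0, or_, degenerate=True, zero_cell=zero)
    p = float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])
    or_, zero = _cross_product_or(a, b, c, d)
    return FisherResult(min(p, 1.0), or_, zero_cell=zero)


def _cross_product_or(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if b * c == 0:
        return (np.inf if a * d > 0 else np.nan, True)
    if a * d == 0:
        return (0.0, True)
    return (a * d) / (b * c), False


# ---------------------------------------------------------------------------
# Logistic association
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """One SNP x genetic-model association estimate."""

    snp: str
    model: str
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    p_adjusted: float | None = None
    estimable: bool = True
    reason: str | None = None
    n_used: int = 0

    def as_dict(self) -> dict:
        return {
            "snp": self.snp,
            "model": self.model,
            "n": self.n_used,
            "OR": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "estimable": self.estimable,
            "reason": self.reason,
        }


_SEPARATION_BETA = 15.0  # |log-OR| beyond this is treated as separation


def logistic_assoc(
    status: np.ndarray,
    coded: np.ndarray,
    covariates: pd.DataFrame | None = None,
    snp: str = "",
    model: str = "",
) -> AssociationResult:
    """Logistic regression of case status on a coded genotype.

    Complete-case over predictor and covariates.  The fit is flagged
    inestimable when the coded genotype is constant overall or within cases
    or within controls (no within-group variation, the situation reported
    as NA in small candidate studies), or when the fit separates.
    Wald 95% CI and two-sided Wald p.
    """
    import statsmodels.api as sm

    y = np.asarray(status, dtype=float)
    g = np.asarray(coded, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y)
    C = None
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.to_numpy(dtype=float)
        ok &= ~np.isnan(C).any(axis=1)
    y, g = y[ok], g[ok]
    if C is not None:
        C = C[ok]
    n_used = int(ok.sum())
    res = AssociationResult(snp, model, None, None, None, None, n_used=n_used)
    if np.all(np.isnan(g)) or n_used == 0:
        res.estimable, res.reason = False, "no informative samples"
        return res
    if y.sum() == 0 or y.sum() == len(y):
        res.estimable, res.reason = False, "only one outcome class"
        return res
    for label, mask in (("overall", np.ones_like(y, bool)), ("cases", y == 1), ("controls", y == 0)):
        if np.unique(g[mask]).size < 2:
            res.estimable = False
            res.reason = f"genotype constant in {label}"
            return res
    design = np.column_stack([np.ones_like(g), g] + ([C] if C is not None else []))
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        beta = fit.params[1]
        se = fit.bse[1]
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        res.estimable, res.reason = False, f"fit failed: {exc}"
        return res
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > _SEPARATION_BETA or se > 50:
        res.estimable, res.reason = False, "separation"
        return res
    z = stats.norm.ppf(0.975)
    res.odds_ratio = float(np.exp(beta))
    res.ci_low = float(np.exp(beta - z * se))
    res.ci_high = float(np.exp(beta + z * se))
    res.p = float(2 * stats.norm.sf(abs(beta / se)))
    return res


# ---------------------------------------------------------------------------
# Correlated multiple-testing adjustment
# ---------------------------------------------------------------------------


def _residualize(predictors: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residualize each predictor column on [1, covariates] by least squares."""
    n = predictors.shape[0]
    design = np.ones((n, 1))
    if covariates is not None and covariates.size:
        design = np.column_stack([design, covariates])
    coef, *_ = np.linalg.lstsq(design, predictors, rcond=None)
    return predictors - design @ coef


def _nearest_corr(R: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and restore a unit diagonal."""
    w, V = np.linalg.eigh(R)
    repaired = bool(w.min() < min_eig)
    if repaired:
        w = np.clip(w, min_eig, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R, repaired


def _mvn_rectangles(
    R: np.ndarray,
    zs: np.ndarray,
    rng: np.random.Generator,
    abseps: float = 1e-4,
    n_start: int = 2**11,
    n_max: int = 2**14,
    n_scrambles: int = 8,
    chunk: int = 16,
) -> np.ndarray:
    """Pr(|Z_j| <= z for all j) under N(0, R), for each z in ``zs``.

    Genz separation-of-variables transform over scrambled Sobol points,
    vectorized across the z thresholds (they share one Cholesky factor and
    one point set).  The point count doubles until the scramble-to-scramble
    standard error drops below ``abseps`` or the cap is reached.
    """
    from scipy.stats import norm, qmc

    m = R.shape[0]
    zs = np.asarray(zs, dtype=float)
    # Cholesky of the (repaired) correlation matrix; a tiny ridge guards the
    # near-singular case of almost perfectly correlated tests
    for ridge in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(R + ridge * np.eye(m))
            break
        except np.linalg.LinAlgError:
            continue
    else:  # pragma: no cover
        w, V = np.linalg.eigh(R)
        L = np.linalg.cholesky((V * np.clip(w, 1e-6, None)) @ V.T)

    if m == 1:
        return norm.cdf(zs) - norm.cdf(-zs)

    out = np.empty_like(zs)
    for lo_k in range(0, len(zs), chunk):
        z = zs[lo_k : lo_k + chunk]          # (K,)
        K = len(z)
        n = n_start
        while True:
            ests = np.empty((n_scrambles, K))
            for s in range(n_scrambles):
                W = qmc.Sobol(d=m - 1, scramble=True, rng=rng).random(n)
                d0 = norm.cdf(-z / L[0, 0])
                e0 = norm.cdf(z / L[0, 0])
                dv = np.tile(d0[:, None], (1, n))
                ev = np.tile(e0[:, None], (1, n))
                f = ev - dv
                y = np.empty((K, n, m - 1))
                for i in range(1, m):
                    u = dv + W[None, :, i - 1] * (ev - dv)
                    y[:, :, i - 1] = norm.ppf(np.clip(u, 1e-15, 1 - 1e-15))
                    t = y[:, :, :i] @ L[i, :i]
                    dv = norm.cdf((-z[:, None] - t) / L[i, i])
                    ev = norm.cdf((z[:, None] - t) / L[i, i])
                    f = f * np.clip(ev - dv, 0.0, 1.0)
                ests[s] = f.mean(axis=1)
            est = ests.mean(axis=0)
            se = ests.std(axis=0, ddof=1) / np.sqrt(n_scrambles)
            if se.max() < abseps or n >= n_max:
                out[lo_k : lo_k + K] = np.clip(est, 0.0, 1.0)
                break
            n *= 2
    return out


def p_act_adjust(
    raw_p: np.ndarray,
    predictors: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, bool]:
    """Adjust correlated two-sided p-values by the MVN rectangle method.

    ``predictors`` is the n x m matrix of model-coded genotype vectors (one
    column per test, rows aligned with the samples used for testing; missing
    entries may be NaN and are mean-imputed for correlation estimation).
    The rectangle probability is evaluated by seeded quasi-Monte-Carlo
    integration.  Returns (adjusted p-values clipped to [raw, 1],
    PSD-repair flag).
    """
    raw_p = np.asarray(raw_p, dtype=float)
    m = raw_p.size
    if m == 0:
        raise ValueError("empty test family")
    if np.any((raw_p <= 0) | (raw_p > 1)):
        raise ValueError("raw p-values must be in (0, 1]")
    if m == 1:
        return raw_p.copy(), False
    P = np.asarray(predictors, dtype=float)
    if P.shape[1] != m:
        raise ValueError("one predictor column per raw p-value is required")
    col_mean = np.nanmean(P, axis=0)
    idx = np.where(np.isnan(P))
    P = P.copy()
    P[idx] = col_mean[idx[1]]
    C = None
    if covariates is not None:
        C = np.asarray(
            covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates,
            dtype=float,
        )
    resid = _residualize(P, C)
    sd = resid.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    R = np.corrcoef(resid, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    R, repaired = _nearest_corr(R)
    z = stats.norm.isf(raw_p / 2.0)
    finite = np.isfinite(z)
    adjusted = raw_p.copy()
    if finite.any():
        rect = _mvn_rectangles(R, z[finite], np.random.default_rng(seed))
        adjusted[finite] = 1.0 - rect
    adjusted = np.clip(adjusted, raw_p, 1.0)
    return adjusted, repaired


# ---------------------------------------------------------------------------
# Panel-level driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateEntry:
    snp: str
    gene: str
    counted_allele: str
    models: tuple[str, ...] = GENETIC_MODELS


@dataclass
class CandidatePanel:
    """Candidate-SNP panel: which SNPs to test under which genetic models."""

    entries: list[CandidateEntry]

    def __post_init__(self) -> None:
        ids = [e.snp for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in candidate panel")
        for e in self.entries:
            if set(e.models) - set(GENETIC_MODELS):
                raise ValueError(f"unknown model for {e.snp}")

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp for e in self.entries]


def default_candidate_panel() -> CandidatePanel:
    """Packaged candidate panel of previously reported INH-DILI variants.

    NAT2 coding SNPs and the 3' tag SNP, the CYP2E1 RsaI/PstI and DraI
    polymorphisms, GSTP1, and TNF-alpha promoter variants; entries absent
    from a given genotype matrix are skipped at run time.
    """
    e = CandidateEntry
    return CandidatePanel(
        entries=[
            e("rs1041983", "NAT2", "T"),
            e("rs1495741", "NAT2", "G"),
            e("rs1799929", "NAT2", "T"),
            e("rs1799930", "NAT2", "A"),
            e("rs1799931", "NAT2", "A"),
            e("rs1801280", "NAT2", "C"),
            e("rs1208", "NAT2", "G"),
            e("rs1801279", "NAT2", "A"),
            e("rs2031920", "CYP2E1", "T"),
            e("rs3813867", "CYP2E1", "C"),
            e("rs6413432", "CYP2E1", "A"),
            e("rs1695", "GSTP1", "G"),
            e("rs1800629", "TNF", "A"),
        ]
    )


def run_association(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    pcs: pd.DataFrame | None = None,
    panel: CandidatePanel | None = None,
    models: tuple[str, ...] = GENETIC_MODELS,
    n_pcs: int = 2,
    adjust: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every panel SNP under every requested model and adjust.

    Covariates: sex indicator plus the first ``n_pcs`` PCA coordinates when
    given.  Inestimable tests are excluded from the adjustment family; the
    estimable family size is reported in the ``family_size`` column.
    """
    if panel is None:
        panel = default_candidate_panel()
    frame = samples_to_frame(samples).set_index("sample_id")
    frame = frame.loc[[s for s in matrix.sample_ids if s in frame.index]]
    status = (frame["status"] == "case").astype(float).to_numpy()
    cov = pd.DataFrame({"female": (frame["sex"] == "F").astype(float)}, index=frame.index)
    if pcs is not None and n_pcs > 0:
        cov = cov.join(pcs.iloc[:, :n_pcs])
    sub = matrix.subset(samples=list(frame.index))

    results: list[AssociationResult] = []
    pred_cols: list[np.ndarray] = []
    present = set(sub.variant_ids)
    for entry in panel.entries:
        if entry.snp not in present:
            continue
        dos = sub.dosages(entry.snp)
        for model in models:
            if model not in entry.models:
                continue
            coded = code_genetic_model(dos, model)
            res = logistic_assoc(status, coded, cov, snp=entry.snp, model=model)
            results.append(res)
            pred_cols.append(coded)

    est = [i for i, r in enumerate(results) if r.estimable]
    if adjust and est:
        raw = np.array([results[i].p for i in est])
        P = np.column_stack([pred_cols[i] for i in est])
        adj, _ = p_act_adjust(raw, P, cov.to_numpy(), seed=seed)
        for k, i in enumerate(est):
            results[i].p_adjusted = float(adj[k])
    out = pd.DataFrame([r.as_dict() for r in results])
    gene_of = {e.snp: e.gene for e in panel.entries}
    if not out.empty:
        out.insert(0, "gene", out["snp"].map(gene_of))
        out["family_size"] = len(est)
    return out


def subgroup_assoc(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    snp: str | None = None,
    exposure: dict[str, bool] | None = None,
    model: str = "additive",
    ethnicities: list[str] | None = None,
) -> pd.DataFrame:
    """Per-ethnic-stratum association for one SNP or an exposure flag.

    Within each stratum the same logistic contract applies (sex covariate
    only; PCs are not meaningful within a single stratum).  A stratum with
    no cases or no controls is flagged inestimable.
    """
    if (snp is None) == (exposure is None):
        raise ValueError("give exactly one of snp or exposure")
    frame = samples_to_frame(samples)
    groups = ethnicities or sorted(frame["ethnicity"].unique())
    rows = []
    for eth in groups:
        ids = frame.loc[frame["ethnicity"] == eth, "sample_id"].tolist()
        if not ids:
            raise ValueError(f"empty stratum {eth!r}")
        sub_frame = frame.set_index("sample_id").loc[ids]
        status = (sub_frame["status"] == "case").astype(float).to_numpy()
        cov = pd.DataFrame(
            {"female": (sub_frame["sex"] == "F").astype(float)}, index=sub_frame.index
        )
        if snp is not None:
            coded = code_genetic_model(matrix.subset(samples=ids).dosages(snp), model)
            label = snp
        else:
            coded = np.array([float(exposure[s]) if exposure.get(s) is not None else np.nan for s in ids])
            label = "exposure"
        res = logistic_assoc(status, coded, cov, snp=label, model=model)
        row = res.as_dict()
        row["ethnicity"] = eth
        row["n_stratum"] = len(ids)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical covariate comparisons
# ---------------------------------------------------------------------------

#: Default variable typing for the sample sheet.
DEFAULT_COVARIATE_TYPES: tuple[tuple[str, str], ...] = (
    ("age", "continuous_normal"),
    ("sex", "binary"),
    ("ethnicity", "categorical"),
)


def clinical_covariate_tests(
    samples: list[SampleRecord],
    variables: tuple[tuple[str, str], ...] = DEFAULT_COVARIATE_TYPES,
) -> pd.DataFrame:
    """Case/control comparison of clinical covariates, Table-1 style.

    Typing decides the test: continuous_normal -> two-sample t test,
    continuous_skewed -> Mann-Whitney U, binary -> chi-square with
    continuity correction on the 2x2, categorical -> Fisher's exact test of
    each level against all others combined plus an overall chi-square row.
    All tests are two-sided; a constant variable yields p = 1 with a flag.
    """
    frame = samples_to_frame(samples)
    case = frame["status"] == "case"
    rows = []
    for name, kind in variables:
        x = frame[name]
        if x.nunique() <= 1:
            rows.append({"variable": name, "level": "", "test": "none",
                         "p": 1.0, "flag": "constant"})
            continue
        if kind in ("continuous_normal", "continuous_skewed"):
            a = x[case].astype(float)
            b = x[~case].astype(float)
            if kind == "continuous_normal":
                stat, p = stats.ttest_ind(a, b, equal_var=True)
                test = "t"
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                test = "mann-whitney"
            rows.append({"variable": name, "level": "", "test": test,
                         "p": float(p), "flag": ""})
        elif kind == "binary":
            lev = sorted(x.unique())[0]
            tab = np.array(
                [
                    [((x == lev) & case).sum(), ((x == lev) & ~case).sum()],
                    [((x != lev) & case).sum(), ((x != lev) & ~case).sum()],
                ]
            )
            p = float(stats.chi2_contingency(tab, correction=True)[1])
            rows.append({"variable": name, "level": str(lev), "test": "chi-square",
                         "p": p, "flag": ""})
        elif kind == "categorical":
            levels = sorted(x.unique())
            if len(levels) > 2:
                tab = pd.crosstab(x, case)
                chi2, p, *_ = stats.chi2_contingency(tab.to_numpy())
                rows.append({"variable": name, "level": "(overall)",
                             "test": "chi-square", "p": float(p), "flag": ""})
            for lev in levels:
                t = ContingencyTable2x2(
                    a=int(((x == lev) & case).sum()),
                    b=int(((x == lev) & ~case).sum()),
                    c=int(((x != lev) & case).sum()),
                    d=int(((x != lev) & ~case).sum()),
                )
                fr = fisher_exact_2x2(t)
                rows.append({"variable": name, "level": str(lev), "test": "fisher",
                             "p": fr.p, "flag": "degenerate" if fr.degenerate else ""})
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


def power_simulation(
    n_cases: int,
    n_controls: int,
    control_maf: float,
    allelic_or: float,
    alpha: float = 0.003,
    n_reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo power of the allelic Fisher test for a 2x2 allele table.

    The case allele frequency comes from the odds transform of the control
    frequency at the given allelic odds ratio; per replicate, case and
    control minor-allele counts are binomial over 2n alleles and the allelic
    2x2 table is tested by two-sided Fisher's exact test.  Returns
    (power, Monte-Carlo SE).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_reps < 100:
        raise ValueError("use at least 100 replicates")
    if not 0 < control_maf < 1:
        raise ValueError("control MAF must be in (0,1)")
    if allelic_or <= 0:
        raise ValueError("odds ratio must be positive")
    odds = control_maf / (1 - control_maf) * allelic_or
    case_f = odds / (1 + odds)
    rng = np.random.default_rng(seed)
    n_ca, n_co = 2 * n_cases, 2 * n_controls
    a = rng.binomial(n_ca, case_f, size=n_reps)
    b = rng.binomial(n_co, control_maf, size=n_reps)
    # identical tables share a p-value: test unique (a, b) pairs once
    pairs, inverse = np.unique(np.column_stack([a, b]), axis=0, return_inverse=True)
    pvals = np.empty(len(pairs))
    for k, (ai, bi) in enumerate(pairs):
        pvals[k] = fisher_exact_2x2(
            ContingencyTable2x2(int(ai), int(bi), n_ca - int(ai), n_co - int(bi))
        ).p
    reject = pvals[inverse] < alpha
    power = float(reject.mean())
    se = float(np.sqrt(power * (1 - power) / n_reps))
    return power, se
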