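import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from pgxvalidity.association import logistic_assoc
from pgxvalidity.nat2 import infer_acetylator
from pgxvalidity.roc import fit_risk_model
from pgxvalidity.sim import default_config, generate_cohort
from pgxvalidity.types import SampleRecord


@pytest.fixture(scope="session")
def study_scale_samples():
    """A 103-sample sheet with the emulated study's sex and ethnicity margins.

    24 cases (9 male), 79 controls (59 male); ethnicity counts
    cases 12/5/1/6 and controls 57/10/7/5 for Chinese/Malay/Indian/Others.
    Only the margins matter to the tests that use this fixture.
    """
    records = []

    def build(prefix, n, n_male, eth_counts, status, grade):
        eths = [e for e, k in eth_counts for _ in range(k)]
        assert len(eths) == n
        for i in range(n):
            records.append(
                SampleRecord(
                    sample_id=f"{prefix}{i + 1:03d}",
                    sex="M" if i < n_male else "F",
                    ethnicity=eths[i],
                    status=status,
                    grade=grade,
                    age=50.0,
                )
            )

    build("CA", 24, 9, [("Chinese", 12), ("Malay", 5), ("Indian", 1), ("Others", 6)],
          "case", 2)
    build("CO", 79, 59, [("Chinese", 57), ("Malay", 10), ("Indian", 7), ("Others", 5)],
          "control", 0)
    return records


@pytest.fixture(scope="session")
def cohort_replicates():
    """Summaries of 200 study-scale simulated cohorts under the default
    generative conditions (slow-acetylator log-OR ln 10), computed once.

    Collected per replicate: inferred-SA fraction, crude SA odds ratio,
    adjusted logistic CI coverage of the true OR 10, exact agreement of
    inferred phenotype with the latent class, pooled case grades, whether
    the clinical+SA model beat the clinical model in apparent AUC, and
    whether the Chinese and Malay stratum ORs shared the risk direction.
    """
    out = {
        "sa_frac": [], "crude_or": [], "covered": [], "latent_match": [],
        "grades": [], "auc_improved": [], "subgroup_direction": [],
    }
    for rep in range(200):
        cfg = default_config(seed=50_000 + rep, n_background_snps=20)
        c = generate_cohort(cfg)
        calls = infer_acetylator(c.genotypes)
        sa = np.array([cl.exposure for cl in calls], dtype=bool)
        case = np.array([s.is_case for s in c.samples])
        out["sa_frac"].append(sa.mean())
        out["latent_match"].append(
            all(cl.phenotype == lat for cl, lat in zip(calls, c.truth.acetylator))
        )
        a, b = (sa & case).sum(), (sa & ~case).sum()
        cc, d = (~sa & case).sum(), (~sa & ~case).sum()
        if b * cc > 0:
            out["crude_or"].append(a * d / (b * cc))
        cov = pd.DataFrame({"female": [float(s.sex == "F") for s in c.samples]})
        res = logistic_assoc(case.astype(float), sa.astype(float), cov)
        if res.estimable:
            out["covered"].append(res.ci_low <= 10.0 <= res.ci_high)
        out["grades"].extend(s.grade for s in c.samples if s.is_case)
        sa_series = pd.Series(sa.astype(float), index=[s.sample_id for s in c.samples])
        m0 = fit_risk_model(c.samples, name="clinical")
        m1 = fit_risk_model(
            c.samples, ("age", "sex", "ethnicity", "SA"), genetic={"SA": sa_series}
        )
        out["auc_improved"].append(m1.auc() > m0.auc())
        same_dir = True
        for eth in ("Chinese", "Malay"):
            idx = [i for i, s in enumerate(c.samples) if s.ethnicity == eth]
            e = sa[idx]
            k = case[idx]
            ah = (e & k).sum() + 0.5
            bh = (e & ~k).sum() + 0.5
            ch = (~e & k).sum() + 0.5
            dh = (~e & ~k).sum() + 0.5
            same_dir &= (ah * dh) / (bh * ch) > 1
        out["subgroup_direction"].append(same_dir)
    return out
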