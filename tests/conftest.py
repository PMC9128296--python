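import numpy as np
import pytest

from xciskew.data_model import XDataset
from xciskew.glm_engine import CoefEstimates, reparameterize

# rs3827440 genotype counts (CC, TC, TT by T-allele dosage 0/1/2)
GWAS_CASE = (163, 508, 444)
GWAS_CONTROL = (219, 541, 367)
REPL_CASE = (471, 1606, 1298)
REPL_CONTROL = (584, 1344, 957)


@pytest.fixture(scope="session")
def gwas_dataset():
    return XDataset.from_grouped_counts(GWAS_CASE, GWAS_CONTROL)


@pytest.fixture(scope="session")
def replication_dataset():
    return XDataset.from_grouped_counts(REPL_CASE, REPL_CONTROL)


@pytest.fixture(scope="session")
def pooled_dataset():
    """GWAS + replication stages with a 0/1 stage covariate."""
    d1 = XDataset.from_grouped_counts(GWAS_CASE, GWAS_CONTROL)
    d2 = XDataset.from_grouped_counts(REPL_CASE, REPL_CONTROL)
    dosage = np.concatenate([d1.dosage, d2.dosage])
    trait = np.concatenate([d1.trait, d2.trait])
    stage = np.concatenate([np.zeros(d1.n), np.ones(d2.n)])[:, None]
    return XDataset(
        subject_id=np.arange(d1.n + d2.n),
        dosage=dosage,
        trait=trait,
        covariates=stage,
        trait_type="qualitative",
    )


def random_coef_estimates(rng, scale=1.0):
    """A random CoefEstimates with a valid PSD (beta1, beta2) covariance."""
    b1, b2 = rng.normal(0.0, scale, size=2)
    a = rng.normal(0.0, 0.3 * scale, size=(2, 2))
    cov2 = a @ a.T + 1e-6 * np.eye(2)
    v1, v2, v12 = reparameterize(cov2)
    full = np.zeros((3, 3))
    full[1:, 1:] = cov2
    return CoefEstimates(
        beta0_hat=0.0,
        beta1_hat=float(b1),
        beta2_hat=float(b2),
        b_hat=np.empty(0),
        v1=v1,
        v2=v2,
        v12=v12,
        full_cov=full,
    )
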