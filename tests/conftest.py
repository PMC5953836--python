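import numpy as np
import pytest
from hypothesis import settings

import tmbkit as tk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study dataset shared across tests."""
    cfg = tk.SimulationConfig(n_patients=40, seed=101)
    return tk.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_variant(patient_id="P1", pos=100, ref="A", alt="T", gene="GENE1",
                 effect_class="nonsynonymous", alt_count=30, depth=100,
                 **kwargs):
    vt = "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"
    return tk.VariantRecord(
        patient_id=patient_id, chrom="chr1", pos=pos, ref=ref, alt=alt,
        gene=gene, effect_class=effect_class, variant_type=vt,
        alt_count=alt_count, depth=depth,
        vaf=alt_count / depth if depth else 0.0, **kwargs,
    )


def make_patient(patient_id="P1", best_response="PR", dcb=True,
                 pfs_months=10.0, pfs_event=True, pd_l1_pct=50.0,
                 histology="non-squamous", smoking="ever", ecog=0,
                 tumor_mean_cov=148.0, normal_mean_cov=81.0, **kwargs):
    return tk.PatientRecord(
        patient_id=patient_id, best_response=best_response, dcb=dcb,
        pfs_months=pfs_months, pfs_event=pfs_event, pd_l1_pct=pd_l1_pct,
        histology=histology, smoking=smoking, ecog=ecog,
        tumor_mean_cov=tumor_mean_cov, normal_mean_cov=normal_mean_cov,
        **kwargs,
    )
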