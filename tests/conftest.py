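import numpy as np
import pandas as pd
import pytest

from venetomics.simulate import EpiSimConfig, simulate_epigenome


@pytest.fixture(scope="session")
def small_epigenome():
    """Noisy epigenome with planted accessibility/methylation shifts and
    flagged probes, shared across QC and accessibility tests."""
    cfg = EpiSimConfig(
        n_probes=2000,
        n_promoter_genes=100,
        probes_per_promoter=2,
        frac_snp=0.10,
        frac_crossreactive=0.05,
        frac_sex_chrom=0.05,
        frac_sig_acc_up=0.05,
        frac_sig_acc_down=0.05,
        frac_sig_meth_up=0.05,
        frac_sig_meth_down=0.05,
        planted_delta=0.3,
        beta_noise_sd=0.02,
        detection_fail_rate=0.01,
        seed=2,
    )
    return simulate_epigenome(cfg)


@pytest.fixture
def beta_pair():
    """Tiny hand-buildable paired β tables (4 probes x 2 samples each arm)."""
    idx = pd.Index([f"cg{i}" for i in range(4)], name="probe_id")
    sssi = pd.DataFrame(
        {"a_1": [0.8, 0.5, 0.2, 0.9], "b_1": [0.7, 0.5, 0.3, 0.8]}, index=idx
    )
    noe = pd.DataFrame(
        {"a_1": [0.2, 0.5, 0.1, 0.4], "b_1": [0.3, 0.5, 0.2, 0.5]}, index=idx
    )
    return sssi, noe
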