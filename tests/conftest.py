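import numpy as np
import pytest

from mimsfit import (
    EnrichmentSpec,
    ExchangeParams,
    FitConfig,
    FlashProtocol,
    FluorDecayParams,
    MimsSimConfig,
)

# Typical wild-type magnitudes used throughout: S2 exchange rates near
# k_f = 111 s^-1 / k_s = 0.93 s^-1, S3 fast rate 29 s^-1, enrichment jump
# 0.07% -> 13%, 100 Hz turnover flashes.


@pytest.fixture
def enrichment() -> EnrichmentSpec:
    return EnrichmentSpec(alpha_i=0.0007, alpha_f=0.13)


@pytest.fixture
def s2_protocol() -> FlashProtocol:
    return FlashProtocol(probed_state="S2", flash_frequency=100.0, k_f_s3=29.0)


@pytest.fixture
def s3_protocol() -> FlashProtocol:
    return FlashProtocol(probed_state="S3", flash_frequency=100.0)


@pytest.fixture
def wt_truth() -> ExchangeParams:
    return ExchangeParams(k_f=111.0, k_s=0.93)


@pytest.fixture
def fit_config(enrichment, s2_protocol) -> FitConfig:
    return FitConfig(enrichment=enrichment, protocol=s2_protocol)


@pytest.fixture
def wt_sim_config(wt_truth, enrichment, s2_protocol) -> MimsSimConfig:
    return MimsSimConfig(truth=wt_truth, enrichment=enrichment, protocol=s2_protocol)


@pytest.fixture
def fluor_truth() -> FluorDecayParams:
    return FluorDecayParams(
        a0=0.02, a1=0.07, a2=0.37, a3=0.54, tau1=0.0035, tau2=0.289, tau3=1.5
    )
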