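import numpy as np
import pytest

from svjudge import (
    Breakpoint,
    GenomicInterval,
    SpikeConfig,
    SupportCounts,
    SVRecord,
    generate_background,
    spike_sv,
)


@pytest.fixture(scope="session")
def small_background():
    """200x background over 10 kb, fixed seed."""
    cfg = SpikeConfig(seed=11)
    region = GenomicInterval("chr2", 0, 10_000)
    return generate_background(region, 200, cfg), region, cfg


@pytest.fixture(scope="session")
def spiked_dataset(small_background):
    ds, region, cfg = small_background
    sv = SVRecord(
        id="del_spiked",
        svtype="DEL",
        bp1=Breakpoint("chr2", 3000),
        bp2=Breakpoint("chr2", 7000),
        support=SupportCounts(DV=10, RV=5),
    )
    from dataclasses import replace

    return spike_sv(ds, sv, replace(cfg, vaf=0.1)), sv


@pytest.fixture
def three_record_callset():
    return [
        SVRecord(
            id="del1",
            svtype="DEL",
            bp1=Breakpoint("chr1", 999, "3to5"),
            bp2=Breakpoint("chr1", 4999, "3to5"),
            caller="delly",
            support=SupportCounts(DV=10, RV=5),
            qual=120.0,
        ),
        SVRecord(
            id="inv1",
            svtype="INV",
            bp1=Breakpoint("chr1", 2000, "3to3"),
            bp2=Breakpoint("chr1", 3000, "3to3"),
            support=SupportCounts(DV=12, RV=7),
        ),
        SVRecord(
            id="bnd1",
            svtype="BND",
            bp1=Breakpoint("chr2", 500, "5to3"),
            bp2=Breakpoint("chr3", 700, "5to3"),
            support=SupportCounts(DV=3),
        ),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
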