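import numpy as np
import pytest

from heartperm import (
    SVP_LACZ,
    CellCountRecord,
    GeneratorConfig,
    default_segments,
    generate_cohort,
)


def make_record(
    embryo_id="e1",
    genotype="wt",
    segment="A2",
    side="L",
    tin_cc=4,
    svp_cc=2,
    svp_pc=2,
    enlarged=False,
    assay=SVP_LACZ,
):
    """A valid hemisegment record with wild-type counts by default."""
    return CellCountRecord(
        embryo_id=embryo_id,
        genotype=genotype,
        segment=segment,
        side=side,
        tin_cc=tin_cc,
        svp_cc=svp_cc,
        svp_pc=svp_pc,
        enlarged_svp_nucleus=enlarged,
        assay=assay,
    )


def make_embryo(embryo_id="e1", genotype="wt", overrides=None, assay=SVP_LACZ):
    """One fully scored embryo (A2–A8 bilateral); ``overrides`` maps
    (segment, side) -> dict of count fields to change."""
    overrides = overrides or {}
    records = []
    for seg, side in default_segments():
        kw = dict(tin_cc=4, svp_cc=2, svp_pc=None if assay != SVP_LACZ else 2)
        kw.update(overrides.get((seg, side), {}))
        records.append(
            CellCountRecord(
                embryo_id=embryo_id,
                genotype=genotype,
                segment=seg,
                side=side,
                enlarged_svp_nucleus=None if assay != SVP_LACZ else False,
                assay=assay,
                **kw,
            )
        )
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """A deterministic mixed cohort with moderate defect rates."""
    cfg = GeneratorConfig(
        n_embryos={"wt": 6, "mut": 6},
        baseline_rate={"tin_symmetric": 0.15, "svp_earlier": 0.1, "svp_asymmetric": 0.05},
        embryo_sd=0.4,
        seed=77,
    )
    return generate_cohort(cfg)
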