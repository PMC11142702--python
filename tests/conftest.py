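"""Shared fixtures and builders for the test suite.

All fixture data is generated programmatically; nothing is read from
checked-in data files.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from mrkit.instruments import InstrumentRecord
from mrkit.io import SummaryStatSet

# MR-PRESSO legitimately warns under the null when the global test is
# marginal; keep test output readable.
logging.getLogger("mrkit.sensitivity").setLevel(logging.ERROR)


def make_record(
    variant_id: str = "rs1",
    ratio: float | None = None,
    weight: float | None = None,
    **kwargs,
) -> InstrumentRecord:
    """Build an instrument with a prescribed Wald ratio and IVW weight.

    With exposure beta fixed at 1, weight w = 1/σy² and outcome beta = ratio
    reproduce any (ρ, w) pair exactly.
    """
    fields = dict(
        variant_id=variant_id,
        chromosome="1",
        position=1,
        effect_allele="A",
        other_allele="G",
        exposure_beta=1.0,
        exposure_se=0.01,
        exposure_eaf=0.3,
        exposure_p=1e-10,
        exposure_n=100_000.0,
        outcome_beta=0.0,
        outcome_se=1.0,
        outcome_p=0.5,
        outcome_n=100_000.0,
    )
    if ratio is not None:
        fields["outcome_beta"] = ratio
    if weight is not None:
        fields["outcome_se"] = 1.0 / np.sqrt(weight)
    fields.update(kwargs)
    return InstrumentRecord(**fields)


def make_records(ratios, weights=None, **kwargs) -> list[InstrumentRecord]:
    weights = weights if weights is not None else [1.0] * len(ratios)
    return [
        make_record(f"rs{i + 1}", ratio=r, weight=w, **kwargs)
        for i, (r, w) in enumerate(zip(ratios, weights))
    ]


def stats_from_rows(rows, trait="trait", ancestry="EUR", binary=False) -> SummaryStatSet:
    """Build a SummaryStatSet from a list of row dicts (defaults filled in)."""
    defaults = dict(
        chromosome="1",
        position=1000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.01,
        p=1e-9,
        n=100_000,
    )
    filled = []
    for i, row in enumerate(rows):
        d = {"variant_id": f"rs{i + 1}", **defaults, **row}
        filled.append(d)
    return SummaryStatSet(trait, ancestry, pd.DataFrame(filled), binary_trait=binary)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def consistent_records(rng):
    """20 instruments exactly consistent with a causal effect of 0.3."""
    x = rng.uniform(0.05, 0.2, 20) * rng.choice([-1, 1], 20)
    sy = rng.uniform(0.005, 0.02, 20)
    return [
        make_record(f"rs{i + 1}", exposure_beta=float(xi), outcome_beta=0.3 * float(xi), outcome_se=float(s))
        for i, (xi, s) in enumerate(zip(x, sy))
    ]


# Printed estimates of the replicated triglycerides -> endometriosis
# analyses (discovery, Sakaue, FinnGen), as OR with 95% CI.
EUR_TG_STUDIES = [
    (1.112, 1.033, 1.198),
    (1.135, 1.016, 1.267),
    (1.149, 1.064, 1.240),
]
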