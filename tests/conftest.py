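"""Shared fixtures: synthetic runs reused across the suite.

Session-scoped simulations keep the suite fast: the β-sweep and the
noise-free uniform run are each computed once and shared between the
property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitoradial as mr
from mitoradial.simulate import SimSpec, generate_fields

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

N_FIELDS_PER_LEVEL = 13  # 4 cells/field -> ~50 interior cells per beta level
BETA_LEVELS = (0.0, 0.5, 1.0, 2.0, 4.0)


def measure_fields(pairs, config):
    """Segment + profile a list of (field, truth) pairs; per-cell summaries."""
    cells = []
    for fieldobj, truth in pairs:
        nuclei = mr.identify_nuclei(fieldobj, config)
        cellobjs = mr.identify_cells(fieldobj, nuclei)
        records = mr.build_cell_records(fieldobj, nuclei, cellobjs, config)
        truth_interior = truth.interior_cells()
        for rec, ct in zip(records, truth_interior):
            part, prof = mr.profile_cell(rec, fieldobj.channels["mitochondria"], config)
            cyto = rec.cytoplasm_mask
            cells.append(
                {
                    "field_id": rec.field_id,
                    "perinuclear": prof.perinuclear_fraction,
                    "peripheral": prof.peripheral_fraction,
                    "fraction_sum": float(prof.fractions.sum()),
                    "true_perinuclear": ct.true_perinuclear,
                    "inner_area_frac": float(part.ring_areas[:2].sum() / part.ring_areas.sum()),
                    "partition_exact": bool(
                        np.array_equal(part.ring_raster > 0, cyto)
                        and part.ring_areas.sum() == cyto.sum()
                    ),
                    "mask_identity": bool(
                        (rec.nucleus_mask & ~rec.cell_mask).sum() == 0
                        and np.array_equal(cyto, rec.cell_mask & ~rec.nucleus_mask)
                        and not (cyto & rec.nucleus_mask).any()
                    ),
                }
            )
    return cells


@pytest.fixture(scope="session")
def config():
    return mr.RunConfig()


@pytest.fixture(scope="session")
def beta_sweep(config):
    """~50 cells per β level with the default (noisy) image model."""
    out = {}
    for beta in BETA_LEVELS:
        spec = SimSpec(beta=beta, seed=int(100 + beta * 10))
        pairs = generate_fields(spec, N_FIELDS_PER_LEVEL)
        out[beta] = measure_fields(pairs, config)
    return out


@pytest.fixture(scope="session")
def uniform_cells(config):
    """Noise-free β = 0 fields: the uniform-placement baseline (~50 cells)."""
    spec = SimSpec(beta=0.0, seed=42, poisson_noise=False, read_noise_sd=0.0, background=0.0)
    pairs = generate_fields(spec, N_FIELDS_PER_LEVEL)
    return measure_fields(pairs, config)
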