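"""Shared fixtures.

The expensive solvent-excluded-surface computations (full monopeptide scale
build, poly-alanine prediction series) run once per session and are shared
across test modules.
"""

import pytest

from ride.constants import ETA_TIP3P_310, T_PHYS
from ride.hydro_scale import (NMA_D0, DiffusionEstimate, build_scale,
                              load_peptide_table, load_shipped_scale)
from ride.sesa import DEFAULT_RADIUS_SET, SESAParams, assign_radii, compute_sesa


class CachingAreaProvider:
    """SESA provider that remembers each structure's total area by label."""

    def __init__(self, params: SESAParams = SESAParams()):
        self.params = params
        self.totals = {}

    def __call__(self, structure):
        result = compute_sesa(assign_radii(structure, DEFAULT_RADIUS_SET),
                              self.params, DEFAULT_RADIUS_SET.name)
        self.totals[structure.label] = result.total
        return result


@pytest.fixture(scope="session")
def peptide_table():
    return load_peptide_table()


@pytest.fixture(scope="session")
def mono_d_table(peptide_table):
    """Capped-monopeptide D_0 estimates at the derivation state point."""
    return {aa: DiffusionEstimate(row["d0_mono"], T_PHYS, ETA_TIP3P_310)
            for aa, row in peptide_table.items()}


@pytest.fixture(scope="session")
def nma_d():
    return DiffusionEstimate(NMA_D0, T_PHYS, ETA_TIP3P_310)


@pytest.fixture(scope="session")
def built_scale_M(mono_d_table, nma_d):
    """M-variant scale freshly derived from fixtures, with the per-structure
    SESA totals that went into it (keyed by structure label)."""
    provider = CachingAreaProvider()
    scale = build_scale(mono_d_table, nma_d, provider, variant="M",
                        radius_set_name=DEFAULT_RADIUS_SET.name)
    return scale, provider.totals


@pytest.fixture(scope="session")
def shipped_scale_M():
    return load_shipped_scale("M")


@pytest.fixture(scope="session")
def shipped_scale_D():
    return load_shipped_scale("D")


@pytest.fixture(scope="session")
def ala_series_predictions(shipped_scale_M, shipped_scale_D):
    """RIDE(M) and RIDE(D) predictions for extended capped ALA_1..ALA_6.

    The SES areas of each chain are computed once and shared between the
    two scale variants.
    """
    from ride.fixtures import PeptideSpec, build_peptide
    from ride.predictor import predict

    out = {}
    for n in range(1, 7):
        s = build_peptide(PeptideSpec("A" * n, "extended", capped=True))
        areas = compute_sesa(assign_radii(s, DEFAULT_RADIUS_SET),
                             SESAParams()).as_area_table()
        out[n] = (predict(s, areas, shipped_scale_M),
                  predict(s, areas, shipped_scale_D))
    return out
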