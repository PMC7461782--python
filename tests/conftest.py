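"""Shared fixtures: a tiny hand-built model and the default synthetic panel."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from chromopan.isbp import design_isbps
from chromopan.reference import GeneModel, ReferenceModel, TeCopy
from chromopan.simulate import DUP_SUFFIX, SimulationConfig, make_panel


def _random_seq(n: int, seed: int = 42) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def tiny_model() -> ReferenceModel:
    """1-kb chromosome, one TE at [100, 300), one gene at [500, 800)."""
    seq = _random_seq(1000)
    model = ReferenceModel(
        chrom_id="chrT",
        sequence=seq,
        te_set=[TeCopy("TE1", "FAM1", "RLG", 100, 300)],
        gene_set=[
            GeneModel("G1", 500, 800, ((500, 620), (700, 790)), "M" + "A" * 69)
        ],
        region_breaks=(100, 350, 650, 900),
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Default study conditions at zero read error (planted-recovery runs)."""
    return SimulationConfig(base_error_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def panel(clean_config):
    """The default 1-Mb / 12-accession / 30x panel, simulated once per session."""
    return make_panel(clean_config)


@pytest.fixture(scope="session")
def panel_markers(panel):
    return panel.markers


def expected_te_status(truth, te_id: str, marker_ends: set[str]) -> str:
    """Ground-truth TE call implied by the planted deletions and the marker set."""
    if not marker_ends:
        return "untestable"
    kind = truth.te_deletions.get(te_id)
    if kind == "full":
        if marker_ends == {"5", "3"}:
            return "full_absent"
        return "partial_absent_5" if "5" in marker_ends else "partial_absent_3"
    if kind == "partial5":
        return "partial_absent_5" if "5" in marker_ends else "present"
    if kind == "partial3":
        return "partial_absent_3" if "3" in marker_ends else "present"
    return "present"


def pair_members(gene_id: str) -> set[str]:
    base = gene_id[: -len(DUP_SUFFIX)] if gene_id.endswith(DUP_SUFFIX) else gene_id
    return {base, base + DUP_SUFFIX}


def precision_recall(called: set, truth: set) -> tuple[float, float]:
    tp = len(called & truth)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
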