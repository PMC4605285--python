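"""Shared fixtures: reference fragments, random annotated sequences, and the
session-wide no-noise validation experiment used by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from silnas.digestion import AnnotatedSequence, Fragment
from silnas.matching import SearchParams
from silnas.pipeline import PipelineConfig, run_pipeline
from silnas.simulator import (
    SimConfig,
    design_ground_truth,
    simulate,
    simulate_ce,
)


@pytest.fixture
def aauug() -> Fragment:
    """The canonical 5-mer T1 product with 5'-OH and 3'-linear phosphate."""
    return Fragment(
        parent_id="5.8S",
        start=74,
        end=78,
        sequence="AAUUG",
        five_prime="OH",
        three_prime="p",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_annotated(
    rng: np.random.Generator,
    length: int,
    with_mods: bool = False,
    three_prime: str = "OH",
) -> AnnotatedSequence:
    residues = "".join(rng.choice(list("ACGU"), size=length))
    mods = {}
    if with_mods:
        n_mods = int(rng.integers(0, max(2, length // 15) + 1))
        positions = rng.choice(length, size=min(n_mods, length), replace=False)
        for pos0 in positions:
            pos = int(pos0) + 1
            base = residues[pos0]
            code = rng.choice(
                {
                    "A": ["Am", "m6A"],
                    "C": ["Cm", "m5C", "ac4C"],
                    "G": ["Gm", "m7G"],
                    "U": ["Um", "Y", "m3U"],
                }[base]
            )
            mods[pos] = (str(code),)
    return AnnotatedSequence(
        id=f"rand{length}", residues=residues, mods=mods, three_prime=three_prime
    )


@pytest.fixture(scope="session")
def validation_design():
    """A 30-site identifiable ground truth on a synthetic rRNA-like parent."""
    return design_ground_truth(30, seed=7)


@pytest.fixture(scope="session")
def validation_run(validation_design):
    """Noise-free simulate -> cyanoethylate -> full pipeline, shared across
    end-to-end assertions (expensive: built once per session)."""
    parent, fractions = validation_design
    config = SimConfig(
        parents=[parent],
        fractions=fractions,
        intensity_cv=0.0,
        mass_error_ppm_sd=0.0,
        rt_jitter_sd=0.0,
        replicates=1,
        include_msms=True,
        seed=1,
    )
    sim = simulate(config)
    ce_table = simulate_ce(sim)
    plain = AnnotatedSequence(parent.id, parent.residues)
    result = run_pipeline(
        [plain],
        sim.features,
        ce_table,
        PipelineConfig(search=SearchParams(variable_mods=(("ac4C", 1),))),
    )
    return sim, ce_table, result
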