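"""Shared fixtures: lineage templates and the detection benchmark genome
(session-scoped so the 2-Mb simulation and scan run once)."""

import numpy as np
import pytest

from retroscape import detect
from retroscape.io import Genome
from retroscape.simulate import build_genome, default_templates, random_sequence


@pytest.fixture(scope="session")
def templates():
    return default_templates(4)


@pytest.fixture(scope="session")
def benchmark_genome(templates):
    """2-Mb genome with 48 elements (ages 1-2 MYA), solo-LTR and fragment
    decoys — the standard detection benchmark conditions."""
    specs = []
    for t in templates:
        specs.append((t.lineage_name, 1.0, 6))
        specs.append((t.lineage_name, 2.0, 6))
    return build_genome(templates, specs, background_length=2_000_000,
                        seed=42, n_solo_ltr=10, n_fragments=10)


@pytest.fixture(scope="session")
def benchmark_detection(benchmark_genome):
    elements = detect.detect_elements(benchmark_genome.genome)
    metrics = detect.evaluate(elements, benchmark_genome.elements)
    return elements, metrics


@pytest.fixture(scope="session")
def null_genome():
    """1 Mb of element-free random sequence."""
    return Genome({"chr1": random_sequence(1_000_000,
                                           np.random.default_rng(123))})
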