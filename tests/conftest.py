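import numpy as np
import pytest

from rnashotgun.chem import default_registry
from rnashotgun.digestion import parse_annotated_sequence
from rnashotgun.ions import build_target_table


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def demo_trna(registry):
    """A short tRNA-like sequence whose anticodon fragment spans positions 8-16."""
    return parse_annotated_sequence(
        "tRNA-demo",
        "AUGCCGGAUCACCUCG",
        [(14, "cmo5U")],
        registry,
        anticodon_index=14,
    )


@pytest.fixture(scope="session")
def demo_targets(registry, demo_trna):
    """Two-state target list (U vs cmo5U) at z=2 with isotopologues M+0..M+2."""
    return build_target_table(
        [demo_trna], {"tRNA-demo": ["U", "cmo5U"]}, charges=(2,), registry=registry, k_max=2
    )


@pytest.fixture(scope="session")
def demo_locus(demo_targets):
    s = demo_targets[0]
    return f"{s.seq_id}:{s.start}-{s.end}"


def random_sequence(rng: np.random.Generator, registry, length: int) -> list[str]:
    """Random residue-code sequence drawn from the full registry alphabet."""
    codes = registry.codes()
    return [codes[i] for i in rng.integers(0, len(codes), size=length)]
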